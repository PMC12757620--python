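"""Shared fixtures: a small hand-built network with known geometry, and
seeded synthetic networks reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from hyrim.network import Junction, RiverNetwork, Segment, StationRecord
from hyrim.synth import SynthConfig, generate_bod_model_consistent, generate_network


@pytest.fixture()
def y_network() -> RiverNetwork:
    """Y-shaped network: two headwaters A, B joining at C, draining to D.

    Geometry is chosen so every quantity is computable by hand:

      A (-300, 400)   B (300, 400)
             \\          /
        L=600, v=0.5  L=500, v=1.0     (chords 500 m each)
              \\       /
               C (0, 0)
                |  L=400, v=0.8        (chord 300 m)
               D (0, -300)

    Strahler orders: A=1, B=1, C=2, D=2. Mainstem above D follows the A
    branch (equal order 1 at the confluence; A's upstream channel is longer).
    """
    junctions = [
        Junction("A", -300.0, 400.0),
        Junction("B", 300.0, 400.0),
        Junction("C", 0.0, 0.0),
        Junction("D", 0.0, -300.0),
    ]
    segments = [
        Segment("A", "C", 600.0, 0.5),   # tt 1200 s, SI 1.2
        Segment("B", "C", 500.0, 1.0),   # tt 500 s,  SI 1.0
        Segment("C", "D", 400.0, 0.8),   # tt 500 s,  SI 4/3
    ]
    stations = [
        StationRecord("SA", "A", -300.0, 400.0, observations={"BOD5": 4.0}),
        StationRecord("SB", "B", 300.0, 400.0, observations={"BOD5": 6.0}),
        StationRecord("SC", "C", 0.0, 0.0, observations={"BOD5": 5.0}),
        StationRecord("SD", "D", 0.0, -300.0, observations={"BOD5": 5.5}),
    ]
    return RiverNetwork(junctions, segments, stations)


@pytest.fixture(scope="session")
def synth_net20() -> RiverNetwork:
    """Seeded 20-station network with a noisy model-consistent field."""
    net = generate_network(SynthConfig(n_stations=20, seed=0))
    generate_bod_model_consistent(net, noise_sd=0.3, seed=0)
    return net


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
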