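"""Preprocessing and regression baselines for water-quality tables.

Preprocessing: an ensemble outlier vote (Z-score filter at |z| > 3,
Isolation Forest, Local Outlier Factor with 20 neighbors; a row flagged by
at least two detectors is removed) and distributional screening
(Shapiro-Wilk normality, Levene variance homogeneity, Kruskal-Wallis group
comparison, Q-Q reference points).

Baselines: backward-elimination multiple linear regression (drop the single
highest-p term while any non-intercept p exceeds alpha) and the
second-degree polynomial regression (2DPR) family — all linear terms, all
squares, all pairwise interactions. Published zone/season MLR equations and
the four calibrated 2DPR coefficient tables ship as read-only fixtures for
evaluation (``predict_fixed``); refitting them requires the original basin
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OutlierReport",
    "RegressionModel",
    "ensemble_outliers",
    "distribution_report",
    "backward_eliminate",
    "build_2dpr_terms",
    "evaluate_terms",
    "predict_fixed",
    "MLR_FIXTURES",
    "TWO_DPR_FIXTURES",
]


# ---------------------------------------------------------------------- #
# outlier ensemble


@dataclass
class OutlierReport:
    flags: pd.DataFrame  # columns: zscore, isolation_forest, lof, votes, removed
    removed_index: np.ndarray
    surviving: pd.DataFrame
    skipped_columns: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return int(self.flags["removed"].sum())


def ensemble_outliers(
    table: pd.DataFrame,
    z_thresh: float = 3.0,
    lof_neighbors: int = 20,
    seed: int = 0,
    vote_threshold: int = 2,
) -> OutlierReport:
    """Majority-vote multivariate outlier removal.

    A row is flagged by the Z-score detector when any column's |z| exceeds
    ``z_thresh`` (column-wise mean/sd on the raw table; constant columns are
    skipped with a note), by Isolation Forest, and by LOF; rows with at
    least ``vote_threshold`` flags are removed.
    """
    from sklearn.ensemble import IsolationForest
    from sklearn.neighbors import LocalOutlierFactor

    if table.empty:
        raise ValueError("empty table")
    num = table.select_dtypes(include=[np.number])
    if num.shape[1] == 0:
        raise ValueError("table has no numeric columns")
    if len(num) <= lof_neighbors:
        raise ValueError(
            f"need more than lof_neighbors={lof_neighbors} rows, got {len(num)}"
        )

    import warnings

    skipped: list[str] = []
    zflags = np.zeros(len(num), dtype=bool)
    for col in num.columns:
        sd = float(num[col].std(ddof=0))
        if sd == 0.0:
            skipped.append(col)
            warnings.warn(f"constant column {col!r} skipped by Z-score filter",
                          stacklevel=2)
            continue
        z = (num[col] - num[col].mean()) / sd
        zflags |= (z.abs() > z_thresh).to_numpy()

    x = num.to_numpy()
    iso = IsolationForest(random_state=seed).fit_predict(x) == -1
    lof = LocalOutlierFactor(n_neighbors=lof_neighbors).fit_predict(x) == -1

    votes = zflags.astype(int) + iso.astype(int) + lof.astype(int)
    removed = votes >= vote_threshold
    flags = pd.DataFrame(
        {
            "zscore": zflags,
            "isolation_forest": iso,
            "lof": lof,
            "votes": votes,
            "removed": removed,
        },
        index=table.index,
    )
    return OutlierReport(
        flags=flags,
        removed_index=table.index.to_numpy()[removed],
        surviving=table.loc[~removed],
        skipped_columns=skipped,
    )


# ---------------------------------------------------------------------- #
# distribution screening


def distribution_report(
    table: pd.DataFrame,
    groups: dict[str, pd.Series] | None = None,
    n_qq_points: int = 25,
) -> pd.DataFrame:
    """Tidy table of distributional tests per numeric variable.

    Rows: Shapiro-Wilk per variable; Levene and Kruskal-Wallis per variable
    x grouping factor; Q-Q reference points (theoretical vs sample normal
    quantiles) emitted as data rows. Groups with fewer than 3 observations
    cause that test to be skipped with a reason.
    """
    num = table.select_dtypes(include=[np.number])
    rows: list[dict] = []
    for col in num.columns:
        x = num[col].dropna().to_numpy()
        if x.size >= 3:
            w, p = stats.shapiro(x)
            rows.append({"variable": col, "test": "shapiro_wilk", "group_by": None,
                         "statistic": float(w), "p_value": float(p), "note": None})
        else:
            rows.append({"variable": col, "test": "shapiro_wilk", "group_by": None,
                         "statistic": None, "p_value": None,
                         "note": "skipped: fewer than 3 observations"})
        probs = (np.arange(1, n_qq_points + 1) - 0.5) / n_qq_points
        theo = stats.norm.ppf(probs)
        samp = np.quantile(x, probs) if x.size else np.full(n_qq_points, np.nan)
        for t, s in zip(theo, samp):
            rows.append({"variable": col, "test": "qq_point", "group_by": None,
                         "statistic": float(t), "p_value": float(s), "note":
                         "statistic=theoretical quantile, p_value=sample quantile"})

    for factor, labels in (groups or {}).items():
        labels = pd.Series(labels, index=table.index)
        for col in num.columns:
            samples, small = [], False
            for _, sub in num[col].groupby(labels):
                vals = sub.dropna().to_numpy()
                if vals.size < 3:
                    small = True
                samples.append(vals)
            for test, func in (("levene", stats.levene),
                               ("kruskal_wallis", stats.kruskal)):
                if small or len(samples) < 2:
                    rows.append({"variable": col, "test": test, "group_by": factor,
                                 "statistic": None, "p_value": None,
                                 "note": "skipped: group with < 3 observations"})
                    continue
                stat, p = func(*samples)
                rows.append({"variable": col, "test": test, "group_by": factor,
                             "statistic": float(stat), "p_value": float(p),
                             "note": None})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
# regression models


@dataclass
class RegressionModel:
    """Polynomial-in-terms linear model: response ~ intercept + terms.

    Term names: a predictor ("T"), a square ("T^2"), or an interaction
    ("T*DO"). Coefficients include "Intercept".
    """

    response: str
    terms: list[str]
    coefficients: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    r2: float | None = None
    n_obs: int | None = None
    eliminated: list[str] = field(default_factory=list)

    @property
    def intercept(self) -> float:
        return self.coefficients.get("Intercept", 0.0)


def build_2dpr_terms(predictors: list[str]) -> list[str]:
    """Full second-degree term list: linear, squares, pairwise interactions."""
    linear = list(predictors)
    squares = [f"{p}^2" for p in predictors]
    inter = [
        f"{a}*{b}"
        for i, a in enumerate(predictors)
        for b in predictors[i + 1:]
    ]
    return linear + squares + inter


def term_class(term: str) -> str:
    if term == "Intercept":
        return "intercept"
    if "^2" in term:
        return "quadratic"
    if "*" in term:
        return "interaction"
    return "linear"


def _term_column(term: str, table: pd.DataFrame) -> np.ndarray:
    if term.endswith("^2"):
        return table[term[:-2]].to_numpy(float) ** 2
    if "*" in term:
        a, b = term.split("*")
        return table[a].to_numpy(float) * table[b].to_numpy(float)
    return table[term].to_numpy(float)


def design_matrix(terms: list[str], table: pd.DataFrame) -> pd.DataFrame:
    cols = {t: _term_column(t, table) for t in terms}
    x = pd.DataFrame(cols, index=table.index)
    x.insert(0, "Intercept", 1.0)
    return x


def evaluate_terms(coefficients: dict[str, float], table: pd.DataFrame) -> np.ndarray:
    """Evaluate stored coefficients on a predictor table (no fitting)."""
    out = np.full(len(table), coefficients.get("Intercept", 0.0), dtype=float)
    for term, beta in coefficients.items():
        if term == "Intercept":
            continue
        out += beta * _term_column(term, table)
    return out


def predict_fixed(model: RegressionModel, table: pd.DataFrame) -> np.ndarray:
    """Pure evaluation of a fitted or published model on new data."""
    return evaluate_terms(model.coefficients, table)


def backward_eliminate(
    x_table: pd.DataFrame,
    y,
    alpha: float = 0.05,
    terms: list[str] | None = None,
    response: str = "BOD5",
) -> RegressionModel:
    """Backward stepwise OLS: drop the single highest-p term while any
    non-intercept p-value exceeds ``alpha``; the intercept is always kept.

    Perfectly collinear columns are dropped (first by column order) with a
    warning before fitting.
    """
    import warnings

    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    terms = list(terms) if terms is not None else list(x_table.columns)
    if len(y) <= len(terms) + 1:
        raise ValueError(
            f"need more rows ({len(y)}) than terms + 1 ({len(terms) + 1})"
        )

    # drop exact collinearity up front, keeping earlier columns
    x_full = design_matrix(terms, x_table)
    rank = np.linalg.matrix_rank(x_full.to_numpy())
    while rank < x_full.shape[1] and len(terms) > 0:
        for drop_idx in range(len(terms) - 1, -1, -1):
            trial = [t for i, t in enumerate(terms) if i != drop_idx]
            xt = design_matrix(trial, x_table)
            if np.linalg.matrix_rank(xt.to_numpy()) == xt.shape[1]:
                warnings.warn(
                    f"dropping collinear term {terms[drop_idx]!r}", stacklevel=2
                )
                terms = trial
                x_full, rank = xt, np.linalg.matrix_rank(xt.to_numpy())
                break
        else:
            break

    eliminated: list[str] = []
    while True:
        x = design_matrix(terms, x_table)
        fit = sm.OLS(y, x).fit()
        pvals = fit.pvalues.drop("Intercept", errors="ignore")
        if pvals.empty or float(pvals.max()) <= alpha:
            break
        worst = str(pvals.idxmax())
        terms = [t for t in terms if t != worst]
        eliminated.append(worst)

    return RegressionModel(
        response=response,
        terms=terms,
        coefficients={k: float(v) for k, v in fit.params.items()},
        p_values={k: float(v) for k, v in fit.pvalues.items()},
        r2=float(fit.rsquared) if len(terms) else None,
        n_obs=int(fit.nobs),
        eliminated=eliminated,
    )


def fit_2dpr(
    x_table: pd.DataFrame,
    y,
    predictors: list[str] | None = None,
    alpha: float = 1.0,
    response: str = "BOD5",
) -> RegressionModel:
    """Fit the full second-degree polynomial model; with alpha < 1 the fit is
    pruned by the same backward-elimination rule as the linear baseline."""
    predictors = predictors if predictors is not None else list(x_table.columns)
    terms = build_2dpr_terms(predictors)
    return backward_eliminate(x_table, y, alpha=alpha, terms=terms, response=response)


def model_to_frame(model: RegressionModel) -> pd.DataFrame:
    """Term/class/coefficient table (one row per term incl. intercept)."""
    rows = [{"term": "Intercept", "class": "intercept",
             "coefficient": model.intercept}]
    for t in model.terms:
        rows.append({"term": t, "class": term_class(t),
                     "coefficient": model.coefficients.get(t)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
# published coefficient fixtures (read-only; evaluation only)

MLR_FIXTURES: dict[str, RegressionModel] = {
    name: RegressionModel(response="BOD5", terms=[t for t in coefs if t != "Intercept"],
                          coefficients=coefs)
    for name, coefs in {
        "fan_zone": {"Intercept": -6.67, "T": 0.70, "Tu": 0.05, "NO3": -19.0,
                     "DO": 0.82, "TS": -0.02},
        "main_river": {"Intercept": -19.19, "T": 0.53, "NO3": 2.29, "DO": 2.01},
        "estuary": {"Intercept": 90.29, "T": -2.22, "Tu": 0.09, "NO3": 2.09,
                    "DO": -7.62, "TS": -0.02},
        "cortex": {"Intercept": 2.67, "T": 0.10, "Tu": 0.02, "NO3": 0.39,
                   "DO": -0.20},
        "subcortical": {"Intercept": 46.14, "T": -1.46, "Tu": 0.08, "NO3": 7.17,
                        "DO": -3.71, "TS": -0.03},
        "cold_season": {"Intercept": -15.79, "T": -0.69, "Tu": 0.02, "NO3": 4.22,
                        "DO": -1.59, "TS": -0.01},
        "warm_season": {"Intercept": -14.62, "T": -0.78, "Tu": 0.05, "NO3": -0.08,
                        "DO": 2.269, "TS": -0.02},
    }.items()
}

# The "full" and "excluding FC" variants were published with identical
# coefficient blocks and different intercepts; fixtures reproduce the tables
# as printed and are keyed by intercept.
_2DPR_FULL_BLOCK = {
    "T": -0.0587, "Tu": -0.0089, "NO3": -1.9338, "DO": 2.1414, "TS": 0.0513,
    "FC": -0.4506,
    "T^2": 0.0310, "Tu^2": 0.0000, "NO3^2": 0.0014, "DO^2": -0.1185,
    "TS^2": 0.0000, "FC^2": 0.0011,
    "T*Tu": -0.0016, "T*NO3": -0.0426, "T*DO": -0.0554, "T*TS": -0.0017,
    "T*FC": 0.0000, "Tu*NO3": -0.0005, "Tu*DO": 0.0003, "Tu*TS": 0.0000,
    "Tu*FC": 0.0010, "NO3*DO": 0.3033, "NO3*TS": 0.0015, "NO3*FC": 0.0176,
    "DO*TS": -0.0049, "DO*FC": 0.0403, "TS*FC": 0.0001,
}

_2DPR_NO_FC_BLOCK = {
    "T": -0.0587, "Tu": -0.0089, "NO3": -1.9338, "DO": 2.1414, "TS": 0.0513,
    "FC": -0.4506,
    "T^2": 0.0310, "Tu^2": 0.0000, "NO3^2": 0.0014, "DO^2": -0.1185,
    "TS^2": 0.0000, "FC^2": 0.0011,
    "T*Tu": -0.0016, "T*NO3": -0.0426, "T*DO": -0.0554, "T*TS": -0.0017,
    "T*FC": 0.0000, "Tu*NO3": -0.0005, "Tu*DO": 0.0003, "Tu*TS": 0.0000,
    "Tu*FC": 0.0010, "NO3*DO": 0.3033,
}

_2DPR_NO_NO3_BLOCK = {
    "T": 2.2307, "Tu": 0.0718, "DO": 3.4116, "TS": -0.0125, "FC": -0.1264,
    "T^2": -0.0635, "Tu^2": -0.0000, "DO^2": -0.2878, "TS^2": 0.0000,
    "FC^2": 0.0007,
    "T*Tu": -0.0022, "T*DO": -0.0890, "T*TS": 0.0007, "T*FC": 0.0048,
    "Tu*DO": -0.0039, "Tu*TS": -0.0000, "Tu*FC": 0.0004, "DO*TS": 0.0008,
    "DO*FC": -0.0038, "TS*FC": -0.0001,
}

_2DPR_COST_EFFECTIVE_BLOCK = {
    "T": 3.1040, "Tu": 0.0527, "DO": 4.9535, "TS": -0.0163,
    "T^2": -0.0784, "Tu^2": -0.0000, "DO^2": -0.3705, "TS^2": 0.0000,
    "T*Tu": -0.0015, "T*DO": -0.1477, "T*TS": 0.0009,
    "Tu*DO": -0.0026, "Tu*TS": 0.0000, "DO*TS": 0.0016,
}


def _fixture(name: str, intercept: float, block: dict[str, float],
             r2: float) -> RegressionModel:
    coefs = {"Intercept": intercept, **block}
    return RegressionModel(response="BOD5", terms=list(block), coefficients=coefs,
                           r2=r2)


TWO_DPR_FIXTURES: dict[str, RegressionModel] = {
    "full": _fixture("full", 0.0, _2DPR_FULL_BLOCK, r2=0.6252),
    "no_fc": _fixture("no_fc", 35.85, _2DPR_NO_FC_BLOCK, r2=0.8250),
    "no_no3": _fixture("no_no3", -17.5383, _2DPR_NO_NO3_BLOCK, r2=0.7153),
    "cost_effective": _fixture("cost_effective", -28.7892,
                               _2DPR_COST_EFFECTIVE_BLOCK, r2=0.6879),
}
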