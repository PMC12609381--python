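"""Cohort statistics: solid-of-revolution test, allometric scaling, group tests.

The central questions for an egg-shaped fruit cohort are (i) whether the
volume predicted from the fitted profile under the solid-of-revolution
assumption agrees with the water-displacement volume — tested by whether
the 95% CI of the V_obs ~ V_pred regression slope contains 1.0 — and
(ii) how surface area and volume scale allometrically with each other and
with L*W^2 on a log-log scale.  For any isometrically scaling solid the
surface-vs-volume exponent is exactly 2/3; empirical exponents below that
measure departure from geometric similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .epe_fitting import FitResult
from .geometry import GeometryResult

__all__ = [
    "RegressionResult",
    "FruitRecord",
    "records_to_frame",
    "ols_with_ci",
    "revolution_test",
    "RevolutionVerdict",
    "relative_error_summary",
    "allometric_fits",
    "group_compare",
    "GroupComparison",
]


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of y on x with the 95% t-interval of the slope.

    ``scale`` records whether both variables were log10-transformed before
    fitting (so the slope is an allometric exponent) or left linear.
    """

    slope: float
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    r_squared: float
    n: int
    p_value: float
    scale: str = "linear"


@dataclass(frozen=True)
class FruitRecord:
    """One fruit: identity, fitted shape, derived geometry, observed volume."""

    fruit_id: str
    cultivar: str
    fit: FitResult
    geometry: GeometryResult
    v_obs: Optional[float] = None


_FRAME_COLUMNS = [
    "fruit_id", "cultivar", "a", "b", "c1", "c2", "c3",
    "rss", "rmse_adj", "converged", "v_pred", "s", "l", "w", "w_over_l",
    "v_obs",
]


def records_to_frame(records: Sequence[FruitRecord]) -> pd.DataFrame:
    """Flatten FruitRecords into the tabular form all analyses consume."""
    rows = []
    for r in records:
        p = r.fit.params
        rows.append({
            "fruit_id": r.fruit_id, "cultivar": r.cultivar,
            "a": p.a, "b": p.b, "c1": p.c1, "c2": p.c2, "c3": p.c3,
            "rss": r.fit.rss, "rmse_adj": r.fit.rmse_adj,
            "converged": r.fit.converged,
            "v_pred": r.geometry.v_pred, "s": r.geometry.s,
            "l": r.geometry.l, "w": r.geometry.w,
            "w_over_l": r.geometry.w_over_l,
            "v_obs": np.nan if r.v_obs is None else r.v_obs,
        })
    return pd.DataFrame(rows, columns=_FRAME_COLUMNS)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(list(records))


def ols_with_ci(x, y, scale: str = "linear",
                ci_level: float = 0.95) -> RegressionResult:
    """Ordinary least squares of y on x with a t-based slope CI.

    On ``scale="log10"`` both variables are log10-transformed first (all
    values must be positive) and the slope is the allometric exponent;
    base choice does not affect slopes, CIs or r^2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations for a slope CI")
    if scale == "log10":
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log10 scale requires strictly positive values")
        x, y = np.log10(x), np.log10(y)
    elif scale != "linear":
        raise ValueError(f"scale must be 'linear' or 'log10', got {scale!r}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=1.0 - ci_level)
    r = np.corrcoef(x, y)[0, 1]
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_ci_low=float(ci[1, 0]),
        slope_ci_high=float(ci[1, 1]),
        r_squared=float(r * r),
        n=n,
        p_value=float(model.pvalues[1]),
        scale=scale,
    )


@dataclass(frozen=True)
class RevolutionVerdict:
    """Outcome of the solid-of-revolution slope test.

    ``strict``: 1.0 lies inside the 95% CI of the slope.  ``banded``: the
    slope itself lies within ``band`` of 1.0 — the informal "close to 1.0"
    reading used when a tight CI narrowly excludes unity.
    """

    strict: bool
    banded: bool
    band: float
    regression: RegressionResult


def revolution_test(records, band: float = 0.1,
                    ci_level: float = 0.95) -> RevolutionVerdict:
    """Regress V_obs on V_pred (linear scale) and test slope ~ 1.

    The observed volume is the response: it carries the water-displacement
    measurement error, while the model-derived V_pred is the cleaner
    regressor (the reverse direction attenuates the slope below 1 through
    errors in variables).
    """
    df = _as_frame(records).dropna(subset=["v_obs"])
    if len(df) < 3:
        raise ValueError("revolution test needs at least 3 records with v_obs")
    reg = ols_with_ci(df["v_pred"], df["v_obs"], scale="linear",
                      ci_level=ci_level)
    return RevolutionVerdict(
        strict=bool(reg.slope_ci_low <= 1.0 <= reg.slope_ci_high),
        banded=bool(abs(reg.slope - 1.0) <= band),
        band=band,
        regression=reg,
    )


def relative_error_summary(records) -> pd.Series:
    """Percent summary of |V_pred - V_obs| / V_obs across a cohort."""
    df = _as_frame(records).dropna(subset=["v_obs"])
    if df.empty:
        raise ValueError("no records with observed volume")
    if (df["v_obs"] <= 0).any():
        raise ValueError("observed volumes must be positive")
    rel = 100.0 * np.abs(df["v_pred"] - df["v_obs"]) / df["v_obs"]
    return pd.Series({
        "median_pct": round(float(rel.median()), 3),
        "mean_pct": float(rel.mean()),
        "q25_pct": float(rel.quantile(0.25)),
        "q75_pct": float(rel.quantile(0.75)),
        "n": float(len(rel)),
    })


def allometric_fits(records, ci_level: float = 0.95) -> pd.DataFrame:
    """The three log-log scaling fits: S~V_obs, V_pred~LW^2, S~LW^2.

    Each row's slope is the allometric exponent with its CI; for a cohort
    of one fixed shape scaled isometrically the exponents are 2/3, 1 and
    2/3 respectively.
    """
    df = _as_frame(records)
    if df.empty:
        raise ValueError("no records to fit")
    lw2 = df["l"] * df["w"] ** 2
    specs = [
        ("s_vs_v_obs", df["v_obs"], df["s"]),
        ("v_pred_vs_lw2", lw2, df["v_pred"]),
        ("s_vs_lw2", lw2, df["s"]),
    ]
    rows = []
    for name, x, y in specs:
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3:
            continue
        reg = ols_with_ci(x[ok], y[ok], scale="log10", ci_level=ci_level)
        rows.append({"relation": name, "exponent": reg.slope,
                     "ci_low": reg.slope_ci_low, "ci_high": reg.slope_ci_high,
                     "intercept": reg.intercept, "r_squared": reg.r_squared,
                     "n": reg.n, "p_value": reg.p_value})
    if not rows:
        raise ValueError("no relation had >= 3 complete observations")
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA + Tukey HSD + compact letters + per-group CV."""

    response: str
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame     # group1, group2, meandiff, p_adj, reject
    letters: dict           # group -> compact letter display
    cv_percent: dict        # group -> 100 * sd / mean
    group_means: dict


def _compact_letters(groups: List[str], nonsig_pairs: set) -> dict:
    """Compact letter display from the non-significance graph.

    Groups sharing a letter are not significantly different.  Letters are
    the maximal cliques of the graph whose edges join non-different pairs,
    ordered by descending clique mean rank.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    g.add_edges_from(nonsig_pairs)
    cliques = list(nx.find_cliques(g))
    order = {name: i for i, name in enumerate(groups)}
    cliques.sort(key=lambda c: min(order[m] for m in c))
    letters = {name: "" for name in groups}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for member in sorted(clique, key=order.get):
            letters[member] += letter
    return letters


def group_compare(records, response: str = "rmse_adj",
                  alpha: float = 0.05) -> GroupComparison:
    """Compare cultivar groups on one response variable.

    Runs a one-way ANOVA, Tukey's HSD pairwise comparisons at ``alpha``
    (studentized-range adjustment), derives the compact letter display and
    the per-group coefficient of variation.
    """
    df = _as_frame(records).dropna(subset=[response])
    groups = df.groupby("cultivar", sort=False)
    names = list(groups.groups)
    if len(names) < 2:
        raise ValueError("group comparison needs at least 2 groups")
    values = [groups.get_group(n)[response].to_numpy(float) for n in names]
    if min(len(v) for v in values) < 2:
        raise ValueError("each group needs at least 2 records")
    f_stat, p_val = stats.f_oneway(*values)

    hsd = pairwise_tukeyhsd(df[response].to_numpy(float),
                            df["cultivar"].to_numpy(), alpha=alpha)
    tukey = pd.DataFrame(hsd.summary().data[1:],
                         columns=[c.replace("-", "_") for c in
                                  hsd.summary().data[0]])
    tukey = tukey.rename(columns={"p_adj": "p_adj"})

    means = {n: float(np.mean(v)) for n, v in zip(names, values)}
    ordered = sorted(names, key=lambda n: -means[n])
    nonsig = set()
    for row in hsd.summary().data[1:]:
        g1, g2, reject = str(row[0]), str(row[1]), bool(row[-1])
        if not reject:
            nonsig.add((g1, g2))
    letters = _compact_letters(ordered, nonsig)

    cv = {}
    for n, v in zip(names, values):
        mean = np.mean(v)
        cv[n] = float(100.0 * np.std(v, ddof=1) / mean) if mean != 0 else np.nan
    return GroupComparison(
        response=response, anova_f=float(f_stat), anova_p=float(p_val),
        tukey=tukey, letters=letters, cv_percent=cv, group_means=means,
    )
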