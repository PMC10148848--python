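"""Cohort-level statistics: composite scores, Pearson matrices, dependent
overlapping-correlation comparisons (Meng z), mixed ANOVA and post-hocs.

The comparison of interest is whether patch-utilization variables (time in
patch, patch changes, water rate) associate more strongly with reward-
maximization deviations (VD, TD) than with classical discounting indices
(k, AUC). Because all composites come from the same animals, correlations
sharing a variable are dependent; they are compared with the z-procedure of
Meng, Rosenthal & Rubin (1992) for overlapping correlations.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "CorrelationComparison",
    "composite_scores",
    "correlation_matrix",
    "meng_z_test",
    "comparison_grid",
    "mixed_anova",
    "posthoc_tests",
    "normality_screen",
    "COMPOSITE_VARS",
]

logger = logging.getLogger(__name__)

#: Composite variables of the correlation analyses, in display order.
COMPOSITE_VARS = ["k", "auc", "vd", "td", "tip", "pc", "wr"]


@dataclass(frozen=True)
class CorrelationComparison:
    """Two dependent correlations sharing variable j, and their Meng z."""

    r_jx: float
    r_jy: float
    r_xy: float
    n: int
    z: float
    p: float
    stronger: str  # "x" or "y": the larger-magnitude correlation


def composite_scores(metrics: pd.DataFrame, fits: pd.DataFrame) -> pd.DataFrame:
    """Per-rat sums of each measure across all delays, joined with k/b/AUC.

    TD is undefined at COD 0 (zero optimal patch time), so its composite
    sums the delays where TD exists; the other composites sum every delay.
    Rats with any other missing cell are excluded (logged).
    """
    sums = []
    for (rat_id, sex), g in metrics.groupby(["rat_id", "sex"], sort=False):
        row = {"rat_id": rat_id, "sex": sex}
        bad = False
        for col, out in [("pc", "pc"), ("tip_s", "tip"), ("wr_ul_min_kg", "wr"),
                         ("vd_pct", "vd")]:
            vals = g[col]
            if vals.isna().any():
                bad = True
            row[out] = float(vals.sum())
        defined_td = g.loc[g["cod_s"] > 0, "td_pct"]
        if defined_td.isna().any():
            bad = True
        row["td"] = float(defined_td.sum())
        if bad:
            logger.info("composite_scores: excluding %s (missing COD cells)", rat_id)
            continue
        sums.append(row)
    out = pd.DataFrame(sums, columns=["rat_id", "sex", "vd", "td", "tip", "pc", "wr"])
    merged = out.merge(fits[["rat_id", "k", "b", "auc"]], on="rat_id", how="left")
    return merged[["rat_id", "sex", "k", "b", "auc", "vd", "td", "tip", "pc", "wr"]]


def correlation_matrix(scores: pd.DataFrame, sex: str) -> pd.DataFrame:
    """Pearson matrix over the composite variables for one sex.

    Pairwise-complete observations; a zero-variance variable gets a missing
    row/column with a warning. Requires at least 4 rats.
    """
    sub = scores.loc[scores["sex"] == sex, COMPOSITE_VARS]
    if len(sub) < 4:
        raise ValueError(f"need >= 4 rats of sex {sex!r}, have {len(sub)}")
    degenerate = [c for c in COMPOSITE_VARS if sub[c].nunique(dropna=True) <= 1]
    if degenerate:
        logger.warning("correlation_matrix: zero-variance variables set to NaN: %s", degenerate)
    mat = sub.corr(method="pearson")  # pairwise complete by construction
    for c in degenerate:
        mat.loc[c, :] = np.nan
        mat.loc[:, c] = np.nan
    np.fill_diagonal(mat.values, 1.0)
    return mat


def meng_z_test(r_jx: float, r_jy: float, r_xy: float, n: int) -> CorrelationComparison:
    """Meng, Rosenthal & Rubin (1992) z for two overlapping correlations.

    Tests r(j,x) = r(j,y) when x and y are measured on the same n subjects
    and correlate r_xy with each other. Fisher-transforms both
    correlations; their difference is scaled by
    sqrt((n - 3) / (2 * (1 - r_xy) * h)) with
    h = (1 - f * rbar2) / (1 - rbar2), rbar2 the mean squared correlation
    and f = min((1 - r_xy) / (2 * (1 - rbar2)), 1). Two-tailed p from the
    standard normal. Antisymmetric in (r_jx, r_jy).
    """
    if n <= 3:
        raise ValueError("Meng z requires n > 3")
    for name, r in [("r_jx", r_jx), ("r_jy", r_jy), ("r_xy", r_xy)]:
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly inside (-1, 1), got {r}")
    rbar2 = (r_jx**2 + r_jy**2) / 2.0
    f = min((1.0 - r_xy) / (2.0 * (1.0 - rbar2)), 1.0)
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (np.arctanh(r_jx) - np.arctanh(r_jy)) * math.sqrt(
        (n - 3) / (2.0 * (1.0 - r_xy) * h)
    )
    p = 2.0 * sps.norm.sf(abs(z))
    return CorrelationComparison(
        r_jx=float(r_jx), r_jy=float(r_jy), r_xy=float(r_xy), n=int(n),
        z=float(z), p=float(p), stronger="x" if abs(r_jx) >= abs(r_jy) else "y",
    )


def comparison_grid(scores: pd.DataFrame, sex: str) -> pd.DataFrame:
    """Meng z grid: discounting vs reward-maximization correlates of each
    patch-utilization variable, one sex.

    Rows are the four (DD, deviation) pairs {k, auc} x {vd, td}; columns the
    shared variables {tip, pc, wr}. Each cell tests r(shared, DD) against
    r(shared, deviation) on the rats complete for that triple.
    """
    sub = scores[scores["sex"] == sex]
    rows = []
    for dd, dev in itertools.product(["k", "auc"], ["vd", "td"]):
        row = {"comparison": f"{dd} vs {dev}"}
        for shared in ["tip", "pc", "wr"]:
            cols = sub[[shared, dd, dev]].dropna()
            n = len(cols)
            r_jx = cols[shared].corr(cols[dd])
            r_jy = cols[shared].corr(cols[dev])
            r_xy = cols[dd].corr(cols[dev])
            try:
                cmp = meng_z_test(r_jx, r_jy, r_xy, n)
                row[f"z_{shared}"] = cmp.z
                row[f"p_{shared}"] = cmp.p
                row[f"stronger_{shared}"] = dd if cmp.stronger == "x" else dev
            except ValueError as err:  # degenerate r (NaN, |r|=1) or n <= 3
                logger.warning("comparison_grid %s|%s: %s", row["comparison"], shared, err)
                row[f"z_{shared}"] = float("nan")
                row[f"p_{shared}"] = float("nan")
                row[f"stronger_{shared}"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def _complete_cases(data: pd.DataFrame, dv: str) -> pd.DataFrame:
    """Drop rats missing any delay cell for this measure (logged)."""
    ok = data.groupby("rat_id")[dv].transform(lambda s: s.notna().all())
    dropped = data.loc[~ok, "rat_id"].unique()
    if len(dropped):
        logger.info("mixed_anova: dropping %d rats with missing cells", len(dropped))
    return data[ok]


def mixed_anova(data: pd.DataFrame, dv: str) -> pd.DataFrame:
    """Two-way mixed ANOVA: delay within-subject, sex between-subject.

    Returns the classical (uncorrected-df) decomposition with partial eta
    squared per effect; the Greenhouse-Geisser corrected p for the within
    effects is reported alongside, the uncorrected F being primary. Input is
    tidy with columns ``rat_id, sex, cod_s`` and the measure ``dv``.
    """
    data = _complete_cases(data[["rat_id", "sex", "cod_s", dv]].copy(), dv)
    table = pg.mixed_anova(
        data=data, dv=dv, within="cod_s", subject="rat_id", between="sex",
        correction=True, effsize="np2",
    )
    keep = [c for c in ["Source", "SS", "DF1", "DF2", "MS", "F", "p-unc",
                        "p-GG-corr", "np2", "eps"] if c in table.columns]
    return table[keep]


def _cohen_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with pooled SD; NaN (flagged) if the pooled SD is zero."""
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    pooled = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    if pooled == 0:
        return float("nan")
    return float((np.mean(a) - np.mean(b)) / pooled)


def posthoc_tests(data: pd.DataFrame, dv: str, alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Bonferroni-corrected post-hocs for one measure.

    ``between``: per-delay independent-samples t (male minus female) with
    Cohen's d (pooled SD); the Bonferroni family is the set of delay levels,
    so the adjusted alpha is ``alpha / n_delays`` and p_bonf = min(1, p*m).
    ``within``: all pairwise delay comparisons by paired t over rats
    (sexes pooled), corrected for the 10 delay pairs.
    """
    data = _complete_cases(data[["rat_id", "sex", "cod_s", dv]].copy(), dv)
    delays = sorted(data["cod_s"].unique())
    m = len(delays)
    rows = []
    for cod in delays:
        males = data.loc[(data["cod_s"] == cod) & (data["sex"] == "male"), dv].to_numpy()
        females = data.loc[(data["cod_s"] == cod) & (data["sex"] == "female"), dv].to_numpy()
        if len(males) < 2 or len(females) < 2:
            raise ValueError(f"need >= 2 rats per sex at delay {cod}")
        t, p = sps.ttest_ind(males, females)
        rows.append(dict(cod_s=cod, t=float(t), df=len(males) + len(females) - 2,
                         p=float(p), p_bonf=min(1.0, float(p) * m),
                         d=_cohen_d(males, females), alpha_bonf=alpha / m))
    between = pd.DataFrame(rows)

    wide = data.pivot_table(index="rat_id", columns="cod_s", values=dv)
    pairs = list(itertools.combinations(delays, 2))
    rows = []
    for a, b in pairs:
        paired = wide[[a, b]].dropna()
        t, p = sps.ttest_rel(paired[a], paired[b])
        rows.append(dict(cod_a=a, cod_b=b, t=float(t), df=len(paired) - 1, p=float(p),
                         p_bonf=min(1.0, float(p) * len(pairs))))
    within = pd.DataFrame(rows)
    return {"between": between, "within": within}


def normality_screen(values) -> tuple[float, bool]:
    """Bias-corrected sample skewness and the |skewness| < 1 screen.

    Returns ``(skewness, passed)``; constant input yields ``(nan, False)``
    (undefined, flagged) rather than a division error.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        raise ValueError("normality screen needs n >= 3")
    if np.ptp(x) == 0:
        return float("nan"), False
    skew = float(sps.skew(x, bias=False))  # adjusted Fisher-Pearson g1
    return skew, abs(skew) < 1.0
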