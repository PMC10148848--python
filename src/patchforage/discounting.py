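"""Hyperbolic delay discounting fits and normalized AUC for rejection-volume
curves.

The task's rejection volume at each changeover delay is treated as a
delay-discounting indifference point: V(D) = b*A / (1 + k*D), where A is the
alternative patch's full volume (150 uL by default), D the travel delay, k
the per-second discount rate, and b a bias anchored so that b*A equals the
0-delay indifference point. After anchoring b, k is the single free
parameter and is found by deterministic bounded least squares in log k.

The normalized area under the indifference curve (AUC) is the model-free
companion measure: delays scaled by the maximum delay, indifference points
scaled by A, trapezoidal area in [0, 1]. Smaller AUC means steeper
discounting / more overharvesting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = ["IndifferenceCurve", "DiscountFit", "fit_hyperbolic", "normalized_auc", "fit_cohort"]

_LOGK_BOUNDS = (-6.0, 2.0)  # log10 k search interval, 1/s


@dataclass(frozen=True)
class IndifferenceCurve:
    """Rejection volumes (indifference points, uL) across delays (s)."""

    delays: tuple[float, ...]
    indifference_points: tuple[float, ...]
    A: float = 150.0

    def __post_init__(self) -> None:
        d = tuple(float(x) for x in self.delays)
        v = tuple(float(x) for x in self.indifference_points)
        object.__setattr__(self, "delays", d)
        object.__setattr__(self, "indifference_points", v)
        if len(d) != len(v):
            raise ValueError("delays and indifference_points must have equal length")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("delays must be strictly increasing")
        if self.A <= 0:
            raise ValueError("A must be positive")
        if any(x < 0 for x in v):
            raise ValueError("indifference points must be non-negative")

    @property
    def exceeds_amount(self) -> bool:
        """True if any point lies above A (possible in noisy data; flagged)."""
        return any(x > self.A for x in self.indifference_points)


@dataclass(frozen=True)
class DiscountFit:
    k: float
    b: float
    auc: float
    rss: float
    converged: bool
    clipped_for_auc: bool = False


def normalized_auc(curve: IndifferenceCurve) -> float:
    """Myerson-style normalized area under the indifference curve.

    Delays are normalized by the maximum delay, points by A (clipping into
    [0, A] first), and the area is the trapezoidal sum — a discounting
    summary not tied to any particular discount function.
    """
    if len(curve.delays) < 2:
        raise ValueError("normalized AUC needs at least 2 points")
    x = np.asarray(curve.delays) / max(curve.delays)
    y = np.clip(curve.indifference_points, 0.0, curve.A) / curve.A
    return float(np.trapezoid(y, x))


def fit_hyperbolic(curve: IndifferenceCurve) -> DiscountFit:
    """Anchored hyperbolic fit V = b*A/(1 + k*D).

    ``b`` is fixed to IP(0)/A (the 0-delay point therefore carries no
    residual and is excluded from the k objective); ``k >= 0`` minimizes the
    residual sum of squares over the remaining delays via bounded scalar
    search in log10 k, with an explicit k = 0 candidate so a flat curve
    returns exactly k = 0. Points above A are used as-is here (only the AUC
    clips them).
    """
    delays = np.asarray(curve.delays, dtype=float)
    points = np.asarray(curve.indifference_points, dtype=float)
    if 0.0 not in delays:
        raise ValueError("the anchored fit requires a 0-delay indifference point")
    if len(delays) < 3:
        raise ValueError("need the 0-delay point plus at least 2 further delays")
    ip0 = float(points[delays == 0.0][0])
    if ip0 <= 0:
        raise ValueError("0-delay indifference point must be positive (b undefined)")
    b = ip0 / curve.A
    mask = delays > 0
    D, V = delays[mask], points[mask]

    def rss_of(k: float) -> float:
        return float(np.sum((b * curve.A / (1.0 + k * D) - V) ** 2))

    res = minimize_scalar(
        lambda logk: rss_of(10.0**logk),
        bounds=_LOGK_BOUNDS,
        method="bounded",
        options={"xatol": 1e-12},
    )
    k_opt = float(10.0**res.x)
    candidates = [(rss_of(0.0), 0.0), (float(res.fun), k_opt)]
    rss, k = min(candidates, key=lambda t: t[0])
    return DiscountFit(
        k=k,
        b=b,
        auc=normalized_auc(curve),
        rss=rss,
        converged=bool(res.success),
        clipped_for_auc=curve.exceeds_amount,
    )


def fit_cohort(metrics: pd.DataFrame, A: float = 150.0) -> pd.DataFrame:
    """Fit every rat in a tidy metrics table; one row per rat.

    Expects columns ``rat_id, sex, cod_s, rejection_ul``. Rats whose curve
    cannot be fitted (missing 0-delay point or nonpositive anchor) are
    returned with NaN parameters and ``converged=False``.
    """
    rows = []
    for (rat_id, sex), g in metrics.groupby(["rat_id", "sex"], sort=False):
        g = g.sort_values("cod_s")
        ok = g["rejection_ul"].notna()
        try:
            curve = IndifferenceCurve(
                delays=tuple(g.loc[ok, "cod_s"]),
                indifference_points=tuple(g.loc[ok, "rejection_ul"]),
                A=A,
            )
            fit = fit_hyperbolic(curve)
            rows.append(dict(rat_id=rat_id, sex=sex, k=fit.k, b=fit.b, auc=fit.auc,
                             rss=fit.rss, converged=fit.converged))
        except ValueError:
            rows.append(dict(rat_id=rat_id, sex=sex, k=float("nan"), b=float("nan"),
                             auc=float("nan"), rss=float("nan"), converged=False))
    return pd.DataFrame(rows)
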