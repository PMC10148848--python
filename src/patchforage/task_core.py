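"""Reward schedule and Marginal Value Theorem optimality for the sequential
patch depletion task.

The task offers two water "patches". Staying in a patch yields geometrically
shrinking rewards (150, 120, 96, ... uL; a 20% reduction per reward) delivered
on a fixed 4-s interval; leaving imposes a changeover delay (COD, the travel
cost) after which the alternative patch pays the full initial volume again.

The MVT-optimal policy maximizes the average volume rate over a full
patch cycle, travel included: for ``n`` rewards collected the cycle earns
``sum_{i=1..n} A * f**(i-1)`` uL in ``cod + iri * (n - 1)`` seconds. The
optimal stay count ``n*`` is the argmax of that cumulative rate, and the
optimal rejection volume is the reward scheduled next at the moment of
leaving, i.e. ``reward_volume(n* + 1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TaskConfig",
    "OptimalPolicy",
    "reward_volume",
    "cumulative_rate",
    "solve_optimal_policy",
    "optimal_curves",
]

#: Upper bound of the exhaustive stay-count search. Volumes fall below
#: 0.1 uL long before n = 100 under the default schedule.
N_MAX = 100


@dataclass(frozen=True)
class TaskConfig:
    """All task constants.

    Parameters
    ----------
    initial_volume:
        Volume of the first reward in a (replenished) patch, uL.
    depletion_factor:
        Per-reward multiplicative shrinkage, dimensionless in (0, 1).
    inter_reward_interval:
        Fixed interval between successive rewards within a patch, s.
    cod_set:
        Changeover delays tested across sessions, s.
    session_duration_cap:
        Maximum session length, s.
    session_volume_cap:
        Cumulative earned volume that ends the session, uL.
    weekly_cod_sequence:
        COD per session within one test week; the first (0-s) session of
        each week is a warm-up excluded from analysis.
    n_cycles:
        Number of weekly cycles in the full protocol.
    """

    initial_volume: float = 150.0
    depletion_factor: float = 0.8
    inter_reward_interval: float = 4.0
    cod_set: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0, 24.0)
    session_duration_cap: float = 600.0
    session_volume_cap: float = 5000.0
    weekly_cod_sequence: tuple[float, ...] = (0.0, 0.0, 6.0, 12.0, 18.0, 24.0)
    n_cycles: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "cod_set", tuple(float(c) for c in self.cod_set))
        object.__setattr__(
            self, "weekly_cod_sequence", tuple(float(c) for c in self.weekly_cod_sequence)
        )
        if self.initial_volume <= 0:
            raise ValueError("initial_volume must be positive")
        if not 0 < self.depletion_factor <= 1:
            # 1.0 = degenerate no-depletion schedule, allowed for analysis
            raise ValueError("depletion_factor must lie in (0, 1]")
        if self.inter_reward_interval <= 0:
            raise ValueError("inter_reward_interval must be positive")
        if any(c < 0 for c in self.cod_set) or any(c < 0 for c in self.weekly_cod_sequence):
            raise ValueError("changeover delays must be non-negative")
        if self.session_duration_cap <= 0 or self.session_volume_cap <= 0:
            raise ValueError("session caps must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be at least 1")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cod_set"] = list(self.cod_set)
        d["weekly_cod_sequence"] = list(self.weekly_cod_sequence)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown TaskConfig fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "TaskConfig":
        """Load from YAML or JSON (decided by content, not extension)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of TaskConfig fields")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix == ".json":
            p.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass(frozen=True)
class OptimalPolicy:
    """MVT solution for one changeover delay.

    ``optimal_time_in_patch`` follows the convention that the patch clock
    runs from the first reward delivery (which coincides with patch entry)
    to the earliest leave opportunity, i.e. ``iri * (n_star - 1)`` — the
    same structure as the rate denominators (COD, COD+4, COD+8, ...), in
    which the COD precedes the first reward. Users preferring a different
    convention can recompute from ``n_star``.
    """

    cod: float
    n_star: int
    optimal_rejection_volume: float
    optimal_time_in_patch: float
    max_rate: float


def reward_volume(n: int, config: TaskConfig = TaskConfig()) -> float:
    """Volume (uL) of the ``n``-th successive reward in a patch.

    ``n`` is 1-based: under defaults n=1 -> 150, n=2 -> 120, n=3 -> 96.
    """
    if isinstance(n, bool) or not (
        isinstance(n, (int, np.integer)) or (isinstance(n, float) and float(n).is_integer())
    ):
        raise ValueError(f"reward index must be a positive integer, got {n!r}")
    n = int(n)
    if n < 1:
        raise ValueError(f"reward index must be >= 1, got {n}")
    return config.initial_volume * config.depletion_factor ** (n - 1)


def cumulative_rate(n: int, cod: float, config: TaskConfig = TaskConfig()) -> float:
    """Average volume rate (uL/s) of a patch cycle with ``n`` rewards.

    The cycle time includes the COD travel before the first reward plus
    ``iri`` between rewards: at COD 6 the rates for n = 1, 2, 3 are
    150/6 = 25, 270/10 = 27 and 366/14 ~ 26.14 uL/s. At COD 0 the first
    reward arrives with zero elapsed time and the rate is +inf (the MVT
    limit of vanishing travel cost).
    """
    if isinstance(n, bool) or not (
        isinstance(n, (int, np.integer)) or (isinstance(n, float) and float(n).is_integer())
    ):
        raise ValueError(f"reward count must be a positive integer, got {n!r}")
    n = int(n)
    if n < 1:
        raise ValueError(f"reward count must be >= 1, got {n}")
    if cod < 0:
        raise ValueError(f"cod must be non-negative, got {cod}")
    A, f = config.initial_volume, config.depletion_factor
    total = A * n if f == 1.0 else A * (1.0 - f**n) / (1.0 - f)
    elapsed = cod + config.inter_reward_interval * (n - 1)
    if elapsed == 0.0:
        return float("inf")
    return total / elapsed


def solve_optimal_policy(
    cod: float, config: TaskConfig = TaskConfig(), n_max: int = N_MAX
) -> OptimalPolicy:
    """MVT-optimal stay count and rejection volume at one COD.

    Exhaustive argmax of :func:`cumulative_rate` over ``n = 1..n_max``;
    ties break toward the smaller ``n`` (leave earlier). For the geometric
    schedule the rate curve is unimodal, so this equals the first local
    maximum.
    """
    if cod < 0:
        raise ValueError(f"cod must be non-negative, got {cod}")
    rates = np.array([cumulative_rate(n, cod, config) for n in range(1, n_max + 1)])
    n_star = int(np.argmax(rates)) + 1  # argmax returns the first maximum
    return OptimalPolicy(
        cod=float(cod),
        n_star=n_star,
        optimal_rejection_volume=reward_volume(n_star + 1, config),
        optimal_time_in_patch=config.inter_reward_interval * (n_star - 1),
        max_rate=float(rates[n_star - 1]),
    )


def optimal_curves(config: TaskConfig = TaskConfig()) -> pd.DataFrame:
    """One :class:`OptimalPolicy` row per COD in ``config.cod_set``."""
    rows = [asdict(solve_optimal_policy(c, config)) for c in config.cod_set]
    return pd.DataFrame(rows, columns=["cod", "n_star", "optimal_rejection_volume",
                                       "optimal_time_in_patch", "max_rate"])
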