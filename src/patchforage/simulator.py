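"""Discrete-event simulation of patch-depletion sessions for parameterized agents.

Timing abstraction: the agent claims every reward at the earliest permitted
instant. The session's first patch entry is at t = 0 with immediate delivery
of the initial volume and no COD (the animal has not yet traveled). Within a
patch, rewards follow every ``inter_reward_interval`` seconds. A stay/leave
decision is evaluated once per reward opportunity, immediately after each
delivered reward; a leave is instantaneous, so the leave event shares the
last reward's timestamp and the next patch's first reward arrives COD
seconds later. Reaction and drinking times are not modeled — these are
exactly the idealized times the optimality arithmetic uses.

Because entry/first-reward and last-reward/leave coincide, event times are
non-decreasing (not strictly increasing); the ``event_index`` carries the
logical order within ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

from .task_core import TaskConfig, reward_volume, solve_optimal_policy

__all__ = [
    "AgentPolicy",
    "RatRecord",
    "Event",
    "SessionLog",
    "decide_stay_or_leave",
    "simulate_session",
    "simulate_protocol",
    "hyperbolic_rejection_volume",
]

POLICY_KINDS = ("mvt_optimal", "volume_threshold", "hyperbolic_discounter")
EVENT_TYPES = ("patch_entry", "reward", "leave", "session_end")
SIDES = ("left", "back")


@dataclass(frozen=True)
class AgentPolicy:
    """Stay/leave decision rule of a simulated rat.

    kind
        ``mvt_optimal`` leaves exactly at the MVT stay count n*(cod);
        ``volume_threshold`` leaves when the next scheduled volume falls
        below a fixed threshold (uL); ``hyperbolic_discounter`` leaves when
        the next volume falls below the hyperbolically discounted value of
        restarting, ``b * A / (1 + k * cod)``.
    choice_noise
        Logistic decision noise in uL: the deterministic comparison's value
        difference is passed through a logistic with this scale. 0 means
        deterministic. Applies to the value-comparing kinds; the count-based
        ``mvt_optimal`` rule is perturbed only through ``lapse``.
    lapse
        Probability per decision of flipping the outcome at random.
    """

    kind: Literal["mvt_optimal", "volume_threshold", "hyperbolic_discounter"]
    k: Optional[float] = None
    b: Optional[float] = None
    threshold: Optional[float] = None
    choice_noise: float = 0.0
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in POLICY_KINDS:
            raise ValueError(f"unknown policy kind {self.kind!r}; expected one of {POLICY_KINDS}")
        if self.choice_noise < 0:
            raise ValueError("choice_noise must be >= 0")
        if not 0 <= self.lapse <= 1:
            raise ValueError("lapse must lie in [0, 1]")
        if self.kind == "hyperbolic_discounter":
            if self.k is None or self.b is None:
                raise ValueError("hyperbolic_discounter requires k and b")
            if self.k < 0:
                raise ValueError("k must be >= 0")
            if not 0 < self.b <= 1:
                raise ValueError("b must lie in (0, 1]")
            if self.threshold is not None:
                raise ValueError("threshold is not a hyperbolic_discounter field")
        elif self.kind == "volume_threshold":
            if self.threshold is None:
                raise ValueError("volume_threshold requires threshold")
            if self.threshold < 0:
                raise ValueError("threshold must be >= 0")
            if self.k is not None or self.b is not None:
                raise ValueError("k/b are not volume_threshold fields")
        else:  # mvt_optimal
            if any(v is not None for v in (self.k, self.b, self.threshold)):
                raise ValueError("mvt_optimal takes no k/b/threshold")


@dataclass(frozen=True)
class RatRecord:
    """One simulated animal: identifier, sex, body weight (kg) and policy."""

    rat_id: str
    sex: Literal["male", "female"]
    body_weight: float
    policy: AgentPolicy

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body_weight must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")


@dataclass(frozen=True)
class Event:
    index: int
    time: float
    event_type: str
    patch_side: Optional[str] = None  # None for session_end
    volume: Optional[float] = None  # set for reward events only


@dataclass
class SessionLog:
    """Ordered event record of one session."""

    rat_id: str
    sex: str
    session_index: int  # 1..24 within the protocol
    cod: float
    events: list[Event] = field(default_factory=list)
    termination_reason: Optional[str] = None  # "time_cap" | "volume_cap"

    @property
    def total_volume(self) -> float:
        return sum(e.volume for e in self.events if e.event_type == "reward")

    def validate(self, config: TaskConfig | None = None) -> None:
        """Check structural invariants; raise ValueError on violation."""
        if self.termination_reason not in ("time_cap", "volume_cap"):
            raise ValueError(f"bad termination_reason {self.termination_reason!r}")
        last_t = -math.inf
        for i, e in enumerate(self.events):
            if e.index != i:
                raise ValueError(f"event {i}: index {e.index} out of order")
            if e.time < last_t:
                raise ValueError(f"event {i}: time {e.time} decreases")
            last_t = e.time
            if e.event_type not in EVENT_TYPES:
                raise ValueError(f"event {i}: unknown type {e.event_type!r}")
            if e.event_type == "reward" and (e.volume is None or e.volume <= 0):
                raise ValueError(f"event {i}: reward without positive volume")
        if not self.events or self.events[-1].event_type != "session_end":
            raise ValueError("log must end with a session_end event")
        if config is not None:
            self._validate_schedule(config)

    def _validate_schedule(self, config: TaskConfig) -> None:
        tol = 1e-9
        in_patch_n = 0
        prev_reward_t = None
        leave_t = None
        first_patch = True
        cum = 0.0
        for e in self.events:
            if e.event_type == "patch_entry":
                if leave_t is not None and e.time - leave_t < self.cod - tol:
                    raise ValueError("patch re-entered before the COD elapsed")
                in_patch_n = 0
                prev_reward_t = None
                if not first_patch:
                    pass  # replenishment is implied by the volume check below
                first_patch = False
            elif e.event_type == "reward":
                in_patch_n += 1
                expected = reward_volume(in_patch_n, config)
                if abs(e.volume - expected) > tol:
                    raise ValueError(
                        f"reward {in_patch_n} in patch has volume {e.volume}, "
                        f"schedule says {expected}"
                    )
                if prev_reward_t is not None and abs(
                    (e.time - prev_reward_t) - config.inter_reward_interval
                ) > tol:
                    raise ValueError("within-patch rewards not separated by the fixed interval")
                prev_reward_t = e.time
                cum += e.volume
            elif e.event_type == "leave":
                leave_t = e.time
        if cum > config.session_volume_cap + config.initial_volume + tol:
            raise ValueError("cumulative volume overshoots the session cap by more than one reward")
        if self.events[-1].time > config.session_duration_cap + tol:
            raise ValueError("events past the session duration cap")


def hyperbolic_rejection_volume(
    k: float, b: float, cod: float, config: TaskConfig = TaskConfig()
) -> float:
    """Closed-form rejection volume of a deterministic hyperbolic agent.

    The agent collects the first reward automatically, then stays while the
    next scheduled volume is at least ``b*A/(1+k*cod)``; the rejection
    volume is therefore the largest schedule volume strictly below that
    threshold (never larger than the second reward). Serves as an
    independent oracle for the simulator.
    """
    A, f = config.initial_volume, config.depletion_factor
    threshold = b * A / (1.0 + k * cod)
    n = 2
    while A * f ** (n - 1) >= threshold:
        n += 1
    return A * f ** (n - 1)


def _deterministic_leave(
    policy: AgentPolicy,
    next_volume: float,
    cod: float,
    config: TaskConfig,
    n_collected: Optional[int],
) -> tuple[bool, Optional[float]]:
    """(leave?, value difference in uL for noisy kinds)."""
    if policy.kind == "mvt_optimal":
        if n_collected is None:
            raise ValueError("mvt_optimal decisions require n_collected")
        n_star = solve_optimal_policy(cod, config).n_star
        return n_collected >= n_star, None
    if policy.kind == "volume_threshold":
        diff = policy.threshold - next_volume
    else:  # hyperbolic_discounter
        diff = policy.b * config.initial_volume / (1.0 + policy.k * cod) - next_volume
    return diff > 0, diff


def decide_stay_or_leave(
    policy: AgentPolicy,
    next_volume: float,
    cod: float,
    config: TaskConfig = TaskConfig(),
    rng: Optional[np.random.Generator] = None,
    n_collected: Optional[int] = None,
) -> str:
    """One stay/leave decision; returns ``"stay"`` or ``"leave"``.

    Deterministic when ``choice_noise == lapse == 0`` (then ``rng`` may be
    omitted). With noise, the value difference (threshold minus next volume,
    uL) passes through a logistic of scale ``choice_noise``; a lapse flips
    the outcome with the stated probability.
    """
    if next_volume <= 0:
        raise ValueError("next_volume must be positive")
    leave, diff = _deterministic_leave(policy, next_volume, cod, config, n_collected)
    stochastic = policy.lapse > 0 or (policy.choice_noise > 0 and diff is not None)
    if stochastic and rng is None:
        raise ValueError("a seeded rng is required for noisy policies")
    if policy.choice_noise > 0 and diff is not None:
        p_leave = 1.0 / (1.0 + math.exp(-diff / policy.choice_noise))
        leave = rng.random() < p_leave
    if policy.lapse > 0 and rng.random() < policy.lapse:
        leave = not leave
    return "leave" if leave else "stay"


def simulate_session(
    rat: RatRecord,
    cod: float,
    config: TaskConfig = TaskConfig(),
    seed: int | Sequence[int] | np.random.Generator | None = 0,
    session_index: int = 1,
) -> SessionLog:
    """Simulate one session; identical seeds give identical logs.

    The session ends when the next scheduled event would start at or past
    the duration cap (``termination_reason="time_cap"``, session_end at the
    cap) or when cumulative earnings reach the volume cap
    (``"volume_cap"``, session_end at the final reward).
    """
    if cod < 0:
        raise ValueError("cod must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    log = SessionLog(rat_id=rat.rat_id, sex=rat.sex, session_index=session_index, cod=float(cod))
    events = log.events
    idx = 0

    def emit(time: float, etype: str, side: Optional[str] = None, volume: Optional[float] = None):
        nonlocal idx
        events.append(Event(index=idx, time=time, event_type=etype,
                            patch_side=side, volume=volume))
        idx += 1

    t = 0.0
    side_i = 0  # alternates deterministically between the two receptacles
    cum = 0.0
    t_cap = config.session_duration_cap
    v_cap = config.session_volume_cap

    while True:
        # enter patch (the first patch incurs no COD; t already includes it otherwise)
        if t >= t_cap:
            emit(t_cap, "session_end")
            log.termination_reason = "time_cap"
            break
        side = SIDES[side_i % 2]
        emit(t, "patch_entry", side)
        n = 0
        left = False
        while True:
            rt = t + config.inter_reward_interval * n
            if rt >= t_cap:
                emit(t_cap, "session_end")
                log.termination_reason = "time_cap"
                break
            n += 1
            vol = reward_volume(n, config)
            emit(rt, "reward", side, vol)
            cum += vol
            if cum >= v_cap:
                emit(rt, "session_end")
                log.termination_reason = "volume_cap"
                break
            choice = decide_stay_or_leave(
                rat.policy, reward_volume(n + 1, config), cod, config,
                rng=rng, n_collected=n,
            )
            if choice == "leave":
                emit(rt, "leave", side)
                t = rt + cod
                side_i += 1
                left = True
                break
        if log.termination_reason is not None:
            break
        if not left:  # pragma: no cover - unreachable: inner loop exits only via cap/leave
            raise AssertionError
    return log


def simulate_protocol(
    rat: RatRecord,
    config: TaskConfig = TaskConfig(),
    seed: int = 0,
) -> list[SessionLog]:
    """Full protocol: the weekly COD sequence repeated ``n_cycles`` times.

    Per-session RNG streams derive from ``(seed, session_index)`` so any
    session reproduces independently of execution order; logs depend on the
    seed and policy only, not on the rat's identifier.
    """
    cods = list(config.weekly_cod_sequence) * config.n_cycles
    logs = []
    for i, cod in enumerate(cods, start=1):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(i,)))
        logs.append(simulate_session(rat, cod, config, seed=rng, session_index=i))
    return logs
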