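"""Experimental design: cost/reward grids, calibration and trial sequences.

The task crosses 5 cost levels x 5 rewards (2,4,6,8,10 credits) x 2
recipients (self / environment), 150 trials per task in 3 blocks of 50,
with each design cell occurring exactly 3 times.  Effort costs are 40-80%
of a participant's maximum voluntary contraction (MVC); time costs are five
individually calibrated waiting durations between 3 and 27 s.  Trial order
is pseudorandomized so that no recipient repeats more than 4 times in a row
and the mean cost level over every window of 5 consecutive trials stays in
[2, 3] (fatigue control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "TaskKind",
    "ParticipantProfile",
    "TrialDesign",
    "DesignError",
    "CalibrationError",
    "calibrate_time_levels",
    "simulate_indifference_search",
    "generate_design",
    "validate_design",
    "CalibrationBoundaryWarning",
]

COST_LEVELS = (1, 2, 3, 4, 5)
REWARDS = (2, 4, 6, 8, 10)
EFFORT_FRACTIONS = (0.40, 0.50, 0.60, 0.70, 0.80)
TIME_RANGE = (3.0, 27.0)
TRIALS_PER_TASK = 150
BLOCKS = 3
TRIALS_PER_BLOCK = 50
MAX_RECIPIENT_RUN = 4
WINDOW = 5
WINDOW_MEAN_RANGE = (2.0, 3.0)


class TaskKind(str, Enum):
    effort = "effort"
    time = "time"


class DesignError(RuntimeError):
    """Raised when a constrained trial sequence cannot be generated."""


class CalibrationError(ValueError):
    """Raised for invalid time-calibration inputs."""


class CalibrationBoundaryWarning(UserWarning):
    """An agent preferred one option over the whole calibration range."""


@dataclass(frozen=True)
class ParticipantProfile:
    """Individual calibration: MVC-scaled effort levels and waiting times."""

    participant_id: str
    mvc: float
    time_levels: tuple[float, float, float, float, float]
    effort_levels: tuple[float, ...] = EFFORT_FRACTIONS

    def __post_init__(self) -> None:
        if not np.isfinite(self.mvc) or self.mvc <= 0:
            raise ValueError("mvc must be positive and finite")
        if tuple(self.effort_levels) != EFFORT_FRACTIONS:
            raise ValueError(f"effort_levels must be {EFFORT_FRACTIONS} of MVC")
        t = np.asarray(self.time_levels, dtype=float)
        if t.shape != (5,):
            raise ValueError("time_levels must hold 5 durations")
        lo, hi = TIME_RANGE
        if np.any(t < lo) or np.any(t > hi):
            raise ValueError(f"time_levels must lie in [{lo}, {hi}] s")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time_levels must be strictly increasing")
        if not np.allclose(np.diff(t), np.diff(t)[0]):
            raise ValueError("time_levels must be equidistant")

    def cost_value(self, task: TaskKind, cost_level: int) -> float:
        """Physical cost for a level: fraction of MVC or seconds."""
        if TaskKind(task) is TaskKind.effort:
            return self.effort_levels[cost_level - 1]
        return float(self.time_levels[cost_level - 1])


def calibrate_time_levels(
    low_indifference: float, high_indifference: float
) -> tuple[float, float, float, float, float]:
    """Interpolate the 5 waiting-time levels from two indifference points.

    The three intermediate levels are equidistant between the calibrated
    endpoints: spacing ``d = (high - low) / 4``.
    """
    lo, hi = float(low_indifference), float(high_indifference)
    bound_lo, bound_hi = TIME_RANGE
    if not (bound_lo <= lo < hi <= bound_hi):
        raise CalibrationError(
            f"need {bound_lo} <= low < high <= {bound_hi}, got ({lo}, {hi})"
        )
    d = (hi - lo) / 4.0
    return (lo, lo + d, lo + 2 * d, lo + 3 * d, hi)


def simulate_indifference_search(
    agent_time_cost_rate: float,
    agent_effort_cost: float,
    rng: np.random.Generator | None = None,
    tol: float = 0.5,
) -> float:
    """Find the waiting time at which a deterministic agent is indifferent.

    Stand-in for the adaptive lab calibration: the agent's disutility of
    waiting ``t`` seconds is ``agent_time_cost_rate * t`` and the effort
    option costs ``agent_effort_cost`` utility; bisection over [3, 27] s
    locates the root of their difference to within ``tol`` seconds.  If one
    option dominates over the whole range the nearer boundary is returned
    with a :class:`CalibrationBoundaryWarning`.

    ``rng`` is accepted for interface symmetry with stochastic searchers;
    the bisection itself is deterministic.
    """
    rate, cost = float(agent_time_cost_rate), float(agent_effort_cost)
    for name, v in (("agent_time_cost_rate", rate), ("agent_effort_cost", cost)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be finite and positive")

    def gap(t: float) -> float:
        # >0 when waiting t is worse than doing the effort
        return rate * t - cost

    lo, hi = TIME_RANGE
    if gap(lo) >= 0:
        warnings.warn(
            "agent prefers effort over waiting across the whole range",
            CalibrationBoundaryWarning,
        )
        return lo
    if gap(hi) <= 0:
        warnings.warn(
            "agent prefers waiting over effort across the whole range",
            CalibrationBoundaryWarning,
        )
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if gap(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class TrialDesign:
    """A pseudorandomized 150-trial sequence for one task."""

    task: TaskKind
    trials: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.trials)

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialDesign":
        df = pd.read_csv(path)
        task = TaskKind(df["task"].iloc[0])
        return cls(task=task, trials=df)


def _cost_sequence(rng: np.random.Generator) -> np.ndarray | None:
    """Cost levels for 150 trials in 30 mini-blocks of five.

    Cell balance makes the overall mean cost level exactly 3, so every
    aligned mini-block must sum to exactly 15 for the rolling window
    constraint to hold; each mini-block is therefore a permutation of
    (1..5), chosen so that the four windows crossing the previous block
    boundary also have sums in [10, 15].
    """
    from itertools import permutations

    lo_sum = int(WINDOW_MEAN_RANGE[0] * WINDOW)  # 10
    hi_sum = int(WINDOW_MEAN_RANGE[1] * WINDOW)  # 15
    n_blocks = TRIALS_PER_TASK // WINDOW
    perms = np.array(list(permutations(COST_LEVELS)))  # (120, 5)
    prefix = perms.cumsum(axis=1)  # prefix sums of each candidate block
    seq: list[np.ndarray] = []
    for b in range(n_blocks):
        if b == 0:
            valid = np.arange(len(perms))
        else:
            prev = seq[-1]
            # window at offset j of the previous block: tail(prev) + head(cand);
            # both blocks sum to 15, so the condition is a prefix-sum bound
            prev_prefix = np.cumsum(prev)
            valid = np.arange(len(perms))
            for j in range(1, WINDOW):
                wsum = (15 - prev_prefix[j - 1]) + prefix[valid, j - 1]
                valid = valid[(wsum >= lo_sum) & (wsum <= hi_sum)]
            if len(valid) == 0:  # cannot happen: prev itself is valid
                return None
        seq.append(perms[valid[rng.integers(len(valid))]])
    return np.concatenate(seq)


def _recipient_sequence(
    cost: np.ndarray, rng: np.random.Generator
) -> np.ndarray | None:
    """Assign self/environment so each (cost, recipient) pair occurs 15x.

    Sequential randomized choice under the remaining-quota and max-run
    constraints; None on a dead end (caller restarts).
    """
    quota = {(c, r): 15 for c in COST_LEVELS for r in ("self", "environment")}
    out: list[str] = []
    run_rec, run_len = None, 0
    for c in cost:
        options = [r for r in ("self", "environment") if quota[(int(c), r)] > 0]
        if run_len >= MAX_RECIPIENT_RUN and run_rec in options:
            options.remove(run_rec)
        if not options:
            return None
        r = options[0] if len(options) == 1 else options[rng.integers(2)]
        quota[(int(c), r)] -= 1
        out.append(r)
        run_rec, run_len = r, (run_len + 1 if r == run_rec else 1)
    return np.asarray(out, dtype=object)


def _try_sequence(task: TaskKind, rng: np.random.Generator) -> list[tuple] | None:
    """One randomized construction attempt; None on dead end."""
    cost = _cost_sequence(rng)
    if cost is None:
        return None
    recipient = _recipient_sequence(cost, rng)
    if recipient is None:
        return None
    # rewards: balanced 3x per (cost, recipient) cell, unconstrained in order
    reward = np.empty(TRIALS_PER_TASK, dtype=int)
    for c in COST_LEVELS:
        for r in ("self", "environment"):
            pos = np.flatnonzero((cost == c) & (recipient == r))
            reward[pos] = rng.permutation(np.repeat(REWARDS, 3))
    return [
        (task.value, recipient[i], int(cost[i]), int(reward[i]))
        for i in range(TRIALS_PER_TASK)
    ]


def generate_design(
    task: TaskKind | str,
    seed: int,
    max_attempts: int = 1000,
) -> TrialDesign:
    """Generate a pseudorandomized trial sequence satisfying all constraints.

    Uses randomized greedy construction with restarts; raises
    :class:`DesignError` after ``max_attempts`` failed attempts rather than
    relaxing any constraint.  The same seed always yields the same design.
    """
    task = TaskKind(task)
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        seq = _try_sequence(task, rng)
        if seq is not None:
            df = pd.DataFrame(
                seq, columns=["task", "recipient", "cost_level", "reward"]
            )
            df.insert(1, "block", np.repeat(np.arange(1, BLOCKS + 1), TRIALS_PER_BLOCK))
            df.insert(2, "trial", np.arange(1, TRIALS_PER_TASK + 1))
            df["baseline_reward"] = 1
            design = TrialDesign(task=task, trials=df)
            validate_design(design)  # defence in depth; never relaxed
            return design
    raise DesignError(
        f"could not satisfy design constraints in {max_attempts} attempts"
    )


def validate_design(design: TrialDesign) -> None:
    """Independent re-check of the three pseudorandomization constraints.

    Counts directly from the trial table: balanced cells (each of the 50
    cost x reward x recipient cells exactly 3 times), recipient runs <= 4,
    and every 5-trial window's mean cost level within [2, 3].  Raises
    ``ValueError`` on any violation.
    """
    df = design.trials
    if len(df) != TRIALS_PER_TASK:
        raise ValueError(f"expected {TRIALS_PER_TASK} trials, got {len(df)}")
    counts = df.groupby(["recipient", "cost_level", "reward"]).size()
    if len(counts) != 50 or not (counts == 3).all():
        raise ValueError("design cells are not balanced 3x over 50 cells")
    rec = df["recipient"].to_numpy()
    run = 1
    for a, b in zip(rec[:-1], rec[1:]):
        run = run + 1 if a == b else 1
        if run > MAX_RECIPIENT_RUN:
            raise ValueError("recipient repeated more than 4 times in a row")
    cost = df["cost_level"].to_numpy(dtype=float)
    means = np.convolve(cost, np.ones(WINDOW) / WINDOW, mode="valid")
    lo, hi = WINDOW_MEAN_RANGE
    if np.any(means < lo - 1e-12) or np.any(means > hi + 1e-12):
        raise ValueError("a 5-trial window has mean cost level outside [2, 3]")
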