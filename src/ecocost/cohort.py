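"""Synthetic cohorts with the statistical structure the analysis assumes.

Subjects are drawn from a log-normal population over (k_self, k_env,
beta_self, beta_env); choices are generated trial-by-trial from the
discounting + softmax model, then corrupted by rare decision omissions
(no response within the 3 s window) and, in the effort task, by
effort-execution failures on chosen-costly trials.  A 12-item Likert
policy-support questionnaire is coupled (sign and strength configurable)
to each subject's discounting asymmetry ``k_self - k_env``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    ParticipantProfile,
    TaskKind,
    TrialDesign,
    calibrate_time_levels,
    generate_design,
    simulate_indifference_search,
)
from .models import ModelSpec, SubjectParameters, choice_probability, subjective_value

__all__ = [
    "GroupParameters",
    "CohortConfig",
    "SubjectParameters",
    "sample_subjects",
    "simulate_choices",
    "simulate_cohort",
    "simulate_questionnaires",
    "DEFAULT_GROUPS",
    "DEFAULT_SPECS",
]

PARAM_NAMES = ("k_self", "k_env", "beta_self", "beta_env")


@dataclass(frozen=True)
class GroupParameters:
    """Log-scale population location/scale for the four subject parameters."""

    mu: dict[str, float]
    sigma: dict[str, float]

    def __post_init__(self) -> None:
        for p in PARAM_NAMES:
            if p not in self.mu or p not in self.sigma:
                raise ValueError(f"missing hyperparameters for {p}")
            if not np.isfinite(self.mu[p]):
                raise ValueError(f"mu[{p}] must be finite")
            if not np.isfinite(self.sigma[p]) or self.sigma[p] < 0:
                raise ValueError(f"sigma[{p}] must be finite and >= 0")


# Population defaults chosen to emulate the study's behavioural signatures
# on the credit scale of the task (costs coded as levels 1-5, baseline worth
# 1 credit): costly-choice rates around 60-70% (effort) and ~80% (time),
# stronger discounting for environmental than self rewards, and a
# heavy-tailed time-task k distribution that yields a subgroup of
# near-always-waiting (ceiling) participants.
DEFAULT_GROUPS: dict[TaskKind, GroupParameters] = {
    TaskKind.effort: GroupParameters(
        mu={
            "k_self": float(np.log(0.25)),
            "k_env": float(np.log(0.35)),
            "beta_self": float(np.log(2.0)),
            "beta_env": float(np.log(2.0)),
        },
        sigma={"k_self": 0.70, "k_env": 0.70, "beta_self": 0.50, "beta_env": 0.50},
    ),
    TaskKind.time: GroupParameters(
        mu={
            "k_self": float(np.log(0.25)),
            "k_env": float(np.log(0.40)),
            "beta_self": float(np.log(3.0)),
            "beta_env": float(np.log(3.0)),
        },
        sigma={"k_self": 1.50, "k_env": 1.50, "beta_self": 0.60, "beta_env": 0.60},
    ),
}

DEFAULT_SPECS: dict[TaskKind, ModelSpec] = {
    TaskKind.effort: ModelSpec.from_name("parabolic-2k2b"),
    TaskKind.time: ModelSpec.from_name("hyperbolic-2k2b"),
}


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to simulate one cohort reproducibly."""

    n_subjects: int = 74
    trials_per_task: int = 150
    omission_rate: float = 0.003
    failure_rate: float = 0.055
    specs: dict[TaskKind, ModelSpec] = field(
        default_factory=lambda: dict(DEFAULT_SPECS)
    )
    groups: dict[TaskKind, GroupParameters] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    questionnaire_coupling: float = 0.8
    # correlation of a subject's log-parameters across the two tasks
    # (cost-type-general individual differences)
    cross_task_correlation: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0 <= self.omission_rate < 1):
            raise ValueError("omission_rate must be in [0, 1)")
        if not (0 <= self.failure_rate < 1):
            raise ValueError("failure_rate must be in [0, 1)")
        if not (0 <= self.cross_task_correlation <= 1):
            raise ValueError("cross_task_correlation must be in [0, 1]")
        if self.trials_per_task != 150:
            raise ValueError("the task design is fixed at 150 trials per task")


def sample_subjects(
    group: GroupParameters, n: int, rng: np.random.Generator
) -> list[SubjectParameters]:
    """Draw ``n`` subjects from the log-normal population implied by (mu, sigma)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    draws = {
        p: np.exp(rng.normal(group.mu[p], group.sigma[p], size=n))
        for p in PARAM_NAMES
    }
    return [
        SubjectParameters(
            k_self=draws["k_self"][i],
            k_env=draws["k_env"][i],
            beta_self=draws["beta_self"][i],
            beta_env=draws["beta_env"][i],
        )
        for i in range(n)
    ]


def _default_profile(
    participant_id: str, rng: np.random.Generator
) -> ParticipantProfile:
    """Individual calibration: MVC plus indifference-search time levels."""
    mvc = float(rng.normal(320.0, 60.0))
    mvc = max(mvc, 80.0)
    # agent dislikes waiting at `rate` utility/s; the low/high effort levels
    # cost `c_low` / `c_high` utility -> two indifference points, interpolated
    rate = float(np.exp(rng.normal(0.0, 0.3)))
    c_low = rate * float(rng.uniform(3.5, 9.0))
    c_high = c_low * float(rng.uniform(1.8, 3.0))
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        t_low = simulate_indifference_search(rate, c_low)
        t_high = simulate_indifference_search(rate, c_high)
    if t_high - t_low < 1.0:  # degenerate search: fall back to a legal spread
        t_low, t_high = 3.0, 15.0
    return ParticipantProfile(
        participant_id=participant_id,
        mvc=mvc,
        time_levels=calibrate_time_levels(t_low, t_high),
    )


def simulate_choices(
    subject: SubjectParameters,
    design: TrialDesign,
    spec: ModelSpec,
    rng: np.random.Generator,
    omission_rate: float = 0.0,
    failure_rate: float = 0.0,
    profile: ParticipantProfile | None = None,
    participant_id: str = "s01",
) -> pd.DataFrame:
    """Simulate one subject's trial records for one task design.

    Choice = costly with the model's softmax probability; an omission then
    overwrites the choice with probability ``omission_rate``; chosen-costly
    effort trials fail with probability ``failure_rate`` (time-task waits
    always complete).
    """
    df = design.trials.copy()
    n = len(df)
    is_env = (df["recipient"] == "environment").to_numpy()
    k = np.where(is_env, subject.k_env, subject.k_self)
    beta = np.where(is_env, subject.beta_env, subject.beta_self)
    sv = subjective_value(
        df["reward"].to_numpy(dtype=float),
        df["cost_level"].to_numpy(dtype=float),
        k,
        spec.family,
    )
    p_costly = choice_probability(sv, 1.0, beta)
    costly = rng.random(n) < p_costly
    omitted = rng.random(n) < omission_rate
    failed = rng.random(n) < failure_rate

    choice = np.where(costly, "costly", "baseline")
    choice = np.where(omitted, "omission", choice)
    is_effort = TaskKind(design.task) is TaskKind.effort
    success = np.where(
        (choice == "costly"),
        ~(failed & is_effort),
        False,
    )
    # success is undefined off the costly branch; stored as NA
    success_col = pd.array(success, dtype="boolean")
    success_col[choice != "costly"] = pd.NA

    df["participant"] = participant_id
    if profile is not None:
        df["cost_value"] = [
            profile.cost_value(design.task, c) for c in df["cost_level"]
        ]
    else:
        df["cost_value"] = np.nan
    df["choice"] = choice
    df["success"] = success_col
    # decision omissions mean no response within the 3 s window
    dt = 0.3 + rng.lognormal(-0.5, 0.4, size=n)
    dt = np.minimum(dt, 2.99)
    dt[choice == "omission"] = np.nan
    df["decision_time"] = np.round(dt, 4)
    earned = np.where(
        choice == "costly",
        np.where(success_col.fillna(False).to_numpy(dtype=bool), df["reward"], 0),
        np.where(choice == "baseline", 1, 0),
    )
    df["earned"] = earned
    cols = [
        "participant", "task", "block", "trial", "recipient", "cost_level",
        "cost_value", "reward", "baseline_reward", "choice", "success",
        "decision_time", "earned",
    ]
    return df[cols]


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort: trial table + ground-truth parameter table.

    The master seed spawns per-subject child seeds, so cohorts are
    reproducible regardless of how subjects are iterated.
    """
    master = np.random.SeedSequence(config.seed)
    subj_seeds = master.spawn(config.n_subjects + 1)
    pop_rng = np.random.default_rng(subj_seeds[-1])

    # subject log-parameters correlate across tasks: a shared individual
    # component plus a task-specific one, so discounting tendencies are
    # cost-type-general to the configured degree
    rho = config.cross_task_correlation
    n = config.n_subjects
    subjects: dict[TaskKind, list[SubjectParameters]] = {}
    z_common = {p: pop_rng.standard_normal(n) for p in PARAM_NAMES}
    for task in (TaskKind.effort, TaskKind.time):
        g = config.groups[task]
        draws = {}
        for p in PARAM_NAMES:
            z = np.sqrt(rho) * z_common[p] + np.sqrt(1 - rho) * pop_rng.standard_normal(n)
            draws[p] = np.exp(g.mu[p] + g.sigma[p] * z)
        subjects[task] = [
            SubjectParameters(
                k_self=draws["k_self"][i],
                k_env=draws["k_env"][i],
                beta_self=draws["beta_self"][i],
                beta_env=draws["beta_env"][i],
            )
            for i in range(n)
        ]

    trial_frames = []
    truth_rows = []
    width = max(2, len(str(config.n_subjects)))
    for i in range(config.n_subjects):
        rng = np.random.default_rng(subj_seeds[i])
        pid = f"s{i + 1:0{width}d}"
        profile = _default_profile(pid, rng)
        for task in (TaskKind.effort, TaskKind.time):
            design_seed = int(rng.integers(0, 2**31 - 1))
            design = generate_design(task, seed=design_seed)
            params = subjects[task][i]
            trial_frames.append(
                simulate_choices(
                    params,
                    design,
                    config.specs[task],
                    rng,
                    omission_rate=config.omission_rate,
                    failure_rate=config.failure_rate,
                    profile=profile,
                    participant_id=pid,
                )
            )
            truth_rows.append(
                {
                    "participant": pid,
                    "task": task.value,
                    "k_self": params.k_self,
                    "k_env": params.k_env,
                    "beta_self": params.beta_self,
                    "beta_env": params.beta_env,
                }
            )
    trials = pd.concat(trial_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return trials, truth


def simulate_questionnaires(
    true_params: pd.DataFrame,
    coupling: float,
    rng: np.random.Generator,
    n_items: int = 12,
) -> pd.DataFrame:
    """Simulate the 12-item policy-support scale (Likert 1-5) per subject.

    Item responses are discretized from a latent normal whose mean shifts
    with the standardized discounting asymmetry ``k_self - k_env`` scaled
    by ``coupling`` (positive coupling -> higher asymmetry, higher score;
    the sign convention is deliberately configurable).
    """
    if not {"participant", "k_self", "k_env"} <= set(true_params.columns):
        raise ValueError("true_params needs participant, k_self, k_env columns")
    diff = (true_params["k_self"] - true_params["k_env"]).to_numpy(dtype=float)
    sd = diff.std(ddof=0)
    z = (diff - diff.mean()) / sd if sd > 0 else np.zeros_like(diff)
    n = len(diff)
    latent = 3.0 + coupling * z[:, None] + rng.normal(0.0, 1.0, size=(n, n_items))
    items = np.clip(np.rint(latent), 1, 5).astype(int)
    out = pd.DataFrame(
        items, columns=[f"item_{j + 1:02d}" for j in range(n_items)]
    )
    out.insert(0, "participant", true_params["participant"].to_numpy())
    out["policy_support"] = items.mean(axis=1)
    return out
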