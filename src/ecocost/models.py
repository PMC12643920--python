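"""Subjective-value, choice-probability and likelihood computations.

The decision model: on each trial a participant chooses between a costly
option (reward ``R`` credits, cost level ``C``) and a no-cost baseline worth
1 credit.  The costly option's subjective value is the reward devalued by
the cost through one of three discounting families

* linear:      ``SV = R - k*C``
* parabolic:   ``SV = R - k*C**2``
* hyperbolic:  ``SV = R / (1 + k*C)``

and choices follow a softmax on the difference in subjective value with
inverse temperature ``beta``.  Discount rate ``k`` and ``beta`` may be
shared ("joint") or recipient-specific ("separate") for self-benefitting vs
pro-environmental trials, giving a 3 x 2 x 2 = 12 model space.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiscountFamily",
    "ModelSpec",
    "SubjectParameters",
    "subjective_value",
    "choice_probability",
    "trial_loglik",
    "dataset_loglik",
    "pointwise_loglik",
    "enumerate_model_space",
]

RECIPIENTS = ("self", "environment")
BASELINE_REWARD = 1.0


class DiscountFamily(str, Enum):
    """The three cost-discounting functional forms."""

    linear = "linear"
    parabolic = "parabolic"
    hyperbolic = "hyperbolic"


_STRUCTURES = ("joint", "separate")


@dataclass(frozen=True)
class ModelSpec:
    """One of the 12 candidate models.

    ``k_structure`` / ``beta_structure`` say whether the discount rate and
    the inverse temperature are shared between the self and environment
    recipients ("joint") or estimated per recipient ("separate").
    """

    family: DiscountFamily
    k_structure: str = "separate"
    beta_structure: str = "separate"

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", DiscountFamily(self.family))
        if self.k_structure not in _STRUCTURES:
            raise ValueError(f"k_structure must be one of {_STRUCTURES}")
        if self.beta_structure not in _STRUCTURES:
            raise ValueError(f"beta_structure must be one of {_STRUCTURES}")

    @property
    def name(self) -> str:
        """Canonical name, e.g. ``parabolic-2k2b``."""
        nk = 1 if self.k_structure == "joint" else 2
        nb = 1 if self.beta_structure == "joint" else 2
        return f"{self.family.value}-{nk}k{nb}b"

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        """Parse a canonical name such as ``hyperbolic-1k2b``."""
        try:
            family, code = name.rsplit("-", 1)
            nk, nb = int(code[0]), int(code[2])
            if code[1] != "k" or code[3] != "b" or len(code) != 4:
                raise ValueError
            if nk not in (1, 2) or nb not in (1, 2):
                raise ValueError
        except (ValueError, IndexError) as exc:
            raise ValueError(f"unparseable model name: {name!r}") from exc
        return cls(
            family=DiscountFamily(family),
            k_structure="joint" if nk == 1 else "separate",
            beta_structure="joint" if nb == 1 else "separate",
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


@dataclass(frozen=True)
class SubjectParameters:
    """Per-subject discount rates and inverse temperatures.

    Under a joint structure the self/environment values coincide; the class
    always carries both so likelihood code is structure-agnostic.
    """

    k_self: float
    k_env: float
    beta_self: float
    beta_env: float

    def __post_init__(self) -> None:
        for field in ("k_self", "k_env", "beta_self", "beta_env"):
            v = getattr(self, field)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{field} must be strictly positive and finite, got {v}")

    def k(self, recipient: str) -> float:
        return self.k_self if recipient == "self" else self.k_env

    def beta(self, recipient: str) -> float:
        return self.beta_self if recipient == "self" else self.beta_env


def enumerate_model_space() -> list[ModelSpec]:
    """All 12 model specifications in a stable order.

    Families iterate slowest (linear, parabolic, hyperbolic), then the k
    structure (joint before separate), then the beta structure.
    """
    return [
        ModelSpec(family=f, k_structure=ks, beta_structure=bs)
        for f in DiscountFamily
        for ks in _STRUCTURES
        for bs in _STRUCTURES
    ]


def subjective_value(reward, cost, k, family: DiscountFamily | str):
    """Evaluate the discounting function; vectorizes over array inputs.

    ``cost`` is in the units the model is parameterized in (by default the
    integer cost level 1-5; see the inference module's ``cost_coding``).
    """
    family = DiscountFamily(family)
    reward = np.asarray(reward, dtype=float)
    cost = np.asarray(cost, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(reward <= 0):
        raise ValueError("reward must be positive")
    if np.any(cost < 0):
        raise ValueError("cost must be non-negative")
    if np.any(k < 0):
        raise ValueError("discount rate k must be non-negative")
    if family is DiscountFamily.linear:
        sv = reward - k * cost
    elif family is DiscountFamily.parabolic:
        sv = reward - k * cost**2
    else:
        sv = reward / (1.0 + k * cost)
    if sv.ndim == 0:
        return float(sv)
    return sv


def choice_probability(sv_costly, sv_baseline, beta):
    """Softmax probability of choosing the costly option.

    ``P = 1 / (1 + exp(-beta * (sv_costly - sv_baseline)))``, computed via
    scipy's stable logistic so extreme ``beta * dSV`` does not overflow.
    """
    from scipy.special import expit

    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0):
        raise ValueError("inverse temperature beta must be non-negative")
    x = beta * (np.asarray(sv_costly, dtype=float) - np.asarray(sv_baseline, dtype=float))
    p = expit(x)
    if p.ndim == 0:
        return float(p)
    return p


def _check_choice_column(choice: np.ndarray) -> np.ndarray:
    if np.any(choice == "omission"):
        raise ValueError(
            "omitted trials must be filtered out before likelihood evaluation"
        )
    bad = ~np.isin(choice, ("costly", "baseline"))
    if np.any(bad):
        raise ValueError(f"unknown choice labels: {set(choice[bad])}")
    return choice == "costly"


def _loglik_terms(
    reward: np.ndarray,
    cost: np.ndarray,
    is_env: np.ndarray,
    chose_costly: np.ndarray,
    k: np.ndarray,
    beta: np.ndarray,
    family: DiscountFamily,
) -> np.ndarray:
    """Stable per-trial log-probabilities; all inputs broadcast per trial."""
    sv_c = subjective_value(reward, cost, k, family)
    x = beta * (np.asarray(sv_c) - BASELINE_REWARD)
    # log sigmoid(x) = -log1p(exp(-x)); sign flips for the baseline choice
    sign = np.where(chose_costly, 1.0, -1.0)
    return -np.logaddexp(0.0, -sign * x)


def trial_loglik(
    trial: Mapping,
    params: SubjectParameters,
    spec: ModelSpec,
    cost_column: str = "cost_level",
) -> float:
    """Log-probability of one observed choice.

    ``trial`` is any mapping (e.g. a DataFrame row) with ``reward``,
    ``recipient``, ``choice`` and the cost column.  Omissions are a
    contract violation here — they carry no choice likelihood.
    """
    choice = trial["choice"]
    if choice == "omission":
        raise ValueError("omitted trial passed to trial_loglik")
    if choice not in ("costly", "baseline"):
        raise ValueError(f"unknown choice label {choice!r}")
    recipient = trial["recipient"]
    if recipient not in RECIPIENTS:
        raise ValueError(f"unknown recipient {recipient!r}")
    return float(
        _loglik_terms(
            np.asarray(float(trial["reward"])),
            np.asarray(float(trial[cost_column])),
            np.asarray(recipient == "environment"),
            np.asarray(choice == "costly"),
            np.asarray(params.k(recipient)),
            np.asarray(params.beta(recipient)),
            spec.family,
        )
    )


def pointwise_loglik(
    trials: pd.DataFrame,
    params_by_subject: Mapping[object, SubjectParameters],
    spec: ModelSpec,
    cost_column: str = "cost_level",
) -> np.ndarray:
    """Vectorized per-trial log-likelihood for a multi-subject trial table.

    ``trials`` must already exclude omissions; rows are matched to subjects
    via the ``participant`` column.
    """
    choice = trials["choice"].to_numpy(dtype=object)
    chose_costly = _check_choice_column(choice)
    is_env = trials["recipient"].to_numpy(dtype=object) == "environment"
    pid = trials["participant"].to_numpy(dtype=object)
    k = np.empty(len(trials))
    beta = np.empty(len(trials))
    for subject, p in params_by_subject.items():
        m = pid == subject
        k[m] = np.where(is_env[m], p.k_env, p.k_self)
        beta[m] = np.where(is_env[m], p.beta_env, p.beta_self)
    return _loglik_terms(
        trials["reward"].to_numpy(dtype=float),
        trials[cost_column].to_numpy(dtype=float),
        is_env,
        chose_costly,
        k,
        beta,
        spec.family,
    )


def dataset_loglik(
    trials: pd.DataFrame,
    params_by_subject: Mapping[object, SubjectParameters] | SubjectParameters,
    spec: ModelSpec,
    cost_column: str = "cost_level",
) -> float:
    """Total log-likelihood of a trial table under one model."""
    if isinstance(params_by_subject, SubjectParameters):
        params_by_subject = {
            s: params_by_subject for s in trials["participant"].unique()
        }
    return float(
        pointwise_loglik(trials, params_by_subject, spec, cost_column).sum()
    )
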