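"""Model comparison by PSIS-LOO and validation of the winning model.

LOOIC = -2 * elpd_loo, where elpd_loo is estimated from the pointwise
log-likelihood matrix by Pareto-smoothed importance sampling (the PSIS
smoothing itself comes from arviz).  Validation covers posterior predictive
checks of per-cell choice proportions and a parameter-recovery round trip:
simulate a cohort from the fitted group-level posterior means, refit the
same model, and check group-level HDI containment plus subject-level
true-vs-recovered correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .cohort import GroupParameters, sample_subjects, simulate_choices
from .design import TaskKind, TrialDesign, generate_design
from .inference import (
    McmcConfig,
    PosteriorFit,
    fit_model,
    subject_point_estimates,
)
from .models import ModelSpec

__all__ = [
    "LooResult",
    "RecoveryReport",
    "compute_loo",
    "compare_models",
    "parameter_recovery",
    "posterior_predictive_check",
    "hdi",
]

PARETO_K_THRESHOLD = 0.7


@dataclass(frozen=True)
class LooResult:
    """PSIS-LOO estimate for one fitted model."""

    elpd_loo: float
    se: float
    pointwise: np.ndarray = field(repr=False)
    pareto_k: np.ndarray = field(repr=False)
    model: str = ""

    @property
    def looic(self) -> float:
        return -2.0 * self.elpd_loo

    @property
    def looic_se(self) -> float:
        return 2.0 * self.se

    @property
    def frac_high_k(self) -> float:
        return float(np.mean(self.pareto_k > PARETO_K_THRESHOLD))


def _relative_efficiency(fit: PosteriorFit, max_cols: int = 40) -> float:
    """MCMC relative efficiency (mean ESS / total draws) of the pointwise
    log-likelihood, estimated on an even subsample of trials."""
    c, d, n = fit.loglik.shape
    cols = np.linspace(0, n - 1, min(n, max_cols)).astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = az.ess(az.convert_to_dataset(np.asarray(fit.loglik[:, :, cols], dtype=float)))
    mean_ess = float(np.asarray(ess.to_array()).mean())
    return float(np.clip(mean_ess / (c * d), 1e-3, 1.0))


def compute_loo(fit: PosteriorFit) -> LooResult:
    """PSIS-smoothed leave-one-out elpd from the pointwise matrix.

    Importance ratios 1/p(y_i | draw) are Pareto-smoothed per trial; the
    fraction of trials with shape diagnostic k > 0.7 is reported (warning,
    not failure).
    """
    ll = np.asarray(fit.loglik_matrix(), dtype=float)  # (draws, n)
    if ll.size == 0:
        raise ValueError("fit carries no pointwise log-likelihood matrix")
    if np.ptp(ll, axis=0).max() == 0:
        # degenerate posterior: all draws identical, LOO is exact
        pointwise = ll[0]
        k = np.full(ll.shape[1], -np.inf)
    else:
        reff = _relative_efficiency(fit)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # psislw smooths over the last axis -> orient as (n, draws)
            lw, k = az.psislw(-ll.T, reff=reff)
        lw = np.asarray(lw)
        k = np.asarray(k)
        # trials whose likelihood is ~constant across draws have ~zero-variance
        # importance ratios; smoothing can NaN out there, but uniform weights
        # are then exact
        bad = ~np.all(np.isfinite(lw), axis=-1)
        if np.any(bad):
            lw[bad] = -np.log(ll.shape[0])
            k[bad] = -np.inf
        pointwise = logsumexp(lw + ll.T, axis=-1)
    elpd = float(pointwise.sum())
    n = pointwise.size
    se = float(np.sqrt(n * pointwise.var(ddof=0)))
    if np.mean(k > PARETO_K_THRESHOLD) > 0:
        warnings.warn(
            f"{np.sum(k > PARETO_K_THRESHOLD)} of {n} trials have Pareto k > "
            f"{PARETO_K_THRESHOLD}; LOO may be unstable for those trials"
        )
    return LooResult(
        elpd_loo=elpd, se=se, pointwise=pointwise, pareto_k=k,
        model=fit.spec.name,
    )


def compare_models(fits: list[PosteriorFit]) -> pd.DataFrame:
    """Rank fitted models by LOOIC (rank 1 = lowest LOOIC = best).

    All fits must be of the same dataset (matching fingerprints).
    """
    if not fits:
        raise ValueError("no fits to compare")
    fps = {f.fingerprint for f in fits}
    if len(fps) != 1:
        raise ValueError("fits are not all of the same dataset")
    rows = []
    for f in fits:
        loo = compute_loo(f)
        rows.append(
            {
                "model": f.spec.name,
                "elpd_loo": loo.elpd_loo,
                "looic": loo.looic,
                "se": loo.se,
                "looic_se": loo.looic_se,
                "frac_pareto_k_high": loo.frac_high_k,
                "max_rhat": f.max_rhat(),
            }
        )
    table = pd.DataFrame(rows).sort_values("looic", kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the samples (via arviz)."""
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 100:
        raise ValueError("need at least 100 samples for a stable HDI")
    if np.ptp(samples) == 0:
        return (float(samples[0]), float(samples[0]))
    lo, hi = az.hdi(samples, hdi_prob=mass)
    return (float(lo), float(hi))


def _group_from_posterior_means(fit: PosteriorFit) -> GroupParameters:
    """Population hyperparameters fixed at their posterior means."""
    mu_k = fit.draws["mu_k"].mean(axis=(0, 1))
    sig_k = fit.draws["sig_k"].mean(axis=(0, 1))
    mu_b = fit.draws["mu_b"].mean(axis=(0, 1))
    sig_b = fit.draws["sig_b"].mean(axis=(0, 1))
    jk_env = len(mu_k) - 1
    jb_env = len(mu_b) - 1
    return GroupParameters(
        mu={
            "k_self": float(mu_k[0]),
            "k_env": float(mu_k[jk_env]),
            "beta_self": float(mu_b[0]),
            "beta_env": float(mu_b[jb_env]),
        },
        sigma={
            "k_self": float(sig_k[0]),
            "k_env": float(sig_k[jk_env]),
            "beta_self": float(sig_b[0]),
            "beta_env": float(sig_b[jb_env]),
        },
    )


@dataclass
class RecoveryReport:
    """Outcome of one simulate-and-refit parameter-recovery round trip."""

    group_containment: dict[str, bool]
    subject_correlations: dict[str, float]
    refit_converged: bool
    true_group: GroupParameters
    n_subjects: int

    @property
    def all_contained(self) -> bool:
        return all(self.group_containment.values())


def parameter_recovery(
    fit: PosteriorFit,
    design: TrialDesign | None = None,
    config: McmcConfig | None = None,
    n_subjects: int | None = None,
    seed: int = 0,
    hdi_mass: float = 0.95,
) -> RecoveryReport:
    """Simulate a cohort from the fitted hyperparameters and refit.

    Subjects are drawn from the log-normal population implied by the
    posterior-mean hyperparameters of ``fit``, choices are simulated on
    ``design`` (a fresh one is generated if omitted), and the same model is
    refitted.  Reported are (a) whether the 95% HDI of each of ``fit``'s
    group-level posteriors contains the refit's posterior-mean estimate and
    (b) the Pearson correlation between true and recovered subject-level
    parameters.  A non-converged refit flags the report instead of raising.
    """
    config = config or fit.config
    n = n_subjects or len(fit.subjects)
    group = _group_from_posterior_means(fit)
    rng = np.random.default_rng(seed)
    if design is None:
        design = generate_design(fit.task, seed=seed)
    subjects = sample_subjects(group, n, rng)
    frames = []
    width = max(2, len(str(n)))
    for i, subj in enumerate(subjects):
        frames.append(
            simulate_choices(
                subj, design, fit.spec, rng, participant_id=f"r{i + 1:0{width}d}"
            )
        )
    sim = pd.concat(frames, ignore_index=True)
    refit = fit_model(
        sim, fit.spec, priors=fit.priors, config=config,
        cost_coding="level" if fit.cost_column == "cost_level" else "physical",
    )

    # group-level containment: HDI of the generating fit's hyper posterior
    # vs the refit's posterior mean, per hyperparameter coordinate
    containment: dict[str, bool] = {}
    for key in ("mu_k", "sig_k", "mu_b", "sig_b"):
        post = fit.draws[key]  # (chains, kept, J)
        refit_mean = refit.draws[key].mean(axis=(0, 1))
        for j in range(post.shape[2]):
            lo, hi = hdi(post[:, :, j], mass=hdi_mass)
            containment[f"{key}[{j}]"] = bool(lo <= refit_mean[j] <= hi)

    true_tab = pd.DataFrame(
        {
            "k_self": [s.k_self for s in subjects],
            "k_env": [s.k_env for s in subjects],
            "beta_self": [s.beta_self for s in subjects],
            "beta_env": [s.beta_env for s in subjects],
        }
    )
    est = subject_point_estimates(refit)
    corrs = {
        p: float(np.corrcoef(true_tab[p], est[p])[0, 1])
        for p in ("k_self", "k_env", "beta_self", "beta_env")
    }
    return RecoveryReport(
        group_containment=containment,
        subject_correlations=corrs,
        refit_converged=refit.converged,
        true_group=group,
        n_subjects=n,
    )


def posterior_predictive_check(
    fit: PosteriorFit,
    dataset: pd.DataFrame | None = None,
    n_draws: int = 500,
    seed: int = 0,
    interval: float = 0.95,
) -> pd.DataFrame:
    """Observed vs simulated costly-choice proportions per design cell.

    For each of ``n_draws`` retained posterior draws, choices are simulated
    for every fitted trial from that draw's subject-level parameters; per
    (cost_level x reward x recipient) cell the observed proportion is
    compared with the predictive mean and central ``interval``.
    """
    trials = fit.trials if dataset is None else dataset[dataset["choice"] != "omission"]
    from .inference import dataset_fingerprint

    if dataset is not None:
        trials = trials.reset_index(drop=True)
        if dataset_fingerprint(trials) != fit.fingerprint:
            raise ValueError("dataset does not match the fitted data")
    rng = np.random.default_rng(seed)
    c, d, n = fit.loglik.shape
    total = c * d
    n_draws = min(n_draws, total)
    idx = np.linspace(0, total - 1, n_draws).astype(int)  # even thinning
    k = fit.draws["k"].reshape(total, -1, 2)[idx]      # (n_draws, S, 2)
    beta = fit.draws["beta"].reshape(total, -1, 2)[idx]

    sid = {s: i for i, s in enumerate(fit.subjects)}
    subj = trials["participant"].map(sid).to_numpy(dtype=np.intp)
    is_env = (trials["recipient"] == "environment").to_numpy().astype(int)
    reward = trials["reward"].to_numpy(dtype=float)
    cost = trials[fit.cost_column].to_numpy(dtype=float)

    from .models import choice_probability, subjective_value

    cell_frame = (
        trials[["cost_level", "reward", "recipient"]]
        .drop_duplicates()
        .sort_values(["cost_level", "reward", "recipient"])
        .reset_index(drop=True)
    )
    cell_key = cell_frame.apply(tuple, axis=1)
    code_of = {key: i for i, key in enumerate(cell_key)}
    cell_codes = (
        trials[["cost_level", "reward", "recipient"]]
        .apply(tuple, axis=1)
        .map(code_of)
        .to_numpy(dtype=np.intp)
    )
    n_cells = len(cell_frame)
    counts = np.bincount(cell_codes, minlength=n_cells)
    observed = np.bincount(
        cell_codes,
        weights=(trials["choice"] == "costly").to_numpy(dtype=float),
        minlength=n_cells,
    ) / counts

    sims = np.empty((n_draws, n_cells))
    for t in range(n_draws):
        k_t = k[t][subj, is_env]
        b_t = beta[t][subj, is_env]
        sv = subjective_value(reward, cost, k_t, fit.spec.family)
        p = choice_probability(sv, 1.0, b_t)
        y = rng.random(len(p)) < p
        sims[t] = np.bincount(
            cell_codes, weights=y.astype(float), minlength=n_cells
        ) / counts

    alpha = (1.0 - interval) / 2.0
    lo = np.quantile(sims, alpha, axis=0)
    hi = np.quantile(sims, 1.0 - alpha, axis=0)
    report = pd.DataFrame(
        {
            "cost_level": cell_frame["cost_level"],
            "reward": cell_frame["reward"],
            "recipient": cell_frame["recipient"],
            "n_trials": counts,
            "observed": observed,
            "predicted_mean": sims.mean(axis=0),
            "predicted_lo": lo,
            "predicted_hi": hi,
        }
    )
    report["inside"] = (report["observed"] >= report["predicted_lo"]) & (
        report["observed"] <= report["predicted_hi"]
    )
    report.attrs["coverage"] = float(report["inside"].mean())
    report.attrs["n_draws"] = int(n_draws)
    return report
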