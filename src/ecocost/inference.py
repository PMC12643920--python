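"""Hierarchical Bayesian estimation of the discounting models.

Subjects share a log-normal population per parameter: on the log scale,
subject effects are non-centered, ``log theta_s = mu + sigma * z_s`` with
``z_s ~ N(0, 1)``, group means ``mu ~ N(0, 1)`` and group scales
``sigma ~ HalfNormal(0.5)``.  Posteriors are sampled with an adaptive
Metropolis-within-Gibbs scheme: a joint random-walk update of each
subject's latent vector (subjects are conditionally independent given the
hyperparameters, so all subjects are updated in one vectorized step),
followed by scalar random-walk updates of each hyperparameter.  Proposal
scales adapt during warmup (diminishing Robbins-Monro adaptation) and are
frozen afterwards, so retained draws form a valid Markov chain.  Runs are
bitwise reproducible for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .models import DiscountFamily, ModelSpec
from .design import TaskKind

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "PosteriorFit",
    "HierarchicalDiscountingModel",
    "fit_model",
    "compute_rhat",
    "subject_point_estimates",
    "dataset_fingerprint",
]

@dataclass(frozen=True)
class PriorSpec:
    """Weakly-informative priors on the log-scale hyperparameters."""

    mu_loc: float = 0.0
    mu_scale: float = 1.0
    sigma_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.mu_scale <= 0 or self.sigma_scale <= 0:
            raise ValueError("prior scales must be positive")


@dataclass(frozen=True)
class McmcConfig:
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need at least 2 chains")
        if not (0 < self.warmup < self.iterations):
            raise ValueError("need 0 < warmup < iterations")

    @property
    def kept(self) -> int:
        return self.iterations - self.warmup


def dataset_fingerprint(trials: pd.DataFrame) -> str:
    """Provenance hash of the likelihood-relevant trial columns."""
    cols = ["participant", "task", "trial", "recipient", "cost_level", "reward", "choice"]
    sub = trials[[c for c in cols if c in trials.columns]]
    payload = sub.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()


@dataclass
class PosteriorFit:
    """MCMC output: draws, diagnostics and the pointwise log-likelihood.

    ``draws`` holds, per chain and retained iteration, the hyperparameters
    (``mu_k``, ``sigma_k``, ``mu_beta``, ``sigma_beta``; trailing axis is
    the group dimension, 1 if joint else 2 ordered self/env) and the
    constrained subject parameters ``k`` and ``beta`` with shape
    (chains, kept, subjects, 2), last axis ordered (self, env).
    """

    spec: ModelSpec
    config: McmcConfig
    priors: PriorSpec
    task: TaskKind
    subjects: list
    draws: dict[str, np.ndarray]
    loglik: np.ndarray  # (chains, kept, n_trials)
    rhat: dict[str, np.ndarray]
    accept_rates: dict[str, float]
    fingerprint: str
    trials: pd.DataFrame = field(repr=False)  # non-omitted trials fitted
    cost_column: str = "cost_level"

    @property
    def n_draws(self) -> int:
        return self.loglik.shape[0] * self.loglik.shape[1]

    @property
    def converged(self) -> bool:
        return bool(max(np.max(v) for v in self.rhat.values()) < 1.05)

    def max_rhat(self) -> float:
        return float(max(np.max(v) for v in self.rhat.values()))

    def loglik_matrix(self) -> np.ndarray:
        """Pointwise matrix flattened to (total draws, n_trials)."""
        c, d, n = self.loglik.shape
        return self.loglik.reshape(c * d, n)

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            path / "draws.npz", loglik=self.loglik,
            **{k: v for k, v in self.draws.items()},
        )
        meta = {
            "spec": self.spec.name,
            "task": self.task.value,
            "subjects": [str(s) for s in self.subjects],
            "config": {
                "chains": self.config.chains,
                "iterations": self.config.iterations,
                "warmup": self.config.warmup,
                "seed": self.config.seed,
            },
            "priors": {
                "mu_loc": self.priors.mu_loc,
                "mu_scale": self.priors.mu_scale,
                "sigma_scale": self.priors.sigma_scale,
            },
            "rhat": {k: np.asarray(v).tolist() for k, v in self.rhat.items()},
            "accept_rates": self.accept_rates,
            "fingerprint": self.fingerprint,
            "cost_column": self.cost_column,
        }
        (path / "fit.json").write_text(json.dumps(meta, indent=2))
        self.trials.to_csv(path / "trials.csv", index=False)

    @classmethod
    def load(cls, path) -> "PosteriorFit":
        path = Path(path)
        meta = json.loads((path / "fit.json").read_text())
        arrays = np.load(path / "draws.npz")
        draws = {k: arrays[k] for k in arrays.files if k != "loglik"}
        return cls(
            spec=ModelSpec.from_name(meta["spec"]),
            config=McmcConfig(**meta["config"]),
            priors=PriorSpec(**meta["priors"]),
            task=TaskKind(meta["task"]),
            subjects=meta["subjects"],
            draws=draws,
            loglik=arrays["loglik"],
            rhat={k: np.asarray(v) for k, v in meta["rhat"].items()},
            accept_rates=meta["accept_rates"],
            fingerprint=meta["fingerprint"],
            trials=pd.read_csv(path / "trials.csv"),
            cost_column=meta["cost_column"],
        )


def compute_rhat(draws: np.ndarray) -> float:
    """Split-R-hat for one parameter from per-chain draws (chains, iters).

    Each chain is split in half; R-hat compares between- and within-chain
    variance of the split halves.  Zero total variance is defined as 1.0
    (with a warning) rather than 0/0.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2 or draws.shape[1] < 4:
        raise ValueError("need (chains >= 2, iters >= 4) draws")
    half = draws.shape[1] // 2
    splits = np.concatenate(
        [draws[:, :half], draws[:, half: 2 * half]], axis=0
    )  # (2m, half)
    if np.allclose(splits.var(), 0):
        warnings.warn("zero variance across draws; R-hat defined as 1.0")
        return 1.0
    w = splits.var(axis=1, ddof=1).mean()
    b = half * splits.mean(axis=1).var(ddof=1)
    var_plus = (half - 1) / half * w + b / half
    if w == 0:
        warnings.warn("zero within-chain variance; R-hat defined as 1.0")
        return 1.0
    return float(np.sqrt(var_plus / w))


# ---------------------------------------------------------------------------
# sampler internals


class _Problem:
    """Precomputed index arrays for vectorized likelihood evaluation."""

    def __init__(self, trials: pd.DataFrame, spec: ModelSpec, cost_column: str):
        self.spec = spec
        self.subjects = sorted(trials["participant"].unique().tolist())
        self.S = len(self.subjects)
        sid = {s: i for i, s in enumerate(self.subjects)}
        self.subj = trials["participant"].map(sid).to_numpy(dtype=np.intp)
        is_env = (trials["recipient"] == "environment").to_numpy()
        self.reward = trials["reward"].to_numpy(dtype=float)
        self.cost = trials[cost_column].to_numpy(dtype=float)
        choice = trials["choice"].to_numpy(dtype=object)
        if np.any(choice == "omission"):
            raise ValueError("omissions must be excluded before fitting")
        self.sign = np.where(choice == "costly", 1.0, -1.0)

        self.Jk = 1 if spec.k_structure == "joint" else 2
        self.Jb = 1 if spec.beta_structure == "joint" else 2
        self.D = self.Jk + self.Jb
        # group-dimension index per trial (0 = self/joint, 1 = env-separate)
        self.jk = np.where(is_env & (self.Jk == 2), 1, 0).astype(np.intp)
        self.jb = np.where(is_env & (self.Jb == 2), 1, 0).astype(np.intp)
        # column of z used per trial
        self.zk = self.jk
        self.zb = self.Jk + self.jb
        self.n = len(trials)

    def loglik(self, mu_k, sig_k, mu_b, sig_b, z, rows=slice(None)) -> np.ndarray:
        """Per-trial log-likelihood for the given state (optionally a subset)."""
        subj = self.subj[rows]
        logk = mu_k[self.jk[rows]] + sig_k[self.jk[rows]] * z[subj, self.zk[rows]]
        logb = mu_b[self.jb[rows]] + sig_b[self.jb[rows]] * z[subj, self.zb[rows]]
        k = np.exp(logk)
        beta = np.exp(logb)
        r = self.reward[rows]
        c = self.cost[rows]
        fam = self.spec.family
        if fam is DiscountFamily.linear:
            sv = r - k * c
        elif fam is DiscountFamily.parabolic:
            sv = r - k * c * c
        else:
            sv = r / (1.0 + k * c)
        return -np.logaddexp(0.0, -self.sign[rows] * (beta * (sv - 1.0)))


def _run_chain(
    prob: _Problem,
    priors: PriorSpec,
    iterations: int,
    warmup: int,
    rng: np.random.Generator,
    init_jitter: float = 0.1,
    max_init_retries: int = 5,
):
    S, Jk, Jb, D = prob.S, prob.Jk, prob.Jb, prob.D

    for attempt in range(max_init_retries + 1):
        mu_k = priors.mu_loc + init_jitter * rng.standard_normal(Jk)
        mu_b = priors.mu_loc + init_jitter * rng.standard_normal(Jb)
        ls_k = np.log(0.3) + init_jitter * rng.standard_normal(Jk)
        ls_b = np.log(0.3) + init_jitter * rng.standard_normal(Jb)
        z = init_jitter * rng.standard_normal((S, D))
        ll = prob.loglik(mu_k, np.exp(ls_k), mu_b, np.exp(ls_b), z)
        if np.all(np.isfinite(ll)):
            break
    else:
        raise RuntimeError("non-finite likelihood at initialization after retries")

    ll_subj = np.bincount(prob.subj, weights=ll, minlength=S)

    def hyper_logprior(mu, ls):
        sig = np.exp(ls)
        lp_mu = -0.5 * ((mu - priors.mu_loc) / priors.mu_scale) ** 2
        lp_sig = -0.5 * (sig / priors.sigma_scale) ** 2 + ls  # half-normal + Jacobian
        return lp_mu.sum() + lp_sig.sum()

    # two per-subject proposal blocks (k-dims, beta-dims), separate scales:
    # beta is weakly identified for near-deterministic choosers and needs
    # larger moves than k
    z_blocks = (np.arange(Jk), np.arange(Jk, D))
    step_z = [np.full(S, 0.5 / np.sqrt(max(len(b), 1))) for b in z_blocks]
    hyper_names = (
        [("mu_k", j) for j in range(Jk)]
        + [("ls_k", j) for j in range(Jk)]
        + [("mu_b", j) for j in range(Jb)]
        + [("ls_b", j) for j in range(Jb)]
    )
    step_h = {h: 0.1 for h in hyper_names}
    state = {"mu_k": mu_k, "ls_k": ls_k, "mu_b": mu_b, "ls_b": ls_b}
    # rows affected by each hyper coordinate (for cheap partial updates)
    rows_of = {}
    for name, j in hyper_names:
        if name.endswith("_k"):
            rows_of[(name, j)] = np.flatnonzero(prob.jk == j)
        else:
            rows_of[(name, j)] = np.flatnonzero(prob.jb == j)

    kept = iterations - warmup
    out_hyper = {h: np.empty(kept) for h in ["mu_k", "sig_k", "mu_b", "sig_b"]}
    out_hyper = {
        "mu_k": np.empty((kept, Jk)), "sig_k": np.empty((kept, Jk)),
        "mu_b": np.empty((kept, Jb)), "sig_b": np.empty((kept, Jb)),
    }
    out_subject = np.empty((kept, S, 4))
    out_ll = np.empty((kept, prob.n))
    acc_z_total = 0.0
    acc_h_total = {h: 0.0 for h in hyper_names}

    z_prior = -0.5 * np.sum(z * z, axis=1)

    for it in range(iterations):
        gamma = (it + 1) ** -0.6 if it < warmup else 0.0
        sig_k, sig_b = np.exp(state["ls_k"]), np.exp(state["ls_b"])

        # --- vectorized per-subject updates of latent z, blockwise ---
        for bi, block in enumerate(z_blocks):
            z_prop = z.copy()
            z_prop[:, block] += step_z[bi][:, None] * rng.standard_normal(
                (S, len(block))
            )
            ll_prop = prob.loglik(state["mu_k"], sig_k, state["mu_b"], sig_b, z_prop)
            ll_subj_prop = np.bincount(prob.subj, weights=ll_prop, minlength=S)
            zp_prior = -0.5 * np.sum(z_prop * z_prop, axis=1)
            log_alpha = (ll_subj_prop + zp_prior) - (ll_subj + z_prior)
            accept = np.log(rng.random(S)) < log_alpha
            z[accept] = z_prop[accept]
            ll_subj = np.where(accept, ll_subj_prop, ll_subj)
            z_prior = np.where(accept, zp_prior, z_prior)
            acc_trial = accept[prob.subj]
            ll = np.where(acc_trial, ll_prop, ll)
            if gamma:
                step_z[bi] *= np.exp(
                    gamma * (np.where(accept, 1.0, 0.0) - 0.3)
                )
            acc_z_total += accept.mean() / len(z_blocks)

        # --- scalar hyperparameter updates ---
        for h in hyper_names:
            name, j = h
            rows = rows_of[h]
            cur = state[name][j]
            prop = cur + step_h[h] * rng.standard_normal()
            old_lp = hyper_logprior(
                np.concatenate([state["mu_k"], state["mu_b"]]),
                np.concatenate([state["ls_k"], state["ls_b"]]),
            )
            state[name][j] = prop
            sig_k, sig_b = np.exp(state["ls_k"]), np.exp(state["ls_b"])
            ll_rows = prob.loglik(
                state["mu_k"], sig_k, state["mu_b"], sig_b, z, rows=rows
            )
            new_lp = hyper_logprior(
                np.concatenate([state["mu_k"], state["mu_b"]]),
                np.concatenate([state["ls_k"], state["ls_b"]]),
            )
            log_alpha_h = (ll_rows.sum() + new_lp) - (ll[rows].sum() + old_lp)
            if np.log(rng.random()) < log_alpha_h:
                ll[rows] = ll_rows
                acc = 1.0
            else:
                state[name][j] = cur
                acc = 0.0
            if gamma:
                step_h[h] *= np.exp(gamma * (acc - 0.44))
            acc_h_total[h] += acc
        ll_subj = np.bincount(prob.subj, weights=ll, minlength=S)

        # --- interweaving (ASIS): refresh hypers conditional on the
        # constrained subject effects held fixed; the likelihood does not
        # change, and the centered conditionals mix mu/sigma far better ---
        for name_mu, name_ls, J, off in (
            ("mu_k", "ls_k", Jk, 0),
            ("mu_b", "ls_b", Jb, Jk),
        ):
            for j in range(J):
                sig = np.exp(state[name_ls][j])
                theta = state[name_mu][j] + sig * z[:, off + j]
                # conjugate normal draw for mu given theta
                prec = S / sig**2 + 1.0 / priors.mu_scale**2
                mean = (theta.sum() / sig**2 + priors.mu_loc / priors.mu_scale**2) / prec
                mu_new = mean + rng.standard_normal() / np.sqrt(prec)
                # MH on log sigma given theta and the new mu
                ls_cur = state[name_ls][j]
                resid2 = np.sum((theta - mu_new) ** 2)

                def _lp(ls):
                    s2 = np.exp(2 * ls)
                    return (
                        -S * ls
                        - 0.5 * resid2 / s2
                        - 0.5 * np.exp(2 * ls) / priors.sigma_scale**2
                        + ls
                    )

                ls_prop = ls_cur + 0.3 * rng.standard_normal()
                if np.log(rng.random()) < _lp(ls_prop) - _lp(ls_cur):
                    ls_new = ls_prop
                else:
                    ls_new = ls_cur
                state[name_mu][j] = mu_new
                state[name_ls][j] = ls_new
                z[:, off + j] = (theta - mu_new) / np.exp(ls_new)
        z_prior = -0.5 * np.sum(z * z, axis=1)

        if it >= warmup:
            t = it - warmup
            sig_k, sig_b = np.exp(state["ls_k"]), np.exp(state["ls_b"])
            out_hyper["mu_k"][t] = state["mu_k"]
            out_hyper["sig_k"][t] = sig_k
            out_hyper["mu_b"][t] = state["mu_b"]
            out_hyper["sig_b"][t] = sig_b
            # constrained subject params, columns (k_self, k_env, b_self, b_env)
            jk_self, jk_env = 0, Jk - 1
            jb_self, jb_env = 0, Jb - 1
            out_subject[t, :, 0] = np.exp(
                state["mu_k"][jk_self] + sig_k[jk_self] * z[:, jk_self]
            )
            out_subject[t, :, 1] = np.exp(
                state["mu_k"][jk_env] + sig_k[jk_env] * z[:, jk_env]
            )
            out_subject[t, :, 2] = np.exp(
                state["mu_b"][jb_self] + sig_b[jb_self] * z[:, Jk + jb_self]
            )
            out_subject[t, :, 3] = np.exp(
                state["mu_b"][jb_env] + sig_b[jb_env] * z[:, Jk + jb_env]
            )
            out_ll[t] = ll

    acc_rates = {
        "z": acc_z_total / iterations,
        **{f"{n}[{j}]": a / iterations for (n, j), a in acc_h_total.items()},
    }
    return out_hyper, out_subject, out_ll, acc_rates


class HierarchicalDiscountingModel(BaseEstimator):
    """Hierarchical Bayesian discounting model, sklearn-style.

    Parameters
    ----------
    model : str or ModelSpec, default "parabolic-2k2b"
        Which of the 12 candidate models to fit (canonical name).
    chains, iterations, warmup : int
        MCMC configuration (defaults 4 chains x 2000 iterations, first
        1000 discarded, leaving 4000 retained draws).
    seed : int
        Seed for the (deterministic) sampler.
    priors : PriorSpec
        Hyperpriors on the log-scale group parameters.
    cost_coding : {"level", "physical"}
        Whether costs enter the discounting function as integer levels 1-5
        (default; keeps k comparable across tasks) or as physical units
        (the ``cost_value`` column: fraction of MVC or seconds).

    Attributes (after ``fit``)
    --------------------------
    fit_ : PosteriorFit
    rhat_ : dict of split-R-hat arrays per parameter block
    subjects_ : list of participant ids
    converged_ : bool, all R-hat < 1.05
    """

    def __init__(
        self,
        model: str | ModelSpec = "parabolic-2k2b",
        chains: int = 4,
        iterations: int = 2000,
        warmup: int = 1000,
        seed: int = 0,
        priors: PriorSpec | None = None,
        cost_coding: str = "level",
    ):
        self.model = model
        self.chains = chains
        self.iterations = iterations
        self.warmup = warmup
        self.seed = seed
        self.priors = priors
        self.cost_coding = cost_coding

    def _spec(self) -> ModelSpec:
        return (
            self.model
            if isinstance(self.model, ModelSpec)
            else ModelSpec.from_name(self.model)
        )

    def fit(self, X: pd.DataFrame, y=None) -> "HierarchicalDiscountingModel":
        """Fit to a one-task trial table (omissions dropped internally)."""
        spec = self._spec()
        priors = self.priors or PriorSpec()
        config = McmcConfig(
            chains=self.chains, iterations=self.iterations,
            warmup=self.warmup, seed=self.seed,
        )
        if self.cost_coding not in ("level", "physical"):
            raise ValueError("cost_coding must be 'level' or 'physical'")
        cost_column = "cost_level" if self.cost_coding == "level" else "cost_value"
        required = {"participant", "task", "recipient", cost_column, "reward", "choice"}
        missing = required - set(X.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        tasks = X["task"].unique()
        if len(tasks) != 1:
            raise ValueError("fit one task at a time; filter the table first")
        trials = X[X["choice"] != "omission"].reset_index(drop=True)
        per_subj = trials.groupby("participant").size()
        if per_subj.empty or (per_subj < 2).any():
            raise ValueError("every subject needs at least 2 non-omitted trials")

        prob = _Problem(trials, spec, cost_column)
        seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
        hypers, subj_draws, lls, accs = [], [], [], []
        for cs in seeds:
            h, s, l, a = _run_chain(
                prob, priors, config.iterations, config.warmup,
                np.random.default_rng(cs),
            )
            hypers.append(h)
            subj_draws.append(s)
            lls.append(l)
            accs.append(a)

        draws = {
            key: np.stack([h[key] for h in hypers])  # (chains, kept, J)
            for key in ("mu_k", "sig_k", "mu_b", "sig_b")
        }
        subj = np.stack(subj_draws)  # (chains, kept, S, 4)
        draws["k"] = subj[..., :2]
        draws["beta"] = subj[..., 2:]
        loglik = np.stack(lls)

        rhat = {}
        for key in ("mu_k", "sig_k", "mu_b", "sig_b"):
            arr = draws[key]  # (chains, kept, J)
            rhat[key] = np.array(
                [compute_rhat(arr[:, :, j]) for j in range(arr.shape[2])]
            )
        # subject-level diagnostics on the log scale (constrained draws are
        # heavy-tailed; log is the sampling scale)
        for key in ("k", "beta"):
            arr = np.log(draws[key])
            rhat[key] = np.array(
                [
                    [compute_rhat(arr[:, :, s, c]) for c in range(2)]
                    for s in range(arr.shape[2])
                ]
            )
        mean_acc = {
            k: float(np.mean([a[k] for a in accs])) for k in accs[0]
        }

        self.fit_ = PosteriorFit(
            spec=spec,
            config=config,
            priors=priors,
            task=TaskKind(tasks[0]),
            subjects=prob.subjects,
            draws=draws,
            loglik=loglik,
            rhat=rhat,
            accept_rates=mean_acc,
            fingerprint=dataset_fingerprint(trials),
            trials=trials,
            cost_column=cost_column,
        )
        self.rhat_ = rhat
        self.subjects_ = prob.subjects
        self.converged_ = self.fit_.converged
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior-mean probability of choosing the costly option per trial."""
        from .models import choice_probability, subjective_value

        fit = self._check_fitted()
        est = subject_point_estimates(fit).set_index("participant")
        is_env = (X["recipient"] == "environment").to_numpy()
        k = np.where(
            is_env,
            est.loc[X["participant"], "k_env"],
            est.loc[X["participant"], "k_self"],
        )
        beta = np.where(
            is_env,
            est.loc[X["participant"], "beta_env"],
            est.loc[X["participant"], "beta_self"],
        )
        sv = subjective_value(
            X["reward"].to_numpy(dtype=float),
            X[fit.cost_column].to_numpy(dtype=float),
            k,
            fit.spec.family,
        )
        return choice_probability(sv, 1.0, beta)

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean per-trial log-likelihood at the posterior point estimates."""
        p = self.predict_proba(X[X["choice"] != "omission"])
        yv = (X.loc[X["choice"] != "omission", "choice"] == "costly").to_numpy()
        return float(np.mean(np.log(np.where(yv, p, 1.0 - p))))

    def _check_fitted(self) -> PosteriorFit:
        if not hasattr(self, "fit_"):
            raise RuntimeError("model is not fitted")
        return self.fit_


def fit_model(
    dataset: pd.DataFrame,
    spec: ModelSpec | str,
    priors: PriorSpec | None = None,
    config: McmcConfig | None = None,
    cost_coding: str = "level",
) -> PosteriorFit:
    """Functional wrapper over :class:`HierarchicalDiscountingModel`."""
    config = config or McmcConfig()
    est = HierarchicalDiscountingModel(
        model=spec if isinstance(spec, str) else spec.name,
        chains=config.chains,
        iterations=config.iterations,
        warmup=config.warmup,
        seed=config.seed,
        priors=priors,
        cost_coding=cost_coding,
    )
    est.fit(dataset)
    return est.fit_


def subject_point_estimates(fit: PosteriorFit) -> pd.DataFrame:
    """Posterior-mean subject parameters on the constrained scale."""
    k = fit.draws["k"].mean(axis=(0, 1))  # (S, 2)
    beta = fit.draws["beta"].mean(axis=(0, 1))
    df = pd.DataFrame(
        {
            "participant": fit.subjects,
            "task": fit.task.value,
            "k_self": k[:, 0],
            "k_env": k[:, 1],
            "beta_self": beta[:, 0],
            "beta_env": beta[:, 1],
        }
    )
    df.attrs["spec"] = fit.spec.name
    df.attrs["k_structure"] = fit.spec.k_structure
    return df
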