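"""Hierarchical Bayesian estimation of the bandit models.

One group of subjects is fitted jointly: each free parameter has a
population (hyper) mean and SD on an unconstrained scale, subject-level
values are non-centered offsets (theta_i = mu + sigma * z_i), and a
probit-style transform maps the real line into each parameter's admissible
range (unit interval for learning rates / decay / lapse; [0, bound] for the
sensitivities, bound 30 by default).

Two fitting paths share the same posterior definition:

``method="mcmc"``
    Blocked adaptive Metropolis-within-Gibbs: all subject blocks update in
    parallel from one batched likelihood evaluation with Laplace-
    preconditioned proposals, the hypermeans by exact conjugate Gibbs
    draws, the hyper-SDs by scalar Metropolis; ``n_chains`` independent
    chains, ``n_samples`` thinned kept draws each.
``method="approx"``
    A fast deterministic approximation for screening and test-suite speed:
    penalized maximum likelihood per subject inside a small EM loop with
    moment-matched hyperparameters, then Laplace draws around the per-
    subject modes.  MCMC is the reference path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.optimize import minimize

from .models import (
    ChoiceDataset,
    InvalidDataError,
    InvalidParameterError,
    ModelSpec,
    batch_log_likelihood,
)

__all__ = [
    "HierarchicalPrior",
    "SamplerConfig",
    "PosteriorDraws",
    "HierarchicalBanditModel",
    "BanditResults",
    "fit_group",
    "map_to_constrained",
    "map_to_unconstrained",
    "summarize",
]

_CLIP = 1e-13


def map_to_constrained(u: np.ndarray, bound: float = 1.0) -> np.ndarray:
    """Probit-style map from the real line onto (0, bound)."""
    return bound * ndtr(np.asarray(u, dtype=float))


def map_to_unconstrained(x: np.ndarray, bound: float = 1.0) -> np.ndarray:
    """Inverse of :func:`map_to_constrained` (round-trips to ~1e-10)."""
    p = np.clip(np.asarray(x, dtype=float) / bound, _CLIP, 1.0 - _CLIP)
    return ndtri(p)


@dataclass(frozen=True)
class HierarchicalPrior:
    """Priors on the unconstrained scale (convention-based; not printed in
    the study): hypermeans ~ Normal(loc, scale), hyper-SDs ~ HalfNormal.
    """

    hypermean_loc: float = 0.0
    hypermean_scale: float = 1.0
    hypersd_scale: float = 1.0
    sensitivity_bound: float = 30.0

    def bounds_for(self, spec: ModelSpec) -> np.ndarray:
        return np.array([
            self.sensitivity_bound if name in ("R", "P") else 1.0
            for name in spec.free_parameters
        ])


@dataclass(frozen=True)
class SamplerConfig:
    """Sampling protocol: four chains of 2000 kept draws after 1000 warmup
    by default.  ``target_accept`` is accepted for API compatibility with
    gradient-based backends; the Metropolis-within-Gibbs sampler adapts
    its own proposal scales and does not use it.
    """

    n_chains: int = 4
    n_warmup: int = 1000
    n_samples: int = 2000
    seed: int = 0
    target_accept: float = 0.8

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_warmup < 0 or self.n_samples < 1:
            raise InvalidParameterError("chain/draw counts must be positive")


@dataclass
class PosteriorDraws:
    """Posterior draws plus pointwise log-likelihood and diagnostics.

    ``subject`` is on the constrained scale; ``hyper_mu``/``hyper_sigma``
    on the unconstrained scale.  ``pointwise_loglik`` is draws x (subjects
    * trials), subject-major — the per-trial unit used for LOO.
    """

    param_names: tuple[str, ...]
    subject_ids: tuple[str, ...]
    bounds: np.ndarray                 # (K,)
    hyper_mu: np.ndarray               # (D, K)
    hyper_sigma: np.ndarray            # (D, K)
    subject: np.ndarray                # (D, S, K) constrained
    chain: np.ndarray                  # (D,) chain index
    pointwise_loglik: np.ndarray       # (D, S*T)
    n_trials: int
    diagnostics: dict = field(default_factory=dict)
    group_label: str = ""

    @property
    def n_draws(self) -> int:
        return int(self.hyper_mu.shape[0])

    @property
    def n_subjects(self) -> int:
        return int(self.subject.shape[1])

    def _k(self, parameter: str) -> int:
        try:
            return self.param_names.index(parameter)
        except ValueError:
            raise KeyError(
                f"parameter {parameter!r} not in posterior ({', '.join(self.param_names)})")

    def population_mean_draws(self, parameter: str) -> np.ndarray:
        """Constrained-scale population mean per draw.

        With theta = bound * Phi(mu + sigma Z), Z ~ N(0,1), the population
        mean is bound * Phi(mu / sqrt(1 + sigma^2)) (closed form).
        Derived composites: alpha = (lr_r + lr_p)/2, beta = (lr_r - lr_p)/2.
        """
        if parameter == "alpha":
            return 0.5 * (self.population_mean_draws("lr_r") + self.population_mean_draws("lr_p"))
        if parameter == "beta":
            return 0.5 * (self.population_mean_draws("lr_r") - self.population_mean_draws("lr_p"))
        k = self._k(parameter)
        mu, sig = self.hyper_mu[:, k], self.hyper_sigma[:, k]
        return self.bounds[k] * ndtr(mu / np.sqrt(1.0 + sig**2))

    def population_sd_draws(self, parameter: str) -> np.ndarray:
        """Constrained-scale population SD per draw (Gauss-Hermite)."""
        k = self._k(parameter)
        mu, sig = self.hyper_mu[:, k], self.hyper_sigma[:, k]
        nodes, weights = np.polynomial.hermite_e.hermegauss(31)
        w = weights / weights.sum()
        theta = self.bounds[k] * ndtr(mu[:, None] + sig[:, None] * nodes[None, :])
        m1 = theta @ w
        m2 = (theta**2) @ w
        return np.sqrt(np.maximum(m2 - m1**2, 0.0))

    def subject_mean(self, parameter: str) -> np.ndarray:
        """Posterior-mean subject-level values, constrained scale, (S,)."""
        if parameter == "alpha":
            return 0.5 * (self.subject_mean("lr_r") + self.subject_mean("lr_p"))
        if parameter == "beta":
            return 0.5 * (self.subject_mean("lr_r") - self.subject_mean("lr_p"))
        return self.subject[:, :, self._k(parameter)].mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: draw, chain, parameter, value (hyper level)."""
        rows = []
        for k, name in enumerate(self.param_names):
            rows.append(pd.DataFrame({
                "draw": np.arange(self.n_draws), "chain": self.chain,
                "parameter": f"mu_{name}", "value": self.hyper_mu[:, k]}))
            rows.append(pd.DataFrame({
                "draw": np.arange(self.n_draws), "chain": self.chain,
                "parameter": f"sigma_{name}", "value": self.hyper_sigma[:, k]}))
            rows.append(pd.DataFrame({
                "draw": np.arange(self.n_draws), "chain": self.chain,
                "parameter": f"pop_mean_{name}", "value": self.population_mean_draws(name)}))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# data packing and the joint log-posterior
# ---------------------------------------------------------------------------

def _stack(datasets: Sequence[ChoiceDataset]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(datasets) < 2:
        raise InvalidDataError("hierarchical fit needs at least 2 subjects")
    T = datasets[0].n_trials
    for ds in datasets:
        if ds.n_trials != T:
            raise InvalidDataError(
                f"all subjects must share the task shape; {ds.subject_id} has {ds.n_trials} trials")
    choice0 = np.stack([ds.choice - 1 for ds in datasets])
    win = np.stack([ds.win for ds in datasets]).astype(float)
    loss = np.stack([ds.loss for ds in datasets]).astype(float)
    return choice0, win, loss


def _split_params(spec: ModelSpec, constrained: np.ndarray) -> dict[str, np.ndarray]:
    """(..., S, K) constrained array -> engine keyword arrays of (..., S)."""
    names = spec.free_parameters
    out = {name: constrained[..., i] for i, name in enumerate(names)}
    return {
        "R": out["R"], "P": out["P"], "lr_r": out["lr_r"], "lr_p": out["lr_p"],
        "d": out.get("d", 0.0), "xi": out.get("xi", 0.0),
    }


class _LogPosterior:
    """Vectorized joint log-posterior over walker batches."""

    def __init__(self, spec, prior, choice0, win, loss, prior_only=False):
        self.spec = spec
        self.prior = prior
        self.choice0, self.win, self.loss = choice0, win, loss
        self.S = choice0.shape[0]
        self.K = len(spec.free_parameters)
        self.bounds = prior.bounds_for(spec)
        self.ndim = self.K * (2 + self.S)
        self.prior_only = prior_only

    def unpack(self, theta: np.ndarray):
        K, S = self.K, self.S
        mu = theta[..., :K]
        log_sig = theta[..., K:2 * K]
        z = theta[..., 2 * K:].reshape(theta.shape[:-1] + (S, K))
        return mu, log_sig, z

    def constrained_subjects(self, theta: np.ndarray) -> np.ndarray:
        mu, log_sig, z = self.unpack(theta)
        raw = mu[..., None, :] + np.exp(log_sig)[..., None, :] * z
        return self.bounds * ndtr(raw)

    def log_lik(self, theta: np.ndarray, pointwise: bool = False) -> np.ndarray:
        con = self.constrained_subjects(theta)
        kw = _split_params(self.spec, con)
        ll = batch_log_likelihood(self.spec, self.choice0, self.win, self.loss,
                                  pointwise=pointwise, **kw)
        return ll

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        mu, log_sig, z = self.unpack(theta)
        sig = np.exp(log_sig)
        pr = self.prior
        lp = (-0.5 * ((mu - pr.hypermean_loc) / pr.hypermean_scale) ** 2).sum(axis=-1)
        lp += (-0.5 * (sig / pr.hypersd_scale) ** 2 + log_sig).sum(axis=-1)  # half-normal + Jacobian
        lp += (-0.5 * z**2).sum(axis=(-1, -2))
        if not self.prior_only:
            lp += self.log_lik(theta).sum(axis=-1)
        return lp


# ---------------------------------------------------------------------------
# MCMC path
# ---------------------------------------------------------------------------

def _run_mwg(
    lp: _LogPosterior, cfg: SamplerConfig, raw0: np.ndarray, chol0: np.ndarray,
    H0: np.ndarray, thin: int = 25, reps: int = 4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Blocked adaptive Metropolis-within-Gibbs on the hierarchical posterior.

    Subject parameter blocks are conditionally independent given the
    hyperparameters, so all subjects are proposed and accepted/rejected in
    parallel from one batched likelihood evaluation, using per-subject
    Laplace-preconditioned Gaussian proposals with scales adapted during
    warmup (target acceptance ~0.3).  The hypermean update is an exact
    conjugate Gibbs draw; the hyper-SD moves by scalar Metropolis on the
    log scale.  Returns (mu_draws, sigma_draws, raw_draws, diagnostics)
    with ``n_chains * n_samples`` kept draws (thinned).

    Hyper-level mixing along likelihood ridges (e.g. sensitivity vs
    learning-rate trade-offs) is helped by an additional global
    translation move: all subject raws and the hypermean shift together
    by a draw from the subjects' average Laplace covariance, which leaves
    the subject-deviation prior invariant.
    """
    import arviz as az

    S, K = lp.S, lp.K
    pr = lp.prior
    # precision-averaged covariance of a coherent all-subject move: the sum
    # of Hessians is the curvature such a translation actually feels
    cov_bar = np.linalg.inv(H0.sum(axis=0) + 1e-9 * np.eye(K))
    chol_bar = np.linalg.cholesky(cov_bar)
    keep_mu = np.empty((cfg.n_chains, cfg.n_samples, K))
    keep_sig = np.empty((cfg.n_chains, cfg.n_samples, K))
    keep_raw = np.empty((cfg.n_chains, cfg.n_samples, S, K))
    accept_stats = []

    def loglik_of(raw: np.ndarray) -> np.ndarray:
        con = lp.bounds * ndtr(raw[None])
        kw = _split_params(lp.spec, con)
        if lp.prior_only:
            return np.zeros(S)
        return batch_log_likelihood(lp.spec, lp.choice0, lp.win, lp.loss, **kw)[0]

    for c in range(cfg.n_chains):
        rng = np.random.default_rng((cfg.seed + 7919 * (c + 1)) % (2**31))
        raw = raw0 + 0.5 * np.einsum("skl,sl->sk", chol0, rng.standard_normal((S, K)))
        mu = raw.mean(axis=0)
        sigma = np.maximum(raw.std(axis=0, ddof=1), 0.2)
        ll = loglik_of(raw)
        scale = np.full(S, 0.5)
        sig_scale = np.full(K, 0.4)
        g_scale = 1.0
        nc_scale = np.full(K, 0.2)
        acc_s = np.zeros(S)
        acc_k = np.zeros(K)
        acc_g = 0.0
        acc_nc = np.zeros(K)
        n_adapt = 0
        mu_hist: list[np.ndarray] = []

        warmup = max(3000, cfg.n_warmup)
        total = warmup + thin * cfg.n_samples
        kept = 0
        for sweep in range(total):
            # --- all-subject Metropolis block (several reps per sweep) ---
            for _ in range(reps):
                eps = rng.standard_normal((S, K))
                prop = raw + scale[:, None] * np.einsum("skl,sl->sk", chol0, eps)
                ll_prop = loglik_of(prop)
                dprior = (0.5 * (((raw - mu) / sigma) ** 2).sum(axis=1)
                          - 0.5 * (((prop - mu) / sigma) ** 2).sum(axis=1))
                logr = ll_prop - ll + dprior
                acc = np.log(rng.random(S)) < logr
                raw[acc] = prop[acc]
                ll[acc] = ll_prop[acc]
                acc_s += acc

            # --- global translation move (subjects + hypermean together) ---
            for _ in range(2):
                g = g_scale * (chol_bar @ rng.standard_normal(K))
                prop = raw + g
                ll_prop = loglik_of(prop)
                mu_prop = mu + g
                dmu = (0.5 * (((mu - pr.hypermean_loc) / pr.hypermean_scale) ** 2).sum()
                       - 0.5 * (((mu_prop - pr.hypermean_loc) / pr.hypermean_scale) ** 2).sum())
                logr_g = (ll_prop - ll).sum() + dmu
                if np.log(rng.random()) < logr_g:
                    raw = prop
                    mu = mu_prop
                    ll = ll_prop
                    acc_g += 1.0

            # --- conjugate hypermean Gibbs draw ---
            prec = S / sigma**2 + 1.0 / pr.hypermean_scale**2
            mean = (raw.sum(axis=0) / sigma**2
                    + pr.hypermean_loc / pr.hypermean_scale**2) / prec
            mu = mean + rng.standard_normal(K) / np.sqrt(prec)

            # --- interweaved non-centered update of (mu_k, log sigma_k):
            # subject z-scores stay fixed while the hyper pair moves, so the
            # hyper-SD can mix even when the centered Gibbs step stalls ---
            for k in list(range(K)) * 2:
                zk = (raw[:, k] - mu[k]) / sigma[k]
                mu_p = mu[k] + nc_scale[k] * rng.standard_normal()
                ls_p = np.log(sigma[k]) + nc_scale[k] * rng.standard_normal()
                sig_p = np.exp(ls_p)
                prop = raw.copy()
                prop[:, k] = mu_p + sig_p * zk
                ll_prop = loglik_of(prop)
                dlp = (-0.5 * ((mu_p - pr.hypermean_loc) / pr.hypermean_scale) ** 2
                       + 0.5 * ((mu[k] - pr.hypermean_loc) / pr.hypermean_scale) ** 2
                       - (sig_p**2 - sigma[k]**2) / (2 * pr.hypersd_scale**2)
                       + (ls_p - np.log(sigma[k])))
                if np.log(rng.random()) < (ll_prop - ll).sum() + dlp:
                    raw = prop
                    mu[k] = mu_p
                    sigma[k] = sig_p
                    ll = ll_prop
                    acc_nc[k] += 1.0

            # --- hyper-SD Metropolis on log(sigma) ---
            ls = np.log(sigma)
            ls_prop = ls + sig_scale * rng.standard_normal(K)
            sp = np.exp(ls_prop)
            ssq = ((raw - mu) ** 2).sum(axis=0)
            def _lp_ls(s, ls_val):
                return (-S * ls_val - ssq / (2 * s**2)
                        - s**2 / (2 * pr.hypersd_scale**2) + ls_val)
            logr_k = _lp_ls(sp, ls_prop) - _lp_ls(sigma, ls)
            acck = np.log(rng.random(K)) < logr_k
            sigma = np.where(acck, sp, sigma)
            acc_k += acck

            # --- warmup adaptation every 50 sweeps; the global-translation
            # covariance switches to the empirical hypermean covariance
            # (adaptive-Metropolis style) once enough history exists ---
            if sweep < warmup:
                mu_hist.append(mu.copy())
                if (sweep + 1) % 50 == 0:
                    scale *= np.exp(np.clip(acc_s / (50.0 * reps) - 0.3, -0.5, 0.5))
                    sig_scale *= np.exp(np.clip(acc_k / 50.0 - 0.4, -0.5, 0.5))
                    g_scale *= float(np.exp(np.clip(acc_g / 100.0 - 0.25, -0.5, 0.5)))
                    nc_scale *= np.exp(np.clip(acc_nc / 100.0 - 0.3, -0.5, 0.5))
                    acc_s[:] = 0
                    acc_k[:] = 0
                    acc_g = 0.0
                    acc_nc[:] = 0
                    n_adapt += 1
                    if len(mu_hist) >= 500 and n_adapt % 4 == 0:
                        emp = np.cov(np.asarray(mu_hist[-2000:]).T)
                        try:
                            chol_bar = np.linalg.cholesky(
                                emp * (2.38**2 / K) + 1e-8 * np.eye(K))
                            g_scale = 1.0
                        except np.linalg.LinAlgError:
                            pass
            if sweep >= warmup and (sweep - warmup) % thin == thin - 1:
                keep_mu[c, kept] = mu
                keep_sig[c, kept] = sigma
                keep_raw[c, kept] = raw
                kept += 1
        denom = max((total - warmup) * reps, 1)
        accept_stats.append(float(np.mean(acc_s) / denom))

    hyper = np.concatenate([keep_mu, np.log(keep_sig)], axis=2)  # (chains, draws, 2K)
    ds = az.convert_to_dataset(hyper)
    ess = az.ess(ds)["x"].values
    if cfg.n_chains >= 2:
        rhat = az.rhat(ds)["x"].values
        max_rhat = float(np.nanmax(rhat))
    else:
        rhat = np.full(2 * K, np.nan)
        max_rhat = float("nan")
    diag = {
        "rhat": rhat.tolist(), "max_rhat": max_rhat,
        "ess": ess.tolist(), "min_ess": float(np.nanmin(ess)),
        "acceptance_fraction": accept_stats, "divergences": 0,
        "converged": bool(max_rhat <= 1.05) if np.isfinite(max_rhat) else False,
        "method": "mcmc",
    }
    D = cfg.n_chains * cfg.n_samples
    return (keep_mu.reshape(D, K), keep_sig.reshape(D, K),
            keep_raw.reshape(D, S, K), diag)


# ---------------------------------------------------------------------------
# fast deterministic approximation
# ---------------------------------------------------------------------------

def _default_starts(lp: _LogPosterior) -> list[np.ndarray]:
    """A few structured starting points on the unconstrained scale; the
    lapse/sensitivity trade-off is multimodal, so low-lapse and low-
    sensitivity starts are both tried."""
    S, K = lp.S, lp.K
    names = lp.spec.free_parameters
    base = np.zeros(K)
    for k, name in enumerate(names):
        if name == "xi":
            base[k] = -1.5          # xi ~ 0.07: start nearly lapse-free
        elif name in ("R", "P"):
            base[k] = -0.5          # sensitivity ~ 9
    starts = [np.tile(base, (S, 1))]
    alt = base.copy()
    for k, name in enumerate(names):
        if name in ("R", "P"):
            alt[k] = -1.2           # sensitivity ~ 3.5
    starts.append(np.tile(alt, (S, 1)))
    starts.append(np.zeros((S, K)))
    return starts


def _penalized_objective(lp: _LogPosterior, raw: np.ndarray, mu, sigma) -> np.ndarray:
    con = lp.bounds * ndtr(raw[None])
    kw = _split_params(lp.spec, con)
    ll = batch_log_likelihood(lp.spec, lp.choice0, lp.win, lp.loss, **kw)[0]
    return -ll + 0.5 * (((raw - mu) / sigma) ** 2).sum(axis=-1)


def _penalized_map(lp: _LogPosterior, n_em: int = 3, maxiter: int = 120):
    """EM-style loop: block penalized-ML for subject raws (multi-start,
    per-subject best; the objective separates over subjects) with
    moment-matched hyperparameters.  Returns (mu_hat, sigma_hat, raw_hat)."""
    S, K = lp.S, lp.K
    mu = np.zeros(K)
    sigma = np.ones(K)
    h = 1e-4

    def f_and_grad(x: np.ndarray):
        r = x.reshape(S, K)
        pts = np.repeat(r[None], 2 * K + 1, axis=0)           # (2K+1, S, K)
        for k in range(K):
            pts[1 + k, :, k] += h
            pts[1 + K + k, :, k] -= h
        con = lp.bounds * ndtr(pts)
        kw = _split_params(lp.spec, con)
        ll = batch_log_likelihood(lp.spec, lp.choice0, lp.win, lp.loss, **kw)  # (2K+1, S)
        pen = 0.5 * (((r - mu) / sigma) ** 2).sum()
        f = -ll[0].sum() + pen
        g_ll = np.empty((S, K))
        for k in range(K):
            g_ll[:, k] = -(ll[1 + k] - ll[1 + K + k]) / (2 * h)
        g = g_ll + (r - mu) / sigma**2
        return f, g.ravel()

    def optimize(start: np.ndarray) -> np.ndarray:
        res = minimize(f_and_grad, start.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter})
        return res.x.reshape(S, K)

    raw = None
    for it in range(n_em):
        starts = _default_starts(lp) if it == 0 else [raw] + _default_starts(lp)[:1]
        sols = [optimize(s) for s in starts]
        objs = np.stack([_penalized_objective(lp, s, mu, sigma) for s in sols])
        pick = objs.argmin(axis=0)
        raw = np.stack([sols[pick[i]][i] for i in range(S)])
        mu = raw.mean(axis=0)
        dev = raw - mu
        sigma = np.sqrt(((dev**2).sum(axis=0) + 0.25) / (S + 1))  # regularized moments
    return mu, sigma, raw


def _subject_hessians(lp: _LogPosterior, raw: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Per-subject Hessians of the negative log posterior at the mode,
    by batched finite differences of the likelihood plus the analytic
    Gaussian-prior curvature."""
    S, K = lp.S, lp.K
    h = 5e-3
    pts = [raw.copy()]
    index = {}
    for j in range(K):
        for sgn in (+1, -1):
            p = raw.copy(); p[:, j] += sgn * h
            index[(j, sgn)] = len(pts); pts.append(p)
    for j in range(K):
        for k in range(j + 1, K):
            for sj, sk in ((1, 1), (-1, -1), (1, -1), (-1, 1)):
                p = raw.copy(); p[:, j] += sj * h; p[:, k] += sk * h
                index[(j, k, sj, sk)] = len(pts); pts.append(p)
    pts = np.stack(pts)                                       # (B, S, K)
    con = lp.bounds * ndtr(pts)
    kw = _split_params(lp.spec, con)
    ll = batch_log_likelihood(lp.spec, lp.choice0, lp.win, lp.loss, **kw)  # (B, S)
    f = -ll
    H = np.empty((S, K, K))
    for j in range(K):
        H[:, j, j] = (f[index[(j, 1)]] + f[index[(j, -1)]] - 2 * f[0]) / h**2
        for k in range(j + 1, K):
            v = (f[index[(j, k, 1, 1)]] + f[index[(j, k, -1, -1)]]
                 - f[index[(j, k, 1, -1)]] - f[index[(j, k, -1, 1)]]) / (4 * h**2)
            H[:, j, k] = H[:, k, j] = v
    H += np.diag(1.0 / sigma**2)
    return H


def _laplace_chol(lp: _LogPosterior, raw: np.ndarray, sigma: np.ndarray):
    """Per-subject proposal factors: Cholesky of PD-repaired inverse
    Hessians, plus the PD-repaired Hessians themselves (for precision-
    averaged global moves)."""
    H = _subject_hessians(lp, raw, sigma)
    chol = np.empty_like(H)
    Hpd = np.empty_like(H)
    for i in range(lp.S):
        w, V = np.linalg.eigh(H[i])
        # saddle-free repair: finite differences at sharp modes can flip the
        # sign of large curvatures, so use |eigenvalue| with a floor no
        # looser than the hierarchical prior precision
        w = np.maximum(np.abs(w), 0.5)
        Hpd[i] = (V * w) @ V.T
        chol[i] = np.linalg.cholesky((V / w) @ V.T)
    return chol, Hpd


def _run_approx(lp: _LogPosterior, cfg: SamplerConfig):
    S, K = lp.S, lp.K
    mu, sigma, raw = _penalized_map(lp)
    chol, _ = _laplace_chol(lp, raw, sigma)
    # measurement-error correction: the spread of per-subject modes mixes
    # true population spread with estimation noise; subtract the average
    # Laplace variance so the population SD is not inflated (which would
    # drag probit-mapped population means toward the mid-range).  The
    # hypermean's standard error still carries both components.
    noise_var = np.einsum("skl,skl->sk", chol, chol).mean(axis=0)
    total_sd = np.sqrt(sigma**2 + noise_var)
    sigma = np.sqrt(np.maximum(sigma**2 - noise_var, 0.25 / (S + 1)))

    D = cfg.n_chains * cfg.n_samples
    rng = np.random.default_rng(cfg.seed)
    sig_draws = sigma * np.sqrt((S - 1) / rng.chisquare(S - 1, size=(D, K)))
    mu_scale = total_sd * np.sqrt((S - 1) / rng.chisquare(S - 1, size=(D, K)))
    mu_draws = mu + mu_scale / np.sqrt(S) * rng.standard_normal((D, K))
    eps = rng.standard_normal((D, S, K))
    raw_draws = raw + np.einsum("skl,dsl->dsk", chol, eps)

    chain_id = np.repeat(np.arange(cfg.n_chains), cfg.n_samples)
    diag = {"converged": True, "method": "approx", "divergences": 0,
            "max_rhat": 1.0, "note": "penalized-ML + Laplace approximation"}
    return mu_draws, sig_draws, chain_id, diag, raw_draws


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------

def fit_group(
    datasets: Sequence[ChoiceDataset],
    spec: ModelSpec | int,
    prior: HierarchicalPrior | None = None,
    config: SamplerConfig | None = None,
    method: str = "mcmc",
    prior_only: bool = False,
    group_label: str | None = None,
) -> PosteriorDraws:
    """Fit one group hierarchically; returns posterior draws with pointwise
    log-likelihood per trial (the LOO unit) and convergence diagnostics."""
    if isinstance(spec, int):
        spec = ModelSpec.from_id(spec)
    prior = prior or HierarchicalPrior()
    config = config or SamplerConfig()
    choice0, win, loss = _stack(datasets)
    lp = _LogPosterior(spec, prior, choice0, win, loss, prior_only=prior_only)
    S, K = lp.S, lp.K

    if method == "mcmc":
        if prior_only:
            raw0 = np.zeros((S, K))
            chol0 = np.tile(np.eye(K), (S, 1, 1))
            H0 = np.tile(np.eye(K), (S, 1, 1))
        else:
            mu0, sigma0, raw0 = _penalized_map(lp)
            chol0, H0 = _laplace_chol(lp, raw0, sigma0)
        mu, sigma, raw_draws, diag = _run_mwg(lp, config, raw0, chol0, H0)
        chain_id = np.repeat(np.arange(config.n_chains), config.n_samples)
        subj_con = lp.bounds * ndtr(raw_draws)
    elif method == "approx":
        if prior_only:
            raise InvalidParameterError("prior_only sampling requires method='mcmc'")
        mu, sigma, chain_id, diag, raw_draws = _run_approx(lp, config)
        subj_con = lp.bounds * ndtr(raw_draws)
    else:
        raise InvalidParameterError(f"unknown method {method!r}")

    D = mu.shape[0]
    if prior_only:
        pw = np.zeros((D, S * choice0.shape[1]))
    else:
        kw = _split_params(spec, subj_con)
        pw = batch_log_likelihood(spec, choice0, win, loss, pointwise=True, **kw)
        pw = pw.reshape(D, S * choice0.shape[1])

    label = group_label if group_label is not None else (datasets[0].group_label or "")
    return PosteriorDraws(
        param_names=spec.free_parameters,
        subject_ids=tuple(ds.subject_id for ds in datasets),
        bounds=lp.bounds,
        hyper_mu=mu, hyper_sigma=sigma, subject=subj_con,
        chain=chain_id, pointwise_loglik=pw,
        n_trials=choice0.shape[1],
        diagnostics=diag, group_label=label,
    )


def summarize(draws: PosteriorDraws, hdi_mass: float = 0.95) -> pd.DataFrame:
    """Group-level parameter table: population mean and SD per parameter
    (posterior means), with the posterior SD and HDI of the population
    mean.  Coupled-model composites (alpha, beta) are derived per draw."""
    from .contrasts import hdi

    names = list(draws.param_names)
    if "lr_r" in names and "lr_p" in names:
        names += ["alpha", "beta"]
    rows = []
    for name in names:
        m = draws.population_mean_draws(name)
        lo, hi = hdi(m, hdi_mass)
        row = {
            "parameter": name,
            "mean": float(m.mean()),
            "post_sd": float(m.std(ddof=1)),
            f"hdi_{hdi_mass:.0%}_low": lo,
            f"hdi_{hdi_mass:.0%}_high": hi,
        }
        if name in draws.param_names:
            row["sd"] = float(draws.population_sd_draws(name).mean())
        else:
            row["sd"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# statsmodels-style front end
# ---------------------------------------------------------------------------

class HierarchicalBanditModel:
    """Hierarchical bandit model for one group of subjects.

    Examples
    --------
    >>> model = HierarchicalBanditModel(datasets, model_id=1)   # doctest: +SKIP
    >>> res = model.fit(SamplerConfig(n_chains=2, n_warmup=500, n_samples=500))
    >>> res.summary()
    """

    def __init__(
        self,
        datasets: Sequence[ChoiceDataset],
        model_id: int = 1,
        prior: HierarchicalPrior | None = None,
    ):
        self.datasets = list(datasets)
        self.spec = ModelSpec.from_id(model_id)
        self.prior = prior or HierarchicalPrior()
        _stack(self.datasets)  # validate early

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, model_id: int = 1, group: str | None = None,
        prior: HierarchicalPrior | None = None,
    ) -> "HierarchicalBanditModel":
        """Build from a tidy behaviour table (subject, group, run, trial,
        choice, win, loss[, onsets]), optionally restricted to one group."""
        if group is not None:
            df = df[df["group"] == group]
        datasets = []
        for sid, sub in df.groupby("subject", sort=True):
            glabel = str(sub["group"].iloc[0]) if "group" in sub.columns else ""
            datasets.append(ChoiceDataset.from_dataframe(sub, subject_id=str(sid),
                                                         group_label=glabel))
        return cls(datasets, model_id=model_id, prior=prior)

    def fit(self, config: SamplerConfig | None = None, method: str = "mcmc",
            prior_only: bool = False) -> "BanditResults":
        draws = fit_group(self.datasets, self.spec, self.prior, config,
                          method=method, prior_only=prior_only)
        return BanditResults(self, draws)


class BanditResults:
    """Fit results: posterior draws, summaries, LOO, diagnostics."""

    def __init__(self, model: HierarchicalBanditModel, draws: PosteriorDraws):
        self.model = model
        self.spec = model.spec
        self.draws = draws

    @property
    def diagnostics(self) -> dict:
        return self.draws.diagnostics

    @property
    def converged(self) -> bool:
        return bool(self.draws.diagnostics.get("converged", False))

    def summary(self, hdi_mass: float = 0.95) -> pd.DataFrame:
        return summarize(self.draws, hdi_mass)

    def loo(self):
        from .comparison import psis_loo
        return psis_loo(self.draws.pointwise_loglik, chain=self.draws.chain)

    def save(self, directory) -> None:
        """Persist draws as a tidy CSV, a compact npz cache, and a JSON
        diagnostics report."""
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        tag = f"model{self.spec.model_id}_{self.draws.group_label or 'group'}"
        self.draws.to_frame().to_csv(d / f"draws_{tag}.csv", index=False)
        np.savez_compressed(
            d / f"draws_{tag}.npz",
            hyper_mu=self.draws.hyper_mu, hyper_sigma=self.draws.hyper_sigma,
            subject=self.draws.subject, chain=self.draws.chain,
            pointwise_loglik=self.draws.pointwise_loglik,
            bounds=self.draws.bounds,
            param_names=np.array(self.draws.param_names),
            subject_ids=np.array(self.draws.subject_ids),
        )
        with open(d / f"diagnostics_{tag}.json", "w") as fh:
            json.dump(self.draws.diagnostics, fh, indent=2)
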