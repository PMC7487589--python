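"""Gibbs sampler for the gamma-negative binomial factor model.

One iteration applies, in order,

    (ell, r)  ->  omega  ->  beta  ->  delta  ->  phi  ->  theta
              ->  (alpha, eta, gamma)  ->  h

where ell are CRT auxiliary counts, omega are Polya-Gamma auxiliary variables,
and every coefficient/factor block has a multivariate-normal full conditional
thanks to the augmentation.  The logit matrix psi is recomputed from the
freshest parameters before each conditional that needs it.

The precision updates follow the standard normal-gamma conjugacy: each ARD
precision gets shape e0 + (#coefficients)/2 and rate f0 + (sum of squared
coefficients)/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .augmentation import PG_DEFAULT_TRUNC, sample_crt, sample_pg
from .model import (
    CountMatrix,
    CovariateSet,
    Hyperparams,
    ModelState,
    compute_psi,
    nb_log_likelihood,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AugmentedState",
    "PosteriorTrace",
    "update_dispersion",
    "update_pg",
    "update_beta",
    "update_delta",
    "update_phi",
    "update_theta",
    "update_precisions",
    "update_h",
    "gibbs_sweep",
    "run_gibbs",
]


@dataclass
class AugmentedState:
    """Auxiliary variables of one sweep: CRT counts ell and PG draws omega."""

    ell: np.ndarray
    omega: np.ndarray


@dataclass
class PosteriorTrace:
    """Recorded MCMC output.

    ``states`` holds one snapshot per recorded iteration, ``log_likelihood``
    the NB data log-likelihood of each, and ``log_posterior`` the joint
    (unnormalized) log posterior density.  ``point_estimate`` is the
    post-burn-in snapshot with the largest data log-likelihood.
    """

    states: list[ModelState]
    log_likelihood: np.ndarray
    log_posterior: np.ndarray
    burn_in: int
    thin: int = 1
    point_estimate: ModelState = field(default=None)  # type: ignore[assignment]
    point_estimate_iteration: int = -1

    def __len__(self) -> int:
        return len(self.states)

    def select_point_estimate(self, criterion: str = "likelihood") -> ModelState:
        """Max-'likelihood' (or 'posterior') snapshot among post-burn-in samples."""
        values = self.log_likelihood if criterion == "likelihood" else self.log_posterior
        first = self.burn_in // self.thin
        if first >= len(self.states):
            raise ValueError("no post-burn-in samples recorded")
        idx = first + int(np.argmax(values[first:]))
        self.point_estimate = self.states[idx]
        self.point_estimate_iteration = idx * self.thin
        return self.point_estimate


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def update_dispersion(
    counts: np.ndarray,
    state: ModelState,
    psi: np.ndarray,
    hyper: Hyperparams,
    rng: np.random.Generator,
) -> np.ndarray:
    """CRT-augmented update of the cell dispersions r_j.

    ell_vj ~ CRT(n_vj, r_j), then
    r_j ~ Gamma(e0 + sum_v ell_vj,  rate  h - sum_v log(1 - p_vj)).
    Returns the drawn ell matrix; mutates ``state.r`` in place.
    """
    ell = sample_crt(counts, state.r[None, :], rng)
    shape = hyper.e0 + ell.sum(axis=0)
    # -log(1 - p) = softplus(psi)
    rate = state.h + _softplus(psi).sum(axis=0)
    state.r = np.maximum(rng.gamma(shape, 1.0 / rate), 1e-300)
    if not np.all(np.isfinite(state.r)) or np.any(state.r <= 0):
        raise FloatingPointError("non-finite or non-positive dispersion draw")
    return ell


def update_pg(
    counts: np.ndarray,
    state: ModelState,
    psi: np.ndarray,
    rng: np.random.Generator,
    trunc: int = PG_DEFAULT_TRUNC,
) -> np.ndarray:
    """omega_vj ~ PG(n_vj + r_j, psi_vj)."""
    return sample_pg(counts + state.r[None, :], psi, rng, trunc=trunc)


def _sample_mvn_batch(
    precision: np.ndarray, lin: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw x_i ~ N(P_i^{-1} b_i, P_i^{-1}) for a stack of precision matrices.

    ``precision``: (N, D, D), ``lin``: (N, D).  Uses a batched Cholesky
    P = L L^T; mean from two triangular solves, noise via L^{-T} z.
    """
    try:
        L = np.linalg.cholesky(precision)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - alpha,eta,gamma > 0
        raise FloatingPointError(f"conditional precision not positive-definite: {exc}")
    # mean: solve L y = b, then L^T mu = y
    y = np.linalg.solve(L, lin[..., None])
    Lt = np.swapaxes(L, -1, -2)
    mu = np.linalg.solve(Lt, y)
    z = rng.standard_normal(lin.shape)[..., None]
    draw = mu + np.linalg.solve(Lt, z)
    return draw[..., 0]


def update_beta(
    counts: np.ndarray,
    state: ModelState,
    omega: np.ndarray,
    covariates: CovariateSet,
    rng: np.random.Generator,
) -> None:
    """Gene-wise coefficients on cell covariates.

    Precision  diag(alpha) + sum_j omega_vj x_j x_j^T; linear term uses the
    PG-augmented pseudo-data (n - r)/2 minus omega times the other psi parts.
    """
    X = covariates.X
    kappa = (counts - state.r[None, :]) / 2.0
    other = covariates.Z @ state.delta.T + state.phi @ state.theta.T  # (V, J)
    resid = kappa - omega * other
    prec = np.einsum("vj,jp,jq->vpq", omega, X, X)
    prec += np.diag(state.alpha)[None, :, :]
    lin = resid @ X  # (V, P)
    state.beta = _sample_mvn_batch(prec, lin, rng)


def update_delta(
    counts: np.ndarray,
    state: ModelState,
    omega: np.ndarray,
    covariates: CovariateSet,
    rng: np.random.Generator,
) -> None:
    """Cell-wise coefficients on gene covariates (mirror of update_beta)."""
    Z = covariates.Z
    kappa = (counts - state.r[None, :]) / 2.0
    other = state.beta @ covariates.X.T + state.phi @ state.theta.T  # (V, J)
    resid = kappa - omega * other  # (V, J)
    prec = np.einsum("vj,vq,vr->jqr", omega, Z, Z)
    prec += np.diag(state.eta)[None, :, :]
    lin = resid.T @ Z  # (J, Q)
    state.delta = _sample_mvn_batch(prec, lin, rng)


def update_phi(
    counts: np.ndarray,
    state: ModelState,
    omega: np.ndarray,
    covariates: CovariateSet,
    rng: np.random.Generator,
) -> None:
    """Factor loadings; prior N(0, I_K)."""
    theta = state.theta
    K = theta.shape[1]
    kappa = (counts - state.r[None, :]) / 2.0
    other = state.beta @ covariates.X.T + covariates.Z @ state.delta.T
    resid = kappa - omega * other
    prec = np.einsum("vj,jk,jl->vkl", omega, theta, theta)
    prec += np.eye(K)[None, :, :]
    lin = resid @ theta  # (V, K)
    state.phi = _sample_mvn_batch(prec, lin, rng)


def update_theta(
    counts: np.ndarray,
    state: ModelState,
    omega: np.ndarray,
    covariates: CovariateSet,
    rng: np.random.Generator,
) -> None:
    """Factor scores; prior N(0, diag(gamma)^{-1})."""
    phi = state.phi
    kappa = (counts - state.r[None, :]) / 2.0
    other = state.beta @ covariates.X.T + covariates.Z @ state.delta.T
    resid = kappa - omega * other  # (V, J)
    prec = np.einsum("vj,vk,vl->jkl", omega, phi, phi)
    prec += np.diag(state.gamma)[None, :, :]
    lin = resid.T @ phi  # (J, K)
    state.theta = _sample_mvn_batch(prec, lin, rng)


def update_precisions(state: ModelState, hyper: Hyperparams, rng: np.random.Generator) -> None:
    """ARD precisions via normal-gamma conjugacy.

    alpha_p ~ Gamma(e0 + V/2, rate f0 + sum_v beta_vp^2 / 2), and likewise
    eta_q, gamma_k with sums over cells.
    """
    V = state.beta.shape[0]
    J = state.delta.shape[0]
    state.alpha = rng.gamma(hyper.e0 + V / 2.0, 1.0 / (hyper.f0 + (state.beta**2).sum(axis=0) / 2.0))
    state.eta = rng.gamma(hyper.e0 + J / 2.0, 1.0 / (hyper.f0 + (state.delta**2).sum(axis=0) / 2.0))
    state.gamma = rng.gamma(hyper.e0 + J / 2.0, 1.0 / (hyper.f0 + (state.theta**2).sum(axis=0) / 2.0))
    for name in ("alpha", "eta", "gamma"):
        arr = np.maximum(getattr(state, name), 1e-300)
        setattr(state, name, arr)


def update_h(state: ModelState, hyper: Hyperparams, rng: np.random.Generator) -> None:
    """h ~ Gamma(e0 (1 + J), rate f0 + sum_j r_j), by gamma-gamma conjugacy."""
    J = state.r.shape[0]
    state.h = float(
        max(rng.gamma(hyper.e0 * (1.0 + J), 1.0 / (hyper.f0 + state.r.sum())), 1e-300)
    )


def log_prior(state: ModelState, hyper: Hyperparams) -> float:
    """Unnormalized joint log prior density of the current state."""
    from scipy.stats import gamma as gamma_dist

    e0, f0 = hyper.e0, hyper.f0
    lp = gamma_dist.logpdf(state.h, e0, scale=1.0 / f0)
    lp += gamma_dist.logpdf(state.r, e0, scale=1.0 / state.h).sum()
    for arr in (state.alpha, state.eta, state.gamma):
        lp += gamma_dist.logpdf(arr, e0, scale=1.0 / f0).sum()
    lp += float(
        -0.5 * (state.beta**2 * state.alpha[None, :]).sum()
        + 0.5 * state.beta.shape[0] * np.log(state.alpha).sum()
    )
    lp += float(
        -0.5 * (state.delta**2 * state.eta[None, :]).sum()
        + 0.5 * state.delta.shape[0] * np.log(state.eta).sum()
    )
    lp += float(-0.5 * (state.phi**2).sum())
    lp += float(
        -0.5 * (state.theta**2 * state.gamma[None, :]).sum()
        + 0.5 * state.theta.shape[0] * np.log(state.gamma).sum()
    )
    return float(lp)


def _check_finite(name: str, arr, iteration: int) -> None:
    if not np.all(np.isfinite(arr)):
        raise FloatingPointError(f"non-finite values in '{name}' at iteration {iteration}")


def gibbs_sweep(
    counts: np.ndarray,
    state: ModelState,
    covariates: CovariateSet,
    hyper: Hyperparams,
    rng: np.random.Generator,
    pg_trunc: int = PG_DEFAULT_TRUNC,
    iteration: int = 0,
) -> AugmentedState:
    """One full Gibbs iteration over all blocks; mutates ``state`` in place."""
    psi = compute_psi(state, covariates)
    ell = update_dispersion(counts, state, psi, hyper, rng)
    omega = update_pg(counts, state, psi, rng, trunc=pg_trunc)
    _check_finite("omega", omega, iteration)
    update_beta(counts, state, omega, covariates, rng)
    _check_finite("beta", state.beta, iteration)
    update_delta(counts, state, omega, covariates, rng)
    _check_finite("delta", state.delta, iteration)
    update_phi(counts, state, omega, covariates, rng)
    _check_finite("phi", state.phi, iteration)
    update_theta(counts, state, omega, covariates, rng)
    _check_finite("theta", state.theta, iteration)
    update_precisions(state, hyper, rng)
    _check_finite("alpha/eta/gamma", np.concatenate([state.alpha, state.eta, state.gamma]), iteration)
    update_h(state, hyper, rng)
    return AugmentedState(ell=ell, omega=omega)


def initial_state(
    V: int,
    J: int,
    P: int,
    Q: int,
    K: int,
    rng: np.random.Generator,
) -> ModelState:
    """Neutral start: r = 1, h = 1, coefficients 0, factors from unit-precision priors."""
    return ModelState(
        r=np.ones(J),
        beta=np.zeros((V, P)),
        delta=np.zeros((J, Q)),
        phi=rng.standard_normal((V, K)),
        theta=rng.standard_normal((J, K)),
        alpha=np.ones(P),
        eta=np.ones(Q),
        gamma=np.ones(K),
        h=1.0,
    )


def run_gibbs(
    counts: CountMatrix | np.ndarray,
    covariates: CovariateSet | None = None,
    hyper: Hyperparams | None = None,
    n_iter: int = 2000,
    burn_in: int = 1000,
    seed: int | np.random.Generator | None = None,
    thin: int = 1,
    pg_trunc: int = PG_DEFAULT_TRUNC,
    point_estimate_criterion: str = "likelihood",
) -> PosteriorTrace:
    """Run the full sampler and return the recorded trace.

    Parameters
    ----------
    counts : CountMatrix or (V, J) integer array, genes x cells.
    covariates : optional designs; defaults to intercept-only (P = Q = 1).
    hyper : hyper-parameters; defaults to e0 = f0 = 0.01, K = 2.
    n_iter, burn_in : total iterations and burn-in (n_iter > burn_in).
    thin : record every ``thin``-th state (log-likelihood recorded for all
        recorded states; burn-in bookkeeping accounts for thinning).
    point_estimate_criterion : 'likelihood' (NB data log-likelihood, default)
        or 'posterior' (joint unnormalized posterior density).

    The point estimate is the post-burn-in recorded state with the highest
    selected criterion.  Fully reproducible for a fixed integer seed.
    """
    if isinstance(counts, CountMatrix):
        n = counts.counts
    else:
        n = CountMatrix(np.asarray(counts)).counts
    V, J = n.shape
    hyper = hyper or Hyperparams()
    if covariates is None:
        covariates = CovariateSet.build(V, J)
    if covariates.X.shape[0] != J or covariates.Z.shape[0] != V:
        raise ValueError(
            f"covariate shapes X {covariates.X.shape} / Z {covariates.Z.shape} do not match "
            f"counts ({V} genes x {J} cells)"
        )
    if n_iter <= burn_in or burn_in < 0:
        raise ValueError(f"need n_iter > burn_in >= 0, got n_iter={n_iter}, burn_in={burn_in}")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    P, Q, K = covariates.X.shape[1], covariates.Z.shape[1], hyper.K
    state = initial_state(V, J, P, Q, K, rng)

    states: list[ModelState] = []
    ll_list: list[float] = []
    lp_list: list[float] = []
    for it in range(n_iter):
        gibbs_sweep(n, state, covariates, hyper, rng, pg_trunc=pg_trunc, iteration=it)
        if it % thin == 0:
            psi = compute_psi(state, covariates)
            ll = nb_log_likelihood(n, state, covariates, psi=psi)
            states.append(state.copy())
            ll_list.append(ll)
            lp_list.append(ll + log_prior(state, hyper))
            if logger.isEnabledFor(logging.INFO):
                logger.info("iteration %d: log-likelihood %.3f", it, ll)
    trace = PosteriorTrace(
        states=states,
        log_likelihood=np.asarray(ll_list),
        log_posterior=np.asarray(lp_list),
        burn_in=burn_in,
        thin=thin,
    )
    trace.select_point_estimate(point_estimate_criterion)
    return trace
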