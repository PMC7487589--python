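"""Core probability model: data containers, the logit link and the NB likelihood.

The model describes a genes x cells matrix of sequencing counts n_vj with a
negative binomial distribution whose dispersion r_j is cell-specific (gamma
distributed with a learned rate) and whose probability parameter p_vj is tied,
through a logit link, to cell-level covariates, gene-level covariates and a
bilinear latent-factor term:

    psi_vj = logit(p_vj) = beta_v . x_j + delta_j . z_v + phi_v . theta_j
    E[n_vj] = r_j * exp(psi_vj)

Everything downstream (the Gibbs sampler, the benchmark generator and the
goodness-of-fit summaries) is phrased in terms of these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

# logit values are clamped to this magnitude before any exponentiation;
# logistic(30) is within 1e-13 of 1 so probabilities are unaffected in practice
PSI_CLIP = 30.0

__all__ = [
    "PSI_CLIP",
    "CountMatrix",
    "CovariateSet",
    "Hyperparams",
    "ModelState",
    "compute_psi",
    "expected_counts",
    "nb_log_likelihood",
    "simulate_counts",
    "simulate_from_prior",
]


@dataclass
class CountMatrix:
    """Genes x cells matrix of non-negative integer read/UMI counts."""

    counts: np.ndarray
    gene_ids: list[str] = field(default=None)  # type: ignore[assignment]
    cell_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError(f"counts must be 2-D (genes x cells), got ndim={counts.ndim}")
        if counts.shape[0] < 1 or counts.shape[1] < 1:
            raise ValueError(f"counts must be at least 1x1, got shape {counts.shape}")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            bad = np.nonzero(~np.isclose(counts, rounded, atol=1e-8) | ~np.isfinite(counts))
            if bad[0].size:
                v, j = bad[0][0], bad[1][0]
                raise ValueError(
                    f"counts must be integer-valued; entry (gene {v}, cell {j}) = {counts[v, j]!r}"
                )
            counts = rounded.astype(np.int64)
        if counts.min(initial=0) < 0:
            v, j = [int(a[0]) for a in np.nonzero(counts < 0)]
            raise ValueError(f"counts must be non-negative; entry (gene {v}, cell {j}) = {counts[v, j]}")
        self.counts = counts.astype(np.int64, copy=False)
        if self.gene_ids is None:
            self.gene_ids = [f"gene_{v}" for v in range(self.n_genes)]
        if self.cell_ids is None:
            self.cell_ids = [f"cell_{j}" for j in range(self.n_cells)]
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        if len(self.gene_ids) != self.n_genes:
            raise ValueError(f"{len(self.gene_ids)} gene labels for {self.n_genes} genes")
        if len(self.cell_ids) != self.n_cells:
            raise ValueError(f"{len(self.cell_ids)} cell labels for {self.n_cells} cells")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def zero_fraction(self) -> float:
        return float(np.mean(self.counts == 0))


@dataclass
class CovariateSet:
    """Cell-level (J x P) and gene-level (V x Q) design matrices.

    ``X`` holds one row x_j per cell, ``Z`` one row z_v per gene.  Use
    :meth:`build` to append intercept columns following the model's default
    convention (intercepts in both designs).
    """

    X: np.ndarray
    Z: np.ndarray
    cell_intercept_added: bool = False
    gene_intercept_added: bool = False

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if not np.all(np.isfinite(self.X)):
            raise ValueError("cell covariates contain non-finite entries")
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("gene covariates contain non-finite entries")
        if self.X.shape[1] < 1 or self.Z.shape[1] < 1:
            raise ValueError("designs must have at least one column (the intercept-only case)")

    @classmethod
    def build(
        cls,
        n_genes: int,
        n_cells: int,
        cell_covariates: np.ndarray | None = None,
        gene_covariates: np.ndarray | None = None,
        cell_intercept: bool = True,
        gene_intercept: bool = True,
    ) -> "CovariateSet":
        """Assemble designs, appending intercept columns where requested.

        Missing covariate tables yield intercept-only designs (P = Q = 1).
        """
        if cell_covariates is None:
            X = np.ones((n_cells, 1))
            x_added = True
        else:
            X = np.atleast_2d(np.asarray(cell_covariates, dtype=float))
            if X.shape[0] != n_cells:
                raise ValueError(f"cell covariates have {X.shape[0]} rows for {n_cells} cells")
            x_added = bool(cell_intercept)
            if cell_intercept:
                X = np.column_stack([np.ones(n_cells), X])
        if gene_covariates is None:
            Z = np.ones((n_genes, 1))
            z_added = True
        else:
            Z = np.atleast_2d(np.asarray(gene_covariates, dtype=float))
            if Z.shape[0] != n_genes:
                raise ValueError(f"gene covariates have {Z.shape[0]} rows for {n_genes} genes")
            z_added = bool(gene_intercept)
            if gene_intercept:
                Z = np.column_stack([np.ones(n_genes), Z])
        return cls(X=X, Z=Z, cell_intercept_added=x_added, gene_intercept_added=z_added)

    @property
    def n_cell_covariates(self) -> int:
        return self.X.shape[1]

    @property
    def n_gene_covariates(self) -> int:
        return self.Z.shape[1]


@dataclass
class Hyperparams:
    """Gamma hyper-priors (shape e0, rate f0) and the number of latent factors K."""

    e0: float = 0.01
    f0: float = 0.01
    K: int = 2

    def __post_init__(self) -> None:
        if self.e0 <= 0 or self.f0 <= 0:
            raise ValueError(f"e0 and f0 must be positive, got e0={self.e0}, f0={self.f0}")
        if int(self.K) < 1:
            raise ValueError(f"K must be a positive integer, got {self.K}")
        self.K = int(self.K)


@dataclass
class ModelState:
    """One full parameter configuration of the model.

    r : (J,) cell dispersions, positive.
    beta : (V, P) gene-wise coefficients on cell covariates.
    delta : (J, Q) cell-wise coefficients on gene covariates.
    phi : (V, K) factor loadings;  theta : (J, K) factor scores.
    alpha : (P,), eta : (Q,), gamma : (K,) ARD precisions, positive.
    h : rate of the gamma prior on r, positive.
    """

    r: np.ndarray
    beta: np.ndarray
    delta: np.ndarray
    phi: np.ndarray
    theta: np.ndarray
    alpha: np.ndarray
    eta: np.ndarray
    gamma: np.ndarray
    h: float

    def __post_init__(self) -> None:
        for name in ("r", "beta", "delta", "phi", "theta", "alpha", "eta", "gamma"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.h = float(self.h)
        self.validate()

    def validate(self) -> None:
        V, P = self.beta.shape
        J, Q = self.delta.shape
        K = self.phi.shape[1]
        if self.r.shape != (J,):
            raise ValueError(f"r has shape {self.r.shape}, expected ({J},)")
        if self.phi.shape != (V, K) or self.theta.shape != (J, K):
            raise ValueError(
                f"factor shapes phi {self.phi.shape} / theta {self.theta.shape} inconsistent "
                f"with V={V}, J={J}, K={K}"
            )
        if self.alpha.shape != (P,) or self.eta.shape != (Q,) or self.gamma.shape != (K,):
            raise ValueError("precision vector shapes inconsistent with coefficient shapes")
        if np.any(self.r <= 0):
            raise ValueError("all dispersions r_j must be positive")
        for name in ("alpha", "eta", "gamma"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"all {name} precisions must be positive")
        if self.h <= 0:
            raise ValueError("h must be positive")

    @property
    def shapes(self) -> tuple[int, int, int, int, int]:
        """(V, J, P, Q, K)."""
        return (
            self.beta.shape[0],
            self.delta.shape[0],
            self.beta.shape[1],
            self.delta.shape[1],
            self.phi.shape[1],
        )

    def copy(self) -> "ModelState":
        return ModelState(
            r=self.r.copy(),
            beta=self.beta.copy(),
            delta=self.delta.copy(),
            phi=self.phi.copy(),
            theta=self.theta.copy(),
            alpha=self.alpha.copy(),
            eta=self.eta.copy(),
            gamma=self.gamma.copy(),
            h=self.h,
        )


def _check_dims(state: ModelState, covariates: CovariateSet) -> tuple[int, int]:
    V, J, P, Q, _K = state.shapes
    if covariates.X.shape != (J, P):
        raise ValueError(
            f"cell design X has shape {covariates.X.shape}, state expects ({J}, {P})"
        )
    if covariates.Z.shape != (V, Q):
        raise ValueError(
            f"gene design Z has shape {covariates.Z.shape}, state expects ({V}, {Q})"
        )
    return V, J


def compute_psi(state: ModelState, covariates: CovariateSet) -> np.ndarray:
    """Logit of the NB probability parameter, clamped to ``[-PSI_CLIP, PSI_CLIP]``.

    psi_vj = beta_v . x_j + delta_j . z_v + phi_v . theta_j
    """
    _check_dims(state, covariates)
    psi = state.beta @ covariates.X.T + covariates.Z @ state.delta.T + state.phi @ state.theta.T
    return np.clip(psi, -PSI_CLIP, PSI_CLIP)


def expected_counts(state: ModelState, covariates: CovariateSet) -> np.ndarray:
    """Model-expected counts E[n_vj] = r_j exp(psi_vj)."""
    psi = compute_psi(state, covariates)
    return state.r[None, :] * np.exp(psi)


def nb_log_likelihood(
    counts: CountMatrix | np.ndarray,
    state: ModelState,
    covariates: CovariateSet,
    psi: np.ndarray | None = None,
) -> float:
    """Total NB data log-likelihood sum_vj log f(n_vj | r_j, p_vj).

    Uses the softplus form  n*psi - (n + r)*log(1 + e^psi)  so that log(1 - p)
    never underflows.  ``psi`` may be passed to avoid recomputation.
    """
    if isinstance(counts, CountMatrix):
        n = counts.counts
    else:
        n = np.asarray(counts)
        if not np.issubdtype(n.dtype, np.integer):
            if not np.allclose(n, np.rint(n)):
                raise ValueError("counts must be integer-valued")
            n = np.rint(n).astype(np.int64)
    if psi is None:
        psi = compute_psi(state, covariates)
    r = state.r[None, :]
    # log(1+e^psi) in stable form
    softplus = np.logaddexp(0.0, psi)
    ll = gammaln(n + r) - gammaln(r) - gammaln(n + 1.0) + n * psi - (n + r) * softplus
    return float(ll.sum())


def simulate_counts(
    state: ModelState,
    covariates: CovariateSet,
    rng: np.random.Generator,
    gene_ids: list[str] | None = None,
    cell_ids: list[str] | None = None,
) -> CountMatrix:
    """Draw one counts matrix n_vj ~ NB(r_j, p_vj) from a given state."""
    p = expit(compute_psi(state, covariates))
    # numpy's parameterization: number of failures before n successes with
    # success probability q; mean n(1-q)/q, so q = 1 - p gives mean r p/(1-p)
    n = rng.negative_binomial(state.r[None, :], 1.0 - p)
    return CountMatrix(counts=n.astype(np.int64), gene_ids=gene_ids, cell_ids=cell_ids)


def simulate_from_prior(
    V: int,
    J: int,
    P: int = 1,
    Q: int = 1,
    K: int = 2,
    hyper: Hyperparams | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[CountMatrix, CovariateSet, ModelState]:
    """Forward-simulate counts, covariates and parameters from the generative model.

    Draws h ~ Gamma(e0, rate f0), then r_j ~ Gamma(e0, rate h); ARD precisions
    alpha, eta, gamma ~ Gamma(e0, rate f0); coefficients and factors from their
    zero-mean normal priors given the drawn precisions; finally counts from
    NB(r_j, p_vj).  Designs are an intercept column plus standard-normal
    covariates.  Fully reproducible for a fixed seed.
    """
    if min(V, J, P, Q, K) < 1:
        raise ValueError("all dimensions must be positive")
    hyper = hyper or Hyperparams(K=K)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    X = np.column_stack([np.ones(J), rng.standard_normal((J, P - 1))]) if P > 1 else np.ones((J, 1))
    Z = np.column_stack([np.ones(V), rng.standard_normal((V, Q - 1))]) if Q > 1 else np.ones((V, 1))
    covariates = CovariateSet(X=X, Z=Z, cell_intercept_added=True, gene_intercept_added=True)

    h = rng.gamma(hyper.e0, 1.0 / hyper.f0)
    r = rng.gamma(hyper.e0, 1.0 / h, size=J)
    r = np.maximum(r, 1e-12)  # numerical floor; Gamma draws can underflow to 0
    alpha = np.maximum(rng.gamma(hyper.e0, 1.0 / hyper.f0, size=P), 1e-12)
    eta = np.maximum(rng.gamma(hyper.e0, 1.0 / hyper.f0, size=Q), 1e-12)
    gamma = np.maximum(rng.gamma(hyper.e0, 1.0 / hyper.f0, size=K), 1e-12)
    beta = rng.standard_normal((V, P)) / np.sqrt(alpha)[None, :]
    delta = rng.standard_normal((J, Q)) / np.sqrt(eta)[None, :]
    phi = rng.standard_normal((V, K))
    theta = rng.standard_normal((J, K)) / np.sqrt(gamma)[None, :]
    state = ModelState(
        r=r, beta=beta, delta=delta, phi=phi, theta=theta,
        alpha=alpha, eta=eta, gamma=gamma, h=max(h, 1e-12),
    )
    counts = simulate_counts(state, covariates, rng)
    return counts, covariates, state
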