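"""Zero-inflated negative binomial benchmark generator.

Emulates the clustering benchmark used to probe robustness to dropout: counts
are drawn from

    n_vj ~ pi_vj * delta_0 + (1 - pi_vj) * NB(mu_vj, size)

with log mu_vj = baseline_v + w_v . theta_j, factor scores theta_j drawn from
a K-variate Gaussian mixture (one component per ground-truth cell cluster),
and a dropout probability pi whose logit is linear in log mu with a negative
slope (lowly expressed genes drop out more).  The logit intercept is
calibrated by bisection so that the overall expected zero fraction hits a
requested target (40/60/80% in the benchmark).

The generator returns ground-truth labels and scores so that a factor model
fitted to the counts can be scored with silhouette widths against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .model import CountMatrix

__all__ = [
    "ZinbSimConfig",
    "ZinbSimResult",
    "default_mixture_means",
    "expected_zero_fraction",
    "calibrate_zero_inflation",
    "simulate_zinb",
    "filter_expressed_genes",
]


def default_mixture_means(n_clusters: int, K: int, separation: float = 3.0) -> np.ndarray:
    """Cluster centers placed on a regular simplex/circle in factor space.

    For K = 2 the components sit on a circle of radius ``separation``; higher
    K embeds the same circle in the first two coordinates.
    """
    angles = 2.0 * np.pi * np.arange(n_clusters) / n_clusters
    means = np.zeros((n_clusters, K))
    means[:, 0] = separation * np.cos(angles)
    if K > 1:
        means[:, 1] = separation * np.sin(angles)
    return means


@dataclass
class ZinbSimConfig:
    """Configuration of one synthetic ZINB dataset.

    Defaults mirror a small scRNA-seq regime: 1000 genes, 100 cells, K = 2
    factors, three clusters of equal weight, NB shape 1 (variance mu + mu^2),
    gene baseline means log-uniform between 0.5 and 50 counts.
    """

    V: int = 1000
    J: int = 100
    K: int = 2
    n_clusters: int = 3
    target_zero_fraction: float = 0.6
    mixture_means: np.ndarray | None = None
    mixture_covs: np.ndarray | None = None
    mixture_weights: np.ndarray | None = None
    cluster_separation: float = 2.0
    nb_dispersion: float = 1.0
    baseline_log_mean_range: tuple[float, float] = (np.log(0.5), np.log(50.0))
    loading_scale: float = 0.4
    dropout_slope: float = 0.7
    min_reads: int = 5
    min_cells: int = 5
    apply_gene_filter: bool = True
    sample_genes: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.target_zero_fraction < 1.0):
            raise ValueError("target_zero_fraction must lie in (0, 1)")
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if min(self.V, self.J, self.K) < 1:
            raise ValueError("dimensions must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.mixture_means is None:
            self.mixture_means = default_mixture_means(
                self.n_clusters, self.K, self.cluster_separation
            )
        self.mixture_means = np.asarray(self.mixture_means, dtype=float)
        if self.mixture_means.shape != (self.n_clusters, self.K):
            raise ValueError(
                f"mixture_means must have shape ({self.n_clusters}, {self.K}), "
                f"got {self.mixture_means.shape}"
            )
        if self.mixture_covs is None:
            self.mixture_covs = np.broadcast_to(
                np.eye(self.K), (self.n_clusters, self.K, self.K)
            ).copy()
        self.mixture_covs = np.asarray(self.mixture_covs, dtype=float)
        if self.mixture_weights is None:
            self.mixture_weights = np.full(self.n_clusters, 1.0 / self.n_clusters)
        self.mixture_weights = np.asarray(self.mixture_weights, dtype=float)
        self.mixture_weights = self.mixture_weights / self.mixture_weights.sum()


@dataclass
class ZinbSimResult:
    """Counts plus the ground truth that generated them."""

    counts: CountMatrix
    labels: np.ndarray  # (J,) in {1..n_clusters}
    true_theta: np.ndarray  # (J, K)
    true_pi: np.ndarray  # (V, J) dropout probabilities (post-filter rows)
    realized_zero_fraction: float
    pi_intercept: float = field(default=np.nan)
    kept_genes: np.ndarray | None = None


def _log_means(config: ZinbSimConfig, rng: np.random.Generator):
    """Draw baselines, loadings, mixture labels/scores; return log mu (V, J)."""
    lo, hi = config.baseline_log_mean_range
    baseline = rng.uniform(lo, hi, size=config.V)
    loadings = rng.normal(0.0, config.loading_scale, size=(config.V, config.K))
    labels = rng.choice(config.n_clusters, size=config.J, p=config.mixture_weights)
    theta = np.empty((config.J, config.K))
    for comp in range(config.n_clusters):
        members = labels == comp
        if members.any():
            theta[members] = rng.multivariate_normal(
                config.mixture_means[comp], config.mixture_covs[comp], size=int(members.sum())
            )
    log_mu = baseline[:, None] + loadings @ theta.T
    return log_mu, labels + 1, theta


def _dropout_logit(log_mu: np.ndarray, intercept: float, slope: float) -> np.ndarray:
    return intercept - slope * log_mu


def _filter_pass_probability(q: np.ndarray, min_cells: int) -> np.ndarray:
    """P(at least min_cells successes) for independent Bernoulli rows of q (V, J).

    Exact dynamic program over cells tracking P(#successes = 0..min_cells-1).
    """
    V, J = q.shape
    state = np.zeros((V, min_cells))
    state[:, 0] = 1.0
    for j in range(J):
        qc = q[:, [j]]
        shifted = np.concatenate([np.zeros((V, 1)), state[:, :-1]], axis=1)
        state = state * (1.0 - qc) + shifted * qc
    return 1.0 - state.sum(axis=1)


def expected_zero_fraction(
    log_mu: np.ndarray,
    intercept: float,
    slope: float,
    nb_dispersion: float,
    min_reads: int | None = None,
    min_cells: int | None = None,
) -> float:
    """Analytic expected overall zero fraction for a given dropout intercept.

    mean over (v, j) of  pi + (1 - pi) P_NB(0),  with
    P_NB(0) = (size / (size + mu))^size.  When ``min_reads``/``min_cells`` are
    given, genes are weighted by their probability of surviving the
    expressed-gene filter (>= min_reads counts in >= min_cells cells), so the
    value approximates the post-filter zero fraction.
    """
    from scipy.stats import nbinom

    mu = np.exp(np.clip(log_mu, -700, 700))
    pi = expit(_dropout_logit(log_mu, intercept, slope))
    size = nb_dispersion
    p0 = np.exp(size * (np.log(size) - np.log(size + mu)))
    zero_prob = pi + (1.0 - pi) * p0
    if min_reads is None or min_cells is None:
        return float(np.mean(zero_prob))
    q_detect = (1.0 - pi) * nbinom.sf(min_reads - 1, size, size / (size + mu))
    w = _filter_pass_probability(q_detect, min_cells)
    w_sum = w.sum()
    if w_sum <= 0:
        return float(np.mean(zero_prob))
    return float((w[:, None] * zero_prob).sum() / (w_sum * log_mu.shape[1]))


def calibrate_zero_inflation(
    log_mu: np.ndarray,
    target: float,
    slope: float,
    nb_dispersion: float,
    tolerance: float = 1e-4,
    bracket: tuple[float, float] = (-40.0, 40.0),
    max_iter: int = 200,
    min_reads: int | None = None,
    min_cells: int | None = None,
) -> float:
    """Bisection on the dropout-logit intercept to hit a target zero fraction.

    The expected zero fraction is monotone increasing in the intercept; the
    lower bracket end corresponds to (almost) no inflation.  Raises if the
    target is not bracketed (e.g. below the NB's structural zero fraction).
    ``min_reads``/``min_cells`` switch the objective to the filter-weighted
    expected zero fraction (see :func:`expected_zero_fraction`).
    """

    def objective(a: float) -> float:
        return expected_zero_fraction(log_mu, a, slope, nb_dispersion, min_reads, min_cells)

    lo, hi = bracket
    f_lo, f_hi = objective(lo), objective(hi)
    if not (f_lo - tolerance <= target <= f_hi + tolerance):
        raise ValueError(
            f"target zero fraction {target:.3f} not reachable: bracket achieves "
            f"[{f_lo:.3f}, {f_hi:.3f}] (lower end is the NB structural zero fraction)"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = objective(mid)
        if abs(f_mid - target) <= tolerance:
            return mid
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def filter_expressed_genes(
    counts: np.ndarray, min_reads: int = 5, min_cells: int = 5
) -> np.ndarray:
    """Boolean mask of genes with >= min_reads counts in >= min_cells cells."""
    return (counts >= min_reads).sum(axis=1) >= min_cells


def simulate_zinb(config: ZinbSimConfig) -> ZinbSimResult:
    """Generate one ZINB benchmark dataset per the configuration.

    Steps: draw cluster labels and mixture factor scores; build log-linear NB
    means; calibrate the dropout intercept to the target zero fraction; draw
    NB counts and dropout indicators; optionally filter lowly expressed genes
    (>= min_reads in >= min_cells) and sub-sample ``sample_genes`` of the
    survivors, mirroring common benchmark preprocessing.
    """
    rng = np.random.default_rng(config.seed)
    log_mu, labels, theta = _log_means(config, rng)
    intercept = calibrate_zero_inflation(
        log_mu,
        config.target_zero_fraction,
        config.dropout_slope,
        config.nb_dispersion,
        min_reads=config.min_reads if config.apply_gene_filter else None,
        min_cells=config.min_cells if config.apply_gene_filter else None,
    )
    pi = expit(_dropout_logit(log_mu, intercept, config.dropout_slope))
    mu = np.exp(log_mu)
    size = config.nb_dispersion
    nb = rng.negative_binomial(size, size / (size + mu))
    dropped = rng.random(pi.shape) < pi
    counts = np.where(dropped, 0, nb).astype(np.int64)

    kept = np.arange(config.V)
    if config.apply_gene_filter:
        mask = filter_expressed_genes(counts, config.min_reads, config.min_cells)
        kept = kept[mask]
    if config.sample_genes is not None and kept.size > config.sample_genes:
        kept = np.sort(rng.choice(kept, size=config.sample_genes, replace=False))
    if kept.size < 1:
        raise ValueError("gene filter removed all genes; raise baselines or lower targets")
    counts = counts[kept]
    pi = pi[kept]

    cm = CountMatrix(
        counts,
        gene_ids=[f"gene_{v}" for v in kept],
        cell_ids=[f"cell_{j}" for j in range(config.J)],
    )
    return ZinbSimResult(
        counts=cm,
        labels=labels,
        true_theta=theta,
        true_pi=pi,
        realized_zero_fraction=cm.zero_fraction(),
        pi_intercept=intercept,
        kept_genes=kept,
    )
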