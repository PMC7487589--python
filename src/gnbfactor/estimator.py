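"""scikit-learn-style estimator wrapping the Gibbs sampler.

``GNBFactorModel`` follows the decomposition-estimator idiom (compare
``sklearn.manifold.TSNE``): ``fit`` runs the MCMC on a cells x genes count
matrix, ``fit_transform`` returns the point-estimate factor scores, and all
posterior summaries are exposed as trailing-underscore attributes.  Because
the latent scores are inferred jointly with the training data, there is no
out-of-sample ``transform``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .augmentation import PG_DEFAULT_TRUNC
from .gibbs import run_gibbs
from .model import CountMatrix, CovariateSet, Hyperparams, compute_psi, expected_counts

__all__ = ["GNBFactorModel"]


class GNBFactorModel(BaseEstimator):
    """Hierarchical gamma-negative binomial factor analysis of count data.

    Models a matrix of sequencing counts with a negative binomial whose
    cell-specific dispersion has a hierarchical gamma prior and whose
    probability parameter is logit-linked to cell covariates, gene covariates
    and a K-dimensional bilinear factor term.  Inference is a fully conjugate
    Gibbs sampler built on Chinese-Restaurant-Table and Polya-Gamma data
    augmentation.  Over-dispersion absorbed by the hierarchy lets the model
    accommodate scRNA-seq dropout without an explicit zero-inflation term.

    Parameters
    ----------
    n_components : int, default 2
        Number of latent factors K.
    n_iter, burn_in : int
        MCMC iterations and burn-in; the reference protocol is 2000/1000.
    e0, f0 : float, default 0.01
        Shape and rate of all gamma hyper-priors.
    thin : int, default 1
        Trace thinning interval.
    pg_trunc : int
        Truncation level of the Polya-Gamma series sampler.
    point_estimate : {'likelihood', 'posterior'}
        Criterion selecting the reported posterior snapshot.
    add_cell_intercept, add_gene_intercept : bool
        Append intercept columns to the covariate designs.
    random_state : int or None
        Seed for the single generator threaded through all samplers.

    Attributes
    ----------
    scores_ : (n_cells, K) point-estimate factor scores theta.
    loadings_ : (n_genes, K) point-estimate factor loadings phi.
    dispersion_ : (n_cells,) point-estimate NB dispersions r.
    beta_, delta_ : regression coefficient point estimates.
    log_likelihood_ : data log-likelihood of the selected snapshot.
    trace_ : the full :class:`~gnbfactor.gibbs.PosteriorTrace`.

    Examples
    --------
    >>> import numpy as np
    >>> from gnbfactor import GNBFactorModel
    >>> X = np.random.default_rng(0).poisson(2.0, size=(30, 50))  # cells x genes
    >>> model = GNBFactorModel(n_components=2, n_iter=50, burn_in=25, random_state=0)
    >>> scores = model.fit_transform(X)
    >>> scores.shape
    (30, 2)
    """

    def __init__(
        self,
        n_components: int = 2,
        n_iter: int = 2000,
        burn_in: int = 1000,
        e0: float = 0.01,
        f0: float = 0.01,
        thin: int = 1,
        pg_trunc: int = PG_DEFAULT_TRUNC,
        point_estimate: str = "likelihood",
        add_cell_intercept: bool = True,
        add_gene_intercept: bool = True,
        random_state: int | None = None,
    ) -> None:
        self.n_components = n_components
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.e0 = e0
        self.f0 = f0
        self.thin = thin
        self.pg_trunc = pg_trunc
        self.point_estimate = point_estimate
        self.add_cell_intercept = add_cell_intercept
        self.add_gene_intercept = add_gene_intercept
        self.random_state = random_state

    def fit(self, X, y=None, cell_covariates=None, gene_covariates=None):
        """Run the Gibbs sampler on a (n_cells, n_genes) count matrix.

        ``X`` follows the scikit-learn samples x features orientation and is
        transposed internally to the genes x cells convention of the model.
        """
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D (n_cells, n_genes) count matrix")
        counts = CountMatrix(X.T)  # validates integer, non-negative
        covariates = CovariateSet.build(
            counts.n_genes,
            counts.n_cells,
            cell_covariates=cell_covariates,
            gene_covariates=gene_covariates,
            cell_intercept=self.add_cell_intercept,
            gene_intercept=self.add_gene_intercept,
        )
        hyper = Hyperparams(e0=self.e0, f0=self.f0, K=self.n_components)
        trace = run_gibbs(
            counts,
            covariates,
            hyper,
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            seed=self.random_state,
            thin=self.thin,
            pg_trunc=self.pg_trunc,
            point_estimate_criterion=self.point_estimate,
        )
        est = trace.point_estimate
        self.trace_ = trace
        self.state_ = est
        self.covariates_ = covariates
        self.n_features_in_ = counts.n_genes
        self.scores_ = est.theta.copy()
        self.loadings_ = est.phi.copy()
        self.dispersion_ = est.r.copy()
        self.beta_ = est.beta.copy()
        self.delta_ = est.delta.copy()
        self.alpha_ = est.alpha.copy()
        self.eta_ = est.eta.copy()
        self.gamma_ = est.gamma.copy()
        self.h_ = est.h
        idx = trace.point_estimate_iteration // trace.thin
        self.log_likelihood_ = float(trace.log_likelihood[idx])
        return self

    def fit_transform(self, X, y=None, **fit_params):
        """Fit the model and return the point-estimate factor scores (n_cells, K)."""
        self.fit(X, y, **fit_params)
        return self.scores_

    def transform(self, X=None):
        """Return the fitted factor scores.

        The scores are posterior quantities inferred jointly with the training
        counts, so transforming new data is not supported; call with ``None``
        or the training matrix.
        """
        check_is_fitted(self, "scores_")
        if X is not None and np.asarray(X).shape[0] != self.scores_.shape[0]:
            raise ValueError(
                "out-of-sample transform is not supported; scores exist only for "
                "the cells the model was fitted on"
            )
        return self.scores_

    def psi_(self) -> np.ndarray:
        """Point-estimate logit matrix psi (genes x cells)."""
        check_is_fitted(self, "state_")
        return compute_psi(self.state_, self.covariates_)

    def expected_counts_(self) -> np.ndarray:
        """Point-estimate expected counts r_j exp(psi_vj) (genes x cells)."""
        check_is_fitted(self, "state_")
        return expected_counts(self.state_, self.covariates_)
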