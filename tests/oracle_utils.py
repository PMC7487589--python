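"""Independent oracles shared by the unit and acceptance tests.

Everything here is deliberately written along a different code path from the
package implementation: plain loops, grid quadrature and textbook formulas.
"""

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import interp1d


def psi_loop(state, cov):
    """Triple-loop evaluation of the logit link (no vectorization)."""
    V, J, P, Q, K = state.shapes
    out = np.empty((V, J))
    for v in range(V):
        for j in range(J):
            acc = 0.0
            for p in range(P):
                acc += state.beta[v, p] * cov.X[j, p]
            for q in range(Q):
                acc += state.delta[j, q] * cov.Z[v, q]
            for k in range(K):
                acc += state.phi[v, k] * state.theta[j, k]
            out[v, j] = min(max(acc, -30.0), 30.0)
    return out


def silhouette_loop(points, labels):
    """O(J^2) double-loop silhouette widths with the max-denominator convention."""
    points = np.atleast_2d(points)
    labels = np.asarray(labels)
    J = points.shape[0]
    dist = np.zeros((J, J))
    for i in range(J):
        for j in range(J):
            dist[i, j] = np.sqrt(((points[i] - points[j]) ** 2).sum())
    s = np.zeros(J)
    for i in range(J):
        own = (labels == labels[i]) & (np.arange(J) != i)
        if not own.any():
            s[i] = 0.0  # singleton
            continue
        a = dist[i, own].mean()
        b = np.inf
        for lab in np.unique(labels):
            if lab == labels[i]:
                continue
            b = min(b, dist[i, labels == lab].mean())
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def grid_cdf(grid, log_density):
    """Normalized CDF interpolator from an unnormalized log density on a grid."""
    log_density = log_density - log_density.max()
    pdf = np.exp(log_density)
    cdf = cumulative_trapezoid(pdf, grid, initial=0.0)
    cdf /= cdf[-1]
    return interp1d(grid, cdf, bounds_error=False, fill_value=(0.0, 1.0))


def chisquare_pvalue(observed, expected):
    """Chi-square GOF p-value with impossible categories checked and sparse
    categories (expected < 5) pooled."""
    from scipy.stats import chisquare

    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    impossible = expected == 0
    assert np.all(observed[impossible] == 0), "draw in zero-probability category"
    observed, expected = observed[~impossible], expected[~impossible]
    sparse = expected < 5
    if sparse.any() and sparse.sum() < expected.size:
        observed = np.append(observed[~sparse], observed[sparse].sum())
        expected = np.append(expected[~sparse], expected[sparse].sum())
    if expected.size < 2:
        return 1.0
    return chisquare(observed, expected).pvalue


def nb_logit_loglik(psi, n, r):
    """log of p^n (1-p)^r with p = logistic(psi), up to the binomial factor."""
    return n * psi - (n + r) * np.logaddexp(0.0, psi)
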