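"""Data-augmentation primitives: Chinese-Restaurant-Table and Polya-Gamma draws.

Both auxiliary variables restore conditional conjugacy in the NB model with a
logit link: CRT counts turn the NB dispersion posterior into a gamma, and
Polya-Gamma variables turn the logit-scale likelihood into a Gaussian form.

The Polya-Gamma sampler uses the infinite gamma-series representation

    PG(b, c)  =d  (1 / 2 pi^2) * sum_{k>=1} g_k / ((k - 1/2)^2 + c^2 / (4 pi^2)),
    g_k ~ Gamma(b, 1) i.i.d.,

truncated after ``trunc`` terms, with the dropped tail replaced by a single
gamma variate whose mean and variance equal the exact tail moments (available
in closed form through tanh/sech^2 identities).  The first two moments of the
returned draw are therefore exact for any truncation level; the truncation
level only controls higher-moment accuracy.  This supports arbitrary real
shape b > 0, which is essential here because b = n_vj + r_j is never an
integer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sample_crt",
    "crt_pmf",
    "crt_mean",
    "sample_pg",
    "pg_mean",
    "pg_var",
    "PG_DEFAULT_TRUNC",
]

PG_DEFAULT_TRUNC = 40

_CRT_PMF_MAX_N = 25
# chunk the flattened Bernoulli stream to bound peak memory on huge counts
_CRT_CHUNK = 20_000_000


def crt_mean(n, r):
    """E[CRT(n, r)] = sum_{t=1}^{n} r / (r + t - 1), vectorized over n, r."""
    n = np.asarray(n)
    r = np.asarray(r, dtype=float)
    nmax = int(n.max(initial=0))
    t = np.arange(1, nmax + 1)
    terms = r[..., None] / (r[..., None] + (t - 1.0))
    mask = t <= n[..., None]
    return (terms * mask).sum(axis=-1)


def sample_crt(n, r, rng: np.random.Generator):
    """Draw from the Chinese-Restaurant-Table distribution CRT(n, r).

    Uses the exact sequential construction ell = sum_{t=1}^{n} b_t with
    b_t ~ Bernoulli(r / (r + t - 1)).  Accepts scalars or arrays of matching
    (broadcastable) shape; returns an int64 array of the broadcast shape
    (or a scalar for scalar input).
    """
    n_arr = np.asarray(n)
    r_arr = np.asarray(r, dtype=float)
    if np.any(n_arr < 0):
        raise ValueError("n must be non-negative")
    if not np.issubdtype(n_arr.dtype, np.integer):
        if not np.allclose(n_arr, np.rint(n_arr)):
            raise ValueError("n must be integer-valued")
        n_arr = np.rint(n_arr).astype(np.int64)
    if np.any(r_arr <= 0):
        raise ValueError("r must be positive")

    if n_arr.max(initial=0) > 50_000_000:
        raise ValueError(
            "counts too large for the Bernoulli-sum CRT construction "
            f"(max n = {int(n_arr.max())}); sequencing counts are not expected at this scale"
        )
    n_b, r_b = np.broadcast_arrays(n_arr, r_arr)
    shape = n_b.shape
    n_flat = n_b.ravel().astype(np.int64)
    r_flat = r_b.ravel().astype(float)
    ell = np.zeros(n_flat.size, dtype=np.int64)

    # process in chunks of entries whose total count stays bounded
    total = int(n_flat.sum())
    if total > 0:
        csum = np.cumsum(n_flat)
        start = 0
        while start < n_flat.size:
            # find end so that counts in [start, end) fit the chunk budget
            base = csum[start - 1] if start > 0 else 0
            end = int(np.searchsorted(csum, base + _CRT_CHUNK, side="right")) + 1
            end = min(max(end, start + 1), n_flat.size)
            ell[start:end] = _crt_chunk(n_flat[start:end], r_flat[start:end], rng)
            start = end
    out = ell.reshape(shape)
    if out.shape == ():
        return int(out)
    return out


def _crt_chunk(n: np.ndarray, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    tot = int(n.sum())
    if tot == 0:
        return np.zeros(n.size, dtype=np.int64)
    idx = np.repeat(np.arange(n.size), n)
    starts = np.concatenate(([0], np.cumsum(n)[:-1]))
    t_minus_1 = np.arange(tot, dtype=float) - np.repeat(starts, n)
    rr = r[idx]
    bern = rng.random(tot) < rr / (rr + t_minus_1)
    return np.bincount(idx, weights=bern, minlength=n.size).astype(np.int64)


def crt_pmf(n: int, r: float) -> np.ndarray:
    """Exact PMF of CRT(n, r) over ell in {0, ..., n}, by dynamic programming.

    Exact-oracle range only (n <= 25): the table is built by convolving the n
    sequential Bernoulli(r / (r + t - 1)) indicators.
    """
    n = int(n)
    if n < 0:
        raise ValueError("n must be non-negative")
    if n > _CRT_PMF_MAX_N:
        raise ValueError(f"crt_pmf is an exact oracle for n <= {_CRT_PMF_MAX_N}, got n={n}")
    if r <= 0:
        raise ValueError("r must be positive")
    pmf = np.zeros(n + 1)
    pmf[0] = 1.0
    for t in range(1, n + 1):
        q = r / (r + (t - 1.0))
        pmf[1 : t + 1] = pmf[1 : t + 1] * (1.0 - q) + pmf[0:t] * q
        pmf[0] *= 1.0 - q
    return pmf


# ---------------------------------------------------------------------------
# Polya-Gamma


def pg_mean(b, c):
    """E[PG(b, c)] = (b / (2c)) tanh(c / 2), with the limit b/4 at c = 0."""
    b = np.asarray(b, dtype=float)
    c = np.abs(np.asarray(c, dtype=float))
    small = c < 1e-6
    cs = np.where(small, 1.0, c)
    out = np.where(small, b / 4.0 * (1.0 - c**2 / 12.0), b / (2.0 * cs) * np.tanh(cs / 2.0))
    return out if out.shape else float(out)


def pg_var(b, c):
    """Var[PG(b, c)] = (b / (4 c^3)) (sinh c - c) sech^2(c / 2); limit b/24 at c=0."""
    b = np.asarray(b, dtype=float)
    c = np.abs(np.asarray(c, dtype=float))
    small = c < 1e-4
    cs = np.where(small, 1.0, c)
    exact = b / (4.0 * cs**3) * (np.sinh(cs) - cs) / np.cosh(cs / 2.0) ** 2
    out = np.where(small, b / 24.0, exact)
    return out if out.shape else float(out)


def _series_sums(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """S1(a) = sum_k 1/((k-1/2)^2 + a^2) and S2(a) = sum_k 1/((k-1/2)^2 + a^2)^2.

    Closed forms: S1 = (pi / 2a) tanh(pi a);  S2 = -dS1/d(a^2).
    Small-a limits: S1 -> pi^2/2, S2 -> pi^4/6.
    """
    small = a < 1e-4
    a_safe = np.where(small, 1.0, a)
    pa = np.pi * a_safe
    s1 = np.where(small, np.pi**2 / 2.0, np.pi / (2.0 * a_safe) * np.tanh(pa))
    s2_exact = np.pi / (4.0 * a_safe**3) * np.tanh(pa) - np.pi**2 / (
        4.0 * a_safe**2
    ) / np.cosh(pa) ** 2
    s2 = np.where(small, np.pi**4 / 6.0, s2_exact)
    return s1, s2


def sample_pg(b, c, rng: np.random.Generator, trunc: int = PG_DEFAULT_TRUNC):
    """Draw from the Polya-Gamma distribution PG(b, c), vectorized.

    Parameters
    ----------
    b : array-like, shape broadcastable with ``c``
        Shape parameter, any real >= 0 (entries with b == 0 return 0).
    c : array-like
        Tilting parameter; the distribution is symmetric in c.
    trunc : int
        Number of exact gamma-series terms; the remaining tail is replaced by
        a gamma variate with the tail's exact mean and variance.
    """
    b_arr = np.asarray(b, dtype=float)
    c_arr = np.asarray(c, dtype=float)
    if np.any(b_arr < 0):
        raise ValueError("b must be non-negative")
    b_b, c_b = np.broadcast_arrays(b_arr, c_arr)
    shape = b_b.shape
    bf = np.ascontiguousarray(b_b, dtype=float).ravel()
    a = np.abs(np.ascontiguousarray(c_b, dtype=float).ravel()) / (2.0 * np.pi)

    k = np.arange(1, trunc + 1, dtype=float)
    denom = (k[:, None] - 0.5) ** 2 + a[None, :] ** 2  # (trunc, N)
    g = rng.standard_gamma(bf[None, :], size=(trunc, bf.size))
    omega = (g / denom).sum(axis=0)

    s1, s2 = _series_sums(a)
    tail_s1 = s1 - (1.0 / denom).sum(axis=0)
    tail_s2 = s2 - (1.0 / denom**2).sum(axis=0)
    tail_s1 = np.maximum(tail_s1, 0.0)
    tail_s2 = np.maximum(tail_s2, 1e-300)
    tail_mean = bf * tail_s1
    tail_var = bf * tail_s2
    with np.errstate(divide="ignore", invalid="ignore"):
        shape_t = np.where(tail_mean > 0, tail_mean**2 / tail_var, 0.0)
        scale_t = np.where(tail_mean > 0, tail_var / np.maximum(tail_mean, 1e-300), 0.0)
    omega = omega + rng.standard_gamma(shape_t) * scale_t
    omega *= 1.0 / (2.0 * np.pi**2)
    omega = np.where(bf > 0, omega, 0.0)
    out = omega.reshape(shape)
    if out.shape == ():
        return float(out)
    return out
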