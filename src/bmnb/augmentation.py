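"""Latent-variable samplers for logistic data augmentation of count models.

Two distributions drive the conditionally conjugate Gibbs sampler for
negative-binomial mixed regression:

* the Pólya-Gamma distribution PG(b, c), whose draws turn the logistic-form
  NB likelihood into a Gaussian one in the linear predictor, and
* the Chinese-restaurant-table distribution CRT(y, r), whose latent table
  counts make the conditional of the dispersion r a gamma distribution.

``sample_pg`` uses the infinite-convolution-of-gammas representation

    PG(b, c)  =d=  (1 / 2π²) · Σ_{k≥1}  g_k / ((k − 1/2)² + c²/(4π²)),
    g_k ~ Gamma(b, 1) i.i.d.,

truncated after ``trunc`` terms, with the remainder replaced by a single
gamma variate matched to the remainder's exact mean and variance.  The first
two moments of the output are therefore exact for every (b, c); the
truncation error lives only in third-and-higher cumulants of the (small)
tail and shrinks like 1/trunc³.  Unlike Devroye-type rejection samplers this
works for arbitrary real b — including the large shapes b = y + r that the
Poisson limit (r ≈ 10³–10⁴) produces — and vectorises over records.

``sample_crt`` uses the defining Bernoulli construction
L = Σ_{l=1..y} d_l with d_l ~ Bernoulli(r / (l − 1 + r)); counts in this
application are at most a few hundred, so the O(y) sum is kept for
transparency.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma

__all__ = ["sample_pg", "sample_crt", "pg_mean", "pg_var", "crt_mean"]

_TWO_PISQ = 2.0 * np.pi**2

# Coefficients of the small-z expansions of S1(z) = Σ 1/((k-1/2)² + z) and
# S2(z) = Σ 1/((k-1/2)² + z)²: c_m = Σ_k (k - 1/2)^{-(2m+2)}.
_C0 = np.pi**2 / 2.0
_C1 = np.pi**4 / 6.0
_C2 = np.pi**6 / 15.0
_C3 = 17.0 * np.pi**8 / 630.0
_C4 = 31.0 * np.pi**10 / 2835.0


def _s1_inf(z: np.ndarray) -> np.ndarray:
    """Σ_{k≥1} 1/((k−1/2)² + z), closed form with a series branch near 0."""
    z = np.asarray(z, dtype=float)
    small = z < 1e-4
    zs = np.where(small, 1.0, z)  # placeholder to keep sqrt well-defined
    u = np.sqrt(zs)
    closed = (np.pi / (2.0 * u)) * np.tanh(np.pi * u)
    series = _C0 - _C1 * z + _C2 * z**2 - _C3 * z**3
    return np.where(small, series, closed)


def _s2_inf(z: np.ndarray) -> np.ndarray:
    """Σ_{k≥1} 1/((k−1/2)² + z)², i.e. −d/dz of ``_s1_inf``."""
    z = np.asarray(z, dtype=float)
    small = z < 1e-4
    zs = np.where(small, 1.0, z)
    u = np.sqrt(zs)
    t = np.tanh(np.pi * u)
    ex = np.exp(-np.pi * u)  # overflow-safe sech²(πu) = (2e^{-x}/(1+e^{-2x}))²
    sech2 = (2.0 * ex / (1.0 + ex * ex)) ** 2
    closed = (np.pi / (4.0 * u**3)) * t - (np.pi**2 / (4.0 * zs)) * sech2
    series = _C1 - 2.0 * _C2 * z + 3.0 * _C3 * z**2 - 4.0 * _C4 * z**3
    return np.where(small, series, closed)


def pg_mean(b, c):
    """Analytic mean of PG(b, c): (b/2c)·tanh(c/2), with limit b/4 at c=0."""
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(
            np.abs(c) < 1e-8,
            b / 4.0 - b * c**2 / 48.0,
            (b / (2.0 * np.where(c == 0.0, 1.0, c))) * np.tanh(c / 2.0),
        )
    return out[()] if out.ndim == 0 else out


def pg_var(b, c):
    """Analytic variance of PG(b, c): b·(sinh c − c)·sech²(c/2) / (4c³)."""
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    small = np.abs(c) < 1e-4
    cs = np.where(small, 1.0, c)
    closed = b * (np.sinh(cs) - cs) / (4.0 * cs**3 * np.cosh(cs / 2.0) ** 2)
    series = b / 24.0 - b * c**2 / 120.0
    out = np.where(small, series, closed)
    return out[()] if out.ndim == 0 else out


def crt_mean(y, r):
    """Analytic mean of CRT(y, r): r·(ψ(r + y) − ψ(r))."""
    return r * (digamma(r + np.asarray(y, dtype=float)) - digamma(r))


def sample_pg(b, c, rng: np.random.Generator, trunc: int = 32):
    """Draw from the Pólya-Gamma distribution PG(b, c), elementwise.

    Parameters
    ----------
    b
        Shape parameter(s), strictly positive, need not be integer.
    c
        Tilt parameter(s), finite reals.
    rng
        Seeded :class:`numpy.random.Generator`.
    trunc
        Number of gamma terms kept before the moment-matched remainder.

    Returns
    -------
    float or ndarray of positive draws, broadcast shape of ``b`` and ``c``.
    """
    b_arr = np.asarray(b, dtype=float)
    c_arr = np.asarray(c, dtype=float)
    if b_arr.size == 0:
        return np.empty(np.broadcast_shapes(b_arr.shape, c_arr.shape))
    if not np.all(np.isfinite(b_arr)) or np.any(b_arr <= 0.0):
        raise ValueError("PG shape parameter b must be finite and > 0")
    if not np.all(np.isfinite(c_arr)):
        raise ValueError("PG tilt parameter c must be finite")
    scalar = b_arr.ndim == 0 and c_arr.ndim == 0
    b_arr, c_arr = np.broadcast_arrays(np.atleast_1d(b_arr), np.atleast_1d(c_arr))

    z = (c_arr / (2.0 * np.pi)) ** 2
    k = np.arange(1, trunc + 1) - 0.5  # (trunc,)
    denom = k**2 + z[..., None]  # (..., trunc)
    g = rng.gamma(np.broadcast_to(b_arr[..., None], denom.shape))
    x = (g / denom).sum(axis=-1) / _TWO_PISQ

    # Remainder of the series: match its exact mean and variance with one
    # gamma variate.  Clamp tiny negative round-off to zero.
    s1_tail = np.maximum(_s1_inf(z) - (1.0 / denom).sum(axis=-1), 0.0)
    s2_tail = np.maximum(_s2_inf(z) - (1.0 / denom**2).sum(axis=-1), 0.0)
    m = b_arr * s1_tail / _TWO_PISQ
    v = b_arr * s2_tail / _TWO_PISQ**2
    ok = (m > 0.0) & (v > 0.0)
    shape = np.where(ok, m * m / np.where(v > 0.0, v, 1.0), 1.0)
    scale = np.where(ok, v / np.where(m > 0.0, m, 1.0), 0.0)
    x = x + rng.gamma(shape) * scale
    return float(x[0]) if scalar else x


def sample_crt(y, r: float, rng: np.random.Generator):
    """Draw Chinese-restaurant-table count(s) L ~ CRT(y, r), elementwise.

    L = Σ_{l=1..y} Bernoulli(r / (l − 1 + r)); the first Bernoulli always
    succeeds, so L = 0 iff y = 0 and L ≥ 1 whenever y ≥ 1.
    """
    y_arr = np.asarray(y)
    if y_arr.size and not np.issubdtype(y_arr.dtype, np.integer):
        if not np.all(np.asarray(y_arr, dtype=float) == np.floor(y_arr)):
            raise ValueError("CRT count y must be integer-valued")
        y_arr = y_arr.astype(np.int64)
    if np.any(y_arr < 0):
        raise ValueError("CRT count y must be non-negative")
    if not np.isfinite(r) or r <= 0.0:
        raise ValueError("CRT dispersion r must be finite and > 0")
    scalar = y_arr.ndim == 0
    y_flat = np.atleast_1d(y_arr).astype(np.int64).ravel()
    seg, table = crt_segments(y_flat)
    out = sample_crt_indexed(seg, table, y_flat.size, r, rng)
    if scalar:
        return int(out[0])
    return out.reshape(np.atleast_1d(y_arr).shape)


def crt_segments(y_flat: np.ndarray):
    """Precompute flattened Bernoulli indices for repeated CRT sampling.

    Returns ``(seg, table)`` where ``table[m]`` is the (0-based) table index
    l−1 of the m-th Bernoulli trial and ``seg[m]`` the record it belongs to.
    Trial l−1 = 0 has success probability 1 and is included for clarity.
    """
    total = int(y_flat.sum())
    seg = np.repeat(np.arange(y_flat.size), y_flat)
    table = np.concatenate([np.arange(n) for n in y_flat]) if total else np.empty(0, np.int64)
    return seg, table


def sample_crt_indexed(seg, table, n, r, rng):
    """CRT draws for precomputed segment/table indices (hot path)."""
    if table.size == 0:
        return np.zeros(n, dtype=np.int64)
    p = r / (table + r)
    hits = rng.random(table.size) < p
    return np.bincount(seg, weights=hits, minlength=n).astype(np.int64)
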