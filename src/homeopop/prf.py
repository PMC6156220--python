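"""Poisson random field machinery for selected site-frequency spectra.

Core quantities for a Wright-Fisher population at stationarity under the
infinite-sites model, following the classic Poisson random field (PRF)
formulation.  The scaled strength of selection *against* a new mutation is
``gamma`` = Ne*s >= 0 (``gamma`` = 0 is neutral).  For a sample of size
``n`` the expected number of segregating sites with derived-allele count
``i`` is proportional to

    B_i(gamma) = C(n,i) * Integral_0^1 H(gamma, x) x^i (1-x)^(n-i) dx

with the sojourn-time density

    H(gamma, x) = (exp(-2*gamma*x) - exp(-2*gamma)) /
                  ((1 - exp(-2*gamma)) * x * (1-x)),

normalised so that B_i(0) = 1/i (the neutral spectrum).  The integral has
a closed form in terms of Kummer's confluent hypergeometric function,

    B_i(gamma) = C(n,i) B(i, n-i) (1F1(i; n; -2*gamma) - exp(-2*gamma))
                 / (1 - exp(-2*gamma)),

which this module evaluates directly (with a power-series fallback near
gamma = 0 where the closed form suffers cancellation).  The relative
fixation probability of a deleterious mutation is 2*gamma / (e^{2*gamma}-1).

Deleterious effects are drawn from a gamma distribution with shape ``beta``
and mean ``mean_gamma``; expectations over that distribution of fitness
effects (DFE) are computed on a fixed logarithmic quadrature grid so that
they can be re-evaluated cheaply for many (shape, mean) pairs inside MCMC.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = [
    "sampling_kernel",
    "fixation_rate",
    "gamma_category_proportions",
    "DFEQuadrature",
    "NES_BREAKS",
]

#: Ne*s boundaries of the conventional effect-size categories:
#: effectively neutral [0,1), mildly deleterious [1,10),
#: deleterious [10,100), strongly deleterious >= 100.
NES_BREAKS = (1.0, 10.0, 100.0)

_SMALL_GAMMA = 0.05  # below this, use the series evaluation


def _kernel_series(i: np.ndarray, n: int, gamma: np.ndarray, terms: int = 14):
    """B_i(gamma) by power series in gamma, stable as gamma -> 0.

    numerator  = 1F1(i;n;-2g) - exp(-2g) = sum_k [ (i)_k/(n)_k - 1 ] (-2g)^k / k!
    denominator = 1 - exp(-2g)           = -sum_{k>=1} (-2g)^k / k!
    """
    i = np.asarray(i, dtype=float)[:, None]
    g = np.asarray(gamma, dtype=float)[None, :]
    z = -2.0 * g
    num = np.zeros_like(i * g)
    den = np.zeros_like(i * g)
    poch_ratio = np.ones_like(i * g)  # (i)_k / (n)_k
    zk_over_fact = np.ones_like(i * g)
    for k in range(1, terms + 1):
        poch_ratio = poch_ratio * (i + k - 1) / (n + k - 1)
        zk_over_fact = zk_over_fact * z / k
        num += (poch_ratio - 1.0) * zk_over_fact
        den -= zk_over_fact
    binom_beta = special.binom(n, i) * special.beta(i, n - i)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = binom_beta * num / den
    # exact neutral limit where gamma == 0
    out = np.where(g == 0.0, 1.0 / i, out)
    return out


def sampling_kernel(gamma, n: int) -> np.ndarray:
    """Expected SFS contribution per derived-count class under selection.

    Parameters
    ----------
    gamma : array-like, >= 0
        Scaled selection strength Ne*s against the mutation.
    n : int
        Sample size (number of haploid sequences), n >= 2.

    Returns
    -------
    ndarray of shape (n-1, len(gamma)):  B[i-1, j] = B_i(gamma_j),
    normalised so the neutral column is 1/i.
    """
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    if np.any(gamma < 0):
        raise ValueError("gamma is a strength of selection against; must be >= 0")
    i = np.arange(1, n)
    out = np.empty((n - 1, gamma.size))
    small = gamma < _SMALL_GAMMA
    if small.any():
        out[:, small] = _kernel_series(i, n, gamma[small])
    big = ~small
    if big.any():
        g = gamma[big][None, :]
        ii = i[:, None].astype(float)
        num = special.hyp1f1(ii, n, -2.0 * g) - np.exp(-2.0 * g)
        den = -np.expm1(-2.0 * g)
        out[:, big] = (special.binom(n, ii) * special.beta(ii, n - ii)) * num / den
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(
            "sampling kernel not finite for gamma in "
            f"[{gamma.min():g}, {gamma.max():g}], n={n}"
        )
    return out


def fixation_rate(gamma) -> np.ndarray:
    """Fixation probability of a deleterious mutation relative to neutral.

    2*gamma / (exp(2*gamma) - 1); equals 1 at gamma = 0 and decays to 0 for
    strong selection.
    """
    gamma = np.asarray(gamma, dtype=float)
    out = np.ones_like(gamma)
    nz = gamma > 0
    with np.errstate(over="ignore"):
        out = np.where(nz, 2.0 * gamma / np.expm1(2.0 * gamma), out)
    return out


def gamma_category_proportions(shape: float, mean_gamma: float,
                               breaks=NES_BREAKS) -> np.ndarray:
    """Probability mass of the gamma(shape, mean) DFE in the Ne*s categories.

    Returns proportions in [0, b1), [b1, b2), ..., [b_last, inf).
    A point mass at 0 (mean_gamma == 0) puts everything in the first class.
    """
    if mean_gamma == 0:
        out = np.zeros(len(breaks) + 1)
        out[0] = 1.0
        return out
    scale = mean_gamma / shape
    cdf = special.gammainc(shape, np.asarray(breaks) / scale)
    edges = np.concatenate([[0.0], cdf, [1.0]])
    return np.diff(edges)


class DFEQuadrature:
    """Fixed-grid quadrature of PRF quantities over a gamma DFE.

    Precomputes the sampling kernel and fixation rate on a logarithmic
    gamma grid (Simpson weights) so that expectations for any
    (shape, mean) pair cost one density evaluation plus a mat-vec.
    Mass below ``gamma_eps`` is treated as exactly neutral (the kernel is
    1/i + O(gamma) there), which keeps small-shape DFEs accurate.
    """

    def __init__(self, n: int, gamma_eps: float = 1e-6, gamma_max: float = 1e8,
                 n_points: int = 2049):
        if n_points % 2 == 0:
            n_points += 1
        self.n = int(n)
        self.gamma_eps = float(gamma_eps)
        u = np.linspace(np.log(gamma_eps), np.log(gamma_max), n_points)
        self.grid = np.exp(u)
        h = u[1] - u[0]
        w = np.ones(n_points)
        w[1:-1:2] = 4.0
        w[2:-1:2] = 2.0
        w *= h / 3.0
        self._w = w
        self._kernel = sampling_kernel(self.grid, n)        # (n-1, G)
        self._fix = fixation_rate(self.grid)                # (G,)
        self._neutral = 1.0 / np.arange(1, n)

    def _density_weights(self, shape: float, mean_gamma: float):
        """Quadrature weights f(gamma)*gamma*w on the log grid, plus the
        probability mass below the grid (treated as neutral)."""
        if shape <= 0:
            raise ValueError("DFE shape must be > 0")
        if mean_gamma < 0:
            raise ValueError("mean gamma must be >= 0")
        if mean_gamma == 0:
            return np.zeros_like(self.grid), 1.0
        scale = mean_gamma / shape
        g = self.grid
        # log pdf of gamma distribution, times g for the log substitution
        logf = (shape * np.log(g / scale) - g / scale
                - special.gammaln(shape)) - np.log(g)
        wts = np.exp(logf) * g * self._w
        mass_below = special.gammainc(shape, self.gamma_eps / scale)
        return wts, mass_below

    def class_means(self, shape: float, mean_gamma: float) -> np.ndarray:
        """E over the DFE of B_i(gamma), i = 1..n-1 (neutral limit: 1/i)."""
        wts, mass0 = self._density_weights(shape, mean_gamma)
        return self._kernel @ wts + mass0 * self._neutral

    def folded_class_means(self, shape: float, mean_gamma: float) -> np.ndarray:
        """Folded version: class j collects derived counts j and n-j."""
        e = self.class_means(shape, mean_gamma)
        return fold_expected(e, self.n)

    def mean_fixation_rate(self, shape: float, mean_gamma: float) -> float:
        """E over the DFE of the relative fixation rate 2g/(e^{2g}-1)."""
        wts, mass0 = self._density_weights(shape, mean_gamma)
        return float(self._fix @ wts + mass0)


def fold_expected(expected_unfolded: np.ndarray, n: int) -> np.ndarray:
    """Fold an unfolded expected SFS (classes 1..n-1) to classes 1..n//2."""
    e = np.asarray(expected_unfolded, dtype=float)
    half = n // 2
    out = np.empty(half)
    for j in range(1, half + 1):
        if j == n - j:
            out[j - 1] = e[j - 1]
        else:
            out[j - 1] = e[j - 1] + e[n - j - 1]
    return out
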