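"""Wavelet-domain fractal analysis of long-memory signals.

The discrete wavelet transform splits a series into octave bands; for a
fractionally integrated process the covariance of detail coefficients at
scale ``q`` follows the scaling law

    upsilon_{x,y}(q)  ~  eta_{x,y} * beta_{x,y} * 2^{q (a_x + a_y)}   (q -> inf)

with the asymptotic constant

    beta_{x,y} = 2 cos(pi (a_x - a_y) / 2)
                 * (1 - 2^{a_x + a_y - 1}) / (1 - a_x - a_y)
                 * (2 pi)^{-(a_x + a_y)}.

This module implements the forward direction (decompose, per-scale
covariance/correlation) and the two inverse problems: maximum-likelihood
estimation of the memory parameter ``a`` from a single channel, and
log-linear regression of the wavelet covariance across scales to recover
the short-memory (nonfractal) covariance ``eta_{x,y}``.

The ML estimator maximizes the exact Gaussian likelihood with the
Toeplitz FIN covariance built from the model autocovariance; the
innovation variance is profiled out in closed form, leaving a bounded
1-D search over ``a``.  Likelihood terms are computed with a
Levinson-Durbin recursion (O(N^2), no matrix ever formed), JIT-compiled
when numba is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.optimize import minimize_scalar

from .lm_model import fin_autocovariance

__all__ = [
    "WaveletSpec",
    "WaveletCoefficients",
    "ScaleCovariances",
    "MemoryEstimate",
    "max_wavelet_depth",
    "wavelet_decompose",
    "wavelet_covariance",
    "wavelet_correlation",
    "asymptotic_beta",
    "estimate_memory_parameter",
    "estimate_short_memory_cov",
]

#: estimates are clipped to this closed interval to keep the scaling
#: constants finite near the stationarity boundary
A_CLIP = 0.49


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet family and boundary rule for the decimated transform."""

    family: str = "db4"
    mode: str = "periodization"


@dataclass(frozen=True)
class WaveletCoefficients:
    """Decimated detail coefficients per scale q = 1..Q (finest first)."""

    details: tuple[np.ndarray, ...]
    approx: np.ndarray
    spec: WaveletSpec
    n_samples: int

    @property
    def n_scales(self) -> int:
        return len(self.details)

    @property
    def n_coeffs(self) -> tuple[int, ...]:
        return tuple(len(d) for d in self.details)


@dataclass(frozen=True)
class ScaleCovariances:
    """Wavelet covariances upsilon(q), q = 1..Q, with per-scale sample sizes."""

    upsilon: np.ndarray
    n_coeffs: tuple[int, ...]
    pair: tuple[int, int] = (0, 0)

    @property
    def n_scales(self) -> int:
        return self.upsilon.size

    def scales(self) -> np.ndarray:
        return np.arange(1, self.n_scales + 1)


@dataclass(frozen=True)
class MemoryEstimate:
    """ML estimate of the memory parameter of one channel."""

    a_hat: float
    eta_hat_diag: float
    loglik: float
    at_boundary: bool = False


def max_wavelet_depth(n: int) -> int:
    """Deepest usable scale for an n-sample series: floor(log2 n)."""
    return int(np.floor(np.log2(n))) if n >= 2 else 0


def default_depth(n: int) -> int:
    """Default analysis depth floor(log2 N) - 2 (avoids the 1-2 coefficient
    coarsest scales where the sample covariance is meaningless)."""
    return max(max_wavelet_depth(n) - 2, 1)


def wavelet_decompose(
    series: np.ndarray, Q: int | None = None, spec: WaveletSpec = WaveletSpec()
) -> WaveletCoefficients:
    """Orthonormal decimated DWT of a single channel, scales 1..Q.

    Periodized boundary handling keeps the transform orthonormal, so the
    coefficient energy equals the input energy and scale q holds N / 2^q
    coefficients (for N divisible by 2^Q).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = series.size
    if Q is None:
        Q = default_depth(n)
    q_max = max_wavelet_depth(n)
    if Q < 1 or Q > q_max:
        raise ValueError(
            f"requested depth Q={Q} infeasible for N={n}; maximum is {q_max}"
        )
    with warnings.catch_warnings():
        # depths past pywt's conservative limit are intentional here: the
        # periodized transform stays orthonormal at every depth, and the
        # coarsest scales are down-weighted/excluded downstream anyway
        warnings.filterwarnings("ignore", message="Level value .* too high")
        coeffs = pywt.wavedec(series, spec.family, mode=spec.mode, level=Q)
    approx, details_coarse_first = coeffs[0], coeffs[1:]
    details = tuple(reversed(details_coarse_first))  # index 0 = scale 1 (finest)
    return WaveletCoefficients(details, approx, spec, n)


def wavelet_covariance(
    Vx: WaveletCoefficients, Vy: WaveletCoefficients, pair: tuple[int, int] = (0, 1)
) -> ScaleCovariances:
    """Per-scale wavelet covariance upsilon(q) = mean_s Vx(q,s) Vy(q,s).

    Detail coefficients of a wavelet with vanishing moments have zero mean
    by construction, so no re-centering is applied; normalization is by
    the coefficient count n (biased).  Scales with fewer than two
    coefficients are reported as NaN with a warning.
    """
    if (
        Vx.n_samples != Vy.n_samples
        or Vx.n_scales != Vy.n_scales
        or Vx.spec != Vy.spec
    ):
        raise ValueError("coefficient sets must share N, Q and wavelet spec")
    ups = np.empty(Vx.n_scales)
    for q0, (dx, dy) in enumerate(zip(Vx.details, Vy.details)):
        if dx.size < 2:
            warnings.warn(
                f"scale {q0 + 1} has {dx.size} coefficient(s); covariance "
                "undefined and excluded",
                stacklevel=2,
            )
            ups[q0] = np.nan
        else:
            ups[q0] = float(dx @ dy) / dx.size
    return ScaleCovariances(ups, Vx.n_coeffs, pair)


def wavelet_correlation(
    cov: ScaleCovariances, var_x: ScaleCovariances, var_y: ScaleCovariances
) -> np.ndarray:
    """Per-scale wavelet correlation delta(q) = upsilon_xy / sqrt(ups_x ups_y).

    A scale where either variance vanishes (or is unavailable) yields NaN
    rather than being dropped, so the scale axis stays aligned.
    """
    if not (cov.n_scales == var_x.n_scales == var_y.n_scales):
        raise ValueError("inputs must cover the same scales")
    vx, vy = var_x.upsilon, var_y.upsilon
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = cov.upsilon / np.sqrt(vx * vy)
    delta = np.where((vx > 0) & (vy > 0), delta, np.nan)
    ok = np.isfinite(delta)
    if np.any(np.abs(delta[ok]) > 1 + 1e-12):
        # sampling noise cannot push a true correlation past 1; anything
        # beyond tiny slack indicates mismatched inputs
        raise ValueError("correlation outside [-1, 1]: inputs are inconsistent")
    return np.clip(delta, -1.0, 1.0, out=delta, where=ok)


def asymptotic_beta(a_x: float, a_y: float) -> float:
    """Asymptotic wavelet-covariance constant beta_{x,y}.

    beta = 2 cos(pi (a_x - a_y)/2) (1 - 2^{a_x+a_y-1})/(1 - a_x - a_y)
           (2 pi)^{-(a_x+a_y)};  beta(0, 0) = 1.
    """
    s = a_x + a_y
    if s >= 1:
        raise ValueError("a_x + a_y must be < 1")
    return (
        2.0
        * np.cos(np.pi * (a_x - a_y) / 2.0)
        * (1.0 - 2.0 ** (s - 1.0))
        / (1.0 - s)
        * (2.0 * np.pi) ** (-s)
    )


# ---------------------------------------------------------------------------
# exact Gaussian likelihood of a stationary series via Levinson-Durbin
# ---------------------------------------------------------------------------


def _levinson_loglik_terms_py(rho: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    """(log det T, r' T^{-1} r) for the Toeplitz matrix T built from rho.

    Runs the Durbin recursion on the model autocovariance while whitening
    the data with the growing-order predictor; never forms T.
    """
    n = r.size
    v = rho[0]
    logdet = np.log(v)
    quad = r[0] * r[0] / v
    phi = np.empty(n)
    for k in range(1, n):
        m = k - 1  # predictor order entering this step
        if m:
            kappa = (rho[k] - phi[:m] @ rho[k - 1 : k - 1 - m : -1]) / v
            phi[:m] = phi[:m] - kappa * phi[m - 1 :: -1]
        else:
            kappa = rho[1] / v
        phi[m] = kappa
        v *= 1.0 - kappa * kappa
        e = r[k] - phi[:k] @ r[k - 1 :: -1]
        quad += e * e / v
        logdet += np.log(v)
    return logdet, quad


try:  # optional JIT of the O(N^2) kernel
    from numba import njit

    @njit(cache=True)
    def _levinson_loglik_terms_nb(rho, r):  # pragma: no cover - numba path
        n = r.shape[0]
        v = rho[0]
        logdet = np.log(v)
        quad = r[0] * r[0] / v
        phi = np.zeros(n)
        tmp = np.zeros(n)
        for k in range(1, n):
            acc = rho[k]
            for j in range(1, k):
                acc -= phi[j - 1] * rho[k - j]
            kappa = acc / v
            for j in range(k - 1):
                tmp[j] = phi[j] - kappa * phi[k - 2 - j]
            for j in range(k - 1):
                phi[j] = tmp[j]
            phi[k - 1] = kappa
            v *= 1.0 - kappa * kappa
            e = r[k]
            for j in range(1, k + 1):
                e -= phi[j - 1] * r[k - j]
            quad += e * e / v
            logdet += np.log(v)
        return logdet, quad

    _levinson_loglik_terms = _levinson_loglik_terms_nb
except ImportError:  # pragma: no cover
    _levinson_loglik_terms = _levinson_loglik_terms_py


def _profiled_neg2_loglik(a: float, r: np.ndarray) -> tuple[float, float]:
    """-2 log L profiled over the innovation variance, and sigma2_hat."""
    n = r.size
    rho = fin_autocovariance(a, 1.0, n - 1)
    logdet, quad = _levinson_loglik_terms(rho, r)
    sigma2 = quad / n
    nll = n * np.log(sigma2) + logdet + n * (1.0 + np.log(2.0 * np.pi))
    return nll, sigma2


def estimate_memory_parameter(
    series: np.ndarray, xatol: float = 1e-5
) -> MemoryEstimate:
    """Maximum-likelihood estimate of the memory parameter of one channel.

    Maximizes the exact Gaussian likelihood under the FIN model.  The
    innovation variance enters the Toeplitz covariance as a scale factor,
    so its MLE given ``a`` is the whitened mean square eta_hat =
    r' T(a)^{-1} r / N, and only ``a`` is searched, over the clipped range
    [-0.49, 0.49].  An estimate within solver tolerance of the bounds is
    flagged ``at_boundary``.
    """
    r = np.asarray(series, dtype=float)
    if r.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if r.size < 16:
        raise ValueError("series too short for memory estimation (N < 16)")
    if np.ptp(r) == 0.0:
        raise ValueError("series is constant; memory parameter undefined")
    r = r - r.mean()

    res = minimize_scalar(
        lambda a: _profiled_neg2_loglik(a, r)[0],
        bounds=(-A_CLIP, A_CLIP),
        method="bounded",
        options={"xatol": xatol},
    )
    a_hat = float(np.clip(res.x, -A_CLIP, A_CLIP))
    nll, sigma2 = _profiled_neg2_loglik(a_hat, r)
    return MemoryEstimate(
        a_hat=a_hat,
        eta_hat_diag=float(sigma2),
        loglik=-0.5 * nll,
        at_boundary=bool(A_CLIP - abs(a_hat) < 10 * xatol),
    )


def estimate_short_memory_cov(
    cov: ScaleCovariances,
    a_x: float,
    a_y: float,
    q_range: np.ndarray | list[int] | None = None,
) -> float:
    """Short-memory covariance eta_hat_{x,y} from wavelet covariances.

    Inverts the asymptotic scaling law by averaging the detrended
    log2-covariances over scales:

        c_hat = mean_q [ log2 |upsilon(q)| - (a_x + a_y) q ]
        eta_hat = 2^(c_hat - 1) (2 pi)^(a_x + a_y)
                  / ( B_{x,y} cos(pi (a_x - a_y)/2) )

    with B = (1 - 2^{a_x+a_y-1}) / (1 - a_x - a_y), i.e. eta_hat =
    2^c_hat / beta_{x,y}, so a noiseless power law
    eta beta 2^{q(a_x+a_y)} round-trips exactly.

    Negative covariances (anticorrelated channels) have no log2; the
    magnitude is regressed and the sign of the scale-averaged covariance
    is reapplied.  ``q_range`` defaults to every scale except the finest
    (q = 1), where the octave-band approximation is most biased.
    """
    ups = cov.upsilon
    if q_range is None:
        q_range = np.arange(2, cov.n_scales + 1)
    q_range = np.asarray(q_range, dtype=int)
    if q_range.size == 0:
        raise ValueError("q_range is empty")
    if q_range.min() < 1 or q_range.max() > cov.n_scales:
        raise ValueError("q_range outside available scales")
    u = ups[q_range - 1]
    if np.any(~np.isfinite(u)):
        raise ValueError("q_range includes scales with undefined covariance")
    if np.all(u == 0.0):
        return 0.0
    sign = 1.0 if float(np.mean(u)) >= 0 else -1.0
    nz = u != 0.0
    c_hat = float(np.mean(np.log2(np.abs(u[nz])) - (a_x + a_y) * q_range[nz]))
    return sign * 2.0**c_hat / asymptotic_beta(a_x, a_y)
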