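"""Long-memory model of BOLD-like signals: fractionally integrated noise (FIN).

A resting-state BOLD signal is modelled as the output of a fractional-
integration filter driven by short-memory "spontaneous activity"
innovations.  For a memory parameter ``a`` in the stationary range
(-1/2, 1/2) the filter impulse response is

    h(t) = Gamma(t + a) / (Gamma(a) * Gamma(t + 1)),

so that the channel spectrum behaves like |1 - e^{-jf}|^{-2a} times the
flat innovation level.  ``a = 0`` is white noise; ``a > 0`` gives the
persistent, 1/f-type behaviour seen in rs-fMRI; the Hurst exponent is
``H = a + 1/2``.  In the multivariate case each channel has its own
exponent and the innovation vectors are i.i.d. Gaussian with covariance
``Sigma_m`` whose entries ``eta_{x,y}`` carry the *nonfractal* (fractal-
free) coupling between channels.

This module provides the exact model quantities (impulse response,
spectral density, autocovariance) and the simulator, which doubles as the
synthetic-data generator for the whole analysis pipeline.

Spectral convention: spectra live on f in (-pi, pi) and white noise with
variance sigma^2 has the constant density sigma^2 / (2 pi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MemoryParams",
    "ShortMemoryCov",
    "TimeSeriesMatrix",
    "LabeledStudy",
    "fip_impulse_response",
    "fin_spectral_density",
    "fin_autocovariance",
    "simulate_multivariate_fin",
    "generate_two_group_study",
]

#: Open stationarity interval for the memory parameter.
A_MIN, A_MAX = -0.5, 0.5


def _check_exponent(a: float, name: str = "a") -> float:
    a = float(a)
    if not (A_MIN < a < A_MAX):
        raise ValueError(
            f"memory parameter {name}={a!r} outside the open stationary "
            f"interval ({A_MIN}, {A_MAX})"
        )
    return a


@dataclass(frozen=True)
class MemoryParams:
    """Per-channel fractional-integration exponents (dimensionless)."""

    a: np.ndarray

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        if a.ndim != 1 or a.size < 1:
            raise ValueError("a must be a 1-D vector with at least one channel")
        for al in a:
            _check_exponent(al)
        object.__setattr__(self, "a", a)

    @property
    def n_channels(self) -> int:
        return self.a.size

    @property
    def hurst(self) -> np.ndarray:
        """Hurst exponents H = a + 1/2 of the channels."""
        return self.a + 0.5


@dataclass(frozen=True)
class ShortMemoryCov:
    """Innovation (nonfractal) covariance Sigma_m with entries eta_{x,y}."""

    eta: np.ndarray
    #: tolerance for the symmetry / positive-semidefiniteness checks
    tol: float = 1e-10

    def __post_init__(self) -> None:
        eta = np.asarray(self.eta, dtype=float)
        if eta.ndim != 2 or eta.shape[0] != eta.shape[1]:
            raise ValueError("eta must be a square matrix")
        if not np.allclose(eta, eta.T, atol=self.tol):
            raise ValueError("eta must be symmetric")
        if np.any(np.diag(eta) <= 0):
            raise ValueError("eta must have a strictly positive diagonal")
        w = np.linalg.eigvalsh(0.5 * (eta + eta.T))
        if w.min() < -self.tol * max(1.0, w.max()):
            raise ValueError(
                f"eta is not positive semi-definite (min eigenvalue {w.min():.3g})"
            )
        object.__setattr__(self, "eta", 0.5 * (eta + eta.T))

    @property
    def n_channels(self) -> int:
        return self.eta.shape[0]

    def correlation(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.eta))
        return self.eta / np.outer(d, d)


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """An N x v multichannel series, rows in time-ascending order."""

    values: np.ndarray
    region_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D (timepoints x regions) array")
        if not np.all(np.isfinite(values)):
            raise ValueError("values contain missing or non-finite entries")
        names = tuple(self.region_names) or tuple(
            f"R{i + 1:03d}" for i in range(values.shape[1])
        )
        if len(names) != values.shape[1]:
            raise ValueError("region_names length must match the channel count")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "region_names", names)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class LabeledStudy:
    """A set of per-subject series with binary group labels (synthetic cohort)."""

    subjects: tuple[TimeSeriesMatrix, ...]
    labels: np.ndarray
    seed: int
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        if labels.size != len(self.subjects):
            raise ValueError("one label per subject required")
        if labels.size and not set(np.unique(labels)) <= {0, 1}:
            raise ValueError("labels must be binary (0/1)")
        object.__setattr__(self, "subjects", tuple(self.subjects))
        object.__setattr__(self, "labels", labels)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def fip_impulse_response(a: float, L: int) -> np.ndarray:
    """Impulse response h(0..L-1) of the fractional-integration filter.

    h(t) = Gamma(t + a) / (Gamma(a) Gamma(t + 1)), computed through the
    overflow-free recursion h(t) = h(t-1) (t - 1 + a) / t with h(0) = 1.
    ``a = 0`` returns the identity filter [1, 0, 0, ...].
    """
    a = _check_exponent(a)
    if L < 1:
        raise ValueError("filter length L must be >= 1")
    h = np.empty(L)
    h[0] = 1.0
    for t in range(1, L):
        h[t] = h[t - 1] * (t - 1 + a) / t
    return h


def fin_spectral_density(
    a_x: float, a_y: float, eta_xy: float, f: float | np.ndarray
) -> complex | np.ndarray:
    """Cross-spectral density eta_{x,y} (1-e^{jf})^{-a_x} (1-e^{-jf})^{-a_y}.

    For ``x == y`` this is eta |1 - e^{-jf}|^{-2a}: the power-law fractal
    factor times the flat nonfractal level.  The density is defined on
    (-pi, pi) excluding 0 whenever a_x + a_y > 0 (the long-memory pole).
    """
    a_x = _check_exponent(a_x, "a_x")
    a_y = _check_exponent(a_y, "a_y")
    f = np.asarray(f, dtype=float)
    if np.any(f == 0.0) and a_x + a_y > 0:
        raise ValueError("spectral density diverges at f=0 for a_x + a_y > 0")
    s = (
        eta_xy
        * (1.0 - np.exp(1j * f)) ** (-a_x)
        * (1.0 - np.exp(-1j * f)) ** (-a_y)
    )
    return s if s.ndim else complex(s)


def fin_autocovariance(a: float, sigma2: float, max_lag: int) -> np.ndarray:
    """Exact autocovariance gamma(0..max_lag) of univariate FIN.

    gamma(k) = sigma2 * Gamma(1-2a) Gamma(k+a) / (Gamma(a) Gamma(1-a)
    Gamma(k+1-a)), evaluated by the stable recursion
    gamma(k) = gamma(k-1) (k-1+a) / (k-a).  White noise (a = 0) gives
    [sigma2, 0, 0, ...].
    """
    a = _check_exponent(a)
    if sigma2 <= 0:
        raise ValueError("innovation variance sigma2 must be positive")
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    from scipy.special import gammaln

    gamma = np.empty(max_lag + 1)
    if a == 0.0:
        gamma[:] = 0.0
        gamma[0] = sigma2
        return gamma
    # gamma(0) = sigma2 * Gamma(1-2a) / Gamma(1-a)^2
    gamma[0] = sigma2 * np.exp(gammaln(1 - 2 * a) - 2 * gammaln(1 - a))
    for k in range(1, max_lag + 1):
        gamma[k] = gamma[k - 1] * (k - 1 + a) / (k - a)
    return gamma


def simulate_multivariate_fin(
    params: MemoryParams,
    cov: ShortMemoryCov,
    N: int,
    seed: int | np.random.SeedSequence,
    burn_in: int | None = None,
) -> TimeSeriesMatrix:
    """Simulate an N x v multivariate FIN sample path.

    Draws i.i.d. Gaussian innovation vectors M(t) ~ N(0, Sigma_m) and
    passes each channel through the truncated fractional-integration
    convolution; a burn-in stretch of max(N, 1000) samples (configurable)
    is generated and discarded so the retained block has effectively
    forgotten the zero initial condition.  The same seed reproduces the
    same array bit-for-bit.
    """
    if cov.n_channels != params.n_channels:
        raise ValueError(
            f"cov dimension {cov.n_channels} does not match "
            f"{params.n_channels} memory parameters"
        )
    if N < 16:
        raise ValueError("N must be >= 16")
    if burn_in is None:
        burn_in = max(N, 1000)
    total = N + burn_in
    rng = np.random.default_rng(seed)
    try:
        chol = np.linalg.cholesky(
            cov.eta + 1e-12 * np.trace(cov.eta) / cov.n_channels * np.eye(cov.n_channels)
        )
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by type
        raise ValueError(
            "innovation covariance is not positive semi-definite; "
            "cannot factorize for simulation"
        ) from exc
    innovations = rng.standard_normal((total, cov.n_channels)) @ chol.T
    from scipy.signal import fftconvolve

    out = np.empty((N, params.n_channels))
    for ch, a in enumerate(params.a):
        if a == 0.0:
            out[:, ch] = innovations[burn_in:, ch]
            continue
        h = fip_impulse_response(a, total)
        r = fftconvolve(innovations[:, ch], h)[:total]
        out[:, ch] = r[burn_in:]
    return TimeSeriesMatrix(out)


def generate_two_group_study(
    n_per_group: int = 30,
    v: int = 20,
    N: int = 256,
    base_cov: ShortMemoryCov | None = None,
    effect_edges: list[tuple[int, int]] | None = None,
    effect_delta: float = 0.4,
    a_range: tuple[float, float] = (0.1, 0.45),
    seed: int = 0,
) -> LabeledStudy:
    """Generate a synthetic two-group cohort of multivariate FIN subjects.

    Group 0 subjects use ``base_cov`` (identity correlation by default);
    group 1 subjects use ``base_cov`` with ``eta`` shifted by
    ``effect_delta`` on ``effect_edges`` — the group difference lives
    purely in the nonfractal (innovation) coupling, while every subject
    carries its own random exponents drawn uniformly from ``a_range``,
    which confounds raw-signal correlation with fractal scaling.  If the
    shifted covariance loses positive semi-definiteness it is projected to
    the nearest PSD matrix (with a warning).

    Subject-level seeds are spawned deterministically from the study seed,
    so individual subjects can be re-simulated in isolation.
    """
    if n_per_group < 2:
        raise ValueError(
            "n_per_group must be >= 2 (cross-validation downstream needs "
            "at least two subjects per group)"
        )
    if base_cov is None:
        base_cov = ShortMemoryCov(np.eye(v))
    if base_cov.n_channels != v:
        raise ValueError("base_cov dimension must equal v")
    lo, hi = a_range
    _check_exponent(lo, "a_range[0]")
    _check_exponent(hi, "a_range[1]")

    eta1 = base_cov.eta.copy()
    for x, y in effect_edges or []:
        if x == y:
            raise ValueError("effect edges must be off-diagonal")
        eta1[x, y] += effect_delta
        eta1[y, x] += effect_delta
    w, U = np.linalg.eigh(0.5 * (eta1 + eta1.T))
    if w.min() < -1e-10:
        warnings.warn(
            "shifted group-1 covariance lost positive semi-definiteness; "
            "projecting to the nearest PSD matrix",
            stacklevel=2,
        )
        eta1 = (U * np.clip(w, 0.0, None)) @ U.T
        eta1 = 0.5 * (eta1 + eta1.T)
        np.fill_diagonal(eta1, np.maximum(np.diag(eta1), 1e-6))
    group_covs = (base_cov, ShortMemoryCov(eta1))

    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(2 * n_per_group)
    subjects: list[TimeSeriesMatrix] = []
    labels: list[int] = []
    for i, ss in enumerate(subject_seeds):
        label = i // n_per_group
        rng = np.random.default_rng(ss.spawn(1)[0])
        a = MemoryParams(rng.uniform(lo, hi, size=v))
        subjects.append(
            simulate_multivariate_fin(a, group_covs[label], N, ss.spawn(1)[0])
        )
        labels.append(label)
    config = {
        "n_per_group": n_per_group,
        "v": v,
        "N": N,
        "effect_edges": [list(e) for e in (effect_edges or [])],
        "effect_delta": effect_delta,
        "a_range": list(a_range),
    }
    return LabeledStudy(tuple(subjects), np.asarray(labels), seed, config)
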