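"""Per-subject connectivity matrices: Pearson, fractal, nonfractal.

Three v x v symmetric matrices with unit diagonal summarize the coupling
of a multichannel recording:

* **pearson** — plain correlation of the raw series; confounded by any
  power-law (fractal) scaling the channels carry.
* **nonfractal** — correlation of the short-memory innovation
  covariances, A_{x,y} = eta_{x,y} / sqrt(eta_{x,x} eta_{y,y}); the
  fractal component is removed through the wavelet-domain estimates of
  the memory parameters and of eta.
* **fractal** — the asymptotic (coarse-scale limit) wavelet correlation,
  delta_inf_{x,y} = A_{x,y} beta_{x,y} / sqrt(beta_{x,x} beta_{y,y});
  equal channel exponents make the beta factors cancel, so fractal and
  nonfractal then coincide.

Because eta is estimated pairwise, the estimated matrix need not be
positive semi-definite; it is used entrywise downstream and a flag
records the violation.  Ratio estimates can leave [-1, 1] under noise and
are clipped, with the clip count reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lm_model import TimeSeriesMatrix
from .wavelet_fractal import (
    WaveletSpec,
    asymptotic_beta,
    default_depth,
    estimate_memory_parameter,
    estimate_short_memory_cov,
    wavelet_covariance,
    wavelet_decompose,
)

__all__ = [
    "ConnectivityMatrix",
    "pearson_connectivity",
    "nonfractal_connectivity",
    "fractal_connectivity",
    "connectivity_matrices",
]

KINDS = ("nonfractal", "fractal", "pearson")

#: scales with fewer coefficients than this are excluded from the
#: short-memory covariance regression: the log2 of a handful-of-samples
#: covariance is noisy enough to dominate the scale average and makes the
#: estimator inconsistent as N (and with it the default depth) grows
MIN_SCALE_COEFFS = 16


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric v x v connectivity with unit diagonal."""

    values: np.ndarray
    kind: str
    subject_id: str = ""
    a_hat: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_clipped: int = 0
    eta_psd: bool = True

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("connectivity must be square")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("connectivity must be symmetric")
        if not np.allclose(np.diag(values), 1.0, atol=1e-10):
            raise ValueError("connectivity diagonal must be 1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "a_hat", np.asarray(self.a_hat, dtype=float))

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def _as_array(ts: TimeSeriesMatrix | np.ndarray) -> np.ndarray:
    if isinstance(ts, TimeSeriesMatrix):
        return ts.values
    return np.asarray(ts, dtype=float)


def pearson_connectivity(
    ts: TimeSeriesMatrix | np.ndarray, subject_id: str = ""
) -> ConnectivityMatrix:
    """Pearson correlation matrix of the raw (mean-centred) channels."""
    x = _as_array(ts)
    bad = np.flatnonzero(np.ptp(x, axis=0) == 0.0)
    if bad.size:
        raise ValueError(f"constant region(s) {bad.tolist()}: correlation undefined")
    p = np.corrcoef(x, rowvar=False)
    p = np.clip(0.5 * (p + p.T), -1.0, 1.0)
    np.fill_diagonal(p, 1.0)
    return ConnectivityMatrix(p, "pearson", subject_id)


def _estimate_fractal_nonfractal(
    x: np.ndarray,
    Q: int | None,
    spec: WaveletSpec,
    q_range: np.ndarray | None,
    a_fixed: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Shared estimation path: (nonfractal A, fractal delta_inf, a_hat, n_clipped)."""
    n, v = x.shape
    if Q is None:
        Q = default_depth(n)
    a_hat = np.empty(v)
    coeffs = []
    for ch in range(v):
        if a_fixed is not None:
            a_hat[ch] = a_fixed[ch] if np.ndim(a_fixed) else float(a_fixed)
        else:
            try:
                a_hat[ch] = estimate_memory_parameter(x[:, ch]).a_hat
            except ValueError as exc:
                raise ValueError(f"region {ch}: {exc}") from exc
        coeffs.append(wavelet_decompose(x[:, ch], Q, spec))

    eta = np.empty((v, v))
    for i in range(v):
        for j in range(i, v):
            ups = wavelet_covariance(coeffs[i], coeffs[j], pair=(i, j))
            qr = q_range
            if qr is None:
                # drop the finest scale (band-approximation bias) and any
                # scale too sparse for a stable log2-covariance; keep at
                # least the three finest usable scales
                qr = [
                    q
                    for q in range(2, ups.n_scales + 1)
                    if ups.n_coeffs[q - 1] >= MIN_SCALE_COEFFS
                ]
                if len(qr) < 3:
                    qr = [
                        q
                        for q in range(2, ups.n_scales + 1)
                        if ups.n_coeffs[q - 1] >= 2
                    ][:3]
            try:
                eta[i, j] = eta[j, i] = estimate_short_memory_cov(
                    ups, a_hat[i], a_hat[j], qr
                )
            except ValueError as exc:
                raise ValueError(f"region pair ({i}, {j}): {exc}") from exc
    if np.any(np.diag(eta) <= 0):
        bad = np.flatnonzero(np.diag(eta) <= 0).tolist()
        raise ValueError(f"non-positive innovation variance for region(s) {bad}")

    d = np.sqrt(np.diag(eta))
    A = eta / np.outer(d, d)
    n_clipped = int(np.count_nonzero(np.abs(A) > 1.0) // 2)
    A = np.clip(0.5 * (A + A.T), -1.0, 1.0)
    np.fill_diagonal(A, 1.0)

    beta = np.array([[asymptotic_beta(ai, aj) for aj in a_hat] for ai in a_hat])
    bdiag = np.sqrt(np.diag(beta))
    delta_inf = A * beta / np.outer(bdiag, bdiag)
    delta_inf = np.clip(0.5 * (delta_inf + delta_inf.T), -1.0, 1.0)
    np.fill_diagonal(delta_inf, 1.0)
    return A, delta_inf, a_hat, n_clipped


def connectivity_matrices(
    ts: TimeSeriesMatrix | np.ndarray,
    kinds: tuple[str, ...] = KINDS,
    subject_id: str = "",
    Q: int | None = None,
    spec: WaveletSpec = WaveletSpec(),
    q_range: np.ndarray | None = None,
    a_fixed: np.ndarray | float | None = None,
) -> dict[str, ConnectivityMatrix]:
    """Compute the requested connectivity kinds in one pass.

    Fractal and nonfractal share the expensive per-channel ML estimation
    and pairwise wavelet covariances, so asking for both costs the same
    as asking for one.  ``a_fixed`` bypasses the per-channel ML step with
    known exponents (scalar or per-channel vector).
    """
    unknown = set(kinds) - set(KINDS)
    if unknown:
        raise ValueError(f"unknown connectivity kind(s) {sorted(unknown)}")
    x = _as_array(ts)
    out: dict[str, ConnectivityMatrix] = {}
    if "pearson" in kinds:
        out["pearson"] = pearson_connectivity(x, subject_id)
    if "nonfractal" in kinds or "fractal" in kinds:
        A, delta_inf, a_hat, n_clipped = _estimate_fractal_nonfractal(
            x, Q, spec, q_range, a_fixed
        )
        eta_psd = bool(np.linalg.eigvalsh(A).min() >= -1e-8)
        if "nonfractal" in kinds:
            out["nonfractal"] = ConnectivityMatrix(
                A, "nonfractal", subject_id, a_hat, n_clipped, eta_psd
            )
        if "fractal" in kinds:
            out["fractal"] = ConnectivityMatrix(
                delta_inf, "fractal", subject_id, a_hat, n_clipped, eta_psd
            )
    return out


def nonfractal_connectivity(
    ts: TimeSeriesMatrix | np.ndarray, subject_id: str = "", **kwargs
) -> ConnectivityMatrix:
    """Innovation-correlation (fractal-free) connectivity A_{x,y}."""
    return connectivity_matrices(ts, ("nonfractal",), subject_id, **kwargs)[
        "nonfractal"
    ]


def fractal_connectivity(
    ts: TimeSeriesMatrix | np.ndarray, subject_id: str = "", **kwargs
) -> ConnectivityMatrix:
    """Asymptotic wavelet-correlation connectivity delta_inf_{x,y}."""
    return connectivity_matrices(ts, ("fractal",), subject_id, **kwargs)["fractal"]
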