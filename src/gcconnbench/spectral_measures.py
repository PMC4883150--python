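"""Frequency-domain connectivity measures of a VAR model.

From a (true or fitted) VAR with coefficients A_r and innovation covariance
Sigma_w, this module evaluates on a grid of normalized frequencies
f in [0, 0.5):

* the coefficient spectrum  Abar(f) = I - sum_r A_r exp(-i 2 pi f r),
* the transfer function     H(f) = Abar(f)^-1,
* the power spectral density S(f) = H Sigma_w H^H,
* squared-magnitude information PDC and information DTF fields.

With abar_j(f) the j-th column of Abar and hbar_i(f) the i-th row of H,

    |iPDC_ij(f)|^2 = (|Abar_ij|^2 / sigma_ii) / (abar_j^H Sigma_w^-1 abar_j)
    |iDTF_ij(f)|^2 = (|H_ij|^2 * rho_jj) / (hbar_i Sigma_w hbar_i^H)

where sigma_ii = (Sigma_w)_ii and rho_jj = 1/(Sigma_w^-1)_jj is the partial
variance of innovation j given the others.  Both reduce to classical PDC and
DTF when Sigma_w = I.  iPDC quantifies *direct* (adjacent) influence; iDTF
quantifies total influence through all pathways, i.e. graph reachability.
Every squared entry lies in [0, 1] (Cauchy-Schwarz in the Sigma_w metric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulators import VARModel

__all__ = [
    "FrequencyGrid",
    "MeasureField",
    "frequency_response",
    "ipdc",
    "idtf",
    "spectral_density",
]


@dataclass
class FrequencyGrid:
    """Normalized frequencies (cycles/sample) in the half-open band [0, 0.5)."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 1 or self.freqs.size == 0:
            raise ValueError("freqs must be a non-empty 1-D array")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.freqs[0] < 0 or self.freqs[-1] >= 0.5:
            raise ValueError("freqs must lie in [0, 0.5)")

    @classmethod
    def uniform(cls, n_freqs: int = 32) -> "FrequencyGrid":
        """f_k = k / (2 n_freqs), k = 0..n_freqs-1 (default 32 points)."""
        if n_freqs < 1:
            raise ValueError("n_freqs must be >= 1")
        return cls(np.arange(n_freqs) / (2.0 * n_freqs))

    @property
    def n_freqs(self) -> int:
        return self.freqs.size


@dataclass
class MeasureField:
    """An (N, N, F) array of a squared-magnitude frequency-domain measure.

    ``values[i, j, k]`` refers to source j -> target i at ``grid.freqs[k]``.
    ``pvalues`` (same shape) is attached by the inference layer when
    asymptotic tests have been run.
    """

    kind: str
    values: np.ndarray
    grid: FrequencyGrid
    pvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"ipdc", "idtf", "pdc", "dtf", "spectrum"}:
            raise ValueError(f"unknown measure kind {self.kind!r}")
        self.values = np.asarray(self.values)
        if self.values.shape[-1] != self.grid.n_freqs:
            raise ValueError("last axis of values must match the frequency grid")


def _phases(order: int, freqs: np.ndarray) -> np.ndarray:
    """exp(-i 2 pi f r) for r = 1..p; shape (F, p)."""
    r = np.arange(1, order + 1)
    return np.exp(-2j * np.pi * freqs[:, None] * r[None, :])


def frequency_response(model: VARModel, grid: FrequencyGrid):
    """Coefficient spectrum Abar(f) and transfer function H(f) = Abar(f)^-1.

    Returns two complex arrays of shape (F, N, N).
    """
    n = model.n_channels
    ph = _phases(model.order, grid.freqs)  # (F, p)
    abar = np.eye(n)[None] - np.einsum("fr,rij->fij", ph, model.coeffs)
    try:
        h = np.linalg.inv(abar)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "coefficient spectrum Abar(f) singular on the grid "
            "(model on or outside the stability boundary)") from exc
    return abar, h


def ipdc(model: VARModel, grid: FrequencyGrid) -> MeasureField:
    """Squared information partial directed coherence field."""
    abar, _ = frequency_response(model, grid)
    sigma = model.innovation_cov
    sigma_inv = np.linalg.inv(sigma)
    sig_d = np.diag(sigma)
    # denominator per (f, source j): abar_j^H Sigma^-1 abar_j
    den = np.einsum("fkj,kl,flj->fj", abar.conj(), sigma_inv, abar).real
    num = (np.abs(abar) ** 2) / sig_d[None, :, None]
    vals = num / den[:, None, :]
    return MeasureField(kind="ipdc", values=np.moveaxis(vals, 0, -1), grid=grid)


def idtf(model: VARModel, grid: FrequencyGrid) -> MeasureField:
    """Squared information directed transfer function field."""
    _, h = frequency_response(model, grid)
    sigma = model.innovation_cov
    sigma_inv = np.linalg.inv(sigma)
    rho = 1.0 / np.diag(sigma_inv)
    den = np.einsum("fik,kl,fil->fi", h, sigma, h.conj()).real
    vals = (np.abs(h) ** 2) * rho[None, None, :] / den[:, :, None]
    return MeasureField(kind="idtf", values=np.moveaxis(vals, 0, -1), grid=grid)


def spectral_density(model: VARModel, grid: FrequencyGrid) -> MeasureField:
    """Power spectral density matrix S(f) = H(f) Sigma_w H(f)^H.

    The returned field holds |S_ij(f)| magnitudes off the diagonal and the
    (real, nonnegative) auto-spectra on the diagonal; the full complex matrix
    is available via :func:`frequency_response` if needed.
    """
    _, h = frequency_response(model, grid)
    s = np.einsum("fik,kl,fjl->fij", h, model.innovation_cov, h.conj())
    out = np.abs(s)
    d_idx = np.arange(model.n_channels)
    out[:, d_idx, d_idx] = s[:, d_idx, d_idx].real
    return MeasureField(kind="spectrum", values=np.moveaxis(out, 0, -1), grid=grid)
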