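"""Multichannel autoregressive model fitting.

Two classical estimators are provided:

* **Nuttall-Strand** — a multichannel Burg-type lattice.  At every stage the
  partial cross-covariance between forward and backward prediction errors is
  estimated by the harmonic-mean rule (a Sylvester equation in the error
  covariances), the reflection matrices follow, and coefficients are
  assembled by the multichannel Levinson recursion.  The construction keeps
  every fitted model stable.
* **LWR (Levinson-Wiggins-Robinson / Whittle)** — the recursive solution of
  the block-Toeplitz multivariate Yule-Walker equations built on biased
  (1/K) sample autocovariances.

Both lattices sweep all orders up to a maximum in a single pass, which makes
AIC order selection cheap.  The fitted object also carries the sample
covariance of the stacked lagged regressor vector, from which the standard
large-sample covariance of the coefficient estimates, (Gamma_p^-1 (x)
Sigma_w)/K, is formed.

Vectorization convention (used by every downstream quadratic form): the
coefficient a_ij(r) sits at position ``(r-1)*N*N + (j-1)*N + (i-1)`` of the
vectorized estimate — lag-major, source-channel next, target index fastest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_sylvester

from .simulators import MultichannelSeries, VARModel

__all__ = [
    "EstimatedVAR",
    "fit_nuttall_strand",
    "fit_yule_walker_lwr",
    "select_order_aic",
    "coefficient_covariance",
    "sample_autocovariances",
]

DEFAULT_P_MAX = 30


@dataclass
class EstimatedVAR:
    """A fitted VAR model plus the ingredients of its asymptotic statistics.

    Attributes
    ----------
    model
        Fitted coefficients and innovation covariance estimate.
    n_samples_used
        Record length K the fit was based on.
    regressor_cov
        ``(N*p, N*p)`` block-Toeplitz sample covariance Gamma_p of the
        stacked lag vector ``[x(t-1); ...; x(t-p)]``.
    method
        ``"nuttall_strand"`` or ``"lwr"``.
    aic_trace
        AIC value per candidate order 1..p_max when order selection was
        requested, else None.
    """

    model: VARModel
    n_samples_used: int
    regressor_cov: np.ndarray
    method: str
    aic_trace: np.ndarray | None = None
    _gamma_inv: np.ndarray | None = field(default=None, repr=False)

    @property
    def coeffs(self) -> np.ndarray:
        return self.model.coeffs

    @property
    def innovation_cov(self) -> np.ndarray:
        return self.model.innovation_cov

    @property
    def order(self) -> int:
        return self.model.order

    @property
    def n_channels(self) -> int:
        return self.model.n_channels

    def regressor_cov_inv(self) -> np.ndarray:
        """Inverse of Gamma_p, cached (symmetrized solve)."""
        if self._gamma_inv is None:
            g = self.regressor_cov
            try:
                inv = np.linalg.solve(g, np.eye(g.shape[0]))
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise np.linalg.LinAlgError(
                    "singular regressor covariance Gamma_p") from exc
            self._gamma_inv = 0.5 * (inv + inv.T)
        return self._gamma_inv


def _demean(series: MultichannelSeries) -> np.ndarray:
    x = np.asarray(series.values, dtype=float)
    return x - x.mean(axis=1, keepdims=True)


def sample_autocovariances(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased (1/K) sample autocovariances R(0..max_lag) of demeaned x.

    ``R[k] = (1/K) sum_t x(t) x(t-k)^T`` with shape (max_lag+1, N, N).  The
    1/K normalization keeps the block-Toeplitz covariance built from these
    matrices positive semi-definite.
    """
    n, k_len = x.shape
    if max_lag >= k_len:
        raise ValueError("max_lag must be below the record length")
    r = np.empty((max_lag + 1, n, n))
    for lag in range(max_lag + 1):
        r[lag] = x[:, lag:] @ x[:, : k_len - lag].T / k_len
    return r


def _block_toeplitz(r: np.ndarray, p: int) -> np.ndarray:
    """Gamma_p with block (u,v) = E[x(t-u) x(t-v)^T] = R(v-u) for v >= u."""
    n = r.shape[1]
    gamma = np.empty((n * p, n * p))
    for u in range(p):
        for v in range(p):
            blk = r[v - u] if v >= u else r[u - v].T
            gamma[u * n:(u + 1) * n, v * n:(v + 1) * n] = blk
    return gamma


def _aic(logdet: float, p: int, n: int, k: int) -> float:
    return logdet + 2.0 * p * n * n / k


def _check_order_args(series: MultichannelSeries, p_max: int) -> np.ndarray:
    x = _demean(series)
    n, k = x.shape
    if p_max < 1:
        raise ValueError("order must be >= 1")
    if k <= n * p_max:
        raise ValueError(
            f"record length K={k} too small for order {p_max} with N={n} channels")
    return x


# ---------------------------------------------------------------------------
# Nuttall-Strand lattice
# ---------------------------------------------------------------------------

def _nuttall_strand_sweep(x: np.ndarray, p_max: int):
    """Run the lattice to p_max; return per-order coefficients, innovation
    covariances and log-determinants.

    The stage-m partial cross-covariance rho solves the harmonic-mean
    (Sylvester) equation

        (Pf_hat Pf^-1) rho + rho (Pb^-1 Pb_hat) = 2 Pfb_hat

    where Pf/Pb are the model's forward/backward error covariances from the
    previous stage and the hatted quantities are empirical sums of the
    current prediction errors.  Reflection matrices are A_mm = rho Pb^-1 and
    B_mm = rho^T Pf^-1.
    """
    n, k = x.shape
    r0 = x @ x.T / k
    pf = r0.copy()
    pb = r0.copy()
    ef = x.copy()
    eb = x.copy()
    a_cur: list[np.ndarray] = []
    b_cur: list[np.ndarray] = []
    coeffs_per_order: list[np.ndarray] = []
    sigma_per_order: list[np.ndarray] = []
    logdet_per_order: list[float] = []
    for m in range(1, p_max + 1):
        eff = ef[:, m:]
        ebb = eb[:, m - 1:k - 1]
        pfhat = eff @ eff.T
        pbhat = ebb @ ebb.T
        pfbhat = eff @ ebb.T
        pf_inv = np.linalg.inv(pf)
        pb_inv = np.linalg.inv(pb)
        rho = solve_sylvester(pfhat @ pf_inv, pb_inv @ pbhat, 2.0 * pfbhat)
        a_mm = rho @ pb_inv
        b_mm = rho.T @ pf_inv
        # error and model-covariance updates
        ef_new = eff - a_mm @ ebb
        eb_new = ebb - b_mm @ eff
        ef[:, m:] = ef_new
        eb[:, m:] = eb_new
        pf = pf - a_mm @ rho.T
        pb = pb - b_mm @ rho
        pf = 0.5 * (pf + pf.T)
        pb = 0.5 * (pb + pb.T)
        # Levinson coefficient update
        a_new = [a_cur[i] - a_mm @ b_cur[m - 2 - i] for i in range(m - 1)]
        b_new = [b_cur[i] - b_mm @ a_cur[m - 2 - i] for i in range(m - 1)]
        a_cur = a_new + [a_mm]
        b_cur = b_new + [b_mm]
        coeffs_per_order.append(np.stack(a_cur))
        sigma_per_order.append(pf.copy())
        sign, logdet = np.linalg.slogdet(pf)
        if sign <= 0 or not np.isfinite(logdet):
            raise np.linalg.LinAlgError(
                f"singular forward-error covariance at lattice stage {m}")
        logdet_per_order.append(logdet)
    return coeffs_per_order, sigma_per_order, np.asarray(logdet_per_order)


def _capped_sweep(series: MultichannelSeries, p_max: int) -> int:
    """Largest identifiable candidate order: min(p_max, (K-1)//(2N))."""
    n, k = series.values.shape
    return max(1, min(p_max, (k - 1) // (2 * n)))


def fit_nuttall_strand(series: MultichannelSeries, order: int | None = None,
                       p_max: int = DEFAULT_P_MAX) -> EstimatedVAR:
    """Fit a VAR by the Nuttall-Strand multichannel Burg lattice.

    With ``order=None`` the order is chosen by AIC over 1..p_max (ties to
    the smaller order); the candidate range shrinks to (K-1)/(2N) on short
    records so the search stays identifiable.  With an explicit ``order``
    that order is used as given.
    """
    sweep_to = order if order is not None else _capped_sweep(series, p_max)
    x = _check_order_args(series, sweep_to)
    n, k = x.shape
    coeffs_all, sigma_all, logdets = _nuttall_strand_sweep(x, sweep_to)
    aic_trace = None
    if order is None:
        aic_trace = np.array([_aic(logdets[p - 1], p, n, k)
                              for p in range(1, sweep_to + 1)])
        order = int(np.argmin(aic_trace)) + 1
    coeffs = coeffs_all[order - 1]
    sigma = sigma_all[order - 1]
    r = sample_autocovariances(x, order)
    gamma = _block_toeplitz(r, order)
    model = VARModel(coeffs=coeffs, innovation_cov=_ensure_pd(sigma))
    return EstimatedVAR(model=model, n_samples_used=k, regressor_cov=gamma,
                        method="nuttall_strand", aic_trace=aic_trace)


def _ensure_pd(sigma: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    sigma = 0.5 * (sigma + sigma.T)
    evals = np.linalg.eigvalsh(sigma)
    if evals[0] <= 0:
        raise np.linalg.LinAlgError("innovation covariance estimate not positive definite")
    return sigma


# ---------------------------------------------------------------------------
# LWR / Whittle recursion
# ---------------------------------------------------------------------------

def _lwr_sweep(r: np.ndarray, p_max: int):
    """Whittle recursion on autocovariances R(0..p_max).

    Returns per-order forward coefficients, forward error covariances and
    their log-determinants.
    """
    r0 = r[0]
    r0_inv = np.linalg.inv(r0)
    a_cur = [r[1] @ r0_inv]
    b_cur = [r[1].T @ r0_inv]
    sf = r0 - a_cur[0] @ r[1].T
    sb = r0 - b_cur[0] @ r[1]
    coeffs_per_order = [np.stack(a_cur)]
    sigma_per_order = [0.5 * (sf + sf.T)]
    logdets = [_slogdet_pd(sf, 1)]
    for m in range(1, p_max):
        delta = r[m + 1] - sum(a_cur[i] @ r[m - i] for i in range(m))
        a_last = delta @ np.linalg.inv(sb)
        b_last = delta.T @ np.linalg.inv(sf)
        a_new = [a_cur[i] - a_last @ b_cur[m - 1 - i] for i in range(m)]
        b_new = [b_cur[i] - b_last @ a_cur[m - 1 - i] for i in range(m)]
        sf = sf - a_last @ delta.T
        sb = sb - b_last @ delta
        sf = 0.5 * (sf + sf.T)
        sb = 0.5 * (sb + sb.T)
        a_cur = a_new + [a_last]
        b_cur = b_new + [b_last]
        coeffs_per_order.append(np.stack(a_cur))
        sigma_per_order.append(sf.copy())
        logdets.append(_slogdet_pd(sf, m + 1))
    return coeffs_per_order, sigma_per_order, np.asarray(logdets)


def _slogdet_pd(mat: np.ndarray, stage: int) -> float:
    sign, logdet = np.linalg.slogdet(mat)
    if sign <= 0 or not np.isfinite(logdet):
        raise np.linalg.LinAlgError(
            f"singular prediction-error covariance at recursion stage {stage}")
    return logdet


def fit_yule_walker_lwr(series: MultichannelSeries, order: int | None = None,
                        p_max: int = DEFAULT_P_MAX) -> EstimatedVAR:
    """Fit a VAR by the LWR solution of the multivariate Yule-Walker system.

    Biased (1/K) sample autocovariances feed the Whittle recursion; with
    ``order=None`` the order minimizes AIC over 1..p_max (capped at
    (K-1)/(2N) on short records).
    """
    sweep_to = order if order is not None else _capped_sweep(series, p_max)
    x = _check_order_args(series, sweep_to)
    n, k = x.shape
    r = sample_autocovariances(x, sweep_to)
    if np.allclose(r[0], 0.0):
        raise np.linalg.LinAlgError("zero autocovariance: constant or empty series")
    coeffs_all, sigma_all, logdets = _lwr_sweep(r, sweep_to)
    aic_trace = None
    if order is None:
        aic_trace = np.array([_aic(logdets[p - 1], p, n, k)
                              for p in range(1, sweep_to + 1)])
        order = int(np.argmin(aic_trace)) + 1
    coeffs = coeffs_all[order - 1]
    sigma = sigma_all[order - 1]
    gamma = _block_toeplitz(r, order)
    model = VARModel(coeffs=coeffs, innovation_cov=_ensure_pd(sigma))
    return EstimatedVAR(model=model, n_samples_used=k, regressor_cov=gamma,
                        method="lwr", aic_trace=aic_trace)


_FITTERS = {"nuttall_strand": fit_nuttall_strand, "ns": fit_nuttall_strand,
            "lwr": fit_yule_walker_lwr, "yule_walker": fit_yule_walker_lwr}


def select_order_aic(series: MultichannelSeries, p_max: int = DEFAULT_P_MAX,
                     fitter: str = "nuttall_strand") -> int:
    """AIC-minimizing order over 1..p_max, AIC(p) = ln det Sigma_w(p) + 2 p N^2 / K."""
    fit = _FITTERS.get(fitter)
    if fit is None:
        raise ValueError(f"unknown fitter {fitter!r}")
    n, k = series.values.shape
    if not 1 <= p_max < k / (2 * n):
        raise ValueError(f"p_max={p_max} out of range [1, K/(2N)) = [1, {k / (2 * n):.1f})")
    est = fit(series, order=None, p_max=p_max)
    return est.order


def coefficient_covariance(est: EstimatedVAR) -> np.ndarray:
    """Asymptotic covariance of the vectorized coefficient estimates.

    Returns the ``(N^2 p, N^2 p)`` matrix ``(Gamma_p^-1 kron Sigma_w) / K``
    under the module's vectorization convention (lag-major, source next,
    target fastest).
    """
    k = est.n_samples_used
    return np.kron(est.regressor_cov_inv(), est.innovation_cov) / k


def pair_coefficient_covariance(est: EstimatedVAR, target: int, source: int) -> np.ndarray:
    """Covariance of the p-vector (a_ij(1), ..., a_ij(p)) for pair j -> i.

    This is the (i,j) sub-block of :func:`coefficient_covariance` extracted
    without forming the full Kronecker product.
    """
    n, p, k = est.n_channels, est.order, est.n_samples_used
    ginv = est.regressor_cov_inv()
    idx = source + n * np.arange(p)
    return ginv[np.ix_(idx, idx)] * est.innovation_cov[target, target] / k
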