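"""Null-hypothesis tests for absent Granger-causal connectivity.

Four detectors share the asymptotic framework of the fitted VAR:

* :func:`granger_causality_test` — time-domain Wald test of joint nullity of
  the lag coefficients from source to target; chi-square with p degrees of
  freedom.  (The chi-square form is used throughout, consistent with the
  large-sample framing; no finite-sample F variant.)
* :func:`pdc_asymptotic_pvalues` — per-frequency p-values for squared iPDC
  or iDTF.  Under the null the scaled squared measure is asymptotically a
  weighted sum of two one-degree chi-squares whose weights are the
  eigenvalues of the 2x2 covariance of the real and imaginary parts of the
  measure's numerator, obtained by projecting the coefficient covariance
  through the frequency map (delta method through H = Abar^-1 for iDTF).
* :func:`conditional_mvgc_test` — Geweke-style pairwise-conditional Granger
  causality: log-ratio of target residual variances between the reduced
  model (source channel removed, same order, LWR fit) and the full model;
  K * F is chi-square with p degrees of freedom under the null.
* :func:`weighted_chisq_tail` — tail evaluator for the weighted chi-square
  null: Patnaik's two-moment approximation by default, exact Imhof
  integration as a cross-check mode.

:func:`decide_connectivity` converts p-values into detection decisions: a
frequency-domain method detects a pair when *some* grid frequency falls
below alpha (a deliberately lax scan that inflates false positives), a
time-domain method when its single p-value does; optional Bonferroni or
Benjamini-Hochberg correction across the N(N-1) ordered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import chi2

from .simulators import MultichannelSeries
from .spectral_measures import FrequencyGrid, MeasureField, frequency_response, idtf, ipdc
from .var_estimation import (
    EstimatedVAR,
    fit_yule_walker_lwr,
    pair_coefficient_covariance,
)

__all__ = [
    "PairwiseTest",
    "WeightedChiSquareNull",
    "PairDecisionMatrix",
    "granger_causality_test",
    "gct_all_pairs",
    "pdc_asymptotic_pvalues",
    "weighted_chisq_tail",
    "conditional_mvgc_test",
    "cmvgc_all_pairs",
    "decide_connectivity",
]


@dataclass
class PairwiseTest:
    """Result of a single j -> i connectivity test."""

    target: int
    source: int
    statistic: float
    dof_or_weights: object
    p_value: float
    method: str


@dataclass
class WeightedChiSquareNull:
    """Null distribution sum_k lambda_k chi2_1 with nonnegative weights."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if not np.any(self.weights > 0):
            raise ValueError("at least one weight must be strictly positive")


@dataclass
class PairDecisionMatrix:
    """N x N boolean detections (diagonal always False)."""

    decisions: np.ndarray
    alpha: float
    correction: str = "none"

    def __post_init__(self) -> None:
        self.decisions = np.asarray(self.decisions, dtype=bool)
        np.fill_diagonal(self.decisions, False)


# ---------------------------------------------------------------------------
# Time-domain Granger causality (Wald)
# ---------------------------------------------------------------------------

def granger_causality_test(est: EstimatedVAR, target: int, source: int) -> PairwiseTest:
    """Wald test of H0: a_ij(1) = ... = a_ij(p) = 0 for the pair j -> i.

    The statistic is a^T C^-1 a with C the asymptotic covariance sub-block of
    the p coefficients from source to target; chi-square tail with p degrees
    of freedom.
    """
    if target == source:
        raise ValueError("Granger causality is defined for ordered pairs i != j")
    p = est.order
    a = est.coeffs[:, target, source]
    c = pair_coefficient_covariance(est, target, source)
    try:
        w = float(a @ np.linalg.solve(c, a))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular coefficient-covariance sub-block") from exc
    w = max(w, 0.0)
    return PairwiseTest(target=target, source=source, statistic=w,
                        dof_or_weights=p, p_value=float(chi2.sf(w, p)),
                        method="gct")


def gct_all_pairs(est: EstimatedVAR) -> np.ndarray:
    """GCT p-values for every ordered pair; (N, N) with NaN diagonal."""
    n = est.n_channels
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = granger_causality_test(est, i, j).p_value
    return out


# ---------------------------------------------------------------------------
# Weighted chi-square tail
# ---------------------------------------------------------------------------

def weighted_chisq_tail(statistic: float, null: WeightedChiSquareNull,
                        method: str = "patnaik") -> float:
    """P(sum_k lambda_k chi2_1 > statistic).

    ``method="patnaik"`` matches the first two moments with a scaled
    chi-square g * chi2_h (g = sum lambda^2 / sum lambda, h = (sum lambda)^2
    / sum lambda^2); ``method="imhof"`` integrates the exact characteristic
    function numerically.
    """
    if statistic < 0:
        raise ValueError("statistic must be nonnegative")
    if statistic == 0:
        return 1.0
    lam = null.weights[null.weights > 0]
    if method == "patnaik":
        s1 = lam.sum()
        s2 = (lam ** 2).sum()
        g = s2 / s1
        h = s1 ** 2 / s2
        return float(chi2.sf(statistic / g, h))
    if method == "imhof":
        return _imhof_tail(statistic, lam)
    raise ValueError(f"unknown tail method {method!r}")


def _imhof_tail(x: float, lam: np.ndarray) -> float:
    """Imhof (1961) inversion for P(Q > x), Q = sum lambda_k chi2_1."""

    def theta(u):
        return 0.5 * np.sum(np.arctan(lam[:, None] * u), axis=0) - 0.5 * x * u

    def rho(u):
        return np.prod((1.0 + (lam[:, None] * u) ** 2) ** 0.25, axis=0)

    def integrand(u):
        u = np.atleast_1d(u)
        return np.sin(theta(u)) / (u * rho(u))

    import warnings

    with warnings.catch_warnings():
        # the oscillatory integrand triggers a subdivision-limit warning long
        # after the quadrature has converged to ~1e-4, ample for a cross-check
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(lambda u: float(integrand(u)[0]), 0.0, np.inf,
                                limit=1000)
    return float(np.clip(0.5 + val / np.pi, 0.0, 1.0))


def _patnaik_sf_two(stat: np.ndarray, l1: np.ndarray, l2: np.ndarray) -> np.ndarray:
    """Vectorized Patnaik tail for at most two weights (l2 may be ~0)."""
    l2 = np.where(l2 > 1e-14 * np.maximum(l1, 1e-300), l2, 0.0)
    # the tail is invariant under joint rescaling of weights and statistic
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        scale = np.maximum(np.maximum(l1, l2), 1e-300)
        u1, u2, us = l1 / scale, l2 / scale, stat / scale
        s1 = u1 + u2
        s2 = u1 ** 2 + u2 ** 2
        g = s2 / s1
        h = s1 ** 2 / s2
        p = chi2.sf(us / g, h)
    return np.where((l1 + l2) > 0, p, np.where(stat > 0, 0.0, 1.0))


# ---------------------------------------------------------------------------
# iPDC / iDTF asymptotic p-values
# ---------------------------------------------------------------------------

def pdc_asymptotic_pvalues(est: EstimatedVAR, grid: FrequencyGrid,
                           measure: str = "ipdc") -> MeasureField:
    """Per-pair, per-frequency null p-values for squared iPDC or iDTF.

    Under H0 (zero measure for j -> i at f), K times the squared estimated
    measure is asymptotically  lambda_1 chi2_1 + lambda_2 chi2_1, where the
    lambdas are the eigenvalues of the 2x2 covariance of [Re, Im] of the
    measure's numerator (the coefficient covariance projected through
    cos/sin frequency maps, or through dH = H dAbar H for iDTF), divided by
    the measure's estimated denominator.  Tail probabilities use the Patnaik
    approximation.  The returned field carries both the squared measure and
    the p-values; diagonal entries have NaN p-values.
    """
    if measure not in {"ipdc", "idtf"}:
        raise ValueError("measure must be 'ipdc' or 'idtf'")
    field = (ipdc if measure == "ipdc" else idtf)(est.model, grid)
    n, p, k = est.n_channels, est.order, est.n_samples_used
    sigma = est.innovation_cov
    ginv = est.regressor_cov_inv()
    freqs = grid.freqs
    nf = freqs.size
    stat = k * field.values  # (N, N, F)

    if measure == "ipdc":
        cosm = np.cos(2 * np.pi * np.outer(freqs, np.arange(1, p + 1)))  # (F, p)
        sinm = np.sin(2 * np.pi * np.outer(freqs, np.arange(1, p + 1)))
        abar, _ = frequency_response(est.model, grid)
        sigma_inv = np.linalg.inv(sigma)
        den_j = np.einsum("fkj,kl,flj->fj", abar.conj(), sigma_inv, abar).real  # (F, N)
        l1 = np.zeros((n, n, nf))
        l2 = np.zeros((n, n, nf))
        for j in range(n):
            idx = j + n * np.arange(p)
            gsub = ginv[np.ix_(idx, idx)]  # (p, p), shared across targets
            cc = np.einsum("fp,pq,fq->f", cosm, gsub, cosm)
            ss = np.einsum("fp,pq,fq->f", sinm, gsub, sinm)
            cs = np.einsum("fp,pq,fq->f", cosm, gsub, sinm)
            # Var[Re, Im] of Abar_ij carries sigma_ii from the Kronecker
            # factor; the numerator |Abar_ij|^2 / sigma_ii cancels it, so the
            # null weights reduce to eig / den_j for every target i.
            e1, e2 = _eig2(cc, ss, cs)
            for i in range(n):
                if i == j:
                    continue
                l1[i, j] = e1 / den_j[:, j]
                l2[i, j] = e2 / den_j[:, j]
        field.pvalues = _assemble_pvals(stat, l1, l2, n)
        return field

    # iDTF: delta method through H = Abar^-1
    _, h = frequency_response(est.model, grid)  # (F, N, N)
    sigma_inv = np.linalg.inv(sigma)
    rho = 1.0 / np.diag(sigma_inv)
    den_i = np.einsum("fik,kl,fil->fi", h, sigma, h.conj()).real  # (F, N)
    phases = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, p + 1)))  # (F, p)
    l1 = np.zeros((n, n, nf))
    l2 = np.zeros((n, n, nf))
    for j in range(n):
        # b[(r,l)] = phase_r * H_lj ; shape (F, p*N)
        b = (phases[:, :, None] * h[:, None, :, j]).reshape(nf, p * n)
        br, bi = b.real, b.imag
        prr = np.einsum("fu,uv,fv->f", br, ginv, br)
        pii = np.einsum("fu,uv,fv->f", bi, ginv, bi)
        pri = np.einsum("fu,uv,fv->f", br, ginv, bi)
        for i in range(n):
            if i == j:
                continue
            a_vec = h[:, i, :]  # (F, N) row i of H
            ar, ai = a_vec.real, a_vec.imag
            srr = np.einsum("fk,kl,fl->f", ar, sigma, ar)
            sii = np.einsum("fk,kl,fl->f", ai, sigma, ai)
            sri = np.einsum("fk,kl,fl->f", ar, sigma, ai)
            q_rr = prr * srr - 2.0 * pri * sri + pii * sii
            q_ii = prr * sii + 2.0 * pri * sri + pii * srr
            q_ri = prr * sri + pri * srr - pri * sii - pii * sri
            e1, e2 = _eig2(q_rr, q_ii, q_ri)
            w_scale = rho[j] / den_i[:, i]
            l1[i, j] = e1 * w_scale
            l2[i, j] = e2 * w_scale
    field.pvalues = _assemble_pvals(stat, l1, l2, n)
    return field


def _eig2(a: np.ndarray, d: np.ndarray, b: np.ndarray):
    """Eigenvalues of symmetric [[a, b], [b, d]], elementwise arrays."""
    tr = a + d
    disc = np.sqrt(np.maximum((a - d) ** 2 + 4.0 * b ** 2, 0.0))
    e1 = 0.5 * (tr + disc)
    e2 = 0.5 * (tr - disc)
    return np.maximum(e1, 0.0), np.maximum(e2, 0.0)


def _assemble_pvals(stat: np.ndarray, l1: np.ndarray, l2: np.ndarray, n: int) -> np.ndarray:
    pvals = _patnaik_sf_two(stat, l1, l2)
    d = np.arange(n)
    pvals[d, d, :] = np.nan
    return pvals


# ---------------------------------------------------------------------------
# Pairwise-conditional multivariate Granger causality
# ---------------------------------------------------------------------------

def cmvgc_all_pairs(series: MultichannelSeries, order: int) -> np.ndarray:
    """Conditional Granger-causality p-values for all ordered pairs.

    For each source j the reduced model drops channel j and is refit by LWR
    at the same order; F_{j->i|rest} = ln(var_reduced_ii / var_full_ii) and
    K * F is referred to the chi-square with ``order`` degrees of freedom.
    Tiny negative log-ratios (numerical) are clipped to zero.  Returns an
    (N, N) array with NaN diagonal.
    """
    n = series.n_channels
    k = series.n_samples
    full = fit_yule_walker_lwr(series, order=order)
    sig_full = np.diag(full.innovation_cov)
    out = np.full((n, n), np.nan)
    for j in range(n):
        keep = [c for c in range(n) if c != j]
        red_series = MultichannelSeries(values=series.values[keep],
                                        labels=[series.labels[c] for c in keep])
        red = fit_yule_walker_lwr(red_series, order=order)
        sig_red = np.diag(red.innovation_cov)
        for pos, i in enumerate(keep):
            f_stat = np.log(sig_red[pos] / sig_full[i])
            f_stat = max(f_stat, 0.0)
            out[i, j] = chi2.sf(k * f_stat, order)
    return out


def conditional_mvgc_test(series: MultichannelSeries, target: int, source: int,
                          order: int) -> PairwiseTest:
    """Geweke-style conditional GC test of source -> target given the rest."""
    if target == source:
        raise ValueError("conditional GC is defined for ordered pairs i != j")
    k = series.n_samples
    full = fit_yule_walker_lwr(series, order=order)
    keep = [c for c in range(series.n_channels) if c != source]
    red_series = MultichannelSeries(values=series.values[keep],
                                    labels=[series.labels[c] for c in keep])
    red = fit_yule_walker_lwr(red_series, order=order)
    f_stat = np.log(red.innovation_cov[keep.index(target), keep.index(target)]
                    / full.innovation_cov[target, target])
    f_stat = max(float(f_stat), 0.0)
    stat = k * f_stat
    return PairwiseTest(target=target, source=source, statistic=stat,
                        dof_or_weights=order, p_value=float(chi2.sf(stat, order)),
                        method="cmvgc")


# ---------------------------------------------------------------------------
# Detection decisions
# ---------------------------------------------------------------------------

def scalarize_pvalues(pvalues: np.ndarray) -> np.ndarray:
    """Reduce a per-frequency p-value field to its per-pair minimum."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.ndim == 3:
        out = np.full(pvalues.shape[:2], np.nan)
        mask = ~np.all(np.isnan(pvalues), axis=2)
        if np.any(mask):
            out[mask] = np.nanmin(pvalues[mask], axis=-1)
        return out
    if pvalues.ndim == 2:
        return pvalues
    raise ValueError("p-values must be (N, N) or (N, N, F)")


def decide_connectivity(pvalues: np.ndarray, alpha: float = 0.01,
                        correction: str = "none") -> PairDecisionMatrix:
    """Detection decisions from per-pair (or per-pair-per-frequency) p-values.

    A frequency-resolved array is first reduced to its minimum over the
    grid ("significant at some frequency").  ``correction`` in
    {"none", "bonferroni", "fdr_bh"} adjusts across the N(N-1) ordered pairs.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    pmat = scalarize_pvalues(pvalues)
    n = pmat.shape[0]
    if pmat.shape != (n, n):
        raise ValueError("p-value matrix must be square")
    off = ~np.eye(n, dtype=bool)
    pvec = pmat[off]
    if np.any(np.isnan(pvec)):
        raise ValueError("NaN p-value on an off-diagonal pair")
    if correction == "none":
        rej = pvec < alpha
    elif correction == "bonferroni":
        rej = np.minimum(pvec * pvec.size, 1.0) < alpha
    elif correction == "fdr_bh":
        from statsmodels.stats.multitest import multipletests
        rej = multipletests(pvec, alpha=alpha, method="fdr_bh")[0]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    decisions = np.zeros((n, n), dtype=bool)
    decisions[off] = rej
    return PairDecisionMatrix(decisions=decisions, alpha=alpha, correction=correction)
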