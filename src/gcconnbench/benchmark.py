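"""Monte Carlo harness: detection-rate benchmarking of connectivity tests.

The experiment replicates, per (model, record length K), many independent
simulations; applies each requested detector to every ordered channel pair;
archives the per-pair p-values (frequency-domain methods contribute their
minimum over the grid, matching the any-frequency detection rule); and
scores detections against ground truth.  Estimator pairing follows the study
protocol: Nuttall-Strand with AIC order selection feeds GCT, iPDC and iDTF,
while the LWR Yule-Walker fit feeds conditional MVGC.

Scoring truth differs by what a method measures: GCT, iPDC and cMVGC are
scored against direct adjacency, iDTF against reachability (it responds to
influence through any pathway).  False-positive rates are defined on absent
pairs, false-negative rates on present pairs; diagonals never count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import cmvgc_all_pairs, gct_all_pairs, pdc_asymptotic_pvalues, \
    decide_connectivity, scalarize_pvalues
from .simulators import Model3Params, MultichannelSeries, TruthGraph, \
    simulate_model1, simulate_model2, simulate_model3, truth_graph
from .spectral_measures import FrequencyGrid
from .var_estimation import fit_nuttall_strand, fit_yule_walker_lwr

__all__ = [
    "BenchmarkConfig",
    "BenchmarkResult",
    "SlopeComparison",
    "run_benchmark",
    "count_fp_fn",
    "slope_comparison",
    "summarize_neglog10",
    "truth_matrix_for_method",
]

ALL_METHODS = ("gct", "ipdc", "idtf", "cmvgc")
_NS_METHODS = {"gct", "ipdc", "idtf"}


@dataclass
class BenchmarkConfig:
    """Settings of one Monte Carlo experiment.

    Defaults mirror the study conditions: 1000 replications, alpha = 1%,
    burn-in 5000 samples, 32-point frequency grid, AIC order search up to 30.
    """

    model_id: str
    methods: tuple = ALL_METHODS
    k_values: tuple = (100, 200, 500, 1000, 2000, 5000, 10000)
    n_reps: int = 1000
    alpha: float = 0.01
    burn_in: int = 5000
    n_freqs: int = 32
    p_max: int = 30
    master_seed: int = 0
    correction: str = "none"
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.model_id not in {"model1", "model2", "model3"}:
            raise ValueError(f"unknown model id {self.model_id!r}")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        if self.n_reps < 0:
            raise ValueError("n_reps must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class BenchmarkResult:
    """Archived p-values and bookkeeping of one experiment.

    ``pvalues[(method, k)]`` is an ``(n_reps, N, N)`` array of per-pair
    p-values (NaN diagonal; frequency-domain methods already reduced to the
    minimum over the grid).  Trials that failed carry NaN everywhere and are
    listed in ``failures[k]``.
    """

    config: BenchmarkConfig
    pvalues: dict = field(default_factory=dict)
    orders: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)

    @property
    def truth(self) -> TruthGraph:
        return truth_graph(self.config.model_id)

    def n_valid(self, method: str, k: int) -> int:
        arr = self.pvalues[(method, k)]
        if arr.shape[0] == 0:
            return 0
        off = ~np.eye(arr.shape[1], dtype=bool)
        return int(np.sum(~np.isnan(arr[:, off]).any(axis=1)))


def truth_matrix_for_method(truth: TruthGraph, method: str) -> np.ndarray:
    """Ground-truth boolean matrix a method is scored against.

    iDTF measures influence through any pathway and is scored against
    reachability; the adjacency-oriented methods (gct, ipdc, cmvgc) against
    direct edges.
    """
    return truth.reachability if method == "idtf" else truth.adjacency


def _simulate_trial(model_id: str, k: int, trial_ss: np.random.SeedSequence,
                    burn_in: int) -> MultichannelSeries:
    if model_id == "model1":
        return simulate_model1(k, seed=trial_ss, burn_in=burn_in)
    if model_id == "model2":
        return simulate_model2(k, seed=trial_ss, burn_in=burn_in)
    # Model 3: exogenous mixing weights a ~ U(0,1) are redrawn every trial
    params_rng = np.random.default_rng(trial_ss.generate_state(4))
    params = Model3Params.draw(params_rng)
    return simulate_model3(k, seed=trial_ss, params=params, burn_in=burn_in)


def _run_trial(model_id: str, k: int, trial_ss, methods, burn_in: int,
               p_max: int, grid: FrequencyGrid):
    """One simulation + all requested detectors; returns per-method (N, N)
    p-value matrices plus the selected orders."""
    series = _simulate_trial(model_id, k, trial_ss, burn_in)
    out = {}
    orders = {}
    if _NS_METHODS & set(methods):
        est = fit_nuttall_strand(series, order=None, p_max=p_max)
        orders["ns"] = est.order
        if "gct" in methods:
            out["gct"] = gct_all_pairs(est)
        for meas in ("ipdc", "idtf"):
            if meas in methods:
                fld = pdc_asymptotic_pvalues(est, grid, meas)
                out[meas] = scalarize_pvalues(fld.pvalues)
    if "cmvgc" in methods:
        lwr = fit_yule_walker_lwr(series, order=None, p_max=p_max)
        orders["lwr"] = lwr.order
        out["cmvgc"] = cmvgc_all_pairs(series, lwr.order)
    return out, orders


def run_benchmark(config: BenchmarkConfig) -> BenchmarkResult:
    """Run the full Monte Carlo experiment described by ``config``.

    Deterministic given ``master_seed`` regardless of ``n_jobs``: every trial
    owns an independent substream spawned from the master seed.  A trial on
    which any stage fails (e.g. a singular fit) is recorded in
    ``failures`` and excluded from all counts; nothing is dropped silently.
    """
    from .simulators import _N_CHANNELS

    n = _N_CHANNELS[config.model_id]
    grid = FrequencyGrid.uniform(config.n_freqs)
    result = BenchmarkResult(config=config)
    k_streams = {k: np.random.SeedSequence((config.master_seed, ki))
                 for ki, k in enumerate(config.k_values)}
    for k in config.k_values:
        trial_seeds = k_streams[k].spawn(config.n_reps)
        args = [(config.model_id, k, trial_seeds[t], config.methods,
                 config.burn_in, config.p_max, grid)
                for t in range(config.n_reps)]
        if config.n_jobs != 1:
            from joblib import Parallel, delayed
            raw = Parallel(n_jobs=config.n_jobs)(
                delayed(_safe_trial)(*a) for a in args)
        else:
            raw = [_safe_trial(*a) for a in args]
        arch = {m: np.full((config.n_reps, n, n), np.nan) for m in config.methods}
        ords = {est: np.full(config.n_reps, -1, dtype=int) for est in ("ns", "lwr")}
        fails = []
        for t, item in enumerate(raw):
            if isinstance(item, str):
                fails.append((t, item))
                continue
            out, orders = item
            for m, mat in out.items():
                arch[m][t] = mat
            for est_name, order in orders.items():
                ords[est_name][t] = order
        for m in config.methods:
            result.pvalues[(m, k)] = arch[m]
        result.orders[k] = ords
        result.failures[k] = fails
    return result


def _safe_trial(*args):
    try:
        return _run_trial(*args)
    except (np.linalg.LinAlgError, ValueError) as exc:
        return f"{type(exc).__name__}: {exc}"


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def count_fp_fn(result: BenchmarkResult, truth: TruthGraph | None = None,
                alpha: float | None = None, correction: str | None = None):
    """False-positive / false-negative accounting against ground truth.

    Returns ``(per_pair, summary)`` DataFrames.  ``per_pair`` has one row per
    (method, K, ordered pair) with the detection count over valid trials;
    ``summary`` aggregates FP rates (min/median/max over absent pairs) and
    the pooled FN rate over present pairs.  FP + TN = FN + TP = n_valid on
    every pair by construction.
    """
    cfg = result.config
    alpha = cfg.alpha if alpha is None else alpha
    correction = cfg.correction if correction is None else correction
    base_truth = result.truth if truth is None else truth
    rows = []
    for (method, k), arr in sorted(result.pvalues.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        tmat = truth_matrix_for_method(base_truth, method)
        n = arr.shape[1]
        off = ~np.eye(n, dtype=bool)
        valid = ~np.isnan(arr[:, off]).any(axis=1)
        det = np.zeros((n, n), dtype=int)
        for t in np.flatnonzero(valid):
            det += decide_connectivity(arr[t], alpha=alpha, correction=correction).decisions
        nv = int(valid.sum())
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                present = bool(tmat[i, j])
                rows.append({"method": method, "k": k, "target": i + 1,
                             "source": j + 1, "present": present,
                             "n_valid": nv, "detected": int(det[i, j]),
                             "fp_rate": np.nan if present else det[i, j] / max(nv, 1),
                             "fn_rate": (nv - det[i, j]) / max(nv, 1) if present else np.nan})
    per_pair = pd.DataFrame(rows)
    summ = []
    for (method, k), g in per_pair.groupby(["method", "k"], sort=True):
        absent = g[~g["present"]]
        present = g[g["present"]]
        summ.append({
            "method": method, "k": k, "n_valid": int(g["n_valid"].iloc[0]),
            "fp_min": absent["fp_rate"].min(), "fp_median": absent["fp_rate"].median(),
            "fp_max": absent["fp_rate"].max(),
            "fn_pooled": (present["fn_rate"] * present["n_valid"]).sum()
                          / max((present["n_valid"]).sum(), 1),
            "fn_max": present["fn_rate"].max() if len(present) else np.nan,
        })
    return per_pair, pd.DataFrame(summ)


@dataclass
class SlopeComparison:
    """Per-pair through-origin slopes of -log10 p between two methods."""

    method_a: str
    method_b: str
    k: int
    slopes: np.ndarray              # (N, N), NaN diagonal
    fp_counts_a: np.ndarray
    fp_counts_b: np.ndarray
    mean: float
    sd: float
    median: float
    min: float
    max: float


def slope_comparison(result: BenchmarkResult, method_a: str, method_b: str,
                     k: int, alpha: float | None = None) -> SlopeComparison:
    """Trial-by-trial comparison of two detectors on shared simulations.

    For every ordered pair the least-squares slope through the origin of
    y = -log10 p(method_a) on x = -log10 p(method_b) across trials is
    computed (shared seeds make the trials strictly paired); aggregates are
    taken across off-diagonal pairs.  FP counts of both methods are reported
    alongside, as in the scatter summaries of the study.
    """
    cfg = result.config
    alpha = cfg.alpha if alpha is None else alpha
    pa = result.pvalues[(method_a, k)]
    pb = result.pvalues[(method_b, k)]
    if pa.shape != pb.shape:
        raise ValueError("methods were run with different trial sets")
    n = pa.shape[1]
    off = ~np.eye(n, dtype=bool)
    valid = ~(np.isnan(pa[:, off]).any(axis=1) | np.isnan(pb[:, off]).any(axis=1))
    pa, pb = pa[valid], pb[valid]
    tiny = np.finfo(float).tiny
    ya = -np.log10(np.clip(pa, tiny, None))
    xb = -np.log10(np.clip(pb, tiny, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.nansum(ya * xb, axis=0)
        den = np.nansum(xb * xb, axis=0)
        slopes = num / den
    slopes[~off] = np.nan
    truth = result.truth
    fa = ((pa < alpha) & ~truth_matrix_for_method(truth, method_a)[None]).sum(axis=0)
    fb = ((pb < alpha) & ~truth_matrix_for_method(truth, method_b)[None]).sum(axis=0)
    fa[~off] = 0
    fb[~off] = 0
    s = slopes[off]
    return SlopeComparison(method_a=method_a, method_b=method_b, k=k,
                           slopes=slopes, fp_counts_a=fa, fp_counts_b=fb,
                           mean=float(np.mean(s)), sd=float(np.std(s, ddof=1)),
                           median=float(np.median(s)), min=float(np.min(s)),
                           max=float(np.max(s)))


def summarize_neglog10(result: BenchmarkResult) -> pd.DataFrame:
    """Five-number summaries of -log10 p per (method, K, ordered pair).

    Whiskers follow the 1.5 IQR rule; ``outliers_above_threshold`` counts
    outlying trials whose -log10 p crosses the rejection line
    -log10(alpha).
    """
    thresh = -np.log10(result.config.alpha)
    tiny = np.finfo(float).tiny
    rows = []
    for (method, k), arr in sorted(result.pvalues.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        n = arr.shape[1]
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                vals = arr[:, i, j]
                vals = vals[~np.isnan(vals)]
                if vals.size == 0:
                    continue
                nl = -np.log10(np.clip(vals, tiny, None))
                q1, med, q3 = np.percentile(nl, [25, 50, 75])
                iqr = q3 - q1
                lo_w = nl[nl >= q1 - 1.5 * iqr].min()
                hi_w = nl[nl <= q3 + 1.5 * iqr].max()
                outliers = nl[(nl < q1 - 1.5 * iqr) | (nl > q3 + 1.5 * iqr)]
                rows.append({"method": method, "k": k, "target": i + 1,
                             "source": j + 1, "q1": q1, "median": med, "q3": q3,
                             "whisker_lo": lo_w, "whisker_hi": hi_w,
                             "n_outliers": int(outliers.size),
                             "outliers_above_threshold": int((outliers > thresh).sum()),
                             "crosses_threshold": bool((nl > thresh).any())})
    return pd.DataFrame(rows)
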