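"""Synthetic multichannel time series from vector-autoregressive toy models.

Three benchmark networks are built in:

* **Model 1** — a 7-channel system with two disconnected substructures: a
  5-node closed loop ``{x1..x5}`` containing a resonant oscillator in ``x1``,
  and an isolated driven pair ``{x6, x7}`` sharing the same oscillation
  frequency.
* **Model 2** — a 5-channel system in which ``x1`` (the oscillator) drives
  ``x2``, ``x3`` and ``x4``, while ``x4`` and ``x5`` form a feedback loop.
* **Model 3** — Model 2's autoregressive skeleton driven by disturbances
  contaminated with a shared exogenous input ``e6(t)`` and a latent, serially
  correlated source ``e7`` entering at lags 1 and 2.  The resulting process
  is *not* a finite-order VAR; it exists to stress-test detectors whose
  theory assumes one.

All generators use zero initial state, discard a long burn-in (default 5000
samples) and draw each innovation source from its own counter-based
substream of the master seed, so that Model 3 with all mixing weights set to
zero reproduces Model 2 sample for sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VARModel",
    "Model3Params",
    "MultichannelSeries",
    "TruthGraph",
    "model1_var",
    "model2_var",
    "simulate_var",
    "simulate_model1",
    "simulate_model2",
    "simulate_model3",
    "truth_graph",
]

_SQ2 = np.sqrt(2.0)

DEFAULT_BURN_IN = 5000


@dataclass
class VARModel:
    """A vector-autoregressive process x(t) = sum_r A_r x(t-r) + w(t).

    Parameters
    ----------
    coeffs
        Array of shape ``(p, N, N)``; ``coeffs[r-1, i, j]`` is the weight
        a_ij(r) of channel ``j`` at lag ``r`` in the equation of channel
        ``i``.
    innovation_cov
        ``N x N`` symmetric positive-definite covariance of the Gaussian
        innovations ``w(t)``.  Defaults to the identity.
    """

    coeffs: np.ndarray
    innovation_cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != self.coeffs.shape[2]:
            raise ValueError("coeffs must have shape (p, N, N)")
        n = self.coeffs.shape[1]
        if self.innovation_cov is None:
            self.innovation_cov = np.eye(n)
        self.innovation_cov = np.asarray(self.innovation_cov, dtype=float)
        if self.innovation_cov.shape != (n, n):
            raise ValueError("innovation_cov must be N x N")
        if not np.allclose(self.innovation_cov, self.innovation_cov.T):
            raise ValueError("innovation_cov must be symmetric")
        # positive definiteness check; raises LinAlgError if not PD
        np.linalg.cholesky(self.innovation_cov)

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    def companion(self) -> np.ndarray:
        """Companion (state-transition) matrix of the stacked lag vector."""
        p, n = self.order, self.n_channels
        comp = np.zeros((n * p, n * p))
        comp[:n] = self.coeffs.transpose(1, 0, 2).reshape(n, n * p)
        if p > 1:
            comp[n:, :-n] = np.eye(n * (p - 1))
        return comp

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def is_stable(self, tol: float = 1e-8) -> bool:
        return self.spectral_radius() < 1.0 - tol


@dataclass
class Model3Params:
    """Mixing weights of Model 3's composite disturbance.

    Channel i receives ``e_i(t) + a[i]*e6(t) + b[i]*e7(t-1) + c[i]*e7(t-2)``.
    The study draws ``a`` uniformly on [0, 1] afresh for every simulated
    trial and keeps ``b = 2`` and ``c = 5`` on every channel.
    """

    a: np.ndarray
    b: np.ndarray = field(default_factory=lambda: np.full(5, 2.0))
    c: np.ndarray = field(default_factory=lambda: np.full(5, 5.0))

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        for name, v in (("a", self.a), ("b", self.b), ("c", self.c)):
            if v.shape != (5,):
                raise ValueError(f"Model3Params.{name} must have length 5")
        if np.any(self.a < 0) or np.any(self.a > 1):
            raise ValueError("Model3Params.a entries must lie in [0, 1]")

    @classmethod
    def draw(cls, rng: np.random.Generator) -> "Model3Params":
        """Draw ``a ~ U(0,1)`` per channel with the default b and c."""
        return cls(a=rng.uniform(0.0, 1.0, size=5))


@dataclass
class MultichannelSeries:
    """N channels x K samples of real values with generation provenance."""

    values: np.ndarray
    labels: list[str] | None = None
    provenance: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (channels x samples) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series contains non-finite values")
        if self.labels is None:
            self.labels = [f"x{i + 1}" for i in range(self.values.shape[0])]
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("one label per channel required")
        if self.provenance is None:
            self.provenance = {}

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class TruthGraph:
    """Ground-truth connectivity: direct edges and directed reachability.

    ``adjacency[i, j]`` is True iff channel ``j`` enters channel ``i``'s
    equation directly (edge j -> i); ``reachability[i, j]`` is True iff a
    directed path j -> ... -> i exists.  Diagonals are excluded from all
    detection accounting.
    """

    adjacency: np.ndarray
    reachability: np.ndarray

    @classmethod
    def from_adjacency(cls, adjacency: np.ndarray) -> "TruthGraph":
        adjacency = np.asarray(adjacency, dtype=bool)
        return cls(adjacency=adjacency, reachability=_transitive_closure(adjacency))

    @property
    def n_channels(self) -> int:
        return self.adjacency.shape[0]


def _transitive_closure(adj: np.ndarray) -> np.ndarray:
    """Boolean transitive closure by Warshall's algorithm (no self-paths
    unless a directed cycle exists)."""
    reach = adj.copy()
    n = adj.shape[0]
    for k in range(n):
        reach |= np.outer(reach[:, k], reach[k, :])
    return reach


# ---------------------------------------------------------------------------
# Built-in model definitions
# ---------------------------------------------------------------------------

def model1_var() -> VARModel:
    """The 7-channel closed-loop model (order 2)."""
    a = np.zeros((2, 7, 7))
    a[0, 0, 0] = 0.95 * _SQ2
    a[1, 0, 0] = -0.9025
    a[1, 0, 4] = 0.5
    a[0, 1, 0] = -0.5
    a[0, 2, 0] = 0.2
    a[1, 2, 1] = 0.4
    a[0, 3, 2] = -0.5
    a[0, 3, 3] = 0.25 * _SQ2
    a[0, 3, 4] = 0.25 * _SQ2
    a[0, 4, 3] = -0.25 * _SQ2
    a[0, 4, 4] = 0.25 * _SQ2
    a[0, 5, 5] = 0.95 * _SQ2
    a[1, 5, 5] = -0.9025
    a[1, 6, 5] = -0.1
    return VARModel(coeffs=a)


def model2_var() -> VARModel:
    """The 5-channel oscillator-driven model (order 3)."""
    a = np.zeros((3, 5, 5))
    a[0, 0, 0] = 0.95 * _SQ2
    a[1, 0, 0] = -0.9025
    a[1, 1, 0] = 0.5
    a[2, 2, 0] = -0.4
    a[1, 3, 0] = -0.5
    a[0, 3, 3] = 0.25 * _SQ2
    a[0, 3, 4] = 0.25 * _SQ2
    a[0, 4, 3] = -0.25 * _SQ2
    a[0, 4, 4] = 0.25 * _SQ2
    return VARModel(coeffs=a)


_ADJACENCY = {
    "model1": [(5, 1), (1, 2), (1, 3), (2, 3), (3, 4), (5, 4), (4, 5), (6, 7)],
    "model2": [(1, 2), (1, 3), (1, 4), (4, 5), (5, 4)],
}
_ADJACENCY["model3"] = _ADJACENCY["model2"]
_N_CHANNELS = {"model1": 7, "model2": 5, "model3": 5}


def truth_graph(model_id: str) -> TruthGraph:
    """Ground-truth adjacency and reachability of a built-in model.

    Edges are the cross-channel terms of the defining equations (self-loops
    are not connectivity).  Model 3 shares Model 2's autoregressive skeleton:
    its exogenous/latent contamination adds no directed edge to the truth.
    """
    if model_id not in _ADJACENCY:
        raise ValueError(f"unknown model id {model_id!r}; expected one of "
                         f"{sorted(_ADJACENCY)}")
    n = _N_CHANNELS[model_id]
    adj = np.zeros((n, n), dtype=bool)
    for src, dst in _ADJACENCY[model_id]:
        adj[dst - 1, src - 1] = True
    return TruthGraph.from_adjacency(adj)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _var_recursion(coeffs: np.ndarray, noise: np.ndarray) -> np.ndarray:
    """Run x(t) = sum_r A_r x(t-r) + noise(t) from zero initial state.

    ``noise`` has shape (T, N); returns (T, N).
    """
    p, n, _ = coeffs.shape
    t_total = noise.shape[0]
    # stack lags so each step is a single (N, p*N) @ (p*N,) product
    astack = np.concatenate([coeffs[r] for r in range(p)], axis=1)  # (N, p*N)
    x = np.zeros((t_total + p, n))
    x[:p] = 0.0
    lagbuf = np.zeros(p * n)
    for t in range(t_total):
        # lag vector [x(t-1); x(t-2); ...; x(t-p)]
        for r in range(p):
            lagbuf[r * n:(r + 1) * n] = x[t + p - 1 - r]
        x[t + p] = astack @ lagbuf + noise[t]
    return x[p:]


def _innovation_streams(seed, n_streams: int, length: int) -> np.ndarray:
    """Independent N(0,1) streams, one substream per innovation source.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.  Returns an
    array of shape ``(length, n_streams)``.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_streams)
    out = np.empty((length, n_streams))
    for k, child in enumerate(children):
        out[:, k] = np.random.Generator(np.random.PCG64(child)).standard_normal(length)
    return out


def simulate_var(
    model: VARModel,
    n_samples: int,
    seed=None,
    burn_in: int = DEFAULT_BURN_IN,
    innovations: np.ndarray | None = None,
    labels: list[str] | None = None,
    model_id: str = "custom",
) -> MultichannelSeries:
    """Simulate a stable VAR process and discard the burn-in.

    Parameters
    ----------
    model
        The generating process; must be stable (companion spectral radius
        below one), otherwise a ``ValueError`` reports the radius.
    n_samples
        Number of post-burn-in samples K to keep.
    seed
        Integer or ``SeedSequence``; each channel's innovation sequence comes
        from its own substream.  Ignored when ``innovations`` is given.
    burn_in
        Samples simulated from zero initial state and discarded.
    innovations
        Optional explicit noise array of shape ``(burn_in + n_samples, N)``;
        bypasses random generation (used for deterministic checks and for
        Model 3's bespoke disturbance path).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    rho = model.spectral_radius()
    if rho >= 1.0:
        raise ValueError(f"unstable VAR model: companion spectral radius {rho:.6f} >= 1")
    n = model.n_channels
    t_total = burn_in + n_samples
    if innovations is None:
        if seed is None:
            raise ValueError("either seed or innovations must be provided")
        noise = _innovation_streams(seed, n, t_total)
        chol = np.linalg.cholesky(model.innovation_cov)
        if not np.allclose(model.innovation_cov, np.eye(n)):
            noise = noise @ chol.T
    else:
        noise = np.asarray(innovations, dtype=float)
        if noise.shape != (t_total, n):
            raise ValueError(f"innovations must have shape {(t_total, n)}")
    x = _var_recursion(model.coeffs, noise)
    prov = {"model": model_id, "seed": _seed_repr(seed), "burn_in": burn_in}
    return MultichannelSeries(values=x[burn_in:].T.copy(), labels=labels, provenance=prov)


def _seed_repr(seed):
    if isinstance(seed, np.random.SeedSequence):
        return tuple(seed.entropy if isinstance(seed.entropy, (list, tuple))
                     else (seed.entropy,)) + tuple(seed.spawn_key)
    return seed


def simulate_model1(n_samples: int, seed=None, burn_in: int = DEFAULT_BURN_IN,
                    innovations: np.ndarray | None = None) -> MultichannelSeries:
    """Simulate the 7-channel closed-loop model with N(0,1) innovations."""
    return simulate_var(model1_var(), n_samples, seed=seed, burn_in=burn_in,
                        innovations=innovations, model_id="model1")


def simulate_model2(n_samples: int, seed=None, burn_in: int = DEFAULT_BURN_IN,
                    innovations: np.ndarray | None = None) -> MultichannelSeries:
    """Simulate the 5-channel oscillator-driven model with N(0,1) innovations."""
    return simulate_var(model2_var(), n_samples, seed=seed, burn_in=burn_in,
                        innovations=innovations, model_id="model2")


def simulate_model3(n_samples: int, seed=None, params: Model3Params | None = None,
                    burn_in: int = DEFAULT_BURN_IN) -> MultichannelSeries:
    """Simulate Model 3: Model 2's VAR skeleton with contaminated disturbances.

    The disturbance of channel i at time t is

        u_i(t) = e_i(t) + a_i e6(t) + b_i e7(t-1) + c_i e7(t-2)

    with all e_k independent N(0,1).  The shared e6 makes the disturbances
    contemporaneously cross-correlated; the lagged latent e7 makes them
    serially correlated, so the observed process has no finite VAR order.
    Streams e1..e7 are substreams 0..6 of the master seed, hence
    ``params = Model3Params(a=0, b=0, c=0)`` reproduces ``simulate_model2``
    with the same seed exactly.
    """
    if params is None:
        raise ValueError("Model3Params required (draw with Model3Params.draw)")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    t_total = burn_in + n_samples
    e = _innovation_streams(seed, 7, t_total)
    e7 = e[:, 6]
    e7_l1 = np.concatenate([[0.0], e7[:-1]])
    e7_l2 = np.concatenate([[0.0, 0.0], e7[:-2]])
    u = (e[:, :5]
         + e[:, 5:6] * params.a[None, :]
         + e7_l1[:, None] * params.b[None, :]
         + e7_l2[:, None] * params.c[None, :])
    series = simulate_var(model2_var(), n_samples, burn_in=burn_in,
                          innovations=u, model_id="model3")
    series.provenance.update({"seed": _seed_repr(
        seed if isinstance(seed, np.random.SeedSequence) else seed),
        "a": params.a.tolist(), "b": params.b.tolist(), "c": params.c.tolist()})
    return series
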