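"""Synthetic EEG, reaction times, and cohorts with known ground truth.

No recordings are deposited with the study this package operationalises,
so verification rests on generated data whose ground truth is planted:

- multichannel band-limited signals whose pairwise constant-phase-lag
  coupling follows a chosen tree topology, so the connectivity and
  spanning-tree stages must recover a known structure;
- ex-Gaussian reaction-time samples, Normal(mu, sigma) + Exp(tau);
- whole cohorts in which the cross-correlations between network metrics
  and RT parameters are imposed through a Gaussian copula.

These are stand-ins: band-limited noise with planted lags is not
biophysically realistic EEG, and the cohort generator draws metric
values directly rather than through simulated recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .io import EEGRecording
from .montage import CHANNELS_19

_TREE_KINDS = ("star", "path", "balanced", "random")


@dataclass
class TreeSpec:
    """A planted coupling topology: n_nodes - 1 edges with strengths."""

    n_nodes: int
    kind: str
    edges: list[tuple[int, int]]
    edge_strengths: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("a tree needs at least 2 nodes")
        if self.kind not in _TREE_KINDS:
            raise ValueError(f"unknown tree kind {self.kind!r}; "
                             f"choose from {_TREE_KINDS}")
        if not self.edge_strengths:
            self.edge_strengths = [0.9] * len(self.edges)
        if len(self.edges) != self.n_nodes - 1:
            raise ValueError(f"{len(self.edges)} edges for {self.n_nodes} nodes")
        if len(self.edge_strengths) != len(self.edges):
            raise ValueError("one strength per edge required")
        if any(not 0 < s <= 1 for s in self.edge_strengths):
            raise ValueError("edge strengths must lie in (0, 1]")
        seen = set()
        parent = list(range(self.n_nodes))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in self.edges:
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"edge ({i}, {j}) outside node range")
            if i == j or frozenset((i, j)) in seen:
                raise ValueError(f"degenerate or duplicate edge ({i}, {j})")
            seen.add(frozenset((i, j)))
            ri, rj = find(i), find(j)
            if ri == rj:
                raise ValueError("edges form a cycle")
            parent[rj] = ri
        # n-1 edges and no cycle => connected

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


@dataclass
class CouplingConfig:
    """Signal-generation settings for one planted-topology recording."""

    band: tuple[float, float] = (8.0, 12.0)
    rate: float = 500.0
    n_samples: int = 4096
    lag_per_edge: float = np.pi / 4
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi < self.rate / 2:
            raise ValueError(f"band ({lo}, {hi}) outside (0, rate/2)")
        if self.n_samples < 4096:
            raise ValueError("n_samples must be >= 4096")
        if abs(np.sin(self.lag_per_edge)) < 1e-9:
            raise ValueError(
                "lag_per_edge is a multiple of pi: phase-lag coupling is "
                "unidentifiable (zero-lag or sign-alternating)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_reference_tree(kind: str, n_nodes: int,
                        strength: float = 0.9,
                        seed: int | None = None) -> TreeSpec:
    """A canonical topology: ``star``, ``path``, ``balanced`` or ``random``.

    The star has one node (index 0) of degree n-1; the path has exactly
    two degree-1 nodes; ``balanced`` is a near-balanced binary tree (two
    directly-connected hubs at small n); ``random`` draws a uniform
    labelled tree from a Prüfer sequence (requires ``seed``).
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if kind == "star":
        edges = [(0, k) for k in range(1, n_nodes)]
    elif kind == "path":
        edges = [(k, k + 1) for k in range(n_nodes - 1)]
    elif kind == "balanced":
        edges = [((k - 1) // 2, k) for k in range(1, n_nodes)]
    elif kind == "random":
        if n_nodes == 2:
            edges = [(0, 1)]
        else:
            rng = np.random.default_rng(seed)
            prufer = rng.integers(0, n_nodes, size=n_nodes - 2)
            edges = _tree_from_prufer(list(prufer), n_nodes)
    else:
        raise ValueError(f"unknown tree kind {kind!r}; choose from {_TREE_KINDS}")
    return TreeSpec(n_nodes=n_nodes, kind=kind, edges=edges,
                    edge_strengths=[strength] * (n_nodes - 1))


def _tree_from_prufer(prufer: list[int], n: int) -> list[tuple[int, int]]:
    """Decode a Prüfer sequence into the edge list of a labelled tree."""
    import heapq

    degree = [1] * n
    for v in prufer:
        degree[v] += 1
    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    edges = []
    for v in prufer:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, v))
        degree[leaf] -= 1
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, v)
    edges.append((heapq.heappop(leaves), heapq.heappop(leaves)))
    return edges


def _bandlimited_noise(rng: np.random.Generator, n: int,
                       band: tuple[float, float], rate: float) -> np.ndarray:
    """Unit-variance Gaussian noise confined to ``band`` (FFT masking)."""
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec = np.fft.rfft(white)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _phase_shift(x: np.ndarray, lag: float) -> np.ndarray:
    """Shift every spectral component of ``x`` by ``lag`` radians."""
    spec = np.fft.rfft(x)
    spec[1:] *= np.exp(-1j * lag)
    return np.fft.irfft(spec, n=len(x))


def simulate_coupled_eeg(tree: TreeSpec, cfg: CouplingConfig,
                         labels: list[str] | None = None) -> EEGRecording:
    """Multichannel signal whose phase-lag coupling follows ``tree``.

    The signal propagates along the tree from the lowest-index node:
    each child channel is its parent's signal phase-delayed by
    ``cfg.lag_per_edge`` and scaled by the edge strength w, plus an
    independent band-limited innovation of amplitude sqrt(1 - w^2).
    The lag direction alternates with tree depth (parent leads at even
    depth, lags at odd depth), so every edge carries a constant lag of
    magnitude ``lag_per_edge`` while the lags of any two-hop path cancel:
    indirect neighbours share only zero-lag signal, which the phase lag
    index discounts by construction. Tree edges therefore score high PLI
    (approaching 1 as w -> 1), the shared component of distant pairs
    attenuates with tree distance, and the maximum spanning tree of the
    resulting PLI matrix recovers the planted topology at low noise.
    Independent band-limited sensor noise of SD ``cfg.noise_sd`` is
    added per channel. Deterministic given ``cfg.seed``.
    """
    n = tree.n_nodes
    if labels is None:
        if n == 19:
            labels = list(CHANNELS_19)
        else:
            labels = [f"ch{k:02d}" for k in range(n)]
    if len(labels) != n:
        raise ValueError("label count must equal n_nodes")
    rng = np.random.default_rng(cfg.seed)

    adjacency: dict[int, list[tuple[int, float]]] = {k: [] for k in range(n)}
    for (i, j), s in zip(tree.edges, tree.edge_strengths):
        adjacency[i].append((j, s))
        adjacency[j].append((i, s))

    x = np.zeros((n, cfg.n_samples))
    root = 0
    x[root] = _bandlimited_noise(rng, cfg.n_samples, cfg.band, cfg.rate)
    depth = {root: 0}
    queue = [root]
    while queue:  # BFS in deterministic (index) order
        parent = queue.pop(0)
        sign = 1.0 if depth[parent] % 2 == 0 else -1.0
        for child, w in sorted(adjacency[parent]):
            if child in depth:
                continue
            innovation = _bandlimited_noise(rng, cfg.n_samples, cfg.band,
                                            cfg.rate)
            x[child] = (w * _phase_shift(x[parent], sign * cfg.lag_per_edge)
                        + np.sqrt(1.0 - w * w) * innovation)
            depth[child] = depth[parent] + 1
            queue.append(child)
    if cfg.noise_sd > 0:
        for k in range(n):
            x[k] += cfg.noise_sd * _bandlimited_noise(
                rng, cfg.n_samples, cfg.band, cfg.rate)
    return EEGRecording(x, cfg.rate, labels)


def simulate_subject_recording(
    tree: TreeSpec,
    cfg: CouplingConfig,
    n_epochs: int = 30,
    labels: list[str] | None = None,
) -> EEGRecording:
    """Concatenate ``n_epochs`` independent coupled segments (default 30
    epochs of 4096 samples, the per-subject analysis budget)."""
    segs = []
    for e in range(n_epochs):
        seg_cfg = CouplingConfig(band=cfg.band, rate=cfg.rate,
                                 n_samples=cfg.n_samples,
                                 lag_per_edge=cfg.lag_per_edge,
                                 noise_sd=cfg.noise_sd,
                                 seed=cfg.seed * 100003 + e)
        segs.append(simulate_coupled_eeg(tree, seg_cfg, labels=labels))
    data = np.concatenate([s.samples for s in segs], axis=1)
    return EEGRecording(data, cfg.rate, segs[0].labels)


# ---------------------------------------------------------------------------
# Reaction times


@dataclass
class ExGaussianParams:
    """(mu, sigma, tau) in milliseconds; see the exgauss module."""

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.tau <= 0:
            raise ValueError("sigma and tau must be positive")


def sample_exgaussian_rts(params: ExGaussianParams, n: int,
                          seed: int | None = None,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` reaction times: Normal(mu, sigma) + Exponential(tau)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    return (rng.normal(params.mu, params.sigma, size=n)
            + rng.exponential(params.tau, size=n))


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortPreset:
    """Generative settings for one synthetic cohort.

    ``variables`` maps column name -> (mean, sd) per group; the joint
    distribution over ``corr_variables`` is tied by ``cross_correlations``
    (a symmetric PSD matrix with unit diagonal) through a Gaussian
    copula, identical in both groups. Clinical covariates are sampled
    from ``clinical`` for the patient group only.
    """

    n_per_group: int = 35
    variables: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict)
    corr_variables: tuple[str, ...] = ()
    cross_correlations: np.ndarray | None = None
    clinical: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "duration_of_illness": (12.31, 5.65),
        "dup": (4.85, 4.79),
        "risperidone_equivalent": (4.37, 1.48),
    })

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.cross_correlations is not None:
            c = np.asarray(self.cross_correlations, dtype=float)
            k = len(self.corr_variables)
            if c.shape != (k, k):
                raise ValueError("correlation matrix shape does not match "
                                 "corr_variables")
            if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
                raise ValueError("correlation matrix must be symmetric with "
                                 "unit diagonal")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ValueError("correlation matrix is not positive "
                                 "semidefinite")
            self.cross_correlations = c
            missing = [v for v in self.corr_variables
                       if not all(v in g for g in self.variables.values())]
            if missing:
                raise ValueError(f"corr_variables not in variables: {missing}")


def generate_cohort(preset: CohortPreset, seed: int | None = None) -> pd.DataFrame:
    """Per-subject rows of metrics, RT parameters and covariates.

    Correlated columns are drawn as multivariate standard normal with the
    preset's correlation matrix (Gaussian copula) and mapped to each
    group's Normal marginals, so empirical cross-correlations converge to
    the targets as n grows. Remaining columns are independent Normals.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for gi, (group, specs) in enumerate(preset.variables.items()):
        n = preset.n_per_group
        cols: dict[str, np.ndarray] = {
            "subject": [f"{group}{i:03d}" for i in range(n)],
            "group": group,
        }
        corr_vars = [v for v in preset.corr_variables if v in specs]
        if corr_vars and preset.cross_correlations is not None:
            c = preset.cross_correlations
            # eigendecomposition handles PSD-but-singular targets
            w, v = np.linalg.eigh(c)
            root = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
            z = rng.standard_normal((n, len(corr_vars))) @ root.T
            for col, name in zip(z.T, corr_vars):
                mean, sd = specs[name]
                cols[name] = mean + sd * col
        for name, (mean, sd) in specs.items():
            if name not in cols:
                cols[name] = rng.normal(mean, sd, size=n)
        if gi == 0:  # patient group carries the clinical covariates
            for name, (mean, sd) in preset.clinical.items():
                cols[name] = np.clip(rng.normal(mean, sd, size=n), 0, None)
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)
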