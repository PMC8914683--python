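"""Self-organizing reservoir network (SORN) learning.

SORN grows a set of node centroids ``C`` and a binary interconnectivity
matrix ``E`` from streamed channel frames, combining an ART-style
vigilance test with ITM-style topology construction:

* a frame within distance ``V`` (the vigilance threshold) of its best
  matching node updates that node toward the frame;
* when every node fails the vigilance test the frame is inserted as a
  new node, linked to the previous best match (ITM insertion);
* when both the best and second-best nodes accept the frame an edge is
  created between them, and any neighbour of the winner that is farther
  from it than the second-best node loses its edge;
* every ``prune_cycle`` learning steps, edgeless nodes are removed,
  least-recently-used first.

Growth stops the moment the node count reaches ``max_nodes``; the final
(C, E) deterministically initialize an echo state network's input and
recurrent weights (see :mod:`soconvesn.reservoir`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class SornConfig:
    """SORN learning hyperparameters.

    vigilance
        ART acceptance radius ``V`` (input units).  0.05 works well for
        hip-centred skeleton coordinates; smaller values give
        finer-grained clusters.
    learning_rate
        Winner update step ``eps_b`` in (0, 1]; 0.5 moves the winner
        halfway toward each accepted frame.
    noise_scale, noise_decay
        Input perturbation z(t) = u(t) + s * t^(-2*eta) * 1; ``s`` is the
        initial amplitude (0.1 default; 0 disables), ``eta`` in [0, 1]
        controls how fast the perturbation fades with the frame index.
    max_nodes
        Reservoir size N; growth stops when reached.  For 9-feature
        channels at least 27 (three times the input dimension) is
        recommended.
    prune_cycle
        Learning steps between prune passes; defaults to 10% of
        ``max_nodes`` (rounded up).
    """

    vigilance: float = 0.05
    learning_rate: float = 0.5
    noise_scale: float = 0.1
    noise_decay: float = 1.0
    max_nodes: int = 27
    prune_cycle: Optional[int] = None
    max_epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vigilance <= 0:
            raise ValueError("vigilance must be > 0")
        if not (0 < self.learning_rate <= 1):
            raise ValueError("learning_rate must be in (0, 1]")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if not (0 <= self.noise_decay <= 1):
            raise ValueError("noise_decay must be in [0, 1]")
        if self.max_nodes < 1:
            raise ValueError("max_nodes must be >= 1")
        if self.prune_cycle is not None and self.prune_cycle < 1:
            raise ValueError("prune_cycle must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")

    @property
    def effective_prune_cycle(self) -> int:
        if self.prune_cycle is not None:
            return self.prune_cycle
        return max(1, math.ceil(0.1 * self.max_nodes))


@dataclass
class SornState:
    """Growing network state: centroids, topology and usage stamps."""

    centroids: np.ndarray  # K x D
    edges: np.ndarray  # K x K binary symmetric, zero diagonal
    last_used: np.ndarray  # K, learning-iteration stamps
    iteration: int = 0

    @classmethod
    def empty(cls, dim: int) -> "SornState":
        return cls(
            centroids=np.empty((0, dim)),
            edges=np.empty((0, 0), dtype=np.int8),
            last_used=np.empty((0,), dtype=np.int64),
        )

    @property
    def n_nodes(self) -> int:
        return self.centroids.shape[0]

    # alias matching the symbol used in the docs
    K = n_nodes

    @property
    def dim(self) -> int:
        return self.centroids.shape[1]

    def validate(self) -> None:
        K = self.n_nodes
        assert self.edges.shape == (K, K)
        assert np.array_equal(self.edges, self.edges.T), "E must be symmetric"
        assert not np.any(np.diag(self.edges)), "E must have zero diagonal"
        assert np.all(np.isfinite(self.centroids))


def perturb_input(u: np.ndarray, t: int, cfg: SornConfig) -> np.ndarray:
    """Additive convergence-accelerating perturbation, fading with time.

    ``z = u + s * t^(-2*eta) * 1`` for a 1-based frame index ``t``; the
    amplitude is non-increasing in ``t`` whenever ``eta > 0``.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    u = np.asarray(u, dtype=float)
    if cfg.noise_scale == 0.0:
        return u.copy()
    return u + cfg.noise_scale * float(t) ** (-2.0 * cfg.noise_decay)


def find_matches(z: np.ndarray, state: SornState) -> Tuple[int, Optional[int]]:
    """Best and second-best matching nodes by Euclidean distance.

    Ties are broken toward the lowest node index.  The second index is
    ``None`` when the network has a single node.
    """
    if state.n_nodes == 0:
        raise ValueError("empty network: insert z as the first node")
    d = np.linalg.norm(state.centroids - np.asarray(z, dtype=float), axis=1)
    b = int(np.argmin(d))
    if state.n_nodes == 1:
        return b, None
    d2 = d.copy()
    d2[b] = np.inf
    return b, int(np.argmin(d2))


def vigilance_test(kl_value: float, V: float) -> bool:
    """ART matching criterion: the sample lies in the node's vigilance region.

    Inclusive at the boundary (``kl == V`` passes).
    """
    if kl_value < 0:
        raise ValueError("distance must be >= 0")
    return kl_value <= V


def _insert_node(state: SornState, z: np.ndarray, link_to: Optional[int]) -> int:
    """Append z as a node; when the net is non-empty, connect it to its
    best match (ITM insertion), so fresh nodes are never edgeless."""
    K = state.n_nodes
    state.centroids = np.vstack([state.centroids, np.asarray(z, dtype=float)])
    edges = np.zeros((K + 1, K + 1), dtype=np.int8)
    edges[:K, :K] = state.edges
    if link_to is not None:
        edges[K, link_to] = edges[link_to, K] = 1
    state.edges = edges
    state.last_used = np.append(state.last_used, 0)
    return K


def _prune(state: SornState) -> None:
    """Remove edgeless nodes, least-recently-used first; never empties
    the network (a lone node is kept)."""
    K = state.n_nodes
    if K <= 1:
        return
    degree = state.edges.sum(axis=0)
    isolated = np.flatnonzero(degree == 0)
    if isolated.size == 0:
        return
    # LRU order: remove the stalest first; keep at least one node overall
    order = isolated[np.argsort(state.last_used[isolated], kind="stable")]
    keep = np.ones(K, dtype=bool)
    for idx in order:
        if keep.sum() <= 1:
            break
        keep[idx] = False
    state.centroids = state.centroids[keep]
    state.edges = state.edges[np.ix_(keep, keep)]
    state.last_used = state.last_used[keep]


def learn_step(
    state: SornState, z: np.ndarray, cfg: SornConfig, allow_growth: bool = True
) -> SornState:
    """One SORN learning iteration on a (perturbed) input frame.

    Mutates and returns ``state``.  Sequence: match -> vigilance cascade
    -> winner update / insertion -> edge creation and pruning of farther
    neighbours -> periodic prune of edgeless nodes.  With
    ``allow_growth=False`` (network at capacity) a frame rejected by
    every node is simply skipped instead of inserted.
    """
    z = np.asarray(z, dtype=float)
    state.iteration += 1
    if state.n_nodes == 0:
        if not allow_growth:
            return state
        b = _insert_node(state, z, link_to=None)
        state.last_used[b] = state.iteration
        return state
    if z.shape[0] != state.dim:
        raise ValueError("dimension mismatch between z and centroids")

    d = np.linalg.norm(state.centroids - z, axis=1)
    order = np.argsort(d, kind="stable")  # ascending distance, ties by index
    winner: Optional[int] = None
    for cand in order:
        if vigilance_test(float(d[cand]), cfg.vigilance):
            winner = int(cand)
            break
    if winner is None:
        # all nodes fail the vigilance test: insert z, linked to the best match
        if allow_growth:
            new = _insert_node(state, z, link_to=int(order[0]))
            state.last_used[new] = state.iteration
    else:
        b = winner
        state.centroids[b] = state.centroids[b] + cfg.learning_rate * (z - state.centroids[b])
        # second-best among the remaining nodes
        if state.n_nodes > 1:
            d2 = d.copy()
            d2[b] = np.inf
            s_idx = int(np.argmin(d2))
            if vigilance_test(float(d2[s_idx]), cfg.vigilance):
                state.edges[b, s_idx] = state.edges[s_idx, b] = 1
                # drop edges to neighbours of b no closer than s
                dist_bs = float(np.linalg.norm(state.centroids[b] - state.centroids[s_idx]))
                neighbours = np.flatnonzero(state.edges[b])
                for n in neighbours:
                    if n == s_idx:
                        continue
                    dist_bn = float(np.linalg.norm(state.centroids[b] - state.centroids[n]))
                    if dist_bs <= dist_bn:
                        state.edges[b, n] = state.edges[n, b] = 0
        state.last_used[b] = state.iteration

    if state.iteration % cfg.effective_prune_cycle == 0:
        _prune(state)
    return state


def save_state(state: SornState, path, cfg: Optional[SornConfig] = None) -> None:
    """Serialize centroids + edges to HDF5 with config/provenance attrs."""
    import json

    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("centroids", data=state.centroids)
        f.create_dataset("edges", data=state.edges)
        f.create_dataset("last_used", data=state.last_used)
        f.attrs["iteration"] = state.iteration
        if cfg is not None:
            f.attrs["config"] = json.dumps(
                {k: getattr(cfg, k) for k in (
                    "vigilance", "learning_rate", "noise_scale", "noise_decay",
                    "max_nodes", "max_epochs", "seed",
                )}
            )


def load_state(path) -> SornState:
    import h5py

    with h5py.File(path, "r") as f:
        return SornState(
            centroids=np.asarray(f["centroids"]),
            edges=np.asarray(f["edges"], dtype=np.int8),
            last_used=np.asarray(f["last_used"], dtype=np.int64),
            iteration=int(f.attrs.get("iteration", 0)),
        )


def fit(channel_data: Sequence[np.ndarray], cfg: SornConfig) -> SornState:
    """Fit a SORN to a collection of ``T x D`` channel series.

    Sample order is reshuffled each epoch (seeded); within a sample,
    frames stream in time order with the perturbation clock restarting
    at t=1.  Growth stops once the node count reaches ``cfg.max_nodes``
    (frames rejected by every node are then skipped), but winner
    updates, topology adaptation and pruning continue to the end of
    that epoch so every sample still shapes the centroids; fitting
    returns after that epoch, or after ``cfg.max_epochs`` passes if
    capacity is never reached.  A final prune pass removes any edgeless
    node before returning.
    """
    series = [np.atleast_2d(np.asarray(s, dtype=float)) for s in channel_data]
    if not series or any(s.size == 0 for s in series):
        raise ValueError("empty channel data")
    dims = {s.shape[1] for s in series}
    if len(dims) > 1:
        raise ValueError(f"inconsistent feature dimensions {sorted(dims)}")
    rng = np.random.default_rng(cfg.seed)
    state = SornState.empty(dim=dims.pop())
    reached_capacity = False
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(len(series))
        for si in order:
            for t in range(1, series[si].shape[0] + 1):
                z = perturb_input(series[si][t - 1], t, cfg)
                allow = state.n_nodes < cfg.max_nodes
                learn_step(state, z, cfg, allow_growth=allow)
                if state.n_nodes >= cfg.max_nodes:
                    reached_capacity = True
        if reached_capacity:
            break
    _prune(state)
    if state.n_nodes < cfg.max_nodes:
        warnings.warn(
            f"SORN terminated with {state.n_nodes} nodes (< max_nodes={cfg.max_nodes})",
            stacklevel=2,
        )
    state.validate()
    return state
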