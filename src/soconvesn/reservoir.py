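"""Deterministic echo state network construction from a fitted SORN.

Instead of drawing random weights, the reservoir's input weights are the
SORN node centroids rescaled into ``[-IS, IS]`` and its recurrent
weights are the binary interconnectivity matrix scaled to a chosen
spectral radius ``SR``.  Driving the reservoir with a channel series
``u(1..T)`` through

    x(t+1) = f(Wres x(t) + Win u(t+1)),   x(0) = 0,

yields the echo state representation (ESR), a ``T x N`` matrix whose
rows are the reservoir states.  ``f`` is tanh by default; with
``SR < 1`` the echo state property (independence from the initial
state) holds in practice, which :func:`esp_convergence_check` verifies
empirically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .sorn import SornState

_ACTIVATIONS: dict = {"tanh": np.tanh, "identity": lambda x: x}


@dataclass
class ReservoirWeights:
    """Fixed ESN weights: ``Win`` (N x D) and ``Wres`` (N x N)."""

    Win: np.ndarray
    Wres: np.ndarray
    input_scaling: float
    spectral_radius: float
    activation: str = "tanh"

    def __post_init__(self) -> None:
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def n_neurons(self) -> int:
        return self.Wres.shape[0]

    @property
    def f(self) -> Callable[[np.ndarray], np.ndarray]:
        return _ACTIVATIONS[self.activation]


@dataclass
class EchoStateMatrix:
    """Time-major ESR: row t is the reservoir state x(t+1)."""

    X: np.ndarray  # T x N
    initial_state: np.ndarray

    @property
    def n_steps(self) -> int:
        return self.X.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.X.shape[1]


def rescale_centroids(C: np.ndarray, input_scaling: float) -> np.ndarray:
    """Affinely map centroid elements into ``[-IS, IS]``.

    The global (scalar) min and max over all elements of ``C`` map to
    -IS and +IS exactly:  ``IS * (2*(c - min)/(max - min) - 1)``.
    """
    C = np.asarray(C, dtype=float)
    if input_scaling <= 0:
        raise ValueError("input_scaling must be > 0")
    cmin, cmax = float(C.min()), float(C.max())
    if cmax == cmin:
        raise ValueError("degenerate centroids: max(C) == min(C)")
    return input_scaling * (2.0 * (C - cmin) / (cmax - cmin) - 1.0)


def rescale_connectivity(E: np.ndarray, spectral_radius: float) -> np.ndarray:
    """Scale the binary interconnectivity so its spectral radius is SR."""
    E = np.asarray(E, dtype=float)
    if spectral_radius <= 0:
        raise ValueError("spectral_radius must be > 0")
    lam = _spectral_radius(E)
    if lam <= 0:
        raise ValueError("zero spectral radius: interconnectivity has no edges")
    return (spectral_radius / lam) * E


def _spectral_radius(W: np.ndarray) -> float:
    if W.shape[0] == 0:
        return 0.0
    if np.array_equal(W, W.T):
        return float(np.max(np.abs(np.linalg.eigvalsh(W))))
    return float(np.max(np.abs(np.linalg.eigvals(W))))


def build_reservoir(
    state: SornState,
    input_scaling: float,
    spectral_radius: float,
    activation: str = "tanh",
) -> ReservoirWeights:
    """Assemble ESN weights from fitted SORN centroids and topology."""
    return ReservoirWeights(
        Win=rescale_centroids(state.centroids, input_scaling),
        Wres=rescale_connectivity(state.edges, spectral_radius),
        input_scaling=input_scaling,
        spectral_radius=spectral_radius,
        activation=activation,
    )


def compute_esr(
    weights: ReservoirWeights,
    u_series: np.ndarray,
    x0: Optional[np.ndarray] = None,
) -> EchoStateMatrix:
    """Propagate a ``T x D`` input series to its echo state representation."""
    u_series = np.atleast_2d(np.asarray(u_series, dtype=float))
    if not np.all(np.isfinite(u_series)):
        raise ValueError("non-finite input")
    N = weights.n_neurons
    if u_series.shape[1] != weights.Win.shape[1]:
        raise ValueError(
            f"input dim {u_series.shape[1]} != Win dim {weights.Win.shape[1]}"
        )
    x = np.zeros(N) if x0 is None else np.asarray(x0, dtype=float).copy()
    if x.shape != (N,):
        raise ValueError("x0 has wrong shape")
    f = weights.f
    drive = u_series @ weights.Win.T  # T x N, precomputed input terms
    X = np.empty((u_series.shape[0], N))
    initial = x.copy()
    for t in range(u_series.shape[0]):
        x = f(weights.Wres @ x + drive[t])
        X[t] = x
    return EchoStateMatrix(X=X, initial_state=initial)


def esp_convergence_check(
    weights: ReservoirWeights,
    u_series: np.ndarray,
    x0_a: np.ndarray,
    x0_b: np.ndarray,
) -> np.ndarray:
    """Per-step distance between state trajectories from two initial states.

    Under the echo state property the trace decays toward zero: the
    reservoir forgets its initial condition and the ESR depends only on
    the input history.
    """
    Xa = compute_esr(weights, u_series, x0=x0_a).X
    Xb = compute_esr(weights, u_series, x0=x0_b).X
    return np.linalg.norm(Xa - Xb, axis=1)


def concatenate_channel_series(series_list) -> np.ndarray:
    """Stack per-sample ``T x D`` series along time (for dataset-level RPs)."""
    return np.vstack([np.atleast_2d(np.asarray(s, dtype=float)) for s in series_list])
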