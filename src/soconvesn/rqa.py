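"""Recurrence plots and recurrence quantification analysis (RQA).

A recurrence plot of an echo state representation is the binary matrix
``R[i, j] = 1`` iff states i and j are within a Euclidean threshold
``tau`` of each other (inclusive: recurrence at the exact threshold
counts).  Four standard RQA measures summarise reservoir dynamics:

LMAX   longest diagonal line (line of identity excluded by default) —
       higher means a more stable reservoir;
DET    fraction of recurrent points on diagonal lines of length >= lmin
       — time dependence / determinism;
LAM    fraction of recurrent points on vertical lines of length >= vmin
       — laminar phases where the state changes slowly;
RR     density of recurrences; low RR signals chaoticity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist

#: recurrence plots above this many time steps are refused (O(T^2) memory)
MAX_RP_SIZE = 5000

_BLOCK = 1024


@dataclass
class RecurrencePlot:
    R: np.ndarray  # T x T binary (uint8)
    threshold: float
    distance: str = "euclidean"

    @property
    def n_steps(self) -> int:
        return self.R.shape[0]


@dataclass
class LineHistograms:
    """Counts of maximal diagonal / vertical runs of 1s, keyed by length."""

    diag_hist: Dict[int, int]
    vert_hist: Dict[int, int]
    exclude_loi: bool = True


@dataclass
class RqaMetrics:
    lmax: int
    lam: float
    det: float
    rr: float
    lmin: int = 2
    vmin: int = 2

    def as_dict(self) -> Dict[str, float]:
        return {
            "LMAX": self.lmax,
            "LAM": self.lam,
            "DET": self.det,
            "RR": self.rr,
            "lmin": self.lmin,
            "vmin": self.vmin,
        }


def max_pairwise_distance(X: np.ndarray) -> float:
    """Largest Euclidean distance between any two rows (blockwise)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    best = 0.0
    for i in range(0, X.shape[0], _BLOCK):
        d = cdist(X[i : i + _BLOCK], X)
        best = max(best, float(d.max()))
    return best


def default_threshold(X: np.ndarray, fraction: float = 0.1) -> float:
    """Default recurrence threshold: a fraction of the state-space diameter."""
    return fraction * max_pairwise_distance(X)


def recurrence_matrix(X: np.ndarray, threshold: Optional[float] = None) -> RecurrencePlot:
    """Thresholded pairwise-distance matrix of the state rows.

    ``R[i, j] = 1`` iff ``d(x_i, x_j) <= threshold`` (Heaviside with
    Theta(0) = 1).  When ``threshold`` is None it defaults to 10% of the
    maximum pairwise distance.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = X.shape[0]
    if T > MAX_RP_SIZE:
        raise ValueError(f"T={T} exceeds the recurrence-plot cap ({MAX_RP_SIZE})")
    if threshold is None:
        threshold = default_threshold(X)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    R = np.empty((T, T), dtype=np.uint8)
    for i in range(0, T, _BLOCK):
        R[i : i + _BLOCK] = cdist(X[i : i + _BLOCK], X) <= threshold
    return RecurrencePlot(R=R, threshold=float(threshold))


def _run_lengths(line: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of 1s in a binary 1-D array."""
    if line.size == 0:
        return np.empty(0, dtype=np.int64)
    padded = np.concatenate(([0], line.astype(np.int8), [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return ends - starts


def line_histograms(rp: RecurrencePlot, exclude_loi: bool = True) -> LineHistograms:
    """Histograms of maximal diagonal and vertical line lengths.

    Diagonals from both triangles are scanned; the main diagonal (line
    of identity) is omitted when ``exclude_loi``.  Runs touching the
    matrix border count as maximal (out-of-range neighbours are 0).
    """
    R = rp.R
    T = R.shape[0]
    diag_hist: Dict[int, int] = {}
    vert_hist: Dict[int, int] = {}
    offsets = range(-(T - 1), T)
    for off in offsets:
        if exclude_loi and off == 0:
            continue
        for length in _run_lengths(np.diagonal(R, offset=off)):
            diag_hist[int(length)] = diag_hist.get(int(length), 0) + 1
    for j in range(T):
        for length in _run_lengths(R[:, j]):
            vert_hist[int(length)] = vert_hist.get(int(length), 0) + 1
    return LineHistograms(diag_hist=diag_hist, vert_hist=vert_hist, exclude_loi=exclude_loi)


def compute_metrics(
    hist: LineHistograms,
    rp: RecurrencePlot,
    lmin: int = 2,
    vmin: int = 2,
) -> RqaMetrics:
    """LMAX, LAM, DET and RR from line histograms and the plot itself.

    Empty denominators (no lines at all) yield a 0 metric with a warning.
    """
    if lmin < 1 or vmin < 1:
        raise ValueError("lmin and vmin must be >= 1")
    T = rp.n_steps
    lmax = max(hist.diag_hist) if hist.diag_hist else 0
    det = _weighted_fraction(hist.diag_hist, lmin, "DET")
    lam = _weighted_fraction(hist.vert_hist, vmin, "LAM")
    rr = float(rp.R.sum()) / float(T * T)
    return RqaMetrics(lmax=int(lmax), lam=lam, det=det, rr=rr, lmin=lmin, vmin=vmin)


def _weighted_fraction(hist: Dict[int, int], minimum: int, name: str) -> float:
    denom = sum(length * count for length, count in hist.items())
    if denom == 0:
        warnings.warn(f"{name}: no lines in histogram; metric set to 0", stacklevel=3)
        return 0.0
    num = sum(length * count for length, count in hist.items() if length >= minimum)
    return num / denom


def analyze(
    X: np.ndarray,
    threshold: Optional[float] = None,
    lmin: int = 2,
    vmin: int = 2,
    exclude_loi: bool = True,
) -> Tuple[RecurrencePlot, RqaMetrics]:
    """Convenience: recurrence plot + all four measures in one call."""
    rp = recurrence_matrix(X, threshold)
    hist = line_histograms(rp, exclude_loi=exclude_loi)
    return rp, compute_metrics(hist, rp, lmin=lmin, vmin=vmin)
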