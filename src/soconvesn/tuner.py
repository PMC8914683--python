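"""Two-stage reservoir hyperparameter tuning driven by recurrence analysis.

Input scaling (IS) and spectral radius (SR) dominate the dynamics of the
self-organized reservoir.  Stage 1 pins SR at the echo-state-property
boundary value 0.99 and sweeps IS, scoring each setting by LMAX (the
longest diagonal line of the recurrence plot of the resulting echo
states — a stability measure).  Stage 2 fixes the chosen IS and sweeps
SR, including values above 1 for diagnosis, but never selecting a value
above the ESP cap.  Ties in LMAX are broken toward the largest
admissible parameter (the top of the stable plateau).

Sweeps run on the concatenation of one channel's series over the
training samples; ``max_frames`` bounds the quadratic recurrence-plot
cost.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .reservoir import build_reservoir, compute_esr, concatenate_channel_series
from .rqa import analyze
from .sorn import SornState

#: stage-1 default grid: 8 log-spaced input scalings spanning 0.07..0.5
DEFAULT_IS_GRID: Tuple[float, ...] = tuple(
    float(v) for v in np.geomspace(0.07, 0.5, 8).round(6)
)
#: stage-2 default grid, straddling the ESP boundary
DEFAULT_SR_GRID: Tuple[float, ...] = (0.5, 0.8, 0.9, 0.99, 1.1, 1.5, 2.0)

ESP_CAP = 0.99


@dataclass
class SweepResult:
    stage: int  # 1 = IS sweep, 2 = SR sweep
    grid: List[float]
    lmax_values: List[int]
    chosen: float
    fixed_partner: float

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.lmax_values):
            raise ValueError("grid and lmax_values lengths differ")
        if self.chosen not in self.grid:
            raise ValueError("chosen value not on the grid")

    def as_dict(self) -> Dict:
        return {
            "stage": self.stage,
            "grid": self.grid,
            "lmax_values": self.lmax_values,
            "chosen": self.chosen,
            "fixed_partner": self.fixed_partner,
        }


def _concatenated_input(channel_data: Sequence[np.ndarray], max_frames: int) -> np.ndarray:
    u = concatenate_channel_series(channel_data)
    return u[:max_frames]


def _lmax_at(
    state: SornState,
    u: np.ndarray,
    input_scaling: float,
    spectral_radius: float,
    threshold: Optional[float],
    lmin: int,
) -> int:
    weights = build_reservoir(state, input_scaling, spectral_radius)
    esr = compute_esr(weights, u)
    _, metrics = analyze(esr.X, threshold=threshold, lmin=lmin)
    return metrics.lmax


def sweep_input_scaling(
    sorn_state: SornState,
    channel_data: Sequence[np.ndarray],
    is_grid: Sequence[float] = DEFAULT_IS_GRID,
    sr_fixed: float = ESP_CAP,
    threshold: Optional[float] = None,
    lmin: int = 2,
    max_frames: int = 1000,
) -> SweepResult:
    """Stage 1: sweep input scaling with the spectral radius held at 0.99."""
    grid = [float(v) for v in is_grid]
    if not grid or any(v <= 0 for v in grid):
        raise ValueError("is_grid must be non-empty with positive values")
    u = _concatenated_input(channel_data, max_frames)
    lmaxes = [_lmax_at(sorn_state, u, v, sr_fixed, threshold, lmin) for v in grid]
    chosen = _argmax_largest(grid, lmaxes)
    return SweepResult(stage=1, grid=grid, lmax_values=lmaxes, chosen=chosen, fixed_partner=sr_fixed)


def sweep_spectral_radius(
    sorn_state: SornState,
    channel_data: Sequence[np.ndarray],
    sr_grid: Sequence[float] = DEFAULT_SR_GRID,
    is_fixed: float = 0.1,
    esp_cap: float = ESP_CAP,
    threshold: Optional[float] = None,
    lmin: int = 2,
    max_frames: int = 1000,
) -> SweepResult:
    """Stage 2: sweep the spectral radius with input scaling fixed.

    LMAX is reported for the whole grid — including SR > 1, where the
    echo state property is violated — but the selected value is always
    the best among grid points ``<= esp_cap``.
    """
    grid = [float(v) for v in sr_grid]
    if not grid or any(v <= 0 for v in grid):
        raise ValueError("sr_grid must be non-empty with positive values")
    admissible = [v for v in grid if v <= esp_cap]
    if not admissible:
        raise ValueError(f"no grid point <= esp_cap={esp_cap}")
    u = _concatenated_input(channel_data, max_frames)
    lmaxes = [_lmax_at(sorn_state, u, is_fixed, v, threshold, lmin) for v in grid]
    adm_lmax = [l for v, l in zip(grid, lmaxes) if v <= esp_cap]
    chosen = _argmax_largest(admissible, adm_lmax)
    return SweepResult(stage=2, grid=grid, lmax_values=lmaxes, chosen=chosen, fixed_partner=is_fixed)


def _argmax_largest(grid: Sequence[float], scores: Sequence[int]) -> float:
    """Grid value with the maximal score; ties go to the largest value."""
    best = max(scores)
    return max(v for v, s in zip(grid, scores) if s == best)


def two_stage_tune(
    sorn_state: SornState,
    channel_data: Sequence[np.ndarray],
    is_grid: Sequence[float] = DEFAULT_IS_GRID,
    sr_grid: Sequence[float] = DEFAULT_SR_GRID,
    esp_cap: float = ESP_CAP,
    threshold: Optional[float] = None,
    max_frames: int = 1000,
) -> Tuple[float, float, SweepResult, SweepResult]:
    """Run both sweeps; returns (IS, SR, stage1 result, stage2 result)."""
    stage1 = sweep_input_scaling(
        sorn_state, channel_data, is_grid, sr_fixed=esp_cap, threshold=threshold, max_frames=max_frames
    )
    stage2 = sweep_spectral_radius(
        sorn_state,
        channel_data,
        sr_grid,
        is_fixed=stage1.chosen,
        esp_cap=esp_cap,
        threshold=threshold,
        max_frames=max_frames,
    )
    return stage1.chosen, stage2.chosen, stage1, stage2


def explainability_report(
    X: np.ndarray,
    threshold: Optional[float] = None,
    lmin: int = 2,
    vmin: int = 2,
    rp_png: Optional[str] = None,
) -> Dict[str, object]:
    """RQA summary of an echo state representation.

    Returns a JSON-serializable report with six-decimal metric strings
    (LMAX, LAM, DET, RR) alongside the raw values; optionally renders
    the recurrence plot to ``rp_png`` (black = recurrence).
    """
    rp, metrics = analyze(X, threshold=threshold, lmin=lmin, vmin=vmin)
    report: Dict[str, object] = {
        "LMAX": metrics.lmax,
        "LAM": float(f"{metrics.lam:.6f}"),
        "DET": float(f"{metrics.det:.6f}"),
        "RR": float(f"{metrics.rr:.6f}"),
        "threshold": rp.threshold,
        "lmin": lmin,
        "vmin": vmin,
        "n_steps": rp.n_steps,
    }
    if rp_png is not None:
        _render_rp(rp.R, rp_png)
    return report


def _render_rp(R: np.ndarray, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(1 - R, cmap="gray", origin="lower", interpolation="nearest")
    ax.set_xlabel("time")
    ax.set_ylabel("time")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_report(report: Dict[str, object], path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
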