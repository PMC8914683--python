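"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (pure-Python loops, explicit
enumeration) so they stay independent of the vectorised implementation
paths they check.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pytest
from hypothesis import settings

import soconvesn as sc
from soconvesn.data_model import PARTS
from soconvesn.synthetic import GeneratorConfig, default_class_specs, generate_action_dataset

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# brute-force RQA oracle
# ---------------------------------------------------------------------------

def brute_diag_hist(R: np.ndarray, exclude_loi: bool) -> Dict[int, int]:
    """Enumerate maximal diagonal runs of 1s by walking every diagonal."""
    T = R.shape[0]
    hist: Dict[int, int] = {}
    for off in range(-(T - 1), T):
        if exclude_loi and off == 0:
            continue
        cells = []
        for i in range(T):
            j = i + off
            if 0 <= j < T:
                cells.append(int(R[i, j]))
        run = 0
        for c in cells + [0]:
            if c:
                run += 1
            elif run:
                hist[run] = hist.get(run, 0) + 1
                run = 0
    return hist


def brute_vert_hist(R: np.ndarray) -> Dict[int, int]:
    T = R.shape[0]
    hist: Dict[int, int] = {}
    for j in range(T):
        run = 0
        for i in list(range(T)) + [None]:
            c = int(R[i, j]) if i is not None else 0
            if c:
                run += 1
            elif run:
                hist[run] = hist.get(run, 0) + 1
                run = 0
    return hist


def brute_metrics(
    R: np.ndarray, lmin: int, vmin: int, exclude_loi: bool
) -> Tuple[int, float, float, float]:
    """(LMAX, LAM, DET, RR) from explicit run enumeration."""
    dh = brute_diag_hist(R, exclude_loi)
    vh = brute_vert_hist(R)
    lmax = max(dh) if dh else 0

    def frac(hist: Dict[int, int], mn: int) -> float:
        denom = sum(l * c for l, c in hist.items())
        if denom == 0:
            return 0.0
        return sum(l * c for l, c in hist.items() if l >= mn) / denom

    T = R.shape[0]
    rr = sum(int(R[i, j]) for i in range(T) for j in range(T)) / (T * T)
    return lmax, frac(vh, vmin), frac(dh, lmin), rr


def random_symmetric_binary(T: int, rng: np.random.Generator, density: float = 0.4) -> np.ndarray:
    M = (rng.random((T, T)) < density).astype(np.uint8)
    R = np.triu(M) | np.triu(M).T
    np.fill_diagonal(R, 1)
    return R


# ---------------------------------------------------------------------------
# naive convolution oracle
# ---------------------------------------------------------------------------

def naive_conv_single(esr: np.ndarray, filt: np.ndarray, bias: float) -> np.ndarray:
    T, N = esr.shape
    k = filt.shape[0]
    out = []
    for start in range(T - k + 1):
        acc = bias
        for a in range(k):
            for n in range(N):
                acc += esr[start + a, n] * filt[a, n]
        out.append(max(acc, 0.0))
    return np.array(out)


def naive_conv_dual(
    esr_l: np.ndarray, esr_r: np.ndarray, filt: np.ndarray, bias: float
) -> np.ndarray:
    T, N = esr_l.shape
    k = filt.shape[0]
    out = []
    for start in range(T - k + 1):
        acc = bias
        for a in range(k):
            for n in range(N):
                acc += esr_l[start + a, n] * filt[a, n, 0]
                acc += esr_r[start + a, n] * filt[a, n, 1]
        out.append(max(acc, 0.0))
    return np.array(out)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def action_dataset():
    """Small 4-class synthetic dataset shared across tests."""
    cfg = GeneratorConfig(classes=default_class_specs(), samples_per_class=10, seed=11)
    return generate_action_dataset(cfg)


@pytest.fixture(scope="session")
def la_series(action_dataset):
    return [cs["LA"].series for cs in action_dataset.channel_sets]


@pytest.fixture(scope="session")
def fitted_sorn(la_series):
    cfg = sc.SornConfig(max_nodes=27, seed=3)
    return sc.fit_sorn(la_series, cfg)


@pytest.fixture(scope="session")
def small_reservoir(fitted_sorn):
    return sc.build_reservoir(fitted_sorn, input_scaling=0.1, spectral_radius=0.99)
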