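"""Hyperparameter optimization of the convolutional readout.

Three search strategies over {number of filters, learning rate, batch
size} are provided, mirroring their standard formulations:

* **BO** — Bayesian optimization with a Gaussian-process surrogate and
  the expected-improvement acquisition; the learning rate is searched on
  a log scale, discrete dimensions are one-hot encoded for the surrogate.
* **ASHA** — asynchronous successive halving: rung budgets
  ``r * eta^i`` up to ``R_max``; a trial is promoted when it ranks in
  the top ``1/eta`` of completed results at its rung.  Workers are
  simulated sequentially; promotion decisions use only results already
  available, as in the asynchronous algorithm.
* **PBT** — population-based training with truncation selection: each
  generation the bottom fraction of the population copies the
  configuration (and, with a stateful objective, the weights) of
  uniformly drawn top performers, then perturbs the learning rate by
  0.8 or 1.2.  The number of filters is never perturbed, since changing
  the architecture would void inherited weights.

The objective contract is ``objective(config, resource, seed) ->
val_accuracy`` and must be deterministic given ``(config, resource,
seed)``; the resource unit is training epochs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

Objective = Callable[[Dict, int, int], float]


@dataclass(frozen=True)
class SearchSpace:
    """Readout search space: discrete filters/batch, continuous lr range."""

    filters: Tuple[int, ...] = (128, 256)
    learning_rate: Tuple[float, float] = (0.001, 0.003)
    batch_size: Tuple[int, ...] = (1, 4)

    def __post_init__(self) -> None:
        if not self.filters or not self.batch_size:
            raise ValueError("discrete dimensions must be non-empty")
        lo, hi = self.learning_rate
        if lo <= 0 or hi < lo:
            raise ValueError("learning_rate interval must be positive and ordered")

    def sample(self, rng: np.random.Generator) -> Dict:
        lo, hi = self.learning_rate
        # log-uniform over the continuous dimension
        lr = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        return {
            "filters": int(rng.choice(self.filters)),
            "learning_rate": lr,
            "batch_size": int(rng.choice(self.batch_size)),
        }


@dataclass
class Trial:
    trial_id: int
    config: Dict
    resource_used: int = 0
    val_accuracy: float = float("nan")
    status: str = "running"  # running | stopped | completed
    rung: Optional[int] = None
    generation: Optional[int] = None

    def as_dict(self) -> Dict:
        return {
            "trial_id": self.trial_id,
            "config": dict(self.config),
            "resource_used": self.resource_used,
            "val_accuracy": self.val_accuracy,
            "status": self.status,
            "rung": self.rung,
            "generation": self.generation,
        }


@dataclass
class SearchResult:
    best_config: Dict
    best_score: float
    trials: List[Trial]
    best_so_far: List[float]

    def as_dict(self) -> Dict:
        return {
            "best_config": self.best_config,
            "best_score": self.best_score,
            "trials": [t.as_dict() for t in self.trials],
            "best_so_far": self.best_so_far,
        }


@dataclass(frozen=True)
class BoConfig:
    acquisition: str = "ei"
    iterations_per_run: int = 5
    independent_runs: int = 25
    warmup_points: int = 2
    resource: int = 30
    n_candidates: int = 256

    def __post_init__(self) -> None:
        if self.iterations_per_run < 1 or self.independent_runs < 1:
            raise ValueError("iterations and runs must be >= 1")
        if self.acquisition != "ei":
            raise ValueError("only expected improvement is supported")


@dataclass(frozen=True)
class AshaConfig:
    reduction_factor: int = 4
    min_resource: int = 1
    max_resource: int = 64
    early_stop_rate: int = 0
    max_trials: int = 16

    def __post_init__(self) -> None:
        if self.reduction_factor < 2:
            raise ValueError("reduction_factor must be >= 2")
        if self.min_resource > self.max_resource:
            raise ValueError("min_resource exceeds max_resource")


@dataclass(frozen=True)
class PbtConfig:
    population: int = 10
    generations: int = 5
    truncation_fraction: float = 0.2
    perturb_factors: Tuple[float, float] = (0.8, 1.2)
    resource_per_generation: int = 2

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not (0 < self.truncation_fraction <= 0.5):
            raise ValueError("truncation_fraction must be in (0, 0.5]")


MethodConfig = Union[BoConfig, AshaConfig, PbtConfig]


# ---------------------------------------------------------------------------
# ASHA
# ---------------------------------------------------------------------------

@dataclass
class AshaSchedule:
    rungs: List[int]
    reduction_factor: int

    def n_promotable(self, n_completed: int) -> int:
        """How many of n completed trials at a rung rank in the top 1/eta.

        A trial is promotable when its rank is below ``n/eta`` — so a
        lone trial (rank 0 < 1/eta) always advances, and 8 completed
        trials at eta=4 yield exactly the top 2.
        """
        if n_completed < 1:
            return 0
        return (n_completed - 1) // self.reduction_factor + 1

    def top_indices(self, scores: Sequence[float]) -> List[int]:
        """Indices of the trials in the promotable top fraction of a rung."""
        n = self.n_promotable(len(scores))
        order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
        return order[:n]


def asha_schedule(cfg: AshaConfig) -> AshaSchedule:
    """Rung resource levels ``r * eta^k`` (k >= early_stop_rate) up to R_max."""
    rungs: List[int] = []
    k = cfg.early_stop_rate
    while True:
        resource = cfg.min_resource * cfg.reduction_factor**k
        if resource > cfg.max_resource:
            break
        rungs.append(resource)
        k += 1
    if not rungs:
        raise ValueError("no rung fits within max_resource")
    return AshaSchedule(rungs=rungs, reduction_factor=cfg.reduction_factor)


def _asha_search(
    space: SearchSpace, cfg: AshaConfig, objective: Objective, seed: int
) -> SearchResult:
    schedule = asha_schedule(cfg)
    rng = np.random.default_rng(seed)
    n_rungs = len(schedule.rungs)
    # per rung: list of (score, trial_id); promoted ids
    rung_results: List[List[Tuple[float, int]]] = [[] for _ in range(n_rungs)]
    promoted: List[set] = [set() for _ in range(n_rungs)]
    trials: List[Trial] = []
    by_id: Dict[int, Trial] = {}
    best_so_far: List[float] = []
    best = -math.inf

    def run_at(trial: Trial, rung: int) -> None:
        nonlocal best
        resource = schedule.rungs[rung]
        try:
            score = float(objective(trial.config, resource, seed))
        except Exception:
            trial.status = "stopped"
            trial.rung = rung
            return
        trial.val_accuracy = score
        trial.resource_used = resource
        trial.rung = rung
        trial.status = "completed" if rung == n_rungs - 1 else "stopped"
        rung_results[rung].append((score, trial.trial_id))
        best = max(best, score)
        best_so_far.append(best)

    for _ in range(cfg.max_trials):
        # asynchronous rule: promote the best eligible trial from the
        # highest rung that has one; otherwise start a new trial at rung 0
        job: Optional[Tuple[int, int]] = None  # (trial_id, target rung)
        for rung in range(n_rungs - 2, -1, -1):
            scores = [s for s, _ in rung_results[rung]]
            ids = [tid for _, tid in rung_results[rung]]
            for pos in schedule.top_indices(scores):
                tid = ids[pos]
                if tid not in promoted[rung]:
                    promoted[rung].add(tid)
                    job = (tid, rung + 1)
                    break
            if job is not None:
                break
        if job is not None:
            tid, target = job
            run_at(by_id[tid], target)
        else:
            trial = Trial(trial_id=len(trials), config=space.sample(rng))
            trials.append(trial)
            by_id[trial.trial_id] = trial
            run_at(trial, 0)

    evaluated = [t for t in trials if not math.isnan(t.val_accuracy)]
    best_trial = max(evaluated, key=lambda t: (t.val_accuracy, t.resource_used))
    return SearchResult(
        best_config=dict(best_trial.config),
        best_score=best_trial.val_accuracy,
        trials=trials,
        best_so_far=best_so_far,
    )


# ---------------------------------------------------------------------------
# PBT
# ---------------------------------------------------------------------------

def pbt_step(
    population: List[Trial],
    cfg: PbtConfig,
    rng: np.random.Generator,
) -> List[Trial]:
    """One exploit/explore generation of population-based training.

    Members in the bottom ``truncation_fraction`` (strictly worse than
    every top-fraction member — ties keep incumbents) copy a uniformly
    sampled top member's configuration, then perturb the learning rate
    by a factor drawn from ``perturb_factors``.  Filters and batch size
    are never perturbed.  Population size is preserved.
    """
    if len(population) < 2:
        raise ValueError("population must have at least 2 members")
    n = len(population)
    q = max(1, int(math.floor(cfg.truncation_fraction * n)))

    def score(i: int) -> float:
        v = population[i].val_accuracy
        return -math.inf if math.isnan(v) else v

    order = sorted(range(n), key=lambda i: (-score(i), i))
    top = order[:q]
    bottom = order[-q:]
    top_floor = min(score(i) for i in top)
    next_gen: List[Trial] = []
    for i, member in enumerate(population):
        cfg_i = dict(member.config)
        if i in bottom and score(i) < top_floor:
            source = population[int(rng.choice(top))]
            cfg_i = dict(source.config)
            factor = float(rng.choice(cfg.perturb_factors))
            cfg_i["learning_rate"] = cfg_i["learning_rate"] * factor
        next_gen.append(
            Trial(
                trial_id=member.trial_id,
                config=cfg_i,
                resource_used=member.resource_used,
                val_accuracy=member.val_accuracy,
                status="running",
                generation=(member.generation or 0) + 1,
            )
        )
    return next_gen


def _pbt_search(
    space: SearchSpace, cfg: PbtConfig, objective: Objective, seed: int
) -> SearchResult:
    rng = np.random.default_rng(seed)
    population = [
        Trial(trial_id=i, config=space.sample(rng), generation=0)
        for i in range(cfg.population)
    ]
    trials: List[Trial] = []
    best_so_far: List[float] = []
    best = -math.inf
    best_cfg: Dict = dict(population[0].config)
    for gen in range(cfg.generations):
        for member in population:
            member.resource_used += cfg.resource_per_generation
            try:
                member.val_accuracy = float(
                    objective(member.config, member.resource_used, seed)
                )
            except Exception:
                member.val_accuracy = float("nan")  # recorded; search continues
            member.status = "completed"
            member.generation = gen
            trials.append(
                Trial(
                    trial_id=member.trial_id,
                    config=dict(member.config),
                    resource_used=member.resource_used,
                    val_accuracy=member.val_accuracy,
                    status="completed",
                    generation=gen,
                )
            )
            if not math.isnan(member.val_accuracy) and member.val_accuracy > best:
                best = member.val_accuracy
                best_cfg = dict(member.config)
            best_so_far.append(best)
        if gen < cfg.generations - 1:
            population = pbt_step(population, cfg, rng)
    return SearchResult(best_config=best_cfg, best_score=best, trials=trials, best_so_far=best_so_far)


# ---------------------------------------------------------------------------
# Bayesian optimization with expected improvement
# ---------------------------------------------------------------------------

def _encode(space: SearchSpace, config: Dict) -> np.ndarray:
    """Surrogate features: log-scaled lr in [0,1] + one-hot discrete dims."""
    lo, hi = space.learning_rate
    if hi > lo:
        x_lr = (np.log(config["learning_rate"]) - np.log(lo)) / (np.log(hi) - np.log(lo))
    else:
        x_lr = 0.0
    onehot_f = [1.0 if config["filters"] == f else 0.0 for f in space.filters]
    onehot_b = [1.0 if config["batch_size"] == b else 0.0 for b in space.batch_size]
    return np.array([x_lr] + onehot_f + onehot_b)


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float) -> np.ndarray:
    from scipy.stats import norm

    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)


def _bo_single_run(
    space: SearchSpace, cfg: BoConfig, objective: Objective, seed: int
) -> Tuple[Dict, float, List[Trial], List[float]]:
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern

    rng = np.random.default_rng(seed)
    evaluated: List[Tuple[Dict, float]] = []
    trials: List[Trial] = []
    best_curve: List[float] = []

    def run(config: Dict) -> None:
        trial = Trial(trial_id=len(trials), config=dict(config), resource_used=cfg.resource)
        trials.append(trial)
        try:
            score = float(objective(config, cfg.resource, seed))
        except Exception:
            trial.status = "stopped"  # failure recorded; search continues
            return
        trial.val_accuracy = score
        trial.status = "completed"
        evaluated.append((config, score))
        best_curve.append(max(s for _, s in evaluated))

    n_warm = min(cfg.warmup_points, cfg.iterations_per_run)
    for _ in range(n_warm):
        run(space.sample(rng))
    for _ in range(cfg.iterations_per_run - n_warm):
        if not evaluated:  # every evaluation failed so far: stay random
            run(space.sample(rng))
            continue
        X = np.array([_encode(space, c) for c, _ in evaluated])
        y = np.array([s for _, s in evaluated])
        kernel = ConstantKernel(1.0) * Matern(length_scale=0.5, nu=2.5)
        gp = GaussianProcessRegressor(
            kernel=kernel, alpha=1e-6, normalize_y=True, random_state=int(seed % 2**31)
        )
        gp.fit(X, y)
        candidates = [space.sample(rng) for _ in range(cfg.n_candidates)]
        Xc = np.array([_encode(space, c) for c in candidates])
        mu, sigma = gp.predict(Xc, return_std=True)
        ei = _expected_improvement(mu, sigma, float(y.max()))
        run(candidates[int(np.argmax(ei))])

    if not evaluated:
        raise RuntimeError("every objective evaluation failed")
    best_cfg, best_score = max(evaluated, key=lambda e: e[1])
    return dict(best_cfg), best_score, trials, best_curve


def _bo_search(
    space: SearchSpace, cfg: BoConfig, objective: Objective, seed: int
) -> SearchResult:
    rng = np.random.default_rng(seed)
    trials: List[Trial] = []
    best_so_far: List[float] = []
    best = -math.inf
    for _run in range(cfg.independent_runs):
        run_seed = int(rng.integers(0, 2**31 - 1))
        _, _, run_trials, curve = _bo_single_run(space, cfg, objective, run_seed)
        for t in run_trials:
            t.trial_id = len(trials)
            trials.append(t)
        for c in curve:
            best = max(best, c)
            best_so_far.append(best)
    best_trial = max(trials, key=lambda t: t.val_accuracy)
    return SearchResult(
        best_config=dict(best_trial.config),
        best_score=best_trial.val_accuracy,
        trials=trials,
        best_so_far=best_so_far,
    )


def search(
    space: SearchSpace,
    method_config: MethodConfig,
    objective: Objective,
    seed: int = 0,
) -> SearchResult:
    """Run one HPO method; returns the best evaluated config and full log."""
    if isinstance(method_config, AshaConfig):
        return _asha_search(space, method_config, objective, seed)
    if isinstance(method_config, PbtConfig):
        return _pbt_search(space, method_config, objective, seed)
    if isinstance(method_config, BoConfig):
        return _bo_search(space, method_config, objective, seed)
    raise TypeError(f"unknown method config {type(method_config).__name__}")
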