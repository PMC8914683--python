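"""End-to-end orchestration: data -> SORN -> tuning -> reservoirs -> readout.

The pipeline mirrors the two-component design of the method: a
self-organizing reservoir stage (per-channel SORN clustering, two-stage
IS/SR tuning via recurrence analysis, deterministic ESN construction)
followed by the convolutional readout stage (ESR extraction, optional
hyperparameter search, Adam training, evaluation).  One global seed
deterministically derives every stage's seed, so a rerun with the same
configuration reproduces every artifact bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import convnet, hpo, sorn, synthetic, tuner
from .data_model import PARTS, LabeledDataset
from .reservoir import ReservoirWeights, build_reservoir, compute_esr
from .tuner import DEFAULT_IS_GRID, DEFAULT_SR_GRID, ESP_CAP, SweepResult


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration; one global seed drives every stage."""

    seed: int = 0
    # data
    samples_per_class: int = 40
    val_fraction: float = 0.25
    # SORN (applied to every channel unless sorn_per_channel overrides)
    vigilance: float = 0.05
    sorn_learning_rate: float = 0.5
    noise_scale: float = 0.1
    noise_decay: float = 1.0
    max_nodes: int = 27
    sorn_max_epochs: int = 10
    sorn_per_channel: Optional[Dict[str, sorn.SornConfig]] = None
    # tuning
    is_grid: Tuple[float, ...] = DEFAULT_IS_GRID
    sr_grid: Tuple[float, ...] = DEFAULT_SR_GRID
    esp_cap: float = ESP_CAP
    tune_channel: str = "CT"
    tune_max_frames: int = 400
    skip_tuning: bool = False
    input_scaling: float = 0.1  # used when skip_tuning
    spectral_radius: float = 0.99
    # readout
    scales: Tuple[int, ...] = (2, 3, 4)
    filters_per_scale: int = 16
    learning_rate: float = 0.001
    batch_size: int = 4
    epochs: int = 30
    # HPO (optional)
    hpo_method: Optional[str] = None  # "bo" | "asha" | "pbt"
    search_space: hpo.SearchSpace = field(default_factory=hpo.SearchSpace)

    def validate(self) -> None:
        if self.tune_channel not in PARTS:
            raise ValueError(f"tune_channel must be one of {PARTS}")
        if self.sorn_per_channel is not None:
            missing = [p for p in PARTS if p not in self.sorn_per_channel]
            if missing:
                raise ValueError(f"missing SORN settings for channel(s): {missing}")

    def config_hash(self) -> str:
        payload = json.dumps(_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class PipelineResult:
    sorn_states: Dict[str, sorn.SornState]
    reservoirs: Dict[str, ReservoirWeights]
    input_scaling: float
    spectral_radius: float
    sweep_stage1: Optional[SweepResult]
    sweep_stage2: Optional[SweepResult]
    model: convnet.ConvEsnReadout
    history: Dict[str, List[float]]
    report: convnet.EvalReport
    hpo_result: Optional[hpo.SearchResult]
    config_hash: str


def derive_seeds(seed: int, n: int) -> List[int]:
    """Deterministic per-stage seeds (< 2**31) from one global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % 2**31 for s in ss.generate_state(n)]


def _channel_series(dataset: LabeledDataset, part: str, trim: bool = True) -> List[np.ndarray]:
    """Per-sample series of one channel; padding rows trimmed when known."""
    out = []
    for i, cs in enumerate(dataset.channel_sets):
        s = cs[part].series
        if trim and dataset.lengths is not None:
            s = s[: dataset.lengths[i]]
        out.append(s)
    return out


def fit_sorn_states(
    dataset: LabeledDataset, rc: RunConfig
) -> Dict[str, sorn.SornState]:
    """Fit one SORN per body-part channel on the training samples."""
    seeds = derive_seeds(rc.seed, len(PARTS))
    states: Dict[str, sorn.SornState] = {}
    for part, part_seed in zip(PARTS, seeds):
        if rc.sorn_per_channel is not None:
            cfg = rc.sorn_per_channel[part]
        else:
            cfg = sorn.SornConfig(
                vigilance=rc.vigilance,
                learning_rate=rc.sorn_learning_rate,
                noise_scale=rc.noise_scale,
                noise_decay=rc.noise_decay,
                max_nodes=rc.max_nodes,
                max_epochs=rc.sorn_max_epochs,
                seed=part_seed,
            )
        states[part] = sorn.fit(_channel_series(dataset, part), cfg)
    return states


def extract_esr_dataset(
    dataset: LabeledDataset,
    reservoirs: Dict[str, ReservoirWeights],
    classes: Sequence[str],
) -> convnet.EsrDataset:
    """Project every sample's five channels to ESRs and stack into blocks."""
    samples: List[Dict[str, np.ndarray]] = []
    for cs in dataset.channel_sets:
        samples.append(
            {part: compute_esr(reservoirs[part], cs[part].series).X for part in PARTS}
        )
    return convnet.stack_esr_samples(samples, dataset.labels, classes=classes)


def run_pipeline(
    rc: RunConfig,
    dataset: Optional[LabeledDataset] = None,
    out_dir: Optional[str] = None,
) -> PipelineResult:
    """Execute the full workflow; optionally write artifacts to ``out_dir``.

    When no dataset is given, a four-class synthetic action dataset is
    generated from the run seed.  Returns every stage's artifact in
    memory; see :class:`PipelineResult`.
    """
    rc.validate()
    seeds = derive_seeds(rc.seed, 16)
    if dataset is None:
        gen_cfg = synthetic.GeneratorConfig(
            classes=synthetic.default_class_specs(),
            samples_per_class=rc.samples_per_class,
            seed=seeds[5],
        )
        dataset = synthetic.generate_action_dataset(gen_cfg)
    if dataset.split is None:
        dataset.split = synthetic.assign_split(
            dataset.labels, val_fraction=rc.val_fraction, seed=seeds[6]
        )
    train_ds = dataset.subset("train")
    val_ds = dataset.subset("val")
    classes = dataset.classes

    # --- stage 1: SORN clustering per channel -------------------------
    states = fit_sorn_states(train_ds, rc)

    # --- stage 2: recurrence-based IS/SR tuning ------------------------
    sweep1: Optional[SweepResult] = None
    sweep2: Optional[SweepResult] = None
    if rc.skip_tuning:
        chosen_is, chosen_sr = rc.input_scaling, rc.spectral_radius
    else:
        chosen_is, chosen_sr, sweep1, sweep2 = tuner.two_stage_tune(
            states[rc.tune_channel],
            _channel_series(train_ds, rc.tune_channel),
            is_grid=rc.is_grid,
            sr_grid=rc.sr_grid,
            esp_cap=rc.esp_cap,
            max_frames=rc.tune_max_frames,
        )

    # --- stage 3: reservoirs + ESR extraction --------------------------
    reservoirs = {
        part: build_reservoir(states[part], chosen_is, chosen_sr) for part in PARTS
    }
    esr_train = extract_esr_dataset(train_ds, reservoirs, classes)
    esr_val = extract_esr_dataset(val_ds, reservoirs, classes)

    # --- stage 4: readout (optionally HPO) -----------------------------
    n_neurons = reservoirs[PARTS[0]].n_neurons
    hpo_result: Optional[hpo.SearchResult] = None
    filters, lr, batch = rc.filters_per_scale, rc.learning_rate, rc.batch_size
    if rc.hpo_method is not None:
        objective = make_objective(esr_train, esr_val, rc, n_neurons, len(classes))
        method_cfg = _default_method_config(rc.hpo_method)
        hpo_result = hpo.search(rc.search_space, method_cfg, objective, seed=seeds[7])
        filters = int(hpo_result.best_config["filters"])
        lr = float(hpo_result.best_config["learning_rate"])
        batch = int(hpo_result.best_config["batch_size"])

    model_cfg = convnet.ModelConfig(
        reservoir_size=n_neurons,
        num_classes=len(classes),
        scales=rc.scales,
        filters_per_scale=filters,
    )
    block_widths = {name: arr.shape[2] for name, arr in esr_train.blocks.items()}
    model = convnet.ConvEsnReadout(model_cfg, seed=seeds[8], block_widths=block_widths)
    tc = convnet.TrainConfig(
        learning_rate=lr, batch_size=batch, epochs=rc.epochs, seed=seeds[9]
    )
    history = model.fit(esr_train, esr_val, tc)
    report = model.evaluate(esr_val)

    result = PipelineResult(
        sorn_states=states,
        reservoirs=reservoirs,
        input_scaling=chosen_is,
        spectral_radius=chosen_sr,
        sweep_stage1=sweep1,
        sweep_stage2=sweep2,
        model=model,
        history=history,
        report=report,
        hpo_result=hpo_result,
        config_hash=rc.config_hash(),
    )
    if out_dir is not None:
        write_artifacts(result, rc, out_dir)
    return result


def _default_method_config(method: str) -> hpo.MethodConfig:
    method = method.lower()
    if method == "bo":
        return hpo.BoConfig(independent_runs=5, resource=10)
    if method == "asha":
        return hpo.AshaConfig(max_resource=16, max_trials=8)
    if method == "pbt":
        return hpo.PbtConfig(population=4, generations=3)
    raise ValueError(f"unknown HPO method {method!r}")


def make_objective(
    esr_train: convnet.EsrDataset,
    esr_val: convnet.EsrDataset,
    rc: RunConfig,
    n_neurons: int,
    n_classes: int,
):
    """Readout-training objective: deterministic in (config, resource, seed)."""

    widths = {name: arr.shape[2] for name, arr in esr_train.blocks.items()}

    def objective(config: Dict, resource: int, seed: int) -> float:
        model_cfg = convnet.ModelConfig(
            reservoir_size=n_neurons,
            num_classes=n_classes,
            scales=rc.scales,
            filters_per_scale=int(config["filters"]),
        )
        model = convnet.ConvEsnReadout(model_cfg, seed=seed % 2**31, block_widths=widths)
        tc = convnet.TrainConfig(
            learning_rate=float(config["learning_rate"]),
            batch_size=int(config["batch_size"]),
            epochs=max(1, int(resource)),
            seed=seed % 2**31,
        )
        model.fit(esr_train, None, tc)
        return model.evaluate(esr_val).accuracy

    return objective


def write_artifacts(result: PipelineResult, rc: RunConfig, out_dir: str) -> None:
    """Persist every stage artifact with config-hash provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": result.config_hash, "seed": rc.seed}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    for part, state in result.sorn_states.items():
        sorn.save_state(state, out / f"sorn_{part}.h5")
    summary = {
        "input_scaling": result.input_scaling,
        "spectral_radius": result.spectral_radius,
        "val_accuracy": result.report.accuracy,
        "confusion": result.report.confusion.tolist(),
        "history": result.history,
        "config_hash": result.config_hash,
    }
    if result.sweep_stage1 is not None:
        summary["sweep_stage1"] = result.sweep_stage1.as_dict()
    if result.sweep_stage2 is not None:
        summary["sweep_stage2"] = result.sweep_stage2.as_dict()
    if result.hpo_result is not None:
        summary["hpo"] = {
            "best_config": result.hpo_result.best_config,
            "best_score": result.hpo_result.best_score,
        }
    (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2))


def check_stale(out_dir: str, rc: RunConfig) -> bool:
    """True when artifacts in out_dir were made under a different config."""
    prov = Path(out_dir) / "provenance.json"
    if not prov.exists():
        return True
    stored = json.loads(prov.read_text()).get("config_hash")
    return stored != rc.config_hash()
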