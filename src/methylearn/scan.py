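"""Randomised hyperparameter / topology search with trial logging.

Each trial samples a learning rate (and, for embedding, a KL weight and
scheduler) from user grids and a network topology from depth/width/latent
ranges; a ``complexity_weight`` in [0, 1] skews topology draws toward
deeper and wider networks (0 = uniform over the low half of each range,
1 = uniform over the high half, linear mixture in between).  Trials run
sequentially, each seeded from ``scan_seed + trial index`` so the log is
fully determined by (scan_seed, space, data) and independent of execution
order.  Divergent trials are recorded with infinite loss rather than
aborting the scan; the best trial is the minimum validation loss with
ties broken by earliest trial id.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigError, ScanFailedError, TrainingDivergedError
from .finetune import (
    FineTuneModel,
    PredictionTask,
    build_finetune_model,
    train_mlp_baseline,
)
from .vae import EncoderTopology, TrainConfig, VAEEmbedder, train_vae


@dataclass
class ScanSpace:
    """Sampling space for the randomised scan."""

    learning_rate_grid: list[float] = field(default_factory=lambda: [1e-2, 5e-3, 1e-3])
    beta_kl_grid: list[float] = field(default_factory=lambda: [0.1, 0.5, 1.0])
    depth_range: tuple[int, int] = (1, 2)
    width_range: tuple[int, int] = (32, 128)
    latent_range: tuple[int, int] = (8, 32)
    scheduler_options: list[str] = field(default_factory=lambda: ["none"])
    complexity_weight: float = 0.5

    def __post_init__(self):
        for name in ("depth_range", "width_range", "latent_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ConfigError(f"{name} invalid: ({lo}, {hi})")
        if not self.learning_rate_grid or any(lr <= 0 for lr in self.learning_rate_grid):
            raise ConfigError("learning_rate_grid must be positive")
        if any(b < 0 for b in self.beta_kl_grid):
            raise ConfigError("beta_kl_grid must be non-negative")
        if not 0.0 <= self.complexity_weight <= 1.0:
            raise ConfigError("complexity_weight must be in [0, 1]")


@dataclass
class TrialRecord:
    trial_id: int
    topology: EncoderTopology
    config: TrainConfig
    best_val_loss: float
    epochs_run: int
    checkpoint: str | None = None
    diverged: bool = False
    model: object = field(default=None, repr=False, compare=False)

    def to_json(self) -> str:
        d = {
            "trial_id": self.trial_id,
            "topology": {"hidden_widths": list(self.topology.hidden_widths),
                         "latent_dim": self.topology.latent_dim},
            "config": asdict(self.config),
            "best_val_loss": self.best_val_loss,
            "epochs_run": self.epochs_run,
            "checkpoint": self.checkpoint,
            "diverged": self.diverged,
        }
        return json.dumps(d)


@dataclass
class ScanLog:
    records: list[TrialRecord]
    mode: str
    scan_seed: int

    def write_jsonl(self, path):
        with open(path, "w") as f:
            for rec in self.records:
                f.write(rec.to_json() + "\n")
        return path


def _skewed_int(rng: np.random.Generator, lo: int, hi: int, weight: float) -> int:
    """Draw from [lo, hi]: mixture of uniform-over-low-half (prob 1-w) and
    uniform-over-high-half (prob w)."""
    if lo == hi:
        return lo
    mid = (lo + hi) // 2
    if rng.uniform() < weight:
        return int(rng.integers(mid + 1, hi + 1))
    return int(rng.integers(lo, mid + 1))


def sample_topology(space: ScanSpace, rng_seed: int) -> EncoderTopology:
    """Seeded topology draw; complexity_weight skews toward deep/wide."""
    rng = np.random.default_rng(rng_seed)
    w = space.complexity_weight
    depth = _skewed_int(rng, *space.depth_range, weight=w)
    widths = [_skewed_int(rng, *space.width_range, weight=w) for _ in range(depth)]
    latent = _skewed_int(rng, *space.latent_range, weight=w)
    return EncoderTopology(hidden_widths=widths, latent_dim=latent)


def _sample_config(space: ScanSpace, rng_seed: int, mode: str,
                   epochs_cap: int, batch_size: int) -> TrainConfig:
    rng = np.random.default_rng(rng_seed + 1)
    lr = float(rng.choice(space.learning_rate_grid))
    beta_kl = float(rng.choice(space.beta_kl_grid)) if mode == "embed" else 0.0
    scheduler = str(rng.choice(space.scheduler_options))
    return TrainConfig(learning_rate=lr, beta_kl=beta_kl, max_epochs=epochs_cap,
                       patience=max(3, epochs_cap // 5), batch_size=batch_size,
                       seed=rng_seed, scheduler=scheduler)


def launch_hyperparameter_scan(
    train, val, mode: str, space: ScanSpace, n_jobs: int, scan_seed: int,
    epochs_cap: int = 50, *, task: PredictionTask | None = None,
    vae: VAEEmbedder | None = None, batch_size: int = 32,
    scan_dir: str | None = None,
) -> ScanLog:
    """Run ``n_jobs`` independent trials and log every one.

    mode="embed" trains VAEs; mode="predict" trains fine-tune models (from
    ``vae`` if given, otherwise MLP baselines) for ``task``.  Trial i is
    seeded with ``scan_seed + i``; with a ``scan_dir`` each completed trial
    writes a checkpoint keyed by trial id and the log is saved as
    JSON-lines.
    """
    if n_jobs < 1:
        raise ConfigError(f"n_jobs must be >= 1, got {n_jobs}")
    if mode not in ("embed", "predict"):
        raise ConfigError(f"mode must be 'embed' or 'predict', got {mode!r}")
    if mode == "predict" and task is None:
        raise ConfigError("mode='predict' requires a task")

    records = []
    for i in range(n_jobs):
        trial_seed = scan_seed + i
        topo = sample_topology(space, trial_seed)
        config = _sample_config(space, trial_seed, mode, epochs_cap, batch_size)
        checkpoint = None
        try:
            if mode == "embed":
                model = train_vae(train, val, topo, config)
            else:
                if vae is not None:
                    model = build_finetune_model(vae, [topo.hidden_widths[-1]],
                                                 task, seed=trial_seed)
                    # scanning topology only varies the head when transferring
                    model.fit(train, val, config)
                else:
                    model = train_mlp_baseline(train, val, topo, task, config)
            log = model.training_log_
            best_val = min(e["val_loss"] for e in log)
            rec = TrialRecord(trial_id=i, topology=topo, config=config,
                              best_val_loss=float(best_val),
                              epochs_run=len(log), model=model)
            if scan_dir is not None and hasattr(model, "save"):
                os.makedirs(scan_dir, exist_ok=True)
                checkpoint = os.path.join(scan_dir, f"trial_{i}.h5")
                model.save(checkpoint)
                rec.checkpoint = checkpoint
        except TrainingDivergedError:
            rec = TrialRecord(trial_id=i, topology=topo, config=config,
                              best_val_loss=math.inf, epochs_run=0,
                              diverged=True)
        records.append(rec)

    if all(r.diverged for r in records):
        raise ScanFailedError(
            "all trials diverged: "
            + "; ".join(f"trial {r.trial_id} ({r.config.learning_rate=})" for r in records)
        )
    log = ScanLog(records=records, mode=mode, scan_seed=scan_seed)
    if scan_dir is not None:
        os.makedirs(scan_dir, exist_ok=True)
        log.write_jsonl(os.path.join(scan_dir, "scan_log.jsonl"))
    return log


def select_best(log: ScanLog) -> TrialRecord:
    """Completed trial with minimum validation loss; ties -> earliest id."""
    completed = [r for r in log.records if not r.diverged and np.isfinite(r.best_val_loss)]
    if not completed:
        raise ScanFailedError("no completed trials to select from")
    return min(completed, key=lambda r: (r.best_val_loss, r.trial_id))
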