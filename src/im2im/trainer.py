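"""Training orchestration: epochs, validation, checkpointing, run records.

The loop is deliberately simple and fully deterministic: every stochastic
decision (split, portion schedule, patch origins, augmentation, weight init)
draws from a named child of the run's seed tree, so two runs with equal seed
and config produce bitwise-identical float32 loss traces on one CPU.

Checkpoints store network parameters, optimizer state, the epoch counter and a
snapshot of the config; ``best`` tracks the first validation metric of the
task, ``last`` always points at the latest epoch. Run records are a CSV of
per-epoch metric rows plus a JSON header with the config digest and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .core.config import RunConfig
from .core.seeding import SeedTree, seed_everything
from .frameworks import build_framework
from .inference import predict_image
from .io_data.cache import cached_dataset
from .io_data.manifest import build_manifest
from .io_data.portion import portion_loader
from .metrics import METRICS_BY_TASK, MetricReport, evaluate_pair
from .preprocess import apply_transform
from .sampling import assemble_batch, sample_patches
from .core.axes import NDImage

log = logging.getLogger(__name__)

PRIMARY_METRIC = {"regression": "pearson", "segmentation": "f1", "instance": "ap50"}


def config_digest(cfg: RunConfig) -> str:
    return hashlib.sha256(cfg.to_yaml().encode()).hexdigest()[:12]


def save_checkpoint(path: str | Path, payload: dict):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(".tmp")
    with open(tmp, "wb") as fh:
        pickle.dump(payload, fh)
    tmp.replace(path)  # atomic


def load_checkpoint(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        return pickle.load(fh)


def _task_of(cfg: RunConfig) -> str:
    if cfg.framework.kind == "embedseg":
        return "instance"
    return cfg.framework.task


def validate_epoch(val_dataset, framework, cfg: RunConfig) -> MetricReport:
    """Full-image inference on every validation record, task metrics per image."""
    task = _task_of(cfg)
    report = MetricReport()
    model = framework.predictor()
    decoder = framework.decoder() if hasattr(framework, "decoder") else None
    for i in range(len(val_dataset)):
        pair = val_dataset.load(i)
        img = NDImage(pair.source, "C" + "ZYX"[-(pair.source.ndim - 1):])
        pred = predict_image(
            img,
            model,
            cfg.inference,
            preprocess=None,  # val dataset arrays are already normalized
            network=cfg.network,
            decoder=decoder,
        )
        pred_arr = np.asarray(pred.data)
        gt = pair.target
        for name, value in evaluate_pair(pred_arr, gt, task).items():
            report.add(pair.record_id, name, value)
    return report


class Trainer:
    def __init__(self, cfg: RunConfig, workdir: str | Path | None = None):
        self.cfg = cfg
        self.workdir = Path(workdir or cfg.trainer.output_dir)
        self.seeds: SeedTree = seed_everything(cfg.trainer.seed)
        if cfg.trainer.precision == "16-mixed":
            log.info("precision 16-mixed requested; running in float32")
        self.framework = build_framework(
            cfg.framework, cfg.network, cfg.trainer, self.seeds.child("init")
        )
        self.start_epoch = 0
        self.history: list[dict] = []
        self._best = -np.inf
        self._swa_state = None
        self._swa_count = 0

    # -- data ----------------------------------------------------------------
    def _datasets(self):
        manifest = build_manifest(self.cfg.data, self.seeds)
        train_ds = cached_dataset(
            manifest,
            self.cfg.preprocess,
            self.cfg.data.cache_dir,
            apply_transform,
            split="train",
        )
        val_ds = cached_dataset(
            manifest,
            self.cfg.preprocess,
            self.cfg.data.cache_dir,
            apply_transform,
            split="val",
        )
        return manifest, train_ds, val_ds

    # -- checkpointing ---------------------------------------------------------
    def _checkpoint_payload(self, epoch: int) -> dict:
        payload = {
            "epoch": epoch,
            "config_yaml": self.cfg.to_yaml(),
            "config_digest": config_digest(self.cfg),
            "networks": self.framework.state_dict(),
            "optimizers": {
                name: opt.state_dict()
                for name, opt in self._optimizers().items()
            },
        }
        if self._swa_state is not None:
            payload["swa"] = {"state": self._swa_state, "count": self._swa_count}
        return payload

    def _optimizers(self) -> dict:
        opts = {}
        for attr in ("opt", "opt_g", "opt_d"):
            if hasattr(self.framework, attr):
                opts[attr] = getattr(self.framework, attr)
        return opts

    def resume(self, checkpoint_path: str | Path):
        ckpt = load_checkpoint(checkpoint_path)
        self.framework.load_state_dict(ckpt["networks"])
        for name, opt in self._optimizers().items():
            if name in ckpt.get("optimizers", {}):
                opt.load_state_dict(ckpt["optimizers"][name])
        self.start_epoch = int(ckpt["epoch"]) + 1
        if "swa" in ckpt:
            self._swa_state = ckpt["swa"]["state"]
            self._swa_count = ckpt["swa"]["count"]

    # -- SWA ---------------------------------------------------------------
    def _swa_update(self):
        gen = self.framework.networks()["generator"]
        state = gen.state_dict()
        if self._swa_state is None:
            self._swa_state = {k: v.copy() for k, v in state.items()}
            self._swa_count = 1
        else:
            self._swa_count += 1
            a = 1.0 / self._swa_count
            for k in self._swa_state:
                self._swa_state[k] = (1 - a) * self._swa_state[k] + a * state[k]

    # -- training loop -----------------------------------------------------
    def fit(self) -> pd.DataFrame:
        cfg = self.cfg
        self.workdir.mkdir(parents=True, exist_ok=True)
        manifest, train_ds, val_ds = self._datasets()
        loader = portion_loader(
            list(range(len(train_ds))),
            cfg.data.portion_fraction,
            cfg.data.reload_every,
            self.seeds.child("io_data.portion"),
        )
        run_meta = {
            "config_digest": config_digest(cfg),
            "seed": cfg.trainer.seed,
            "start_time": time.time(),
            "n_train": len(train_ds),
            "n_val": len(val_ds),
        }
        task = _task_of(cfg)
        primary = PRIMARY_METRIC[task]
        stall = 0

        for epoch in range(self.start_epoch, cfg.trainer.max_epochs):
            rng = self.seeds.child(f"epoch.{epoch}")
            indices = loader.epoch_indices(epoch)
            order = rng.permutation(len(indices))
            losses: list[float] = []
            pending = []
            steps = 0
            for oi in order:
                pair = train_ds.load(indices[int(oi)])
                pending.extend(sample_patches(pair, cfg.sampling, rng))
                while len(pending) >= cfg.trainer.batch_size:
                    batch = assemble_batch(pending[: cfg.trainer.batch_size])
                    pending = pending[cfg.trainer.batch_size:]
                    logs = self.framework.training_step(batch)
                    losses.append(logs["loss"])
                    steps += 1
                    if (
                        cfg.trainer.steps_per_epoch
                        and steps >= cfg.trainer.steps_per_epoch
                    ):
                        break
                if cfg.trainer.steps_per_epoch and steps >= cfg.trainer.steps_per_epoch:
                    break
            if pending and not losses:
                batch = assemble_batch(pending)
                logs = self.framework.training_step(batch)
                losses.append(logs["loss"])

            row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if len(val_ds) > 0:
                report = validate_epoch(val_ds, self.framework, cfg)
                for m, (mu, sd) in report.summary.items():
                    row[f"val_{m}_mean"] = mu
                    row[f"val_{m}_std"] = sd
                score = row.get(f"val_{primary}_mean", -np.inf)
                if score > self._best:
                    self._best = score
                    stall = 0
                    save_checkpoint(
                        self.workdir / "best.ckpt", self._checkpoint_payload(epoch)
                    )
                else:
                    stall += 1
            if cfg.trainer.swa_enabled:
                self._swa_update()
            self.history.append(row)
            if (epoch + 1) % cfg.trainer.checkpoint_every == 0 or (
                epoch == cfg.trainer.max_epochs - 1
            ):
                save_checkpoint(
                    self.workdir / "last.ckpt", self._checkpoint_payload(epoch)
                )
            log.info("epoch %d: %s", epoch, row)
            if cfg.trainer.early_stop and stall >= cfg.trainer.early_stop:
                log.info("early stop at epoch %d", epoch)
                break

        save_checkpoint(
            self.workdir / "last.ckpt",
            self._checkpoint_payload(self.history[-1]["epoch"] if self.history else 0),
        )
        run_meta["end_time"] = time.time()
        frame = pd.DataFrame(self.history)
        # run record: append, never overwrite
        record_csv = self.workdir / "run_record.csv"
        frame.to_csv(
            record_csv,
            mode="a",
            header=not record_csv.exists(),
            index=False,
        )
        with open(self.workdir / "run_record.json", "w") as fh:
            json.dump(run_meta, fh, indent=2)
        return frame
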