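"""Training, evaluation and loss-comparison harness.

Ties the phantom generator, the two-branch networks and the loss zoo
together: seeded end-to-end training with per-step loss-term logging, Dice
model selection on a deterministic validation split, metrics CSV export and
a multi-loss / multi-seed comparison table.  Every output embeds the config
hash and master seed so any run is regenerable from its artifacts alone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import losses as L
from .autodiff import Tensor
from .band_operators import DegenerateBandWarning
from .metrics import MetricsRecord, evaluate, write_metrics_csv
from .networks import (
    BackboneConfig,
    TwoBranchNet,
    build_backbone,
    load_checkpoint,
    save_checkpoint,
)
from .nn import Adam
from .synthdata import PhantomConfig, load_dataset, make_batch

__all__ = [
    "ExperimentConfig",
    "TrainResult",
    "train",
    "evaluate_checkpoint",
    "compare",
    "LOSS_NAMES",
]

LOSS_NAMES = ("ce", "dice", "focal", "osc", "nbac")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce a run.

    Defaults mirror common 2D settings: Adam with learning rate 1e-2 and
    weight decay 1e-4 (use lr 2e-4 for 3D backbones).  ``loss`` selects from
    ``ce | dice | focal | osc | nbac``.
    """

    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    loss: str = "nbac"
    nbac: L.NBACWeights = field(default_factory=L.NBACWeights)
    focal: L.FocalParams = field(default_factory=L.FocalParams)
    osc: L.OscParams = field(default_factory=L.OscParams)
    lr: float = 1e-2
    weight_decay: float = 1e-4
    steps: int = 200
    batch_size: int = 8
    seed: int = 0
    n_train: int = 64
    n_val: int = 16
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    data_dir: str | None = None
    out_dir: str = "runs/latest"
    eval_every: int = 25
    grad_clip: float = 0.0

    def __post_init__(self):
        if self.loss not in LOSS_NAMES:
            raise ValueError(f"unknown loss {self.loss!r}; choose from {LOSS_NAMES}")

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "backbone" in d and isinstance(d["backbone"], dict):
            d["backbone"] = BackboneConfig(**d["backbone"])
        if "nbac" in d and isinstance(d["nbac"], dict):
            d["nbac"] = L.NBACWeights(**d["nbac"])
        if "focal" in d and isinstance(d["focal"], dict):
            d["focal"] = L.FocalParams(**d["focal"])
        if "osc" in d and isinstance(d["osc"], dict):
            d["osc"] = L.OscParams(**d["osc"])
        if "phantom" in d and isinstance(d["phantom"], dict):
            p = dict(d["phantom"])
            for key in ("dims", "proportions", "class_means", "class_stds", "vessel_radius"):
                if p.get(key) is not None:
                    p[key] = tuple(p[key])
            d["phantom"] = PhantomConfig(**p)
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(json.loads(json.dumps(self.to_dict(), default=list))))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        import hashlib

        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------


def _one_hot(masks: np.ndarray, K: int) -> np.ndarray:
    """(N, *sp) int labels -> (N, K, *sp) float one-hot."""
    out = np.zeros((masks.shape[0], K) + masks.shape[1:], dtype=np.float64)
    for c in range(K):
        out[:, c] = masks == c
    return out


def _load_or_generate(cfg: ExperimentConfig):
    if cfg.data_dir is not None:
        images, masks, _ = load_dataset(cfg.data_dir)
        n_val = max(1, len(images) // 5)
        # deterministic 80/20 split by item parity
        idx = np.arange(len(images))
        val = idx[idx % 5 == 4][: n_val]
        tr = np.setdiff1d(idx, val)
        return images[tr], masks[tr], images[val], masks[val]
    phantom = replace(cfg.phantom, seed=cfg.seed)
    img_tr, m_tr = make_batch(cfg.n_train, phantom)
    phantom_val = replace(cfg.phantom, seed=cfg.seed + 10_000)
    img_va, m_va = make_batch(cfg.n_val, phantom_val)
    return img_tr, m_tr, img_va, m_va


# ---------------------------------------------------------------------------
# loss dispatch
# ---------------------------------------------------------------------------


def _compute_loss(cfg: ExperimentConfig, out, onehot: np.ndarray):
    """Return (total loss Tensor, dict of scalar components) for one batch."""
    probs = out.probs
    spec = cfg.backbone.band_spec
    nd = cfg.backbone.nd
    comps: dict[str, float] = {}
    if cfg.loss == "ce":
        total = L.region_loss(probs_flat(probs), onehot_flat(onehot))
        comps["region"] = float(total.data)
    elif cfg.loss == "dice":
        total = _batch_mean(
            lambda i: L.multiclass_dice_loss(probs[i], onehot[i]), len(onehot)
        )
        comps["dice"] = float(total.data)
    elif cfg.loss == "focal":
        total = _batch_mean(
            lambda i: L.multiclass_focal_loss(probs[i], onehot[i], cfg.focal),
            len(onehot),
        )
        comps["focal"] = float(total.data)
    elif cfg.loss == "osc":
        total = _batch_mean(
            lambda i: L.osc_loss(probs[i], onehot[i], cfg.osc, spatial_ndim=nd),
            len(onehot),
        )
        comps["osc"] = float(total.data)
    else:  # nbac
        l1 = L.region_loss(probs_flat(probs), onehot_flat(onehot))
        l2 = _batch_mean(
            lambda i: L.nbac_multiclass_band_loss(
                probs[i], onehot[i], out.F_LC[i], out.F_LN[i], spec, cfg.nbac, nd
            ),
            len(onehot),
        )
        total = L.nbac_total_loss(l1, l2, cfg.nbac)
        comps["region_l1"] = float(l1.data)
        comps["band_l2"] = float(l2.data) if isinstance(l2, Tensor) else float(l2)
    comps["total"] = float(total.data) if isinstance(total, Tensor) else float(total)
    return total, comps


def probs_flat(probs: Tensor) -> Tensor:
    """(N, K, *sp) -> (K, N, *sp) so the categorical loss sums over axis 0."""
    return probs.moveaxis(1, 0)


def onehot_flat(onehot: np.ndarray) -> np.ndarray:
    return np.moveaxis(onehot, 1, 0)


def _batch_mean(fn, n: int):
    total = None
    for i in range(n):
        v = fn(i)
        total = v if total is None else total + v
    return total / n


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainResult:
    checkpoint: Path
    log: pd.DataFrame
    best_val_dice: float
    config_hash: str


def _val_dice(net: TwoBranchNet, images: np.ndarray, masks: np.ndarray, K: int) -> float:
    net.eval()
    dices = []
    for i in range(len(images)):
        pred = net.predict(images[i][None, None])
        rec = evaluate(pred[0], masks[i], K)
        dices.append(rec.macro_dice)
    net.train()
    return float(np.mean(dices))


def train(cfg: ExperimentConfig) -> TrainResult:
    """Run a seeded training loop and return the best checkpoint + log."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    img_tr, m_tr, img_va, m_va = _load_or_generate(cfg)
    K = cfg.backbone.num_classes
    oh_tr = _one_hot(m_tr, K)

    net = build_backbone(cfg.backbone, seed=cfg.seed)
    opt = Adam(net.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)

    rows = []
    best_dice, best_step = -1.0, -1
    ckpt_path = out_dir / "best.npz"
    n = len(img_tr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateBandWarning)
        for step in range(cfg.steps):
            idx = rng.choice(n, size=min(cfg.batch_size, n), replace=False)
            batch = Tensor(img_tr[idx][:, None])  # (B, 1, *sp)
            out = net(batch)
            total, comps = _compute_loss(cfg, out, oh_tr[idx])
            if not np.isfinite(comps["total"]):
                diag = out_dir / f"nan_batch_step{step}.npz"
                np.savez(diag, images=img_tr[idx], masks=m_tr[idx])
                raise FloatingPointError(
                    f"non-finite loss at step {step}; offending batch dumped to {diag}"
                )
            opt.zero_grad()
            total.backward()
            if cfg.grad_clip > 0:
                norm = np.sqrt(
                    sum(float((p.grad**2).sum()) for p in net.parameters() if p.grad is not None)
                )
                if norm > cfg.grad_clip:
                    scale = cfg.grad_clip / norm
                    for p in net.parameters():
                        if p.grad is not None:
                            p.grad *= scale
                    comps["grad_clipped"] = 1.0
            opt.step()
            row = {"step": step, **comps}
            if step % cfg.eval_every == 0 or step == cfg.steps - 1:
                dice = _val_dice(net, img_va, m_va, K)
                row["val_dice"] = dice
                if dice > best_dice:
                    best_dice, best_step = dice, step
                    save_checkpoint(
                        net,
                        ckpt_path,
                        seed=cfg.seed,
                        meta={
                            "config_hash": cfg.hash(),
                            "step": step,
                            "val_dice": dice,
                        },
                    )
            rows.append(row)

    log = pd.DataFrame(rows)
    log.attrs["config_hash"] = cfg.hash()
    log_path = out_dir / "train_log.csv"
    with log_path.open("w") as fh:
        fh.write(f"# config_hash={cfg.hash()} seed={cfg.seed}\n")
        log.to_csv(fh, index=False)
    cfg.to_yaml(out_dir / "config.yaml")
    return TrainResult(ckpt_path, log, best_dice, cfg.hash())


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate_checkpoint(
    checkpoint, images: np.ndarray, masks: np.ndarray, out_csv=None
) -> dict[str, MetricsRecord]:
    """Per-case metrics of a saved model on a dataset (argmax decision rule)."""
    net, header = load_checkpoint(checkpoint)
    K = net.cfg.num_classes
    if masks.max() >= K:
        raise ValueError(
            f"dataset has {int(masks.max()) + 1} classes but checkpoint expects {K}"
        )
    net.eval()
    records: dict[str, MetricsRecord] = {}
    for i in range(len(images)):
        pred = net.predict(images[i][None, None])[0]
        records[f"case_{i:04d}"] = evaluate(pred, masks[i], K)
    if out_csv is not None:
        write_metrics_csv(records, out_csv)
    return records


# ---------------------------------------------------------------------------
# comparison harness
# ---------------------------------------------------------------------------


def compare(
    cfg: ExperimentConfig,
    loss_names: tuple[str, ...] = ("ce", "dice", "focal", "nbac"),
    seeds: tuple[int, ...] = (0, 1, 2),
    out_csv=None,
) -> pd.DataFrame:
    """Train each loss with identical backbone/seeds on the same phantoms.

    Emits one row per (loss, seed) with DSC/IoU/Pre/Rec on the validation
    phantoms, plus per-loss median rows — the desk-scale analogue of a
    published loss-comparison table.
    """
    rows = []
    for name in loss_names:
        if name not in LOSS_NAMES:
            raise ValueError(f"unknown loss {name!r}")
        for seed in seeds:
            run_cfg = replace(
                cfg, loss=name, seed=seed, out_dir=str(Path(cfg.out_dir) / f"{name}_s{seed}")
            )
            result = train(run_cfg)
            img_va, m_va = make_batch(
                run_cfg.n_val, replace(run_cfg.phantom, seed=seed + 10_000)
            )
            records = evaluate_checkpoint(result.checkpoint, img_va, m_va)
            rows.append(
                {
                    "loss": name,
                    "seed": seed,
                    "dsc": float(np.mean([r.macro_dice for r in records.values()])),
                    "iou": float(np.mean([r.macro_iou for r in records.values()])),
                    "pre": float(np.mean([r.macro_precision for r in records.values()])),
                    "rec": float(np.mean([r.macro_recall for r in records.values()])),
                    "config_hash": result.config_hash,
                }
            )
    df = pd.DataFrame(rows)
    medians = (
        df.groupby("loss")[["dsc", "iou", "pre", "rec"]].median().reset_index()
    )
    medians.insert(1, "seed", "median")
    medians["config_hash"] = cfg.hash()
    table = pd.concat([df, medians], ignore_index=True)
    if out_csv is not None:
        Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_csv, index=False)
    return table
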