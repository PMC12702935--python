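"""Training, evaluation, ablation and checkpointing on top of the model.

Everything here is a plain function over in-memory arrays so the CLI stays
a thin argument parser.  A run is a pure function of (config, seed): model
initialisation, batch shuffling and augmentation all draw from seeds
derived from the run seed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .blocks_sepconv import count_parameters
from .model import IapTransUNet, ModelConfig, build_model
from .nn import SGD, Tensor
from .objectives_metrics import MetricReport, evaluate_case, total_loss_logits
from .phantoms import AugmentSpec, augment

__all__ = [
    "OptimizerConfig", "RunConfig", "desk_model_config",
    "train_model", "predict", "evaluate_model", "aggregate_reports",
    "ablation_grid", "run_ablation", "save_checkpoint", "load_checkpoint",
]

#: Table-style structural ablation: name -> (use_eca, use_cbam_aspp, use_dsc)
ABLATION_VARIANTS = {
    "TransUNet": (False, False, False),
    "Model1": (True, False, False),
    "Model2": (False, True, False),
    "Model3": (False, False, True),
    "Model4": (True, True, False),
    "Model5": (True, False, True),
    "Model6": (False, True, True),
    "IAP-TransUNet": (True, True, True),
}


@dataclass(frozen=True)
class OptimizerConfig:
    """SGD settings; defaults follow the reference training protocol.

    ``lr_schedule`` is "constant" (the default) or "poly", the lineage's
    polynomial decay lr * (1 - step/total_steps)^0.9.
    """
    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    lr_schedule: str = "constant"
    poly_power: float = 0.9

    def __post_init__(self):
        if self.lr_schedule not in ("constant", "poly"):
            raise ValueError(f"lr_schedule must be 'constant' or 'poly', "
                             f"got {self.lr_schedule!r}")


@dataclass(frozen=True)
class RunConfig:
    model: ModelConfig
    optimizer: OptimizerConfig = OptimizerConfig()
    batch_size: int = 4                 # reference protocol uses 24; desk default 4
    max_epochs: int = 10
    augment: AugmentSpec | None = AugmentSpec()
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["model"] = ModelConfig.from_dict(d["model"])
        d["optimizer"] = OptimizerConfig(**d.get("optimizer", {}))
        if d.get("augment") is not None:
            d["augment"] = AugmentSpec(**d["augment"])
        return cls(**d)


def desk_model_config(num_classes: int, **overrides) -> ModelConfig:
    """Reduced-width preset for CPU-scale experiments: 64x64 single-channel
    input, width multiplier 0.25, no dropout; all toggles on by default."""
    base = dict(num_classes=num_classes, in_channels=1, input_size=64,
                width_multiplier=0.25, dropout=0.0)
    base.update(overrides)
    return ModelConfig(**base)


# -- training -------------------------------------------------------------

def train_model(model: IapTransUNet, images: np.ndarray, labels: np.ndarray, *,
                optimizer: OptimizerConfig = OptimizerConfig(),
                batch_size: int = 4, epochs: int = 10, seed: int = 0,
                augment_spec: AugmentSpec | None = None,
                max_steps: int | None = None, stop_loss: float | None = None,
                out_dir=None, verbose: bool = False) -> dict:
    """SGD training loop on an in-memory stack of (image, label) pairs.

    Returns a history dict with per-epoch mean loss and per-step losses.
    ``stop_loss`` ends training early once a step's loss falls below it;
    ``max_steps`` caps the total number of optimizer steps.  A NaN loss
    aborts with a diagnostic rather than training on.
    """
    n = images.shape[0]
    if labels.shape[0] != n:
        raise ValueError("images and labels disagree on the number of cases")
    opt = SGD(model.parameters(), lr=optimizer.lr, momentum=optimizer.momentum,
              weight_decay=optimizer.weight_decay)
    steps_per_epoch = int(np.ceil(n / batch_size))
    total_steps = epochs * steps_per_epoch if max_steps is None \
        else min(max_steps, epochs * steps_per_epoch)
    rng = np.random.default_rng([seed, 0xA00])
    model.train()
    step = 0
    epoch_losses: list[float] = []
    step_losses: list[float] = []
    done = False
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses_this_epoch = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = images[idx], labels[idx]
            if augment_spec is not None:
                pairs = [augment(xb[i], yb[i], augment_spec,
                                 [seed, epoch, int(idx[i])])
                         for i in range(len(idx))]
                xb = np.stack([p[0] for p in pairs])
                yb = np.stack([p[1] for p in pairs])
            if optimizer.lr_schedule == "poly":
                opt.lr = optimizer.lr * (1.0 - step / total_steps) \
                    ** optimizer.poly_power
            model.zero_grad()
            logits = model(Tensor(xb))
            loss = total_loss_logits(logits, yb)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss {value} at epoch {epoch} step {step}; "
                    "check learning rate / data scaling")
            loss.backward()
            opt.step()
            step_losses.append(value)
            losses_this_epoch.append(value)
            step += 1
            if (stop_loss is not None and value < stop_loss) or \
               (max_steps is not None and step >= max_steps):
                done = True
                break
        if losses_this_epoch:
            epoch_losses.append(float(np.mean(losses_this_epoch)))
        if verbose and losses_this_epoch:
            print(f"epoch {epoch + 1}/{epochs}  loss {epoch_losses[-1]:.4f}")
        if done:
            break
    history = {"epoch_loss": epoch_losses, "step_loss": step_losses,
               "steps": step}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "loss.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "mean_loss"])
            for e, v in enumerate(epoch_losses, 1):
                writer.writerow([e, f"{v:.6f}"])
    return history


# -- inference / evaluation ----------------------------------------------

def predict(model: IapTransUNet, images: np.ndarray,
            batch_size: int = 8) -> np.ndarray:
    """Hard label maps (n, H, W) for a stack of images, in eval mode."""
    model.eval()
    preds = []
    for start in range(0, images.shape[0], batch_size):
        logits = model(Tensor(images[start:start + batch_size]))
        preds.append(logits.data.argmax(axis=1))
    model.train()
    return np.concatenate(preds).astype(np.int64)


def evaluate_model(model: IapTransUNet, images: np.ndarray, labels: np.ndarray,
                   ) -> list[MetricReport]:
    """Per-case metric reports for a stack of (image, label) pairs."""
    preds = predict(model, images)
    M = model.cfg.num_classes
    return [evaluate_case(preds[i], labels[i], M) for i in range(len(preds))]


def aggregate_reports(reports: list[MetricReport]) -> dict:
    """Mean foreground DSC / HD over cases (undefined HDs excluded)."""
    mean_dsc = float(np.mean([r.mean_dsc for r in reports]))
    hds = [r.mean_hd for r in reports if not np.isnan(r.mean_hd)]
    return {
        "n_cases": len(reports),
        "mean_dsc": mean_dsc,
        "mean_hd": float(np.mean(hds)) if hds else None,
        "n_cases_with_undefined_hd": int(sum(r.n_undefined_hd > 0
                                             for r in reports)),
    }


def write_reports(reports: list[MetricReport], out_dir, case_ids=None) -> dict:
    """Serialise per-case reports to CSV (one row per case x class) + JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    case_ids = case_ids or [f"case_{i:04d}" for i in range(len(reports))]
    rows = [row for cid, r in zip(case_ids, reports) for row in r.rows(cid)]
    with open(out_dir / "metrics.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["case_id", "class", "dsc",
                                                "hd", "hd_defined"])
        writer.writeheader()
        writer.writerows(rows)
    summary = aggregate_reports(reports)
    summary["per_case"] = {cid: r.to_dict() for cid, r in zip(case_ids, reports)}
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


# -- ablation -------------------------------------------------------------

def ablation_grid(base: ModelConfig) -> list[tuple[str, ModelConfig]]:
    """The eight structural variants derived from a base config."""
    grid = []
    for name, (eca, aspp, dsc) in ABLATION_VARIANTS.items():
        cfg = ModelConfig.from_dict({**base.to_dict(), "use_eca": eca,
                                     "use_cbam_aspp": aspp, "use_dsc": dsc})
        grid.append((name, cfg))
    return grid


def run_ablation(base: ModelConfig, *, seed: int = 0,
                 train_data: tuple[np.ndarray, np.ndarray] | None = None,
                 eval_data: tuple[np.ndarray, np.ndarray] | None = None,
                 epochs: int = 2, batch_size: int = 4,
                 optimizer: OptimizerConfig = OptimizerConfig(),
                 verbose: bool = False) -> list[dict]:
    """Build (and optionally briefly train + score) all eight variants.

    Dry run (no data): rows carry the toggle pattern and parameter count
    only.  With data, each variant is trained for ``epochs`` passes and
    scored on the evaluation stack.
    """
    rows = []
    for name, cfg in ablation_grid(base):
        model = build_model(cfg, seed=seed)
        row = {"variant": name, "use_eca": cfg.use_eca,
               "use_cbam_aspp": cfg.use_cbam_aspp, "use_dsc": cfg.use_dsc,
               "params": count_parameters(model)}
        if train_data is not None:
            train_model(model, *train_data, optimizer=optimizer,
                        batch_size=batch_size, epochs=epochs, seed=seed,
                        verbose=verbose)
            if eval_data is not None:
                agg = aggregate_reports(evaluate_model(model, *eval_data))
                row["mean_dsc"] = agg["mean_dsc"]
                row["mean_hd"] = agg["mean_hd"]
        rows.append(row)
        if verbose:
            print(row)
    return rows


# -- checkpointing --------------------------------------------------------

def save_checkpoint(path, model: IapTransUNet) -> Path:
    """Single-file .npz archive: parameter/buffer arrays + the model config."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8)
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **state)
    return path


def load_checkpoint(path) -> IapTransUNet:
    """Rebuild the model from a checkpoint; round-trips ``save_checkpoint``."""
    path = Path(path)
    if not path.exists() and path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path) as archive:
        state = {k: archive[k] for k in archive.files}
    cfg = ModelConfig.from_dict(
        json.loads(state.pop("__config__").tobytes().decode()))
    model = build_model(cfg, seed=0)
    model.load_state_dict(state)
    return model
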