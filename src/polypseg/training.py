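"""Training recipe: momentum SGD with polynomial LR decay.

The reference recipe trains for 200 epochs with SGD (momentum 0.9,
weight decay 1e-4), an initial learning rate of 5e-3 decayed per
iteration as ``base_lr * (1 - iter/total_iters)**power`` (power 0.9),
and the 0.5/0.5-weighted BCE + Dice loss.  Runs are fully seeded:
weight init, shuffling and augmentation all derive from
``TrainConfig.seed``.  Checkpoints store the weights, the full model
config (with a hash validated on load), the seed and the history.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from PIL import Image

from .data.augment import AugmentationConfig, augment_pair, pair_rng
from .data.pairs import ImageMaskPair, resize_pair, split_dataset
from .losses import LossWeights, combined_loss
from .metrics import MetricsReport, evaluate_dataset
from .model import ModelConfig, NestedUNetTransformer, build_model
from .nn import no_grad
from .nn.optim import SGD


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 8
    base_lr: float = 5e-3
    momentum: float = 0.9
    weight_decay: float = 1e-4
    poly_power: float = 0.9
    seed: int = 0
    checkpoint_every: int = 0       # 0: only best + last
    device: str = "cpu"
    val_fraction: float = 0.1
    max_iterations: int | None = None
    loss_weights: LossWeights = dataclasses.field(default_factory=LossWeights)

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0,1)")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TrainConfig":
        d = dict(d)
        if isinstance(d.get("loss_weights"), dict):
            d["loss_weights"] = LossWeights(**d["loss_weights"])
        return cls(**d)


@dataclasses.dataclass
class TrainState:
    iteration: int = 0
    epoch: int = 0
    lr: float = 0.0
    best_mdice: float = -1.0
    history: list[dict[str, float]] = dataclasses.field(default_factory=list)


def poly_lr(iteration: int, total_iters: int, base_lr: float,
            power: float = 0.9) -> float:
    """base_lr * (1 - iter/total)^power; hits base_lr at 0 and 0 at total."""
    if not 0 <= iteration <= total_iters:
        raise ValueError(
            f"iteration {iteration} outside [0, {total_iters}]")
    return base_lr * (1.0 - iteration / total_iters) ** power


def _to_batch(pairs: Sequence[ImageMaskPair]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.image for p in pairs]).astype(np.float32) / 255.0
    x = x.transpose(0, 3, 1, 2)
    y = np.stack([p.mask for p in pairs]).astype(np.float32)[:, None]
    return x, y


def train(model_cfg: ModelConfig, train_cfg: TrainConfig,
          dataset: Sequence[ImageMaskPair],
          val_dataset: Sequence[ImageMaskPair] | None = None,
          augmentation: AugmentationConfig | None = None,
          out_dir: str | Path | None = None,
          ) -> tuple[dict[str, Any], TrainState]:
    """Run the recipe; returns (checkpoint dict of the best model, state).

    When no explicit validation set is given and ``val_fraction`` > 0,
    that fraction of the training set is held out for best-checkpoint
    selection; otherwise the train set itself is used.
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    dataset = list(dataset)
    if val_dataset is None and train_cfg.val_fraction > 0 and len(dataset) >= 4:
        dataset, val_dataset = split_dataset(
            dataset, (1 - train_cfg.val_fraction, train_cfg.val_fraction),
            train_cfg.seed)
        if not val_dataset:
            val_dataset = None

    model = build_model(model_cfg, seed=train_cfg.seed)
    opt = SGD(model, lr=train_cfg.base_lr, momentum=train_cfg.momentum,
              weight_decay=train_cfg.weight_decay)

    n = len(dataset)
    batches_per_epoch = int(np.ceil(n / train_cfg.batch_size))
    total_iters = train_cfg.epochs * batches_per_epoch
    if train_cfg.max_iterations is not None:
        total_iters = min(total_iters, train_cfg.max_iterations)

    state = TrainState()
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence([train_cfg.seed, 0xC0FFEE]))
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    best_checkpoint: dict[str, Any] | None = None
    done = False
    for epoch in range(train_cfg.epochs):
        if done:
            break
        model.train()
        order = shuffle_rng.permutation(n)
        epoch_losses = []
        for b in range(batches_per_epoch):
            if state.iteration >= total_iters:
                done = True
                break
            idx = order[b * train_cfg.batch_size:(b + 1) * train_cfg.batch_size]
            batch_pairs = []
            for i in idx:
                p = dataset[i]
                if augmentation is not None:
                    p = augment_pair(p, augmentation,
                                     pair_rng(train_cfg.seed, p.id, epoch))
                batch_pairs.append(p)
            x, y = _to_batch(batch_pairs)
            lr = poly_lr(state.iteration, total_iters, train_cfg.base_lr,
                         train_cfg.poly_power)
            opt.lr = lr
            out = model(x)
            loss = combined_loss(out.probabilities, y, train_cfg.loss_weights)
            loss_val = loss.item()
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite loss at iteration {state.iteration} "
                    f"(lr={lr:.3e}, batch ids={[p.id for p in batch_pairs]})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss_val)
            state.iteration += 1
            state.lr = lr

        state.epoch = epoch
        train_loss = float(np.mean(epoch_losses)) if epoch_losses else float("nan")
        val_report = evaluate(model, val_dataset) if val_dataset else \
            evaluate(model, dataset)
        val_mdice = val_report.mdice
        state.history.append({"epoch": epoch, "train_loss": train_loss,
                              "lr": state.lr, "val_mdice": val_mdice})
        if val_mdice >= state.best_mdice:
            state.best_mdice = val_mdice
            best_checkpoint = make_checkpoint(model, model_cfg, train_cfg, state)
            if out_dir is not None:
                save_checkpoint(best_checkpoint, out_dir / "best.npz")
        if out_dir is not None:
            _append_log(out_dir / "train_log.csv", state.history[-1])
            if (train_cfg.checkpoint_every
                    and (epoch + 1) % train_cfg.checkpoint_every == 0):
                save_checkpoint(make_checkpoint(model, model_cfg, train_cfg, state),
                                out_dir / f"epoch_{epoch + 1:04d}.npz")

    last_checkpoint = make_checkpoint(model, model_cfg, train_cfg, state)
    if out_dir is not None:
        save_checkpoint(last_checkpoint, out_dir / "last.npz")
    if best_checkpoint is None:
        best_checkpoint = last_checkpoint
    return best_checkpoint, state


def _append_log(path: Path, row: dict[str, float]) -> None:
    new = not path.exists()
    with open(path, "a", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(row))
        if new:
            writer.writeheader()
        writer.writerow(row)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def make_checkpoint(model: NestedUNetTransformer, model_cfg: ModelConfig,
                    train_cfg: TrainConfig, state: TrainState) -> dict[str, Any]:
    return {
        "state_dict": model.state_dict(),
        "model_config": model_cfg.to_dict(),
        "config_hash": model_cfg.hash(),
        "train_config": train_cfg.to_dict(),
        "seed": train_cfg.seed,
        "iteration": state.iteration,
        "best_mdice": state.best_mdice,
        "history": list(state.history),
    }


def save_checkpoint(ckpt: dict[str, Any], path: str | Path) -> None:
    """Weights as .npz plus a JSON sidecar (config, seed, history)."""
    path = Path(path)
    np.savez(path, **{f"param/{k}": v for k, v in ckpt["state_dict"].items()})
    meta = {k: v for k, v in ckpt.items() if k != "state_dict"}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    with np.load(path) as npz:
        state_dict = {k[len("param/"):]: npz[k] for k in npz.files}
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig.from_dict(meta["model_config"])
    if cfg.hash() != meta["config_hash"]:
        raise ValueError(
            f"checkpoint config hash mismatch: stored {meta['config_hash']}, "
            f"recomputed {cfg.hash()}")
    meta["state_dict"] = state_dict
    return meta


def model_from_checkpoint(ckpt: dict[str, Any]) -> NestedUNetTransformer:
    cfg = ModelConfig.from_dict(ckpt["model_config"])
    if "config_hash" in ckpt and cfg.hash() != ckpt["config_hash"]:
        raise ValueError("checkpoint config hash mismatch")
    model = build_model(cfg, seed=ckpt.get("seed", 0))
    model.load_state_dict(ckpt["state_dict"])
    return model


# ---------------------------------------------------------------------------
# evaluation and prediction
# ---------------------------------------------------------------------------

def evaluate(model_or_ckpt, dataset: Sequence[ImageMaskPair],
             batch_size: int = 4,
             input_size: tuple[int, int] | None = None) -> MetricsReport:
    """Deterministic per-image metrics at threshold 0.5 (eval mode)."""
    if not dataset:
        raise ValueError("evaluation dataset is empty")
    model = model_or_ckpt if isinstance(model_or_ckpt, NestedUNetTransformer) \
        else model_from_checkpoint(model_or_ckpt)
    pairs = [resize_pair(p, input_size) if input_size else p for p in dataset]
    was_training = model.training
    model.eval()
    probs, gts, ids = [], [], []
    with no_grad():
        for s in range(0, len(pairs), batch_size):
            chunk = pairs[s:s + batch_size]
            x, _ = _to_batch(chunk)
            out = model(x)
            for j, p in enumerate(chunk):
                probs.append(out.probabilities.data[j, 0])
                gts.append(p.mask)
                ids.append(p.id)
    if was_training:
        model.train()
    return evaluate_dataset(probs, gts, ids=ids)


def predict_probabilities(model_or_ckpt, images: Sequence[np.ndarray],
                          batch_size: int = 4) -> list[np.ndarray]:
    """Probability maps for H x W x 3 uint8 images (size divisible by 16)."""
    model = model_or_ckpt if isinstance(model_or_ckpt, NestedUNetTransformer) \
        else model_from_checkpoint(model_or_ckpt)
    model.eval()
    out_maps = []
    with no_grad():
        for s in range(0, len(images), batch_size):
            chunk = images[s:s + batch_size]
            x = np.stack(chunk).astype(np.float32).transpose(0, 3, 1, 2) / 255.0
            out = model(x)
            out_maps.extend(out.probabilities.data[j, 0] for j in range(len(chunk)))
    return out_maps


def _heatmap_overlay(image: np.ndarray, prob: np.ndarray) -> np.ndarray:
    """Blend a jet-style colouring of the probability map over the image."""
    import matplotlib
    cmap = matplotlib.colormaps["jet"]
    heat = (cmap(prob)[..., :3] * 255.0)
    return np.clip(0.55 * image + 0.45 * heat, 0, 255).astype(np.uint8)


def predict(model_or_ckpt, image_paths: Sequence[str | Path],
            out_dir: str | Path,
            input_size: tuple[int, int] | None = (224, 224)) -> list[dict]:
    """Write a binary mask PNG {0,255} and a heat-map overlay per image.

    Unreadable inputs are reported in the returned record list and
    skipped; the rest of the batch continues.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = model_or_ckpt if isinstance(model_or_ckpt, NestedUNetTransformer) \
        else model_from_checkpoint(model_or_ckpt)
    records = []
    for path in image_paths:
        path = Path(path)
        try:
            image = np.asarray(Image.open(path).convert("RGB"))
        except Exception as exc:  # noqa: BLE001 - per-file error, keep going
            records.append({"input": str(path), "error": str(exc)})
            continue
        if input_size is not None:
            net_in = np.asarray(
                Image.fromarray(image).resize(input_size[::-1], Image.BILINEAR))
        else:
            net_in = image
        prob = predict_probabilities(model, [net_in])[0]
        mask = ((prob >= 0.5) * 255).astype(np.uint8)
        mask_path = out_dir / f"{path.stem}_mask.png"
        overlay_path = out_dir / f"{path.stem}_overlay.png"
        Image.fromarray(mask).save(mask_path)
        Image.fromarray(_heatmap_overlay(net_in, prob)).save(overlay_path)
        records.append({"input": str(path), "mask": str(mask_path),
                        "overlay": str(overlay_path)})
    return records
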