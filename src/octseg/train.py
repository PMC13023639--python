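"""Training and evaluation driver.

One integer seed controls everything stochastic: weight initialization,
batch order and augmentation draws.  Optimization is AdamW at a constant
learning rate with early stopping on validation Dice; the checkpoint
kept is the best-by-validation-Dice one.  The objective is the composite
OCT loss on the main head plus a 0.5-weighted copy on the auxiliary
(deep-supervision) head.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np

from . import metrics as M
from .grad import AdamW, no_grad
from .losses import LossWeights, oct_loss
from .network import OCTSegNet, ModelConfig, save_checkpoint
from .phantom import AugmentConfig, load_manifest, load_png


@dataclasses.dataclass
class TrainConfig:
    lr: float = 1e-4
    warmup_steps: int = 0  # linear LR ramp from 0 over the first steps
    weight_decay: float = 1e-4
    clip_norm: float = 1.0
    batch_size: int = 8
    epochs: int = 50
    patience: int = 10
    seed: int = 0
    augment: bool = True
    aux_weight: float = 0.5
    threshold: float = 0.5
    spacing_mm: float = M.DEFAULT_SPACING_MM

    def validate(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


def clip_gradients(params, max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``.

    Overlap losses on sub-3% foregrounds produce occasional large loss
    spikes; clipping keeps AdamW from driving the head into sigmoid
    saturation (a dead all-foreground state)."""
    total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in params if p.grad is not None))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return total


def load_split(data_dir: str | Path, split: str):
    """(images, masks) arrays for one manifest split."""
    data_dir = Path(data_dir)
    manifest = load_manifest(data_dir)
    imgs, msks = [], []
    for e in manifest["entries"]:
        if e["split"] != split:
            continue
        imgs.append(load_png(data_dir / e["image"]))
        msks.append((load_png(data_dir / e["mask"]) > 0.5).astype(np.uint8))
    return np.array(imgs), np.array(msks)


def predict_mask(model: OCTSegNet, image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    with no_grad():
        prob = model(image[None]).numpy()[0, 0]
    return (prob >= threshold).astype(np.uint8)


def evaluate_model(model: OCTSegNet, images: np.ndarray, masks: np.ndarray,
                   threshold: float = 0.5,
                   spacing_mm: float = M.DEFAULT_SPACING_MM) -> tuple[list[dict], dict]:
    records = [M.evaluate_pair(predict_mask(model, img, threshold), msk, spacing_mm)
               for img, msk in zip(images, masks)]
    return records, M.aggregate(records)


def train(data_dir: str | Path, model_config: ModelConfig | dict,
          train_config: TrainConfig | None = None,
          out_dir: str | Path | None = None,
          augment_config: AugmentConfig | None = None,
          log=None) -> dict:
    """Train on a phantom dataset directory; returns the run history.

    History keys: per-epoch ``train_loss`` / ``val_dice`` lists, the best
    epoch/Dice, and (when ``out_dir`` is given) the checkpoint path.
    """
    tc = train_config or TrainConfig()
    tc.validate()
    if isinstance(model_config, dict):
        model_config = ModelConfig.from_dict(model_config)
    aug_cfg = augment_config or AugmentConfig()

    train_imgs, train_msks = load_split(data_dir, "train")
    val_imgs, val_msks = load_split(data_dir, "val")
    if len(train_imgs) == 0:
        raise ValueError("training split is empty")

    rng = np.random.default_rng(tc.seed)
    model = OCTSegNet(model_config, seed=int(rng.integers(2 ** 31)))
    opt = AdamW(model.parameters(), lr=tc.lr, weight_decay=tc.weight_decay)
    weights = LossWeights()

    history: dict = {"train_loss": [], "val_dice": [], "epoch_time_s": []}
    best = {"val_dice": -1.0, "epoch": -1, "state": None}
    stale = 0
    step_count = 0

    from .phantom import augment_pair  # local import avoids cycle at module load

    n = len(train_imgs)
    for epoch in range(tc.epochs):
        t0 = time.time()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tc.batch_size):
            idx = order[start:start + tc.batch_size]
            imgs, msks = [], []
            for i in idx:
                img, msk = train_imgs[i], train_msks[i]
                if tc.augment:
                    img, msk = augment_pair(img, msk, aug_cfg,
                                            int(rng.integers(2 ** 31)))
                imgs.append(img)
                msks.append(msk)
            batch = np.stack(imgs)
            target = np.stack(msks).astype(np.float64)
            main, aux = model.forward_train(batch)
            sh = target.shape
            l_main, _ = oct_loss(main.reshape(sh), target, weights)
            l_aux, _ = oct_loss(aux.reshape(sh), target, weights)
            loss = l_main + tc.aux_weight * l_aux
            opt.zero_grad()
            loss.backward()
            clip_gradients(opt.params, tc.clip_norm)
            step_count += 1
            if tc.warmup_steps > 0:
                opt.lr = tc.lr * min(1.0, step_count / tc.warmup_steps)
            opt.step()
            losses.append(loss.item())

        if len(val_imgs):
            val_dice = float(np.mean([
                M.dice_score(predict_mask(model, img, tc.threshold), msk)
                for img, msk in zip(val_imgs, val_msks)]))
        else:
            val_dice = float("nan")
        epoch_loss = float(np.mean(losses))
        history["train_loss"].append(epoch_loss)
        history["val_dice"].append(val_dice)
        history["epoch_time_s"].append(round(time.time() - t0, 3))
        if log:
            log({"epoch": epoch, "train_loss": epoch_loss, "val_dice": val_dice})

        if not np.isnan(val_dice) and val_dice > best["val_dice"]:
            best.update(val_dice=val_dice, epoch=epoch, state=model.state_dict())
            stale = 0
        else:
            stale += 1
            if stale >= tc.patience:
                break

    if best["state"] is not None:
        model.load_state_dict(best["state"])
    history["best_val_dice"] = best["val_dice"]
    history["best_epoch"] = best["epoch"]
    history["model"] = model

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ckpt = out_dir / "checkpoint.npz"
        save_checkpoint(model, ckpt, extra={
            "best_val_dice": best["val_dice"], "best_epoch": best["epoch"],
            "seed": tc.seed})
        with open(out_dir / "history.json", "w") as fh:
            json.dump({k: v for k, v in history.items() if k != "model"}, fh, indent=1)
        with open(out_dir / "train_config.json", "w") as fh:
            json.dump({**dataclasses.asdict(tc),
                       "model_config": model_config.to_dict()}, fh, indent=1)
        history["checkpoint"] = str(ckpt)
    return history
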