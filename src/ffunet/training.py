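"""Training and inference.

Networks are trained per lesion class on preprocessed tiles with the
balanced focal loss and Adam (beta1=0.9, beta2=0.999), for a fixed number of
epochs at batch size 64 by default. When the optimized loss stops
decreasing for `plateau_patience` epochs the learning rate is divided by
`lr_factor` (10), down to a floor of lr_init * min_lr_fraction. The initial
learning rate is 2e-3. The best-validation checkpoint is retained. A fixed seed fixes initialization, data order and
augmentation draws (floating-point reductions aside, runs are reproducible).

The module is organised around two objects, in the style of statistical
modelling packages: :class:`LesionSegmenter` is built from data and
configuration, and its ``fit()`` returns a :class:`SegmentationFit` carrying
the trained weights, the per-epoch history, validation scores and a
``summary()`` table; prediction and persistence hang off the fit. The
functional :func:`train` underneath is available directly.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ShapeError
from .losses import LossConfig, balanced_focal_loss, estimate_class_weight, make_loss
from .metrics import confusion_counts, segmentation_scores
from .model import FFUNet, ModelConfig, build_model, count_parameters
from .nn import Adam, Tensor
from .preprocess import AugmentConfig, FundusImage, NormStats, augment, preprocess_image
from .tiler import dice, filter_background, merge

__all__ = ["TrainConfig", "TrainHistory", "train", "predict_image",
           "save_checkpoint", "load_checkpoint",
           "LesionSegmenter", "SegmentationFit"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 64
    lr_init: float = 2e-3
    lr_factor: float = 10.0
    plateau_patience: int = 5
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    seed: int = 0
    lesion_class: str = "EX"
    val_fraction: float = 0.2
    head_bias_prior: bool = True
    plateau_rel_threshold: float = 1e-4
    min_lr_fraction: float = 1e-2

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.lr_init <= 0:
            raise ConfigurationError("lr_init must be positive")
        if self.lr_factor <= 1:
            raise ConfigurationError("lr_factor must be > 1")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ConfigurationError("val_fraction must be in [0, 1)")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_sen: list[float] = field(default_factory=list)
    val_iou: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("epoch,train_loss,val_loss,val_sen,val_iou,val_dice,lr\n")
        for i in range(len(self)):
            buf.write(f"{i + 1},{self.train_loss[i]:.6g},{self.val_loss[i]:.6g},"
                      f"{self.val_sen[i]:.4f},{self.val_iou[i]:.4f},"
                      f"{self.val_dice[i]:.4f},{self.learning_rate[i]:.6g}\n")
        return buf.getvalue()


def _to_batch(tiles) -> np.ndarray:
    """(H, W, 3) tile list -> (N, 3, H, W) float batch."""
    arr = np.stack([np.asarray(t, dtype=np.float64) for t in tiles])
    return arr.transpose(0, 3, 1, 2)


def _stratified_split(masks, val_fraction: float, rng: np.random.Generator):
    pos_idx = [i for i, m in enumerate(masks) if np.any(m)]
    neg_idx = [i for i in range(len(masks)) if i not in set(pos_idx)]
    val: list[int] = []
    for group in (pos_idx, neg_idx):
        if not group:
            continue
        k = int(round(len(group) * val_fraction))
        if val_fraction > 0 and k == 0 and len(group) > 1:
            k = 1
        chosen = rng.choice(len(group), size=k, replace=False)
        val.extend(group[j] for j in sorted(chosen.tolist()))
    train = [i for i in range(len(masks)) if i not in set(val)]
    if not train:  # degenerate tiny dataset: validate in-sample
        train = list(range(len(masks)))
        val = list(range(len(masks)))
    if not val:
        val = list(train)
    return train, val


def _resolve_loss(loss, masks):
    """Accept a callable, a {"name", "w", "gamma"} dict, or None (defaults)."""
    if callable(loss):
        return loss, {"name": "custom"}
    spec = {"name": "balanced_focal", "w": "auto", "gamma": 2.0}
    if isinstance(loss, dict):
        spec.update(loss)
    if spec.get("w") == "auto":
        if not any(np.any(m) for m in masks):
            raise ConfigurationError(
                'loss.w="auto" degenerates on an all-negative dataset; '
                "supply a numeric class weight")
        spec["w"] = estimate_class_weight(masks)
    fn = make_loss(spec["name"], w=spec["w"], gamma=spec.get("gamma", 2.0),
                   reduction="mean")
    return fn, spec


def _epoch_batches(train_idx, masks, batch_size, rng):
    """Yield index batches; positive/negative tiles interleaved ~1:1 when
    both exist, so imbalanced tile sets don't starve the positives."""
    if len(train_idx) <= batch_size:
        # everything fits in one batch: oversampling would only add
        # composition noise to the optimized loss
        yield np.asarray(train_idx)
        return
    pos = [i for i in train_idx if np.any(masks[i])]
    neg = [i for i in train_idx if not np.any(masks[i])]
    if pos and neg:
        half = max(1, batch_size // 2)
        n_steps = max(1, int(np.ceil(len(train_idx) / batch_size)))
        for _ in range(n_steps):
            p = rng.choice(pos, size=min(half, len(pos)), replace=len(pos) < half)
            q = rng.choice(neg, size=min(half, len(neg)), replace=len(neg) < half)
            yield np.concatenate([p, q])
    else:
        order = rng.permutation(train_idx)
        for s in range(0, len(order), batch_size):
            yield order[s:s + batch_size]


def train(model: FFUNet, dataset, config: TrainConfig, loss=None,
          augment_config: AugmentConfig | None = None):
    """Optimize the model on (tile, mask) pairs; returns (checkpoint, history).

    ``dataset`` is a sequence of (H x W x 3 tile, H x W binary mask) pairs
    for one lesion class, already preprocessed/normalized.
    """
    pairs = list(dataset)
    if not pairs:
        raise ConfigurationError("training dataset is empty")
    tiles = [np.asarray(t, dtype=np.float64) for t, _ in pairs]
    masks = [np.asarray(m).astype(np.float64) for _, m in pairs]
    for t, m in zip(tiles, masks):
        if t.shape[:2] != m.shape:
            raise ShapeError(f"tile {t.shape} and mask {m.shape} misaligned")

    loss_fn, loss_spec = _resolve_loss(loss, masks)

    # Start the output head at the lesion-prevalence logit so the first
    # epochs are not spent un-learning a miscalibrated background rate —
    # the standard companion to focal-style losses on rare-positive tasks.
    if config.head_bias_prior and getattr(model, "head", None) is not None \
            and model.head.bias is not None:
        prior = float(np.clip(np.mean([m.mean() for m in masks]), 1e-4, 0.5))
        model.head.bias.data[:] = np.log(prior / (1.0 - prior))

    rng = np.random.default_rng(config.seed)
    train_idx, val_idx = _stratified_split(masks, config.val_fraction, rng)

    opt = Adam(model.parameters(), lr=config.lr_init,
               beta1=config.adam_beta1, beta2=config.adam_beta2)
    history = TrainHistory()
    lr = config.lr_init
    min_lr = config.lr_init * config.min_lr_fraction
    best_val = np.inf
    best_state = model.state_dict()
    # the schedule watches the optimized (training) loss; validation loss
    # only selects the checkpoint
    best_monitor = np.inf
    plateau = 0

    val_x = _to_batch([tiles[i] for i in val_idx])
    val_y = np.stack([masks[i] for i in val_idx])[:, None]

    for epoch in range(config.epochs):
        model.train()
        epoch_losses = []
        for step, batch_idx in enumerate(
                _epoch_batches(train_idx, masks, config.batch_size, rng)):
            bt, bm = [], []
            for j, i in enumerate(batch_idx):
                if augment_config is not None:
                    aug_seed = int((config.seed * 97 + epoch * 131071
                                    + step * 257 + j) % (2**31 - 1))
                    img, msk = augment(
                        FundusImage(tiles[i], value_range="normalized"),
                        masks[i] > 0.5, aug_seed, augment_config)
                    bt.append(img.pixels)
                    bm.append(msk.astype(np.float64))
                else:
                    bt.append(tiles[i])
                    bm.append(masks[i])
            x = Tensor(_to_batch(bt))
            y = np.stack(bm)[:, None]
            pred = model(x)
            loss_val = loss_fn(pred, y)
            opt.zero_grad()
            loss_val.backward()
            opt.step()
            epoch_losses.append(loss_val.item())

        model.eval()
        val_pred = model(Tensor(val_x)).data
        val_loss = float(loss_fn(val_pred, val_y))
        scores = segmentation_scores(
            confusion_counts(val_pred >= 0.5, val_y >= 0.5))

        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.val_sen.append(scores.sen)
        history.val_iou.append(scores.iou)
        history.val_dice.append(scores.dice)
        history.learning_rate.append(lr)

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.state_dict()

        monitor = history.train_loss[-1]
        if monitor < best_monitor * (1.0 - config.plateau_rel_threshold):
            best_monitor = monitor
            plateau = 0
        else:
            plateau += 1
            if plateau >= config.plateau_patience:
                lr = max(lr / config.lr_factor, min_lr)
                opt.lr = lr
                plateau = 0

    model.load_state_dict(best_state)
    checkpoint = {
        "state": best_state,
        "model_config": model.config.to_dict(),
        "train_config": config.to_dict(),
        "loss": {k: (v if not isinstance(v, float) else float(v))
                 for k, v in loss_spec.items()},
        "best_val_loss": float(best_val),
    }
    return checkpoint, history


def save_checkpoint(checkpoint: dict, path) -> None:
    """Persist weights plus configs as an .npz archive."""
    meta = {k: v for k, v in checkpoint.items() if k != "state"}
    arrays = {f"state/{k}": v for k, v in checkpoint["state"].items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Load a checkpoint and rebuild its model (evaluation mode)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("state/"):]: data[k] for k in data.files
                 if k.startswith("state/")}
    model = build_model(ModelConfig.from_dict(meta["model_config"]))
    model.load_state_dict(state)
    model.eval()
    checkpoint = dict(meta)
    checkpoint["state"] = state
    return model, checkpoint


def _forward_tiles(model, tiles_chw: np.ndarray, batch: int = 8) -> np.ndarray:
    outs = []
    for s in range(0, len(tiles_chw), batch):
        chunk = tiles_chw[s:s + batch]
        if isinstance(model, FFUNet):
            pred = model(Tensor(chunk)).data[:, 0]
        else:  # any callable stub mapping (N,3,H,W) -> (N,H,W)
            pred = np.asarray(model(chunk))
        outs.append(pred)
    return np.concatenate(outs, axis=0)


def predict_image(model, image: FundusImage, stats: NormStats | None = None,
                  *, window: int = 256, stride: int = 64,
                  min_roi_fraction: float = 0.5, preprocess: bool = True):
    """Segment a full fundus photograph.

    Pipeline: preprocess (crop/denoise/CLAHE/normalize) -> dice ->
    background-tile filtering -> per-tile forward pass -> overlap-averaged
    merge. Returns (probability map over the cropped frame, bounding box of
    the crop). Pixels only background tiles cover are NaN.
    """
    if isinstance(model, FFUNet):
        model.eval()
    if preprocess:
        proc, box = preprocess_image(image, stats)
    else:
        proc, box = image, None
    h, w = proc.height, proc.width
    if window > min(h, w):
        raise ShapeError(f"image {h}x{w} smaller than window {window}")
    grid, tiles = dice(proc, window=window, stride=stride)
    if proc.roi_mask is not None:
        grid = filter_background(grid, proc.roi_mask, min_roi_fraction)
    valid_tiles = [t for t, ok in zip(tiles, grid.valid_flags) if ok]
    if valid_tiles:
        batch = _to_batch(valid_tiles)
        preds = _forward_tiles(model, batch)
        prob = merge(list(preds), grid)
    else:
        prob = np.full((h, w), np.nan)
    return prob, box


# ---------------------------------------------------------------------------
# Model/Results objects
# ---------------------------------------------------------------------------


class LesionSegmenter:
    """A lesion-segmentation model bound to its training tiles.

    Parameters
    ----------
    dataset : sequence of (tile, mask) pairs
        Preprocessed, normalized tiles with aligned binary masks for one
        lesion class.
    model_config : ModelConfig, optional
    loss : dict or callable, optional
        e.g. ``{"name": "balanced_focal", "w": "auto", "gamma": 2}``.
    """

    def __init__(self, dataset, model_config: ModelConfig | None = None,
                 loss=None, lesion_class: str = "EX"):
        self.dataset = list(dataset)
        if not self.dataset:
            raise ConfigurationError("dataset must be nonempty")
        self.model_config = model_config or ModelConfig()
        self.loss = loss
        self.lesion_class = lesion_class

    @classmethod
    def from_images(cls, images, masks, *, window: int = 256, stride: int = 64,
                    model_config: ModelConfig | None = None, loss=None,
                    lesion_class: str = "EX", min_roi_fraction: float = 0.5):
        """Build from full images: preprocess, normalize, dice, filter."""
        stats = compute_stats_after_enhance(images)
        pairs = []
        for img, msk in zip(images, masks):
            msk = np.asarray(msk.pixels if hasattr(msk, "pixels") else msk)
            proc, _, msk_c = preprocess_image(img, stats, msk)
            grid, tiles = dice(proc, window=window, stride=stride)
            if proc.roi_mask is not None:
                grid = filter_background(grid, proc.roi_mask, min_roi_fraction)
            _, mtiles = dice(msk_c.astype(np.float64), window=window,
                             stride=stride)
            for (t, m), ok in zip(zip(tiles, mtiles), grid.valid_flags):
                if ok:
                    pairs.append((t, m > 0.5))
        obj = cls(pairs, model_config=model_config, loss=loss,
                  lesion_class=lesion_class)
        obj.stats = stats
        return obj

    def fit(self, train_config: TrainConfig | None = None,
            augment_config: AugmentConfig | None = None) -> "SegmentationFit":
        cfg = train_config or TrainConfig(lesion_class=self.lesion_class)
        model = build_model(self.model_config, seed=cfg.seed)
        checkpoint, history = train(model, self.dataset, cfg, loss=self.loss,
                                    augment_config=augment_config)
        return SegmentationFit(self, model, checkpoint, history, cfg)


def compute_stats_after_enhance(images) -> NormStats:
    """Dataset normalization statistics measured on cropped+enhanced images."""
    from .preprocess import compute_dataset_stats, crop_to_roi, denoise, \
        enhance_contrast
    processed = []
    for img in images:
        cropped, _ = crop_to_roi(img)
        processed.append(enhance_contrast(denoise(cropped)))
    return compute_dataset_stats(processed)


class SegmentationFit:
    """Results of fitting a :class:`LesionSegmenter`."""

    def __init__(self, parent: LesionSegmenter, model: FFUNet,
                 checkpoint: dict, history: TrainHistory, config: TrainConfig):
        self.model = model.eval()
        self.checkpoint = checkpoint
        self.history = history
        self.config = config
        self.lesion_class = parent.lesion_class
        self.n_parameters = count_parameters(model)
        self.n_tiles = len(parent.dataset)

    @property
    def best_val_loss(self) -> float:
        return self.checkpoint["best_val_loss"]

    def predict_tiles(self, tiles) -> np.ndarray:
        """Probability maps for a batch of (H, W, 3) tiles."""
        return _forward_tiles(self.model, _to_batch(tiles))

    def predict_image(self, image: FundusImage, stats: NormStats | None = None,
                      **kwargs):
        return predict_image(self.model, image, stats, **kwargs)

    def save(self, path) -> None:
        save_checkpoint(self.checkpoint, path)

    def summary(self) -> str:
        h = self.history
        best = int(np.argmin(h.val_loss)) if len(h) else -1
        lines = [
            "Lesion segmentation fit",
            "=" * 56,
            f"{'lesion class':<24}{self.lesion_class}",
            f"{'tiles (train+val)':<24}{self.n_tiles}",
            f"{'parameters':<24}{self.n_parameters:,}",
            f"{'epochs run':<24}{len(h)}",
            f"{'loss':<24}{self.checkpoint['loss']}",
            f"{'best val loss':<24}{self.best_val_loss:.6g} (epoch {best + 1})",
        ]
        if len(h):
            lines += [
                f"{'final val SEN':<24}{h.val_sen[-1]:.4f}",
                f"{'final val IOU':<24}{h.val_iou[-1]:.4f}",
                f"{'final val DICE':<24}{h.val_dice[-1]:.4f}",
                f"{'final learning rate':<24}{h.learning_rate[-1]:.3g}",
            ]
        return "\n".join(lines)
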