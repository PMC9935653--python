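"""Patch-based thalamus segmentation as a scikit-learn style estimator.

``ThalamusSegmenter.fit`` trains the 3D encoder-decoder on (volume, label
map) pairs with on-the-fly augmentation; ``predict`` runs patch-wise tiled
inference with overlapping patches and Gaussian-weighted score blending,
then extracts per-structure volumes in mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .augment import AugmentParams, augment_pair
from .image_io import CODEBOOK, TIV_LABELS, LabelMap, VolumeImage
from .nn import Adam, NetConfig, UNet3D, composite_loss_and_grad, one_hot, softmax


@dataclass
class SegmentationResult:
    """Output of one segmentation: labels, soft scores, volumes, run log."""

    label_map: LabelMap
    scores: np.ndarray  # (n_classes, D, H, W), per-voxel softmax scores
    volumes: dict  # mL per structure name, plus THALV and TIV
    log: dict = field(default_factory=dict)


def volumes_from_labels(l: LabelMap) -> dict:
    """Per-class volumes in mL: count(label==k) * voxel volume / 1000.

    Also reports ``THALV`` (left + right thalamus) and ``TIV`` (all
    non-background classes).
    """
    vv = l.voxel_volume_ml()
    out = {name: float((l.data == k).sum()) * vv for k, name in CODEBOOK.items() if k != 0}
    out["THALV"] = out[CODEBOOK[1]] + out[CODEBOOK[2]]
    out["TIV"] = float(sum(out[CODEBOOK[k]] for k in TIV_LABELS))
    return out


def hard_dice(pred: np.ndarray, ref: np.ndarray, label) -> float:
    """Hard Dice of one label (or tuple of labels pooled) between two maps."""
    labels = (label,) if np.isscalar(label) else tuple(label)
    a = np.isin(pred, labels)
    b = np.isin(ref, labels)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def _gaussian_window(patch_size: int) -> np.ndarray:
    """Separable Gaussian blending weight, sigma = patch/4, floor > 0."""
    x = np.arange(patch_size) - (patch_size - 1) / 2.0
    g = np.exp(-(x**2) / (2 * (patch_size / 4.0) ** 2))
    w = g[:, None, None] * g[None, :, None] * g[None, None, :]
    return (w / w.max()).astype(np.float32) + 1e-4


def _tile_positions(size: int, patch: int, overlap: float):
    stride = max(1, int(round(patch * (1.0 - overlap))))
    if size <= patch:
        return [0]
    pos = list(range(0, size - patch + 1, stride))
    if pos[-1] != size - patch:
        pos.append(size - patch)
    return pos


def _foreground_center(labels: np.ndarray) -> np.ndarray:
    fg = np.argwhere(labels > 0)
    if fg.size == 0:
        return (np.asarray(labels.shape) - 1) / 2.0
    return (fg.min(axis=0) + fg.max(axis=0)) / 2.0


class ThalamusSegmenter(BaseEstimator):
    """Patch-based 3D encoder-decoder segmenter for deep gray matter.

    The clinical-scale configuration is ``patch_size=160, depth=4``; the
    defaults here are the desk-scale configuration (``patch_size=32,
    depth=2``) that trains on one CPU. Training uses a two-stage schedule
    (full augmentation at a higher learning rate, then fine-tuning at a
    lower rate) with the composite cross-entropy + soft-Dice loss.

    Parameters
    ----------
    patch_size, depth, base_channels, n_classes, res_blocks_per_level
        Network architecture; ``patch_size`` must be divisible by
        ``2**depth``.
    epochs_stage1, lr_stage1, epochs_stage2, lr_stage2
        Two-stage training schedule.
    augment
        ``AugmentParams`` for on-the-fly augmentation, or None to train on
        the raw samples.
    class_weights
        Optional per-class cross-entropy weights (length ``n_classes``).
    val_fraction, val_interval
        Held-out split used for the per-epoch training log and how often
        (in epochs) the held-out Dice is evaluated.
    overlap
        Fractional patch overlap of the inference tiling.

    Attributes
    ----------
    net_ : UNet3D
        The trained network.
    config_ : NetConfig
    history_ : list of dict
        Per-epoch loss components and (at ``val_interval``) per-class
        held-out patch Dice.
    """

    def __init__(
        self,
        patch_size: int = 32,
        depth: int = 2,
        base_channels: int = 8,
        n_classes: int = 5,
        res_blocks_per_level: int = 1,
        epochs_stage1: int = 12,
        lr_stage1: float = 1e-3,
        epochs_stage2: int = 4,
        lr_stage2: float = 2e-4,
        batch_size: int = 1,
        dice_weight: float = 1.0,
        class_weights=None,
        augment: AugmentParams | None = None,
        normalize: str = "zscore",
        uniform_crop_fraction: float = 0.25,
        overlap: float = 0.5,
        val_fraction: float = 0.2,
        val_interval: int = 1,
        random_state: int = 0,
        verbose: int = 0,
    ):
        self.patch_size = patch_size
        self.depth = depth
        self.base_channels = base_channels
        self.n_classes = n_classes
        self.res_blocks_per_level = res_blocks_per_level
        self.epochs_stage1 = epochs_stage1
        self.lr_stage1 = lr_stage1
        self.epochs_stage2 = epochs_stage2
        self.lr_stage2 = lr_stage2
        self.batch_size = batch_size
        self.dice_weight = dice_weight
        self.class_weights = class_weights
        self.augment = augment
        self.normalize = normalize
        self.uniform_crop_fraction = uniform_crop_fraction
        self.overlap = overlap
        self.val_fraction = val_fraction
        self.val_interval = val_interval
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _make_config(self) -> NetConfig:
        return NetConfig(
            patch_size=self.patch_size,
            depth=self.depth,
            base_channels=self.base_channels,
            n_classes=self.n_classes,
            res_blocks_per_level=self.res_blocks_per_level,
        )

    def build_network(self) -> UNet3D:
        """Fresh network with seeded deterministic initialization."""
        return UNet3D(self._make_config(), seed=self.random_state)

    def _norm(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data, dtype=np.float32)
        if self.normalize == "zscore":
            sd = data.std()
            return (data - data.mean()) / (sd if sd > 0 else 1.0)
        return data

    def _pad_to_patch(self, data, pad_value=0):
        """Symmetric padding up to the patch size; returns (padded, pads)."""
        ps = self.patch_size
        pads = []
        for n in data.shape:
            missing = max(0, ps - n)
            pads.append((missing // 2, missing - missing // 2))
        if any(lo or hi for lo, hi in pads):
            data = np.pad(data, pads, constant_values=pad_value)
        return data, pads

    def _crop(self, img, lab, rng):
        """Random training patch.

        Mostly centered near the foreground with jitter, but a fraction of
        crops is uniform over the grid so that background-dominant regions
        (and hence whole-volume tiling at inference) stay in-distribution.
        """
        ps = self.patch_size
        img, _ = self._pad_to_patch(img)
        lab, _ = self._pad_to_patch(lab)
        start = []
        if rng.random() < self.uniform_crop_fraction:
            for ax in range(3):
                start.append(int(rng.integers(0, img.shape[ax] - ps + 1)))
        else:
            center = _foreground_center(lab)
            jitter = rng.integers(-ps // 2, ps // 2 + 1, size=3)
            for ax in range(3):
                s = int(round(center[ax] + jitter[ax] - ps / 2))
                start.append(min(max(s, 0), img.shape[ax] - ps))
        sl = tuple(slice(s, s + ps) for s in start)
        return np.ascontiguousarray(img[sl], dtype=np.float32), lab[sl]

    def _check_labels(self, y, names=None):
        for i, l in enumerate(y):
            bad = set(np.unique(l.data)) - set(range(self.n_classes))
            if bad:
                name = names[i] if names else f"sample {i}"
                raise ValueError(
                    f"label(s) {sorted(bad)} outside the {self.n_classes}-class "
                    f"codebook in {name}"
                )

    # ------------------------------------------------------------------
    def fit(self, X, y):
        """Train on lists of ``VolumeImage`` (X) and ``LabelMap`` (y)."""
        if len(X) == 0 or len(X) != len(y):
            raise ValueError("X and y must be nonempty lists of equal length")
        self._check_labels(y)
        rng = np.random.default_rng(self.random_state)

        idx = rng.permutation(len(X))
        n_val = int(round(self.val_fraction * len(X)))
        if len(X) - n_val < 1:
            n_val = len(X) - 1
        val_idx, train_idx = idx[:n_val], idx[n_val:]
        train = [(X[i], y[i]) for i in train_idx]
        val = [(X[i], y[i]) for i in val_idx]

        self.config_ = self._make_config()
        self.net_ = UNet3D(self.config_, seed=self.random_state)
        opt = Adam(self.net_.params(), lr=self.lr_stage1)
        self.history_ = []

        stages = [
            (self.epochs_stage1, self.lr_stage1, self.augment),
            (self.epochs_stage2, self.lr_stage2, self.augment),
        ]
        epoch = 0
        for n_epochs, lr, aug in stages:
            opt.lr = lr
            for _ in range(n_epochs):
                order = rng.permutation(len(train))
                losses, ces, dls = [], [], []
                opt.zero_grad()
                since_step = 0
                for k, j in enumerate(order):
                    v, l = train[j]
                    if aug is not None:
                        seed = int(
                            np.random.default_rng(
                                [self.random_state, epoch, int(j)]
                            ).integers(2**31)
                        )
                        v, l = augment_pair(v, l, aug, seed)
                    img, lab = self._crop(self._norm(v.data), np.asarray(l.data), rng)
                    logits = self.net_.forward(img[None])
                    loss, dlogits, parts = composite_loss_and_grad(
                        logits, lab, self.class_weights, self.dice_weight
                    )
                    self.net_.backward(dlogits)
                    losses.append(loss)
                    ces.append(parts["ce"])
                    dls.append(parts["dice_loss"])
                    since_step += 1
                    if since_step == self.batch_size or k == len(order) - 1:
                        if since_step > 1:
                            for p in self.net_.params():
                                p.grad /= since_step
                        opt.step()
                        opt.zero_grad()
                        since_step = 0
                record = {
                    "epoch": epoch,
                    "loss": float(np.mean(losses)),
                    "ce": float(np.mean(ces)),
                    "dice_loss": float(np.mean(dls)),
                }
                if val and (epoch % self.val_interval == 0 or epoch == sum(
                    s[0] for s in stages
                ) - 1):
                    record["val_dice"] = self._patch_dice(val)
                self.history_.append(record)
                if self.verbose:
                    print(
                        f"epoch {epoch:3d}  loss {record['loss']:.4f}  "
                        f"val {record.get('val_dice', '')}"
                    )
                epoch += 1
        return self

    def _patch_dice(self, pairs):
        """Per-class hard Dice on a single centered patch per validation pair."""
        dices = np.zeros(self.n_classes)
        for v, l in pairs:
            img, _ = self._pad_to_patch(self._norm(v.data))
            lab, _ = self._pad_to_patch(np.asarray(l.data))
            center = _foreground_center(lab)
            sl = []
            for ax in range(3):
                s = int(round(center[ax] - self.patch_size / 2))
                s = min(max(s, 0), img.shape[ax] - self.patch_size)
                sl.append(slice(s, s + self.patch_size))
            sl = tuple(sl)
            pred = np.argmax(self.net_.forward(img[sl][None]), axis=0)
            for c in range(self.n_classes):
                dices[c] += hard_dice(pred, lab[sl], c)
        return (dices / len(pairs)).round(4).tolist()

    # ------------------------------------------------------------------
    def predict(self, X):
        """Segment one ``VolumeImage`` or a list of them."""
        single = isinstance(X, VolumeImage)
        results = [self._segment_one(v) for v in ([X] if single else X)]
        return results[0] if single else results

    def _segment_one(self, v: VolumeImage) -> SegmentationResult:
        if not hasattr(self, "net_"):
            raise RuntimeError("segmenter is not fitted")
        ps = self.patch_size
        data = self._norm(v.data)
        padded, pads = self._pad_to_patch(data)
        log = {}
        if any(lo or hi for lo, hi in pads):
            log["padded"] = pads

        shape = padded.shape
        probs = np.zeros((self.n_classes,) + shape, dtype=np.float32)
        weight = np.zeros(shape, dtype=np.float32)
        window = _gaussian_window(ps)
        positions = [
            _tile_positions(shape[ax], ps, self.overlap) for ax in range(3)
        ]
        n_patches = 0
        for z in positions[0]:
            for yy in positions[1]:
                for x in positions[2]:
                    sl = (slice(z, z + ps), slice(yy, yy + ps), slice(x, x + ps))
                    logits = self.net_.forward(padded[sl][None])
                    probs[(slice(None),) + sl] += softmax(logits) * window
                    weight[sl] += window
                    n_patches += 1
        probs /= weight[None]
        log["n_patches"] = n_patches

        unpad = tuple(
            slice(lo, shape[ax] - hi) for ax, (lo, hi) in enumerate(pads)
        )
        probs = probs[(slice(None),) + unpad]
        labels = np.argmax(probs, axis=0).astype(np.int16)
        label_map = LabelMap(labels, v.affine.copy())
        return SegmentationResult(
            label_map=label_map,
            scores=probs,
            volumes=volumes_from_labels(label_map),
            log=log,
        )

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Persist weights + architecture to an .npz checkpoint."""
        meta = np.array(
            [
                self.patch_size,
                self.depth,
                self.base_channels,
                self.n_classes,
                self.res_blocks_per_level,
            ]
        )
        np.savez_compressed(path, __meta__=meta, **self.net_.state_dict())

    @classmethod
    def load(cls, path, **kwargs) -> "ThalamusSegmenter":
        with np.load(path) as ckpt:
            meta = ckpt["__meta__"].astype(int)
            est = cls(
                patch_size=int(meta[0]),
                depth=int(meta[1]),
                base_channels=int(meta[2]),
                n_classes=int(meta[3]),
                res_blocks_per_level=int(meta[4]),
                **kwargs,
            )
            est.config_ = est._make_config()
            est.net_ = UNet3D(est.config_, seed=est.random_state)
            est.net_.load_state_dict({k: ckpt[k] for k in ckpt.files if k != "__meta__"})
        return est


def train_segmenter(X, y, **params) -> ThalamusSegmenter:
    """Thin functional wrapper: fit a ``ThalamusSegmenter`` on pairs."""
    return ThalamusSegmenter(**params).fit(X, y)


def segment(est: ThalamusSegmenter, v: VolumeImage) -> SegmentationResult:
    """Thin functional wrapper over ``ThalamusSegmenter.predict``."""
    return est.predict(v)
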