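"""Dataset manifests, splitting, augmentation and preprocessing.

The unit of exchange between pipeline stages is the
:class:`DatasetManifest`: an ordered list of labelled image records with
train/val/test split tags. Manifests load from a class-per-subfolder
directory tree or from a delimited text file (columns
``path,label[,lesion_id,split]``, header required) and round-trip
losslessly through that format.

Splitting is stratified per class at an 8:1:1 ratio by default:
within each class the samples are shuffled with the given seed, the
training set takes round(0.8 n) samples (matching published per-class
training counts for the reference task), the test set takes
round(0.1 n) of what remains, and the validation set the rest. The
test-before-validation order guarantees that very small classes are
represented in the test set, where per-class metrics are computed.

Augmentation (training split only) follows the reference protocol:
random horizontal/vertical flips, random cropping removing at most 10%
of the image area, and random translation of up to 10% per axis with
edge padding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "DEFAULT_CLASSES",
    "ImageSample",
    "DatasetManifest",
    "AugmentConfig",
    "load_manifest",
    "split_dataset",
    "augment",
    "preprocess",
    "class_weights",
    "inverse_frequency_weights",
]

#: class vocabulary of the reference lung-adenocarcinoma subtyping task
DEFAULT_CLASSES = ("Grade 1", "Grade 2", "Grade 3", "AIS", "MIA")

SPLITS = ("train", "val", "test")
_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass
class ImageSample:
    path: str
    label: str
    lesion_id: str | None = None
    split: str = "unassigned"


@dataclass
class DatasetManifest:
    """Ordered labelled image records plus the class vocabulary."""

    samples: list[ImageSample]
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        vocab = set(self.classes)
        bad = [s.path for s in self.samples if s.label not in vocab]
        if bad:
            raise ValueError(f"labels outside vocabulary for: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.samples)

    def class_index(self, label: str) -> int:
        return self.classes.index(label)

    def class_counts(self, split: str | None = None) -> np.ndarray:
        counts = np.zeros(len(self.classes), dtype=int)
        for s in self.samples:
            if split is None or s.split == split:
                counts[self.class_index(s.label)] += 1
        return counts

    def split_counts(self) -> dict[str, int]:
        out = {name: 0 for name in (*SPLITS, "unassigned")}
        for s in self.samples:
            out[s.split] += 1
        return out

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest(
            [s for s in self.samples if s.split == split], self.classes
        )

    def labels(self) -> np.ndarray:
        return np.array([self.class_index(s.label) for s in self.samples])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "path": [s.path for s in self.samples],
                "label": [s.label for s in self.samples],
                "lesion_id": [s.lesion_id or "" for s in self.samples],
                "split": [s.split for s in self.samples],
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, classes: Sequence[str] | None = None
    ) -> "DatasetManifest":
        if "path" not in frame.columns or "label" not in frame.columns:
            raise ValueError("manifest needs 'path' and 'label' columns")
        labels = frame["label"].astype(str)
        vocab = tuple(classes) if classes is not None else _default_vocab(labels)
        unknown = sorted(set(labels) - set(vocab))
        if unknown:
            rows = frame.index[labels.isin(unknown)].tolist()
            raise ValueError(f"unknown labels {unknown} at rows {rows[:10]}")
        samples = []
        for _, row in frame.iterrows():
            lesion = str(row.get("lesion_id", "") or "") or None
            split = str(row.get("split", "") or "") or "unassigned"
            samples.append(ImageSample(str(row["path"]), str(row["label"]), lesion, split))
        return cls(samples, vocab)


def _default_vocab(labels: Iterable[str]) -> tuple[str, ...]:
    present = set(labels)
    if present <= set(DEFAULT_CLASSES):
        return DEFAULT_CLASSES
    return tuple(sorted(present))


def load_manifest(
    source: str | Path,
    classes: Sequence[str] | None = None,
    *,
    verify_images: bool = False,
) -> DatasetManifest:
    """Build a manifest from a directory tree or a manifest file.

    Directory mode expects one subfolder per class containing PNG/JPEG
    files. With ``verify_images=True`` unreadable images are skipped
    with a warning instead of being listed.
    """
    source = Path(source)
    if source.is_dir():
        samples: list[ImageSample] = []
        skipped = 0
        for sub in sorted(p for p in source.iterdir() if p.is_dir()):
            for f in sorted(sub.iterdir()):
                if f.suffix.lower() not in _IMAGE_SUFFIXES:
                    continue
                if verify_images:
                    try:
                        with Image.open(f) as im:
                            im.verify()
                    except Exception:
                        skipped += 1
                        continue
                samples.append(ImageSample(str(f), sub.name))
        if skipped:
            warnings.warn(f"skipped {skipped} unreadable image(s)", stacklevel=2)
        if not samples:
            raise ValueError(f"no labelled images found under {source}")
        vocab = (
            tuple(classes)
            if classes is not None
            else _default_vocab(s.label for s in samples)
        )
        return DatasetManifest(samples, vocab)
    if source.is_file():
        frame = pd.read_csv(source, dtype=str, keep_default_na=False)
        if len(frame) == 0:
            raise ValueError(f"manifest file {source} is empty")
        return DatasetManifest.from_frame(frame, classes)
    raise FileNotFoundError(source)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_counts_for(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    """Deterministic per-class train/val/test counts.

    Train gets round(r_train * n) (at least 1 for a nonempty class),
    test gets round(r_test * n) of the remainder, validation the rest.
    For n = 10 at 8:1:1 this is exactly 8/1/1.
    """
    if n == 0:
        return 0, 0, 0
    n_train = min(max(_round_half_up(ratios[0] * n), 1), n)
    n_test = min(_round_half_up(ratios[2] * n), n - n_train)
    n_val = n - n_train - n_test
    return n_train, n_val, n_test


def split_dataset(
    manifest: DatasetManifest,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    *,
    stratified: bool = True,
    group_by_lesion: bool = False,
) -> DatasetManifest:
    """Assign train/val/test tags, stratified per class by default.

    Deterministic given ``seed``; per-class counts follow
    :func:`split_counts_for`. With ``group_by_lesion=True`` all images
    of a lesion move into the same split (avoids leakage between splits
    when multiple photographs of one lesion exist).
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    new_samples = [replace(s) for s in manifest.samples]

    def assign(indices: list[int]) -> None:
        order = list(rng.permutation(len(indices)))
        if group_by_lesion:
            # keep lesion groups contiguous in the shuffled order
            groups: dict[str, list[int]] = {}
            for pos in order:
                i = indices[pos]
                key = new_samples[i].lesion_id or f"__solo_{i}"
                groups.setdefault(key, []).append(i)
            flat = [i for grp in groups.values() for i in grp]
        else:
            flat = [indices[pos] for pos in order]
        n_train, n_val, n_test = split_counts_for(len(flat), ratios)
        for j, i in enumerate(flat):
            if j < n_train:
                new_samples[i].split = "train"
            elif j < n_train + n_test:
                new_samples[i].split = "test"
            else:
                new_samples[i].split = "val"

    if stratified:
        for label in manifest.classes:
            idx = [i for i, s in enumerate(new_samples) if s.label == label]
            if idx:
                assign(idx)
    else:
        assign(list(range(len(new_samples))))
    return DatasetManifest(new_samples, manifest.classes)


# ---------------------------------------------------------------------------
# augmentation & preprocessing
# ---------------------------------------------------------------------------

@dataclass
class AugmentConfig:
    """Augmentation and preprocessing settings.

    The crop cap of 10% of image area and the 10% per-axis translation
    limit follow the reference training protocol; augmentation is meant
    for the training split only.
    """

    horizontal_flip: float = 0.5
    vertical_flip: float = 0.5
    max_crop_fraction: float = 0.1
    max_translate_fraction: float = 0.1
    target_size: int = 224
    channels: int = 3
    mean: tuple[float, ...] = (0.0, 0.0, 0.0)
    std: tuple[float, ...] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_crop_fraction <= 0.1:
            raise ValueError("max_crop_fraction must lie in [0, 0.1]")
        if self.max_translate_fraction < 0:
            raise ValueError("max_translate_fraction must be >= 0")
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")
        for p in (self.horizontal_flip, self.vertical_flip):
            if not 0.0 <= p <= 1.0:
                raise ValueError("flip probabilities must lie in [0, 1]")


def sample_crop_window(
    rng: np.random.Generator, height: int, width: int, max_fraction: float
) -> tuple[int, int, int, int]:
    """Random (top, left, h, w) retaining at least 1 - max_fraction of area."""
    retained = 1.0 - rng.uniform(0.0, max_fraction)
    # split the area reduction between the two axes
    ratio = rng.uniform(0.0, 1.0)
    fh = retained**ratio
    fw = retained / fh
    h = max(1, int(round(height * fh)))
    w = max(1, int(round(width * fw)))
    h, w = min(h, height), min(w, width)
    # enforce the cap after integer rounding
    while h * w < (1.0 - max_fraction) * height * width - 1e-9:
        if h < height:
            h += 1
        elif w < width:
            w += 1
        else:  # pragma: no cover - full window always satisfies the cap
            break
    top = int(rng.integers(0, height - h + 1))
    left = int(rng.integers(0, width - w + 1))
    return top, left, h, w


def augment(
    image: np.ndarray, config: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Random flip / crop / translate; output has the input's size.

    Each transform draws independently from ``rng``. A configuration
    with all probabilities and fractions at zero is the identity.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        img = img[:, :, None]
    if img.ndim != 3 or img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError(f"degenerate image of shape {np.asarray(image).shape}")
    height, width = img.shape[:2]

    if config.horizontal_flip > 0 and rng.random() < config.horizontal_flip:
        img = img[:, ::-1]
    if config.vertical_flip > 0 and rng.random() < config.vertical_flip:
        img = img[::-1]
    if config.max_crop_fraction > 0:
        top, left, h, w = sample_crop_window(rng, height, width, config.max_crop_fraction)
        if (h, w) != (height, width):
            crop = img[top : top + h, left : left + w]
            pil = Image.fromarray(np.ascontiguousarray(crop.squeeze().astype(np.uint8)))
            pil = pil.resize((width, height), Image.BILINEAR)
            img = np.asarray(pil)
            if img.ndim == 2:
                img = img[:, :, None]
    if config.max_translate_fraction > 0:
        dy = int(rng.integers(
            -int(config.max_translate_fraction * height),
            int(config.max_translate_fraction * height) + 1,
        ))
        dx = int(rng.integers(
            -int(config.max_translate_fraction * width),
            int(config.max_translate_fraction * width) + 1,
        ))
        if dy or dx:
            img = _translate_edge_padded(img, dy, dx)
    out = np.ascontiguousarray(img)
    if out.shape[2] == 1 and np.asarray(image).ndim == 2:
        out = out[:, :, 0]
    return out.astype(np.asarray(image).dtype, copy=False)


def _translate_edge_padded(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    h, w = img.shape[:2]
    padded = np.pad(img, ((abs(dy),) * 2, (abs(dx),) * 2, (0, 0)), mode="edge")
    top = abs(dy) - dy
    left = abs(dx) - dx
    return padded[top : top + h, left : left + w]


def preprocess(image, config: AugmentConfig) -> np.ndarray:
    """Decode / resize / scale / normalize into a (C, S, S) float array.

    Accepts a file path, a PIL image, or an HWC array. Pixels are scaled
    to [0, 1] and normalized per channel with the configured mean/std.
    """
    if isinstance(image, (str, Path)):
        try:
            with Image.open(image) as im:
                pil = im.convert("RGB" if config.channels == 3 else "L")
        except Exception as exc:
            raise IOError(f"cannot read image file {image}: {exc}") from exc
    elif isinstance(image, Image.Image):
        pil = image.convert("RGB" if config.channels == 3 else "L")
    else:
        arr = np.asarray(image)
        if arr.dtype != np.uint8:
            arr = np.clip(arr, 0, 255).astype(np.uint8)
        pil = Image.fromarray(arr.squeeze()).convert(
            "RGB" if config.channels == 3 else "L"
        )
    if pil.size != (config.target_size, config.target_size):
        pil = pil.resize((config.target_size, config.target_size), Image.BILINEAR)
    arr = np.asarray(pil, dtype=np.float32) / 255.0
    if arr.ndim == 2:
        arr = arr[:, :, None]
    arr = arr.transpose(2, 0, 1)
    mean = np.asarray(config.mean, dtype=np.float32)[: config.channels, None, None]
    std = np.asarray(config.std, dtype=np.float32)[: config.channels, None, None]
    return (arr - mean) / std


# ---------------------------------------------------------------------------
# class weights
# ---------------------------------------------------------------------------

def inverse_frequency_weights(counts: Sequence[int]) -> np.ndarray:
    """Inverse-frequency class weights normalized to mean 1.

    ``w_c ∝ N / (C * n_c)``; dividing by the mean makes the weights
    scale-invariant in the counts, so doubling every class count leaves
    them unchanged.
    """
    n = np.asarray(counts, dtype=float)
    if np.any(n <= 0):
        raise ValueError(f"every class needs at least one sample, got counts {counts}")
    w = 1.0 / n
    return w / w.mean()


def class_weights(manifest: DatasetManifest, split: str | None = None) -> np.ndarray:
    """Inverse-frequency weights (mean 1) from a manifest's class counts."""
    return inverse_frequency_weights(manifest.class_counts(split))
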