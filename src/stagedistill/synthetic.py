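"""Synthetic imbalanced 5-class image dataset.

The clinical dataset the method was developed for (surgical-specimen
section photographs of lung adenocarcinoma subtypes) is not publicly
available, so this module generates a stand-in with the two statistical
properties the training framework actually exercises:

* severe class imbalance — default class proportions 41 : 1317 : 196 :
  121 : 546, the published per-class image counts of the reference
  task;
* class-discriminative colour/texture structure — each class has its
  own base hue, elliptical "cell blob" density and radius range, and
  "vein" line count, rendered on a noisy colour canvas.

A single ``difficulty`` knob in [0, 1] linearly interpolates every
class's appearance parameters toward their common mean: at 0 the
classes are maximally separable for the default palette, at 1 they are
statistically identical and only chance-level performance is possible.
No attempt is made at histological realism.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .data import DEFAULT_CLASSES, DatasetManifest, ImageSample

__all__ = [
    "SyntheticConfig",
    "generate_dataset",
    "expected_separability",
    "class_counts_for",
]

#: published per-class image counts of the reference task, used as the
#: default imbalance profile
REFERENCE_PROPORTIONS = (41, 1317, 196, 121, 546)

# Per-class appearance defaults (one entry per class, in DEFAULT_CLASSES
# order). Hue spacing is deliberately commensurate with the per-image hue
# jitter so that intermediate difficulty values yield intermediate (not
# ceiling) classifier performance: interpolation toward the mean shrinks
# the class gaps into the jitter band instead of leaving them trivially
# separable.
_BASE_HUES = (0.04, 0.13, 0.22, 0.31, 0.40)
_BLOB_DENSITY = (4.0, 8.0, 12.0, 16.0, 20.0)  # blobs per 1000 px^2
_BLOB_RADIUS = ((2.0, 4.0), (2.5, 4.5), (3.0, 5.0), (3.5, 5.5), (4.0, 6.0))
_VEIN_COUNT = (0.0, 2.0, 4.0, 6.0, 8.0)

#: per-image random shift of the background hue (std dev)
_HUE_JITTER = 0.025


@dataclass
class SyntheticConfig:
    image_size: int = 64
    class_proportions: tuple[float, ...] = REFERENCE_PROPORTIONS
    total_images: int = 300
    classes: tuple[str, ...] = DEFAULT_CLASSES
    base_hues: tuple[float, ...] = _BASE_HUES
    blob_density: tuple[float, ...] = _BLOB_DENSITY
    blob_radius: tuple[tuple[float, float], ...] = _BLOB_RADIUS
    vein_count: tuple[float, ...] = _VEIN_COUNT
    noise_std: float = 0.06
    difficulty: float = 0.3
    seed: int = 7

    def __post_init__(self) -> None:
        n = len(self.classes)
        for name in ("class_proportions", "base_hues", "blob_density", "blob_radius", "vein_count"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per class ({n})")
        if any(p <= 0 for p in self.class_proportions):
            raise ValueError("class proportions must be positive")
        if not 0.0 <= self.difficulty <= 1.0:
            raise ValueError("difficulty must lie in [0, 1]")
        if self.image_size < 8:
            raise ValueError("image_size must be at least 8")
        counts = class_counts_for(self)
        if min(counts) < 5:
            raise ValueError(
                f"per-class counts {counts} — every class needs >= 5 images; "
                "raise total_images or flatten the proportions"
            )

    def interpolated_params(self) -> dict[str, np.ndarray]:
        """Per-class appearance parameters after difficulty blending."""
        d = self.difficulty
        out = {}
        for name in ("base_hues", "blob_density", "vein_count"):
            v = np.asarray(getattr(self, name), dtype=float)
            out[name] = (1 - d) * v + d * v.mean()
        r = np.asarray(self.blob_radius, dtype=float)
        out["blob_radius"] = (1 - d) * r + d * r.mean(axis=0)
        return out


def class_counts_for(config: SyntheticConfig) -> list[int]:
    """Largest-remainder apportionment of total_images to the classes."""
    p = np.asarray(config.class_proportions, dtype=float)
    quota = config.total_images * p / p.sum()
    counts = np.floor(quota).astype(int)
    remainder = config.total_images - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    return counts.tolist()


def _render_image(
    rng: np.random.Generator,
    size: int,
    hue: float,
    density: float,
    radius: tuple[float, float],
    veins: float,
) -> np.ndarray:
    bg_hue = (hue + rng.normal(0, _HUE_JITTER)) % 1.0
    bg = colorsys.hsv_to_rgb(bg_hue, 0.45, 0.75)
    img = Image.new("RGB", (size, size), tuple(int(c * 255) for c in bg))
    draw = ImageDraw.Draw(img)

    n_blobs = rng.poisson(density * size * size / 1000.0)
    blob_hue = (hue + 0.08) % 1.0
    for _ in range(n_blobs):
        r1 = rng.uniform(*radius)
        r2 = rng.uniform(*radius)
        cx = rng.uniform(0, size)
        cy = rng.uniform(0, size)
        col = colorsys.hsv_to_rgb(
            (blob_hue + rng.normal(0, 0.02)) % 1.0, 0.6, rng.uniform(0.35, 0.55)
        )
        draw.ellipse(
            [cx - r1, cy - r2, cx + r1, cy + r2],
            fill=tuple(int(c * 255) for c in col),
        )

    n_veins = rng.poisson(veins) if veins > 0 else 0
    vein_col = colorsys.hsv_to_rgb(hue, 0.3, 0.95)
    for _ in range(n_veins):
        x0, y0 = rng.uniform(0, size, 2)
        angle = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.3, 1.0) * size
        x1 = x0 + length * np.cos(angle)
        y1 = y0 + length * np.sin(angle)
        draw.line(
            [x0, y0, x1, y1],
            fill=tuple(int(c * 255) for c in vein_col),
            width=1,
        )

    return np.asarray(img, dtype=np.float32)


def generate_dataset(
    config: SyntheticConfig, output_dir: str | Path
) -> DatasetManifest:
    """Write the synthetic dataset as PNGs in class subfolders.

    Per-class counts follow the configured proportions by
    largest-remainder rounding. Fully deterministic given
    ``config.seed`` (byte-identical files on regeneration). Returns the
    manifest, which is also written to ``manifest.csv`` in the output
    directory.
    """
    output_dir = Path(output_dir)
    try:
        output_dir.mkdir(parents=True, exist_ok=True)
        probe = output_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory {output_dir} is not writable: {exc}") from exc

    counts = class_counts_for(config)
    params = config.interpolated_params()
    rng = np.random.default_rng(config.seed)
    samples: list[ImageSample] = []
    for ci, (label, n) in enumerate(zip(config.classes, counts)):
        sub = output_dir / label
        sub.mkdir(exist_ok=True)
        for j in range(n):
            arr = _render_image(
                rng,
                config.image_size,
                float(params["base_hues"][ci]),
                float(params["blob_density"][ci]),
                tuple(params["blob_radius"][ci]),
                float(params["vein_count"][ci]),
            )
            noise = rng.normal(0.0, config.noise_std * 255.0, arr.shape)
            out = np.clip(arr + noise, 0, 255).astype(np.uint8)
            path = sub / f"{label.replace(' ', '_').lower()}_{j:04d}.png"
            Image.fromarray(out).save(path)
            samples.append(ImageSample(str(path), label))
    manifest = DatasetManifest(samples, config.classes)
    manifest.save(output_dir / "manifest.csv")
    return manifest


def expected_separability(config: SyntheticConfig) -> float:
    """Cheap proxy for how distinguishable the classes are, in [0, 1].

    Mean pairwise Euclidean distance between the classes'
    difficulty-interpolated appearance-parameter vectors (each feature
    scaled to its default dynamic range), normalized by the same
    quantity at difficulty 0. Linearly decreasing in difficulty by
    construction: 1 at difficulty 0, 0 at difficulty 1.
    """

    def vectors(difficulty: float) -> np.ndarray:
        cfg = SyntheticConfig(
            image_size=config.image_size,
            class_proportions=config.class_proportions,
            total_images=config.total_images,
            classes=config.classes,
            base_hues=config.base_hues,
            blob_density=config.blob_density,
            blob_radius=config.blob_radius,
            vein_count=config.vein_count,
            noise_std=config.noise_std,
            difficulty=difficulty,
            seed=config.seed,
        )
        p = cfg.interpolated_params()
        feats = np.column_stack(
            [
                p["base_hues"],
                p["blob_density"] / max(_BLOB_DENSITY),
                p["blob_radius"].mean(axis=1) / max(r[1] for r in _BLOB_RADIUS),
                p["vein_count"] / max(max(_VEIN_COUNT), 1.0),
            ]
        )
        return feats

    def mean_pairwise(feats: np.ndarray) -> float:
        n = feats.shape[0]
        d = [
            np.linalg.norm(feats[i] - feats[j])
            for i in range(n)
            for j in range(i + 1, n)
        ]
        return float(np.mean(d)) if d else 0.0

    base = mean_pairwise(vectors(0.0))
    if base == 0.0:
        return 0.0
    return float(np.clip(mean_pairwise(vectors(config.difficulty)) / base, 0.0, 1.0))
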