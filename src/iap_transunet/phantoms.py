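"""Synthetic multi-organ phantom generator and training-time augmentation.

Each phantom is one background class plus k foreground "organ" regions
(k in 3..8): randomly placed, sized and oriented ellipses, optionally with
a low-order Fourier perturbation of the boundary radius so that outlines
are irregular the way abdominal organs are.  Every organ class carries its
own mean intensity (evenly spaced, with a small per-phantom jitter) and
the rendered image is intensity + additive Gaussian noise, clamped to
[0, 1].  With zero noise the label map is exactly recoverable from the
image by thresholding, which pins down the generator/metric plumbing
end to end.

The generator emulates the *statistical shape* of multi-organ CT/MRI
slices — several compact structures of differing size, intensity and
boundary smoothness on a dark background — not the imaging physics (no
bias fields, beam hardening or 3-d continuity).

Augmentation follows the usual protocol for this architecture family:
horizontal and vertical flips each with probability 0.5 and a rotation
drawn uniformly from [-10, 10] degrees (bilinear for the image, nearest
neighbour for the label map, zero padding, about the image centre).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "PhantomSpec", "AugmentSpec", "GenerationError", "class_intensities",
    "generate_phantom", "augment", "make_dataset", "load_manifest",
]


class GenerationError(RuntimeError):
    """An organ could not be placed within the attempt budget."""


@dataclass(frozen=True)
class PhantomSpec:
    image_size: int = 64
    n_classes: int = 4                       # background + (n_classes - 1) organs
    organ_size_range: tuple[float, float] = (0.10, 0.26)  # semi-axis / image side
    background_intensity: float = 0.08
    intensity_low: float = 0.35
    intensity_high: float = 0.95
    intensity_jitter: float = 0.02           # per-phantom per-class std
    noise_sigma: float = 0.03
    boundary: str = "perturbed"              # "smooth" | "perturbed"
    boundary_amplitude: float = 0.12
    max_attempts: int = 100

    def __post_init__(self):
        if not (4 <= self.n_classes <= 9):
            raise ValueError("n_classes must be in 4..9 "
                             "(background + 3..8 organs)")
        lo, hi = self.organ_size_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError(f"organ_size_range must satisfy 0 < lo <= hi < 0.5, "
                             f"got {self.organ_size_range}")
        if self.boundary not in ("smooth", "perturbed"):
            raise ValueError(f"boundary must be 'smooth' or 'perturbed', "
                             f"got {self.boundary!r}")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")


@dataclass(frozen=True)
class AugmentSpec:
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    rotation_deg: float = 10.0               # drawn uniformly from +-rotation_deg

    def __post_init__(self):
        if not (0 <= self.p_hflip <= 1 and 0 <= self.p_vflip <= 1):
            raise ValueError("flip probabilities must lie in [0, 1]")
        if self.rotation_deg < 0:
            raise ValueError("rotation_deg must be non-negative")


def class_intensities(spec: PhantomSpec) -> np.ndarray:
    """(n_classes,) nominal mean intensity per class, background first."""
    organs = np.linspace(spec.intensity_low, spec.intensity_high,
                         spec.n_classes - 1)
    return np.concatenate([[spec.background_intensity], organs])


def _organ_mask(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    """One candidate organ: (possibly perturbed) ellipse as a boolean mask."""
    s = spec.image_size
    lo, hi = spec.organ_size_range
    a = rng.uniform(lo, hi) * s
    b = rng.uniform(lo, hi) * s
    margin = max(a, b) * (1.0 + spec.boundary_amplitude)
    cy = rng.uniform(margin, s - margin) if s > 2 * margin else s / 2
    cx = rng.uniform(margin, s - margin) if s > 2 * margin else s / 2
    phi = rng.uniform(0.0, np.pi)
    yy, xx = np.mgrid[0:s, 0:s]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    if spec.boundary == "perturbed":
        theta = np.arctan2(v, u)
        wob = np.zeros_like(theta)
        for m in (2, 3, 4):
            wob += (rng.uniform(-1, 1) * np.cos(m * theta)
                    + rng.uniform(-1, 1) * np.sin(m * theta))
        limit = 1.0 + spec.boundary_amplitude * wob / 3.0
    else:
        limit = 1.0
    return rho <= limit


def generate_phantom(spec: PhantomSpec, seed) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom: (image (1, H, W) float32 in [0,1], label (H, W) int64).

    Deterministic per (spec, seed).  Organs are drawn in class order and a
    later organ overwrites earlier ones; a placement is accepted only if
    every already-placed class keeps at least a few visible pixels, so all
    classes are present in every phantom.  A placement that fails
    ``max_attempts`` times raises :class:`GenerationError`.
    """
    rng = np.random.default_rng(seed)
    s = spec.image_size
    min_pixels = 8
    label = np.zeros((s, s), dtype=np.int64)
    for c in range(1, spec.n_classes):
        for attempt in range(spec.max_attempts):
            mask = _organ_mask(rng, spec)
            if mask.sum() < min_pixels:
                continue
            # later organs overwrite earlier ones, but every class must stay
            # visibly present
            candidate = label.copy()
            candidate[mask] = c
            counts = np.bincount(candidate.ravel(), minlength=c + 1)
            if (counts[1:c + 1] >= min_pixels).all():
                label = candidate
                break
        else:
            raise GenerationError(
                f"could not place organ {c} within {spec.max_attempts} attempts")
    levels = class_intensities(spec)
    jitter = rng.normal(0.0, spec.intensity_jitter, size=spec.n_classes)
    image = (levels + jitter)[label]
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return image[None], label


def augment(image: np.ndarray, label: np.ndarray, spec: AugmentSpec, seed
            ) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random flip/flip/rotate draw to an (image, label) pair.

    Draw order is fixed — horizontal flip, vertical flip, angle — so a seed
    fully determines the transform.  The same geometry is applied to both
    arrays: bilinear interpolation for the image, nearest neighbour for the
    label (which therefore can never invent a class), zero padding.
    """
    if image.shape[-2:] != label.shape[-2:]:
        raise ValueError(f"image {image.shape} and label {label.shape} "
                         "spatial dims differ")
    rng = np.random.default_rng(seed)
    image = np.asarray(image, dtype=np.float32)
    label = np.asarray(label)
    if rng.random() < spec.p_hflip:
        image, label = image[..., ::-1], label[..., ::-1]
    if rng.random() < spec.p_vflip:
        image, label = image[..., ::-1, :], label[..., ::-1, :]
    angle = rng.uniform(-spec.rotation_deg, spec.rotation_deg)
    if angle != 0.0:
        image = ndimage.rotate(image, angle, axes=(-2, -1), reshape=False,
                               order=1, mode="constant", cval=0.0)
        label = ndimage.rotate(label, angle, axes=(-2, -1), reshape=False,
                               order=0, mode="constant", cval=0)
    return np.ascontiguousarray(image), np.ascontiguousarray(label)


def _split_counts(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    # floor for train and val; the remainder goes to test
    n_train = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    return n_train, n_val, n - n_train - n_val


def make_dataset(n: int, spec: PhantomSpec, seed: int, out_dir,
                 split: tuple[float, float, float] = (0.7, 0.1, 0.2)) -> dict:
    """Write n phantoms (PNG pairs + one NPZ bundle) and a JSON manifest.

    The master seed is split into per-phantom streams by index, so phantom
    i is identical no matter how many others are generated.  Re-running
    with the same arguments reproduces identical files.
    """
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {split}")
    out_dir = Path(out_dir)
    try:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directory {out_dir}: {exc}") from exc
    images, labels, files = [], [], []
    for i in range(n):
        image, label = generate_phantom(spec, [seed, i])
        images.append(image)
        labels.append(label)
        img_name = f"images/phantom_{i:04d}.png"
        msk_name = f"masks/phantom_{i:04d}.png"
        Image.fromarray(np.round(image[0] * 255).astype(np.uint8), mode="L") \
            .save(out_dir / img_name)
        Image.fromarray(label.astype(np.uint8), mode="L").save(out_dir / msk_name)
        files.append({"image": img_name, "mask": msk_name})
    np.savez(out_dir / "bundle.npz",
             images=np.stack(images), labels=np.stack(labels))
    n_train, n_val, n_test = _split_counts(n, split)
    assignment = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    manifest = {
        "n": n,
        "seed": seed,
        "spec": asdict(spec),
        "split_rule": "floor(train*n), floor(val*n), remainder to test, in index order",
        "split_fractions": list(split),
        "split": assignment,
        "files": files,
        "bundle": "bundle.npz",
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_manifest(dataset_dir) -> tuple[dict, np.ndarray, np.ndarray]:
    """Read back a dataset: (manifest, images (n,1,H,W), labels (n,H,W))."""
    dataset_dir = Path(dataset_dir)
    path = dataset_dir / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"no manifest.json under {dataset_dir}")
    with open(path) as fh:
        manifest = json.load(fh)
    with np.load(dataset_dir / manifest["bundle"]) as bundle:
        images = bundle["images"].astype(np.float32)
        labels = bundle["labels"].astype(np.int64)
    return manifest, images, labels
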