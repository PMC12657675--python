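"""Seeded generator of severity-graded brain-phantom images.

Each phantom is a single-channel image in [0, 1] containing an elliptical
"brain" with a bright outer "cortex" band and a central dark "ventricle"
disk. Severity (0 = Non-Demented ... 3 = Moderate) is encoded geometrically:
the ventricle radius grows and the cortical band thins with severity,
mimicking the ventricular enlargement and cortical thinning seen in
Alzheimer's progression. Phantoms are deliberately geometric rather than
anatomically realistic — the downstream pipeline only needs class-structured
grayscale images.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

CLASS_NAMES = ["ND", "VMD", "MD", "MOD"]

#: default ventricle radius, as a fraction of the brain radius, per severity
VENTRICLE_RADIUS_FRACS = (0.10, 0.16, 0.24, 0.34)
#: default cortical band thickness, as a fraction of the brain radius
CORTEX_THICKNESS_FRACS = (0.18, 0.15, 0.11, 0.07)

# fixed intensity palette (chosen so the ventricle/background sit below the
# 0.2 dark threshold and the cortex band is the brightest structure)
_BG, _TISSUE, _CORTEX, _VENTRICLE = 0.05, 0.55, 0.90, 0.05


class InvalidSpecError(ValueError):
    """Raised for a phantom specification outside its contract."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one severity-graded phantom.

    ``ventricle_radius_frac`` / ``cortex_thickness_frac`` default to the
    per-severity tables above; ``jitter_frac`` perturbs both uniformly per
    image so classes are distributions, not single shapes.
    """

    image_size: int = 128
    severity: int = 0
    ventricle_radius_frac: float | None = None
    cortex_thickness_frac: float | None = None
    noise_sd: float = 0.03
    jitter_frac: float = 0.02

    def __post_init__(self):
        if self.image_size < 16:
            raise InvalidSpecError(f"image_size must be >= 16, got {self.image_size}")
        if self.severity not in (0, 1, 2, 3):
            raise InvalidSpecError(f"severity must be in 0..3, got {self.severity}")
        if self.ventricle_radius_frac is None:
            object.__setattr__(
                self, "ventricle_radius_frac", VENTRICLE_RADIUS_FRACS[self.severity]
            )
        if self.cortex_thickness_frac is None:
            object.__setattr__(
                self, "cortex_thickness_frac", CORTEX_THICKNESS_FRACS[self.severity]
            )
        for name in ("ventricle_radius_frac", "cortex_thickness_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InvalidSpecError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class ImageDataset:
    """Images + severity labels + provenance flags.

    ``convention`` records the intensity range: ``"unit"`` for [0, 1]
    storage (canonical) or ``"symmetric"`` for the GAN's [-1, 1] space.
    """

    images: np.ndarray  # (N, H, W) float64
    labels: np.ndarray  # (N,) int
    provenance: list[str] = field(default_factory=list)
    class_names: list[str] = field(default_factory=lambda: list(CLASS_NAMES))
    convention: str = "unit"

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not self.provenance:
            self.provenance = ["real"] * len(self.labels)
        if not (len(self.images) == len(self.labels) == len(self.provenance)):
            raise ValueError("images, labels and provenance lengths differ")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "ImageDataset":
        idx = np.asarray(idx)
        if idx.dtype != bool:
            idx = idx.astype(np.int64)
        else:
            idx = np.flatnonzero(idx)
        return ImageDataset(
            self.images[idx],
            self.labels[idx],
            [self.provenance[i] for i in idx],
            list(self.class_names),
            self.convention,
        )

    def concat(self, other: "ImageDataset") -> "ImageDataset":
        if self.convention != other.convention:
            raise ValueError("cannot concatenate datasets in different conventions")
        return ImageDataset(
            np.concatenate([self.images, other.images]),
            np.concatenate([self.labels, other.labels]),
            self.provenance + other.provenance,
            list(self.class_names),
            self.convention,
        )


def _image_seed(master_seed: int, severity: int, index: int) -> np.random.Generator:
    # SeedSequence keyed on (master, class, index): adding images never
    # reshuffles existing ones
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(severity), int(index)])
    )


def generate_phantom(spec: PhantomSpec, seed: int) -> np.ndarray:
    """Render one phantom; identical (spec, seed) gives bit-identical output."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = spec.image_size
    jit = spec.jitter_frac

    def jitter(v: float) -> float:
        return v * (1.0 + rng.uniform(-jit, jit)) if jit > 0 else v

    cy, cx = (s - 1) / 2.0, (s - 1) / 2.0
    ay = jitter(0.42 * s)  # brain semi-axes
    ax = jitter(0.36 * s)
    brain_r = min(ay, ax)
    vent_r = jitter(spec.ventricle_radius_frac) * brain_r
    cortex_t = jitter(spec.cortex_thickness_frac) * brain_r

    yy, xx = np.mgrid[0:s, 0:s]  # origin top-left, row-major
    # normalized elliptical radius: 1.0 on the brain boundary
    er = np.sqrt(((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2)
    img = np.full((s, s), _BG)
    img[er <= 1.0] = _TISSUE
    band_lo = 1.0 - cortex_t / brain_r
    img[(er <= 1.0) & (er >= band_lo)] = _CORTEX
    rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    img[rr <= vent_r] = _VENTRICLE

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=(s, s))
    return np.clip(img, 0.0, 1.0)


def generate_dataset(
    class_sizes: tuple[int, int, int, int],
    image_size: int = 128,
    seed: int = 0,
    noise_sd: float = 0.03,
    jitter_frac: float = 0.02,
) -> ImageDataset:
    """Generate ``class_sizes[c]`` phantoms per severity class c.

    Per-image generators derive from (seed, class, index), so any subset is
    reproducible independently of the other classes.
    """
    if any(n < 0 for n in class_sizes):
        raise InvalidSpecError("class sizes must be non-negative")
    images, labels = [], []
    for severity, n in enumerate(class_sizes):
        spec = PhantomSpec(
            image_size=image_size,
            severity=severity,
            noise_sd=noise_sd,
            jitter_frac=jitter_frac,
        )
        for i in range(n):
            images.append(generate_phantom(spec, _image_seed(seed, severity, i)))
            labels.append(severity)
    if not images:
        images = np.zeros((0, image_size, image_size))
    return ImageDataset(np.asarray(images), np.asarray(labels, dtype=np.int64))


def ventricle_area(image: np.ndarray, threshold: float = 0.2) -> int:
    """Dark-pixel count inside the central half of the image (ventricle proxy)."""
    s = image.shape[0]
    lo, hi = s // 4, 3 * s // 4
    return int((image[lo:hi, lo:hi] < threshold).sum())


def cortex_band_mean_width(image: np.ndarray, threshold: float = 0.75) -> float:
    """Mean per-row run length of bright cortex pixels (band-width proxy)."""
    bright = image > threshold
    widths = bright.sum(axis=1)
    rows = widths[widths > 0]
    return float(rows.mean()) if rows.size else 0.0


def roi_masks(image_size: int) -> dict[str, np.ndarray]:
    """Nominal (jitter-free) region masks for the phantom geometry.

    ``ventricle``: central disk at the largest severity's radius;
    ``cortex``: the outer band between the thinnest-cortex inner edge and
    the brain boundary. These play the role anatomical ROI masks (e.g.
    hippocampus, amygdala) play on real scans.
    """
    s = image_size
    cy = cx = (s - 1) / 2.0
    ay, ax = 0.42 * s, 0.36 * s
    brain_r = min(ay, ax)
    yy, xx = np.mgrid[0:s, 0:s]
    er = np.sqrt(((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2)
    rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    vent = rr <= max(VENTRICLE_RADIUS_FRACS) * brain_r
    band_lo = 1.0 - max(CORTEX_THICKNESS_FRACS)  # widest band inner edge
    cortex = (er <= 1.0) & (er >= band_lo)
    return {"ventricle": vent, "cortex": cortex}


def save_dataset_png(dataset: ImageDataset, out_dir: str | Path) -> Path:
    """Write 8-bit grayscale PNGs plus a ``manifest.csv`` (filename,label,provenance)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "provenance"])
        for i, (img, lab, prov) in enumerate(
            zip(dataset.images, dataset.labels, dataset.provenance)
        ):
            if dataset.convention == "symmetric":
                img = (img + 1.0) / 2.0
            name = f"img_{i:06d}.png"
            arr = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(out_dir / name)
            writer.writerow([name, int(lab), prov])
    return manifest


def load_dataset_png(manifest: str | Path) -> ImageDataset:
    """Read a PNG + manifest directory back into an :class:`ImageDataset`."""
    manifest = Path(manifest)
    root = manifest.parent
    images, labels, prov = [], [], []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            arr = np.asarray(Image.open(root / row["filename"]).convert("L"))
            images.append(arr.astype(np.float64) / 255.0)
            labels.append(int(row["label"]))
            prov.append(row["provenance"])
    return ImageDataset(np.asarray(images), np.asarray(labels), prov)


def save_dataset_npz(dataset: ImageDataset, path: str | Path) -> None:
    """Packed single-file format (compressed array container)."""
    np.savez_compressed(
        path,
        images=dataset.images,
        labels=dataset.labels,
        provenance=np.asarray(dataset.provenance),
        convention=np.asarray(dataset.convention),
    )


def load_dataset_npz(path: str | Path) -> ImageDataset:
    with np.load(path, allow_pickle=False) as z:
        return ImageDataset(
            z["images"],
            z["labels"],
            [str(p) for p in z["provenance"]],
            convention=str(z["convention"]),
        )


__all__ = [
    "CLASS_NAMES",
    "VENTRICLE_RADIUS_FRACS",
    "CORTEX_THICKNESS_FRACS",
    "InvalidSpecError",
    "PhantomSpec",
    "ImageDataset",
    "generate_phantom",
    "generate_dataset",
    "ventricle_area",
    "cortex_band_mean_width",
    "roi_masks",
    "save_dataset_png",
    "load_dataset_png",
    "save_dataset_npz",
    "load_dataset_npz",
]
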