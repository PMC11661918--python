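"""Seeded synthetic segmentation fixtures and dataset I/O.

The generator emulates the structure of the CT/MRI/endoscopy slices the
network targets: a multi-class label map containing several elliptical
"organ" regions of varying size and orientation on a background, and an
intensity image in which each class has a characteristic base intensity
(organs appear as roughly homogeneous regions, as soft tissue does in a
windowed CT slice) corrupted by additive Gaussian noise, replicated to
three channels. Later shapes overwrite earlier ones, producing the
partial occlusions real anatomy exhibits. Every sample is a pure
function of (seed, index).

Datasets live on disk as paired 8-bit PNGs, ``images/<stem>.png`` (RGB)
and ``masks/<stem>.png`` (single-channel integer labels), plus a small
``meta.json``. NIfTI volumes can be sliced axially into the same
in-memory form.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.draw import ellipse

__all__ = ["FixtureSpec", "generate_sample", "write_dataset", "read_dataset",
           "Dataset", "augment", "read_nifti_slices"]


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions of the synthetic study.

    Defaults: 64 px slices (desk-scale, divisible by 32), four classes
    (background + three organ classes, the cardiac-segmentation layout),
    five blobs per image so classes can occur multiple times or occlude,
    and noise_sd 0.05 — mild acquisition noise relative to the ~0.2
    inter-class intensity separation.
    """

    size: int = 64
    n_classes: int = 4
    n_shapes: int = 5
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.size % 32:
            raise ValueError("size must divide by 32")
        if self.n_classes < 2:
            raise ValueError("need at least background plus one class")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def class_intensities(n_classes: int) -> np.ndarray:
    """Base intensity per label: dark background, evenly spaced organs."""
    return np.concatenate([[0.08], np.linspace(0.35, 0.9, n_classes - 1)])


def generate_sample(spec: FixtureSpec, index: int) -> tuple[np.ndarray, np.ndarray]:
    """One (image, label map) pair; image float32 (H,W,3) in [0,1], labels int64."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, int(index)]))
    s = spec.size
    labels = np.zeros((s, s), dtype=np.int64)
    for _ in range(spec.n_shapes):
        cls = int(rng.integers(1, spec.n_classes))
        cy, cx = rng.uniform(0.15 * s, 0.85 * s, size=2)
        ry, rx = rng.uniform(0.06 * s, 0.22 * s, size=2)
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(cy, cx, ry, rx, shape=(s, s), rotation=rot)
        labels[rr, cc] = cls  # later shapes overwrite earlier ones
    base = class_intensities(spec.n_classes)
    image = base[labels]
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return np.repeat(image[..., None], 3, axis=-1), labels


@dataclass
class Dataset:
    """In-memory dataset handle: parallel lists of images and label maps."""

    images: list
    masks: list
    n_classes: int

    def __len__(self):
        return len(self.images)

    def __getitem__(self, i):
        return self.images[i], self.masks[i]


def make_dataset(spec: FixtureSpec, n: int) -> Dataset:
    pairs = [generate_sample(spec, i) for i in range(n)]
    return Dataset([p[0] for p in pairs], [p[1] for p in pairs], spec.n_classes)


def write_dataset(spec: FixtureSpec, n: int, out_dir) -> Path:
    """Write n generated pairs as PNGs under out_dir/{images,masks}."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    if spec.n_classes > 256:
        raise ValueError("8-bit mask PNGs support at most 256 classes")
    for i in range(n):
        image, labels = generate_sample(spec, i)
        stem = f"sample_{i:04d}"
        Image.fromarray((image * 255).round().astype(np.uint8)).save(
            out / "images" / f"{stem}.png")
        Image.fromarray(labels.astype(np.uint8), mode="L").save(
            out / "masks" / f"{stem}.png")
    with open(out / "meta.json", "w") as fh:
        json.dump({"n_classes": spec.n_classes, "spec": asdict(spec), "n": n}, fh)
    return out


def read_dataset(path) -> Dataset:
    """Read a paired PNG dataset; masks are recovered exactly."""
    root = Path(path)
    meta_path = root / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no meta.json under {root}")
    meta = json.loads(meta_path.read_text())
    n_classes = int(meta["n_classes"])
    image_files = sorted((root / "images").glob("*.png"))
    mask_files = sorted((root / "masks").glob("*.png"))
    img_stems = [f.stem for f in image_files]
    mask_stems = [f.stem for f in mask_files]
    if img_stems != mask_stems:
        odd = set(img_stems).symmetric_difference(mask_stems)
        raise ValueError(f"unpaired image/mask files: {sorted(odd)}")
    images, masks = [], []
    for imf, mf in zip(image_files, mask_files):
        image = np.asarray(Image.open(imf), dtype=np.float32) / 255.0
        labels = np.asarray(Image.open(mf), dtype=np.int64)
        if labels.max() >= n_classes:
            raise ValueError(
                f"{mf.name}: label {labels.max()} >= n_classes {n_classes}")
        images.append(image)
        masks.append(labels)
    return Dataset(images, masks, n_classes)


def augment(image: np.ndarray, mask: np.ndarray,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random flips and 90-degree rotations, applied identically to both.

    Restricted to the dihedral group so the label map needs no
    interpolation; the per-class pixel histogram is exactly preserved.
    """
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask extents differ")
    if rng.random() < 0.5:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if rng.random() < 0.5:
        image, mask = image[::-1, :], mask[::-1, :]
    k = int(rng.integers(0, 4))
    if k:
        image, mask = np.rot90(image, k), np.rot90(mask, k)
    return np.ascontiguousarray(image), np.ascontiguousarray(mask)


def read_nifti_slices(volume_path, label_path) -> list[tuple[np.ndarray, np.ndarray]]:
    """Axial slices of a NIfTI volume/label pair as (image, label map) tuples.

    Intensities are min-max scaled to [0,1] over the volume and replicated
    to three channels; labels are cast to integers unchanged.
    """
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(volume_path)).dataobj).astype(np.float64)
    lab = np.asanyarray(nib.load(str(label_path)).dataobj)
    if vol.shape != lab.shape:
        raise ValueError(f"volume shape {vol.shape} != label shape {lab.shape}")
    lo, hi = vol.min(), vol.max()
    vol = (vol - lo) / (hi - lo) if hi > lo else np.zeros_like(vol)
    out = []
    for z in range(vol.shape[2]):
        sl = vol[:, :, z].astype(np.float32)
        out.append((np.repeat(sl[..., None], 3, axis=-1),
                    np.rint(np.asarray(lab[:, :, z], dtype=np.float64)).astype(np.int64)))
    return out
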