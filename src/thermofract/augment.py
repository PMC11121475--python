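"""Geometric augmentation of spectrum images.

Each image receives exactly ONE randomly chosen transform — rotation,
translation or shear — and the augmented image replaces the original, so
the dataset never grows.  Parameter ranges: rotation uniform in
[-90, 90] degrees, translation integer pixels in [-3, 3] per axis, shear
factors uniform in [-2, 2] per axis.  Exposed regions are zero-filled
(no spectral content is invented); rotation and shear interpolate
bilinearly about the image center.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import ndimage

from .preprocess import SpectrumImage, TARGET_SHAPE
from .synthetic import CohortDataset, Participant

KINDS = ("rotation", "translation", "shear")

__all__ = ["KINDS", "AugmentationSpec", "sample_augmentation", "apply_augmentation", "augment_dataset"]

ROTATION_RANGE = (-90.0, 90.0)
TRANSLATE_RANGE = (-3, 3)
SHEAR_RANGE = (-2.0, 2.0)


@dataclass(frozen=True)
class AugmentationSpec:
    """One transform applied to one image; only ``kind``'s parameters are used."""

    kind: str
    rotation_deg: float = 0.0
    translate_px: tuple[int, int] = (0, 0)
    shear_factor: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if not (ROTATION_RANGE[0] <= self.rotation_deg <= ROTATION_RANGE[1]):
            raise ValueError("rotation_deg outside [-90, 90]")
        for d in self.translate_px:
            if not (TRANSLATE_RANGE[0] <= d <= TRANSLATE_RANGE[1]):
                raise ValueError("translate_px outside [-3, 3]")
        for s in self.shear_factor:
            if not (SHEAR_RANGE[0] <= s <= SHEAR_RANGE[1]):
                raise ValueError("shear_factor outside [-2, 2]")


def sample_augmentation(
    rng: np.random.Generator,
    shear_range: tuple[float, float] = SHEAR_RANGE,
) -> AugmentationSpec:
    """Draw kind uniformly from the three schemes and its parameters uniformly.

    ``shear_range`` may narrow (never widen) the default shear interval.
    Shear pairs with sx * sy near 1 make the affine map near-singular and
    blank the frame; at the full +/-2 range a fraction of sheared images
    is destroyed this way, so small-cohort configurations narrow it.
    """
    lo, hi = shear_range
    if lo < SHEAR_RANGE[0] or hi > SHEAR_RANGE[1] or lo > hi:
        raise ValueError(f"shear_range must lie within {SHEAR_RANGE}")
    kind = KINDS[int(rng.integers(len(KINDS)))]
    if kind == "rotation":
        return AugmentationSpec(kind, rotation_deg=float(rng.uniform(*ROTATION_RANGE)))
    if kind == "translation":
        dx, dy = rng.integers(TRANSLATE_RANGE[0], TRANSLATE_RANGE[1] + 1, size=2)
        return AugmentationSpec(kind, translate_px=(int(dx), int(dy)))
    sx, sy = rng.uniform(lo, hi, size=2)
    return AugmentationSpec(kind, shear_factor=(float(sx), float(sy)))


def _affine_about_center(image: np.ndarray, transform: np.ndarray) -> np.ndarray:
    """Apply a forward affine map about the image center, bilinear, zero fill.

    ndimage.affine_transform pulls: output[y] = input[M @ y + offset], so M
    is the inverse of the forward transform and the offset re-centers it.
    """
    inv = np.linalg.inv(transform)
    center = (np.asarray(image.shape) - 1) / 2.0
    offset = center - inv @ center
    return ndimage.affine_transform(image, inv, offset=offset, order=1, mode="constant", cval=0.0)


def _translate(image: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Integer-pixel shift with zero fill: out[i + dr, j + dc] = in[i, j]."""
    dr, dc = shift
    out = np.zeros_like(image)
    h, w = image.shape
    src_r = slice(max(0, -dr), min(h, h - dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_r = slice(max(0, dr), min(h, h + dr))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[dst_r, dst_c] = image[src_r, src_c]
    return out


def apply_augmentation(image: np.ndarray, spec: AugmentationSpec) -> np.ndarray:
    """Apply the single transform in ``spec`` to a 100 x 100 image."""
    image = np.asarray(image, dtype=float)
    if image.shape != TARGET_SHAPE:
        raise ValueError(f"image must be {TARGET_SHAPE}, got {image.shape}")

    if spec.kind == "rotation":
        if spec.rotation_deg == 0.0:
            return image.copy()
        t = np.deg2rad(spec.rotation_deg)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        return _affine_about_center(image, rot)
    if spec.kind == "translation":
        return _translate(image, spec.translate_px)
    sx, sy = spec.shear_factor
    if sx == 0.0 and sy == 0.0:
        return image.copy()
    shear = np.array([[1.0, sx], [sy, 1.0]])
    if abs(np.linalg.det(shear)) < 1e-9:
        raise ValueError("shear factors sx*sy = 1 give a singular transform")
    return _affine_about_center(image, shear)


def augment_dataset(
    dataset: CohortDataset,
    seed: int,
    shear_range: tuple[float, float] = SHEAR_RANGE,
) -> tuple[CohortDataset, dict]:
    """Replace every spectrum image by its augmented version (size unchanged).

    Returns the augmented dataset and an audit map
    {(participant_id, frame_index): AugmentationSpec}.  Deterministic given
    ``seed``; each image's spec is drawn from a per-participant substream
    so participant order does not matter.
    """
    specs: dict[tuple[str, int], AugmentationSpec] = {}
    participants = []
    for p in dataset:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed) & 0x7FFFFFFF, abs(hash_stable(p.participant_id))])
        )
        items = []
        for item in p.items:
            spec = sample_augmentation(rng, shear_range=shear_range)
            augmented = apply_augmentation(item.magnitude, spec)
            # bilinear weights are convex so negatives can only arise from
            # float rounding; clip keeps the magnitude-image invariant
            augmented = np.clip(augmented, 0.0, None)
            items.append(SpectrumImage(augmented, item.participant_id, item.frame_index))
            specs[(p.participant_id, item.frame_index)] = spec
        participants.append(Participant(p.participant_id, p.label, items))
    return CohortDataset(participants, stage=dataset.stage), specs


def hash_stable(text: str) -> int:
    """32-bit hash independent of PYTHONHASHSEED."""
    import zlib

    return zlib.crc32(text.encode("utf-8"))
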