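"""Synthetic thermal-wrist cohort generator.

Real infrared recordings of injured wrists cannot be shared for ethical
reasons, so this module fabricates cohorts with the same statistical
structure: per-participant baseline skin temperature, a smooth anatomical
temperature field shared by both wrists, an injury-site hotspot whose
amplitude is larger for fractures than for sprains, and frame-to-frame
sensor noise.  Every downstream stage (normalization, FFT preprocessing,
splitting, training, evaluation) is exercised on these cohorts.

The temperature model for one participant is

    uninjured(t) = baseline + field + noise_t
    injured(t)   = baseline + field + delta * bump + noise_t'

where ``field`` is a smooth zero-mean spatial field drawn once per
participant (identical for both wrists, so contralateral-mean subtraction
cancels it), ``bump`` is a centered 2D Gaussian with peak 1 and
sigma = min(roi dims)/4, ``delta`` is the injury-site elevation in deg C,
and ``noise_t`` is iid pixel noise redrawn every frame.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

LABELS = ("fracture", "sprain")

__all__ = [
    "LABELS",
    "ParticipantProfile",
    "ThermalFrame",
    "CohortConfig",
    "Participant",
    "CohortDataset",
    "gaussian_bump",
    "bump_mean_to_peak",
    "generate_participant",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
]


class InvalidConfigurationError(ValueError):
    """A cohort or participant configuration violates its invariants."""


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent generative parameters for one participant.

    injury_delta is the peak elevation (deg C) of the injury hotspot over
    the contralateral baseline; spatial_sd is the standard deviation of the
    smooth anatomical field shared by both wrists (0 gives a flat field).
    """

    participant_id: str
    label: str
    baseline_temp: float
    injury_delta: float
    n_frames: int
    frame_noise_sd: float
    roi_height: int
    roi_width: int
    spatial_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise InvalidConfigurationError(f"label must be one of {LABELS}")
        if self.n_frames < 1:
            raise InvalidConfigurationError("n_frames must be >= 1")
        if self.frame_noise_sd < 0:
            raise InvalidConfigurationError("frame_noise_sd must be >= 0")
        if self.roi_height < 1 or self.roi_width < 1:
            raise InvalidConfigurationError("ROI dims must be >= 1")
        if self.injury_delta < 0:
            raise InvalidConfigurationError("injury_delta must be >= 0")
        if self.spatial_sd < 0:
            raise InvalidConfigurationError("spatial_sd must be >= 0")


@dataclass(frozen=True)
class ThermalFrame:
    """One temperature matrix (deg C) for one wrist at one time point."""

    participant_id: str
    wrist: str  # "injured" | "uninjured"
    frame_index: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.wrist not in ("injured", "uninjured"):
            raise ValueError("wrist must be 'injured' or 'uninjured'")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("thermal frame contains non-finite pixels")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation parameters.

    Defaults reproduce the study conditions: 19 fracture and 21 sprain
    participants, 299 frames each, fracture hotspot amplitudes of
    0.8-2.0 deg C (the forearm-fracture elevation range reported for this
    cohort) and sprain amplitudes of 0.1-0.4 deg C, below the smallest
    fracture elevation, so the classes are separable but adjacent.
    """

    n_fracture: int = 19
    n_sprain: int = 21
    frames_per_participant: int = 299
    fracture_delta_range: tuple[float, float] = (0.8, 2.0)
    sprain_delta_range: tuple[float, float] = (0.1, 0.4)
    baseline_mean: float = 31.0
    baseline_sd: float = 1.0
    frame_noise_sd: float = 0.05
    spatial_sd: float = 0.3
    roi_side_range: tuple[int, int] = (60, 160)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fracture + self.n_sprain < 2:
            raise InvalidConfigurationError("cohort needs at least 2 participants")
        if self.n_fracture < 0 or self.n_sprain < 0:
            raise InvalidConfigurationError("class counts must be >= 0")
        if self.frames_per_participant < 1:
            raise InvalidConfigurationError("frames_per_participant must be >= 1")
        for lo, hi in (self.fracture_delta_range, self.sprain_delta_range):
            if lo < 0 or hi < lo:
                raise InvalidConfigurationError("delta ranges must be non-negative and ordered")
        if self.roi_side_range[0] < 1 or self.roi_side_range[1] < self.roi_side_range[0]:
            raise InvalidConfigurationError("roi_side_range must be ordered and >= 1")
        if self.frame_noise_sd < 0 or self.spatial_sd < 0 or self.baseline_sd < 0:
            raise InvalidConfigurationError("noise amplitudes must be >= 0")


@dataclass
class Participant:
    """A labeled participant owning an ordered list of per-frame items.

    ``items`` holds (injured, uninjured) ThermalFrame pairs after
    generation, and SpectrumImage instances after preprocessing.
    """

    participant_id: str
    label: str
    items: list = field(default_factory=list)

    @property
    def n_items(self) -> int:
        return len(self.items)


@dataclass
class CohortDataset:
    """Ordered collection of labeled participants.

    ``stage`` records what the items currently are ("thermal" frame pairs
    or "spectrum" images); participant-level splitting operates on ids and
    labels only, so it works at either stage.
    """

    participants: list[Participant]
    stage: str = "thermal"

    def __iter__(self) -> Iterator[Participant]:
        return iter(self.participants)

    def __len__(self) -> int:
        return len(self.participants)

    @property
    def participant_ids(self) -> list[str]:
        return [p.participant_id for p in self.participants]

    @property
    def n_images(self) -> int:
        """Number of injured-wrist images across the cohort."""
        return sum(p.n_items for p in self.participants)

    def labels_by_id(self) -> dict[str, str]:
        return {p.participant_id: p.label for p in self.participants}

    def count_by_label(self) -> dict[str, int]:
        counts = {lab: 0 for lab in LABELS}
        for p in self.participants:
            counts[p.label] += 1
        return counts

    def get(self, participant_id: str) -> Participant:
        for p in self.participants:
            if p.participant_id == participant_id:
                return p
        raise KeyError(participant_id)

    def subset(self, ids: Sequence[str]) -> "CohortDataset":
        wanted = set(ids)
        return CohortDataset(
            [p for p in self.participants if p.participant_id in wanted],
            stage=self.stage,
        )


def _stable_id_hash(participant_id: str) -> list[int]:
    """Map a participant id to 32-bit words, independent of PYTHONHASHSEED."""
    digest = hashlib.sha256(participant_id.encode("utf-8")).digest()
    return [int.from_bytes(digest[i : i + 4], "big") for i in range(0, 16, 4)]


def participant_seed_sequence(master_seed: int, participant_id: str) -> np.random.SeedSequence:
    """Per-participant random stream keyed by (master seed, stable id hash).

    Adding or removing a participant never perturbs the frames of any other
    participant, because each stream depends only on its own id.
    """
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *_stable_id_hash(participant_id)])


def gaussian_bump(height: int, width: int) -> np.ndarray:
    """Centered 2D Gaussian hotspot, peak exactly 1, sigma = min(h, w)/4."""
    sigma = min(height, width) / 4.0
    r = np.arange(height) - (height - 1) / 2.0
    c = np.arange(width) - (width - 1) / 2.0
    rr, cc = np.meshgrid(r, c, indexing="ij")
    return np.exp(-(rr**2 + cc**2) / (2.0 * sigma**2))


def bump_mean_to_peak(height: int, width: int) -> float:
    """Mean of the unit-peak hotspot: converts a peak delta to an ROI-mean delta."""
    return float(gaussian_bump(height, width).mean())


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sd: float) -> np.ndarray:
    """Zero-mean smooth spatial field with pixel standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    raw = gaussian_filter(rng.standard_normal(shape), sigma=min(shape) / 6.0, mode="reflect")
    raw -= raw.mean()
    scale = raw.std()
    if scale == 0:  # degenerate 1x1 ROI
        return np.zeros(shape)
    return raw * (sd / scale)


def generate_participant(
    profile: ParticipantProfile, rng_seed: int | np.random.SeedSequence
) -> list[tuple[ThermalFrame, ThermalFrame]]:
    """Generate all (injured, uninjured) frame pairs for one participant.

    Deterministic given the seed.  Both wrists share the participant's
    anatomical field, so with zero noise the injured-minus-uninjured ROI
    mean difference equals injury_delta * bump_mean_to_peak exactly.
    """
    rng = np.random.default_rng(rng_seed)
    shape = (profile.roi_height, profile.roi_width)
    anat = _smooth_field(rng, shape, profile.spatial_sd)
    bump = profile.injury_delta * gaussian_bump(*shape)
    base = profile.baseline_temp + anat

    pairs: list[tuple[ThermalFrame, ThermalFrame]] = []
    for idx in range(profile.n_frames):
        if profile.frame_noise_sd > 0:
            noise_inj = rng.normal(0.0, profile.frame_noise_sd, shape)
            noise_uni = rng.normal(0.0, profile.frame_noise_sd, shape)
        else:
            noise_inj = noise_uni = 0.0
        injured = ThermalFrame(profile.participant_id, "injured", idx, base + bump + noise_inj)
        uninjured = ThermalFrame(profile.participant_id, "uninjured", idx, base + noise_uni)
        pairs.append((injured, uninjured))
    return pairs


def draw_profiles(config: CohortConfig) -> list[ParticipantProfile]:
    """Draw per-participant latent parameters from the cohort config."""
    profiles = []
    for label, count, delta_range in (
        ("fracture", config.n_fracture, config.fracture_delta_range),
        ("sprain", config.n_sprain, config.sprain_delta_range),
    ):
        prefix = label[0].upper()
        for i in range(count):
            pid = f"{prefix}{i + 1:02d}"
            rng = np.random.default_rng(participant_seed_sequence(config.seed, pid + "/profile"))
            lo, hi = config.roi_side_range
            profiles.append(
                ParticipantProfile(
                    participant_id=pid,
                    label=label,
                    baseline_temp=float(rng.normal(config.baseline_mean, config.baseline_sd)),
                    injury_delta=float(rng.uniform(*delta_range)),
                    n_frames=config.frames_per_participant,
                    frame_noise_sd=config.frame_noise_sd,
                    roi_height=int(rng.integers(lo, hi + 1)),
                    roi_width=int(rng.integers(lo, hi + 1)),
                    spatial_sd=config.spatial_sd,
                )
            )
    return profiles


def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Generate the full cohort; bit-reproducible from ``config.seed``."""
    participants = []
    for profile in draw_profiles(config):
        seed_seq = participant_seed_sequence(config.seed, profile.participant_id + "/frames")
        pairs = generate_participant(profile, seed_seq)
        participants.append(Participant(profile.participant_id, profile.label, pairs))
    return CohortDataset(participants, stage="thermal")


# ---------------------------------------------------------------------------
# Disk round-trip: cohort/<pid>/<wrist>/<frame_index>.npy + manifest.csv

def save_cohort(dataset: CohortDataset, out_dir: str | Path) -> Path:
    """Write frames as .npy matrices plus a manifest CSV; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "label", "wrist", "frame_index", "path"])
        for p in dataset:
            for injured, uninjured in p.items:
                for frame in (injured, uninjured):
                    rel = Path(p.participant_id) / frame.wrist / f"{frame.frame_index:04d}.npy"
                    dest = out / rel
                    dest.parent.mkdir(parents=True, exist_ok=True)
                    np.save(dest, frame.pixels)
                    writer.writerow([p.participant_id, p.label, frame.wrist, frame.frame_index, rel.as_posix()])
    return manifest_path


def load_cohort(in_dir: str | Path) -> CohortDataset:
    """Inverse of :func:`save_cohort`."""
    root = Path(in_dir)
    rows: dict[str, dict] = {}
    with open(root / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            pid = row["participant_id"]
            entry = rows.setdefault(pid, {"label": row["label"], "frames": {}})
            idx = int(row["frame_index"])
            pixels = np.load(root / row["path"])
            frame = ThermalFrame(pid, row["wrist"], idx, pixels)
            entry["frames"].setdefault(idx, {})[row["wrist"]] = frame
    participants = []
    for pid in sorted(rows):
        entry = rows[pid]
        pairs = [
            (entry["frames"][i]["injured"], entry["frames"][i]["uninjured"])
            for i in sorted(entry["frames"])
        ]
        participants.append(Participant(pid, entry["label"], pairs))
    return CohortDataset(participants, stage="thermal")
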