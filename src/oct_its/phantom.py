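"""Synthetic OCT-phantom cohort generator.

Real spectral-domain OCT cohorts arrive as a patient → volume → B-scan
hierarchy with one diagnostic label per volume. This module emulates that
structure with rendered phantoms so that every downstream stage — patient-wise
splitting, label-fraction subsetting, supervised training and the iterative
teacher-student loop — is exercisable at desk scale without any image
download.

A phantom B-scan is a dark background with smooth bright horizontal bands
standing in for the retinal layer complex. The three classes differ only in
how the lowest (brightest, RPE-like) band is perturbed:

* ``normal``  — undisturbed bands; with zero noise every pixel column carries
  the identical intensity profile.
* ``drusen``  — 1–5 small dome-shaped upward deflections of the lowest band,
  mimicking sub-RPE drusen deposits of early dry AMD.
* ``cnv``     — a single large bright blob beneath a locally disrupted lowest
  band, mimicking the subretinal neovascular complex of wet AMD.

Per-volume nuisance factors (vertical position, brightness, band thickness)
and small per-image jitter make volumes from different patients genuinely
heterogeneous, so that a classifier trained on few labeled volumes
generalizes imperfectly — the regime the semi-supervised method targets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from ._common import CLASSES, UNLABELED, logger

__all__ = [
    "PhantomSpec",
    "ImageRecord",
    "Cohort",
    "VolumeEffects",
    "render_bscan",
    "generate_cohort",
    "save_cohort",
    "load_manifest",
]

# Band geometry in relative row units (0 = top of image, 1 = bottom).
# (center, sigma, amplitude); the last band is the bright RPE-like band that
# carries all class-specific pathology.
_BANDS = (
    (0.30, 0.040, 0.55),
    (0.42, 0.028, 0.40),
    (0.60, 0.035, 0.85),
)
_BACKGROUND = 0.03


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the structure of a public 3-class AMD OCT cohort:
    volume-level class proportions of roughly 0.51 / 0.30 / 0.19 over
    (normal, drusen, cnv), around 30 B-scans per volume, and about a quarter
    of patients contributing a second volume (both eyes scanned).
    """

    n_patients: int = 50
    volumes_per_patient: tuple[int, int] = (1, 2)
    bscans_per_volume: tuple[int, int] = (28, 32)
    class_proportions: tuple[float, float, float] = (0.51, 0.30, 0.19)
    image_height: int = 64
    image_width: int = 64
    noise_sd: float = 0.05
    seed: int = 0
    #: probability of each extra volume beyond the range minimum
    multi_volume_fraction: float = 0.25

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be a positive integer")
        for name in ("volumes_per_patient", "bscans_per_volume"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name}: require 1 <= low <= high, got ({lo}, {hi})")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.shape != (3,) or np.any(props < 0):
            raise ValueError("class_proportions must be three non-negative fractions")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"class_proportions must sum to 1 (got {props.sum():.12f})"
            )
        if self.image_height < 32 or self.image_width < 32:
            raise ValueError("image_height and image_width must be >= 32")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 <= self.multi_volume_fraction <= 1.0):
            raise ValueError("multi_volume_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ImageRecord:
    """One B-scan with its identity in the patient/volume hierarchy."""

    image_id: str
    patient_id: str
    volume_id: str
    label: str
    pixels: np.ndarray = field(repr=False)

    def with_label(self, label: str) -> "ImageRecord":
        return dataclasses.replace(self, label=label)


@dataclass
class Cohort:
    """A list of B-scan records plus provenance (spec or manifest path)."""

    records: list[ImageRecord]
    spec: PhantomSpec | None = None
    provenance: str = "phantom"

    def __post_init__(self) -> None:
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("image_ids are not unique")
        vol_patient: dict[str, str] = {}
        for r in self.records:
            prev = vol_patient.setdefault(r.volume_id, r.patient_id)
            if prev != r.patient_id:
                raise ValueError(
                    f"volume {r.volume_id} appears under two patients"
                )
        self._by_id = {r.image_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, image_id: str) -> ImageRecord:
        return self._by_id[image_id]

    @property
    def image_ids(self) -> list[str]:
        return [r.image_id for r in self.records]

    def patients(self) -> dict[str, list[ImageRecord]]:
        out: dict[str, list[ImageRecord]] = {}
        for r in self.records:
            out.setdefault(r.patient_id, []).append(r)
        return out

    def volumes(self) -> dict[str, list[ImageRecord]]:
        out: dict[str, list[ImageRecord]] = {}
        for r in self.records:
            out.setdefault(r.volume_id, []).append(r)
        return out

    def subset(self, image_ids) -> list[ImageRecord]:
        return [self._by_id[i] for i in image_ids]


@dataclass(frozen=True)
class VolumeEffects:
    """Per-volume nuisance factors shared by all B-scans of one volume.

    All effects are column-invariant so that a noise-free normal scan keeps
    identical pixel columns. Ranges are small relative to the class-defining
    perturbations but large enough that a handful of labeled volumes does not
    cover the nuisance distribution.
    """

    shift: float = 0.0        # vertical offset of every band, relative rows
    amp_scale: float = 1.0    # global brightness multiplier
    sigma_scale: float = 1.0  # band thickness multiplier

    @staticmethod
    def sample(rng: np.random.Generator) -> "VolumeEffects":
        return VolumeEffects(
            shift=float(rng.uniform(-0.05, 0.05)),
            amp_scale=float(rng.uniform(0.85, 1.15)),
            sigma_scale=float(rng.uniform(0.9, 1.1)),
        )


def render_bscan(
    label: str,
    height: int,
    width: int,
    rng: np.random.Generator,
    noise_sd: float = 0.0,
    effects: VolumeEffects | None = None,
) -> np.ndarray:
    """Render one phantom B-scan for ``label`` as a float array in [0, 1].

    The image is deterministic given the generator state; all stochastic
    elements (per-image jitter, pathology geometry, noise) are drawn from
    ``rng`` in a fixed order.
    """
    if label not in CLASSES:
        raise ValueError(f"unknown label for phantom rendering: {label!r}")
    if height < 32 or width < 32:
        raise ValueError("height and width must be >= 32")
    eff = effects or VolumeEffects()

    # Per-image column-invariant jitter (acquisition-to-acquisition variation
    # within a volume).
    img_shift = float(rng.uniform(-0.015, 0.015))
    img_amp = float(rng.uniform(0.92, 1.08))

    rows = np.linspace(0.0, 1.0, height)[:, None]          # (h, 1)
    cols = np.arange(width, dtype=float)[None, :]          # (1, w)

    image = np.full((height, width), _BACKGROUND)
    shift = eff.shift + img_shift
    amp_mul = eff.amp_scale * img_amp

    # Upper bands: never pathological, always column-invariant.
    for center, sigma, amp in _BANDS[:-1]:
        c = center + shift
        s = sigma * eff.sigma_scale
        image += (amp * amp_mul) * np.exp(-((rows - c) ** 2) / (2.0 * s**2))

    # Lowest band: class-specific deformation of its per-column center and
    # amplitude.
    base_center, base_sigma, base_amp = _BANDS[-1]
    c3 = np.full(width, base_center + shift)               # per-column center
    a3 = np.full(width, base_amp * amp_mul)                # per-column amplitude
    s3 = base_sigma * eff.sigma_scale

    if label == "drusen":
        n_bumps = int(rng.integers(1, 6))
        for _ in range(n_bumps):
            m = rng.uniform(0.15 * width, 0.85 * width)
            h_r = rng.uniform(0.025, 0.085)                # dome height, rel rows
            s_c = rng.uniform(0.03 * width, 0.08 * width)  # dome width, cols
            c3 = c3 - h_r * np.exp(-((cols[0] - m) ** 2) / (2.0 * s_c**2))
    elif label == "cnv":
        m = rng.uniform(0.25 * width, 0.75 * width)
        s_d = rng.uniform(0.08 * width, 0.15 * width)
        atten = rng.uniform(0.35, 0.65)
        dome = rng.uniform(0.02, 0.06)
        window = np.exp(-((cols[0] - m) ** 2) / (2.0 * s_d**2))
        a3 = a3 * (1.0 - atten * window)                   # local disruption
        c3 = c3 - dome * window                            # fluid pushes band up
        # Bright neovascular blob beneath the band.
        blob_amp = rng.uniform(0.30, 0.60) * amp_mul
        blob_dr = rng.uniform(0.10, 0.18)
        blob_sr = rng.uniform(0.04, 0.07)
        blob_sc = rng.uniform(0.06 * width, 0.12 * width)
        blob_center = base_center + shift + blob_dr
        image += blob_amp * np.exp(
            -((rows - blob_center) ** 2) / (2.0 * blob_sr**2)
            - ((cols - m) ** 2) / (2.0 * blob_sc**2)
        )

    image += a3[None, :] * np.exp(-((rows - c3[None, :]) ** 2) / (2.0 * s3**2))

    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=(height, width))
    return np.clip(image, 0.0, 1.0)


def generate_cohort(spec: PhantomSpec) -> Cohort:
    """Sample a full phantom cohort; byte-identical for identical specs.

    Patients receive 1 + Binomial(high-low, multi_volume_fraction) volumes,
    each volume a class label drawn from ``class_proportions``, its nuisance
    effects, and a uniform B-scan count from ``bscans_per_volume``. The two
    volumes of one patient are labeled independently, so patient-wise
    splitting is a strictly stronger constraint than volume-wise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    props = np.asarray(spec.class_proportions, dtype=float)
    props = props / props.sum()

    records: list[ImageRecord] = []
    v_lo, v_hi = spec.volumes_per_patient
    b_lo, b_hi = spec.bscans_per_volume
    for p in range(spec.n_patients):
        patient_id = f"P{p:04d}"
        n_vol = v_lo + int(rng.binomial(v_hi - v_lo, spec.multi_volume_fraction))
        for v in range(n_vol):
            volume_id = f"{patient_id}_V{v + 1}"
            label = CLASSES[int(rng.choice(3, p=props))]
            effects = VolumeEffects.sample(rng)
            n_bscans = int(rng.integers(b_lo, b_hi + 1))
            for b in range(n_bscans):
                pixels = render_bscan(
                    label,
                    spec.image_height,
                    spec.image_width,
                    rng,
                    noise_sd=spec.noise_sd,
                    effects=effects,
                )
                records.append(
                    ImageRecord(
                        image_id=f"{volume_id}_B{b + 1:03d}",
                        patient_id=patient_id,
                        volume_id=volume_id,
                        label=label,
                        pixels=pixels,
                    )
                )
    logger.info(
        "generated phantom cohort: %d patients, %d volumes, %d B-scans",
        spec.n_patients,
        len({r.volume_id for r in records}),
        len(records),
    )
    return Cohort(records=records, spec=spec, provenance="phantom")


def save_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write one 8-bit grayscale PNG per B-scan plus ``manifest.csv``.

    The manifest schema (image_id, patient_id, volume_id, label,
    relative_path) is the ingestion contract shared with real-data adapters;
    the pipeline never assumes phantom origin.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for r in cohort.records:
        rel = f"images/{r.image_id}.png"
        arr = np.clip(np.rint(r.pixels * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out / rel)
        rows.append(
            {
                "image_id": r.image_id,
                "patient_id": r.patient_id,
                "volume_id": r.volume_id,
                "label": r.label,
                "relative_path": rel,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_manifest(manifest_path: str | Path) -> Cohort:
    """Load a cohort from a manifest written by :func:`save_cohort`.

    Also accepts manifests prepared for real data, provided images are
    grayscale and labels are in {normal, drusen, cnv} or UNLABELED.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"image_id", "patient_id", "volume_id", "label", "relative_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    base = manifest_path.parent
    records = []
    for row in df.itertuples(index=False):
        if row.label not in CLASSES and row.label != UNLABELED:
            raise ValueError(f"manifest contains unknown label: {row.label!r}")
        with Image.open(base / row.relative_path) as im:
            pixels = np.asarray(im.convert("L"), dtype=float) / 255.0
        records.append(
            ImageRecord(
                image_id=str(row.image_id),
                patient_id=str(row.patient_id),
                volume_id=str(row.volume_id),
                label=str(row.label),
                pixels=pixels,
            )
        )
    return Cohort(records=records, spec=None, provenance=str(manifest_path))
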