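"""Synthetic cohorts for desk-scale testing of the MIL pipeline.

Two generators are provided. ``generate_feature_bags`` emits per-patient bags of
feature vectors in which a minority of "planted" instances carry a class-specific
signature while the majority are drawn from a background distribution shared by
every class — the statistical situation the attention model is designed for,
where a diagnosis rests on a few pathognomonic cells among many unremarkable
ones. ``generate_cell_images`` renders crude stained-smear cell images so the
image-level QC filters and the single-cell feature extractor can be exercised
without clinical data.

Neither generator aims at photorealism; see docs/methods.md for what these
fixtures do and do not emulate.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

CLASS_NAMES = ("PML::RARA", "NPM1", "CBFB::MYH11", "RUNX1::RUNX1T1", "control")
#: differential-count columns whose sum is compared against the blast threshold
BLAST_COLUMNS = ("pct_myeloblasts", "pct_promyelocytes", "pct_myelocytes")

DEFAULT_PLANTED = (0.2, 0.2, 0.2, 0.2, 0.0)
#: needle-in-haystack preset for attention-recovery stress tests
RARE_PLANTED = (0.05, 0.05, 0.05, 0.05, 0.0)


class SpecValidationError(ValueError):
    """A cohort/image spec field violates its invariant; names the field."""


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic feature-bag cohort.

    Defaults mirror the real-cohort regime: five classes with the last one a
    healthy control, 99-500 cells per patient, and a planted (diagnostic)
    sub-population of 20% in each AML class and none in controls.
    """

    n_classes: int = 5
    bags_per_class: int = 40
    bag_size_range: tuple[int, int] = (99, 500)
    feature_dim: int = 64
    planted_fraction: tuple[float, ...] = DEFAULT_PLANTED
    signature_separation: float = 4.0
    noise_sd: float = 1.0
    seed: int = 0
    class_names: tuple[str, ...] = CLASS_NAMES

    def validate(self) -> None:
        if self.n_classes < 2:
            raise SpecValidationError("n_classes must be >= 2")
        if len(self.class_names) != self.n_classes:
            raise SpecValidationError("class_names length must equal n_classes")
        lo, hi = self.bag_size_range
        if lo < 1 or hi < lo:
            raise SpecValidationError("bag_size_range must satisfy 1 <= min <= max")
        if self.feature_dim < self.n_classes:
            # signature directions are orthogonal axes; need one per AML class
            raise SpecValidationError("feature_dim must be >= n_classes")
        if len(self.planted_fraction) != self.n_classes:
            raise SpecValidationError("planted_fraction length must equal n_classes")
        if any(not (0.0 <= f <= 1.0) for f in self.planted_fraction):
            raise SpecValidationError("planted_fraction entries must lie in [0, 1]")
        if self.planted_fraction[-1] != 0.0:
            raise SpecValidationError("planted_fraction of the control class must be 0")
        if self.signature_separation < 0:
            raise SpecValidationError("signature_separation must be >= 0")
        if self.noise_sd <= 0:
            raise SpecValidationError("noise_sd must be > 0")

    def signature_means(self) -> np.ndarray:
        """(n_classes, d) matrix of class signature means.

        Mutually orthogonal canonical axes scaled by ``signature_separation``;
        the control row is all zeros (no signature).
        """
        mu = np.zeros((self.n_classes, self.feature_dim))
        for c in range(self.n_classes - 1):
            mu[c, c] = self.signature_separation
        return mu


@dataclass
class SyntheticBag:
    """One synthetic patient: a feature bag with per-instance ground truth."""

    patient_id: str
    label: int
    features: np.ndarray        # (N, d) float32
    planted: np.ndarray         # (N,) bool, True = carries the class signature
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cell_ids:
            self.cell_ids = [f"{self.patient_id}_cell{k:04d}" for k in range(len(self.features))]

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]


def generate_feature_bags(spec: SyntheticCohortSpec) -> list[SyntheticBag]:
    """Draw a cohort of feature bags, deterministic in ``spec.seed``.

    Background instances come from N(0, noise_sd^2 I) shared across classes;
    planted instances from N(mu_c, noise_sd^2 I) with mu_c the class signature.
    Which instances are planted is a per-instance Bernoulli(planted_fraction)
    draw, so bags of the same class vary in their diagnostic-cell content.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mu = spec.signature_means()
    lo, hi = spec.bag_size_range
    bags: list[SyntheticBag] = []
    for c in range(spec.n_classes):
        for b in range(spec.bags_per_class):
            n = int(rng.integers(lo, hi + 1))
            planted = rng.random(n) < spec.planted_fraction[c]
            x = rng.normal(0.0, spec.noise_sd, size=(n, spec.feature_dim))
            x[planted] += mu[c]
            pid = f"P{c}{spec.class_names[c].split(':')[0][:4]}_{b:03d}"
            bags.append(SyntheticBag(pid, c, x.astype(np.float32), planted))
    return bags


# ---------------------------------------------------------------------------
# image generator


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Parameters for rendering synthetic single-cell smear images.

    Per-class morphology knobs (radius, lobes, granularity) are crude stand-ins
    for the cytomorphology that distinguishes AML subtypes: large granulated
    promyelocyte-like cells vs small scant-cytoplasm blasts vs segmented
    neutrophil-like controls.
    """

    image_size: int = 144
    cell_radius: tuple[float, ...] = (38.0, 26.0, 32.0, 22.0, 30.0)
    n_lobes: tuple[int, ...] = (2, 1, 1, 1, 3)
    granularity: tuple[float, ...] = (0.9, 0.2, 0.5, 0.1, 0.3)
    blur_fraction: float = 0.0
    blur_sigma: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 8:
            raise SpecValidationError("image_size must be >= 8")
        if not (0.0 <= self.blur_fraction <= 1.0):
            raise SpecValidationError("blur_fraction must lie in [0, 1]")
        n = len(self.cell_radius)
        if not (len(self.n_lobes) == len(self.granularity) == n):
            raise SpecValidationError("per-class shape parameter tuples must have equal length")


def _render_cell(rng: np.random.Generator, size: int, radius: float,
                 lobes: int, granularity: float) -> np.ndarray:
    """One 8-bit RGB cell image: eosin-pink background, basophilic nucleus."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy, cx = size / 2 + rng.normal(0, 2, 2)
    img = np.empty((size, size, 3))
    # stained background with plasma texture
    img[..., 0] = 235.0
    img[..., 1] = 215.0
    img[..., 2] = 225.0
    img += rng.normal(0, 6, size=(size, size, 1))

    # cytoplasm: slightly elliptical disc
    ang = rng.uniform(0, np.pi)
    ca, sa = np.cos(ang), np.sin(ang)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    ecc = rng.uniform(0.8, 1.2)
    cyto = (u / radius) ** 2 + (v / (radius * ecc)) ** 2 <= 1.0
    img[cyto] = [186, 182, 222]
    # azurophilic granulation: speckle inside the cytoplasm
    if granularity > 0:
        speck = (rng.random((size, size)) < 0.25 * granularity) & cyto
        img[speck] = [120, 60, 130]

    # nucleus: one or several lobes
    for lb in range(lobes):
        off = 0.45 * radius if lobes > 1 else 0.0
        th = 2 * np.pi * lb / max(lobes, 1) + rng.uniform(0, np.pi)
        ny = cy + off * np.sin(th)
        nx = cx + off * np.cos(th)
        nr = radius * (0.55 if lobes == 1 else 0.38)
        nucleus = ((xx - nx) ** 2 + (yy - ny) ** 2) <= nr ** 2
        img[nucleus & cyto] = [94, 52, 122]
    # chromatin texture
    img += rng.normal(0, 4, size=(size, size, 1))
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_cell_images(spec: SyntheticImageSpec, labels: list[int]
                         ) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Render one image per label; deterministic in ``spec.seed``.

    Exactly ``round(blur_fraction * len(labels))`` images are Gaussian-blurred
    to near-featurelessness (the count is deterministic so QC tests can assert
    exact exclusion numbers); which images are blurred is a seeded draw.
    Returns the images and a metadata frame (label, blurred flag).
    """
    spec.validate()
    n_param_classes = len(spec.cell_radius)
    for lab in labels:
        if not (0 <= int(lab) < n_param_classes):
            raise SpecValidationError(f"label {lab} outside configured classes 0..{n_param_classes - 1}")
    rng = np.random.default_rng(spec.seed)
    n = len(labels)
    images = [
        _render_cell(rng, spec.image_size, spec.cell_radius[lab],
                     spec.n_lobes[lab], spec.granularity[lab])
        for lab in labels
    ]
    n_blur = int(round(spec.blur_fraction * n))
    blur_idx = rng.choice(n, size=n_blur, replace=False) if n_blur else np.array([], dtype=int)
    blurred = np.zeros(n, dtype=bool)
    blurred[blur_idx] = True
    for i in blur_idx:
        out = np.empty_like(images[i], dtype=float)
        for ch in range(3):
            out[..., ch] = ndimage.gaussian_filter(images[i][..., ch].astype(float), spec.blur_sigma)
        images[i] = np.clip(out, 0, 255).astype(np.uint8)
    meta = pd.DataFrame({"label": list(labels), "blurred": blurred})
    return images, meta


# ---------------------------------------------------------------------------
# cohort writer


def _differential_counts(rng: np.random.Generator, label: int, planted_frac: float,
                         low_blast: bool, class_names: tuple[str, ...]) -> dict[str, float]:
    """Synthesize routine differential-count percentages for one patient.

    Blast percentage tracks the planted fraction with additive noise plus an
    offset so planted-rich AML patients clear the 20% threshold; designated
    low-blast patients and controls fall well below it.
    """
    if label == len(class_names) - 1:          # control
        total = rng.uniform(0.0, 5.0)
    elif low_blast:
        total = rng.uniform(8.0, 16.0)
    else:
        total = float(np.clip(100.0 * planted_frac + 12.0 + rng.normal(0.0, 3.0), 1.0, 95.0))
    w = rng.dirichlet(np.ones(len(BLAST_COLUMNS)))
    counts = {col: round(total * wi, 2) for col, wi in zip(BLAST_COLUMNS, w)}
    counts["pct_other"] = round(100.0 - sum(counts.values()), 2)
    return counts


def write_cohort(bags: list[SyntheticBag], out_dir: str | os.PathLike,
                 spec: SyntheticCohortSpec | None = None,
                 low_blast_ids: tuple[str, ...] = (),
                 images_by_patient: dict[str, list[np.ndarray]] | None = None,
                 ) -> pd.DataFrame:
    """Write a cohort to disk in the layout the readers expect.

    Layout: ``<out>/manifest.tsv`` plus one folder per patient containing
    ``features.npy`` (N x d float32), ``cells.tsv`` (row index -> cell id,
    planted flag) and, when images are supplied, one TIFF per cell.
    Returns the manifest.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    spec = spec or SyntheticCohortSpec()
    rng = np.random.default_rng(spec.seed + 1)     # independent of feature draws
    class_names = spec.class_names
    rows = []
    for bag in bags:
        pdir = os.path.join(out_dir, bag.patient_id)
        os.makedirs(pdir, exist_ok=True)
        np.save(os.path.join(pdir, "features.npy"), bag.features)
        pd.DataFrame({
            "row": np.arange(bag.n_instances),
            "cell_id": bag.cell_ids,
            "planted": bag.planted.astype(int),
        }).to_csv(os.path.join(pdir, "cells.tsv"), sep="\t", index=False)
        if images_by_patient and bag.patient_id in images_by_patient:
            for k, img in enumerate(images_by_patient[bag.patient_id]):
                tifffile.imwrite(os.path.join(pdir, f"{bag.patient_id}_cell{k:04d}.tif"), img)
        row = {
            "patient_id": bag.patient_id,
            "label": class_names[bag.label],
            "bag_file": os.path.join(bag.patient_id, "features.npy"),
        }
        row.update(_differential_counts(
            rng, bag.label, spec.planted_fraction[bag.label],
            bag.patient_id in low_blast_ids, class_names))
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    return manifest


def read_cohort(cohort_dir: str | os.PathLike,
                class_names: tuple[str, ...] = CLASS_NAMES,
                ) -> tuple[pd.DataFrame, list[SyntheticBag]]:
    """Inverse of :func:`write_cohort` for feature-bag cohorts."""
    cohort_dir = os.fspath(cohort_dir)
    manifest = pd.read_csv(os.path.join(cohort_dir, "manifest.tsv"), sep="\t")
    bags = []
    label_index = {name: i for i, name in enumerate(class_names)}
    for _, row in manifest.iterrows():
        pdir = os.path.join(cohort_dir, row["patient_id"])
        x = np.load(os.path.join(cohort_dir, row["bag_file"]))
        cells = pd.read_csv(os.path.join(pdir, "cells.tsv"), sep="\t")
        bags.append(SyntheticBag(
            row["patient_id"], label_index[row["label"]], x,
            cells["planted"].to_numpy(dtype=bool),
            cells["cell_id"].tolist()))
    return manifest, bags
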