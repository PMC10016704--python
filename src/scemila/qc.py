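"""Data-cleaning cascade for single-cell smear cohorts.

Three stages, applied in order: (1) per-image blur exclusion by Canny edge sum,
(2) per-patient exclusion of AML samples whose routine differential count shows
fewer than 20% blast-lineage cells (myeloblasts + promyelocytes + myelocytes;
the conventional WHO blast threshold for most AML subtypes), and (3) a manual
exclusion hook that ingests expert verdicts. Every stage is accounted for in a
consort-style report.
"""

from __future__ import annotations

import json
import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from skimage import feature as skfeature

from .synthetic import BLAST_COLUMNS, CLASS_NAMES

logger = logging.getLogger(__name__)

#: max response of a 3x3 Sobel operator on an 8-bit image, per axis.
#: Config thresholds are given in these 8-bit gradient units; dividing by this
#: constant converts them to the unit-intensity gradient scale scikit-image
#: works in ((100, 200) maps to (0.098, 0.196)).
_SOBEL_8BIT_SCALE = 1020.0


@dataclass(frozen=True)
class EdgeFilterConfig:
    """Blur filter settings.

    ``edge_sum_threshold`` compares against the sum of the edge map with edge
    pixels valued 255 (the default 5e4 therefore corresponds to ~196 edge
    pixels). ``mode='count'`` switches to the alternative reading where the
    threshold is compared against the raw number of edge pixels.
    """

    edge_sum_threshold: float = 5e4
    canny_low: float = 100.0
    canny_high: float = 200.0
    sigma: float = 1.0
    mode: str = "sum"       # 'sum' (0/255-valued map) or 'count' (edge pixels)

    def validate(self) -> None:
        if self.edge_sum_threshold < 0:
            raise ValueError("edge_sum_threshold must be >= 0")
        if not (0 < self.canny_low < self.canny_high):
            raise ValueError("canny thresholds must satisfy 0 < low < high")
        if self.mode not in ("sum", "count"):
            raise ValueError("mode must be 'sum' or 'count'")


@dataclass(frozen=True)
class BlastFilterConfig:
    """Low-blast patient filter settings (applies to AML classes only)."""

    blast_cell_categories: tuple[str, ...] = BLAST_COLUMNS
    min_percent: float = 20.0
    control_label: str = CLASS_NAMES[-1]

    def validate(self) -> None:
        if not self.blast_cell_categories:
            raise ValueError("blast_cell_categories must be non-empty")
        if not (0.0 <= self.min_percent <= 100.0):
            raise ValueError("min_percent must lie in [0, 100]")


@dataclass
class ConsortReport:
    """Stage-by-stage accounting of inclusions and exclusions."""

    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, *, images_before: int | None = None,
                  images_after: int | None = None, patients_before: int | None = None,
                  patients_after: int | None = None, exclusions: list[dict] | None = None,
                  config: dict | None = None) -> None:
        self.stages.append({
            "stage": name,
            "images_before": images_before,
            "images_after": images_after,
            "patients_before": patients_before,
            "patients_after": patients_after,
            "n_excluded": len(exclusions or []),
            "exclusions": exclusions or [],
            "config": config or {},
        })

    def validate_monotone(self) -> None:
        for key in ("images", "patients"):
            vals = [(s[f"{key}_before"], s[f"{key}_after"]) for s in self.stages
                    if s[f"{key}_before"] is not None]
            for before, after in vals:
                if after > before:
                    raise AssertionError(f"{key} count increased within a stage")

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        text = json.dumps({"stages": self.stages}, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _to_gray8(image: np.ndarray) -> np.ndarray:
    """Luma-weighted grayscale on an 8-bit intensity scale."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114
    return img


def edge_sum(image: np.ndarray | str | os.PathLike,
             cfg: EdgeFilterConfig | None = None) -> float:
    """Sum of the Canny edge map (edge pixels valued 255) of an image.

    Blurring suppresses gradients, so blurry images score near zero while
    sharp, textured cells score well above the 5e4 default threshold.
    """
    cfg = cfg or EdgeFilterConfig()
    cfg.validate()
    if isinstance(image, (str, os.PathLike)):
        try:
            image = tifffile.imread(os.fspath(image))
        except (OSError, ValueError) as err:
            raise OSError(f"cannot read image {image!r}: {err}") from err
    image = np.asarray(image)
    if image.shape[0] < 8 or image.shape[1] < 8:
        raise ValueError(f"image too small for edge analysis: {image.shape}")
    gray = _to_gray8(image) / 255.0
    edges = skfeature.canny(
        gray, sigma=cfg.sigma,
        low_threshold=cfg.canny_low / _SOBEL_8BIT_SCALE,
        high_threshold=cfg.canny_high / _SOBEL_8BIT_SCALE)
    n_edge = int(edges.sum())
    return float(n_edge if cfg.mode == "count" else 255 * n_edge)


def filter_blurry(images: list, cfg: EdgeFilterConfig | None = None,
                  ids: list[str] | None = None) -> tuple[list[int], pd.DataFrame]:
    """Partition images into kept and excluded by the blur criterion.

    An image is excluded iff its edge sum is strictly below the threshold
    (an image exactly at the threshold is kept). Unreadable images are
    excluded with reason ``unreadable``. Returns the kept indices and an
    exclusion table (id, reason, value).
    """
    cfg = cfg or EdgeFilterConfig()
    cfg.validate()
    ids = ids or [str(i) for i in range(len(images))]
    kept: list[int] = []
    excl_rows = []
    for i, img in enumerate(images):
        try:
            value = edge_sum(img, cfg)
        except OSError as err:
            logger.warning("unreadable image %s: %s", ids[i], err)
            excl_rows.append({"id": ids[i], "index": i, "reason": "unreadable", "value": np.nan})
            continue
        if value < cfg.edge_sum_threshold:
            excl_rows.append({"id": ids[i], "index": i, "reason": "blurry", "value": value})
        else:
            kept.append(i)
    excluded = pd.DataFrame(excl_rows, columns=["id", "index", "reason", "value"])
    assert len(kept) + len(excluded) == len(images)
    return kept, excluded


def filter_low_blast(manifest: pd.DataFrame, cfg: BlastFilterConfig | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude AML patients whose blast-lineage percentages sum below threshold.

    Controls are exempt: the blast criterion is defined on AML samples. The
    comparison is strict (<), so a patient at exactly the threshold is kept.
    """
    cfg = cfg or BlastFilterConfig()
    cfg.validate()
    is_control = manifest["label"] == cfg.control_label
    for col in cfg.blast_cell_categories:
        if col not in manifest.columns:
            bad = manifest.loc[~is_control, "patient_id"].iloc[0] if (~is_control).any() else "?"
            raise ValueError(f"manifest lacks differential-count column {col!r} "
                             f"required for AML patient {bad!r}")
        missing = manifest.loc[~is_control, col].isna()
        if missing.any():
            pid = manifest.loc[~is_control].loc[missing, "patient_id"].iloc[0]
            raise ValueError(f"AML patient {pid!r} has no value in column {col!r}")
    blast_sum = manifest[list(cfg.blast_cell_categories)].sum(axis=1)
    exclude = (~is_control) & (blast_sum < cfg.min_percent)
    kept = manifest.loc[~exclude].copy()
    excluded = manifest.loc[exclude].copy()
    excluded["reason"] = "low_blast"
    excluded["value"] = blast_sum[exclude]
    return kept, excluded


def apply_manual_exclusions(manifest: pd.DataFrame, exclusion_ids: list[str],
                            report: ConsortReport | None = None) -> pd.DataFrame:
    """Remove patients listed by an expert reviewer; unknown ids warn and are skipped."""
    known = set(manifest["patient_id"])
    unknown = [pid for pid in exclusion_ids if pid not in known]
    if unknown:
        warnings.warn(f"manual exclusion list contains unknown patient ids: {unknown}",
                      stacklevel=2)
        logger.warning("ignoring unknown patient ids in manual exclusions: %s", unknown)
    applied = [pid for pid in exclusion_ids if pid in known]
    kept = manifest[~manifest["patient_id"].isin(applied)].copy()
    if report is not None:
        report.add_stage(
            "manual", patients_before=len(manifest), patients_after=len(kept),
            exclusions=[{"id": pid, "reason": "manual"} for pid in applied])
    return kept


def run_qc_cascade(cohort_dir: str | os.PathLike,
                   edge_cfg: EdgeFilterConfig | None = None,
                   blast_cfg: BlastFilterConfig | None = None,
                   manual_exclusions: list[str] | None = None,
                   out_dir: str | os.PathLike | None = None,
                   ) -> tuple[ConsortReport, pd.DataFrame, dict[str, list[str]]]:
    """Run blur -> blast -> manual filtering over an on-disk image cohort.

    Returns the consort report, the cleaned manifest, and the per-patient
    lists of kept image files. Patients whose folders contain no TIFFs are
    passed through the image stage untouched (feature-bag cohorts).
    """
    cohort_dir = os.fspath(cohort_dir)
    edge_cfg = edge_cfg or EdgeFilterConfig()
    blast_cfg = blast_cfg or BlastFilterConfig()
    manifest = pd.read_csv(os.path.join(cohort_dir, "manifest.tsv"), sep="\t")
    report = ConsortReport()

    kept_images: dict[str, list[str]] = {}
    n_img_before = 0
    blur_exclusions: list[dict] = []
    for pid in manifest["patient_id"]:
        pdir = os.path.join(cohort_dir, pid)
        files = sorted(f for f in os.listdir(pdir) if f.lower().endswith((".tif", ".tiff")))
        n_img_before += len(files)
        if not files:
            kept_images[pid] = []
            continue
        paths = [os.path.join(pdir, f) for f in files]
        kept_idx, excluded = filter_blurry(paths, edge_cfg, ids=files)
        kept_images[pid] = [files[i] for i in kept_idx]
        for rec in excluded.to_dict("records"):
            rec["patient_id"] = pid
            blur_exclusions.append(rec)
    n_img_after = sum(len(v) for v in kept_images.values())
    report.add_stage(
        "blur", images_before=n_img_before, images_after=n_img_after,
        patients_before=len(manifest), patients_after=len(manifest),
        exclusions=blur_exclusions,
        config={"edge_sum_threshold": edge_cfg.edge_sum_threshold,
                "canny_low": edge_cfg.canny_low, "canny_high": edge_cfg.canny_high,
                "sigma": edge_cfg.sigma, "mode": edge_cfg.mode})

    kept, excluded = filter_low_blast(manifest, blast_cfg)
    report.add_stage(
        "blast", patients_before=len(manifest), patients_after=len(kept),
        exclusions=excluded[["patient_id", "reason", "value"]].rename(
            columns={"patient_id": "id"}).to_dict("records"),
        config={"min_percent": blast_cfg.min_percent,
                "categories": list(blast_cfg.blast_cell_categories)})

    cleaned = apply_manual_exclusions(kept, manual_exclusions or [], report)
    kept_images = {pid: kept_images.get(pid, []) for pid in cleaned["patient_id"]}

    report.validate_monotone()
    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        cleaned.to_csv(os.path.join(out_dir, "manifest_clean.tsv"), sep="\t", index=False)
        report.to_json(os.path.join(out_dir, "consort_report.json"))
    return report, cleaned, kept_images
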