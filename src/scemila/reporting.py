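"""Cohort IO, metric serialization, 2-D embedding and composition reports."""

from __future__ import annotations

import hashlib
import json
import logging
import os
import platform

import numpy as np
import pandas as pd

from .mil import CLASS_NAMES, CrossValidationResults
from .synthetic import SyntheticBag

logger = logging.getLogger(__name__)


def load_cohort(cohort_dir: str | os.PathLike,
                class_names: tuple[str, ...] = CLASS_NAMES,
                strict: bool = True) -> tuple[pd.DataFrame, list[SyntheticBag]]:
    """Read a cohort directory (manifest.tsv + per-patient bag files).

    Validates the schema: unique patient ids, labels within the configured
    class set, referenced bag files present. ``strict=False`` logs and skips
    inconsistent rows instead of raising. On-disk cell order is preserved.
    """
    cohort_dir = os.fspath(cohort_dir)
    manifest = pd.read_csv(os.path.join(cohort_dir, "manifest.tsv"), sep="\t")
    dupes = manifest.loc[manifest["patient_id"].duplicated(), "patient_id"].tolist()
    if dupes:
        raise ValueError(f"duplicate patient ids in manifest: {dupes}")
    label_index = {name: i for i, name in enumerate(class_names)}
    bags, keep_rows = [], []
    for r, row in manifest.iterrows():
        problems = []
        if row["label"] not in label_index:
            problems.append(f"unknown label {row['label']!r} "
                            f"(allowed: {list(class_names)})")
        bag_path = os.path.join(cohort_dir, str(row.get("bag_file", "")))
        if not os.path.exists(bag_path):
            problems.append(f"missing bag file {bag_path}")
        if problems:
            if strict:
                raise ValueError(f"patient {row['patient_id']!r}: " + "; ".join(problems))
            logger.warning("skipping patient %s: %s", row["patient_id"], problems)
            continue
        x = np.load(bag_path)
        pdir = os.path.dirname(bag_path)
        cells_path = os.path.join(pdir, "cells.tsv")
        if os.path.exists(cells_path):
            cells = pd.read_csv(cells_path, sep="\t")
            cell_ids = cells["cell_id"].tolist()
            planted = cells.get("planted", pd.Series(np.zeros(len(x)))).to_numpy(dtype=bool)
        else:
            cell_ids = [f"{row['patient_id']}_cell{k:04d}" for k in range(len(x))]
            planted = np.zeros(len(x), dtype=bool)
        bags.append(SyntheticBag(row["patient_id"], label_index[row["label"]],
                                 x, planted, cell_ids))
        keep_rows.append(r)
    return manifest.loc[keep_rows].reset_index(drop=True), bags


# ---------------------------------------------------------------------------
# 2-D embedding (UMAP fit on one fold, transform for the rest)


def fit_embedding(features: np.ndarray, seed: int = 0, **umap_kwargs):
    """Fit a 2-D UMAP on one fold's cell features.

    Library defaults are used for the neighborhood parameters (the embedding
    is a visualization, not a quantitative claim); the seed is fixed so the
    same data give identical coordinates.
    """
    import umap   # deferred: slow import

    features = np.asarray(features)
    if len(features) < 10:
        raise ValueError("need at least 10 feature vectors to fit an embedding")
    if np.allclose(features, features[0]):
        raise ValueError("degenerate input: all feature vectors identical")
    reducer = umap.UMAP(n_components=2, random_state=seed, **umap_kwargs)
    reducer.fit(features)
    return reducer


def map_into_embedding(reducer, features: np.ndarray,
                       predictions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Project new cells into a fitted embedding without refitting.

    Optionally joins instance predictions so each point carries its predicted
    class and the model output for that class (the color/intensity channel of
    the embedding plots).
    """
    features = np.asarray(features)
    if len(features) == 0:
        return pd.DataFrame(columns=["cell_id", "x", "y", "pred_class", "probability"])
    expected = reducer._raw_data.shape[1]
    if features.shape[1] != expected:
        raise ValueError(f"feature dim {features.shape[1]} does not match "
                         f"embedding dim {expected}")
    coords = reducer.transform(features)
    out = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1]})
    if predictions is not None:
        out.insert(0, "cell_id", predictions["cell_id"].to_numpy())
        out["pred_class"] = predictions["predicted_class"].to_numpy()
        out["probability"] = predictions["predicted_probability"].to_numpy()
    else:
        out.insert(0, "cell_id", [f"cell{k}" for k in range(len(out))])
    return out


# ---------------------------------------------------------------------------
# composition report (per-patient deconvolution bar data)


def composition_report(instance_predictions: dict[str, pd.DataFrame],
                       bag_predictions: dict[str, object],
                       labels: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-patient ordered cell-composition table.

    Within a patient, cells are ordered by the predicted class's attention
    (ascending: low-attention cells first); patients are ordered by the
    strength of their bag-level output activation, strongest first. Each row
    carries the cell's individual predicted class, so a stacked bar per
    patient shows the smear's predicted cellular composition.
    """
    patient_order = sorted(
        bag_predictions,
        key=lambda pid: -float(bag_predictions[pid].probabilities[
            bag_predictions[pid].predicted_index]))
    frames = []
    for rank, pid in enumerate(patient_order):
        bp = bag_predictions[pid]
        inst = instance_predictions[pid].copy()
        order = np.argsort(bp.attention, kind="stable")
        inst = inst.iloc[order].reset_index(drop=True)
        inst["attention"] = bp.attention[order]
        inst["cell_order"] = np.arange(len(inst))
        inst["patient_rank"] = rank
        inst["bag_predicted_class"] = bp.predicted_label
        inst["bag_activation"] = float(bp.probabilities[bp.predicted_index])
        if labels is not None:
            inst["bag_correct"] = bool(bp.predicted_index == labels[pid])
        frames.append(inst)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# metrics bundle


def report_metrics(cv: CrossValidationResults,
                   out_dir: str | os.PathLike | None = None,
                   consort: dict | None = None,
                   seeds: dict | None = None) -> dict:
    """Serialize cross-validation metrics as a deterministic JSON/CSV bundle."""
    f1 = cv.f1_summary()
    auc = cv.auc_summary()
    bundle = {
        "n_patients": int(len(cv.y_true)),
        "n_folds": len(cv.folds),
        "class_names": list(cv.class_names),
        "f1_mean": {n: float(f1.loc[n, "mean"]) for n in cv.class_names},
        "f1_sd": {n: float(f1.loc[n, "sd"]) for n in cv.class_names},
        "roc_auc": {n: float(auc.loc[n, "roc_auc"]) for n in cv.class_names},
        "pr_auc": {n: float(auc.loc[n, "pr_auc"]) for n in cv.class_names},
        "macro_f1_pooled": cv.macro_f1(),
        "aml_vs_control_accuracy": cv.aml_vs_control_accuracy(),
        "confusion_matrix": cv.confusion.values.tolist(),
    }
    if consort is not None:
        bundle["consort"] = consort
    bundle["provenance"] = provenance(seeds or {})
    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
            json.dump(bundle, fh, indent=2, sort_keys=True)
        cv.confusion.to_csv(os.path.join(out_dir, "confusion_matrix.csv"))
    return bundle


def provenance(seeds: dict) -> dict:
    """Versions + seeds block written with every run for re-runnability."""
    import scemila
    import sklearn
    payload = {
        "scemila": scemila.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "sklearn": sklearn.__version__,
        "python": platform.python_version(),
        "seeds": {k: int(v) for k, v in seeds.items()},
    }
    digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()
    payload["config_hash"] = digest[:16]
    return payload


#: default palette following the subtype color convention
CLASS_COLORS = {
    "PML::RARA": "#f28e2b", "NPM1": "#e15759", "CBFB::MYH11": "#8c7a3f",
    "RUNX1::RUNX1T1": "#4e79a7", "control": "#59a14f",
}


def cell_montage(images: list[np.ndarray], path: str | os.PathLike,
                 n_cols: int = 12, titles: list[str] | None = None) -> None:
    """Write a grid-montage PNG of cell images (review artifacts)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(images)
    n_rows = (n + n_cols - 1) // n_cols
    fig, axes = plt.subplots(n_rows, n_cols, figsize=(n_cols, n_rows),
                             squeeze=False)
    for ax in axes.ravel():
        ax.axis("off")
    for i, img in enumerate(images):
        ax = axes[i // n_cols][i % n_cols]
        ax.imshow(img)
        if titles:
            ax.set_title(titles[i], fontsize=5)
    fig.tight_layout(pad=0.1)
    fig.savefig(os.fspath(path), dpi=120)
    plt.close(fig)
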