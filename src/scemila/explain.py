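"""Explainability analyses for a fitted attention-MIL model.

* instance-wise deconvolution: every cell classified on its own via a
  bag-of-one forward pass;
* attention ranking and the attention-quartile vs expert-annotation
  concordance analysis;
* per-class representative cells pooled across cross-validation folds;
* robustness of the bag prediction to subsampling the number of cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mil import (AttentionMILResults, BagPrediction, CrossValidationResults,
                  forward)


def predict_instances(results: AttentionMILResults, bag) -> pd.DataFrame:
    """Classify each cell of a bag individually (bag-of-one deconvolution).

    Returns one row per cell, in bag order, with the class probability vector,
    the predicted class, and the source patient. For a singleton bag the
    attention weight is trivially 1, so the instance prediction coincides with
    the bag prediction on that cell.
    """
    params = results.params
    names = results.class_names
    H = _embedded(bag, params)
    # singleton-bag algebra: with a_i = [1], z_i = h_k, so s_i = u_i.h_k + c_i
    logits = H @ params.U.T + params.c
    probs = _softmax_rows(logits)
    pred = probs.argmax(axis=1)
    cell_ids = getattr(bag, "cell_ids", [f"cell{k:04d}" for k in range(len(H))])
    out = pd.DataFrame(probs, columns=[f"p_{n}" for n in names])
    out.insert(0, "cell_id", cell_ids)
    out.insert(1, "patient_id", getattr(bag, "patient_id", None))
    out["predicted_index"] = pred
    out["predicted_class"] = [names[i] for i in pred]
    out["predicted_probability"] = probs[np.arange(len(pred)), pred]
    return out


def _embedded(bag, params) -> np.ndarray:
    from .mil import embed_instances
    X = bag.features if hasattr(bag, "features") else np.asarray(bag)
    return embed_instances(X, params)


def _softmax_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def rank_by_attention(prediction: BagPrediction,
                      cell_ids: list[str] | None = None) -> pd.DataFrame:
    """Cells ordered by the predicted class's attention, ascending.

    The sort is stable: tied attention values keep their bag order, and the
    result is a permutation of the input cells.
    """
    alpha = prediction.attention
    order = np.argsort(alpha, kind="stable")
    cell_ids = cell_ids or [f"cell{k:04d}" for k in range(len(alpha))]
    return pd.DataFrame({
        "rank": np.arange(len(order)),
        "bag_index": order,
        "cell_id": [cell_ids[i] for i in order],
        "attention": alpha[order],
    })


@dataclass
class QuartileSummary:
    """Composition of attention quartiles by annotation relevance group."""

    counts: pd.DataFrame          # quartile x relevance-group cell counts
    fractions: pd.DataFrame       # rows sum to 1
    boundaries: list[float]       # attention values at quartile edges
    relevant_fraction: pd.Series | None = None   # per quartile, if mapping given
    n_unannotated: int = 0

    @property
    def top_quartile_relevant_fraction(self) -> float:
        if self.relevant_fraction is None:
            raise ValueError("no relevance mapping was provided")
        return float(self.relevant_fraction.iloc[-1])


def quartile_concordance(ranked: pd.DataFrame, annotations: pd.DataFrame,
                         relevant_groups: set[str] | None = None) -> QuartileSummary:
    """Split attention-ranked cells into four rank quartiles and summarize
    the annotation composition of each.

    Quartiles are rank-based (equal counts, sizes differing by at most one),
    ordered Q1 = lowest attention to Q4 = highest. ``annotations`` needs
    columns ``cell_id`` and ``relevance_group``; cells without an annotation
    are excluded from the fractions and counted separately. If
    ``relevant_groups`` names the groups considered diagnostically relevant,
    a per-quartile relevant fraction is added.
    """
    if annotations["cell_id"].duplicated().any():
        dupes = annotations.loc[annotations["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"ambiguous duplicate annotations for cells: {dupes[:5]}")
    ann = annotations.set_index("cell_id")["relevance_group"]
    merged = ranked.copy()
    merged["relevance_group"] = merged["cell_id"].map(ann)
    n_unannotated = int(merged["relevance_group"].isna().sum())
    merged = merged.dropna(subset=["relevance_group"]).reset_index(drop=True)

    n = len(merged)
    if n == 0:
        raise ValueError("no annotated cells among the ranked list")
    # equal-count quartiles over the rank order; larger quartiles first
    sizes = [(n + 3 - q) // 4 for q in range(4)]
    labels = np.repeat(np.arange(4), sizes)
    merged["quartile"] = [f"Q{q + 1}" for q in labels]

    counts = (merged.groupby(["quartile", "relevance_group"]).size()
              .unstack(fill_value=0).reindex([f"Q{i}" for i in range(1, 5)], fill_value=0))
    fractions = counts.div(counts.sum(axis=1).replace(0, np.nan), axis=0)
    boundaries = [float(merged.loc[labels == q, "attention"].max()) for q in range(4)]
    relevant = None
    if relevant_groups is not None:
        rel = merged["relevance_group"].isin(relevant_groups)
        relevant = (merged.assign(rel=rel).groupby("quartile")["rel"].mean()
                    .reindex([f"Q{i}" for i in range(1, 5)]))
    return QuartileSummary(counts, fractions, boundaries, relevant, n_unannotated)


def representative_cells(cv: CrossValidationResults, bags: list,
                         k_per_fold: int = 2) -> pd.DataFrame:
    """Top-activation cells per class, pooled across folds (k per fold).

    For every fold, each test-set cell is classified individually; the
    ``k_per_fold`` cells with the highest output activation for a class
    represent that class (5 folds x 2 = 10 cells per class by default).
    Activation ties break deterministically by (patient_id, cell_id).
    """
    by_pid = {b.patient_id: b for b in bags}
    names = cv.class_names
    rows = []
    for fold, res in zip(cv.folds, cv.fold_results):
        frames = []
        for pid in fold.test_ids:
            if pid in by_pid:
                frames.append(predict_instances(res, by_pid[pid]))
        if not frames:
            continue
        inst = pd.concat(frames, ignore_index=True)
        for ci, cname in enumerate(names):
            ranked = inst.sort_values([f"p_{cname}", "patient_id", "cell_id"],
                                      ascending=[False, True, True])
            top = ranked.head(k_per_fold)
            if len(top) < k_per_fold:
                import warnings
                warnings.warn(f"fold {fold.fold}: only {len(top)} candidate cells "
                              f"for class {cname}", stacklevel=2)
            for _, r in top.iterrows():
                rows.append({"class": cname, "fold": fold.fold,
                             "patient_id": r["patient_id"], "cell_id": r["cell_id"],
                             "activation": r[f"p_{cname}"]})
    return pd.DataFrame(rows, columns=["class", "fold", "patient_id", "cell_id", "activation"])


DEFAULT_SUBSAMPLE_SIZES = (1, 2, 5, 10, 20, 50, 100, 200, 500)


def subsample_robustness(results: AttentionMILResults, bags: list,
                         sizes: tuple[int, ...] = DEFAULT_SUBSAMPLE_SIZES,
                         reps: int = 100, seed: int = 0,
                         random_cell_baseline: bool = True) -> pd.DataFrame:
    """How bag predictions degrade when only s cells are available.

    For each patient and each size s <= N, ``reps`` subsets of s cells are
    drawn without replacement and passed through the model; reported per size
    are the mean classification accuracy over patients and the mean output
    activation for the patient's true class. The per-patient full bag (s = N)
    is always included, where the subsample trivially reproduces the full-bag
    prediction. A "random cell from dataset" baseline draws single cells from
    the pooled cohort, ignoring patient ground truth.
    """
    rng = np.random.default_rng(seed)
    params = results.params
    rows = []
    for bag in bags:
        X = bag.features
        n = len(X)
        y = int(bag.label)
        for s in sorted(set(int(v) for v in sizes if v <= n) | {n}):
            r = 1 if s == n else reps
            correct, act = 0.0, 0.0
            for _ in range(r):
                idx = rng.choice(n, size=s, replace=False) if s < n else np.arange(n)
                pred = forward(X[idx], params, results.class_names)
                correct += pred.predicted_index == y
                act += pred.probabilities[y]
            rows.append({"patient_id": bag.patient_id, "size": s, "full_bag": s == n,
                         "accuracy": correct / r, "true_class_activation": act / r,
                         "label": y})
    out = pd.DataFrame(rows)
    if random_cell_baseline:
        pool_x = np.concatenate([b.features for b in bags])
        pool_y = np.concatenate([np.full(b.n_instances, b.label) for b in bags])
        correct = 0.0
        for _ in range(reps):
            j = int(rng.integers(len(pool_x)))
            pred = forward(pool_x[j:j + 1], params, results.class_names)
            correct += pred.predicted_index == pool_y[j]
        out.attrs["random_cell_accuracy"] = correct / reps
    return out


def mean_accuracy_by_size(table: pd.DataFrame) -> pd.DataFrame:
    """Average the subsample table over patients, per subset size.

    Sizes exceeding a patient's bag are absent for that patient (recorded by
    their absence); the per-patient full-bag rows are aggregated separately
    under size label 'full'.
    """
    ladder = (table[~table["full_bag"]].groupby("size")
              .agg(mean_accuracy=("accuracy", "mean"),
                   mean_true_class_activation=("true_class_activation", "mean"),
                   n_patients=("patient_id", "nunique")).reset_index())
    full = table[table["full_bag"]]
    full_row = pd.DataFrame([{
        "size": "full",
        "mean_accuracy": full["accuracy"].mean(),
        "mean_true_class_activation": full["true_class_activation"].mean(),
        "n_patients": full["patient_id"].nunique(),
    }])
    return pd.concat([ladder, full_row], ignore_index=True)
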