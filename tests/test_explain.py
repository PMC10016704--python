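"""Tests of the explainability suite (deconvolution, ranking, quartiles,
representative cells, subsampling robustness)."""

import numpy as np
import pandas as pd
import pytest

from scemila import explain as ex
from scemila.mil import forward


class TestPredictInstances:
    def test_shape_and_order(self, small_cohort, small_results):
        _, bags = small_cohort
        inst = ex.predict_instances(small_results, bags[0])
        assert len(inst) == bags[0].n_instances
        assert list(inst["cell_id"]) == bags[0].cell_ids
        probs = inst[[c for c in inst.columns if c.startswith("p_")]].to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_singleton_bag_equals_bag_prediction(self, small_cohort, small_results):
        """Bag-of-one consistency: the instance classifier is exactly the
        bag classifier on a size-1 bag."""
        _, bags = small_cohort
        bag = bags[3]
        inst = ex.predict_instances(small_results, bag)
        for k in (0, bag.n_instances - 1):
            single = forward(bag.features[k:k + 1], small_results.params,
                             small_results.class_names)
            probs = inst.iloc[k][[f"p_{n}" for n in small_results.class_names]]
            np.testing.assert_allclose(probs.to_numpy(dtype=float),
                                       single.probabilities, atol=1e-6)

    def test_planted_cells_recovered_more_often(self, small_cohort, small_results):
        """In correctly classified AML-like bags, planted instances are
        individually assigned to the bag's class more often than background."""
        _, bags = small_cohort
        planted_rate, background_rate = [], []
        for bag in bags:
            if bag.label == 2 or not bag.planted.any():
                continue
            pred = small_results.predict(bag)
            if pred.predicted_index != bag.label:
                continue
            inst = ex.predict_instances(small_results, bag)
            match = (inst["predicted_index"] == bag.label).to_numpy()
            planted_rate.append(match[bag.planted].mean())
            background_rate.append(match[~bag.planted].mean())
        assert np.mean(planted_rate) > np.mean(background_rate)


class TestRanking:
    def test_stable_ascending_permutation(self, small_cohort, small_results):
        _, bags = small_cohort
        pred = small_results.predict(bags[0])
        ranked = ex.rank_by_attention(pred, bags[0].cell_ids)
        att = ranked["attention"].to_numpy()
        assert np.all(np.diff(att) >= 0)
        assert sorted(ranked["cell_id"]) == sorted(bags[0].cell_ids)
        # independent sort oracle
        oracle = np.argsort(pred.attention, kind="stable")
        np.testing.assert_array_equal(ranked["bag_index"].to_numpy(), oracle)

    def test_uniform_attention_preserves_bag_order(self):
        from scemila.mil import BagPrediction
        n = 6
        pred = BagPrediction(np.full(3, 1 / 3), 0, "a", np.full(n, 1 / n),
                             np.full((3, n), 1 / n), np.zeros((3, 2)), np.zeros(3))
        ranked = ex.rank_by_attention(pred)
        np.testing.assert_array_equal(ranked["bag_index"], np.arange(n))


class TestQuartiles:
    def _ranked(self, n, attention=None):
        att = attention if attention is not None else np.linspace(0.01, 0.2, n)
        return pd.DataFrame({"rank": range(n), "bag_index": range(n),
                             "cell_id": [f"c{i}" for i in range(n)],
                             "attention": att})

    def test_constructed_top_quartile_fully_relevant(self):
        """Top-2 of 8 cells annotated relevant -> top quartile 100% relevant."""
        ranked = self._ranked(8)
        ann = pd.DataFrame({"cell_id": [f"c{i}" for i in range(8)],
                            "relevance_group": ["healthy"] * 6 + ["relevant"] * 2})
        qs = ex.quartile_concordance(ranked, ann, relevant_groups={"relevant"})
        assert qs.top_quartile_relevant_fraction == 1.0
        assert qs.relevant_fraction.loc["Q1"] == 0.0

    def test_single_group_everywhere(self):
        ranked = self._ranked(10)
        ann = pd.DataFrame({"cell_id": [f"c{i}" for i in range(10)],
                            "relevance_group": ["g"] * 10})
        qs = ex.quartile_concordance(ranked, ann)
        np.testing.assert_allclose(qs.fractions["g"].to_numpy(), 1.0)

    def test_quartile_sizes_balanced(self):
        for n in (8, 9, 10, 11):
            ranked = self._ranked(n)
            ann = pd.DataFrame({"cell_id": [f"c{i}" for i in range(n)],
                                "relevance_group": ["g"] * n})
            qs = ex.quartile_concordance(ranked, ann)
            sizes = qs.counts.sum(axis=1).to_numpy()
            assert sizes.sum() == n and sizes.max() - sizes.min() <= 1

    def test_fractions_sum_to_one_per_quartile(self):
        rng = np.random.default_rng(0)
        n = 40
        ranked = self._ranked(n, rng.random(n))
        ann = pd.DataFrame({"cell_id": [f"c{i}" for i in range(n)],
                            "relevance_group": rng.choice(list("abc"), n)})
        qs = ex.quartile_concordance(ranked, ann)
        np.testing.assert_allclose(qs.fractions.sum(axis=1), 1.0)

    def test_duplicate_annotation_rejected(self):
        ranked = self._ranked(4)
        ann = pd.DataFrame({"cell_id": ["c0", "c0", "c1", "c2"],
                            "relevance_group": list("aaaa")})
        with pytest.raises(ValueError, match="duplicate"):
            ex.quartile_concordance(ranked, ann)

    def test_unannotated_cells_reported_separately(self):
        ranked = self._ranked(8)
        ann = pd.DataFrame({"cell_id": [f"c{i}" for i in range(6)],
                            "relevance_group": ["g"] * 6})
        qs = ex.quartile_concordance(ranked, ann)
        assert qs.n_unannotated == 2
        assert qs.counts.sum().sum() == 6


class TestRepresentativeCells:
    def test_count_and_dominance(self, small_cohort, small_cv):
        """At most k_per_fold x folds cells per class; each returned cell's
        activation is at least that of any non-returned cell in its fold,
        and for signal classes the returned cells are predominantly planted."""
        _, bags = small_cohort
        top = ex.representative_cells(small_cv, bags, k_per_fold=2)
        by_id = {b.patient_id: b for b in bags}
        cell_row = {b.patient_id: {cid: k for k, cid in enumerate(b.cell_ids)}
                    for b in bags}
        for cname, grp in top.groupby("class"):
            assert len(grp) <= 2 * len(small_cv.folds)
            assert (grp.groupby("fold").size() <= 2).all()
        # activation dominance within each fold
        for (cname, fold), grp in top.groupby(["class", "fold"]):
            test_ids = small_cv.folds[fold].test_ids
            res = small_cv.fold_results[fold]
            worst_returned = grp["activation"].min()
            best_other = 0.0
            returned = set(zip(grp["patient_id"], grp["cell_id"]))
            for pid in test_ids:
                inst = ex.predict_instances(res, by_id[pid])
                mask = [(pid, cid) not in returned for cid in inst["cell_id"]]
                if any(mask):
                    best_other = max(best_other,
                                     inst.loc[mask, f"p_{cname}"].max())
            assert worst_returned >= best_other - 1e-12
        # planted dominance for the signal classes (A = 0, B = 1)
        planted_hits, n = 0, 0
        for _, row in top[top["class"].isin(["A", "B"])].iterrows():
            bag = by_id[row["patient_id"]]
            planted_hits += bool(bag.planted[cell_row[row["patient_id"]][row["cell_id"]]])
            n += 1
        assert planted_hits / n > 0.5


class TestSubsampling:
    def test_full_size_reproduces_full_bag_exactly(self, small_cohort, small_results):
        _, bags = small_cohort
        sub = ex.subsample_robustness(small_results, bags[:6], sizes=(2, 5),
                                      reps=3, seed=0)
        full = sub[sub["full_bag"]]
        for _, row in full.iterrows():
            bag = next(b for b in bags if b.patient_id == row["patient_id"])
            pred = small_results.predict(bag)
            assert row["accuracy"] == float(pred.predicted_index == bag.label)
            assert row["true_class_activation"] == pytest.approx(
                float(pred.probabilities[bag.label]), abs=1e-12)

    def test_oversized_requests_skipped(self, small_cohort, small_results):
        _, bags = small_cohort
        sub = ex.subsample_robustness(small_results, bags[:2], sizes=(5, 10_000),
                                      reps=2, seed=0)
        assert 10_000 not in set(sub["size"])

    def test_singleton_size_matches_instance_predictions(self, small_cohort, small_results):
        """Accuracy at s=1 equals the fraction of cells whose individual
        prediction matches the patient label (up to sampling of reps)."""
        _, bags = small_cohort
        bag = bags[1]
        inst = ex.predict_instances(small_results, bag)
        exact = (inst["predicted_index"] == bag.label).mean()
        sub = ex.subsample_robustness(small_results, [bag], sizes=(1,),
                                      reps=400, seed=1, random_cell_baseline=False)
        est = sub[sub["size"] == 1]["accuracy"].iloc[0]
        assert abs(est - exact) < 0.15

    def test_random_baseline_recorded(self, small_cohort, small_results):
        _, bags = small_cohort
        sub = ex.subsample_robustness(small_results, bags[:4], sizes=(2,),
                                      reps=3, seed=0)
        assert 0.0 <= sub.attrs["random_cell_accuracy"] <= 1.0

    def test_mean_table_has_full_row(self, small_cohort, small_results):
        _, bags = small_cohort
        sub = ex.subsample_robustness(small_results, bags[:4], sizes=(2, 5),
                                      reps=2, seed=0)
        table = ex.mean_accuracy_by_size(sub)
        assert "full" in set(table["size"])
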