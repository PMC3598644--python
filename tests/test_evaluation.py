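import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catres.evaluation import (
    ConfusionCounts,
    assign_cluster_folds,
    classification_metrics,
    confusion_counts,
    cross_validate,
    cumulative_separation,
    f1_percent,
    feature_correlations,
    matthews_cc,
)
from catres.net import TrainingConfig

from oracles import pearson_oracle


class TestConfusion:
    def test_perfect_agreement(self):
        c = confusion_counts([1, 0, 1], [1, 0, 1])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 0, 0)

    def test_complement(self):
        c = confusion_counts([0, 1, 0], [1, 0, 1])
        assert (c.tp, c.tn) == (0, 0)
        assert (c.fp, c.fn) == (1, 2)

    def test_matches_manual_tally(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 2, 20)
        truth = rng.integers(0, 2, 20)
        c = confusion_counts(calls, truth)
        tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for a, b in zip(calls, truth):
            tally[{(1, 1): "tp", (0, 0): "tn", (1, 0): "fp", (0, 1): "fn"}[(a, b)]] += 1
        assert (c.tp, c.tn, c.fp, c.fn) == tuple(tally.values())
        assert c.total == 20

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_counts([1], [1, 0])


class TestMCC:
    def test_perfect_prediction(self):
        assert matthews_cc(ConfusionCounts(5, 5, 0, 0)) == 1.0

    def test_formula_on_test_set_counts(self):
        # 70 true positives among 411 returned; 111 annotated in 9262 residues
        c = ConfusionCounts(tp=70, tn=8810, fp=341, fn=41)
        expected = (70 * 8810 - 341 * 41) / np.sqrt(411 * 111 * 9151 * 8851)
        assert matthews_cc(c) == pytest.approx(expected, abs=1e-12)
        assert matthews_cc(c) == pytest.approx(0.3135, abs=5e-4)

    def test_zero_marginal_convention(self):
        assert matthews_cc(ConfusionCounts(0, 3, 0, 2)) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_bounded_and_one_iff_no_errors(self, counts):
        c = ConfusionCounts(*counts)
        mcc = matthews_cc(c)
        assert -1.0 - 1e-12 <= mcc <= 1.0 + 1e-12
        if c.fp == c.fn == 0 and c.tp > 0 and c.tn > 0:
            assert mcc == pytest.approx(1.0)


class TestMetrics:
    def test_test_set_arithmetic(self):
        m = classification_metrics(ConfusionCounts(tp=70, tn=8810, fp=341, fn=41))
        assert m.sensitivity == pytest.approx(63.06, abs=0.005)
        assert m.precision == pytest.approx(17.03, abs=0.005)
        assert m.f1 == pytest.approx(26.82, abs=0.005)

    @pytest.mark.parametrize(
        "sens,prec,f1",
        [
            (64.7, 19.07, 29.46),
            (89.8, 6.98, 12.95),
            (46.0, 28.0, 34.81),
            (51.35, 21.75, 30.56),
            (54.05, 7.85, 13.71),
            (60.14, 18.26, 28.01),
        ],
    )
    def test_f1_reproduces_reported_pairs(self, sens, prec, f1):
        assert f1_percent(sens, prec) == pytest.approx(f1, abs=0.005)

    def test_one_lcb_precision(self):
        m = classification_metrics(ConfusionCounts(tp=6, tn=295, fp=14, fn=0))
        assert m.precision == pytest.approx(30.0)

    def test_degenerate_cases(self):
        m = classification_metrics(ConfusionCounts(0, 5, 0, 0))
        assert m.sensitivity is None and m.precision is None and m.f1 is None
        assert f1_percent(0.0, 0.0) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.1, 100), st.floats(0.1, 100))
    def test_f1_between_min_and_max(self, s, p):
        f1 = f1_percent(s, p)
        assert min(s, p) - 1e-9 <= f1 <= max(s, p) + 1e-9


class TestCorrelations:
    def _table(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        conserv = rng.uniform(0, 4.3, n)
        return pd.DataFrame(
            {
                "conserv": conserv,
                "distance": rng.normal(10, 3, n),
                "closeness": rng.uniform(0, 1, n),
                "between": rng.uniform(0, 1, n),
                "pagerank": rng.uniform(0, 1, n),
                "rsa": rng.uniform(0, 100, n),
                "function": (conserv > 3.5).astype(int),
            }
        )

    def test_unit_diagonal_and_symmetry(self):
        m = feature_correlations(self._table())
        np.testing.assert_allclose(np.diag(m), 1.0)
        np.testing.assert_allclose(m.to_numpy(), m.to_numpy().T)

    def test_anticorrelated_pair(self):
        t = self._table()
        t["distance"] = -t["conserv"]
        m = feature_correlations(t)
        assert m.loc["conserv", "distance"] == pytest.approx(-1.0)

    def test_matches_closed_form_pearson(self):
        t = self._table(n=5, seed=3)
        m = feature_correlations(t)
        for a in ("conserv", "distance", "rsa"):
            for b in ("closeness", "pagerank"):
                assert m.loc[a, b] == pytest.approx(
                    pearson_oracle(t[a], t[b]), abs=1e-12
                )

    def test_zero_variance_column_gives_nan(self):
        t = self._table()
        t["rsa"] = 7.0
        m = feature_correlations(t)
        assert np.isnan(m.loc["rsa", "conserv"])

    def test_label_column_required(self):
        with pytest.raises(ValueError):
            feature_correlations(self._table().drop(columns="function"))


class TestCumulativeSeparation:
    def test_identical_distributions_give_zero_difference(self):
        vals = np.r_[np.arange(10.0), np.arange(10.0)]
        labels = np.r_[np.ones(10), np.zeros(10)]
        out = cumulative_separation(vals, labels)
        np.testing.assert_allclose(
            out["ecdf_functional"], out["ecdf_nonfunctional"]
        )

    def test_perfect_separation_has_unit_gap(self):
        vals = np.r_[np.zeros(5), np.ones(5) * 10]
        labels = np.r_[np.ones(5), np.zeros(5)]
        out = cumulative_separation(vals, labels)
        assert out["metadata"]["max_abs_gap"] == pytest.approx(1.0)

    def test_matches_bruteforce_ecdf(self):
        rng = np.random.default_rng(1)
        vals = np.r_[rng.normal(0, 1, 30), rng.normal(2, 1, 50)]
        labels = np.r_[np.ones(30), np.zeros(50)]
        out = cumulative_separation(vals, labels)
        grid = out["grid"]
        pos_vals = vals[labels == 1]
        expected = np.array([(pos_vals <= g).mean() for g in grid])
        np.testing.assert_allclose(out["ecdf_functional"], expected)
        assert np.all(np.diff(out["ecdf_functional"]) >= 0)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            cumulative_separation([1.0, 2.0], [1, 1])


class TestCrossValidation:
    def test_fold_assignment_balanced(self):
        folds = assign_cluster_folds(list(range(10)), k=10, seed=0)
        assert sorted(len(f) for f in folds) == [1] * 10
        folds = assign_cluster_folds(list(range(23)), k=10, seed=0)
        assert sorted(set(len(f) for f in folds)) == [2, 3]
        assert sorted(c for f in folds for c in f) == list(range(23))

    def test_fewer_clusters_than_folds(self):
        with pytest.raises(ValueError):
            assign_cluster_folds([1, 2], k=3, seed=0)

    def test_no_cluster_spans_folds_and_metrics_returned(self):
        from catres.fixtures import planted_scan_tables

        rng = np.random.default_rng(0)
        blocks = []
        for s in range(6):
            t, _, _ = planted_scan_tables(seed=s)
            t = t.assign(structure_id=f"S{s}").sample(120, random_state=s)
            blocks.append(t)
        table = pd.concat(blocks, ignore_index=True)
        cluster_of = {f"S{s}": f"c{s % 3}" for s in range(6)}  # paired structures
        cfg = TrainingConfig(seed=0, max_epochs=40)
        per_fold, mean = cross_validate(table, cluster_of, k=3, cfg=cfg)
        assert len(per_fold) == 3
        assert -1 <= mean.mcc <= 1
        if mean.sensitivity is not None:
            assert 0 <= mean.sensitivity <= 100
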