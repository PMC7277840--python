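"""Agreement statistics: confusion bookkeeping, accuracy, weighted kappa."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import echoview as ev
from echoview.core import ViewLabel
from echoview.evaluate import VIEW_NAMES, ConfusionTable


def brute_force_kappa(counts: np.ndarray, weighting: str) -> float:
    """Independent cell-by-cell evaluation of the weighted-kappa formula."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    k = counts.shape[0]
    row = [counts[i, :].sum() / n for i in range(k)]
    col = [counts[:, j].sum() / n for j in range(k)]
    num = den = 0.0
    for i in range(k):
        for j in range(k):
            if weighting == "unweighted":
                w = 0.0 if i == j else 1.0
            elif weighting == "linear":
                w = abs(i - j) / (k - 1)
            else:
                w = ((i - j) / (k - 1)) ** 2
            num += w * counts[i, j] / n
            den += w * row[i] * col[j]
    return 1.0 - num / den


def table_to_labels(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t, p = [], []
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            t += [i] * int(counts[i, j])
            p += [j] * int(counts[i, j])
    return np.array(t), np.array(p)


class TestConfusion:
    def test_all_correct_is_diagonal(self):
        preds = [(v, np.eye(5)[v.index]) for v in ev.VIEW_ORDER for _ in range(20)]
        table = ev.confusion(preds)
        assert np.trace(table.counts) == 100
        assert table.total == 100

    def test_empty_predictions_zero_table(self):
        assert ev.confusion([]).total == 0

    def test_three_ap4_as_ap3_bookkeeping(self):
        preds = [(v, np.eye(5)[v.index]) for v in ev.VIEW_ORDER for _ in range(5)]
        wrong = np.eye(5)[ViewLabel.AP3.index]
        preds += [(ViewLabel.AP4, wrong)] * 3
        table = ev.confusion(preds)
        assert table.counts[ViewLabel.AP4.index, ViewLabel.AP3.index] == 3

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError, match="true label"):
            ev.confusion([(None, np.eye(5)[0])])

    def test_dataframe_input_with_probabilities(self):
        df = pd.DataFrame([{"true_view": "PLAX", "p_PLAX": 0.9, "p_PSAX": 0.1,
                            "p_AP3": 0.0, "p_AP4": 0.0, "p_AP2": 0.0}])
        assert ev.confusion(df).counts[0, 0] == 1


class TestAccuracy:
    def test_identity_table(self):
        assert ev.accuracy(ConfusionTable(np.eye(5, dtype=int) * 7)) == 1.0

    def test_uniform_table_is_chance(self):
        assert ev.accuracy(ConfusionTable(np.full((5, 5), 4))) == pytest.approx(0.2)

    def test_constructed_981_per_mille(self):
        counts = np.diag([197, 196, 196, 196, 196])
        counts[2, 4] = 10
        counts[3, 2] = 9
        table = ConfusionTable(counts)
        assert table.total == 1000
        assert ev.accuracy(table) == pytest.approx(0.981)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ev.accuracy(ConfusionTable(np.zeros((5, 5), int)))


class TestWeightedKappa:
    @pytest.mark.parametrize("weighting", ["unweighted", "linear", "quadratic"])
    def test_identity_table_kappa_one(self, weighting):
        res = ev.weighted_kappa(ConfusionTable(np.eye(5, dtype=int) * 9), weighting)
        assert res.kappa == pytest.approx(1.0)

    def test_marginal_product_table_kappa_zero(self):
        r = np.array([1, 2, 3, 4, 5])
        c = np.array([2, 1, 3, 4, 5])
        res = ev.weighted_kappa(ConfusionTable(np.outer(r, c)))
        assert res.kappa == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("weighting", ["unweighted", "linear", "quadratic"])
    def test_matches_brute_force_on_random_tables(self, weighting, rng):
        for _ in range(60):
            counts = rng.integers(0, 30, (5, 5))
            counts[np.arange(5), np.arange(5)] += rng.integers(5, 40, 5)
            got = ev.weighted_kappa(ConfusionTable(counts), weighting).kappa
            assert got == pytest.approx(brute_force_kappa(counts, weighting),
                                        abs=1e-10)

    @pytest.mark.parametrize("weighting", ["unweighted", "linear", "quadratic"])
    def test_matches_sklearn_oracle(self, weighting, rng):
        sk = pytest.importorskip("sklearn.metrics")
        sk_w = {"unweighted": None, "linear": "linear",
                "quadratic": "quadratic"}[weighting]
        for _ in range(10):
            counts = rng.integers(0, 20, (5, 5)) + np.eye(5, dtype=int) * 10
            t, p = table_to_labels(counts)
            want = sk.cohen_kappa_score(t, p, weights=sk_w)
            got = ev.weighted_kappa(ConfusionTable(counts), weighting).kappa
            assert got == pytest.approx(want, abs=1e-10)

    def test_permutation_invariance(self, rng):
        counts = rng.integers(0, 25, (5, 5)) + np.eye(5, dtype=int) * 30
        perm = rng.permutation(5)
        permuted = counts[np.ix_(perm, perm)]
        a = ev.weighted_kappa(ConfusionTable(counts), "unweighted")
        b = ev.weighted_kappa(ConfusionTable(permuted), "unweighted")
        assert a.kappa == pytest.approx(b.kappa, abs=1e-12)
        assert ev.accuracy(ConfusionTable(counts)) == pytest.approx(
            ev.accuracy(ConfusionTable(permuted)))

    def test_kappa_below_one_iff_off_diagonal_mass(self, rng):
        counts = np.eye(5, dtype=int) * 10
        assert ev.weighted_kappa(ConfusionTable(counts)).kappa == 1.0
        counts[0, 1] = 1
        assert ev.weighted_kappa(ConfusionTable(counts)).kappa < 1.0

    def test_empty_class_dropped(self):
        counts = np.eye(5, dtype=int) * 10
        counts[4, :] = 0
        counts[:, 4] = 0
        res = ev.weighted_kappa(ConfusionTable(counts))
        assert res.kappa == pytest.approx(1.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ev.weighted_kappa(ConfusionTable(np.zeros((5, 5), int)))

    def test_se_agrees_with_bootstrap(self, rng):
        """Delta-method SE vs bootstrap resampling: within 15% relative."""
        counts = np.array([
            [80, 5, 2, 1, 0],
            [4, 70, 6, 2, 1],
            [1, 5, 85, 4, 2],
            [0, 2, 5, 75, 3],
            [1, 1, 2, 4, 90],
        ])
        res = ev.weighted_kappa(ConfusionTable(counts), "linear")
        t, p = table_to_labels(counts)
        n = len(t)
        kappas = []
        for _ in range(600):
            idx = rng.integers(0, n, n)
            boot = np.zeros((5, 5), int)
            np.add.at(boot, (t[idx], p[idx]), 1)
            kappas.append(ev.weighted_kappa(ConfusionTable(boot), "linear").kappa)
        boot_se = np.std(kappas, ddof=1)
        assert res.se == pytest.approx(boot_se, rel=0.15)
        lo, hi = res.ci95
        assert lo <= res.kappa <= hi


class TestMisclassificationReport:
    def _preds(self, rows):
        recs = []
        for i, (true, pred) in enumerate(rows):
            rec = {"clip_id": f"c{i}", "patient_id": f"p{i}",
                   "true_view": true, "predicted_view": pred}
            for v in VIEW_NAMES:
                rec[f"p_{v}"] = 0.2
            recs.append(rec)
        return pd.DataFrame(recs)

    def test_no_errors_empty_report(self):
        df = self._preds([("AP4", "AP4"), ("PLAX", "PLAX")])
        assert len(ev.misclassification_report(df)) == 0

    def test_single_error_named(self, tmp_path):
        df = self._preds([("AP4", "AP4"), ("PSAX", "PLAX")])
        rep = ev.misclassification_report(df, out_dir=tmp_path)
        assert len(rep) == 1
        assert rep.iloc[0]["clip_id"] == "c1"
        assert (tmp_path / "misclassified.csv").exists()

    def test_adjacent_apical_confusions_listed_first(self):
        df = self._preds([("PLAX", "PSAX"), ("AP3", "AP2"), ("AP4", "AP3")])
        rep = ev.misclassification_report(df)
        assert rep["adjacent_apical"].tolist() == [True, True, False]
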