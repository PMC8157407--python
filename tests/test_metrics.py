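import numpy as np
import pytest

from interpbench import metrics
from interpbench.ground_truth import AtomTruth
from interpbench.interpretation import ContributionVector


def contrib(values, mol_id="m", level="atom", targets=None):
    values = np.asarray(values, dtype=float)
    if targets is None:
        targets = [frozenset({i}) for i in range(len(values))]
    return ContributionVector(
        mol_id=mol_id, level=level, targets=targets, contributions=values, base_prediction=0.0
    )


def truth(expected, mol_id="m"):
    return AtomTruth(mol_id, np.asarray(expected, dtype=float))


# --- independent brute-force oracles --------------------------------------

def auc_oracle(scores, labels):
    """Mann-Whitney pair counting with ties worth 0.5."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    if not pos or not neg:
        return float("nan")
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def top_n_oracle(values, true_atoms):
    """Sort by (contribution desc, index asc), count true atoms in top n."""
    n = len(true_atoms)
    order = sorted(range(len(values)), key=lambda i: (-values[i], i))
    return sum(1 for a in order[:n] if a in true_atoms), n


class TestPredictiveScores:
    def test_perfect_regression(self):
        p = metrics.PredictionSet(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]), "regression")
        s = metrics.predictive_scores(p)
        assert s["Q2"] == 1.0 and s["RMSE"] == 0.0

    def test_hand_computed_regression(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        pred = np.array([1.1, 1.9, 3.2, 3.8, 5.3, 5.7])
        s = metrics.predictive_scores(metrics.PredictionSet(obs, pred, "regression"))
        ss_res = float(((pred - obs) ** 2).sum())
        ss_tot = float(((obs - obs.mean()) ** 2).sum())
        assert s["Q2"] == pytest.approx(1 - ss_res / ss_tot)
        assert s["RMSE"] == pytest.approx(np.sqrt(ss_res / 6))

    def test_zero_variance_undefined(self):
        p = metrics.PredictionSet(np.ones(4), np.ones(4), "regression")
        assert np.isnan(metrics.predictive_scores(p)["Q2"])

    def test_balanced_accuracy(self):
        obs = np.array(["active"] * 2 + ["inactive"] * 4)
        pred = np.array(["active", "active", "inactive", "inactive", "active", "active"])
        s = metrics.predictive_scores(metrics.PredictionSet(obs, pred, "classification"))
        assert s["sensitivity"] == 1.0
        assert s["specificity"] == 0.5
        assert s["balanced_accuracy"] == 0.75

    def test_confusion_totals(self):
        obs = ["active", "inactive", "active", "inactive"]
        pred = ["active", "active", "inactive", "inactive"]
        c = metrics.confusion_counts(obs, pred)
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 1, 1)
        assert c.total == 4

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            metrics.PredictionSet(np.ones(3), np.ones(2), "regression")


class TestMoleculeAuc:
    def test_perfect_ranking(self):
        cv = contrib([0.9, 0.1, 0.8])
        t = truth([1, 0, 1])
        assert metrics.molecule_auc(cv, t, "positive") == 1.0

    def test_inverted(self):
        cv = contrib([0.1, 0.9])
        assert metrics.molecule_auc(cv, truth([1, 0]), "positive") == 0.0

    def test_negative_sign_ranks_ascending(self):
        cv = contrib([-0.9, 0.5, 0.1])
        t = truth([-1, 0, 0])
        assert metrics.molecule_auc(cv, t, "negative") == 1.0

    def test_undefined_without_sign_atoms(self):
        cv = contrib([0.5, 0.2])
        assert np.isnan(metrics.molecule_auc(cv, truth([0, 0]), "positive"))
        assert np.isnan(metrics.molecule_auc(cv, truth([1, 1]), "positive"))

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = 10
            # discrete values force ties
            values = rng.integers(-3, 4, size=n).astype(float) / 2
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            cv = contrib(values)
            t = truth(labels)
            assert metrics.molecule_auc(cv, t, "positive") == pytest.approx(
                auc_oracle(values, labels), abs=1e-12
            )

    def test_label_rewriting_ignores_other_sign(self):
        # negative atoms are relabeled 0 for AUC+
        cv = contrib([0.9, -0.5, 0.1])
        t = truth([1, -1, 0])
        assert metrics.molecule_auc(cv, t, "positive") == 1.0


class TestDatasetAuc:
    def test_mean(self):
        cvs = [contrib([0.9, 0.1], "a"), contrib([0.5, 0.5], "b")]
        truths = {"a": truth([1, 0], "a"), "b": truth([1, 0], "b")}
        mean, nex = metrics.dataset_auc(cvs, truths)
        assert mean == pytest.approx(0.75)
        assert nex == 0

    def test_exclusions(self):
        cvs = [contrib([0.9, 0.1], "a"), contrib([0.5, 0.5], "b")]
        truths = {"a": truth([1, 0], "a"), "b": truth([0, 0], "b")}
        mean, nex = metrics.dataset_auc(cvs, truths)
        assert mean == 1.0 and nex == 1

    def test_singleton(self):
        cvs = [contrib([0.9, 0.1], "a")]
        mean, nex = metrics.dataset_auc(cvs, {"a": truth([1, 0], "a")})
        assert mean == 1.0

    def test_all_undefined(self):
        cvs = [contrib([0.9, 0.1], "a")]
        mean, nex = metrics.dataset_auc(cvs, {"a": truth([0, 0], "a")})
        assert np.isnan(mean) and nex == 1


class TestTopN:
    def test_worked_example_half(self):
        # two positive atoms, one retrieved in top 2 -> m=1, n=2, score 0.5
        cv = contrib([0.9, 0.8, 0.1, 0.7])
        t = truth([1, 0, 0, 1])
        m, n = metrics.top_n_counts(cv, t)
        assert (m, n) == (1, 2)
        assert metrics.top_n_score([cv], {"m": t}) == 0.5

    def test_perfect(self):
        cv = contrib([1.0, 0.0, 1.0, 0.0])
        t = truth([1, 0, 1, 0])
        assert metrics.top_n_score([cv], {"m": t}) == 1.0

    def test_bottom_direction(self):
        cv = contrib([-0.9, 0.5, 0.1])
        t = truth([-1, 0, 0])
        assert metrics.top_n_score([cv], {"m": t}, direction="bottom") == 1.0

    def test_undefined_when_no_atoms(self):
        cv = contrib([0.5, 0.5])
        assert np.isnan(metrics.top_n_score([cv], {"m": truth([0, 0])}))

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(3, 15))
            values = rng.integers(-2, 3, size=n).astype(float)
            labels = (rng.random(n) < 0.4).astype(float)
            cv = contrib(values)
            t = truth(labels)
            m, nn = metrics.top_n_counts(cv, t)
            m_o, n_o = top_n_oracle(values, set(np.flatnonzero(labels)))
            assert (m, nn) == (m_o, n_o)

    def test_expected_tie_mode_hypergeometric(self):
        # all contributions tied, 2 of 4 atoms positive: E[m] = 2 * 2/4 = 1
        cv = contrib([0.3, 0.3, 0.3, 0.3])
        t = truth([1, 1, 0, 0])
        m, n = metrics.top_n_counts(cv, t, ties="expected")
        assert m == pytest.approx(1.0) and n == 2

    def test_tie_mode_index_deterministic(self):
        cv = contrib([0.3, 0.3, 0.3, 0.3])
        t = truth([0, 0, 1, 1])
        m, _ = metrics.top_n_counts(cv, t, ties="index")
        assert m == 0.0  # atoms 0,1 win the tie on index


class TestContributionRmse:
    def test_zero_when_exact(self):
        cv = contrib([1.0, 0.0, -1.0])
        per, mean = metrics.contribution_rmse([cv], {"m": truth([1, 0, -1])})
        assert mean == 0.0

    def test_unit_error(self):
        cv = contrib([0.0, 0.0])
        per, mean = metrics.contribution_rmse([cv], {"m": truth([1, 1])})
        assert per[0] == 1.0 and mean == 1.0

    def test_hand_formula_random(self):
        rng = np.random.default_rng(3)
        cvs, truths = [], {}
        expect = []
        for i in range(5):
            a = int(rng.integers(3, 9))
            c = rng.normal(size=a)
            e = rng.normal(size=a)
            cvs.append(contrib(c, f"m{i}"))
            truths[f"m{i}"] = truth(e, f"m{i}")
            expect.append(np.sqrt(np.sum((c - e) ** 2) / a))
        per, mean = metrics.contribution_rmse(cvs, truths)
        np.testing.assert_allclose(per, expect)
        assert mean == pytest.approx(np.mean(expect))

    def test_length_mismatch_fatal(self):
        with pytest.raises(ValueError, match="mismatch"):
            metrics.contribution_rmse([contrib([1.0, 2.0])], {"m": truth([1.0])})

    def test_includes_pattern_free_molecules(self):
        cvs = [contrib([0.2, 0.2], "a"), contrib([0.0, 0.0], "b")]
        truths = {"a": truth([0, 0], "a"), "b": truth([0, 0], "b")}
        per, mean = metrics.contribution_rmse(cvs, truths)
        assert len(per) == 2  # no exclusions for RMSE


class TestTopkPercentage:
    def test_both_in_top2(self):
        cv = contrib([0.9, 0.8, 0.1, 0.0])
        t = truth([1, 1, 0, 0])
        assert metrics.topk_percentage([cv], {"m": t}, 2) == 100.0

    def test_equivalence_with_top_n_for_two_center_molecules(self):
        rng = np.random.default_rng(5)
        cvs, truths = [], {}
        for i in range(50):
            a = int(rng.integers(5, 12))
            values = rng.normal(size=a)
            pos = rng.choice(a, size=2, replace=False)
            e = np.zeros(a)
            e[pos] = 1.0
            cvs.append(contrib(values, f"m{i}"))
            truths[f"m{i}"] = truth(e, f"m{i}")
        top2 = metrics.topk_percentage(cvs, truths, 2)
        topn = metrics.top_n_score(cvs, truths)
        assert top2 == pytest.approx(topn * 100.0)

    def test_k_beyond_atom_count(self):
        cv = contrib([0.1, 0.2])
        t = truth([1, 1])
        assert metrics.topk_percentage([cv], {"m": t}, 5) == 100.0

    def test_monotone_in_k(self):
        rng = np.random.default_rng(9)
        cvs, truths = [], {}
        for i in range(30):
            a = int(rng.integers(6, 20))
            e = np.zeros(a)
            e[rng.choice(a, size=2, replace=False)] = 1.0
            cvs.append(contrib(rng.normal(size=a), f"m{i}"))
            truths[f"m{i}"] = truth(e, f"m{i}")
        vals = [metrics.topk_percentage(cvs, truths, k) for k in (2, 3, 5)]
        assert vals[0] <= vals[1] <= vals[2]


class TestFragmentTop2:
    def _frag_cv(self, frag_atoms, values, mol_id="m"):
        return contrib(
            values, mol_id, level="fragment", targets=[frozenset(f) for f in frag_atoms]
        )

    def test_both_centers_covered(self):
        cv = self._frag_cv([{0, 1}, {2}, {3}], [0.9, 0.8, 0.1])
        t = truth([1, 0, 1, 0])
        assert metrics.fragment_top2([cv], {"m": t}) == 1.0

    def test_one_center_covered(self):
        cv = self._frag_cv([{0, 1}, {1}, {3}], [0.9, 0.8, 0.1])
        t = truth([1, 0, 1, 0])
        assert metrics.fragment_top2([cv], {"m": t}) == 0.5

    def test_none_covered(self):
        cv = self._frag_cv([{1}, {3}, {0}], [0.9, 0.8, 0.1])
        t = truth([1, 0, 1, 0])
        assert metrics.fragment_top2([cv], {"m": t}) == 0.0

    def test_single_fragment_molecule(self):
        cv = self._frag_cv([{0, 2}], [0.9])
        t = truth([1, 0, 1, 0])
        assert metrics.fragment_top2([cv], {"m": t}) == 1.0

    def test_average(self):
        a = self._frag_cv([{0}, {2}], [0.9, 0.8], "a")
        b = self._frag_cv([{1}, {3}], [0.9, 0.8], "b")
        truths = {"a": truth([1, 0, 1, 0], "a"), "b": truth([1, 0, 1, 0], "b")}
        assert metrics.fragment_top2([a, b], truths) == pytest.approx(0.5)


class TestBreakdown:
    def test_all_row_matches_global(self):
        rng = np.random.default_rng(1)
        cvs, truths, counts = [], {}, {}
        for i in range(20):
            a = int(rng.integers(4, 10))
            e = np.zeros(a)
            c = int(rng.integers(1, 4))
            e[rng.choice(a, size=min(c * 2, a - 1), replace=False)] = 1.0
            cvs.append(contrib(rng.normal(size=a), f"m{i}"))
            truths[f"m{i}"] = truth(e, f"m{i}")
            counts[f"m{i}"] = c
        table = metrics.breakdown_by_pattern_count(cvs, truths, counts, max_count=3)
        all_row = table["All"]
        assert all_row["top_n"] == pytest.approx(metrics.top_n_score(cvs, truths))
        auc, _ = metrics.dataset_auc(cvs, truths)
        assert all_row["mean_auc_pos"] == pytest.approx(auc)

    def test_single_count_population(self):
        cvs = [contrib([0.9, 0.1, 0.2], "a")]
        truths = {"a": truth([1, 0, 0], "a")}
        table = metrics.breakdown_by_pattern_count(cvs, truths, {"a": 1}, max_count=2)
        assert table["1"]["n"] == 1
        assert table["2"]["n"] == 0
        assert np.isnan(table["2"]["top_n"])
        assert table["1"]["top_n"] == table["All"]["top_n"]


class TestBounds:
    def test_all_scores_in_unit_interval(self):
        rng = np.random.default_rng(11)
        cvs, truths = [], {}
        for i in range(100):
            a = int(rng.integers(3, 20))
            e = np.zeros(a)
            k = int(rng.integers(0, a))
            if k:
                e[rng.choice(a, size=k, replace=False)] = 1.0
            cvs.append(contrib(rng.normal(size=a), f"m{i}"))
            truths[f"m{i}"] = truth(e, f"m{i}")
        for cv in cvs:
            v = metrics.molecule_auc(cv, truths[cv.mol_id])
            assert np.isnan(v) or 0.0 <= v <= 1.0
        s = metrics.top_n_score(cvs, truths)
        assert 0.0 <= s <= 1.0


def test_interpretation_report_aggregates():
    cvs = [contrib([0.9, 0.1, -0.8], "a")]
    truths = {"a": truth([1, 0, -1], "a")}
    rep = metrics.interpretation_report(cvs, truths)
    assert rep.mean_auc_pos == 1.0
    assert rep.mean_auc_neg == 1.0
    assert rep.top_n == 1.0 and rep.bottom_n == 1.0
    assert rep.mean_rmse == pytest.approx(np.sqrt((0.1**2 + 0.1**2 + 0.2**2) / 3))
    d = rep.to_dict()
    assert "top2_pct" in d and "mean_auc_pos" in d
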