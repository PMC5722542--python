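import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pgxmark import (
    adjust_pvalues,
    associations_for_drug,
    predict_single_gene,
    select_best_marker,
)
from pgxmark import single_gene as sg
from pgxmark.single_gene import GDSC_FIXED_CUTOFF, MarkerClassifier, RESISTANCE, SENSITISING


def _pooled_t_oracle(a, b):
    """Closed-form pooled-variance two-sample t-test (two-sided)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return 2 * stats.t.sf(abs(t), na + nb - 2)


class TestAssociation:
    def test_strong_sensitising_association(self):
        mut = np.array([-3.0, -3.1, -2.9])
        wt = np.array([0.0, 0.1, -0.1])
        responses = np.concatenate([mut, wt])
        flags = np.array([1, 1, 1, 0, 0, 0])
        res = sg.test_association("d", "g", responses, flags)
        assert res.p_value < 0.01
        assert res.effect_direction == SENSITISING
        assert res.p_value == pytest.approx(_pooled_t_oracle(mut, wt), abs=1e-12)

    def test_matches_pooled_t_oracle_on_random_draws(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(8, 40)
            flags = (rng.random(n) < 0.4).astype(int)
            if flags.sum() < 3 or (1 - flags).sum() < 3:
                continue
            resp = rng.normal(size=n)
            res = sg.test_association("d", "g", resp, flags)
            assert res.p_value == pytest.approx(
                _pooled_t_oracle(resp[flags == 1], resp[flags == 0]), abs=1e-12
            )

    def test_too_few_mutants_is_untestable(self):
        res = sg.test_association("d", "g", np.arange(10.0), np.array([1] + [0] * 9))
        assert not res.testable and res.p_value == 1.0

    def test_zero_variance_equal_means_gives_p_one(self):
        resp = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        res = sg.test_association("d", "g", resp, np.array([1, 1, 1, 0, 0, 0]))
        assert res.p_value == 1.0

    def test_null_pvalues_are_uniform(self):
        """Permutation-null calibration: p-values under H0 are uniform (KS)."""
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(300):
            resp = rng.normal(size=40)
            flags = np.zeros(40, dtype=int)
            flags[rng.choice(40, size=12, replace=False)] = 1
            pvals.append(sg.test_association("d", "g", resp, flags).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3


class TestAdjustPvalues:
    def _results(self, pvals):
        return [
            sg.test_association("d", f"g{i}", np.arange(8.0), np.array([1, 1, 1, 0, 0, 0, 0, 0]))
            for i in range(len(pvals))
        ]

    def _with_pvals(self, pvals):
        results = self._results(pvals)
        for r, p in zip(results, pvals):
            r.p_value = p
        return results

    def test_bh_step_up_example(self):
        results = adjust_pvalues(self._with_pvals([0.001, 0.02, 0.9]), mode="bh", fdr=0.2)
        assert [r.adjusted_significant for r in results] == [True, True, False]

    def test_bh_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        pvals = np.concatenate([rng.uniform(size=40), rng.uniform(size=10) * 1e-4])
        rng.shuffle(pvals)
        results = adjust_pvalues(self._with_pvals(list(pvals)), mode="bh", fdr=0.2)
        # brute-force step-up: largest k with p_(k) <= k/m * q; reject smallest k p-values
        m = len(pvals)
        order = np.argsort(pvals)
        ks = [k for k in range(1, m + 1) if pvals[order[k - 1]] <= 0.2 * k / m]
        cutoff_rank = max(ks) if ks else 0
        expected = np.zeros(m, dtype=bool)
        expected[order[:cutoff_rank]] = True
        assert [r.adjusted_significant for r in results] == expected.tolist()

    def test_all_ones_nothing_significant(self):
        results = adjust_pvalues(self._with_pvals([1.0, 1.0, 1.0]), mode="bh", fdr=0.2)
        assert not any(r.adjusted_significant for r in results)

    def test_fixed_cutoff_mode(self):
        results = adjust_pvalues(self._with_pvals([0.008, 0.009]), mode="fixed")
        assert [r.adjusted_significant for r in results] == [True, False]
        assert 0.008 <= GDSC_FIXED_CUTOFF <= 0.009

    def test_invalid_fdr_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues(self._with_pvals([0.5]), mode="bh", fdr=1.5)


class TestBestMarker:
    def _result(self, feature, p, diff=1.0):
        r = sg.test_association("d", feature, np.arange(8.0), np.array([1, 1, 1, 0, 0, 0, 0, 0]))
        r.p_value, r.mean_difference = p, diff
        return r

    def test_lowest_p_wins(self):
        best = select_best_marker([self._result("TP53", 0.03), self._result("MYCN", 0.002)])
        assert best.feature_name == "MYCN"

    def test_tie_breaks_on_effect_size_then_name(self):
        best = select_best_marker(
            [self._result("A", 0.01, diff=0.5), self._result("B", 0.01, diff=-2.0)]
        )
        assert best.feature_name == "B"
        best = select_best_marker(
            [self._result("B", 0.01, diff=1.0), self._result("A", 0.01, diff=1.0)]
        )
        assert best.feature_name == "A"

    def test_non_significant_best_marker_still_returned(self):
        best = select_best_marker([self._result("G", 0.7)])
        assert best is not None and not best.adjusted_significant

    def test_all_untestable_gives_markerless(self):
        r = sg.test_association("d", "g", np.arange(6.0), np.array([1, 0, 0, 0, 0, 0]))
        assert select_best_marker([r]) is None


class TestPredictSingleGene:
    @pytest.fixture()
    def features(self):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            (rng.random((10, 4)) < 0.4).astype(int),
            index=[f"c{i}" for i in range(10)],
            columns=["g1", "g2", "g3", "g4"],
        )

    def test_mutant_predicted_sensitive(self, features):
        marker = MarkerClassifier("d", "g2", 0.01, SENSITISING)
        pred = predict_single_gene(marker, features, list(features.index))
        assert (pred == features["g2"].astype(bool)).all()

    def test_prediction_ignores_other_columns(self, features):
        """Metamorphic: permuting non-marker columns leaves predictions unchanged."""
        marker = MarkerClassifier("d", "g1", 0.01, SENSITISING)
        base = predict_single_gene(marker, features, list(features.index))
        shuffled = features.copy()
        shuffled[["g2", "g3", "g4"]] = features[["g4", "g2", "g3"]].to_numpy()
        assert (predict_single_gene(marker, shuffled, list(features.index)) == base).all()

    def test_direction_unaware_by_default(self, features):
        """A resistance-associated marker still predicts mutants sensitive."""
        marker = MarkerClassifier("d", "g3", 0.01, RESISTANCE)
        pred = predict_single_gene(marker, features, list(features.index))
        assert (pred == features["g3"].astype(bool)).all()
        flipped = predict_single_gene(marker, features, list(features.index), direction_aware=True)
        assert (flipped == ~features["g3"].astype(bool)).all()

    def test_missing_marker_feature_rejected(self, features):
        marker = MarkerClassifier("d", "absent", 0.01, SENSITISING)
        with pytest.raises(KeyError):
            predict_single_gene(marker, features, list(features.index))


def test_associations_recover_planted_driver(small_cohort):
    """On single-driver synthetic drugs the planted gene has the lowest p."""
    r1, r2, truth = small_cohort
    recovered = 0
    singles = [d for d, k in truth.drug_kind.items() if k == "single"]
    for drug in singles:
        resp = r1.responses_for_drug(drug)
        results = associations_for_drug(drug, resp, r1.features.loc[resp.index])
        best = select_best_marker(results)
        recovered += best.feature_name in truth.drivers[drug]
    assert recovered >= 0.8 * len(singles)
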