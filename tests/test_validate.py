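import numpy as np
import pytest

import scdr
from scdr.validate import (
    accuracy_over_drugs,
    compare_methods,
    cross_validate,
    group_drs_comparison,
    min_max_rescale,
    wilcoxon_separation,
    wpci,
)

from conftest import brute_force_cindex, exact_rank_sum_p


class TestWilcoxonSeparation:
    def test_most_extreme_small_case(self):
        # most extreme of the C(6,3) = 20 arrangements: p = 1/20 exactly,
        # which is not strictly below alpha = 0.05
        res = wilcoxon_separation([4, 5, 6], [1, 2, 3])
        assert res.p_value == pytest.approx(1 / 20, abs=1e-12)
        assert not res.accurate

    def test_opposite_tail(self):
        res = wilcoxon_separation([1, 2, 3], [4, 5, 6])
        assert res.p_value >= 0.95
        assert not res.accurate

    @pytest.mark.parametrize("n_r,n_s,seed", [
        (2, 3, 0), (4, 4, 1), (5, 3, 2), (6, 6, 3), (8, 8, 4), (8, 5, 5),
    ])
    def test_agrees_with_exact_enumeration(self, n_r, n_s, seed):
        rng = np.random.default_rng(seed)
        r = rng.normal(0.5, 1, n_r)
        s = rng.normal(0.0, 1, n_s)
        res = wilcoxon_separation(r, s)
        assert res.p_value == pytest.approx(exact_rank_sum_p(r, s), abs=1e-9)

    def test_type_one_calibration_large_n(self):
        rng = np.random.default_rng(6)
        hits = 0
        reps = 1000
        for _ in range(reps):
            r = rng.normal(size=25)
            s = rng.normal(size=25)
            hits += wilcoxon_separation(r, s).accurate
        # binomial 99% band around 0.05 for 1000 reps
        assert 0.05 - 2.58 * np.sqrt(0.05 * 0.95 / reps) <= hits / reps \
            <= 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / reps)

    def test_empty_group_error(self):
        with pytest.raises(ValueError, match="nonempty"):
            wilcoxon_separation([], [1.0])


class TestAccuracy:
    def test_fractions(self):
        def mk(acc):
            return scdr.SeparationResult("d", 3, 3, 1.0, 0.01 if acc else 0.5,
                                         acc, 0.05)

        assert accuracy_over_drugs([mk(True)] * 4) == 1.0
        assert accuracy_over_drugs([mk(False)] * 4) == 0.0
        results = [mk(True)] * 439 + [mk(False)] * 42
        assert accuracy_over_drugs(results) == pytest.approx(439 / 481)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            accuracy_over_drugs([])


class TestMinMaxRescale:
    def test_linear_map(self):
        np.testing.assert_allclose(min_max_rescale([2, 4, 6]), [0, 0.5, 1])

    def test_constant_maps_to_half(self):
        np.testing.assert_allclose(min_max_rescale([3, 3, 3]), [0.5] * 3)

    def test_rank_preserving(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=50)
        out = min_max_rescale(v)
        assert (out >= 0).all() and (out <= 1).all()
        np.testing.assert_array_equal(np.argsort(out), np.argsort(v))


@pytest.fixture(scope="module")
def planted():
    cfg = scdr.SimulationConfig(
        seed=31, n_genes=1000, n_signature_up=100, n_signature_down=100,
        n_resistant=12, n_sensitive=12, n_intermediate=6,
        effect_log2fc=1.0, auc_coupling=1.0,
    )
    expr, responses, truth = scdr.simulate_bulk_cohort(cfg)
    labels = scdr.classify_cell_lines(responses, cfg.drug)
    return expr, labels


class TestCrossValidate:
    def test_planted_signal_high_accuracy(self, planted):
        expr, labels = planted
        report = cross_validate(expr, labels, folds=3, permutations=5,
                                seed=2, n_top=100)
        assert report.n_tests == 15
        assert report.accuracy_fraction >= 0.9

    def test_deterministic(self, planted):
        expr, labels = planted
        a = cross_validate(expr, labels, permutations=2, seed=5, n_top=100)
        b = cross_validate(expr, labels, permutations=2, seed=5, n_top=100)
        assert a.per_test == b.per_test
        assert a.accuracy_fraction == b.accuracy_fraction

    def test_bookkeeping_folds_times_permutations(self, planted):
        expr, labels = planted
        report = cross_validate(expr, labels, folds=3, permutations=4,
                                seed=0, n_top=100)
        assert report.n_tests + report.n_invalid == 3 * 4
        folds_seen = {f for f, _, _ in report.per_test}
        assert folds_seen == {0, 1, 2}

    def test_permuted_labels_control_type_one_error(self, planted):
        """CV on shuffled labels never calls separation above chance.

        Each 4-vs-4 exact rank-sum test has attainable level 2/70 at
        alpha = 0.05, and selection on training folds anti-correlates with
        held-out composition, so the null accuracy must sit at or below the
        binomial upper bound around alpha.
        """
        expr, _ = planted
        rng = np.random.default_rng(13)
        shuffled = rng.permutation(sorted(expr.sample_ids))
        null_labels = scdr.ResponseLabels("null", set(shuffled[:12]),
                                          set(shuffled[12:24]), 0.0, 1.0, 0.8)
        report = cross_validate(expr, null_labels, folds=3, permutations=100,
                                seed=7, n_top=100)
        upper = 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / report.n_tests)
        assert report.accuracy_fraction <= upper

    def test_too_few_lines_error(self, toy):
        labels = scdr.classify_cell_lines(toy["responses"], toy["drug"])
        with pytest.raises(ValueError, match="need >="):
            cross_validate(toy["expr"], labels, folds=3)


class TestWPCI:
    def test_perfect_concordance_and_reversal(self):
        auc = {f"L{i}": float(i) for i in range(10)}
        pred = {f"L{i}": float(i) * 2 + 1 for i in range(10)}
        assert wpci(auc, pred).wpci == 1.0
        rev = {f"L{i}": -float(i) for i in range(10)}
        assert wpci(auc, rev).wpci == 0.0

    def test_unit_weights_equal_classical_cindex(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(5, 51))
            lines = [f"L{i}" for i in range(n)]
            auc = dict(zip(lines, rng.normal(size=n)))
            pred = dict(zip(lines, rng.normal(size=n)))
            got = wpci(auc, pred, unit_weights=True).wpci
            assert got == pytest.approx(brute_force_cindex(auc, pred), abs=1e-12)

    def test_invariant_under_monotone_transform_of_predictions(self):
        rng = np.random.default_rng(10)
        lines = [f"L{i}" for i in range(30)]
        auc = dict(zip(lines, rng.normal(size=30)))
        pred = dict(zip(lines, rng.normal(size=30)))
        base = wpci(auc, pred, noise_sd=0.5).wpci
        for f in (lambda x: 3 * x + 2, np.tanh, lambda x: x**3):
            transformed = {l: float(f(v)) for l, v in pred.items()}
            assert wpci(auc, transformed, noise_sd=0.5).wpci == pytest.approx(base)

    def test_random_predictions_near_half(self):
        rng = np.random.default_rng(12)
        lines = [f"L{i}" for i in range(50)]
        auc = dict(zip(lines, rng.normal(size=50)))
        vals = [
            wpci(auc, dict(zip(lines, rng.normal(size=50)))).wpci
            for _ in range(200)
        ]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.02)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError, match="shared"):
            wpci({"a": 1.0}, {"b": 2.0})
        with pytest.raises(ValueError, match="distinct"):
            wpci({"a": 1.0, "b": 1.0}, {"a": 0.0, "b": 1.0})


class TestCompareMethods:
    def _signal_data(self, seed=13, n_drugs=8, n_lines=20):
        rng = np.random.default_rng(seed)
        truth, a, b = {}, {}, {}
        for d in range(n_drugs):
            lines = [f"L{i}" for i in range(n_lines)]
            auc = rng.normal(size=n_lines)
            truth[f"d{d}"] = dict(zip(lines, auc))
            a[f"d{d}"] = dict(zip(lines, auc + rng.normal(0, 0.3, n_lines)))
            b[f"d{d}"] = {l: -v for l, v in a[f"d{d}"].items()}
        return truth, a, b

    def test_self_comparison(self):
        truth, a, _ = self._signal_data()
        cmp = compare_methods(truth, a, a)
        assert cmp.n_a_higher == 0
        assert cmp.p_value == 1.0

    def test_rank_reversal_loses_everywhere(self):
        truth, a, b = self._signal_data()
        cmp = compare_methods(truth, a, b)
        assert cmp.fraction_a_higher == 1.0
        assert cmp.p_value < 0.05

    def test_drug_mismatch_error(self):
        truth, a, b = self._signal_data()
        del b["d0"]
        with pytest.raises(ValueError, match="cover exactly"):
            compare_methods(truth, a, b)


class TestGroupComparison:
    def _drs(self, rng, shift=0.0, n=20):
        cells = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        scores = np.concatenate([rng.normal(shift, 1, n), rng.normal(0, 1, n)])
        drs = scdr.DRSMatrix(["d1", "d2"], cells,
                             np.vstack([scores, rng.normal(size=2 * n)]),
                             {"d1": 10, "d2": 10})
        grouping = scdr.SampleGrouping(
            {c: ("A" if c.startswith("a") else "B") for c in cells}
        )
        return drs, grouping

    def test_strong_separation(self):
        rng = np.random.default_rng(14)
        cells = [f"a{i}" for i in range(20)] + [f"b{i}" for i in range(20)]
        scores = np.concatenate([np.arange(20) + 100.0, np.arange(20.0)])
        drs = scdr.DRSMatrix(["d"], cells, scores[None, :], {"d": 5})
        grouping = scdr.SampleGrouping(
            {c: ("A" if c.startswith("a") else "B") for c in cells}
        )
        (res,) = group_drs_comparison(drs, grouping, "A", "B")
        assert res.p_value < 1e-6

    def test_minimal_enumeration(self):
        drs = scdr.DRSMatrix(["d"], ["x", "y"], np.array([[1.0, 2.0]]), {"d": 1})
        grouping = scdr.SampleGrouping({"x": "A", "y": "B"})
        (res,) = group_drs_comparison(drs, grouping, "A", "B")
        assert res.p_value == pytest.approx(1.0)  # A < B: upper tail covers all
        (res2,) = group_drs_comparison(drs, grouping, "B", "A")
        assert res2.p_value == pytest.approx(0.5)

    def test_null_rarely_significant(self):
        rng = np.random.default_rng(15)
        hits = 0
        for _ in range(200):
            drs, grouping = self._drs(rng)
            res = group_drs_comparison(drs, grouping, "A", "B")[0]
            hits += res.accurate
        assert hits / 200 < 0.10

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(16)
        drs, grouping = self._drs(rng, shift=2.0)
        raw = group_drs_comparison(drs, grouping, "A", "B")
        adj = group_drs_comparison(drs, grouping, "A", "B", adjust=True)
        for r, a in zip(raw, adj):
            assert a.p_adjusted >= r.p_value - 1e-15

    def test_unknown_group_error(self):
        rng = np.random.default_rng(17)
        drs, grouping = self._drs(rng)
        with pytest.raises(KeyError):
            group_drs_comparison(drs, grouping, "A", "NOPE")
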