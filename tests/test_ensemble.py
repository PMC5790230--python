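"""Ensemble protocol: sampling, splits, thresholds, TSS weighting, deltas."""

import itertools

import numpy as np
import pytest

from cropsuit.ensemble import (
    ConfusionCounts,
    EnsembleConfig,
    EnsembleSuitabilityModel,
    FrequencyMap,
    SuitabilityMap,
    build_frequency_map,
    confusion,
    ensemble_suitability,
    roc_threshold,
    run_plan,
    sample_pseudo_absences,
    split_calibration,
    suitability_delta,
    tss,
)


def brute_force_best_tss(scores, labels):
    """Exhaustive search over *all* thresholds (every score value and
    midpoints, plus below-min/above-max) for the maximal TSS."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    candidates = np.concatenate(
        [scores, 0.5 * (np.sort(scores)[:-1] + np.sort(scores)[1:]),
         [scores.min() - 1, scores.max() + 1]]
    )
    best = -np.inf
    for t in candidates:
        pred = scores >= t
        if pred.all() or (~pred).all():
            continue
        best = max(best, tss(confusion(pred, labels)))
    return best


class TestPseudoAbsences:
    def _cells(self, n, offset=0):
        return np.array([(i + offset, 0) for i in range(n)])

    def test_count_at_prevalence_half(self, rng):
        pa = sample_pseudo_absences(self._cells(500, 100), self._cells(100), 0.5, rng)
        assert len(pa) == 100

    def test_deterministic_given_seed(self):
        bg, pres = self._cells(500, 100), self._cells(100)
        a = sample_pseudo_absences(bg, pres, 0.5, np.random.default_rng(5))
        b = sample_pseudo_absences(bg, pres, 0.5, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_never_coincides_with_presence(self, rng):
        grid_cells = np.array(list(itertools.product(range(20), range(20))))
        for _ in range(100):
            idx = rng.choice(400, size=50, replace=False)
            pres = grid_cells[idx]
            mask = np.ones(400, dtype=bool)
            mask[idx] = False
            pa = sample_pseudo_absences(grid_cells[mask], pres, 0.5, rng)
            assert not {tuple(c) for c in pa} & {tuple(c) for c in pres}

    def test_insufficient_background_signals(self, rng):
        with pytest.raises(ValueError, match="insufficient background"):
            sample_pseudo_absences(self._cells(10, 100), self._cells(100), 0.5, rng)

    def test_presence_in_background_rejected(self, rng):
        with pytest.raises(ValueError, match="exclude presence"):
            sample_pseudo_absences(self._cells(100), self._cells(10), 0.5, rng)


class TestSplitCalibration:
    def test_75_25_counts(self, rng):
        labels = np.repeat([1, 0], 100)
        cal, ev = split_calibration(labels, 0.75, rng)
        assert len(cal) == 150 and len(ev) == 50
        assert labels[cal].sum() == 75 and labels[ev].sum() == 25

    def test_disjoint_and_exhaustive(self, rng):
        labels = np.repeat([1, 0], [37, 61])
        cal, ev = split_calibration(labels, 0.75, rng)
        assert set(cal) | set(ev) == set(range(98))
        assert not set(cal) & set(ev)

    def test_stratified_prevalence(self, rng):
        for _ in range(20):
            n1, n0 = rng.integers(10, 200, 2)
            labels = np.repeat([1, 0], [n1, n0])
            cal, ev = split_calibration(labels, 0.75, rng)
            overall = n1 / (n1 + n0)
            ev_prev = labels[ev].mean()
            # stratification keeps evaluation prevalence within rounding
            assert abs(ev_prev - overall) <= 1.5 / len(ev)

    def test_tiny_class_signals(self, rng):
        with pytest.raises(ValueError, match="cannot split"):
            split_calibration(np.array([1, 0, 0]), 0.75, rng)


class TestRocThreshold:
    def test_separable_case_midpoint(self):
        scores = np.array([0.9, 0.8, 0.7, 0.4, 0.3, 0.2])
        labels = np.array([1, 1, 1, 0, 0, 0])
        t = roc_threshold(scores, labels)
        assert t == pytest.approx(0.55)
        assert tss(confusion(scores >= t, labels == 1)) == 1.0

    def test_matches_exhaustive_search(self, rng):
        for _ in range(50):
            scores = rng.random(15)
            labels = rng.integers(0, 2, 15)
            if labels.min() == labels.max():
                continue
            t = roc_threshold(scores, labels)
            achieved = tss(confusion(scores >= t, labels == 1))
            assert achieved == pytest.approx(brute_force_best_tss(scores, labels))

    def test_monotone_transform_same_partition(self, rng):
        scores = rng.random(20)
        labels = rng.integers(0, 2, 20)
        t1 = roc_threshold(scores, labels)
        t2 = roc_threshold(scores**3, labels)
        np.testing.assert_array_equal(scores >= t1, scores**3 >= t2)

    def test_degenerate_scores_signal(self):
        with pytest.raises(ValueError, match="degenerate"):
            roc_threshold(np.ones(6), np.array([1, 1, 1, 0, 0, 0]))


class TestTss:
    def test_perfect_prediction(self):
        assert tss(ConfusionCounts(tp=5, fn=0, fp=0, tn=5)) == 1.0

    def test_closed_form(self):
        # sensitivity 0.9, specificity 0.8
        assert tss(ConfusionCounts(tp=9, fn=1, fp=2, tn=8)) == pytest.approx(0.7)

    def test_chance_level_zero(self):
        # tp/(tp+fn) = fp/(fp+tn) = 0.5
        assert tss(ConfusionCounts(tp=5, fn=5, fp=10, tn=10)) == pytest.approx(0.0)

    def test_empty_class_signals(self):
        with pytest.raises(ValueError, match="empty"):
            tss(ConfusionCounts(tp=0, fn=0, fp=1, tn=1))


class TestFrequencyAndConsensus:
    def test_vote_fractions(self):
        preds = [np.array([[1.0, 0.0]]) for _ in range(25)] + [
            np.array([[0.0, 0.0]]) for _ in range(25)
        ]
        fm = build_frequency_map("m", "c", preds, [0.5] * 50)
        assert fm.frequency[0, 0] == pytest.approx(0.5)
        assert fm.frequency[0, 1] == 0.0

    def test_frequencies_are_multiples_of_inverse_replicates(self, rng):
        n_rep = 7
        preds = [rng.integers(0, 2, (5, 5)).astype(float) for _ in range(n_rep)]
        fm = build_frequency_map("m", "c", preds, [0.4] * n_rep)
        np.testing.assert_allclose(
            np.round(fm.frequency * n_rep), fm.frequency * n_rep, atol=1e-12
        )

    def test_grid_mismatch_signals(self):
        with pytest.raises(ValueError, match="incompatible"):
            build_frequency_map("m", "c", [np.zeros((2, 2)), np.zeros((3, 3))], [0.5, 0.5])

    def test_weighted_consensus_examples(self):
        a = FrequencyMap("m1", "c", np.array([[0.2]]), 10, mean_tss=0.5)
        b = FrequencyMap("m2", "c", np.array([[0.8]]), 10, mean_tss=0.5)
        assert ensemble_suitability([a, b]).values[0, 0] == pytest.approx(0.5)
        b_zero = FrequencyMap("m2", "c", np.array([[0.8]]), 10, mean_tss=-0.1)
        assert ensemble_suitability([a, b_zero]).values[0, 0] == pytest.approx(0.2)

    def test_consensus_bounded_by_inputs(self, rng):
        maps = [
            FrequencyMap(f"m{i}", "c", rng.random((6, 6)), 10, mean_tss=rng.random())
            for i in range(4)
        ]
        cons = ensemble_suitability(maps).values
        stack = np.array([m.frequency for m in maps])
        assert np.all(cons >= stack.min(axis=0) - 1e-12)
        assert np.all(cons <= stack.max(axis=0) + 1e-12)

    def test_all_weights_zero_signals(self):
        m = FrequencyMap("m", "c", np.zeros((2, 2)), 10, mean_tss=-0.2)
        with pytest.raises(ValueError, match="no skilful"):
            ensemble_suitability([m])


class TestSuitabilityDelta:
    def test_identical_maps_no_loss(self):
        m = SuitabilityMap(values=np.full((3, 3), 0.4))
        delta, summary = suitability_delta(m, m)
        assert np.all(delta == 0)
        assert summary["fraction_losing"] == 0.0

    def test_uniform_loss(self):
        cur = SuitabilityMap(values=np.full((3, 3), 0.5))
        fut = SuitabilityMap(values=np.full((3, 3), 0.4))
        _, summary = suitability_delta(cur, fut)
        assert summary["fraction_losing"] == 1.0

    def test_constructed_loss_fraction(self):
        values = np.full((10, 10), 0.5)
        fut = values.copy()
        fut.ravel()[:72] -= 0.1
        _, summary = suitability_delta(SuitabilityMap(values=values), SuitabilityMap(values=fut))
        assert summary["fraction_losing"] == pytest.approx(0.72)


class TestProtocolBookkeeping:
    def test_run_plan_counts(self):
        config = EnsembleConfig(n_replicates=3, methods=("a", "b"))
        plan = run_plan(config, ["c1", "c2"])
        assert len(plan) == 3 * 2 * 2
        assert len(set(plan)) == len(plan)

    def test_end_to_end_on_landscape(self, landscape):
        model = EnsembleSuitabilityModel(
            methods=("bioclim", "euclidean"), n_replicates=5, random_state=11
        ).fit(
            landscape.presence_cells,
            landscape.current_env,
            {"fut": landscape.future_env},
        )
        # one frequency map per (method, scenario); consensus in [0, 1]
        assert len(model.frequency_maps_) == 2 * 2
        vals = model.suitability_current_.values
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 1
        # reproducible from the master seed
        again = EnsembleSuitabilityModel(
            methods=("bioclim", "euclidean"), n_replicates=5, random_state=11
        ).fit(
            landscape.presence_cells,
            landscape.current_env,
            {"fut": landscape.future_env},
        )
        np.testing.assert_array_equal(vals, again.suitability_current_.values)

    def test_single_map_consensus_equals_map(self, landscape):
        model = EnsembleSuitabilityModel(
            methods=("euclidean",), n_replicates=4, random_state=2
        ).fit(landscape.presence_cells, landscape.current_env)
        (fm,) = model.frequency_maps_
        np.testing.assert_array_equal(model.suitability_current_.values, fm.frequency)
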