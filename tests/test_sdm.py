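"""Ensemble SDM machinery: splits, TSS, member selection, ensembling,
binarization and per-period range statistics."""

import numpy as np
import pytest

from rangerecon.sdm import (EnsembleSDM, FitRecord, SDMSettings,
                            TechniqueSpec, binarize, ensemble_predict, evaluate_tss,
                            fit_technique, max_tss, range_stats, run_period,
                            select_members, split_evaluation, tss_curve)


def brute_force_max_tss(scores, y):
    """Enumerate every cut-point between sorted scores (plus the extremes)
    and return the maximum TSS."""
    y = np.asarray(y, dtype=bool)
    cuts = np.concatenate([[-np.inf], np.sort(scores), [np.inf]])
    best = -np.inf
    for c in cuts:
        pred = scores > c
        sens = pred[y].mean()
        spec = (~pred[~y]).mean()
        best = max(best, sens + spec - 1)
    return best


class TestSplitEvaluation:
    def test_partition_and_counts(self, rng):
        Xp = rng.normal(size=(100, 3))
        Xa = rng.normal(size=(50, 3))
        (Xtr, ytr), (Xte, yte) = split_evaluation(Xp, Xa, run_index=1, seed=0)
        assert int(ytr.sum()) == 80 and int(yte.sum()) == 20
        assert len(ytr) + len(yte) == 150
        joined = np.vstack([Xtr, Xte])
        assert len(np.unique(joined, axis=0)) == 150  # disjoint, union = input

    def test_deterministic_per_run_index(self, rng):
        Xp, Xa = rng.normal(size=(40, 2)), rng.normal(size=(30, 2))
        a = split_evaluation(Xp, Xa, 3, seed=9)
        b = split_evaluation(Xp, Xa, 3, seed=9)
        np.testing.assert_array_equal(a[0][0], b[0][0])
        c = split_evaluation(Xp, Xa, 4, seed=9)
        assert not np.array_equal(a[0][0], c[0][0])

    def test_too_few_presences_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 10"):
            split_evaluation(rng.normal(size=(5, 2)), rng.normal(size=(50, 2)), 1, 0)


class TestTechniques:
    def test_separable_data_perfect_accuracy(self, rng):
        X = np.vstack([rng.normal(5, 0.3, size=(50, 2)), rng.normal(-5, 0.3, size=(50, 2))])
        y = np.concatenate([np.ones(50), np.zeros(50)])
        model = fit_technique(TechniqueSpec("regularized-logistic"), X, y)
        assert np.all((model.predict_proba(X)[:, 1] > 0.5) == y)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        with pytest.raises(ValueError, match="both classes"):
            fit_technique(TechniqueSpec("regularized-logistic"), X, np.ones(20))

    def test_unknown_technique_rejected(self):
        with pytest.raises(ValueError, match="unknown technique"):
            TechniqueSpec("kriging")

    def test_pure_noise_labels_give_near_zero_tss(self):
        """Null simulation: labels independent of features."""
        tss_vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(2000, 3))
            y = rng.integers(0, 2, size=2000).astype(float)
            model = fit_technique(TechniqueSpec("regularized-logistic"),
                                  X[:1600], y[:1600])
            tss, _ = evaluate_tss(model, X[1600:], y[1600:])
            tss_vals.append(tss)
        assert abs(np.mean(tss_vals)) < 0.15


class TestTSS:
    def test_worked_six_point_example(self):
        """Presence scores (0.9, 0.8, 0.6), absence (0.7, 0.3, 0.1): at
        threshold 0.5 sens=1, spec=2/3, TSS=2/3 — also the grid maximum,
        agreeing with brute-force cut-point enumeration."""
        scores = np.array([0.9, 0.8, 0.6, 0.7, 0.3, 0.1])
        y = np.array([1, 1, 1, 0, 0, 0])
        curve = tss_curve(scores, y)
        assert curve[50] == pytest.approx(2 / 3)  # threshold 0.50
        tss, thr = max_tss(scores, y)
        assert tss == pytest.approx(2 / 3)
        assert tss == pytest.approx(brute_force_max_tss(scores, y))
        assert thr == pytest.approx(0.30)  # lowest threshold attaining the max

    def test_perfect_ranking_gives_one(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([1, 1, 0, 0])
        tss, _ = max_tss(scores, y)
        assert tss == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_grid_matches_bruteforce_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 40)
        # scores on the grid resolution so the 0.01 grid can realise every cut
        scores = rng.integers(0, 101, size=n) / 100.0
        y = np.concatenate([[0, 1], rng.integers(0, 2, size=n - 2)])
        tss, _ = max_tss(scores, y)
        assert tss == pytest.approx(brute_force_max_tss(scores, y))
        assert -1.0 - 1e-12 <= tss <= 1.0 + 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            tss_curve(np.array([0.1, 0.9]), np.array([1, 1]))


class TestMemberSelection:
    def _fits(self, tss_values):
        return [FitRecord("t", i, t, 0.5, None) for i, t in enumerate(tss_values)]

    def test_mean_threshold_arithmetic(self):
        members, mean = select_members(self._fits([0.2, 0.4, 0.6, 0.8]))
        assert mean == pytest.approx(0.5)
        assert sorted(m.tss for m in members) == [0.6, 0.8]

    def test_all_equal_all_retained(self):
        members, _ = select_members(self._fits([0.5] * 6))
        assert len(members) == 6

    def test_uniform_tss_retains_about_half(self, rng):
        fracs = []
        for _ in range(50):
            members, _ = select_members(self._fits(rng.uniform(0, 1, size=80)))
            fracs.append(len(members) / 80)
        assert abs(np.mean(fracs) - 0.5) < 0.05


class _ConstModel:
    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        p = np.full(len(X), self.p)
        return np.column_stack([1 - p, p])


def _manual_ensemble(probs, tss, weighted=False):
    ens = EnsembleSDM.__new__(EnsembleSDM)
    ens.weighted = weighted
    ens.members_ = [FitRecord("t", i, t, 0.5, _ConstModel(p))
                    for i, (p, t) in enumerate(zip(probs, tss))]
    return ens


class TestEnsemblePrediction:
    def test_single_member_identity(self, small_scenario):
        ens = _manual_ensemble([0.37], [0.5])
        grid = ens._ensemble_scores(np.zeros((5, 2)))
        np.testing.assert_allclose(grid, 0.37)

    def test_unweighted_mean(self):
        ens = _manual_ensemble([0.2, 0.8], [0.5, 0.5])
        np.testing.assert_allclose(ens._ensemble_scores(np.zeros((3, 1))), 0.5)

    def test_tss_weighted_mean(self):
        ens = _manual_ensemble([0.2, 0.8], [1.0, 3.0], weighted=True)
        np.testing.assert_allclose(ens._ensemble_scores(np.zeros((3, 1))), 0.65)

    def test_ensemble_within_member_envelope(self, rng):
        probs = rng.uniform(0, 1, size=5)
        ens = _manual_ensemble(probs, rng.uniform(0, 1, size=5))
        s = ens._ensemble_scores(np.zeros((2, 1)))
        assert probs.min() - 1e-12 <= s[0] <= probs.max() + 1e-12

    def test_missing_layer_named_in_error(self, small_scenario):
        ens = _manual_ensemble([0.5], [0.5])
        with pytest.raises(KeyError, match="snow_depth"):
            ensemble_predict(ens, small_scenario.stacks[0], ["MAT", "snow_depth"])


class TestBinarize:
    def test_all_above_threshold_present(self):
        assert binarize(np.ones((2, 2)), 0.5).all()

    def test_equal_to_cutoff_is_absent(self):
        """'Present' requires strictly above the cut-off P."""
        p = np.array([[0.5, 0.51], [0.49, 0.5]])
        out = binarize(p, 0.5)
        assert out.tolist() == [[False, True], [False, False]]

    def test_range_monotone_in_cutoff(self, rng):
        prob = rng.uniform(0, 1, size=(20, 20))
        areas = [binarize(prob, c).sum() for c in np.linspace(0, 1, 21)]
        assert all(b <= a for a, b in zip(areas, areas[1:]))


class TestRangeStats:
    def test_area_arithmetic(self):
        binary = np.zeros((4, 4), dtype=bool)
        binary[0, :5 % 4] = True
        binary[1, :2] = True  # 5 presence cells total: 3 + 2
        binary[0, 2] = True
        elev = np.full((4, 4), 100.0)
        area, _ = range_stats(binary, elev, cell_area_km2=1.0)
        assert area == binary.sum() * 1.0

    def test_mean_elevation_over_presences(self):
        binary = np.array([[True, True], [False, False]])
        elev = np.array([[600.0, 800.0], [0.0, 0.0]])
        area, me = range_stats(binary, elev, 1.0)
        assert me == pytest.approx(700.0)

    def test_empty_range_elevation_missing(self):
        area, me = range_stats(np.zeros((2, 2), bool), np.ones((2, 2)), 1.0)
        assert area == 0 and me is None

    def test_full_grid_conserves_study_area(self, small_config):
        spec = small_config.grid
        binary = np.ones(spec.shape, dtype=bool)
        area, _ = range_stats(binary, np.ones(spec.shape), spec.cell_area_km2)
        assert area == pytest.approx(spec.total_area_km2)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="co-registered"):
            range_stats(np.zeros((2, 2), bool), np.zeros((3, 3)), 1.0)


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(2, 1, size=(80, 3)), rng.normal(-2, 1, size=(200, 3))])
    y = np.concatenate([np.ones(80), np.zeros(200)])
    return X, y


@pytest.fixture(scope="module")
def period_inputs(small_scenario):
    from rangerecon.pipeline import RunSettings, prepare_period
    settings = RunSettings.fast()
    th, pa, sel = prepare_period(small_scenario, 0, settings, seed=7)
    return small_scenario, th, pa, sel


class TestEnsembleSDMEstimator:
    def test_fit_selects_members_and_cutoff(self, toy):
        X, y = toy
        ens = EnsembleSDM(techniques=("regularized-logistic",), n_runs=4,
                          random_state=0).fit(X, y)
        assert len(ens.fits_) == 4
        assert all(m.tss >= ens.tss_mean_ for m in ens.members_)
        assert 0.0 <= ens.cutoff_ <= 1.0
        assert ens.tss_consensus_ > 0.8  # well-separated classes

    def test_predictions_probabilistic(self, toy):
        X, y = toy
        ens = EnsembleSDM(techniques=("regularized-logistic",), n_runs=3,
                          random_state=0).fit(X, y)
        p = ens.predict_proba(X)
        assert p.shape == (len(X), 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)
        assert set(np.unique(ens.predict(X))) <= {0.0, 1.0}

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        ens = EnsembleSDM(n_runs=2)
        assert clone(ens).n_runs == 2


class TestRunPeriod:
    def test_single_repetition_reduces_to_plain_ensemble(self, period_inputs):
        sc, th, pa, sel = period_inputs
        settings = SDMSettings(techniques=("regularized-logistic",),
                               n_runs=2, n_repetitions=1)
        res = run_period(th, pa, sc.stacks[0], sel, settings=settings, seed=1)
        # K = 1: consensus binary == that single ensemble's binarization
        np.testing.assert_array_equal(
            res.binary, binarize(res.probability, res.cutoff) & sc.stacks[0].mask)

    def test_fit_record_bookkeeping(self, period_inputs):
        sc, th, pa, sel = period_inputs
        settings = SDMSettings(techniques=("regularized-logistic", "spline-logistic"),
                               n_runs=3, n_repetitions=2)
        res = run_period(th, pa, sc.stacks[0], sel, settings=settings, seed=1)
        assert len(res.fit_records) == 2 * 3 * 2  # techniques x runs x repetitions

    def test_probability_within_unit_interval(self, period_inputs):
        sc, th, pa, sel = period_inputs
        settings = SDMSettings(techniques=("regularized-logistic",),
                               n_runs=2, n_repetitions=1)
        res = run_period(th, pa, sc.stacks[0], sel, settings=settings, seed=2)
        vals = res.probability[np.isfinite(res.probability)]
        assert vals.min() >= 0 and vals.max() <= 1
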