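import numpy as np
import pytest
from scipy.stats import norm

from maxratio import (
    CutoffCandidates,
    CutoffModel,
    DegenerateDataError,
    LabelledResult,
    MaxRatioResult,
    TrainingError,
    classify,
    derive_cutoff_candidates,
    fit_em_mixture,
    load_model,
    save_model,
    select_cutoff,
    split_train_query,
    train_cutoff_model,
)


def lr(mr, fcn, label):
    return LabelledResult(MaxRatioResult(mr=mr, fcn=fcn, discrete_argmax=0), label)


class TestSplit:
    def test_published_split_sizes(self):
        data = list(range(15744))
        training, query = split_train_query(data, fraction=1920 / 15744, seed=1)
        assert len(training) == 1920
        assert len(query) == 13824

    def test_deterministic_for_fixed_seed(self):
        data = list(range(1000))
        a = split_train_query(data, 0.25, seed=7)
        b = split_train_query(data, 0.25, seed=7)
        assert a == b
        c = split_train_query(data, 0.25, seed=8)
        assert c != a

    def test_disjoint_exhaustive(self):
        data = list(range(10))
        training, query = split_train_query(data, 0.5, seed=3)
        assert len(training) == 5 and len(query) == 5
        assert sorted(training + query) == data
        assert not set(training) & set(query)

    def test_degenerate_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_train_query(list(range(10)), 0.001, seed=0)
        with pytest.raises(ValueError):
            split_train_query([], 0.5, seed=0)


class TestEmMixture:
    def test_recovers_bimodal_means(self):
        rng = np.random.default_rng(11)
        values = np.concatenate(
            [rng.normal(0.01, 0.003, 500), rng.normal(0.30, 0.05, 500)]
        )
        fit = fit_em_mixture(values)
        assert fit.converged
        assert abs(fit.means[0] - 0.01) < 0.005
        assert abs(fit.means[1] - 0.30) < 0.005

    def test_mean_recovery_over_20_replicates(self):
        """Mean absolute error of recovered means < 0.01 across seeds."""
        errors = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            values = np.concatenate(
                [rng.normal(0.01, 0.003, 500), rng.normal(0.30, 0.05, 500)]
            )
            fit = fit_em_mixture(values)
            errors.append(abs(fit.means[0] - 0.01))
            errors.append(abs(fit.means[1] - 0.30))
        assert np.mean(errors) < 0.01

    def test_tight_separated_clusters(self):
        rng = np.random.default_rng(2)
        values = np.concatenate(
            [rng.normal(0, 1e-6, 50), rng.normal(1, 1e-6, 50)]
        )
        fit = fit_em_mixture(values)
        assert fit.means[0] == pytest.approx(0, abs=1e-5)
        assert fit.means[1] == pytest.approx(1, abs=1e-5)
        assert fit.weights[0] == pytest.approx(0.5, abs=0.01)

    def test_degenerate_data_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_em_mixture([0.5] * 50)

    def test_weights_sum_to_one_and_means_ordered(self):
        rng = np.random.default_rng(3)
        fit = fit_em_mixture(rng.normal(0.1, 0.05, 200))
        assert fit.weights[0] + fit.weights[1] == pytest.approx(1, abs=1e-9)
        assert fit.means[0] <= fit.means[1]

    def test_agrees_with_sklearn_gaussian_mixture(self):
        """Independent EM implementation recovers the same components."""
        sklearn_mixture = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(5)
        values = np.concatenate(
            [rng.normal(0.02, 0.01, 400), rng.normal(0.25, 0.06, 300)]
        )
        fit = fit_em_mixture(values)
        gm = sklearn_mixture.GaussianMixture(2, random_state=0, n_init=3).fit(
            values.reshape(-1, 1)
        )
        ref_means = np.sort(gm.means_.ravel())
        assert fit.means[0] == pytest.approx(ref_means[0], abs=0.003)
        assert fit.means[1] == pytest.approx(ref_means[1], abs=0.003)


class TestCandidates:
    def test_forced_arithmetic(self):
        from maxratio.cutoffs import MixtureFit

        fit = MixtureFit((0.0, 1.0), (0.1, 0.1), (0.5, 0.5), 0.0, 1, True)
        cand = derive_cutoff_candidates(fit, z=3)
        assert cand.lower == pytest.approx(0.3)
        assert cand.mid == pytest.approx(0.5)
        assert cand.upper == pytest.approx(0.7)

    def test_published_midpoint_rounding(self):
        from maxratio import round_half_up

        cand = CutoffCandidates(lower=0.018, upper=0.035)
        assert round_half_up(cand.mid, 3) == 0.027

    def test_overlap_collapses_to_posterior_crossing(self):
        from maxratio.cutoffs import MixtureFit

        fit = MixtureFit((0.0, 0.3), (0.2, 0.2), (0.5, 0.5), 0.0, 1, True)
        cand = derive_cutoff_candidates(fit, z=3)
        assert cand.lower == cand.upper == cand.mid
        # dense-scan oracle over posterior probabilities
        grid = np.linspace(0.0, 0.3, 200001)
        post = 0.5 * norm.pdf(grid, 0.0, 0.2) - 0.5 * norm.pdf(grid, 0.3, 0.2)
        crossing = grid[np.argmin(np.abs(post))]
        assert cand.mid == pytest.approx(crossing, abs=1e-5)

    def test_unordered_means_rejected(self):
        from maxratio.cutoffs import MixtureFit

        fit = MixtureFit((0.5, 0.5), (0.1, 0.1), (0.5, 0.5), 0.0, 1, True)
        with pytest.raises(ValueError):
            derive_cutoff_candidates(fit)


class TestSelectCutoff:
    TRAINING = (
        [lr(0.01, 30, 0) for _ in range(20)]
        + [lr(0.25, 25, 1) for _ in range(20)]
        + [lr(0.45, 22, 1)]
    )

    def test_choose_error_minimizer(self):
        # lower (0.005) lets every negative through as FP; upper (0.30)
        # loses the positives; mid (0.1525) is clean
        cand = CutoffCandidates(lower=0.005, upper=0.30)
        assert select_cutoff(cand, self.TRAINING, watershed=20) == "mid"

    def test_tie_prefers_mid_then_lower(self):
        cand = CutoffCandidates(lower=0.05, upper=0.2)  # all give 0 errors
        assert select_cutoff(cand, self.TRAINING, watershed=20) == "mid"
        # degenerate candidates: identical values, still mid by tie rule
        cand = CutoffCandidates(lower=0.1, upper=0.1)
        assert select_cutoff(cand, self.TRAINING, watershed=20) == "mid"

    def test_empty_late_region_rejected(self):
        cand = CutoffCandidates(lower=0.1, upper=0.2)
        with pytest.raises(TrainingError):
            select_cutoff(cand, self.TRAINING, watershed=100)


def small_training_set():
    """Training set with the published geometry: watershed 9.47, early
    maximum MR 0.045, bimodal late MR populations."""
    rng = np.random.default_rng(17)
    data = [lr(0.045, 5.0, 0), lr(0.02, 3.0, 0), lr(0.01, 7.5, 0)]
    data += [lr(float(m), float(f), 1)
             for m, f in zip(rng.normal(0.25, 0.04, 30), rng.uniform(9.47, 40, 30))]
    data[3] = lr(0.25, 9.47, 1)  # pin the lowest positive FCN
    data += [lr(float(abs(m)), float(f), 0)
             for m, f in zip(rng.normal(0.01, 0.003, 30), rng.uniform(10, 44, 30))]
    return data


class TestTrainModel:
    def test_published_early_cutoff_arithmetic(self):
        from maxratio import round_half_up

        model = train_cutoff_model(small_training_set(), multiplier=1.5)
        assert model.fcn_watershed == 9.47
        assert model.early_cutoff == pytest.approx(1.5 * 0.045)
        assert round_half_up(model.early_cutoff, 3) == 0.068

    def test_identity_multiplier(self):
        model = train_cutoff_model(small_training_set(), multiplier=1.0)
        assert model.early_cutoff == pytest.approx(0.045)

    def test_no_positives_rejected(self):
        with pytest.raises(TrainingError):
            train_cutoff_model([lr(0.01, 30, 0)] * 20)

    def test_no_early_region_defaults_to_late_cutoff(self):
        data = [r for r in small_training_set() if r.result.fcn >= 9.47]
        model = train_cutoff_model(data)
        assert model.early_cutoff == model.late_cutoff

    def test_late_cutoff_separates_generated_populations(self):
        model = train_cutoff_model(small_training_set())
        late = [r for r in small_training_set() if r.result.fcn >= 9.47]
        errors = sum(
            1 for r in late
            if (r.result.mr >= model.late_cutoff) != bool(r.label)
        )
        assert errors / len(late) <= 0.01

    def test_round_trip_serialization(self, tmp_path):
        model = train_cutoff_model(small_training_set())
        path = tmp_path / "model.txt"
        save_model(model, path)
        back = load_model(path)
        assert back == model


class TestClassify:
    MODEL = CutoffModel(
        fcn_watershed=9.47,
        early_cutoff=0.068,
        late_cutoff=0.027,
        multiplier=1.5,
        z=3.0,
        candidates=CutoffCandidates(lower=0.018, upper=0.035),
        selection="mid",
    )

    @pytest.mark.parametrize(
        "mr, fcn, expected",
        [
            (0.117, 9.45, 1),   # the sole early positive of the query set
            (0.020, 33.82, 0),  # weak MR below the late cutoff
            (0.027, 33.82, 1),  # boundary inclusive
            (0.068, 5.00, 1),   # boundary inclusive, early region
            (0.0679, 5.00, 0),
            (0.027, 9.47, 1),   # FCN exactly at the watershed -> late cutoff
        ],
    )
    def test_rule_applications(self, mr, fcn, expected):
        result = MaxRatioResult(mr=mr, fcn=fcn, discrete_argmax=0)
        assert classify(result, self.MODEL) == expected

    def test_raising_cutoffs_is_monotone(self):
        rng = np.random.default_rng(23)
        points = [
            MaxRatioResult(float(m), float(f), 0)
            for m, f in zip(rng.uniform(0, 0.2, 200), rng.uniform(2, 45, 200))
        ]
        base_calls = [classify(p, self.MODEL) for p in points]
        import dataclasses

        for early, late in [(0.1, 0.027), (0.068, 0.05), (0.2, 0.1)]:
            raised = dataclasses.replace(
                self.MODEL, early_cutoff=early, late_cutoff=late
            )
            for p, base in zip(points, base_calls):
                if base == 0:
                    assert classify(p, raised) == 0


class TestEndToEnd:
    def test_synthetic_train_classify_accuracy(
        self, training_labelled, query_labelled
    ):
        """Train on one seeded plate, classify another: accuracy >= 0.99."""
        model = train_cutoff_model(training_labelled)
        correct = [
            classify(r.result, model) == r.label for r in query_labelled
        ]
        assert np.mean(correct) >= 0.99
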