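import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cfaphys.core import InvalidInputError
from cfaphys.decoder import (
    CLASSES,
    _nll_and_grad,
    build_training_set,
    cross_validate_lambda,
    fit_multinomial_l1,
    lambda_grid,
    one_second_count_stats,
    peak_indices,
    reactivation_rate,
    sliding_posteriors,
    sliding_window_starts,
)


@pytest.fixture(scope="module")
def toy_separable(scope="module"):
    rng = np.random.default_rng(0)
    centers = {"flavour": [4, 0], "water": [0, 4], "baseline": [-4, -4]}
    X, y = [], []
    for cls, c in centers.items():
        X.append(rng.normal(c, 0.3, (20, 2)))
        y += [cls] * 20
    return np.vstack(X), np.array(y, dtype=object)


class TestTrainingSet:
    def test_default_session_counts(self, planted_session):
        X, y, stats = build_training_set(
            planted_session["spikes"], planted_session["events"]
        )
        assert np.sum(y == "flavour") == 30
        assert np.sum(y == "water") == 30
        assert np.sum(y == "baseline") == 60
        assert X.shape == (120, 300)
        assert stats.provenance["scale"].startswith("s.d. of 1-s counts")

    def test_constant_rate_population_gives_null_features(self):
        from cfaphys.simulate import SimConfig, simulate_population, simulate_task_events

        cfg = SimConfig(seed=13, n_neurons=20, frac_flavour=0.0, frac_water=0.0,
                        malaise_mode="none")
        ev = simulate_task_events(cfg)
        spikes, _ = simulate_population(cfg, ev, t_stop=ev.epochs["consumption"].end + 2)
        X, y, _ = build_training_set(spikes, ev, min_population=0)
        for cls in CLASSES:
            for other in CLASSES:
                d = X[y == cls].mean(0) - X[y == other].mean(0)
                assert np.abs(d).max() < 1.0  # no class separation beyond noise

    def test_two_neuron_fixture_exact_features(self):
        from cfaphys.core import Epoch, EventLog

        # neuron 0 spikes once per second; neuron 1 fires a burst after the reward
        spikes = [np.arange(0.5, 40.0, 1.0), np.array([20.1, 20.2, 20.3])]
        ev = EventLog(
            cue_times=[18.0], cue_ports=["flavour"], reward_times=[20.0],
            reward_ports=["flavour"], entry_times=[20.0], entry_ports=["flavour"],
            stim_bouts=np.empty((0, 2)),
            epochs={"consumption": Epoch("consumption", 0.0, 40.0),
                    "delay": Epoch("delay", 40.0, 50.0)},
        )
        with pytest.raises(InvalidInputError):
            build_training_set(spikes, ev, min_population=0)  # no water delivery
        ev.reward_ports = np.array(["flavour"], dtype=object)
        ev.cue_times = np.array([18.0, 30.0])
        ev.cue_ports = np.array(["flavour", "water"], dtype=object)
        ev.reward_times = np.array([20.0, 31.0])
        ev.reward_ports = np.array(["flavour", "water"], dtype=object)
        X, y, stats = build_training_set(spikes, ev, min_population=0)
        # neuron 0: every 1-s window holds exactly 1 spike -> sd 0 -> feature 0
        assert np.all(X[:, 0] == 0.0)
        # neuron 1: counts tiled over [0, 40) are 37 zeros and one 3 ->
        # mean 3/40, sd sqrt(3^2/40 - (3/40)^2); pre-cue windows hold 0 spikes
        mu, sd = 3 / 40, np.sqrt(9 / 40 - (3 / 40) ** 2)
        assert stats.mean[1] == pytest.approx(0.0)  # pre-cue mean count
        expected_flavour = (3 - 0.0) / sd
        assert X[y == "flavour", 1][0] == pytest.approx(expected_flavour)
        assert X[y == "water", 1][0] == pytest.approx(0.0)

    def test_population_gate(self, planted_session):
        with pytest.raises(InvalidInputError):
            build_training_set(planted_session["spikes"][:40], planted_session["events"])


class TestFit:
    def test_separable_toy_reaches_perfect_accuracy(self, toy_separable):
        X, y = toy_separable
        model = fit_multinomial_l1(X, y, lam=1e-6)
        pred = model.posteriors(X).argmax(axis=1)
        truth = np.array([model.classes.index(c) for c in y])
        assert (pred == truth).mean() == 1.0

    def test_huge_penalty_zeroes_weights_and_leaves_priors(self, toy_separable):
        X, y = toy_separable
        model = fit_multinomial_l1(X, y, lam=1e6)
        assert np.abs(model.weights).max() < 1e-8
        P = model.posteriors(X)
        freqs = np.array([np.mean(y == c) for c in model.classes])
        assert np.allclose(P, freqs, atol=1e-3)

    def test_gradient_matches_central_differences(self, rng):
        X = rng.normal(size=(12, 5))
        Y = np.zeros((12, 3))
        Y[np.arange(12), rng.integers(0, 3, 12)] = 1.0
        W = rng.normal(size=(3, 5)) * 0.5
        b = rng.normal(size=3) * 0.5
        _, gW, gb = _nll_and_grad(W, b, X, Y)
        eps = 1e-6
        for idx in [(0, 0), (1, 3), (2, 4)]:
            Wp, Wm = W.copy(), W.copy()
            Wp[idx] += eps
            Wm[idx] -= eps
            fp = _nll_and_grad(Wp, b, X, Y)[0]
            fm = _nll_and_grad(Wm, b, X, Y)[0]
            assert gW[idx] == pytest.approx((fp - fm) / (2 * eps), abs=1e-6)
        for k in range(3):
            bp, bm = b.copy(), b.copy()
            bp[k] += eps
            bm[k] -= eps
            fp = _nll_and_grad(W, bp, X, Y)[0]
            fm = _nll_and_grad(W, bm, X, Y)[0]
            assert gb[k] == pytest.approx((fp - fm) / (2 * eps), abs=1e-6)

    def test_objective_trace_monotone(self, toy_separable):
        X, y = toy_separable
        model = fit_multinomial_l1(X, y, lam=1.0)
        assert np.all(np.diff(model.objective_trace) <= 1e-9)
        assert model.converged

    def test_weight_mass_nonincreasing_in_lambda(self, toy_separable):
        X, y = toy_separable
        masses = [
            np.abs(fit_multinomial_l1(X, y, lam=lam).weights).sum()
            for lam in lambda_grid()
        ]
        assert all(a >= b - 1e-6 for a, b in zip(masses, masses[1:]))

    def test_agrees_with_sklearn_reference(self, toy_separable):
        from sklearn.linear_model import LogisticRegression

        X, y = toy_separable
        lam = 2.0
        mine = fit_multinomial_l1(X, y, lam=lam, tol=1e-9, max_iter=20000)
        ref = LogisticRegression(
            penalty="l1", C=1.0 / lam, solver="saga", max_iter=50000, tol=1e-8
        ).fit(X, y.astype(str))
        order = [list(ref.classes_).index(c) for c in mine.classes]
        Wr, br = ref.coef_[order], ref.intercept_[order]
        Y = np.zeros((X.shape[0], 3))
        for k, c in enumerate(mine.classes):
            Y[y == c, k] = 1.0
        obj = lambda W, b: _nll_and_grad(W, b, X, Y)[0] + lam * np.abs(W).sum()
        assert obj(mine.weights, mine.intercepts) <= obj(Wr, br) + 1e-2

    def test_single_class_errors(self):
        with pytest.raises(InvalidInputError):
            fit_multinomial_l1(np.ones((5, 2)), np.array(["flavour"] * 5, dtype=object), 1.0)


class TestCrossValidation:
    def test_grid_is_nine_log_spaced_values(self):
        assert np.allclose(lambda_grid(), np.logspace(-4, 4, 9))

    def test_pure_noise_accuracy_near_prior(self, rng):
        errs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(80, 10))
            y = np.array(
                ["flavour"] * 20 + ["water"] * 20 + ["baseline"] * 40, dtype=object
            )
            cv = cross_validate_lambda(X, y, folds=5, grid=np.array([1.0]), seed=seed)
            errs.append(cv["mean_misclassification"][0])
        acc = 1.0 - np.mean(errs)
        prior = 0.5  # majority class frequency
        sem = np.std(1.0 - np.array(errs)) / np.sqrt(len(errs))
        assert abs(acc - prior) < 3 * sem + 0.05

    def test_default_session_misclassification_low_at_lambda_one(self, planted_session):
        X, y, _ = build_training_set(planted_session["spikes"], planted_session["events"])
        cv = cross_validate_lambda(X, y, folds=10, grid=np.array([1.0]), seed=0)
        assert cv["mean_misclassification"][0] <= 0.02

    def test_single_class_errors(self):
        with pytest.raises(InvalidInputError):
            cross_validate_lambda(
                np.ones((5, 2)), np.array(["water"] * 5, dtype=object)
            )


class TestSlidingPosteriors:
    def test_window_count_formula(self):
        starts = sliding_window_starts(0.0, 100.0)
        assert starts.size == int(np.floor((100.0 - 1.0) / 0.15)) + 1

    def test_rows_sum_to_one(self, planted_session):
        spikes = planted_session["spikes"]
        ev = planted_session["events"]
        X, y, _ = build_training_set(spikes, ev)
        model = fit_multinomial_l1(X, y, 1.0)
        stats = one_second_count_stats(spikes, ev.epochs["delay"].start,
                                       ev.epochs["delay"].end)
        series = sliding_posteriors(model, spikes, stats, t_range=(0.0, 600.0))
        assert np.allclose(series.posteriors.sum(axis=1), 1.0, atol=1e-12)

    def test_bout_windows_have_higher_flavour_posterior(self, planted_session):
        spikes = planted_session["spikes"]
        ev = planted_session["events"]
        X, y, _ = build_training_set(spikes, ev)
        model = fit_multinomial_l1(X, y, 1.0)
        stats = one_second_count_stats(spikes, ev.epochs["delay"].start,
                                       ev.epochs["delay"].end)
        stim = ev.epochs["stimulation"]
        series = sliding_posteriors(model, spikes, stats, t_range=(stim.start, stim.end))
        onsets = ev.stim_bouts[:, 0]
        j = np.searchsorted(onsets, series.times, side="right") - 1
        in_bout = (j >= 0) & (series.times < ev.stim_bouts[np.clip(j, 0, None), 1])
        pf = series.class_series("flavour")
        assert pf[in_bout].mean() > pf[~in_bout].mean()

    def test_window_larger_than_session_errors(self):
        with pytest.raises(InvalidInputError):
            sliding_window_starts(0.0, 0.5)


class TestPeaks:
    def test_known_series_example(self):
        idx = peak_indices(np.array([0.1, 0.6, 0.4, 0.7, 0.9, 0.2]))
        assert idx.tolist() == [1, 4]

    def test_all_below_threshold(self):
        assert peak_indices(np.array([0.2, 0.5, 0.1])).size == 0

    def test_plateau_contributes_first_index(self):
        idx = peak_indices(np.array([0.1, 0.8, 0.8, 0.8, 0.2]))
        assert idx.tolist() == [1]

    def test_endpoints_eligible(self):
        assert peak_indices(np.array([0.9, 0.1])).tolist() == [0]
        assert peak_indices(np.array([0.1, 0.9])).tolist() == [1]

    @given(st.lists(st.integers(0, 10), min_size=1, max_size=60))
    def test_matches_brute_force_scan(self, vals):
        v = np.array(vals, dtype=float) / 10.0
        got = set(peak_indices(v, 0.5).tolist())
        ref = set()
        n = v.size
        for i in range(n):
            if v[i] <= 0.5:
                continue
            left = i == 0 or v[i - 1] < v[i]
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            right = j == n - 1 or v[j + 1] < v[i]
            if left and right and not (i == 0 and j == n - 1):
                ref.add(i)
        assert got == ref


class TestReactivationRate:
    def test_counting(self):
        centers, rate = reactivation_rate(np.array([10.0, 20.0, 30.0]), (0.0, 60.0))
        assert rate[0] == 3.0

    def test_empty(self):
        centers, rate = reactivation_rate(np.array([]), (0.0, 300.0))
        assert not rate.any()

    def test_poisson_rate_recovered(self):
        means = []
        r = 2.5 / 60.0  # 2.5 events per minute
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = rng.poisson(r * 3600.0)
            events = np.sort(rng.uniform(0.0, 3600.0, n))
            _, rate = reactivation_rate(events, (0.0, 3600.0))
            means.append(rate.mean())
        sem = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means) - 2.5) < 3 * sem
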