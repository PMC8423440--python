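"""The evidence core, bounded accumulator, covert bound, and confidence model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from confacc.observer import (
    ObserverParams,
    accumulate_optimal,
    confidence_bounds,
    decision_bound,
    decision_update,
    first_crossing,
    leaky_accumulate,
    optimal_choice,
    sample_loglik,
    simulate_confidence,
    simulate_free_trial,
    simulate_internal_trace,
    simulate_replay_batch,
    simulate_replay_trial,
)
from confacc.tasks import CategoryModel, StimulusSequence, sample_sequence


def make_seq(orientations, category=1, sid=0):
    return StimulusSequence(sid, category, np.asarray(orientations, dtype=float))


class TestEvidenceCore:
    def test_loglik_at_own_mean(self, model):
        assert sample_loglik(-np.pi / 4, 1, model) == pytest.approx(0.5)

    def test_loglik_at_antipode(self, model):
        assert sample_loglik(-np.pi / 4 + np.pi / 2, 1, model) == pytest.approx(-0.5)

    def test_loglik_consistent_with_density(self, model):
        from scipy.special import i0

        from confacc.tasks import category_density

        theta = np.linspace(-np.pi / 2 + 1e-9, np.pi / 2, 201)
        for psi in (1, 2):
            lhs = sample_loglik(theta, psi, model)
            rhs = np.log(category_density(theta, psi, model)) + np.log(np.pi * i0(0.5))
            np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_update_closed_form(self, model):
        theta = np.linspace(-np.pi / 2 + 1e-9, np.pi / 2, 201)
        np.testing.assert_allclose(
            decision_update(theta, model), -2 * model.kappa * np.sin(2 * theta),
            atol=1e-12,
        )

    @pytest.mark.parametrize(
        "theta,expected", [(0.0, 0.0), (-np.pi / 4, 1.0), (np.pi / 4, -1.0)]
    )
    def test_update_examples(self, model, theta, expected):
        assert decision_update(theta, model) == pytest.approx(expected, abs=1e-12)

    def test_accumulation_examples(self, model):
        single = accumulate_optimal(make_seq([-np.pi / 4]), model)
        np.testing.assert_allclose(single.L, [1.0])
        pair = accumulate_optimal(make_seq([-np.pi / 4, np.pi / 4]), model)
        np.testing.assert_allclose(pair.L, [1.0, 0.0], atol=1e-15)
        triple = accumulate_optimal(make_seq([-np.pi / 4] * 3), model)
        assert triple.L[-1] == pytest.approx(3.0)


class TestBounds:
    def test_pure_linear_when_scale_zero(self, params):
        p = params.with_(bound_b=0.0)
        n = np.arange(1, 20)
        np.testing.assert_allclose(decision_bound(n, p), n * p.bound_a)

    def test_no_decline_when_lambda_zero(self, params):
        p = params.with_(bound_lambda=0.0)
        np.testing.assert_allclose(decision_bound(5, p), 5 * p.bound_a + p.bound_b)

    def test_additive_parse_value(self):
        p = ObserverParams(bound_a=0.1, bound_b=2.0, bound_lambda=0.5)
        assert decision_bound(4, p) == pytest.approx(0.4 + 2 * np.exp(-2.0))

    def test_multiplicative_parse(self):
        p = ObserverParams(
            bound_a=0.1, bound_b=2.0, bound_lambda=0.5, bound_form="multiplicative"
        )
        assert decision_bound(4, p) == pytest.approx(4 * (0.1 + 2 * np.exp(-2.0)))

    def test_confidence_bounds_ordered_for_all_n(self, params):
        cb = confidence_bounds(np.arange(1, 41), params)
        assert np.all(cb[0] < cb[1]) and np.all(cb[1] < cb[2])

    def test_invalid_sample_index(self, params):
        with pytest.raises(ValueError):
            decision_bound(0, params)


class TestInternalTrace:
    def test_noiseless_identity(self, model):
        seq = sample_sequence(1, 12, model, seed=0)
        trace = simulate_internal_trace(
            decision_update(seq.orientations, model),
            ObserverParams(sigma=0.0, alpha=1.0), n_draws=5, seed=1,
        )
        np.testing.assert_allclose(trace.Lstar, np.tile(trace.L, (5, 1)), atol=1e-12)

    def test_terminal_variance_analytic(self):
        p = ObserverParams(sigma=0.5, alpha=1.0)
        trace = simulate_internal_trace(np.zeros(10), p, n_draws=100_000, seed=2)
        var = trace.Lstar[:, -1].var()
        expected = 10 * 0.25
        se = expected * np.sqrt(2 / (100_000 - 1))
        assert abs(var - expected) < 3 * se

    def test_primacy_weight_ratio(self):
        p = ObserverParams(sigma=0.0, alpha=1.2)
        ell = np.eye(10)  # unit pulse at each sample position
        terminal = leaky_accumulate(ell, 1.2)[:, -1]
        assert terminal[0] / terminal[9] == pytest.approx(1.2**9)

    @pytest.mark.parametrize("alpha", [0.8, 1.0, 1.3])
    def test_terminal_weight_identity(self, alpha):
        rng = np.random.default_rng(4)
        ell = rng.standard_normal(17)
        recursive = leaky_accumulate(ell, alpha)[-1]
        weights = alpha ** (17 - 1 - np.arange(17))
        assert recursive == pytest.approx(float(ell @ weights), abs=1e-10)


class TestFirstCrossing:
    def test_flat_trajectory_never_crosses(self, params):
        assert first_crossing(np.zeros(10), params) == (None, None)

    def test_crossing_sample_and_choice(self):
        p = ObserverParams(bound_a=0.0, bound_b=2.0, bound_lambda=0.0)
        n, choice = first_crossing(np.array([0.5, 1.5, 3.0]), p)
        assert (n, choice) == (3, 1)

    def test_negative_crossing_gives_category_two(self):
        p = ObserverParams(bound_a=0.0, bound_b=2.0, bound_lambda=0.0)
        n, choice = first_crossing(np.array([-0.5, -2.5]), p)
        assert (n, choice) == (2, 2)


class TestFreeTrial:
    def test_deterministic_when_noiseless(self, model):
        seq = make_seq([-np.pi / 4] * 8)
        p = ObserverParams(sigma=0.0, alpha=1.0, ndt_sigma=0.0)
        outcomes = {
            simulate_free_trial(seq, p, model, seed=s).response_sample
            for s in range(5)
        }
        assert len(outcomes) == 1

    def test_rt_offset_equals_ndt_mean_when_ndt_deterministic(self, model):
        seq = make_seq([-np.pi / 4] * 8)
        p = ObserverParams(sigma=0.0, ndt_sigma=0.0)
        out = simulate_free_trial(seq, p, model, seed=0)
        assert out.committed_sample is not None
        crossing_time = out.committed_sample * (1 / 3)
        assert out.rt - crossing_time == pytest.approx(p.ndt_mu)

    def test_noiseless_generous_bound_matches_optimal_observer(self, model):
        # with no noise and an unreachable bound the simulated choice is sign(L)
        rng = np.random.default_rng(8)
        p = ObserverParams(sigma=0.0, alpha=1.0, bound_a=50.0)
        agree = 0
        for s in range(200):
            seq = sample_sequence(rng.integers(1, 3), 10, model, seed=100 + s)
            out = simulate_free_trial(seq, p, model, seed=s)
            L = accumulate_optimal(seq, model).L[-1]
            agree += out.choice == int(optimal_choice(L))
        assert agree == 200


class TestReplayTrial:
    def test_without_covert_bound_choice_is_cue_time_sign(self, model):
        seq = make_seq([-np.pi / 4, np.pi / 4, np.pi / 4, np.pi / 4])
        p = ObserverParams(sigma=0.0, covert_bound=False)
        out = simulate_replay_trial(seq, 4, p, model, seed=0)
        assert out.choice == 2 and out.committed_sample is None

    def test_covert_freeze_ignores_later_reversal(self, model):
        # strong early evidence for category 1, then a long reversal
        seq = make_seq([-np.pi / 4] * 4 + [np.pi / 4] * 5)
        p = ObserverParams(
            sigma=0.0, covert_bound=True, bound_a=0.0, bound_b=2.5, bound_lambda=0.0
        )
        out = simulate_replay_trial(seq, 9, p, model, seed=0)
        assert out.committed_sample == 3
        assert out.choice == 1  # frozen despite terminal evidence favouring 2

    def test_freezing_never_changes_uncommitted_trials(self, model):
        rng = np.random.default_rng(3)
        ell = rng.standard_normal((60, 12)) * 0.6
        Z = rng.standard_normal((40, 60, 12))
        n_shown = np.full(60, 12)
        with_bound = simulate_replay_batch(
            ell, n_shown, ObserverParams(covert_bound=True), Z.copy()
        )
        without = simulate_replay_batch(
            ell, n_shown, ObserverParams(covert_bound=False), Z.copy()
        )
        uncommitted = with_bound["committed"] == 0
        np.testing.assert_array_equal(
            with_bound["choice"][uncommitted], without["choice"][uncommitted]
        )

    def test_invalid_n_shown(self, model, params):
        with pytest.raises(ValueError):
            simulate_replay_trial(make_seq([0.1] * 4), 9, params, model, seed=0)


class TestConfidence:
    def test_extreme_evidence_hits_rating_extremes(self, model):
        strong = make_seq([-np.pi / 4] * 30)
        p = ObserverParams(sigma=0.0, conf_sigma=0.0)
        assert simulate_confidence(strong, 30, 1, p, model, seed=0) == 4
        # same evidence but signed against the (wrong) choice
        assert simulate_confidence(strong, 30, 2, p, model, seed=0) == 1

    def test_reduces_to_shared_accumulator(self, model):
        seq = sample_sequence(1, 10, model, seed=5)
        p = ObserverParams(sigma=0.0, conf_sigma=0.0, conf_alpha=1.0, alpha=1.0)
        ell = decision_update(seq.orientations, model)
        L = ell.sum()
        rating = simulate_confidence(seq, 10, 1, p, model, seed=0)
        expected = 1 + int((L > confidence_bounds(10, p)).sum())
        assert rating == expected

    def test_mean_rating_monotone_in_confidence_evidence(self, model):
        rng = np.random.default_rng(6)
        ell = rng.standard_normal((400, 10)) * 0.8
        p = ObserverParams()
        Z = rng.standard_normal((1, 400, 10))
        Zc = rng.standard_normal((1, 400, 10))
        sim = simulate_replay_batch(ell, np.full(400, 10), p, Z, Zc=Zc)
        ev = np.abs(sim["conf_evidence"][0])
        rating = sim["confidence"][0]
        bins = np.quantile(ev, [0, 0.25, 0.5, 0.75, 1.0])
        means = [
            rating[(ev >= lo) & (ev <= hi)].mean()
            for lo, hi in zip(bins[:-1], bins[1:])
        ]
        assert all(b >= a - 1e-9 for a, b in zip(means[:-1], means[1:]))

    def test_accuracy_nondecreasing_in_sequence_length(self, model):
        rng = np.random.default_rng(7)
        accs = []
        for T in (2, 6, 12, 24):
            correct = 0
            for s in range(300):
                cat = int(rng.integers(1, 3))
                seq = sample_sequence(cat, T, model, seed=int(rng.integers(2**31)))
                L = accumulate_optimal(seq, model).L[-1]
                correct += int(optimal_choice(L)) == cat
            accs.append(correct / 300)
        assert all(b >= a - 0.05 for a, b in zip(accs[:-1], accs[1:]))

    def test_invalid_choice_rejected(self, model, params):
        with pytest.raises(ValueError):
            simulate_confidence(make_seq([0.1] * 4), 4, 3, params, model, seed=0)
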