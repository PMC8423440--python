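"""Monte-Carlo likelihoods, observer fitting, and model comparison mechanics."""

import warnings

import numpy as np
import pandas as pd
import pytest

from confacc.fitting import (
    ModelVariant,
    crossval_compare,
    fit_observer,
    free_outcome_distribution,
    mc_trial_likelihood,
    negative_log_likelihood,
)
from confacc.observer import ObserverParams, decision_update
from confacc.tasks import StimulusSequence, make_predefined_sequences


def toy_sequence(T=6, sid=0):
    rng = np.random.default_rng(sid)
    ori = rng.uniform(-np.pi / 2 + 1e-6, np.pi / 2, T)
    return StimulusSequence(sid, 1, ori)


class TestMCTrialLikelihood:
    def test_deterministic_crossing_has_probability_one(self, model):
        seq = StimulusSequence(0, 1, np.full(8, -np.pi / 4))
        p = ObserverParams(sigma=0.0, ndt_sigma=0.0)
        from confacc.observer import simulate_free_trial

        out = simulate_free_trial(seq, p, model, seed=0)
        trial = {
            "task": "free", "sequence_id": 0, "choice": out.choice,
            "response_sample": out.response_sample,
        }
        assert mc_trial_likelihood(trial, seq, p, model, n_mc=200, seed=1) == 1.0

    def test_impossible_outcome_floored_not_zero(self, model):
        seq = StimulusSequence(0, 1, np.full(8, -np.pi / 4))
        p = ObserverParams(sigma=0.0, ndt_sigma=0.0)
        trial = {"task": "free", "sequence_id": 0, "choice": 2, "response_sample": 8}
        lik = mc_trial_likelihood(trial, seq, p, model, n_mc=200, seed=1)
        assert lik == pytest.approx(1 / 400)

    def test_n_mc_floor_requirement(self, model, params):
        seq = toy_sequence()
        with pytest.raises(ValueError, match="n_mc"):
            mc_trial_likelihood(
                {"task": "free", "sequence_id": 0, "choice": 1, "response_sample": 1},
                seq, params, model, n_mc=10,
            )

    @pytest.mark.parametrize("T", [3, 6])
    def test_outcome_probabilities_sum_to_one(self, model, params, T):
        dist = free_outcome_distribution(
            toy_sequence(T), params, model, n_mc=1000, seed=3
        )
        assert dist.shape == (T, 2)
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)

    def test_outcome_distribution_matches_independent_tally(self, model):
        """Brute-force per-draw oracle for the (sample, choice) distribution."""
        from confacc.observer import SOA, decision_bound

        seq = toy_sequence(5, sid=4)
        p = ObserverParams(sigma=0.7, alpha=1.1)
        n_mc = 4000
        ell = decision_update(seq.orientations, model)
        bounds = [float(decision_bound(n, p)) for n in range(1, 6)]
        rng = np.random.default_rng(99)
        tally = np.zeros((5, 2))
        for _ in range(n_mc):
            a, crossed = 0.0, None
            for n in range(1, 6):
                a = p.alpha * a + ell[n - 1] + p.sigma * rng.standard_normal()
                if crossed is None and abs(a) > bounds[n - 1]:
                    crossed = (n, 1 if a > 0 else 2)
            if crossed is None:
                m, c = 5, (1 if a > 0 else 2)
            else:
                ndt = max(0.0, p.ndt_mu + p.ndt_sigma * rng.standard_normal())
                m = min(5, crossed[0] + int(ndt / SOA))
                c = crossed[1]
            tally[m - 1, c - 1] += 1
        tally /= n_mc
        dist = free_outcome_distribution(seq, p, model, n_mc=n_mc, seed=123)
        assert np.abs(dist - tally).sum() / 2 < 0.05  # total variation


@pytest.fixture(scope="module")
def replay_data(model):
    from confacc.synth import simulate_subject_behaviour

    seqs = make_predefined_sequences(40, 40, model, seed=21)
    truth = ObserverParams(sigma=0.6, alpha=1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trials, _ = simulate_subject_behaviour(
            0, seqs, truth, model, np.random.default_rng(21)
        )
    return trials[trials["task"] == "replay"], seqs, truth


class TestFitObserver:

    def test_refit_nll_self_consistent_within_mc_error(self, model, replay_data):
        trials, seqs, truth = replay_data
        variant = ModelVariant("m", ("sigma",), truth, "replay_choice")
        fit = fit_observer(
            trials, seqs, model, variant, n_mc=200, seed=5, n_starts=2
        )
        nll_truth = negative_log_likelihood(
            trials, seqs, model, truth, "replay_choice", n_mc=200, seed=5
        )
        # the fitted sigma cannot do much worse than the generating one
        assert fit.nll <= nll_truth + 0.05 * len(trials)
        assert abs(fit.params.sigma - truth.sigma) < 0.25

    def test_multistart_weakly_improves_nll(self, model, replay_data):
        trials, seqs, truth = replay_data
        variant = ModelVariant("m", ("sigma", "alpha"), truth, "replay_choice")
        nlls = [
            fit_observer(
                trials.head(120), seqs, model, variant,
                n_mc=150, seed=5, n_starts=k,
            ).nll
            for k in (1, 3)
        ]
        assert nlls[1] <= nlls[0] + 1e-9

    def test_degenerate_identical_responses_flagged(self, model):
        seqs = make_predefined_sequences(10, 8, model, seed=2)
        trials = pd.DataFrame({
            "subject_id": 0, "task": "replay",
            "sequence_id": [s.sequence_id for s in seqs],
            "n_shown": 8, "choice": 1,
            "condition": "same",
        })
        variant = ModelVariant("m", ("sigma",), ObserverParams(), "replay_choice")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_observer(trials, seqs, model, variant, n_mc=150, seed=0,
                               n_starts=1)
        assert fit.boundary_flag

    def test_likelihood_floor_below_any_attainable_probability(self, model, params):
        dist = free_outcome_distribution(toy_sequence(4), params, model, n_mc=200,
                                         seed=0)
        floor = 1 / (2 * 200)
        attainable = dist[dist > 0]
        assert np.all(attainable >= floor)


class TestCrossvalCompare:
    def test_identical_variants_give_null_delta(self, model, small_cohort):
        trials = small_cohort["trials"]
        replay = trials[
            (trials["task"] == "replay") & (trials["subject_id"] == 0)
        ]
        v = ModelVariant("same", ("sigma",), ObserverParams(), "replay_choice")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmp_ = crossval_compare(
                replay, small_cohort["sequences"], model, v, v,
                n_folds=2, n_boot=500, seed=1, n_mc=150, n_starts=1,
            )
        se = cmp_.per_trial_delta_ll.std(ddof=1) / np.sqrt(len(replay))
        assert abs(cmp_.mean_delta) < 2 * se + 1e-6
        assert 0 < cmp_.boot_p <= 1

    def test_sequence_level_folds_have_no_repeat_leakage(self, model, small_cohort):
        from confacc.fitting import _sequence_folds

        trials = small_cohort["trials"]
        fold = _sequence_folds(trials, 3, np.random.default_rng(0))
        frame = pd.DataFrame({"sequence_id": trials["sequence_id"], "fold": fold})
        assert (frame.groupby("sequence_id")["fold"].nunique() == 1).all()

    def test_single_fold_rejected(self, model, small_cohort):
        trials = small_cohort["trials"]
        v = ModelVariant("m", ("sigma",), ObserverParams(), "replay_choice")
        with pytest.raises(ValueError, match="n_folds"):
            crossval_compare(
                trials, small_cohort["sequences"], model, v, v, n_folds=1
            )
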