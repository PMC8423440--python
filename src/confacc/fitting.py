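"""Monte-Carlo trial likelihoods, observer fitting, and model comparison.

The generative model has no closed-form trial likelihood: the probability of
an observed outcome (response sample and choice in the Free task; cue-time
choice and optionally confidence in the Replay task) is estimated as its
relative frequency over Monte-Carlo draws of the inference noise.  Frequencies
are floored at 1/(2*n_mc) so a single unlucky outcome cannot contribute
-inf to the log-likelihood.

Fitting minimises the summed negative log-likelihood with a bounded
derivative-free optimiser (Nelder-Mead with box bounds).  Two stabilisers tame
the stochastic objective: common random numbers (the standard-normal noise
draws are frozen per fit and rescaled by the candidate sigma), and multistart
from a deterministic set of start points, returning the best end point.

Model comparison is cross-validated: variants are fitted on training folds
(stratified at the sequence level so repeats of one sequence never straddle a
fold boundary) and scored per held-out trial; the per-trial log-likelihood
differences are summarised by their mean and a bootstrap p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .observer import (
    ObserverParams,
    decision_update,
    simulate_free_batch,
    simulate_replay_batch,
)
from .tasks import CategoryModel, StimulusSequence

#: default box bounds per fittable parameter
DEFAULT_BOX: dict[str, tuple[float, float]] = {
    "sigma": (0.01, 2.0),
    "alpha": (0.5, 1.6),
    "bound_a": (0.0, 1.0),
    "bound_b": (0.0, 8.0),
    "bound_lambda": (0.0, 1.5),
    "ndt_mu": (0.05, 1.0),
    "ndt_sigma": (0.01, 0.5),
    "conf_sigma": (0.0, 2.0),
    "conf_alpha": (0.5, 1.6),
    "conf_bound_a": (0.0, 1.0),
}


@dataclass(frozen=True)
class ModelVariant:
    """A fittable model specification: which parameters are free, on what data.

    ``likelihood`` selects the outcome being fitted: ``"free"`` fits the
    (response sample, choice) outcome of Free-task trials, ``"replay_choice"``
    the cue-time choice of Replay trials, ``"replay_choice_conf"`` the joint
    (choice, confidence) outcome.
    """

    name: str
    free: tuple[str, ...]
    base: ObserverParams
    likelihood: str = "replay_choice"

    def __post_init__(self) -> None:
        if self.likelihood not in ("free", "replay_choice", "replay_choice_conf"):
            raise ValueError(f"unknown likelihood mode {self.likelihood!r}")
        unknown = set(self.free) - set(DEFAULT_BOX)
        if unknown:
            raise ValueError(f"unknown free parameters: {sorted(unknown)}")

    def params_from_vector(self, x: np.ndarray) -> ObserverParams:
        return self.base.with_(**dict(zip(self.free, np.asarray(x, dtype=float))))


@dataclass
class FitResult:
    params: ObserverParams
    nll: float
    n_mc: int
    seed: int
    converged: bool
    optimizer_trace: list = field(default_factory=list)
    boundary_flag: bool = False
    variant_name: str = ""

    def to_dict(self) -> dict:
        return {
            "variant": self.variant_name,
            "params": self.params.to_dict(),
            "nll": self.nll,
            "n_mc": self.n_mc,
            "seed": self.seed,
            "converged": self.converged,
            "boundary_flag": self.boundary_flag,
        }


@dataclass
class ModelComparison:
    per_trial_delta_ll: np.ndarray
    mean_delta: float
    boot_p: float
    n_folds: int
    n_boot: int

    def to_dict(self) -> dict:
        return {
            "mean_delta": self.mean_delta,
            "boot_p": self.boot_p,
            "n_folds": self.n_folds,
            "n_boot": self.n_boot,
            "n_trials": int(self.per_trial_delta_ll.size),
        }


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def _sequence_map(sequences) -> dict[int, StimulusSequence]:
    if isinstance(sequences, dict):
        return sequences
    return {s.sequence_id: s for s in sequences}


def prepare_trials(
    trials: pd.DataFrame, sequences, model: CategoryModel
) -> dict:
    """Pack a trial table into padded arrays for batch simulation.

    Returns dict with ``ell`` (n_trials, T_max), ``lengths``/``n_shown``,
    observed ``choice``/``response_sample``/``confidence`` and the trial index.
    """
    seqmap = _sequence_map(sequences)
    n = len(trials)
    T = max(len(seqmap[sid]) for sid in trials["sequence_id"])
    ell = np.zeros((n, T))
    lengths = np.zeros(n, dtype=int)
    for i, sid in enumerate(trials["sequence_id"].to_numpy()):
        seq = seqmap[sid]
        ell[i, : len(seq)] = decision_update(seq.orientations, model)
        lengths[i] = len(seq)
    out = {
        "ell": ell,
        "lengths": lengths,
        "choice": trials["choice"].to_numpy(dtype=int),
        "index": trials.index.to_numpy(),
    }
    if "n_shown" in trials:
        n_shown = trials["n_shown"].to_numpy()
        out["n_shown"] = np.where(
            np.isnan(n_shown.astype(float)), lengths, n_shown
        ).astype(int)
    else:
        out["n_shown"] = lengths
    if "response_sample" in trials:
        out["response_sample"] = trials["response_sample"].to_numpy(dtype=int)
    if "confidence" in trials:
        conf = trials["confidence"].to_numpy(dtype=float)
        out["confidence"] = conf
    return out


def _crn_draws(rng: np.random.Generator, n_mc: int, n: int, T: int, mode: str):
    """Frozen standard-normal draws reused across objective evaluations."""
    Z = rng.standard_normal((n_mc, n, T))
    U = rng.standard_normal((n_mc, n)) if mode == "free" else None
    Zc = rng.standard_normal((n_mc, n, T)) if mode == "replay_choice_conf" else None
    return Z, U, Zc


def _batch_probabilities(packed, params, mode, Z, U, Zc, floor):
    """Per-trial probability of the observed outcome under one parameter set."""
    if mode == "free":
        sim = simulate_free_batch(packed["ell"], packed["lengths"], params, Z, U)
        hit = (sim["response_sample"] == packed["response_sample"][None, :]) & (
            sim["choice"] == packed["choice"][None, :]
        )
    else:
        sim = simulate_replay_batch(
            packed["ell"], packed["n_shown"], params, Z, Zc=Zc
        )
        hit = sim["choice"] == packed["choice"][None, :]
        if mode == "replay_choice_conf":
            hit &= sim["confidence"] == packed["confidence"][None, :].astype(int)
    p = hit.mean(axis=0)
    if floor:
        p = np.maximum(p, 1.0 / (2.0 * Z.shape[0]))
    return p


# ---------------------------------------------------------------------------
# per-trial Monte-Carlo likelihood
# ---------------------------------------------------------------------------

def mc_trial_likelihood(
    trial: dict | pd.Series,
    sequence: StimulusSequence,
    params: ObserverParams,
    model: CategoryModel,
    n_mc: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo probability of one trial's observed outcome.

    ``trial`` needs ``task`` ("free" | "replay"), ``choice``, and for the Free
    task ``response_sample``; ``n_shown`` and ``confidence`` select the Replay
    outcome granularity (confidence included when present and not NaN).
    The estimate is floored at 1/(2*n_mc).
    """
    if n_mc < 100:
        raise ValueError("n_mc must be >= 100 for a usable frequency estimate")
    task = trial["task"]
    frame = pd.DataFrame([dict(trial)])
    packed = prepare_trials(frame, [sequence], model)
    rng = np.random.default_rng(seed)
    conf = trial.get("confidence", None)
    has_conf = conf is not None and not (isinstance(conf, float) and np.isnan(conf))
    mode = (
        "free"
        if task == "free"
        else ("replay_choice_conf" if has_conf else "replay_choice")
    )
    Z, U, Zc = _crn_draws(rng, n_mc, 1, packed["ell"].shape[-1], mode)
    return float(_batch_probabilities(packed, params, mode, Z, U, Zc, floor=True)[0])


def free_outcome_distribution(
    sequence: StimulusSequence,
    params: ObserverParams,
    model: CategoryModel,
    n_mc: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Unfloored MC frequencies over all (response sample, choice) outcomes.

    Returns an array of shape (T, 2): entry [n-1, c-1] is the estimated
    probability of responding at sample n with choice c.  Rows/columns sum to
    1 exactly because every draw lands in exactly one outcome cell.
    """
    ell = decision_update(sequence.orientations, model)[None, :]
    lengths = np.array([len(sequence)])
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_mc, 1, ell.shape[-1]))
    U = rng.standard_normal((n_mc, 1))
    sim = simulate_free_batch(ell, lengths, params, Z, U)
    T = len(sequence)
    out = np.zeros((T, 2))
    resp = sim["response_sample"][:, 0] - 1
    choice = sim["choice"][:, 0] - 1
    np.add.at(out, (resp, choice), 1.0)
    return out / n_mc


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def negative_log_likelihood(
    trials: pd.DataFrame,
    sequences,
    model: CategoryModel,
    params: ObserverParams,
    likelihood: str,
    n_mc: int = 1000,
    seed: int = 0,
) -> float:
    """Summed -log MC likelihood of a trial table under one parameter set."""
    packed = prepare_trials(trials, sequences, model)
    rng = np.random.default_rng(seed)
    Z, U, Zc = _crn_draws(rng, n_mc, len(trials), packed["ell"].shape[-1], likelihood)
    p = _batch_probabilities(packed, params, likelihood, Z, U, Zc, floor=True)
    return float(-np.log(p).sum())


def _start_points(box_arr: np.ndarray, n_starts: int, rng: np.random.Generator):
    """Deterministic start list: the box centre, then uniform draws.

    The list for ``n_starts`` is a prefix of the list for any larger count, so
    adding starts can only improve (weakly) the best NLL found.
    """
    lo, hi = box_arr[:, 0], box_arr[:, 1]
    starts = [0.5 * (lo + hi)]
    for _ in range(n_starts - 1):
        starts.append(lo + (hi - lo) * rng.uniform(0.15, 0.85, size=lo.size))
    return starts


def fit_observer(
    trials: pd.DataFrame,
    sequences,
    model: CategoryModel,
    variant: ModelVariant,
    box: dict[str, tuple[float, float]] | None = None,
    n_mc: int = 1000,
    seed: int = 0,
    n_starts: int = 5,
    maxiter: int | None = None,
) -> FitResult:
    """Fit a model variant by bounded derivative-free NLL minimisation.

    Uses common random numbers (one frozen noise tensor per fit, rescaled by
    the candidate noise parameters) and multistart Nelder-Mead within the box
    bounds.  A fit ending on a box edge is flagged, not raised.
    """
    if len(trials) < 50:
        warnings.warn(
            f"fitting on {len(trials)} trials; >= 50 recommended", stacklevel=2
        )
    box = {**DEFAULT_BOX, **(box or {})}
    box_arr = np.array([box[name] for name in variant.free], dtype=float)
    packed = prepare_trials(trials, sequences, model)
    rng = np.random.default_rng(seed)
    Z, U, Zc = _crn_draws(
        rng, n_mc, len(trials), packed["ell"].shape[-1], variant.likelihood
    )

    def objective(x: np.ndarray) -> float:
        p = _batch_probabilities(
            packed, variant.params_from_vector(x), variant.likelihood, Z, U, Zc, True
        )
        return float(-np.log(p).sum())

    trace = []
    best = None
    maxiter = maxiter or 120 * len(variant.free)
    for x0 in _start_points(box_arr, n_starts, rng):
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=box_arr,
            options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-3},
        )
        trace.append({"x0": x0.tolist(), "x": res.x.tolist(), "nll": float(res.fun),
                      "success": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    span = box_arr[:, 1] - box_arr[:, 0]
    on_edge = np.any(
        (best.x - box_arr[:, 0] < 1e-3 * span) | (box_arr[:, 1] - best.x < 1e-3 * span)
    )
    return FitResult(
        params=variant.params_from_vector(best.x),
        nll=float(best.fun),
        n_mc=n_mc,
        seed=seed,
        converged=bool(best.success),
        optimizer_trace=trace,
        boundary_flag=bool(on_edge),
        variant_name=variant.name,
    )


# ---------------------------------------------------------------------------
# cross-validated model comparison
# ---------------------------------------------------------------------------

def _sequence_folds(trials: pd.DataFrame, n_folds: int, rng: np.random.Generator):
    """Assign sequences (hence all their repeats) to folds, shuffled."""
    sids = np.array(sorted(trials["sequence_id"].unique()))
    rng.shuffle(sids)
    fold_of = {int(sid): i % n_folds for i, sid in enumerate(sids)}
    return trials["sequence_id"].map(fold_of).to_numpy()


def crossval_compare(
    trials: pd.DataFrame,
    sequences,
    model: CategoryModel,
    variant_a: ModelVariant,
    variant_b: ModelVariant,
    n_folds: int = 5,
    n_boot: int = 10_000,
    seed: int = 0,
    n_mc: int = 400,
    n_starts: int = 2,
    box: dict | None = None,
) -> ModelComparison:
    """Cross-validated per-trial log-likelihood comparison of two variants.

    Positive ``mean_delta`` favours variant A.  Folds are assigned at the
    sequence level; held-out likelihoods use a fresh Monte-Carlo seed so the
    comparison is not biased by the common random numbers used in fitting.
    The bootstrap resamples trials (percentile method, two-sided p, floored
    at 1/n_boot).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    fold_id = _sequence_folds(trials, n_folds, rng)
    delta = np.full(len(trials), np.nan)
    for k in range(n_folds):
        train = trials.loc[fold_id != k]
        test = trials.loc[fold_id == k]
        if train.empty or test.empty:
            raise ValueError(f"fold {k} is degenerate; reduce n_folds")
        # common random numbers across the two variants: same fitting seed and
        # same held-out noise draws, so identical variants give delta == 0
        fit_seed = int(rng.integers(2**31 - 1))
        eval_seed = int(rng.integers(2**31 - 1))
        lls = {}
        for tag, variant in (("a", variant_a), ("b", variant_b)):
            fit = fit_observer(
                train, sequences, model, variant, box=box,
                n_mc=n_mc, seed=fit_seed, n_starts=n_starts,
            )
            packed = prepare_trials(test, sequences, model)
            r2 = np.random.default_rng(eval_seed)
            Z, U, Zc = _crn_draws(
                r2, n_mc, len(test), packed["ell"].shape[-1], variant.likelihood
            )
            p = _batch_probabilities(
                packed, fit.params, variant.likelihood, Z, U, Zc, True
            )
            lls[tag] = np.log(p)
        delta[fold_id == k] = lls["a"] - lls["b"]
    assert not np.isnan(delta).any()
    mean_delta = float(delta.mean())
    boots = rng.choice(delta, size=(n_boot, delta.size), replace=True).mean(axis=1)
    p_lo = float(np.mean(boots <= 0))
    p_hi = float(np.mean(boots >= 0))
    boot_p = max(1.0 / n_boot, 2.0 * min(p_lo, p_hi))
    return ModelComparison(
        per_trial_delta_ll=delta,
        mean_delta=mean_delta,
        boot_p=min(1.0, boot_p),
        n_folds=n_folds,
        n_boot=n_boot,
    )


def covert_bound_comparison(
    trials: pd.DataFrame,
    sequences,
    model: CategoryModel,
    n_folds: int = 2,
    n_boot: int = 2000,
    seed: int = 0,
    n_mc: int = 200,
    n_starts: int = 2,
    free: tuple = ("sigma", "alpha", "bound_b"),
    box: dict | None = None,
) -> ModelComparison:
    """Does the Free-task decision bound operate covertly in the Replay task?

    The decision bound is identified by the Free task, where it is overt: the
    observer's response-sample distribution pins down sigma, alpha, and the
    bound scale.  The covert-bound question is then whether applying that same
    fitted bound covertly predicts held-out Replay choices better than
    accumulating to the cue.  Per subject and fold (sequence-level folds),
    the shared parameters are fitted to the training Free-task trials; every
    held-out Replay trial is scored under both applications of the bound.
    Positive ``mean_delta`` favours the covert bound.
    """
    rng = np.random.default_rng(seed)
    deltas = []
    for subj, subj_trials in trials.groupby("subject_id"):
        free_trials = subj_trials[subj_trials["task"] == "free"]
        replay_trials = subj_trials[subj_trials["task"] == "replay"]
        if free_trials.empty or replay_trials.empty:
            raise ValueError(f"subject {subj} lacks free or replay trials")
        fold_id = _sequence_folds(replay_trials, n_folds, rng)
        for k in range(n_folds):
            held_seqs = set(
                replay_trials.loc[fold_id == k, "sequence_id"].unique()
            )
            train_free = free_trials[~free_trials["sequence_id"].isin(held_seqs)]
            test = replay_trials.loc[fold_id == k]
            variant = ModelVariant(
                name="shared", free=free,
                base=ObserverParams(), likelihood="free",
            )
            fit = fit_observer(
                train_free, sequences, model, variant, box=box,
                n_mc=n_mc, seed=int(rng.integers(2**31 - 1)), n_starts=n_starts,
            )
            packed = prepare_trials(test, sequences, model)
            r2 = np.random.default_rng(int(rng.integers(2**31 - 1)))
            Z, _, _ = _crn_draws(
                r2, n_mc, len(test), packed["ell"].shape[-1], "replay_choice"
            )
            lls = {}
            for tag, flag in (("covert", True), ("nobound", False)):
                p = _batch_probabilities(
                    packed, fit.params.with_(covert_bound=flag),
                    "replay_choice", Z, None, None, True,
                )
                lls[tag] = np.log(p)
            deltas.append(lls["covert"] - lls["nobound"])
    delta = np.concatenate(deltas)
    boots = rng.choice(delta, size=(n_boot, delta.size), replace=True).mean(axis=1)
    boot_p = max(
        1.0 / n_boot, 2.0 * min(float(np.mean(boots <= 0)), float(np.mean(boots >= 0)))
    )
    return ModelComparison(
        per_trial_delta_ll=delta,
        mean_delta=float(delta.mean()),
        boot_p=min(1.0, boot_p),
        n_folds=n_folds,
        n_boot=n_boot,
    )
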