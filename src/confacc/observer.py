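"""Optimal and suboptimal observer models for sequential categorisation.

The optimal observer accumulates, over the samples of a trial, the difference
in log-likelihood between the two orientation categories,

    ell_n = kappa * [cos(2*(theta_n - mu1)) - cos(2*(theta_n - mu2))],
    L_N   = sum_{n<=N} ell_n,

and chooses category 1 iff the terminal L is positive.  The suboptimal
observer corrupts each update with i.i.d. Gaussian inference noise of SD
``sigma`` and integrates with a leak/primacy weight ``alpha``:

    A_N = alpha * A_{N-1} + (ell_N + eps_N),

so that at the end of a T-sample trial, sample n carries weight alpha**(T-n)
(alpha > 1 gives primacy, alpha < 1 recency).  In the Free task the observer
responds when |A_N| exceeds a collapsing bound

    bound(n) = n*a + b*exp(-n*lambda)          (additive parse, default)
    bound(n) = n*(a + b*exp(-n*lambda))        (multiplicative parse)

after which the key press is delayed by a Gaussian non-decision time.  In the
Replay task responses are cued after a fixed number of samples; with a covert
bound enabled, a bound crossing before the cue freezes the choice and later
samples are ignored for the perceptual decision.  Confidence is read from a
second accumulator over the same noisy evidence, with extra per-sample noise
``conf_sigma`` and its own integration weight ``conf_alpha``; the terminal
confidence evidence, signed by the perceptual choice, is partitioned into a
four-point rating by three increasing collapsing bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .tasks import CategoryModel, StimulusSequence

#: default stimulus onset asynchrony, seconds (samples presented at ~3 Hz)
SOA = 1.0 / 3.0


@dataclass(frozen=True)
class ObserverParams:
    """Generative-model parameters of the suboptimal observer.

    Units: evidence quantities are in log-likelihood-ratio units set by the
    category model (kappa=0.5 gives per-sample updates in roughly [-1, 1]);
    non-decision time is in seconds.
    """

    sigma: float = 0.6            # inference noise SD per sample
    alpha: float = 1.0            # integration weight (>1 primacy, <1 recency)
    bound_a: float = 0.15         # decision-bound linear coefficient
    bound_b: float = 3.0          # decision-bound scale
    bound_lambda: float = 0.12    # decision-bound decline rate
    bound_form: str = "additive"  # "additive" | "multiplicative"
    covert_bound: bool = True     # apply the bound covertly in the Replay task
    ndt_mu: float = 0.35          # non-decision-time mean, s
    ndt_sigma: float = 0.08       # non-decision-time SD, s
    conf_sigma: float = 0.4       # extra per-sample confidence noise SD
    conf_alpha: float = 1.0       # confidence integration weight
    conf_bound_a: float = 0.18    # confidence-bound linear coefficient
    conf_bound_scales: tuple = (0.5, 2.0, 4.0)  # increasing scales c1<c2<c3
    conf_bound_lambda: float = 0.1
    conf_noise_locus: str = "per_sample"  # "per_sample" | "terminal"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.ndt_sigma < 0:
            raise ValueError("ndt_sigma must be >= 0")
        if self.bound_form not in ("additive", "multiplicative"):
            raise ValueError(f"unknown bound_form {self.bound_form!r}")
        if self.conf_noise_locus not in ("per_sample", "terminal"):
            raise ValueError(f"unknown conf_noise_locus {self.conf_noise_locus!r}")
        scales = tuple(float(s) for s in self.conf_bound_scales)
        if len(scales) != 3 or not (scales[0] < scales[1] < scales[2]):
            raise ValueError("conf_bound_scales must be three increasing values")
        object.__setattr__(self, "conf_bound_scales", scales)

    def with_(self, **kwargs) -> "ObserverParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "sigma": self.sigma, "alpha": self.alpha,
            "bound_a": self.bound_a, "bound_b": self.bound_b,
            "bound_lambda": self.bound_lambda, "bound_form": self.bound_form,
            "covert_bound": self.covert_bound,
            "ndt_mu": self.ndt_mu, "ndt_sigma": self.ndt_sigma,
            "conf_sigma": self.conf_sigma, "conf_alpha": self.conf_alpha,
            "conf_bound_a": self.conf_bound_a,
            "conf_bound_scales": list(self.conf_bound_scales),
            "conf_bound_lambda": self.conf_bound_lambda,
            "conf_noise_locus": self.conf_noise_locus,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ObserverParams":
        d = dict(d)
        if "conf_bound_scales" in d:
            d["conf_bound_scales"] = tuple(d["conf_bound_scales"])
        return cls(**d)


@dataclass(frozen=True)
class EvidenceTrace:
    """Per-sample decision updates, optimal cumulative evidence, and noisy draws."""

    ell: np.ndarray                 # (T,) decision updates
    L: np.ndarray                   # (T,) cumulative optimal evidence
    Lstar: np.ndarray | None = None  # (n_draws, T) internal accumulator draws


@dataclass(frozen=True)
class TrialOutcome:
    """Simulated outcome of one trial."""

    choice: int                      # 1 | 2
    response_sample: int | None      # sample at which the key press lands
    committed_sample: int | None     # covert-bound crossing sample, if any
    rt: float | None                 # seconds from sequence onset
    confidence: int | None           # 1..4


# ---------------------------------------------------------------------------
# evidence core
# ---------------------------------------------------------------------------

def sample_loglik(theta, psi: int, model: CategoryModel):
    """Log-likelihood of orientation theta under category psi, up to a constant.

    The dropped constant, -log(pi*I0(kappa)), is identical for both categories
    and cancels in every evidence difference.
    """
    theta = np.asarray(theta, dtype=float)
    mu = model.mu(psi)
    return model.kappa * np.cos(2.0 * (theta - mu))


def decision_update(theta, model: CategoryModel):
    """Per-sample decision update ell_n; positive favours category 1."""
    theta = np.asarray(theta, dtype=float)
    return model.kappa * (
        np.cos(2.0 * (theta - model.mu1)) - np.cos(2.0 * (theta - model.mu2))
    )


def accumulate_optimal(sequence: StimulusSequence, model: CategoryModel) -> EvidenceTrace:
    """Optimal evidence trace (ell and running L) over one sequence."""
    if len(sequence) < 1:
        raise ValueError("sequence must contain at least one sample")
    ell = decision_update(sequence.orientations, model)
    return EvidenceTrace(ell=ell, L=np.cumsum(ell))


def optimal_choice(L_terminal) -> np.ndarray:
    """Bayesian-optimal choice: 1 if L > 0 else 2."""
    return np.where(np.asarray(L_terminal) > 0, 1, 2)


# ---------------------------------------------------------------------------
# bounds
# ---------------------------------------------------------------------------

def decision_bound(n, params: ObserverParams):
    """Positive decision bound at sample n (the negative bound is its mirror)."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("sample index n must be >= 1")
    decay = params.bound_b * np.exp(-n * params.bound_lambda)
    if params.bound_form == "additive":
        return n * params.bound_a + decay
    return n * (params.bound_a + decay)


def confidence_bounds(n, params: ObserverParams) -> np.ndarray:
    """The three increasing confidence bounds c1(n) < c2(n) < c3(n).

    Shape: (3,) + shape(n).  Same functional family as the decision bound,
    with a shared linear term and decline rate and three increasing scales.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("sample index n must be >= 1")
    scales = np.asarray(params.conf_bound_scales)
    decay = np.multiply.outer(scales, np.exp(-n * params.conf_bound_lambda))
    if params.bound_form == "additive":
        return n * params.conf_bound_a + decay
    return n * (params.conf_bound_a + decay)


def bound_schedule(T: int, params: ObserverParams) -> np.ndarray:
    """Decision bound evaluated at samples 1..T."""
    return decision_bound(np.arange(1, T + 1), params)


# ---------------------------------------------------------------------------
# accumulation
# ---------------------------------------------------------------------------

def leaky_accumulate(x: np.ndarray, alpha: float) -> np.ndarray:
    """Recursive accumulation A_n = alpha*A_{n-1} + x_n along the last axis."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    acc = np.zeros(x.shape[:-1])
    for t in range(x.shape[-1]):
        acc = alpha * acc + x[..., t]
        out[..., t] = acc
    return out


def simulate_internal_trace(
    ell: np.ndarray,
    params: ObserverParams,
    n_draws: int,
    seed: int | np.random.Generator,
) -> EvidenceTrace:
    """Monte-Carlo draws of the internal (noisy, biased) accumulator.

    Returns the trace with ``Lstar`` of shape (n_draws, T); row i is one
    realisation of A_1..A_T under inference noise sigma and weight alpha.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    ell = np.asarray(ell, dtype=float)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n_draws, ell.size)) * params.sigma
    Lstar = leaky_accumulate(ell[None, :] + eps, params.alpha)
    return EvidenceTrace(ell=ell, L=np.cumsum(ell), Lstar=Lstar)


def first_crossing(trajectory: np.ndarray, params: ObserverParams):
    """First sample where |A_N| exceeds the bound, and the sign-determined choice.

    Returns ``(sample_index, choice)`` 1-based, or ``(None, None)`` if the
    trajectory never crosses.
    """
    A = np.asarray(trajectory, dtype=float)
    bounds = bound_schedule(A.size, params)
    over = np.abs(A) > bounds
    if not over.any():
        return None, None
    idx = int(np.argmax(over))
    choice = 1 if A[idx] > 0 else 2
    return idx + 1, choice


# ---------------------------------------------------------------------------
# vectorised batch simulation (shared by fitting and the cohort generator)
# ---------------------------------------------------------------------------

def batch_first_crossing(A: np.ndarray, bounds: np.ndarray, limits: np.ndarray):
    """Vectorised first bound crossing within per-trial sample limits.

    A: (..., n_trials, T) accumulator trajectories; bounds: (T,) positive bound;
    limits: (n_trials,) number of samples within which a crossing counts.
    Returns (crossed bool, idx0 int 0-based crossing index, sign at crossing).
    """
    T = A.shape[-1]
    within = np.arange(T) < np.asarray(limits)[..., :, None]
    over = (np.abs(A) > bounds) & within
    crossed = over.any(axis=-1)
    idx0 = np.argmax(over, axis=-1)
    a_at = np.take_along_axis(A, idx0[..., None], axis=-1)[..., 0]
    return crossed, idx0, np.where(a_at > 0, 1, 2)


def simulate_free_batch(
    ell: np.ndarray,
    lengths: np.ndarray,
    params: ObserverParams,
    Z: np.ndarray,
    U: np.ndarray,
    soa: float = SOA,
):
    """Simulate Free-task outcomes for many trials and noise draws at once.

    ell: (n_trials, T) padded decision updates; lengths: (n_trials,) valid
    sample counts; Z: (n_mc, n_trials, T) standard-normal inference-noise
    draws; U: (n_mc, n_trials) standard-normal non-decision-time draws.

    Returns dict with ``response_sample`` (1-based, capped at the trial
    length), ``choice``, ``cross_sample`` (0 where the bound was never
    reached), and ``rt`` in seconds.  A never-crossed trial resolves at the
    final sample by the sign of the accumulator.
    """
    T = ell.shape[-1]
    A = leaky_accumulate(ell[None, :, :] + params.sigma * Z, params.alpha)
    bounds = bound_schedule(T, params)
    crossed, idx0, sign_choice = batch_first_crossing(A, bounds, lengths)
    # resolve never-crossed trials at the last valid sample
    last_idx = (np.asarray(lengths) - 1)[None, :].repeat(A.shape[0], axis=0)
    a_last = np.take_along_axis(A, last_idx[..., None], axis=-1)[..., 0]
    choice = np.where(crossed, sign_choice, np.where(a_last > 0, 1, 2))
    cross_n = np.where(crossed, idx0 + 1, lengths[None, :])
    ndt = np.maximum(0.0, params.ndt_mu + params.ndt_sigma * U)
    resp = np.minimum(lengths[None, :], cross_n + (ndt / soa).astype(int))
    rt = cross_n * soa + ndt
    return {
        "response_sample": resp,
        "choice": choice,
        "cross_sample": np.where(crossed, idx0 + 1, 0),
        "rt": rt,
        "A": A,
    }


def simulate_replay_batch(
    ell: np.ndarray,
    n_shown: np.ndarray,
    params: ObserverParams,
    Z: np.ndarray,
    Zc: np.ndarray | None = None,
):
    """Simulate Replay-task outcomes (choice, optional confidence) in batch.

    ell: (n_trials, T) padded updates; n_shown: (n_trials,) samples shown
    before the cue; Z: (n_mc, n_trials, T) shared inference-noise draws;
    Zc: like Z, the extra confidence-noise draws (None skips confidence).

    With ``params.covert_bound`` a crossing at N <= n_shown freezes the
    perceptual choice at N; confidence accumulation always continues to the
    cue.  Returns dict with ``choice``, ``committed`` (0 = never), and
    ``confidence`` (ratings 1..4) when Zc is given.
    """
    n_shown = np.asarray(n_shown)
    x = ell[None, :, :] + params.sigma * Z
    A = leaky_accumulate(x, params.alpha)
    cue_idx = (n_shown - 1)[None, :].repeat(A.shape[0], axis=0)
    a_cue = np.take_along_axis(A, cue_idx[..., None], axis=-1)[..., 0]
    cue_choice = np.where(a_cue > 0, 1, 2)
    if params.covert_bound:
        bounds = bound_schedule(ell.shape[-1], params)
        crossed, idx0, sign_choice = batch_first_crossing(A, bounds, n_shown)
        choice = np.where(crossed, sign_choice, cue_choice)
        committed = np.where(crossed, idx0 + 1, 0)
    else:
        choice = cue_choice
        committed = np.zeros_like(choice)
    out = {"choice": choice, "committed": committed, "A": A}
    if Zc is not None:
        if params.conf_noise_locus == "per_sample":
            B = leaky_accumulate(x + params.conf_sigma * Zc, params.conf_alpha)
            b_cue = np.take_along_axis(B, cue_idx[..., None], axis=-1)[..., 0]
        else:  # single terminal noise draw
            B = leaky_accumulate(x, params.conf_alpha)
            b_cue = (
                np.take_along_axis(B, cue_idx[..., None], axis=-1)[..., 0]
                + params.conf_sigma * Zc[..., 0]
            )
        signed = np.where(choice == 1, b_cue, -b_cue)
        cb = confidence_bounds(n_shown, params)  # (3, n_trials)
        rating = 1 + (signed[None, ...] > cb[:, None, :]).sum(axis=0)
        out["confidence"] = rating
        out["conf_evidence"] = signed
        out["B"] = B
    return out


# ---------------------------------------------------------------------------
# single-trial conveniences
# ---------------------------------------------------------------------------

def simulate_free_trial(
    sequence: StimulusSequence,
    params: ObserverParams,
    model: CategoryModel,
    seed: int | np.random.Generator,
    soa: float = SOA,
) -> TrialOutcome:
    """Simulate one Free-task trial (response sample, choice, RT)."""
    rng = np.random.default_rng(seed)
    ell = decision_update(sequence.orientations, model)[None, :]
    lengths = np.array([len(sequence)])
    Z = rng.standard_normal((1, 1, ell.shape[-1]))
    U = rng.standard_normal((1, 1))
    sim = simulate_free_batch(ell, lengths, params, Z, U, soa=soa)
    cross = int(sim["cross_sample"][0, 0])
    return TrialOutcome(
        choice=int(sim["choice"][0, 0]),
        response_sample=int(sim["response_sample"][0, 0]),
        committed_sample=cross if cross > 0 else None,
        rt=float(sim["rt"][0, 0]),
        confidence=None,
    )


def simulate_replay_trial(
    sequence: StimulusSequence,
    n_shown: int,
    params: ObserverParams,
    model: CategoryModel,
    seed: int | np.random.Generator,
) -> TrialOutcome:
    """Simulate one Replay-task trial (cue-time choice; covert commitment)."""
    if not 1 <= n_shown <= len(sequence):
        raise ValueError(f"n_shown must be in [1, {len(sequence)}], got {n_shown}")
    rng = np.random.default_rng(seed)
    ell = decision_update(sequence.orientations[:n_shown], model)[None, :]
    Z = rng.standard_normal((1, 1, n_shown))
    Zc = rng.standard_normal((1, 1, n_shown))
    sim = simulate_replay_batch(ell, np.array([n_shown]), params, Z, Zc=Zc)
    committed = int(sim["committed"][0, 0])
    return TrialOutcome(
        choice=int(sim["choice"][0, 0]),
        response_sample=n_shown,
        committed_sample=committed if committed > 0 else None,
        rt=None,
        confidence=int(sim["confidence"][0, 0]),
    )


def simulate_confidence(
    sequence: StimulusSequence,
    n_shown: int,
    perceptual_choice: int,
    params: ObserverParams,
    model: CategoryModel,
    seed: int | np.random.Generator,
) -> int:
    """Simulate a 1-4 confidence rating for an already-made perceptual choice.

    The confidence accumulator runs over all ``n_shown`` samples with its own
    integration weight and extra noise on top of (freshly drawn) shared noisy
    evidence; the terminal evidence is signed by the perceptual choice and
    compared against the three confidence bounds evaluated at the cue.
    """
    if perceptual_choice not in (1, 2):
        raise ValueError("perceptual_choice must be 1 or 2")
    rng = np.random.default_rng(seed)
    ell = decision_update(sequence.orientations[:n_shown], model)
    x = ell + params.sigma * rng.standard_normal(n_shown)
    if params.conf_noise_locus == "per_sample":
        xc = x + params.conf_sigma * rng.standard_normal(n_shown)
        b = leaky_accumulate(xc, params.conf_alpha)[-1]
    else:
        b = leaky_accumulate(x, params.conf_alpha)[-1]
        b = b + params.conf_sigma * rng.standard_normal()
    signed = b if perceptual_choice == 1 else -b
    return int(1 + (signed > confidence_bounds(n_shown, params)).sum())
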