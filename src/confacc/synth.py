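"""One-stop synthetic cohort generator: behaviour plus linked neural epochs.

The generator emulates the structure of the experiment end to end.  Each
simulated observer runs the Free task on three repeats of the predefined
sequences; the Replay Less/Same/More sample counts are derived from their own
Free-task response counts; Replay choices and confidence ratings come from the
bounded accumulator with (optionally) a covert decision bound.

Stimulus-locked epochs follow a linear forward model with three encoding
variables, each with its own latency window and scalp topography, mimicking
the characteristic time courses of the evoked representations: a transient
orientation code over posterior channels (100-200 ms), a sustained
decision-update code over posterior-central channels (400-600 ms), and a
long-lived accumulated-evidence code over frontal+occipital channels
(600-800 ms).  Epoch-level representation noise on the accumulated-evidence
code is injected inside a fixed (electrode, time) "scan mask", with inflated
variance on trials whose responses deviate from the optimal observer — the
ground-truth effect the scan statistic is meant to recover.  After a covert
commitment, the accumulated-evidence encoding gain is attenuated for the
remaining samples of the trial.

Response-locked epochs carry a motor-band oscillation over left and right
motor channel groups; the oscillation over the hemisphere contralateral to
the response hand is suppressed (desynchronisation) from the time the
decision was made — at the covert commitment in committed Replay trials,
just before the key press otherwise — with a suppression depth that grows
with the decision evidence at that moment.

Ground truth (per-subject parameters, per-epoch injected noise, true scan
mask) is persisted next to the generated data and is never read by any
analysis stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .observer import (
    SOA,
    ObserverParams,
    decision_update,
    optimal_choice,
    simulate_free_batch,
    simulate_replay_batch,
)
from .behaviour import optimal_confidence_label
from .decoding import EpochTensor
from .tasks import (
    CategoryModel,
    derive_replay_lengths,
    make_predefined_sequences,
    replay_designs_to_frame,
    sequences_to_frame,
)

CONDITIONS = ("less", "same", "more")


@dataclass
class NeuralSpec:
    """Forward model of the synthetic epochs (sizes, latencies, noise)."""

    n_channels: int = 64
    fs: float = 256.0
    t_start: float = -0.1
    t_end: float = 0.9
    # latency windows (s) per encoding variable
    window_orientation: tuple = (0.10, 0.20)
    window_update: tuple = (0.40, 0.60)
    window_accumulated: tuple = (0.60, 0.80)
    gain_orientation: float = 1.0
    gain_update: float = 1.0
    gain_accumulated: float = 2.0
    sensor_noise_sd: float = 1.0
    linking_noise_sd: float = 0.8       # SD of the epoch-level L* deviation
    nonoptimal_inflation: float = 2.0   # linking-noise SD multiplier, non-optimal trials
    commitment_attenuation: float = 0.1  # accumulated-evidence gain after commitment
    # response-locked epochs
    resp_t_start: float = -1.5
    resp_t_end: float = 0.25
    motor_freq: float = 20.0
    motor_amp_base: float = 3.0          # baseline motor-band oscillation amplitude
    motor_suppression: float = 0.25      # contralateral desynchronisation depth
    motor_suppression_evidence: float = 0.2   # extra suppression per unit |evidence|
    motor_ramp_s: float = 0.4           # suppression rise time after the decision
    motor_lead_s: float = 0.3           # preparation lead before an overt response


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_subjects: int = 20
    n_sequences: int = 100
    repeats: int = 3
    max_samples: int = 40
    kappa: float = 0.5
    covert_bound: bool = True
    seed: int = 0
    # parameter priors: uniform ranges per observer parameter
    priors: dict = field(default_factory=lambda: {
        "sigma": (0.2, 1.0),
        "alpha": (0.85, 1.2),
    })
    base_params: ObserverParams = field(default_factory=ObserverParams)
    neural: NeuralSpec = field(default_factory=NeuralSpec)
    per_subject_sequences: bool = False
    include_epochs: bool = True

    def validate(self) -> None:
        problems = []
        if self.n_subjects < 1:
            problems.append("n_subjects must be >= 1")
        if self.n_sequences < 2 or self.n_sequences % 2:
            problems.append("n_sequences must be even and >= 2")
        if self.repeats != 3:
            problems.append("repeats must be 3 (Less/Same/More need three counts)")
        for name, (lo, hi) in self.priors.items():
            if not lo <= hi:
                problems.append(f"empty prior range for {name}")
        if problems:
            raise ValueError("invalid cohort spec: " + "; ".join(problems))


def scalp_montage(n_channels: int) -> tuple[list, np.ndarray]:
    """Deterministic schematic montage: golden-angle spiral in the unit disc.

    y > 0 is anterior.  Returns labels and (n_channels, 2) positions.
    """
    k = np.arange(n_channels)
    r = 0.95 * np.sqrt((k + 0.5) / n_channels)
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    pos = np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)
    labels = [f"CH{i:02d}" for i in range(n_channels)]
    return labels, pos


def _gauss_bump(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    centre = 0.5 * (window[0] + window[1])
    sd = (window[1] - window[0]) / 4.0
    return np.exp(-0.5 * ((times - centre) / sd) ** 2)


def _channel_map(pos: np.ndarray, region: str, rng: np.random.Generator) -> np.ndarray:
    """Smooth loading map concentrated on a scalp region, unit norm."""
    x, y = pos[:, 0], pos[:, 1]
    if region == "posterior":
        w = np.exp(-((y + 0.6) ** 2) / 0.18)
    elif region == "central":
        w = np.exp(-(y**2) / 0.18)
    elif region == "frontal_occipital":
        w = np.exp(-((y - 0.6) ** 2) / 0.18) + np.exp(-((y + 0.6) ** 2) / 0.18)
    elif region == "motor_left":
        w = np.exp(-((x + 0.5) ** 2 + y**2) / 0.15)
    elif region == "motor_right":
        w = np.exp(-((x - 0.5) ** 2 + y**2) / 0.15)
    else:
        raise ValueError(f"unknown region {region!r}")
    w = w * (1.0 + 0.2 * rng.standard_normal(w.size))
    return w / np.linalg.norm(w)


@dataclass
class GroundTruth:
    """Write-only record of what the generator injected."""

    subject_params: dict
    scan_mask: np.ndarray | None
    epoch_noise: np.ndarray | None

    def save(self, path) -> None:
        payload = {
            "subject_params": self.subject_params,
            "scan_mask": None if self.scan_mask is None
            else self.scan_mask.astype(int).tolist(),
            "epoch_noise": None if self.epoch_noise is None
            else np.round(self.epoch_noise, 6).tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def _draw_subject_params(spec: CohortSpec, rng: np.random.Generator) -> ObserverParams:
    overrides = {
        name: float(rng.uniform(lo, hi)) for name, (lo, hi) in spec.priors.items()
    }
    overrides["covert_bound"] = spec.covert_bound
    return spec.base_params.with_(**overrides)


def simulate_subject_behaviour(
    subject_id: int,
    sequences,
    params: ObserverParams,
    model: CategoryModel,
    rng: np.random.Generator,
    repeats: int = 3,
) -> tuple[pd.DataFrame, list]:
    """Free task (three repeats), Replay design derivation, and Replay trials."""
    n_seq = len(sequences)
    T = max(len(s) for s in sequences)
    ell = np.zeros((n_seq, T))
    lengths = np.zeros(n_seq, dtype=int)
    cats = np.zeros(n_seq, dtype=int)
    for i, seq in enumerate(sequences):
        ell[i, : len(seq)] = decision_update(seq.orientations, model)
        lengths[i] = len(seq)
        cats[i] = seq.category

    Z = rng.standard_normal((repeats, n_seq, T))
    U = rng.standard_normal((repeats, n_seq))
    free = simulate_free_batch(ell, lengths, params, Z, U)

    rows = []
    for rep in range(repeats):
        for i, seq in enumerate(sequences):
            cross = int(free["cross_sample"][rep, i])
            rows.append({
                "subject_id": subject_id, "task": "free", "condition": "free",
                "sequence_id": seq.sequence_id, "repeat": rep + 1,
                "n_shown": int(free["response_sample"][rep, i]),
                "choice": int(free["choice"][rep, i]),
                "response_sample": int(free["response_sample"][rep, i]),
                "committed_sample": cross if cross else np.nan,
                "rt_s": float(free["rt"][rep, i]),
                "confidence": np.nan,
                "true_category": int(cats[i]),
            })

    designs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # p_min floor warnings summarised below
        for i, seq in enumerate(sequences):
            d = derive_replay_lengths(
                seq.sequence_id, free["response_sample"][:, i]
            )
            designs.append(d)
    n_capped = sum(d.n_more > lengths[i] for i, d in enumerate(designs))
    if n_capped:
        warnings.warn(
            f"subject {subject_id}: More count capped at sequence length on "
            f"{n_capped} sequences", stacklevel=2,
        )

    n_shown_by_cond = {
        "less": np.array([d.n_less for d in designs]),
        "same": np.array([d.n_same for d in designs]),
        "more": np.array([min(d.n_more, int(lengths[i])) for i, d in enumerate(designs)]),
    }
    for cond in CONDITIONS:
        n_shown = n_shown_by_cond[cond]
        Zr = rng.standard_normal((1, n_seq, T))
        Zc = rng.standard_normal((1, n_seq, T))
        sim = simulate_replay_batch(ell, n_shown, params, Zr, Zc=Zc)
        for i, seq in enumerate(sequences):
            committed = int(sim["committed"][0, i])
            rows.append({
                "subject_id": subject_id, "task": "replay", "condition": cond,
                "sequence_id": seq.sequence_id, "repeat": 1,
                "n_shown": int(n_shown[i]),
                "choice": int(sim["choice"][0, i]),
                "response_sample": int(n_shown[i]),
                "committed_sample": committed if committed else np.nan,
                "rt_s": np.nan,
                "confidence": int(sim["confidence"][0, i]),
                "true_category": int(cats[i]),
            })
    return pd.DataFrame(rows), designs


def _annotate_optimality(trials: pd.DataFrame, sequences, model: CategoryModel):
    """Optimal-observer reference labels for Replay trials, per subject."""
    seqmap = {s.sequence_id: s for s in sequences}
    trials = trials.copy()
    L_term = np.array([
        decision_update(
            seqmap[sid].orientations[:n], model
        ).sum()
        for sid, n in zip(trials["sequence_id"], trials["n_shown"].astype(int))
    ])
    trials["L_terminal"] = L_term
    trials["perceptual_optimal"] = (
        trials["choice"].to_numpy() == optimal_choice(L_term)
    )
    # evidence for the chosen category
    L_chosen = np.where(trials["choice"].to_numpy() == 1, L_term, -L_term)
    trials["L_chosen"] = L_chosen
    conf_opt = np.zeros(len(trials), dtype=bool)
    for subj, idx in trials.groupby("subject_id").indices.items():
        replay = idx[(trials["task"].to_numpy()[idx] == "replay")]
        if replay.size >= 2:
            high_opt = optimal_confidence_label(L_chosen[replay])
            high_obs = trials["confidence"].to_numpy()[replay] >= 3
            conf_opt[replay] = high_obs == high_opt
    trials["confidence_optimal"] = conf_opt
    return trials


def _stimulus_epochs(
    trials: pd.DataFrame,
    sequences,
    model: CategoryModel,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> tuple[EpochTensor, np.ndarray, np.ndarray]:
    """Forward-model stimulus-locked epochs for all Replay trials."""
    ns = spec.neural
    seqmap = {s.sequence_id: s for s in sequences}
    times = np.arange(
        round(ns.t_start * ns.fs), round(ns.t_end * ns.fs)
    ) / ns.fs
    labels_ch, pos = scalp_montage(ns.n_channels)
    map_rng = np.random.default_rng(spec.seed + 101)  # maps shared by all subjects
    maps = {
        "sin": _channel_map(pos, "posterior", map_rng),
        "cos": _channel_map(pos, "posterior", map_rng),
        "update": _channel_map(pos, "central", map_rng),
        "accum": _channel_map(pos, "frontal_occipital", map_rng),
    }
    bumps = {
        "sin": _gauss_bump(times, ns.window_orientation),
        "cos": _gauss_bump(times, ns.window_orientation),
        "update": _gauss_bump(times, ns.window_update),
        "accum": _gauss_bump(times, ns.window_accumulated),
    }
    # true scan mask: cells carrying the behaviour-linked part of the L code
    mask = (
        (np.abs(maps["accum"])[:, None] > np.quantile(np.abs(maps["accum"]), 0.85))
        & (bumps["accum"][None, :] > 0.5)
    )

    replay = trials[trials["task"] == "replay"].reset_index(drop=True)
    rows = []
    for t_idx, tr in replay.iterrows():
        seq = seqmap[tr["sequence_id"]]
        ell = decision_update(seq.orientations, model)
        L = np.cumsum(ell)
        committed = tr["committed_sample"]
        committed = int(committed) if np.isfinite(committed) else 0
        for n in range(1, int(tr["n_shown"]) + 1):
            theta = seq.orientations[n - 1]
            rows.append({
                "subject_id": tr["subject_id"], "trial": t_idx,
                "sequence_id": tr["sequence_id"], "condition": tr["condition"],
                "sample_index": n, "n_shown": int(tr["n_shown"]),
                "theta": theta, "sin2theta": np.sin(2 * theta),
                "cos2theta": np.cos(2 * theta),
                "update": ell[n - 1], "accumulated": L[n - 1],
                "post_commitment": bool(committed and n > committed),
                "perceptual_optimal": bool(tr["perceptual_optimal"]),
                "confidence_optimal": bool(tr["confidence_optimal"]),
                "choice": int(tr["choice"]),
            })
    lab = pd.DataFrame(rows)
    n_epochs = len(lab)
    eta_sd = ns.linking_noise_sd * np.where(
        lab["perceptual_optimal"].to_numpy(), 1.0, ns.nonoptimal_inflation
    )
    eta = rng.standard_normal(n_epochs) * eta_sd
    gain_acc = ns.gain_accumulated * np.where(
        lab["post_commitment"].to_numpy(), ns.commitment_attenuation, 1.0
    )
    data = np.empty((n_epochs, ns.n_channels, times.size), dtype=np.float32)
    base = (
        ns.gain_orientation * lab["sin2theta"].to_numpy()[:, None, None]
        * maps["sin"][None, :, None] * bumps["sin"][None, None, :]
        + ns.gain_orientation * lab["cos2theta"].to_numpy()[:, None, None]
        * maps["cos"][None, :, None] * bumps["cos"][None, None, :]
        + ns.gain_update * lab["update"].to_numpy()[:, None, None]
        * maps["update"][None, :, None] * bumps["update"][None, None, :]
        + gain_acc[:, None, None] * lab["accumulated"].to_numpy()[:, None, None]
        * maps["accum"][None, :, None] * bumps["accum"][None, None, :]
    )
    linked = (
        eta[:, None, None]
        * (maps["accum"][:, None] * bumps["accum"][None, :] * mask)[None, :, :]
    )
    data[:] = base + linked + ns.sensor_noise_sd * rng.standard_normal(base.shape)
    epochs = EpochTensor(
        data=data, times=times, channel_labels=labels_ch, channel_pos=pos,
        lock="stimulus",
        trial_link=lab[["subject_id", "trial", "sample_index"]].copy(),
        labels=lab,
    )
    return epochs, mask, eta


def _response_epochs(
    trials: pd.DataFrame,
    sequences,
    model: CategoryModel,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> EpochTensor:
    """Response-locked epochs with a choice-lateralised motor-band oscillation."""
    ns = spec.neural
    seqmap = {s.sequence_id: s for s in sequences}
    times = np.arange(
        round(ns.resp_t_start * ns.fs), round(ns.resp_t_end * ns.fs)
    ) / ns.fs
    labels_ch, pos = scalp_montage(ns.n_channels)
    map_rng = np.random.default_rng(spec.seed + 202)
    map_l = _channel_map(pos, "motor_left", map_rng)
    map_r = _channel_map(pos, "motor_right", map_rng)

    sel = trials.reset_index(drop=True)
    rows = []
    data = np.empty((len(sel), ns.n_channels, times.size), dtype=np.float32)
    for i, tr in sel.iterrows():
        seq = seqmap[tr["sequence_id"]]
        ell = decision_update(seq.orientations, model)
        n_shown = int(tr["n_shown"])
        committed = tr["committed_sample"]
        committed = int(committed) if np.isfinite(committed) else 0
        if committed:
            # decision made (n_shown - committed) samples before the cue
            t_decision = -(n_shown - committed) * SOA - ns.motor_lead_s
            evidence = np.abs(np.cumsum(ell)[committed - 1])
        else:
            t_decision = -ns.motor_lead_s
            evidence = np.abs(np.cumsum(ell)[n_shown - 1])
        # motor preparation = contralateral desynchronisation: the motor-band
        # oscillation over the hemisphere contralateral to the response hand is
        # suppressed from the decision time on, more deeply for stronger evidence
        supp = np.clip(
            ns.motor_suppression + ns.motor_suppression_evidence * evidence, 0, 0.95
        )
        ramp = np.clip((times - t_decision) / ns.motor_ramp_s, 0.0, 1.0)
        osc_l = np.sin(2 * np.pi * ns.motor_freq * times + rng.uniform(0, 2 * np.pi))
        osc_r = np.sin(2 * np.pi * ns.motor_freq * times + rng.uniform(0, 2 * np.pi))
        # choice 1 = left hand -> right hemisphere suppressed
        amp_l = ns.motor_amp_base * (1 - supp * ramp * (int(tr["choice"]) == 2))
        amp_r = ns.motor_amp_base * (1 - supp * ramp * (int(tr["choice"]) == 1))
        data[i] = (
            map_l[:, None] * (amp_l * osc_l)[None, :]
            + map_r[:, None] * (amp_r * osc_r)[None, :]
            + ns.sensor_noise_sd * rng.standard_normal((ns.n_channels, times.size))
        )
        rows.append({
            "subject_id": tr["subject_id"], "trial": i, "sample_index": n_shown,
            "sequence_id": tr["sequence_id"],
            "condition": tr["condition"], "task": tr["task"],
            "n_shown": n_shown, "choice": int(tr["choice"]),
            "committed_sample": committed,
        })
    lab = pd.DataFrame(rows)
    return EpochTensor(
        data=data, times=times, channel_labels=labels_ch, channel_pos=pos,
        lock="response",
        trial_link=lab[["subject_id", "trial", "sample_index"]].copy(),
        labels=lab,
    )


def generate_cohort(spec: CohortSpec, outdir: str | Path | None = None) -> dict:
    """Generate a complete synthetic cohort, reproducible from ``spec.seed``.

    Returns a dict with ``sequences``, ``replay_design``, ``trials`` (the
    behavioural table), ``stim_epochs``/``resp_epochs`` (when
    ``spec.include_epochs``), and ``ground_truth``.  When ``outdir`` is given,
    the standard files (sequences.csv, replay_design.csv, trials.csv,
    epochs_stim.h5, epochs_resp.h5, ground_truth.json) are written there.
    """
    spec.validate()
    model = CategoryModel(kappa=spec.kappa)
    root = np.random.SeedSequence(spec.seed)
    seq_seed, *subj_seeds = root.spawn(spec.n_subjects + 1)

    cohort_sequences = make_predefined_sequences(
        spec.n_sequences, spec.max_samples, model,
        seed=int(seq_seed.generate_state(1)[0] % (2**31)),
    )

    all_trials = []
    designs_frames = []
    subject_params: dict = {}
    per_subject_seqs = {}
    for s in range(spec.n_subjects):
        rng = np.random.default_rng(subj_seeds[s])
        params = _draw_subject_params(spec, rng)
        subject_params[str(s)] = params.to_dict()
        if spec.per_subject_sequences:
            seqs = make_predefined_sequences(
                spec.n_sequences, spec.max_samples, model,
                seed=int(rng.integers(2**31 - 1)),
            )
        else:
            seqs = cohort_sequences
        per_subject_seqs[s] = seqs
        trials, designs = simulate_subject_behaviour(
            s, seqs, params, model, rng, repeats=spec.repeats
        )
        trials = _annotate_optimality(trials, seqs, model)
        all_trials.append(trials)
        frame = replay_designs_to_frame(designs)
        frame.insert(0, "subject_id", s)
        designs_frames.append(frame)
    trials = pd.concat(all_trials, ignore_index=True)
    replay_design = pd.concat(designs_frames, ignore_index=True)

    out = {
        "sequences": cohort_sequences,
        "per_subject_sequences": per_subject_seqs,
        "trials": trials,
        "replay_design": replay_design,
        "model": model,
    }
    mask = eta = None
    if spec.include_epochs:
        stim_list, resp_list, etas = [], [], []
        for s in range(spec.n_subjects):
            erng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, 7919, s])
            )
            subj_trials = trials[trials["subject_id"] == s]
            stim, mask, eta_s = _stimulus_epochs(
                subj_trials, per_subject_seqs[s], model, spec, erng
            )
            resp = _response_epochs(
                subj_trials, per_subject_seqs[s], model, spec, erng
            )
            stim_list.append(stim)
            resp_list.append(resp)
            etas.append(eta_s)
        out["stim_epochs"] = _concat_epochs(stim_list)
        out["resp_epochs"] = _concat_epochs(resp_list)
        eta = np.concatenate(etas)
        out["scan_mask"] = mask
    ground_truth = GroundTruth(
        subject_params=subject_params, scan_mask=mask, epoch_noise=eta
    )
    out["ground_truth"] = ground_truth

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sequences_to_frame(cohort_sequences).to_csv(
            outdir / "sequences.csv", index=False
        )
        replay_design.to_csv(outdir / "replay_design.csv", index=False)
        trials.to_csv(outdir / "trials.csv", index=False)
        if spec.include_epochs:
            out["stim_epochs"].save(outdir / "epochs_stim.h5")
            out["resp_epochs"].save(outdir / "epochs_resp.h5")
        ground_truth.save(outdir / "ground_truth.json")
    return out


def _concat_epochs(parts: list[EpochTensor]) -> EpochTensor:
    return EpochTensor(
        data=np.concatenate([p.data for p in parts], axis=0),
        times=parts[0].times,
        channel_labels=parts[0].channel_labels,
        channel_pos=parts[0].channel_pos,
        lock=parts[0].lock,
        trial_link=pd.concat([p.trial_link for p in parts], ignore_index=True),
        labels=pd.concat([p.labels for p in parts], ignore_index=True),
    )


def parameter_recovery_suite(
    spec: CohortSpec,
    n_replicates: int = 20,
    n_mc: int = 300,
    n_starts: int = 2,
    free: tuple = ("sigma", "alpha"),
    seed: int | None = None,
) -> dict:
    """Simulate-and-refit loop: per-parameter recovery over synthetic observers.

    Each replicate draws one observer from the priors, simulates their full
    session, and refits the free parameters on the Replay-task choices.
    Returns bias, RMSE, and truth-estimate correlation per parameter.
    """
    from .fitting import ModelVariant, fit_observer

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if n_replicates < 10:
        warnings.warn("fewer than 10 replicates gives unstable recovery metrics",
                      stacklevel=2)
    model = CategoryModel(kappa=spec.kappa)
    base_seed = spec.seed if seed is None else seed
    truths = {name: [] for name in free}
    fits = {name: [] for name in free}
    for rep in range(n_replicates):
        rng = np.random.default_rng(base_seed + 1000 + rep)
        params = _draw_subject_params(spec, rng)
        seqs = make_predefined_sequences(
            spec.n_sequences, spec.max_samples, model,
            seed=int(rng.integers(2**31 - 1)),
        )
        trials, _ = simulate_subject_behaviour(rep, seqs, params, model, rng)
        replay = trials[trials["task"] == "replay"]
        variant = ModelVariant(
            name="recovery", free=free,
            base=params.with_(**{name: getattr(ObserverParams(), name)
                                 for name in free}),
            likelihood="replay_choice",
        )
        fit = fit_observer(
            replay, seqs, model, variant,
            n_mc=n_mc, seed=base_seed + 2000 + rep, n_starts=n_starts,
        )
        for name in free:
            truths[name].append(getattr(params, name))
            fits[name].append(getattr(fit.params, name))
    report = {}
    for name in free:
        t = np.array(truths[name])
        f = np.array(fits[name])
        report[name] = {
            "bias": float((f - t).mean()),
            "rmse": float(np.sqrt(((f - t) ** 2).mean())),
            "correlation": float(np.corrcoef(t, f)[0, 1]) if t.std() > 0 else np.nan,
            "truth": t.tolist(),
            "estimate": f.tolist(),
        }
    report["n_replicates"] = n_replicates
    return report
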