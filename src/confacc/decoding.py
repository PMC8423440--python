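"""Model-based decoding of encoding variables from multichannel epochs.

Stimulus-locked epochs are summarised by band-limited analytic-signal features
and decoded with ridge regression (10-fold cross-validation, ridge penalty 1).
Representation precision is the Fisher transform of the Pearson correlation
between held-out predictions and the encoding variable, pooled over folds.
Temporal generalisation applies weights trained at one time point to data from
another.  Response classification uses linear discriminant analysis of band
power, scored by ROC AUC, with a per-trial prediction strength given by the
relative normalised Euclidean distance to the class means in discriminant
space.  Precision contrasts between outcome cells or conditions are assessed
with sign-flip cluster permutation over subjects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, fftconvolve, hilbert
from scipy.stats import t as t_dist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import Ridge
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold, KFold

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class EpochTensor:
    """Stimulus- or response-locked multichannel epochs with per-epoch labels.

    ``data`` is (n_epochs, n_channels, n_times); ``trial_link`` and ``labels``
    are per-epoch tables (subject, trial, sample index; encoding variables and
    outcome flags).
    """

    data: np.ndarray
    times: np.ndarray
    channel_labels: list
    channel_pos: np.ndarray          # (n_channels, 2) schematic scalp x,y
    lock: str                        # "stimulus" | "response"
    trial_link: pd.DataFrame
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_times)")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.isnan(self.data).any():
            raise ValueError("epochs must not contain missing values")
        if len(self.trial_link) != self.data.shape[0]:
            raise ValueError("every epoch must be linked to a trial row")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times", data=self.times)
            f.create_dataset(
                "channels/labels",
                data=np.array(self.channel_labels, dtype=h5py.string_dtype()),
            )
            f.create_dataset("channels/pos", data=self.channel_pos)
            f.attrs["lock"] = self.lock
            for name, frame in (("trial_link", self.trial_link), ("labels", self.labels)):
                grp = f.create_group(name)
                grp.attrs["columns"] = list(frame.columns)
                for col in frame.columns:
                    vals = frame[col].to_numpy()
                    if vals.dtype == object:
                        vals = vals.astype(h5py.string_dtype())
                    grp.create_dataset(col, data=vals)

    @classmethod
    def load(cls, path) -> "EpochTensor":
        with h5py.File(path, "r") as f:
            def read_frame(name):
                grp = f[name]
                cols = list(grp.attrs["columns"])
                data = {}
                for col in cols:
                    v = grp[col][()]
                    if v.dtype.kind in ("S", "O"):
                        v = np.array([s.decode() if isinstance(s, bytes) else s for s in v])
                    data[col] = v
                return pd.DataFrame(data)

            return cls(
                data=f["data"][()],
                times=f["times"][()],
                channel_labels=[
                    s.decode() if isinstance(s, bytes) else s
                    for s in f["channels/labels"][()]
                ],
                channel_pos=f["channels/pos"][()],
                lock=f.attrs["lock"],
                trial_link=read_frame("trial_link"),
                labels=read_frame("labels"),
            )


@dataclass
class PrecisionCurve:
    """Fisher-z representation precision per time point (or time-by-time)."""

    z: np.ndarray
    n_epochs: int
    times: np.ndarray | None = None


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def hilbert_features(
    data: np.ndarray, fs: float, band: tuple[float, float] = (1.0, 8.0)
) -> np.ndarray:
    """Band-limited analytic-signal features: real and imaginary parts.

    Zero-phase Butterworth bandpass along time then Hilbert transform; the
    channel axis doubles (real parts first, imaginary parts second).
    """
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError(f"invalid band {band}")
    if fs < 4.0 * hi:
        raise ValueError(
            f"sampling rate {fs} Hz too low for band top {hi} Hz (need >= 4x)"
        )
    b, a = butter(4, [lo, hi], btype="band", fs=fs)
    filtered = filtfilt(b, a, data, axis=-1)
    analytic = hilbert(filtered, axis=-1)
    return np.concatenate([analytic.real, analytic.imag], axis=-2)


def wavelet_power(
    data: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    smoothing: float = 0.25,
) -> np.ndarray:
    """Time-frequency power via complex Morlet convolution.

    Each taper has spectral bandwidth ``smoothing`` (fractional, default 25%)
    of its centre frequency.  Returns (..., n_freqs, n_times); the epoch must
    span at least three cycles of the lowest frequency.
    """
    data = np.asarray(data, dtype=float)
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    n_times = data.shape[-1]
    if n_times / fs < 3.0 / freqs.min():
        raise ValueError(
            f"epoch of {n_times / fs:.3f}s too short for {freqs.min()} Hz "
            "(need >= 3 cycles)"
        )
    out = np.empty(data.shape[:-1] + (freqs.size, n_times))
    for i, f0 in enumerate(freqs):
        sigma_f = smoothing * f0
        sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
        half = int(np.ceil(4 * sigma_t * fs))
        t = np.arange(-half, half + 1) / fs
        wavelet = np.exp(2j * np.pi * f0 * t) * np.exp(-(t**2) / (2 * sigma_t**2))
        # unit-energy normalisation: white-noise power is flat across tapers
        # even though the absolute bandwidth grows with centre frequency
        wavelet /= np.linalg.norm(wavelet)
        conv = fftconvolve(
            data[..., None, :], wavelet.reshape((1,) * data.ndim + (-1,)), mode="same",
            axes=-1,
        )
        out[..., i, :] = np.abs(conv[..., 0, :]) ** 2
    return out


# ---------------------------------------------------------------------------
# ridge decoding
# ---------------------------------------------------------------------------

def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    return np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))


def circular_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Circular correlation (Jammalamadaka-SenGupta) of two angle vectors."""
    sa = np.sin(a - np.angle(np.exp(1j * a).mean()))
    sb = np.sin(b - np.angle(np.exp(1j * b).mean()))
    denom = np.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0:
        raise ValueError("undefined circular correlation (constant angles)")
    return float((sa * sb).sum() / denom)


def _folds(n_epochs: int, n_folds: int, seed: int, groups=None):
    if groups is not None:
        splitter = GroupKFold(n_splits=min(n_folds, len(np.unique(groups))))
        return list(splitter.split(np.arange(n_epochs), groups=groups))
    splitter = KFold(n_splits=min(n_folds, n_epochs), shuffle=True, random_state=seed)
    return list(splitter.split(np.arange(n_epochs)))


def _check_target(target: np.ndarray) -> np.ndarray:
    target = np.asarray(target, dtype=float)
    flat = target.reshape(len(target), -1)
    if np.any(flat.std(axis=0) == 0):
        raise ValueError("undefined correlation: constant decoding target")
    return target


def _as3d(features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    if features.ndim == 2:
        features = features[..., None]
    return features


def cv_predictions(
    features: np.ndarray,
    target: np.ndarray,
    n_folds: int = 10,
    ridge: float = 1.0,
    groups=None,
    seed: int = 0,
    return_folds: bool = False,
):
    """Cross-validated ridge predictions per time point.

    features: (n_epochs, n_features, n_times); target: (n_epochs,) or
    (n_epochs, k).  Returns predictions of shape target.shape + (n_times,)
    (and, with ``return_folds``, the per-epoch fold id).
    """
    features = _as3d(features)
    target = _check_target(target)
    n_epochs, _, n_times = features.shape
    preds = np.empty(target.shape + (n_times,))
    fold_id = np.empty(n_epochs, dtype=int)
    for k, (train, test) in enumerate(_folds(n_epochs, n_folds, seed, groups)):
        fold_id[test] = k
        for ti in range(n_times):
            model = Ridge(alpha=ridge).fit(features[train, :, ti], target[train])
            preds[test, ..., ti] = model.predict(features[test, :, ti])
    if return_folds:
        return preds, fold_id
    return preds


def _fold_centred(x: np.ndarray, fold_id: np.ndarray | None) -> np.ndarray:
    """Remove the per-fold mean — the cross-validation pooling artifact.

    Pooled held-out predictions carry each fold's training-set mean in their
    intercept, which anti-correlates with that fold's held-out targets and
    biases the pooled correlation; centring predictions and targets within
    fold before pooling restores the null distribution of r.
    """
    if fold_id is None:
        return x - x.mean()
    out = np.asarray(x, dtype=float).copy()
    for k in np.unique(fold_id):
        out[fold_id == k] -= out[fold_id == k].mean()
    return out


def precision_from_predictions(
    preds: np.ndarray,
    target: np.ndarray,
    orientation: bool = False,
    fold_id: np.ndarray | None = None,
) -> np.ndarray:
    """Fisher-z precision per time point from pooled held-out predictions."""
    target = np.asarray(target, dtype=float)
    n_times = preds.shape[-1]
    z = np.empty(n_times)
    for ti in range(n_times):
        if orientation:
            pred_angle = 0.5 * np.arctan2(preds[:, 0, ti], preds[:, 1, ti])
            true_angle = 0.5 * np.arctan2(target[:, 0], target[:, 1])
            r = circular_corr(2 * pred_angle, 2 * true_angle)
        else:
            a = _fold_centred(preds[..., ti].ravel(), fold_id)
            b = _fold_centred(target.ravel(), fold_id)
            r = np.corrcoef(a, b)[0, 1]
        z[ti] = fisher_z(r)
    return z


def null_precision_distribution(
    predictions: np.ndarray, n_null: int = 500, seed: int = 0
) -> np.ndarray:
    """Null draws of the Fisher-z precision for fixed held-out predictions.

    Scores the predictions against independent standard-normal targets; the
    resulting z values follow the Fisher null (SD ~ 1/sqrt(n-3)), which is
    the reference distribution for assessing decoding significance.  (The
    pooled cross-validated r under joint train-and-score target shuffling is
    slightly over-dispersed relative to this null because every fold's
    weights are trained on the targets scored in other folds.)
    """
    predictions = np.asarray(predictions, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    zs = np.empty(n_null)
    for i in range(n_null):
        y = rng.standard_normal(predictions.size)
        zs[i] = fisher_z(np.corrcoef(predictions, y)[0, 1])
    return zs


def ridge_decode(
    features: np.ndarray,
    target: np.ndarray,
    n_folds: int = 10,
    ridge: float = 1.0,
    groups=None,
    seed: int = 0,
    times: np.ndarray | None = None,
    orientation: bool = False,
) -> PrecisionCurve:
    """Cross-validated ridge decoding of one encoding variable.

    Precision per time point is atanh(Pearson r) between held-out predictions
    (pooled over folds) and the target.  For ``orientation=True`` the target
    must be the (sin 2theta, cos 2theta) pair; precision is computed on the
    reconstructed angle with a circular correlation.
    """
    if len(features) < 2:
        raise ValueError("need at least two epochs")
    preds, fold_id = cv_predictions(
        features, target, n_folds, ridge, groups, seed, return_folds=True
    )
    z = precision_from_predictions(
        preds, target, orientation=orientation, fold_id=fold_id
    )
    return PrecisionCurve(z=z, n_epochs=len(features), times=times)


def temporal_generalization(
    features: np.ndarray,
    target: np.ndarray,
    n_folds: int = 10,
    ridge: float = 1.0,
    groups=None,
    seed: int = 0,
    train_times=None,
    test_times=None,
) -> PrecisionCurve:
    """Precision matrix from training at one time and testing at another.

    Returns z of shape (n_train_times, n_test_times); the diagonal (for
    identical train/test grids) equals the ``ridge_decode`` output because the
    folds and fits are shared.
    """
    features = _as3d(features)
    target = _check_target(target)
    if target.ndim != 1:
        raise ValueError("temporal generalisation expects a scalar target")
    n_epochs, _, n_times = features.shape
    train_times = np.arange(n_times) if train_times is None else np.asarray(train_times)
    test_times = np.arange(n_times) if test_times is None else np.asarray(test_times)
    preds = np.empty((n_epochs, train_times.size, test_times.size))
    fold_id = np.empty(n_epochs, dtype=int)
    for k, (train, test) in enumerate(_folds(n_epochs, n_folds, seed, groups)):
        fold_id[test] = k
        for i, t1 in enumerate(train_times):
            model = Ridge(alpha=ridge).fit(features[train, :, t1], target[train])
            # apply the t1 weights at every test time at once
            block = features[test][:, :, test_times]
            preds[test, i, :] = (
                np.einsum("ecT,c->eT", block, model.coef_) + model.intercept_
            )
    z = np.empty((train_times.size, test_times.size))
    tc = _fold_centred(target, fold_id)
    for i in range(train_times.size):
        for j in range(test_times.size):
            pc = _fold_centred(preds[:, i, j], fold_id)
            z[i, j] = fisher_z(np.corrcoef(pc, tc)[0, 1])
    return PrecisionCurve(z=z, n_epochs=n_epochs)


# ---------------------------------------------------------------------------
# cluster permutation over subjects
# ---------------------------------------------------------------------------

@dataclass
class TimeCluster:
    start: int
    stop: int           # exclusive
    mass: float
    p_value: float


def _contiguous_clusters(stat: np.ndarray, crit: float, sign: int):
    above = sign * stat > crit
    clusters = []
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j < above.size and above[j]:
                j += 1
            clusters.append((i, j, float(stat[i:j].sum())))
            i = j
        else:
            i += 1
    return clusters


def cluster_permutation_test(
    effects: np.ndarray,
    n_perm: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    tail: int = 0,
) -> list[TimeCluster]:
    """Sign-flip cluster-mass permutation test over subjects.

    ``effects`` is (n_subjects, n_times); per-time one-sample t statistics are
    thresholded at the two-sided alpha critical value, contiguous
    supra-threshold runs form clusters scored by summed t, and the null is the
    maximum cluster mass over subject-level sign flips.  ``tail`` of +1/-1
    restricts to positive/negative clusters.
    """
    effects = np.asarray(effects, dtype=float)
    n_subj = effects.shape[0]
    crit = t_dist.ppf(1 - alpha / 2, df=n_subj - 1)

    def tstats(x):
        sd = x.std(axis=0, ddof=1)
        sd = np.where(sd == 0, np.inf, sd)
        return x.mean(axis=0) / (sd / np.sqrt(n_subj))

    t_obs = tstats(effects)
    signs = [1, -1] if tail == 0 else [tail]
    observed = []
    for s in signs:
        observed.extend((s, c) for c in _contiguous_clusters(t_obs, crit, s))
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=(n_subj, 1))
        t_p = tstats(effects * flips)
        masses = [0.0]
        for s in signs:
            masses.extend(abs(c[2]) for c in _contiguous_clusters(t_p, crit, s))
        null_max[p] = max(masses)
    out = []
    for s, (i, j, mass) in observed:
        p_val = float((null_max >= abs(mass)).mean())
        p_val = max(p_val, 1.0 / n_perm)
        out.append(TimeCluster(start=i, stop=j, mass=mass, p_value=p_val))
    return out


# ---------------------------------------------------------------------------
# precision contrasts
# ---------------------------------------------------------------------------

def _per_subject_precision(
    features, target, subject_ids, mask, n_folds, ridge, seed, orientation=False
):
    """Per-subject precision time courses over a boolean epoch mask."""
    zs = []
    subjects = np.unique(subject_ids)
    for subj in subjects:
        sel = mask & (subject_ids == subj)
        if sel.sum() < 2 * 2:
            raise ValueError(f"too few epochs ({sel.sum()}) for subject {subj}")
        curve = ridge_decode(
            features[sel], target[sel], n_folds=min(n_folds, int(sel.sum()) // 2),
            ridge=ridge, seed=seed, orientation=orientation,
        )
        zs.append(curve.z)
    return subjects, np.array(zs)


def precision_by_outcome(
    features: np.ndarray,
    target: np.ndarray,
    flags: pd.DataFrame,
    n_folds: int = 10,
    ridge: float = 1.0,
    seed: int = 0,
    n_perm: int = 2000,
    alpha: float = 0.05,
) -> dict:
    """Precision per perceptual-optimal x confidence-optimal cell, with tests.

    ``flags`` needs boolean columns ``perceptual_optimal`` and
    ``confidence_optimal`` plus ``subject_id``.  Returns per-cell precision
    (subject x time), and sign-permutation cluster tests of the two main
    effects and their interaction across subjects.
    """
    perc = flags["perceptual_optimal"].to_numpy(dtype=bool)
    conf = flags["confidence_optimal"].to_numpy(dtype=bool)
    subj = flags["subject_id"].to_numpy()
    cells = {}
    for p_flag in (True, False):
        for c_flag in (True, False):
            mask = (perc == p_flag) & (conf == c_flag)
            if mask.sum() == 0:
                raise ValueError(
                    f"degenerate design: empty cell perceptual={p_flag}, "
                    f"confidence={c_flag}"
                )
            if mask.sum() < 30:
                warnings.warn(
                    f"cell perceptual={p_flag}, confidence={c_flag} has only "
                    f"{mask.sum()} epochs", stacklevel=2,
                )
            subjects, z = _per_subject_precision(
                features, target, subj, mask, n_folds, ridge, seed
            )
            cells[(p_flag, c_flag)] = z
    main_perc = 0.5 * (
        cells[(True, True)] + cells[(True, False)]
        - cells[(False, True)] - cells[(False, False)]
    )
    main_conf = 0.5 * (
        cells[(True, True)] - cells[(True, False)]
        + cells[(False, True)] - cells[(False, False)]
    )
    interaction = (
        cells[(True, True)] - cells[(True, False)]
        - cells[(False, True)] + cells[(False, False)]
    )
    tests = {
        name: cluster_permutation_test(eff, n_perm=n_perm, alpha=alpha, seed=seed)
        for name, eff in (
            ("perceptual", main_perc),
            ("confidence", main_conf),
            ("interaction", interaction),
        )
    }
    return {
        "cells": cells,
        "effects": {
            "perceptual": main_perc,
            "confidence": main_conf,
            "interaction": interaction,
        },
        "clusters": tests,
        "subjects": subjects,
    }


def last_samples_contrast(
    features: np.ndarray,
    target: np.ndarray,
    labels: pd.DataFrame,
    k: int = 4,
    conditions: tuple[str, str] = ("more", "less"),
    n_folds: int = 10,
    ridge: float = 1.0,
    seed: int = 0,
    n_perm: int = 2000,
    alpha: float = 0.05,
) -> dict:
    """Precision difference (conditions[0] - conditions[1]) on the last k samples.

    ``labels`` needs ``subject_id``, ``condition``, ``sample_index`` (1-based)
    and ``n_shown`` per epoch.  Trials shorter than k contribute all their
    samples (logged).  Returns per-subject difference time courses and the
    sign-permutation cluster test.
    """
    sample_idx = labels["sample_index"].to_numpy(dtype=int)
    n_shown = labels["n_shown"].to_numpy(dtype=int)
    last_k = sample_idx > (n_shown - k)
    short = n_shown < k
    if short.any():
        logger.info(
            "%d epochs from trials shorter than k=%d contribute all samples",
            int(short.sum()), k,
        )
    cond = labels["condition"].to_numpy()
    subj = labels["subject_id"].to_numpy()
    per_cond = {}
    for c in conditions:
        subjects, z = _per_subject_precision(
            features, target, subj, last_k & (cond == c), n_folds, ridge, seed
        )
        per_cond[c] = z
    diff = per_cond[conditions[0]] - per_cond[conditions[1]]
    clusters = cluster_permutation_test(diff, n_perm=n_perm, alpha=alpha, seed=seed)
    return {
        "per_condition": per_cond,
        "difference": diff,
        "clusters": clusters,
        "subjects": subjects,
    }


# ---------------------------------------------------------------------------
# LDA response classification
# ---------------------------------------------------------------------------

def _lda_scores_matrix(
    train_power, train_labels, eval_power, folds, train_times, test_times
):
    """Pooled discriminant scores: (n_eval_epochs, n_train_times, n_test_times)."""
    scores = np.empty((eval_power.shape[0], train_times.size, test_times.size))
    for train, test in folds:
        for i, t1 in enumerate(train_times):
            lda = LinearDiscriminantAnalysis().fit(
                train_power[train, :, t1], train_labels[train]
            )
            block = eval_power[test][:, :, test_times]
            scores[test, i, :] = (
                np.einsum("ecT,c->eT", block, lda.coef_[0]) + lda.intercept_[0]
            )
    return scores


def lda_response_classifier(
    band_power: np.ndarray,
    labels: np.ndarray,
    test_power: np.ndarray | None = None,
    test_labels: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
    train_times=None,
    test_times=None,
    strength_time: int | tuple[int, int] | None = None,
) -> dict:
    """LDA classification of the perceptual response from band power.

    ``band_power``: (n_trials, n_channels, n_times) power averaged over the
    motor band; ``labels``: responses (two classes).  Without a test set the
    AUC matrix is cross-validated within the training set; with one (e.g.
    train on the Free task, test on Replay conditions) folds apply to the
    training set only and the full test set is scored by every fold's model
    (scores averaged).

    Per-trial prediction strength at ``strength_time`` (a (train, test) index
    pair, default the last time point) is the relative normalised Euclidean
    distance of the trial from the class means in discriminant space: 0.5 for
    an equidistant trial, 1 for a trial at its own response's class mean.
    """
    band_power = np.asarray(band_power, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("response classification needs exactly two classes")
    n_times = band_power.shape[-1]
    train_times = np.arange(n_times) if train_times is None else np.asarray(train_times)
    cross = test_power is not None
    if cross:
        test_power = np.asarray(test_power, dtype=float)
        eval_labels = np.asarray(test_labels)
        n_test_times = test_power.shape[-1]
    else:
        eval_labels = labels
        n_test_times = n_times
    test_times = (
        np.arange(n_test_times) if test_times is None else np.asarray(test_times)
    )

    counts = np.array([np.sum(labels == c) for c in classes])
    n_splits = int(min(n_folds, counts.min()))
    if n_splits < 2:
        raise ValueError("need at least two trials of each response class")
    folds = list(
        KFold(n_splits=n_splits, shuffle=True, random_state=seed).split(
            np.arange(len(labels))
        )
    )
    # guard against single-class training folds: re-stratify deterministically
    for train, _ in folds:
        if np.unique(labels[train]).size < 2:
            order = np.argsort(labels, kind="stable")
            folds = [
                (np.setdiff1d(np.arange(len(labels)), order[k::n_splits]),
                 order[k::n_splits])
                for k in range(n_splits)
            ]
            break

    if cross:
        all_scores = np.zeros((test_power.shape[0], train_times.size, test_times.size))
        for train, _ in folds:
            all_scores += _lda_scores_matrix(
                band_power, labels, test_power,
                [(train, np.arange(test_power.shape[0]))], train_times, test_times,
            )
        scores = all_scores / len(folds)
    else:
        scores = _lda_scores_matrix(
            band_power, labels, band_power, folds, train_times, test_times
        )

    y = (eval_labels == classes[1]).astype(int)
    auc = np.empty((train_times.size, test_times.size))
    for i in range(train_times.size):
        for j in range(test_times.size):
            auc[i, j] = roc_auc_score(y, scores[:, i, j])

    if strength_time is None:
        si, sj = train_times.size - 1, test_times.size - 1
    else:
        si, sj = (strength_time if isinstance(strength_time, tuple)
                  else (strength_time, strength_time))
    s = scores[:, si, sj]
    m = [s[eval_labels == c].mean() for c in classes]
    d_to = np.abs(s[:, None] - np.array(m)[None, :])
    own = (eval_labels == classes[1]).astype(int)
    d_own = d_to[np.arange(s.size), own]
    d_other = d_to[np.arange(s.size), 1 - own]
    strength = d_other / np.maximum(d_own + d_other, 1e-12)
    return {"auc": auc, "scores": scores, "strength": strength, "classes": classes}


def strength_evidence_regression(
    strength: np.ndarray,
    evidence_by_horizon: np.ndarray,
    condition: np.ndarray,
    subject_id: np.ndarray,
) -> dict:
    """Linear regression of classifier strength on choice-signed evidence.

    ``evidence_by_horizon``: (n_trials, n_horizons), column h holding the
    accumulated evidence (signed by the entered response) up to h samples
    before the cue.  The evidence regressor is z-scored within each cell so
    the slopes are on a correlation scale and comparable across horizons
    (whose raw evidence variances differ).  Returns per subject x condition x
    horizon slopes and the condition-by-horizon repeated-measures interaction.
    """
    strength = np.asarray(strength, dtype=float)
    rows = []
    for subj in np.unique(subject_id):
        for cond in np.unique(condition):
            sel = (subject_id == subj) & (condition == cond)
            if sel.sum() < evidence_by_horizon.shape[1] + 2:
                raise ValueError(f"too few trials in cell {subj}/{cond}")
            for h in range(evidence_by_horizon.shape[1]):
                x = evidence_by_horizon[sel, h]
                if np.std(x) == 0:
                    raise ValueError(f"rank-deficient design in cell {subj}/{cond}")
                x = (x - x.mean()) / x.std()
                beta = np.polyfit(x, strength[sel], 1)[0]
                rows.append((subj, cond, h, beta))
    table = pd.DataFrame(rows, columns=["subject_id", "condition", "horizon", "beta"])
    interaction_F = interaction_p = None
    if table["condition"].nunique() > 1:
        from statsmodels.stats.anova import AnovaRM

        aov = AnovaRM(
            table, depvar="beta", subject="subject_id",
            within=["condition", "horizon"],
        ).fit()
        row = aov.anova_table.loc["condition:horizon"]
        interaction_F = float(row["F Value"])
        interaction_p = float(row["Pr > F"])
    return {"betas": table, "interaction_F": interaction_F, "interaction_p": interaction_p}
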