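"""Behavioural summaries: sensitivity, optimal-confidence labels, evidence GLMs.

The evidence GLMs relate the optimal accumulated evidence L to behaviour: a
probit regression of the perceptual choice (or the binarised confidence
rating, signed by the choice) on L accumulated either to the final sample
("full") or to four samples before the cue ("minus4").  Under a covert
decision bound, the final samples of the More condition carry no extra
predictive power for the choice, so the full-vs-minus4 contrast shrinks in
More relative to Less — while for confidence, which keeps accumulating, the
contrast survives.  The condition-by-horizon interaction is assessed with a
within-subject repeated-measures ANOVA on the per-subject coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.anova import AnovaRM
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .observer import decision_update
from .tasks import CategoryModel

HORIZONS = ("full", "minus4")


@dataclass
class EvidenceGLMResult:
    """Per-subject probit coefficients of behaviour on accumulated evidence."""

    per_subject: pd.DataFrame     # columns: subject_id, condition, horizon, beta
    beta_full: float
    beta_minus4: float
    contrast_by_condition: pd.DataFrame  # per condition: mean (beta_full - beta_minus4)
    interaction_F: float | None = None
    interaction_p: float | None = None
    flags: list = field(default_factory=list)


def dprime(choices, truths) -> float:
    """Sensitivity d' = z(hit rate) - z(false-alarm rate).

    Category 1 plays the role of the signal class.  Rates are clipped to
    [1/(2N), 1 - 1/(2N)] per class so perfect separation stays finite.
    """
    choices = np.asarray(choices)
    truths = np.asarray(truths)
    if np.unique(truths).size < 2:
        raise ValueError("both true categories must be present to compute d'")
    sig = truths == 1
    n_sig, n_noise = int(sig.sum()), int((~sig).sum())
    hit = np.clip((choices[sig] == 1).mean(), 1 / (2 * n_sig), 1 - 1 / (2 * n_sig))
    fa = np.clip(
        (choices[~sig] == 1).mean(), 1 / (2 * n_noise), 1 - 1 / (2 * n_noise)
    )
    return float(norm.ppf(hit) - norm.ppf(fa))


def optimal_confidence_label(L_chosen) -> np.ndarray:
    """High/low optimal-confidence labels per trial.

    The optimal observer reports high confidence when the evidence for the
    chosen category exceeds the median across trials; ties count as low.
    Returns a boolean array (True = high).
    """
    L_chosen = np.asarray(L_chosen, dtype=float)
    if L_chosen.size < 2:
        raise ValueError("need at least two trials to split at the median")
    return L_chosen > np.median(L_chosen)


# ---------------------------------------------------------------------------
# accumulated evidence at horizons
# ---------------------------------------------------------------------------

def accumulated_evidence(
    trials: pd.DataFrame, sequences, model: CategoryModel, horizon: str
) -> np.ndarray:
    """Optimal L accumulated to the cue ("full") or four samples earlier ("minus4")."""
    if horizon not in HORIZONS:
        raise ValueError(f"horizon must be one of {HORIZONS}, got {horizon!r}")
    seqmap = (
        sequences if isinstance(sequences, dict)
        else {s.sequence_id: s for s in sequences}
    )
    out = np.empty(len(trials))
    for i, (sid, n_shown) in enumerate(
        zip(trials["sequence_id"].to_numpy(), trials["n_shown"].to_numpy(dtype=int))
    ):
        stop = n_shown if horizon == "full" else max(1, n_shown - 4)
        ell = decision_update(seqmap[sid].orientations[:stop], model)
        out[i] = ell.sum()
    return out


def _probit_beta(
    y: np.ndarray, x: np.ndarray, flags: list, tag: str, standardize: bool = True
) -> float:
    """Slope of a probit GLM of y on x; ridge fallback under separation.

    With ``standardize`` (default) the regressor is z-scored within the cell,
    so coefficients measure predictive strength per SD of evidence and are
    comparable across horizons whose raw evidence scales differ.
    """
    if np.unique(y).size < 2:
        raise ValueError(f"degenerate responses (single class) in cell {tag}")
    if np.std(x) == 0:
        raise ValueError(f"constant evidence regressor in cell {tag}")
    if standardize:
        x = (x - x.mean()) / x.std()
    X = sm.add_constant(x)
    try:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            model = sm.GLM(
                y, X, family=sm.families.Binomial(sm.families.links.Probit())
            )
            res = model.fit(maxiter=100)
        beta = float(res.params[1])
        # on a z-scored regressor a slope beyond ~5 marks (near-)separation
        if np.isfinite(beta) and abs(beta) < 5:
            return beta
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        pass
    flags.append(f"separation in {tag}; penalised fallback")
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(C=1.0).fit(x[:, None], y)
    # logit slope rescaled to the probit scale (logistic SD = pi/sqrt(3))
    return float(lr.coef_[0, 0] * np.sqrt(3) / np.pi)


def _glm_by_cell(
    trials: pd.DataFrame,
    sequences,
    model: CategoryModel,
    response: np.ndarray,
    conditions,
    flags: list,
) -> pd.DataFrame:
    rows = []
    for horizon in HORIZONS:
        L = accumulated_evidence(trials, sequences, model, horizon)
        for subj, subj_idx in trials.groupby("subject_id").indices.items():
            for cond in conditions:
                sel = subj_idx[
                    trials["condition"].to_numpy()[subj_idx] == cond
                ] if cond is not None else subj_idx
                if sel.size == 0:
                    continue
                beta = _probit_beta(
                    response[sel], L[sel], flags, f"{subj}/{cond}/{horizon}"
                )
                rows.append((subj, cond if cond is not None else "all", horizon, beta))
    return pd.DataFrame(rows, columns=["subject_id", "condition", "horizon", "beta"])


def _finish(per_subject: pd.DataFrame, flags: list) -> EvidenceGLMResult:
    means = per_subject.groupby("horizon")["beta"].mean()
    wide = per_subject.pivot_table(
        index=["subject_id", "condition"], columns="horizon", values="beta"
    ).reset_index()
    wide["contrast"] = wide["full"] - wide["minus4"]
    contrast = wide.groupby("condition")["contrast"].agg(["mean", "sem", "count"])
    interaction_F = interaction_p = None
    if per_subject["condition"].nunique() > 1:
        n_per = per_subject.groupby(["subject_id", "condition", "horizon"]).size()
        if (n_per == 1).all():
            aov = AnovaRM(
                per_subject, depvar="beta", subject="subject_id",
                within=["condition", "horizon"],
            ).fit()
            row = aov.anova_table.loc["condition:horizon"]
            interaction_F = float(row["F Value"])
            interaction_p = float(row["Pr > F"])
    return EvidenceGLMResult(
        per_subject=per_subject,
        beta_full=float(means.get("full", np.nan)),
        beta_minus4=float(means.get("minus4", np.nan)),
        contrast_by_condition=contrast,
        interaction_F=interaction_F,
        interaction_p=interaction_p,
        flags=flags,
    )


def evidence_glm_choice(
    trials: pd.DataFrame,
    sequences,
    model: CategoryModel,
    conditions=("less", "same", "more"),
) -> EvidenceGLMResult:
    """Probit GLM of the perceptual choice on accumulated evidence L.

    Fits one coefficient per subject, condition, and horizon (full vs four
    samples before the cue) and the condition-by-horizon interaction.
    """
    y = (trials["choice"].to_numpy(dtype=int) == 1).astype(float)
    flags: list = []
    per_subject = _glm_by_cell(trials, sequences, model, y, conditions, flags)
    return _finish(per_subject, flags)


def evidence_glm_confidence(
    trials: pd.DataFrame,
    sequences,
    model: CategoryModel,
    conditions=("less", "same", "more"),
) -> EvidenceGLMResult:
    """Probit GLM of binarised confidence on choice-signed evidence.

    Ratings 1-2 count as Low and 3-4 as High; the evidence regressor at both
    horizons is signed by the recorded perceptual choice, so positive values
    mean evidence in favour of the chosen category.
    """
    conf = trials["confidence"].to_numpy(dtype=float)
    if np.isnan(conf).any():
        raise ValueError("confidence ratings missing on some trials")
    y = (conf >= 3).astype(float)
    sign = np.where(trials["choice"].to_numpy(dtype=int) == 1, 1.0, -1.0)
    flags: list = []
    rows = []
    for horizon in HORIZONS:
        L = accumulated_evidence(trials, sequences, model, horizon) * sign
        for subj, subj_idx in trials.groupby("subject_id").indices.items():
            for cond in conditions:
                sel = subj_idx[trials["condition"].to_numpy()[subj_idx] == cond]
                if sel.size == 0:
                    continue
                beta = _probit_beta(
                    y[sel], L[sel], flags, f"{subj}/{cond}/{horizon}"
                )
                rows.append((subj, cond, horizon, beta))
    per_subject = pd.DataFrame(
        rows, columns=["subject_id", "condition", "horizon", "beta"]
    )
    return _finish(per_subject, flags)


def behaviour_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per subject-by-condition accuracy, d', and mean confidence."""
    rows = []
    for (subj, cond), grp in trials.groupby(["subject_id", "condition"]):
        truths = grp["true_category"].to_numpy(dtype=int)
        choices = grp["choice"].to_numpy(dtype=int)
        d = dprime(choices, truths) if np.unique(truths).size == 2 else np.nan
        conf = grp["confidence"].mean() if "confidence" in grp else np.nan
        rows.append((subj, cond, (choices == truths).mean(), d, conf, len(grp)))
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "condition", "prop_correct", "dprime",
            "mean_confidence", "n_trials",
        ],
    )
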