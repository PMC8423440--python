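"""Category distributions, predefined stimulus sequences, and the Replay design.

The perceptual task is a weather-prediction-style categorisation: on each trial
the observer sees a sequence of oriented Gabors whose orientations are drawn
from one of two overlapping circular-Gaussian (Von Mises) distributions over
orientation, centred at -45 deg and +45 deg from vertical with concentration
``kappa``.  Orientation is an axial variable, so the category density

    p(theta | psi) = exp(kappa * cos(2 * (theta - mu_psi))) / (pi * I0(kappa))

is a Von Mises on the doubled angle, supported on the half-open interval
(-pi/2, pi/2].

A session consists of ``n_sequences`` predefined sequences of up to
``max_samples`` orientations, balanced across the two categories, replayed
three times in the Free task.  The Replay task then shows, for each sequence,
a number of samples derived from how many the observer chose to respond to in
the Free task: two fewer than the minimum (Less), the median (Same), and four
more than the maximum (More).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import i0

logger = logging.getLogger(__name__)

#: half width of the orientation support (-pi/2, pi/2]
HALF_PI = np.pi / 2.0


@dataclass(frozen=True)
class CategoryModel:
    """The two Von Mises category distributions over stimulus orientation."""

    mu1: float = -np.pi / 4.0
    mu2: float = np.pi / 4.0
    kappa: float = 0.5

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        if not np.isclose(self.mu1, -self.mu2):
            raise ValueError("category means must be symmetric (mu1 = -mu2)")

    def mu(self, psi: int) -> float:
        if psi == 1:
            return self.mu1
        if psi == 2:
            return self.mu2
        raise ValueError(f"category must be 1 or 2, got {psi!r}")


@dataclass(frozen=True)
class StimulusSequence:
    """One predefined sequence of stimulus orientations (radians)."""

    sequence_id: int
    category: int
    orientations: np.ndarray

    def __post_init__(self) -> None:
        ori = np.asarray(self.orientations, dtype=float)
        if ori.ndim != 1 or ori.size < 1:
            raise ValueError("a sequence needs at least one orientation")
        if np.any(ori <= -HALF_PI) or np.any(ori > HALF_PI):
            raise ValueError("orientations must lie in (-pi/2, pi/2]")
        object.__setattr__(self, "orientations", ori)

    def __len__(self) -> int:
        return self.orientations.size


@dataclass(frozen=True)
class ReplayDesign:
    """Number of samples shown per Replay condition for one sequence."""

    sequence_id: int
    n_less: int
    n_same: int
    n_more: int


def wrap_orientation(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into the canonical axial support (-pi/2, pi/2]."""
    wrapped = -(np.mod(-(np.asarray(theta)) + HALF_PI, np.pi) - HALF_PI)
    return wrapped


def category_density(theta, psi: int, model: CategoryModel):
    """Probability density of orientation ``theta`` under category ``psi``.

    Integrates to 1 over the axial support (-pi/2, pi/2].
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    mu = model.mu(psi)
    return np.exp(model.kappa * np.cos(2.0 * (theta - mu))) / (np.pi * i0(model.kappa))


def sample_orientations(
    category: int, n_samples: int, model: CategoryModel, rng: np.random.Generator
) -> np.ndarray:
    """Draw i.i.d. orientations from one category.

    Sampling draws phi from a Von Mises with mean ``2 * mu_psi`` and
    concentration kappa, then halves the angle, which realises the doubled-angle
    density above on (-pi/2, pi/2].
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    mu = model.mu(category)
    phi = rng.vonmises(2.0 * mu, model.kappa, size=n_samples)
    return wrap_orientation(phi / 2.0)


def sample_sequence(
    category: int,
    n_samples: int,
    model: CategoryModel,
    seed: int | np.random.Generator,
    sequence_id: int = 0,
) -> StimulusSequence:
    """Sample one stimulus sequence from a category; reproducible under seed."""
    rng = np.random.default_rng(seed)
    ori = sample_orientations(category, n_samples, model, rng)
    return StimulusSequence(sequence_id=sequence_id, category=category, orientations=ori)


def make_predefined_sequences(
    n_sequences: int,
    max_samples: int,
    model: CategoryModel,
    seed: int,
) -> list[StimulusSequence]:
    """Build the balanced set of predefined sequences for one session.

    Half the sequences come from each category; each holds ``max_samples``
    orientations (a trial truncates the sequence at the response).  Each
    sequence uses its own counter-derived stream so the draws do not depend on
    generation order.
    """
    if n_sequences < 2 or n_sequences % 2 != 0:
        raise ValueError("n_sequences must be even (half per category)")
    if max_samples < 1:
        raise ValueError("max_samples must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_sequences)
    sequences = []
    for sid in range(n_sequences):
        category = 1 if sid < n_sequences // 2 else 2
        rng = np.random.default_rng(streams[sid])
        ori = sample_orientations(category, max_samples, model, rng)
        sequences.append(
            StimulusSequence(sequence_id=sid, category=category, orientations=ori)
        )
    return sequences


def derive_replay_lengths(sequence_id: int, free_counts) -> ReplayDesign:
    """Derive the Replay Less/Same/More sample counts from Free-task behaviour.

    Less shows ``min - 2`` samples (floored at 1, with a warning), Same the
    median, More ``max + 4`` of the three response counts recorded for that
    sequence in the Free task.  The More count is not capped here; callers cap
    it at sequence length (the generator logs when the cap binds).
    """
    counts = np.asarray(free_counts, dtype=int)
    if counts.size != 3:
        raise ValueError(
            f"need the three Free-task repeat counts, got {counts.size}"
        )
    if np.any(counts < 1):
        raise ValueError("Free-task response counts must be positive")
    n_less = int(counts.min()) - 2
    if n_less < 1:
        warnings.warn(
            f"sequence {sequence_id}: p_min - 2 = {n_less} floored at 1 sample",
            stacklevel=2,
        )
        n_less = 1
    return ReplayDesign(
        sequence_id=sequence_id,
        n_less=n_less,
        n_same=int(np.median(counts)),
        n_more=int(counts.max()) + 4,
    )


def sequences_to_frame(sequences: list[StimulusSequence]) -> pd.DataFrame:
    """Long-format table: sequence_id, sample_index (1-based), orientation, category."""
    rows = []
    for seq in sequences:
        for i, theta in enumerate(seq.orientations, start=1):
            rows.append((seq.sequence_id, i, theta, seq.category))
    return pd.DataFrame(
        rows, columns=["sequence_id", "sample_index", "orientation_rad", "category"]
    )


def frame_to_sequences(frame: pd.DataFrame) -> list[StimulusSequence]:
    sequences = []
    for sid, grp in frame.groupby("sequence_id", sort=True):
        grp = grp.sort_values("sample_index")
        sequences.append(
            StimulusSequence(
                sequence_id=int(sid),
                category=int(grp["category"].iloc[0]),
                orientations=grp["orientation_rad"].to_numpy(),
            )
        )
    return sequences


def replay_designs_to_frame(designs: list[ReplayDesign]) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.sequence_id, d.n_less, d.n_same, d.n_more) for d in designs],
        columns=["sequence_id", "n_less", "n_same", "n_more"],
    )
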