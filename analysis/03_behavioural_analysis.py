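"""Behavioural evidence GLMs: which evidence drives choices and confidence?

On the simulated cohort from 01_simulate_cohort.py, regress the perceptual
choice (probit) and binarised confidence on the optimal accumulated evidence,
at two horizons: the final sample vs four samples before the response cue.
Under a covert bound, the final samples of the More condition stop predicting
the choice — but keep predicting confidence.

Run from the repository root (after 01):
    python analysis/03_behavioural_analysis.py
"""

import warnings
from pathlib import Path

import pandas as pd

from confacc.behaviour import evidence_glm_choice, evidence_glm_confidence
from confacc.tasks import CategoryModel, frame_to_sequences

COHORT = Path("results/cohort")
OUT = Path("results")


def main() -> None:
    trials = pd.read_csv(COHORT / "trials.csv")
    sequences = frame_to_sequences(pd.read_csv(COHORT / "sequences.csv"))
    replay = trials[trials["task"] == "replay"]
    model = CategoryModel()

    rows = []
    for name, fn in (("choice", evidence_glm_choice),
                     ("confidence", evidence_glm_confidence)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fn(replay, sequences, model)
        print(f"{name} GLM: beta_full={res.beta_full:.3f} "
              f"beta_minus4={res.beta_minus4:.3f} "
              f"condition x horizon F={res.interaction_F:.2f} "
              f"p={res.interaction_p:.4f}")
        print("  full-vs-minus4 contrast by condition "
              "(positive = final samples add predictive power):")
        print(res.contrast_by_condition.round(3).to_string())
        tab = res.per_subject.copy()
        tab.insert(0, "response", name)
        rows.append(tab)
    pd.concat(rows, ignore_index=True).to_csv(
        OUT / "evidence_glm_betas.csv", index=False
    )
    print("per-subject coefficients written to", OUT / "evidence_glm_betas.csv")


if __name__ == "__main__":
    main()
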