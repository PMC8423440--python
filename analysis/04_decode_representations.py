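"""Decode the three encoding variables from the simulated epochs.

Ridge regression (penalty 1, 10-fold CV) on band-limited analytic-signal
features predicts stimulus orientation, the momentary decision update, and
the accumulated evidence at every epoch time point; precision is the Fisher-z
correlation between held-out predictions and the encoded value.  The script
also runs the temporal-generalisation matrix for the accumulated evidence and
the More-minus-Less precision contrast on the last four samples, where covert
commitment attenuates the accumulated-evidence representation.

Run from the repository root (after 01):
    python analysis/04_decode_representations.py
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from confacc.decoding import (
    EpochTensor,
    hilbert_features,
    last_samples_contrast,
    ridge_decode,
    temporal_generalization,
)

COHORT = Path("results/cohort")
OUT = Path("results")


def main() -> None:
    ep = EpochTensor.load(COHORT / "epochs_stim.h5")
    feats = hilbert_features(ep.data, ep.fs, band=(1.0, 8.0))[:, :, ::2]
    times = ep.times[::2]

    curves = {}
    for name, target, ori in (
        ("orientation", ep.labels[["sin2theta", "cos2theta"]].to_numpy(), True),
        ("update", ep.labels["update"].to_numpy(), False),
        ("accumulated", ep.labels["accumulated"].to_numpy(), False),
    ):
        curve = ridge_decode(feats, target, n_folds=10, orientation=ori)
        curves[name] = curve.z
        peak = times[int(np.argmax(curve.z))]
        print(f"{name}: peak precision z={curve.z.max():.3f} at {peak*1000:.0f} ms")
    pd.DataFrame({"time_s": times, **curves}).to_csv(
        OUT / "representation_precision.csv", index=False
    )

    y = ep.labels["accumulated"].to_numpy()
    tg = temporal_generalization(feats[:, :, ::2], y, n_folds=5)
    np.savetxt(OUT / "temporal_generalization_accumulated.csv", tg.z,
               delimiter=",")
    print(f"temporal generalisation: diag mean z={np.diag(tg.z).mean():.3f}, "
          f"off-diag mean z={tg.z[~np.eye(tg.z.shape[0], dtype=bool)].mean():.3f}")

    lab = ep.labels
    last4 = (lab["sample_index"] > lab["n_shown"] - 4).to_numpy()
    res = last_samples_contrast(
        feats[last4], y[last4], lab[last4].reset_index(drop=True),
        k=4, n_folds=5, n_perm=1000,
    )
    sig = [c for c in res["clusters"] if c.p_value < 0.05]
    print("More - Less precision difference on the last four samples:")
    for c in res["clusters"]:
        print(f"  cluster {times[c.start]*1000:.0f}-{times[c.stop-1]*1000:.0f} ms: "
              f"mass={c.mass:.1f}, p={c.p_value:.3f}")
    if not res["clusters"]:
        print("  no clusters")
    pd.DataFrame(res["difference"], columns=[f"t{t:.3f}" for t in times]).to_csv(
        OUT / "more_minus_less_precision.csv", index=False
    )
    print("written to", OUT)


if __name__ == "__main__":
    main()
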