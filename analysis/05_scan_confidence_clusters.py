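"""Isolate behaviourally linked representation-error clusters (scan statistic).

Per electrode and time point, single-electrode decoders of the accumulated
evidence yield representation errors; the Bayesian scan statistic searches
for contiguous regions where the error variance is inflated on epochs leading
to non-optimal responses — the signature of signals reflecting the internal
evidence actually used by the observer rather than the presented evidence.
The winning cluster is then re-decoded as a whole, and epochs are ranked into
Noise Min / Noise Max quartiles by the magnitude of their representation
error.

Run from the repository root (after 01):
    python analysis/05_scan_confidence_clusters.py
"""

import json
import warnings
from pathlib import Path

import numpy as np

from confacc.decoding import EpochTensor, cv_predictions
from confacc.scan import (
    cluster_representation_error,
    representation_errors,
    scan_statistic_clusters,
)

COHORT = Path("results/cohort")
OUT = Path("results")


def main() -> None:
    ep = EpochTensor.load(COHORT / "epochs_stim.h5")
    y = ep.labels["accumulated"].to_numpy()
    data = ep.data[:, :, ::2]
    times = ep.times[::2]

    predictions = np.empty_like(data)
    for c in range(data.shape[1]):
        predictions[:, c, :] = cv_predictions(data[:, c : c + 1, :], y, n_folds=5)
    # expectation of the decoded value is fitted within condition x commitment
    # x sample-position groups: encoding gain drops after a covert commitment,
    # and that systematic change must not masquerade as representation noise
    lab = ep.labels
    groups = (
        lab["condition"].astype(str)
        + "/" + lab["post_commitment"].astype(str)
        + "/" + np.minimum(lab["sample_index"], 30).astype(str)
    ).to_numpy()
    errors = representation_errors(predictions, y, groups=groups)

    nonopt = ~ep.labels["perceptual_optimal"].to_numpy(dtype=bool)
    res = scan_statistic_clusters(errors, nonopt, ep.channel_pos)
    print(f"{len(res['clusters'])} cluster(s) with posterior odds > 1")
    payload = []
    for cl in res["clusters"]:
        ts = [times[t] for _, t in cl.cells]
        payload.append({
            "n_cells": len(cl.cells),
            "electrodes": sorted({int(e) for e, _ in cl.cells}),
            "time_span_ms": [1000 * min(ts), 1000 * max(ts)],
            "sum_llr": cl.sum_llr,
            "log_posterior_odds": cl.log_posterior_odds,
        })
        print(f"  {len(cl.cells)} cells over "
              f"{payload[-1]['time_span_ms'][0]:.0f}-"
              f"{payload[-1]['time_span_ms'][1]:.0f} ms, "
              f"sum LLR={cl.sum_llr:.1f}")

    if res["clusters"]:
        top = res["clusters"][0]
        rep = cluster_representation_error(data, y, top, n_folds=10)
        payload[0]["cluster_precision_z"] = rep["precision_z"]
        payload[0]["n_noise_min"] = int(len(rep["noise_min"]))
        payload[0]["n_noise_max"] = int(len(rep["noise_max"]))
        print(f"top cluster re-decoded: precision z={rep['precision_z']:.3f}; "
              f"{len(rep['noise_min'])} Noise Min / {len(rep['noise_max'])} "
              f"Noise Max epochs selected")

    (OUT / "scan_clusters.json").write_text(json.dumps(payload, indent=2))
    print("written to", OUT / "scan_clusters.json")


if __name__ == "__main__":
    main()
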