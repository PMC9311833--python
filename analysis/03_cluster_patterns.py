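"""Cluster each scan's perfusion values with v-fold cross-validated K selection.

Univariate k-means per scan (interictal, ictal and change vectors); the
clusters with lowest / highest centroid are the scan's hypo- / hyperperfused
regions of interest.  Writes results/clusters.csv and kselection.json and
reports the distribution of selected K.
"""

import json
from collections import Counter
from pathlib import Path

import pandas as pd

from perfuse_sudep import PerfusionVector
from perfuse_sudep.pipeline import RunConfig, solutions_to_frame, stage_cluster

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 42) -> None:
    frame = pd.read_csv(ROOT / "pi.csv")
    vectors = {
        (p, s): PerfusionVector(p, s, grp.set_index("structure")["value"])
        for (p, s), grp in frame.groupby(["patient", "state"])
    }
    config = RunConfig(seed=seed)
    solutions, traces = stage_cluster(vectors, config)
    solutions_to_frame(solutions, vectors).to_csv(ROOT / "clusters.csv", index=False)
    (ROOT / "kselection.json").write_text(json.dumps(
        {f"{p}|{s}": t.as_dict() for (p, s), t in sorted(traces.items())}, indent=2
    ))
    by_state: dict = {}
    for (p, s), t in traces.items():
        by_state.setdefault(s, []).append(t.chosen_k)
    for s, ks in sorted(by_state.items()):
        print(f"selected K ({s}): {dict(sorted(Counter(ks).items()))}")
    print(f"wrote {ROOT}/clusters.csv, kselection.json")


if __name__ == "__main__":
    main()
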