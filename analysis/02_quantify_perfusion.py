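"""Quantify perfusion indexes and interictal->ictal change vectors.

Reads the simulated ROI tables (run 01 first), computes leave-one-out
perfusion indexes per scan, re-keys structures to the ipsilateral/contralateral
frame using each patient's seizure-onset side, and derives relative change
vectors.  Outputs results/pi.csv.
"""

from pathlib import Path

import pandas as pd

from perfuse_sudep import RoiActivityTable, default_atlas
from perfuse_sudep.pipeline import RunConfig, stage_quantify, vectors_to_frame

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    atlas = default_atlas()
    frame = pd.read_csv(ROOT / "cohort" / "roi_tables.csv")
    tables = {(t.patient_id, t.state): t for t in RoiActivityTable.from_frame(frame)}
    clinical = pd.read_csv(ROOT / "cohort" / "clinical.csv").set_index("patient")
    vectors = stage_quantify(tables, clinical, atlas, RunConfig())
    out = vectors_to_frame(vectors)
    out.to_csv(ROOT / "pi.csv", index=False)
    pi = out[out.state != "change"]
    print(f"quantified {len(vectors)} vectors ({len(pi)} PI rows)")
    print("PI range per state:")
    print(out.groupby("state")["value"].agg(["min", "max"]).round(3).to_string())
    print(f"wrote {ROOT}/pi.csv")


if __name__ == "__main__":
    main()
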