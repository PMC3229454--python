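#!/usr/bin/env python
"""Score every stage's output against the planted ground truth.

Compares the general-filter survivors, the recovered shared synexpression
group and the temporal category calls with the labels the simulator planted,
reporting precision/recall, Jaccard overlap and per-category accuracy.
"""

import json
from pathlib import Path

import pandas as pd

from bmptc.synthetic_data import GroundTruth, SimulationConfig, evaluate_recovery

DATA = Path("scratch/data")
RESULTS = Path("results")

raw = json.loads((DATA / "truth.json").read_text())
truth = GroundTruth(
    probe_class=raw["probe_class"], onset_category=raw["onset_category"],
    onset_time=raw["onset_time"], signs=raw["signs"],
    group_members=raw["group_members"], shared_group=raw["shared_group"],
    planted_term_id=raw["planted_term_id"],
    planted_term_category=raw["planted_term_category"],
    config=SimulationConfig(**{k: v for k, v in raw["config"].items()
                               if k not in ("cell_lines",)}),
)

retained = {lig: (Path("scratch") / f"general_filter_{lig}.txt").read_text().split()
            for lig in ("BMP4", "BMP7")}
shared = pd.read_csv(RESULTS / "03_shared_group_probes.tsv", sep="\t")["probe_id"].tolist()
calls: dict[str, str] = {}
for path in sorted(Path("scratch").glob("temporal_BMP4_*_membership.tsv")):
    for row in pd.read_csv(path, sep="\t").itertuples():
        calls.setdefault(row.probe_id, row.category)  # first cell line wins

metrics = evaluate_recovery(truth, retained=retained, shared_group=shared,
                            probe_category=calls)
metrics.to_csv(RESULTS / "06_recovery_metrics.tsv", sep="\t", index=False)
print(metrics.to_string(index=False))
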