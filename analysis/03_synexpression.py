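#!/usr/bin/env python
"""Find the shared synexpression group across the two ligands.

General-filter survivors are clustered with UPGMA on correlation distance,
tight clusters are extracted per ligand (the analogue of visually boxed
co-expression blocks), and the per-ligand top clusters are intersected to
give the shared group and its uniquely annotated gene subset.
"""

from pathlib import Path

import pandas as pd

from bmptc.coexpression import (
    average_linkage_cluster, clusters_to_frame, extract_tight_clusters, intersect_clusters,
)
from bmptc.io_model import read_annotation, read_expression_matrix

DATA = Path("scratch/data")
RESULTS = Path("results")
RESULTS.mkdir(exist_ok=True)

annotations = read_annotation(DATA / "annotation.tsv")
tops = {}
for lig in ("BMP4", "BMP7"):
    matrix = read_expression_matrix(Path("scratch") / f"normalized_{lig}.tsv")
    kept = (Path("scratch") / f"general_filter_{lig}.txt").read_text().split()
    sub = matrix.subset_probes(kept)
    dendro = average_linkage_cluster(sub)
    dendro.write(Path("scratch") / f"dendrogram_{lig}.nwk")
    tight = extract_tight_clusters(dendro, sub)  # cut 0.3, min 20, tightness 0.8
    clusters_to_frame(tight).to_csv(RESULTS / f"03_tight_clusters_{lig}.tsv",
                                    sep="\t", index=False)
    print(f"{lig}: {len(tight)} tight cluster(s); "
          f"largest has {tight[0].size} probes at mean r = {tight[0].mean_correlation:.3f}")
    tops[lig] = tight[0]

group = intersect_clusters(tops["BMP4"], tops["BMP7"], annotations)
pd.DataFrame({"probe_id": group.shared_probes}).to_csv(
    RESULTS / "03_shared_group_probes.tsv", sep="\t", index=False)
print(f"shared group: {group.size} probes present in both ligands' clusters "
      f"({len(group.unique_genes)} uniquely annotated genes)")
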