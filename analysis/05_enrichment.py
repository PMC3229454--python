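#!/usr/bin/env python
"""GO enrichment of the shared synexpression group and temporal categories.

One-sided Fisher's exact (hypergeometric) test of each gene set against the
whole-array uniquely-annotated universe; top terms per set are tabulated.
"""

from pathlib import Path

import pandas as pd

from bmptc.enrichment import category_enrichment, fisher_enrichment
from bmptc.io_model import read_annotation, read_ontology, unique_gene_map

DATA = Path("scratch/data")
RESULTS = Path("results")
RESULTS.mkdir(exist_ok=True)

annotations = read_annotation(DATA / "annotation.tsv")
ontology = read_ontology(DATA / "ontology.tsv")
p2g = unique_gene_map(annotations)
background = sorted(set(p2g.values()))

shared = pd.read_csv(RESULTS / "03_shared_group_probes.tsv", sep="\t")["probe_id"]
group_genes = sorted({p2g[p] for p in shared if p in p2g})
table = fisher_enrichment(group_genes, background, ontology)
table.head(25).to_csv(RESULTS / "05_enrichment_shared_group.tsv", sep="\t", index=False)
print(f"shared group ({len(group_genes)} genes): best term "
      f"{table.iloc[0]['term_id']} ({table.iloc[0]['term_name']}) "
      f"p = {table.iloc[0]['p_value']:.2e}")

category_genes: dict[str, set] = {}
for path in sorted(Path("scratch").glob("temporal_BMP4_*_membership.tsv")):
    members = pd.read_csv(path, sep="\t")
    for row in members.itertuples():
        if row.category != "undetermined" and row.probe_id in p2g:
            category_genes.setdefault(row.category, set()).add(p2g[row.probe_id])

rows = []
for cat, result in category_enrichment(category_genes, ontology, background).items():
    top = result.head(5).copy()
    top.insert(0, "category", cat)
    rows.append(top)
    print(f"{cat}: {len(result)} terms tested, best p = {result.iloc[0]['p_value']:.2e} "
          f"({result.iloc[0]['term_id']})")
pd.concat(rows).to_csv(RESULTS / "05_enrichment_categories_BMP4.tsv", sep="\t", index=False)
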