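"""GO-term over-representation by Fisher's exact (hypergeometric) test.

For each term with m background genes out of N, and k study genes with the
term out of a study set of size K, the one-sided over-representation p-value
is the upper hypergeometric tail

    p = sum_{i >= k} C(m, i) * C(N - m, K - i) / C(N, K).

The background universe is an explicit input — by convention all uniquely
annotated genes on the array — and genes are counted once per term
regardless of probe multiplicity. No multiple-testing correction is applied
by default; Benjamini-Hochberg q-values are emitted as an optional column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_model import OntologyMap, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyCounts:
    k: int  # study genes with the term
    K: int  # study size
    m: int  # background genes with the term
    N: int  # background size

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.m) and self.K <= self.N and self.m <= self.N):
            raise ValidationError(f"inconsistent contingency counts {self}")


def hypergeom_tail(counts: ContingencyCounts) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, m, K)."""
    return float(hypergeom.sf(counts.k - 1, counts.N, counts.m, counts.K))


def fisher_enrichment(
    study: Iterable[str],
    background: Iterable[str],
    ontology: OntologyMap,
    min_term_size: int = 5,
    with_q: bool = False,
) -> pd.DataFrame:
    """Per-term over-representation of ``study`` against ``background``.

    Terms annotating fewer than ``min_term_size`` background genes are
    skipped. Returns a table sorted by ascending p (ties: term_id) with
    columns term_id, term_name, namespace, k, K, m, N, p_value[, q_value].
    """
    study_set = set(study)
    background_set = set(background)
    if not study_set:
        raise ValidationError("empty study set")
    if not study_set <= background_set:
        extra = sorted(study_set - background_set)
        raise ValidationError(f"study genes absent from background: {extra[:5]}")
    N = len(background_set)
    K = len(study_set)
    rows = []
    terms = ontology.terms().set_index("term_id")
    for term_id, genes in sorted(ontology.term_to_genes().items()):
        bg_genes = genes & background_set
        m = len(bg_genes)
        if m < min_term_size:
            continue
        k = len(bg_genes & study_set)
        counts = ContingencyCounts(k=k, K=K, m=m, N=N)
        rows.append({
            "term_id": term_id,
            "term_name": terms.loc[term_id, "term_name"],
            "namespace": terms.loc[term_id, "namespace"],
            "k": k, "K": K, "m": m, "N": N,
            "p_value": hypergeom_tail(counts),
        })
    result = pd.DataFrame(
        rows, columns=["term_id", "term_name", "namespace", "k", "K", "m", "N", "p_value"]
    )
    if with_q and len(result):
        result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
    return result.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)


def category_enrichment(
    category_genes: Mapping[str, Iterable[str]],
    ontology: OntologyMap,
    background: Iterable[str],
    min_term_size: int = 5,
    with_q: bool = False,
) -> dict[str, pd.DataFrame]:
    """Enrichment per temporal responder category.

    ``category_genes`` maps a category name to the union of member genes of
    that category's clusters. Empty categories are skipped with a log note;
    results are reported per category (no p-value pooling across cell lines —
    combine by concatenating tables term-wise downstream).
    """
    background_set = set(background)
    out: dict[str, pd.DataFrame] = {}
    for category, genes in category_genes.items():
        genes = set(genes) & background_set
        if not genes:
            logger.info("category %s has no genes in the background; skipped", category)
            continue
        out[category] = fisher_enrichment(
            genes, background_set, ontology, min_term_size=min_term_size, with_q=with_q
        )
    return out
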