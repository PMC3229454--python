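"""Orchestrated end-to-end workflow with a reproducibility manifest.

Runs, per ligand: linear normalization -> the three fold-change filters ->
event-count gene ranking -> correlation/average-linkage clustering with
tight-cluster extraction -> cross-ligand synexpression intersection ->
per-cell-line model-based temporal clustering -> GO enrichment of the shared
group and of the temporal categories. Every stage is a pure function of
(inputs, config, seed); the manifest records the config snapshot, input
digests, per-stage parameters and a digest for every output file, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .coexpression import (
    average_linkage_cluster,
    clusters_to_frame,
    extract_tight_clusters,
    intersect_clusters,
)
from .enrichment import category_enrichment, fisher_enrichment
from .filtering import (
    FilterConfig,
    cellline_filter,
    count_events_table,
    general_filter,
    rank_genes,
    timepoint_filter,
    up_fraction,
)
from .io_model import (
    CANONICAL_TIMES,
    read_annotation,
    read_expression_matrix,
    read_ontology,
    unique_gene_map,
)
from .preprocess import linear_normalize
from .temporal import TemporalConfig, probe_categories, temporal_pipeline

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


DEFAULT_CONFIG: dict[str, Any] = {
    "normalize": {"method": "median_center"},
    "filtering": {"fc2": 2.0, "fc3": 3.0, "min_events_fc3": 3, "min_events_fc2": 4,
                  "rank_min_total": 6, "up_fraction_top_n": 100},
    "coexpression": {"cut_height": 0.3, "min_size": 20, "tightness": 0.8},
    "temporal": {"k_min": 2, "k_max": 25,
                 "families": ["spherical_equal", "spherical_varying",
                              "diagonal_equal", "diagonal_varying", "full"],
                 "seed": 7, "n_init": 10, "regulation_threshold": 2.0},
    "enrichment": {"min_term_size": 5, "with_q": False},
}


def _merge(base: Mapping, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: Mapping[str, Any] | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the full workflow; returns the manifest (also written to disk)."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir if out_dir is not None else cfg.get("output_dir", "run"))
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {
        "package_version": __version__,
        "config": cfg,
        "inputs": {},
        "stages": {},
        "outputs": {},
    }
    outputs: dict[str, Path] = {}

    def record(name: str, path: Path) -> None:
        outputs[name] = path

    stage = "inputs"
    try:
        inputs = cfg["inputs"]
        matrices = {}
        for lig, path in sorted(inputs["expression"].items()):
            p = Path(path)
            if not p.exists():
                raise FileNotFoundError(f"expression matrix for {lig}: {p}")
            manifest["inputs"][f"expression_{lig}"] = {"path": str(p), "sha256": _sha256(p)}
            matrices[lig] = read_expression_matrix(p)
            matrices[lig].validate_grid()
        for key in ("annotation", "ontology"):
            p = Path(inputs[key])
            if not p.exists():
                raise FileNotFoundError(f"{key} file: {p}")
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}
        annotations = read_annotation(inputs["annotation"])
        ontology = read_ontology(inputs["ontology"])
        probe_to_gene = unique_gene_map(annotations)
        background = sorted(set(probe_to_gene.values()))

        # -- normalization ----------------------------------------------------
        stage = "normalize"
        method = cfg["normalize"]["method"]
        manifest["stages"]["normalize"] = {"method": method}
        for lig in sorted(matrices):
            matrices[lig], report = linear_normalize(matrices[lig], method=method)
            path = out / f"normalized_{lig}.tsv"
            matrices[lig].write_tsv(path)
            record(f"normalized_{lig}", path)
            rpath = out / f"normalization_report_{lig}.tsv"
            report.to_frame().to_csv(rpath, sep="\t", float_format="%.10g")
            record(f"normalization_report_{lig}", rpath)

        # -- filtering and ranking --------------------------------------------
        stage = "filtering"
        fcfg = FilterConfig(
            fc2_threshold=cfg["filtering"]["fc2"],
            fc3_threshold=cfg["filtering"]["fc3"],
            general_min_events_fc3=cfg["filtering"]["min_events_fc3"],
            general_min_events_fc2=cfg["filtering"]["min_events_fc2"],
        )
        manifest["stages"]["filtering"] = dict(cfg["filtering"])
        survivors: dict[str, list[str]] = {}
        cellline_survivors: dict[str, dict[str, list[str]]] = {}
        for lig, matrix in sorted(matrices.items()):
            per_line = {}
            for cl in matrix.cell_lines:
                kept = cellline_filter(matrix.subset_cell_line(cl, lig), fcfg)
                per_line[cl] = kept
                logger.info("%s %s: %d cell-line DEPs", lig, cl, len(kept))
            cellline_survivors[lig] = per_line
            tp_counts = {t: len(timepoint_filter(matrix, t, fcfg)) for t in CANONICAL_TIMES}
            survivors[lig] = sorted(general_filter(matrix, fcfg))
            logger.info("%s: %d general-filter DEPs", lig, len(survivors[lig]))
            path = out / f"general_filter_{lig}.txt"
            path.write_text("\n".join(survivors[lig]) + "\n")
            record(f"general_filter_{lig}", path)
            dep = pd.DataFrame(
                [{"cell_line": cl, "n_deps": len(v)} for cl, v in sorted(per_line.items())]
                + [{"cell_line": f"timepoint_{t:g}h", "n_deps": c}
                   for t, c in tp_counts.items()]
            )
            path = out / f"dep_counts_{lig}.tsv"
            _write_tsv(dep, path)
            record(f"dep_counts_{lig}", path)

            counts = count_events_table(matrix, probe_to_gene, fcfg,
                                        probe_ids=survivors[lig])
            ranked = rank_genes(counts, min_total=cfg["filtering"]["rank_min_total"])
            path = out / f"ranked_genes_{lig}.tsv"
            _write_tsv(ranked, path)
            record(f"ranked_genes_{lig}", path)
            top_n = min(cfg["filtering"]["up_fraction_top_n"], len(ranked))
            manifest["stages"][f"up_fraction_{lig}"] = (
                {"top_n": top_n, "value": up_fraction(ranked, top_n)} if top_n else {}
            )

        # -- coexpression ------------------------------------------------------
        stage = "coexpression"
        ccfg = cfg["coexpression"]
        manifest["stages"]["coexpression"] = dict(ccfg)
        top_clusters = {}
        for lig, matrix in sorted(matrices.items()):
            sub = matrix.subset_probes(survivors[lig])
            dendro = average_linkage_cluster(sub)
            dendro.write(out / f"dendrogram_{lig}.nwk", out / f"dendrogram_{lig}.json")
            record(f"dendrogram_{lig}_nwk", out / f"dendrogram_{lig}.nwk")
            record(f"dendrogram_{lig}_json", out / f"dendrogram_{lig}.json")
            tight = extract_tight_clusters(
                dendro, sub, cut_height=ccfg["cut_height"],
                min_size=ccfg["min_size"], tightness=ccfg["tightness"],
            )
            path = out / f"tight_clusters_{lig}.tsv"
            _write_tsv(clusters_to_frame(tight), path)
            record(f"tight_clusters_{lig}", path)
            if tight:
                top_clusters[lig] = tight[0]

        group_genes: list[str] = []
        if len(top_clusters) == 2:
            a, b = (top_clusters[lig] for lig in sorted(top_clusters))
            group = intersect_clusters(a, b, annotations)
            group_genes = group.unique_genes
            frame = pd.DataFrame({"probe_id": group.shared_probes})
            frame["gene_id"] = frame["probe_id"].map(
                lambda p: probe_to_gene.get(p, ""))
            path = out / "synexpression_group.tsv"
            _write_tsv(frame, path)
            record("synexpression_group", path)
            manifest["stages"]["synexpression"] = {
                "size_a": group.size_a, "size_b": group.size_b,
                "shared": group.size, "unique_genes": len(group.unique_genes),
            }

        # -- temporal clustering -----------------------------------------------
        stage = "temporal"
        tcfg_raw = cfg["temporal"]
        manifest["stages"]["temporal"] = dict(tcfg_raw)
        category_genes: dict[str, dict[str, set[str]]] = {}
        for lig, matrix in sorted(matrices.items()):
            category_genes[lig] = {}
            for cl in matrix.cell_lines:
                kept = cellline_survivors[lig][cl]
                if len(kept) < 2 * tcfg_raw["k_min"]:
                    logger.info("%s %s: too few DEPs for temporal clustering", lig, cl)
                    continue
                sub = matrix.subset_cell_line(cl, lig).subset_probes(kept)
                tcfg = TemporalConfig(
                    k_min=tcfg_raw["k_min"], k_max=tcfg_raw["k_max"],
                    families=tuple(tcfg_raw["families"]), seed=tcfg_raw["seed"],
                    n_init=tcfg_raw["n_init"],
                    regulation_threshold=tcfg_raw["regulation_threshold"],
                )
                clusters, summary, trace = temporal_pipeline(sub, tcfg)
                base = f"temporal_{lig}_{cl}"
                membership = pd.DataFrame(
                    [{"cluster_id": c.cluster_id, "probe_id": m, "category": c.category}
                     for c in clusters for m in c.members]
                )
                _write_tsv(membership, out / f"{base}_membership.tsv")
                record(f"{base}_membership", out / f"{base}_membership.tsv")
                _write_tsv(summary, out / f"{base}_summary.tsv")
                record(f"{base}_summary", out / f"{base}_summary.tsv")
                _write_tsv(trace, out / f"{base}_bic.tsv")
                record(f"{base}_bic", out / f"{base}_bic.tsv")
                for probe, cat in probe_categories(clusters).items():
                    gene = probe_to_gene.get(probe)
                    if gene is not None and cat != "undetermined":
                        category_genes[lig].setdefault(cat, set()).add(gene)

        # -- enrichment --------------------------------------------------------
        stage = "enrichment"
        ecfg = cfg["enrichment"]
        manifest["stages"]["enrichment"] = dict(ecfg)
        if group_genes:
            table = fisher_enrichment(group_genes, background, ontology,
                                      min_term_size=ecfg["min_term_size"],
                                      with_q=ecfg["with_q"])
            path = out / "enrichment_synexpression_group.tsv"
            _write_tsv(table, path)
            record("enrichment_synexpression_group", path)
        for lig in sorted(category_genes):
            results = category_enrichment(
                {c: g for c, g in sorted(category_genes[lig].items())},
                ontology, background,
                min_term_size=ecfg["min_term_size"], with_q=ecfg["with_q"],
            )
            for cat, table in sorted(results.items()):
                path = out / f"enrichment_{lig}_{cat}.tsv"
                _write_tsv(table, path)
                record(f"enrichment_{lig}_{cat}", path)
    except Exception as exc:  # record a partial manifest naming the stage
        manifest["failed_stage"] = stage
        manifest["outputs"] = {n: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
                               for n, p in sorted(outputs.items())}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise PipelineError(stage, exc) from exc

    # output paths are recorded relative to the run directory so reruns into
    # different directories produce byte-identical manifests
    manifest["outputs"] = {n: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
                           for n, p in sorted(outputs.items())}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
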