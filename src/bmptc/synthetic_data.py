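"""Seeded simulator of BMP-style time-course expression datasets.

The generator emulates the layout the analysis assumes: per-ligand
probes x events matrices over five cell lines and six time points
(0.5-24 h), with

* null probes — i.i.d. Normal(0, sigma^2) log2 ratios;
* responder probes — a saturating step response of magnitude A (log2 units)
  switched on at an onset time drawn from one of the four responder
  categories (early: 0.5/1 h, early-intermediate: 3/6 h, late-intermediate:
  12 h, late: 24 h), with a cell-line-dependent sign (each (probe, cell
  line) flips to repression with a configurable probability), added to the
  noise in every cell line of both ligands;
* a planted synexpression group — probes that share one latent step profile
  per (cell line, ligand) plus reduced probe-level noise, with a configurable
  fraction of the group common to both ligands; in the cell lines treated
  with both ligands the common probes reuse the identical latent profile, so
  the shared co-expression block is recoverable by cluster intersection;
* a flat synthetic ontology with uniformly random terms plus one planted
  term whose genes are drawn from one onset category.

All randomness flows from the single seed; a fixed seed reproduces the
dataset exactly. Ground-truth labels for every planted structure are
returned alongside the data so each pipeline stage has a recovery metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .io_model import (
    CANONICAL_TIMES,
    EventKey,
    ExpressionMatrix,
    OntologyMap,
    ProbeAnnotation,
    ValidationError,
)

BMP4_LINES = ("HCC1954", "MDA-MB-361", "ZR-75-30", "HCC1419", "SK-BR-3")
BMP7_LINES = ("HCC1954", "MDA-MB-361", "ZR-75-30", "MDA-MB-231", "T-47D")

_ONSETS = {
    "early": (0.5, 1.0),
    "early_intermediate": (3.0, 6.0),
    "late_intermediate": (12.0,),
    "late": (24.0,),
}


@dataclass(frozen=True)
class SimulationConfig:
    n_probes: int = 2000
    cell_lines: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {"BMP4": BMP4_LINES, "BMP7": BMP7_LINES}
    )
    noise_sd: float = 0.25
    responder_fraction: float = 0.2
    onset_mixture: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.25 for c in _ONSETS}
    )
    response_magnitude: float = 1.5
    sign_flip_prob: float = 0.3
    response_shape: str = "step"  # or "pulse" (on at onset and the next point only)
    group_size: int = 40
    group_shared_fraction: float = 0.8
    annotation_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"unique": 0.66, "multiple": 0.16, "unannotated": 0.18}
    )
    n_terms: int = 200
    genes_per_term: int = 20
    planted_term_category: str = "early"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in [("responder_fraction", self.responder_fraction),
                        ("group_shared_fraction", self.group_shared_fraction),
                        ("sign_flip_prob", self.sign_flip_prob)]:
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.noise_sd <= 0 or self.response_magnitude <= 0:
            raise ValidationError("noise_sd and response_magnitude must be positive")
        if self.response_shape not in ("step", "pulse"):
            raise ValidationError("response_shape must be 'step' or 'pulse'")
        n_structured = round(self.responder_fraction * self.n_probes)
        if self.group_size > n_structured:
            raise ValidationError(
                f"group_size {self.group_size} exceeds the responder pool {n_structured}"
            )
        if abs(sum(self.onset_mixture.values()) - 1) > 1e-9:
            raise ValidationError("onset mixture must sum to 1")


@dataclass
class GroundTruth:
    """Planted labels consistent with the emitted matrices by construction."""

    probe_class: dict[str, str]                 # probe -> null | responder
    onset_category: dict[str, str]              # non-group responders only
    onset_time: dict[str, float]
    signs: dict[str, dict[str, int]]            # cell_line -> probe -> +-1
    group_members: dict[str, list[str]]         # ligand -> probes
    shared_group: list[str]
    planted_term_id: str
    planted_term_category: str
    config: SimulationConfig

    @property
    def responders(self) -> set[str]:
        return {p for p, c in self.probe_class.items() if c == "responder"}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "probe_class": self.probe_class,
            "onset_category": self.onset_category,
            "onset_time": self.onset_time,
            "signs": self.signs,
            "group_members": self.group_members,
            "shared_group": self.shared_group,
            "planted_term_id": self.planted_term_id,
            "planted_term_category": self.planted_term_category,
            "config": _config_dict(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["cell_lines"] = {k: list(v) for k, v in config.cell_lines.items()}
    d["onset_mixture"] = dict(config.onset_mixture)
    d["annotation_proportions"] = dict(config.annotation_proportions)
    return d


def _step(onset: float, shape: str) -> np.ndarray:
    times = np.array(CANONICAL_TIMES)
    on = times >= onset
    if shape == "pulse":
        idx = int(np.argmax(on))
        pulse = np.zeros(len(times), dtype=bool)
        pulse[idx: idx + 2] = True
        on = pulse
    return on.astype(float)


def generate_dataset(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[dict[str, ExpressionMatrix], dict[str, ProbeAnnotation], OntologyMap, GroundTruth]:
    """Simulate per-ligand matrices, annotation, ontology and ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_probes
    probes = [f"P{i:05d}" for i in range(n)]
    ligands = list(config.cell_lines)
    all_lines = sorted({cl for lines in config.cell_lines.values() for cl in lines})
    shared_lines = [cl for cl in all_lines
                    if all(cl in lines for lines in config.cell_lines.values())]

    # -- planted structure assignment ----------------------------------------
    n_resp = round(config.responder_fraction * n)
    resp_idx = rng.choice(n, size=n_resp, replace=False)
    responders = [probes[i] for i in sorted(resp_idx)]

    g = config.group_size
    n_shared = round(config.group_shared_fraction * g) if len(ligands) > 1 else 0
    pool = list(responders)
    rng.shuffle(pool)
    group_members: dict[str, list[str]] = {}
    if ligands:
        need = g + (len(ligands) - 1) * (g - n_shared)
        if need > len(pool):
            raise ValidationError("responder pool too small for the requested group sizes")
        shared = sorted(pool[:n_shared])
        cursor = n_shared
        for lig in ligands:
            own = pool[cursor: cursor + g - n_shared]
            cursor += g - n_shared
            group_members[lig] = sorted(shared + own)
    group_all = {p for members in group_members.values() for p in members}

    onset_category: dict[str, str] = {}
    onset_time: dict[str, float] = {}
    cats = list(config.onset_mixture)
    cat_p = np.array([config.onset_mixture[c] for c in cats])
    for p in responders:
        if p in group_all:
            continue
        cat = cats[rng.choice(len(cats), p=cat_p)]
        onset_category[p] = cat
        onset_time[p] = float(rng.choice(_ONSETS[cat]))

    signs: dict[str, dict[str, int]] = {
        cl: {p: int(1 - 2 * (rng.random() < config.sign_flip_prob)) for p in responders}
        for cl in all_lines
    }

    # group latent profiles: one per (cell line, ligand); identical across
    # ligands in the cell lines treated with both
    latents: dict[tuple[str, str], np.ndarray] = {}
    for cl in all_lines:
        base = None
        for lig in ligands:
            if cl not in config.cell_lines[lig]:
                continue
            if cl in shared_lines and base is not None:
                latents[(lig, cl)] = base
                continue
            sign = 1 - 2 * (rng.random() < config.sign_flip_prob)
            onset = float(rng.choice([0.5, 1.0, 3.0, 6.0]))
            prof = sign * config.response_magnitude * _step(onset, "step")
            latents[(lig, cl)] = prof
            if cl in shared_lines:
                base = prof

    # -- matrices -------------------------------------------------------------
    probe_pos = {p: i for i, p in enumerate(probes)}
    matrices: dict[str, ExpressionMatrix] = {}
    for lig in ligands:
        lines = config.cell_lines[lig]
        cols = [EventKey(cl, lig, t) for cl in lines for t in CANONICAL_TIMES]
        values = rng.normal(0.0, config.noise_sd, size=(n, len(cols)))
        for ci, cl in enumerate(lines):
            block = slice(ci * 6, ci * 6 + 6)
            for p in responders:
                if p in group_all:
                    continue
                h = _step(onset_time[p], config.response_shape)
                values[probe_pos[p], block] += (
                    signs[cl][p] * config.response_magnitude * h
                )
            latent = latents[(lig, cl)]
            for p in group_members.get(lig, []):
                values[probe_pos[p], block] = latent + rng.normal(
                    0.0, config.noise_sd / 2.0, size=6
                )
        df = pd.DataFrame(values, index=probes, columns=[c.token for c in cols])
        matrices[lig] = ExpressionMatrix(df)

    # -- annotation -----------------------------------------------------------
    structured = sorted(set(responders) | group_all)
    annotations: dict[str, ProbeAnnotation] = {}
    gene_of: dict[str, str] = {}
    for p in structured:  # planted probes are always uniquely annotated
        gene = f"G{probe_pos[p]:05d}"
        annotations[p] = ProbeAnnotation(p, (gene,))
        gene_of[p] = gene
    props = config.annotation_proportions
    n_unique = max(round(props["unique"] * n), len(structured))
    n_multiple = round(props["multiple"] * n)
    nulls = [p for p in probes if p not in annotations]
    rng.shuffle(nulls)
    extra_unique = n_unique - len(structured)
    for j, p in enumerate(nulls):
        if j < extra_unique:
            gene = f"G{probe_pos[p]:05d}"
            annotations[p] = ProbeAnnotation(p, (gene,))
            gene_of[p] = gene
        elif j < extra_unique + n_multiple:
            annotations[p] = ProbeAnnotation(
                p, (f"G{probe_pos[p]:05d}", f"GM{probe_pos[p]:05d}")
            )
        else:
            annotations[p] = ProbeAnnotation(p, ())

    # -- ontology -------------------------------------------------------------
    background = sorted(gene_of.values())
    planted_genes = sorted({
        gene_of[p] for p in responders
        if onset_category.get(p) == config.planted_term_category
    })
    if len(planted_genes) > config.genes_per_term:
        idx = rng.choice(len(planted_genes), size=config.genes_per_term, replace=False)
        planted_genes = [planted_genes[i] for i in sorted(idx)]
    rows = []
    planted_term_id = "T0000"
    rows += [{"gene_id": gid, "term_id": planted_term_id,
              "term_name": "planted synthetic response module",
              "namespace": "biological_process"} for gid in planted_genes]
    for t in range(1, config.n_terms + 1):
        term_id = f"T{t:04d}"
        idx = rng.choice(len(background), size=min(config.genes_per_term, len(background)),
                         replace=False)
        rows += [{"gene_id": background[i], "term_id": term_id,
                  "term_name": f"synthetic term {t}",
                  "namespace": "biological_process"} for i in sorted(idx)]
    ontology = OntologyMap(pd.DataFrame(rows, columns=["gene_id", "term_id",
                                                       "term_name", "namespace"]))

    truth = GroundTruth(
        probe_class={p: ("responder" if p in set(responders) else "null") for p in probes},
        onset_category=onset_category,
        onset_time=onset_time,
        signs=signs,
        group_members=group_members,
        shared_group=sorted(set.intersection(*map(set, group_members.values())))
        if len(group_members) > 1 else [],
        planted_term_id=planted_term_id,
        planted_term_category=config.planted_term_category,
        config=config,
    )
    return matrices, annotations, ontology, truth


# -- recovery metrics ---------------------------------------------------------


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def evaluate_recovery(
    truth: GroundTruth,
    retained: Mapping[str, Iterable[str]] | None = None,
    cluster_labels: Mapping[str, int] | None = None,
    shared_group: Iterable[str] | None = None,
    probe_category: Mapping[str, str] | None = None,
    enrichment: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score pipeline outputs against the planted ground truth.

    Any subset of outputs may be supplied; each contributes its metrics:
    general-filter precision/recall per ligand, clustering adjusted Rand
    index against the planted probe classes, synexpression Jaccard, a
    per-category accuracy (plus a confusion long-format block) and the
    planted term's rank in an enrichment table.
    """
    rows: list[dict] = []
    universe = set(truth.probe_class)
    if retained is not None:
        for lig, kept in retained.items():
            kept = set(kept)
            if not kept <= universe:
                raise ValidationError("retained probes outside the simulated universe")
            # a responder carries signal in this ligand's matrix unless it
            # belongs exclusively to the other ligand's synexpression group
            group_all = {p for m in truth.group_members.values() for p in m}
            own_group = set(truth.group_members.get(lig, []))
            true_pos = {p for p in truth.responders
                        if p not in group_all or p in own_group}
            tp = len(kept & true_pos)
            rows.append({"metric": f"filter_precision_{lig}",
                         "value": tp / len(kept) if kept else 0.0})
            rows.append({"metric": f"filter_recall_{lig}",
                         "value": tp / len(true_pos) if true_pos else 1.0})
    if cluster_labels is not None:
        common = sorted(set(cluster_labels) & universe)
        pred = [cluster_labels[p] for p in common]
        true = [truth.onset_category.get(p, "group" if any(
            p in m for m in truth.group_members.values()) else "null") for p in common]
        rows.append({"metric": "clustering_ari",
                     "value": float(adjusted_rand_score(true, pred))})
    if shared_group is not None:
        rows.append({"metric": "synexpression_jaccard",
                     "value": jaccard(shared_group, truth.shared_group)})
    if probe_category is not None:
        evaluable = [p for p in probe_category
                     if p in truth.onset_category]
        correct = sum(probe_category[p] == truth.onset_category[p] for p in evaluable)
        rows.append({"metric": "category_accuracy",
                     "value": correct / len(evaluable) if evaluable else float("nan")})
        for cat in _ONSETS:
            in_cat = [p for p in evaluable if truth.onset_category[p] == cat]
            if in_cat:
                acc = sum(probe_category[p] == cat for p in in_cat) / len(in_cat)
                rows.append({"metric": f"category_accuracy_{cat}", "value": acc})
    if enrichment is not None and len(enrichment):
        order = enrichment.sort_values(["p_value", "term_id"]).reset_index(drop=True)
        where = order.index[order["term_id"] == truth.planted_term_id]
        rank = int(where[0]) + 1 if len(where) else -1
        rows.append({"metric": "planted_term_rank", "value": float(rank)})
    return pd.DataFrame(rows, columns=["metric", "value"])


def write_dataset(
    out_dir: str | Path,
    matrices: Mapping[str, ExpressionMatrix],
    annotations: dict[str, ProbeAnnotation],
    ontology: OntologyMap,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write the TSV matrices, annotation, ontology and truth JSON."""
    from .io_model import write_annotation

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for lig, matrix in matrices.items():
        paths[f"matrix_{lig}"] = out / f"expression_{lig}.tsv"
        matrix.write_tsv(paths[f"matrix_{lig}"])
    paths["annotation"] = out / "annotation.tsv"
    write_annotation(annotations, paths["annotation"])
    paths["ontology"] = out / "ontology.tsv"
    ontology.write_tsv(paths["ontology"])
    paths["truth"] = out / "truth.json"
    truth.to_json(paths["truth"])
    return paths
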