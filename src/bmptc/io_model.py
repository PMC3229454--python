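"""Domain types and file I/O for the BMP time-course expression data.

The unit of observation is an *event*: one (cell line, ligand, time point)
combination. A dataset is a probes x events matrix of log2(treatment/vehicle)
expression ratios sampled at six canonical time points (0.5, 1, 3, 6, 12 and
24 h after ligand addition). Columns are named with the token grammar
``CELLLINE_LIGAND_TIMEh`` (e.g. ``HCC1954_BMP4_0.5h``), which encodes the full
event key losslessly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CANONICAL_TIMES: tuple[float, ...] = (0.5, 1.0, 3.0, 6.0, 12.0, 24.0)
LIGANDS: tuple[str, ...] = ("BMP4", "BMP7")


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


class ParseError(ValueError):
    """Raised when a file or header token cannot be parsed."""


def _format_time(t: float) -> str:
    return f"{t:g}h"


@dataclass(frozen=True, order=True)
class EventKey:
    """One (cell line, ligand, time point) treatment event."""

    cell_line: str
    ligand: str
    time_point: float  # hours

    def __post_init__(self) -> None:
        if self.ligand not in LIGANDS:
            raise ValidationError(f"unknown ligand {self.ligand!r} (expected one of {LIGANDS})")
        if self.time_point not in CANONICAL_TIMES:
            raise ValidationError(
                f"non-canonical time point {self.time_point!r} "
                f"(expected one of {CANONICAL_TIMES})"
            )

    @property
    def token(self) -> str:
        return f"{self.cell_line}_{self.ligand}_{_format_time(self.time_point)}"

    @classmethod
    def from_token(cls, token: str) -> "EventKey":
        parts = token.rsplit("_", 2)
        if len(parts) != 3 or not parts[0]:
            raise ParseError(f"malformed event token {token!r}; expected CELLLINE_LIGAND_TIMEh")
        cell_line, ligand, time_str = parts
        if not time_str.endswith("h"):
            raise ParseError(f"malformed time field in token {token!r}; expected e.g. '3h'")
        try:
            time_point = float(time_str[:-1])
        except ValueError as exc:
            raise ParseError(f"unparseable time in token {token!r}") from exc
        if ligand not in LIGANDS:
            raise ValidationError(f"column {token!r}: unknown ligand {ligand!r}")
        if time_point not in CANONICAL_TIMES:
            raise ValidationError(
                f"column {token!r}: non-canonical time point {time_str!r}"
            )
        return cls(cell_line=cell_line, ligand=ligand, time_point=time_point)


@dataclass
class ExpressionMatrix:
    """Probes x events matrix of log2(treatment/vehicle) ratios.

    ``data`` is a DataFrame indexed by probe id whose columns are event
    tokens; ``events`` is the parallel list of parsed :class:`EventKey`.
    Column order groups by cell line then ascending time.
    """

    data: pd.DataFrame
    events: list[EventKey] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.events:
            self.events = [EventKey.from_token(c) for c in self.data.columns]
        self.validate()

    def validate(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValidationError("expression matrix must be non-empty")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dups[:5]}")
        if len(self.events) != self.data.shape[1]:
            raise ValidationError("events list does not match column count")
        tokens = [e.token for e in self.events]
        if len(set(tokens)) != len(tokens):
            raise ValidationError("duplicate event columns")
        # columns group by (cell line, ligand) contiguously, ascending in time
        seen: list[tuple[str, str]] = []
        by_line: dict[tuple[str, str], list[float]] = {}
        for e in self.events:
            key = (e.cell_line, e.ligand)
            if key in by_line and seen[-1] != key:
                raise ValidationError(f"columns for {key} are not contiguous")
            by_line.setdefault(key, []).append(e.time_point)
            seen.append(key)
        for (cl, lig), times in by_line.items():
            if times != sorted(times):
                raise ValidationError(f"columns for {cl} ({lig}) not in ascending time order")

    def validate_grid(self) -> None:
        """Require the full design: six canonical time points per cell line."""
        by_line: dict[tuple[str, str], list[float]] = {}
        for e in self.events:
            by_line.setdefault((e.cell_line, e.ligand), []).append(e.time_point)
        for (cl, lig), times in by_line.items():
            if sorted(times) != list(CANONICAL_TIMES):
                raise ValidationError(
                    f"cell line {cl} ({lig}) does not carry the six canonical "
                    f"time points: has {sorted(times)}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_lines(self) -> list[str]:
        seen: list[str] = []
        for e in self.events:
            if e.cell_line not in seen:
                seen.append(e.cell_line)
        return seen

    @property
    def ligands(self) -> list[str]:
        return sorted({e.ligand for e in self.events})

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_cell_line(self, cell_line: str, ligand: str | None = None) -> "ExpressionMatrix":
        cols = [
            e.token
            for e in self.events
            if e.cell_line == cell_line and (ligand is None or e.ligand == ligand)
        ]
        if not cols:
            raise KeyError(f"no columns for cell line {cell_line!r}")
        return ExpressionMatrix(self.data[cols].copy())

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = set(probe_ids) - set(self.data.index)
        if missing:
            raise KeyError(f"unknown probe ids: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.data.loc[list(probe_ids)].copy())

    def write_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t", float_format="%.10g", na_rep="NA")


def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a probes x events log2-ratio matrix.

    ``dialect='tsv'``: plain TSV whose header encodes events as
    ``CELLLINE_LIGAND_TIMEh`` tokens, first column the probe id.
    ``dialect='geo_series_matrix'``: same layout but metadata lines are
    prefixed with ``!`` and fields may be double-quoted (the GEO series-matrix
    convention); sample titles must use the same token grammar.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    elif dialect == "geo_series_matrix":
        lines = [
            ln for ln in path.read_text().splitlines()
            if ln.strip() and not ln.startswith("!")
        ]
        df = pd.read_csv(
            io.StringIO("\n".join(lines)), sep="\t", index_col=0,
            na_values=["NA", "null", ""], quotechar='"',
        )
        df.index = df.index.astype(str).str.strip('"')
        df.columns = [str(c).strip('"') for c in df.columns]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df.index = df.index.astype(str)
    events = [EventKey.from_token(str(c)) for c in df.columns]
    return ExpressionMatrix(df.astype(float), events)


# -- probe annotation ---------------------------------------------------------

_STATUSES = ("unique", "multiple", "unannotated")


@dataclass(frozen=True)
class ProbeAnnotation:
    """Mapping from one probe to zero or more stable gene identifiers."""

    probe_id: str
    gene_ids: tuple[str, ...]

    @property
    def status(self) -> str:
        n = len(self.gene_ids)
        return "unannotated" if n == 0 else ("unique" if n == 1 else "multiple")


def read_annotation(path: str | Path) -> dict[str, ProbeAnnotation]:
    """Read a 2-column TSV of probe_id and ';'-separated gene ids."""
    annotations: dict[str, ProbeAnnotation] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in {"probe_id", "probe"}:
                continue
            probe_id = fields[0]
            raw = fields[1] if len(fields) > 1 else ""
            gene_ids = tuple(g for g in raw.split(";") if g)
            ann = ProbeAnnotation(probe_id, gene_ids)
            if probe_id in annotations and annotations[probe_id].gene_ids != gene_ids:
                raise ValidationError(
                    f"probe {probe_id!r} listed twice with conflicting gene sets"
                )
            annotations[probe_id] = ann
    return annotations


def annotation_summary(annotations: Iterable[ProbeAnnotation]) -> dict[str, float]:
    """Proportions of unique / multiple / unannotated probes (sum to 1)."""
    counts = {s: 0 for s in _STATUSES}
    total = 0
    for ann in annotations:
        counts[ann.status] += 1
        total += 1
    if total == 0:
        raise ValidationError("empty annotation collection")
    return {s: counts[s] / total for s in _STATUSES}


def unique_gene_map(annotations: dict[str, ProbeAnnotation]) -> dict[str, str]:
    """probe_id -> gene_id restricted to uniquely annotated probes."""
    return {p: a.gene_ids[0] for p, a in annotations.items() if a.status == "unique"}


def write_annotation(annotations: dict[str, ProbeAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tgene_ids\n")
        for probe_id in sorted(annotations):
            fh.write(f"{probe_id}\t{';'.join(annotations[probe_id].gene_ids)}\n")


# -- ontology map -------------------------------------------------------------

_NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


@dataclass
class OntologyMap:
    """Flat gene -> GO-term mapping (no DAG propagation)."""

    table: pd.DataFrame  # columns: gene_id, term_id, term_name, namespace

    def __post_init__(self) -> None:
        required = ["gene_id", "term_id", "term_name", "namespace"]
        if list(self.table.columns) != required:
            raise ValidationError(f"ontology table must have columns {required}")
        if self.table.duplicated(["gene_id", "term_id"]).any():
            raise ValidationError("duplicate (gene_id, term_id) pairs in ontology map")
        per_term = self.table.groupby("term_id")[["term_name", "namespace"]].nunique()
        bad = per_term[(per_term > 1).any(axis=1)].index.tolist()
        if bad:
            raise ValidationError(f"terms with conflicting name/namespace: {bad[:5]}")
        unknown_ns = set(self.table["namespace"]) - set(_NAMESPACES)
        if unknown_ns:
            raise ValidationError(f"unknown namespaces: {sorted(unknown_ns)}")

    def genes_for_term(self, term_id: str) -> set[str]:
        return set(self.table.loc[self.table["term_id"] == term_id, "gene_id"])

    def terms(self) -> pd.DataFrame:
        return self.table.drop_duplicates("term_id")[["term_id", "term_name", "namespace"]]

    def term_to_genes(self) -> dict[str, set[str]]:
        return {t: set(g) for t, g in self.table.groupby("term_id")["gene_id"]}

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_ontology(path: str | Path) -> OntologyMap:
    """Read a gene->GO TSV: either the 4-column native layout or a 2-column
    GAF-style core (gene_id, term_id), in which case term names default to the
    term id and the namespace to biological_process."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if set(cols) >= {"gene_id", "term_id", "term_name", "namespace"}:
        df = df[["gene_id", "term_id", "term_name", "namespace"]]
    elif cols[:2] == ["gene_id", "term_id"] or len(cols) == 2:
        df = df.iloc[:, :2]
        df.columns = ["gene_id", "term_id"]
        df["term_name"] = df["term_id"]
        df["namespace"] = "biological_process"
    else:
        raise ParseError(f"unrecognized ontology layout with columns {cols}")
    return OntologyMap(df.reset_index(drop=True))
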