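"""Annotation linkage from local lookup tables.

Transcript probe codes are mapped to Arabidopsis (At) and Solanaceae
Unigene (SGN-U) identifiers plus a free-text description; metabolite names
are mapped to KEGG compound identifiers and the pathways they participate
in.  Both maps are read from plain tab-separated files the user exports
themselves, which keeps the package fully offline.

Transcript table columns (header required):

    probe_code  at_id  sgn_u  description

Metabolite table columns (header required):

    metabolite  kegg_compound  pathways

where ``pathways`` is a semicolon-separated list of ``id:name`` entries,
e.g. ``ko00250:Alanine, aspartate and glutamate metabolism;ko00410:...``.

Annotation is a pure decoration: it never changes membership or counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from ilsom.analysis import NeuronReport
from ilsom.datatypes import KIND_METABOLITE, KIND_TRANSCRIPT, ProfileDataset

logger = logging.getLogger(__name__)

_TRANSCRIPT_HEADER = ["probe_code", "at_id", "sgn_u", "description"]
_METABOLITE_HEADER = ["metabolite", "kegg_compound", "pathways"]

#: Synthetic example tables bundled with the package (invented identifiers).
EXAMPLE_TRANSCRIPT_TABLE = (
    Path(__file__).parent / "data" / "example_annotations_synthetic.tsv"
)
EXAMPLE_METABOLITE_TABLE = (
    Path(__file__).parent / "data" / "example_metabolites_synthetic.tsv"
)


@dataclass
class TranscriptAnnotation:
    probe_code: str
    at_id: str
    sgn_u: str
    description: str


@dataclass
class MetaboliteAnnotation:
    name: str
    kegg_compound: str
    pathways: list[tuple[str, str]]  # (pathway id, pathway name)


@dataclass
class AnnotationTable:
    """Case-insensitive lookup maps for transcripts and metabolites."""

    transcript_map: dict[str, TranscriptAnnotation] = field(default_factory=dict)
    metabolite_map: dict[str, MetaboliteAnnotation] = field(default_factory=dict)

    def lookup_transcript(self, probe_code: str) -> TranscriptAnnotation | None:
        return self.transcript_map.get(probe_code.lower())

    def lookup_metabolite(self, name: str) -> MetaboliteAnnotation | None:
        return self.metabolite_map.get(name.lower())

    def merge(self, other: "AnnotationTable") -> "AnnotationTable":
        merged = AnnotationTable(
            transcript_map=dict(self.transcript_map),
            metabolite_map=dict(self.metabolite_map),
        )
        merged.transcript_map.update(other.transcript_map)
        merged.metabolite_map.update(other.metabolite_map)
        return merged


def _parse_pathways(cell: str) -> list[tuple[str, str]]:
    pathways = []
    for entry in cell.split(";"):
        entry = entry.strip()
        if not entry:
            continue
        pid, _, pname = entry.partition(":")
        pathways.append((pid.strip(), pname.strip()))
    return pathways


def load_annotation_table(*paths: str | Path) -> AnnotationTable:
    """Load one or more tab-separated annotation tables.

    The schema of each file is detected from its header row.  Malformed
    rows are skipped with a warning and counted; duplicate keys are
    last-wins with a warning.  Unreadable files raise OSError.
    """
    table = AnnotationTable()
    for path in paths:
        path = Path(path)
        lines = path.read_text().splitlines()
        rows = [ln.split("\t") for ln in lines if ln.strip()]
        if not rows:
            logger.warning("%s: empty annotation table", path)
            continue
        header = [c.strip().lower() for c in rows[0]]
        if header == _TRANSCRIPT_HEADER:
            table = table.merge(_load_transcript_rows(path, rows[1:]))
        elif header == _METABOLITE_HEADER:
            table = table.merge(_load_metabolite_rows(path, rows[1:]))
        else:
            raise ValueError(
                f"{path}: unrecognized header {header}; expected "
                f"{_TRANSCRIPT_HEADER} or {_METABOLITE_HEADER}"
            )
    return table


def _load_transcript_rows(path: Path, rows: list[list[str]]) -> AnnotationTable:
    table = AnnotationTable()
    skipped = 0
    for row in rows:
        if len(row) != 4 or not row[0].strip():
            skipped += 1
            continue
        key = row[0].strip().lower()
        if key in table.transcript_map:
            logger.warning("%s: duplicate probe code %r, last wins", path, row[0])
        table.transcript_map[key] = TranscriptAnnotation(
            probe_code=row[0].strip(),
            at_id=row[1].strip(),
            sgn_u=row[2].strip(),
            description=row[3].strip(),
        )
    if skipped:
        logger.warning("%s: skipped %d malformed rows", path, skipped)
    return table


def _load_metabolite_rows(path: Path, rows: list[list[str]]) -> AnnotationTable:
    table = AnnotationTable()
    skipped = 0
    for row in rows:
        if len(row) != 3 or not row[0].strip():
            skipped += 1
            continue
        key = row[0].strip().lower()
        if key in table.metabolite_map:
            logger.warning("%s: duplicate metabolite %r, last wins", path, row[0])
        table.metabolite_map[key] = MetaboliteAnnotation(
            name=row[0].strip(),
            kegg_compound=row[1].strip(),
            pathways=_parse_pathways(row[2]),
        )
    if skipped:
        logger.warning("%s: skipped %d malformed rows", path, skipped)
    return table


UNANNOTATED = "unannotated"


def annotation_lines(
    pattern_kind: str, entity_id: str, table: AnnotationTable
) -> list[str]:
    """Human-readable annotation lines for one entity (never empty)."""
    if pattern_kind == KIND_TRANSCRIPT:
        hit = table.lookup_transcript(entity_id)
        if hit is None:
            return [UNANNOTATED]
        return [f"At: {hit.at_id}", f"SGN-U: {hit.sgn_u}", hit.description]
    hit_m = table.lookup_metabolite(entity_id)
    if hit_m is None:
        return [UNANNOTATED]
    lines = [f"KEGG: {hit_m.kegg_compound}"]
    lines += [f"pathway {pid}: {pname}" for pid, pname in hit_m.pathways]
    return lines or [UNANNOTATED]


def annotate_neuron(
    report: NeuronReport, table: AnnotationTable, dataset: ProfileDataset
) -> NeuronReport:
    """Attach annotation lines to every member of a neuron report.

    Members without a table entry are marked "unannotated", never dropped;
    membership, counts, composition and cohesion are untouched.
    """
    report.annotations = {
        i: annotation_lines(
            dataset.patterns[i].kind, dataset.patterns[i].entity_id, table
        )
        for i in report.members
    }
    return report
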