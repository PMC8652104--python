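"""Readers and writers for the on-disk formats.

PAV matrix dialect (tab-separated, UTF-8, ``\\n`` or ``\\r\\n``):

    #Chromosome  Start  Stop  BlockID  SimilarBlocks  Function  <genome1>  <genome2> ...

The six fixed leading columns carry the linear position data, then one
column per genome holds an integer copy count (0 = absent).  Coordinates
are 0-based half-open.  ``SimilarBlocks`` is ``.`` when the block is
unique, else semicolon-joined ``panchromosome:start`` tokens pointing at
repeated occurrences; ``Function`` is free text, ``.`` when empty.

GFF3 is read with its native 1-based inclusive coordinates and converted
to the internal 0-based half-open convention; ``seqid`` must name a
panchromosome of the matrix.  Newick trees are parsed with dendropy and
reduced to their left-to-right leaf order (branch lengths ignored).

All readers have a collecting counterpart exposed through
:func:`validate`, which returns a :class:`ValidationReport` instead of
raising; a file with at least one ERROR never silently loads.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, TextIO

import dendropy
import pandas as pd

from .model import PangenomeBlock, PavMatrix, PavModelError

__all__ = [
    "PAV_FIXED_COLUMNS",
    "Severity",
    "Issue",
    "ValidationReport",
    "PavFormatError",
    "AnnotationFeature",
    "AnnotationCard",
    "read_pav",
    "write_pav",
    "read_annotations",
    "read_tree",
    "validate",
]

PAV_FIXED_COLUMNS = ("#Chromosome", "Start", "Stop", "BlockID", "SimilarBlocks", "Function")


class Severity(str, Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"


@dataclass(frozen=True)
class Issue:
    severity: Severity
    code: str
    message: str
    line: int | None = None

    def __str__(self) -> str:
        where = f" (line {self.line})" if self.line is not None else ""
        return f"{self.severity.value} [{self.code}]{where}: {self.message}"


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    def error(self, code: str, message: str, line: int | None = None) -> None:
        self.issues.append(Issue(Severity.ERROR, code, message, line))

    def warning(self, code: str, message: str, line: int | None = None) -> None:
        self.issues.append(Issue(Severity.WARNING, code, message, line))

    @property
    def n_errors(self) -> int:
        return sum(1 for i in self.issues if i.severity is Severity.ERROR)

    @property
    def n_warnings(self) -> int:
        return sum(1 for i in self.issues if i.severity is Severity.WARNING)

    @property
    def ok(self) -> bool:
        return self.n_errors == 0

    def __str__(self) -> str:
        if not self.issues:
            return "OK (no issues)"
        return "\n".join(str(i) for i in self.issues)


class PavFormatError(ValueError):
    """Raised by readers on malformed input; carries the full report."""

    def __init__(self, report: ValidationReport):
        self.report = report
        super().__init__(str(report))


def _as_text(stream: str | TextIO) -> str:
    if isinstance(stream, str):
        return stream
    return stream.read()


def _lines(text: str) -> list[str]:
    return text.replace("\r\n", "\n").split("\n")


# ---------------------------------------------------------------------------
# PAV matrix
# ---------------------------------------------------------------------------

def _parse_similar(token: str) -> tuple[tuple[str, int], ...]:
    if token == "." or token == "":
        return ()
    out = []
    for part in token.split(";"):
        chrom, _, start = part.rpartition(":")
        if not chrom:
            raise ValueError(f"malformed SimilarBlocks token {part!r}")
        out.append((chrom, int(start)))
    return tuple(out)


def _format_similar(positions: Iterable[tuple[str, int]]) -> str:
    toks = [f"{c}:{s}" for c, s in positions]
    return ";".join(toks) if toks else "."


def _read_pav_collect(text: str, report: ValidationReport) -> PavMatrix | None:
    lines = _lines(text)
    header = None
    header_no = 0
    for i, line in enumerate(lines, start=1):
        if line.strip():
            header, header_no = line, i
            break
    if header is None or not header.startswith(PAV_FIXED_COLUMNS[0]):
        report.error("PAV_NO_HEADER", "missing header line starting with '#Chromosome'")
        return None
    cols = header.rstrip("\n").split("\t")
    if tuple(cols[: len(PAV_FIXED_COLUMNS)]) != PAV_FIXED_COLUMNS:
        report.error(
            "PAV_BAD_HEADER",
            f"fixed columns must be {PAV_FIXED_COLUMNS}, got {tuple(cols[:6])}",
            header_no,
        )
        return None
    genomes = cols[len(PAV_FIXED_COLUMNS):]
    if not genomes:
        report.error("PAV_NO_GENOMES", "header declares no genome columns", header_no)
        return None
    if len(set(genomes)) != len(genomes):
        report.error("PAV_DUP_GENOME", "duplicate genome names in header", header_no)
        return None

    blocks: list[PangenomeBlock] = []
    counts: dict[str, dict[str, int]] = {}
    seen_ids: set[str] = set()
    for i, line in enumerate(lines, start=1):
        if i <= header_no or not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(cols):
            report.error(
                "PAV_BAD_FIELD_COUNT",
                f"expected {len(cols)} tab-separated fields, got {len(fields)}",
                i,
            )
            continue
        chrom, start_s, stop_s, block_id, similar_s, function = fields[:6]
        try:
            start, stop = int(start_s), int(stop_s)
        except ValueError:
            report.error("PAV_BAD_COORD", f"non-integer coordinates {start_s!r}/{stop_s!r}", i)
            continue
        if stop <= start:
            report.error("PAV_BAD_INTERVAL", f"stop ({stop}) <= start ({start})", i)
            continue
        if not block_id:
            report.error("PAV_EMPTY_ID", "empty BlockID", i)
            continue
        if block_id in seen_ids:
            report.error("PAV_DUP_ID", f"duplicate BlockID {block_id!r}", i)
            continue
        try:
            similar = _parse_similar(similar_s)
        except ValueError as exc:
            report.error("PAV_BAD_SIMILAR", str(exc), i)
            continue
        row: dict[str, int] = {}
        bad_cell = False
        for g, cell in zip(genomes, fields[6:]):
            try:
                c = int(cell)
            except ValueError:
                report.error("PAV_BAD_COUNT", f"non-integer count {cell!r} for genome {g!r}", i)
                bad_cell = True
                break
            if c < 0:
                report.error("PAV_NEG_COUNT", f"negative count {c} for genome {g!r}", i)
                bad_cell = True
                break
            row[g] = c
        if bad_cell:
            continue
        if max(row.values()) < 1:
            report.error(
                "PAV_ABSENT_EVERYWHERE", f"block {block_id!r} absent from every genome", i
            )
            continue
        seen_ids.add(block_id)
        blocks.append(
            PangenomeBlock(
                block_id=block_id,
                panchromosome=chrom,
                start=start,
                stop=stop,
                function_note="" if function == "." else function,
                similar_positions=similar,
            )
        )
        counts[block_id] = row
    if not report.ok:
        return None
    try:
        return PavMatrix(genomes, blocks, counts)
    except PavModelError as exc:
        report.error("PAV_MODEL", str(exc))
        return None


def read_pav(stream: str | TextIO) -> PavMatrix:
    """Parse a PAV TSV file into a :class:`PavMatrix`.

    Raises :class:`PavFormatError` (with the full issue list) on any ERROR.
    """
    report = ValidationReport()
    matrix = _read_pav_collect(_as_text(stream), report)
    if matrix is None:
        raise PavFormatError(report)
    return matrix


def write_pav(matrix: PavMatrix, stream: TextIO | None = None) -> str:
    """Serialize to canonical PAV TSV (blocks sorted by panchromosome, start).

    Returns the text; also writes it to ``stream`` when given.
    """
    out = _stdio.StringIO()
    out.write("\t".join(PAV_FIXED_COLUMNS + tuple(matrix.genomes)) + "\n")
    for b in matrix.iter_blocks():
        row = matrix.counts.loc[b.block_id]
        fields = [
            b.panchromosome,
            str(b.start),
            str(b.stop),
            b.block_id,
            _format_similar(b.similar_positions),
            b.function_note if b.function_note else ".",
        ] + [str(int(row[g])) for g in matrix.genomes]
        out.write("\t".join(fields) + "\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# GFF3 annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationFeature:
    """One GFF3 feature in pan-coordinates (0-based half-open)."""

    feature_id: str
    panchromosome: str
    start: int
    stop: int
    strand: str
    feature_type: str
    parent_id: str = ""
    attributes: tuple[tuple[str, str], ...] = ()

    @property
    def attribute_map(self) -> dict[str, str]:
        return dict(self.attributes)


@dataclass(frozen=True)
class AnnotationCard:
    """A gene with its mRNA/exon children and function text, for one track mark."""

    gene_id: str
    panchromosome: str
    start: int
    stop: int
    children: tuple[AnnotationFeature, ...] = ()
    function_text: str = ""

    @property
    def span(self) -> tuple[str, int, int]:
        return (self.panchromosome, self.start, self.stop)


def _parse_gff3_attributes(col: str) -> tuple[tuple[str, str], ...]:
    out = []
    for part in col.split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition("=")
        out.append((key, value))
    return tuple(out)


def _read_gff3_collect(
    text: str, matrix: PavMatrix | None, report: ValidationReport
) -> list[AnnotationFeature]:
    lines = _lines(text)
    if not any(l.startswith("##gff-version") for l in lines[:5]):
        report.warning("GFF_NO_VERSION", "missing ##gff-version pragma")
    known_chroms = set(matrix.blocks) if matrix is not None else None
    features: list[AnnotationFeature] = []
    for i, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 9:
            report.error("GFF_BAD_COLUMNS", f"expected 9 tab-separated columns, got {len(cols)}", i)
            continue
        seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            report.error("GFF_BAD_COORD", f"non-integer coordinates {start_s!r}/{end_s!r}", i)
            continue
        if end1 < start1:
            report.error("GFF_BAD_INTERVAL", f"end ({end1}) < start ({start1})", i)
            continue
        if strand not in ("+", "-", "."):
            report.error("GFF_BAD_STRAND", f"strand must be +, - or ., got {strand!r}", i)
            continue
        if known_chroms is not None and seqid not in known_chroms:
            report.warning(
                "GFF_UNKNOWN_CHROM",
                f"feature on panchromosome {seqid!r} absent from the matrix; dropped",
                i,
            )
            continue
        attrs = _parse_gff3_attributes(attr_s)
        amap = dict(attrs)
        fid = amap.get("ID", f"{ftype}@{seqid}:{start1}-{end1}@L{i}")
        features.append(
            AnnotationFeature(
                feature_id=fid,
                panchromosome=seqid,
                start=start1 - 1,  # GFF3 1-based inclusive -> 0-based half-open
                stop=end1,
                strand=strand,
                feature_type=ftype,
                parent_id=amap.get("Parent", ""),
                attributes=attrs,
            )
        )
    return features


def build_cards(features: list[AnnotationFeature], report: ValidationReport) -> list[AnnotationCard]:
    """Group features into gene-level cards via Parent links.

    Children whose Parent is missing from the set are kept as orphan
    cards with a WARNING.  A card's span covers all of its children.
    """
    by_id = {f.feature_id: f for f in features}

    def root_of(f: AnnotationFeature) -> AnnotationFeature:
        seen = {f.feature_id}
        while f.parent_id:
            parent = by_id.get(f.parent_id)
            if parent is None:
                report.warning(
                    "GFF_MISSING_PARENT",
                    f"feature {f.feature_id!r} references missing Parent "
                    f"{f.parent_id!r}; kept as orphan card",
                )
                return f
            if parent.feature_id in seen:  # cycle guard
                return f
            seen.add(parent.feature_id)
            f = parent
        return f

    groups: dict[str, list[AnnotationFeature]] = {}
    roots: dict[str, AnnotationFeature] = {}
    for f in features:
        root = root_of(f)
        roots[root.feature_id] = root
        groups.setdefault(root.feature_id, []).append(f)

    cards = []
    for root_id, members in groups.items():
        root = roots[root_id]
        children = tuple(m for m in members if m.feature_id != root_id)
        start = min(m.start for m in members)
        stop = max(m.stop for m in members)
        amap = root.attribute_map
        function_text = amap.get("Note", amap.get("product", amap.get("Name", "")))
        cards.append(
            AnnotationCard(
                gene_id=root_id,
                panchromosome=root.panchromosome,
                start=start,
                stop=stop,
                children=children,
                function_text=function_text,
            )
        )
    cards.sort(key=lambda c: (c.panchromosome, c.start, c.gene_id))
    return cards


def read_annotations(
    stream: str | TextIO,
    matrix: PavMatrix | None = None,
    report: ValidationReport | None = None,
) -> list[AnnotationCard]:
    """Read a GFF3 file into annotation cards on pan-coordinates.

    Features on panchromosomes absent from ``matrix`` are dropped with a
    WARNING.  Pass a ``report`` to collect warnings; errors always raise.
    """
    own_report = report if report is not None else ValidationReport()
    features = _read_gff3_collect(_as_text(stream), matrix, own_report)
    if not own_report.ok:
        raise PavFormatError(own_report)
    return build_cards(features, own_report)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_tree(stream: str | TextIO) -> list[str]:
    """Leaf names of a Newick tree, in left-to-right written order."""
    text = _as_text(stream)
    report = ValidationReport()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        msg = str(exc)
        if "multiple occurrences" in msg.lower() or "duplicate" in msg.lower():
            report.error("NWK_DUP_LEAF", f"duplicate leaf names: {msg}")
        else:
            report.error("NWK_PARSE", f"Newick parse failure: {msg}")
        raise PavFormatError(report) from exc
    leaves = [
        (leaf.taxon.label if leaf.taxon is not None else "")
        for leaf in tree.leaf_node_iter()
    ]
    if any(not name for name in leaves):
        report.error("NWK_UNNAMED_LEAF", "tree contains an unnamed leaf")
    if len(set(leaves)) != len(leaves):
        dups = sorted({n for n in leaves if leaves.count(n) > 1})
        report.error("NWK_DUP_LEAF", f"duplicate leaf names: {dups}")
    if not report.ok:
        raise PavFormatError(report)
    return leaves


# ---------------------------------------------------------------------------
# validate
# ---------------------------------------------------------------------------

def validate(stream: str | TextIO, kind: str) -> ValidationReport:
    """Collect every detectable issue in a file without raising.

    ``kind`` is one of ``pav``, ``gff3``, ``newick``, ``gfa``.  The report
    is ERROR-free exactly when the corresponding reader succeeds.
    """
    text = _as_text(stream)
    report = ValidationReport()
    if kind == "pav":
        _read_pav_collect(text, report)
    elif kind == "gff3":
        _read_gff3_collect(text, None, report)
    elif kind == "newick":
        try:
            read_tree(text)
        except PavFormatError as exc:
            report.issues.extend(exc.report.issues)
    elif kind == "gfa":
        from .gfa import _parse_gfa_collect

        _parse_gfa_collect(text, report)
    else:
        raise ValueError(f"unknown kind {kind!r}; expected pav/gff3/newick/gfa")
    return report
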