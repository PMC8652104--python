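"""GFA1 variation-graph parsing and linearization into a PAV matrix.

A GFA1 graph declares sequence segments (``S`` lines, with an explicit
sequence or an ``LN:i`` length tag) and genome paths through them (``P``
lines).  Linearization flattens the graph onto one pan-axis per backbone
path: backbone segments keep their path order, and every off-backbone
segment is inserted immediately after its *anchor* — the backbone segment
that most recently precedes it in a path containing it, the earliest such
path in file order deciding.  Segments with no backbone predecessor go in
front of the first backbone segment.  The rule is one deterministic
choice among many defensible linear orders; it lives entirely in this
module so alternatives can be swapped in.

Cell values are traversal counts (a path visiting a segment twice yields
copy count 2); orientation is recorded per traversal but ignored for
presence.  Path names of the form ``genome#chrom`` group multiple paths
into one genome with one panchromosome per chrom (labelled by the
backbone path's name); plain path names are genome names on a single
panchromosome ``pan_1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TextIO

import pandas as pd

from .io import PavFormatError, ValidationReport, _as_text, _lines
from .model import PangenomeBlock, PavMatrix, PavModelError, recompute_coordinates

__all__ = ["LinearizedGraph", "parse_gfa", "linearize", "segment_coordinate_table"]


@dataclass
class LinearizedGraph:
    """Segments, paths, and (after linearization) a backbone block order."""

    segments: dict[str, int]  # segment_id -> length (bp)
    paths: dict[str, list[tuple[str, str]]]  # path_name -> [(segment_id, orientation)]
    backbone: str | None = None
    block_order: list[str] = field(default_factory=list)


def _parse_gfa_collect(text: str, report: ValidationReport) -> LinearizedGraph | None:
    segments: dict[str, int] = {}
    paths: dict[str, list[tuple[str, str]]] = {}
    for i, line in enumerate(_lines(text), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        tag = fields[0]
        if tag == "H" or tag == "L":
            continue  # links carry no ordering information here
        if tag == "S":
            if len(fields) < 3:
                report.error("GFA_BAD_S", "S line needs at least name and sequence", i)
                continue
            name, seq = fields[1], fields[2]
            if name in segments:
                report.error("GFA_DUP_SEGMENT", f"duplicate segment {name!r}", i)
                continue
            length = None
            if seq != "*":
                length = len(seq)
            for opt in fields[3:]:
                if opt.startswith("LN:i:"):
                    try:
                        length = int(opt[5:])
                    except ValueError:
                        report.error("GFA_BAD_LN", f"malformed LN tag {opt!r}", i)
            if length is None:
                report.error(
                    "GFA_NO_LENGTH", f"segment {name!r} has neither sequence nor LN tag", i
                )
                continue
            segments[name] = length
        elif tag == "P":
            if len(fields) < 3:
                report.error("GFA_BAD_P", "P line needs a name and a segment list", i)
                continue
            name, seglist = fields[1], fields[2]
            if name in paths:
                report.error("GFA_DUP_PATH", f"duplicate path {name!r}", i)
                continue
            steps: list[tuple[str, str]] = []
            ok = True
            for step in seglist.split(","):
                if len(step) < 2 or step[-1] not in "+-":
                    report.error("GFA_BAD_STEP", f"malformed path step {step!r}", i)
                    ok = False
                    break
                steps.append((step[:-1], step[-1]))
            if not ok:
                continue
            if not steps:
                report.error("GFA_EMPTY_PATH", f"path {name!r} traverses no segment", i)
                continue
            paths[name] = steps
        # other record types are tolerated and ignored
    for pname, steps in paths.items():
        for seg, _ in steps:
            if seg not in segments:
                report.error(
                    "GFA_UNDECLARED_SEGMENT",
                    f"path {pname!r} references undeclared segment {seg!r}",
                )
    if not report.ok:
        return None
    return LinearizedGraph(segments=segments, paths=paths)


def parse_gfa(stream: str | TextIO) -> LinearizedGraph:
    """Parse GFA1 text (S/P lines; L lines tolerated and ignored)."""
    report = ValidationReport()
    graph = _parse_gfa_collect(_as_text(stream), report)
    if graph is None:
        raise PavFormatError(report)
    return graph


def _split_path_name(name: str) -> tuple[str, str | None]:
    """``genome#chrom`` -> (genome, chrom); plain name -> (name, None)."""
    genome, sep, chrom = name.partition("#")
    return (genome, chrom) if sep else (name, None)


def _order_component(
    graph: LinearizedGraph, backbone_path: str, member_paths: list[str]
) -> list[str]:
    """Block order for one panchromosome: backbone order + anchor rule."""
    backbone_steps = graph.paths[backbone_path]
    backbone_order: list[str] = []
    backbone_set: set[str] = set()
    for seg, _ in backbone_steps:
        if seg not in backbone_set:
            backbone_order.append(seg)
            backbone_set.add(seg)

    # anchor[segment] = backbone segment most recently preceding it in the
    # earliest (file-order) path containing it; None = before first block.
    anchored: dict[str | None, list[str]] = {a: [] for a in [None] + backbone_order}
    placed: set[str] = set(backbone_set)
    for pname in member_paths:
        last_backbone: str | None = None
        for seg, _ in graph.paths[pname]:
            if seg in backbone_set:
                last_backbone = seg
            elif seg not in placed:
                anchored[last_backbone].append(seg)
                placed.add(seg)

    order: list[str] = list(anchored[None])
    for bseg in backbone_order:
        order.append(bseg)
        order.extend(anchored[bseg])
    return order


def linearize(graph: LinearizedGraph, backbone: str) -> PavMatrix:
    """Flatten the graph onto pan-coordinates using ``backbone`` as reference.

    ``backbone`` may be a path name or, with ``genome#chrom`` path naming,
    a genome name whose per-chromosome paths each become the backbone of
    one panchromosome.
    """
    if not graph.paths:
        raise PavModelError("graph has no paths")
    path_names = list(graph.paths)  # file order
    named = {n: _split_path_name(n) for n in path_names}
    uses_chrom = any(chrom is not None for _, chrom in named.values())

    if backbone in graph.paths:
        backbone_genome = named[backbone][0]
    elif uses_chrom and backbone in {gname for gname, _ in named.values()}:
        backbone_genome = backbone
    else:
        raise PavModelError(f"unknown backbone path or genome {backbone!r}")

    genomes: list[str] = []
    for n in path_names:
        gname = named[n][0]
        if gname not in genomes:
            genomes.append(gname)

    # group paths into components: one per backbone-genome chromosome,
    # or a single component when no '#' naming is used
    if uses_chrom:
        backbone_paths = [n for n in path_names if named[n][0] == backbone_genome]
        if not backbone_paths:
            raise PavModelError(f"backbone genome {backbone_genome!r} has no paths")
        backbone_chroms = {named[n][1] for n in backbone_paths}
        orphans = sorted(
            {named[n][1] for n in path_names if named[n][1] not in backbone_chroms},
            key=str,
        )
        if orphans:
            raise PavModelError(
                f"chromosomes {orphans} have no path in backbone genome "
                f"{backbone_genome!r}"
            )
        components = []
        for bpath in backbone_paths:
            chrom = named[bpath][1]
            members = [n for n in path_names if named[n][1] == chrom]
            components.append((bpath, bpath, members))  # label = backbone path name
    else:
        bpath = backbone
        components = [("pan_1", bpath, path_names)]

    blocks: list[PangenomeBlock] = []
    counts: dict[str, dict[str, int]] = {}
    assigned: set[str] = set()
    for label, bpath, members in components:
        order = [s for s in _order_component(graph, bpath, members) if s not in assigned]
        assigned.update(order)
        coords = recompute_coordinates([graph.segments[s] for s in order])
        for seg, (start, stop) in zip(order, coords):
            blocks.append(
                PangenomeBlock(block_id=seg, panchromosome=label, start=start, stop=stop)
            )
            counts[seg] = {gname: 0 for gname in genomes}
    for pname in path_names:
        gname = named[pname][0]
        for seg, _ in graph.paths[pname]:
            counts[seg][gname] += 1

    graph.backbone = backbone
    graph.block_order = [b.block_id for b in blocks]
    return PavMatrix(genomes, blocks, counts)


def segment_coordinate_table(matrix: PavMatrix) -> pd.DataFrame:
    """Sidecar table mapping segment_id -> (panchromosome, pan-start)."""
    rows = [
        {"segment_id": b.block_id, "panchromosome": b.panchromosome, "pan_start": b.start}
        for b in matrix.iter_blocks()
    ]
    return pd.DataFrame(rows, columns=["segment_id", "panchromosome", "pan_start"])
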