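"""Seeded synthetic pangenome fixtures with planted, recoverable structure.

Every generator is fully deterministic given its seed, and each artifact
kind derives its own independent random stream from ``(seed, kind)``, so
adding a generator never perturbs another's output.

The PAV generator emulates a gene- or block-level eukaryotic pangenome:
a fraction of blocks forced present in every genome (the core), a 0.9
background presence probability elsewhere (so random runs of joint
absence longer than a few blocks are vanishingly rare, keeping
planted-structure recovery sharp), plus explicitly planted hollow areas
(a genome subset absent over a consecutive block run, with presence
forced on the flanks and for all other genomes inside the run, so the
planted interval and genome set are exactly the maximal ones) and
planted repeat groups (blocks cross-listing one another as similar
positions).  It does not model phylogenetically correlated gain/loss or
nucleotide content.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import PangenomeBlock, PavMatrix, PavModelError, recompute_coordinates

__all__ = ["FixtureSpec", "generate_matrix", "generate_gfa", "generate_gff3", "generate_newick"]

BACKGROUND_PRESENCE = 0.9


def _stream(seed: int, kind: str) -> np.random.Generator:
    """Independent deterministic stream per (seed, artifact kind)."""
    mix = zlib.crc32(kind.encode()) & 0x7FFFFFFF
    return np.random.default_rng([seed & 0x7FFFFFFF, mix])


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic PAV matrix."""

    n_genomes: int = 5
    n_blocks: int = 100
    n_panchromosomes: int = 1
    core_fraction: float = 0.3
    planted_hollows: tuple[tuple[str, int, int, tuple[str, ...]], ...] = ()
    # each: (panchromosome, first_block_index, n_blocks, genome names absent)
    planted_repeats: tuple[tuple[str, ...], ...] = ()  # groups of block_ids
    block_length_range: tuple[int, int] = (1000, 10000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise PavModelError("n_genomes must be >= 2")
        if self.n_blocks < 1 or self.n_panchromosomes < 1:
            raise PavModelError("n_blocks and n_panchromosomes must be >= 1")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise PavModelError("core_fraction must be in [0, 1]")
        if self.block_length_range[0] < 1 or self.block_length_range[1] < self.block_length_range[0]:
            raise PavModelError("invalid block_length_range")

    @property
    def genome_names(self) -> list[str]:
        return [f"g{i + 1}" for i in range(self.n_genomes)]

    def panchromosome_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_panchromosomes)]

    def blocks_per_panchromosome(self) -> dict[str, int]:
        base, rem = divmod(self.n_blocks, self.n_panchromosomes)
        names = self.panchromosome_names()
        return {c: base + (1 if i < rem else 0) for i, c in enumerate(names)}


def _block_id(chrom: str, idx: int) -> str:
    return f"{chrom}_b{idx:04d}"


def generate_matrix(spec: FixtureSpec) -> PavMatrix:
    """Deterministic PAV matrix with the planted structure of ``spec``.

    Guarantees: core-forced blocks present in all genomes; inside each
    planted hollow exactly the listed genomes are absent on exactly the
    listed blocks (other genomes forced present there, listed genomes
    forced present on the flanking blocks); any all-absent column is
    repaired by forcing one presence drawn from the seeded stream.
    """
    rng = _stream(spec.seed, "pav")
    genomes = spec.genome_names
    g_index = {gname: i for i, gname in enumerate(genomes)}
    per_chrom = spec.blocks_per_panchromosome()

    # validate planted hollows against bounds and each other
    hollow_cells: dict[tuple[str, int], set[str]] = {}
    for chrom, first, n, subset in spec.planted_hollows:
        if chrom not in per_chrom:
            raise PavModelError(f"planted hollow on unknown panchromosome {chrom!r}")
        if not subset or any(s not in g_index for s in subset):
            raise PavModelError(f"planted hollow genome subset {subset!r} invalid")
        if len(set(subset)) == spec.n_genomes:
            raise PavModelError("planted hollow cannot cover every genome of a block")
        if first < 0 or n < 1 or first + n > per_chrom[chrom]:
            raise PavModelError(
                f"planted hollow ({chrom}, {first}, {n}) outside bounds"
            )
        for k in range(first, first + n):
            cell = hollow_cells.setdefault((chrom, k), set())
            cell.update(subset)
            if len(cell) == spec.n_genomes:
                raise PavModelError("overlapping hollows cover every genome of a block")

    blocks: list[PangenomeBlock] = []
    presence_rows: dict[str, np.ndarray] = {}
    order: list[tuple[str, int, str]] = []  # (chrom, local index, block_id)
    for chrom in spec.panchromosome_names():
        n_b = per_chrom[chrom]
        lengths = rng.integers(
            spec.block_length_range[0], spec.block_length_range[1] + 1, size=n_b
        )
        coords = recompute_coordinates([int(x) for x in lengths])
        for k, (start, stop) in enumerate(coords):
            order.append((chrom, k, _block_id(chrom, k)))
            blocks.append(
                PangenomeBlock(
                    block_id=_block_id(chrom, k),
                    panchromosome=chrom,
                    start=start,
                    stop=stop,
                )
            )

    # choose core-forced blocks among blocks untouched by hollows
    n_core = int(round(spec.core_fraction * spec.n_blocks))
    eligible = [i for i, (c, k, _) in enumerate(order) if (c, k) not in hollow_cells]
    if n_core > len(eligible):
        raise PavModelError(
            f"core_fraction requires {n_core} hollow-free blocks, "
            f"only {len(eligible)} available"
        )
    core_idx = set(
        int(i) for i in rng.choice(eligible, size=n_core, replace=False)
    ) if n_core else set()

    flank_force: dict[tuple[str, int], set[str]] = {}
    for chrom, first, n, subset in spec.planted_hollows:
        for k in (first - 1, first + n):
            if 0 <= k < per_chrom[chrom]:
                flank_force.setdefault((chrom, k), set()).update(subset)

    for i, (chrom, k, bid) in enumerate(order):
        row = (rng.random(spec.n_genomes) < BACKGROUND_PRESENCE).astype(np.int64)
        if i in core_idx:
            row[:] = 1
        absent_here = hollow_cells.get((chrom, k))
        if absent_here:
            row[:] = 1  # non-listed genomes forced present inside the hollow
            for gname in absent_here:
                row[g_index[gname]] = 0
        for gname in flank_force.get((chrom, k), ()):
            if not (absent_here and gname in absent_here):
                row[g_index[gname]] = 1
        if row.max() < 1:  # repair all-absent column
            row[int(rng.integers(spec.n_genomes))] = 1
        presence_rows[bid] = row

    # planted repeat groups: members cross-list each other's positions
    if spec.planted_repeats:
        pos = {b.block_id: (b.panchromosome, b.start) for b in blocks}
        by_id = {b.block_id: b for b in blocks}
        for group in spec.planted_repeats:
            unknown = [bid for bid in group if bid not in by_id]
            if unknown:
                raise PavModelError(f"planted repeat group names unknown blocks {unknown}")
            for bid in group:
                partners = tuple(pos[other] for other in group if other != bid)
                b = by_id[bid]
                by_id[bid] = PangenomeBlock(
                    block_id=b.block_id,
                    panchromosome=b.panchromosome,
                    start=b.start,
                    stop=b.stop,
                    function_note=b.function_note,
                    similar_positions=partners,
                )
        blocks = [by_id[b.block_id] for b in blocks]

    counts = pd.DataFrame(
        np.vstack([presence_rows[bid] for _, _, bid in order]),
        index=[bid for _, _, bid in order],
        columns=genomes,
    )
    return PavMatrix(genomes, blocks, counts)


def generate_gfa(n_segments: int, n_paths: int, seed: int = 0) -> str:
    """GFA1 text: a backbone path over all segments plus derived paths
    that drop or duplicate segments at seeded random.

    Path ``g1`` is the backbone and traverses every segment in order, so
    after linearization its column is everywhere >= 1.
    """
    if n_segments < 2:
        raise PavModelError("n_segments must be >= 2")
    if n_paths < 1:
        raise PavModelError("n_paths must be >= 1")
    rng = _stream(seed, "gfa")
    lengths = rng.integers(100, 5000, size=n_segments)
    seg_ids = [f"s{i + 1}" for i in range(n_segments)]
    lines = ["H\tVN:Z:1.0"]
    for sid, length in zip(seg_ids, lengths):
        lines.append(f"S\t{sid}\t*\tLN:i:{int(length)}")
    path_steps: list[list[str]] = [[f"{sid}+" for sid in seg_ids]]
    for _ in range(1, n_paths):
        steps: list[str] = []
        for sid in seg_ids:
            r = rng.random()
            if r < 0.15:
                continue  # dropped
            steps.append(f"{sid}+")
            if r > 0.95:
                steps.append(f"{sid}+")  # duplicated traversal
        if not steps:  # a path must traverse something
            steps = [f"{seg_ids[int(rng.integers(n_segments))]}+"]
        path_steps.append(steps)
    for i, steps in enumerate(path_steps):
        lines.append(f"P\tg{i + 1}\t{','.join(steps)}\t*")
    return "\n".join(lines) + "\n"


def generate_gff3(
    matrix: PavMatrix, n_genes: int, seed: int = 0, exons_per_gene: int = 2
) -> str:
    """GFF3 annotations (gene -> mRNA -> exons) on the matrix's pan-axis.

    Gene spans are drawn inside random blocks so every gene overlaps at
    least one block.  Coordinates written 1-based inclusive per GFF3.
    """
    rng = _stream(seed, "gff3")
    all_blocks = list(matrix.iter_blocks())
    lines = ["##gff-version 3"]
    for i in range(n_genes):
        b = all_blocks[int(rng.integers(len(all_blocks)))]
        lo = int(b.start + rng.integers(max(1, b.width // 4)))
        hi = int(min(b.stop, lo + 1 + rng.integers(max(2, b.width // 2))))
        gid = f"gene{i + 1:03d}"
        lines.append(
            f"{b.panchromosome}\tsynth\tgene\t{lo + 1}\t{hi}\t.\t+\t.\t"
            f"ID={gid};Note=synthetic function {i + 1}"
        )
        mid = f"{gid}.m1"
        lines.append(
            f"{b.panchromosome}\tsynth\tmRNA\t{lo + 1}\t{hi}\t.\t+\t.\t"
            f"ID={mid};Parent={gid}"
        )
        edges = sorted(
            {lo, hi} | {int(lo + rng.integers(1, max(2, hi - lo)))
                        for _ in range(max(0, exons_per_gene - 1))}
        )
        for e, (a, z) in enumerate(zip(edges, edges[1:])):
            lines.append(
                f"{b.panchromosome}\tsynth\texon\t{a + 1}\t{z}\t.\t+\t.\t"
                f"ID={mid}.e{e + 1};Parent={mid}"
            )
    return "\n".join(lines) + "\n"


def generate_newick(genomes: Sequence[str], seed: int = 0) -> str:
    """Random bifurcating Newick tree over the genome names."""
    rng = _stream(seed, "newick")
    nodes = [str(gname) for gname in genomes]
    nodes = [nodes[int(i)] for i in rng.permutation(len(nodes))]
    while len(nodes) > 1:
        a = nodes.pop(int(rng.integers(len(nodes))))
        b = nodes.pop(int(rng.integers(len(nodes))))
        nodes.append(f"({a},{b})")
    return nodes[0] + ";\n"
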