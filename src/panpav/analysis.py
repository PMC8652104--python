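"""Exploration algorithms over a PAV matrix.

Hollow areas
------------
A *hollow area* is a maximal run of consecutive blocks on one
panchromosome that are jointly absent from the same set of at least ``g``
genomes.  Jointly means intersection: the reported genome set is exactly
the genomes absent in *every* block of the run, and extending the run by
one block on either side would shrink that intersection below ``g``.
Because the intersection can only shrink as a run grows, overlapping
maximal runs with different absent sets can coexist and are all reported.

The finder uses a sliding window: for each left end the right end can
only move forward, and per-genome absence counts over the window give the
intersection size in O(genomes) per step, so the scan is linear in the
number of blocks — fast enough for hundreds of genomes times tens of
thousands of blocks.

Genome sorting
--------------
Three deterministic row orders for the matrix display: by phylogenetic
leaf order, by Hamming distance to a pivot genome's presence pattern over
a block range, and by how many genes of a list each genome fully carries.
All ties break by matrix order, so every ordering is reproducible without
seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .io import AnnotationCard
from .model import PavMatrix, PavModelError

__all__ = [
    "HollowArea",
    "SortMode",
    "GenomeOrdering",
    "find_hollow_areas",
    "hollow_areas_to_bed",
    "sort_genomes_by_tree",
    "sort_genomes_by_region",
    "sort_genomes_by_gene_list",
]


@dataclass(frozen=True)
class HollowArea:
    """Maximal run of consecutive blocks jointly absent from >= g genomes."""

    panchromosome: str
    first_block_index: int  # 0-based, inclusive, within the panchromosome
    last_block_index: int   # inclusive
    absent_genomes: frozenset[str]
    n_blocks: int
    span_bp: int


class SortMode(str, Enum):
    TREE = "TREE"
    REGION_PATTERN = "REGION_PATTERN"
    GENE_LIST = "GENE_LIST"


@dataclass(frozen=True)
class GenomeOrdering:
    order: tuple[str, ...]
    mode: SortMode
    keys: tuple[float, ...]  # per-genome sort key, aligned with order

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise PavModelError("ordering is not a permutation")


def find_hollow_areas(
    matrix: PavMatrix, min_blocks: int = 1, min_genomes: int = 1
) -> list[HollowArea]:
    """All maximal hollow areas with >= ``min_blocks`` blocks and an
    absent-genome intersection of >= ``min_genomes`` genomes.

    Results are sorted by (panchromosome, first_block_index).
    """
    if min_blocks < 1:
        raise PavModelError(f"min_blocks must be >= 1, got {min_blocks}")
    if not 1 <= min_genomes <= matrix.n_genomes:
        raise PavModelError(
            f"min_genomes must be in [1, {matrix.n_genomes}], got {min_genomes}"
        )
    g, L = min_genomes, min_blocks
    genome_names = np.array(matrix.genomes)
    results: list[HollowArea] = []
    for chrom in matrix.panchromosomes:
        blist = matrix.blocks[chrom]
        n = len(blist)
        ids = [b.block_id for b in blist]
        absent = ~(matrix.counts.loc[ids].to_numpy() >= 1)  # n_blocks x n_genomes
        widths = np.array([b.width for b in blist], dtype=np.int64)
        cum_w = np.concatenate([[0], np.cumsum(widths)])

        counts = np.zeros(matrix.n_genomes, dtype=np.int64)
        j = -1  # window is [i, j]; empty when j < i
        prev_jmax = -1  # jmax of i-1, or -1 when undefined
        for i in range(n):
            if j < i - 1:
                j = i - 1
                counts[:] = 0
            # grow right while the intersection stays >= g
            while j + 1 < n:
                cand = counts + absent[j + 1]
                if int((cand == (j + 2 - i)).sum()) >= g:
                    counts = cand
                    j += 1
                else:
                    break
            width = j - i + 1
            if j >= i and int((counts == width).sum()) >= g:
                jmax = j
                left_maximal = i == 0 or prev_jmax < jmax
                if left_maximal and width >= L:
                    inter = frozenset(str(g) for g in genome_names[counts == width])
                    results.append(
                        HollowArea(
                            panchromosome=chrom,
                            first_block_index=i,
                            last_block_index=j,
                            absent_genomes=inter,
                            n_blocks=width,
                            span_bp=int(cum_w[j + 1] - cum_w[i]),
                        )
                    )
                prev_jmax = jmax
            else:
                prev_jmax = -1
            # slide the left end out of the window
            if j >= i:
                counts = counts - absent[i]
    results.sort(key=lambda h: (h.panchromosome, h.first_block_index))
    return results


def hollow_areas_to_bed(matrix: PavMatrix, areas: Sequence[HollowArea]) -> str:
    """BED serialization: pan-start of first block, pan-stop of last,
    name = comma-joined absent genomes (in matrix genome order)."""
    rank = {gname: k for k, gname in enumerate(matrix.genomes)}
    lines = []
    for h in areas:
        blist = matrix.blocks[h.panchromosome]
        start = blist[h.first_block_index].start
        stop = blist[h.last_block_index].stop
        name = ",".join(sorted(h.absent_genomes, key=rank.__getitem__))
        lines.append(f"{h.panchromosome}\t{start}\t{stop}\t{name}")
    return "\n".join(lines) + ("\n" if lines else "")


def sort_genomes_by_tree(matrix: PavMatrix, leaf_order: Sequence[str]) -> GenomeOrdering:
    """Genomes in phylogenetic leaf order; leaves not in the matrix are
    ignored, matrix genomes missing from the tree are appended in matrix
    order after the tree-ordered ones."""
    in_matrix = set(matrix.genomes)
    ordered = [name for name in leaf_order if name in in_matrix]
    seen = set(ordered)
    ordered += [gname for gname in matrix.genomes if gname not in seen]
    keys = tuple(float(k) for k in range(len(ordered)))
    return GenomeOrdering(tuple(ordered), SortMode.TREE, keys)


def sort_genomes_by_region(
    matrix: PavMatrix,
    panchromosome: str,
    block_range: tuple[int, int],
    pivot: str,
) -> GenomeOrdering:
    """Genomes by ascending Hamming distance of their binarized presence
    vector over ``block_range`` (inclusive indices) to the pivot's vector.

    The pivot comes first with distance 0; ties break by matrix order.
    """
    if pivot not in matrix.genomes:
        raise PavModelError(f"unknown pivot genome {pivot!r}")
    if panchromosome not in matrix.blocks:
        raise PavModelError(f"unknown panchromosome {panchromosome!r}")
    blist = matrix.blocks[panchromosome]
    first, last = block_range
    if not (0 <= first <= last < len(blist)):
        raise PavModelError(
            f"block range {block_range} outside [0, {len(blist) - 1}] or empty"
        )
    ids = [b.block_id for b in blist[first : last + 1]]
    pres = matrix.counts.loc[ids].to_numpy() >= 1  # range-blocks x genomes
    pivot_col = matrix.genomes.index(pivot)
    dist = (pres != pres[:, [pivot_col]]).sum(axis=0)
    order_idx = sorted(range(matrix.n_genomes), key=lambda k: (int(dist[k]), k))
    return GenomeOrdering(
        tuple(matrix.genomes[k] for k in order_idx),
        SortMode.REGION_PATTERN,
        tuple(float(dist[k]) for k in order_idx),
    )


def sort_genomes_by_gene_list(
    matrix: PavMatrix,
    cards: Sequence[AnnotationCard],
    gene_ids: Sequence[str],
) -> GenomeOrdering:
    """Genomes by descending count of listed genes they fully carry.

    A genome "carries" a gene when every block overlapping the gene's card
    span is present (count >= 1).  Each gene must resolve to a card whose
    span overlaps at least one block.  Ties break by matrix order.
    """
    by_id = {c.gene_id: c for c in cards}
    keys = np.zeros(matrix.n_genomes, dtype=np.int64)
    for gid in gene_ids:
        card = by_id.get(gid)
        if card is None:
            raise PavModelError(f"gene {gid!r} not found in the annotation cards")
        blist = matrix.blocks.get(card.panchromosome, [])
        sel = [
            b.block_id
            for b in blist
            if b.start < card.stop and card.start < b.stop  # half-open overlap
        ]
        if not sel:
            raise PavModelError(
                f"gene {gid!r} overlaps no block on panchromosome "
                f"{card.panchromosome!r}"
            )
        pres = matrix.counts.loc[sel].to_numpy() >= 1
        keys += pres.all(axis=0)
    order_idx = sorted(range(matrix.n_genomes), key=lambda k: (-int(keys[k]), k))
    return GenomeOrdering(
        tuple(matrix.genomes[k] for k in order_idx),
        SortMode.GENE_LIST,
        tuple(float(keys[k]) for k in order_idx),
    )
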