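"""Linearized-pangenome data model.

A pangenome is flattened onto one linear axis per *panchromosome*: an
ordered succession of :class:`PangenomeBlock` units (genes or sequence
segments), each carrying 0-based half-open pan-coordinates.  A
:class:`PavMatrix` couples that block ordering with a genomes × blocks
table of non-negative copy counts (0 = absent).  Copy counts rather than
booleans are stored because a genome's path through a variation graph may
traverse the same segment several times; presence everywhere in this
package means ``count >= 1``.

Blocks present in at least ``threshold`` of the genomes belong to the
*core* genome; the rest form the *variable* (dispensable) genome.  The
default threshold is 0.95, the common soft-core convention; it is
user-overridable everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CORE_THRESHOLD",
    "PangenomeBlock",
    "PavMatrix",
    "Status",
    "CoreVariableCall",
    "classify_block",
    "classify_matrix",
    "recompute_coordinates",
    "repetition_profile",
]

DEFAULT_CORE_THRESHOLD = 0.95


class PavModelError(ValueError):
    """Raised when a model invariant is violated."""


@dataclass(frozen=True)
class PangenomeBlock:
    """One unit of the linear pan-reference.

    Coordinates are 0-based, half-open (BED convention).
    ``similar_positions`` lists ``(panchromosome, start)`` locations of
    repeated occurrences of this block elsewhere in the pangenome.
    """

    block_id: str
    panchromosome: str
    start: int
    stop: int
    function_note: str = ""
    similar_positions: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.block_id:
            raise PavModelError("block_id must be non-empty")
        if self.stop <= self.start:
            raise PavModelError(
                f"block {self.block_id!r}: stop ({self.stop}) must exceed "
                f"start ({self.start})"
            )
        object.__setattr__(
            self, "similar_positions", tuple((str(c), int(s)) for c, s in self.similar_positions)
        )

    @property
    def width(self) -> int:
        return self.stop - self.start


class PavMatrix:
    """Presence/absence matrix over ordered pangenomic blocks.

    Parameters
    ----------
    genomes
        Ordered, unique, non-empty genome names.
    blocks
        All blocks, any order; grouped per panchromosome and sorted by
        start internally.  Within a panchromosome blocks must not overlap.
    counts
        Either a mapping ``{block_id: {genome: count}}`` or a
        :class:`pandas.DataFrame` indexed by block_id with one column per
        genome.  Every cell must be a non-negative integer and every block
        must be present (count >= 1) in at least one genome.
    """

    def __init__(
        self,
        genomes: Sequence[str],
        blocks: Iterable[PangenomeBlock],
        counts: pd.DataFrame | dict,
    ) -> None:
        genomes = list(genomes)
        if len(genomes) == 0:
            raise PavModelError("at least one genome required")
        if any(not g for g in genomes):
            raise PavModelError("genome names must be non-empty")
        if len(set(genomes)) != len(genomes):
            raise PavModelError("genome names must be unique")
        self.genomes: list[str] = genomes

        by_chrom: dict[str, list[PangenomeBlock]] = {}
        seen_ids: set[str] = set()
        for b in blocks:
            if b.block_id in seen_ids:
                raise PavModelError(f"duplicate block_id {b.block_id!r}")
            seen_ids.add(b.block_id)
            by_chrom.setdefault(b.panchromosome, []).append(b)
        for chrom, blist in by_chrom.items():
            blist.sort(key=lambda b: (b.start, b.stop))
            for prev, cur in zip(blist, blist[1:]):
                if cur.start < prev.stop:
                    raise PavModelError(
                        f"blocks {prev.block_id!r} and {cur.block_id!r} overlap "
                        f"on panchromosome {chrom!r}"
                    )
        self.blocks: dict[str, list[PangenomeBlock]] = by_chrom

        order = [b.block_id for b in self.iter_blocks()]
        if isinstance(counts, dict):
            counts = pd.DataFrame.from_dict(counts, orient="index")
        missing = set(order) - set(counts.index)
        if missing:
            raise PavModelError(f"counts missing for blocks: {sorted(missing)[:5]}")
        extra = set(counts.index) - set(order)
        if extra:
            raise PavModelError(f"counts given for unknown blocks: {sorted(extra)[:5]}")
        missing_g = set(genomes) - set(counts.columns)
        if missing_g:
            raise PavModelError(f"counts missing for genomes: {sorted(missing_g)}")
        counts = counts.loc[order, genomes]
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == arr.astype(np.int64)):
                raise PavModelError("copy counts must be integers")
            arr = arr.astype(np.int64)
        if (arr < 0).any():
            raise PavModelError("copy counts must be non-negative")
        if (arr.max(axis=1) < 1).any():
            bad = [order[i] for i in np.flatnonzero(arr.max(axis=1) < 1)]
            raise PavModelError(f"blocks absent from every genome: {bad[:5]}")
        self.counts: pd.DataFrame = pd.DataFrame(arr, index=order, columns=genomes)

    # -- views -------------------------------------------------------------

    def iter_blocks(self, panchromosome: str | None = None):
        """Yield blocks in (panchromosome, start) order."""
        if panchromosome is not None:
            if panchromosome not in self.blocks:
                raise PavModelError(f"unknown panchromosome {panchromosome!r}")
            yield from self.blocks[panchromosome]
            return
        for chrom in sorted(self.blocks):
            yield from self.blocks[chrom]

    @property
    def panchromosomes(self) -> list[str]:
        return sorted(self.blocks)

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    @property
    def n_blocks(self) -> int:
        return sum(len(v) for v in self.blocks.values())

    def presence(self) -> pd.DataFrame:
        """Boolean presence table (count >= 1), blocks × genomes."""
        return self.counts >= 1

    def presence_counts(self) -> pd.Series:
        """Per block, the number of genomes carrying it."""
        return self.presence().sum(axis=1)

    def block(self, block_id: str) -> PangenomeBlock:
        for b in self.iter_blocks():
            if b.block_id == block_id:
                return b
        raise PavModelError(f"unknown block {block_id!r}")

    def extent(self, panchromosome: str) -> tuple[int, int]:
        """(min start, max stop) over the blocks of one panchromosome."""
        blist = self.blocks.get(panchromosome)
        if not blist:
            raise PavModelError(f"unknown panchromosome {panchromosome!r}")
        return blist[0].start, max(b.stop for b in blist)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PavMatrix):
            return NotImplemented
        return (
            self.genomes == other.genomes
            and self.blocks == other.blocks
            and self.counts.equals(other.counts)
        )

    def __repr__(self) -> str:
        return (
            f"<PavMatrix {self.n_genomes} genomes x {self.n_blocks} blocks "
            f"on {len(self.blocks)} panchromosome(s)>"
        )


class Status(str, Enum):
    CORE = "CORE"
    VARIABLE = "VARIABLE"


@dataclass(frozen=True)
class CoreVariableCall:
    block_id: str
    presence_count: int
    presence_fraction: float
    status: Status


def classify_block(
    presence_count: int, n_genomes: int, threshold: float = DEFAULT_CORE_THRESHOLD,
    block_id: str = "",
) -> CoreVariableCall:
    """Classify one block as CORE or VARIABLE.

    A block is CORE when ``presence_count / n_genomes >= threshold``
    (boundary inclusive, so threshold 1.0 means strictly "present in all").
    ``presence_count`` of 0 is invalid: a block absent everywhere has no
    place on the pan-reference.
    """
    if n_genomes < 1:
        raise PavModelError("n_genomes must be >= 1")
    if presence_count == 0:
        raise PavModelError("block absent from every genome is invalid")
    if not 1 <= presence_count <= n_genomes:
        raise PavModelError(
            f"presence_count {presence_count} outside [1, {n_genomes}]"
        )
    if not 0.0 < threshold <= 1.0:
        raise PavModelError(f"threshold {threshold} outside (0, 1]")
    frac = presence_count / n_genomes
    status = Status.CORE if frac >= threshold else Status.VARIABLE
    return CoreVariableCall(block_id, presence_count, frac, status)


def classify_matrix(
    matrix: PavMatrix, threshold: float = DEFAULT_CORE_THRESHOLD
) -> list[CoreVariableCall]:
    """One :class:`CoreVariableCall` per block, in block order."""
    pc = matrix.presence_counts()
    n = matrix.n_genomes
    return [
        classify_block(int(pc[b.block_id]), n, threshold, block_id=b.block_id)
        for b in matrix.iter_blocks()
    ]


def recompute_coordinates(block_lengths: Sequence[int]) -> list[tuple[int, int]]:
    """Canonical contiguous tiling of the pan-axis from block lengths.

    Starts are cumulative sums beginning at 0; blocks tile the axis with
    no gaps, so the final stop equals the total length.
    """
    coords: list[tuple[int, int]] = []
    pos = 0
    for length in block_lengths:
        if length < 1:
            raise PavModelError(f"block length must be positive, got {length}")
        coords.append((pos, pos + length))
        pos += length
    return coords


def repetition_profile(matrix: PavMatrix) -> pd.Series:
    """Per-block repeat counts (number of similar positions), block order."""
    return pd.Series(
        {b.block_id: len(b.similar_positions) for b in matrix.iter_blocks()},
        dtype=int,
    ).loc[[b.block_id for b in matrix.iter_blocks()]]
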