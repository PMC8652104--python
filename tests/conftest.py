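"""Shared fixtures and independent oracles.

The hollow-area oracle enumerates every interval exhaustively; the
classification oracle recounts presence cell by cell.  Both stay
independent of the library code paths they are used to check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from panpav import PangenomeBlock, PavMatrix


def matrix_from_absent_sets(genomes, absent_sets, chrom="chr1", width=10):
    """Build a PavMatrix from per-block absent-genome sets (presence = 1)."""
    blocks = [
        PangenomeBlock(f"b{i + 1}", chrom, i * width, (i + 1) * width)
        for i in range(len(absent_sets))
    ]
    counts = {
        f"b{i + 1}": {g: (0 if g in a else 1) for g in genomes}
        for i, a in enumerate(absent_sets)
    }
    return PavMatrix(genomes, blocks, counts)


def random_small_matrix(rng: np.random.Generator, max_genomes=8, max_blocks=40):
    """Random dense PAV matrix for oracle-equivalence testing."""
    n_g = int(rng.integers(2, max_genomes + 1))
    n_b = int(rng.integers(1, max_blocks + 1))
    genomes = [f"g{i + 1}" for i in range(n_g)]
    # high absence rate so hollow areas actually occur
    present = rng.random((n_b, n_g)) < 0.6
    for i in range(n_b):  # every block must be present somewhere
        if not present[i].any():
            present[i, int(rng.integers(n_g))] = True
    absent_sets = [
        {genomes[j] for j in range(n_g) if not present[i, j]} for i in range(n_b)
    ]
    return matrix_from_absent_sets(genomes, absent_sets)


def brute_force_hollow_areas(matrix: PavMatrix, min_blocks: int, min_genomes: int):
    """Exhaustive O(n^2) enumeration of maximal shared-absence intervals.

    Returns {(panchromosome, first, last, frozenset(absent))}.
    """
    out = set()
    for chrom in matrix.panchromosomes:
        blist = matrix.blocks[chrom]
        n = len(blist)
        absent = []
        for b in blist:
            row = matrix.counts.loc[b.block_id]
            absent.append(frozenset(g for g in matrix.genomes if row[g] == 0))

        def inter(i, j):
            s = absent[i]
            for k in range(i + 1, j + 1):
                s = s & absent[k]
            return s

        for i, j in itertools.combinations_with_replacement(range(n), 2):
            s = inter(i, j)
            if len(s) < min_genomes or (j - i + 1) < min_blocks:
                continue
            if i > 0 and len(inter(i - 1, j)) >= min_genomes:
                continue  # extensible left
            if j < n - 1 and len(inter(i, j + 1)) >= min_genomes:
                continue  # extensible right
            out.add((chrom, i, j, s))
    return out


@pytest.fixture
def toy_matrix():
    """Three genomes, six blocks; absent sets b1:{} b2:{B,C} b3:{B,C} b4:{B} b5:{} b6:{C}."""
    return matrix_from_absent_sets(
        ["A", "B", "C"],
        [set(), {"B", "C"}, {"B", "C"}, {"B"}, set(), {"C"}],
    )


TOY_GFA = (
    "H\tVN:Z:1.0\n"
    "S\ts1\t*\tLN:i:4\n"
    "S\ts2\t*\tLN:i:3\n"
    "S\ts3\t*\tLN:i:5\n"
    "P\tgA\ts1+,s2+,s3+\t*\n"
    "P\tgB\ts1+,s3+\t*\n"
)


@pytest.fixture
def toy_gfa_text():
    return TOY_GFA
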