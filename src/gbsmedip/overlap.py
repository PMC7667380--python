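"""Interval-overlap counting and the randomization overlap test.

Two intervals "overlap" at gap tolerance ``max_gap`` when their
edge-to-edge gap is at most ``max_gap`` bp (0 = touching or intersecting).
The permutation test re-places one set uniformly at random within its own
chromosomes, preserving interval lengths and chromosomal composition, and
scores the merged-component overlap count against the fixed set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GenomeModel, GenomicInterval


@dataclass
class VennCounts:
    """Overlap bookkeeping between two interval sets.

    ``a_only``/``b_only`` count intervals with no partner in the other set
    at the gap tolerance; ``pair_count`` counts all cross-set partner
    pairs; ``merged_overlaps`` counts connected components (linking any
    two intervals within the gap) that contain members of both sets — the
    Venn-intersection count when runs of mutually close DMRs collapse to
    one event.
    """

    a_only: int
    b_only: int
    merged_overlaps: int
    pair_count: int
    n_a: int
    n_b: int


def _as_arrays(intervals: list[GenomicInterval]):
    chroms = np.array([iv.chrom for iv in intervals])
    starts = np.array([iv.start for iv in intervals], dtype=np.int64)
    ends = np.array([iv.end for iv in intervals], dtype=np.int64)
    return chroms, starts, ends


def _pair_stats(a_arrays, b_arrays, max_gap: int):
    """Per-side partner counts via interval stabbing with sorted arrays.

    An interval of B partners A's interval ``a`` iff ``b.start <= a.end +
    max_gap + 1`` is false only when starting too late, i.e. partners(a) =
    n_b(chrom) − #{b.start > a.end + gap} − #{b.end < a.start − gap}; the
    two excluded sets are disjoint, so the count is exact.
    """
    a_chroms, a_starts, a_ends = a_arrays
    b_chroms, b_starts, b_ends = b_arrays
    partners = np.zeros(len(a_chroms), dtype=np.int64)
    for chrom in np.unique(a_chroms):
        am = a_chroms == chrom
        bm = b_chroms == chrom
        nb = int(bm.sum())
        if nb == 0:
            continue
        bs = np.sort(b_starts[bm])
        be = np.sort(b_ends[bm])
        # partner condition: b.start <= a.end + gap + 1 and b.end >= a.start - gap - 1
        too_late = nb - np.searchsorted(bs, a_ends[am] + max_gap + 1, side="right")
        too_early = np.searchsorted(be, a_starts[am] - max_gap - 1, side="left")
        partners[am] = nb - too_late - too_early
    return partners


def overlap_counts(
    set_a: list[GenomicInterval], set_b: list[GenomicInterval], max_gap: int = 0
) -> VennCounts:
    """Count overlaps between two interval sets at gap tolerance ``max_gap``."""
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    a_arrays = _as_arrays(set_a)
    b_arrays = _as_arrays(set_b)
    partners_a = _pair_stats(a_arrays, b_arrays, max_gap) if set_a and set_b else np.zeros(len(set_a), dtype=int)
    partners_b = _pair_stats(b_arrays, a_arrays, max_gap) if set_a and set_b else np.zeros(len(set_b), dtype=int)

    # merged connected components across the union of both sets: sweep the
    # sorted union, linking intervals whose gap is <= max_gap
    merged_overlaps = 0
    n = len(set_a) + len(set_b)
    if n:
        chroms = np.concatenate([a_arrays[0], b_arrays[0]])
        starts = np.concatenate([a_arrays[1], b_arrays[1]])
        ends = np.concatenate([a_arrays[2], b_arrays[2]])
        tags = np.concatenate([np.zeros(len(set_a), dtype=np.int8), np.ones(len(set_b), dtype=np.int8)])
        order = np.lexsort((ends, starts, chroms))
        comp_has = [False, False]
        comp_chrom, comp_end = None, None
        for idx in order:
            if comp_chrom == chroms[idx] and starts[idx] - comp_end - 1 <= max_gap:
                comp_has[tags[idx]] = True
                comp_end = max(comp_end, int(ends[idx]))
            else:
                if comp_has[0] and comp_has[1]:
                    merged_overlaps += 1
                comp_has = [False, False]
                comp_has[tags[idx]] = True
                comp_chrom, comp_end = chroms[idx], int(ends[idx])
        if comp_has[0] and comp_has[1]:
            merged_overlaps += 1

    return VennCounts(
        a_only=int((partners_a == 0).sum()),
        b_only=int((partners_b == 0).sum()),
        merged_overlaps=merged_overlaps,
        pair_count=int(partners_a.sum()),
        n_a=len(set_a),
        n_b=len(set_b),
    )


@dataclass
class OverlapTestResult:
    observed: VennCounts
    n_permutations: int
    max_gap: int
    permuted_overlaps: np.ndarray
    p_value: float  # add-one estimator, never 0
    seed: int | None = None


def _random_placement(
    intervals: list[GenomicInterval], genome: GenomeModel, rng: np.random.Generator
) -> list[GenomicInterval]:
    placed = []
    for iv in intervals:
        length = genome.length(iv.chrom)
        if iv.width > length:
            raise ValueError(
                f"interval {iv.region_string()} longer than chromosome ({length} bp)"
            )
        start = int(rng.integers(1, length - iv.width + 2))
        placed.append(GenomicInterval(iv.chrom, start, start + iv.width - 1))
    return placed


def permutation_overlap_test(
    set_a: list[GenomicInterval],
    set_b: list[GenomicInterval],
    genome: GenomeModel,
    n: int = 100,
    max_gap: int = 0,
    seed: int | None = None,
) -> OverlapTestResult:
    """Randomization test of the overlap between two DMR sets.

    Each permutation re-places every interval of ``set_b`` uniformly at
    random within its original chromosome (length preserved, no mutual
    exclusion) and recomputes the merged-component overlap count with the
    fixed ``set_a``.  The empirical p-value uses the add-one estimator
    ``(k + 1) / (n + 1)`` with ``k`` the number of permutations reaching
    the observed overlap, so p is never 0 and lies in (0, 1].
    """
    if n < 1:
        raise ValueError("need at least 1 permutation")
    rng = np.random.default_rng(seed)
    observed = overlap_counts(set_a, set_b, max_gap)
    permuted = np.empty(n, dtype=int)
    for i in range(n):
        placed = _random_placement(set_b, genome, rng)
        permuted[i] = overlap_counts(set_a, placed, max_gap).merged_overlaps
    if not set_a or not set_b:
        p = 1.0
    else:
        k = int((permuted >= observed.merged_overlaps).sum())
        p = (k + 1) / (n + 1)
    return OverlapTestResult(
        observed=observed,
        n_permutations=n,
        max_gap=max_gap,
        permuted_overlaps=permuted,
        p_value=float(p),
        seed=seed,
    )
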