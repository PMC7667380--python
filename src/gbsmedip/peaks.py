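"""Peak-based preselection of candidate regions (ROIs).

Pooled S and pooled C coverage are compared on fine genome bins with a
local Poisson background in the style of MACS-type callers: the control
track is scaled to the treatment total, the local rate is the maximum of
the genome-wide rate and the control averages over 1 kb, 5 kb and 10 kb
windows centred on the bin, and bins beating that rate at FDR <= q_max are
merged into peaks.  Calling is run in both directions (S over C and C over
S) and the union, tagged by direction, forms the ROI set that the exact
test then evaluates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .digest import FragmentSet
from .intervals import GenomeModel, GenomicInterval, merge_intervals

logger = logging.getLogger(__name__)

LOCAL_WINDOWS_BP = (1_000, 5_000, 10_000)


@dataclass
class PeakRecord:
    interval: GenomicInterval
    direction: str  # "S" or "C" (which group is enriched)
    fold_enrichment: float
    p_value: float
    q_value: float

    @property
    def width(self) -> int:
        return self.interval.width


@dataclass
class BinnedCoverage:
    """Per-bin pooled counts for each group over a genome tiling."""

    bins: list[GenomicInterval]
    chrom_slices: dict[str, slice]
    pooled: dict[str, np.ndarray]  # group -> per-bin float counts
    bin_size: int


def binned_coverage(
    fragments: FragmentSet,
    pooled_counts: dict[str, np.ndarray],
    genome: GenomeModel,
    bin_size: int = 10,
) -> BinnedCoverage:
    """Spread per-fragment pooled counts uniformly over genome bins.

    ``pooled_counts`` maps a group label to per-fragment totals.  A
    fragment's mass lands on each bin in proportion to the overlapped
    share of the fragment; totals are conserved exactly (no rounding).
    """
    if bin_size < 1:
        raise ValueError("bin size must be >= 1")
    bins: list[GenomicInterval] = []
    chrom_slices: dict[str, slice] = {}
    offset = 0
    for name in genome.names:
        length = genome.length(name)
        n = -(-length // bin_size)
        for i in range(n):
            start = i * bin_size + 1
            bins.append(GenomicInterval(name, start, min(start + bin_size - 1, length)))
        chrom_slices[name] = slice(offset, offset + n)
        offset += n

    out = {g: np.zeros(len(bins)) for g in pooled_counts}
    frag_arrays = {g: np.asarray(v, dtype=float) for g, v in pooled_counts.items()}
    for g, arr in frag_arrays.items():
        if len(arr) != len(fragments):
            raise ValueError("pooled counts must align with fragments")
    for f_idx, frag in enumerate(fragments.fragments):
        sl = chrom_slices.get(frag.chrom)
        if sl is None:
            raise ValueError(f"fragment on unknown chromosome {frag.chrom}")
        first = (frag.start - 1) // bin_size
        last = (frag.end - 1) // bin_size
        for b in range(first, last + 1):
            bin_start = b * bin_size + 1
            bin_end = bin_start + bin_size - 1
            ov = min(bin_end, frag.end) - max(bin_start, frag.start) + 1
            frac = ov / frag.width
            for g in out:
                out[g][sl.start + b] += frac * frag_arrays[g][f_idx]
    return BinnedCoverage(bins=bins, chrom_slices=chrom_slices, pooled=out, bin_size=bin_size)


def _centered_mean(x: np.ndarray, half_bins: int) -> np.ndarray:
    """Mean of ``x`` over a window of ``2*half_bins+1`` bins, edge-truncated."""
    n = len(x)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    lo = np.maximum(np.arange(n) - half_bins, 0)
    hi = np.minimum(np.arange(n) + half_bins + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def _call_one_direction(
    cov: BinnedCoverage,
    treat_group: str,
    ctrl_group: str,
    q_max: float,
    merge_gap_bp: int,
    min_width_bp: int,
) -> list[PeakRecord]:
    treat = cov.pooled[treat_group]
    ctrl = cov.pooled[ctrl_group]
    n_bins = len(treat)
    treat_total = treat.sum()
    ctrl_total = ctrl.sum()
    if treat_total <= 0:
        return []
    if ctrl_total > 0:
        ctrl_scaled = ctrl * (treat_total / ctrl_total)
        lam_genome = np.full(n_bins, ctrl_scaled.sum() / n_bins)
    else:
        logger.warning("all-zero control: applying 1 pseudo-count per bin as lambda floor")
        ctrl_scaled = np.zeros(n_bins)
        lam_genome = np.ones(n_bins)

    lam = lam_genome.copy()
    for name, sl in cov.chrom_slices.items():
        seg = ctrl_scaled[sl]
        for w_bp in LOCAL_WINDOWS_BP:
            half = max(1, w_bp // (2 * cov.bin_size))
            lam[sl] = np.maximum(lam[sl], _centered_mean(seg, half))

    k = np.floor(treat + 0.5)
    p = stats.poisson.sf(k - 1, lam)
    p = np.where(k > 0, p, 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    sig = q <= q_max
    if not sig.any():
        return []
    sig_bins = [cov.bins[i] for i in np.flatnonzero(sig)]
    merged = merge_intervals(sig_bins, max_gap=merge_gap_bp)

    # index significant bins per merged peak for summary statistics
    records = []
    sig_idx = np.flatnonzero(sig)
    for peak in merged:
        if peak.width < min_width_bp:
            continue
        in_peak = [
            i
            for i in sig_idx
            if cov.bins[i].chrom == peak.chrom
            and cov.bins[i].start >= peak.start
            and cov.bins[i].end <= peak.end
        ]
        treat_sum = float(treat[in_peak].sum())
        lam_sum = float(lam[in_peak].sum())
        records.append(
            PeakRecord(
                interval=peak,
                direction=treat_group,
                fold_enrichment=treat_sum / lam_sum if lam_sum > 0 else np.inf,
                p_value=float(np.min(p[in_peak])),
                q_value=float(np.min(q[in_peak])),
            )
        )
    return records


def call_peaks(
    cov: BinnedCoverage,
    q_max: float = 0.1,
    merge_gap_bp: int = 100,
    min_width_bp: int = 50,
) -> list[PeakRecord]:
    """Call enriched regions in both directions on pooled binned coverage.

    ``cov.pooled`` must hold the two group tracks under keys "S" and "C".
    Swapping the groups swaps peak directions but not coordinates.
    """
    if not {"S", "C"} <= set(cov.pooled):
        raise ValueError('binned coverage must carry pooled tracks "S" and "C"')
    peaks = _call_one_direction(cov, "S", "C", q_max, merge_gap_bp, min_width_bp)
    peaks += _call_one_direction(cov, "C", "S", q_max, merge_gap_bp, min_width_bp)
    peaks.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return peaks


def rois_to_regions(peaks: list[PeakRecord]) -> list[GenomicInterval]:
    """Strip directions and merge overlapping peaks into testable regions."""
    return merge_intervals([p.interval for p in peaks], max_gap=0)
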