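"""Genomic-context statistics for DMR sets.

Covers the downstream spatial analyses: per-chromosome enrichment against
a randomization expectancy (random windows with a truncated-normal length
model), nearest-neighbour distance profiles on mantissa-magnitude bins,
signed distance-to-TSS distributions with mode detection, histogram
correlation between profiles, and gene-relative functional annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneModel, GenomeModel, GenomicInterval

logger = logging.getLogger(__name__)


# ------------------------------------------------------------- expectancy
@dataclass
class ExpectancyProfile:
    """Per-chromosome observed vs randomly expected DMR fractions."""

    table: pd.DataFrame  # chrom, chrom_class, expected_count, expected_fraction
    # (+ observed_count, observed_fraction, fold_enrichment once observed set applied)
    n_random: int
    length_mean: float
    length_sd: float
    seed: int | None = None


def random_window_expectancy(
    genome: GenomeModel,
    n: int = 100_000,
    length_mean: float = 237.0,
    length_sd: float = 184.0,
    seed: int | None = None,
) -> ExpectancyProfile:
    """Expected per-chromosome fractions of randomly placed windows.

    Window lengths are drawn from Normal(length_mean, length_sd) truncated
    to [1, length_mean + 4·length_sd]; a chromosome is chosen with
    probability proportional to its length and the start is uniform over
    valid placements.  Chromosomes shorter than the maximum window length
    are excluded (logged).
    """
    if n < 1 or length_mean <= 0:
        raise ValueError("n >= 1 and length_mean > 0 required")
    rng = np.random.default_rng(seed)
    max_len = length_mean + 4.0 * length_sd
    usable = [name for name in genome.names if genome.length(name) >= max_len]
    excluded = set(genome.names) - set(usable)
    if excluded:
        logger.info("chromosomes too short for random windows, excluded: %s", sorted(excluded))
    if not usable:
        raise ValueError("no chromosome long enough for the window length model")

    lengths = np.array([genome.length(c) for c in usable], dtype=float)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(usable), size=n, p=probs)
    if length_sd > 0:
        a = (1.0 - length_mean) / length_sd
        b = (max_len - length_mean) / length_sd
        win_len = stats.truncnorm.rvs(
            a, b, loc=length_mean, scale=length_sd, size=n, random_state=rng
        )
    else:
        win_len = np.full(n, length_mean)
    win_len = np.maximum(1, np.round(win_len)).astype(int)
    # uniform start over valid placements (start position itself not needed
    # for the expectancy, only the chromosome assignment)
    counts = np.bincount(chrom_idx, minlength=len(usable)).astype(float)
    table = pd.DataFrame(
        {
            "chrom": usable,
            "chrom_class": [genome.chrom_class(c) for c in usable],
            "length": lengths.astype(int),
            "expected_count": counts,
            "expected_fraction": counts / counts.sum(),
        }
    )
    return ExpectancyProfile(
        table=table, n_random=n, length_mean=length_mean, length_sd=length_sd, seed=seed
    )


def fold_enrichment(
    observed: list[GenomicInterval], expectancy: ExpectancyProfile
) -> ExpectancyProfile:
    """Attach observed counts and per-chromosome fold enrichment.

    ``fold = (obs_c / obs_total) / (exp_c / exp_total)``; chromosomes with
    zero expected fraction get NaN (undefined).
    """
    if not observed:
        raise ValueError("observed interval set is empty")
    table = expectancy.table.copy()
    obs_counts = pd.Series([iv.chrom for iv in observed]).value_counts()
    table["observed_count"] = table["chrom"].map(obs_counts).fillna(0).astype(float)
    total = table["observed_count"].sum()
    table["observed_fraction"] = table["observed_count"] / total if total > 0 else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = table["observed_fraction"] / table["expected_fraction"]
    table["fold_enrichment"] = fold.where(table["expected_fraction"] > 0, np.nan)
    return ExpectancyProfile(
        table=table,
        n_random=expectancy.n_random,
        length_mean=expectancy.length_mean,
        length_sd=expectancy.length_sd,
        seed=expectancy.seed,
    )


# -------------------------------------------------------------- distances
@dataclass
class DistanceProfile:
    """Distances with their histogram.

    ``kind`` is "magnitude" (mantissa-magnitude bins ``[d·10^k, (d+1)·10^k)``
    for inter-DMR gaps, plus a zero bin) or "linear" (fixed-width signed
    bins for TSS distances).  ``bin_labels`` and ``bin_counts`` align; the
    counts sum to the number of distances.
    """

    distances: np.ndarray
    kind: str
    bin_labels: list
    bin_counts: np.ndarray
    bin_centers: np.ndarray | None = None
    unplaced: list[str] = field(default_factory=list)  # ids that contributed nothing

    def mass_fractions(self) -> np.ndarray:
        total = self.bin_counts.sum()
        return self.bin_counts / total if total > 0 else self.bin_counts.astype(float)


def magnitude_bin(d: int) -> tuple[int, int]:
    """Mantissa-magnitude bin of a nonnegative distance: (leading digit, 10^k)."""
    if d < 0:
        raise ValueError("magnitude bins are for nonnegative distances")
    if d == 0:
        return (0, 0)
    k = int(np.floor(np.log10(d)))
    return (int(d // 10**k), 10**k)


def _magnitude_profile(distances: list[int], unplaced: list[str]) -> DistanceProfile:
    dist = np.array(sorted(distances), dtype=int)
    bins = [magnitude_bin(int(d)) for d in dist]
    labels = sorted(set(bins), key=lambda b: b[0] * b[1])
    counts = np.array([bins.count(lbl) for lbl in labels], dtype=int)
    centers = np.array([lbl[0] * lbl[1] * 1.5 if lbl[1] else 0.0 for lbl in labels])
    return DistanceProfile(
        distances=dist,
        kind="magnitude",
        bin_labels=labels,
        bin_counts=counts,
        bin_centers=centers,
        unplaced=unplaced,
    )


def inter_dmr_distances(dmrs: list[GenomicInterval]) -> DistanceProfile:
    """Nearest-neighbour edge-to-edge distance for each DMR, same chromosome.

    Overlapping or touching DMRs contribute distance 0; a DMR alone on its
    chromosome contributes nothing (recorded in ``unplaced``).
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in dmrs:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    distances: list[int] = []
    unplaced: list[str] = []
    any_pair = False
    for chrom, ivs in by_chrom.items():
        if len(ivs) < 2:
            unplaced.extend(iv.region_string() for iv in ivs)
            logger.info("single DMR on %s contributes no distance", chrom)
            continue
        any_pair = True
        ivs = sorted(ivs, key=lambda iv: (iv.start, iv.end))
        # left neighbour: running max of preceding ends (an early long
        # interval can end closer than the immediately preceding one);
        # right neighbour: the next start is minimal among later starts
        max_end_before = None
        for i, iv in enumerate(ivs):
            cands = []
            if max_end_before is not None:
                cands.append(max(0, iv.start - max_end_before - 1))
            if i < len(ivs) - 1:
                cands.append(max(0, ivs[i + 1].start - iv.end - 1))
            distances.append(min(cands))
            max_end_before = iv.end if max_end_before is None else max(max_end_before, iv.end)
    if not any_pair:
        raise ValueError("need at least 2 DMRs on some chromosome")
    return _magnitude_profile(distances, unplaced)


def tss_distances(
    dmrs: list[GenomicInterval],
    genes: list[GeneModel],
    bin_width: int = 5_000,
    span: int = 100_000,
) -> DistanceProfile:
    """Signed distance from each DMR midpoint to its nearest TSS.

    The distance is ``(midpoint − TSS)`` multiplied by +1 on + strand
    genes and −1 on − strand genes, so negative values are upstream of the
    gene regardless of strand.  The nearest TSS is chosen by absolute
    distance (ties broken toward the larger coordinate).  Distances are
    histogrammed on ``bin_width`` bins spanning ±``span`` (values beyond
    the span are clipped into the edge bins so counts always sum to n).
    DMRs on chromosomes without genes are flagged unannotatable.
    """
    if not genes:
        raise ValueError("need at least one gene with a TSS")
    tss_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        sign = 1 if g.strand == "+" else -1
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, sign))
    for chrom in tss_by_chrom:
        tss_by_chrom[chrom].sort()

    signed: list[float] = []
    unplaced: list[str] = []
    for iv in dmrs:
        entries = tss_by_chrom.get(iv.chrom)
        if not entries:
            unplaced.append(iv.region_string())
            continue
        mid = iv.midpoint
        best = None
        for tss, sign in entries:
            d_abs = abs(mid - tss)
            # ties broken toward the + coordinate direction (larger TSS)
            key = (d_abs, -tss)
            if best is None or key < best[0]:
                best = (key, (mid - tss) * sign)
        signed.append(best[1])

    dist = np.array(signed, dtype=float)
    edges = np.arange(-span, span + bin_width, bin_width, dtype=float)
    clipped = np.clip(dist, edges[0], np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(clipped, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    labels = [(int(lo), int(hi)) for lo, hi in zip(edges[:-1], edges[1:])]
    return DistanceProfile(
        distances=dist,
        kind="linear",
        bin_labels=labels,
        bin_counts=counts,
        bin_centers=centers,
        unplaced=unplaced,
    )


@dataclass
class Mode:
    bin_index: int
    center: float
    mass_fraction: float


def detect_modes(
    profile: DistanceProfile, smooth_window: int = 3, min_mass: float = 0.05
) -> list[Mode]:
    """Strict local maxima of the smoothed histogram with enough mass.

    The histogram is smoothed with a centred moving average of
    ``smooth_window`` bins; a mode is a bin strictly greater than both
    neighbours (edge bins compare against their single neighbour) whose
    smoothed mass fraction is at least ``min_mass``.  Modes are returned
    ordered by mass, largest first.
    """
    counts = profile.bin_counts.astype(float)
    if len(counts) < 3:
        raise ValueError("need at least 3 bins")
    if counts.sum() == 0:
        return []
    half = smooth_window // 2
    padded = np.pad(counts, half, mode="edge")
    kernel = np.ones(smooth_window) / smooth_window
    smooth = np.convolve(padded, kernel, mode="valid")
    frac = smooth / smooth.sum()
    modes = []
    # plateaus of equal smoothed mass (a single-bin spike smooths into one)
    # count as one mode anchored at their highest raw bin
    i = 0
    n = len(smooth)
    while i < n:
        j = i
        while j + 1 < n and smooth[j + 1] == smooth[i]:
            j += 1
        left_ok = i == 0 or smooth[i] > smooth[i - 1]
        right_ok = j == n - 1 or smooth[j] > smooth[j + 1]
        full_span = i == 0 and j == n - 1  # flat histogram: no mode
        if left_ok and right_ok and not full_span and frac[i] >= min_mass and smooth[i] > 0:
            k = i + int(np.argmax(counts[i : j + 1]))
            center = profile.bin_centers[k] if profile.bin_centers is not None else float(k)
            modes.append(Mode(bin_index=k, center=float(center), mass_fraction=float(frac[i])))
        i = j + 1
    modes.sort(key=lambda m: -m.mass_fraction)
    return modes


def histogram_correlation(a: DistanceProfile, b: DistanceProfile) -> float:
    """Pearson correlation of two profiles' matched bin counts."""
    if a.kind != b.kind or a.bin_labels != b.bin_labels:
        raise ValueError("profiles must share identical binning")
    x, y = a.bin_counts.astype(float), b.bin_counts.astype(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("histogram correlation undefined: zero variance")
    r, _ = stats.pearsonr(x, y)
    return float(r)


# -------------------------------------------------------------- annotation
CATEGORY_PRECEDENCE = [
    "coding sequence",
    "5 prime UTR",
    "3 prime UTR",
    "intron",
    "upstream gene",
    "downstream gene",
    "intergenic",
]


@dataclass
class FeatureAnnotation:
    dmr_id: str
    category: str  # primary (highest-precedence) category
    label: str  # full label, per-gene categories joined with "/"
    gene_ids: list[str]
    gene_strands: list[str]


def _gene_category(dmr: GenomicInterval, gene: GeneModel, flank: int) -> str | None:
    """Category of ``dmr`` relative to one gene, or None if unrelated."""
    touched: list[str] = []
    if dmr.overlaps(gene.interval):
        in_utr5 = any(dmr.overlaps(u) for u in gene.utr5)
        in_utr3 = any(dmr.overlaps(u) for u in gene.utr3)
        in_exon = any(dmr.overlaps(e) for e in gene.exons)
        # intron = gene-body bases not covered by exons
        lo = max(dmr.start, gene.interval.start)
        hi = min(dmr.end, gene.interval.end)
        exon_cover = 0
        for e in gene.exons:
            exon_cover += max(0, min(hi, e.end) - max(lo, e.start) + 1)
        in_intron = bool(gene.exons) and exon_cover < (hi - lo + 1)
        if in_exon and not (in_utr5 or in_utr3):
            touched.append("coding sequence")
        elif in_exon:
            # exon overlap that extends beyond the UTR footprint is coding
            utr_cover = 0
            for u in gene.utr5 + gene.utr3:
                utr_cover += max(0, min(hi, u.end) - max(lo, u.start) + 1)
            if exon_cover > utr_cover:
                touched.append("coding sequence")
        if in_utr5:
            touched.append("5 prime UTR")
        if in_utr3:
            touched.append("3 prime UTR")
        if in_intron:
            touched.append("intron")
    else:
        if gene.strand == "+":
            upstream = GenomicInterval(gene.chrom, max(1, gene.tss - flank), max(1, gene.tss - 1))
            down_anchor = gene.interval.end
            downstream = GenomicInterval(gene.chrom, down_anchor + 1, down_anchor + flank)
        else:
            upstream = GenomicInterval(gene.chrom, gene.tss + 1, gene.tss + flank)
            down_anchor = gene.interval.start
            downstream = GenomicInterval(
                gene.chrom, max(1, down_anchor - flank), max(1, down_anchor - 1)
            )
        if dmr.overlaps(upstream):
            touched.append("upstream gene")
        elif dmr.overlaps(downstream):
            touched.append("downstream gene")
    if not touched:
        return None
    touched.sort(key=CATEGORY_PRECEDENCE.index)
    return ", ".join(touched)


def annotate_feature(
    dmr: GenomicInterval, genes: list[GeneModel], flank: int = 5_000
) -> FeatureAnnotation:
    """Gene-relative annotation of a DMR.

    Precedence over all qualifying genes: coding sequence > 5' UTR >
    3' UTR > intron > upstream gene (within ``flank`` bp 5' of the TSS,
    strand-aware) > downstream gene (within ``flank`` bp 3' of the gene
    end) > intergenic.  Per-gene labels may be compound ("coding
    sequence, intron") when the DMR spans a feature boundary; multiple
    qualifying genes are all listed, labels joined with "/".
    """
    hits: list[tuple[str, GeneModel]] = []
    for gene in genes:
        if gene.chrom != dmr.chrom:
            continue
        cat = _gene_category(dmr, gene, flank)
        if cat is not None:
            hits.append((cat, gene))
    if not hits:
        return FeatureAnnotation(
            dmr_id=dmr.region_string(),
            category="intergenic",
            label="intergenic",
            gene_ids=[],
            gene_strands=[],
        )
    hits.sort(key=lambda h: CATEGORY_PRECEDENCE.index(h[0].split(", ")[0]))
    primary = hits[0][0].split(", ")[0]
    return FeatureAnnotation(
        dmr_id=dmr.region_string(),
        category=primary,
        label="/".join(cat for cat, _ in hits),
        gene_ids=[g.gene_id for _, g in hits],
        gene_strands=[g.strand for _, g in hits],
    )
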