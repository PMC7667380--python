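"""In-silico restriction digestion and library quality-control statistics.

The reduced-representation protocol this package models digests the genome
with PstI (recognition site CTGCAG, cut between the A and the final G:
CTGCA^G) and size-selects fragments compatible with short-read libraries.
The QC statistics mirror standard MeDIP practice: per-chromosome expectancy
checks, CpG enrichment scores (relH and GoGe) of the captured fraction
against the genome, and breadth/depth coverage summaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomeModel, GenomicInterval

PSTI_MOTIF = "CTGCAG"
PSTI_CUT_OFFSET = 5  # CTGCA^G


def count_cpg(seq: str) -> int:
    return seq.upper().count("CG")


@dataclass
class FragmentSet:
    """Restriction fragments with per-fragment CpG counts.

    Fragments are non-overlapping, sorted, and (before size selection) tile
    each chromosome exactly.
    """

    fragments: list[GenomicInterval]
    cpg_counts: list[int]
    motif: str = PSTI_MOTIF
    size_bounds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.fragments) != len(self.cpg_counts):
            raise ValueError("fragments and cpg_counts length mismatch")

    def __len__(self) -> int:
        return len(self.fragments)

    def widths(self) -> np.ndarray:
        return np.array([f.width for f in self.fragments], dtype=int)

    def total_bp(self) -> int:
        return int(self.widths().sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [f.chrom for f in self.fragments],
                "start": [f.start for f in self.fragments],
                "end": [f.end for f in self.fragments],
                "width": self.widths(),
                "cpg_count": self.cpg_counts,
            }
        )


def digest(genome: GenomeModel, motif: str = PSTI_MOTIF, cut_offset: int = PSTI_CUT_OFFSET) -> FragmentSet:
    """Digest every chromosome at each occurrence of ``motif``.

    The cut is placed after ``cut_offset`` bases of the recognition site
    (PstI: offset 5, CTGCA^G).  Fragments are the spans between successive
    cuts on the forward strand; their widths sum to the chromosome length
    and a chromosome with *k* sites yields *k* + 1 fragments.
    """
    if not motif or not set(motif) <= set("ACGT"):
        raise ValueError(f"unsupported motif {motif!r}: must be non-empty uppercase ACGT")
    if not 0 < cut_offset < len(motif) + 1:
        raise ValueError("cut offset must fall inside the motif")
    if not genome.has_sequence:
        raise ValueError("digestion requires genome sequence")
    frags: list[GenomicInterval] = []
    cpgs: list[int] = []
    pat = re.compile(re.escape(motif))
    for name in genome.names:
        seq = genome.sequence(name)
        # cut positions: last base of the left fragment (1-based)
        cuts = [m.start() + cut_offset for m in pat.finditer(seq)]
        bounds = [0] + cuts + [len(seq)]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            iv = GenomicInterval(name, lo + 1, hi)
            frags.append(iv)
            cpgs.append(count_cpg(seq[lo:hi]))
    return FragmentSet(frags, cpgs, motif=motif)


def size_select(fragments: FragmentSet, lo: int, hi: int) -> FragmentSet:
    """Retain fragments with width in [lo, hi], bounds inclusive."""
    if lo <= 0 or lo > hi:
        raise ValueError(f"invalid size-selection bounds [{lo}, {hi}]")
    keep = [(f, c) for f, c in zip(fragments.fragments, fragments.cpg_counts) if lo <= f.width <= hi]
    return FragmentSet(
        [f for f, _ in keep],
        [c for _, c in keep],
        motif=fragments.motif,
        size_bounds=(lo, hi),
    )


# --------------------------------------------------------- expectancy test
@dataclass
class ChromExpectancyReport:
    """Per-chromosome deviation report with two summary tests.

    ``p_value`` comes from the multinomial chi-square goodness-of-fit of
    the observed counts against length proportions (conditioning on the
    total), the calibrated test of "counts track chromosome length".  The
    descriptive one-sample t-test of the relative deviations against zero
    is also reported (``t_statistic``/``t_p_value``); because the expected
    counts are estimated from the same total, the deviations are
    sum-constrained and that t-test is strongly conservative — it is kept
    for descriptive continuity, not inference.
    """

    table: pd.DataFrame  # chrom, observed, expected, rel_deviation
    chi2_statistic: float
    p_value: float
    t_statistic: float
    t_p_value: float


def chrom_expectancy_ttest(observed: dict[str, float], genome: GenomeModel) -> ChromExpectancyReport:
    """Test whether per-chromosome counts track chromosome length.

    The expected count for chromosome *c* is ``total * length_c / genome
    length``; the report lists each chromosome's relative deviation
    ``(obs - exp) / exp``.  All-zero deviations (counts exactly
    proportional to length) are reported as statistic 0, p = 1.
    """
    names = [n for n in genome.names if n in observed]
    if len(names) < 3:
        raise ValueError("need counts on at least 3 chromosomes")
    obs = np.array([observed[n] for n in names], dtype=float)
    lengths = np.array([genome.length(n) for n in names], dtype=float)
    if (lengths <= 0).any():
        raise ValueError("zero-length chromosome")
    exp = obs.sum() * lengths / lengths.sum()
    rel = (obs - exp) / exp
    if np.allclose(rel, 0.0):
        chi2_stat, p = 0.0, 1.0
        t_stat, t_p = 0.0, 1.0
    else:
        chi2_stat = float(((obs - exp) ** 2 / exp).sum())
        p = float(stats.chi2.sf(chi2_stat, len(names) - 1))
        t_stat, t_p = (float(v) for v in stats.ttest_1samp(rel, 0.0))
    table = pd.DataFrame(
        {"chrom": names, "observed": obs, "expected": exp, "rel_deviation": rel}
    )
    return ChromExpectancyReport(table, chi2_stat, p, t_stat, t_p)


# ---------------------------------------------------------- CpG enrichment
@dataclass
class EnrichmentScores:
    """CpG enrichment of a region set relative to the genome.

    relH is the CpG dinucleotide frequency per 100 bp; GoGe is the observed
    over expected CpG ratio ``n_CpG * n_bp / (n_C * n_G)``.  Each score is
    the region-set value divided by the genome value, so a region set with
    genome-average composition scores 1 on both.
    """

    relh_regions: float
    relh_genome: float
    goge_regions: float
    goge_genome: float

    @property
    def relh_ratio(self) -> float:
        return self.relh_regions / self.relh_genome

    @property
    def goge_ratio(self) -> float:
        return self.goge_regions / self.goge_genome


def _composition(seqs: list[str]) -> tuple[int, int, int, int]:
    n_cpg = sum(count_cpg(s) for s in seqs)
    n_c = sum(s.count("C") for s in seqs)
    n_g = sum(s.count("G") for s in seqs)
    n_bp = sum(len(s) for s in seqs)
    return n_cpg, n_c, n_g, n_bp


def cpg_enrichment(regions: list[GenomicInterval], genome: GenomeModel) -> EnrichmentScores:
    """Compute relH and GoGe CpG enrichment of ``regions`` vs the genome."""
    if not genome.has_sequence:
        raise ValueError("enrichment scoring requires genome sequence")
    region_seqs = [genome.fetch(iv) for iv in regions]
    genome_seqs = [genome.sequence(n) for n in genome.names]

    def scores(seqs: list[str]) -> tuple[float, float]:
        n_cpg, n_c, n_g, n_bp = _composition(seqs)
        if n_c == 0 or n_g == 0 or n_bp == 0:
            raise ValueError("undefined enrichment score: zero C or G content")
        relh = n_cpg / n_bp * 100.0
        goge = n_cpg * n_bp / (n_c * n_g)
        return relh, goge

    relh_r, goge_r = scores(region_seqs)
    relh_g, goge_g = scores(genome_seqs)
    return EnrichmentScores(relh_r, relh_g, goge_r, goge_g)


# --------------------------------------------------------- coverage summary
@dataclass
class CoverageSummary:
    """Per-sample sequencing summary: depth, bp sequenced, breadth, % covered.

    Breadth is bp sequenced / depth; percent covered is breadth over the
    genome length × 100.
    """

    sample_id: str
    depth: float
    bp_sequenced: float
    breadth: float
    pct_genome_covered: float


def coverage_summary(
    counts: pd.DataFrame,
    fragments: FragmentSet,
    genome: GenomeModel,
    sample_ids: list[str] | None = None,
) -> list[CoverageSummary]:
    """Summarise coverage per sample from a per-fragment counts table.

    A fragment with count *k* contributes ``k × width`` sequenced bp; depth
    is the count-weighted mean count over covered fragments; breadth = bp
    sequenced / depth.
    """
    widths = fragments.widths()
    if len(counts) != len(fragments):
        raise ValueError("counts rows must match fragment set")
    if sample_ids is None:
        from .io import COUNTS_INDEX_COLS

        sample_ids = [c for c in counts.columns if c not in COUNTS_INDEX_COLS]
    out = []
    glen = genome.total_length
    for sid in sample_ids:
        k = counts[sid].to_numpy(dtype=float)
        if (k < 0).any():
            raise ValueError("negative counts")
        bp = float((k * widths).sum())
        covered = k > 0
        if not covered.any():
            raise ValueError(f"sample {sid}: zero depth, breadth undefined")
        depth = bp / float(widths[covered].sum())
        breadth = bp / depth
        out.append(
            CoverageSummary(
                sample_id=sid,
                depth=depth,
                bp_sequenced=bp,
                breadth=breadth,
                pct_genome_covered=breadth / glen * 100.0,
            )
        )
    return out
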