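"""Synthetic GBS+MeDIP data with planted ground truth.

The generator emulates the structure of a reduced-representation
methylome experiment: a toy multi-chromosome genome with controlled CpG
and PstI-site densities, non-overlapping gene models, size-selected
restriction fragments, and per-fragment negative-binomial counts in which
immunoprecipitation is modelled as a saturating CpG-dependent capture
probability.  Treatment effects are planted symmetrically (stressed
samples ×2^{+e/2}, controls ×2^{-e/2}) so the planted log2 fold-change is
exactly ``e``; an optional input channel ignores methylation and carries
planted copy-number folds instead.  Every stage is deterministic under
the configuration seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .digest import PSTI_MOTIF, FragmentSet, digest, size_select
from .intervals import GeneModel, GenomeModel, GenomicInterval
from .windows import SampleInfo, WindowCountMatrix

logger = logging.getLogger(__name__)

# background base distribution (A, C, G, T): mildly AT-rich like a real
# vertebrate genome; CpG and PstI content are controlled separately
_BASE_PROBS = np.array([0.29, 0.21, 0.21, 0.29])
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3


@dataclass
class ChromSpec:
    name: str
    length: int
    chrom_class: str = "macro"
    cpg_density: float = 0.01  # planted CpG dinucleotides per bp
    psti_density: float = 0.0025  # planted CTGCAG sites per bp


@dataclass
class CNVSpec:
    n: int = 2
    fold: float = 3.0
    length: int = 2_000


@dataclass
class SimulationConfig:
    """Study conditions for one simulated population."""

    seed: int = 0
    chromosomes: list[ChromSpec] = field(
        default_factory=lambda: [
            ChromSpec("chr1", 1_200_000, "macro"),
            ChromSpec("chr2", 900_000, "macro"),
            ChromSpec("chr11", 450_000, "micro"),
            ChromSpec("chrZ", 450_000, "sexZ"),
        ]
    )
    n_genes: int = 60
    n_s: int = 8
    n_c: int = 8
    depth: float = 30.0  # mean MeDIP count per fully captured fragment per sample
    input_depth: float = 20.0
    phi: float = 0.2  # NB dispersion of fragment counts
    libsize_log_sd: float = 0.2  # log-normal sd of per-sample size factors
    n_true_dmrs: int = 20
    effect_size: float = 2.0  # |log2FC| of planted DMRs (signs alternate)
    effect_sizes: list[float] | None = None  # explicit signed effects override
    placement_weights: dict[str, float] = field(
        default_factory=lambda: {"macro": 1.0, "micro": 2.5, "sexZ": 4.0}
    )
    size_min: int = 200
    size_max: int = 600
    with_input: bool = False
    cnv: CNVSpec | None = None
    capture_epsilon: float = 0.05
    capture_sat_quantile: float = 0.90

    def __post_init__(self) -> None:
        if self.n_s < 1 or self.n_c < 1:
            raise ValueError("need at least one sample per group")
        if any(w < 0 for w in self.placement_weights.values()) or not any(
            self.placement_weights.values()
        ):
            raise ValueError("placement weights must be >= 0 and not all zero")
        if self.effect_sizes is not None and any(e == 0 for e in self.effect_sizes):
            raise ValueError("planted effects must be nonzero")


@dataclass
class TruthSet:
    """Planted ground truth of one simulated data set."""

    dmrs: list[tuple[GenomicInterval, float]]  # (interval, signed log2FC)
    cnvs: list[tuple[GenomicInterval, float]]  # (interval, fold in S inputs)
    library_size_factors: dict[str, float]
    seed: int
    warnings: list[str] = field(default_factory=list)


# ------------------------------------------------------------------ genome
def _scrub_background(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Remove every CG dinucleotide and CTG trinucleotide from a sequence.

    With CG and CTG absent, the background contains no CpG and cannot
    contain a PstI site (CTGCAG starts with CTG); both are then planted
    explicitly at their configured densities.
    """
    for _ in range(100):
        cg = np.flatnonzero((codes[:-1] == _C) & (codes[1:] == _G))
        ctg = np.flatnonzero(
            (codes[:-2] == _C) & (codes[1:-1] == _T) & (codes[2:] == _G)
        )
        if cg.size == 0 and ctg.size == 0:
            return codes
        bad = np.unique(np.concatenate([cg + 1, ctg + 2]))  # offending G positions
        codes[bad] = rng.choice(np.array([_A, _C, _T]), size=bad.size)
    raise RuntimeError("background scrub failed to converge")


def _plant_positions(
    n: int, valid_len: int, occupied: np.ndarray, min_gap: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample up to ``n`` sorted start positions, pairwise >= min_gap apart
    and avoiding occupied starts."""
    if n <= 0 or valid_len <= 0:
        return np.empty(0, dtype=int)
    pool = rng.choice(valid_len, size=min(valid_len, 2 * n), replace=False)
    pool.sort()
    chosen = []
    last = -min_gap
    occ = set(np.flatnonzero(occupied))
    for p in pool:
        if p - last < min_gap:
            continue
        if any((p + k) in occ for k in range(min_gap)):
            continue
        chosen.append(p)
        last = p
        if len(chosen) == n:
            break
    return np.array(chosen, dtype=int)


def generate_genome(config: SimulationConfig) -> GenomeModel:
    """Generate the toy genome with configured CpG and PstI densities.

    Planted densities are accurate to a few percent (collisions between
    planted elements are dropped); background sequence contributes no CpG
    or PstI occurrences at all, so zero configured density means zero
    occurrences.
    """
    if len(config.chromosomes) < 2:
        raise ValueError("need at least 2 chromosomes")
    seqs: dict[str, str] = {}
    chrom_specs = []
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.chromosomes))
    for spec, child in zip(config.chromosomes, children):
        if spec.length < 2_000:
            raise ValueError(f"chromosome {spec.name} shorter than 2 kb")
        rng = np.random.default_rng(child)
        codes = rng.choice(4, size=spec.length, p=_BASE_PROBS).astype(np.int8)
        codes = _scrub_background(codes, rng)

        occupied = np.zeros(spec.length, dtype=bool)
        n_psti = int(round(spec.psti_density * spec.length))
        psti_pos = _plant_positions(n_psti, spec.length - 6, occupied, 7, rng)
        for p in psti_pos:
            codes[p : p + 6] = [_C, _T, _G, _C, _A, _G]
            occupied[max(0, p - 1) : p + 7] = True

        n_cpg = int(round(spec.cpg_density * spec.length))
        cpg_pos = _plant_positions(n_cpg, spec.length - 2, occupied, 2, rng)
        for p in cpg_pos:
            codes[p] = _C
            codes[p + 1] = _G

        seqs[spec.name] = _BASES[codes].tobytes().decode()
        chrom_specs.append((spec.name, spec.length, spec.chrom_class))
    return GenomeModel(chrom_specs, sequences=seqs)


# ------------------------------------------------------------------- genes
def plant_genes(
    genome: GenomeModel,
    n_genes: int,
    seed: int,
    length_range: tuple[int, int] = (2_000, 8_000),
) -> list[GeneModel]:
    """Place non-overlapping genes with exons, UTRs and alternating strands."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    lengths = np.array([genome.length(c) for c in genome.names], dtype=float)
    probs = lengths / lengths.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.names}
    genes: list[GeneModel] = []
    attempts = 0
    while len(genes) < n_genes:
        attempts += 1
        if attempts > 200 * n_genes:
            raise RuntimeError(f"could not place {n_genes} genes on this genome")
        chrom = genome.names[int(rng.choice(len(lengths), p=probs))]
        glen = int(rng.integers(length_range[0], length_range[1] + 1))
        if glen + 2 > genome.length(chrom):
            continue
        start = int(rng.integers(1, genome.length(chrom) - glen + 1))
        end = start + glen - 1
        if any(s <= end and start <= e for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        strand = "+" if len(genes) % 2 == 0 else "-"
        gene = _build_gene(f"gene{len(genes) + 1}", chrom, start, end, strand, rng)
        genes.append(gene)
    genes.sort(key=lambda g: (g.chrom, g.interval.start))
    return genes


def _build_gene(
    gid: str, chrom: str, start: int, end: int, strand: str, rng: np.random.Generator
) -> GeneModel:
    glen = end - start + 1
    n_exons = int(rng.integers(1, 5))
    # 2k-1 alternating exon/intron segments with random positive shares
    shares = rng.dirichlet(np.ones(2 * n_exons - 1))
    sizes = np.maximum(50, np.round(shares * glen).astype(int))
    sizes = np.round(sizes * glen / sizes.sum()).astype(int)
    sizes[-1] = max(50, glen - sizes[:-1].sum())
    exons = []
    pos = start
    for i, sz in enumerate(sizes):
        seg_end = min(end, pos + sz - 1)
        if i % 2 == 0:
            exons.append(GenomicInterval(chrom, pos, seg_end))
        pos = seg_end + 1
        if pos > end:
            break
    if exons[-1].end > end:
        exons[-1] = GenomicInterval(chrom, exons[-1].start, end)
    # 5' UTR: leading fifth of the first exon in transcript orientation
    first = exons[0] if strand == "+" else exons[-1]
    last = exons[-1] if strand == "+" else exons[0]
    u5len = max(1, first.width // 5)
    u3len = max(1, last.width // 5)
    if strand == "+":
        utr5 = [GenomicInterval(chrom, first.start, first.start + u5len - 1)]
        utr3 = [GenomicInterval(chrom, last.end - u3len + 1, last.end)]
    else:
        utr5 = [GenomicInterval(chrom, first.end - u5len + 1, first.end)]
        utr3 = [GenomicInterval(chrom, last.start, last.start + u3len - 1)]
    return GeneModel(
        gene_id=gid,
        symbol=gid.upper(),
        interval=GenomicInterval(chrom, start, end),
        strand=strand,
        exons=exons,
        utr5=utr5,
        utr3=utr3,
    )


# ------------------------------------------------------------------- truth
def plant_truth(
    genome: GenomeModel, fragments: FragmentSet, config: SimulationConfig
) -> TruthSet:
    """Choose planted DMR locations (on fragments) and CNV intervals.

    DMR-carrying fragments are drawn with probability proportional to the
    placement weight of their chromosome's class, emulating the uneven
    chromosomal distribution of treatment effects; effects alternate in
    sign at |log2FC| = ``effect_size`` unless explicit signed effects are
    configured.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    if config.n_true_dmrs > len(fragments):
        raise ValueError("more planted DMRs than fragments")
    w = np.array(
        [config.placement_weights.get(genome.chrom_class(f.chrom), 0.0) for f in fragments.fragments]
    )
    if w.sum() == 0:
        raise ValueError("placement weights exclude every fragment")
    idx = rng.choice(len(fragments), size=config.n_true_dmrs, replace=False, p=w / w.sum())
    idx.sort()
    if config.effect_sizes is not None:
        effects = [config.effect_sizes[i % len(config.effect_sizes)] for i in range(len(idx))]
    else:
        effects = [config.effect_size * (1 if i % 2 == 0 else -1) for i in range(len(idx))]
    dmrs = [(fragments.fragments[i], float(e)) for i, e in zip(idx, effects)]

    cnvs: list[tuple[GenomicInterval, float]] = []
    if config.cnv is not None:
        lengths = np.array([genome.length(c) for c in genome.names], dtype=float)
        for _ in range(config.cnv.n):
            chrom = genome.names[int(rng.choice(len(lengths), p=lengths / lengths.sum()))]
            L = min(config.cnv.length, genome.length(chrom))
            start = int(rng.integers(1, genome.length(chrom) - L + 2))
            cnvs.append((GenomicInterval(chrom, start, start + L - 1), config.cnv.fold))
    return TruthSet(dmrs=dmrs, cnvs=cnvs, library_size_factors={}, seed=config.seed)


# ------------------------------------------------------------------ counts
@dataclass
class SimulatedData:
    medip: WindowCountMatrix
    input: WindowCountMatrix | None
    truth: TruthSet
    fragments: FragmentSet


def _capture_probability(fragments: FragmentSet, config: SimulationConfig) -> np.ndarray:
    c = np.asarray(fragments.cpg_counts, dtype=float)
    c_sat = max(1.0, float(np.quantile(c, config.capture_sat_quantile)))
    eps = config.capture_epsilon
    return (1.0 - eps) * np.minimum(1.0, c / c_sat) + eps


def _nb_draw(mu: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
    return rng.poisson(lam)


def simulate_counts(
    genome: GenomeModel,
    fragments: FragmentSet,
    truth: TruthSet,
    config: SimulationConfig,
) -> SimulatedData:
    """Draw per-fragment MeDIP (and optional input) counts.

    MeDIP mean for sample *i* and fragment *f* is ``depth × libsize_i ×
    capture(f)``, multiplied by ``2^{±e/2}`` inside planted DMRs (sign by
    group); counts are NB with dispersion ``phi`` (Poisson at phi = 0).
    The input channel ignores methylation and applies the planted CNV fold
    to S-group samples over CNV intervals.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    n_frag = len(fragments)
    samples = [SampleInfo(f"S{i + 1}", "S") for i in range(config.n_s)] + [
        SampleInfo(f"C{i + 1}", "C") for i in range(config.n_c)
    ]
    lib = np.exp(rng.normal(0.0, config.libsize_log_sd, size=len(samples)))
    truth.library_size_factors = {s.sample_id: float(f) for s, f in zip(samples, lib)}

    capture = _capture_probability(fragments, config)
    effect = np.zeros(n_frag)
    for dmr_iv, e in truth.dmrs:
        hit = [
            i
            for i, f in enumerate(fragments.fragments)
            if f.overlaps(dmr_iv)
        ]
        if not hit:
            msg = f"planted DMR {dmr_iv.region_string()} covers no fragment"
            logger.warning(msg)
            truth.warnings.append(msg)
        for i in hit:
            effect[i] = e

    group_sign = np.array([1.0 if s.group == "S" else -1.0 for s in samples])
    mu = (
        config.depth
        * lib[None, :]
        * capture[:, None]
        * np.power(2.0, group_sign[None, :] * effect[:, None] / 2.0)
    )
    counts = _nb_draw(mu, config.phi, rng)
    medip = WindowCountMatrix(
        windows=list(fragments.fragments),
        counts=counts,
        samples=samples,
        cpg_counts=np.asarray(fragments.cpg_counts),
    )

    input_matrix = None
    if config.with_input:
        in_samples = [SampleInfo(f"I{s.sample_id}", s.group, "input") for s in samples]
        cnv_mult = np.ones(n_frag)
        for cnv_iv, fold in truth.cnvs:
            for i, f in enumerate(fragments.fragments):
                if f.overlaps(cnv_iv):
                    cnv_mult[i] = fold
        mu_in = (
            config.input_depth
            * lib[None, :]
            * np.where(group_sign[None, :] > 0, cnv_mult[:, None], 1.0)
        )
        in_counts = _nb_draw(mu_in, config.phi, rng)
        input_matrix = WindowCountMatrix(
            windows=list(fragments.fragments),
            counts=in_counts,
            samples=in_samples,
            cpg_counts=np.asarray(fragments.cpg_counts),
        )
    return SimulatedData(medip=medip, input=input_matrix, truth=truth, fragments=fragments)


def simulate_dataset(config: SimulationConfig) -> tuple[GenomeModel, list[GeneModel], SimulatedData]:
    """End-to-end generation: genome, genes, digestion, truth, counts."""
    genome = generate_genome(config)
    genes = plant_genes(genome, config.n_genes, config.seed)
    frags = size_select(digest(genome, PSTI_MOTIF), config.size_min, config.size_max)
    truth = plant_truth(genome, frags, config)
    return genome, genes, simulate_counts(genome, frags, truth, config)


# ----------------------------------------------------------------- presets
def br_like_config(seed: int = 0) -> SimulationConfig:
    """Higher-breadth, lower-depth population with an input channel (16 v 16)."""
    return SimulationConfig(
        seed=seed,
        n_s=16,
        n_c=16,
        depth=10.0,
        size_min=200,
        size_max=600,
        with_input=True,
        cnv=CNVSpec(n=2, fold=3.0, length=2_000),
    )


def sw_like_config(seed: int = 0) -> SimulationConfig:
    """Lower-breadth, higher-depth population without inputs (8 v 6)."""
    return SimulationConfig(
        seed=seed,
        n_s=8,
        n_c=6,
        depth=35.0,
        size_min=250,
        size_max=450,
        with_input=False,
    )
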