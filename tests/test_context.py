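import numpy as np
import pytest
from scipy import stats

from gbsmedip.context import (
    annotate_feature,
    detect_modes,
    fold_enrichment,
    histogram_correlation,
    inter_dmr_distances,
    magnitude_bin,
    random_window_expectancy,
    tss_distances,
)
from gbsmedip.intervals import GeneModel, GenomeModel, GenomicInterval


BIG = GenomeModel([("chrA", 80_000_000, "macro"), ("chrB", 20_000_000, "micro")])


def test_expected_fractions_follow_chromosome_length():
    prof = random_window_expectancy(BIG, n=100_000, length_mean=237, length_sd=184, seed=1)
    t = prof.table.set_index("chrom")
    assert t.loc["chrA", "expected_fraction"] == pytest.approx(0.8, abs=0.01)
    assert t.loc["chrB", "expected_fraction"] == pytest.approx(0.2, abs=0.01)
    assert prof.table["expected_fraction"].sum() == pytest.approx(1.0)


def test_expectancy_deterministic_under_seed():
    a = random_window_expectancy(BIG, n=5_000, seed=7)
    b = random_window_expectancy(BIG, n=5_000, seed=7)
    assert a.table.equals(b.table)


def test_expectancy_matches_closed_form_within_multinomial_error():
    genome = GenomeModel([(f"c{i}", int(l)) for i, l in enumerate([5e6, 2e6, 8e6, 1e6])])
    n = 100_000
    prof = random_window_expectancy(genome, n=n, length_mean=237, length_sd=184, seed=3)
    lengths = np.array([genome.length(c) for c in prof.table["chrom"]], dtype=float)
    expected = lengths / lengths.sum()
    observed = prof.table["expected_fraction"].to_numpy()
    sigma = np.sqrt(expected * (1 - expected) / n)
    assert (np.abs(observed - expected) <= 3 * sigma + 1e-12).all()


def test_short_chromosomes_are_excluded():
    g = GenomeModel([("big", 1_000_000), ("tiny", 500)])
    prof = random_window_expectancy(g, n=1000, length_mean=237, length_sd=184, seed=0)
    assert list(prof.table["chrom"]) == ["big"]


def test_fold_enrichment_arithmetic():
    prof = random_window_expectancy(BIG, n=100_000, seed=2)
    obs = [GenomicInterval("chrB", 100, 200)] * 10
    full = fold_enrichment(obs, prof)
    t = full.table.set_index("chrom")
    assert t.loc["chrB", "fold_enrichment"] == pytest.approx(
        1.0 / t.loc["chrB", "expected_fraction"]
    )
    # doubling observed counts leaves folds unchanged
    full2 = fold_enrichment(obs * 2, prof)
    assert np.allclose(
        full.table["fold_enrichment"], full2.table["fold_enrichment"], equal_nan=True
    )
    with pytest.raises(ValueError):
        fold_enrichment([], prof)


def test_fold_enrichment_null_concentrates_near_one():
    rng = np.random.default_rng(9)
    prof = random_window_expectancy(BIG, n=100_000, seed=5)
    fracs = prof.table.set_index("chrom")["expected_fraction"]
    chroms = rng.choice(fracs.index, size=1000, p=fracs.to_numpy())
    obs = [GenomicInterval(c, 1000, 1200) for c in chroms]
    full = fold_enrichment(obs, prof)
    folds = full.table["fold_enrichment"].dropna()
    assert ((folds >= 0.5) & (folds <= 2.0)).all()
    assert 0.8 <= float(np.median(folds)) <= 1.25


def test_no_length_trend_on_uniformly_planted_dmrs():
    rng = np.random.default_rng(33)
    genome = GenomeModel(
        [(f"c{i}", int(l)) for i, l in enumerate(rng.integers(2_000_000, 50_000_000, 12))]
    )
    lengths = np.array([genome.length(n) for n in genome.names], dtype=float)
    chroms = rng.choice(genome.names, size=2000, p=lengths / lengths.sum())
    obs = [GenomicInterval(c, 500, 700) for c in chroms]
    prof = fold_enrichment(obs, random_window_expectancy(genome, n=100_000, seed=6))
    t = prof.table.dropna(subset=["fold_enrichment"])
    rho = stats.spearmanr(t["length"], t["fold_enrichment"]).statistic
    assert abs(rho) <= 0.3


@pytest.mark.parametrize(
    "d,expected",
    [(0, (0, 0)), (1500, (1, 1000)), (25_000, (2, 10_000)), (9, (9, 1)), (10, (1, 10))],
)
def test_magnitude_binning(d, expected):
    assert magnitude_bin(d) == expected


def test_inter_dmr_distances_examples_and_oracle():
    dmrs = [
        GenomicInterval("c", 1000, 1100),
        GenomicInterval("c", 2601, 2700),  # gap 1500 to first
        GenomicInterval("c", 27_701, 27_800),  # gap 25000 to second
    ]
    prof = inter_dmr_distances(dmrs)
    assert dict(zip(prof.bin_labels, prof.bin_counts)) == {(1, 1000): 2, (2, 10_000): 1}
    # overlapping -> distance 0 bin
    prof0 = inter_dmr_distances([GenomicInterval("c", 1, 100), GenomicInterval("c", 50, 150)])
    assert prof0.bin_labels == [(0, 0)]
    # random set vs all-pairs brute force
    rng = np.random.default_rng(12)
    rand = []
    for _ in range(200):
        s = int(rng.integers(1, 1_000_000))
        rand.append(GenomicInterval(f"c{rng.integers(1, 4)}", s, s + int(rng.integers(50, 500))))
    prof_r = inter_dmr_distances(rand)
    brute = []
    for iv in rand:
        others = [o for o in rand if o.chrom == iv.chrom and o is not iv]
        if others:
            brute.append(min(iv.distance_to(o) for o in others))
    assert sorted(prof_r.distances.tolist()) == sorted(brute)


def _gene(chrom, start, end, strand, gid="g1"):
    return GeneModel(gid, gid.upper(), GenomicInterval(chrom, start, end), strand,
                     exons=[GenomicInterval(chrom, start, end)])


def test_tss_distance_sign_conventions():
    plus = _gene("c", 10_000, 20_000, "+")
    prof = tss_distances([GenomicInterval("c", 9985, 9995)], [plus])  # midpoint 9990
    assert prof.distances.tolist() == [-10.0]
    minus = _gene("c", 2_000, 10_000, "-")  # TSS at 10000
    prof2 = tss_distances([GenomicInterval("c", 9985, 9995)], [minus])
    assert prof2.distances.tolist() == [10.0]


def test_tss_nearest_matches_brute_force():
    rng = np.random.default_rng(21)
    genes = []
    for i in range(50):
        s = int(rng.integers(1000, 5_000_000))
        genes.append(_gene("c", s, s + 2000, "+" if i % 2 else "-", gid=f"g{i}"))
    dmrs = []
    for _ in range(300):
        s = int(rng.integers(1, 5_000_000))
        dmrs.append(GenomicInterval("c", s, s + 200))
    prof = tss_distances(dmrs, genes)
    for iv, d in zip(dmrs, prof.distances):
        mid = iv.midpoint
        best = min(abs(mid - g.tss) for g in genes)
        assert abs(d) == pytest.approx(best)
    assert prof.bin_counts.sum() == len(prof.distances)


def test_dmr_without_genes_on_chromosome_is_flagged():
    prof = tss_distances(
        [GenomicInterval("other", 100, 200), GenomicInterval("c", 100, 200)],
        [_gene("c", 1000, 3000, "+")],
    )
    assert prof.unplaced == ["other:100-200"]
    assert len(prof.distances) == 1


def test_mode_detection_spike_trimodal_uniform():
    from gbsmedip.context import DistanceProfile

    def profile_from_counts(counts, bin_width=5000.0, origin=-100_000):
        n = len(counts)
        centers = np.arange(n) * bin_width + origin
        half = bin_width / 2
        return DistanceProfile(
            distances=np.repeat(centers, counts),
            kind="linear",
            bin_labels=[(int(c - half), int(c + half)) for c in centers],
            bin_counts=np.array(counts),
            bin_centers=centers,
        )

    spike = [0] * 41
    spike[10] = 50
    modes = detect_modes(profile_from_counts(spike))
    assert len(modes) == 1 and modes[0].bin_index == 10

    # trimodal mixture at -10 kb / 0 / +20 kb; 2.5-kb bins keep the first
    # two components more than two bins apart so smoothing resolves them
    rng = np.random.default_rng(14)
    comp = np.concatenate(
        [
            rng.normal(-10_000, 1000, 300),
            rng.normal(0, 1000, 400),
            rng.normal(20_000, 1000, 300),
        ]
    )
    edges = np.arange(-101_250, 103_750, 2500)
    counts, _ = np.histogram(comp, bins=edges)
    prof = profile_from_counts(counts.tolist(), bin_width=2500.0, origin=-100_000)
    modes = detect_modes(prof)
    centers = sorted(m.center for m in modes)
    assert len(modes) == 3
    assert centers[0] == pytest.approx(-10_000, abs=1250)
    assert abs(centers[1]) <= 1250
    assert centers[2] == pytest.approx(20_000, abs=1250)

    assert detect_modes(profile_from_counts([10] * 41)) == []


def test_histogram_correlation_properties():
    from gbsmedip.context import DistanceProfile

    def prof(counts):
        counts = np.array(counts)
        return DistanceProfile(
            distances=np.empty(0),
            kind="linear",
            bin_labels=list(range(len(counts))),
            bin_counts=counts,
            bin_centers=np.arange(len(counts), dtype=float),
        )

    a = prof([1, 5, 20, 5, 1])
    assert histogram_correlation(a, prof([1, 5, 20, 5, 1])) == pytest.approx(1.0)
    assert histogram_correlation(prof([1, 2, 3, 4, 5]), prof([5, 4, 3, 2, 1])) < 0
    with pytest.raises(ValueError, match="zero variance"):
        histogram_correlation(a, prof([3, 3, 3, 3, 3]))
    with pytest.raises(ValueError, match="binning"):
        histogram_correlation(a, prof([1, 2, 3]))


def test_histogram_self_similarity_between_samples():
    rng = np.random.default_rng(15)
    edges = np.arange(-100_000, 105_000, 5000)

    def draw():
        comp = np.concatenate(
            [
                rng.normal(-10_000, 3000, 150),
                rng.normal(0, 3000, 200),
                rng.normal(20_000, 3000, 150),
            ]
        )
        counts, _ = np.histogram(np.clip(comp, -99_999, 99_999), bins=edges)
        from gbsmedip.context import DistanceProfile

        return DistanceProfile(
            distances=comp,
            kind="linear",
            bin_labels=list(range(len(counts))),
            bin_counts=counts,
            bin_centers=(edges[:-1] + edges[1:]) / 2,
        )

    assert histogram_correlation(draw(), draw()) >= 0.9


def _annotation_gene():
    # gene 10000-20000 on + strand: exons 10000-12000 / 15000-16000 / 19000-20000
    chrom = "c"
    exons = [
        GenomicInterval(chrom, 10_000, 12_000),
        GenomicInterval(chrom, 15_000, 16_000),
        GenomicInterval(chrom, 19_000, 20_000),
    ]
    return GeneModel(
        "g1",
        "G1",
        GenomicInterval(chrom, 10_000, 20_000),
        "+",
        exons=exons,
        utr5=[GenomicInterval(chrom, 10_000, 10_400)],
        utr3=[GenomicInterval(chrom, 19_600, 20_000)],
    )


def test_annotation_categories():
    gene = _annotation_gene()
    intron = annotate_feature(GenomicInterval("c", 13_000, 13_100), [gene])
    assert intron.category == "intron" and intron.label == "intron"
    # spanning exon/intron boundary: compound coding label
    span = annotate_feature(GenomicInterval("c", 15_500, 17_000), [gene])
    assert span.label == "coding sequence, intron"
    assert span.category == "coding sequence"
    utr5 = annotate_feature(GenomicInterval("c", 10_100, 10_200), [gene])
    assert utr5.category == "5 prime UTR"
    inter = annotate_feature(GenomicInterval("c", 500_000, 500_100), [gene])
    assert inter.category == "intergenic" and inter.gene_ids == []


def test_upstream_annotation_within_flank():
    """A DMR 1,994 bp 5' of a TSS falls in 'upstream gene' at 5-kb flank."""
    gene = _annotation_gene()  # TSS at 10000, + strand
    dmr = GenomicInterval("c", 7_907, 8_006)  # ends 1,994 bp before the TSS
    ann = annotate_feature(dmr, [gene], flank=5_000)
    assert ann.category == "upstream gene"
    far = annotate_feature(GenomicInterval("c", 1_000, 1_100), [gene], flank=5_000)
    assert far.category == "intergenic"


def test_downstream_annotation_strand_aware():
    minus = GeneModel(
        "g2",
        "G2",
        GenomicInterval("c", 50_000, 60_000),
        "-",
        exons=[GenomicInterval("c", 50_000, 60_000)],
    )
    # 3' end of a - strand gene is its interval start
    ann = annotate_feature(GenomicInterval("c", 48_000, 48_100), [minus], flank=5_000)
    assert ann.category == "downstream gene"
    up = annotate_feature(GenomicInterval("c", 61_000, 61_100), [minus], flank=5_000)
    assert up.category == "upstream gene"


def test_every_dmr_gets_exactly_one_primary_category(small_dataset):
    _, genome, genes, data = small_dataset
    rng = np.random.default_rng(2)
    cats = set()
    for _ in range(200):
        chrom = genome.names[int(rng.integers(0, len(genome.names)))]
        s = int(rng.integers(1, genome.length(chrom) - 300))
        ann = annotate_feature(GenomicInterval(chrom, s, s + 250), genes)
        from gbsmedip.context import CATEGORY_PRECEDENCE

        assert ann.category in CATEGORY_PRECEDENCE
        cats.add(ann.category)
    assert "intergenic" in cats  # sanity: toy genome is mostly intergenic
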