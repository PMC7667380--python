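import numpy as np
import pytest
from scipy import stats

from gbsmedip.digest import digest, size_select
from gbsmedip.dmr import test_windows as window_test
from gbsmedip.normalize import tmm_factors
from gbsmedip.simulate import (
    ChromSpec,
    SimulationConfig,
    generate_genome,
    plant_genes,
    plant_truth,
    simulate_counts,
    simulate_dataset,
)


SMALL = [
    ChromSpec("chr1", 300_000, "macro"),
    ChromSpec("chr11", 150_000, "micro"),
    ChromSpec("chrZ", 100_000, "sexZ"),
]


def test_genome_deterministic_under_seed():
    cfg = SimulationConfig(seed=8, chromosomes=SMALL)
    a = generate_genome(cfg)
    b = generate_genome(cfg)
    assert all(a.sequence(n) == b.sequence(n) for n in a.names)
    c = generate_genome(SimulationConfig(seed=9, chromosomes=SMALL))
    assert c.sequence("chr1") != a.sequence("chr1")


def test_zero_psti_density_means_no_sites():
    cfg = SimulationConfig(
        seed=1,
        chromosomes=[
            ChromSpec("a", 100_000, "macro", cpg_density=0.02, psti_density=0.0),
            ChromSpec("b", 50_000, "micro"),
        ],
    )
    g = generate_genome(cfg)
    assert g.sequence("a").count("CTGCAG") == 0


def test_cpg_density_within_20_percent():
    cfg = SimulationConfig(
        seed=2,
        chromosomes=[
            ChromSpec("a", 100_000, "macro", cpg_density=0.02),
            ChromSpec("b", 50_000, "micro", cpg_density=0.005),
        ],
    )
    g = generate_genome(cfg)
    n = g.sequence("a").count("CG")
    assert 0.8 * 2000 <= n <= 1.2 * 2000
    n_b = g.sequence("b").count("CG")
    assert 0.8 * 250 <= n_b <= 1.2 * 250


def test_psti_density_within_20_percent():
    cfg = SimulationConfig(seed=3, chromosomes=[ChromSpec("a", 200_000, "macro"), SMALL[1]])
    g = generate_genome(cfg)
    n = g.sequence("a").count("CTGCAG")
    assert 0.8 * 500 <= n <= 1.2 * 500


def test_too_short_chromosome_rejected():
    with pytest.raises(ValueError, match="2 kb"):
        generate_genome(SimulationConfig(chromosomes=[ChromSpec("a", 1500), ChromSpec("b", 5000)]))


def test_genes_non_overlapping_both_strands():
    g = generate_genome(SimulationConfig(seed=4, chromosomes=SMALL))
    genes = plant_genes(g, 40, seed=4)
    assert len(genes) == 40
    assert {gene.strand for gene in genes} == {"+", "-"}
    assert all(len(gene.exons) >= 1 for gene in genes)
    # interval sweep: sorted genes on each chromosome must not overlap
    by_chrom = {}
    for gene in genes:
        by_chrom.setdefault(gene.chrom, []).append(gene.interval)
    for ivs in by_chrom.values():
        ivs = sorted(ivs, key=lambda iv: iv.start)
        for prev, cur in zip(ivs, ivs[1:]):
            assert prev.end < cur.start
    assert plant_genes(g, 40, seed=4)[0].interval == genes[0].interval  # deterministic


def test_tss_consistent_with_strand():
    g = generate_genome(SimulationConfig(seed=5, chromosomes=SMALL))
    (gene,) = plant_genes(g, 1, seed=5)
    if gene.strand == "+":
        assert gene.tss == gene.interval.start
    else:
        assert gene.tss == gene.interval.end


def test_counts_deterministic_and_labelled():
    cfg = SimulationConfig(seed=6, chromosomes=SMALL, n_s=4, n_c=4, n_true_dmrs=5)
    _, _, d1 = simulate_dataset(cfg)
    _, _, d2 = simulate_dataset(cfg)
    assert np.array_equal(d1.medip.counts, d2.medip.counts)
    assert [s.group for s in d1.medip.samples] == ["S"] * 4 + ["C"] * 4
    assert d1.truth.dmrs == d2.truth.dmrs


def test_null_simulation_pvalues_uniform():
    """No planted effects: two-group p-values look Uniform(0,1) by KS."""
    chroms = [
        ChromSpec("chr1", 1_200_000, "macro"),
        ChromSpec("chr2", 600_000, "macro"),
        ChromSpec("chr11", 300_000, "micro"),
    ]
    cfg = SimulationConfig(
        seed=3, depth=60.0, n_s=8, n_c=6, chromosomes=chroms, n_true_dmrs=1, n_genes=5
    )
    genome, _, data = simulate_dataset(cfg)
    planted = {iv.region_string() for iv, _ in data.truth.dmrs}
    tab = window_test(data.medip)
    keep = [i for i, w in enumerate(data.medip.windows) if w.region_string() not in planted]
    p = tab["p_value"].to_numpy()[keep][:2000]
    assert len(p) >= 1500
    assert stats.kstest(p, "uniform").pvalue > 0.01


def test_poisson_limit_variance_tracks_mean():
    cfg = SimulationConfig(
        seed=7, chromosomes=SMALL, n_s=30, n_c=30, phi=0.0, libsize_log_sd=0.0,
        n_true_dmrs=1, depth=30.0,
    )
    _, _, data = simulate_dataset(cfg)
    planted = {iv.region_string() for iv, _ in data.truth.dmrs}
    keep = [i for i, w in enumerate(data.medip.windows) if w.region_string() not in planted]
    counts = data.medip.counts[keep]
    m = counts.mean(axis=1)
    v = counts.var(axis=1, ddof=1)
    big = m > 5
    # across fragments, variance/mean ratio concentrates near 1
    ratio = np.median(v[big] / m[big])
    assert 0.85 <= ratio <= 1.15


def test_planted_effect_ratio_within_monte_carlo_band():
    """+2 log2FC at depth 30, 8v8: group-mean ratio lands in [3.0, 5.3]."""
    cfg = SimulationConfig(
        seed=7, depth=30.0, n_s=8, n_c=8, n_true_dmrs=5, effect_sizes=[2.0]
    )
    _, _, data = simulate_dataset(cfg)
    idx_s = data.medip.group_indices("S")
    idx_c = data.medip.group_indices("C")
    for iv, _ in data.truth.dmrs:
        rows = [i for i, f in enumerate(data.fragments.fragments) if f.overlaps(iv)]
        ratio = data.medip.counts[rows][:, idx_s].mean() / data.medip.counts[rows][:, idx_c].mean()
        assert 3.0 <= ratio <= 5.3


def test_library_size_variation_recoverable():
    cfg = SimulationConfig(seed=4, depth=30.0, n_s=8, n_c=8, n_true_dmrs=1)
    _, _, data = simulate_dataset(cfg)
    assert len(data.fragments) >= 2000
    norm = tmm_factors(data.medip)
    truth = np.array([data.truth.library_size_factors[s] for s in data.medip.sample_ids])
    rho = stats.spearmanr(norm.effective_sizes, truth).statistic
    assert rho >= 0.9


def test_placement_bias_favors_configured_classes():
    cfg = SimulationConfig(
        seed=10,
        chromosomes=SMALL,
        n_true_dmrs=40,
        placement_weights={"macro": 0.0, "micro": 1.0, "sexZ": 1.0},
    )
    genome = generate_genome(cfg)
    frags = size_select(digest(genome), cfg.size_min, cfg.size_max)
    truth = plant_truth(genome, frags, cfg)
    classes = {genome.chrom_class(iv.chrom) for iv, _ in truth.dmrs}
    assert "macro" not in classes


def test_input_channel_carries_cnv_not_methylation():
    from gbsmedip.simulate import CNVSpec

    cfg = SimulationConfig(
        seed=11, chromosomes=SMALL, n_s=6, n_c=6, with_input=True,
        cnv=CNVSpec(n=1, fold=3.0, length=3_000), n_true_dmrs=3,
    )
    _, _, data = simulate_dataset(cfg)
    assert data.input is not None
    assert all(s.channel == "input" for s in data.input.samples)
    (cnv_iv, fold) = data.truth.cnvs[0]
    rows = [i for i, f in enumerate(data.fragments.fragments) if f.overlaps(cnv_iv)]
    if rows:
        s_mean = data.input.counts[rows][:, data.input.group_indices("S")].mean()
        c_mean = data.input.counts[rows][:, data.input.group_indices("C")].mean()
        assert s_mean / c_mean > 1.5  # the 3x fold shows in S inputs
    # methylation effect absent from inputs at planted DMRs not under the CNV
    clean = [
        i
        for iv, _ in data.truth.dmrs
        for i, f in enumerate(data.fragments.fragments)
        if f.overlaps(iv) and not f.overlaps(cnv_iv)
    ]
    s_in = data.input.counts[clean][:, data.input.group_indices("S")].mean()
    c_in = data.input.counts[clean][:, data.input.group_indices("C")].mean()
    assert 0.6 <= s_in / c_in <= 1.6
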