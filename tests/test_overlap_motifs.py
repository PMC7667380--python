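import numpy as np
import pytest

from gbsmedip.intervals import GenomeModel, GenomicInterval
from gbsmedip.motifs import PWM, motif_selection, pwm_scan, read_pwms, reverse_complement
from gbsmedip.overlap import overlap_counts, permutation_overlap_test


GENOME = GenomeModel([("c1", 1_000_000), ("c2", 500_000)])


def _rand_set(rng, n, chroms=("c1", "c2"), wmax=500):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        s = int(rng.integers(1, GENOME.length(chrom) - wmax))
        out.append(GenomicInterval(chrom, s, s + int(rng.integers(50, wmax))))
    return out


def test_identical_sets_fully_overlap():
    rng = np.random.default_rng(1)
    a = _rand_set(rng, 30)
    v = overlap_counts(a, list(a))
    assert v.a_only == 0 and v.b_only == 0
    assert v.pair_count >= len(a)


def test_gap_boundary():
    a = [GenomicInterval("c1", 1000, 1100)]
    b = [GenomicInterval("c1", 2001, 2100)]  # gap = 900
    assert overlap_counts(a, b, max_gap=1000).merged_overlaps == 1
    assert overlap_counts(a, b, max_gap=899).merged_overlaps == 0
    assert overlap_counts(a, b, max_gap=0).merged_overlaps == 0


def test_overlap_counts_match_brute_force():
    rng = np.random.default_rng(2)
    for _ in range(10):
        a = _rand_set(rng, 40)
        b = _rand_set(rng, 40)
        gap = int(rng.choice([0, 100, 1000]))
        v = overlap_counts(a, b, max_gap=gap)
        brute_pairs = sum(
            1
            for x in a
            for y in b
            if x.chrom == y.chrom and y.start - x.end - 1 <= gap and x.start - y.end - 1 <= gap
        )
        assert v.pair_count == brute_pairs
        assert v.a_only == sum(
            1
            for x in a
            if not any(
                y.chrom == x.chrom and y.start - x.end - 1 <= gap and x.start - y.end - 1 <= gap
                for y in b
            )
        )


def test_merged_component_count_is_symmetric():
    rng = np.random.default_rng(3)
    a, b = _rand_set(rng, 50), _rand_set(rng, 50)
    assert (
        overlap_counts(a, b, max_gap=500).merged_overlaps
        == overlap_counts(b, a, max_gap=500).merged_overlaps
    )


def test_permutation_p_never_zero_and_dense_self_overlap():
    rng = np.random.default_rng(4)
    a = _rand_set(rng, 40, wmax=200)
    res = permutation_overlap_test(a, list(a), GENOME, n=100, seed=5)
    assert res.p_value == pytest.approx(1 / 101)
    assert (res.permuted_overlaps < res.observed.merged_overlaps).all()


def test_empty_set_gives_p_one():
    rng = np.random.default_rng(6)
    b = _rand_set(rng, 10)
    res = permutation_overlap_test([], b, GENOME, n=50, seed=1)
    assert res.observed.merged_overlaps == 0
    assert res.p_value == 1.0


def test_permutation_test_calibration_on_null_sets():
    """Random vs random: rejection rate at 0.05 stays near nominal.

    The sets are dense enough that the overlap count statistic takes many
    values and the permutation p-value is close to continuous.
    """
    rng = np.random.default_rng(7)
    rejections = 0
    n_rep = 200
    for rep in range(n_rep):
        a = _rand_set(rng, 150, wmax=1000)
        b = _rand_set(rng, 150, wmax=1000)
        res = permutation_overlap_test(a, b, GENOME, n=100, max_gap=0, seed=1000 + rep)
        if res.p_value <= 0.05:
            rejections += 1
    assert 0.02 <= rejections / n_rep <= 0.09


def test_interval_longer_than_chromosome_rejected():
    a = [GenomicInterval("c1", 1, 100)]
    b = [GenomicInterval("c2", 1, 600_000)]
    g = GenomeModel([("c1", 1_000_000), ("c2", 500_000)])
    with pytest.raises(ValueError, match="longer than chromosome"):
        permutation_overlap_test(a, b, g, n=5, seed=0)


# ---------------------------------------------------------------- motifs
def _point_mass_pwm(consensus, threshold=None):
    rows = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        mat[i, rows[b]] = 1.0
    pwm = PWM("pm", mat)
    if threshold is None:
        pwm.threshold = pwm.max_score() - 1e-9
    else:
        pwm.threshold = threshold
    return pwm


def test_consensus_single_forward_hit():
    pwm = _point_mass_pwm("TACGT")
    hits = pwm_scan("AAAATACGTAAAA", pwm)
    fwd = [h for h in hits if h.strand == "+"]
    assert len(fwd) == 1 and fwd[0].position == 5
    assert fwd[0].score == pytest.approx(pwm.max_score())


def test_reverse_complement_strand_symmetry():
    pwm = _point_mass_pwm("TACGT")
    seq = "AAAATACGTAAAA"
    rc = reverse_complement(seq)
    fwd = [h for h in pwm_scan(seq, pwm) if h.strand == "+"]
    rev = [h for h in pwm_scan(rc, pwm) if h.strand == "-"]
    assert len(fwd) == len(rev) == 1
    assert fwd[0].score == pytest.approx(rev[0].score)


def test_scores_match_brute_force_oracle():
    rng = np.random.default_rng(8)
    mat = rng.dirichlet(np.ones(4), size=6)
    pwm = PWM("r", mat)
    seq = "".join(rng.choice(list("ACGTN"), size=80, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
    lo = pwm.log_odds()
    idx = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
    hits = {(h.position, h.strand): h.score for h in pwm_scan(seq, pwm, threshold=-np.inf)}
    for off in range(len(seq) - 6 + 1):
        expected = sum(lo[j, idx[seq[off + j]]] for j in range(6))
        assert hits[(off + 1, "+")] == pytest.approx(expected, abs=1e-9)


def test_short_sequence_yields_no_hits():
    pwm = _point_mass_pwm("TACGT")
    assert pwm_scan("ACG", pwm) == []


def test_read_pwms_jaspar_like(tmp_path):
    p = tmp_path / "m.txt"
    p.write_text(
        ">M1 First\nA [ 4 19 0 ]\nC [16 0 20]\nG [ 0 1 0 ]\nT [ 0 0 0 ]\n"
        ">M2\nA 1 0\nC 0 1\nG 0 0\nT 0 0\n"
    )
    pwms = read_pwms(p)
    assert [m.motif_id for m in pwms] == ["M1", "M2"]
    assert len(pwms[0]) == 3
    assert np.allclose(pwms[0].matrix.sum(axis=1), 1.0)


def test_motif_selection_criteria():
    rng = np.random.default_rng(9)
    consensus = "TACGTA"
    pwm = _point_mass_pwm(consensus)

    def rand_seq(n):
        return "".join(rng.choice(list("AT"), size=n))  # consensus-free background

    # 60% of DMRs carry the consensus -> passes the 50% majority criterion
    seqs = {}
    for i in range(10):
        body = rand_seq(150)
        if i < 6:
            body = body[:70] + consensus + body[76:]
        seqs[f"d{i}"] = body
    report = motif_selection(seqs, [pwm])
    row = report.table.iloc[0]
    assert row["frac_with_significant_hit"] == pytest.approx(0.6)
    assert row["pass_majority"]

    # absent motif fails both criteria
    absent = {f"d{i}": rand_seq(150) for i in range(10)}
    row2 = motif_selection(absent, [pwm]).table.iloc[0]
    assert not row2["pass_majority"] and not row2["pass_presence"]

    # exactly 50% passes (inclusive)
    half = {}
    for i in range(10):
        body = rand_seq(150)
        if i < 5:
            body = body[:10] + consensus + body[16:]
        half[f"d{i}"] = body
    assert motif_selection(half, [pwm]).table.iloc[0]["pass_majority"]


def test_criterion_a_vacuous_without_long_dmrs():
    pwm = _point_mass_pwm("TACGTA")
    seqs = {"short": "ATATATATAT"}
    report = motif_selection(seqs, [pwm])
    row = report.table.iloc[0]
    assert row["criterion_a_vacuous"] and row["pass_presence"]
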