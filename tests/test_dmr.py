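import numpy as np
import pytest
from scipy import stats

from gbsmedip.dmr import (
    call_adjw_dmrs,
    exact_p_from_sums,
    input_cnv_filter,
    nb_exact_test,
    test_rois as roi_test,
    test_windows as window_test,
)
from gbsmedip.windows import assign_counts
from tests.conftest import make_matrix


def _enumeration_oracle(ss, sc, ns, nc, phi):
    """Brute-force two-sided conditional p by high-precision enumeration."""
    import mpmath as mp

    s = ss + sc
    if s == 0:
        return 1.0
    with mp.workdps(40):
        if phi <= 1e-10:
            p = mp.mpf(ns) / (ns + nc)
            pmf = [mp.binomial(s, x) * p**x * (1 - p) ** (s - x) for x in range(s + 1)]
        else:
            a, b = mp.mpf(ns) / phi, mp.mpf(nc) / phi
            pmf = [
                mp.binomial(s, x) * mp.beta(x + a, s - x + b) / mp.beta(a, b)
                for x in range(s + 1)
            ]
        total = sum(pmf)
        pmf = [v / total for v in pmf]
        obs = pmf[ss]
        pval = sum(v for v in pmf if v <= obs * (1 + mp.mpf("1e-12")))
        return float(min(1, pval))


def test_balanced_sums_give_p_one():
    assert exact_p_from_sums(50, 50, 4, 4, 0.2) == 1.0
    assert exact_p_from_sums(0, 0, 4, 4, 0.2) == 1.0  # untestable convention


def test_poisson_limit_small_case():
    """phi->0, 1v1, sums 3 vs 0: Binomial(3, 1/2) two-sided -> 0.25."""
    assert exact_p_from_sums(3, 0, 1, 1, 0.0) == pytest.approx(0.25)


def test_exact_test_matches_enumeration_oracle():
    rng = np.random.default_rng(13)
    for _ in range(150):
        ss, sc = (int(v) for v in rng.integers(0, 300, 2))
        ns, nc = (int(v) for v in rng.integers(1, 12, 2))
        phi = float(rng.choice([0.0, 0.01, 0.1, 0.3, 1.0]))
        assert exact_p_from_sums(ss, sc, ns, nc, phi) == pytest.approx(
            _enumeration_oracle(ss, sc, ns, nc, phi), abs=1e-12
        )


def test_group_swap_symmetry():
    for ss, sc in [(10, 40), (0, 7), (33, 21)]:
        assert exact_p_from_sums(ss, sc, 5, 5, 0.2) == pytest.approx(
            exact_p_from_sums(sc, ss, 5, 5, 0.2), abs=1e-12
        )


def test_nb_exact_test_scales_counts_to_common_size():
    # sample 2 has double the library: equal underlying rates -> p = 1
    p = nb_exact_test(
        np.array([10.0]), np.array([20.0]), 0.0, np.array([100.0]), np.array([200.0])
    )
    assert p == 1.0


def test_window_table_properties():
    rng = np.random.default_rng(30)
    counts = rng.poisson(30, size=(300, 12))
    m = make_matrix(counts, 6, 6)
    tab = window_test(m)
    assert ((tab["p_value"] >= 0) & (tab["p_value"] <= 1)).all()
    ok = tab["testable"]
    assert (tab.loc[ok, "q_value"] >= tab.loc[ok, "p_value"] - 1e-12).all()
    assert (tab.loc[ok, "q_value"] <= 1).all()
    # q monotone in p
    sub = tab[ok].sort_values("p_value")
    assert (np.diff(sub["q_value"]) >= -1e-12).all()


def test_equal_group_means_give_no_dmrs():
    counts = np.tile(np.array([[30], [40], [25]]), (1, 8))
    m = make_matrix(counts, 4, 4)
    dmrs, _ = call_adjw_dmrs(m, phi=0.1)
    assert all(len(v) == 0 for v in dmrs.values())


def test_planted_adjacent_windows_merge_into_one_dmr():
    """+2 log2FC over 3 adjacent windows at depth 30, 8v8 -> one 300-bp DMR."""
    rng = np.random.default_rng(99)
    n_win, n_s, n_c = 60, 8, 8
    counts = rng.poisson(30, size=(n_win, n_s + n_c))
    counts[10:13, :n_s] = rng.poisson(120, size=(3, n_s))  # 4x in S
    cpg = np.full(n_win, 2)
    m = make_matrix(counts, n_s, n_c, cpg=cpg)
    dmrs, tab = call_adjw_dmrs(m)
    found = [d for d in dmrs[0.005] if d.interval.start == 1001 and d.interval.end == 1300]
    assert len(found) == 1
    d = found[0]
    assert d.direction == "hyper" and d.log2fc > 1
    assert d.cpg_count == 6
    assert len(d.component_windows) == 3
    assert d.p_value <= 0.005


def test_merging_requires_same_direction():
    rng = np.random.default_rng(7)
    n_s = n_c = 8
    counts = rng.poisson(30, size=(40, n_s + n_c))
    counts[20, :n_s] = rng.poisson(150, size=n_s)  # hyper
    counts[21, n_s:] = rng.poisson(150, size=n_c)  # hypo (adjacent)
    m = make_matrix(counts, n_s, n_c)
    dmrs, _ = call_adjw_dmrs(m)
    starts = sorted(d.interval.start for d in dmrs[0.05] if 1900 <= d.interval.start <= 2200)
    assert len(starts) == 2  # not merged across the direction flip


def test_hyper_records_have_positive_log2fc(small_dataset):
    _, genome, _, data = small_dataset
    dmrs, _ = call_adjw_dmrs(data.medip)
    for recs in dmrs.values():
        for d in recs:
            assert (d.direction == "hyper") == (d.log2fc > 0)


def test_roi_untestable_regions_excluded_from_bh():
    rng = np.random.default_rng(40)
    counts = rng.poisson(20, size=(30, 8))
    counts[5] = 0  # untestable region
    m = make_matrix(counts, 4, 4)
    recs, tab = roi_test(m, threshold=0.05)
    assert not tab.loc[5, "testable"]
    assert np.isnan(tab.loc[5, "q_value"])
    assert tab.loc[5, "p_value"] == 1.0


def test_roi_single_region_equal_sums_p_one():
    counts = np.tile(np.array([[25]]), (1, 8))
    m = make_matrix(counts, 4, 4)
    # single window: dispersion not estimable -> supply phi
    recs, tab = roi_test(m, threshold=0.05, phi=0.1)
    assert tab["p_value"].iloc[0] == 1.0
    assert recs == []


def test_input_filter_identity_when_inputs_equal(small_dataset):
    """Equal inputs across groups leave the DMR list unchanged."""
    _, genome, _, data = small_dataset
    dmrs, _ = call_adjw_dmrs(data.medip, thresholds=(0.005,))
    base = dmrs[0.005]
    counts = np.tile(np.array([[30]] * data.medip.n_windows), (1, 16))
    input_m = make_matrix(np.zeros((0, 16), dtype=int), 8, 8)  # placeholder
    from gbsmedip.windows import WindowCountMatrix, SampleInfo

    input_m = WindowCountMatrix(
        data.medip.windows,
        counts,
        [SampleInfo(f"I{i}", "S" if i < 8 else "C", "input") for i in range(16)],
    )
    kept, removed, _ = input_cnv_filter(base, input_m)
    assert kept == base and removed == []


def test_input_filter_removes_cnv_backed_dmr():
    rng = np.random.default_rng(50)
    n_s = n_c = 8
    counts = rng.poisson(30, size=(40, n_s + n_c))
    counts[12, :n_s] = rng.poisson(120, size=n_s)  # looks like a DMR
    m = make_matrix(counts, n_s, n_c)
    dmrs, _ = call_adjw_dmrs(m, thresholds=(0.05,))
    assert any(d.interval.start == 1201 for d in dmrs[0.05])
    # the input channel shows the same 3x fold: a copy-number artifact
    in_counts = rng.poisson(20, size=(40, n_s + n_c))
    in_counts[12, :n_s] = rng.poisson(60, size=n_s)
    from gbsmedip.windows import WindowCountMatrix, SampleInfo

    input_m = WindowCountMatrix(
        m.windows,
        in_counts,
        [SampleInfo(f"I{i}", "S" if i < n_s else "C", "input") for i in range(n_s + n_c)],
    )
    kept, removed, _ = input_cnv_filter(dmrs[0.05], input_m)
    assert any(d.interval.start == 1201 for d in removed)
    assert not any(d.interval.start == 1201 for d in kept)
    assert input_cnv_filter([], input_m)[0] == []


def test_input_filter_skipped_without_input_channel():
    kept, removed, tab = input_cnv_filter([], None)
    assert kept == [] and removed == [] and tab is None
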