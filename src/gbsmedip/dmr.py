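"""Differential-methylation testing: the NB exact test and both DMR routes.

The test is a conditional exact test on group count sums.  Counts are
first scaled to a common effective library size; within-group sums
``s_S, s_C`` are then compared conditionally on ``s = s_S + s_C``.  If each
sample's count is negative binomial with common dispersion ``phi``, the
group sum of ``n`` samples is NB with size parameter ``r = n / phi``, and
conditional on the total the S-group sum follows a beta-binomial
(Dirichlet-multinomial with two categories):

    P(S_S = x | s) = C(x + r_S - 1, x) C(s - x + r_C - 1, s - x)
                     / C(s + r_S + r_C - 1, s)

which reduces to Binomial(s, n_S / (n_S + n_C)) as ``phi -> 0``.  The
two-sided p-value sums the probabilities of all outcomes no more likely
than the observed one — the standard exact-test convention, checkable by
direct enumeration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval
from .normalize import NormalizationResult, estimate_dispersion, normalized_counts, tmm_factors
from .windows import WindowCountMatrix, _round_half_up

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.05, 0.005, 0.0005)
_PHI_POISSON_LIMIT = 1e-10
_TIE_REL_TOL = 1e-12


@dataclass
class DMRRecord:
    """A tested (possibly merged) region with its differential statistics."""

    interval: GenomicInterval
    method: str  # "ADJW" or "ROI"
    log2fc: float
    p_value: float
    q_value: float
    cpg_count: int | None = None
    direction: str = ""  # "hyper" or "hypo" (S relative to C)
    component_windows: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in ("ADJW", "ROI"):
            raise ValueError(f"method must be ADJW or ROI, got {self.method!r}")
        if not self.direction:
            self.direction = "hyper" if self.log2fc > 0 else "hypo"

    @property
    def width(self) -> int:
        return self.interval.width

    @property
    def cpg_percent(self) -> float | None:
        if self.cpg_count is None:
            return None
        return self.cpg_count / self.width * 100.0


def _log_binom(n: np.ndarray | float, k: np.ndarray | float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _conditional_pmf(s: int, r_s: float, r_c: float) -> np.ndarray:
    """P(S_S = x | s) for x = 0..s under the two-group Dirichlet-multinomial.

    Built by the stable ratio recurrence
    ``P(x+1)/P(x) = (x + r_s)(s - x) / ((x + 1)(s - x - 1 + r_c))``
    from the distribution's mode and normalized at the end, which keeps
    relative error near machine precision even for large ``s`` (a direct
    log-gamma evaluation loses ~1e-12 to cancellation there).
    """
    x = np.arange(s, dtype=float)
    ratios = (x + r_s) * (s - x) / ((x + 1.0) * (s - x - 1.0 + r_c))
    log_ratios = np.log(ratios)
    log_rel = np.concatenate([[0.0], np.cumsum(log_ratios)])
    log_rel -= log_rel.max()
    pmf = np.exp(log_rel)
    return pmf / pmf.sum()


def _binom_logpmf(x: np.ndarray, s: int, p: float) -> np.ndarray:
    return _log_binom(s, x) + x * np.log(p) + (s - x) * np.log1p(-p)


def exact_p_from_sums(s_s: int, s_c: int, n_s: int, n_c: int, phi: float) -> float:
    """Two-sided conditional exact p-value for group sums ``s_s`` vs ``s_c``.

    ``n_s`` and ``n_c`` are the group sizes; ``phi`` the common NB
    dispersion (0 gives the binomial limit).  ``s_s + s_c == 0`` returns 1
    (untestable by convention).
    """
    if s_s < 0 or s_c < 0:
        raise ValueError("group sums must be nonnegative")
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    s = s_s + s_c
    if s == 0:
        return 1.0
    if phi <= _PHI_POISSON_LIMIT:
        x = np.arange(s + 1)
        logpmf = _binom_logpmf(x, s, n_s / (n_s + n_c))
        logpmf -= logpmf.max()
        pmf = np.exp(logpmf)
        pmf /= pmf.sum()
    else:
        pmf = _conditional_pmf(s, n_s / phi, n_c / phi)
    obs = pmf[s_s]
    p = pmf[pmf <= obs * (1.0 + _TIE_REL_TOL)].sum()
    return float(min(p, 1.0))


def nb_exact_test(
    counts_s: np.ndarray,
    counts_c: np.ndarray,
    phi: float,
    effective_sizes_s: np.ndarray,
    effective_sizes_c: np.ndarray,
) -> float:
    """Exact test for one window given per-sample counts and library sizes.

    Counts are rescaled to the geometric mean effective size (rounded half
    up), summed within groups, and passed to the conditional exact test.
    """
    counts_s = np.asarray(counts_s, dtype=float)
    counts_c = np.asarray(counts_c, dtype=float)
    eff = np.concatenate([np.asarray(effective_sizes_s), np.asarray(effective_sizes_c)])
    common = np.exp(np.mean(np.log(eff)))
    scaled_s = _round_half_up(counts_s * common / np.asarray(effective_sizes_s))
    scaled_c = _round_half_up(counts_c * common / np.asarray(effective_sizes_c))
    return exact_p_from_sums(
        int(scaled_s.sum()), int(scaled_c.sum()), len(counts_s), len(counts_c), phi
    )


# ------------------------------------------------------------ window tests
def test_windows(
    matrix: WindowCountMatrix,
    norm: NormalizationResult | None = None,
    phi: float | None = None,
    pseudo_count: float = 0.5,
) -> pd.DataFrame:
    """Per-window differential test of S vs C.

    Returns a data frame with one row per window: coordinates, group mean
    normalized counts, ``log2fc`` (pseudo-count stabilized), ``p_value``,
    BH ``q_value`` over testable windows, and a ``testable`` flag (all-zero
    windows get p = 1 and are excluded from the BH denominator).
    """
    if norm is None:
        norm = tmm_factors(matrix)
    if phi is None:
        phi = estimate_dispersion(matrix, norm)
    idx_s = matrix.group_indices("S")
    idx_c = matrix.group_indices("C")
    if len(idx_s) == 0 or len(idx_c) == 0:
        raise ValueError("both groups must be present")
    eff = norm.effective_sizes
    common = np.exp(np.mean(np.log(eff)))
    scaled = _round_half_up(matrix.counts * (common / eff)[None, :])
    sums_s = scaled[:, idx_s].sum(axis=1)
    sums_c = scaled[:, idx_c].sum(axis=1)

    p_values = np.ones(matrix.n_windows)
    cache: dict[tuple[int, int], float] = {}
    n_s, n_c = len(idx_s), len(idx_c)
    for i, (ss, sc) in enumerate(zip(sums_s, sums_c)):
        key = (int(ss), int(sc))
        if key not in cache:
            cache[key] = exact_p_from_sums(key[0], key[1], n_s, n_c, phi)
        p_values[i] = cache[key]

    x = normalized_counts(matrix, norm)
    mean_s = x[:, idx_s].mean(axis=1)
    mean_c = x[:, idx_c].mean(axis=1)
    log2fc = np.log2((mean_s + pseudo_count) / (mean_c + pseudo_count))

    testable = (sums_s + sums_c) > 0
    q_values = np.full(matrix.n_windows, np.nan)
    if testable.any():
        _, q, _, _ = multipletests(p_values[testable], method="fdr_bh")
        q_values[testable] = q

    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in matrix.windows],
            "start": [w.start for w in matrix.windows],
            "end": [w.end for w in matrix.windows],
            "mean_norm_S": mean_s,
            "mean_norm_C": mean_c,
            "log2fc": log2fc,
            "p_value": p_values,
            "q_value": q_values,
            "testable": testable,
            "row_sum": matrix.counts.sum(axis=1),
            "cpg_count": (
                matrix.cpg_counts if matrix.cpg_counts is not None else np.full(matrix.n_windows, -1)
            ),
            "phi": phi,
        }
    )


def _merge_significant(
    table: pd.DataFrame,
    windows: list[GenomicInterval],
    threshold: float,
    method: str,
) -> list[DMRRecord]:
    sig = table.index[(table["p_value"] <= threshold) & table["testable"]].to_numpy()
    records: list[DMRRecord] = []
    run: list[int] = []

    def flush(run: list[int]) -> None:
        if not run:
            return
        sub = table.iloc[run]
        ivs = [windows[i] for i in run]
        weights = sub["row_sum"].to_numpy(dtype=float)
        if weights.sum() == 0:
            weights = np.ones(len(run))
        log2fc = float(np.average(sub["log2fc"], weights=weights))
        i_min = int(sub["p_value"].to_numpy().argmin())
        cpgs = None
        if (sub["cpg_count"] >= 0).all():
            cpgs = int(sub["cpg_count"].sum())
        records.append(
            DMRRecord(
                interval=GenomicInterval(ivs[0].chrom, ivs[0].start, ivs[-1].end),
                method=method,
                log2fc=log2fc,
                p_value=float(sub["p_value"].iloc[i_min]),
                q_value=float(sub["q_value"].iloc[i_min]),
                cpg_count=cpgs,
                component_windows=ivs,
            )
        )

    for i in sig:
        if run:
            prev = windows[run[-1]]
            cur = windows[i]
            same_dir = np.sign(table["log2fc"].iloc[i]) == np.sign(table["log2fc"].iloc[run[-1]])
            adjacent = prev.chrom == cur.chrom and cur.start == prev.end + 1
            if adjacent and same_dir:
                run.append(int(i))
                continue
            flush(run)
            run = []
        run.append(int(i))
    flush(run)
    return records


def call_adjw_dmrs(
    matrix: WindowCountMatrix,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    norm: NormalizationResult | None = None,
    phi: float | None = None,
) -> tuple[dict[float, list[DMRRecord]], pd.DataFrame]:
    """Adjacent-window route: test each window, then merge by threshold.

    For each p-value threshold, significant windows that are directly
    adjacent (zero gap) and change in the same direction are merged into a
    single DMR carrying the minimum component p-value, the count-weighted
    mean log2 fold-change and the summed CpG count.

    Returns ``(dmrs_by_threshold, window_table)``.
    """
    table = test_windows(matrix, norm=norm, phi=phi)
    out = {
        float(t): _merge_significant(table, matrix.windows, float(t), "ADJW")
        for t in thresholds
    }
    return out, table


def test_rois(
    region_matrix: WindowCountMatrix,
    threshold: float = 0.05,
    norm: NormalizationResult | None = None,
    phi: float | None = None,
) -> tuple[list[DMRRecord], pd.DataFrame]:
    """Region route: exact-test counts aggregated over preselected regions.

    ``region_matrix`` holds counts already aggregated per region (build it
    with :func:`gbsmedip.windows.assign_counts` over the ROI intervals).
    Regions with zero counts in every sample are flagged untestable and
    excluded from the BH denominator.  Returns the significant regions as
    ROI DMR records plus the full per-region table.
    """
    table = test_windows(region_matrix, norm=norm, phi=phi)
    records = []
    for i, row in table.iterrows():
        if row["testable"] and row["p_value"] <= threshold:
            iv = region_matrix.windows[i]
            cpg = int(row["cpg_count"]) if row["cpg_count"] >= 0 else None
            records.append(
                DMRRecord(
                    interval=iv,
                    method="ROI",
                    log2fc=float(row["log2fc"]),
                    p_value=float(row["p_value"]),
                    q_value=float(row["q_value"]),
                    cpg_count=cpg,
                )
            )
    return records, table


# ----------------------------------------------------------- input filter
def input_cnv_filter(
    dmrs: list[DMRRecord],
    input_matrix: WindowCountMatrix | None,
    alpha: float = 0.05,
) -> tuple[list[DMRRecord], list[DMRRecord], pd.DataFrame | None]:
    """Remove DMRs that coincide with copy-number differences in the inputs.

    The input channel (non-immunoprecipitated libraries) is tested S vs C
    with the same exact test; windows with input p <= ``alpha`` are
    CNV-suspect, and any DMR overlapping a suspect window by at least one
    base is removed.  Returns ``(kept, removed, input_table)``.  A missing
    input channel skips the filter (all DMRs kept, logged).
    """
    if input_matrix is None:
        logger.info("no input channel: CNV filter skipped")
        return list(dmrs), [], None
    table = test_windows(input_matrix)
    suspect = [
        input_matrix.windows[i]
        for i in table.index[(table["p_value"] <= alpha) & table["testable"]]
    ]
    kept, removed = [], []
    for dmr in dmrs:
        if any(dmr.interval.overlaps(w) for w in suspect):
            removed.append(dmr)
        else:
            kept.append(dmr)
    return kept, removed, table


def dmrs_to_frame(dmrs: list[DMRRecord]) -> pd.DataFrame:
    """Tabulate DMR records in the report layout (Location, Width, ...)."""
    return pd.DataFrame(
        {
            "location": [d.interval.region_string() for d in dmrs],
            "width": [d.width for d in dmrs],
            "method": [d.method for d in dmrs],
            "log2fc": [d.log2fc for d in dmrs],
            "p_value": [d.p_value for d in dmrs],
            "fdr_q_value": [d.q_value for d in dmrs],
            "cpg_count": [d.cpg_count for d in dmrs],
            "cpg_percent": [d.cpg_percent for d in dmrs],
            "direction": [d.direction for d in dmrs],
        }
    )
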