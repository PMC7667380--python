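"""Between-sample normalization and dispersion estimation for window counts.

Normalization uses the trimmed mean of M-values (TMM): per-sample scaling
factors computed from doubly-trimmed, precision-weighted log count ratios
against a reference sample, rescaled to geometric mean 1.  Effective
library size = raw library size × factor.

Dispersion is a single (common) negative-binomial dispersion estimated by
method of moments on normalized counts and shared across windows — the
minimal estimator adequate for the conditional exact test downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .windows import WindowCountMatrix


@dataclass
class NormalizationResult:
    sample_ids: list[str]
    factors: np.ndarray  # TMM factors, geometric mean 1
    library_sizes: np.ndarray  # raw
    reference_index: int

    @property
    def effective_sizes(self) -> np.ndarray:
        return self.library_sizes * self.factors


def tmm_factors(
    matrix: WindowCountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationResult:
    """Compute TMM scaling factors for each sample.

    The reference is the sample whose 75th-percentile count fraction is
    closest to the mean of those fractions.  For each other sample, M
    (log2 ratio of count fractions) and A (mean log2 abundance) are formed
    over windows nonzero in both sample and reference; the most extreme
    ``trim_m`` of M and ``trim_a`` of A (split over both tails) are
    discarded, and the factor is 2 to the precision-weighted mean of the
    surviving M values, with weights the inverse binomial asymptotic
    variances.  Factors are rescaled to geometric mean 1.
    """
    counts = matrix.counts.astype(float)
    lib = matrix.library_sizes.astype(float)
    n_windows, n_samples = counts.shape
    if n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    zero_samples = [sid for sid, tot in zip(matrix.sample_ids, counts.sum(axis=0)) if tot == 0]
    if zero_samples:
        raise ValueError(f"samples with all-zero counts: {zero_samples}")

    frac = counts / lib[None, :]
    q75 = np.percentile(frac, 75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    log_factors = np.zeros(n_samples)
    yr, nr = counts[:, ref], lib[ref]
    for k in range(n_samples):
        if k == ref:
            continue
        yk, nk = counts[:, k], lib[k]
        ok = (yk > 0) & (yr > 0)
        if not ok.any():
            raise ValueError(
                f"sample {matrix.sample_ids[k]} shares no nonzero window with reference"
            )
        m = np.log2((yk[ok] / nk) / (yr[ok] / nr))
        a = 0.5 * np.log2((yk[ok] / nk) * (yr[ok] / nr))
        var = (nk - yk[ok]) / (nk * yk[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        w = 1.0 / np.maximum(var, 1e-12)  # floor: a window holding a whole library

        keep = np.ones(len(m), dtype=bool)
        keep &= _interior_mask(m, trim_m)
        keep &= _interior_mask(a, trim_a)
        if not keep.any():  # fully trimmed (tiny inputs): fall back to untrimmed
            keep[:] = True
        log_factors[k] = np.sum(w[keep] * m[keep]) / np.sum(w[keep])

    log_factors -= log_factors.mean()  # geometric mean of 2**lf becomes 1
    return NormalizationResult(
        sample_ids=list(matrix.sample_ids),
        factors=2.0 ** log_factors,
        library_sizes=lib,
        reference_index=ref,
    )


def _interior_mask(values: np.ndarray, trim: float) -> np.ndarray:
    """Mask keeping values strictly inside the two-tailed ``trim`` fraction."""
    n = len(values)
    k = int(np.floor(n * trim / 2.0))
    if k == 0:
        return np.ones(n, dtype=bool)
    order = np.argsort(values, kind="stable")
    mask = np.ones(n, dtype=bool)
    mask[order[:k]] = False
    mask[order[n - k :]] = False
    return mask


def normalized_counts(matrix: WindowCountMatrix, norm: NormalizationResult) -> np.ndarray:
    """Counts rescaled to the geometric mean of the effective library sizes."""
    eff = norm.effective_sizes
    common = np.exp(np.mean(np.log(eff)))
    return matrix.counts * (common / eff)[None, :]


def estimate_dispersion(matrix: WindowCountMatrix, norm: NormalizationResult) -> float:
    """Common NB dispersion by method of moments on normalized counts.

    Per window, using within-group means and a pooled within-group
    variance: ``phi_w = (s2 - m) / m**2``.  The common dispersion is the
    median of the per-window values with a chi-square median-bias
    correction (the pooled variance's median sits below its mean, so the
    raw median underestimates phi and would make the exact test
    anti-conservative), floored at 0.
    """
    if matrix.n_windows < 2:
        raise ValueError("need at least 2 windows to estimate dispersion")
    idx_s = matrix.group_indices("S")
    idx_c = matrix.group_indices("C")
    if len(idx_s) < 2 or len(idx_c) < 2:
        raise ValueError("need at least 2 samples per group")
    x = normalized_counts(matrix, norm)
    xs, xc = x[:, idx_s], x[:, idx_c]
    ms, mc = xs.mean(axis=1), xc.mean(axis=1)
    vs = xs.var(axis=1, ddof=1)
    vc = xc.var(axis=1, ddof=1)
    n_s, n_c = len(idx_s), len(idx_c)
    # pooled within-group variance and grand within-group mean
    s2 = ((n_s - 1) * vs + (n_c - 1) * vc) / (n_s + n_c - 2)
    m = (n_s * ms + n_c * mc) / (n_s + n_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_w = (s2 - m) / (m * m)
    ok = np.isfinite(phi_w)
    if not ok.any():
        return 0.0
    df = n_s + n_c - 2
    c = float(chi2.ppf(0.5, df) / df)  # median of chi2_df / df
    m_med = float(np.median(m[ok]))
    if m_med <= 0:
        return 0.0
    phi = (float(np.median(phi_w[ok])) + (1.0 - c) / m_med) / c
    return max(0.0, phi)
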