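"""Window tiling, fragment-to-window count assignment, and row-sum filtering.

The adjacent-window (ADJW) route tests fixed 100-bp tiles; the region
route tests arbitrary preselected intervals.  Both consume a
:class:`WindowCountMatrix` built here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digest import FragmentSet
from .intervals import GenomeModel, GenomicInterval


@dataclass
class SampleInfo:
    sample_id: str
    group: str  # "S" or "C"
    channel: str = "medip"  # or "input"

    def __post_init__(self) -> None:
        if self.group not in ("S", "C"):
            raise ValueError(f"group must be 'S' or 'C', got {self.group!r}")
        if self.channel not in ("medip", "input"):
            raise ValueError(f"channel must be 'medip' or 'input', got {self.channel!r}")


@dataclass
class WindowCountMatrix:
    """Windows × samples integer count matrix with group/channel labels.

    ``library_sizes`` are the raw column sums; they are recomputed rather
    than stored so filtered views stay consistent is *not* done — library
    sizes are frozen at construction so that row filtering (minRowSum) does
    not change the normalization denominator, matching how count pipelines
    treat library size.
    """

    windows: list[GenomicInterval]
    counts: np.ndarray  # shape (n_windows, n_samples), nonnegative ints
    samples: list[SampleInfo]
    library_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]
    cpg_counts: np.ndarray | None = None  # per-window CpG counts

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.windows), len(self.samples)):
            raise ValueError("counts must be (n_windows, n_samples)")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        keys = [(w.chrom, w.start, w.end) for w in self.windows]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate windows")
        # windows must come in contiguous per-chromosome blocks, sorted by
        # start within each block (chromosome block order is free)
        seen_chroms: list[str] = []
        prev_chrom, prev_start = None, None
        for chrom, start, _end in keys:
            if chrom != prev_chrom:
                if chrom in seen_chroms:
                    raise ValueError("windows of one chromosome must be contiguous")
                seen_chroms.append(chrom)
                prev_chrom, prev_start = chrom, start
            else:
                if start <= prev_start:
                    raise ValueError("windows must be sorted by start within chromosome")
                prev_start = start
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.cpg_counts is not None:
            self.cpg_counts = np.asarray(self.cpg_counts)
            if len(self.cpg_counts) != len(self.windows):
                raise ValueError("cpg_counts length mismatch")

    # -- convenience -----------------------------------------------------
    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def group_indices(self, group: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples) if s.group == group], dtype=int)

    def channel_view(self, channel: str) -> "WindowCountMatrix":
        idx = [i for i, s in enumerate(self.samples) if s.channel == channel]
        if not idx:
            raise ValueError(f"no samples on channel {channel!r}")
        return WindowCountMatrix(
            windows=self.windows,
            counts=self.counts[:, idx],
            samples=[self.samples[i] for i in idx],
            library_sizes=self.library_sizes[idx],
            cpg_counts=self.cpg_counts,
        )

    def subset_windows(self, mask: np.ndarray) -> "WindowCountMatrix":
        mask = np.asarray(mask, dtype=bool)
        return WindowCountMatrix(
            windows=[w for w, m in zip(self.windows, mask) if m],
            counts=self.counts[mask],
            samples=self.samples,
            library_sizes=self.library_sizes,
            cpg_counts=None if self.cpg_counts is None else self.cpg_counts[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "window_id": [w.region_string() for w in self.windows],
                "chrom": [w.chrom for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
            }
        )
        for j, sid in enumerate(self.sample_ids):
            df[sid] = self.counts[:, j]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, samples: list[SampleInfo]) -> "WindowCountMatrix":
        windows = [
            GenomicInterval(str(r.chrom), int(r.start), int(r.end))
            for r in df.itertuples(index=False)
        ]
        counts = df[[s.sample_id for s in samples]].to_numpy(dtype=int)
        order = sorted(range(len(windows)), key=lambda i: (windows[i].chrom, windows[i].start))
        windows = [windows[i] for i in order]
        counts = counts[order]
        return cls(windows=windows, counts=counts, samples=samples)


def tile_windows(genome: GenomeModel, size: int = 100) -> list[GenomicInterval]:
    """Tile every chromosome with consecutive ``size``-bp windows from base 1.

    A trailing partial window is emitted when the chromosome length is not
    a multiple of ``size``, so the windows exactly partition the genome.
    """
    if size < 1:
        raise ValueError("window size must be >= 1")
    windows: list[GenomicInterval] = []
    for name in genome.names:
        length = genome.length(name)
        for start in range(1, length + 1, size):
            windows.append(GenomicInterval(name, start, min(start + size - 1, length)))
    return windows


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


def assign_counts(
    fragments: FragmentSet,
    counts: pd.DataFrame | np.ndarray,
    windows: list[GenomicInterval],
    samples: list[SampleInfo],
    genome: GenomeModel | None = None,
) -> WindowCountMatrix:
    """Distribute per-fragment counts over windows by overlap fraction.

    Each fragment's count is split across the windows it overlaps in
    proportion to the overlapping share of the *fragment*, accumulated in
    floating point and rounded half-up at the end, so total mass is
    conserved to within half a count per fragment.

    ``windows`` need not tile the genome (the region route passes arbitrary
    non-overlapping intervals); fragment mass falling outside every window
    is dropped.
    """
    if isinstance(counts, pd.DataFrame):
        from .io import COUNTS_INDEX_COLS

        sample_cols = [s.sample_id for s in samples]
        counts = counts[sample_cols].to_numpy(dtype=float)
    else:
        counts = np.asarray(counts, dtype=float)
    if counts.shape != (len(fragments), len(samples)):
        raise ValueError("counts must be (n_fragments, n_samples)")
    if genome is not None:
        genome.validate_intervals(fragments.fragments)

    order = sorted(range(len(windows)), key=lambda i: (windows[i].chrom, windows[i].start))
    windows = [windows[i] for i in order]
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    idx_all = np.arange(len(windows))
    chroms = np.array([w.chrom for w in windows])
    starts = np.array([w.start for w in windows])
    ends = np.array([w.end for w in windows])
    for chrom in dict.fromkeys(chroms):
        m = chroms == chrom
        by_chrom[chrom] = (starts[m], ends[m], idx_all[m])

    acc = np.zeros((len(windows), len(samples)), dtype=float)
    for f_idx, frag in enumerate(fragments.fragments):
        entry = by_chrom.get(frag.chrom)
        if entry is None:
            continue
        w_starts, w_ends, w_idx = entry
        lo = np.searchsorted(w_ends, frag.start, side="left")
        hi = np.searchsorted(w_starts, frag.end, side="right")
        if lo >= hi:
            continue
        ov = np.minimum(w_ends[lo:hi], frag.end) - np.maximum(w_starts[lo:hi], frag.start) + 1
        ov = np.clip(ov, 0, None)
        frac = ov / frag.width
        acc[w_idx[lo:hi]] += frac[:, None] * counts[f_idx][None, :]
    return WindowCountMatrix(
        windows=windows, counts=_round_half_up(acc), samples=samples
    )


def filter_min_row_sum(matrix: WindowCountMatrix, min_row_sum: int) -> WindowCountMatrix:
    """Keep windows whose count sum across all samples is >= ``min_row_sum``."""
    if min_row_sum < 0:
        raise ValueError("min_row_sum must be >= 0")
    mask = matrix.counts.sum(axis=1) >= min_row_sum
    return matrix.subset_windows(mask)
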