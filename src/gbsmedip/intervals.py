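"""Genomic coordinate model and interval arithmetic.

Coordinates are 1-based and inclusive on both ends throughout the package,
so ``width = end - start + 1`` — the convention of the tabular DMR reports
this pipeline produces.  BED files on disk keep their native 0-based
half-open convention; the conversion happens at the I/O boundary only
(see :mod:`gbsmedip.io`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence


class RegionParseError(ValueError):
    """A region string did not match ``chrom:start-end``."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval on a chromosome, 1-based inclusive.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        First and last base of the interval, 1-based, ``start <= end``.
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unstranded, the default).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def region_string(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end

    def distance_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge gap in bp; 0 when touching or overlapping.

        Raises if the intervals sit on different chromosomes.
        """
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.start <= other.end and other.start <= self.end:
            return 0
        if self.end < other.start:
            return other.start - self.end - 1
        return self.start - other.end - 1


_REGION_RE = re.compile(r"^(?P<chrom>[^:\s]+):(?P<start>\d+)-(?P<end>\d+)$")


def parse_region(text: str) -> GenomicInterval:
    """Parse ``"chrom:start-end"`` into a :class:`GenomicInterval`.

    >>> parse_region("chr1:61077901-61078200").width
    300
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise RegionParseError(f"malformed region string: {text!r}")
    start, end = int(m.group("start")), int(m.group("end"))
    if end < start:
        raise RegionParseError(f"region end before start in {text!r}")
    return GenomicInterval(m.group("chrom"), start, end)


def merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose edge-to-edge gap is at most ``max_gap`` bp.

    ``max_gap=0`` merges touching or overlapping intervals (adjacent
    100-bp windows, e.g. end=100 followed by start=101, coalesce).  Merging
    never crosses chromosomes; output is sorted and strand is dropped.
    The operation is idempotent.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start - merged[-1].end - 1 <= max_gap
        ):
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


CHROM_CLASSES = ("macro", "micro", "sexZ")


@dataclass
class Chromosome:
    name: str
    length: int
    chrom_class: str = "macro"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name} has nonpositive length")
        if self.chrom_class not in CHROM_CLASSES:
            raise ValueError(
                f"chromosome class must be one of {CHROM_CLASSES}, got {self.chrom_class!r}"
            )


class GenomeModel:
    """Ordered chromosomes with lengths, class tags and optional sequence.

    The class tag partitions chromosomes into macrochromosomes,
    microchromosomes and the avian Z sex chromosome; it is supplied by the
    caller (genome configuration), never inferred from length, because the
    Z is a macro-sized chromosome that downstream statistics treat
    separately.

    Parameters
    ----------
    chromosomes : sequence of (name, length) or (name, length, class)
    sequences : optional mapping name -> str
        Uppercase-insensitive DNA; lengths must match when given.
    """

    def __init__(
        self,
        chromosomes: Sequence[tuple],
        sequences: dict[str, str] | None = None,
    ) -> None:
        self.chromosomes: list[Chromosome] = []
        seen: set[str] = set()
        for spec in chromosomes:
            chrom = Chromosome(*spec)
            if chrom.name in seen:
                raise ValueError(f"duplicate chromosome name {chrom.name!r}")
            seen.add(chrom.name)
            self.chromosomes.append(chrom)
        self._by_name = {c.name: c for c in self.chromosomes}
        self._sequences: dict[str, str] = {}
        if sequences is not None:
            for name, seq in sequences.items():
                self.set_sequence(name, seq)

    # -- basic accessors -------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def length(self, chrom: str) -> int:
        return self._chrom(chrom).length

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def chrom_class(self, chrom: str) -> str:
        return self._chrom(chrom).chrom_class

    def _chrom(self, name: str) -> Chromosome:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    # -- sequence --------------------------------------------------------
    @property
    def has_sequence(self) -> bool:
        return len(self._sequences) == len(self.chromosomes)

    def set_sequence(self, chrom: str, seq: str) -> None:
        c = self._chrom(chrom)
        if len(seq) != c.length:
            raise ValueError(
                f"sequence length {len(seq)} != declared length {c.length} for {chrom}"
            )
        self._sequences[chrom] = seq.upper()

    def sequence(self, chrom: str, start: int | None = None, end: int | None = None) -> str:
        """Sequence of ``chrom`` (1-based inclusive slice when bounds given)."""
        seq = self._sequences.get(chrom)
        if seq is None:
            raise ValueError(f"no sequence loaded for chromosome {chrom!r}")
        if start is None:
            return seq
        end = end if end is not None else self._chrom(chrom).length
        return seq[start - 1 : end]

    def fetch(self, interval: GenomicInterval) -> str:
        return self.sequence(interval.chrom, interval.start, interval.end)

    def validate_interval(self, interval: GenomicInterval) -> None:
        """Raise if the interval names an unknown chromosome or exceeds it."""
        c = self._chrom(interval.chrom)
        if interval.end > c.length:
            raise ValueError(
                f"interval {interval.region_string()} exceeds chromosome length {c.length}"
            )

    def validate_intervals(self, intervals: Iterable[GenomicInterval]) -> None:
        for iv in intervals:
            self.validate_interval(iv)


@dataclass
class GeneModel:
    """A gene with strand-aware TSS and exon structure.

    The TSS is the 5' end of the gene span: ``interval.start`` on the +
    strand, ``interval.end`` on the − strand.
    """

    gene_id: str
    symbol: str
    interval: GenomicInterval
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be '+' or '-', got {self.strand!r}")
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"exon {ex.region_string()} outside gene {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def chrom(self) -> str:
        return self.interval.chrom
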