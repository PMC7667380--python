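"""Readers and writers for the flat-file formats the pipeline consumes.

BED is 0-based half-open on disk and converted to the package's 1-based
inclusive coordinates on read (+1 to start) and back on write.  All other
tables carry 1-based inclusive coordinates as printed.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from pyfaidx import Fasta

from .intervals import GeneModel, GenomeModel, GenomicInterval


# ---------------------------------------------------------------------- BED
def read_bed(path, genome: GenomeModel | None = None) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into 1-based inclusive intervals.

    When ``genome`` is given, records on unknown chromosomes or beyond the
    chromosome end raise a ``ValueError`` (never silently dropped: the
    downstream expectancy statistics need a closed chromosome universe).
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: BED needs >= 3 columns")
            chrom, start0, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            iv = GenomicInterval(chrom, start0 + 1, end, strand)
            if genome is not None:
                try:
                    genome.validate_interval(iv)
                except (KeyError, ValueError) as exc:
                    raise ValueError(f"{path}:{line_no}: {exc}") from exc
            intervals.append(iv)
    return intervals


def write_bed(
    intervals: Iterable[GenomicInterval],
    path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write intervals as BED6 (name/score optional, strand preserved)."""
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            score = scores[i] if scores is not None else 0
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


# --------------------------------------------------------------------- GFF3
def _gff3_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path, genome: GenomeModel | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 (gene / exon / five_prime_UTR / three_prime_UTR).

    Exons and UTRs are attached to their gene via the ``Parent`` (or
    ``gene_id``) attribute chain; mRNA features are transparent.
    """
    genes: dict[str, GeneModel] = {}
    parent_of: dict[str, str] = {}  # transcript id -> gene id
    pending: list[tuple[str, str, GenomicInterval]] = []  # (kind, parent, iv)
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{line_no}: GFF3 needs 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attr_text = fields
            attrs = _gff3_attributes(attr_text)
            iv = GenomicInterval(chrom, int(start), int(end), strand if strand in "+-" else ".")
            if genome is not None:
                genome.validate_interval(iv)
            fid = attrs.get("ID", "")
            if ftype == "gene":
                gid = fid or attrs.get("gene_id", f"gene{line_no}")
                genes[gid] = GeneModel(
                    gene_id=gid,
                    symbol=attrs.get("Name", gid),
                    interval=iv,
                    strand=strand,
                )
            elif ftype in ("mRNA", "transcript"):
                parent_of[fid] = attrs.get("Parent", "")
            elif ftype in ("exon", "five_prime_UTR", "three_prime_UTR", "CDS"):
                pending.append((ftype, attrs.get("Parent", ""), iv))
    for ftype, parent, iv in pending:
        gid = parent_of.get(parent, parent)
        if gid not in genes:
            continue
        gene = genes[gid]
        if ftype == "exon":
            gene.exons.append(iv)
        elif ftype == "five_prime_UTR":
            gene.utr5.append(iv)
        elif ftype == "three_prime_UTR":
            gene.utr3.append(iv)
    out = list(genes.values())
    out.sort(key=lambda g: (g.chrom, g.interval.start))
    for g in out:
        g.exons.sort(key=lambda e: e.start)
    return out


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tgbsmedip\tgene\t{iv.start}\t{iv.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Name={g.symbol}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{iv.chrom}\tgbsmedip\tmRNA\t{iv.start}\t{iv.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for kind, feats in (
                ("exon", g.exons),
                ("five_prime_UTR", g.utr5),
                ("three_prime_UTR", g.utr3),
            ):
                for f in feats:
                    fh.write(
                        f"{f.chrom}\tgbsmedip\t{kind}\t{f.start}\t{f.end}\t.\t{g.strand}\t.\t"
                        f"Parent={mrna_id}\n"
                    )


# -------------------------------------------------------------------- FASTA
def read_fasta(path, chrom_classes: dict[str, str] | None = None) -> GenomeModel:
    """Load a genome FASTA into a :class:`GenomeModel` with full sequences.

    ``chrom_classes`` maps chromosome name to {macro, micro, sexZ}; unnamed
    chromosomes default to macro.
    """
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    chrom_classes = chrom_classes or {}
    chroms = []
    seqs = {}
    for name in fa.keys():
        seq = str(fa[name][:])
        chroms.append((name, len(seq), chrom_classes.get(name, "macro")))
        seqs[name] = seq
    return GenomeModel(chroms, sequences=seqs)


def write_fasta(genome: GenomeModel, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome.names:
            fh.write(f">{name}\n")
            seq = genome.sequence(name)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width])
                fh.write("\n")


# ------------------------------------------------------------- counts table
COUNTS_INDEX_COLS = ["window_id", "chrom", "start", "end"]


def read_counts_table(path) -> pd.DataFrame:
    """Read a window/fragment counts table (TSV).

    Columns: window_id, chrom, start, end (1-based inclusive), then one
    integer column per sample.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in COUNTS_INDEX_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"counts table missing columns: {missing}")
    sample_cols = [c for c in df.columns if c not in COUNTS_INDEX_COLS]
    df[sample_cols] = df[sample_cols].astype(int)
    return df


def write_counts_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- sample sheet
SAMPLE_SHEET_COLS = ["sample_id", "population", "group", "channel"]


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    bad_group = set(df["group"]) - {"S", "C"}
    if bad_group:
        raise ValueError(f"sample sheet group must be S or C, got {bad_group}")
    bad_channel = set(df["channel"]) - {"medip", "input"}
    if bad_channel:
        raise ValueError(f"sample sheet channel must be medip or input, got {bad_channel}")
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df[SAMPLE_SHEET_COLS].to_csv(path, sep="\t", index=False)
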