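"""PWM motif scanning and the two-part TFBS presence criterion.

Position-frequency matrices are scored as log-odds against a background
base composition at every offset on both strands; a motif "hits" a DMR
when some offset scores above the motif's floor, and hits are
"significant" above the motif's own threshold (supplied per motif, e.g. a
maximum-precision operating point).  A motif is selected when (a) every
DMR longer than 100 bp carries at least one hit of any strength, and (b)
at least half of all DMRs carry a significant hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """A position weight matrix with background and scoring threshold.

    ``matrix`` has shape (length, 4) over A,C,G,T; columns (positions) are
    normalized to sum to 1 at construction.  ``threshold`` is the
    per-motif significant-hit log-odds cutoff; ``floor`` is the weakest
    score still counted as "a hit at all" (criterion (a)).
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold: float = 0.0
    floor: float = 0.0
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError("PWM matrix must be (length >= 1, 4)")
        if (self.matrix < 0).any():
            raise ValueError("PWM frequencies must be nonnegative")
        sums = self.matrix.sum(axis=1, keepdims=True)
        if (sums == 0).any():
            raise ValueError("PWM has an all-zero position")
        self.matrix = self.matrix / sums
        self.background = np.asarray(self.background, dtype=float)
        self.background = self.background / self.background.sum()

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """(length, 5) log2-odds; the 5th column (N) scores 0."""
        p = self.matrix + self.pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        lo = np.log2(p / self.background[None, :])
        return np.hstack([lo, np.zeros((len(self), 1))])

    def max_score(self) -> float:
        return float(self.log_odds()[:, :4].max(axis=1).sum())


def read_pwms(path) -> list[PWM]:
    """Read PWMs from a JASPAR-like flat text file.

    Each record is a header line starting with ``>`` (motif id, optional
    name) followed by four rows, one per base, of whitespace-separated
    counts or frequencies, optionally wrapped in brackets:

        >MA0001 MyMotif
        A [ 4 19  0 ]
        C [16  0  20]
        G [ 0  1   0]
        T [ 0  0   0]
    """
    pwms: list[PWM] = []
    current_id = None
    rows: dict[str, list[float]] = {}

    def flush():
        nonlocal current_id, rows
        if current_id is None:
            return
        missing = [b for b in BASES if b not in rows]
        if missing:
            raise ValueError(f"motif {current_id}: missing base rows {missing}")
        mat = np.array([rows[b] for b in BASES]).T
        pwms.append(PWM(motif_id=current_id, matrix=mat))
        current_id, rows = None, {}

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0]
            else:
                base = line[0].upper()
                if base not in _BASE_INDEX:
                    raise ValueError(f"unexpected PWM row: {line!r}")
                nums = line[1:].replace("[", " ").replace("]", " ").split()
                rows[base] = [float(x) for x in nums]
    flush()
    return pwms


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)  # default N
    for b, i in _BASE_INDEX.items():
        codes[arr == ord(b)] = i
    return codes


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifHit:
    position: int  # 1-based start within the scanned sequence (forward coords)
    strand: str
    score: float


def _scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    length = lo.shape[0]
    n = len(codes) - length + 1
    if n <= 0:
        return np.empty(0)
    out = np.zeros(n)
    for j in range(length):
        out += lo[j, codes[j : j + n]]
    return out


def pwm_scan(
    sequence: str,
    pwm: PWM,
    threshold: float | None = None,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan a sequence for motif hits with score >= threshold.

    ``threshold`` defaults to the motif's own threshold.  Positions are
    1-based in forward-strand coordinates; a − strand hit at position p
    covers the same bases as a forward window starting at p.  Ambiguous
    bases (N) contribute a log-odds of 0.  A sequence shorter than the
    motif yields no hits.
    """
    thr = pwm.threshold if threshold is None else threshold
    lo = pwm.log_odds()
    codes = _encode(sequence)
    hits: list[MotifHit] = []
    fwd = _scores(codes, lo)
    for i in np.flatnonzero(fwd >= thr):
        hits.append(MotifHit(position=int(i) + 1, strand="+", score=float(fwd[i])))
    if both_strands:
        rc_codes = _encode(reverse_complement(sequence))
        rev = _scores(rc_codes, lo)
        L = len(sequence)
        m = len(pwm)
        for i in np.flatnonzero(rev >= thr):
            hits.append(
                MotifHit(position=L - int(i) - m + 1, strand="-", score=float(rev[i]))
            )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


@dataclass
class MotifSelectionReport:
    table: pd.DataFrame  # per motif: fractions and pass flags
    n_dmrs: int
    n_long_dmrs: int  # DMRs longer than 100 bp (criterion (a) universe)


def motif_selection(
    dmr_sequences: dict[str, str],
    pwms: list[PWM],
    long_cutoff: int = 100,
) -> MotifSelectionReport:
    """Apply the two-part TFBS presence criterion to a DMR sequence set.

    (a) every DMR longer than ``long_cutoff`` bp has at least one hit at
    any score above the motif's floor (vacuously true, and flagged, when
    no DMR is that long); (b) at least 50% of all DMRs (inclusive) have a
    hit at or above the motif's significance threshold.
    """
    if not dmr_sequences or not pwms:
        raise ValueError("need at least one DMR sequence and one PWM")
    ids = list(dmr_sequences)
    long_ids = [i for i in ids if len(dmr_sequences[i]) > long_cutoff]
    rows = []
    for pwm in pwms:
        any_hit_long = 0
        above_thr = 0
        for did in ids:
            seq = dmr_sequences[did]
            best = None
            hits = pwm_scan(seq, pwm, threshold=-np.inf)
            if hits:
                best = max(h.score for h in hits)
            if best is not None and best >= pwm.threshold:
                above_thr += 1
            if did in set(long_ids) and best is not None and best > pwm.floor:
                any_hit_long += 1
        frac_any_long = any_hit_long / len(long_ids) if long_ids else float("nan")
        frac_above = above_thr / len(ids)
        pass_a = (not long_ids) or any_hit_long == len(long_ids)
        pass_b = frac_above >= 0.5
        rows.append(
            {
                "motif_id": pwm.motif_id,
                "frac_long_with_any_hit": frac_any_long,
                "frac_with_significant_hit": frac_above,
                "pass_presence": pass_a,
                "pass_majority": pass_b,
                "selected": pass_a and pass_b,
                "criterion_a_vacuous": not long_ids,
            }
        )
    return MotifSelectionReport(
        table=pd.DataFrame(rows), n_dmrs=len(ids), n_long_dmrs=len(long_ids)
    )
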