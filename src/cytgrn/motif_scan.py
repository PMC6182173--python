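"""PWM log-odds scanning of promoter sequences.

A position weight matrix stores per-position base probabilities; a window
of sequence scores sum_i log2(p_i(base_i) / background(base_i)) in bits.
Both strands of each 2 kb promoter are scanned and windows scoring at or
above the threshold (default 10, a stringent cut-off) are reported as
binding sites.  Windows containing N are skipped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_THRESHOLD = 10.0
DEFAULT_PSEUDOCOUNT = 0.01


@dataclass
class PWM:
    """Per-position base-probability matrix (rows = positions, cols ACGT)."""

    matrix: np.ndarray
    motif_id: str = ""
    tf_symbol: str = ""
    pseudo: float = 0.0
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4 (A, C, G, T)")
        if len(self) < 4:
            raise ValueError("PWM length must be >= 4")
        if (self.matrix < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM position must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass
class MotifHit:
    gene: str
    offset: int  # 0-based start within the promoter, forward coordinates
    strand: str  # '+' or '-'
    score: float


def load_pwm(path: str | Path, pseudo: float = DEFAULT_PSEUDOCOUNT,
             tf_symbol: str = "") -> PWM:
    """Load a CIS-BP-style or MEME-minimal matrix file.

    Counts or frequencies are smoothed with ``pseudo`` per cell and
    renormalized per position.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    rows: list[list[float]] = []
    motif_id = path.stem
    in_matrix = False
    for line in lines:
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.lower().startswith("motif"):
            parts = stripped.split()
            if len(parts) > 1:
                motif_id = parts[1]
            continue
        if stripped.lower().startswith("letter-probability"):
            in_matrix = True
            continue
        fields = stripped.split()
        # CIS-BP header: "Pos A C G T"
        if fields[0].lower() in {"pos", "position"}:
            in_matrix = True
            continue
        try:
            values = [float(f) for f in fields]
        except ValueError:
            if in_matrix:
                break
            continue
        # CIS-BP rows lead with the position index
        if len(values) == 5:
            values = values[1:]
        if len(values) != 4:
            raise ValueError(f"{path}: expected 4 base columns, got {len(values)}")
        rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no matrix rows parsed")
    mat = np.asarray(rows, dtype=float)
    if (mat < 0).any():
        raise ValueError(f"{path}: negative matrix entries")
    if (mat.sum(axis=1) == 0).any():
        raise ValueError(f"{path}: all-zero matrix row")
    mat = mat + pseudo
    mat /= mat.sum(axis=1, keepdims=True)
    return PWM(matrix=mat, motif_id=motif_id, tf_symbol=tf_symbol, pseudo=pseudo)


def write_pwm(pwm: PWM, path: str | Path) -> None:
    """Write in the CIS-BP text layout (Pos A C G T)."""
    with open(path, "w") as fh:
        fh.write("Pos\tA\tC\tG\tT\n")
        for i, row in enumerate(pwm.matrix, start=1):
            fh.write(f"{i}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), -1, dtype=np.int64)
    for base, i in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = i
    return codes


def _window_scores(log_odds: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Score every window; windows containing N (code -1) get -inf."""
    L = log_odds.shape[0]
    n_win = len(codes) - L + 1
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    for i in range(L):
        col = codes[i:i + n_win]
        ok = col >= 0
        valid &= ok
        scores += np.where(ok, log_odds[i, np.where(ok, col, 0)], 0.0)
    scores[~valid] = -np.inf
    return scores


def scan_promoter(pwm: PWM, sequence: str,
                  threshold: float = DEFAULT_THRESHOLD,
                  gene: str = "") -> list[MotifHit]:
    """Scan both strands; return hits scoring >= ``threshold``, by offset.

    Offsets are 0-based starts in forward promoter coordinates (offset 0 =
    the 5' end of the supplied 2 kb region); minus-strand hits report the
    start of the window on the forward strand.
    """
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over the alphabet {A,C,G,T,N}")
    L = len(pwm)
    if len(seq) < L:
        warnings.warn("sequence shorter than motif; no windows to scan")
        return []
    lo = pwm.log_odds
    codes = _encode(seq)
    hits = []
    fwd = _window_scores(lo, codes)
    for off in np.nonzero(fwd >= threshold)[0]:
        hits.append(MotifHit(gene=gene, offset=int(off), strand="+",
                             score=float(fwd[off])))
    rev = _window_scores(lo, _encode(reverse_complement(seq)))
    n_win = len(seq) - L + 1
    for off in np.nonzero(rev >= threshold)[0]:
        hits.append(MotifHit(gene=gene, offset=int(n_win - 1 - off), strand="-",
                             score=float(rev[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


class PromoterSet(dict):
    """gene symbol -> promoter sequence (5'->3' on the coding strand)."""

    @classmethod
    def read_fasta(cls, path: str | Path) -> "PromoterSet":
        return cls({rec.id: str(rec.seq).upper()
                    for rec in SeqIO.parse(str(path), "fasta")})

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gene, seq in self.items():
                fh.write(f">{gene}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")


def count_sites(pwm: PWM, promoters: Mapping[str, str],
                threshold: float = DEFAULT_THRESHOLD) -> dict[str, int]:
    """Number of binding sites per gene promoter (overlaps counted)."""
    return {gene: len(scan_promoter(pwm, seq, threshold, gene=gene))
            for gene, seq in promoters.items()}


def hits_to_bed(hits: Iterable[MotifHit], motif_length: int) -> str:
    """BED-like TSV (gene, start, end, strand, score)."""
    lines = ["gene\tstart\tend\tstrand\tscore"]
    for h in hits:
        lines.append(f"{h.gene}\t{h.offset}\t{h.offset + motif_length}"
                     f"\t{h.strand}\t{h.score:.3f}")
    return "\n".join(lines) + "\n"
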