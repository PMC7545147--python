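"""Position weight matrices and log-odds motif scanning.

Scanning is occurrence-only: user-supplied PWMs (MEME minimal format)
are scored over region sequences on both strands, and windows reaching
a fraction of the maximum attainable log-odds are reported as hits.
Sequence headers of the form ``chrom:start-end`` anchor hits back to
genomic coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = ["PWM", "MotifHit", "scan_pwm", "parse_region_header"]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_HEADER_RE = re.compile(r"^(?P<chrom>[^:\s]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass
class PWM:
    """Per-position nucleotide probabilities over A/C/G/T."""

    motif_id: str
    matrix: np.ndarray  # (length, 4)
    background: np.ndarray = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (length, 4)")
        if len(self.matrix) < 4:
            raise ValueError("PWM length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")

    def __len__(self) -> int:
        return len(self.matrix)

    def log_odds(self) -> np.ndarray:
        """(length, 5) log-odds; column 4 (N) is -inf."""
        with np.errstate(divide="ignore"):
            lo = np.log(self.matrix / self.background)
        return np.hstack([lo, np.full((len(self.matrix), 1), -np.inf)])

    def max_score(self) -> float:
        return float(self.log_odds()[:, :4].max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.matrix[::-1, ::-1], self.background[::-1])


@dataclass
class MotifHit:
    motif_id: str
    chrom: str
    start: int
    end: int
    strand: str
    score: float

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def parse_region_header(header: str) -> tuple[str, int, int]:
    """Parse a ``chrom:start-end`` FASTA header to genomic coordinates."""
    m = _HEADER_RE.match(header)
    if not m:
        raise ValueError(f"sequence header {header!r} is not chrom:start-end")
    return m["chrom"], int(m["start"]), int(m["end"])


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        if idx < 4:
            out[np.frombuffer(seq.encode(), dtype=np.uint8) ==
                ord(base)] = idx
    return out


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    L = len(log_odds)
    n = len(codes) - L + 1
    if n <= 0:
        return np.zeros(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return log_odds[np.arange(L), windows].sum(axis=1)


def scan_pwm(
    sequences: Mapping[str, str],
    pwm: PWM,
    score_frac: float = 0.8,
) -> list[MotifHit]:
    """Scan both strands of each sequence for high-scoring windows.

    A window is a hit when its log-odds reaches ``score_frac`` times the
    PWM's maximum attainable log-odds. N bases score -inf. Overlapping
    hits on opposite strands are both reported. Hit coordinates are
    genomic when headers parse as ``chrom:start-end``, else
    sequence-local with chrom = header.
    """
    if not (0 < score_frac <= 1):
        raise ValueError("score_frac must lie in (0, 1]")
    threshold = score_frac * pwm.max_score()
    lo_fwd = pwm.log_odds()
    lo_rev = pwm.reverse_complement().log_odds()
    hits: list[MotifHit] = []
    for header, seq in sequences.items():
        try:
            chrom, gstart, _ = parse_region_header(header)
        except ValueError:
            chrom, gstart = header, 0
        codes = _encode(seq.upper())
        for strand, lo in (("+", lo_fwd), ("-", lo_rev)):
            scores = _window_scores(codes, lo)
            with np.errstate(invalid="ignore"):
                where = np.nonzero(scores >= threshold)[0]
            for off in where:
                hits.append(MotifHit(
                    motif_id=pwm.motif_id,
                    chrom=chrom,
                    start=gstart + int(off),
                    end=gstart + int(off) + len(pwm),
                    strand=strand,
                    score=float(scores[off]),
                ))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits
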