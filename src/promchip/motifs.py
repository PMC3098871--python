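"""Position-weight-matrix scanning with an empirically calibrated cutoff.

A motif matrix holds per-position base frequencies; windows are scored as
log-odds against a uniform background with a small pseudocount.  Rather
than an analytic score distribution, the hit threshold is a type-I cutoff:
the (1 - alpha) quantile of scores of random sequences of the motif width
drawn with uniform base composition, so a background window exceeds the
cutoff with probability about alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InsufficientDataError, MotifFormatError

__all__ = [
    "MotifMatrix",
    "MotifHit",
    "calibrate_cutoff",
    "scan_region",
    "fraction_with_hit",
    "BASES",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifMatrix:
    """A base-frequency matrix plus its calibrated score cutoff.

    Attributes
    ----------
    freq : (width, 4) array
        Per-position probabilities over A, C, G, T; rows sum to 1.
    name : str
        Free-text identifier (e.g. the source matrix accession).
    pseudocount : float
        Added to each frequency before taking log-odds.
    cutoff : float or None
        Calibrated hit threshold; ``None`` until calibrated.
    """

    freq: np.ndarray
    name: str = "motif"
    pseudocount: float = 0.01
    cutoff: float | None = None

    def __post_init__(self):
        freq = np.asarray(self.freq, dtype=np.float64)
        if freq.ndim != 2 or freq.shape[1] != 4 or freq.shape[0] == 0:
            raise MotifFormatError("frequency matrix must be non-empty with 4 columns")
        if np.any(freq < 0) or np.any(~np.isfinite(freq)):
            raise MotifFormatError("frequencies must be finite and non-negative")
        if not np.allclose(freq.sum(axis=1), 1.0, atol=1e-6):
            raise MotifFormatError("each position's frequencies must sum to 1 (+-1e-6)")
        object.__setattr__(self, "freq", freq)

    @property
    def width(self) -> int:
        return self.freq.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """Per-cell score ``ln(((freq + pc) / (1 + 4 pc)) / 0.25)``."""
        pc = self.pseudocount
        return np.log(((self.freq + pc) / (1.0 + 4.0 * pc)) / 0.25)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freq.argmax(axis=1))

    def with_cutoff(self, cutoff: float) -> "MotifMatrix":
        return replace(self, cutoff=float(cutoff))

    @classmethod
    def from_counts(cls, counts, name: str = "motif", **kw) -> "MotifMatrix":
        """Build from a per-position count matrix (columns normalised)."""
        counts = np.asarray(counts, dtype=np.float64)
        if np.any(counts < 0):
            raise MotifFormatError("counts must be non-negative")
        totals = counts.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise MotifFormatError("a matrix position has zero total count")
        return cls(counts / totals, name=name, **kw)

    def score_sequences(self, encoded: np.ndarray) -> np.ndarray:
        """Score integer-encoded sequences (rows of base indices 0..3)."""
        lo = self.log_odds
        return lo[np.arange(self.width), encoded].sum(axis=-1)


@dataclass(frozen=True)
class MotifHit:
    position: int  # 0-based window start on the plus strand
    strand: str  # "+" or "-"
    score: float


def calibrate_cutoff(
    matrix: MotifMatrix, alpha: float = 0.05, n_samples: int = 10000, seed=0
) -> float:
    """Type-I score cutoff at level ``alpha`` by background sampling.

    Draws ``n_samples`` i.i.d. sequences of the motif width with uniform
    base probabilities (0.25 each), scores them with the matrix, and
    returns the empirical ``(1 - alpha)`` quantile (the smallest sampled
    score with at least that fraction of samples at or below it), so a
    random background window scores at or above the cutoff with
    probability about ``alpha``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_samples < 100:
        raise ValueError("need at least 100 background samples")
    if np.any(~np.isfinite(matrix.log_odds)):
        raise MotifFormatError("degenerate matrix: non-finite log-odds cell")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, 4, size=(n_samples, matrix.width))
    scores = matrix.score_sequences(draws)
    return float(np.quantile(scores, 1.0 - alpha, method="higher"))


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    out = np.full(len(seq), -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return out


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def scan_region(sequence: str, matrix: MotifMatrix, cutoff: float | None = None):
    """Scan one sequence on both strands for windows scoring >= cutoff.

    Windows containing any non-ACGT character are skipped.  Hit positions
    are 0-based window starts on the plus strand regardless of the strand
    scored; minus-strand windows are scored on the reverse complement.

    Returns a list of :class:`MotifHit` sorted by position then strand.
    """
    if cutoff is None:
        cutoff = matrix.cutoff
    if cutoff is None:
        raise ValueError("matrix has no cutoff; calibrate first or pass one")
    w = matrix.width
    if len(sequence) < w:
        raise InsufficientSequence(sequence, w)
    enc = _encode(sequence)
    n_win = len(sequence) - w + 1
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    ok = (windows >= 0).all(axis=1)
    hits: list[MotifHit] = []
    if ok.any():
        idx = np.nonzero(ok)[0]
        fwd = matrix.score_sequences(windows[idx])
        # minus strand: score the reverse complement of each window, which
        # equals scoring reversed complemented indices (3 - base) in place
        rc = (3 - windows[idx])[:, ::-1]
        rev = matrix.score_sequences(rc)
        for pos, fs, rs in zip(idx, fwd, rev):
            if fs >= cutoff:
                hits.append(MotifHit(int(pos), "+", float(fs)))
            if rs >= cutoff:
                hits.append(MotifHit(int(pos), "-", float(rs)))
    assert n_win == windows.shape[0]
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


class InsufficientSequence(InsufficientDataError):
    def __init__(self, sequence, width):
        super().__init__(
            f"sequence of length {len(sequence)} shorter than motif width {width}"
        )


def best_score(sequence: str, matrix: MotifMatrix) -> float:
    """Best log-odds window score over both strands (-inf if no window)."""
    hits = scan_region(sequence, matrix, cutoff=-np.inf)
    if not hits:
        return float("-inf")
    return max(h.score for h in hits)


def fraction_with_hit(regions, matrix: MotifMatrix):
    """Fraction of regions with at least one motif hit, plus a per-region table.

    Parameters
    ----------
    regions : mapping name -> sequence, or iterable of objects with
        ``gene_id`` and ``sequence`` attributes (bound regions).
    matrix : MotifMatrix with a calibrated cutoff.

    Returns
    -------
    (fraction, table)
        ``fraction`` = #regions with >= 1 hit / #regions; ``table`` has one
        row per region with its best score and hit count.
    """
    if isinstance(regions, Mapping):
        items = list(regions.items())
    else:
        items = [(r.gene_id, r.sequence) for r in regions]
    if not items:
        raise EmptyInputError("fraction_with_hit requires at least one region")
    rows = []
    for name, seq in items:
        hits = scan_region(seq, matrix)
        all_scores = scan_region(seq, matrix, cutoff=-np.inf)
        best = max((h.score for h in all_scores), default=float("-inf"))
        rows.append(
            {"region": name, "n_hits": len(hits), "best_score": best, "hit": len(hits) > 0}
        )
    table = pd.DataFrame(rows)
    return float(table["hit"].mean()), table
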