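"""Position-weight-matrix scanning with exact score-distribution thresholds.

A PFM's counts are turned into log2-odds scores against a background base
composition.  The match threshold for a motif is derived from the exact
distribution of the score of a random background sequence, computed by
dynamic-programming convolution over columns on a fine score grid; a window
matches when its score reaches the threshold whose upper-tail probability is
at most the requested p-value cutoff (the convention of motif scanners such
as motifmatchr/MOODS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .formats import PFM, NarrowPeakRecord, SequenceStore

logger = logging.getLogger(__name__)

__all__ = [
    "MotifHit",
    "UNIFORM_BACKGROUND",
    "pfm_to_pwm",
    "pwm_threshold",
    "scan_motifs",
    "scan_sequence",
]

UNIFORM_BACKGROUND = np.array([0.25, 0.25, 0.25, 0.25])

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class MotifHit:
    """One motif match inside a peak's sequence.

    `offset` is 0-based within the peak on the forward strand; a minus-strand
    hit means the reverse complement of the window matches the motif.
    """

    peak: NarrowPeakRecord
    motif_id: str
    offset: int
    strand: str
    score: float


def pfm_to_pwm(
    pfm: PFM,
    background: np.ndarray = UNIFORM_BACKGROUND,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Log2-odds matrix (4 x w) from counts with a background-weighted pseudocount."""
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or (background <= 0).any() or not np.isclose(
        background.sum(), 1.0
    ):
        raise ValueError("background must be 4 positive probabilities summing to 1")
    counts = pfm.counts
    probs = (counts + pseudocount * background[:, None]) / (
        counts.sum(axis=0, keepdims=True) + pseudocount
    )
    return np.log2(probs / background[:, None])


def pwm_threshold(
    pfm: PFM,
    background: np.ndarray = UNIFORM_BACKGROUND,
    p_cutoff: float = 5e-5,
    pseudocount: float = 1.0,
    bin_width: float = 1e-4,
) -> float:
    """Smallest score t (bits) with P(random background window >= t) <= p_cutoff.

    The null score distribution is computed exactly by convolving the
    per-column score distributions on a grid of `bin_width` bits.  Returns
    +inf (with a warning) when even the maximum attainable
    score is too probable, in which case nothing can match.
    """
    if not (0.0 < p_cutoff <= 1.0):
        raise ValueError(f"p_cutoff must lie in (0,1], got {p_cutoff}")
    background = np.asarray(background, dtype=float)
    pwm = pfm_to_pwm(pfm, background, pseudocount)
    bins = np.rint(pwm / bin_width).astype(np.int64)  # (4, w)
    # distribution of the binned score sum, tracked as (array, lowest bin)
    dist = np.array([1.0])
    cur_lo = 0
    for j in range(pfm.width):
        col = bins[:, j]
        new_lo = cur_lo + int(col.min())
        new_hi = cur_lo + dist.size - 1 + int(col.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            start = cur_lo + int(col[b]) - new_lo
            new[start : start + dist.size] += background[b] * dist
        dist, cur_lo = new, new_lo
    tail = np.cumsum(dist[::-1])[::-1]
    # smallest *attainable* score whose upper tail is within the cutoff
    ok = np.nonzero((tail <= p_cutoff * (1 + 1e-12)) & (dist > 0))[0]
    if ok.size == 0:
        logger.warning(
            "motif %s: no attainable threshold at p_cutoff=%g; returning +inf",
            pfm.motif_id,
            p_cutoff,
        )
        return float("inf")
    # map back to true-score space: each of the w columns was rounded to the
    # grid, so shave the worst-case rounding margin to keep every sequence
    # whose exact score reaches the chosen level above the threshold
    return float((cur_lo + int(ok[0])) * bin_width - pfm.width * bin_width / 2)


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return codes


def _revcomp_pwm(pwm: np.ndarray) -> np.ndarray:
    # reverse columns and swap A<->T, C<->G: scoring the forward strand with
    # this matrix equals scoring the reverse complement with the original
    return pwm[::-1, ::-1]


def _window_scores(codes: np.ndarray, pwm: np.ndarray) -> np.ndarray:
    """Score every window; windows containing N (code -1) become -inf."""
    w = pwm.shape[1]
    n_win = codes.size - w + 1
    if n_win <= 0:
        return np.empty(0)
    safe = np.where(codes < 0, 0, codes)
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    for j in range(w):
        seg = codes[j : j + n_win]
        scores += pwm[safe[j : j + n_win], j]
        valid &= seg >= 0
    scores[~valid] = -np.inf
    return scores


def scan_sequence(
    seq: str, pfm: PFM, threshold: float, background: np.ndarray = UNIFORM_BACKGROUND,
    pseudocount: float = 1.0,
) -> list[tuple[int, str, float]]:
    """All (offset, strand, score) matches of one motif in one sequence."""
    codes = _encode(seq.upper())
    pwm = pfm_to_pwm(pfm, background, pseudocount)
    hits: list[tuple[int, str, float]] = []
    for strand, mat in (("+", pwm), ("-", _revcomp_pwm(pwm))):
        scores = _window_scores(codes, mat)
        for off in np.nonzero(scores >= threshold)[0]:
            hits.append((int(off), strand, float(scores[off])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def scan_motifs(
    seq_store: SequenceStore,
    peaks: Sequence[NarrowPeakRecord],
    pfms: Sequence[PFM],
    thresholds: Mapping[str, float] | None = None,
    p_cutoff: float = 5e-5,
    background: np.ndarray = UNIFORM_BACKGROUND,
    pseudocount: float = 1.0,
) -> list[MotifHit]:
    """Scan peak sequences on both strands against each PFM.

    `thresholds` maps motif_id -> score threshold; when omitted, thresholds
    are derived from `p_cutoff` via the exact null score distribution.
    Windows containing N never match.
    """
    if thresholds is None:
        thresholds = {
            p.motif_id: pwm_threshold(p, background, p_cutoff, pseudocount)
            for p in pfms
        }
    hits: list[MotifHit] = []
    for peak in peaks:
        seq = seq_store.fetch_interval(peak.interval)
        for pfm in pfms:
            for off, strand, score in scan_sequence(
                seq, pfm, thresholds[pfm.motif_id], background, pseudocount
            ):
                hits.append(MotifHit(peak, pfm.motif_id, off, strand, score))
    return hits
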