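"""TFBS gain/loss classification of variants by PWM scanning.

A variant is scanned in a reference sequence window centered on its
position and in the same window with the alternate base substituted. For
each position-weight matrix, a hit is a window offset whose relative
log-odds score, (score - min) / (max - min), reaches a threshold (default
0.85; both strands scanned). The variant is a TFBS-gain for a motif when a
hit overlapping the variant position exists in the alternate sequence but
not the reference, a TFBS-loss for the converse, "both" when different
motifs are gained and lost, and "none" otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .types import SomalexError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PwmHit:
    offset: int
    strand: str  # '+' or '-'
    rel_score: float


class ScoredMotif:
    """A PWM in log-odds form with min/max normalization.

    Column probabilities are regularized with a small pseudocount before
    the log2(odds vs uniform background) conversion, so zero counts stay
    finite. When all columns are flat (max == min) every window scores a
    relative 0.
    """

    def __init__(self, name: str, counts: np.ndarray, pseudocount: float = 0.01):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x length matrix (ACGT rows)")
        if (counts < 0).any():
            raise ValueError("PWM counts must be non-negative")
        self.name = name
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("every PWM column needs positive total count")
        freq = (counts + pseudocount) / (totals + 4 * pseudocount)
        self.log_odds = np.log2(freq / 0.25)
        self.min_score = float(self.log_odds.min(axis=0).sum())
        self.max_score = float(self.log_odds.max(axis=0).sum())

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]

    @classmethod
    def from_biopython(cls, motif, pseudocount: float = 0.01) -> "ScoredMotif":
        counts = np.array([motif.counts[b] for b in "ACGT"], dtype=float)
        name = getattr(motif, "matrix_id", None) or motif.name or "motif"
        return cls(name, counts, pseudocount=pseudocount)

    def _score_at(self, seq: str, offset: int) -> float:
        return float(
            sum(
                self.log_odds[_BASE_INDEX[seq[offset + i]], i]
                for i in range(self.length)
            )
        )

    def relative_scores(self, seq: str) -> np.ndarray:
        """Relative score of every window of ``seq`` on the given strand."""
        n = len(seq) - self.length + 1
        if n < 1:
            return np.empty(0)
        span = self.max_score - self.min_score
        idx = np.array([_BASE_INDEX[b] for b in seq])
        raw = np.array(
            [self.log_odds[idx[o : o + self.length], np.arange(self.length)].sum()
             for o in range(n)]
        )
        if span == 0:
            return np.zeros(n)
        return (raw - self.min_score) / span


def _validate_seq(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise SomalexError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    return seq


def scan_pwm(
    seq: str,
    motif: ScoredMotif,
    rel_score_threshold: float = 0.85,
    scan_both_strands: bool = True,
) -> List[PwmHit]:
    """All motif hits in ``seq`` at or above the relative-score threshold.

    Reverse-strand hits are reported at the forward-strand offset of the
    window they occupy.
    """
    seq = _validate_seq(seq)
    if len(seq) < motif.length:
        raise SomalexError(
            f"sequence shorter than motif {motif.name} ({motif.length} nt)"
        )
    hits: List[PwmHit] = []
    fwd = motif.relative_scores(seq)
    for o, s in enumerate(fwd):
        if s >= rel_score_threshold:
            hits.append(PwmHit(offset=o, strand="+", rel_score=float(s)))
    if scan_both_strands:
        rev = motif.relative_scores(reverse_complement(seq))
        n = len(rev)
        for o, s in enumerate(rev):
            if s >= rel_score_threshold:
                hits.append(
                    PwmHit(offset=n - 1 - o, strand="-", rel_score=float(s))
                )
    return hits


@dataclass(frozen=True)
class TfbsResult:
    category: str  # 'gain' | 'loss' | 'both' | 'none'
    gained_motifs: Tuple[str, ...]
    lost_motifs: Tuple[str, ...]


def _hits_over_center(
    seq: str, motif: ScoredMotif, center: int, threshold: float, both: bool
) -> bool:
    for h in scan_pwm(seq, motif, threshold, both):
        if h.offset <= center <= h.offset + motif.length - 1:
            return True
    return False


def classify_tfbs_change(
    ref_window: str,
    ref_allele: str,
    alt_allele: str,
    motifs: Sequence[ScoredMotif],
    *,
    center: Optional[int] = None,
    rel_score_threshold: float = 0.85,
    scan_both_strands: bool = True,
) -> TfbsResult:
    """Classify one variant as TFBS gain / loss / both / none.

    ``ref_window`` is reference sequence centered on the variant (or with
    an explicit ``center`` index) and must extend at least motif length - 1
    on each side. The window center must carry ``ref_allele``.
    """
    ref_window = _validate_seq(ref_window)
    if center is None:
        center = len(ref_window) // 2
    if ref_window[center] != ref_allele.upper():
        raise SomalexError(
            f"window center base {ref_window[center]!r} != ref allele "
            f"{ref_allele!r}"
        )
    if motifs:
        need = max(m.length for m in motifs) - 1
        if center < need or len(ref_window) - 1 - center < need:
            raise SomalexError(
                f"window too short: need {need} nt on each side of the variant"
            )
    alt_window = ref_window[:center] + alt_allele.upper() + ref_window[center + 1 :]

    gained, lost = [], []
    for m in motifs:
        in_ref = _hits_over_center(
            ref_window, m, center, rel_score_threshold, scan_both_strands
        )
        in_alt = _hits_over_center(
            alt_window, m, center, rel_score_threshold, scan_both_strands
        )
        if in_alt and not in_ref:
            gained.append(m.name)
        elif in_ref and not in_alt:
            lost.append(m.name)
    if gained and lost:
        category = "both"
    elif gained:
        category = "gain"
    elif lost:
        category = "loss"
    else:
        category = "none"
    return TfbsResult(category, tuple(gained), tuple(lost))


def classify_variants(
    variants,
    genome,
    motifs: Sequence[ScoredMotif],
    *,
    rel_score_threshold: float = 0.85,
    scan_both_strands: bool = True,
    flank: Optional[int] = None,
):
    """Per-variant TFBS table (variant key fields, category, motif IDs).

    ``genome`` maps chromosome -> sequence (str or pyfaidx record).
    Variants whose window would run off the contig are reported as
    'unscored'.
    """
    import pandas as pd

    from .data_io import fetch_window

    if flank is None:
        flank = (max((m.length for m in motifs), default=1) - 1) + 4
    rows = []
    for v in variants.itertuples(index=False):
        rec = {
            "sample_id": v.sample_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref_allele": v.ref_allele,
            "alt_allele": v.alt_allele,
        }
        try:
            window = fetch_window(genome, v.chrom, int(v.pos), flank)
            res = classify_tfbs_change(
                window,
                v.ref_allele,
                v.alt_allele,
                motifs,
                rel_score_threshold=rel_score_threshold,
                scan_both_strands=scan_both_strands,
            )
            rec.update(
                category=res.category,
                gained_motifs=",".join(res.gained_motifs),
                lost_motifs=",".join(res.lost_motifs),
            )
        except SomalexError:
            rec.update(category="unscored", gained_motifs="", lost_motifs="")
        rows.append(rec)
    return pd.DataFrame(rows)
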