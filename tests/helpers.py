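"""Hand-built transcript fixtures for the NMD rule engine, independent of
the synthetic-cohort generator's gene construction."""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional, Tuple

from somalex.types import TranscriptModel

# four 200-nt exons, 100-nt introns; CDS spans mRNA offsets 20..739
STD_EXONS = ((1000, 1199), (1300, 1499), (1600, 1799), (1900, 2099))
# 200 / 700 / 200-nt exons; CDS spans mRNA offsets 20..979
LONG_EXONS = ((1000, 1199), (1300, 1999), (2100, 2299))
SINGLE_EXON = ((1000, 1799),)


def make_transcript(
    exons: Tuple[Tuple[int, int], ...],
    cds_m: Tuple[int, int],
    strand: str = "+",
    half_life: Optional[float] = None,
    insensitive: bool = False,
    tid: str = "T1",
) -> TranscriptModel:
    skeleton = TranscriptModel(
        transcript_id=tid, gene="G1", chrom="chr1", strand=strand, exons=exons
    )
    g1 = skeleton.genomic_pos(cds_m[0])
    g2 = skeleton.genomic_pos(cds_m[1])
    return dataclasses.replace(
        skeleton,
        cds_start=min(g1, g2),
        cds_end=max(g1, g2),
        half_life_hours=half_life,
        nmd_insensitive=insensitive,
    )


def mirror(t: TranscriptModel, pos: int, axis: int = 100_000):
    """Reflect a transcript and a position through a coordinate axis,
    flipping the strand. The spliced-coordinate geometry is unchanged."""
    exons = tuple(sorted((axis - e, axis - s) for s, e in t.exons))
    mirrored = dataclasses.replace(
        t,
        strand="-" if t.strand == "+" else "+",
        exons=exons,
        cds_start=axis - t.cds_end if t.cds_end is not None else None,
        cds_end=axis - t.cds_start if t.cds_start is not None else None,
    )
    return mirrored, axis - pos


def cds_seq_with_aug(length: int = 720, aug_at: Optional[int] = 300) -> str:
    """A CDS of Cs with an optional in-frame ATG planted at a codon start."""
    seq = ["C"] * length
    if aug_at is not None:
        assert aug_at % 3 == 0
        seq[aug_at : aug_at + 3] = "ATG"
    return "".join(seq)
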