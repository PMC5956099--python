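"""NMD-elicit vs NMD-escape classification of premature terminating variants.

A PTV-bearing transcript is predicted to escape nonsense-mediated decay
(NMD) when any of six rules fires:

1. the premature termination codon (PTC) lies in the last exon or no more
   than 50 nt upstream of the last exon-exon junction;
2. the PTC lies within the first 200 coding nucleotides and an
   alternative in-frame AUG exists in the CDS downstream of it
   (translation re-initiation);
3. the PTC lies in a long exon (> 400 nt by default) and within 250 nt of
   the closest exon boundary;
4. the transcript is short-lived (half-life < 1 h);
5. the transcript is single-exon;
6. the gene is on a curated NMD-insensitive list.

The verdict is "escape" iff any flag is true, otherwise "elicit". Rule 1
implements the canonical last-junction boundary rule; a configuration
switch (``rule1_literal``) inverts it for sensitivity analyses. All
distances are measured in spliced mRNA coordinates and are strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Set

import pandas as pd

from .types import SomalexError, TranscriptModel, UndefinedValueError, VariantSite

ESCAPE_RULES = (
    "last_eej_proximal",
    "start_proximal_alt_aug",
    "long_exon_boundary",
    "short_half_life",
    "single_exon",
    "nmd_insensitive",
)


@dataclass(frozen=True)
class NMDConfig:
    last_eej_window_nt: int = 50
    start_proximal_window_nt: int = 200
    long_exon_threshold_nt: int = 400
    boundary_window_nt: int = 250
    short_half_life_hours: float = 1.0
    #: If True, rule 1 follows the literal "more than 50 bp upstream"
    #: wording instead of the canonical boundary-rule direction.
    rule1_literal: bool = False


@dataclass(frozen=True)
class PtcLocation:
    """Spliced-mRNA coordinates of a premature termination codon."""

    ptc_cds_offset: int  # nt from the first coding base, 0-based
    exon_index: int      # 1-based, transcription order
    exon_length: int
    #: nt from the PTC to the last exon-exon junction (the junction sits
    #: after the last base of the penultimate exon); negative when the PTC
    #: is in the last exon, None for single-exon transcripts.
    dist_last_eej: Optional[int]
    dist_nearest_exon_boundary: int


@dataclass(frozen=True)
class NMDAnnotation:
    variant_key: str
    transcript_id: str
    location: PtcLocation
    flags: Dict[str, bool]
    verdict: str  # "elicit" | "escape"

    def __post_init__(self) -> None:
        expected = "escape" if any(self.flags.values()) else "elicit"
        if self.verdict != expected:
            raise ValueError("verdict inconsistent with rule flags")


def locate_ptc(gpos: int, t: TranscriptModel) -> PtcLocation:
    """Locate a PTC (genomic position of the variant) on a transcript.

    Raises when the transcript is non-coding or the position lies outside
    its CDS.
    """
    if not t.is_coding:
        raise SomalexError(f"transcript {t.transcript_id} is non-coding")
    m = t.mrna_pos(gpos)  # raises if not exonic
    offset = m - t.cds_start_m
    if offset < 0 or m > t.cds_end_m:
        raise SomalexError(
            f"position {gpos} outside the CDS of {t.transcript_id}"
        )
    exon_index, exon_length, in_exon = t.exon_at(gpos)
    if t.n_exons > 1:
        # mRNA offset of the last base of the penultimate exon
        last_junction_m = t.mrna_length - (
            t.exons_tx_order[-1][1] - t.exons_tx_order[-1][0] + 1
        ) - 1
        dist_last_eej: Optional[int] = last_junction_m - m
    else:
        dist_last_eej = None
    return PtcLocation(
        ptc_cds_offset=offset,
        exon_index=exon_index,
        exon_length=exon_length,
        dist_last_eej=dist_last_eej,
        dist_nearest_exon_boundary=min(in_exon, exon_length - 1 - in_exon),
    )


def has_downstream_inframe_aug(cds_sequence: str, ptc_cds_offset: int) -> bool:
    """True iff an in-frame AUG codon starts strictly downstream of the PTC
    within the CDS (codon positions after the PTC's codon)."""
    seq = cds_sequence.upper()
    first = (ptc_cds_offset // 3 + 1) * 3
    return any(seq[i : i + 3] == "ATG" for i in range(first, len(seq) - 2, 3))


def classify_nmd(
    gpos: int,
    t: TranscriptModel,
    *,
    variant_key: str = "",
    half_life_hours: Optional[float] = None,
    nmd_insensitive: bool = False,
    cds_sequence: Optional[str] = None,
    config: NMDConfig = NMDConfig(),
) -> NMDAnnotation:
    """Evaluate the six escape rules for one PTV on one transcript.

    ``half_life_hours`` overrides the transcript's own annotation when
    given; a missing half-life leaves rule 4 false (assumed stable).
    ``cds_sequence`` (spliced, coding strand) is needed for rule 2; without
    it the alternative-AUG flag is false.
    """
    hl = half_life_hours if half_life_hours is not None else t.half_life_hours
    insensitive = nmd_insensitive or t.nmd_insensitive
    loc = locate_ptc(gpos, t)

    if loc.dist_last_eej is None:
        rule1 = False  # single exon: covered by rule 5
    elif config.rule1_literal:
        rule1 = loc.dist_last_eej > config.last_eej_window_nt
    else:
        rule1 = loc.dist_last_eej <= config.last_eej_window_nt

    rule2 = (
        loc.ptc_cds_offset < config.start_proximal_window_nt
        and cds_sequence is not None
        and has_downstream_inframe_aug(cds_sequence, loc.ptc_cds_offset)
    )
    rule3 = (
        loc.exon_length > config.long_exon_threshold_nt
        and loc.dist_nearest_exon_boundary < config.boundary_window_nt
    )
    rule4 = hl is not None and hl < config.short_half_life_hours
    rule5 = t.n_exons == 1
    rule6 = insensitive

    flags = dict(
        zip(ESCAPE_RULES, (rule1, rule2, rule3, rule4, rule5, rule6))
    )
    verdict = "escape" if any(flags.values()) else "elicit"
    return NMDAnnotation(
        variant_key=variant_key,
        transcript_id=t.transcript_id,
        location=loc,
        flags=flags,
        verdict=verdict,
    )


def annotate_ptvs(
    variants: pd.DataFrame,
    models: Mapping[str, TranscriptModel],
    genome: Optional[Mapping[str, object]] = None,
    half_life: Optional[Mapping[str, float]] = None,
    insensitive_genes: Optional[Set[str]] = None,
    config: NMDConfig = NMDConfig(),
) -> pd.DataFrame:
    """NMD annotation table for every PTV row of ``variants``.

    The transcript is taken from the variant record; when absent or
    unknown, the gene's longest-CDS model is used as a fallback. PTVs that
    cannot be located on any coding model are reported with verdict
    'unresolved'. ``genome`` (mapping chrom -> sequence) enables the
    alternative-AUG rule.
    """
    from .data_io import fetch_sequence  # local import to avoid a cycle

    half_life = half_life or {}
    insensitive_genes = insensitive_genes or set()
    by_gene: Dict[str, TranscriptModel] = {}
    for t in models.values():
        if t.is_coding:
            best = by_gene.get(t.gene)
            if best is None or t.cds_length > best.cds_length:
                by_gene[t.gene] = t

    rows = []
    for v in variants.itertuples(index=False):
        if v.consequence != "PTV":
            continue
        t = models.get(getattr(v, "transcript_id", "") or "")
        if t is None or not t.is_coding:
            t = by_gene.get(v.gene)
        key = f"{v.sample_id}:{v.chrom}:{v.pos}:{v.ref_allele}>{v.alt_allele}"
        base = {
            "variant_key": key,
            "sample_id": v.sample_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "gene": v.gene,
        }
        if t is None:
            rows.append({**base, "transcript_id": "", "verdict": "unresolved"})
            continue
        cds_seq = None
        if genome is not None:
            mrna = fetch_sequence(genome, t)
            cds_seq = mrna[t.cds_start_m : t.cds_end_m + 1]
        try:
            ann = classify_nmd(
                int(v.pos),
                t,
                variant_key=key,
                half_life_hours=half_life.get(t.transcript_id),
                nmd_insensitive=t.gene in insensitive_genes,
                cds_sequence=cds_seq,
                config=config,
            )
        except SomalexError:
            rows.append(
                {**base, "transcript_id": t.transcript_id, "verdict": "unresolved"}
            )
            continue
        loc = ann.location
        rows.append(
            {
                **base,
                "transcript_id": t.transcript_id,
                "ptc_cds_offset": loc.ptc_cds_offset,
                "exon_index": loc.exon_index,
                "exon_length": loc.exon_length,
                "dist_last_eej": loc.dist_last_eej,
                "dist_nearest_exon_boundary": loc.dist_nearest_exon_boundary,
                **ann.flags,
                "verdict": ann.verdict,
            }
        )
    return pd.DataFrame(rows)
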