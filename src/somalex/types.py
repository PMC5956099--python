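"""Core domain types for somatic allele-expression analysis.

The unit of analysis is a somatic single-nucleotide variant observed in four
sequencing datasets from the same patient: normal exome (Nex), normal
transcriptome (Ntr), tumor exome (Tex) and tumor transcriptome (Ttr).
Coordinates are 1-based inclusive throughout (MAF convention); BED input is
converted on ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

VALID_BASES = frozenset("ACGT")

#: Predicted effect of the variant on the protein. PTV = premature
#: terminating (stop-gain) variant.
CONSEQUENCES = ("PTV", "missense", "silent", "splice", "other")

#: The four per-patient sequencing datasets.
DATASETS = ("nex", "ntr", "tex", "ttr")

#: Tumor-purity estimation methods and the single-letter prefix used for
#: purity-weighted V_R:D columns (aV_R:D = ABSOLUTE-weighted, etc.).
PURITY_METHODS = ("ESTIMATE", "ABSOLUTE", "LUMP", "IHC", "CPE")
PURITY_PREFIX = {"ESTIMATE": "e", "ABSOLUTE": "a", "LUMP": "l", "IHC": "i", "CPE": "c"}


class SomalexError(Exception):
    """Base class for all errors raised by this package."""


class UndefinedValueError(SomalexError):
    """A quantity is mathematically undefined for the given inputs
    (e.g. VAF at zero depth, V_R:D at VAF_tDNA = 0)."""


class InsufficientDepthError(SomalexError):
    """Read depth is below the configured minimum for a status call."""


class InputFormatError(SomalexError):
    """An input file violates its declared dialect."""


@dataclass(frozen=True)
class VariantSite:
    """One somatic SNV in one sample."""

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    cancer_type: str = ""
    gene: str = ""
    transcript_id: str = ""
    consequence: str = "other"
    is_cgc: bool = False
    pathogenicity: Optional[Mapping[str, object]] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise ValueError(
                f"alleles must be single bases in ACGT, got "
                f"{self.ref_allele!r}>{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele and alt_allele must differ")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def key(self) -> str:
        """Stable per-sample variant identifier."""
        return f"{self.sample_id}:{self.chrom}:{self.pos}:{self.ref_allele}>{self.alt_allele}"


@dataclass(frozen=True)
class QuadCounts:
    """Reference/variant read counts for one variant across the four datasets."""

    nex_ref: int = 0
    nex_var: int = 0
    ntr_ref: int = 0
    ntr_var: int = 0
    tex_ref: int = 0
    tex_var: int = 0
    ttr_ref: int = 0
    ttr_var: int = 0

    def __post_init__(self) -> None:
        for name in (
            "nex_ref", "nex_var", "ntr_ref", "ntr_var",
            "tex_ref", "tex_var", "ttr_ref", "ttr_var",
        ):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    def counts(self, dataset: str) -> Tuple[int, int]:
        """(n_ref, n_var) for one of nex/ntr/tex/ttr."""
        if dataset not in DATASETS:
            raise ValueError(f"unknown dataset {dataset!r}")
        return getattr(self, f"{dataset}_ref"), getattr(self, f"{dataset}_var")

    def depth(self, dataset: str) -> int:
        r, v = self.counts(dataset)
        return r + v


@dataclass(frozen=True)
class PurityEstimates:
    """Tumor-purity fractions for one sample, one per estimation method.

    Any subset of methods may be missing; downstream analyses require at
    least three of the five to be present.
    """

    estimate: Optional[float] = None
    absolute: Optional[float] = None
    lump: Optional[float] = None
    ihc: Optional[float] = None
    cpe: Optional[float] = None

    def __post_init__(self) -> None:
        for m in PURITY_METHODS:
            v = self.value(m)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"purity {m} outside [0, 1]: {v}")

    def value(self, method: str) -> Optional[float]:
        return getattr(self, method.lower())

    @property
    def n_available(self) -> int:
        return sum(self.value(m) is not None for m in PURITY_METHODS)

    def as_dict(self) -> dict:
        return {m: self.value(m) for m in PURITY_METHODS}


@dataclass(frozen=True)
class SegmentRecord:
    """One copy-number segment: mean is log2(copy-number/2)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    segment_mean: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start > end: {self.start} > {self.end}")


@dataclass(frozen=True)
class ExpressionPair:
    """Matched tumor/normal expression of one gene in one sample
    (FPKM-like non-negative abundances)."""

    gene: str
    sample_id: str
    tumor_expr: float
    normal_expr: float

    def __post_init__(self) -> None:
        if self.tumor_expr < 0 or self.normal_expr < 0:
            raise ValueError("expression abundances must be non-negative")


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` are genomic 1-based inclusive intervals, stored in ascending
    genomic order and non-overlapping; transcription order follows
    ``strand``. ``cds_start``/``cds_end`` are the genomic low/high bounds of
    the coding region (the translation start is ``cds_start`` on '+' and
    ``cds_end`` on '-'). Non-coding transcripts carry ``cds_start is None``.
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    half_life_hours: Optional[float] = None
    nmd_insensitive: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon start > end in {self.transcript_id}")
            if prev_end is not None and s <= prev_end:
                raise ValueError(
                    f"exons overlap or are unsorted in {self.transcript_id}"
                )
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must both be set or both None")
        if self.cds_start is not None:
            if self.cds_start > self.cds_end:
                raise ValueError("cds_start > cds_end")
            for g in (self.cds_start, self.cds_end):
                if not self._in_exon(g):
                    raise ValueError(
                        f"CDS boundary {g} outside exons of {self.transcript_id}"
                    )
        if self.half_life_hours is not None and self.half_life_hours <= 0:
            raise ValueError("half_life_hours must be positive")

    def _in_exon(self, gpos: int) -> bool:
        return any(s <= gpos <= e for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exons_tx_order(self) -> Tuple[Tuple[int, int], ...]:
        """Exons ordered 5'->3' in transcription direction."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    @property
    def mrna_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def translation_start_g(self) -> int:
        if not self.is_coding:
            raise UndefinedValueError(f"{self.transcript_id} is non-coding")
        return self.cds_start if self.strand == "+" else self.cds_end

    @property
    def translation_end_g(self) -> int:
        if not self.is_coding:
            raise UndefinedValueError(f"{self.transcript_id} is non-coding")
        return self.cds_end if self.strand == "+" else self.cds_start

    def mrna_pos(self, gpos: int) -> int:
        """0-based offset of genomic position ``gpos`` in the spliced mRNA."""
        offset = 0
        for s, e in self.exons_tx_order:
            if s <= gpos <= e:
                return offset + (gpos - s if self.strand == "+" else e - gpos)
            offset += e - s + 1
        raise UndefinedValueError(
            f"position {gpos} is not exonic in {self.transcript_id}"
        )

    def genomic_pos(self, m: int) -> int:
        """Inverse of :meth:`mrna_pos`."""
        if m < 0 or m >= self.mrna_length:
            raise UndefinedValueError(f"mRNA offset {m} outside transcript")
        offset = 0
        for s, e in self.exons_tx_order:
            length = e - s + 1
            if m < offset + length:
                rel = m - offset
                return s + rel if self.strand == "+" else e - rel
            offset += length
        raise AssertionError("unreachable")

    def exon_at(self, gpos: int) -> Tuple[int, int, int]:
        """(1-based exon index in transcription order, exon length,
        0-based offset of ``gpos`` within the exon in transcription order)."""
        for i, (s, e) in enumerate(self.exons_tx_order, start=1):
            if s <= gpos <= e:
                off = gpos - s if self.strand == "+" else e - gpos
                return i, e - s + 1, off
        raise UndefinedValueError(
            f"position {gpos} is not exonic in {self.transcript_id}"
        )

    @property
    def cds_start_m(self) -> int:
        """mRNA offset of the first coding base."""
        return self.mrna_pos(self.translation_start_g)

    @property
    def cds_end_m(self) -> int:
        """mRNA offset of the last coding base."""
        return self.mrna_pos(self.translation_end_g)

    @property
    def cds_length(self) -> int:
        return self.cds_end_m - self.cds_start_m + 1
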