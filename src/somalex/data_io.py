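"""Readers and writers for every external format the pipeline touches.

Canonical formats: MAF (GDC dialect) or a light VCF dialect for variants,
GTF for gene models, BED (0-based half-open, converted to 1-based
inclusive on ingestion) for imprinted regions, JASPAR text for PWMs,
FASTA for reference sequence, and headered TSV tables for quad read
counts, purity, copy-number segments, expression, transcript half-lives
and gene lists. An optional pileup counter over coordinate-sorted
alignments can produce the quad count table; count tables remain the
canonical input so analyses never require alignment files.

All result tables are written as TSV with a header and a leading
provenance comment line, and round-trip bit-exactly through
:func:`write_table` / :func:`read_table`.
"""

from __future__ import annotations

import io
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .types import (
    InputFormatError,
    PURITY_METHODS,
    PurityEstimates,
    QuadCounts,
    SomalexError,
    TranscriptModel,
    VariantSite,
)

logger = logging.getLogger("somalex")

#: MAF Variant_Classification -> consequence mapping. Editable: callers may
#: update this module-level table to match their annotation vocabulary.
#: Splice-annotated classes are kept distinct so the filter cascade can
#: exclude them; anything unlisted maps to "other" (non-exonic scope).
MAF_CONSEQUENCE_MAP: Dict[str, str] = {
    "Nonsense_Mutation": "PTV",
    "Missense_Mutation": "missense",
    "Silent": "silent",
    "Splice_Site": "splice",
    "Splice_Region": "splice",
}

_MAF_REQUIRED = (
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Variant_Type",
    "Tumor_Sample_Barcode",
)

# ---------------------------------------------------------------------------
# variants


def read_variants(path, dialect: str = "maf") -> List[VariantSite]:
    """Read somatic SNVs from a MAF or VCF file.

    Indels and multi-allelic rows are rejected (counted in the log);
    coordinates are 1-based on return. MAF rows may carry an optional
    ``cancer_type`` column. The VCF dialect expects single-base REF/ALT
    and the INFO keys SAMPLE, GENE, CSQ (consequence), CANCER (optional).
    """
    if dialect == "maf":
        return _read_maf(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_maf(path) -> List[VariantSite]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in _MAF_REQUIRED:
        if col not in df.columns:
            raise InputFormatError(f"MAF is missing required column {col!r}")
    out: List[VariantSite] = []
    n_rejected = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        ref = str(row.Reference_Allele)
        alt = str(row.Tumor_Seq_Allele2)
        if row.Variant_Type != "SNP" or len(ref) != 1 or len(alt) != 1 or "," in alt:
            n_rejected += 1
            continue
        try:
            out.append(
                VariantSite(
                    sample_id=row.Tumor_Sample_Barcode,
                    cancer_type=str(getattr(row, "cancer_type", "") or ""),
                    chrom=str(row.Chromosome),
                    pos=int(row.Start_Position),
                    ref_allele=ref,
                    alt_allele=alt,
                    gene=str(row.Hugo_Symbol),
                    transcript_id=str(getattr(row, "Transcript_ID", "") or ""),
                    consequence=MAF_CONSEQUENCE_MAP.get(
                        str(row.Variant_Classification), "other"
                    ),
                )
            )
        except (ValueError, TypeError) as exc:
            raise InputFormatError(f"unparseable MAF row at line {i}: {exc}") from exc
    if n_rejected:
        logger.info("read_variants: rejected %d non-SNV MAF rows", n_rejected)
    return out


def _read_vcf(path) -> List[VariantSite]:
    from cyvcf2 import VCF

    out: List[VariantSite] = []
    n_rejected = 0
    for rec in VCF(str(path)):
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1:
            n_rejected += 1
            continue
        info = dict(rec.INFO)
        out.append(
            VariantSite(
                sample_id=str(info.get("SAMPLE", "")),
                cancer_type=str(info.get("CANCER", "")),
                chrom=rec.CHROM,
                pos=rec.POS,
                ref_allele=rec.REF,
                alt_allele=alts[0],
                gene=str(info.get("GENE", "")),
                transcript_id=str(info.get("TRANSCRIPT", "")),
                consequence=str(info.get("CSQ", "other")),
            )
        )
    if n_rejected:
        logger.info("read_variants: rejected %d non-SNV VCF rows", n_rejected)
    return out


def variants_to_frame(variants: Sequence[VariantSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [v.sample_id for v in variants],
            "cancer_type": [v.cancer_type for v in variants],
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "ref_allele": [v.ref_allele for v in variants],
            "alt_allele": [v.alt_allele for v in variants],
            "gene": [v.gene for v in variants],
            "transcript_id": [v.transcript_id for v in variants],
            "consequence": [v.consequence for v in variants],
        }
    )


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path) -> Dict[str, TranscriptModel]:
    """Parse a GTF into transcript models keyed by transcript_id.

    Exons are stored in ascending genomic order (transcription order is
    derived from the strand). Transcripts without CDS features are
    retained as non-coding and skipped by the NMD rule engine; a
    transcript with CDS but no exons is an error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: Dict[str, List[Tuple[int, int]]] = {}
    cds: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise InputFormatError(
                f"{feat.featuretype} feature without transcript_id at "
                f"{feat.seqid}:{feat.start}"
            )
        gene = feat.attributes.get(
            "gene_name", feat.attributes.get("gene_id", [""])
        )[0]
        meta[tid] = (gene, feat.seqid, feat.strand)
        target = exons if feat.featuretype == "exon" else cds
        target.setdefault(tid, []).append((feat.start, feat.end))

    models: Dict[str, TranscriptModel] = {}
    for tid, (gene, chrom, strand) in meta.items():
        if tid not in exons:
            raise InputFormatError(
                f"transcript {tid} has CDS but no exon features"
            )
        ex = tuple(sorted(exons[tid]))
        if tid in cds:
            cds_start = min(s for s, _ in cds[tid])
            cds_end = max(e for _, e in cds[tid])
        else:
            cds_start = cds_end = None
        models[tid] = TranscriptModel(
            transcript_id=tid,
            gene=gene,
            chrom=chrom,
            strand=strand,
            exons=ex,
            cds_start=cds_start,
            cds_end=cds_end,
        )
    n_noncoding = sum(not m.is_coding for m in models.values())
    if n_noncoding:
        logger.info(
            "read_gene_models: %d transcripts lack CDS (non-coding, "
            "excluded from NMD analysis)", n_noncoding,
        )
    return models


# ---------------------------------------------------------------------------
# pileup counting (optional; count tables are the canonical input)


def pileup_quad_counts(
    alignments: Mapping[str, str],
    site: VariantSite,
    min_base_quality: int = 20,
    min_mapping_quality: int = 20,
) -> QuadCounts:
    """Count reference/variant reads at a site in each of the four
    coordinate-sorted, indexed alignment files.

    ``alignments`` maps dataset name (nex/ntr/tex/ttr) to a BAM/CRAM path.
    Reads below either quality threshold, duplicates and QC failures are
    skipped; bases other than the ref or alt allele are ignored.
    """
    import pysam

    values = {}
    for dataset, path in alignments.items():
        with pysam.AlignmentFile(str(path)) as af:
            if site.chrom not in af.references:
                raise SomalexError(
                    f"contig {site.chrom!r} absent from the {dataset} alignment"
                )
            n_ref = n_var = 0
            for col in af.pileup(
                site.chrom,
                site.pos - 1,
                site.pos,
                truncate=True,
                stepper="samtools",  # honors quality filters, skips dup/QC-fail
                min_base_quality=min_base_quality,
                min_mapping_quality=min_mapping_quality,
            ):
                for pr in col.pileups:
                    if pr.is_del or pr.is_refskip or pr.query_position is None:
                        continue
                    base = pr.alignment.query_sequence[pr.query_position]
                    if base == site.ref_allele:
                        n_ref += 1
                    elif base == site.alt_allele:
                        n_var += 1
            values[f"{dataset}_ref"] = n_ref
            values[f"{dataset}_var"] = n_var
    return QuadCounts(**values)


# ---------------------------------------------------------------------------
# TSV tables

_COUNT_TABLE_COLS = [
    "sample_id", "chrom", "pos", "ref_allele", "alt_allele",
    "nex_ref", "nex_var", "ntr_ref", "ntr_var",
    "tex_ref", "tex_var", "ttr_ref", "ttr_var",
]


def read_counts_table(path) -> pd.DataFrame:
    df = read_table(path)
    for col in _COUNT_TABLE_COLS:
        if col not in df.columns:
            raise InputFormatError(f"counts table missing column {col!r}")
    num = df[_COUNT_TABLE_COLS[5:]]
    if (num < 0).any().any():
        raise InputFormatError("negative read counts in counts table")
    return df


def read_purity_table(path) -> pd.DataFrame:
    """Per-sample purity: sample_id plus one column per method; blank cells
    are missing estimates."""
    df = read_table(path)
    if "sample_id" not in df.columns:
        raise InputFormatError("purity table missing column 'sample_id'")
    for m in PURITY_METHODS:
        if m in df.columns:
            vals = df[m]
            bad = vals.dropna()
            if ((bad < 0) | (bad > 1)).any():
                raise InputFormatError(f"purity {m} outside [0, 1]")
    return df


def purity_row_to_estimates(row: pd.Series) -> PurityEstimates:
    kwargs = {}
    for m in PURITY_METHODS:
        v = row.get(m)
        kwargs[m.lower()] = None if v is None or pd.isna(v) else float(v)
    return PurityEstimates(**kwargs)


def read_segments_table(path) -> pd.DataFrame:
    df = read_table(path)
    for col in ("sample_id", "chrom", "start", "end", "segment_mean"):
        if col not in df.columns:
            raise InputFormatError(f"segments table missing column {col!r}")
    if (df["start"] > df["end"]).any():
        bad = df.index[df["start"] > df["end"]][0]
        raise InputFormatError(f"segment start > end at row {bad}")
    return df


def read_expression_table(path) -> pd.DataFrame:
    df = read_table(path)
    for col in ("gene", "sample_id", "tumor_expr", "normal_expr"):
        if col not in df.columns:
            raise InputFormatError(f"expression table missing column {col!r}")
    if (df[["tumor_expr", "normal_expr"]] < 0).any().any():
        raise InputFormatError("negative expression abundance")
    return df


def read_half_life_table(path) -> Dict[str, float]:
    df = read_table(path)
    for col in ("transcript_id", "half_life_hours"):
        if col not in df.columns:
            raise InputFormatError(f"half-life table missing column {col!r}")
    return dict(zip(df["transcript_id"], df["half_life_hours"].astype(float)))


def read_gene_list(path) -> Set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out: Set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def read_bed(path) -> List[Tuple[str, int, int]]:
    """BED intervals (0-based half-open) as 1-based inclusive tuples."""
    intervals = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise InputFormatError(f"BED line {i} has fewer than 3 fields")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if end < start:
            raise InputFormatError(f"BED line {i}: end < start")
        intervals.append((chrom, start + 1, end))
    return intervals


def read_jaspar_motifs(path, pseudocount: float = 0.01):
    """JASPAR-format PWMs as :class:`~somalex.tfbs_change.ScoredMotif`."""
    from Bio import motifs as bio_motifs

    from .tfbs_change import ScoredMotif

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    return [ScoredMotif.from_biopython(m, pseudocount=pseudocount) for m in parsed]


# ---------------------------------------------------------------------------
# sequence access


def open_fasta(path):
    """Open a FASTA through pyfaidx (creates the .fai index if absent)."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def fetch_window(genome, chrom: str, pos: int, flank: int) -> str:
    """Reference window of ``2*flank + 1`` bases centered on a 1-based
    position; raises when the window runs off the contig."""
    if chrom not in genome:
        raise SomalexError(f"contig {chrom!r} absent from the reference")
    seq = genome[chrom]
    n = len(seq)
    if pos - flank < 1 or pos + flank > n:
        raise SomalexError(
            f"window around {chrom}:{pos} extends beyond the contig"
        )
    return str(seq[pos - flank - 1 : pos + flank]).upper()


def fetch_sequence(genome, t: TranscriptModel) -> str:
    """Spliced mRNA sequence of a transcript from a genome mapping."""
    from .tfbs_change import reverse_complement

    parts = [str(genome[t.chrom][s - 1 : e]).upper() for s, e in t.exons]
    seq = "".join(parts)
    return reverse_complement(seq) if t.strand == "-" else seq


# ---------------------------------------------------------------------------
# generic TSV round-trip


def write_table(df: pd.DataFrame, path, comment: Optional[str] = None) -> None:
    """Write a TSV with a provenance comment line and a header.

    Floats use Python's shortest-repr formatting, so reading the file back
    reproduces the values bit-exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# somalex v{__version__}" + (f" | {comment}" if comment else "") + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    # round_trip parsing so written floats come back bit-exactly
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
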