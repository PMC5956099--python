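"""Synthetic study generator with recorded ground truth.

Produces a complete input bundle — somatic variants (MAF), quad read
counts, gene models (GTF), reference genome (FASTA), imprinted regions
(BED), purity estimates, copy-number segments, matched tumor/normal
expression, transcript half-lives, gene lists and a JASPAR PWM set —
under a generative model whose parameters are serialized alongside the
outputs, so every pipeline stage can be exercised against known truth.

Generative model
----------------
Each somatic variant is clonal and heterozygous in a diploid tumor
(f_D = 0.5) admixed with diploid normal tissue at tumor purity pi, so the
expected tumor-DNA variant fraction is v = f_D * pi. Allelic selection in
the transcriptome acts as an odds multiplier s on the variant allele:
mu = s*v / (s*v + 1 - v), which makes V_R:D approximately s near
v = 0.5 and is invertible. PTVs on transcripts that elicit
nonsense-mediated decay have their variant-allele share further degraded
by a factor (1 - d), renormalized. A small fraction of variants undergo
mono-allelic transcription events (variant- or reference-allele
silencing), producing the SOM-L / SOM-E extremes. Observed counts are
binomial at a sampled depth with a per-read sequencing error rate;
normal-sample counts carry error-rate variant reads only (except planted
germline contaminants). Tumor expression equals normal expression times
2**beta, with beta correlated (Spearman-inducing Gaussian copula) with
log(s) at a configurable rho.

Gene models cover archetypes that make every NMD escape rule fire in
truth: last-exon / junction-proximal PTCs, start-proximal PTCs with a
planted downstream in-frame AUG, long-exon PTCs near an exon boundary,
short-lived transcripts, single-exon genes and NMD-insensitive genes.
TFBS gains and losses are planted by writing near-consensus or consensus
motif occurrences into the genome around selected variant positions.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__, expression_status
from .tfbs_change import ScoredMotif
from .types import SomalexError, TranscriptModel

# ---------------------------------------------------------------------------
# configuration

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class CohortConfig:
    """Study conditions of the default synthetic cohort.

    The defaults describe a mid-sized multi-cancer cohort: 60 patients in
    five cancer types, ~33 somatic SNVs per patient (~2000 variants),
    tumor purity centered at 0.65, sequencing depth ~100x in the tumor
    datasets, mild negative selection on PTVs, NMD degradation of 0.8 on
    NMD-elicit PTV transcripts, and a Gaussian-copula correlation of 0.3
    between log selection and the log2 expression change.
    """

    n_samples: int = 60
    cancer_types: Tuple[str, ...] = ("BLCA", "BRCA", "HNSC", "KIRC", "LUAD")
    mean_variants_per_sample: float = 33.0
    n_genes: int = 400
    cgc_gene_fraction: float = 0.10

    frac_ptv: float = 0.10
    frac_missense: float = 0.60
    frac_silent: float = 0.30

    # tumor purity ~ Beta(alpha, beta); per-method estimates add noise
    purity_alpha: float = 6.5
    purity_beta: float = 3.5
    purity_fixed: Optional[float] = None
    purity_noise_sd: float = 0.04
    purity_method_presence: float = 0.95

    f_dna: float = 0.5  # clonal heterozygous, diploid
    depth_tumor_dna: float = 100.0
    depth_tumor_rna: float = 100.0
    depth_normal_dna: float = 60.0
    depth_normal_rna: float = 40.0
    depth_fixed: bool = False  # Poisson depths unless True
    seq_error_rate: float = 0.005

    sigma_log_selection: float = 0.5  # natural-log scale
    ptv_log_selection_shift: float = -0.4  # mild negative selection on PTVs
    rho_selection_expression: float = 0.3
    sd_log2_expression_change: float = 1.0
    expression_noise_sd_log2: float = 0.1
    median_normal_expression: float = 20.0

    nmd_degradation: float = 0.8
    ptv_elicit_fraction: float = 0.5

    p_variant_allele_silenced: float = 0.12
    p_reference_allele_silenced: float = 0.05

    # planned-filter fractions (exercise the exclusion cascade)
    p_planned_germline: float = 0.02
    p_planned_low_depth: float = 0.02
    p_planned_chrx: float = 0.02
    p_planned_imprinted: float = 0.02

    n_hypermutators: int = 1
    hypermutator_load: float = 6.0

    frac_tfbs_gain: float = 0.10
    frac_tfbs_loss: float = 0.08

    segment_mean_sd: float = 0.15

    def __post_init__(self) -> None:
        fr = self.frac_ptv + self.frac_missense + self.frac_silent
        if abs(fr - 1.0) > 1e-9:
            raise SomalexError("consequence fractions must sum to 1")
        if not (0.0 <= self.nmd_degradation <= 1.0):
            raise SomalexError("nmd_degradation must lie in [0, 1]")
        if self.n_samples < 1 or self.n_genes < 20:
            raise SomalexError("cohort too small to generate")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cancer_types"] = list(self.cancer_types)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "cancer_types" in d:
            d["cancer_types"] = tuple(d["cancer_types"])
        return cls(**d)


# exon layouts (offsets within the gene, 1-based lengths) and the mRNA
# windows used to place PTVs so that the intended NMD outcome holds
_STRUCTURES = {
    "A": dict(exon_offsets=[(0, 199), (300, 499), (600, 799), (900, 1099)],
              cds_m=(20, 739)),
    "B": dict(exon_offsets=[(0, 199), (300, 999), (1100, 1299)],
              cds_m=(20, 979)),
    "C": dict(exon_offsets=[(0, 799)], cds_m=(20, 739)),
}

_ARCHETYPE_STRUCTURE = {
    "standard": "A",
    "atg": "A",
    "longexon": "B",
    "shortlife": "A",
    "singleexon": "C",
    "insensitive": "A",
    "chrx": "A",
    "imprinted": "A",
}

_ARCHETYPE_FRACTIONS = {
    "standard": 0.58,
    "atg": 0.08,
    "longexon": 0.08,
    "shortlife": 0.08,
    "singleexon": 0.07,
    "insensitive": 0.07,
    "chrx": 0.02,
    "imprinted": 0.02,
}

# mRNA windows (inclusive) per intended PTV outcome
_W_ELICIT = (430, 545)   # structure A exon 3, every escape rule false
_W_LAST = (610, 730)     # structure A exon 4 (last exon)
_W_START = (40, 180)     # structure A, CDS offset < 200 ("atg" genes)
_W_LONG = (230, 420)     # structure B exon 2 (700 nt), near 5' boundary
_W_SINGLE = (300, 500)   # structure C, away from boundaries

#: escape rule -> (host archetype, PTV window, sampling weight)
_ESCAPE_ROUTES = {
    "last_eej_proximal": ("standard", _W_LAST, 0.30),
    "start_proximal_alt_aug": ("atg", _W_START, 0.15),
    "long_exon_boundary": ("longexon", _W_LONG, 0.15),
    "short_half_life": ("shortlife", _W_ELICIT, 0.15),
    "single_exon": ("singleexon", _W_SINGLE, 0.15),
    "nmd_insensitive": ("insensitive", _W_ELICIT, 0.10),
}

# planted ATG: codon starting at CDS offset 240 (mRNA 260), downstream of
# every PTC placed in _W_START and clear of their TFBS windows
_ATG_CDS_OFFSET = 240

_MOTIF_CONSENSUS = {"SYN1": "TGACGT", "SYN2": "CGGAAG"}


def default_motifs(pseudocount: float = 0.01) -> List[ScoredMotif]:
    """Two sharp synthetic 6-mer PWMs (97:1:1:1 per column), for which any
    single mismatch drops the relative score to 5/6 < 0.85."""
    out = []
    for name, consensus in _MOTIF_CONSENSUS.items():
        counts = np.ones((4, len(consensus)))
        for j, b in enumerate(consensus):
            counts["ACGT".index(b), j] = 97.0
        out.append(ScoredMotif(name, counts, pseudocount=pseudocount))
    return out


def jaspar_text() -> str:
    lines = []
    for name, consensus in _MOTIF_CONSENSUS.items():
        lines.append(f">{name} {name}")
        for b in "ACGT":
            row = ["97" if c == b else "1" for c in consensus]
            lines.append(f"{b}  [ " + " ".join(f"{v:>3}" for v in row) + " ]")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# cohort containers


@dataclass
class Cohort:
    config: CohortConfig
    seed: int
    samples: pd.DataFrame        # sample_id, cancer_type, purity_true
    variants: pd.DataFrame       # canonical variant table
    counts: pd.DataFrame         # quad counts per variant
    purity: pd.DataFrame         # sample_id + method columns
    segments: pd.DataFrame
    expression: pd.DataFrame
    models: Dict[str, TranscriptModel]
    genome: Dict[str, str]
    imprinted: List[Tuple[str, int, int]]   # 1-based inclusive
    cgc_genes: Set[str]
    insensitive_genes: Set[str]
    half_life: Dict[str, float]
    truth: pd.DataFrame


def _build_gene(
    name: str, archetype: str, chrom: str, strand: str, gene_start: int
) -> TranscriptModel:
    struct = _STRUCTURES[_ARCHETYPE_STRUCTURE[archetype]]
    exons = tuple(
        (gene_start + s, gene_start + e) for s, e in struct["exon_offsets"]
    )
    skeleton = TranscriptModel(
        transcript_id=f"T_{name}", gene=name, chrom=chrom, strand=strand,
        exons=exons,
    )
    lo_m, hi_m = struct["cds_m"]
    g1, g2 = skeleton.genomic_pos(lo_m), skeleton.genomic_pos(hi_m)
    return dataclasses.replace(
        skeleton, cds_start=min(g1, g2), cds_end=max(g1, g2)
    )


def _assign_archetypes(n_genes: int, rng: np.random.Generator) -> List[str]:
    names = list(_ARCHETYPE_FRACTIONS)
    counts = [int(round(_ARCHETYPE_FRACTIONS[a] * n_genes)) for a in names]
    counts[0] += n_genes - sum(counts)  # absorb rounding into "standard"
    out: List[str] = []
    for a, c in zip(names, counts):
        out.extend([a] * c)
    rng.shuffle(out)
    return out


def _write_mrna_bases(
    genome: Dict[str, np.ndarray], t: TranscriptModel, m: int, bases: str
) -> None:
    """Write ``bases`` into the genome so that the transcript's mRNA reads
    them at offset ``m`` (strand-aware)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i, b in enumerate(bases):
        g = t.genomic_pos(m + i)
        out = b if t.strand == "+" else comp[b]
        genome[t.chrom][g - 1] = np.bytes_(out.encode())


# ---------------------------------------------------------------------------
# generation


def generate_cohort(
    config: Optional[CohortConfig] = None, seed: int = 0
) -> Cohort:
    """Deterministically generate a full synthetic study for one seed."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)

    # --- samples -----------------------------------------------------------
    n_types = len(cfg.cancer_types)
    sample_ids, cancer_types = [], []
    for i in range(cfg.n_samples):
        ct = cfg.cancer_types[i % n_types]
        sample_ids.append(f"{ct}-S{i:03d}")
        cancer_types.append(ct)
    if cfg.purity_fixed is not None:
        purity_true = np.full(cfg.n_samples, float(cfg.purity_fixed))
    else:
        purity_true = rng.beta(cfg.purity_alpha, cfg.purity_beta, cfg.n_samples)
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "cancer_type": cancer_types,
         "purity_true": purity_true}
    )

    purity_rows = []
    for sid, p in zip(sample_ids, purity_true):
        row = {"sample_id": sid}
        for m in ("ESTIMATE", "ABSOLUTE", "LUMP", "IHC", "CPE"):
            if rng.random() < cfg.purity_method_presence:
                row[m] = float(
                    np.clip(p + rng.normal(0, cfg.purity_noise_sd), 0.01, 1.0)
                )
            else:
                row[m] = np.nan
        purity_rows.append(row)
    purity = pd.DataFrame(purity_rows)

    # --- genes and genome --------------------------------------------------
    archetypes = _assign_archetypes(cfg.n_genes, rng)
    chroms = [f"chr{i}" for i in range(1, 6)]
    cursors = {c: 1000 for c in chroms + ["chrX"]}
    models: Dict[str, TranscriptModel] = {}
    gene_archetype: Dict[str, str] = {}
    by_archetype: Dict[str, List[str]] = {a: [] for a in _ARCHETYPE_FRACTIONS}
    half_life: Dict[str, float] = {}
    insensitive: Set[str] = set()
    imprinted: List[Tuple[str, int, int]] = []
    for i, arch in enumerate(archetypes):
        name = f"G{i:04d}"
        chrom = "chrX" if arch == "chrx" else chroms[i % len(chroms)]
        strand = "+" if i % 2 == 0 else "-"
        start = cursors[chrom]
        t = _build_gene(name, arch, chrom, strand, start)
        cursors[chrom] = t.exons[-1][1] + 2000
        models[t.transcript_id] = t
        gene_archetype[name] = arch
        by_archetype[arch].append(name)
        if arch == "shortlife":
            half_life[t.transcript_id] = float(rng.uniform(0.2, 0.8))
        else:
            half_life[t.transcript_id] = float(rng.uniform(2.0, 20.0))
        if arch == "insensitive":
            insensitive.add(name)
        if arch == "imprinted":
            imprinted.append((chrom, t.exons[0][0], t.exons[-1][1]))

    genome: Dict[str, np.ndarray] = {
        c: rng.choice(_BASES, size=cursors[c] + 1000)
        for c in chroms + ["chrX"]
    }
    model_by_gene = {t.gene: t for t in models.values()}
    for name in by_archetype["atg"]:
        t = model_by_gene[name]
        _write_mrna_bases(genome, t, t.cds_start_m + _ATG_CDS_OFFSET, "ATG")

    cgc = set(
        rng.choice(
            sorted(model_by_gene),
            size=int(round(cfg.cgc_gene_fraction * cfg.n_genes)),
            replace=False,
        )
    )

    # --- variant plan ------------------------------------------------------
    escape_rules = list(_ESCAPE_ROUTES)
    escape_w = np.array([_ESCAPE_ROUTES[r][2] for r in escape_rules])
    escape_w = escape_w / escape_w.sum()
    normal_pool = [
        g for g, a in gene_archetype.items() if a not in ("chrx", "imprinted")
    ]
    standard_pool = by_archetype["standard"]

    taken: Set[Tuple[str, str, int]] = set()
    plan: List[dict] = []
    for si, sid in enumerate(sample_ids):
        lam = cfg.mean_variants_per_sample
        if si < cfg.n_hypermutators:
            lam *= cfg.hypermutator_load
        n_var = max(1, int(rng.poisson(lam)))
        for _ in range(n_var):
            consequence = str(
                rng.choice(
                    ["PTV", "missense", "silent"],
                    p=[cfg.frac_ptv, cfg.frac_missense, cfg.frac_silent],
                )
            )
            u = rng.random()
            if u < cfg.p_planned_chrx and by_archetype["chrx"]:
                planned = "chrx"
            elif u < cfg.p_planned_chrx + cfg.p_planned_imprinted and by_archetype["imprinted"]:
                planned = "imprinted"
            else:
                u -= cfg.p_planned_chrx + cfg.p_planned_imprinted
                if u < cfg.p_planned_germline:
                    planned = "germline"
                elif u < cfg.p_planned_germline + cfg.p_planned_low_depth:
                    planned = "low_depth"
                else:
                    planned = "none"

            nmd_rule = ""
            verdict = ""
            if planned == "chrx":
                gene = str(rng.choice(by_archetype["chrx"]))
            elif planned == "imprinted":
                gene = str(rng.choice(by_archetype["imprinted"]))
            elif consequence == "PTV":
                if rng.random() < cfg.ptv_elicit_fraction:
                    verdict = "elicit"
                    gene = str(rng.choice(standard_pool))
                else:
                    rule = str(rng.choice(escape_rules, p=escape_w))
                    verdict = "escape"
                    nmd_rule = rule
                    gene = str(rng.choice(by_archetype[_ESCAPE_ROUTES[rule][0]]))
            else:
                gene = str(rng.choice(normal_pool))
            t = model_by_gene[gene]

            if consequence == "PTV" and planned not in ("chrx", "imprinted"):
                if verdict == "elicit":
                    w = _W_ELICIT
                else:
                    w = _ESCAPE_ROUTES[nmd_rule][1]
            else:
                w = (t.cds_start_m + 3, t.cds_end_m - 3)
                if consequence == "PTV":
                    # filtered variant; place in the always-elicit window
                    w = _W_ELICIT
                    verdict = "elicit"
            pos = None
            for _attempt in range(20):
                m = int(rng.integers(w[0], w[1] + 1))
                g = t.genomic_pos(m)
                if (sid, t.chrom, g) not in taken:
                    pos = g
                    break
            if pos is None:
                continue
            taken.add((sid, t.chrom, pos))

            if planned == "none":
                r = rng.random()
                if r < cfg.frac_tfbs_gain:
                    tfbs = "gain"
                elif r < cfg.frac_tfbs_gain + cfg.frac_tfbs_loss:
                    tfbs = "loss"
                else:
                    tfbs = "none"
            else:
                tfbs = "none"
            plan.append(
                dict(
                    sample_id=sid,
                    cancer_type=cancer_types[si],
                    gene=gene,
                    transcript_id=t.transcript_id,
                    chrom=t.chrom,
                    pos=pos,
                    consequence=consequence,
                    planned_filter=planned,
                    nmd_verdict="" if consequence != "PTV" else (verdict or "elicit"),
                    nmd_rule=nmd_rule,
                    tfbs_truth=tfbs,
                )
            )

    # --- TFBS planting -----------------------------------------------------
    motifs = default_motifs()
    motif_names = list(_MOTIF_CONSENSUS)
    planted_alt: Dict[Tuple[str, int], str] = {}
    tfbs_motif: List[str] = []
    for rec in plan:
        if rec["tfbs_truth"] == "none":
            tfbs_motif.append("")
            continue
        mname = str(rng.choice(motif_names))
        consensus = _MOTIF_CONSENSUS[mname]
        L = len(consensus)
        o = L // 2
        chrom, pos = rec["chrom"], rec["pos"]
        arr = genome[chrom]
        for j, b in enumerate(consensus):
            arr[pos - o - 1 + j] = np.bytes_(b.encode())
        if rec["tfbs_truth"] == "gain":
            others = [b for b in "ACGT" if b != consensus[o]]
            ref = str(rng.choice(others))
            arr[pos - 1] = np.bytes_(ref.encode())
            planted_alt[(chrom, pos)] = consensus[o]
        else:  # loss: reference carries the consensus, alt disrupts it
            others = [b for b in "ACGT" if b != consensus[o]]
            planted_alt[(chrom, pos)] = str(rng.choice(others))
        tfbs_motif.append(mname)

    genome_str = {c: arr.tobytes().decode() for c, arr in genome.items()}

    # --- alleles -----------------------------------------------------------
    refs, alts = [], []
    for rec in plan:
        ref = genome_str[rec["chrom"]][rec["pos"] - 1]
        alt = planted_alt.get((rec["chrom"], rec["pos"]))
        if alt is None or alt == ref:
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        refs.append(ref)
        alts.append(alt)

    df = pd.DataFrame(plan)
    df["ref_allele"] = refs
    df["alt_allele"] = alts
    df["tfbs_motif"] = tfbs_motif
    n = len(df)

    # --- selection, expression change, RNA allele share --------------------
    z1 = rng.normal(size=n)
    z2 = rng.normal(size=n)
    log_s = cfg.sigma_log_selection * z1
    log_s = np.where(
        df["consequence"] == "PTV", log_s + cfg.ptv_log_selection_shift, log_s
    )
    rho = cfg.rho_selection_expression
    beta = cfg.sd_log2_expression_change * (
        rho * z1 + math.sqrt(max(0.0, 1 - rho**2)) * z2
    )
    s = np.exp(log_s)

    pi = df["sample_id"].map(samples.set_index("sample_id")["purity_true"]).to_numpy()
    v = cfg.f_dna * pi
    mu = s * v / (s * v + (1 - v))
    is_elicit_ptv = (
        (df["consequence"] == "PTV") & (df["nmd_verdict"] == "elicit")
    ).to_numpy()
    d = cfg.nmd_degradation
    degraded = mu * (1 - d) / (mu * (1 - d) + (1 - mu))
    mu = np.where(is_elicit_ptv, degraded, mu)

    ev = rng.random(n)
    allelic_event = np.where(
        ev < cfg.p_variant_allele_silenced,
        "variant_silenced",
        np.where(
            ev < cfg.p_variant_allele_silenced + cfg.p_reference_allele_silenced,
            "reference_silenced",
            "none",
        ),
    )
    mu = np.where(allelic_event == "variant_silenced", 0.01, mu)
    mu = np.where(allelic_event == "reference_silenced", 0.98, mu)

    # --- observed read counts ----------------------------------------------
    e = cfg.seq_error_rate

    def draw_depth(mean: float, size: int) -> np.ndarray:
        if cfg.depth_fixed:
            return np.full(size, int(round(mean)), dtype=np.int64)
        return rng.poisson(mean, size)

    planned = df["planned_filter"].to_numpy()
    dep_tex = draw_depth(cfg.depth_tumor_dna, n)
    dep_ttr = np.where(
        planned == "low_depth",
        rng.poisson(5.0, n),
        draw_depth(cfg.depth_tumor_rna, n),
    )
    dep_nex = draw_depth(cfg.depth_normal_dna, n)
    dep_ntr = draw_depth(cfg.depth_normal_rna, n)

    p_dna = v * (1 - e) + (1 - v) * e
    p_rna = mu * (1 - e) + (1 - mu) * e
    p_norm = np.where(planned == "germline", 0.3, e)
    tex_var = rng.binomial(dep_tex, p_dna)
    ttr_var = rng.binomial(dep_ttr, p_rna)
    nex_var = rng.binomial(dep_nex, p_norm)
    ntr_var = rng.binomial(dep_ntr, p_norm)

    counts = pd.DataFrame(
        {
            "sample_id": df["sample_id"],
            "chrom": df["chrom"],
            "pos": df["pos"],
            "ref_allele": df["ref_allele"],
            "alt_allele": df["alt_allele"],
            "nex_ref": dep_nex - nex_var,
            "nex_var": nex_var,
            "ntr_ref": dep_ntr - ntr_var,
            "ntr_var": ntr_var,
            "tex_ref": dep_tex - tex_var,
            "tex_var": tex_var,
            "ttr_ref": dep_ttr - ttr_var,
            "ttr_var": ttr_var,
        }
    )

    # --- expression --------------------------------------------------------
    expr_pairs = df[["gene", "sample_id"]].drop_duplicates().reset_index(drop=True)
    idx_first = df.drop_duplicates(["gene", "sample_id"]).index.to_numpy()
    normal_expr = rng.lognormal(
        math.log(cfg.median_normal_expression), 1.0, len(expr_pairs)
    )
    noise = rng.normal(0, cfg.expression_noise_sd_log2, len(expr_pairs))
    tumor_expr = normal_expr * np.power(2.0, beta[idx_first] + noise)
    expression = pd.DataFrame(
        {
            "gene": expr_pairs["gene"],
            "sample_id": expr_pairs["sample_id"],
            "tumor_expr": tumor_expr,
            "normal_expr": normal_expr,
        }
    )

    # --- CNA segments (diploid; whole-chromosome segments with small noise)
    seg_rows = []
    for sid in sample_ids:
        for c in chroms + ["chrX"]:
            seg_rows.append(
                {
                    "sample_id": sid,
                    "chrom": c,
                    "start": 1,
                    "end": len(genome_str[c]),
                    "segment_mean": float(rng.normal(0, cfg.segment_mean_sd)),
                }
            )
    segments = pd.DataFrame(seg_rows)

    variants = df[
        [
            "sample_id", "cancer_type", "chrom", "pos",
            "ref_allele", "alt_allele", "gene", "transcript_id", "consequence",
        ]
    ].copy()

    truth = df[
        [
            "sample_id", "cancer_type", "chrom", "pos", "ref_allele",
            "alt_allele", "gene", "transcript_id", "consequence",
            "planned_filter", "nmd_verdict", "nmd_rule", "tfbs_truth",
            "tfbs_motif",
        ]
    ].copy()
    truth["purity_true"] = pi
    truth["f_dna"] = cfg.f_dna
    truth["selection"] = s
    truth["log_selection"] = log_s
    truth["beta_log2fc"] = beta
    truth["expected_vaf_tdna"] = v
    truth["mu_rna"] = mu
    truth["allelic_event"] = allelic_event
    truth["nmd_degradation_applied"] = np.where(
        is_elicit_ptv & (allelic_event == "none"), d, 0.0
    )

    return Cohort(
        config=cfg,
        seed=seed,
        samples=samples,
        variants=variants,
        counts=counts,
        purity=purity,
        segments=segments,
        expression=expression,
        models=models,
        genome=genome_str,
        imprinted=imprinted,
        cgc_genes=cgc,
        insensitive_genes=insensitive,
        half_life=half_life,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# serialization

_MAF_CLASS = {
    "PTV": "Nonsense_Mutation",
    "missense": "Missense_Mutation",
    "silent": "Silent",
    "splice": "Splice_Site",
    "other": "3'UTR",
}


def _gtf_text(models: Dict[str, TranscriptModel]) -> str:
    lines = []
    for tid in sorted(models):
        t = models[tid]
        attrs = f'gene_id "{t.gene}"; transcript_id "{t.transcript_id}"; gene_name "{t.gene}";'
        lines.append(
            "\t".join(
                [t.chrom, "somalex", "transcript", str(t.exons[0][0]),
                 str(t.exons[-1][1]), ".", t.strand, ".", attrs]
            )
        )
        for s, e in t.exons:
            lines.append(
                "\t".join(
                    [t.chrom, "somalex", "exon", str(s), str(e), ".",
                     t.strand, ".", attrs]
                )
            )
            if t.is_coding:
                cs, ce = max(s, t.cds_start), min(e, t.cds_end)
                if cs <= ce:
                    lines.append(
                        "\t".join(
                            [t.chrom, "somalex", "CDS", str(cs), str(ce),
                             ".", t.strand, "0", attrs]
                        )
                    )
    return "\n".join(lines) + "\n"


def write_bundle(cohort: Cohort, outdir) -> Dict[str, Path]:
    """Write every input file of the synthetic study, in the exact dialects
    the readers consume, plus the ground truth and a ready-to-run pipeline
    config. Byte-identical across runs with the same seed."""
    from . import data_io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    maf = pd.DataFrame(
        {
            "Hugo_Symbol": cohort.variants["gene"],
            "Chromosome": cohort.variants["chrom"],
            "Start_Position": cohort.variants["pos"],
            "End_Position": cohort.variants["pos"],
            "Reference_Allele": cohort.variants["ref_allele"],
            "Tumor_Seq_Allele2": cohort.variants["alt_allele"],
            "Variant_Classification": cohort.variants["consequence"].map(_MAF_CLASS),
            "Variant_Type": "SNP",
            "Tumor_Sample_Barcode": cohort.variants["sample_id"],
            "Transcript_ID": cohort.variants["transcript_id"],
            "cancer_type": cohort.variants["cancer_type"],
        }
    )
    paths["variants"] = out / "variants.maf"
    with open(paths["variants"], "w") as fh:
        fh.write("#version somalex-synthetic\n")
        maf.to_csv(fh, sep="\t", index=False)

    for key, frame in (
        ("counts", cohort.counts),
        ("purity", cohort.purity),
        ("segments", cohort.segments),
        ("expression", cohort.expression),
        ("truth", cohort.truth),
    ):
        paths[key] = out / f"{key}.tsv"
        data_io.write_table(frame, paths[key], comment=f"synthetic {key}")

    paths["gene_models"] = out / "gene_models.gtf"
    paths["gene_models"].write_text(_gtf_text(cohort.models))

    paths["genome"] = out / "genome.fa"
    with open(paths["genome"], "w") as fh:
        for chrom in sorted(cohort.genome):
            fh.write(f">{chrom}\n")
            seq = cohort.genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    paths["imprinted_bed"] = out / "imprinted.bed"
    with open(paths["imprinted_bed"], "w") as fh:
        for chrom, s, e in cohort.imprinted:
            fh.write(f"{chrom}\t{s - 1}\t{e}\n")

    paths["cgc_genes"] = out / "cgc_genes.txt"
    paths["cgc_genes"].write_text(
        "\n".join(sorted(cohort.cgc_genes)) + "\n"
    )
    paths["nmd_insensitive"] = out / "nmd_insensitive_genes.txt"
    paths["nmd_insensitive"].write_text(
        "\n".join(sorted(cohort.insensitive_genes)) + "\n"
    )

    paths["half_life"] = out / "half_life.tsv"
    hl = pd.DataFrame(
        sorted(cohort.half_life.items()),
        columns=["transcript_id", "half_life_hours"],
    )
    data_io.write_table(hl, paths["half_life"], comment="synthetic half-lives")

    paths["motifs"] = out / "motifs.jaspar"
    paths["motifs"].write_text(jaspar_text())

    config = {
        "seed": cohort.seed,
        "generator": cohort.config.to_dict(),
        "inputs": {
            "variants": "variants.maf",
            "dialect": "maf",
            "counts": "counts.tsv",
            "purity": "purity.tsv",
            "segments": "segments.tsv",
            "expression": "expression.tsv",
            "gene_models": "gene_models.gtf",
            "genome": "genome.fa",
            "imprinted_bed": "imprinted.bed",
            "cgc_genes": "cgc_genes.txt",
            "nmd_insensitive": "nmd_insensitive_genes.txt",
            "half_life": "half_life.tsv",
            "motifs": "motifs.jaspar",
        },
    }
    paths["config"] = out / "config.yaml"
    paths["config"].write_text(yaml.safe_dump(config, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# focused simulators


def simulate_null_call_rate(
    n_variants: int = 10_000,
    depth: int = 50,
    vaf: float = 0.5,
    seed: int = 0,
    **call_kwargs,
) -> float:
    """Fraction of balanced-expression variants (true VAF_tRNA = VAF_tDNA)
    miscalled SOM-E or SOM-L at the given depth."""
    rng = np.random.default_rng(seed)
    tex_var = rng.binomial(depth, vaf, n_variants)
    ttr_var = rng.binomial(depth, vaf, n_variants)
    status, _, _ = expression_status.call_status_arrays(
        depth - tex_var, tex_var, depth - ttr_var, ttr_var, **call_kwargs
    )
    return float(np.mean((status == "SOM_E") | (status == "SOM_L")))
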