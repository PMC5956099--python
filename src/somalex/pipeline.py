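"""End-to-end orchestration: filters -> allele metrics -> status calls ->
NMD -> TFBS -> associations -> gene ranking.

``run_pipeline`` consumes a YAML/dict config naming the input files, runs
the stages in order, writes every result table as TSV plus a
machine-readable ``summary.json`` and a reproducibility ``manifest.json``
(config hash, package version, row counts — no timestamps, so identical
config and inputs give byte-identical outputs). Stages whose inputs are
absent (e.g. no expression table) are skipped with a logged warning; the
allele table is always produced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__, associations, cohort_filters, data_io
from .allele_metrics import build_allele_table
from .cohort_filters import FilterConfig
from .nmd_classifier import NMDConfig, annotate_ptvs
from .tfbs_change import classify_variants
from .types import SomalexError

logger = logging.getLogger("somalex")


@dataclass
class PipelineParams:
    min_depth: int = 10
    p_err: float = 0.05
    alpha: float = 0.05
    min_dna_minor_reads: int = 2
    max_normal_var_reads: int = 1
    min_group_size: int = 10
    expression_floor: float = 0.01
    vrd_extreme_threshold: float = 2.0
    log2fc_extreme_threshold: float = 1.0
    rank_min_mutations: int = 3
    rank_top_n: int = 50
    tfbs_rel_score_threshold: float = 0.85
    nmd: NMDConfig = field(default_factory=NMDConfig)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        cfg = yaml.safe_load(text)
        cfg.setdefault("_base_dir", str(Path(config).parent))
        return cfg
    return dict(config)


def _params_from_config(cfg: dict) -> PipelineParams:
    p = dict(cfg.get("params", {}))
    nmd = NMDConfig(**p.pop("nmd", {}))
    return PipelineParams(nmd=nmd, **p)


def _resolve(base: Path, value: Optional[str]) -> Optional[Path]:
    if value is None:
        return None
    path = Path(value)
    return path if path.is_absolute() else base / path


def run_pipeline(config, outdir) -> dict:
    """Run every stage on the configured inputs; returns the summary dict.

    Raises :class:`SomalexError` naming the config key when a required
    input is missing.
    """
    cfg = _load_config(config)
    base = Path(cfg.get("_base_dir", "."))
    inputs = cfg.get("inputs", {})
    params = _params_from_config(cfg)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    def require(key: str) -> Path:
        path = _resolve(base, inputs.get(key))
        if path is None or not path.exists():
            raise SomalexError(f"missing required input: config key inputs.{key}")
        return path

    def optional(key: str) -> Optional[Path]:
        path = _resolve(base, inputs.get(key))
        if path is None:
            return None
        if not path.exists():
            raise SomalexError(f"configured input does not exist: inputs.{key}")
        return path

    # ---- load -------------------------------------------------------------
    variants = data_io.variants_to_frame(
        data_io.read_variants(require("variants"), inputs.get("dialect", "maf"))
    )
    counts = data_io.read_counts_table(require("counts"))
    purity = data_io.read_purity_table(require("purity"))
    cgc_path = optional("cgc_genes")
    cgc = data_io.read_gene_list(cgc_path) if cgc_path else set()
    variants["is_cgc"] = variants["gene"].isin(cgc)

    imprinted_path = optional("imprinted_bed")
    imprinted = data_io.read_bed(imprinted_path) if imprinted_path else []

    # ---- sample filters ---------------------------------------------------
    fconfig = FilterConfig(
        min_depth=params.min_depth,
        max_normal_var_reads=params.max_normal_var_reads,
        min_group_size=params.min_group_size,
    )
    method_cols = [m for m in data_io.PURITY_METHODS if m in purity.columns]
    purity_ok = pd.Series(
        (purity[method_cols].notna().sum(axis=1) >= 3).to_numpy(),
        index=purity["sample_id"],
    )
    samples = variants[["sample_id", "cancer_type"]].drop_duplicates()
    per_sample = variants.groupby("sample_id").size()
    retained_samples, sample_audit = cohort_filters.apply_sample_filters(
        samples, per_sample, purity_ok, fconfig
    )
    data_io.write_table(sample_audit, out / "sample_audit.tsv", "sample filters")
    n_input_variants = len(variants)
    variants = variants[
        variants["sample_id"].isin(retained_samples["sample_id"])
    ].copy()
    n_dropped_sample = n_input_variants - len(variants)

    # ---- variant filters --------------------------------------------------
    key = ["sample_id", "chrom", "pos", "ref_allele", "alt_allele"]
    merged = variants.merge(counts, on=key, how="left")
    retained, variant_audit, tally = cohort_filters.apply_variant_filters(
        merged, imprinted, fconfig
    )
    data_io.write_table(variant_audit, out / "variant_audit.tsv", "variant filters")
    conservation_ok = len(retained) + sum(tally.values()) == len(merged)

    # ---- allele metrics & status calls -------------------------------------
    calls = build_allele_table(
        retained[variants.columns],
        counts,
        purity,
        p_err=params.p_err,
        alpha=params.alpha,
        min_depth=params.min_depth,
        min_dna_minor_reads=params.min_dna_minor_reads,
    )

    # ---- expression -------------------------------------------------------
    expression_path = optional("expression")
    if expression_path is not None:
        expression = associations.log2_fold_change_frame(
            data_io.read_expression_table(expression_path),
            floor=params.expression_floor,
        )
        calls = calls.merge(
            expression[["gene", "sample_id", "tumor_expr", "normal_expr", "log2fc"]],
            on=["gene", "sample_id"],
            how="left",
        )
    else:
        logger.warning("no expression table configured; expression analyses skipped")
        calls["log2fc"] = np.nan

    # ---- NMD --------------------------------------------------------------
    gtf_path = optional("gene_models")
    genome_path = optional("genome")
    nmd_table = pd.DataFrame()
    if gtf_path is not None:
        models = data_io.read_gene_models(gtf_path)
        genome = data_io.open_fasta(genome_path) if genome_path else None
        hl_path = optional("half_life")
        half_life = data_io.read_half_life_table(hl_path) if hl_path else {}
        ins_path = optional("nmd_insensitive")
        insensitive = data_io.read_gene_list(ins_path) if ins_path else set()
        nmd_table = annotate_ptvs(
            calls, models, genome, half_life, insensitive, params.nmd
        )
        if not nmd_table.empty:
            data_io.write_table(nmd_table, out / "nmd_annotations.tsv", "NMD rules")
            calls = calls.merge(
                nmd_table[["sample_id", "chrom", "pos", "verdict"]].rename(
                    columns={"verdict": "nmd_verdict"}
                ),
                on=["sample_id", "chrom", "pos"],
                how="left",
            )
    if "nmd_verdict" not in calls.columns:
        calls["nmd_verdict"] = np.nan

    # ---- TFBS -------------------------------------------------------------
    motifs_path = optional("motifs")
    if motifs_path is not None and genome_path is not None:
        motifs = data_io.read_jaspar_motifs(motifs_path)
        genome = data_io.open_fasta(genome_path)
        tfbs = classify_variants(
            calls, genome, motifs,
            rel_score_threshold=params.tfbs_rel_score_threshold,
        )
        if not tfbs.empty:
            data_io.write_table(tfbs, out / "tfbs_table.tsv", "TFBS gain/loss")
            calls = calls.merge(
                tfbs[["sample_id", "chrom", "pos", "category"]].rename(
                    columns={"category": "tfbs_category"}
                ),
                on=["sample_id", "chrom", "pos"],
                how="left",
            )
    if "tfbs_category" not in calls.columns:
        calls["tfbs_category"] = np.nan

    data_io.write_table(calls, out / "allele_table.tsv", "per-variant allele table")

    # ---- associations ------------------------------------------------------
    summary: Dict[str, object] = {
        "n_variants_input": int(n_input_variants),
        "n_variants_after_sample_filters": int(len(merged)),
        "n_variants_dropped_with_samples": int(n_dropped_sample),
        "n_variants_retained": int(len(retained)),
        "variant_filter_tally": {k: int(v) for k, v in tally.items()},
        "filter_conservation_ok": bool(conservation_ok),
        "n_samples_input": int(len(samples)),
        "n_samples_retained": int(len(retained_samples)),
    }

    status_pooled = associations.status_summary(calls)
    status_by_type = associations.status_summary(calls, by="cancer_type")
    data_io.write_table(
        pd.concat([status_pooled, status_by_type]),
        out / "status_summary.tsv",
        "SOM/SOM-E/SOM-L",
    )
    summary["status"] = status_pooled.iloc[0].to_dict()

    called = calls.dropna(subset=["vaf_tdna", "vaf_trna"])
    if len(called) >= 5:
        rho, p = associations.spearman(called["vaf_tdna"], called["vaf_trna"])
        summary["spearman_vaf_rna_dna"] = {"rho": rho, "p": p, "n": len(called)}

    strata = [
        ("all", pd.Series(True, index=calls.index)),
        ("cgc", calls["is_cgc"]),
        ("non_cgc", ~calls["is_cgc"]),
    ]
    for csq in ("PTV", "missense", "silent"):
        strata.append((csq, calls["consequence"] == csq))
        strata.append((f"cgc_{csq}", calls["is_cgc"] & (calls["consequence"] == csq)))
    corr = associations.correlation_by_strata(calls, "v_rd", "log2fc", strata)
    data_io.write_table(corr, out / "correlations.tsv", "V_R:D vs log2[T/N]")
    summary["vrd_log2fc"] = {
        r["stratum"]: {"rho": r["rho"], "p": r["p"], "n": int(r["n"])}
        for _, r in corr.iterrows()
    }

    by_csq = {
        c: g["v_rd"].dropna().to_numpy()
        for c, g in calls.groupby("consequence")
        if g["v_rd"].notna().sum() > 0
    }
    if len(by_csq) >= 2:
        h, p = associations.kruskal_wallis(list(by_csq.values()))
        summary["vrd_by_consequence_kruskal"] = {"H": h, "p": p}

    nmd_summary: Dict[str, object] = {}
    ptv = calls[(calls["consequence"] == "PTV") & calls["v_rd"].notna()]
    elicit = ptv.loc[ptv["nmd_verdict"] == "elicit", "v_rd"].to_numpy()
    escape = ptv.loc[ptv["nmd_verdict"] == "escape", "v_rd"].to_numpy()
    nmd_summary["n_elicit"] = int(len(elicit))
    nmd_summary["n_escape"] = int(len(escape))
    if len(elicit) >= 3 and len(escape) >= 3:
        h, p = associations.kruskal_wallis([elicit, escape])
        nmd_summary.update(
            mean_vrd_elicit=float(np.mean(elicit)),
            mean_vrd_escape=float(np.mean(escape)),
            p_kruskal=p,
        )
    summary["nmd"] = nmd_summary

    tf_counts = calls["tfbs_category"].value_counts(dropna=True)
    tfbs_summary = {
        f"n_{k}": int(tf_counts.get(k, 0)) for k in ("gain", "loss", "both", "none")
    }
    gain_v = calls.loc[
        calls["tfbs_category"].isin(["gain", "both"]), "v_rd"
    ].dropna()
    loss_v = calls.loc[
        calls["tfbs_category"].isin(["loss", "both"]), "v_rd"
    ].dropna()
    if len(gain_v) >= 3 and len(loss_v) >= 3:
        _, p = associations.kruskal_wallis([gain_v, loss_v])
        tfbs_summary["p_kruskal_gain_vs_loss"] = p
    summary["tfbs"] = tfbs_summary

    if calls["log2fc"].notna().any():
        up, down = associations.select_extremes(
            calls,
            vrd_threshold=params.vrd_extreme_threshold,
            log2fc_threshold=params.log2fc_extreme_threshold,
        )
        data_io.write_table(up, out / "extremes_up.tsv", "V_R:D>2, log2fc>=1")
        data_io.write_table(down, out / "extremes_down.tsv", "V_R:D>2, log2fc<=-1")
        summary["extremes"] = {"n_up": int(len(up)), "n_down": int(len(down))}

    ranking = associations.rank_genes_by_mean_vrd(
        calls, min_mutations=params.rank_min_mutations
    )
    data_io.write_table(ranking, out / "gene_ranking.tsv", "mean V_R:D ranking")
    enrichment: Dict[str, object] = {}
    background = set(calls.dropna(subset=["v_rd"])["gene"])
    if cgc and len(ranking) > 0:
        top = set(ranking.head(params.rank_top_n)["gene"])
        try:
            chi2, p, table = associations.cgc_enrichment(top, background, cgc)
            enrichment["top_genes_by_mean_vrd"] = {
                "chi2": chi2, "p": p, "table": table.astype(int).tolist(),
                "n_selected": len(top),
            }
        except SomalexError as exc:
            enrichment["top_genes_by_mean_vrd"] = {"skipped": str(exc)}
    summary["cgc_enrichment"] = enrichment

    segments_path = optional("segments")
    if segments_path is not None:
        segments = data_io.read_segments_table(segments_path)
        with_seg, n_unmatched = associations.attach_segment_means(calls, segments)
        seg_tables = []
        for col, label in (("is_cgc", "cgc"), ("status", "status")):
            cmp_df = associations.compare_absolute_segment_means(with_seg, col)
            cmp_df.insert(0, "comparison", label)
            seg_tables.append(cmp_df)
        seg_out = pd.concat(seg_tables, ignore_index=True)
        data_io.write_table(
            seg_out, out / "segment_comparison.tsv", "|segment mean| by group"
        )
        summary["segments"] = {
            "n_unmatched": int(n_unmatched),
            "comparisons": json.loads(seg_out.to_json(orient="records")),
        }

    # ---- manifest ----------------------------------------------------------
    cfg_for_hash = {k: v for k, v in cfg.items() if not k.startswith("_")}
    manifest = {
        "package": "somalex",
        "version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_for_hash, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": cfg.get("seed"),
        "tables": {
            "allele_table": int(len(calls)),
            "nmd_annotations": int(len(nmd_table)),
            "gene_ranking": int(len(ranking)),
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n"
    )
    return summary
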