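"""Statistical linkage of allele frequency to expression and gene features.

Non-parametric throughout: Spearman rank correlation for continuous
relationships, Kruskal-Wallis rank-sum tests for group comparisons, and a
2x2 chi-square for gene-set enrichment. Raw p-values are always reported;
no multiple-testing correction is applied at this layer so users can
correct downstream as they see fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import SomalexError, UndefinedValueError


def log2_fold_change(
    tumor_expr: float, normal_expr: float, floor: float = 0.01
) -> float:
    """log2((tumor + floor) / (normal + floor)).

    Missing (NaN) when neither value exceeds the floor; negative
    abundances are an error.
    """
    if tumor_expr < 0 or normal_expr < 0:
        raise ValueError("expression abundances must be non-negative")
    if tumor_expr <= floor and normal_expr <= floor:
        return float("nan")
    return math.log2((tumor_expr + floor) / (normal_expr + floor))


def log2_fold_change_frame(
    expression: pd.DataFrame, floor: float = 0.01
) -> pd.DataFrame:
    """Add a ``log2fc`` column to an expression table
    (gene, sample_id, tumor_expr, normal_expr)."""
    df = expression.copy()
    if (df[["tumor_expr", "normal_expr"]] < 0).any().any():
        raise ValueError("expression abundances must be non-negative")
    with np.errstate(divide="ignore"):
        fc = np.log2((df["tumor_expr"] + floor) / (df["normal_expr"] + floor))
    defined = (df["tumor_expr"] > floor) | (df["normal_expr"] > floor)
    df["log2fc"] = np.where(defined, fc, np.nan)
    return df


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation with average ranks for ties and a
    two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise SomalexError("Spearman correlation needs at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Degenerate all-identical data yields H = 0, p = 1.
    """
    if len(groups) < 2:
        raise SomalexError("Kruskal-Wallis needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise SomalexError("Kruskal-Wallis groups must be non-empty")
    try:
        h, p = stats.kruskal(*arrays)
    except ValueError:
        # all observations identical: no rank variation at all
        return 0.0, 1.0
    return float(h), float(p)


def select_extremes(
    calls: pd.DataFrame,
    *,
    vrd_threshold: float = 2.0,
    log2fc_threshold: float = 1.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Variants with extreme allele preference and extreme expression change.

    Returns (high-AF/up, high-AF/down): V_R:D above ``vrd_threshold``
    combined with at least a two-fold expression increase
    (log2fc >= ``log2fc_threshold``) or decrease (log2fc <= -threshold).
    The two sets are disjoint by construction.
    """
    high = calls[calls["v_rd"] > vrd_threshold]
    up = high[high["log2fc"] >= log2fc_threshold].copy()
    down = high[high["log2fc"] <= -log2fc_threshold].copy()
    return up, down


def rank_genes_by_mean_vrd(
    calls: pd.DataFrame, min_mutations: int = 3
) -> pd.DataFrame:
    """Genes with >= ``min_mutations`` somatic variants, ranked by mean
    V_R:D (descending; alphabetical tie-break)."""
    usable = calls.dropna(subset=["v_rd"])
    grouped = usable.groupby("gene").agg(
        n_mutations=("v_rd", "size"), mean_v_rd=("v_rd", "mean")
    )
    grouped = grouped[grouped["n_mutations"] >= min_mutations].reset_index()
    grouped = grouped.sort_values(
        ["mean_v_rd", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    grouped["rank"] = np.arange(1, len(grouped) + 1)
    return grouped[["rank", "gene", "n_mutations", "mean_v_rd"]]


def cgc_enrichment(
    selected_genes: Iterable[str],
    background_genes: Iterable[str],
    cgc_genes: Iterable[str],
    *,
    continuity_correction: bool = False,
) -> Tuple[float, float, np.ndarray]:
    """Chi-square enrichment of a gene selection in CGC members.

    The 2x2 table compares CGC membership inside vs outside the selection
    (selection must be a subset of the background). Returns
    (chi2, p, table); degenerate tables with a zero margin are an error.
    """
    sel = set(selected_genes)
    bg = set(background_genes)
    cgc = set(cgc_genes)
    if not sel:
        raise SomalexError("empty gene selection")
    if not sel <= bg:
        raise SomalexError("selected genes must be a subset of the background")
    rest = bg - sel
    table = np.array(
        [
            [len(sel & cgc), len(sel - cgc)],
            [len(rest & cgc), len(rest - cgc)],
        ],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise SomalexError("degenerate 2x2 table (zero margin)")
    chi2, p, _, _ = stats.chi2_contingency(
        table, correction=continuity_correction
    )
    return float(chi2), float(p), table


def attach_segment_means(
    calls: pd.DataFrame, segments: pd.DataFrame
) -> Tuple[pd.DataFrame, int]:
    """Join each variant to the copy-number segment covering it in the same
    sample. Returns (frame with a ``segment_mean`` column, count of
    variants overlapping no segment, which are excluded)."""
    seg_by_key: Dict[Tuple[str, str], List[Tuple[int, int, float]]] = {}
    for s in segments.itertuples(index=False):
        seg_by_key.setdefault((s.sample_id, s.chrom), []).append(
            (int(s.start), int(s.end), float(s.segment_mean))
        )
    means = np.full(len(calls), np.nan)
    for i, v in enumerate(calls.itertuples(index=False)):
        for start, end, mean in seg_by_key.get((v.sample_id, v.chrom), ()):
            if start <= v.pos <= end:
                means[i] = mean
                break
    out = calls.copy()
    out["segment_mean"] = means
    n_unmatched = int(np.isnan(means).sum())
    return out[~np.isnan(means)].copy(), n_unmatched


def compare_absolute_segment_means(
    calls_with_segments: pd.DataFrame, group_col: str
) -> pd.DataFrame:
    """Compare |segment mean| distributions between the groups defined by
    ``group_col`` (e.g. CGC membership, or SOM-E vs SOM-L status).

    Returns one row per group (n, median and mean |segment mean|) plus the
    Kruskal-Wallis p-value across groups in a ``p_kruskal`` column.
    """
    df = calls_with_segments.dropna(subset=["segment_mean", group_col])
    groups = {
        name: np.abs(sub["segment_mean"].to_numpy())
        for name, sub in df.groupby(group_col)
        if len(sub) > 0
    }
    rows = [
        {
            "group": name,
            "n": len(vals),
            "median_abs_segment_mean": float(np.median(vals)),
            "mean_abs_segment_mean": float(np.mean(vals)),
        }
        for name, vals in groups.items()
    ]
    out = pd.DataFrame(rows)
    if len(groups) >= 2:
        _, p = kruskal_wallis(list(groups.values()))
        out["p_kruskal"] = p
    else:
        out["p_kruskal"] = np.nan
    return out


def status_percentages(
    n_som_e: int, n_som_l: int, n_total: int
) -> Dict[str, float]:
    """SOM-E / SOM-L shares of all called variants, as percentages rounded
    to one decimal (the precision used in reports)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_som_e + n_som_l > n_total:
        raise ValueError("status counts exceed the total")
    return {
        "SOM_E": round(100.0 * n_som_e / n_total, 1),
        "SOM_L": round(100.0 * n_som_l / n_total, 1),
        "SOM": round(100.0 * (n_total - n_som_e - n_som_l) / n_total, 1),
    }


def status_summary(calls: pd.DataFrame, by: Optional[str] = None) -> pd.DataFrame:
    """Counts and percentages of SOM/SOM-E/SOM-L, pooled or stratified by a
    column such as cancer_type."""
    called = calls.dropna(subset=["status"])
    strata = [("pooled", called)] if by is None else list(called.groupby(by))
    rows = []
    for name, sub in strata:
        n = len(sub)
        counts = sub["status"].value_counts()
        pct = status_percentages(
            int(counts.get("SOM_E", 0)), int(counts.get("SOM_L", 0)), max(n, 1)
        )
        rows.append(
            {
                "stratum": name,
                "n_called": n,
                "n_som": int(counts.get("SOM", 0)),
                "n_som_e": int(counts.get("SOM_E", 0)),
                "n_som_l": int(counts.get("SOM_L", 0)),
                "pct_som_e": pct["SOM_E"],
                "pct_som_l": pct["SOM_L"],
            }
        )
    return pd.DataFrame(rows)


def correlation_by_strata(
    calls: pd.DataFrame,
    x_col: str,
    y_col: str,
    strata: Sequence[Tuple[str, pd.Series]],
    min_n: int = 5,
) -> pd.DataFrame:
    """Spearman correlation of two columns within each named boolean
    stratum; strata below ``min_n`` defined pairs yield NaN."""
    rows = []
    for name, mask in strata:
        sub = calls[mask].dropna(subset=[x_col, y_col])
        if len(sub) >= min_n and sub[x_col].nunique() > 1 and sub[y_col].nunique() > 1:
            rho, p = spearman(sub[x_col], sub[y_col])
        else:
            rho, p = float("nan"), float("nan")
        rows.append({"stratum": name, "n": len(sub), "rho": rho, "p": p})
    return pd.DataFrame(rows)
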