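"""Sample-level and variant-level filter cascade with an audit trail.

Sample filters: sufficient purity estimates, hypermutator exclusion
(mutation load more than 1.5 IQR above the third quartile), and a minimum
number of samples per cancer type. Variant filters: minimum tumor DNA/RNA
depth, X-chromosome exclusion, imprinted-region overlap, germline
evidence in the normal datasets, splice-annotated consequences, and
exonic-only scope. Every exclusion is attributed to the first failing rule
so that retained + per-rule exclusions always equals the input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .types import SomalexError

#: Variant-filter rules in application order. Attribution (not membership
#: of the retained set) depends on this order.
VARIANT_FILTER_RULES = (
    "missing_counts",
    "min_depth",
    "chrx",
    "imprinted",
    "germline",
    "splice",
    "non_exonic",
)

_CHRX_NAMES = {"X", "chrX", "x", "chrx"}


@dataclass
class FilterConfig:
    min_depth: int = 10
    max_normal_var_reads: int = 1
    min_group_size: int = 10


def hypermutator_cutoff(
    mutation_counts: pd.Series,
) -> Tuple[float, Set[str]]:
    """Hypermutator threshold Q3 + 1.5*IQR over per-sample mutation counts.

    Quartiles use linear interpolation between order statistics. Samples
    strictly above the threshold are excluded. Requires at least four
    samples for a meaningful quartile estimate.
    """
    counts = pd.Series(mutation_counts, dtype=float)
    if len(counts) < 4:
        raise SomalexError(
            f"hypermutator cutoff needs >= 4 samples, got {len(counts)}"
        )
    q1, q3 = np.percentile(counts.to_numpy(), [25, 75])
    threshold = q3 + 1.5 * (q3 - q1)
    excluded = set(counts.index[counts > threshold].astype(str))
    return float(threshold), excluded


def min_group_size(
    samples: pd.DataFrame, minimum: int = 10
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Drop cancer types with fewer than ``minimum`` samples.

    ``samples`` needs columns sample_id and cancer_type; returns the
    retained frame and a mapping of dropped cancer type -> its sample count.
    """
    if samples.empty:
        return samples.copy(), {}
    sizes = samples.groupby("cancer_type")["sample_id"].nunique()
    dropped = {ct: int(n) for ct, n in sizes.items() if n < minimum}
    retained = samples[~samples["cancer_type"].isin(dropped)].copy()
    return retained, dropped


def _overlaps_imprinted(
    chrom: pd.Series, pos: pd.Series, imprinted: Iterable[Tuple[str, int, int]]
) -> np.ndarray:
    """Boolean mask of positions inside any imprinted interval
    (1-based inclusive intervals)."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for c, s, e in imprinted:
        by_chrom.setdefault(str(c), []).append((int(s), int(e)))
    hit = np.zeros(len(chrom), dtype=bool)
    for c, intervals in by_chrom.items():
        on_c = (chrom == c).to_numpy()
        if not on_c.any():
            continue
        p = pos.to_numpy()
        for s, e in intervals:
            hit |= on_c & (p >= s) & (p <= e)
    return hit


def apply_variant_filters(
    variants_with_counts: pd.DataFrame,
    imprinted: Sequence[Tuple[str, int, int]] = (),
    config: FilterConfig = FilterConfig(),
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, int]]:
    """Variant-level filter cascade.

    Input is the variant table joined to quad counts (count columns NaN
    where no count record exists). Returns (retained, audit, tally): the
    audit frame holds one row per input variant with the first failing
    rule (or 'retained'); the tally maps rule -> exclusion count and
    satisfies |retained| + sum(tally) = |input|.
    """
    df = variants_with_counts
    count_cols = ["nex_ref", "nex_var", "ntr_ref", "ntr_var",
                  "tex_ref", "tex_var", "ttr_ref", "ttr_var"]
    missing = df[count_cols].isna().any(axis=1).to_numpy() if set(
        count_cols
    ).issubset(df.columns) else np.ones(len(df), dtype=bool)

    tex_depth = (df.get("tex_ref", 0) + df.get("tex_var", 0)).to_numpy()
    ttr_depth = (df.get("ttr_ref", 0) + df.get("ttr_var", 0)).to_numpy()
    low_depth = (tex_depth < config.min_depth) | (ttr_depth < config.min_depth)

    chrx = df["chrom"].isin(_CHRX_NAMES).to_numpy()
    imp = _overlaps_imprinted(df["chrom"], df["pos"], imprinted)
    germ = (
        (df.get("nex_var", 0) > config.max_normal_var_reads)
        | (df.get("ntr_var", 0) > config.max_normal_var_reads)
    ).to_numpy()
    splice = (df["consequence"] == "splice").to_numpy()
    non_exonic = (df["consequence"] == "other").to_numpy()

    fail_masks = {
        "missing_counts": missing,
        "min_depth": low_depth & ~missing,
        "chrx": chrx,
        "imprinted": imp,
        "germline": germ & ~missing,
        "splice": splice,
        "non_exonic": non_exonic,
    }
    reason = np.full(len(df), "retained", dtype=object)
    unassigned = np.ones(len(df), dtype=bool)
    for rule in VARIANT_FILTER_RULES:
        m = fail_masks[rule] & unassigned
        reason[m] = rule
        unassigned &= ~m

    audit = pd.DataFrame(
        {
            "sample_id": df["sample_id"].to_numpy(),
            "chrom": df["chrom"].to_numpy(),
            "pos": df["pos"].to_numpy(),
            "reason": reason,
        }
    )
    retained = df[reason == "retained"].copy()
    tally = {
        rule: int((reason == rule).sum()) for rule in VARIANT_FILTER_RULES
    }
    assert len(retained) + sum(tally.values()) == len(df)
    return retained, audit, tally


def apply_sample_filters(
    samples: pd.DataFrame,
    variant_counts_per_sample: pd.Series,
    purity_ok: pd.Series,
    config: FilterConfig = FilterConfig(),
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Sample-level cascade: purity availability -> hypermutator -> group size.

    ``samples``: sample_id, cancer_type. ``purity_ok``: boolean per
    sample_id (at least three purity estimates available).
    Returns (retained samples, audit frame with first failing rule).
    """
    df = samples.drop_duplicates("sample_id").copy()
    reason = pd.Series("retained", index=df["sample_id"].to_numpy(), dtype=object)

    ok_purity = df["sample_id"].map(purity_ok).fillna(False).to_numpy(dtype=bool)
    reason[df["sample_id"][~ok_purity]] = "insufficient_purity"

    surviving = df[ok_purity]
    counts = variant_counts_per_sample.reindex(surviving["sample_id"]).fillna(0)
    if len(counts) >= 4:
        _, hyper = hypermutator_cutoff(counts)
    else:
        hyper = set()
    reason[list(hyper)] = "hypermutator"

    surviving = surviving[~surviving["sample_id"].isin(hyper)]
    retained, dropped_groups = min_group_size(surviving, config.min_group_size)
    for ct in dropped_groups:
        mask = surviving["cancer_type"] == ct
        reason[surviving["sample_id"][mask]] = "small_group"

    audit = pd.DataFrame(
        {"sample_id": reason.index, "reason": reason.to_numpy()}
    )
    return retained, audit
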