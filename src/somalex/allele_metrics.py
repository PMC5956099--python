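"""Variant allele fraction (VAF), the RNA/DNA ratio V_R:D, and
purity-weighted V_R:D variants.

VAF = n_var / (n_ref + n_var) is computed separately for tumor DNA
(VAF_tDNA) and tumor RNA (VAF_tRNA); V_R:D = VAF_tRNA / VAF_tDNA expresses
the transcriptome allele balance relative to the DNA. A value of 1 means
the RNA mirrors the DNA; values above 1 indicate preferential expression of
the variant allele. V_R:D is deliberately not capped above. Weighting by
purity multiplies V_R:D by the tumor-cell fraction of the sample, one
weighted value per estimation method (aV_R:D, iV_R:D, eV_R:D, lV_R:D,
cV_R:D).
"""

from __future__ import annotations

from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

from .types import (
    PURITY_METHODS,
    PURITY_PREFIX,
    PurityEstimates,
    UndefinedValueError,
)
from . import expression_status

#: Allele-table column for each purity-weighted ratio, e.g. ``ev_rd`` for
#: the ESTIMATE-weighted V_R:D.
WEIGHTED_COLUMNS = {m: f"{PURITY_PREFIX[m]}v_rd" for m in PURITY_METHODS}


def vaf(n_ref: int, n_var: int) -> float:
    """Variant allele fraction n_var / (n_ref + n_var).

    Raises :class:`UndefinedValueError` at zero depth.
    """
    if n_ref < 0 or n_var < 0:
        raise ValueError("read counts must be non-negative")
    depth = n_ref + n_var
    if depth == 0:
        raise UndefinedValueError("VAF undefined at zero depth")
    return n_var / depth


def v_ratio(vaf_trna: float, vaf_tdna: float) -> float:
    """V_R:D = VAF_tRNA / VAF_tDNA.

    Undefined (error) when VAF_tDNA is 0; a return value of 0 means the
    variant allele is absent from the transcriptome.
    """
    if not (0.0 <= vaf_trna <= 1.0) or not (0.0 <= vaf_tdna <= 1.0):
        raise ValueError("VAF values must lie in [0, 1]")
    if vaf_tdna == 0:
        raise UndefinedValueError("V_R:D undefined when VAF_tDNA = 0")
    return vaf_trna / vaf_tdna


def weight_by_purity(
    v_rd: float, purity: PurityEstimates
) -> Dict[str, float]:
    """Purity-weighted V_R:D per estimation method.

    Returns a mapping method -> weighted value; methods without a purity
    estimate map to NaN (missing in, missing out).
    """
    out: Dict[str, float] = {}
    for m in PURITY_METHODS:
        p = purity.value(m)
        out[m] = v_rd * p if p is not None else float("nan")
    return out


def purity_sufficient(purity: PurityEstimates) -> bool:
    """True iff at least three of the five purity estimates are present."""
    return purity.n_available >= 3


def build_allele_table(
    variants: pd.DataFrame,
    counts: pd.DataFrame,
    purity: Optional[pd.DataFrame] = None,
    *,
    p_err: float = 0.05,
    alpha: float = 0.05,
    min_depth: int = 10,
    min_dna_minor_reads: int = 2,
) -> pd.DataFrame:
    """Per-variant allele table: quad counts, VAFs, V_R:D, weighted V_R:D
    and SOM/SOM-E/SOM-L status.

    ``variants`` and ``counts`` are joined on
    (sample_id, chrom, pos, ref_allele, alt_allele). Rows whose tumor DNA
    or RNA depth is below ``min_depth`` are expected to have been excluded
    upstream; any that remain get a missing V_R:D and no status call.
    ``purity`` (sample_id plus one column per method) adds the weighted
    columns; samples without purity yield NaN weights.
    """
    key = ["sample_id", "chrom", "pos", "ref_allele", "alt_allele"]
    df = variants.merge(counts, on=key, how="left", validate="one_to_one")

    tex_depth = df["tex_ref"] + df["tex_var"]
    ttr_depth = df["ttr_ref"] + df["ttr_var"]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["vaf_tdna"] = np.where(tex_depth > 0, df["tex_var"] / tex_depth, np.nan)
        df["vaf_trna"] = np.where(ttr_depth > 0, df["ttr_var"] / ttr_depth, np.nan)
        vrd = df["vaf_trna"] / df["vaf_tdna"]
    usable = (
        (tex_depth >= min_depth)
        & (ttr_depth >= min_depth)
        & (df["vaf_tdna"] > 0)
    )
    df["v_rd"] = np.where(usable, vrd, np.nan)

    status, p_loss, p_gain = expression_status.call_status_arrays(
        df["tex_ref"].to_numpy(),
        df["tex_var"].to_numpy(),
        df["ttr_ref"].to_numpy(),
        df["ttr_var"].to_numpy(),
        p_err=p_err,
        alpha=alpha,
        min_depth=min_depth,
        min_dna_minor_reads=min_dna_minor_reads,
    )
    df["status"] = status
    df["p_som_l"] = p_loss
    df["p_som_e"] = p_gain

    if purity is not None:
        pur = purity.set_index("sample_id")
        for m in PURITY_METHODS:
            col = WEIGHTED_COLUMNS[m]
            if m in pur.columns:
                df[col] = df["v_rd"] * df["sample_id"].map(pur[m])
            else:
                df[col] = np.nan
    return df
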