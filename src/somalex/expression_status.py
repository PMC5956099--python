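"""SOM / SOM-E / SOM-L expression-status calls from quad read counts.

A somatic variant with a bi-allelic DNA signal (0 < VAF_tDNA < 1, both
tumor-DNA alleles supported by a minimum number of reads) is called

* SOM-L ("lost") when the variant reads in the tumor RNA are consistent
  with sequencing noise alone: the noise-only binomial model
  X ~ Binomial(n, p_err) is not rejected at level alpha, i.e.
  P(X >= n_var) >= alpha;
* SOM-E ("over-expressed") when the mirrored condition holds for the
  reference reads (VAF_tRNA ~ 1);
* SOM otherwise.

Each extreme uses a one-sided upper tail against an explicit per-read
noise rate ``p_err``. In the degenerate low-depth regime both tails can
exceed alpha; the call then goes to the side with the larger tail
probability, which keeps SOM-E and SOM-L mutually exclusive at every
depth. Variants whose normal DNA or RNA carries variant reads above a
tolerance are flagged as germline-suspect and removed upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy.stats import binom

from .types import InsufficientDepthError, QuadCounts

STATUSES = ("SOM", "SOM_E", "SOM_L")


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), exact upper tail."""
    if not (0 <= k <= n):
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability outside [0, 1]: {p}")
    return float(binom.sf(k - 1, n, p))


@dataclass(frozen=True)
class StatusCall:
    status: str
    #: tail p-values of the noise-only model for each extreme
    pvalues: Dict[str, float]


def call_status_arrays(
    tex_ref: np.ndarray,
    tex_var: np.ndarray,
    ttr_ref: np.ndarray,
    ttr_var: np.ndarray,
    *,
    p_err: float = 0.05,
    alpha: float = 0.05,
    min_depth: int = 10,
    min_dna_minor_reads: int = 2,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized status calls.

    Returns (status, p_som_l, p_som_e) arrays; rows with tumor DNA or RNA
    depth below ``min_depth`` get status ``None`` and NaN p-values.
    """
    tex_ref = np.asarray(tex_ref, dtype=np.int64)
    tex_var = np.asarray(tex_var, dtype=np.int64)
    ttr_ref = np.asarray(ttr_ref, dtype=np.int64)
    ttr_var = np.asarray(ttr_var, dtype=np.int64)
    n_rna = ttr_ref + ttr_var
    ok = (tex_ref + tex_var >= min_depth) & (n_rna >= min_depth)

    with np.errstate(divide="ignore", invalid="ignore"):
        p_loss = binom.sf(ttr_var - 1, np.maximum(n_rna, 1), p_err)
        p_gain = binom.sf(ttr_ref - 1, np.maximum(n_rna, 1), p_err)
    biallelic = (tex_ref >= min_dna_minor_reads) & (tex_var >= min_dna_minor_reads)

    loss_ok = biallelic & (p_loss >= alpha)
    gain_ok = biallelic & (p_gain >= alpha)
    status = np.full(tex_ref.shape, "SOM", dtype=object)
    status[loss_ok & (~gain_ok | (p_loss >= p_gain))] = "SOM_L"
    status[gain_ok & (~loss_ok | (p_gain > p_loss))] = "SOM_E"
    status[~ok] = None
    p_loss = np.where(ok, p_loss, np.nan)
    p_gain = np.where(ok, p_gain, np.nan)
    return status, p_loss, p_gain


def call_status(
    q: QuadCounts,
    *,
    p_err: float = 0.05,
    alpha: float = 0.05,
    min_depth: int = 10,
    min_dna_minor_reads: int = 2,
) -> StatusCall:
    """Expression-status call for a single variant.

    Raises :class:`InsufficientDepthError` when the tumor DNA or RNA depth
    is below ``min_depth``; such variants are excluded upstream.
    """
    if q.depth("tex") < min_depth or q.depth("ttr") < min_depth:
        raise InsufficientDepthError(
            f"tumor depth below {min_depth} (tex={q.depth('tex')}, "
            f"ttr={q.depth('ttr')})"
        )
    status, p_loss, p_gain = call_status_arrays(
        np.array([q.tex_ref]),
        np.array([q.tex_var]),
        np.array([q.ttr_ref]),
        np.array([q.ttr_var]),
        p_err=p_err,
        alpha=alpha,
        min_depth=min_depth,
        min_dna_minor_reads=min_dna_minor_reads,
    )
    return StatusCall(
        status=str(status[0]),
        pvalues={"som_l": float(p_loss[0]), "som_e": float(p_gain[0])},
    )


def has_germline_evidence(q: QuadCounts, max_normal_var_reads: int = 1) -> bool:
    """True iff variant reads in the normal DNA or RNA exceed the tolerated
    noise level, suggesting germline origin."""
    if max_normal_var_reads < 0:
        raise ValueError("max_normal_var_reads must be non-negative")
    return q.nex_var > max_normal_var_reads or q.ntr_var > max_normal_var_reads
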