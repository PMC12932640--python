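"""Wald-ratio / IVW causal estimation with Cochran's Q model choice.

Single instrument -> Wald ratio. Multiple instruments -> fixed-effects
IVW; when the heterogeneity test rejects (q_pvalue < het_alpha) the
random-effects variant is reported, with the standard error inflated
multiplicatively by sqrt(max(1, Q/df)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from mrcoloc.instruments import HarmonizedInstrument, InstrumentSet

METHOD_WALD = "wald"
METHOD_IVW_FIXED = "ivw_fixed"
METHOD_IVW_RANDOM = "ivw_random"


@dataclass
class MRResult:
    """Per-protein causal estimate (outcome units per SD of exposure)."""

    protein_id: str
    theta: float
    se_theta: float
    pvalue: float
    method: str
    n_snps: int
    Q: float = 0.0
    q_df: int = 0
    q_pvalue: float = 1.0
    significant_bonferroni: bool = False
    het_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.se_theta <= 0:
            raise ValueError("se_theta must be positive")
        if (self.method == METHOD_WALD) != (self.n_snps == 1):
            raise ValueError("method 'wald' iff exactly one instrument")
        if self.Q < 0:
            raise ValueError("Q must be non-negative")


def ztest_p(theta: float, se: float) -> float:
    """Two-sided normal p-value, stable far into the tail."""
    if se <= 0:
        raise ValueError("se must be positive")
    return float(2.0 * stats.norm.sf(abs(theta / se)))


def wald_ratio(instrument: HarmonizedInstrument,
               second_order_se: bool = False) -> tuple[float, float]:
    """Single-instrument ratio estimate with delta-method SE.

    First order ignores the exposure SE (the default of the standard IVW
    implementations); ``second_order_se`` adds the exposure-uncertainty
    term.
    """
    bx, by = instrument.beta_exp, instrument.beta_out
    if bx == 0:
        raise ZeroDivisionError("beta_exp is zero: Wald ratio undefined")
    theta = by / bx
    se = instrument.se_out / abs(bx)
    if second_order_se:
        se = float(np.sqrt(se**2 + (by**2 * instrument.se_exp**2) / bx**4))
    return theta, se


def ivw(
    instruments: InstrumentSet | Sequence[HarmonizedInstrument],
    protein_id: str | None = None,
    het_alpha: float = 0.05,
    second_order_se: bool = False,
) -> MRResult:
    """Inverse-variance-weighted combination of per-instrument ratios."""
    if isinstance(instruments, InstrumentSet):
        ins_list = instruments.instruments
        protein_id = protein_id or instruments.protein_id
    else:
        ins_list = list(instruments)
        protein_id = protein_id or ""
    if not ins_list:
        raise ValueError("empty instrument set")

    ratios = np.array([wald_ratio(i, second_order_se)[0] for i in ins_list])
    ses = np.array([wald_ratio(i, second_order_se)[1] for i in ins_list])
    k = len(ins_list)

    if k == 1:
        theta, se = ratios[0], ses[0]
        return MRResult(
            protein_id=protein_id,
            theta=float(theta),
            se_theta=float(se),
            pvalue=ztest_p(theta, se),
            method=METHOD_WALD,
            n_snps=1,
            het_alpha=het_alpha,
        )

    w = 1.0 / ses**2
    theta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (ratios - theta) ** 2))
    q_df = k - 1
    q_p = float(stats.chi2.sf(q, q_df))

    if q_p < het_alpha:
        method = METHOD_IVW_RANDOM
        se = se_fixed * float(np.sqrt(max(1.0, q / q_df)))
    else:
        method = METHOD_IVW_FIXED
        se = se_fixed
    return MRResult(
        protein_id=protein_id,
        theta=theta,
        se_theta=se,
        pvalue=ztest_p(theta, se),
        method=method,
        n_snps=k,
        Q=q,
        q_df=q_df,
        q_pvalue=q_p,
        het_alpha=het_alpha,
    )


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def apply_bonferroni(results: Sequence[MRResult], alpha: float = 0.05,
                     n_tests: int | None = None) -> float:
    """Flag each result against alpha / n_tests (default: len(results)).

    Returns the threshold used. A result is significant iff its p-value
    is strictly below the threshold.
    """
    n = n_tests if n_tests is not None else len(results)
    thr = bonferroni_threshold(alpha, n)
    for res in results:
        res.significant_bonferroni = res.pvalue < thr
    return thr
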