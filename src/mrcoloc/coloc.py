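"""Approximate-Bayes-factor colocalization for two traits over one region.

Per-SNP evidence is the Wakefield-style ABF computed from (beta, se)
under a Gaussian effect-size prior. Five hypotheses are scored: no
association (H0), trait-1 only (H1), trait-2 only (H2), two distinct
causal variants (H3), one shared causal variant (H4). All sums and
products of Bayes factors are done in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

DEFAULT_PRIOR_SD = {"quantitative": 0.15, "binary": 0.2}


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities of association."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if not (0.0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("require 0 < p12 <= min(p1, p2)")
        if max(self.p1, self.p2) >= 1.0:
            raise ValueError("p1 and p2 must be < 1")

    def check_region_size(self, n_snps: int) -> bool:
        """True when the implied region-level prior mass stays below 1."""
        return n_snps * (self.p1 + self.p2 + self.p12) < 1.0


@dataclass
class AbfVector:
    """Per-SNP log approximate Bayes factors for one trait."""

    snp_ids: list[str]
    log_abf: np.ndarray
    prior_sd: float

    def __post_init__(self) -> None:
        self.log_abf = np.asarray(self.log_abf, dtype=float)
        if len(self.snp_ids) != len(self.log_abf):
            raise ValueError("snp_ids and log_abf lengths differ")
        if not np.all(np.isfinite(self.log_abf)):
            raise ValueError("log ABF must be finite")

    def aligned(self, snp_ids: Sequence[str]) -> np.ndarray:
        index = {s: j for j, s in enumerate(self.snp_ids)}
        return self.log_abf[[index[s] for s in snp_ids]]


@dataclass
class ColocPosterior:
    """Posterior probabilities of H0..H4 for one dataset combination."""

    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_snps: int
    priors: ColocPriors
    label: str = "unconditional/unconditional"

    def __post_init__(self) -> None:
        total = self.pp0 + self.pp1 + self.pp2 + self.pp3 + self.pp4
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posteriors sum to {total}, not 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "pp0": self.pp0, "pp1": self.pp1, "pp2": self.pp2,
            "pp3": self.pp3, "pp4": self.pp4,
        }


def abf(
    snp_ids: Sequence[str],
    beta: np.ndarray,
    se: np.ndarray,
    trait_type: str = "quantitative",
    prior_sd: float | None = None,
) -> AbfVector:
    """Log ABF per SNP: 0.5 * [log(1 - r) + r z^2] with r = W / (W + V),
    W the prior effect variance and V the squared standard error."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    if prior_sd is None:
        prior_sd = DEFAULT_PRIOR_SD[trait_type]
    w = prior_sd**2
    v = se**2
    r = w / (w + v)
    z = beta / se
    log_abf = 0.5 * (np.log1p(-r) + r * z**2)
    return AbfVector(snp_ids=list(snp_ids), log_abf=log_abf, prior_sd=prior_sd)


def coloc_posteriors(
    abf1: AbfVector,
    abf2: AbfVector,
    priors: ColocPriors | None = None,
    label: str = "unconditional/unconditional",
) -> ColocPosterior:
    """Combine two aligned ABF vectors into H0..H4 posteriors.

    The SNP lists must already be the harmonized intersection. With
    S1 = sum(ABF1), S2 = sum(ABF2), S12 = sum(ABF1*ABF2), the unnormalized
    hypothesis weights are 1, p1*S1, p2*S2, p1*p2*(S1*S2 - S12), p12*S12;
    the H3 term is clamped at zero against rounding.
    """
    priors = priors or ColocPriors()
    if abf1.snp_ids != abf2.snp_ids:
        common = [s for s in abf1.snp_ids if s in set(abf2.snp_ids)]
        if not common:
            raise ValueError("no common SNPs between the two ABF vectors")
        la1, la2 = abf1.aligned(common), abf2.aligned(common)
        n = len(common)
    else:
        la1, la2 = abf1.log_abf, abf2.log_abf
        n = len(abf1.snp_ids)
    if n == 0:
        raise ValueError("empty SNP set")

    log_s1 = float(logsumexp(la1))
    log_s2 = float(logsumexp(la2))
    log_s12 = float(logsumexp(la1 + la2))

    log_l = np.empty(5)
    log_l[0] = 0.0
    log_l[1] = np.log(priors.p1) + log_s1
    log_l[2] = np.log(priors.p2) + log_s2
    # log(S1*S2 - S12), clamped at -inf when the difference underflows
    gap = log_s1 + log_s2 - log_s12
    if n == 1 or gap <= 0:
        log_l[3] = -np.inf
    else:
        # log(e^gap - 1); for large gaps expm1 would overflow but the
        # correction term is below double precision anyway
        log_gap = gap if gap > 33 else np.log(np.expm1(gap))
        log_l[3] = np.log(priors.p1) + np.log(priors.p2) + log_s12 + log_gap
    log_l[4] = np.log(priors.p12) + log_s12

    pp = np.exp(log_l - logsumexp(log_l))
    pp /= pp.sum()
    return ColocPosterior(
        pp0=float(pp[0]), pp1=float(pp[1]), pp2=float(pp[2]),
        pp3=float(pp[3]), pp4=float(pp[4]),
        n_snps=n, priors=priors, label=label,
    )


def coloc_from_stats(
    snp_ids: Sequence[str],
    beta1: np.ndarray, se1: np.ndarray,
    beta2: np.ndarray, se2: np.ndarray,
    trait_type1: str = "quantitative",
    trait_type2: str = "binary",
    priors: ColocPriors | None = None,
    prior_sd1: float | None = None,
    prior_sd2: float | None = None,
    label: str = "unconditional/unconditional",
) -> ColocPosterior:
    """Convenience wrapper: ABFs for both traits, then posteriors."""
    a1 = abf(snp_ids, beta1, se1, trait_type1, prior_sd1)
    a2 = abf(snp_ids, beta2, se2, trait_type2, prior_sd2)
    return coloc_posteriors(a1, a2, priors, label=label)
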