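"""cis-pQTL instrument selection, harmonization and LD pruning.

Selection keeps SNPs that are within the cis window of the protein's
gene, strongly associated with the protein, non protein-altering, common
(MAF > 1%) and present in the outcome GWAS. Palindromic SNPs with EAF in
[0.45, 0.55] are dropped; remaining palindromic SNPs are oriented by
allele-frequency side. Every exclusion carries a reason code and the
retained/excluded sets partition the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from mrcoloc.ld import GenotypePanel
from mrcoloc.sumstats import SumStatRecord, SumStatTable, VariantAnnotation

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# exclusion reason codes
R_CIS = "cis_window"
R_PVAL = "pvalue"
R_CODING = "protein_altering"
R_MAF = "maf"
R_NOT_IN_OUTCOME = "not_in_outcome"
R_PALINDROMIC = "palindromic_ambiguous"
R_MISMATCH = "allele_mismatch"
R_PRUNED = "pruned"


@dataclass
class InstrumentParams:
    """Tunable thresholds of the selection procedure."""

    cis_window: int = 1_000_000  # bp each side of the TSS, closed interval
    p_threshold: float = 5e-8
    maf_threshold: float = 0.01  # strict: min(eaf, 1-eaf) must exceed this
    palindromic_band: tuple[float, float] = (0.45, 0.55)  # inclusive
    prune_r2: float = 0.01


@dataclass(frozen=True)
class Candidate:
    """Exposure record that survived selection, before harmonization."""

    record: SumStatRecord
    palindromic: bool = False


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure/outcome pair on a shared effect-allele orientation."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float
    eaf_out: float
    p_exp: float

    def __post_init__(self) -> None:
        if self.se_exp <= 0 or self.se_out <= 0:
            raise ValueError("standard errors must be positive")


@dataclass
class InstrumentSet:
    """Final pruned instruments for one protein plus the exclusion log."""

    protein_id: str
    instruments: list[HarmonizedInstrument]
    exclusions: list[tuple[str, str]] = field(default_factory=list)  # (snp_id, reason)

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def snp_ids(self) -> list[str]:
        return [ins.snp_id for ins in self.instruments]

    def log_exclusion(self, snp_id: str, reason: str) -> None:
        self.exclusions.append((snp_id, reason))


def is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


def select_cis_pqtls(
    exposure: SumStatTable,
    annotations: Mapping[str, VariantAnnotation],
    outcome: SumStatTable,
    gene: str,
    params: InstrumentParams | None = None,
) -> tuple[list[Candidate], list[tuple[str, str]]]:
    """Apply the cis/p-value/coding/MAF/outcome-presence filters.

    Returns the surviving candidates and the exclusion log. Raises
    ``KeyError`` when ``gene`` has no annotated TSS.
    """
    params = params or InstrumentParams()
    tss_positions = {a.tss_pos for a in annotations.values() if a.gene == gene}
    if not tss_positions:
        raise KeyError(f"gene {gene!r} absent from annotation")
    tss = min(tss_positions)

    kept: list[Candidate] = []
    excluded: list[tuple[str, str]] = []
    for rec in exposure:
        annot = annotations.get(rec.snp_id)
        in_cis = (
            annot is not None
            and annot.gene == gene
            and abs(rec.pos - tss) <= params.cis_window
        )
        if not in_cis:
            excluded.append((rec.snp_id, R_CIS))
        elif rec.pvalue >= params.p_threshold:
            excluded.append((rec.snp_id, R_PVAL))
        elif annot.protein_altering:
            excluded.append((rec.snp_id, R_CODING))
        elif rec.maf <= params.maf_threshold:
            excluded.append((rec.snp_id, R_MAF))
        elif rec.snp_id not in outcome:
            excluded.append((rec.snp_id, R_NOT_IN_OUTCOME))
        else:
            kept.append(Candidate(record=rec, palindromic=is_palindromic(
                rec.effect_allele, rec.other_allele)))
    return kept, excluded


def remove_palindromic(
    candidates: Iterable[Candidate],
    band: tuple[float, float] = (0.45, 0.55),
) -> tuple[list[Candidate], list[tuple[str, str]]]:
    """Drop palindromic SNPs whose exposure EAF lies inside ``band``
    (inclusive); other palindromic SNPs stay flagged for frequency-based
    orientation."""
    lo, hi = band
    kept, excluded = [], []
    for cand in candidates:
        if cand.palindromic and lo <= cand.record.eaf <= hi:
            excluded.append((cand.record.snp_id, R_PALINDROMIC))
        else:
            kept.append(cand)
    return kept, excluded


def _orientation(cand: SumStatRecord, out: SumStatRecord) -> str | None:
    """Classify the outcome's allele orientation relative to the exposure.

    Returns "same", "swapped", "comp" (strand flip, same orientation),
    "comp_swapped", or None when the pairs are incompatible.
    """
    ea, oa = cand.effect_allele, cand.other_allele
    cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
    pair = (out.effect_allele, out.other_allele)
    if pair == (ea, oa):
        return "same"
    if pair == (oa, ea):
        return "swapped"
    if pair == (cea, coa):
        return "comp"
    if pair == (coa, cea):
        return "comp_swapped"
    return None


def harmonize(
    candidates: Iterable[Candidate],
    outcome: SumStatTable,
    band: tuple[float, float] = (0.45, 0.55),
) -> tuple[list[HarmonizedInstrument], list[tuple[str, str]]]:
    """Orient outcome records onto each exposure record's effect allele.

    Swapped orientations negate the outcome beta and reflect its EAF;
    strand-flipped non-palindromic pairs are aligned by complementing.
    Palindromic SNPs (for which "comp" and "swapped" are indistinguishable)
    are oriented by EAF side agreement and dropped when the outcome EAF is
    itself ambiguous (inside ``band``).
    """
    lo, hi = band
    kept: list[HarmonizedInstrument] = []
    excluded: list[tuple[str, str]] = []
    for cand in candidates:
        rec = cand.record
        out = outcome.get(rec.snp_id)
        if out is None:
            excluded.append((rec.snp_id, R_NOT_IN_OUTCOME))
            continue
        if cand.palindromic:
            orient = _orientation(rec, out)
            if orient is None:
                excluded.append((rec.snp_id, R_MISMATCH))
                continue
            if lo <= out.eaf <= hi:
                excluded.append((rec.snp_id, R_PALINDROMIC))
                continue
            # allele labels cannot resolve strand; match frequency sides
            flip = (rec.eaf < 0.5) != (out.eaf < 0.5)
        else:
            orient = _orientation(rec, out)
            if orient is None:
                excluded.append((rec.snp_id, R_MISMATCH))
                continue
            flip = orient in ("swapped", "comp_swapped")
        beta_out = -out.beta if flip else out.beta
        eaf_out = 1.0 - out.eaf if flip else out.eaf
        kept.append(
            HarmonizedInstrument(
                snp_id=rec.snp_id,
                effect_allele=rec.effect_allele,
                other_allele=rec.other_allele,
                beta_exp=rec.beta,
                se_exp=rec.se,
                beta_out=beta_out,
                se_out=out.se,
                eaf_exp=rec.eaf,
                eaf_out=eaf_out,
                p_exp=rec.pvalue,
            )
        )
    return kept, excluded


def _prune_order(instruments: Sequence[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    # deterministic: p ascending, |z| descending, snp_id lexical
    return sorted(
        instruments,
        key=lambda ins: (ins.p_exp, -abs(ins.beta_exp / ins.se_exp), ins.snp_id),
    )


def ld_prune(
    instruments: Sequence[HarmonizedInstrument],
    panel: GenotypePanel,
    r2_threshold: float = 0.01,
    protein_id: str = "",
    prior_exclusions: Iterable[tuple[str, str]] = (),
) -> InstrumentSet:
    """Greedy LD pruning: keep the most significant SNP, then accept each
    next SNP only if its reference r-squared with every accepted SNP is at
    or below ``r2_threshold``."""
    missing = [ins.snp_id for ins in instruments if ins.snp_id not in panel]
    if missing:
        raise KeyError(f"instrument SNP(s) absent from reference panel: {', '.join(missing)}")

    accepted: list[HarmonizedInstrument] = []
    exclusions = list(prior_exclusions)
    cols: list[np.ndarray] = []
    for ins in _prune_order(instruments):
        x = panel.column(ins.snp_id)
        sd = x.std()
        if sd == 0:
            exclusions.append((ins.snp_id, R_PRUNED))
            continue
        xc = (x - x.mean()) / sd
        ok = True
        for other in cols:
            r = float(xc @ other) / len(xc)
            if r * r > r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(ins)
            cols.append(xc)
        else:
            exclusions.append((ins.snp_id, R_PRUNED))
    return InstrumentSet(protein_id=protein_id, instruments=accepted, exclusions=exclusions)


def build_instrument_set(
    exposure: SumStatTable,
    annotations: Mapping[str, VariantAnnotation],
    outcome: SumStatTable,
    panel: GenotypePanel,
    gene: str,
    params: InstrumentParams | None = None,
) -> InstrumentSet:
    """Full selection pipeline: cis filters, palindromic removal,
    harmonization, LD pruning. All exclusions accumulate in the result."""
    params = params or InstrumentParams()
    candidates, excl = select_cis_pqtls(exposure, annotations, outcome, gene, params)
    candidates, excl2 = remove_palindromic(candidates, params.palindromic_band)
    harmonized, excl3 = harmonize(candidates, outcome, params.palindromic_band)
    return ld_prune(
        harmonized,
        panel,
        r2_threshold=params.prune_r2,
        protein_id=gene,
        prior_exclusions=excl + excl2 + excl3,
    )


def write_exclusions(exclusions: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("SNP\tREASON\n")
        for snp_id, reason in exclusions:
            fh.write(f"{snp_id}\t{reason}\n")
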