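"""End-to-end proteome-wide driver.

Per protein: instrument selection -> MR -> Bonferroni screen; proteins
passing the screen go on to pairwise conditional colocalization over the
region around the lead cis-pQTL. The Bonferroni denominator is the count
of proteins with at least one valid instrument, not the count supplied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from mrcoloc import __version__
from mrcoloc.cojo import CojoWorkspace
from mrcoloc.coloc import ColocPriors
from mrcoloc.instruments import InstrumentParams, InstrumentSet, build_instrument_set
from mrcoloc.ld import GenotypePanel
from mrcoloc.mr import MRResult, apply_bonferroni, ivw
from mrcoloc.pwcoco import PWCoCoConfig, PWCoCoResult, run_pwcoco
from mrcoloc.sumstats import SumStatTable, VariantAnnotation

logger = logging.getLogger(__name__)

VERDICT_YES = "yes"
VERDICT_NO = "no"
VERDICT_NOT_TESTED = "not_tested"
VERDICT_NOT_TESTABLE = "not_testable"


@dataclass
class ProteinData:
    """Everything the pipeline needs for one protein locus."""

    protein_id: str
    gene: str
    exposure: SumStatTable
    outcome: SumStatTable
    panel: GenotypePanel
    annotations: Mapping[str, VariantAnnotation]


@dataclass
class PipelineParams:
    instrument: InstrumentParams = field(default_factory=InstrumentParams)
    het_alpha: float = 0.05
    alpha: float = 0.05
    priors: ColocPriors = field(default_factory=ColocPriors)
    prior_sd_exposure: float = 0.15
    prior_sd_outcome: float = 0.2
    pp4_threshold: float = 0.8
    cojo_p_cutoff: float = 5e-8
    collinearity_r2: float = 0.9
    coloc_window: int = 500_000  # bp each side of the lead cis-pQTL
    single_signal_condition: bool = False

    def as_dict(self) -> dict:
        return {
            "cis_window": self.instrument.cis_window,
            "instrument_p_threshold": self.instrument.p_threshold,
            "maf_threshold": self.instrument.maf_threshold,
            "palindromic_band": list(self.instrument.palindromic_band),
            "prune_r2": self.instrument.prune_r2,
            "het_alpha": self.het_alpha,
            "alpha": self.alpha,
            "coloc_priors": {"p1": self.priors.p1, "p2": self.priors.p2,
                             "p12": self.priors.p12},
            "prior_sd_exposure": self.prior_sd_exposure,
            "prior_sd_outcome": self.prior_sd_outcome,
            "pp4_threshold": self.pp4_threshold,
            "cojo_p_cutoff": self.cojo_p_cutoff,
            "collinearity_r2": self.collinearity_r2,
            "coloc_window": self.coloc_window,
            "single_signal_condition": self.single_signal_condition,
        }


@dataclass
class ProteinReport:
    gene: str
    protein: str
    instruments: InstrumentSet | None
    mr: MRResult | None
    pwcoco: PWCoCoResult | None
    verdict: str

    @property
    def testable(self) -> bool:
        return self.mr is not None


def _coloc_region(data: ProteinData, instruments: InstrumentSet,
                  window: int) -> list[str]:
    """SNPs within ``window`` of the lead instrument, present in both
    trait tables and the reference panel."""
    lead = min(instruments.instruments, key=lambda i: i.p_exp)
    lead_pos = data.exposure[lead.snp_id].pos
    region = []
    for rec in data.exposure:
        if abs(rec.pos - lead_pos) <= window and rec.snp_id in data.outcome \
                and rec.snp_id in data.panel:
            region.append(rec.snp_id)
    return region


def analyse_protein(data: ProteinData, params: PipelineParams) -> ProteinReport:
    """Instruments + MR for one protein (colocalization is gated later)."""
    try:
        iset = build_instrument_set(
            data.exposure, data.annotations, data.outcome, data.panel,
            data.gene, params.instrument,
        )
    except KeyError as exc:
        logger.error("protein %s: %s", data.protein_id, exc)
        return ProteinReport(data.gene, data.protein_id, None, None, None,
                             VERDICT_NOT_TESTABLE)
    if len(iset) == 0:
        return ProteinReport(data.gene, data.protein_id, iset, None, None,
                             VERDICT_NOT_TESTABLE)
    mr_res = ivw(iset, protein_id=data.protein_id, het_alpha=params.het_alpha)
    return ProteinReport(data.gene, data.protein_id, iset, mr_res, None,
                         VERDICT_NOT_TESTED)


def colocalize_protein(data: ProteinData, report: ProteinReport,
                       params: PipelineParams) -> None:
    """Run PWCoCo for a Bonferroni-significant protein, in place."""
    region = _coloc_region(data, report.instruments, params.coloc_window)
    if not region:
        report.verdict = VERDICT_NOT_TESTABLE
        return
    ws_exp = CojoWorkspace(data.exposure.subset(region), data.panel)
    ws_out = CojoWorkspace(data.outcome.subset(region), data.panel)
    cfg = PWCoCoConfig(
        priors=params.priors,
        prior_sd1=params.prior_sd_exposure,
        prior_sd2=params.prior_sd_outcome,
        pp4_threshold=params.pp4_threshold,
        p_cutoff=params.cojo_p_cutoff,
        collinearity_r2=params.collinearity_r2,
        single_signal_condition=params.single_signal_condition,
    )
    report.pwcoco = run_pwcoco(
        ws_exp, ws_out, cfg,
        trait_type1=data.exposure.trait_type,
        trait_type2=data.outcome.trait_type,
        region_id=data.protein_id,
    )
    report.verdict = VERDICT_YES if report.pwcoco.evidence else VERDICT_NO


def run_proteome_mr(
    proteome: Sequence[ProteinData], params: PipelineParams | None = None
) -> tuple[list[ProteinReport], float]:
    """Screen every protein; colocalize only the Bonferroni-significant.

    Returns the reports (input order) and the Bonferroni threshold used.
    The threshold denominator is the number of proteins with >= 1 valid
    instrument.
    """
    params = params or PipelineParams()
    reports = [analyse_protein(data, params) for data in proteome]
    tested = [r.mr for r in reports if r.mr is not None]
    if not tested:
        return reports, params.alpha
    threshold = apply_bonferroni(tested, alpha=params.alpha, n_tests=len(tested))
    by_id = {d.protein_id: d for d in proteome}
    for report in reports:
        if report.mr is not None and report.mr.significant_bonferroni:
            colocalize_protein(by_id[report.protein], report, params)
    return reports, threshold


def run_secondary_outcomes(
    proteome: Sequence[ProteinData],
    outcomes: Mapping[str, SumStatTable],
    params: PipelineParams | None = None,
) -> dict[str, tuple[list[ProteinReport], float]]:
    """Re-run the MR machinery against each secondary outcome table.

    Bonferroni flags are computed per outcome (nominal p-values are kept
    in each MRResult so nominal significance can be read off directly).
    """
    params = params or PipelineParams()
    results = {}
    for outcome_id, table in outcomes.items():
        swapped = [
            ProteinData(d.protein_id, d.gene, d.exposure, table, d.panel, d.annotations)
            for d in proteome
        ]
        reports = [analyse_protein(d, params) for d in swapped]
        tested = [r.mr for r in reports if r.mr is not None]
        thr = apply_bonferroni(tested, alpha=params.alpha) if tested else params.alpha
        results[outcome_id] = (reports, thr)
    return results


def format_pvalue(p: float) -> str:
    """Scientific notation with two significant digits: 6.5E-43."""
    s = f"{p:.1E}"
    mantissa, exp = s.split("E")
    return f"{mantissa}E{int(exp)}"


def render_results_table(reports: Sequence[ProteinReport]) -> str:
    """Tab-delimited results table, rows sorted by ascending MR p-value.

    Columns mirror the headline report: gene, protein, causal estimate
    (2 dp), SE (2 dp), p (two significant digits), colocalization verdict.
    """
    header = "Gene\tProtein\tBeta\tSE\tP\tColocalization"
    rows = []
    testable = [r for r in reports if r.mr is not None]
    for r in sorted(testable, key=lambda r: r.mr.pvalue):
        rows.append(
            f"{r.gene}\t{r.protein}\t{r.mr.theta:.2f}\t{r.mr.se_theta:.2f}"
            f"\t{format_pvalue(r.mr.pvalue)}\t{r.verdict}"
        )
    for r in reports:
        if r.mr is None:
            rows.append(f"{r.gene}\t{r.protein}\tNA\tNA\tNA\t{VERDICT_NOT_TESTABLE}")
    return "\n".join([header] + rows) + "\n"


def write_manifest(path: Path, params: PipelineParams, threshold: float,
                   n_proteins: int, seed: int | None = None) -> None:
    manifest = {
        "package_version": __version__,
        "params": params.as_dict(),
        "bonferroni_threshold": threshold,
        "n_proteins_tested": n_proteins,
        "seed": seed,
        "notes": {
            "het_alpha": "heterogeneity alpha for fixed/random choice (assumed 0.05)",
            "coloc_priors": "method defaults; configurable",
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
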