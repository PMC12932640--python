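"""Locus-scale GWAS summary-statistic simulation with LD.

Haplotypes are drawn by thresholding a latent AR(1) Gaussian at per-SNP
MAF quantiles; dosage is the sum of two haplotypes. Exposure/outcome
cohorts and the reference panel are independent draws from the same
haplotype process, which is the two-sample MR setting.

Architectures for the outcome trait:

``shared``
    outcome liability = theta x (genetic exposure score) + noise, so the
    outcome's causal variants are exactly the exposure's.
``distinct``
    the outcome's causal variant(s) differ from the exposure's but sit in
    the same LD block (confounding-by-LD regime).
``null``
    no genetic effect on the outcome.
``two_signal_one_shared``
    the exposure carries >= 2 independent signals; only the first is
    causal for the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from mrcoloc.ld import GenotypePanel
from mrcoloc.sumstats import SumStatRecord, SumStatTable, VariantAnnotation

ARCHITECTURES = ("shared", "distinct", "null", "two_signal_one_shared")

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of one simulated locus pair."""

    m_snps: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.9
    n_exposure: int = 5_000
    n_outcome: int = 20_000
    n_ref: int = 2_000
    exposure_causals: list[tuple[int, float]] = field(default_factory=lambda: [(100, 0.3)])
    outcome_architecture: str = "shared"
    outcome_causals: list[tuple[int, float]] | None = None  # used when architecture=distinct
    theta: float = 0.0
    outcome_type: str = "quantitative"
    binary_model: str = "logistic_score"  # or "linear_probability"
    case_fraction: float = 0.1
    chrom: str = "1"
    start_pos: int = 1_000_000
    pos_step: int = 1_000
    snp_prefix: str = "rs"
    seed: int = 0

    def validate(self) -> None:
        if self.m_snps < 1:
            raise ValueError("m_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        for name in ("n_exposure", "n_outcome", "n_ref"):
            if getattr(self, name) < 50:
                raise ValueError(f"{name} must be >= 50")
        for idx, _ in self.exposure_causals:
            if not (0 <= idx < self.m_snps):
                raise ValueError(f"causal index {idx} out of range")
        if self.outcome_architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.outcome_architecture!r}")
        if self.outcome_architecture == "distinct" and self.m_snps < 2:
            raise ValueError("distinct architecture requires m_snps >= 2")
        if self.outcome_architecture == "two_signal_one_shared" and len(self.exposure_causals) < 2:
            raise ValueError("two_signal_one_shared requires >= 2 exposure causals")
        if self.outcome_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown outcome_type {self.outcome_type!r}")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must be in (0, 1)")


@dataclass
class SimTruth:
    """Ground-truth record emitted alongside every simulated locus pair."""

    exposure_causals: list[tuple[int, float]]
    outcome_causals: list[tuple[int, float]]
    theta: float
    shared: bool
    ld_rho: float
    mafs: list[float]
    snp_ids: list[str]
    seed: int

    @property
    def exposure_causal_ids(self) -> list[str]:
        return [self.snp_ids[i] for i, _ in self.exposure_causals]

    @property
    def outcome_causal_ids(self) -> list[str]:
        return [self.snp_ids[i] for i, _ in self.outcome_causals]


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    """Named independent RNG streams derived from one global seed."""
    root = np.random.SeedSequence(seed)
    # genotype streams per cohort plus separate phenotype-noise streams
    names = ("meta", "exposure", "outcome", "reference",
             "exposure_pheno", "outcome_pheno")
    children = root.spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _draw_haplotypes(rng: np.random.Generator, n_hap: int, thresholds: np.ndarray,
                     ld_rho: float) -> np.ndarray:
    """0/1 haplotype matrix from the latent AR(1) Gaussian model."""
    m = thresholds.shape[0]
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        innov = rng.standard_normal((n_hap, m - 1))
        scale = np.sqrt(1.0 - ld_rho**2)
        for j in range(1, m):
            z[:, j] = ld_rho * z[:, j - 1] + scale * innov[:, j - 1]
    return (z < thresholds).astype(np.int8)


def _snp_ids(config: SimConfig) -> list[str]:
    return [f"{config.snp_prefix}{j}" for j in range(config.m_snps)]


def _panel_alleles(config: SimConfig, rng: np.random.Generator) -> list[tuple[str, str]]:
    """Random non-palindromic allele pairs (effect, other) per SNP."""
    pairs = []
    for _ in range(config.m_snps):
        ea = rng.choice(_BASES)
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}[ea]
        oa = rng.choice([b for b in _BASES if b not in (ea, comp)])
        pairs.append((str(ea), str(oa)))
    return pairs


def simulate_genotypes(config: SimConfig) -> dict[str, GenotypePanel]:
    """Simulate dosage panels for the exposure cohort, outcome cohort and
    reference panel — three independent draws from one haplotype model."""
    config.validate()
    streams = _substreams(config.seed)
    meta = streams["meta"]
    mafs = meta.uniform(*config.maf_range, size=config.m_snps)
    thresholds = stats.norm.ppf(mafs)
    alleles = _panel_alleles(config, meta)
    ids = _snp_ids(config)

    panels = {}
    for name, n in (
        ("exposure", config.n_exposure),
        ("outcome", config.n_outcome),
        ("reference", config.n_ref),
    ):
        rng = streams[name]
        h1 = _draw_haplotypes(rng, n, thresholds, config.ld_rho)
        h2 = _draw_haplotypes(rng, n, thresholds, config.ld_rho)
        panels[name] = GenotypePanel(
            snp_ids=list(ids), alleles=list(alleles), dosages=(h1 + h2).astype(float)
        )
    panels["_mafs"] = mafs  # type: ignore[assignment]
    return panels


def _genetic_score(dosages: np.ndarray, causals: Sequence[tuple[int, float]]) -> np.ndarray:
    """Sum of standardized causal dosages weighted by effect size."""
    score = np.zeros(dosages.shape[0])
    for idx, beta in causals:
        g = dosages[:, idx]
        sd = g.std()
        if sd == 0:
            continue
        score += beta * (g - g.mean()) / sd
    return score


def _add_noise_to_unit_variance(rng: np.random.Generator, score: np.ndarray) -> np.ndarray:
    var_g = score.var()
    noise_var = max(1.0 - var_g, 1e-6)
    return score + rng.standard_normal(len(score)) * np.sqrt(noise_var)


def _marginal_ols(dosages: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-SNP simple linear regression (beta, se)."""
    n = len(y)
    gc = dosages - dosages.mean(axis=0)
    yc = y - y.mean()
    ss = np.einsum("ij,ij->j", gc, gc)
    ss = np.where(ss == 0, np.nan, ss)
    beta = gc.T @ yc / ss
    rss = yc @ yc - beta**2 * ss
    sigma2 = np.maximum(rss, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / ss)
    return beta, se


def _marginal_logistic_score(dosages: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Score-test approximation to per-SNP logistic beta/se (log-odds)."""
    mu = y.mean()
    gc = dosages - dosages.mean(axis=0)
    ss = np.einsum("ij,ij->j", gc, gc)
    ss = np.where(ss == 0, np.nan, ss)
    v = mu * (1.0 - mu)
    beta = gc.T @ (y - mu) / (v * ss)
    se = 1.0 / np.sqrt(v * ss)
    return beta, se


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, np.nextafter(0, 1), 1.0)


def _build_table(trait_id: str, trait_type: str, panel: GenotypePanel, config: SimConfig,
                 beta: np.ndarray, se: np.ndarray, n: int) -> SumStatTable:
    pvals = _two_sided_p(beta, se)
    table = SumStatTable(trait_id, trait_type=trait_type)
    eafs = panel.dosages.mean(axis=0) / 2.0
    for j, snp in enumerate(panel.snp_ids):
        if not np.isfinite(beta[j]) or not np.isfinite(se[j]) or se[j] <= 0:
            continue  # monomorphic in this cohort
        eaf = float(np.clip(eafs[j], 1e-6, 1 - 1e-6))
        ea, oa = panel.alleles[j]
        table.add(
            SumStatRecord(
                snp_id=snp,
                chrom=config.chrom,
                pos=config.start_pos + j * config.pos_step,
                effect_allele=ea,
                other_allele=oa,
                eaf=eaf,
                beta=float(beta[j]),
                se=float(se[j]),
                pvalue=float(pvals[j]),
                n=float(n),
            )
        )
    return table


def _resolve_outcome_causals(config: SimConfig) -> list[tuple[int, float]]:
    arch = config.outcome_architecture
    if arch == "null":
        return []
    if arch == "shared":
        return [(i, config.theta * b) for i, b in config.exposure_causals]
    if arch == "two_signal_one_shared":
        i, b = config.exposure_causals[0]
        return [(i, config.theta * b)]
    # distinct: explicit causals, or a neighbour of the exposure causal
    if config.outcome_causals is not None:
        return list(config.outcome_causals)
    exp_idx = {i for i, _ in config.exposure_causals}
    candidates = [j for j in range(config.m_snps) if j not in exp_idx]
    idx0, beta0 = config.exposure_causals[0]
    # prefer a SNP a few steps away: same LD block, not the same variant
    offsets = sorted(candidates, key=lambda j: abs(abs(j - idx0) - 5))
    return [(offsets[0], config.theta * beta0 if config.theta else beta0)]


def simulate_locus_pair(
    config: SimConfig,
) -> tuple[SumStatTable, SumStatTable, GenotypePanel, SimTruth]:
    """Simulate one locus: exposure and outcome summary statistics, a
    reference panel, and the generating truth."""
    config.validate()
    panels = simulate_genotypes(config)
    mafs = panels.pop("_mafs")
    streams = _substreams(config.seed)
    ids = _snp_ids(config)

    # exposure phenotype and marginals
    exp_panel = panels["exposure"]
    exp_score = _genetic_score(exp_panel.dosages, config.exposure_causals)
    x = _add_noise_to_unit_variance(streams["exposure_pheno"], exp_score)
    beta_x, se_x = _marginal_ols(exp_panel.dosages, x)
    exposure = _build_table(
        "exposure", "quantitative", exp_panel, config, beta_x, se_x, config.n_exposure
    )

    # outcome liability and marginals
    out_panel = panels["outcome"]
    out_causals = _resolve_outcome_causals(config)
    out_score = _genetic_score(out_panel.dosages, out_causals)
    liability = _add_noise_to_unit_variance(streams["outcome_pheno"], out_score)
    if config.outcome_type == "binary":
        cut = np.quantile(liability, 1.0 - config.case_fraction)
        y = (liability > cut).astype(float)
        if config.binary_model == "linear_probability":
            beta_y, se_y = _marginal_ols(out_panel.dosages, y)
        else:
            beta_y, se_y = _marginal_logistic_score(out_panel.dosages, y)
        trait_type = "binary"
    else:
        beta_y, se_y = _marginal_ols(out_panel.dosages, liability)
        trait_type = "quantitative"
    outcome = _build_table(
        "outcome", trait_type, out_panel, config, beta_y, se_y, config.n_outcome
    )

    truth = SimTruth(
        exposure_causals=list(config.exposure_causals),
        outcome_causals=out_causals,
        theta=config.theta,
        shared=config.outcome_architecture in ("shared", "two_signal_one_shared"),
        ld_rho=config.ld_rho,
        mafs=[float(f) for f in mafs],
        snp_ids=ids,
        seed=config.seed,
    )
    return exposure, outcome, panels["reference"], truth


@dataclass
class SimulatedProtein:
    """One protein locus from a simulated proteome."""

    protein_id: str
    exposure: SumStatTable
    outcome: SumStatTable
    reference: GenotypePanel
    truth: SimTruth
    annotations: list[VariantAnnotation]


def locus_annotations(config: SimConfig, protein_id: str,
                      protein_altering: Sequence[int] = ()) -> list[VariantAnnotation]:
    """Annotation rows for a simulated locus; the TSS sits at the locus
    midpoint so the whole locus is cis to ``protein_id``."""
    tss = config.start_pos + (config.m_snps // 2) * config.pos_step
    coding = set(protein_altering)
    return [
        VariantAnnotation(
            snp_id=f"{config.snp_prefix}{j}",
            gene=protein_id,
            tss_pos=tss,
            protein_altering=j in coding,
        )
        for j in range(config.m_snps)
    ]


def simulate_proteome(
    configs: dict[str, SimConfig], seed: int | None = None
) -> list[SimulatedProtein]:
    """Simulate independent loci, one per protein.

    Each protein's config gets a deterministic per-protein seed derived
    from ``seed`` (or its own seed when ``seed`` is None), a unique SNP id
    prefix and a distinct chromosome label, so loci never collide.
    """
    out = []
    for k, (protein_id, cfg) in enumerate(sorted(configs.items())):
        cfg = replace(cfg, snp_prefix=f"{protein_id}_rs", chrom=str(k + 1))
        if seed is not None:
            cfg = replace(cfg, seed=int(np.random.SeedSequence([seed, k]).generate_state(1)[0]))
        exposure, outcome, reference, truth = simulate_locus_pair(cfg)
        exposure.trait_id = protein_id
        out.append(
            SimulatedProtein(
                protein_id=protein_id,
                exposure=exposure,
                outcome=outcome,
                reference=reference,
                truth=truth,
                annotations=locus_annotations(cfg, protein_id),
            )
        )
    return out


def write_truth(truth: SimTruth, path) -> None:
    """Write the truth record as structured key-value text."""
    lines = [
        f"seed\t{truth.seed}",
        f"theta\t{truth.theta!r}",
        f"shared\t{int(truth.shared)}",
        f"ld_rho\t{truth.ld_rho!r}",
        "exposure_causals\t" + ";".join(f"{i}:{b!r}" for i, b in truth.exposure_causals),
        "outcome_causals\t" + ";".join(f"{i}:{b!r}" for i, b in truth.outcome_causals),
        "snp_ids\t" + ";".join(truth.snp_ids),
        "mafs\t" + ";".join(format(f, ".17g") for f in truth.mafs),
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
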