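import numpy as np
import pytest

from mrcoloc.ld import GenotypePanel
from mrcoloc.simulate import SimConfig, simulate_locus_pair
from mrcoloc.sumstats import SumStatRecord, SumStatTable


def make_record(snp_id="rs1", **kwargs) -> SumStatRecord:
    defaults = dict(
        snp_id=snp_id, chrom="1", pos=1000, effect_allele="A", other_allele="G",
        eaf=0.3, beta=0.1, se=0.02, pvalue=1e-6, n=5000.0,
    )
    defaults.update(kwargs)
    return SumStatRecord(**defaults)


def panel_from_haplotype_freqs(freqs: dict[str, float], n_ind: int,
                               seed: int = 0) -> GenotypePanel:
    """Panel of 2 SNPs built from explicit two-locus haplotype frequencies.

    Haplotype counts are exact (deterministic rounding); pairing into
    diplotypes is random under the seed.
    """
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_ind
    order = ["AB", "Ab", "aB", "ab"]
    counts = [int(round(freqs.get(k, 0.0) * n_hap)) for k in order]
    counts[-1] = n_hap - sum(counts[:-1])
    hap_a, hap_b = [], []
    for (a, b), c in zip([(1, 1), (1, 0), (0, 1), (0, 0)], counts):
        hap_a += [a] * c
        hap_b += [b] * c
    hap = np.column_stack([hap_a, hap_b])
    perm = rng.permutation(n_hap)
    hap = hap[perm]
    dosages = hap[:n_ind] + hap[n_ind:]
    return GenotypePanel(
        snp_ids=["snpA", "snpB"],
        alleles=[("A", "G"), ("C", "A")],
        dosages=dosages.astype(float),
    )


@pytest.fixture(scope="session")
def small_shared_locus():
    """One strongly-shared locus reused by several test modules."""
    cfg = SimConfig(
        m_snps=60, n_exposure=2000, n_outcome=4000, n_ref=1000,
        exposure_causals=[(30, 0.35)], outcome_architecture="shared",
        theta=0.5, seed=7,
    )
    return simulate_locus_pair(cfg)


def table_from_arrays(trait_id, snp_ids, betas, ses, trait_type="quantitative",
                      eafs=None, n=5000.0):
    from scipy import stats as st
    table = SumStatTable(trait_id, trait_type=trait_type)
    for j, s in enumerate(snp_ids):
        eaf = 0.3 if eafs is None else eafs[j]
        p = float(np.clip(2 * st.norm.sf(abs(betas[j] / ses[j])), 1e-300, 1.0))
        table.add(make_record(
            snp_id=s, pos=1000 + j, eaf=eaf, beta=float(betas[j]),
            se=float(ses[j]), pvalue=p, n=n,
        ))
    return table
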