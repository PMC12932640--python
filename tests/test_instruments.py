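import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrcoloc.instruments import (
    Candidate,
    HarmonizedInstrument,
    InstrumentParams,
    R_CIS,
    R_CODING,
    R_MAF,
    R_NOT_IN_OUTCOME,
    R_PALINDROMIC,
    R_PVAL,
    build_instrument_set,
    harmonize,
    is_palindromic,
    ld_prune,
    remove_palindromic,
    select_cis_pqtls,
    write_exclusions,
)
from mrcoloc.ld import GenotypePanel
from mrcoloc.sumstats import SumStatTable, VariantAnnotation

from conftest import make_record


def annot_for(table, gene="G1", tss=1000, coding=()):
    return {
        r.snp_id: VariantAnnotation(r.snp_id, gene, tss, r.snp_id in coding)
        for r in table
    }


def outcome_like(table, beta=0.05):
    out = SumStatTable("out", trait_type="binary")
    for r in table:
        out.add(make_record(r.snp_id, pos=r.pos, effect_allele=r.effect_allele,
                            other_allele=r.other_allele, eaf=r.eaf, beta=beta,
                            se=0.01, pvalue=0.5))
    return out


class TestSelect:
    def reasons(self, excluded):
        return dict(excluded)

    def test_low_maf_excluded(self):
        exp = SumStatTable("p", [make_record("rs1", eaf=0.005, pvalue=1e-10),
                                 make_record("rs2", eaf=0.3, pvalue=1e-10)])
        out = outcome_like(exp)
        kept, excl = select_cis_pqtls(exp, annot_for(exp), out, "G1")
        assert self.reasons(excl)["rs1"] == R_MAF
        assert [c.record.snp_id for c in kept] == ["rs2"]

    def test_protein_altering_excluded(self):
        exp = SumStatTable("p", [make_record("rs1", pvalue=1e-30),
                                 make_record("rs2", pvalue=1e-10)])
        out = outcome_like(exp)
        kept, excl = select_cis_pqtls(exp, annot_for(exp, coding=("rs1",)), out, "G1")
        assert self.reasons(excl)["rs1"] == R_CODING
        assert [c.record.snp_id for c in kept] == ["rs2"]

    def test_absent_from_outcome_excluded(self):
        exp = SumStatTable("p", [make_record("rs1", pvalue=1e-10),
                                 make_record("rs2", pvalue=1e-10)])
        out = outcome_like(exp.subset(["rs2"]))
        kept, excl = select_cis_pqtls(exp, annot_for(exp), out, "G1")
        assert self.reasons(excl)["rs1"] == R_NOT_IN_OUTCOME

    def test_cis_window_and_pvalue(self):
        exp = SumStatTable("p", [
            make_record("rs1", pos=5_000_000, pvalue=1e-10),  # too far
            make_record("rs2", pos=1_000, pvalue=1e-4),       # too weak
            make_record("rs3", pos=1_000, pvalue=1e-10),
        ])
        out = outcome_like(exp)
        kept, excl = select_cis_pqtls(exp, annot_for(exp), out, "G1")
        reasons = self.reasons(excl)
        assert reasons["rs1"] == R_CIS and reasons["rs2"] == R_PVAL
        assert [c.record.snp_id for c in kept] == ["rs3"]

    def test_unknown_gene_raises(self):
        exp = SumStatTable("p", [make_record("rs1")])
        with pytest.raises(KeyError):
            select_cis_pqtls(exp, annot_for(exp), outcome_like(exp), "NOPE")

    def test_partition_invariant(self):
        # every input SNP appears exactly once in kept + excluded
        exp = SumStatTable("p", [
            make_record("rs1", eaf=0.005, pvalue=1e-10),
            make_record("rs2", pos=9_999_999, pvalue=1e-10),
            make_record("rs3", pvalue=1e-10),
            make_record("rs4", pvalue=0.5),
        ])
        out = outcome_like(exp)
        kept, excl = select_cis_pqtls(exp, annot_for(exp), out, "G1")
        seen = sorted([c.record.snp_id for c in kept] + [s for s, _ in excl])
        assert seen == sorted(exp.snp_ids)


class TestPalindromic:
    @pytest.mark.parametrize("ea,oa,expected", [
        ("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
        ("A", "G", False), ("C", "T", False),
    ])
    def test_is_palindromic(self, ea, oa, expected):
        assert is_palindromic(ea, oa) is expected

    def test_ambiguous_band_removed(self):
        c = Candidate(make_record("rs1", effect_allele="A", other_allele="T",
                                  eaf=0.50), palindromic=True)
        kept, excl = remove_palindromic([c])
        assert not kept and excl == [("rs1", R_PALINDROMIC)]

    def test_band_endpoints_inclusive(self):
        for eaf in (0.45, 0.55):
            c = Candidate(make_record("rs1", effect_allele="A", other_allele="T",
                                      eaf=eaf), palindromic=True)
            kept, excl = remove_palindromic([c])
            assert excl == [("rs1", R_PALINDROMIC)]

    def test_outside_band_retained_flagged(self):
        c = Candidate(make_record("rs1", effect_allele="A", other_allele="T",
                                  eaf=0.10), palindromic=True)
        kept, excl = remove_palindromic([c])
        assert kept[0].palindromic and not excl

    def test_non_palindromic_at_half_retained(self):
        c = Candidate(make_record("rs1", effect_allele="A", other_allele="G",
                                  eaf=0.50), palindromic=False)
        kept, excl = remove_palindromic([c])
        assert kept and not excl


class TestHarmonize:
    def out_table(self, ea, oa, beta, eaf=0.3):
        return SumStatTable("out", [make_record(
            "rs1", effect_allele=ea, other_allele=oa, beta=beta, eaf=eaf,
            se=0.01, pvalue=0.5)], trait_type="binary")

    def cand(self, ea="A", oa="G", eaf=0.3, beta=0.1):
        rec = make_record("rs1", effect_allele=ea, other_allele=oa, eaf=eaf,
                          beta=beta, pvalue=1e-10)
        return Candidate(rec, palindromic=is_palindromic(ea, oa))

    # exhaustive enumeration of the orientation cases for exposure A/G
    @pytest.mark.parametrize("ea,oa,expected_sign", [
        ("A", "G", +1),   # same orientation
        ("G", "A", -1),   # swapped -> negate
        ("T", "C", +1),   # strand flip, same orientation
        ("C", "T", -1),   # strand flip + swap -> negate
    ])
    def test_orientation_cases(self, ea, oa, expected_sign):
        kept, excl = harmonize([self.cand()], self.out_table(ea, oa, 0.05))
        assert not excl
        assert kept[0].beta_out == pytest.approx(expected_sign * 0.05)

    def test_swapped_reflects_eaf(self):
        kept, _ = harmonize([self.cand()], self.out_table("G", "A", 0.05, eaf=0.7))
        assert kept[0].eaf_out == pytest.approx(0.3)

    def test_incompatible_alleles_removed(self):
        kept, excl = harmonize([self.cand()], self.out_table("A", "C", 0.05))
        assert not kept and excl[0][1] == "allele_mismatch"

    def test_palindromic_frequency_sides_disagree_flips(self):
        cand = self.cand(ea="A", oa="T", eaf=0.10)
        kept, _ = harmonize([cand], self.out_table("A", "T", 0.05, eaf=0.88))
        assert kept[0].beta_out == pytest.approx(-0.05)
        assert kept[0].eaf_out == pytest.approx(0.12)

    def test_palindromic_frequency_sides_agree_keeps(self):
        cand = self.cand(ea="A", oa="T", eaf=0.10)
        kept, _ = harmonize([cand], self.out_table("T", "A", 0.05, eaf=0.12))
        assert kept[0].beta_out == pytest.approx(0.05)

    def test_palindromic_ambiguous_outcome_eaf_removed(self):
        cand = self.cand(ea="A", oa="T", eaf=0.10)
        kept, excl = harmonize([cand], self.out_table("A", "T", 0.05, eaf=0.50))
        assert not kept and excl[0][1] == R_PALINDROMIC

    @given(beta=st.floats(-1, 1, allow_nan=False),
           eaf=st.floats(0.05, 0.95))
    @settings(max_examples=50, deadline=None)
    def test_involution(self, beta, eaf):
        # swapping outcome allele labels and negating its beta leaves the
        # harmonized instrument unchanged
        cand = self.cand()
        out_a = self.out_table("A", "G", beta, eaf=eaf)
        out_b = self.out_table("G", "A", -beta, eaf=1 - eaf)
        kept_a, _ = harmonize([cand], out_a)
        kept_b, _ = harmonize([cand], out_b)
        assert kept_a[0].beta_out == pytest.approx(kept_b[0].beta_out)
        assert kept_a[0].eaf_out == pytest.approx(kept_b[0].eaf_out)


def _instr(snp_id, p_exp, beta_exp=0.1):
    return HarmonizedInstrument(
        snp_id=snp_id, effect_allele="A", other_allele="G",
        beta_exp=beta_exp, se_exp=0.01, beta_out=0.05, se_out=0.01,
        eaf_exp=0.3, eaf_out=0.3, p_exp=p_exp,
    )


def _panel_with_corr(seed=0):
    """Panel where A-B r2 ~ 0.4, B-C r2 ~ 0.4, A-C r2 tiny.

    Haplotypes are thresholded latent Gaussians with the target
    correlation structure (possible because A and C are conditionally
    anticorrelated given B).
    """
    rng = np.random.default_rng(seed)
    n = 20_000
    cov = np.array([[1.0, 0.71, 0.02], [0.71, 1.0, 0.71], [0.02, 0.71, 1.0]])
    chol = np.linalg.cholesky(cov)
    h1 = (rng.standard_normal((n, 3)) @ chol.T) < 0.0
    h2 = (rng.standard_normal((n, 3)) @ chol.T) < 0.0
    dos = (h1.astype(float) + h2.astype(float))
    return GenotypePanel(["A", "B", "C"], [("A", "G")] * 3, dos)


class TestPrune:
    def test_duplicate_keeps_most_significant(self):
        rng = np.random.default_rng(1)
        x = rng.binomial(2, 0.3, 1000).astype(float)
        panel = GenotypePanel(["a", "b"], [("A", "G")] * 2, np.column_stack([x, x]))
        iset = ld_prune([_instr("a", 1e-20), _instr("b", 1e-8)], panel)
        assert iset.snp_ids == ["a"]
        assert ("b", "pruned") in iset.exclusions

    def test_uncorrelated_set_unchanged(self):
        rng = np.random.default_rng(2)
        dos = rng.binomial(2, 0.3, size=(50_000, 3)).astype(float)
        panel = GenotypePanel(["a", "b", "c"], [("A", "G")] * 3, dos)
        iset = ld_prune([_instr(s, 1e-10) for s in "abc"], panel)
        assert sorted(iset.snp_ids) == ["a", "b", "c"]

    def test_chain_keeps_a_and_c(self):
        panel = _panel_with_corr()
        from mrcoloc.ld import ld_r2
        assert ld_r2(panel, "A", "B") > 0.1
        assert ld_r2(panel, "B", "C") > 0.1
        assert ld_r2(panel, "A", "C") < 0.05

        # brute-force oracle: evaluate the greedy rule explicitly
        order = ["A", "B", "C"]  # p(A) < p(B) < p(C)
        accepted = []
        for s in order:
            if all(ld_r2(panel, s, t) <= 0.05 for t in accepted):
                accepted.append(s)
        instrs = [_instr("A", 1e-20), _instr("B", 1e-15), _instr("C", 1e-10)]
        iset = ld_prune(instrs, panel, r2_threshold=0.05)
        assert iset.snp_ids == accepted == ["A", "C"]

    def test_max_pairwise_r2_invariant(self):
        panel = _panel_with_corr(seed=3)
        from mrcoloc.ld import ld_r2
        iset = ld_prune([_instr(s, 10.0 ** -(20 - i))
                         for i, s in enumerate("ABC")], panel, r2_threshold=0.05)
        for i, a in enumerate(iset.snp_ids):
            for b in iset.snp_ids[i + 1:]:
                assert ld_r2(panel, a, b) <= 0.05

    def test_missing_snp_raises(self):
        panel = _panel_with_corr()
        with pytest.raises(KeyError, match="ZZZ"):
            ld_prune([_instr("ZZZ", 1e-10)], panel)

    def test_deterministic_tiebreak_on_equal_p(self):
        rng = np.random.default_rng(4)
        dos = rng.binomial(2, 0.3, size=(1000, 2)).astype(float)
        dos[:, 1] = dos[:, 0]
        panel = GenotypePanel(["zz", "aa"], [("A", "G")] * 2, dos)
        # equal p and |z|: lexical snp_id breaks the tie
        iset = ld_prune([_instr("zz", 1e-10), _instr("aa", 1e-10)], panel)
        assert iset.snp_ids == ["aa"]


def test_build_instrument_set_end_to_end(small_shared_locus, tmp_path):
    exposure, outcome, panel, truth = small_shared_locus
    annots = {r.snp_id: VariantAnnotation(r.snp_id, "G1", exposure[truth.exposure_causal_ids[0]].pos)
              for r in exposure}
    iset = build_instrument_set(exposure, annots, outcome, panel, "G1",
                                InstrumentParams())
    assert len(iset) >= 1
    assert truth.exposure_causal_ids[0] in iset.snp_ids
    # partition: every exposure SNP is retained or excluded exactly once
    seen = sorted(iset.snp_ids + [s for s, _ in iset.exclusions])
    assert seen == sorted(exposure.snp_ids)
    write_exclusions(iset.exclusions, tmp_path / "excl.tsv")
    assert (tmp_path / "excl.tsv").read_text().startswith("SNP\tREASON")
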