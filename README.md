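# mrcoloc

Proteome-wide cis-pQTL Mendelian randomization (MR) with pairwise
conditional colocalization, plus a locus-scale GWAS summary-statistics
simulator so the whole pipeline can be exercised without any external
data.

The pipeline screens circulating proteins for causal effects on a
disease outcome:

1. **Instrument selection** — non protein-altering cis-pQTLs within
   ±1 Mb of the gene's TSS, p < 5×10⁻⁸, MAF > 1%, present in the
   outcome GWAS; palindromic SNPs with EAF in [0.45, 0.55] dropped;
   alleles harmonized across traits; greedy LD pruning at r² ≤ 0.01.
2. **MR** — Wald ratio (one instrument) or inverse-variance-weighted
   meta-analysis of per-instrument ratios, with fixed/random effects
   chosen by Cochran's Q; two-sided z-test p-values; Bonferroni screen
   over the proteins with valid instruments (0.05 / 1,615 ≈ 3.1×10⁻⁵ at
   the headline scale).
3. **Pairwise conditional colocalization** — for proteins passing the
   screen: approximate-Bayes-factor colocalization (PP.H0–PP.H4) on
   unconditional statistics first; if PP.H4 < 0.8, stepwise
   (GCTA-COJO-style) selection of conditionally independent signals per
   trait from summary statistics + a reference LD panel, construction of
   signal-isolating conditional datasets, and colocalization of every
   conditional/unconditional combination, reporting the maximum PP.H4.

## Layout

| module | contents |
| --- | --- |
| `mrcoloc.sumstats` | summary-statistic records/tables, tab-delimited I/O, variant annotations |
| `mrcoloc.ld` | reference dosage panel, genotypic r/r², EM-based D′ |
| `mrcoloc.simulate` | latent-Gaussian AR(1) haplotype model; locus-pair and proteome simulation with ground-truth records |
| `mrcoloc.instruments` | cis-pQTL selection, palindromic filtering, harmonization, LD pruning |
| `mrcoloc.mr` | Wald ratio, IVW, Cochran's Q, z-tests, Bonferroni |
| `mrcoloc.coloc` | per-SNP log ABFs and H0–H4 posteriors (log-sum-exp throughout) |
| `mrcoloc.cojo` | summary-level joint/conditional fits, stepwise signal selection |
| `mrcoloc.pwcoco` | the conditional-colocalization search |
| `mrcoloc.pipeline` | end-to-end proteome driver, gating, Table-style report |
| `mrcoloc.cli` | `mrcoloc` command-line interface |

## CLI

All inputs are plain tab-delimited text (default sumstat header
`SNP CHR BP EA OA EAF BETA SE P N`; dosage matrix + SNP sidecar for the
reference panel).

```sh
# write a synthetic proteome (per-locus sumstats, panel, truth record)
mrcoloc simulate --config config.yaml --seed 1 --out-dir sim/

# end-to-end screen (simulated, or file-based via a `proteins:` config)
mrcoloc run --config config.yaml --seed 1 --out-dir run/

# single-locus stages
mrcoloc instruments --exposure exp.tsv --outcome out.tsv \
    --annotations annot.tsv --dosages ref.tsv --panel-meta snps.tsv \
    --gene GENE1 --out-dir ins/
mrcoloc mr ...          # same inputs, prints the MR result as JSON
mrcoloc coloc --trait1 exp.tsv --trait2 out.tsv
mrcoloc pwcoco --trait1 exp.tsv --trait2 out.tsv \
    --dosages ref.tsv --panel-meta snps.tsv
mrcoloc report --reports run/reports.json
```

`run` writes `results.tsv` (gene, protein, beta, SE, p, colocalization
verdict, sorted by p), `reports.json` (full machine-readable results),
`manifest.json` (config echo, thresholds, priors, version) and a run
log. Identical seed + config produce byte-identical outputs.

Example simulation config:

```yaml
simulate:
  n_proteins: 10
  n_causal: 2
  m_snps: 100
  n_exposure: 5000
  n_outcome: 20000
  n_ref: 2000
  theta: 0.3
params:
  pp4_threshold: 0.8
  het_alpha: 0.05
```

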