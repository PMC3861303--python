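# cogsea

Linking the genetics of heritable quantitative traits (endophenotypes such
as cognitive test scores) to disorder GWAS signal, using only per-SNP
summary statistics on the disorder side.

Many psychiatric disorders are genetically correlated with cognition, but
single-SNP tests in either domain are underpowered. `cogsea` implements the
gene-set route: score genes in a quantitative-trait *discovery* GWAS, take
the top-ranked genes as candidate sets, and ask whether those sets are
enriched for association in an independent *target* (disorder) GWAS.

The pipeline:

1. **QC + GWAS** (discovery cohort): exclude SNPs with call rate < 0.95,
   MAF < 0.01 or HWE exact-test P < 0.001; per-SNP OLS of the trait on
   allele count with age and sex covariates.
2. **Gene scoring**: assign SNPs to genes by position within ±10 kb
   extended boundaries *or* LD tagging at r² ≥ 0.8 to any position inside
   them; score each gene by the Sidak-adjusted minimum SNP p,
   p_gene = 1 − (1 − p_min)^n (n = SNPs in the bin); rank by ascending
   p_gene, report −log10(p_gene).
3. **Candidate sets**: nested top-K sets per trait,
   K ∈ {25, 50, …, 2000} (11 thresholds; 9 traits ⇒ 99 sets).
4. **Enrichment** against the target-ranked gene list: weighted (w = 1)
   running-sum enrichment score; 1000 gene-label permutations for the
   nominal p; NES = ES / |mean same-sign null ES|; FDR q pooled over all
   sets; three runs averaged. Declared enriched at p ≤ 0.05 and mean
   q ≤ 0.25.
5. **Validation**: each declared set must score an NES higher than 98 of
   100 random sets matched on gene count and per-gene SNP count.

A synthetic-cohort generator (genes + block-LD genotypes + covariate
phenotypes + target summary statistics with a configurable shared causal
gene set) makes the entire chain testable end to end; see
`docs/methods.md` for the model and its limits.

## Worked example

```bash
python examples/02_gsea_with_mimic_validation.py
```

runs a reduced study (3 traits × 4 thresholds, 150 genes, 1200 SNPs; the
first trait shares 5 of its 10 causal genes with the target) and prints:

```
 set_name  effective_size       es      nes  p_nominal  q_fdr_mean  rank_R  enriched validated
trait1-10              10 0.807105 1.591959   0.010460    0.044775       1      True      True
trait1-25              25 0.699890 1.524284   0.002004    0.096898       2      True      True
trait3-10              10 0.667118 1.323215   0.113684    0.182265       3     False      n.a.
...
```

`es` is the peak of the weighted running sum along the target-ranked gene
list, `nes` its permutation-normalized form, `p_nominal` the same-sign
permutation p, `q_fdr_mean` the pooled FDR q averaged over three runs, and
`rank_R` the set's position by that q. The injected trait's small sets
lead the table, are declared (`enriched`) and beat the SNP-count-matched
random sets (`validated`); sets from the null traits are `n.a.` (never
declared, so never sent to validation).

The other examples show the discovery arm in isolation
(`01_simulate_and_score.py`) and the specificity check against a
signal-free target (`03_specificity_null_target.py`).

A `cogsea` command exposes the stages for file-based use
(`simulate`, `qc`, `score-genes`, `build-sets`, `gsea`, `mimic-sets`,
`specificity`, `pipeline`); every stage reads and writes plain-text
standard formats (BED/GFF3, PLINK-style association tables, GMT, RNK), so
any stage can be rerun from disk.

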