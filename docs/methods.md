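# Methods

`cogsea` implements a two-arm procedure for asking whether the genes that
drive variation in heritable quantitative traits (endophenotypes such as
cognitive test performance) are enriched for association signal in a
case-control disorder GWAS, using only per-SNP summary statistics on the
target side.

## Gene scoring

**SNP-to-gene binning.** Gene boundaries are extended by `flank_bp`
(default 10 000 bp) on both sides; strand is ignored because the flank is
symmetric. A SNP joins a gene's bin if (a) its position lies inside the
extended interval, or (b) a pairwise-LD record links it, at
r² ≥ `r2_min` (default 0.8, inclusive), to *any position* inside the
extended interval. The LD table is treated as symmetric and matched at the
position level, so the LD reference may contain positions that were never
genotyped (the situation with an external haplotype reference panel). A
SNP may sit in several bins; genes with empty bins are omitted rather than
scored zero — an unscored gene is absence of evidence, not evidence of
non-association.

**Sidak min-p score.** A gene with n binned SNPs and minimum SNP p-value
p_min receives the Sidak-adjusted score

    p_gene = 1 − (1 − p_min)^n,

computed as `-expm1(n·log1p(−p_min))`, which is accurate for p_min down to
1e-300 and n up to ~1e5 (verified against a 400-digit decimal oracle).
Under independent, uniformly distributed SNP p-values this is exactly the
distribution of the minimum, so the score is calibrated across genes with
different SNP counts; correlated SNPs make it conservative. Genes are
ranked by ascending p_gene (ties broken by gene id so the ranking is a
deterministic function of the input), and the reported score is
−log10(p_gene).

**QC and discovery GWAS.** SNPs are excluded when call rate < 0.95,
MAF < 0.01 or the Hardy–Weinberg exact test gives P < 0.001 — the
inequalities are strict, so values equal to a threshold are kept. The HWE
test is the standard exact conditional test (sum of the probabilities of
all heterozygote configurations no more probable than the observed one;
not mid-p), implemented in log-space and checked exhaustively against an
exact-rational enumeration for all tables with ≤ 60 genotypes. The GWAS is
per-SNP OLS of phenotype on allele count plus intercept, age and sex, with
a two-sided t test on the allele-count coefficient; individuals missing a
call are dropped for that SNP only (complete-case per SNP — the simplest
defensible choice). Covariate sets are configurable per trait, so a trait
already adjusted for age can opt out.

## Candidate sets and enrichment

**Nested top-K sets.** For each trait, one candidate set per threshold
K ∈ {25, 50, 100, 250, 500, 750, 1000, 1250, 1500, 1750, 2000} holds the K
best-ranked genes; with the default nine traits that is 99 sets tested
together. Scanning several sizes replaces an arbitrary p-value cutoff,
whose meaning varies with GWAS power.

**Weighted running-sum ES.** Along the target-ranked list g_1..g_N (scores
s_i descending), the running sum gains |s_i|^w / Σ_members |s_j|^w at a
member and loses 1/(N − N_hits) at a non-member (w = 1 by default, so
members high in the list count more). The ES is the extremum of largest
magnitude; on (mathematically exact) magnitude ties the earliest position
wins, which fixes the leading edge deterministically. Two extrema whose
magnitudes agree to 1e-9 relative are treated as tied, because exact ties
otherwise resolve by floating-point summation order. The leading edge is
the members at or before the extremum for positive ES, strictly after it
for negative ES.

**Permutation null, p, NES.** The null permutes gene labels over the
ranked positions (scores stay in place) — with only summary statistics on
the target side, sample-level permutation is not available. One
permutation of the whole list is shared by all sets within a run, which is
what pooling the FDR across sets assumes. Nominal p is one-sided on the
same-sign part of the null (for es ≥ 0, p = #(null ≥ es)/#(null ≥ 0));
a zero numerator is reported as p = 0 with an explicit below-resolution
flag meaning "< 1/n_permutations". NES = es / |mean same-sign null ES|,
sign preserved.

**Pooled FDR q.** Every permutation ES of every set is normalized by that
set's same-sign null mean and pooled; for a set with nes ≥ 0,

    q = [#(pool ≥ nes)/#(pool ≥ 0)] / [#(observed ≥ nes)/#(observed ≥ 0)],

clipped to [0, 1] and mirrored for negative NES. This adjusts jointly for
the number of sets and for set size. Each analysis runs `n_runs` = 3 times
with independent permutation seeds; the mean and SD of q across runs are
reported, while the ES is run-invariant and NES/p come from the first run
(the upstream convention prints a single p). Sets are ranked (column
`rank_R`) by ascending mean q, ties by p then name. A set is *declared*
enriched when p ≤ 0.05 and mean q ≤ 0.25.

**Mimic validation.** Each declared set is re-tested against 100 random
sets that mimic it in gene count and per-gene SNP count: every candidate
gene is replaced by a uniform draw (without replacement within a mimic)
from non-candidate genes in the same SNP-count decile. Matching uses
quantile bins because exact count matching is generally infeasible. The
candidate is *validated* when its NES strictly exceeds at least 98 of the
100 mimic NES values (the required count scales proportionally if a mimic
NES is not computable). Because mimics share the candidate's SNP-count
profile, this controls for the residual dependence of scores on bin size.

**LD pruning of gene lists.** As a robustness tool, a gene set can be
pruned by visiting genes in rank order and removing any that share a
binned SNP with a better-ranked retained gene (greedy); sharing binned
SNPs is the gene-level LD surrogate the pipeline already has.

## Synthetic cohorts

The generator exists so the full chain is testable without access to
cohort genotypes. It emulates, at desk scale, one quantitative-trait
discovery cohort and one disorder GWAS published as summary statistics:

* **Genome.** 2 200 genes (2–20 kb) on 4 chromosomes, separated by
  intergenic gaps of 35–80 kb, with 19 000 SNP positions placed uniformly.
  The gap range keeps ±10 kb extended gene intervals disjoint, as in the
  human genome, where mean gene spacing (~150 kb) is an order of magnitude
  larger than the flank. SNP density (~1/8 kb) gives ≈ 4 SNPs per extended
  gene so that > 2 000 of the genes are scorable and the largest top-K
  threshold remains a proper subset of the ranked list.
* **LD.** Consecutive runs of 3 SNPs form blocks. The emitted LD table
  assigns all within-block pairs r² = 0.8 (cross-block pairs are absent).
  The block length is chosen so a block's physical reach (~2 SNP spacings,
  ≈ 16 kb) stays below the smallest intergenic separation of extended gene
  intervals: real recombination hotspots sit between genes, so LD that
  bridges an intergenic gap and fuses two genes' bins would misrepresent
  the setting being emulated. (Two earlier, denser layouts — 5–30 kb gaps,
  then 5-SNP blocks over 25–60 kb gaps — made up to half the genes share
  binned SNPs with a neighbour and visibly inflated the pipeline's null
  behaviour through gene clustering alone.)
  Genotypes: the block anchor is Binomial(2, MAF) with MAF ~ U(0.05, 0.5)
  per block; every other allele copies the anchor allele with probability
  c and is redrawn from Bernoulli(MAF) otherwise — a literal allele flip
  would distort the MAF, a redraw preserves it and gives allele
  correlation c. c is solved so the mean within-block pairwise genotype r²
  equals the target (anchor–copy pairs have r² = c², copy–copy pairs c⁴).
* **Phenotype.** 2 000 individuals; one designated causal SNP per causal
  gene (the SNP nearest the gene midpoint) keeps the truth set
  unambiguous. Phenotype = β·Σ causal genotypes + γ_age·age + γ_sex·sex +
  N(0, 1), with β scaled so genetic variance / (genetic + noise) equals
  the configured heritability (0.5 over 25 causal genes by default — a
  deliberately well-powered regime so recovery is a property of the
  pipeline, not of marginal power). Age ~ U{18..79} and sex ~ Bernoulli(½)
  are drawn once per cohort and shared by all traits; the covariate
  effects (−0.02/year, +0.25) are fixed non-zero so adjustment is actually
  exercised. Only the first trait carries the causal genes; the remaining
  traits are genetically null negative controls.
* **Target.** Published-summary-statistics form only: every SNP gets
  p ~ U(0, 1], except the designated causal SNP of each *shared* causal
  gene (60 % of 25 by default), whose p is the upper tail of a draw from a
  1-df non-central χ² with non-centrality 12 — association strength just
  past genome-wide suggestive at this SNP count.

Per-stage seeds are derived as SeedSequence(master_seed, crc32(stage)), so
every stage is independently reproducible and the whole bundle is
byte-identical across reruns of one master seed.

**What the generator does not model:** demography and population
structure, imputation, genotyping error, missingness (supported in the
data model, not generated), X chromosome, realistic minor-allele spectra,
gene-length/GC biases, and inter-block LD. Passing tests therefore show
that the *procedure* behaves as specified under a clean additive model,
not that any particular real-data finding is correct.

## Operating characteristics measured here

With a signal-free target (shared fraction 0), the fraction of the 99 sets
at nominal p ≤ 0.05, pooled over 20 replicates, sits near 0.05. Sets that
are both declared and mimic-validated under the null are rare but not
absent — roughly one per four replicate suites at this scale. That rate is
an intrinsic selection effect of declare-then-validate: a set declared
under the complete null is, by construction, the extreme of 99 dependent
tests, and such a selected extreme beats 98 of 100 fresh matched random
sets with substantial probability. The effect is amplified at desk scale,
where the top-2000 threshold covers 91 % of the ranked list rather than a
small fraction as it would with a full genome's worth of genes. With the
default shared genetics, the injected trait's top-25 set is declared and
validated in a large majority of replicates. The replicate counts (20) and
cohort sizes were chosen as the smallest at which these rates are stable
enough to assert; `scripts/acceptance.py` recomputes them from scratch.

## Numerical and degenerate-input choices

* Sets whose effective membership (genes found in the ranked list) is
  below 2, or covers the whole list, get NaN statistics rather than
  aborting the report; only an entirely degenerate collection is an error.
* p = 0 from permutations always carries a machine-readable
  below-resolution flag.
* Constant genotype columns are flagged not-testable instead of crashing
  the GWAS.
* Mimic construction fails loudly, naming the exhausted SNP-count bin,
  when the non-candidate universe cannot supply a required bin; at desk
  scale this happens for very large candidate sets (K close to half the
  universe), and such sets are reported as not-checkable rather than
  validated.
* The q-value SD across runs uses the sample (n−1) form and is 0 for a
  single run.

## Known limitations

Gene-gene correlation induced by shared binned SNPs is not represented in
the label-permutation null; the mimic stage compensates only for SNP-count
effects, so strongly clustered candidate lists can still inflate
enrichment (the LD-pruning tool exists to probe this). FDR pooling assumes
the sets are exchangeable after NES normalization, which nested sets
violate in the conservative direction. The synthetic target draws
independent SNP p-values, so the target-side Sidak scores are exactly
calibrated — more than can be said for real summary statistics with LD.
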