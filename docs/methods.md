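# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `singlestep`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The animal model and its two relationship matrices

All inference is for the single-trait animal model y = Xb + Za + e with
fixed herd-year-season (HYS) and sex effects and one additive genetic
effect per animal. Two covariance structures are supported:

* **PBLUP** — a ~ N(0, σ²ₐA), A the pedigree numerator relationship
  matrix. A is built by the tabular method (guarded at N = 20,000 for
  dense materialization); inbreeding coefficients use the Meuwissen–Luo
  ancestor-climbing recursion, which is exact and O(N·ancestry) without
  materializing A; A⁻¹ is assembled sparsely by Henderson's rules *with*
  inbreeding, i.e. per-animal Mendelian-sampling variances
  d = ½ − ¼(F_s+F_d) (¾ − ¼F_p with one known parent, 1 with none).
  Unknown parents are treated as a single unrelated, non-inbred base
  population; no unknown-parent groups or metafounders.
* **ssGBLUP** — a ~ N(0, σ²ₐH), H⁻¹ = A⁻¹ + [0 0; 0 G*⁻¹ − A₂₂⁻¹].
  A₂₂ and its inverse are computed exactly by tabular evaluation on the
  pedigree pruned to the genotyped animals' ancestors. G is VanRaden's
  first method, G = WWᵀ/k with W = M − 2p and k = 2Σpⱼ(1−pⱼ), allele
  frequencies taken from the observed genotyped animals (no base-frequency
  reconstruction is attempted). G is then moment-tuned (α + βG matched to
  mean diagonal and mean off-diagonal of A₂₂) and blended,
  G* = 0.95·G_tuned + 0.05·A₂₂, the standard default; both weights are
  configuration parameters. Tuning absorbs the base-population mismatch
  between current-data allele frequencies and the pedigree base; blending
  guarantees positive definiteness when G is rank-deficient (m < n_g or
  frequencies estimated from the same data).

Fixed effects use set-to-zero dummy coding (intercept plus each factor
minus a reference level), so X has full column rank and the MME can be
solved by Cholesky; only estimable functions are compared in tests, which
makes results invariant to this choice versus generalized-inverse
conventions used by other software.

## AI-REML

Variance components (σ²ₐ, σ²ₑ) are estimated by average-information REML on
the mixed-model equations. Per iteration, one Cholesky factorization of the
coefficient matrix C gives: solutions (b̂, â); the inverse block Cᵃᵃ and
the trace T = tr(K⁻¹Cᵃᵃ) for the first derivatives via the standard
identities tr(P) = (n−p−q+λT)/σ²ₑ and tr(PZKZᵀ) = (q−λT)/σ²ₐ; and the AI
matrix from two extra MME solves with working vectors Zâ/σ²ₐ and ê/σ²ₑ.
The Newton/AI update is taken whenever it stays in the parameter space;
otherwise the iteration falls back to an EM step (σ²ₐ ← (âᵀK⁻¹â + σ²ₑT)/q,
σ²ₑ ← êᵀy/(n−p)), which cannot decrease the REML likelihood. The REML
log-likelihood is tracked each iteration through MME quantities (it equals
the dense −½[log|V| + log|XᵀV⁻¹X| + yᵀPy] up to a constant; the test suite
asserts agreement with a dense oracle to 1e-6). Defaults: start values
σ²ₐ = σ²ₑ = var(y)/2, relative tolerance 1e-8 on both components, 200
iterations maximum, variance floor 1e-8·var(y). Non-convergence returns
the best estimates flagged `converged=False`. The SE of h² uses the delta
method on the inverse AI matrix at convergence; this is one of several
defensible SE conventions and is documented rather than matched to any
external implementation.

The coefficient matrix is factorized densely; the systems this package
targets (10²–10⁴ equations) are desk scale, and a dense Cholesky per AI
iteration is both the fastest and the numerically simplest option there.

## GWAS by back-solving

SNP effects are recovered from the GEBVs of the genotyped animals as
û = (1/k)·D Wᵀ G*⁻¹ â_g with D = I (unweighted, single-iteration ssGWAS; no
iterative reweighting). The reference formulation writes the same operator
as λDMᵀG*⁻¹â_g and DMᵀ(MDMᵀ)⁻¹â_g; these coincide when G* = MDMᵀ/k and
λ = 1/k, the VanRaden scaling — this package applies the operator to the
*blended/tuned* G* actually used in the mixed model, keeping the back-solve
consistent with the fit. (A transpose omitted in the source expression
"(MDM)" is treated as a typographical slip for (MDMᵀ).)

Sampling variances come from pushing the GEBV sampling covariance through
the back-solve operator: Var(û) = B(σ²ₐG* − PEV)Bᵀ with B = (1/k)DWᵀG*⁻¹
and PEV = σ²ₑCᵃᵃ from the MME inverse. z = û/sd(û) is referred to the
standard normal, two-sided. Nonpositive variances (numerically defective
SNPs) get p = 1 and a flag. Genome-wide thresholds are Bonferroni 0.05/m
and suggestive 1/m with strict inequality at both cutoffs. Simulation
checks in the acceptance suite verify that under a marker-determined
polygenic null the pooled fraction of p < 0.05 is near nominal, and that a
planted QTL carrying 10% of the additive variance is the genome-wide top
marker in ≥ 8/10 replicates.

## Quality control

SNP filters run in a fixed order — call rate < 0.90, then MAF < 0.01, then
Hardy–Weinberg exact-test p < 1e-6 — with each removed SNP attributed to
the first filter it fails; animals are never removed. The HWE test is the
Wigginton exact test (conditional on allele counts, summing configurations
no more probable than the observed heterozygote count), computed in log
space; it is validated against exhaustive enumeration and shown
super-uniform under the null. Missing dosages surviving QC are mean-imputed
(2pⱼ) before G is built.

## Linkage disequilibrium

Pairwise haplotype frequencies for unphased genotypes come from the
two-locus EM algorithm: only the double-heterozygote class is
phase-ambiguous; its cis/trans split is re-estimated each iteration from
the current frequencies. Initialization is at linkage equilibrium (allele
frequency products) with a fixed iteration order, so results are
reproducible; a perfectly symmetric likelihood (cis and trans products
tied) is flagged `ambiguous`. Convergence: relative tolerance 1e-9, 100
iterations. D′ and r² follow the usual normalizations. "Blocks" are
deliberately simplified to maximal runs of consecutive markers whose every
within-run pair has D′ ≥ 0.8 (threshold configurable); confidence-interval
block definitions need coverage parameters that are out of scope here. The
heatmap bins D′ at fixed boundaries 0.2/0.4/0.6/0.8.

## Annotation and enrichment

A SNP inside a gene interval (1-based inclusive; BED input is converted
from 0-based half-open) is *genic*; otherwise both flanking genes are
reported with unsigned distances to their nearer boundary — strand is
ignored, matching the unsigned-distance reporting convention. Transcript
structure (intron/UTR classes) is out of scope; only genic/intergenic is
distinguished. Term enrichment is a one-sided hypergeometric upper tail
P(X ≥ k) per term against an explicit, user-supplied background universe
(the reference analysis leaves its background unstated, so it is a required
input). Raw p < 0.05 flags enrichment, as is customary for small candidate
lists; a Benjamini–Hochberg column is emitted alongside but not used for
flagging.

## The simulator: what it emulates, and what it does not

`singlestep.simulate` produces a closed nucleus-herd-like population:
founders, then discrete generations of random hierarchical mating (each
female of the previous generation mated to one randomly drawn male, sires
reused; sex ratio ~17% male, configurable; at least one of each sex per
generation is enforced). Genotypes are gene-dropped: founder alleles drawn
per SNP at frequencies uniform in `maf_range`, gametes recombining under
the Haldane model (switch probability ½(1−e^{−2d}) between adjacent
markers). Markers are evenly spaced with 1 cM ≙ 1 Mb. The genotyped subset
is the youngest fraction of the population, as in real genomic-selection
programs. Phenotypes follow y = HYS + sex + a + e exactly; the additive
value is the sum of (i) an explicit marker-QTL part (effects drawn normal
and rescaled so the founder QTL variance is `qtl_variance_share`·σ²ₐ
exactly) and (ii) a pedigree-polygenic part built by parent average plus
Mendelian sampling with inbreeding-adjusted variance. HYS level effects are
drawn with SD = ½√(σ²ₐ+σ²ₑ) by default — large enough that ignoring them
would visibly bias estimates, small enough to keep designs well connected;
the reference data offer no magnitudes. All randomness flows from one
generator seeded by a single integer, making whole datasets byte-identical
across runs.

Deliberately not modeled: selection or overlapping generations, mutation,
X-linked inheritance, genotyping error and missingness patterns, and any
LD present among founder haplotypes (founder alleles are drawn
independently per SNP, so LD arises only from co-segregation and drift
within the simulated pedigree). Passing tests therefore demonstrate
correctness of the estimators under the stated generative model, not
robustness to real-data artifacts such as pedigree errors, selective
genotyping or population admixture.

### Architecture choice in the validation studies

The estimand of ssGBLUP REML is the additive variance with respect to H —
i.e. it presumes the genetic covariance of the trait follows the marker-
based relationships for genotyped animals. The parameter-recovery and
calibration studies therefore simulate a fully marker-determined additive
architecture (every SNP a small-effect QTL, `qtl_variance_share = 1`), so
that simulated truth and model assumption coincide and deviations measure
estimator error rather than model mis-specification. With a purely
pedigree-polygenic trait, a G built from a few thousand SNPs is a noisy
proxy for the trait's realized relationships and the single-step σ²ₐ is
attenuated — an errors-in-variables effect, visible in this package by
swapping architectures, and worth remembering when interpreting real-data
single-step estimates from sparse panels.

Problem sizes used by the validation studies (chosen to be comfortably
informative at desk scale): recovery — ten populations of ~2,120 animals
(120 founders, 4 generations), 1,060 genotyped at 2,000 SNPs on 10
chromosomes of 1 Morgan; calibration — ten populations of ~1,000 animals
at 600 SNPs; power — ten populations of ~2,120 animals (1,060 genotyped)
with a single QTL at 10% of σ²ₐ.

## Degenerate inputs and tie-breaks

* Monomorphic or all-missing SNPs: frequency NaN, removed by the MAF
  filter; LD on a monomorphic locus is flagged undefined rather than
  computed.
* PLINK text reading counts the data-determined minor allele (lexicographic
  tie-break); an explicit `counted_alleles` list pins the orientation when
  exact dosage round-trips are required. Orientation does not affect G, LD
  or p-values; it flips only the sign of û.
* Pedigree cycles and duplicate ids are errors naming an involved id;
  phenotyped animals absent from the pedigree are errors listing ids.
* A singular A₂₂ (e.g. cloned records) raises with a suggestion to jitter;
  a singular MME names confounded fixed-effect levels.
* SNPs tied exactly at a significance threshold are classed by strict
  inequality (p must be *below* the cutoff).

## Known limitations

Single trait only; no permanent-environment or maternal effects; no Gibbs
sampling or APY approximation for very large genotyped sets; dense
factorizations bound the practical system size to a few tens of thousands
of equations; the enrichment test treats annotations as given (no GO graph
propagation); LD runs are a heuristic, not Gabriel-style blocks.
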