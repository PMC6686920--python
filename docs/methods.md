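# Methods

`forestgs` re-creates, end to end, a genomic-prediction study in a
structured conifer breeding population: simulate the population and six
trait architectures, fit marker-based (BayesA, RKHS kernel averaging),
pedigree-based, and combined models by Gibbs sampling, and score how well
each predicts breeding values (BV), dominance deviations (DD), whole
genotypic values (G = BV + DD) and phenotypes under three
cross-validation designs.

## Population model

The simulated history has three stages.

1. **Base population.** 2,000 haplotypes for 1,000 founders are sampled
   from a neutral equilibrium population with effective size
   Ne = 10,000 and per-site mutation rate 2.5e-8, on a genome of 12
   chromosomes of 100 cM. The default generator is the standard neutral
   coalescent with binary mutations (msprime); a forward Wright–Fisher
   mixing phase seeded from the neutral site-frequency spectrum is
   available behind the same interface for environments where a
   coalescent simulator is unavailable or for didactic use. Only
   equilibrium diversity matters downstream, not the generator.
2. **Breeding cycle.** 100 individuals are truncation-selected on
   phenotype and mated at random (distinct pairs) to produce 1,000
   offspring.
3. **Full-sib mating design.** 42 phenotypically selected parents are
   crossed into 71 distinct full-sib families whose sizes are rounded
   normal(13, 5) draws truncated at 1 and re-drawn until the total lands
   in [900, 950] — about 923 genotyped offspring, the generation on
   which all models are trained and validated.

Meiosis assumes no crossover interference: crossover counts per
chromosome are Poisson with one expected crossover per Morgan, placed
uniformly, with a random starting strand; chromosomes assort
independently. This reproduces Haldane's map function
r = (1 − e^(−2d))/2 for the recombinant fraction at map distance d.

**Numerical shortcut.** Each chromosome's coalescent history is simulated
as 20 independent 5 cM sub-segments concatenated at their true map
positions. At Ne = 10,000 the expected LD between loci even one segment
apart is r² ≈ 1/(4·Ne·d) < 10⁻³, so the approximation discards only
negligible ancestral associations while reducing the per-run scaled
recombination rate ~20-fold (the ancestral-recombination-graph cost is
strongly superlinear in it). All recent LD — the signal genomic
prediction actually exploits in this design, generated by the two
bottleneck/selection generations — arises in the forward-simulated
meioses and is unaffected. The physical length per chromosome (default
500 kb) is an internal knob that only controls how many segregating
sites exist; it is sized so the expected count comfortably exceeds the
10,000 markers + 1,000 QTL requirement.

## Trait architectures

Six architectures: {oligogenic (30 QTL), polygenic (1,000 QTL)} ×
dominance ratio d² ∈ {0, 0.1, 0.2}. QTL are segregating loci disjoint
from the marker panel. Additive effects a_i (half the homozygote
difference) are gamma(shape 0.4, rate 1.66) with random sign
(oligogenic) or standard normal (polygenic). Dominance effects are
d_i = a_i·τ_i with τ_i ~ N(0, 1) (medium) or N(0, 2) (high); the whole
τ vector is rejection-sampled until the realized d² falls in
[0.09, 0.11] or [0.19, 0.21] respectively, which makes the bounds a hard
guarantee.

Parametric values use the allele-substitution decomposition at the
genotyped generation's allele frequencies:

    BV_j = Σ_i [I(x=1)·2q + I(x=0)·(q−p) − I(x=−1)·2p] · α_i,
    α_i = a_i + d_i (q_i − p_i)
    DD_j = Σ_i [−I(x=1)·2q² + I(x=0)·2pq − I(x=−1)·2p²] · d_i

with x the −1/0/1 genotype code. Environmental variance is solved so
Var(BV)/(Var(G) + σ²_e) = h² = 0.25 and phenotypes are y* = G + e. The
dominance ratio is evaluated on the same denominator, d² =
Var(DD)/(Var(G) + σ²_e), so both targets are simultaneously satisfiable.

Selection in stages 2–3 uses the trait's additive genetic value plus
noise at the same h². The dominance draw is defined on the genotyped
generation (where accuracy is assessed), which does not exist until the
pedigree is complete, so selection cannot see the dominance deviations;
for the h² = 0.25 architectures simulated here the effect on the
selection differential is second-order.

## Models

All models share y*_j = μ + g_j + u_j + δ_j + e_j with optional pedigree
polygenic terms u | A σ²_u, δ | D σ²_δ. A is the numerator relationship
matrix (tabular method); D uses the non-inbred construction
D_jk = ¼(A_{s_j s_k} A_{d_j d_k} + A_{s_j d_k} A_{d_j s_k}) with a
warning under inbreeding, unknown parents as unique unrelated founders,
and a 1e-8 ridge before factorisation.

* **BayesA** (additive or additive–dominance):
  g_j = Σ_i (x_ij a_i + w_ij d_i), with per-marker variances
  σ²_ai ~ scaled-inv-χ²(ν_a, S_a) and a gamma hyperprior on the scale
  S_a (likewise for dominance), so the scale is learned rather than
  fixed.
* **RKHS kernel averaging**: g = Σ_r g_r,
  g_r ~ N(0, K_r σ²_gr), K_r = exp(−φ_r·D²) on the squared Euclidean
  distances of the additive coding X (Ka, 3 kernels) and optionally the
  heterozygosity coding W (Ka–Kd, 6 kernels). Bandwidths are fixed at
  φ = 5/h, 1/h, 0.2/h where h is the 5th percentile of the off-diagonal
  distances — local, intermediate and global kernels.
* **Pedigree**: g absent; u and δ are the breeding values and dominance
  deviations.

### Sampling

A single Gibbs engine cycles: intercept (flat prior) → marker effects in
a fresh random permutation each sweep (single-site normal full
conditionals, numba inner loop) → per-marker variances
(scaled-inv-χ²(ν+1, ·)) → scales (gamma full conditional) → each
Gaussian-process block → residual variance. Each covariance matrix (A,
D, kernels) is eigendecomposed once per fit; a multivariate-normal block
draw then costs two matrix–vector products, with eigenvalues below
1e-8 of the maximum truncated (this removes D's null space for sparse
designs). Chain defaults are the full-length settings — 100,000
iterations, 20,000 burn-in, thinning 3 — and every result object records
⌊(n_iter − burn_in)/thin⌋ retained samples.

### Hyperparameters

The priors are reconstructed from the conventions of standard Bayesian
genomic-prediction software: ν = 5 for every scaled-inv-χ² prior; prior
scales solved so the prior modes jointly account for R² = 50% of Var(y),
split equally across genetic terms (for markers, divided by the summed
column variance of the design; for kernels, by the mean kernel
diagonal); the residual scale gets the remaining half. The gamma
hyperprior on S_a/S_d has shape 1.1 with rate placing its mode at the
solved scale. All are configurable; fixed-variance switches turn the
samplers into their ridge/BLUP special cases for the closed-form
cross-checks in the test suite.

## Cross-validation and scoring

Three 10-fold schemes partition the genotyped generation: across-family
(whole families per fold, greedily size-balanced), within-family (each
family's members dealt round-robin over folds), and random. Models are
fitted on training folds only; marker allele frequencies, kernel
bandwidths and relationship sub-matrices all come from the training set.
Validation individuals get random-effect predictions by the conditional
(BLUP-at-the-posterior-mean) extension u_test = C[test,train]
C[train,train]⁻¹ u_train for each covariance C; marker effects predict
directly through the EBV/EDD formulas above with posterior-mean effects.
RKHS predicts only whole genotypic values, which are scored against
every target since the BV/DD partition is unavailable — matching how
such models are evaluated in practice.

Accuracy is the Pearson correlation of prediction with the parametric
target, computed per fold and averaged (not pooled); bias is the
least-squares slope of truth on prediction (1 = unbiased).
Zero-variance predictions (e.g. dominance deviations of a d² = 0 trait)
are recorded as missing. Variance components from marker fits use

    V̂_A = 2 Σ p q [σ̂²_ai + (q−p)² σ̂²_di] + σ̂²_u,
    V̂_D = 4 Σ (pq)² σ̂²_di + σ̂²_δ

with h², d², H² as shares of V̂_A + V̂_D + σ̂²_e; RKHS fits report only
total genotypic variance and H².

## What the simulator does and does not emulate

It reproduces the design features that drive prediction accuracy in this
setting: a diverse equilibrium base population, two generations of
selection-induced bottleneck and the resulting long-range LD and family
structure, a realistic full-sib design, exact control of h² and d², and
disjoint marker/QTL panels. It does not model sequence-level realism
(marker ascertainment, allele-frequency matching to an SNP array),
selfing, overlapping generations, genotype-by-environment interaction,
epistasis, or common-environment (plot/block) effects; passing tests
therefore speak to model implementations and design effects, not to
absolute accuracies attainable on any particular real population.

## Problem sizes in the shipped runs

The test suite and default analysis scripts run the same code at reduced
sizes chosen as desk-scale representatives of the design: genomes of
2–12 chromosomes, marker panels of 120–2,000 loci, genotyped generations
of ~200–500, chains of 300–10,000 iterations; `analysis/03_cross_validate.py
--full` restores the complete factorial (10,000 markers, ~923
genotyped, 100,000-iteration chains, 10 replicates), a multi-day
single-CPU computation. Accuracies at reduced scale sit below the
full-scale study values — fewer markers weaken marker–QTL tracking and
smaller training sets weaken everything — but the qualitative contrasts
(markers > pedigree for oligogenic breeding values; across-family <
random-sample accuracy; near-unit slopes for genotypic-value prediction)
are preserved and are what the scaled tests assert.

## Known limitations

* The non-inbred D construction is only approximate once selection makes
  parents related; the implementation warns rather than switching to an
  inbreeding-aware recursion.
* BayesA mixing over marker variances is slow for short chains; variance
  components from chains much shorter than the default settings should
  be treated as indicative.
* The Wright–Fisher fallback distorts the site-frequency spectrum
  slightly (drift during the mixing phase), which is why the coalescent
  route is the default.
* Family ids, not marker data, define the fold schemes; real datasets
  with pedigree errors would need reconciliation first.
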