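# Methods

This note documents the models, estimators and numerical choices behind
`admixinfer`, and what the synthetic-data validation does and does not show.

## The drift model

Allele frequencies evolve on a rooted admixture graph. Each site draws an
ancestral frequency p₀ uniformly on an interval inside (0, 1) (generic
default (0.1, 0.9)). Along a drift edge of length t the frequency gains an
independent Gaussian increment with variance t·p₀(1−p₀), clipped to [0, 1];
an admixture node with weight w takes the instantaneous linear mixture
w·p₁ + (1−w)·p₂ of its parents' frequencies and drifts further on the edge
below it.

Gaussian-with-clipping was chosen over a Beta / Balding–Nichols law because
it makes expected f2 *exactly additive* in drift lengths — the property all
the estimator-recovery tests lean on — at the cost of realism near the
frequency boundaries. Consequences worth knowing:

* **Heterozygosity scaling.** Because the increment variance carries the
  factor p₀(1−p₀), the expected f2 between two leaves equals the drift-path
  length times E[p₀(1−p₀)] (≈0.1967 for U(0.1, 0.9); exposed as
  `DriftScenario.expected_het_factor`). All admixture *weights* are
  dimensionless and unaffected; fitted graph drift lengths are reported in
  observed-f2 units and absorb the factor.
* **Clipping bias.** When root-to-leaf drift variance becomes comparable to
  the squared distance to the frequency boundary, clipping shrinks long-path
  f2 values by a few percent and additivity degrades. The bundled baboon-like
  scenarios use larger drift lengths than the generic default (up to 0.15 f2
  units on the deep source stem), so they narrow the ancestral range to
  (0.2, 0.8), which keeps measured clipping bias below the estimators'
  Monte-Carlo noise. The f4-ratio itself is insensitive even to the residual
  clipping on the shared source stem, because the clipped segment enters its
  numerator and denominator identically.

Genotypes are Binomial(2, p) per diploid; the per-population sample sizes in
the bundled scenarios (1–4 diploids) mirror the small cross-species panels
this kind of study actually has. Site positions are uniform over
2 × 100 Mb chromosomes by default, dense enough to populate 5-Mb jackknife
blocks. Low-coverage degradation keeps each call with probability
`keep_prob` (default 3 × 10⁻⁴, the Picard-style downsampling regime) and
replaces it with a single random allele encoded {0, 2}, the usual
pseudo-haploid representation.

## f-statistics and the jackknife

Per-site estimators, with p̂ the population allele frequency from n called
alleles and h = p̂(1−p̂)·n/(n−1):

* f2(A,B) = (p̂_A−p̂_B)² − h_A/n_A − h_B/n_B (unbiased; needs n ≥ 2 both sides)
* f3(T;A,B) = (p̂_T−p̂_A)(p̂_T−p̂_B) − h_T/n_T; Z ≤ −3 flags admixture
* f4(P1,P2;P3,P4) = (p̂₁−p̂₂)(p̂₃−p̂₄). When a population appears once in each
  pair its sampling variance leaks into the product; the estimator subtracts
  the appropriate ±h/n covariance term. This matters concretely for the
  f4-ratio denominator f4(A, O; O, C): at 1–4 diploids per population the
  uncorrected denominator is dominated by binomial noise variance (measured:
  a simulated 8% proportion reads as ~1.4% without the term and ~8% with
  it). Distinct quadruples are unaffected; `corrected=False` restores plain
  products.
* D = Σ(p̂₁−p̂₂)(p̂₃−p̂₄) / Σ(p̂₁+p̂₂−2p̂₁p̂₂)(p̂₃+p̂₄−2p̂₃p̂₄). Polarity: in the
  ordering D(outgroup, X, H1, H2), D > 0 means excess sharing between X and
  H2. The pseudo-haploid variant samples one allele per individual per site
  and reduces to the same ratio over {−1, 0, 1} site patterns.

Standard errors use the weighted delete-m_j block jackknife (Busing's
formulation) over half-open, 0-anchored 5-Mb windows weighted by the number
of loci actually used by each statistic; ratio statistics pool numerator and
denominator per leave-one-out replicate before dividing. Calibration is
tested: at 100 blocks the mean jackknife SE of f2 matches the across-seed SD
of the estimator to a few percent. Sites lacking the required called alleles
are skipped per statistic, not globally. A statistic with a single usable
block reports its estimate with an undefined (NaN) SE.

The f4-ratio α = f4(A,O;X,C)/f4(A,O;B,C) is flagged unreliable when the
denominator's |Z| < 3. It is exactly unbiased when the true source of the
admixture is the sampled population B itself (no source-specific drift after
the split); with an unsampled drifted source it underestimates, which is a
property of the estimator, not of this implementation. The bundled recovery
scenarios therefore place the source at the sampled population's lineage
node. The X-chromosome "hybrid" mode needs no special code path: building
the allele counts with haploid flags for male X genotypes makes a male
contribute one called allele, which is the whole requirement.

## Admixture-graph fitting

Expected f2/f4 are exact quadratic forms in edge lengths, computed by
propagating mixture coefficients (per-edge usage probabilities) from the
root — no path enumeration, any number of admixture nodes.
`AdmixtureGraphModel` fits free edge lengths (≥ 0) and weights ([0, 1]) by
`scipy.optimize.least_squares` (TRF) on inverse-SE-weighted residuals of all
leaf-pair f2 values, from 20 seeded random starts (lengths scaled to the
observed f2 magnitude, weights U(0.05, 0.95)); the best converged optimum
wins, and total non-convergence raises. Support is judged by the worst f4
residual: over every quadruple pairing of leaves, Z = (observed −
predicted)/jackknife-SE; |worst Z| < 3 means supported.

**Identifiability is a real constraint, not a numerical nuisance.** Root
placement is invisible to any f2 basis, so one root-adjacent edge must be
pinned (the outgroup terminal edge absorbs it). More importantly, a
five-leaf graph whose admixed leaf draws from freely drifting *unsampled*
sources is provably under-determined: the fit Jacobian at the truth loses
two ranks, and exact-data refits return cyno-related weights anywhere in
~[0.2, 0.4] at zero cost. The bundled topology therefore asserts the
sampled populations as the admixture sources (source-terminal edges fixed at
0), matching the simulated truth; under that regime the Jacobian has full
rank and exact-data refits return both weights to machine precision. The
diagonal (per-entry) weighting is a deliberate simplification; adding all
f4 quadruples to the residual vector was tested and does not reduce weight
variance, as the f4s are linear combinations of the f2 basis.

`compare_outgroup_modes` refits after dissolving any admixture event sourced
on the root-to-outgroup lineage (the admixed child keeps its other parent),
which is how "formal outgroup" is interpreted here; when the outgroup
lineage is clean the two modes coincide exactly.

## Local-ancestry dating

Dosages ≥ 0.8 are called ancestry 1, ≤ 0.2 ancestry 2, the rest unassigned
(cutoffs ≤ 0.5 are rejected; the 1−cutoff boundary is inclusive under an
epsilon for float safety). Switches are counted between consecutive
*assigned* sites with different labels — unassigned runs are skipped, since
undecidable SNPs are removed before counting; a flag restores the stricter
break-at-unassigned behaviour. Chromosome boundaries never contribute.

Dating inverts E[B] = ploidy · 2 · r · T · L · a(1−a) with r = 0.01 per Mb
per generation: T̂ = B / (ploidy · 2 · r · L · a(1−a)). The printed form of
the haploid inversion is typeset ambiguously in the literature this follows;
the implementation resolves the division scope by dimensional analysis and
consistency with the diploid expectation. A genetic-map mode substitutes a
supplied total map length in Morgans for the product r·L. Both a pooled
estimate (haplotypes merged before inversion) and the mean of per-haplotype
estimates are reported, since pipelines differ on this. The simulator's
two-state Markov process (switch intensities T·r·(1−a) and T·r·a per Mb)
reproduces the expected counts; end-to-end recovery of T = 15 at a = 0.11
over a 2500-Mb diploid genome is accurate to ~3% with a small downward bias
caused by the positive correlation between the estimated proportion â and
the observed switch count on a finite genome.

## PCA and projection

Sites are centred at 2p̂ and, in Patterson normalization, scaled by
√(p̂(1−p̂)); the decomposition is an economy SVD of the samples × sites
matrix, with component signs fixed by making each component's
largest-magnitude loading positive (bit-reproducible output). Projection of
new samples solves the least-squares problem restricted to each sample's
non-missing sites (the "lsqproject" behaviour) rather than mean-imputing,
because the motivating use is a 0.03X genome with ~10⁻⁴ of sites called.
Pseudo-haploid {0, 2} calls are projected as-is; their doubled per-site
variance shrinks coordinates toward the origin, visibly along PC1 — the
documented, expected artefact, which decreases monotonically as coverage
rises (tested at three retention levels). Projections using fewer than 100
sites carry a `low_overlap` flag.

## Bundled scenarios and their parameter choices

`scenarios` fixes the study conditions used by the tests and the acceptance
script: a gelada outgroup over northern/southern baboon-like clades with
1–4 diploids per population; a 4-population f4-ratio design whose target
mixes 8% (Gorongosa-like) or 11% (admixed-olive-baboon-like) source
ancestry; and a 5-leaf graph whose Mozambique-like leaf mixes 37%
cynocephalus-related and 3% proto-northern ancestry. Drift lengths are not
observable quantities in the motivating study and were fixed once at
plausible between-species magnitudes (0.005–0.15 f2 units; gelada deeper);
the deep source stem (0.15) was sized by a power calculation so that the
20-replicate mean of α̂ has a standard error of ~0.25 percentage points at
2 × 10⁵ sites. Tract dating uses T = 15 generations, a = 0.11, L = 2500 Mb,
diploid — squarely inside the 10–20 generation window such analyses target.

Problem sizes throughout (2 × 10⁵ sites, 20 replicates, 20 multi-starts,
2500-Mb tract genomes) keep every validation run within seconds to a couple
of minutes on one CPU.

## What the synthetic validation does not show

The generator draws unlinked sites (no LD beyond the block structure the
jackknife assumes), exact Hardy–Weinberg binomial genotypes with no calling
error, drift that is Gaussian rather than bounded-diffusion, and ancestry
tracts with exponential lengths and noiseless dosages unless Beta noise is
requested. Passing these tests therefore demonstrates correctness of the
estimators under their own assumptions — not robustness to genotyping
artefacts, reference bias, background selection, or misspecified graph
topologies beyond the specific wrong-topology checks included.
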