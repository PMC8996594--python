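# admixinfer

Admixture inference for small cross-species genome panels, built around the
question that motivates studies like the Gorongosa (Mozambique) baboon one:
given a handful of diploid genomes per species, did a focal population
receive ancestry from a related species — how much, from whom, and how long
ago?

The package provides, as a single tested library with a CLI:

* **Site handling** (`genio`): VCF / EIGENSTRAT genotype tables, the
  standard panel filters (biallelic → singleton → MAF ≥ 0.05), per-population
  allele counts, per-sample heterozygosity, 5-Mb jackknife blocks, and sex
  assignment from the X / chr20 coverage ratio.
* **f-statistics** (`fstats`): unbiased f2 and f3, f4 and the ABBA-BABA D
  statistic, all with weighted delete-m_j block-jackknife standard errors,
  a pseudo-haploid random-allele D for low-coverage genomes, and the
  f4-ratio ancestry-proportion estimator

  α = f4(A, O; X, C) / f4(A, O; B, C),

  the proportion of ancestry the admixed target X received from the source
  related to B (sister C, outgroup pair A, O).
* **Admixture graphs** (`graph`, `graphfit`): a rooted DAG of populations
  with drift-length edges and weighted admixture nodes; exact expected
  f2/f4 by mixture-coefficient propagation; `AdmixtureGraphModel.fit()`
  estimates free drift lengths and weights by bounded multi-start least
  squares and reports the *worst f4 residual Z-score* — the topology is
  "supported" when |Z| < 3.
* **Local-ancestry tracts** (`tracts`): dosage thresholding at 0.8, global
  ancestry proportions, ancestry-switch counting, and admixture dating from
  the linear relation E[B] = ploidy · 2 · r · T · L · a(1 − a) with
  r = 0.01 per Mb per generation (1e-8 per bp).
* **PCA** (`pca`): Patterson-normalized PCA with missing-data-aware
  least-squares projection of held-out or 0.03X-style pseudo-haploid samples.
* **Synthetic data** (`simulate`, `scenarios`): Gaussian allele-frequency
  drift along any admixture graph, binomial genotype sampling at 1–4
  diploids per population, Markov ancestry tracts, low-coverage degradation
  and coverage profiles — every estimator above is validated against this
  generator's known truth.

## Worked example

Estimate how much cynocephalus-related ancestry an admixed target carries,
on data simulated with a known truth of 8%:

```python
from admixinfer import fstats, genio, scenarios, simulate

sc = scenarios.gnp_scenario(n_sites=200_000, seed=1)       # truth: alpha = 0.08
freqs = simulate.simulate_frequencies(sc)
gm = simulate.sample_genotypes(freqs, sc.samples_per_pop, seed=2)
counts = genio.pop_allele_counts(gm, simulate.default_popmap(sc.samples_per_pop))
blocks = genio.define_blocks(gm)                           # 5-Mb jackknife blocks

r = fstats.f4_ratio(counts, "gelada", "cyno", "gnp", "cyno", "ursinus", blocks)
print(r.summary())
```

```
f4_ratio(gelada, cyno, gnp, cyno, ursinus) = 0.0721935 +/- 0.0118 (Z = 6.12, 40 blocks, 200000 sites)
```

The estimate 0.072 ± 0.012 covers the simulated 8%; `r.notes["reliable"]`
confirms the denominator f4 is significantly nonzero (a precondition for the
ratio to mean anything). Fitting the five-population admixture graph on the
same kind of data recovers the simulated 37% contribution (here 38.3%) and reports the
topology as supported:

```python
from admixinfer.graphfit import AdmixtureGraphModel
sc = scenarios.papio_like_scenario(n_sites=200_000, seed=1)
freqs = simulate.simulate_frequencies(sc)
gm = simulate.sample_genotypes(freqs, sc.samples_per_pop, seed=2)
counts = genio.pop_allele_counts(gm, simulate.default_popmap(sc.samples_per_pop))
model = AdmixtureGraphModel.from_counts(
    scenarios.papio_like_free_topology(), counts, genio.define_blocks(gm))
res = model.fit(n_starts=20, seed=3)
print(f"{res.weights['moz_mix']:.3f}", res.supported)
```

```
0.383 True
```

An end-to-end pipeline (filter → heterozygosity → PCA → D/f3/f4-ratio →
graph fit → tract dating) is available as `admixinfer replay --seed 1
--outdir out/`, writing a single JSON report that is byte-identical for a
given seed.

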