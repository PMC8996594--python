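import numpy as np
import pandas as pd
import pytest

from admixinfer import genio, simulate
from admixinfer.genio import BlockSpec, GenotypeMatrix, PopAlleleCounts, PopMap
from admixinfer.graph import AdmixtureGraph


@pytest.fixture
def two_leaf_graph():
    return AdmixtureGraph([("root", "A", 0.01), ("root", "B", 0.02)])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_sites(n, chrom="1", spacing=100_000, start=1):
    return pd.DataFrame({
        "chrom": chrom,
        "pos": start + spacing * np.arange(n),
        "ref": "A",
        "alt": "G",
        "biallelic": True,
    })


def counts_from_freqs(freqs: dict[str, np.ndarray], n_alleles: int = 2_000_000,
                      spacing: int = 100_000) -> PopAlleleCounts:
    """Exact allele counts at effectively infinite sample size."""
    pops = sorted(freqs)
    n_sites = len(next(iter(freqs.values())))
    alt = np.column_stack([
        np.round(np.asarray(freqs[p], dtype=float) * n_alleles).astype(np.int64)
        for p in pops
    ])
    total = np.full_like(alt, n_alleles)
    return PopAlleleCounts(make_sites(n_sites, spacing=spacing), pops, alt, total)


def random_genotypes(rng, n_sites=60, n_samples=10, missing_frac=0.1,
                     spacing=200_000) -> GenotypeMatrix:
    calls = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int16)
    if missing_frac:
        calls[rng.random(calls.shape) < missing_frac] = genio.MISSING
    samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(make_sites(n_sites, spacing=spacing), samples, calls)


@pytest.fixture
def small_panel(rng):
    """Random 60x10 genotype matrix with missingness plus a 2-pop map."""
    gm = random_genotypes(rng)
    pm = PopMap({s: ("P1" if i < 5 else "P2") for i, s in enumerate(gm.samples)})
    return gm, pm


def simulated_counts(graph, samples_per_pop, n_sites=40_000, seed=0,
                     freq_range=(0.1, 0.9)):
    """Simulate genotypes under a graph and return (gm, counts, blocks)."""
    sc = simulate.DriftScenario(
        graph=graph, n_sites=n_sites, samples_per_pop=samples_per_pop,
        ancestral_freq_range=freq_range, seed=seed,
    )
    ft = simulate.simulate_frequencies(sc)
    gm = simulate.sample_genotypes(ft, samples_per_pop, seed=seed + 77_000)
    pm = simulate.default_popmap(samples_per_pop)
    counts = genio.pop_allele_counts(gm, pm)
    blocks = genio.define_blocks(gm)
    return gm, counts, blocks
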