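"""Synthetic data with known truth for every downstream stage.

Four generators, all deterministic given their seed:

* allele frequencies drifting along an admixture graph (Gaussian increments
  with variance ``t * p0 * (1 - p0)`` per edge of drift length ``t``, clipped
  to [0, 1]; admixture nodes mix parental frequencies linearly).  Gaussian
  drift keeps expected f2 additive in drift lengths — the property the
  f-statistic recovery tests rely on — at the price of distributional realism
  near the frequency boundaries, which the default ancestral range (0.1, 0.9)
  keeps rare;
* binomial diploid genotypes at small per-population sample sizes
  (1-4 diploids mirrors cross-species sequencing panels);
* two-state Markov ancestry tracts with stationary minor-ancestry proportion
  ``a`` and switch intensity proportional to generations since admixture;
* low-coverage degradation (random site retention at a Picard-style keep
  probability, default 3e-4, with pseudo-haploid {0, 2} recalls) and
  per-chromosome coverage profiles for sex assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, CoverageProfile, GenotypeMatrix, PopMap
from .graph import AdmixtureGraph, GraphError
from .tracts import AncestryDosageTrack

__all__ = [
    "DriftScenario",
    "TractScenario",
    "FreqTable",
    "simulate_frequencies",
    "sample_genotypes",
    "simulate_tracts",
    "degrade_to_low_coverage",
    "simulate_coverage",
    "default_popmap",
]

_DEFAULT_CHROMS = (("1", 100_000_000), ("2", 100_000_000))


@dataclass
class DriftScenario:
    """Study conditions for a drift simulation on an admixture graph."""

    graph: AdmixtureGraph
    n_sites: int = 200_000
    chrom_lengths: tuple = _DEFAULT_CHROMS
    samples_per_pop: dict[str, int] | None = None  # default: 2 diploids/leaf
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_freq_range must be inside (0, 1)")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if any(length <= 0 for _, length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.samples_per_pop is None:
            self.samples_per_pop = {leaf: 2 for leaf in self.graph.leaves()}
        for leaf in self.graph.leaves():
            if self.samples_per_pop.get(leaf, 0) < 1:
                raise ValueError(f"leaf {leaf} needs >= 1 diploid sample")

    @property
    def expected_het_factor(self) -> float:
        """E[p0 (1 - p0)] under the uniform ancestral-frequency draw.

        Simulated f2 values equal graph drift lengths times this factor.
        """
        lo, hi = self.ancestral_freq_range
        ep = 0.5 * (lo + hi)
        ep2 = (hi**3 - lo**3) / (3.0 * (hi - lo))
        return ep - ep2


@dataclass
class TractScenario:
    """Study conditions for Markov ancestry-tract simulation."""

    T: float = 15.0                 # generations since admixture
    a: float = 0.11                 # minor-ancestry (ancestry 1) proportion
    L_mb: float = 2500.0            # genome length, Mb
    r_per_mb: float = 0.01          # recombination rate per Mb per generation
    ploidy: int = 2
    n_chromosomes: int = 20
    grid_bp: int = 10_000           # dosage emission grid spacing
    dosage_noise_beta: float | None = None  # Beta(1, b) symmetric noise
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.a < 1.0:
            raise ValueError("a must be in (0, 1)")
        if self.T <= 0 or self.L_mb <= 0 or self.r_per_mb <= 0:
            raise ValueError("T, L_mb, r_per_mb must be positive")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")


@dataclass
class FreqTable:
    """Latent per-site, per-leaf allele frequencies (simulation truth)."""

    sites: pd.DataFrame  # chrom, pos
    populations: list[str]
    freqs: np.ndarray    # (n_sites, n_pops) in [0, 1]

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if (self.freqs < 0).any() or (self.freqs > 1).any():
            raise ValueError("frequencies must lie in [0, 1]")
        if self.freqs.shape != (len(self.sites), len(self.populations)):
            raise ValueError("freqs shape mismatch")

    def freq(self, pop: str) -> np.ndarray:
        return self.freqs[:, self.populations.index(pop)]


# ---------------------------------------------------------------------- #
# frequencies and genotypes
# ---------------------------------------------------------------------- #
def _site_positions(rng: np.random.Generator, n_sites: int,
                    chrom_lengths) -> pd.DataFrame:
    """Uniform random positions, allocated to chromosomes by length."""
    lengths = np.array([length for _, length in chrom_lengths], dtype=float)
    alloc = np.floor(n_sites * lengths / lengths.sum()).astype(int)
    for i in np.argsort(-lengths):
        if alloc.sum() >= n_sites:
            break
        alloc[i] += n_sites - alloc.sum()
    frames = []
    for (chrom, length), k in zip(chrom_lengths, alloc):
        if k == 0:
            continue
        pos = np.unique(rng.integers(1, length + 1, size=k))
        while len(pos) < k:  # top up collisions (rare at genomic densities)
            extra = rng.integers(1, length + 1, size=k - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        frames.append(pd.DataFrame({"chrom": str(chrom), "pos": pos[:k]}))
    return pd.concat(frames, ignore_index=True)


def simulate_frequencies(scenario: DriftScenario) -> FreqTable:
    """Propagate ancestral frequencies down the graph with Gaussian drift.

    Each site draws an ancestral frequency p0 uniformly in the scenario
    range; along an edge of drift length t the frequency gains an independent
    Normal(0, t * p0 * (1 - p0)) increment (clipped to [0, 1]); an admixture
    node with weight w takes ``w * p(parent1) + (1 - w) * p(parent2)``.
    """
    graph = scenario.graph
    if not graph.is_fully_specified():
        raise GraphError("simulation graph must have no free parameters")
    rng = np.random.default_rng(scenario.seed)
    sites = _site_positions(rng, scenario.n_sites, scenario.chrom_lengths)
    n = len(sites)
    lo, hi = scenario.ancestral_freq_range
    p0 = rng.uniform(lo, hi, size=n)
    scale0 = np.sqrt(p0 * (1.0 - p0))

    import networkx as nx
    freqs: dict[str, np.ndarray] = {}
    order = list(nx.topological_sort(graph._g))
    for node in order:
        if node == graph.root:
            freqs[node] = p0.copy()
        elif node in graph.admixture_nodes():
            (p1, p2), w = graph.admixture(node)
            freqs[node] = w * freqs[p1] + (1.0 - w) * freqs[p2]
        else:
            (parent,) = graph._g.predecessors(node)
            t = graph.edge_length(parent, node)
            f = freqs[parent]
            if t > 0:
                f = f + rng.normal(0.0, 1.0, size=n) * np.sqrt(t) * scale0
            freqs[node] = np.clip(f, 0.0, 1.0)
    leaves = graph.leaves()
    return FreqTable(sites, leaves, np.column_stack([freqs[x] for x in leaves]))


def default_popmap(samples_per_pop: dict[str, int]) -> PopMap:
    """Population map matching :func:`sample_genotypes` sample naming."""
    return PopMap({
        f"{pop}_{i + 1}": pop
        for pop in samples_per_pop for i in range(samples_per_pop[pop])
    })


def sample_genotypes(freqs: FreqTable, samples_per_pop: dict[str, int],
                     seed: int = 0) -> GenotypeMatrix:
    """Binomial(2, p) diploid genotypes from latent frequencies.

    Sample names are ``<pop>_<i>``; no missingness is introduced.
    """
    missing = [p for p in samples_per_pop if p not in freqs.populations]
    if missing:
        raise ValueError(f"populations absent from frequency table: {missing}")
    rng = np.random.default_rng(seed)
    names, cols = [], []
    for pop in samples_per_pop:
        p = freqs.freq(pop)
        for i in range(samples_per_pop[pop]):
            names.append(f"{pop}_{i + 1}")
            cols.append(rng.binomial(2, p).astype(np.int16))
    sites = freqs.sites.assign(ref="A", alt="G", biallelic=True)
    return GenotypeMatrix(sites, names, np.column_stack(cols))


# ---------------------------------------------------------------------- #
# ancestry tracts
# ---------------------------------------------------------------------- #
def simulate_tracts(scenario: TractScenario) -> AncestryDosageTrack:
    """Two-state Markov ancestry along chromosomes, emitted on a site grid.

    State 1 (minor ancestry) has stationary probability ``a``; transition
    intensities are T*r*(1-a) out of state 1 and T*r*a out of state 2 per Mb,
    so the stationary switch rate is 2*T*r*a(1-a) per Mb per haplotype and
    the expected haploid-genome switch count is 2*r*T*L*a(1-a).  Dosages are
    hard 0/1 unless ``dosage_noise_beta`` adds symmetric Beta(1, b) noise.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    chrom_mb = sc.L_mb / sc.n_chromosomes
    rate1 = sc.T * sc.r_per_mb * (1.0 - sc.a)  # out of minor ancestry
    rate2 = sc.T * sc.r_per_mb * sc.a          # into minor ancestry
    haps = [f"hap{i + 1}" for i in range(sc.ploidy)]
    positions, dosages = {}, {}
    n_grid = max(1, int(round(chrom_mb * 1e6 / sc.grid_bp)))
    grid_bp = (np.arange(n_grid) + 1) * sc.grid_bp
    grid_mb = grid_bp / 1e6
    for c in range(sc.n_chromosomes):
        chrom = str(c + 1)
        dos = np.zeros((sc.ploidy, n_grid))
        for h in range(sc.ploidy):
            state1 = bool(rng.random() < sc.a)
            breakpoints = []
            pos = 0.0
            while True:
                rate = rate1 if state1 else rate2
                pos += rng.exponential(1.0 / rate)
                if pos >= chrom_mb:
                    break
                breakpoints.append(pos)
                state1 = not state1
            # parity of breakpoints before each grid point gives the state
            k = np.searchsorted(np.asarray(breakpoints), grid_mb, side="right")
            start1 = (len(breakpoints) + (1 if state1 else 0)) % 2 == 1
            is1 = (k % 2 == 0) if start1 else (k % 2 == 1)
            dos[h] = is1.astype(float)
        if sc.dosage_noise_beta is not None:
            eps = rng.beta(1.0, sc.dosage_noise_beta, size=dos.shape)
            dos = np.where(dos >= 0.5, 1.0 - eps, eps)
        positions[chrom] = grid_bp.copy()
        dosages[chrom] = dos
    return AncestryDosageTrack(positions, dosages, haps, ploidy=sc.ploidy)


# ---------------------------------------------------------------------- #
# degradation and coverage
# ---------------------------------------------------------------------- #
def degrade_to_low_coverage(gm: GenotypeMatrix, keep_prob: float = 0.0003,
                            seed: int = 0) -> GenotypeMatrix:
    """Random site retention with pseudo-haploid recalls.

    Each call is retained independently with probability ``keep_prob``;
    retained genotypes are replaced by a single randomly drawn allele encoded
    as a homozygous dosage (0 or 2), mirroring how projected low-coverage
    samples are represented; everything else becomes missing.
    """
    if not 0.0 < keep_prob <= 1.0:
        raise ValueError("keep_prob must be in (0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.random(gm.calls.shape) < keep_prob
    allele = rng.random(gm.calls.shape) < gm.calls / 2.0
    calls = np.where(keep & (gm.calls != MISSING),
                     np.where(allele, 2, 0).astype(np.int16), MISSING)
    return GenotypeMatrix(gm.sites.copy(), list(gm.samples),
                          calls.astype(np.int16), dict(gm.haploid))


def simulate_coverage(sex: str, autosomal_depth: float = 35.0,
                      noise_sd: float = 1.0, seed: int = 0) -> CoverageProfile:
    """Chromosome-20 and X mean depths for a male or female individual.

    Males carry one X, so X depth centres on half the autosomal depth;
    females on the full depth.  Gaussian noise with ``noise_sd`` is added to
    each chromosome independently (depths floored at 0).
    """
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    if autosomal_depth <= 0:
        raise ValueError("autosomal_depth must be positive")
    rng = np.random.default_rng(seed)
    x_mean = autosomal_depth / 2.0 if sex == "male" else autosomal_depth
    depths = {
        "20": max(0.0, autosomal_depth + rng.normal(0.0, noise_sd)),
        "X": max(0.0, x_mean + rng.normal(0.0, noise_sd)),
    }
    return CoverageProfile(depths)
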