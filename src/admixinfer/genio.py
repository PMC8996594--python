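"""Genotype tables, site filters, allele counts, jackknife blocks, sex checks.

The central container is :class:`GenotypeMatrix`: biallelic sites by samples,
holding diploid alt-allele dosages in {0, 1, 2} with ``-1`` for missing.
Haploid calls (male X) are encoded {0, 2, missing} and flagged per
sample-and-chromosome, so downstream code can count one called allele rather
than two.

Formats: VCF 4.2 (read through cyvcf2, written as plain text) and the
EIGENSTRAT geno/snp/ind triplet (one digit 0/1/2/9 per site per sample; we
keep chromosome names verbatim rather than recoding them numerically, which
round-trips exactly within this package).

Site filtering follows variant-panel practice for small cross-species panels:
non-biallelic records first, then singletons (pooled minor-allele count of
exactly 1), then minor allele frequency below a cutoff (default 0.05), with
MAF computed over all *called* alleles pooled across samples (missing alleles
shrink the denominator).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PopMap",
    "FilterConfig",
    "FilterReport",
    "PopAlleleCounts",
    "BlockSpec",
    "CoverageProfile",
    "read_genotypes",
    "write_genotypes",
    "filter_sites",
    "pop_allele_counts",
    "heterozygosity",
    "assign_sex",
    "define_blocks",
]


# ---------------------------------------------------------------------- #
# containers
# ---------------------------------------------------------------------- #
@dataclass
class GenotypeMatrix:
    """Sites x samples diploid alt-allele dosages.

    Attributes
    ----------
    sites : DataFrame with columns chrom, pos (1-based), ref, alt and a
        boolean ``biallelic`` flag (False for multiallelic/indel records kept
        for the filter stage).
    samples : ordered sample names.
    calls : int16 array (n_sites, n_samples), values in {0, 1, 2, -1}.
    haploid : mapping chrom -> frozenset of sample names that are haploid on
        that chromosome (calls restricted to {0, 2, -1}, one allele each).
    """

    sites: pd.DataFrame
    samples: list[str]
    calls: np.ndarray
    haploid: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if "biallelic" not in self.sites.columns:
            self.sites = self.sites.assign(biallelic=True)
        self.sites = self.sites.reset_index(drop=True)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        self.validate()

    def validate(self) -> None:
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls contain values outside {0, 1, 2, missing}")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                if (np.diff(pos) == 0).any():
                    raise ValueError(f"duplicated position on chromosome {chrom}")
                raise ValueError(f"positions not increasing on chromosome {chrom}")
        for chrom, who in self.haploid.items():
            idx = [self.samples.index(s) for s in who if s in self.samples]
            rows = self.sites["chrom"].to_numpy() == chrom
            sub = self.calls[np.ix_(rows, idx)]
            if np.isin(sub, 1).any():
                raise ValueError(
                    f"haploid calls on chromosome {chrom} must be in {{0, 2, missing}}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def is_haploid(self, sample: str, chrom: str) -> bool:
        return sample in self.haploid.get(chrom, frozenset())

    def haploid_matrix(self) -> np.ndarray:
        """Boolean (n_sites, n_samples): True where the call is haploid."""
        out = np.zeros(self.calls.shape, dtype=bool)
        for chrom, who in self.haploid.items():
            rows = self.sites["chrom"].to_numpy() == chrom
            for s in who:
                if s in self.samples:
                    out[rows, self.samples.index(s)] = True
        return out

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.sites.iloc[idx].reset_index(drop=True),
            list(self.samples),
            self.calls[idx],
            dict(self.haploid),
        )

    def subset_samples(self, names) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in names]
        return GenotypeMatrix(
            self.sites.copy(), list(names), self.calls[:, idx], dict(self.haploid)
        )


@dataclass
class PopMap:
    """Sample -> population label, with optional role tags (outgroup/target)."""

    mapping: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)

    def populations(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def samples_of(self, pop: str) -> list[str]:
        return [s for s, p in self.mapping.items() if p == pop]

    def __getitem__(self, sample: str) -> str:
        return self.mapping[sample]

    @classmethod
    def read_tsv(cls, path) -> "PopMap":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        return cls(dict(zip(df[0].astype(str), df[1].astype(str))))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s, p in self.mapping.items():
                fh.write(f"{s}\t{p}\n")


@dataclass
class FilterConfig:
    require_biallelic: bool = True
    drop_singletons: bool = True
    min_maf: float = 0.05
    max_missing_fraction: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.min_maf < 0.5:
            raise ValueError("min_maf must be in [0, 0.5)")


@dataclass
class FilterReport:
    input_sites: int
    removed_non_biallelic: int
    removed_singleton: int
    removed_low_maf: int
    removed_missing: int
    output_sites: int

    def to_json(self, path=None) -> str | None:
        text = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text + "\n")
        return None


@dataclass
class PopAlleleCounts:
    """Per-site, per-population (alt-allele count, called-allele total)."""

    sites: pd.DataFrame
    populations: list[str]
    alt: np.ndarray    # (n_sites, n_pops) int
    total: np.ndarray  # (n_sites, n_pops) int

    def __post_init__(self):
        self.alt = np.asarray(self.alt)
        self.total = np.asarray(self.total)
        if (self.alt > self.total).any() or (self.alt < 0).any():
            raise ValueError("invalid allele counts")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def index_of(self, pop: str) -> int:
        return self.populations.index(pop)

    def freq(self, pop: str) -> np.ndarray:
        """Alt-allele frequency, NaN where the population has no called allele."""
        j = self.index_of(pop)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.total[:, j] > 0, self.alt[:, j] / self.total[:, j], np.nan
            )


@dataclass
class BlockSpec:
    """Half-open genomic windows used as jackknife blocks.

    ``block_ids`` assigns each retained site to a block (dense 0..n_blocks-1,
    never spanning chromosomes); ``weights`` are per-block site counts.
    """

    block_ids: np.ndarray
    weights: np.ndarray
    blocks: pd.DataFrame  # chrom, start, end per block
    block_size: int

    @property
    def n_blocks(self) -> int:
        return len(self.weights)


@dataclass
class CoverageProfile:
    """Mean sequencing depth per chromosome."""

    depths: dict[str, float]

    def __post_init__(self):
        if any(d < 0 for d in self.depths.values()):
            raise ValueError("depths must be non-negative")

    def __getitem__(self, chrom: str) -> float:
        return self.depths[chrom]


# ---------------------------------------------------------------------- #
# I/O
# ---------------------------------------------------------------------- #
def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Load a genotype matrix from VCF or an EIGENSTRAT triplet prefix.

    Multiallelic / indel records are loaded with missing calls and flagged
    ``biallelic=False`` so the filter stage can report them; half-missing
    diploid genotypes (e.g. ``./1``) are treated as missing.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "eigenstrat":
        return _read_eigenstrat(path)
    raise ValueError(f"unknown format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, call_rows = [], []
    haploid: dict[str, set[str]] = {}
    seen: set[tuple[str, int]] = set()
    for i, rec in enumerate(vcf):
        chrom, pos = rec.CHROM, rec.POS
        if (chrom, pos) in seen:
            raise ValueError(f"duplicated record {chrom}:{pos} (record {i + 1})")
        seen.add((chrom, pos))
        alts = rec.ALT or []
        biallelic = (
            len(alts) == 1 and len(rec.REF) == 1 and len(alts[0]) == 1
            and alts[0] in "ACGT" and rec.REF in "ACGT"
        )
        row = np.full(len(samples), MISSING, dtype=np.int16)
        if biallelic:
            for j, gt in enumerate(rec.genotypes):
                alleles = [a for a in gt[:-1] if a is not None]
                if len(alleles) == 1:  # haploid call
                    if alleles[0] >= 0:
                        row[j] = 2 * alleles[0]
                        haploid.setdefault(chrom, set()).add(samples[j])
                elif len(alleles) == 2 and min(alleles) >= 0:
                    row[j] = alleles[0] + alleles[1]
        rows.append(
            (chrom, pos, rec.REF, alts[0] if alts else ".", biallelic)
        )
        call_rows.append(row)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "biallelic"])
    calls = (
        np.vstack(call_rows) if call_rows
        else np.empty((0, len(samples)), dtype=np.int16)
    )
    return GenotypeMatrix(
        sites, samples, calls, {c: frozenset(s) for c, s in haploid.items()}
    )


def _read_eigenstrat(prefix) -> GenotypeMatrix:
    prefix = str(prefix)
    snp = pd.read_csv(
        prefix + ".snp", sep=r"\s+", header=None,
        names=["id", "chrom", "gpos", "pos", "ref", "alt"],
        dtype={"chrom": str},
    )
    ind = pd.read_csv(
        prefix + ".ind", sep=r"\s+", header=None, names=["sample", "sex", "pop"]
    )
    samples = ind["sample"].astype(str).tolist()
    with open(prefix + ".geno") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) != len(snp):
        raise ValueError(".geno and .snp row counts disagree")
    calls = np.empty((len(lines), len(samples)), dtype=np.int16)
    for i, ln in enumerate(lines):
        if len(ln) != len(samples):
            raise ValueError(f".geno line {i + 1} has {len(ln)} columns")
        arr = (np.frombuffer(ln.encode(), dtype=np.uint8) - ord("0")).astype(np.int16)
        calls[i] = np.where(arr == 9, MISSING, arr)
    sites = snp[["chrom", "pos", "ref", "alt"]].assign(biallelic=True)
    return GenotypeMatrix(sites, samples, calls)


def write_genotypes(gm: GenotypeMatrix, path, format: str = "vcf",
                    popmap: PopMap | None = None) -> None:
    """Write a genotype matrix as VCF text or an EIGENSTRAT triplet."""
    if format == "vcf":
        _write_vcf(gm, path)
    elif format == "eigenstrat":
        _write_eigenstrat(gm, path, popmap)
    else:
        raise ValueError(f"unknown format {format!r}")


_DIPLOID_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_HAPLOID_GT = {0: "0", 2: "1", MISSING: "."}


def _write_vcf(gm: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=admixinfer\n")
        for chrom, grp in gm.sites.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples) + "\n"
        )
        hap = gm.haploid_matrix()
        chroms = gm.sites["chrom"].to_numpy()
        poss = gm.sites["pos"].to_numpy()
        refs = gm.sites["ref"].to_numpy()
        alts = gm.sites["alt"].to_numpy()
        for i in range(gm.n_sites):
            gts = [
                _HAPLOID_GT[int(gm.calls[i, j])] if hap[i, j]
                else _DIPLOID_GT[int(gm.calls[i, j])]
                for j in range(gm.n_samples)
            ]
            fh.write(
                f"{chroms[i]}\t{poss[i]}\t.\t{refs[i]}\t{alts[i]}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def _write_eigenstrat(gm: GenotypeMatrix, prefix, popmap: PopMap | None) -> None:
    prefix = str(prefix)
    with open(prefix + ".geno", "w") as fh:
        for i in range(gm.n_sites):
            row = "".join(
                "9" if c == MISSING else str(int(c)) for c in gm.calls[i]
            )
            fh.write(row + "\n")
    with open(prefix + ".snp", "w") as fh:
        for i, r in gm.sites.iterrows():
            fh.write(
                f"{r['chrom']}_{r['pos']}\t{r['chrom']}\t0.0\t{r['pos']}"
                f"\t{r['ref']}\t{r['alt']}\n"
            )
    with open(prefix + ".ind", "w") as fh:
        for s in gm.samples:
            pop = popmap.mapping.get(s, "pop") if popmap else "pop"
            fh.write(f"{s}\tU\t{pop}\n")


# ---------------------------------------------------------------------- #
# filtering and summaries
# ---------------------------------------------------------------------- #
def filter_sites(gm: GenotypeMatrix, cfg: FilterConfig | None = None
                 ) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply biallelic -> singleton -> MAF -> missingness filters, in order.

    Minor-allele counts and frequencies are computed from all called alleles
    pooled across samples (haploid calls contribute one allele).  Each site is
    charged to the first rule that removes it, so the report itemizes the
    rules in application order.
    """
    cfg = cfg or FilterConfig()
    hap = gm.haploid_matrix()
    calls = gm.calls
    called = calls != MISSING
    alleles = np.where(hap, 1, 2) * called                    # called alleles/entry
    alt = np.where(called, np.where(hap, calls // 2, calls), 0)
    total = alleles.sum(axis=1)
    alt_total = alt.sum(axis=1)
    minor = np.minimum(alt_total, total - alt_total)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(total > 0, minor / np.maximum(total, 1), 0.0)
    max_alleles = np.where(hap, 1, 2).sum(axis=1)
    missing_frac = 1.0 - total / np.maximum(max_alleles, 1)

    keep = np.ones(gm.n_sites, dtype=bool)
    biallelic = gm.sites["biallelic"].to_numpy(dtype=bool)
    n_bi = n_single = n_maf = n_miss = 0
    if cfg.require_biallelic:
        drop = keep & ~biallelic
        n_bi = int(drop.sum())
        keep &= biallelic
    if cfg.drop_singletons:
        drop = keep & (minor == 1)
        n_single = int(drop.sum())
        keep &= ~drop
    drop = keep & (maf < cfg.min_maf)
    n_maf = int(drop.sum())
    keep &= ~drop
    if cfg.max_missing_fraction < 1.0:
        drop = keep & (missing_frac > cfg.max_missing_fraction)
        n_miss = int(drop.sum())
        keep &= ~drop

    out = gm.take_sites(keep)
    report = FilterReport(
        input_sites=gm.n_sites,
        removed_non_biallelic=n_bi,
        removed_singleton=n_single,
        removed_low_maf=n_maf,
        removed_missing=n_miss,
        output_sites=out.n_sites,
    )
    return out, report


def pop_allele_counts(gm: GenotypeMatrix, popmap: PopMap) -> PopAlleleCounts:
    """Aggregate alt-allele counts and called totals per population.

    Missing genotypes shrink the totals; haploid calls contribute a single
    allele (alt count 0 or 1).
    """
    unlabeled = [s for s in gm.samples if s not in popmap.mapping]
    if unlabeled:
        raise ValueError(f"samples without population label: {unlabeled}")
    pops = sorted({popmap[s] for s in gm.samples})
    hap = gm.haploid_matrix()
    called = gm.calls != MISSING
    per_entry_total = np.where(hap, 1, 2) * called
    per_entry_alt = np.where(called, np.where(hap, gm.calls // 2, gm.calls), 0)
    alt = np.zeros((gm.n_sites, len(pops)), dtype=np.int64)
    total = np.zeros_like(alt)
    for j, s in enumerate(gm.samples):
        k = pops.index(popmap[s])
        alt[:, k] += per_entry_alt[:, j]
        total[:, k] += per_entry_total[:, j]
    return PopAlleleCounts(gm.sites.copy(), pops, alt, total)


def heterozygosity(gm: GenotypeMatrix, mode: str = "per_variant_set",
                   genome_length_bp: int | None = None) -> pd.Series:
    """Per-sample heterozygosity.

    ``per_variant_set``: heterozygous calls over non-missing calls within the
    variant set.  ``per_genome_length``: heterozygous calls over a supplied
    total genome length in bp.  Samples with no called site get NaN.
    """
    het = (gm.calls == 1).sum(axis=0).astype(float)
    if mode == "per_variant_set":
        called = (gm.calls != MISSING).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(called > 0, het / called, np.nan)
    elif mode == "per_genome_length":
        if genome_length_bp is None:
            raise ValueError("per_genome_length mode requires genome_length_bp")
        vals = het / float(genome_length_bp)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.Series(vals, index=gm.samples, name=f"heterozygosity_{mode}")


def assign_sex(cov: CoverageProfile, x_chrom: str = "X", autosome: str = "20",
               male_band: tuple[float, float] = (0.35, 0.65),
               female_band: tuple[float, float] = (0.85, 1.15),
               ) -> tuple[str, float]:
    """Sex from the X/autosome coverage ratio.

    A single X chromosome halves X coverage relative to the autosomes, so a
    ratio near 0.5 indicates a male and near 1 a female; anything outside both
    bands is reported as ambiguous.
    """
    auto = cov[autosome]
    if auto <= 0:
        raise ValueError("autosomal depth must be positive")
    ratio = cov[x_chrom] / auto
    if male_band[0] <= ratio <= male_band[1]:
        return "male", ratio
    if female_band[0] <= ratio <= female_band[1]:
        return "female", ratio
    return "ambiguous", ratio


def define_blocks(gm_or_sites, block_size_bp: int = 5_000_000) -> BlockSpec:
    """Assign sites to half-open, 0-anchored genomic windows per chromosome.

    Windows are [k*W, (k+1)*W) in bp; empty windows are dropped and the
    per-block site counts are returned as jackknife weights.
    """
    sites = gm_or_sites.sites if hasattr(gm_or_sites, "sites") else gm_or_sites
    chrom = sites["chrom"].astype(str).to_numpy()
    win = (sites["pos"].to_numpy() // block_size_bp).astype(np.int64)
    uniq, ids = _dense_block_ids(chrom, win)
    weights = np.bincount(ids)
    blocks = pd.DataFrame(
        [(c, int(w) * block_size_bp, (int(w) + 1) * block_size_bp) for c, w in uniq],
        columns=["chrom", "start", "end"],
    )
    return BlockSpec(ids, weights, blocks, block_size_bp)


def _dense_block_ids(chrom: np.ndarray, win: np.ndarray):
    keys = list(zip(chrom.tolist(), win.tolist()))
    uniq = sorted(set(keys))
    lookup = {k: i for i, k in enumerate(uniq)}
    ids = np.fromiter((lookup[k] for k in keys), dtype=np.int64, count=len(keys))
    return uniq, ids
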