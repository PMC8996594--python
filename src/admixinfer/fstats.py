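"""f2/f3/f4/D statistics with weighted block-jackknife standard errors.

All statistics consume per-population allele counts
(:class:`admixinfer.genio.PopAlleleCounts`) and a genomic block assignment
(:class:`admixinfer.genio.BlockSpec`, default 5-Mb windows).  Standard errors
come from a delete-one-block jackknife weighted by the number of loci per
block (the delete-m_j formulation of Busing et al. 1999, as used by the
standard f-statistic toolkits); for ratio statistics the numerator and
denominator are pooled per leave-one-out replicate before dividing.

Estimator conventions:

* f2(A, B): per-site ``(pA - pB)^2 - hA/nA - hB/nB`` with
  ``h = p(1-p) * n/(n-1)`` — unbiased under binomial sampling of ``n`` called
  alleles.  Requires n >= 2 in both populations at a site.
* f3(T; A, B): per-site ``(t - pA)(t - pB) - hT/nT``; a significantly
  negative value (Z <= -3) is the classic admixture signal for T.
* f4(P1, P2; P3, P4): product ``(p1 - p2)(p3 - p4)``.  When all four
  populations are distinct no bias term is needed; when a population repeats
  across the two pairs (as in the f4-ratio denominator f4(A, O; O, C)) its
  sampling variance leaks into the product and is removed with the usual
  ``h/n`` covariance correction (disable with ``corrected=False``).
* D(P1, P2, P3, P4): ratio of summed f4 numerators to summed
  ``(p1 + p2 - 2 p1 p2)(p3 + p4 - 2 p3 p4)`` heterozygosity terms.  In the
  ordering D(outgroup, X, H1, H2), D > 0 indicates excess allele sharing
  between X and H2.
* f4-ratio alpha = f4(A, O; X, C) / f4(A, O; B, C): the ancestry proportion
  the admixed target X received from the source related to B (with sister
  population C and outgroup pair A, O); flagged unreliable when the
  denominator is not significantly nonzero.

Sites lacking the required called alleles in any involved population are
skipped per statistic, and block weights are recomputed from the sites
actually used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, BlockSpec, GenotypeMatrix, PopAlleleCounts

__all__ = [
    "FStatResult",
    "weighted_jackknife",
    "jackknife",
    "f2",
    "f3",
    "f4",
    "d_stat",
    "d_stat_pseudohaploid",
    "f4_ratio",
    "results_to_frame",
]


@dataclass
class FStatResult:
    """Point estimate, weighted-jackknife SE and Z-score of one statistic."""

    name: str
    pops: tuple
    estimate: float
    se: float
    z: float
    n_blocks: int
    n_sites: int
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "statistic": self.name,
            "pops": ",".join(self.pops),
            "estimate": self.estimate,
            "se": self.se,
            "z": self.z,
            "n_blocks": self.n_blocks,
            "n_sites": self.n_sites,
        }
        d.update(self.notes)
        return d

    def summary(self) -> str:
        return (
            f"{self.name}({', '.join(self.pops)}) = {self.estimate:.6g} "
            f"+/- {self.se:.3g} (Z = {self.z:.2f}, "
            f"{self.n_blocks} blocks, {self.n_sites} sites)"
        )


def results_to_frame(results) -> pd.DataFrame:
    """Tabulate FStatResults (one row per statistic) for TSV export."""
    return pd.DataFrame([r.to_dict() for r in results])


# ---------------------------------------------------------------------- #
# jackknife machinery
# ---------------------------------------------------------------------- #
def weighted_jackknife(estimate: float, loo: np.ndarray,
                       weights: np.ndarray) -> tuple[float, float]:
    """Weighted delete-m_j jackknife standard error.

    ``loo[j]`` is the statistic recomputed with block j removed and
    ``weights[j]`` the number of loci in block j.  Reduces to the ordinary
    delete-1 jackknife when all weights are equal.
    """
    loo = np.asarray(loo, dtype=float)
    m = np.asarray(weights, dtype=float)
    g = len(loo)
    if g < 2:
        raise ValueError("need at least two blocks for a jackknife SE")
    n = m.sum()
    h = n / m
    theta_j = g * estimate - ((1.0 - m / n) * loo).sum()
    tau = h * estimate - (h - 1.0) * loo
    var = ((tau - theta_j) ** 2 / (h - 1.0)).sum() / g
    return theta_j, float(np.sqrt(var))


def jackknife(block_values: np.ndarray, block_weights: np.ndarray
              ) -> tuple[float, float]:
    """Estimate and SE of a weighted mean from per-block means.

    ``block_values[j]`` is the mean of the per-site statistic within block j
    and ``block_weights[j]`` its locus count; the pooled estimate is the
    weight-averaged mean and the SE comes from leave-one-block-out replicates.
    """
    v = np.asarray(block_values, dtype=float)
    m = np.asarray(block_weights, dtype=float)
    total = (v * m).sum()
    n = m.sum()
    est = total / n
    if len(v) < 2:
        return est, np.nan
    loo = (total - v * m) / (n - m)
    _, se = weighted_jackknife(est, loo, m)
    return est, se


def _block_ratio(num: np.ndarray, den: np.ndarray, block_ids: np.ndarray
                 ) -> tuple[float, float, int, int]:
    """Ratio-of-sums estimate with delete-one-block jackknife.

    ``den`` may be all-ones (plain mean) or a per-site denominator (D and
    ratio statistics).  Returns (estimate, se, n_blocks, n_sites).
    """
    ids, dense = np.unique(block_ids, return_inverse=True)
    g = len(ids)
    num_b = np.bincount(dense, weights=num, minlength=g)
    den_b = np.bincount(dense, weights=den, minlength=g)
    m = np.bincount(dense, minlength=g).astype(float)
    N, D = num_b.sum(), den_b.sum()
    if D == 0:
        raise ZeroDivisionError("statistic denominator is zero over all sites")
    est = N / D
    if g < 2:
        return est, np.nan, g, len(num)
    loo_den = D - den_b
    if (loo_den == 0).any():
        raise ZeroDivisionError("a leave-one-block-out denominator is zero")
    loo = (N - num_b) / loo_den
    _, se = weighted_jackknife(est, loo, m)
    return est, se, g, len(num)


def _finish(name, pops, num, den, block_ids, mask, notes=None) -> FStatResult:
    if not mask.any():
        raise ValueError(f"{name}: no usable sites")
    est, se, g, n_sites = _block_ratio(num[mask], den[mask], block_ids[mask])
    z = est / se if (se and np.isfinite(se) and se > 0) else np.nan
    return FStatResult(name, tuple(pops), float(est), float(se), float(z),
                       g, n_sites, notes or {})


# ---------------------------------------------------------------------- #
# allele-frequency helpers
# ---------------------------------------------------------------------- #
def _freq_and_n(counts: PopAlleleCounts, pop: str):
    j = counts.index_of(pop)
    n = counts.total[:, j].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, counts.alt[:, j] / np.maximum(n, 1), np.nan)
    return p, n


def _het_term(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    """h/n with h = p(1-p) n/(n-1): the sampling-noise correction term."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return p * (1.0 - p) / np.maximum(n - 1.0, 1e-300)


# ---------------------------------------------------------------------- #
# statistics
# ---------------------------------------------------------------------- #
def f2(counts: PopAlleleCounts, A: str, B: str, blocks: BlockSpec,
       corrected: bool = True) -> FStatResult:
    """Unbiased f2 between two populations (shared-drift distance)."""
    pa, na = _freq_and_n(counts, A)
    pb, nb = _freq_and_n(counts, B)
    need = 2 if corrected else 1
    mask = (na >= need) & (nb >= need)
    v = (pa - pb) ** 2
    if corrected:
        v = v - _het_term(pa, na) - _het_term(pb, nb)
    v = np.where(mask, v, 0.0)
    return _finish("f2", (A, B), v, np.ones_like(v), blocks.block_ids, mask,
                   {"corrected": corrected})


def f3(counts: PopAlleleCounts, target: str, A: str, B: str,
       blocks: BlockSpec, z_threshold: float = -3.0) -> FStatResult:
    """f3(target; A, B) with target-size bias correction.

    Reports ``admixture_signal=True`` when Z is at or below ``z_threshold``
    (default -3), the conventional cutoff for calling the target admixed
    between sources related to A and B.
    """
    pt, nt = _freq_and_n(counts, target)
    pa, na = _freq_and_n(counts, A)
    pb, nb = _freq_and_n(counts, B)
    if not (nt >= 2).any():
        raise ValueError("f3: target population never has >= 2 called alleles")
    mask = (nt >= 2) & (na >= 1) & (nb >= 1)
    v = (pt - pa) * (pt - pb) - _het_term(pt, nt)
    v = np.where(mask, v, 0.0)
    res = _finish("f3", (target, A, B), v, np.ones_like(v),
                  blocks.block_ids, mask)
    res.notes["admixture_signal"] = bool(
        np.isfinite(res.z) and res.z <= z_threshold
    )
    return res


def _f4_site_values(counts: PopAlleleCounts, P1, P2, P3, P4,
                    corrected: bool = True):
    """Per-site f4 values and their validity mask.

    The covariance correction applies only where a population appears once
    in each pair: E[(p1-p2)(p3-p4)] picks up +/- Var(p_hat) for the repeated
    population, which the h/n term removes.  Populations needing a
    correction must have >= 2 called alleles at a site.
    """
    ps, ns = zip(*(_freq_and_n(counts, p) for p in (P1, P2, P3, P4)))
    pops = (P1, P2, P3, P4)
    mask = np.all([n >= 1 for n in ns], axis=0)
    v = (ps[0] - ps[1]) * (ps[2] - ps[3])
    if corrected:
        # sign of the sampling covariance of the repeated population
        for i, j, sign in ((0, 2, 1.0), (0, 3, -1.0), (1, 2, -1.0), (1, 3, 1.0)):
            if pops[i] == pops[j]:
                v = v - sign * _het_term(ps[i], ns[i])
                mask = mask & (ns[i] >= 2)
    return v, mask


def f4(counts: PopAlleleCounts, P1: str, P2: str, P3: str, P4: str,
       blocks: BlockSpec, corrected: bool = True) -> FStatResult:
    """f4(P1, P2; P3, P4) = mean (p1 - p2)(p3 - p4).

    Distinct quadruples need no bias term; repeated populations across the
    two pairs get the h/n covariance correction unless ``corrected=False``.
    """
    v, mask = _f4_site_values(counts, P1, P2, P3, P4, corrected=corrected)
    v = np.where(mask, v, 0.0)
    return _finish("f4", (P1, P2, P3, P4), v, np.ones_like(v),
                   blocks.block_ids, mask)


def d_stat(counts: PopAlleleCounts, P1: str, P2: str, P3: str, P4: str,
           blocks: BlockSpec) -> FStatResult:
    """Normalized allele-sharing D statistic, jackknifed on the ratio.

    With the conventional ordering D(outgroup, X, H1, H2), positive values
    indicate excess sharing between X and H2, negative between X and H1;
    |Z| >= 3 is the customary significance cutoff.
    """
    ps, ns = zip(*(_freq_and_n(counts, p) for p in (P1, P2, P3, P4)))
    mask = np.all([n >= 1 for n in ns], axis=0)
    p1, p2, p3, p4 = ps
    num = (p1 - p2) * (p3 - p4)
    den = (p1 + p2 - 2.0 * p1 * p2) * (p3 + p4 - 2.0 * p3 * p4)
    num = np.where(mask, num, 0.0)
    den = np.where(mask, den, 0.0)
    return _finish("D", (P1, P2, P3, P4), num, den, blocks.block_ids, mask)


def d_stat_pseudohaploid(gm: GenotypeMatrix, samples: tuple[str, str, str, str],
                         blocks: BlockSpec, seed: int = 0) -> FStatResult:
    """Random-allele D for low-coverage individuals (one sample per slot).

    Samples one allele per individual per site (a heterozygous call
    contributes either allele with probability 1/2) and computes the ABBA/BABA
    count ratio, with the same sign convention as :func:`d_stat`.  Sites with
    any missing individual are skipped.
    """
    idx = [gm.samples.index(s) for s in samples]
    calls = gm.calls[:, idx].astype(float)
    mask = (calls != MISSING).all(axis=1)
    rng = np.random.default_rng(seed)
    alleles = (rng.random(calls.shape) < calls / 2.0).astype(float)
    a1, a2, a3, a4 = alleles.T
    num = (a1 - a2) * (a3 - a4)
    num = np.where(mask, num, 0.0)
    den = np.abs(num)
    res = _finish("D_pseudohaploid", tuple(samples), num, den,
                  blocks.block_ids, mask)
    n_abba = int(num[mask][num[mask] > 0].sum())
    n_baba = int(-num[mask][num[mask] < 0].sum())
    res.notes.update({"n_informative": n_abba + n_baba})
    return res


def f4_ratio(counts: PopAlleleCounts, A: str, O: str, X: str, B: str, C: str,
             blocks: BlockSpec, z_threshold: float = 3.0) -> FStatResult:
    """Ancestry proportion alpha = f4(A, O; X, C) / f4(A, O; B, C).

    X is the admixed target, B the population related to the introgressing
    source, C the target's unadmixed sister and (A, O) the outgroup pair;
    for an exact mixture X = alpha * B + (1 - alpha) * C in frequencies the
    ratio returns alpha identically.  The jackknife pools numerator and
    denominator per replicate before dividing.  ``reliable`` is False when
    the denominator f4 has |Z| below ``z_threshold``.

    For X-chromosome panels mixing males and females, build the counts with
    haploid flags set for male X genotypes: a haploid call then contributes a
    single allele, which is all the hybrid mode requires.
    """
    num, mask_n = _f4_site_values(counts, A, O, X, C)
    den, mask_d = _f4_site_values(counts, A, O, B, C)
    mask = mask_n & mask_d
    num = np.where(mask, num, 0.0)
    den = np.where(mask, den, 0.0)
    den_res = f4(counts, A, O, B, C, blocks)
    res = _finish("f4_ratio", (A, O, X, B, C), num, den, blocks.block_ids, mask)
    res.notes.update({
        "denominator_estimate": den_res.estimate,
        "denominator_z": den_res.z,
        "reliable": bool(np.isfinite(den_res.z)
                         and abs(den_res.z) >= z_threshold),
    })
    return res
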