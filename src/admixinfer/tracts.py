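"""Local-ancestry dosage tracks: thresholding, proportions, switch dating.

Input is the tabular export of a local-ancestry deconvolution (one dosage of
"ancestry 1" per site per haplotype, in [0, 1]; diploid dosages in [0, 2] are
accepted and halved).  Sites are assigned hard labels only when the dosage is
decisive (>= cutoff for ancestry 1, <= 1-cutoff for ancestry 2, default
cutoff 0.8); everything else is left unassigned and skipped.

Admixture dating uses the linear relation between generations since admixture
T and the expected count of ancestry switches along chromosomes.  With a
uniform recombination rate r per Mb per generation (default 0.01, i.e.
1e-8 per bp), genome length L Mb and minor-ancestry proportion a, the
expected number of recombination events in a haploid genome is r*T*L and a
fraction 2*a*(1-a) of them joins haplotypes of opposite ancestry, so

    E[B] = ploidy * 2 * r * T * L * a * (1 - a)

and the point estimate inverts this: T_hat = B / (ploidy * 2 * r * L * a(1-a)).
A genetic-map mode replaces the uniform-rate product r*L by a supplied total
genetic length in Morgans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNASSIGNED = 0
ANCESTRY1 = 1
ANCESTRY2 = 2

__all__ = [
    "AncestryDosageTrack",
    "AncestryCalls",
    "AncestryProportion",
    "SwitchCount",
    "TractDating",
    "threshold_calls",
    "global_proportion",
    "count_switches",
    "expected_switches",
    "date_admixture",
    "date_track",
    "read_dosage_tsv",
    "write_dosage_tsv",
]


@dataclass
class AncestryDosageTrack:
    """Per-haplotype ancestry-1 dosages along chromosomes.

    ``positions[chrom]`` is a strictly increasing 1-based bp array and
    ``dosages[chrom]`` an (n_haplotypes, n_sites) float array in [0, 1].
    """

    positions: dict[str, np.ndarray]
    dosages: dict[str, np.ndarray]
    haplotypes: list[str]
    ploidy: int = 1

    def __post_init__(self):
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos)
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not increasing on {chrom}")
            d = np.asarray(self.dosages[chrom], dtype=float)
            if d.shape != (len(self.haplotypes), len(pos)):
                raise ValueError(f"dosage shape mismatch on {chrom}")
            if (d < 0).any() or (d > 1).any():
                raise ValueError("dosages must lie in [0, 1]")
            self.positions[chrom] = pos
            self.dosages[chrom] = d

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions)

    @property
    def n_sites(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def length_mb(self) -> float:
        """Genome length spanned by the site grid, in Mb."""
        return sum(float(p[-1]) for p in self.positions.values() if len(p)) / 1e6


@dataclass
class AncestryCalls:
    """Hard per-site labels: 1 (ancestry 1), 2 (ancestry 2), 0 (unassigned)."""

    positions: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]  # int8 (n_haplotypes, n_sites)
    haplotypes: list[str]
    length_mb_hint: float | None = None

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions)

    def length_mb(self) -> float:
        if self.length_mb_hint is not None:
            return self.length_mb_hint
        return sum(float(p[-1]) for p in self.positions.values() if len(p)) / 1e6


@dataclass
class AncestryProportion:
    pooled: float
    per_haplotype: pd.Series
    n_assigned: int

    def __float__(self) -> float:
        return self.pooled


@dataclass
class SwitchCount:
    total: int
    per_haplotype: pd.Series


@dataclass
class TractDating:
    """Dating summary: inputs (a, B, L, r, ploidy) and the T estimates.

    ``t_hat`` pools switch counts and proportions over haplotypes before
    applying the inversion; ``t_hat_mean_per_haplotype`` averages per-haplotype
    estimates instead (both reported because pooling conventions differ
    between pipelines).
    """

    a: float
    b_switches: int
    l_mb: float
    r_per_mb: float
    ploidy: int
    t_hat: float
    t_hat_mean_per_haplotype: float
    per_haplotype: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "B": self.b_switches,
            "L_mb": self.l_mb,
            "r_per_mb": self.r_per_mb,
            "ploidy": self.ploidy,
            "T_hat": self.t_hat,
            "T_hat_mean_per_haplotype": self.t_hat_mean_per_haplotype,
        }


# ---------------------------------------------------------------------- #
# operations
# ---------------------------------------------------------------------- #
def threshold_calls(track: AncestryDosageTrack, cutoff: float = 0.8) -> AncestryCalls:
    """Label sites whose dosage is decisive; leave the rest unassigned.

    A site is ancestry 1 when dosage >= cutoff and ancestry 2 when
    dosage <= 1 - cutoff.  Cutoffs at or below 0.5 would let the two label
    regions overlap and are rejected.
    """
    if cutoff <= 0.5:
        raise ValueError("cutoff must exceed 0.5 (labels would overlap)")
    labels = {}
    eps = 1e-9  # keep the 1-cutoff boundary inclusive under float rounding
    for chrom, d in track.dosages.items():
        lab = np.full(d.shape, UNASSIGNED, dtype=np.int8)
        lab[d >= cutoff - eps] = ANCESTRY1
        lab[d <= (1.0 - cutoff) + eps] = ANCESTRY2
        labels[chrom] = lab
    return AncestryCalls(
        {c: p.copy() for c, p in track.positions.items()},
        labels,
        list(track.haplotypes),
        length_mb_hint=track.length_mb(),
    )


def global_proportion(calls: AncestryCalls) -> AncestryProportion:
    """Genome-wide ancestry-1 proportion among assigned sites (pooled and per
    haplotype)."""
    n1 = np.zeros(len(calls.haplotypes))
    n_assigned = np.zeros(len(calls.haplotypes))
    for lab in calls.labels.values():
        n1 += (lab == ANCESTRY1).sum(axis=1)
        n_assigned += (lab != UNASSIGNED).sum(axis=1)
    total_assigned = int(n_assigned.sum())
    if total_assigned == 0:
        raise ValueError("no assigned sites")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_hap = np.where(n_assigned > 0, n1 / np.maximum(n_assigned, 1), np.nan)
    return AncestryProportion(
        pooled=float(n1.sum() / total_assigned),
        per_haplotype=pd.Series(per_hap, index=calls.haplotypes, name="a"),
        n_assigned=total_assigned,
    )


def count_switches(calls: AncestryCalls, break_at_unassigned: bool = False
                   ) -> SwitchCount:
    """Count ancestry transitions along each chromosome and haplotype.

    Unassigned runs are skipped: a switch is counted between consecutive
    *assigned* sites with different labels (so [1, U, U, 2] counts one
    switch).  ``break_at_unassigned=True`` instead treats unassigned runs as
    tract breaks, counting no switch across them.  Chromosome ends never
    contribute switches.
    """
    per_hap = np.zeros(len(calls.haplotypes), dtype=np.int64)
    for lab in calls.labels.values():
        for h in range(lab.shape[0]):
            assigned = lab[h][lab[h] != UNASSIGNED]
            if break_at_unassigned:
                runs = _assigned_runs(lab[h])
                per_hap[h] += sum(
                    int((np.diff(r) != 0).sum()) for r in runs
                )
            elif len(assigned) > 1:
                per_hap[h] += int((np.diff(assigned) != 0).sum())
    return SwitchCount(
        total=int(per_hap.sum()),
        per_haplotype=pd.Series(per_hap, index=calls.haplotypes, name="B"),
    )


def _assigned_runs(labels: np.ndarray) -> list[np.ndarray]:
    mask = labels != UNASSIGNED
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    return [labels[chunk] for chunk in np.split(idx, splits)]


def expected_switches(T: float, L_mb: float, a: float, ploidy: int = 2,
                      r: float = 0.01) -> float:
    """Expected ancestry-switch count: ploidy * 2 * r * T * L * a(1-a)."""
    return ploidy * 2.0 * r * T * L_mb * a * (1.0 - a)


def date_admixture(B: float, L_mb: float, a: float, ploidy: int = 2,
                   r: float = 0.01,
                   genetic_length_morgans: float | None = None) -> float:
    """Generations since admixture from an observed switch count.

    Inverts :func:`expected_switches`; with ``genetic_length_morgans`` given,
    the uniform-rate product r*L_mb is replaced by that map length.
    """
    if not 0.0 < a < 1.0:
        raise ValueError("ancestry proportion a must be strictly inside (0, 1)")
    if L_mb <= 0:
        raise ValueError("L_mb must be positive")
    if B < 0:
        raise ValueError("switch count must be non-negative")
    rl = genetic_length_morgans if genetic_length_morgans is not None else r * L_mb
    return B / (ploidy * 2.0 * rl * a * (1.0 - a))


def date_track(track: AncestryDosageTrack, cutoff: float = 0.8,
               r: float = 0.01, L_mb: float | None = None,
               genetic_length_morgans: float | None = None) -> TractDating:
    """Threshold -> proportion -> switch count -> date, in one call.

    Pools haplotypes for the headline estimate and also reports the mean of
    per-haplotype estimates (each haplotype dated with its own a and B over
    the haploid genome length).
    """
    calls = threshold_calls(track, cutoff)
    prop = global_proportion(calls)
    sw = count_switches(calls)
    L = L_mb if L_mb is not None else track.length_mb()
    n_hap = len(track.haplotypes)
    t_pooled = date_admixture(
        sw.total, L, prop.pooled, ploidy=n_hap, r=r,
        genetic_length_morgans=genetic_length_morgans,
    )
    per_rows = []
    t_each = []
    for h in track.haplotypes:
        a_h = prop.per_haplotype[h]
        b_h = int(sw.per_haplotype[h])
        if np.isfinite(a_h) and 0.0 < a_h < 1.0:
            t_h = date_admixture(b_h, L, a_h, ploidy=1, r=r,
                                 genetic_length_morgans=genetic_length_morgans)
        else:
            t_h = np.nan
        t_each.append(t_h)
        per_rows.append((h, a_h, b_h, t_h))
    per = pd.DataFrame(per_rows, columns=["haplotype", "a", "B", "T_hat"])
    t_mean = float(np.nanmean(t_each)) if len(t_each) else np.nan
    return TractDating(
        a=prop.pooled, b_switches=sw.total, l_mb=L, r_per_mb=r, ploidy=n_hap,
        t_hat=t_pooled, t_hat_mean_per_haplotype=t_mean, per_haplotype=per,
    )


# ---------------------------------------------------------------------- #
# I/O: ELAI-style dosage TSV (chrom, pos, haplotype, dosage)
# ---------------------------------------------------------------------- #
def read_dosage_tsv(path, diploid_scale: bool = False) -> AncestryDosageTrack:
    """Read a long-format dosage table (columns chrom, pos, haplotype, dosage).

    ``diploid_scale=True`` halves dosages reported on the [0, 2] scale.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "haplotype", "dosage"}
    if not required.issubset(df.columns):
        raise ValueError(f"dosage TSV must have columns {sorted(required)}")
    if diploid_scale:
        df = df.assign(dosage=df["dosage"] / 2.0)
    haps = sorted(df["haplotype"].astype(str).unique())
    positions, dosages = {}, {}
    for chrom, grp in df.groupby("chrom", sort=False):
        wide = grp.pivot_table(index="pos", columns="haplotype", values="dosage")
        wide = wide.sort_index()
        positions[str(chrom)] = wide.index.to_numpy()
        dosages[str(chrom)] = wide[
            [h for h in haps if h in wide.columns]
        ].to_numpy().T
    return AncestryDosageTrack(positions, dosages, haps)


def write_dosage_tsv(track: AncestryDosageTrack, path) -> None:
    rows = []
    for chrom in track.chromosomes:
        pos = track.positions[chrom]
        d = track.dosages[chrom]
        for h, hap in enumerate(track.haplotypes):
            rows.append(pd.DataFrame({
                "chrom": chrom, "pos": pos, "haplotype": hap, "dosage": d[h],
            }))
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)
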