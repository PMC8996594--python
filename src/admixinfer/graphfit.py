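"""Least-squares fitting of admixture graphs to observed f-statistics.

:class:`AdmixtureGraphModel` follows the model/results idiom: the model is
built from a fit topology (an :class:`~admixinfer.graph.AdmixtureGraph` with
free drift lengths and admixture weights) plus an observed f2 basis with
jackknife standard errors, usually via :meth:`AdmixtureGraphModel.from_counts`.
``fit()`` minimizes the inverse-variance-weighted squared residuals between
the topology's expected f2 matrix and the observed one, over bounded
parameters (lengths >= 0, weights in [0, 1]) with seeded multi-start, and
returns a :class:`GraphFitResults`.

Topology support follows the conventional residual criterion: over every
leaf quadruple, compare the observed f4 (with its jackknife SE) to the fitted
graph's expectation; the topology is *supported* when the worst residual
Z-score satisfies |Z| < 3.

Fitted drift lengths are in the units of the observed f2 basis (for data
simulated with this package that is drift length times the genome-wide
heterozygosity factor); admixture weights are scale-free.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import fstats
from .genio import BlockSpec, PopAlleleCounts
from .graph import AdmixtureGraph, GraphError

__all__ = [
    "AdmixtureGraphModel",
    "GraphFitResults",
    "worst_f4_z",
    "compare_outgroup_modes",
]

Z_SUPPORT = 3.0


def _quadruple_pairings(leaves):
    """The three distinct f4 pairings for each unordered leaf quadruple."""
    for quad in itertools.combinations(leaves, 4):
        a, b, c, d = quad
        yield (a, b, c, d)
        yield (a, c, b, d)
        yield (a, d, b, c)


def worst_f4_z(graph: AdmixtureGraph, counts: PopAlleleCounts,
               blocks: BlockSpec) -> tuple[float, tuple, pd.DataFrame]:
    """Worst f4 residual Z-score of a fully specified graph.

    For every leaf-quadruple pairing compares the observed f4 against the
    graph expectation; returns the signed Z of the worst quadruple, the
    quadruple itself, and the full residual table.
    """
    rows = []
    for quad in _quadruple_pairings(graph.leaves()):
        obs = fstats.f4(counts, *quad, blocks)
        pred = graph.expected_f4(*quad)
        z = (obs.estimate - pred) / obs.se if obs.se > 0 else np.nan
        rows.append((quad, obs.estimate, pred, obs.se, z))
    table = pd.DataFrame(
        rows, columns=["quadruple", "observed", "predicted", "se", "z"]
    )
    k = table["z"].abs().idxmax()
    return float(table.loc[k, "z"]), table.loc[k, "quadruple"], table


@dataclass
class GraphFitResults:
    """Fitted parameters, residual diagnostics and the support verdict."""

    topology: AdmixtureGraph
    fitted_graph: AdmixtureGraph
    lengths: dict
    weights: dict
    cost: float
    converged: bool
    n_starts: int
    f2_observed: pd.DataFrame
    f2_predicted: pd.DataFrame
    f2_se: pd.DataFrame
    worst_f4_z: float = np.nan
    worst_f4_quadruple: tuple | None = None
    f4_residuals: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def supported(self) -> bool:
        """Topology support rule: worst f4 residual |Z| < 3."""
        return bool(np.isfinite(self.worst_f4_z)
                    and abs(self.worst_f4_z) < Z_SUPPORT)

    def summary(self) -> str:
        lines = ["Admixture graph fit", "=" * 19]
        lines.append(f"leaves:      {', '.join(self.topology.leaves())}")
        lines.append(f"cost:        {self.cost:.4g}   "
                     f"(converged: {self.converged}, starts: {self.n_starts})")
        if np.isfinite(self.worst_f4_z):
            lines.append(
                f"worst f4 Z:  {self.worst_f4_z:.3f} at "
                f"{self.worst_f4_quadruple}  -> "
                f"{'supported' if self.supported else 'NOT supported'} (|Z| < 3)"
            )
        lines.append("edges (fitted length):")
        for (u, v), t in sorted(self.lengths.items()):
            lines.append(f"  {u} -> {v}: {t:.5f}")
        for child, w in sorted(self.weights.items()):
            (p1, p2), _ = self.topology.admixture(child)
            lines.append(
                f"admixture {child}: {w:.3f} from {p1}, {1 - w:.3f} from {p2}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "lengths": {f"{u}->{v}": t for (u, v), t in sorted(self.lengths.items())},
            "weights": dict(sorted(self.weights.items())),
            "cost": self.cost,
            "converged": self.converged,
            "worst_f4_z": None if not np.isfinite(self.worst_f4_z)
            else self.worst_f4_z,
            "worst_f4_quadruple": list(self.worst_f4_quadruple or ()),
            "supported": self.supported,
        }

    def to_json(self, path=None) -> str | None:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text + "\n")
        return None


class AdmixtureGraphModel:
    """Fit free drift lengths and admixture weights to an observed f2 basis.

    Parameters
    ----------
    topology
        Graph whose free parameters (``length=None`` edges, ``weight=None``
        admixtures) are to be estimated; fixed parameters are honoured.
    f2_observed, f2_se
        Leaf-by-leaf observed f2 matrix and jackknife SEs (index/columns must
        cover the topology's leaves).
    counts, blocks
        Optional allele counts and block spec; when given, ``fit()`` also
        scores all f4 residuals and the support criterion.
    """

    def __init__(self, topology: AdmixtureGraph, f2_observed: pd.DataFrame,
                 f2_se: pd.DataFrame, counts: PopAlleleCounts | None = None,
                 blocks: BlockSpec | None = None):
        self.topology = topology
        self.leaves = topology.leaves()
        missing = [x for x in self.leaves if x not in f2_observed.index]
        if missing:
            raise ValueError(f"observed f2 matrix lacks leaves {missing}")
        self.f2_observed = f2_observed.loc[self.leaves, self.leaves]
        self.f2_se = f2_se.loc[self.leaves, self.leaves]
        self.counts = counts
        self.blocks = blocks
        self._pairs = list(itertools.combinations(self.leaves, 2))
        self._free_edges = topology.free_edges()
        self._free_weights = topology.free_weights()
        if not self._free_edges and not self._free_weights:
            raise GraphError("topology has no free parameters to fit")

    @classmethod
    def from_counts(cls, topology: AdmixtureGraph, counts: PopAlleleCounts,
                    blocks: BlockSpec, corrected: bool = True
                    ) -> "AdmixtureGraphModel":
        """Build the observed f2 basis (with jackknife SEs) from counts."""
        leaves = topology.leaves()
        obs = pd.DataFrame(0.0, index=leaves, columns=leaves)
        se = pd.DataFrame(0.0, index=leaves, columns=leaves)
        for a, b in itertools.combinations(leaves, 2):
            r = fstats.f2(counts, a, b, blocks, corrected=corrected)
            obs.loc[a, b] = obs.loc[b, a] = r.estimate
            se.loc[a, b] = se.loc[b, a] = r.se
        return cls(topology, obs, se, counts=counts, blocks=blocks)

    # ------------------------------------------------------------------ #
    def _unpack(self, x: np.ndarray):
        k = len(self._free_edges)
        lengths = dict(zip(self._free_edges, x[:k]))
        weights = dict(zip(self._free_weights, x[k:]))
        return lengths, weights

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        lengths, weights = self._unpack(x)
        g = self.topology.with_parameters(lengths, weights)
        coeffs = g.mixture_coefficients()
        out = np.empty(len(self._pairs))
        for i, (a, b) in enumerate(self._pairs):
            pred = g._f2_from_coeffs(coeffs, a, b)
            se = self.f2_se.loc[a, b]
            out[i] = (pred - self.f2_observed.loc[a, b]) / (se if se > 0 else 1.0)
        return out

    def fit(self, n_starts: int = 20, seed: int = 0,
            score_f4: bool = True) -> GraphFitResults:
        """Bounded nonlinear least squares with seeded multi-start.

        Drift lengths start near the scale of the observed f2 values;
        weights start Uniform(0.05, 0.95).  The best of ``n_starts`` local
        optima is returned; non-convergence of every start raises.
        """
        rng = np.random.default_rng(seed)
        k = len(self._free_edges)
        scale = max(float(np.nanmax(self.f2_observed.to_numpy())), 1e-6)
        lb = np.concatenate([np.zeros(k), np.zeros(len(self._free_weights))])
        ub = np.concatenate([
            np.full(k, 10.0 * scale), np.ones(len(self._free_weights))
        ])
        best = None
        n_ok = 0
        for _ in range(max(1, n_starts)):
            x0 = np.concatenate([
                rng.uniform(0.05, 1.0, size=k) * scale,
                rng.uniform(0.05, 0.95, size=len(self._free_weights)),
            ])
            try:
                sol = least_squares(self._residuals, x0, bounds=(lb, ub),
                                    method="trf", xtol=1e-12, ftol=1e-12)
            except Exception:
                continue
            if sol.success:
                n_ok += 1
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise RuntimeError(
                f"graph fit failed to converge in any of {n_starts} starts"
            )
        lengths, weights = self._unpack(best.x)
        fitted = self.topology.with_parameters(lengths, weights)
        pred = fitted.expected_f2_matrix().loc[self.leaves, self.leaves]
        res = GraphFitResults(
            topology=self.topology,
            fitted_graph=fitted,
            lengths={e: float(t) for e, t in lengths.items()},
            weights={c: float(w) for c, w in weights.items()},
            cost=float(best.cost),
            converged=n_ok > 0,
            n_starts=n_starts,
            f2_observed=self.f2_observed,
            f2_predicted=pred,
            f2_se=self.f2_se,
        )
        if score_f4 and self.counts is not None and self.blocks is not None:
            z, quad, table = worst_f4_z(fitted, self.counts, self.blocks)
            res.worst_f4_z = z
            res.worst_f4_quadruple = tuple(quad)
            res.f4_residuals = table
        return res


def compare_outgroup_modes(topology: AdmixtureGraph, counts: PopAlleleCounts,
                           blocks: BlockSpec, formal_outgroup: str | None = None,
                           n_starts: int = 20, seed: int = 0
                           ) -> tuple[GraphFitResults, GraphFitResults]:
    """Fit a topology with free outgroup placement and with a formal outgroup.

    The free mode fits the topology as given.  The formal mode constrains
    ``formal_outgroup`` to be a clean outgroup — admixture events drawing
    from its lineage are dissolved — and refits; comparing the two support
    verdicts shows whether the data are consistent with the outgroup
    assumption.  When the outgroup lineage carries no admixture the two
    topologies coincide.
    """
    og = formal_outgroup or topology.outgroup
    if og is None:
        raise GraphError("no formal outgroup given")
    if og not in topology.leaves():
        raise GraphError(f"outgroup {og!r} is not a leaf of the topology")
    free_fit = AdmixtureGraphModel.from_counts(topology, counts, blocks).fit(
        n_starts=n_starts, seed=seed
    )
    constrained = topology.formal_outgroup_topology(og)
    constrained_fit = AdmixtureGraphModel.from_counts(
        constrained, counts, blocks
    ).fit(n_starts=n_starts, seed=seed)
    return free_fit, constrained_fit
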