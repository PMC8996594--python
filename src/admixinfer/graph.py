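"""Admixture graphs: populations related by drift edges and admixture events.

An :class:`AdmixtureGraph` is a rooted directed acyclic graph.  Ordinary
("drift") edges carry a non-negative length in f2 units — the expected squared
allele-frequency change accumulated along the edge, up to a genome-wide
heterozygosity factor.  An *admixture node* has exactly two parents and a
weight ``w`` in [0, 1]: its allele frequency is the instantaneous mixture
``w * p(parent1) + (1 - w) * p(parent2)``.  Post-admixture drift is modelled
by a drift edge below the admixture node.

Under this model every leaf's frequency deviation from the ancestral value is
a fixed linear combination of the independent per-edge drift increments,
with coefficients given by products of admixture weights ("mixture
coefficients").  Expected f-statistics are therefore exact quadratic forms in
the edge lengths:

    E[f2(A, B)]          = sum_e t_e * (c_A(e) - c_B(e))**2
    E[f4(A, B; C, D)]    = sum_e t_e * (c_A(e) - c_B(e)) * (c_C(e) - c_D(e))

where ``c_X(e)`` is the probability-weighted usage of edge ``e`` by leaf X.
These are computed exactly by forward propagation (no path enumeration is
needed; graphs here have at most a few admixture nodes anyway).

Edge lengths and admixture weights may be left *free* (``None``) — the graph
then acts as a fit topology for :class:`admixinfer.graphfit.AdmixtureGraphModel`.
"""

from __future__ import annotations

import itertools
import json
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["AdmixtureGraph", "GraphError"]


class GraphError(ValueError):
    """Raised for structurally invalid admixture graphs."""


class AdmixtureGraph:
    """Rooted DAG of populations with drift-length edges and admixture nodes.

    Parameters
    ----------
    edges
        Iterable of ``(parent, child, length)`` drift edges.  ``length`` may be
        ``None`` to mark a free parameter.
    admixtures
        Iterable of ``(child, (parent1, parent2), weight)`` records.  The
        weight is the proportion inherited from ``parent1`` and may be ``None``
        (free).  Admixture children receive *only* these two mixing edges;
        drift below the event is modelled by a separate drift edge out of the
        admixture node.
    outgroup
        Optional leaf designated as the formal outgroup.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str, float | None]],
        admixtures: Iterable[tuple[str, tuple[str, str], float | None]] = (),
        outgroup: str | None = None,
    ):
        g = nx.DiGraph()
        for u, v, t in edges:
            if g.has_edge(u, v):
                raise GraphError(f"duplicate edge {u}->{v}")
            g.add_edge(u, v, kind="drift", length=None if t is None else float(t))
        self._admix: dict[str, tuple[tuple[str, str], float | None]] = {}
        for child, parents, w in admixtures:
            p1, p2 = parents
            if child in self._admix:
                raise GraphError(f"node {child} has two admixture records")
            w = None if w is None else float(w)
            g.add_edge(p1, child, kind="admix")
            g.add_edge(p2, child, kind="admix")
            self._admix[child] = ((p1, p2), w)
        self._g = g
        self.outgroup = outgroup
        self.validate()

    # ------------------------------------------------------------------ #
    # structure
    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        g = self._g
        if g.number_of_nodes() == 0:
            raise GraphError("empty graph")
        if not nx.is_directed_acyclic_graph(g):
            raise GraphError("graph contains a cycle")
        roots = [n for n in g if g.in_degree(n) == 0]
        if len(roots) != 1:
            raise GraphError(f"graph must have exactly one root, found {roots}")
        root = roots[0]
        for n in g:
            indeg = g.in_degree(n)
            if n in self._admix:
                if indeg != 2:
                    raise GraphError(f"admixture node {n} must have 2 parents")
            elif n != root and indeg != 1:
                raise GraphError(f"node {n} must have exactly one parent")
        for n in g:
            if n != root and not nx.has_path(g, root, n):
                raise GraphError(f"node {n} unreachable from root")
        for u, v, d in g.edges(data=True):
            if d["kind"] == "drift" and d["length"] is not None and d["length"] < 0:
                raise GraphError(f"negative drift length on {u}->{v}")
        for child, (_, w) in self._admix.items():
            if w is not None and not 0.0 <= w <= 1.0:
                raise GraphError(f"admixture weight of {child} outside [0, 1]: {w}")
        if self.outgroup is not None and self.outgroup not in self.leaves():
            raise GraphError(f"outgroup {self.outgroup!r} is not a leaf")

    @property
    def root(self) -> str:
        return next(n for n in self._g if self._g.in_degree(n) == 0)

    def leaves(self) -> list[str]:
        return sorted(n for n in self._g if self._g.out_degree(n) == 0)

    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    def drift_edges(self) -> list[tuple[str, str]]:
        return [(u, v) for u, v, d in self._g.edges(data=True) if d["kind"] == "drift"]

    def edge_length(self, u: str, v: str) -> float | None:
        return self._g.edges[u, v]["length"]

    def admixture_nodes(self) -> list[str]:
        return sorted(self._admix)

    def admixture(self, child: str) -> tuple[tuple[str, str], float | None]:
        return self._admix[child]

    def free_edges(self) -> list[tuple[str, str]]:
        return sorted((u, v) for u, v in self.drift_edges() if self.edge_length(u, v) is None)

    def free_weights(self) -> list[str]:
        return sorted(c for c, (_, w) in self._admix.items() if w is None)

    def is_fully_specified(self) -> bool:
        return not self.free_edges() and not self.free_weights()

    def with_parameters(
        self,
        lengths: Mapping[tuple[str, str], float] | None = None,
        weights: Mapping[str, float] | None = None,
    ) -> "AdmixtureGraph":
        """Return a copy with free (or overridden) parameters filled in."""
        lengths = dict(lengths or {})
        weights = dict(weights or {})
        edges = []
        for u, v in self.drift_edges():
            t = lengths.get((u, v), self.edge_length(u, v))
            edges.append((u, v, t))
        admix = []
        for child, (parents, w) in self._admix.items():
            admix.append((child, parents, weights.get(child, w)))
        return AdmixtureGraph(edges, admix, outgroup=self.outgroup)

    # ------------------------------------------------------------------ #
    # expectations
    # ------------------------------------------------------------------ #
    def mixture_coefficients(self) -> dict[str, dict[tuple[str, str], float]]:
        """Per node: coefficient of each drift edge in the node's frequency.

        The coefficient of edge ``e`` for node X is the product-of-weights
        probability that X's ancestry at a locus passed through ``e``; for an
        unadmixed node it is simply 1 on each edge of its root path.
        """
        self._require_specified()
        coeffs: dict[str, dict[tuple[str, str], float]] = {}
        for n in nx.topological_sort(self._g):
            if self._g.in_degree(n) == 0:
                coeffs[n] = {}
            elif n in self._admix:
                (p1, p2), w = self._admix[n]
                c: dict[tuple[str, str], float] = {}
                for e, v in coeffs[p1].items():
                    c[e] = c.get(e, 0.0) + w * v
                for e, v in coeffs[p2].items():
                    c[e] = c.get(e, 0.0) + (1.0 - w) * v
                coeffs[n] = c
            else:
                (parent,) = self._g.predecessors(n)
                c = dict(coeffs[parent])
                c[(parent, n)] = c.get((parent, n), 0.0) + 1.0
                coeffs[n] = c
        return coeffs

    def _require_specified(self) -> None:
        if not self.is_fully_specified():
            raise GraphError(
                "graph has free parameters; fill them with with_parameters() first"
            )

    def expected_f2(self, a: str, b: str) -> float:
        coeffs = self.mixture_coefficients()
        return self._f2_from_coeffs(coeffs, a, b)

    def _f2_from_coeffs(self, coeffs, a: str, b: str) -> float:
        ca, cb = coeffs[a], coeffs[b]
        total = 0.0
        for e in set(ca) | set(cb):
            d = ca.get(e, 0.0) - cb.get(e, 0.0)
            if d:
                total += self._g.edges[e]["length"] * d * d
        return total

    def expected_f2_matrix(self) -> pd.DataFrame:
        """Symmetric leaf-by-leaf matrix of expected f2 values (zero diagonal)."""
        leaves = self.leaves()
        coeffs = self.mixture_coefficients()
        m = pd.DataFrame(0.0, index=leaves, columns=leaves)
        for a, b in itertools.combinations(leaves, 2):
            v = self._f2_from_coeffs(coeffs, a, b)
            m.loc[a, b] = m.loc[b, a] = v
        return m

    def expected_f4(self, a: str, b: str, c: str, d: str) -> float:
        """Expected f4(a, b; c, d) = E[(p_a - p_b)(p_c - p_d)]."""
        coeffs = self.mixture_coefficients()
        ca, cb, cc, cd = (coeffs[x] for x in (a, b, c, d))
        total = 0.0
        for e in set(ca) | set(cb) | set(cc) | set(cd):
            d1 = ca.get(e, 0.0) - cb.get(e, 0.0)
            d2 = cc.get(e, 0.0) - cd.get(e, 0.0)
            if d1 and d2:
                total += self._g.edges[e]["length"] * d1 * d2
        return total

    # ------------------------------------------------------------------ #
    # outgroup surgery
    # ------------------------------------------------------------------ #
    def formal_outgroup_topology(self, outgroup: str) -> "AdmixtureGraph":
        """Topology with ``outgroup`` constrained to be a clean outgroup.

        Every admixture event drawing ancestry from a node on the
        root-to-outgroup drift path is dissolved: the admixed child keeps its
        other parent only (weight collapses to 1).  If no such event exists
        the topology is returned unchanged (up to the outgroup tag).
        """
        if outgroup not in self.leaves():
            raise GraphError(f"outgroup {outgroup!r} is not a leaf of the graph")
        # nodes on the drift path root -> outgroup
        path_nodes = {outgroup}
        node = outgroup
        while True:
            preds = [p for p in self._g.predecessors(node)
                     if self._g.edges[p, node]["kind"] == "drift"]
            if not preds:
                break
            node = preds[0]
            path_nodes.add(node)
        edges = [(u, v, self.edge_length(u, v)) for u, v in self.drift_edges()]
        admix = []
        for child, ((p1, p2), w) in self._admix.items():
            if p1 in path_nodes and p2 in path_nodes:
                raise GraphError(
                    f"both parents of {child} lie on the outgroup lineage"
                )
            if p1 in path_nodes:
                edges.append((p2, child, 0.0))
            elif p2 in path_nodes:
                edges.append((p1, child, 0.0))
            else:
                admix.append((child, (p1, p2), w))
        return AdmixtureGraph(edges, admix, outgroup=outgroup)

    # ------------------------------------------------------------------ #
    # serialization
    # ------------------------------------------------------------------ #
    def to_dict(self) -> dict:
        d: dict = {
            "nodes": sorted(self.nodes()),
            "edges": [
                {"from": u, "to": v}
                | ({"free": True} if self.edge_length(u, v) is None
                   else {"length": self.edge_length(u, v)})
                for u, v in self.drift_edges()
            ],
            "admixtures": [
                {"child": c, "parents": list(parents)}
                | ({"free": True} if w is None else {"weight": w})
                for c, (parents, w) in sorted(self._admix.items())
            ],
        }
        if self.outgroup is not None:
            d["outgroup"] = self.outgroup
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AdmixtureGraph":
        edges = [(e["from"], e["to"], e.get("length")) for e in d.get("edges", [])]
        admix = [
            (a["child"], tuple(a["parents"]), a.get("weight"))
            for a in d.get("admixtures", [])
        ]
        return cls(edges, admix, outgroup=d.get("outgroup"))

    def to_json(self, path=None, **kw) -> str | None:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kw)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text + "\n")
        return None

    @classmethod
    def from_json(cls, source: str) -> "AdmixtureGraph":
        """Load from a JSON string or a path to a JSON file."""
        try:
            d = json.loads(source)
        except (json.JSONDecodeError, ValueError):
            with open(source) as fh:
                d = json.load(fh)
        return cls.from_dict(d)

    def to_dot(self) -> str:
        lines = ["digraph admixture {", "  rankdir=TB;"]
        for n in self.nodes():
            shape = "box" if n in set(self.leaves()) else "point"
            label = f' label="{n}"' if shape == "box" else ""
            lines.append(f'  "{n}" [shape={shape}{label}];')
        for u, v in self.drift_edges():
            t = self.edge_length(u, v)
            lab = "free" if t is None else f"{t:.4g}"
            lines.append(f'  "{u}" -> "{v}" [label="{lab}"];')
        for c, ((p1, p2), w) in sorted(self._admix.items()):
            w1 = "w" if w is None else f"{w:.3g}"
            w2 = "1-w" if w is None else f"{1 - w:.3g}"
            lines.append(f'  "{p1}" -> "{c}" [style=dashed, label="{w1}"];')
            lines.append(f'  "{p2}" -> "{c}" [style=dashed, label="{w2}"];')
        lines.append("}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AdmixtureGraph({len(self.nodes())} nodes, "
            f"{len(self.leaves())} leaves, {len(self._admix)} admixture events)"
        )
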