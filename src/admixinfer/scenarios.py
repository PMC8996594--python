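"""Canonical baboon-like simulation scenarios.

These encode the study conditions used throughout the test-suite and the
replay pipeline: a *Papio*-like species panel (gelada outgroup; northern and
southern clades; 1-4 diploids per population, as in published cross-species
baboon panels) with admixture events at the proportions inferred for the
Gorongosa (Mozambique) baboon and for the admixed olive-baboon individual.

Drift lengths are not published for these populations; the values here are
fixed once at Papio-plausible magnitudes (0.005-0.1 f2 units between
congeners, larger for the gelada outgroup).  Because these drifts are larger
than the generator's generic default anticipates, the scenarios narrow the
ancestral-frequency range to (0.2, 0.8), keeping boundary clipping — which
biases long-path f2 values downward — rare, as the drift model requires.

For the f4-ratio scenarios the admixture source is the cynocephalus-lineage
node itself (no residual source-specific drift), the regime in which the
ratio f4(out, src; target, sister) / f4(out, src; src, sister) is an exact
estimate of the mixing proportion.
"""

from __future__ import annotations

from .graph import AdmixtureGraph
from .simulate import DriftScenario

__all__ = [
    "f4_ratio_graph",
    "gnp_scenario",
    "admixed_anubis_scenario",
    "papio_like_graph",
    "papio_like_free_topology",
    "GNP_ALPHA",
    "ANUBIS_ALPHA",
    "CYNO_WEIGHT",
    "NORTHERN_WEIGHT",
]

# Admixture proportions used as simulation truth (cynocephalus-related
# contribution into the Mozambique/Gorongosa genome and into the admixed
# olive baboon, and the small proto-northern contribution).
GNP_ALPHA = 0.08
ANUBIS_ALPHA = 0.11
CYNO_WEIGHT = 0.37
NORTHERN_WEIGHT = 0.03


def f4_ratio_graph(alpha: float, target: str = "gnp", source: str = "cyno",
                   sister: str = "ursinus", outgroup: str = "gelada"
                   ) -> AdmixtureGraph:
    """Four-population tree with an admixed target: ((out,(src,(target,sis))).

    The target draws a fraction ``alpha`` of its ancestry from the source
    lineage node (zero drift between that node and the source leaf) and the
    rest from its sister's lineage, then drifts on its own terminal edge.
    """
    edges = [
        ("root", outgroup, 0.05),
        ("root", "n1", 0.01),
        ("n1", "src_anc", 0.15),
        ("src_anc", source, 0.0),
        ("n1", "n2", 0.015),
        ("n2", sister, 0.02),
        ("n2", "target_base", 0.005),
        ("target_mix", target, 0.005),
    ]
    admixtures = [("target_mix", ("src_anc", "target_base"), alpha)]
    return AdmixtureGraph(edges, admixtures, outgroup=outgroup)


def gnp_scenario(n_sites: int = 200_000, seed: int = 0) -> DriftScenario:
    """Gorongosa-like four-population scenario (8% cynocephalus-related)."""
    return DriftScenario(
        graph=f4_ratio_graph(GNP_ALPHA, target="gnp", source="cyno",
                             sister="ursinus"),
        n_sites=n_sites,
        samples_per_pop={"gelada": 1, "cyno": 2, "gnp": 1, "ursinus": 2},
        ancestral_freq_range=(0.2, 0.8),
        seed=seed,
    )


def admixed_anubis_scenario(n_sites: int = 200_000, seed: int = 0
                            ) -> DriftScenario:
    """Admixed olive-baboon scenario (11% cynocephalus-related into one
    individual, with a Guinea-baboon-like sister lineage)."""
    return DriftScenario(
        graph=f4_ratio_graph(ANUBIS_ALPHA, target="anubis30877",
                             source="cyno", sister="papio"),
        n_sites=n_sites,
        samples_per_pop={"gelada": 1, "cyno": 2, "anubis30877": 1, "papio": 2},
        ancestral_freq_range=(0.2, 0.8),
        seed=seed,
    )


def papio_like_graph(cyno_weight: float = CYNO_WEIGHT,
                     northern_weight: float = NORTHERN_WEIGHT
                     ) -> AdmixtureGraph:
    """Five-leaf Papio-like graph with a doubly admixed Mozambique leaf.

    Northern (anubis-like) and southern (cynocephalus + ursinus) clades under
    a gelada outgroup.  The Mozambique leaf mixes a cynocephalus-related
    contribution (weight ``cyno_weight``) with a remainder drawn from the
    ursinus lineage carrying a small proto-northern share
    (``northern_weight`` of total ancestry, sourced at the Papio stem node).

    The admixture sources sit at the sampled cynocephalus and ursinus
    populations themselves (zero source-terminal drift): with freely drifting
    unsampled sources this graph's weights are provably unidentifiable from
    any f2/f3/f4 basis (the fit Jacobian loses rank), so the sampled-source
    regime is the study condition here, asserted identically in the fit
    topology.
    """
    base_w = northern_weight / (1.0 - cyno_weight)  # share within the remainder
    edges = [
        ("root", "gelada", 0.06),
        ("root", "papio_anc", 0.01),
        ("papio_anc", "northern", 0.03),
        ("papio_anc", "south_anc", 0.01),
        ("south_anc", "cyno_anc", 0.03),
        ("cyno_anc", "cyno", 0.0),
        ("south_anc", "urs_anc", 0.03),
        ("urs_anc", "ursinus", 0.0),
        ("moz_mix", "mozambique", 0.005),
    ]
    admixtures = [
        ("moz_base", ("papio_anc", "urs_anc"), base_w),
        ("moz_mix", ("cyno_anc", "moz_base"), cyno_weight),
    ]
    return AdmixtureGraph(edges, admixtures, outgroup="gelada")


def papio_like_free_topology() -> AdmixtureGraph:
    """The same topology with the drift lengths and weights free.

    Two kinds of edges stay pinned at 0 for identifiability: the
    root-to-Papio stem (root placement is invisible to any f2 basis, so it is
    exactly confounded with the outgroup terminal edge, which absorbs it) and
    the source-terminal edges below the two admixture sources (the topology
    asserts the sampled populations are the sources, matching the simulated
    truth; see :func:`papio_like_graph`).
    """
    edges = [
        ("root", "gelada", None),
        ("root", "papio_anc", 0.0),
        ("papio_anc", "northern", None),
        ("papio_anc", "south_anc", None),
        ("south_anc", "cyno_anc", None),
        ("cyno_anc", "cyno", 0.0),
        ("south_anc", "urs_anc", None),
        ("urs_anc", "ursinus", 0.0),
        ("moz_mix", "mozambique", None),
    ]
    admixtures = [
        ("moz_base", ("papio_anc", "urs_anc"), None),
        ("moz_mix", ("cyno_anc", "moz_base"), None),
    ]
    return AdmixtureGraph(edges, admixtures, outgroup="gelada")


def papio_like_scenario(n_sites: int = 200_000, seed: int = 0) -> DriftScenario:
    """Drift scenario over the five-leaf Papio-like graph (panel-like sizes)."""
    return DriftScenario(
        graph=papio_like_graph(),
        n_sites=n_sites,
        samples_per_pop={
            "gelada": 1, "northern": 2, "cyno": 2, "ursinus": 2,
            "mozambique": 1,
        },
        ancestral_freq_range=(0.2, 0.8),
        seed=seed,
    )
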