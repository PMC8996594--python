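"""f-statistics: hand-checked values, algebraic identities, oracle loops."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admixinfer import fstats, genio, simulate
from admixinfer.fstats import (
    d_stat,
    d_stat_pseudohaploid,
    f2,
    f3,
    f4,
    f4_ratio,
    jackknife,
    weighted_jackknife,
)
from admixinfer.genio import GenotypeMatrix, define_blocks
from admixinfer.graph import AdmixtureGraph

from conftest import counts_from_freqs, make_sites, simulated_counts


def random_counts(rng, n_sites=400, pops=("A", "B", "C", "D"), max_n=8,
                  spacing=600_000):
    """Random finite-sample allele counts (every pop has >= 2 alleles)."""
    n = rng.integers(2, max_n + 1, size=(n_sites, len(pops))) * 2
    alt = rng.binomial(n, rng.uniform(0.05, 0.95, size=(n_sites, 1)))
    counts = genio.PopAlleleCounts(
        make_sites(n_sites, spacing=spacing), list(pops), alt, n
    )
    return counts, define_blocks(counts)


class TestJackknife:
    def test_equal_weight_delete_one_arithmetic(self):
        # data mean 2.0; leave-one-out means 2.5, 2.0, 1.5:
        # se = sqrt((2/3) * (0.25 + 0 + 0.25)) = 0.5774
        _, se = weighted_jackknife(2.0, np.array([2.5, 2.0, 1.5]),
                                   np.ones(3))
        assert se == pytest.approx(np.sqrt(1.0 / 3.0), rel=1e-12)

    def test_identical_blocks_zero_se(self):
        est, se = jackknife(np.full(6, 1.3), np.full(6, 10.0))
        assert est == pytest.approx(1.3)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_weighted_equals_unweighted_for_equal_blocks(self, rng):
        vals = rng.normal(size=8)
        est1, se1 = jackknife(vals, np.full(8, 50.0))
        est2, se2 = jackknife(vals, np.full(8, 7.0))
        assert est1 == pytest.approx(est2)
        assert se1 == pytest.approx(se2)

    def test_single_block_flagged_undefined(self):
        est, se = jackknife(np.array([2.0]), np.array([10.0]))
        assert est == 2.0 and np.isnan(se)


class TestF2:
    def test_known_frequencies(self):
        counts = counts_from_freqs({"A": np.array([0.5]), "B": np.array([0.25])})
        r = f2(counts, "A", "B", define_blocks(counts))
        assert r.estimate == pytest.approx(0.0625, abs=1e-5)

    def test_self_comparison_near_zero(self, rng):
        counts, blocks = random_counts(rng, pops=("A", "B"))
        # duplicate A's counts as a pseudo-population with identical samples
        dup = genio.PopAlleleCounts(
            counts.sites, ["A", "A2"],
            np.column_stack([counts.alt[:, 0]] * 2),
            np.column_stack([counts.total[:, 0]] * 2),
        )
        r = f2(dup, "A", "A2", define_blocks(dup))
        # identical counts: squared difference is 0, bias terms subtract
        assert r.estimate < 0  # pure -2h/n, negative as expected
        g = AdmixtureGraph([("root", "A", 0.01), ("root", "B", 0.01)])
        _, counts2, blocks2 = simulated_counts(g, {"A": 4, "B": 4},
                                               n_sites=20_000, seed=3)
        rb = f2(counts2, "A", "B", blocks2)
        assert abs(rb.estimate - 0.02 * 0.19667) < 3 * rb.se

    def test_matches_per_site_loop(self, rng):
        counts, blocks = random_counts(rng, n_sites=300, pops=("A", "B"))
        r = f2(counts, "A", "B", blocks)
        vals = []
        for i in range(counts.n_sites):
            pa = counts.alt[i, 0] / counts.total[i, 0]
            pb = counts.alt[i, 1] / counts.total[i, 1]
            na, nb = counts.total[i, 0], counts.total[i, 1]
            ha = pa * (1 - pa) * na / (na - 1)
            hb = pb * (1 - pb) * nb / (nb - 1)
            vals.append((pa - pb) ** 2 - ha / na - hb / nb)
        assert r.estimate == pytest.approx(np.mean(vals), rel=1e-10)


class TestF3:
    def test_known_frequencies(self):
        counts = counts_from_freqs({
            "T": np.array([0.5]), "A": np.array([0.0]), "B": np.array([1.0]),
        })
        r = f3(counts, "T", "A", "B", define_blocks(counts))
        assert r.estimate == pytest.approx(-0.25, abs=1e-5)

    def test_f2_decomposition_identity(self, rng):
        """f3(T;A,B) = [f2(T,A) + f2(T,B) - f2(A,B)] / 2 holds per dataset."""
        counts, blocks = random_counts(rng, pops=("T", "A", "B"))
        lhs = f3(counts, "T", "A", "B", blocks).estimate
        rhs = 0.5 * (f2(counts, "T", "A", blocks).estimate
                     + f2(counts, "T", "B", blocks).estimate
                     - f2(counts, "A", "B", blocks).estimate)
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_fifty_fifty_mixture_flags_admixture(self):
        g = AdmixtureGraph(
            [("root", "a_anc", 0.04), ("a_anc", "A", 0.0),
             ("root", "b_anc", 0.04), ("b_anc", "B", 0.0),
             ("mix", "T", 0.001)],
            [("mix", ("a_anc", "b_anc"), 0.5)],
        )
        _, counts, blocks = simulated_counts(
            g, {"A": 4, "B": 4, "T": 4}, n_sites=60_000, seed=8
        )
        r = f3(counts, "T", "A", "B", blocks)
        assert r.estimate < 0
        assert r.z <= -3
        assert r.notes["admixture_signal"]


class TestF4:
    def test_two_site_hand_value(self):
        counts = counts_from_freqs({
            "P1": np.array([0.0, 1.0]), "P2": np.array([1.0, 1.0]),
            "P3": np.array([0.0, 0.0]), "P4": np.array([1.0, 0.0]),
        })
        r = f4(counts, "P1", "P2", "P3", "P4", define_blocks(counts))
        assert r.estimate == pytest.approx(0.5, abs=1e-6)

    def test_antisymmetry_is_exact(self, rng):
        counts, blocks = random_counts(rng)
        base = f4(counts, "A", "B", "C", "D", blocks).estimate
        assert f4(counts, "B", "A", "C", "D", blocks).estimate == -base
        assert f4(counts, "A", "B", "D", "C", blocks).estimate == -base
        assert f4(counts, "B", "A", "D", "C", blocks).estimate == base

    def test_f4_self_pair_equals_f2_convention(self, rng):
        counts, blocks = random_counts(rng, pops=("A", "B"))
        plain = f4(counts, "A", "B", "A", "B", blocks, corrected=False)
        uncorr_f2 = f2(counts, "A", "B", blocks, corrected=False)
        assert plain.estimate == pytest.approx(uncorr_f2.estimate, rel=1e-12)
        corr = f4(counts, "A", "B", "A", "B", blocks)
        corr_f2 = f2(counts, "A", "B", blocks)
        assert corr.estimate == pytest.approx(corr_f2.estimate, rel=1e-12)

    def test_matches_per_site_loop(self, rng):
        counts, blocks = random_counts(rng, n_sites=250)
        r = f4(counts, "A", "B", "C", "D", blocks)
        p = counts.alt / counts.total
        vals = (p[:, 0] - p[:, 1]) * (p[:, 2] - p[:, 3])
        assert r.estimate == pytest.approx(vals.mean(), rel=1e-10)


class TestDStat:
    def test_two_site_hand_value(self):
        counts = counts_from_freqs({
            "P1": np.array([0.0, 1.0]), "P2": np.array([1.0, 1.0]),
            "P3": np.array([0.0, 0.0]), "P4": np.array([1.0, 0.0]),
        })
        r = d_stat(counts, "P1", "P2", "P3", "P4", define_blocks(counts))
        assert r.estimate == pytest.approx(1.0, abs=1e-6)

    def test_null_tree_not_significant(self):
        g = AdmixtureGraph([
            ("root", "O", 0.03), ("root", "n", 0.01),
            ("n", "X", 0.02), ("n", "m", 0.01),
            ("m", "H1", 0.01), ("m", "H2", 0.01),
        ])
        _, counts, blocks = simulated_counts(
            g, {"O": 2, "X": 2, "H1": 2, "H2": 2}, n_sites=50_000, seed=12
        )
        r = d_stat(counts, "O", "X", "H1", "H2", blocks)
        assert abs(r.z) < 3

    def test_gene_flow_detected(self):
        # X contributes 15% ancestry to H2: expect D(O, X, H1, H2) > 0, Z >= 3
        g = AdmixtureGraph(
            [
                ("root", "O", 0.03), ("root", "n", 0.01),
                ("n", "xa", 0.05), ("xa", "X", 0.0),
                ("n", "m", 0.01),
                ("m", "H1", 0.01), ("m", "h2b", 0.005),
                ("h2mix", "H2", 0.005),
            ],
            [("h2mix", ("xa", "h2b"), 0.15)],
        )
        _, counts, blocks = simulated_counts(
            g, {"O": 2, "X": 2, "H1": 2, "H2": 2}, n_sites=200_000, seed=13
        )
        r = d_stat(counts, "O", "X", "H1", "H2", blocks)
        assert r.z >= 3
        assert r.estimate > 0

    def test_allele_flip_invariance(self, rng):
        counts, blocks = random_counts(rng, n_sites=200)
        flipped = genio.PopAlleleCounts(
            counts.sites, counts.populations,
            counts.total - counts.alt, counts.total,
        )
        for stat in (d_stat, f4):
            a = stat(counts, "A", "B", "C", "D", blocks)
            b = stat(flipped, "A", "B", "C", "D", blocks)
            assert a.estimate == pytest.approx(b.estimate, rel=1e-10)


class TestDStatPseudohaploid:
    def _homozygous_gm(self, rng, n_sites=200):
        calls = rng.choice([0, 2], size=(n_sites, 4)).astype(np.int16)
        return GenotypeMatrix(make_sites(n_sites, spacing=400_000),
                              ["a", "b", "c", "d"], calls)

    def test_homozygous_equals_frequency_d(self, rng):
        gm = self._homozygous_gm(rng)
        blocks = define_blocks(gm)
        pm = genio.PopMap({s: s.upper() for s in gm.samples})
        counts = genio.pop_allele_counts(gm, pm)
        full = d_stat(counts, "A", "B", "C", "D", blocks)
        ph = d_stat_pseudohaploid(gm, ("a", "b", "c", "d"), blocks, seed=4)
        assert ph.estimate == pytest.approx(full.estimate, rel=1e-10)

    def test_pooled_mean_tracks_full_data_d(self):
        g = AdmixtureGraph([
            ("root", "O", 0.03), ("root", "n", 0.02),
            ("n", "X", 0.03), ("n", "m", 0.015),
            ("m", "H1", 0.02), ("m", "H2", 0.02),
        ])
        gm, counts, blocks = simulated_counts(
            g, {"O": 1, "X": 1, "H1": 1, "H2": 1}, n_sites=50_000, seed=21
        )
        full = d_stat(counts, "O", "X", "H1", "H2", blocks)
        ests = [
            d_stat_pseudohaploid(
                gm, ("O_1", "X_1", "H1_1", "H2_1"), blocks, seed=s
            ).estimate
            for s in range(30)
        ]
        assert np.std(ests, ddof=1) > 0  # sampling varies across seeds
        assert np.mean(ests) == pytest.approx(full.estimate, abs=0.02)

    def test_degraded_sample_consistent_with_source(self):
        """A pseudo-haploid low-coverage copy is not distinguishable from its
        own full-coverage source when tested head-to-head."""
        g = AdmixtureGraph([
            ("root", "O", 0.03), ("root", "n", 0.02),
            ("n", "X", 0.03), ("n", "GNP", 0.02),
        ])
        sc = simulate.DriftScenario(
            graph=g, n_sites=150_000,
            samples_per_pop={"O": 1, "X": 1, "GNP": 1}, seed=31,
        )
        ft = simulate.simulate_frequencies(sc)
        gm = simulate.sample_genotypes(ft, sc.samples_per_pop, seed=32)
        low = simulate.degrade_to_low_coverage(gm, keep_prob=1.0, seed=33)
        merged = GenotypeMatrix(
            gm.sites.copy(), gm.samples + ["BB1"],
            np.column_stack([gm.calls,
                             low.calls[:, gm.samples.index("GNP_1")]]),
        )
        blocks = define_blocks(merged)
        r = d_stat_pseudohaploid(merged, ("O_1", "X_1", "GNP_1", "BB1"),
                                 blocks, seed=34)
        assert abs(r.z) < 3


class TestF4Ratio:
    def test_exact_mixture_recovers_alpha(self, rng):
        n = 400
        pa = rng.uniform(0.1, 0.9, n)
        po = rng.uniform(0.1, 0.9, n)
        pb = rng.uniform(0.1, 0.9, n)
        pc = rng.uniform(0.1, 0.9, n)
        alpha = 0.37
        px = alpha * pb + (1 - alpha) * pc
        counts = counts_from_freqs(
            {"A": pa, "O": po, "X": px, "B": pb, "C": pc}, spacing=500_000
        )
        r = f4_ratio(counts, "A", "O", "X", "B", "C", define_blocks(counts))
        assert r.estimate == pytest.approx(alpha, abs=1e-4)

    def test_clone_of_sister_gives_zero(self, rng):
        n = 400
        pa, po, pb = (rng.uniform(0.1, 0.9, n) for _ in range(3))
        pc = rng.uniform(0.1, 0.9, n)
        counts = counts_from_freqs(
            {"A": pa, "O": po, "X": pc.copy(), "B": pb, "C": pc},
            spacing=500_000,
        )
        r = f4_ratio(counts, "A", "O", "X", "B", "C", define_blocks(counts))
        assert r.estimate == pytest.approx(0.0, abs=1e-4)

    def test_unreliable_flag_on_null_denominator(self, rng):
        counts, blocks = random_counts(rng, pops=("A", "O", "X", "B", "C"),
                                       n_sites=500)
        r = f4_ratio(counts, "A", "O", "X", "B", "C", blocks)
        assert r.notes["reliable"] is False


class TestCalibration:
    def test_jackknife_se_matches_empirical_sd(self):
        """Jackknife SEs track the across-replicate SD within a factor 1.3
        at ~100 blocks (f2 on a two-population drift simulation)."""
        g = AdmixtureGraph([("root", "A", 0.02), ("root", "B", 0.03)])
        ests, ses = [], []
        for s in range(40):
            sc = simulate.DriftScenario(
                graph=g, n_sites=30_000, seed=s,
                chrom_lengths=(("1", 250_000_000), ("2", 250_000_000)),
                samples_per_pop={"A": 2, "B": 2},
            )
            ft = simulate.simulate_frequencies(sc)
            gm = simulate.sample_genotypes(ft, sc.samples_per_pop,
                                           seed=50_000 + s)
            counts = genio.pop_allele_counts(
                gm, simulate.default_popmap(sc.samples_per_pop)
            )
            r = f2(counts, "A", "B", define_blocks(gm))
            ests.append(r.estimate)
            ses.append(r.se)
        assert r.n_blocks == 100
        ratio = np.mean(ses) / np.std(ests, ddof=1)
        assert 1 / 1.3 < ratio < 1.3

    def test_streaming_equals_naive_double_loop(self, rng):
        """Blocked/vectorized statistics equal explicit per-site loops."""
        counts, blocks = random_counts(rng, n_sites=500)
        p = counts.alt / counts.total
        d = d_stat(counts, "A", "B", "C", "D", blocks)
        num = den = 0.0
        for i in range(counts.n_sites):
            p1, p2, p3, p4 = p[i]
            num += (p1 - p2) * (p3 - p4)
            den += (p1 + p2 - 2 * p1 * p2) * (p3 + p4 - 2 * p3 * p4)
        assert d.estimate == pytest.approx(num / den, rel=1e-10)
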