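"""Position-bias background and Z statistic, seeded target calling, permutation FDR."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

import motifnet as mn
from motifnet.network import CoexpressionNetwork
from motifnet.promoters import MotifHit
from motifnet.synthetic import generate_promoters, plant_motif
from motifnet.targets import BiasError, PermutationFDR


def hits_at(distances, gene="g", strand="+"):
    return [MotifHit(gene, -abs(d), strand, 0.0) for d in distances]


class TestBiasBackground:
    def test_unmasked_two_promoter_hand_case(self):
        ps = generate_promoters(2, 4, 0, 0.0, seed=3)
        bg = mn.bias_background(ps, ps.gene_ids)
        assert bg.K == 10
        assert bg.E_d == pytest.approx(2.0)
        assert bg.V_d == pytest.approx(2.0)

    def test_masked_hand_case(self, two_promoter_set):
        """k_i = (1,1,2,2,2) over -4..0: K=8, E=13/8, V=35/8-(13/8)^2."""
        bg = mn.bias_background(two_promoter_set, two_promoter_set.gene_ids)
        assert bg.K == 8
        assert list(bg.k_i) == [1, 1, 2, 2, 2]
        assert bg.E_d == pytest.approx(1.625)
        assert bg.V_d == pytest.approx(1.734375)

    def test_single_position_promoter_degenerate(self):
        import motifnet.promoters as pr

        ps = pr.PromoterSet(["g"], ["A"], np.ones((1, 1), bool), 0, 0)
        bg = mn.bias_background(ps, ["g"])
        assert bg.E_d == 0.0 and bg.V_d == 0.0

    def test_all_masked_errors(self):
        ps = generate_promoters(2, 10, 0, 1.0, seed=5)
        with pytest.raises(BiasError, match="K = 0"):
            mn.bias_background(ps, ps.gene_ids)

    def test_empty_group_errors(self, unmasked_promoters):
        with pytest.raises(BiasError):
            mn.bias_background(unmasked_promoters, [])

    @settings(max_examples=20, derandomize=True)
    @given(M=st.integers(0, 300), N=st.integers(0, 300))
    def test_unmasked_closed_form(self, M, N):
        """E(d) = (M(M+1) + N(N+1)) / (2(M+N+1)) with no masking."""
        assume(M + N >= 1)
        ps = generate_promoters(3, M, N, 0.0, seed=6)
        bg = mn.bias_background(ps, ps.gene_ids)
        assert bg.E_d == pytest.approx(mn.unmasked_expected_distance(M, N))

    def test_monte_carlo_moments_match_background(self, two_promoter_set):
        """100k uniform single placements reproduce E(d), V(d) within 1%, masked or not."""
        rng = np.random.default_rng(17)
        for ps in (two_promoter_set, generate_promoters(4, 60, 15, 0.0, seed=7)):
            bg = mn.bias_background(ps, ps.gene_ids)
            d = np.abs(rng.choice(bg.positions, size=100_000, p=bg.k_i / bg.K))
            assert np.mean(d) == pytest.approx(bg.E_d, rel=0.01)
            assert np.var(d) == pytest.approx(bg.V_d, rel=0.01)


class TestBiasZ:
    def test_hand_case_z_four(self):
        bg = mn.BiasBackground(4, 0, np.array([2, 2, 2, 2, 2]), 10, E_d=2.0, V_d=2.0)
        stat = mn.bias_z(bg, hits_at([0] * 8))
        assert stat.z == pytest.approx(4.0)
        assert stat.n == 8 and stat.mean_abs_x == 0.0

    def test_null_centered_mean_gives_zero(self):
        bg = mn.BiasBackground(4, 0, np.array([2, 2, 2, 2, 2]), 10, E_d=2.0, V_d=2.0)
        stat = mn.bias_z(bg, hits_at([2] * 6))
        assert stat.z == 0.0

    def test_multiple_occurrences_per_promoter_all_counted(self):
        bg = mn.BiasBackground(9, 0, np.full(10, 3), 30, E_d=4.5, V_d=8.25)
        stat = mn.bias_z(bg, hits_at([1, 1, 2], gene="same") + hits_at([3, 4], gene="other"))
        assert stat.n == 5
        assert stat.mean_abs_x == pytest.approx(11 / 5)

    def test_too_few_occurrences_rejected(self):
        bg = mn.BiasBackground(4, 0, np.full(5, 2), 10, E_d=2.0, V_d=2.0)
        with pytest.raises(BiasError, match="min_occurrences"):
            mn.bias_z(bg, hits_at([0, 1]))
        with pytest.raises(BiasError, match="zero occurrences"):
            mn.bias_z(bg, [])

    def test_small_min_occurrences_warns(self):
        bg = mn.BiasBackground(4, 0, np.full(5, 2), 10, E_d=2.0, V_d=2.0)
        with pytest.warns(UserWarning, match="normal"):
            mn.bias_z(bg, hits_at([0, 1]), min_occurrences=2)

    def test_degenerate_variance_rejected(self):
        bg = mn.BiasBackground(0, 0, np.array([5]), 5, E_d=0.0, V_d=0.0)
        with pytest.raises(BiasError, match="V"):
            mn.bias_z(bg, hits_at([0] * 6))

    def test_null_monte_carlo_calibration(self):
        """Uniformly placed occurrences give Z with mean ~0 and sd ~1."""
        ps = generate_promoters(20, 1000, 0, 0.2, seed=8)
        bg = mn.bias_background(ps, ps.gene_ids)
        rng = np.random.default_rng(9)
        pos = rng.choice(bg.positions, size=(2000, 20), p=bg.k_i / bg.K)
        zs = np.array([mn.bias_z(bg, hits_at(np.abs(row))).z for row in pos])
        assert abs(zs.mean()) < 0.1
        assert 0.85 < zs.std() < 1.15


class TestNeighborhoodEnrichment:
    def test_exact_extreme_case(self):
        pop = [f"g{k}" for k in range(10)]
        motif = pop[:5]
        assert mn.neighborhood_enrichment(motif, motif, pop) == pytest.approx(1 / 252)

    def test_zero_overlap_gives_one(self):
        pop = [f"g{k}" for k in range(10)]
        assert mn.neighborhood_enrichment(pop[5:7], pop[:3], pop) <= 1.0
        assert mn.neighborhood_enrichment(pop[3:5], [], pop) == 1.0

    def test_matches_brute_force_on_random_small_cases(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            N = int(rng.integers(1, 31))
            pop = [f"g{k}" for k in range(N)]
            K = int(rng.integers(0, N + 1))
            m = int(rng.integers(1, N + 1))
            motif = list(rng.choice(pop, size=K, replace=False))
            group = list(rng.choice(pop, size=m, replace=False))
            k_obs = len(set(group) & set(motif))
            brute = sum(
                math.comb(K, k) * math.comb(N - K, m - k) / math.comb(N, m)
                for k in range(k_obs, min(m, K) + 1)
            )
            assert mn.neighborhood_enrichment(group, motif, pop) == pytest.approx(brute)

    def test_empty_population_rejected(self):
        with pytest.raises(BiasError):
            mn.neighborhood_enrichment([], [], [])


def biased_star_fixture(seed=20):
    """Star network: seed gene + 6 neighbors, all with TSS-proximal planted CCAATCAG."""
    ps = generate_promoters(8, 1000, 0, 0.0, seed=seed, gene_prefix="n")
    pwm = mn.PWM.from_consensus("CCAATCAG")
    members = ps.gene_ids[:7]
    planted, truth = plant_motif(ps, pwm, members, placement="tss_biased",
                                 per_gene_count=2, seed=seed + 1, scale=40)
    g = nx.Graph()
    for nb in members[1:]:
        g.add_edge(members[0], nb, weight=0.05)
    g.add_node(ps.gene_ids[7])
    net = CoexpressionNetwork(g, 0.04)
    threshold = mn.pwm_score_threshold(pwm, 4.0**-8)
    hits = mn.scan_promoters(planted, pwm, threshold)
    return net, planted, hits, members, pwm, threshold


class TestCallTargets:
    def test_planted_bias_fixture_calls_seed_and_neighbors(self):
        net, ps, hits, members, _, _ = biased_star_fixture()
        ts = mn.call_targets(net, ps, hits, z_cutoff=3.5, p_cutoff=1e-12)
        assert set(members) <= ts.targets
        genes_with_hits = {h.gene_id for h in hits}
        assert ts.targets <= genes_with_hits  # every target contains a hit

    def test_seed_without_motif_contributes_no_calls(self):
        ps = generate_promoters(7, 1000, 0, 0.0, seed=30, gene_prefix="n")
        pwm = mn.PWM.from_consensus("CCAATCAG")
        center, leaves = ps.gene_ids[0], ps.gene_ids[1:]
        planted, _ = plant_motif(ps, pwm, leaves, placement="tss_biased",
                                 per_gene_count=2, seed=31, scale=40)
        g = nx.Graph()
        for leaf in leaves:
            g.add_edge(center, leaf, weight=0.05)
        net = CoexpressionNetwork(g, 0.04)
        hits = mn.scan_promoters(planted, pwm, mn.pwm_score_threshold(pwm, 4.0**-8))
        assert center not in {h.gene_id for h in hits}
        # the center seed's group is full of motif genes with huge bias,
        # but the center itself lacks the motif; leaf seeds' 2-gene groups
        # carry too few occurrences and no enrichment signal
        ts = mn.call_targets(net, planted, hits, z_cutoff=3.5, p_cutoff=1e-6)
        called_via_center = [s for entries in ts.provenance.values()
                            for s, _ in entries if s == center]
        assert called_via_center == []

    def test_cutoffs_are_inclusive(self):
        net, ps, hits, members, _, _ = biased_star_fixture(seed=40)
        ts = mn.call_targets(net, ps, hits, z_cutoff=3.5, p_cutoff=1e-12)
        z_obs = max(nb.bias.z for nb in ts.neighborhoods if nb.bias is not None)
        at_tie = mn.call_targets(net, ps, hits, z_cutoff=z_obs, p_cutoff=1e-300)
        assert any(nb.called and nb.bias is not None and nb.bias.z == z_obs
                   for nb in at_tie.neighborhoods)

    def test_union_invariant_to_node_order(self):
        net, ps, hits, members, _, _ = biased_star_fixture(seed=50)
        reversed_graph = nx.Graph()
        for a, b, w in reversed(list(net.graph.edges(data="weight"))):
            reversed_graph.add_edge(b, a, weight=w)
        for n in net.graph.nodes:
            reversed_graph.add_node(n)
        ts1 = mn.call_targets(net, ps, hits)
        ts2 = mn.call_targets(CoexpressionNetwork(reversed_graph, 0.04), ps, hits)
        assert ts1.targets == ts2.targets

    def test_network_gene_without_promoter_rejected(self, unmasked_promoters):
        g = nx.Graph()
        g.add_edge("ghost_a", "ghost_b", weight=0.1)
        with pytest.raises(BiasError, match="ghost"):
            mn.call_targets(CoexpressionNetwork(g, 0.04), unmasked_promoters, [])


class TestPermutationFDR:
    def test_planted_fixture_low_fdr(self):
        net, ps, hits, members, pwm, threshold = biased_star_fixture(seed=60)
        res = mn.permutation_fdr(net, ps, pwm, threshold, z_cutoff=3.5,
                                 p_cutoff=1e-12, n_perm=10, seed=61)
        assert res.observed_count >= 7
        assert res.fdr <= 0.05

    def test_shuffle_preserves_mask_geometry_and_composition(self):
        ps = generate_promoters(10, 300, 50, 0.3, seed=62)
        rng = np.random.default_rng(63)
        for dinuc in (False, True):
            sh = mn.shuffle_promoters(ps, rng, preserve_mask=True, dinucleotide=dinuc)
            assert np.array_equal(sh.free_mask, ps.free_mask)
            for g in range(len(ps)):
                assert sorted(sh.sequences[g]) == sorted(ps.sequences[g])
                masked = ~ps.free_mask[g]
                orig = np.array(list(ps.sequences[g]))[masked]
                new = np.array(list(sh.sequences[g]))[masked]
                assert np.array_equal(orig, new)  # masked blocks untouched

    def test_full_shuffle_moves_masked_letters_too(self):
        ps = generate_promoters(5, 300, 0, 0.5, seed=64)
        rng = np.random.default_rng(65)
        sh = mn.shuffle_promoters(ps, rng, preserve_mask=False)
        moved = [sh.sequences[g] != ps.sequences[g] for g in range(5)]
        assert all(moved)

    def test_fdr_arithmetic_from_counts(self):
        """Mean permutation count over observed: 34/3062 -> 1.1%, 3/8048 -> 0.04%."""
        assert PermutationFDR.from_counts(3062, [34]).fdr * 100 == pytest.approx(1.1, abs=0.05)
        assert PermutationFDR.from_counts(8048, [3]).fdr * 100 == pytest.approx(0.04, abs=0.005)
        mixed = PermutationFDR.from_counts(100, [2, 4])
        assert mixed.fdr == pytest.approx(0.03)

    def test_zero_permutations_rejected(self):
        net, ps, hits, members, pwm, threshold = biased_star_fixture(seed=70)
        with pytest.raises(BiasError):
            mn.permutation_fdr(net, ps, pwm, threshold, n_perm=0)
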