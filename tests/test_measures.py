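"""Heterogeneity index, its normalization, and the comparison indices."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetdeg import extremal, generators, measures


class TestDegreeDistribution:
    def test_regular_graph_is_delta_function(self):
        dist = measures.degree_distribution(extremal.complete_graph(4))
        assert dist.support.tolist() == [3]
        assert dist.probs.tolist() == [1.0]

    def test_star_degree_multiset(self):
        dist = measures.degree_distribution(extremal.star_graph(50))
        assert dist.support.tolist() == [1, 49]
        assert np.allclose(dist.probs, [49 / 50, 1 / 50])

    def test_completely_heterogeneous_probabilities(self):
        # every degree has probability 1/N except k*, which has 2/N
        dist = measures.degree_distribution(extremal.complete_heterogeneous_graph(6))
        assert dist.support.tolist() == [1, 2, 3, 4, 5]
        assert np.allclose(dist.probs, [1 / 6, 1 / 6, 2 / 6, 1 / 6, 1 / 6])

    def test_isolated_nodes_contribute_degree_zero(self):
        g = nx.empty_graph(3)
        g.add_edge(0, 1)
        dist = measures.degree_distribution(g)
        assert dist.support.tolist() == [0, 1]

    def test_k_spectrum_examples(self):
        assert measures.k_spectrum(extremal.regular_graph(10, 4)) == [4]
        assert measures.k_spectrum(extremal.complete_heterogeneous_graph(7)) == [1, 2, 3, 4, 5, 6]
        assert measures.k_spectrum(extremal.star_graph(50)) == [1, 49]


class TestHeterogeneityIndex:
    @pytest.mark.parametrize("n,k", [(10, 4), (6, 5), (12, 3), (7, 2)])
    def test_regular_graphs_score_zero(self, n, k):
        assert measures.heterogeneity_index(extremal.regular_graph(n, k)) == 0.0
        assert measures.hm(extremal.regular_graph(n, k)) == 0.0

    def test_star50_hand_value(self):
        # two-term sum: (1 - 49/50)^2 + (1 - 1/50)^2, divided by 50
        expected = math.sqrt(((1 - 49 / 50) ** 2 + (1 - 1 / 50) ** 2) / 50)
        assert measures.heterogeneity_index(extremal.star_graph(50)) == pytest.approx(
            expected, abs=1e-15)

    def test_extremal_graph_matches_closed_form_n10(self):
        # term-by-term oracle over the N-1 support degrees
        n = 10
        h2 = ((n - 2) * (1 - 1 / n) ** 2 + (1 - 2 / n) ** 2) / n
        g = extremal.complete_heterogeneous_graph(n)
        assert measures.heterogeneity_index(g) == pytest.approx(math.sqrt(h2), abs=1e-15)
        assert measures.h_het_closed_form(n) == pytest.approx(math.sqrt(0.712), abs=1e-12)

    def test_h_het_monotone_increasing_and_below_one(self):
        vals = [measures.h_het_closed_form(n) for n in range(4, 200)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(v < 1 for v in vals)
        assert measures.h_het_closed_form(10**9) == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("n", [3, 2, 1])
    def test_normalization_undefined_below_four_nodes(self, n):
        with pytest.raises(ValueError):
            measures.h_het_closed_form(n)
        with pytest.raises(ValueError):
            measures.hm(nx.path_graph(n))

    def test_hm_is_one_on_extremal_graphs(self):
        for n in (4, 9, 25, 60):
            g = extremal.complete_heterogeneous_graph(n)
            assert measures.hm(g) == pytest.approx(1.0, abs=1e-12)

    def test_star_hm_between_regular_and_scale_free(self):
        # topology ordering at N=50: regular < star < scale-free < extremal
        star = measures.hm(extremal.star_graph(50))
        sf = measures.hm(generators.barabasi_albert(50, 2, seed=0))
        assert 0.0 < star < sf < 1.0

    def test_diversity_monotonicity(self):
        # enlarging the degree support while pushing shared P(k) toward 0
        # must increase h: complete < star < star plus one leaf-leaf edge
        n = 10
        star = extremal.star_graph(n)
        star_plus = star.copy()
        star_plus.add_edge(1, 2)
        hs = [measures.heterogeneity_index(g)
              for g in (extremal.complete_graph(n), star, star_plus)]
        assert hs[0] < hs[1] < hs[2]


class TestComparisonIndices:
    def test_variance_hand_values(self, path3):
        assert measures.variance_heterogeneity(path3) == pytest.approx(2 / 9)
        assert measures.variance_heterogeneity(extremal.star_graph(4)) == pytest.approx(0.75)
        assert measures.variance_heterogeneity(extremal.regular_graph(8, 3)) == 0.0

    def test_albertson_hand_values(self, path3):
        assert measures.albertson_index(path3) == 2
        assert measures.albertson_index(extremal.star_graph(4)) == 6
        assert measures.albertson_index(extremal.regular_graph(8, 3)) == 0

    @pytest.mark.parametrize("n", [3, 10, 57, 100])
    def test_estrada_star_normalization_is_exactly_one(self, n):
        rho, rho_n = measures.estrada_heterogeneity(extremal.star_graph(n))
        assert rho == pytest.approx(n - 2 * math.sqrt(n - 1), rel=1e-12)
        assert rho_n == pytest.approx(1.0, abs=1e-12)

    def test_estrada_regular_graph_is_zero(self):
        rho, rho_n = measures.estrada_heterogeneity(extremal.regular_graph(10, 4))
        assert rho == 0.0 and rho_n == 0.0

    def test_estrada_scale_free_order_of_magnitude(self):
        # a typical scale-free network scores roughly a tenth of the star
        _, rho_n = measures.estrada_heterogeneity(generators.barabasi_albert(2000, 2, seed=1))
        assert 0.03 < rho_n < 0.3

    def test_randic_hand_values(self, path3):
        assert measures.randic_index(path3) == pytest.approx(2 / math.sqrt(2))
        assert measures.randic_index(extremal.star_graph(50)) == pytest.approx(math.sqrt(49))
        assert measures.randic_index(extremal.complete_graph(6)) == pytest.approx(3.0)

    def test_isolated_nodes_rejected_where_inverse_degree_needed(self):
        g = nx.empty_graph(4)
        g.add_edge(0, 1)
        with pytest.raises(ValueError):
            measures.estrada_heterogeneity(g)
        with pytest.raises(ValueError):
            measures.randic_index(g)

    def test_randic_bounds_on_random_graphs(self):
        # sqrt(N-1) <= R <= N/2 across many generator draws
        for seed in range(300):
            g = generators.erdos_renyi(30, 0.2, seed=seed)
            g.remove_nodes_from(list(nx.isolates(g)))
            n = g.number_of_nodes()
            if n < 3:
                continue
            r = measures.randic_index(g)
            assert math.sqrt(n - 1) - 1e-9 <= r <= n / 2 + 1e-9


class TestInvariances:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), n=st.integers(5, 40))
    def test_permutation_invariance(self, seed, n):
        g = generators.erdos_renyi(n, 0.3, seed=seed)
        rng = np.random.default_rng(seed)
        perm = dict(zip(g.nodes(), rng.permutation(n).tolist()))
        h = nx.relabel_nodes(g, perm)
        assert measures.heterogeneity_index(h) == pytest.approx(
            measures.heterogeneity_index(g), abs=1e-14)
        assert measures.variance_heterogeneity(h) == pytest.approx(
            measures.variance_heterogeneity(g), abs=1e-12)
        assert measures.albertson_index(h) == measures.albertson_index(g)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_hm_in_unit_interval_for_generator_output(self, seed):
        g = generators.erdos_renyi(50, 0.15, seed=seed)
        assert 0.0 <= measures.hm(g) <= 1.0

    def test_report_collects_all_indices(self, star50):
        rep = measures.report(star50)
        assert rep.estrada_rho_n == pytest.approx(1.0)
        assert rep.hm == pytest.approx(
            measures.heterogeneity_index(star50) / measures.h_het_closed_form(50))

    def test_report_small_graph_has_nan_normalization(self, path3):
        rep = measures.report(path3)
        assert math.isnan(rep.hm) and math.isnan(rep.h_het)
        assert rep.h > 0
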