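"""Correlation network, cohesiveness clustering, KS test, group means."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from osptm.netstats import (
    cluster_cohesive,
    cohesiveness,
    correlation_network,
    group_average,
    ks_two_sample,
)
from osptm.simulate import planted_response_matrix


def _clique(graph, labels, weight=1.0):
    for u, v in itertools.combinations(labels, 2):
        graph.add_edge(u, v, weight=weight)


class TestCorrelationNetwork:
    def test_identical_profiles_edge_weight_one(self):
        m = pd.DataFrame([[1, 2, 3, 4], [2, 4, 6, 8]], index=["a", "b"])
        g = correlation_network(m)
        assert g["a"]["b"]["weight"] == pytest.approx(1.0)

    def test_uncorrelated_profiles_no_edge(self):
        m = pd.DataFrame([[1, -1, 1, -1], [1, 1, -1, -1]], index=["a", "b"])
        g = correlation_network(m)
        assert not g.has_edge("a", "b")

    def test_negative_correlation_never_makes_edges(self):
        m = pd.DataFrame([[1, 2, 3, 4], [4, 3, 2, 1]], index=["a", "b"])
        assert correlation_network(m).number_of_edges() == 0

    def test_zero_variance_rows_excluded(self):
        m = pd.DataFrame([[1, 1, 1, 1], [1, 2, 3, 4]], index=["flat", "b"])
        g = correlation_network(m)
        assert "flat" not in g

    def test_matches_all_pairs_oracle(self):
        """Edge set equals a brute-force all-pairs Pearson scan on a
        50-site matrix."""
        rng = np.random.default_rng(20)
        m = pd.DataFrame(rng.normal(size=(50, 9)), index=[f"s{i}" for i in range(50)])
        g = correlation_network(m, r_min=0.5)
        expected = set()
        for i, j in itertools.combinations(range(50), 2):
            r = np.corrcoef(m.iloc[i], m.iloc[j])[0, 1]
            if r > 0.5:
                expected.add((f"s{i}", f"s{j}"))
        got = {tuple(sorted(e)) for e in g.edges}
        assert got == {tuple(sorted(e)) for e in expected}


class TestCohesiveness:
    def test_isolated_5_clique_is_exactly_half(self):
        """W_in = 10, no boundary: f = 10 / (10 + 0 + 2*5) = 0.5."""
        g = nx.Graph()
        _clique(g, range(5))
        assert cohesiveness(g, set(range(5)), penalty=2.0) == pytest.approx(0.5)

    def test_boundary_weight_lowers_score(self):
        g = nx.Graph()
        _clique(g, range(5))
        g.add_edge(0, 99, weight=1.0)
        assert cohesiveness(g, set(range(5)), penalty=2.0) == pytest.approx(10 / 21)


class TestClustering:
    def test_two_disjoint_cliques_recovered_exactly(self):
        g = nx.Graph()
        _clique(g, [f"a{i}" for i in range(6)])
        _clique(g, [f"b{i}" for i in range(6)])
        clusters = cluster_cohesive(g, min_size=5)
        assert len(clusters) == 2
        members = sorted(sorted(c.members) for c in clusters)
        assert members == [sorted(f"a{i}" for i in range(6)), sorted(f"b{i}" for i in range(6))]
        # fully separated clusters: maximal significance
        assert all(c.p_value == 0.0 for c in clusters)

    def test_small_clusters_discarded(self):
        g = nx.Graph()
        _clique(g, range(4))
        assert cluster_cohesive(g, min_size=5) == []

    def test_empty_graph(self):
        assert cluster_cohesive(nx.Graph()) == []

    def test_deterministic(self):
        m, _ = planted_response_matrix(seed=21)
        g = correlation_network(m)
        a = cluster_cohesive(g)
        b = cluster_cohesive(g)
        assert [c.members for c in a] == [c.members for c in b]

    def test_planted_modules_recovered(self):
        """Both anti-correlated planted modules are recovered with
        Jaccard >= 0.7 on average across replicate matrices, with the
        planted response signs."""
        jaccards = []
        for seed in range(5):
            m, truth = planted_response_matrix(seed=seed)
            clusters = cluster_cohesive(correlation_network(m))
            hfd12 = [c for c in m.columns if c.startswith("HFD12")]
            ctrl = [c for c in m.columns if c.startswith("control")]
            contrast = m[hfd12].mean(axis=1) - m[ctrl].mean(axis=1)
            for mi, sign in ((0, -1), (1, +1)):
                best = max(
                    clusters,
                    key=lambda c: len(c.members & truth[mi]) / len(c.members | truth[mi]),
                )
                jaccards.append(len(best.members & truth[mi]) / len(best.members | truth[mi]))
                assert np.sign(contrast.loc[sorted(best.members)].mean()) == sign
        assert np.mean(jaccards) >= 0.7

    def test_pipeline_cluster_signs_match_planted_modules(self, default_dataset, default_analysis):
        """On the full synthetic experiment the two clusters best
        matching the planted modules respond in the planted directions
        and are significant."""
        from conftest import truth_site_label

        _, _, truth, _ = default_dataset
        res = default_analysis
        contrast = res.group_means["HFD12_vs_control"]
        for mi, sign in ((0, -1), (1, +1)):
            members = {
                truth_site_label(s, res) for s in truth.sites if s.module == mi
            }
            best = max(
                res.clusters,
                key=lambda c: len(c.members & members) / len(c.members | members),
            )
            overlap = len(best.members & members) / len(members)
            assert overlap >= 0.8  # most module sites land in one cluster
            mean = contrast.loc[[m for m in best.members if m in contrast.index]].mean()
            assert np.sign(mean) == sign
            assert best.p_value < 0.05


class TestKS:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports_exact_p(self):
        """D = 1; under label exchange only 2 of C(10,5) arrangements
        reach it, so the exact p-value is 2/252."""
        d, p = ks_two_sample([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert d == 1.0
        assert p == pytest.approx(2 / math.comb(10, 5), rel=1e-6)

    def test_too_small_sample_errors(self):
        with pytest.raises(ValueError):
            ks_two_sample([1.0], [1, 2, 3])

    def test_planted_cluster_contrast_detected(self):
        """Group-averaged values of planted module members differ from
        the all-site background."""
        m, truth = planted_response_matrix(seed=22)
        hfd12 = [c for c in m.columns if c.startswith("HFD12")]
        ctrl = [c for c in m.columns if c.startswith("control")]
        contrast = m[hfd12].mean(axis=1) - m[ctrl].mean(axis=1)
        _, p = ks_two_sample(contrast.loc[sorted(truth[0])], contrast)
        assert p < 0.05


class TestGroupAverage:
    DESIGN = {f"{g}_{r}": g for g in ("control", "HFD3", "HFD12") for r in (1, 2, 3)}

    def test_identical_replicates_mean_is_value(self):
        m = pd.DataFrame(
            [[1.0, 1.0, 1.0, 2.0, 2.0, 2.0, 3.0, 3.0, 3.0]],
            index=["a"], columns=list(self.DESIGN),
        )
        out = group_average(m, self.DESIGN, control="control")
        assert out.loc["a", "control"] == 1.0
        assert out.loc["a", "HFD12"] == 3.0
        assert out.loc["a", "HFD12_vs_control"] == 2.0

    def test_matches_independent_tally(self):
        rng = np.random.default_rng(23)
        m = pd.DataFrame(
            rng.normal(size=(10, 9)), index=[f"s{i}" for i in range(10)],
            columns=list(self.DESIGN),
        )
        out = group_average(m, self.DESIGN)
        for g in ("control", "HFD3", "HFD12"):
            cols = [s for s, gg in self.DESIGN.items() if gg == g]
            np.testing.assert_allclose(out[g], m[cols].mean(axis=1))

    def test_unknown_control_errors(self):
        m = pd.DataFrame([[1.0] * 9], index=["a"], columns=list(self.DESIGN))
        with pytest.raises(ValueError):
            group_average(m, self.DESIGN, control="nope")

    def test_empty_design_errors(self):
        m = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["x", "y"])
        with pytest.raises(ValueError):
            group_average(m, {})
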