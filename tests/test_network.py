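import itertools

import networkx as nx
import numpy as np
import pytest

from haplokit.distance import DistanceMatrix, hamming_matrix
from haplokit.haplotype import Haplotype, HaplotypeSet
from haplokit.network import build_network, mst_total_weight
from haplokit.seqio import Alignment, PopulationMap


def dm(labels, values):
    return DistanceMatrix(labels=list(labels), values=np.array(values, float))


def toy_hs(ids, counts=None):
    counts = counts or [1] * len(ids)
    haps = [
        Haplotype(id=h, sequence=f"S{i}", members=[f"{h}m{j}" for j in range(c)])
        for i, (h, c) in enumerate(zip(ids, counts))
    ]
    return HaplotypeSet(haplotypes=haps, n_samples=sum(counts))


def brute_force_mst_weight(values):
    """Exhaustive minimum over all spanning trees (oracle for <=6 nodes)."""
    k = len(values)
    edges = [(i, j) for i in range(k) for j in range(i + 1, k)]
    best = None
    for combo in itertools.combinations(edges, k - 1):
        g = nx.Graph(combo)
        if g.number_of_nodes() == k and nx.is_connected(g):
            w = sum(values[i][j] for i, j in combo)
            best = w if best is None else min(best, w)
    return best


class TestBuildNetwork:
    def test_two_haplotypes_single_link(self):
        net = build_network(dm(["H1", "H2"], [[0, 3], [3, 0]]), toy_hs(["H1", "H2"]))
        assert [(l.u, l.v, l.weight, l.kind) for l in net.links] == [
            ("H1", "H2", 3, "mst")
        ]
        assert mst_total_weight(net) == 3

    def test_triangle_with_unique_mst(self):
        # distances (1,1,2): both weight-1 links kept, weight-2 pair absent
        net = build_network(
            dm(["A", "B", "C"], [[0, 1, 2], [1, 0, 1], [2, 1, 0]]),
            toy_hs(["A", "B", "C"]),
        )
        assert {(l.u, l.v) for l in net.mst_links} == {("A", "B"), ("B", "C")}
        assert net.alternative_links == []

    def test_equilateral_triangle_gains_alternative(self):
        net = build_network(
            dm(["A", "B", "C"], [[0, 1, 1], [1, 0, 1], [1, 1, 0]]),
            toy_hs(["A", "B", "C"]),
        )
        assert len(net.mst_links) == 2
        assert len(net.alternative_links) == 1
        assert net.alternative_links[0].weight == 1

    def test_alt_threshold_adds_links(self, ref_hs):
        d = hamming_matrix(list(zip(ref_hs.ids, ref_hs.sequences)))
        base = build_network(d, ref_hs)
        widened = build_network(d, ref_hs, alt_threshold=3)
        assert len(widened.links) > len(base.links)
        assert {(l.u, l.v) for l in widened.mst_links} == {
            (l.u, l.v) for l in base.mst_links
        }
        extra = {(l.u, l.v) for l in widened.alternative_links}
        for l in widened.alternative_links:
            assert l.weight <= 3 or (l.u, l.v) in {
                (a.u, a.v) for a in base.alternative_links
            }

    def test_non_integer_distances_rejected(self, ref_hs):
        with pytest.raises(ValueError):
            build_network(
                dm(["H1", "H2"], [[0, 1.5], [1.5, 0]]), toy_hs(["H1", "H2"])
            )

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_network(dm(["X", "Y"], [[0, 1], [1, 0]]), toy_hs(["H1", "H2"]))

    def test_level_requires_population_map(self):
        with pytest.raises(ValueError):
            build_network(
                dm(["H1", "H2"], [[0, 1], [1, 0]]),
                toy_hs(["H1", "H2"]),
                level="population",
            )


class TestMSTProperties:
    @pytest.mark.parametrize("k", [3, 4, 5, 6])
    def test_total_weight_matches_exhaustive_minimum(self, k):
        rng = np.random.default_rng(50 + k)
        for rep in range(15):
            w = rng.integers(1, 12, size=(k, k))
            values = np.triu(w, 1)
            values = values + values.T
            net = build_network(
                dm([f"H{i+1}" for i in range(k)], values),
                toy_hs([f"H{i+1}" for i in range(k)]),
            )
            assert mst_total_weight(net) == brute_force_mst_weight(values.tolist())

    @pytest.mark.parametrize("k", [4, 5, 6])
    def test_cycle_property(self, k):
        # no non-tree pair may beat the heaviest edge on its tree path
        rng = np.random.default_rng(80 + k)
        for rep in range(10):
            w = rng.integers(1, 12, size=(k, k))
            values = np.triu(w, 1)
            values = values + values.T
            ids = [f"H{i+1}" for i in range(k)]
            net = build_network(dm(ids, values), toy_hs(ids))
            g = nx.Graph()
            for l in net.mst_links:
                g.add_edge(l.u, l.v, weight=l.weight)
            for i, a in enumerate(ids):
                for b in ids[i + 1 :]:
                    if g.has_edge(a, b):
                        continue
                    path = nx.shortest_path(g, a, b)
                    heaviest = max(
                        g[u][v]["weight"] for u, v in zip(path, path[1:])
                    )
                    assert values[ids.index(a)][ids.index(b)] >= heaviest

    def test_reference_matrix_total_weight_anchor(self, ref_hs, ref_hamming):
        # regression anchor, verified against an exhaustive/independent MST
        net = build_network(ref_hamming, ref_hs)
        assert mst_total_weight(net) == 96
        g = nx.Graph()
        k = ref_hamming.k
        for i in range(k):
            for j in range(i + 1, k):
                g.add_edge(
                    ref_hamming.labels[i],
                    ref_hamming.labels[j],
                    weight=ref_hamming.values[i, j],
                )
        t = nx.minimum_spanning_tree(g)
        assert sum(d["weight"] for _, _, d in t.edges(data=True)) == 96

    def test_spanning_tree_shape(self, ref_hs, ref_hamming):
        net = build_network(ref_hamming, ref_hs)
        assert len(net.mst_links) == ref_hamming.k - 1
        g = nx.Graph((l.u, l.v) for l in net.mst_links)
        assert nx.is_tree(g)
        for l in net.links:
            assert l.weight == ref_hamming.get(l.u, l.v)

    def test_deterministic_under_label_reordering(self, ref_hs, ref_hamming):
        perm = np.random.default_rng(3).permutation(ref_hamming.k)
        shuffled = DistanceMatrix(
            labels=[ref_hamming.labels[i] for i in perm],
            values=ref_hamming.values[np.ix_(perm, perm)],
            metric="hamming",
        )
        a = build_network(ref_hamming, ref_hs)
        b = build_network(shuffled, ref_hs)
        assert {(l.u, l.v, l.weight, l.kind) for l in a.links} == {
            (l.u, l.v, l.weight, l.kind) for l in b.links
        }


class TestComposition:
    def test_sizes_and_compositions_match_frequency_matrix(self, cytb_hs, cytb_pm, cytb_vst):
        from haplokit.haplotype import population_matrix

        d = hamming_matrix(list(zip(cytb_hs.ids, cytb_vst.states)))
        net = build_network(d, cytb_hs, cytb_pm, level="population")
        mat = population_matrix(cytb_hs, cytb_pm, "population")
        assert sum(net.sizes.values()) == cytb_hs.n_samples
        for h in cytb_hs.ids:
            assert net.sizes[h] == mat.loc[h].sum()
            assert net.compositions[h] == {
                p: int(c) for p, c in mat.loc[h].items() if c > 0
            }

    def test_group_level_composition(self, cytb_hs, cytb_pm, cytb_vst):
        d = hamming_matrix(list(zip(cytb_hs.ids, cytb_vst.states)))
        net = build_network(d, cytb_hs, cytb_pm, level="group")
        assert set(net.categories()) <= {"greenhouse", "firm", "nature"}
        totals = {}
        for comp in net.compositions.values():
            for g, c in comp.items():
                totals[g] = totals.get(g, 0) + c
        assert totals == {"greenhouse": 45, "firm": 15, "nature": 60}

    def test_individual_level_slices(self, ref_hs):
        d = hamming_matrix(list(zip(ref_hs.ids, ref_hs.sequences)))
        net = build_network(d, ref_hs, level="individual")
        h11 = net.compositions["H11"]
        assert sum(h11.values()) == 55 and all(v == 1 for v in h11.values())
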