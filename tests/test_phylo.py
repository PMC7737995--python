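import io
import re

import dendropy
import numpy as np
import pytest

from haplokit.distance import DistanceMatrix, hamming_matrix
from haplokit.phylo import (
    Tree,
    bin_support,
    bipartitions,
    bootstrap_support,
    nj_tree,
    write_newick,
)
from haplokit.seqio import Alignment


def dm(labels, values):
    return DistanceMatrix(labels=list(labels), values=np.array(values, float))


def random_additive(rng, n):
    """Independent oracle: distances generated directly as path lengths
    on a random binary tree with continuous branch lengths (tie-free)."""
    clusters = [{f"T{i}": 0.0} for i in range(n)]
    splits = set()
    D = {}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        e1, e2 = rng.uniform(0.5, 2.0, size=2)
        c1, c2 = clusters[i], clusters[j]
        for t1, d1 in c1.items():
            for t2, d2 in c2.items():
                D[frozenset((t1, t2))] = d1 + e1 + d2 + e2
        merged = {t: d + e1 for t, d in c1.items()}
        merged.update({t: d + e2 for t, d in c2.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        if 2 <= len(merged) <= n - 2:
            splits.add(frozenset(merged))
    labels = sorted(clusters[0])
    values = [
        [0.0 if a == b else D[frozenset((a, b))] for b in labels] for a in labels
    ]
    anchor = min(labels)
    all_taxa = frozenset(labels)
    canon = {s if anchor not in s else all_taxa - s for s in splits}
    canon = {s for s in canon if 2 <= len(s) <= n - 2}
    return dm(labels, values), canon


def dendropy_nj_splits(d: DistanceMatrix):
    """Independent NJ implementation used as a topology cross-check."""
    csv = "," + ",".join(d.labels) + "\n"
    for i, lab in enumerate(d.labels):
        csv += lab + "," + ",".join(str(v) for v in d.values[i]) + "\n"
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        io.StringIO(csv), delimiter=","
    )
    tree = pdm.nj_tree()
    return _dendropy_splits(tree, d.labels)


def _dendropy_splits(tree, labels):
    anchor = min(labels)
    all_taxa = frozenset(labels)
    out = set()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if 2 <= len(below) <= len(labels) - 2:
            out.add(below if anchor not in below else all_taxa - below)
    return out


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        t = nj_tree(dm("ABC", [[0, 3, 4], [3, 0, 5], [4, 5, 0]]))
        lengths = {c.name: c.length for c in t.root.children}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_two_taxa_single_edge(self):
        t = nj_tree(dm("AB", [[0, 0.4], [0.4, 0]]))
        assert t.tip_distances().get("A", "B") == pytest.approx(0.4)
        assert write_newick(t) == "(A:0.2,B:0.2);"

    def test_four_taxon_additive_example(self):
        d = dm(
            "ABCD",
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
        )
        t = nj_tree(d)
        assert set(bipartitions(t).values()) == {frozenset({"C", "D"})}
        paths = t.tip_distances()
        for i, a in enumerate(d.labels):
            for j, b in enumerate(d.labels):
                assert paths.get(a, b) == pytest.approx(d.values[i, j], abs=1e-12)

    def test_unrooted_binary_internal_degree(self, rng):
        d, _ = random_additive(rng, 8)
        t = nj_tree(d)
        # root is the basal trifurcation, all other internal nodes binary
        assert len(t.root.children) == 3
        for n in t.internal_nodes():
            if n is not t.root:
                assert len(n.children) == 2

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_recovers_additive_matrices(self, n):
        rng = np.random.default_rng(100 + n)
        for rep in range(20):
            d, true_splits = random_additive(rng, n)
            t = nj_tree(d)
            assert set(bipartitions(t).values()) == true_splits
            paths = t.tip_distances()
            reordered = paths.to_dataframe().loc[d.labels, d.labels].values
            assert np.allclose(reordered, d.values, atol=1e-9)

    def test_agrees_with_independent_nj_on_noisy_matrix(self, rng):
        d, _ = random_additive(rng, 7)
        noisy = d.values + rng.uniform(0, 0.05, d.values.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        nd = dm(d.labels, noisy)
        assert set(bipartitions(nj_tree(nd)).values()) == dendropy_nj_splits(nd)

    def test_label_order_invariance(self, rng):
        d, _ = random_additive(rng, 6)
        perm = rng.permutation(len(d.labels))
        pd_ = dm(
            [d.labels[i] for i in perm],
            d.values[np.ix_(perm, perm)],
        )
        assert set(bipartitions(nj_tree(d)).values()) == set(
            bipartitions(nj_tree(pd_)).values()
        )

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(dm("A", [[0]]))

    def test_clamp_negative_flag(self):
        # a strongly non-additive matrix can yield a negative branch
        d = dm("ABCD", [[0, 1, 9, 9], [1, 0, 1, 9], [9, 1, 0, 1], [9, 9, 1, 0]])
        t = nj_tree(d, clamp_negative=True)

        def all_lengths(node):
            for c in node.children:
                yield c.length
                yield from all_lengths(c)

        assert all(l >= 0 for l in all_lengths(t.root))


def split_alignment():
    """Two tip pairs separated by 20 homoplasy-free fixed differences."""
    cols = []
    cols += [("A", "A", "C", "C")] * 20  # the only informative signal
    cols += [("G", "T", "G", "G")]  # distinguish A1/A2
    cols += [("G", "G", "G", "T")]  # distinguish B1/B2
    cols += [("A", "A", "A", "A")] * 20
    seqs = ["".join(c[i] for c in cols) for i in range(4)]
    return Alignment(labels=["A1", "A2", "B1", "B2"], sequences=seqs)


class TestBootstrap:
    def test_homoplasy_free_split_gets_full_support(self):
        t = bootstrap_support(split_alignment(), B=100, seed=7, model="hamming")
        bps = bipartitions(t)
        supports = {
            tuple(sorted(bp)): node.support
            for node in t.internal_nodes()
            for key, bp in bps.items()
            if key == id(node)
        }
        assert supports[("B1", "B2")] == 100

    def test_same_seed_reproduces_supports(self):
        t1 = bootstrap_support(split_alignment(), B=50, seed=3)
        t2 = bootstrap_support(split_alignment(), B=50, seed=3)
        s1 = [n.support for n in t1.internal_nodes()]
        s2 = [n.support for n in t2.internal_nodes()]
        assert s1 == s2

    def test_single_replicate_pigeonhole(self):
        t = bootstrap_support(split_alignment(), B=1, seed=0)
        for n in t.internal_nodes():
            if n.support is not None:
                assert n.support in (0, 100)

    def test_signal_free_alignment_has_uncertain_edges(self):
        rng = np.random.default_rng(11)
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(6)]
        al = Alignment(labels=[f"s{i}" for i in range(6)], sequences=seqs)
        t = bootstrap_support(al, B=100, seed=1)
        supports = [n.support for n in t.internal_nodes() if n.support is not None]
        assert supports and min(supports) < 100

    def test_supports_within_range(self):
        t = bootstrap_support(split_alignment(), B=25, seed=5)
        for n in t.internal_nodes():
            if n.support is not None:
                assert 0 <= n.support <= 100


class TestBinSupport:
    @pytest.mark.parametrize(
        "s,expected",
        [(90, "strong"), (86, "strong"), (85, "moderate"), (71, "moderate"),
         (70, "weak"), (51, "weak"), (50, "poor"), (0, "poor")],
    )
    def test_cut_style_intervals(self, s, expected):
        assert bin_support(s) == expected

    def test_text_convention_differs_at_boundaries(self):
        assert bin_support(85, convention="text") == "strong"
        assert bin_support(70, convention="text") == "moderate"
        assert bin_support(50, convention="text") == "poor"

    def test_monotone_total_step_function(self):
        order = {"poor": 0, "weak": 1, "moderate": 2, "strong": 3}
        cats = [order[bin_support(s)] for s in range(101)]
        assert cats == sorted(cats)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_support(101)


class TestNewick:
    def test_support_emitted_as_internal_label(self):
        t = bootstrap_support(split_alignment(), B=10, seed=0)
        nwk = write_newick(t)
        sup = [n.support for n in t.internal_nodes() if n.support is not None]
        for s in sup:
            assert re.search(rf"\){s}:", nwk)

    def test_metacharacter_labels_are_quoted(self):
        d = dm(["Bayatbadem 24", "Kumluca_6"], [[0, 1], [1, 0]])
        nwk = write_newick(nj_tree(d))
        assert "'Bayatbadem 24'" in nwk and "'Kumluca_6'" in nwk

    def test_round_trip_preserves_splits_and_lengths(self, rng):
        d, _ = random_additive(rng, 10)
        t = nj_tree(d)
        parsed = dendropy.Tree.get(
            data=write_newick(t), schema="newick",
            suppress_internal_node_taxa=True, preserve_underscores=True,
        )
        assert _dendropy_splits(parsed, d.labels) == set(bipartitions(t).values())
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in parsed.taxon_namespace}
        mine = t.tip_distances()
        for a in d.labels:
            for b in d.labels:
                if a == b:
                    continue
                assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                    mine.get(a, b), abs=1e-8
                )
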