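"""Distance matrices, neighbor joining, midpoint rooting, bootstrap."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix

from helpers_oracles import best_additive_topology
from phenoscreen.families import MultipleAlignment
from phenoscreen.phylo import (
    _bipartitions,
    bootstrap_support,
    kimura_correction,
    midpoint_root,
    nj_tree,
    protein_distance,
)
from phenoscreen.simulate import FamilySimSpec, evolve_family

AA = "ACDEFGHIKLMNPQRSTVWY"


def _aln(rows, family_id="fam"):
    return MultipleAlignment(
        rows=tuple((f"s{i}", r) for i, r in enumerate(rows)) if isinstance(rows, list)
        else rows,
        family_id=family_id,
    )


def _random_additive_dm(labels, rng):
    """Distances from a random binary tree with positive branch lengths."""
    import itertools

    # build a random tree as nested sets with edge lengths
    nodes = [frozenset([x]) for x in labels]
    parent_len = {}
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        merged = a | b
        parent_len[a] = float(rng.uniform(0.5, 3.0))
        parent_len[b] = float(rng.uniform(0.5, 3.0))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    for n in nodes:
        parent_len[n] = float(rng.uniform(0.5, 3.0))
    # leaf-to-leaf distance = sum of lengths of edges separating them
    edges = list(parent_len.items())
    dist = {a: {b: 0.0 for b in labels} for a in labels}
    for p, q in itertools.combinations(labels, 2):
        d = sum(
            ln for side, ln in edges if (p in side) != (q in side)
        )
        dist[p][q] = dist[q][p] = d
    return dist


def _canonical(bp, all_labels):
    ref = min(all_labels)
    return frozenset(all_labels) - bp if ref in bp else bp


class TestProteinDistance:
    def test_identical_rows_zero(self):
        dm = protein_distance(_aln(["MKVLW" * 4, "MKVLW" * 4]))
        assert dm[0, 1] == 0.0

    def test_kimura_closed_form(self):
        # D = 0.10 -> d = -ln(1 - 0.10 - 0.2*0.01)
        expected = -math.log(1 - 0.10 - 0.2 * 0.01)
        assert kimura_correction(0.10) == pytest.approx(expected, rel=1e-12)
        row = "A" * 10
        other = "C" + "A" * 9  # one difference in ten columns
        dm = protein_distance(_aln([row, other]))
        assert dm[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_domain_overflow_hits_ceiling(self):
        assert kimura_correction(0.99, ceiling=5.0) == 5.0

    def test_symmetry_and_zero_diagonal(self, rng):
        rows = ["".join(rng.choice(list(AA), 30)) for _ in range(4)]
        dm = protein_distance(_aln(rows))
        m = dm.data
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0)

    def test_no_comparable_columns_names_pair(self):
        with pytest.raises(ValueError, match="s0.*s1"):
            protein_distance(_aln(["A--", "-CC", "ACC"]))


class TestNJTree:
    def test_recovers_additive_4_and_5_taxon_matrices(self, rng):
        for n in (4, 5):
            for _ in range(10):
                labels = [f"t{i}" for i in range(n)]
                dist = _random_additive_dm(labels, rng)
                res, true_top, _ = best_additive_topology(labels, dist)
                assert res < 1e-18  # matrix really is additive
                dm = DistanceMatrix(
                    np.array([[dist[a][b] for b in labels] for a in labels]),
                    labels,
                )
                tree = nj_tree(dm)
                got = {_canonical(bp, labels) for bp in _bipartitions(tree)}
                want = {_canonical(bp, labels) for bp in true_top}
                assert got == want
                # additive data: path lengths reproduce the input distances
                for i, a in enumerate(labels):
                    for b in labels[i + 1 :]:
                        assert tree.find(a).distance(
                            tree.find(b)
                        ) == pytest.approx(dist[a][b], abs=1e-9)

    def test_two_labels_single_edge(self):
        dm = DistanceMatrix(np.array([[0.0, 0.8], [0.8, 0.0]]), ["a", "b"])
        tree = nj_tree(dm)
        assert tree.find("a").distance(tree.find("b")) == pytest.approx(0.8)

    def test_simulated_tree_recovered(self, rng):
        # ultrametric distances from a known 4-taxon tree
        labels = ["a", "b", "c", "d"]
        # ((a,b),(c,d)): within-cherry 2.0, across 6.0
        m = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], float
        )
        tree = nj_tree(DistanceMatrix(m, labels))
        bps = {_canonical(bp, labels) for bp in _bipartitions(tree)}
        assert bps == {frozenset(["c", "d"])}


class TestMidpointRoot:
    def _depths(self, tree):
        return [tree.find(t.name).accumulate_to_ancestor(tree) for t in tree.tips()]

    def test_symmetric_tree_balances(self):
        labels = ["a", "b", "c", "d"]
        m = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], float
        )
        rooted = midpoint_root(nj_tree(DistanceMatrix(m, labels)))
        depths = sorted(self._depths(rooted), reverse=True)
        assert depths[0] == pytest.approx(depths[1], abs=1e-9)
        assert depths[0] == pytest.approx(3.0, abs=1e-9)

    def test_caterpillar_roots_on_long_terminal_branch(self, rng):
        labels = ["a", "b", "c", "d"]
        dist = _random_additive_dm(labels, rng)
        for k in labels[1:]:
            dist["a"][k] += 50.0
            dist[k]["a"] += 50.0
        dm = DistanceMatrix(
            np.array([[dist[x][y] for y in labels] for x in labels]), labels
        )
        rooted = midpoint_root(nj_tree(dm))
        depths = sorted(self._depths(rooted), reverse=True)
        assert depths[0] == pytest.approx(depths[1], abs=1e-9)
        # root sits on the long branch: 'a' alone on one side of the root
        sides = [frozenset(t.name for t in c.tips()) or frozenset([c.name])
                 for c in rooted.children]
        assert frozenset(["a"]) in sides

    def test_rooting_idempotent(self):
        labels = ["a", "b", "c", "d"]
        m = np.array(
            [[0, 3, 7, 8], [3, 0, 8, 9], [7, 8, 0, 5], [8, 9, 5, 0]], float
        )
        r1 = midpoint_root(nj_tree(DistanceMatrix(m, labels)))
        r2 = midpoint_root(r1)
        assert r1.compare_rfd(r2) == 0
        d1 = sorted(self._depths(r1))
        d2 = sorted(self._depths(r2))
        assert np.allclose(d1, d2)


def _two_clade_alignment(rng, n_per_clade=4, length=120):
    anc1 = "".join(rng.choice(list(AA), length))
    anc2 = list(anc1)
    for p in rng.choice(length, size=length // 2, replace=False):
        anc2[p] = rng.choice([a for a in AA if a != anc2[p]])
    anc2 = "".join(anc2)
    rows = []
    for g, anc in (("x", anc1), ("y", anc2)):
        for i in range(n_per_clade):
            chars = list(anc)
            for p in rng.choice(length, size=2, replace=False):
                chars[p] = rng.choice([a for a in AA if a != chars[p]])
            rows.append((f"{g}{i}", "".join(chars)))
    return MultipleAlignment(rows=tuple(rows), family_id="two_clades")


class TestBootstrap:
    def test_clean_split_gets_full_support(self, rng):
        aln = _two_clade_alignment(rng)
        tree, support = bootstrap_support(aln, n_reps=100, seed=7)
        labels = [sid for sid, _ in aln.rows]
        split = _canonical(
            frozenset(l for l in labels if l.startswith("y")), labels
        )
        assert support[split] == 100.0

    def test_single_replicate_degenerate_supports(self, rng):
        aln = _two_clade_alignment(rng)
        _, support = bootstrap_support(aln, n_reps=1, seed=3)
        assert set(support.values()) <= {0.0, 100.0}

    def test_fixed_seed_reproducible(self, rng):
        aln = _two_clade_alignment(rng)
        _, s1 = bootstrap_support(aln, n_reps=25, seed=5)
        _, s2 = bootstrap_support(aln, n_reps=25, seed=5)
        assert s1 == s2

    def test_supports_invariant_under_leaf_permutation(self, rng):
        aln = _two_clade_alignment(rng)
        perm = list(aln.rows)
        rng.shuffle(perm)
        _, s1 = bootstrap_support(aln, n_reps=25, seed=9)
        _, s2 = bootstrap_support(
            MultipleAlignment(rows=tuple(perm), family_id="p"), n_reps=25, seed=9
        )
        assert s1 == s2

    def test_invalid_reps(self, rng):
        with pytest.raises(ValueError):
            bootstrap_support(_two_clade_alignment(rng), n_reps=0)
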