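"""NJ correctness, MSA properties, bootstrap and Newick round trips."""

import io
import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from aldhkit.errors import InputError
from aldhkit.phylo import (
    Msa,
    bipartitions,
    bootstrap_support,
    forms_clade,
    newick_string,
    nj_tree,
    pdistance,
    progressive_msa,
    read_newick,
)
from aldhkit.records import ProteinRecord
from aldhkit.synthetic import SyntheticSpec, make_genome_layout, random_protein


# ---------------------------------------------------------------------------
# Oracles

def random_additive_tree(rng, n=6):
    """A random binary tree with uniform branch lengths, as (dm, bipartitions)."""
    labels = [f"T{i}" for i in range(n)]
    nodes = {lab: TreeNode(name=lab) for lab in labels}
    active = list(labels)
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        parent = TreeNode()
        ta, tb = nodes.pop(a), nodes.pop(b)
        ta.length = float(rng.uniform(0.1, 1.0))
        tb.length = float(rng.uniform(0.1, 1.0))
        parent.extend([ta, tb])
        lab = min(a, b)
        nodes[lab] = parent
        active = [x for x in active if x not in (a, b)] + [lab]
    a, b = active
    root, other = nodes[a], nodes[b]
    other.length = float(rng.uniform(0.1, 1.0))
    root.append(other)
    dm = root.tip_tip_distances()
    taxa = frozenset(t.name for t in root.tips())
    ref = min(taxa)
    bips = set()
    for node in root.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = taxa - side
        if 2 <= len(side) <= len(taxa) - 2:
            bips.add(side)
    return DistanceMatrix(dm.data, ids=list(dm.ids)), bips


def enumerate_topologies(taxa):
    """Edge lists of every unrooted binary topology on the taxa."""
    trees = [[(taxa[0], "i0"), (taxa[1], "i0"), (taxa[2], "i0")]]
    for idx, t in enumerate(taxa[3:]):
        new = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                ni = f"i{idx + 1}"
                new.append(edges[:k] + edges[k + 1:] + [(u, ni), (v, ni), (t, ni)])
        trees = new
    return trees


def topology_bipartitions(edges, taxa):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    taxa_set = frozenset(taxa)
    ref = min(taxa_set)
    bips = set()
    for u, v in edges:
        if u in taxa_set or v in taxa_set:
            continue  # pendant edge: trivial split
        seen = {u}
        stack = [u]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y != v and y not in seen and not (x == u and y == v):
                    seen.add(y)
                    stack.append(y)
        side = frozenset(x for x in seen if x in taxa_set)
        if ref in side:
            side = taxa_set - side
        if 2 <= len(side) <= len(taxa_set) - 2:
            bips.add(side)
    return bips


def least_squares_best_topology(dm: DistanceMatrix):
    """Fit branch lengths of every topology by OLS; return the best one's
    bipartitions. Independent of the NJ algorithm under test."""
    taxa = list(dm.ids)
    pairs = list(itertools.combinations(range(len(taxa)), 2))
    best = None
    for edges in enumerate_topologies(taxa):
        adj = {}
        for u, v in edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        edge_index = {frozenset(e): k for k, e in enumerate(edges)}

        def path_edges(a, b):
            prev = {a: None}
            stack = [a]
            while stack:
                x = stack.pop()
                if x == b:
                    break
                for y in adj[x]:
                    if y not in prev:
                        prev[y] = x
                        stack.append(y)
            out = []
            x = b
            while prev[x] is not None:
                out.append(edge_index[frozenset((x, prev[x]))])
                x = prev[x]
            return out

        X = np.zeros((len(pairs), len(edges)))
        y = np.zeros(len(pairs))
        for r, (i, j) in enumerate(pairs):
            for e in path_edges(taxa[i], taxa[j]):
                X[r, e] = 1.0
            y[r] = dm[taxa[i], taxa[j]]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((X @ beta - y) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, edges)
    return topology_bipartitions(best[1], taxa)


# ---------------------------------------------------------------------------

class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ids=list("ABC"))
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_four_taxon_additive_exact(self):
        # ((A:1,B:2):1,(C:3,D:4)) gives a unique additive matrix
        dm = DistanceMatrix(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            ids=list("ABCD"))
        tree = nj_tree(dm)
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        assert bipartitions(tree) == least_squares_best_topology(dm)

    def test_additive_recovery_50_seeds(self):
        hits = 0
        for seed in range(50):
            dm, truth_bips = random_additive_tree(np.random.default_rng(seed))
            hits += bipartitions(nj_tree(dm)) == truth_bips
        assert hits == 50

    def test_matches_least_squares_oracle(self):
        for seed in range(10):
            dm, _ = random_additive_tree(np.random.default_rng(100 + seed))
            assert bipartitions(nj_tree(dm)) == least_squares_best_topology(dm)

    def test_agrees_with_skbio_reference(self):
        from skbio.tree import nj as skbio_nj
        for seed in (0, 1, 2):
            dm, _ = random_additive_tree(np.random.default_rng(seed))
            theirs = skbio_nj(dm)
            taxa = frozenset(t.name for t in theirs.tips())
            ref = min(taxa)
            their_bips = set()
            for node in theirs.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if ref in side:
                    side = taxa - side
                if 2 <= len(side) <= len(taxa) - 2:
                    their_bips.add(side)
            assert bipartitions(nj_tree(dm)) == their_bips

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(Exception):
            nj_tree(DistanceMatrix([[0, 1, 2], [9, 0, 1], [2, 1, 0]], ids=list("ABC")))

    def test_negative_lengths_clamped(self):
        dm = DistanceMatrix(
            [[0, 0.1, 5, 5], [0.1, 0, 5, 5], [5, 5, 0, 0.1], [5, 5, 0.1, 0]],
            ids=list("ABCD"))
        tree = nj_tree(dm)
        assert all((t.length or 0) >= 0 for t in tree.traverse())


class TestPDistance:
    def test_identical_rows_zero(self):
        msa = Msa(["a", "b"], ["ACDEF", "ACDEF"])
        assert pdistance(msa)["a", "b"] == 0.0

    def test_constructed_case(self):
        # 3 mismatches over 10 comparable columns
        msa = Msa(["a", "b"], ["ACDEFGHIKL", "ACDEFGHWWW"])
        assert pdistance(msa)["a", "b"] == pytest.approx(0.3)

    def test_pairwise_deletion(self):
        msa = Msa(["a", "b"], ["AC-EF", "ACD-F"])  # 3 comparable, 0 mismatch
        assert pdistance(msa)["a", "b"] == 0.0

    def test_counting_oracle(self, rng):
        for _ in range(10):
            rows = []
            for _ in range(4):
                rows.append("".join(rng.choice(list("ACD-"), size=30)))
            # ensure comparability
            rows = [r[:5] + "AAAAA" + r[10:] for r in rows]
            msa = Msa([f"s{i}" for i in range(4)], rows)
            dm = pdistance(msa)
            for i in range(4):
                for j in range(i + 1, 4):
                    comp = [(x, y) for x, y in zip(rows[i], rows[j])
                            if x != "-" and y != "-"]
                    expect = sum(x != y for x, y in comp) / len(comp)
                    assert dm[f"s{i}", f"s{j}"] == pytest.approx(expect)

    def test_incomparable_pair_named(self):
        msa = Msa(["left", "right"], ["A--", "--C"])
        with pytest.raises(InputError, match="left.*right"):
            pdistance(msa)


class TestProgressiveMsa:
    def test_two_sequences_reduce_to_pairwise(self, rng):
        from aldhkit.classify import global_align
        a, b = random_protein(40, rng), random_protein(35, rng)
        msa = progressive_msa([ProteinRecord("a", a), ProteinRecord("b", b)])
        aln = global_align(a, b)
        assert msa.rows == [aln.a, aln.b]

    def test_identical_triple_gapless(self):
        s = "MKVLAWCDEF" * 3
        msa = progressive_msa([ProteinRecord(f"s{i}", s) for i in range(3)])
        assert msa.rows == [s, s, s]

    def test_rows_equal_length_and_degap_recovers(self, rng):
        records = [ProteinRecord(f"s{i}", random_protein(int(rng.integers(30, 60)), rng))
                   for i in range(5)]
        msa = progressive_msa(records)
        assert len({len(r) for r in msa.rows}) == 1
        assert msa.degapped() == {r.id: r.seq for r in records}

    def test_planted_indel_triple_matches_bruteforce(self):
        # one clean deletion: the SP-optimal alignment is unambiguous
        full = "MKVLAWCD"
        short = "MKVAWCD"  # L deleted
        msa = progressive_msa([
            ProteinRecord("a", full), ProteinRecord("b", short),
            ProteinRecord("c", full)])
        sp = sum_of_pairs_score(msa.rows)
        assert sp == brute_force_sp_optimum([full, short, full])
        row_b = msa.rows[msa.ids.index("b")]
        assert row_b.count("-") == 1

    def test_single_sequence_warns(self):
        with pytest.warns(UserWarning):
            msa = progressive_msa([ProteinRecord("one", "MKVLAW")])
        assert msa.rows == ["MKVLAW"]


def sum_of_pairs_score(rows, gap=-8.0):
    from Bio.Align import substitution_matrices
    S = substitution_matrices.load("BLOSUM62")
    total = 0.0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            for x, y in zip(rows[i], rows[j]):
                if x == "-" and y == "-":
                    continue
                total += gap if "-" in (x, y) else S[x][y]
    return total


def brute_force_sp_optimum(seqs, gap=-8.0):
    """Exhaustive 3-way DP maximizing the sum-of-pairs score."""
    from Bio.Align import substitution_matrices
    S = substitution_matrices.load("BLOSUM62")
    a, b, c = seqs

    def col_score(x, y, z):
        total = 0.0
        for p, q in ((x, y), (x, z), (y, z)):
            if p is None and q is None:
                continue
            total += gap if (p is None or q is None) else S[p][q]
        return total

    import math
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(i, j, k):
        if (i, j, k) == (0, 0, 0):
            return 0.0
        best = -math.inf
        for di, dj, dk in itertools.product((0, 1), repeat=3):
            if (di, dj, dk) == (0, 0, 0):
                continue
            if di > i or dj > j or dk > k:
                continue
            x = a[i - 1] if di else None
            y = b[j - 1] if dj else None
            z = c[k - 1] if dk else None
            best = max(best, f(i - di, j - dj, k - dk) + col_score(x, y, z))
        return best

    return f(len(a), len(b), len(c))


class TestBootstrap:
    def _family_msa(self, seed=0, n_families=3, members=3, seq_len=120):
        g = make_genome_layout(SyntheticSpec(
            seed=seed, n_families=n_families, members_per_family=members,
            seq_len=seq_len))
        return progressive_msa(g.proteins), g

    def test_identical_sequences_full_support(self):
        s = "MKVLAWCDEF" * 4
        msa = Msa([f"s{i}" for i in range(5)], [s] * 5)
        tree = bootstrap_support(msa, n_reps=50, seed=3)
        sups = [n.support for n in tree.non_tips(include_self=False)
                if getattr(n, "support", None) is not None]
        assert sups and all(s == 100.0 for s in sups)

    def test_deterministic_given_seed(self):
        msa, _ = self._family_msa(seed=2)
        t1 = bootstrap_support(msa, n_reps=30, seed=11)
        t2 = bootstrap_support(msa, n_reps=30, seed=11)
        s1 = sorted(n.support for n in t1.non_tips(include_self=False))
        s2 = sorted(n.support for n in t2.non_tips(include_self=False))
        assert s1 == s2

    def test_deep_split_high_support(self):
        # two well-separated families: the family split should be near 100
        msa, g = self._family_msa(seed=4, n_families=2, members=3)
        tree = bootstrap_support(msa, n_reps=200, seed=9)
        part = g.truth_partition()
        fam_sides = [frozenset(s) for s in part.values()]
        taxa = frozenset(msa.ids)
        ref = min(taxa)
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            canon = taxa - side if ref in side else side
            if canon in fam_sides or (taxa - canon) in fam_sides:
                assert node.support >= 95.0

    def test_too_few_columns_rejected(self):
        with pytest.raises(InputError):
            bootstrap_support(Msa(["a", "b", "c"], ["A", "A", "A"]), 10, 1)

    def test_family_coherence_over_seeds(self):
        # same-family members form a clade in nearly all generated censuses
        ok = 0
        for seed in range(20):
            msa, g = self._family_msa(seed=seed, seq_len=100)
            tree = nj_tree(pdistance(msa))
            ok += all(forms_clade(tree, set(members))
                      for members in g.truth_partition().values())
        assert ok >= 19


class TestNewickRoundTrip:
    def test_topology_lengths_supports_preserved(self):
        g = make_genome_layout(SyntheticSpec(seed=6, n_families=2,
                                             members_per_family=3, seq_len=100))
        msa = progressive_msa(g.proteins)
        tree = bootstrap_support(msa, n_reps=20, seed=2)
        s = newick_string(tree)
        back = read_newick(io.StringIO(s))
        assert bipartitions(back) == bipartitions(tree)
        orig = {frozenset(t.name for t in [tip]): tip.length for tip in tree.tips()}
        new = {frozenset(t.name for t in [tip]): tip.length for tip in back.tips()}
        for k in orig:
            assert abs(orig[k] - new[k]) < 1e-9
        sup_orig = sorted(n.support for n in tree.non_tips(include_self=False)
                          if getattr(n, "support", None) is not None)
        sup_new = sorted(n.support for n in back.non_tips(include_self=False)
                         if getattr(n, "support", None) is not None)
        assert sup_orig == sup_new
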