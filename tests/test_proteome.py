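"""Protein alignment statistics, API/BSR, neighbor joining and bootstrap."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from phagekit import proteome as pm

AA = list("ACDEFGHIKLMNPQRSTVWY")
B62 = substitution_matrices.load("BLOSUM62")


def random_protein(rng, n):
    return "".join(rng.choice(AA, n))


def sw_oracle(p, q, gap_open=-11, gap_extend=-1):
    """Exhaustive affine-gap local DP, written independently of the package."""
    n, m = len(p), len(q)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in p extends along q
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            H[i, j] = max(0.0,
                          H[i - 1, j - 1] + B62[p[i - 1]][q[j - 1]],
                          E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def mutate(rng, protein, n_subs):
    out = list(protein)
    for pos in rng.choice(len(out), size=n_subs, replace=False):
        out[pos] = AA[int(rng.integers(20))]
    return "".join(out)


class TestAlignProteins:
    def test_self_alignment_full_identity(self):
        rng = np.random.default_rng(0)
        p = random_protein(rng, 80)
        hit = pm.align_proteins(p, p)
        assert hit.identity == 100.0
        assert hit.e_value < 1e-5

    def test_random_pair_identity_below_display_cutoff(self):
        rng = np.random.default_rng(1)
        p, q = random_protein(rng, 300), random_protein(rng, 300)
        hit = pm.align_proteins(p, q)
        assert hit.identity < 35.0 or hit.e_value > 1e-5

    def test_scores_match_exhaustive_dp_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = random_protein(rng, int(rng.integers(5, 41)))
            q = random_protein(rng, int(rng.integers(5, 41)))
            assert pm.sw_score(p, q) == pytest.approx(sw_oracle(p, q))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pm.align_proteins("", "MKT")


def make_set(genome_id, proteins):
    return pm.ProteinSet(genome_id, [(f"{genome_id}_{i}", p)
                                     for i, p in enumerate(proteins)])


class TestBestHitsAndApi:
    def test_self_comparison_all_hits_identical(self):
        rng = np.random.default_rng(3)
        a = make_set("A", [random_protein(rng, 120) for _ in range(6)])
        hits = pm.best_hits(a, a)
        assert len(hits) == 6
        assert all(h.identity == 100.0 for h in hits)
        assert pm.api(a, a) == pytest.approx(100.0)

    def test_disjoint_random_proteomes_no_hits(self):
        rng = np.random.default_rng(4)
        a = make_set("A", [random_protein(rng, 100) for _ in range(4)])
        b = make_set("B", [random_protein(rng, 100) for _ in range(4)])
        assert pm.best_hits(a, b) == []
        with pytest.raises(ValueError, match="API undefined"):
            pm.api(a, b)

    def test_api_is_mean_of_best_hit_identities(self):
        """Dual route: api() must equal the mean taken over an independently
        assembled best-hit table, mixing strong and weak homologs."""
        rng = np.random.default_rng(5)
        base = [random_protein(rng, 150) for _ in range(6)]
        mutated = [mutate(rng, p, 15 if i % 2 else 60)
                   for i, p in enumerate(base)]
        a = make_set("A", base)
        b = make_set("B", mutated)
        hits = pm.best_hits(a, b)
        assert len(hits) >= 2
        expected = float(np.mean([h.identity for h in hits]))
        assert pm.api(a, b) == pytest.approx(expected)
        spread = {round(h.identity) for h in hits}
        assert max(spread) - min(spread) > 20  # both identity levels present


class TestMeanBsr:
    def test_self_is_one(self):
        rng = np.random.default_rng(6)
        a = make_set("A", [random_protein(rng, 100) for _ in range(5)])
        assert pm.mean_bsr(a, a) == pytest.approx(1.0)

    def test_unrelated_is_zero(self):
        rng = np.random.default_rng(7)
        a = make_set("A", [random_protein(rng, 90) for _ in range(4)])
        b = make_set("B", [random_protein(rng, 90) for _ in range(4)])
        assert pm.mean_bsr(a, b) == pytest.approx(0.0, abs=0.05)

    def test_half_shared_proteome_closed_form(self):
        """Half identical, half absent: mean BSR = 0.5 exactly."""
        rng = np.random.default_rng(8)
        shared = [random_protein(rng, 110) for _ in range(5)]
        a = make_set("A", shared + [random_protein(rng, 110) for _ in range(5)])
        b = make_set("B", shared + [random_protein(rng, 110) for _ in range(5)])
        assert pm.mean_bsr(a, b) == pytest.approx(0.5, abs=1 / 20)

    def test_monotone_decrease_with_divergence(self):
        rng = np.random.default_rng(9)
        base = [random_protein(rng, 120) for _ in range(4)]
        a = make_set("A", base)
        values = []
        for n_subs in (0, 20, 50, 90):
            b = make_set("B", [mutate(rng, p, n_subs) for p in base])
            values.append(pm.mean_bsr(a, b))
        assert values[0] == pytest.approx(1.0)
        assert all(x > y for x, y in zip(values, values[1:]))


def random_additive_matrix(rng, n_taxa):
    """Random binary tree -> path-length (additive) distance matrix."""
    names = [f"t{i}" for i in range(n_taxa)]
    # build a random topology by sequential attachment; track leaf paths
    import itertools
    next_id = itertools.count(n_taxa)
    # represent tree as parent pointers with branch lengths
    parent, blen = {}, {}
    nodes = [0, 1]
    root = next(next_id)
    parent[0], parent[1] = root, root
    blen[0] = float(rng.integers(1, 10))
    blen[1] = float(rng.integers(1, 10))
    edges = [0, 1]
    for leaf in range(2, n_taxa):
        target = edges[int(rng.integers(len(edges)))]
        mid = next(next_id)
        parent[mid] = parent[target]
        blen[mid] = float(rng.integers(1, 10))
        parent[target] = mid
        blen[target] = max(blen[target] - blen[mid], 1.0)
        parent[leaf] = mid
        blen[leaf] = float(rng.integers(1, 10))
        edges += [leaf, mid]
    def path_to_root(x):
        out = {}
        d = 0.0
        while x in parent:
            d += blen[x]
            x = parent[x]
            out[x] = d
        return out
    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        pi = path_to_root(i)
        for j in range(i + 1, n_taxa):
            pj = path_to_root(j)
            shared = min(pi[x] + pj[x] for x in pi if x in pj)
            D[i, j] = D[j, i] = shared
    return names, D


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        tree = pm.nj_tree(["A", "B", "C"], np.array(
            [[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 1.0}

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:1))
        D = np.array([[0, 3, 5, 3], [3, 0, 6, 4],
                      [5, 6, 0, 4], [3, 4, 4, 0]], dtype=float)
        tree = pm.nj_tree(list("ABCD"), D)
        dm = tree.tip_tip_distances(list("ABCD"))
        np.testing.assert_allclose(dm.data, D, atol=1e-9)
        assert frozenset({"A", "B"}) in pm.tree_bipartitions(tree) or \
               frozenset({"C", "D"}) in pm.tree_bipartitions(tree)

    def test_additive_matrices_recovered_exactly_up_to_eight_taxa(self):
        rng = np.random.default_rng(10)
        for n_taxa in (4, 5, 6, 7, 8):
            for _ in range(4):
                names, D = random_additive_matrix(rng, n_taxa)
                tree = pm.nj_tree(names, D)
                dm = tree.tip_tip_distances(names)
                np.testing.assert_allclose(dm.data, D, atol=1e-9)

    def test_topology_agrees_with_reference_nj(self):
        """Independent oracle: scikit-bio's neighbor joining recovers the
        same bipartitions on additive matrices."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            names, D = random_additive_matrix(rng, 6)
            ours = pm.tree_bipartitions(pm.nj_tree(names, D))
            ref_tree = skbio_nj(DistanceMatrix(D, names))
            theirs = pm.tree_bipartitions(ref_tree)
            assert ours == theirs

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            pm.nj_tree(["a", "b", "c"], np.array(
                [[0, 1, 2], [9, 0, 1], [2, 1, 0]], dtype=float))
        with pytest.raises(ValueError):
            pm.nj_tree(["a", "b", "c"], np.array(
                [[0, -1, 2], [-1, 0, 1], [2, 1, 0]], dtype=float))


class TestBootstrap:
    MSA = [("a", "MKKLLVAA"), ("b", "MKKLLVAA"),
           ("c", "MRRLIVGG"), ("d", "MRRLIVGG")]

    def test_clade_with_unanimous_columns_gets_full_support(self):
        tree, supports = pm.bootstrap_msa_tree(self.MSA, n_replicates=200, seed=1)
        assert supports[frozenset({"c", "d"})] == 1.0

    def test_single_replicate_supports_are_binary(self):
        _, supports = pm.bootstrap_msa_tree(self.MSA, n_replicates=1, seed=2)
        assert set(supports.values()) <= {0.0, 1.0}

    def test_fixed_seed_reproducible(self):
        _, s1 = pm.bootstrap_msa_tree(self.MSA, n_replicates=50, seed=7)
        _, s2 = pm.bootstrap_msa_tree(self.MSA, n_replicates=50, seed=7)
        assert s1 == s2

    def test_fewer_than_four_taxa_warns(self):
        msa = [("a", "MKL"), ("b", "MKL"), ("c", "MRL")]
        with pytest.warns(UserWarning):
            _, supports = pm.bootstrap_msa_tree(msa, n_replicates=5, seed=0)
        assert supports == {}


class TestProgressiveMsa:
    def test_identical_pair_gap_free(self):
        msa = pm.msa_progressive([("x", "MKTAYI"), ("y", "MKTAYI")])
        assert msa == [("x", "MKTAYI"), ("y", "MKTAYI")]

    def test_single_gap_small_case(self):
        msa = pm.msa_progressive([("x", "ACDE"), ("y", "ACE")])
        assert dict(msa) == {"x": "ACDE", "y": "AC-E"}

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            pm.msa_progressive([("x", "MKT")])

    def test_recovers_generating_topology(self):
        """Sequences mutated along a known 4-taxon tree: NJ on the MSA
        p-distances reproduces the generating split."""
        rng = np.random.default_rng(12)
        root = random_protein(rng, 120)
        left = mutate(rng, root, 25)
        right = mutate(rng, root, 25)
        seqs = [("a", mutate(rng, left, 6)), ("b", mutate(rng, left, 6)),
                ("c", mutate(rng, right, 6)), ("d", mutate(rng, right, 6))]
        msa = pm.msa_progressive(seqs)
        assert len(set(len(s) for _, s in msa)) == 1
        D = pm.msa_p_distance(msa)
        tree = pm.nj_tree([n for n, _ in msa], D)
        parts = pm.tree_bipartitions(tree)
        assert frozenset({"c", "d"}) in parts
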