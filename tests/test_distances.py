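"""Li-Wu-Luo distances, distance matrices and neighbor-joining."""

import numpy as np
import pytest

from batvision.codonseq import CodonAlignment
from batvision.distances import (
    DistanceMatrix, lwl_distance, nj_tree, pairwise_matrix,
)
from batvision.errors import SaturationError
from batvision.evomodels import CodonModel
from batvision.simulate import simulate_alignment
from batvision.trees import read_newick, robinson_foulds
from conftest import balanced_tree


class TestLwl:
    def test_identical_sequences_zero(self):
        seq = "ATGGCTAAAGGT" * 5
        res = lwl_distance(seq, seq)
        assert res.Ka == 0.0 and res.Ks == 0.0

    def test_single_transition_fourfold_closed_form(self):
        a = "GGT" * 100
        b = "GGT" * 99 + "GGC"
        res = lwl_distance(a, b)
        p4 = 1.0 / res.L4
        a4 = 0.5 * np.log(1 / (1 - 2 * p4)) - 0.25 * np.log(1.0)
        expected_ks = 3 * res.L4 * a4 / (res.L2 + 3 * res.L4)
        assert res.Ka == 0.0
        assert res.Ks == pytest.approx(expected_ks, rel=1e-12)

    def test_single_transversion_zerofold(self):
        a = "GGT" * 100
        b = "GGT" * 99 + "GTT"  # Gly -> Val at a 0-fold second position
        res = lwl_distance(a, b)
        assert res.Ks == 0.0
        assert res.Ka > 0
        q0 = 1.0 / res.L0
        a0 = 0.5 * np.log(1 / (1 - q0)) - 0.25 * np.log(1 / (1 - 2 * q0))
        b0 = 0.5 * np.log(1 / (1 - 2 * q0))
        assert res.Ka == pytest.approx(
            3 * res.L0 * (a0 + b0) / (2 * res.L2 + 3 * res.L0), rel=1e-12)

    def test_site_count_partition(self):
        a = "ATGGCTAAAGGTTTCCAT" * 10
        b = "ATGGCCAAAGGTTTCCAT" * 5 + "ATGGCTAGAGGTTTCCAT" * 5
        res = lwl_distance(a, b)
        assert res.L0 + res.L2 + res.L4 == pytest.approx(3 * res.n_codons)

    def test_symmetry(self):
        a = "ATGGCTAAAGGTTTCCATAGA" * 8
        b = ("ATGTCTAAAGGTTTCCATAGA" * 4) + ("ATGGCTAGAGGATTCCATAAA" * 4)
        r1, r2 = lwl_distance(a, b), lwl_distance(b, a)
        assert r1.Ka == pytest.approx(r2.Ka, rel=1e-12)
        assert r1.Ks == pytest.approx(r2.Ks, rel=1e-12)
        assert (r1.L0, r1.L2, r1.L4) == pytest.approx((r2.L0, r2.L2, r2.L4))

    def test_gapped_and_stopless_sites_skipped(self):
        a = "ATG---AAAGGT" + "GGT" * 20
        b = "ATGGCTAAAGGC" + "GGT" * 20
        res = lwl_distance(a, b)
        assert res.n_codons == 23  # the gapped codon pair is excluded

    def test_small_distance_first_order(self):
        """A_i + B_i ~ P_i + Q_i as distances -> 0 (within 1%)."""
        n = 4000
        a = "GGT" * n
        # 8 transitions + 4 transversions at 4-fold sites: P+Q = 12/n
        mutated = ["GGC"] * 8 + ["GGA"] * 4 + ["GGT"] * (n - 12)
        res = lwl_distance(a, "".join(mutated))
        direct = res.P4 + res.Q4
        corrected = res.A4 + res.B4
        assert direct < 0.01
        assert corrected == pytest.approx(direct, rel=0.01)

    def test_saturation_error_identifies_class(self):
        a = "GGA" * 10
        b = "GGT" * 10  # every 4-fold site differs by a transversion
        with pytest.raises(SaturationError) as err:
            lwl_distance(a, b)
        assert err.value.degeneracy_class == 4

    def test_sign_tracks_selection_regime(self):
        """Ka/Ks < 1 under purifying simulation, > 1 under positive."""
        tree = read_newick("(x:0.15,y:0.15);")
        for omega, expect_low in ((0.1, True), (4.0, False)):
            hits = 0
            n_rep = 10
            for seed in range(n_rep):
                rec = simulate_alignment(tree, CodonModel(2.0, omega), 2000,
                                         seed=100 + seed)
                res = lwl_distance(*rec.alignment.seqs)
                hits += (res.ka_ks < 1) == expect_low
            assert hits >= 9, f"omega={omega}: {hits}/{n_rep}"

    def test_single_position_differences_from_counts(self):
        """Oracle: when every differing codon pair differs at one position
        and the two codons agree on that position's class, P/Q counts and
        the corrected distances follow directly from tallies."""
        import collections
        from batvision.codonseq import classify_degeneracy, is_transition
        tree = read_newick("(x:0.02,y:0.02);")
        rec = simulate_alignment(tree, CodonModel(2.0, 0.3), 600, seed=5)
        s1, s2 = rec.alignment.seqs
        keep1, keep2 = [], []
        for j in range(len(s1) // 3):
            c1, c2 = s1[3 * j:3 * j + 3], s2[3 * j:3 * j + 3]
            diff = [p for p in range(3) if c1[p] != c2[p]]
            if len(diff) > 1:
                continue
            if diff and (classify_degeneracy(c1, diff[0] + 1) !=
                         classify_degeneracy(c2, diff[0] + 1)):
                continue
            keep1.append(c1)
            keep2.append(c2)
        ts = collections.Counter()
        tv = collections.Counter()
        L = collections.Counter()
        for c1, c2 in zip(keep1, keep2):
            for pos in (1, 2, 3):
                L[classify_degeneracy(c1, pos)] += 0.5
                L[classify_degeneracy(c2, pos)] += 0.5
                if c1[pos - 1] != c2[pos - 1]:
                    cls = classify_degeneracy(c1, pos)
                    (ts if is_transition(c1[pos - 1], c2[pos - 1]) else tv)[cls] += 1
        res = lwl_distance("".join(keep1), "".join(keep2))
        for cls in (0, 2, 4):
            assert getattr(res, f"L{cls}") == pytest.approx(L[cls])
            assert getattr(res, f"P{cls}") == pytest.approx(
                ts[cls] / L[cls] if L[cls] else 0.0)
            assert getattr(res, f"Q{cls}") == pytest.approx(
                tv[cls] / L[cls] if L[cls] else 0.0)


class TestPairwiseMatrix:
    def test_identical_sequences_zero_matrix(self):
        aln = CodonAlignment(["a", "b", "c"], ["ATGGCTAAA"] * 3)
        for which in ("ka", "ks", "p"):
            mat = pairwise_matrix(aln, which)
            assert np.all(mat.d == 0)

    def test_entries_match_pairwise_recomputation(self, small_codon_sim):
        _, rec = small_codon_sim
        aln = rec.alignment
        mat = pairwise_matrix(aln, "ka")
        assert np.allclose(mat.d, mat.d.T)
        assert np.all(np.diag(mat.d) == 0)
        for i in range(0, aln.n_taxa, 3):
            for j in range(i + 1, aln.n_taxa, 2):
                assert mat.d[i, j] == pytest.approx(
                    lwl_distance(aln.seqs[i], aln.seqs[j]).Ka, rel=1e-12)

    def test_saturated_pair_names_taxa(self):
        aln = CodonAlignment(["ok", "t1", "t2"],
                             ["GGA" * 10, "GGA" * 10, "GGT" * 10])
        with pytest.raises(SaturationError) as err:
            pairwise_matrix(aln, "ks")
        assert "t2" in str(err.value)

    def test_phylip_roundtrip(self, small_codon_sim):
        _, rec = small_codon_sim
        mat = pairwise_matrix(rec.alignment, "p")
        back = DistanceMatrix.from_phylip(mat.to_phylip())
        assert back.taxa == mat.taxa
        assert np.allclose(back.d, mat.d, atol=1e-6)


def tree_distances(tree):
    """Additive pairwise path-length matrix of a tree (test oracle)."""
    leaves = tree.leaf_indices()
    names = [tree.name[v] for v in leaves]
    n = len(leaves)

    def path_to_root(v):
        out = {}
        while tree.parent[v] != -1:
            out[v] = tree.length[v]
            v = tree.parent[v]
        return out

    d = np.zeros((n, n))
    paths = [path_to_root(v) for v in leaves]
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = paths[i], paths[j]
            shared = set(pi) & set(pj)
            dist = sum(t for v, t in pi.items() if v not in shared)
            dist += sum(t for v, t in pj.items() if v not in shared)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(names, d)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, .3, .4], [.3, 0, .5], [.4, .5, 0]]))
        tree = nj_tree(d)
        lengths = {tree.name[v]: tree.length[v] for v in tree.leaf_indices()}
        assert lengths["A"] == pytest.approx((.3 + .4 - .5) / 2)
        assert lengths["B"] == pytest.approx((.3 + .5 - .4) / 2)
        assert lengths["C"] == pytest.approx((.4 + .5 - .3) / 2)

    def test_additive_matrix_exact_recovery(self):
        source = read_newick(
            "((A:0.11,B:0.07):0.05,(C:0.21,(D:0.03,E:0.09):0.06):0.04);")
        mat = tree_distances(source)
        recovered = nj_tree(mat)
        assert robinson_foulds(source, recovered) == 0
        assert np.allclose(sorted(tree_distances(recovered).d.ravel()),
                           sorted(mat.d.ravel()), atol=1e-10)

    def test_input_order_invariance(self):
        source = balanced_tree(6, seed=9)
        mat = tree_distances(source)
        rng = np.random.default_rng(0)
        reference = None
        for _ in range(6):
            perm = rng.permutation(len(mat.taxa))
            shuffled = DistanceMatrix([mat.taxa[i] for i in perm],
                                      mat.d[np.ix_(perm, perm)])
            tree = nj_tree(shuffled)
            if reference is None:
                reference = tree
            assert robinson_foulds(reference, tree) == 0

    def test_recovers_generating_topology_from_sequences(self):
        source = balanced_tree(16, seed=5, lo=0.03, hi=0.25)
        rec = simulate_alignment(source, CodonModel(2.0, 0.2), 1500, seed=17)
        mat = pairwise_matrix(rec.alignment, "p")
        assert robinson_foulds(source, nj_tree(mat)) == 0

    def test_scikit_bio_cross_check(self):
        skbio = pytest.importorskip("skbio")
        source = balanced_tree(7, seed=13)
        mat = tree_distances(source)
        ours = nj_tree(mat)
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(mat.d, ids=mat.taxa))
        sk_parsed = read_newick(str(sk_tree))
        assert robinson_foulds(ours, sk_parsed) == 0

    def test_rejects_bad_matrices(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b", "c"],
                                   np.array([[0, 1, 2], [1, 0, 3],
                                             [2.5, 3, 0]])))
        bad = np.zeros((3, 3))
        bad[0, 1] = bad[1, 0] = np.nan
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b", "c"], bad))
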