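"""Rate matrices, transition probabilities, pruning likelihood, M0 fit."""

import itertools

import numpy as np
import pytest

from batvision.codonseq import CodonAlignment, ProteinAlignment
from batvision.errors import ModelError
from batvision.evomodels import (
    AA_ALPHABET, AminoAcidModel, CodonModel, Eigensystem, PruningEngine,
    codon_model_for, encode_alignment, fit_m0, fit_protein_branch_lengths,
    pruning_loglik,
)
from batvision.simulate import simulate_alignment
from batvision.trees import PhyloTree, read_newick
from conftest import balanced_tree


def all_models():
    uniform = CodonModel(2.0, 0.5)
    f3x4 = codon_model_for(
        CodonAlignment(["a", "b"], ["ATGGCTAAAGGT", "ATGGCCAAAGGA"]),
        kappa=3.0, omega=0.1)
    return [uniform.rate_matrix(), f3x4.rate_matrix(),
            AminoAcidModel.poisson().rate_matrix(),
            AminoAcidModel.jtt().rate_matrix()]


class TestRateMatrices:
    def test_codon_entry_structure(self):
        model = CodonModel(2.0, 0.5)
        Q, pi = model.rate_matrix()
        codons = model.code.sense_codons
        idx = {c: k for k, c in enumerate(codons)}
        scale = Q[idx["AAA"], idx["AAG"]] / (model.kappa * pi[idx["AAG"]])
        # AAA->AAG: synonymous transition, proportional to kappa*pi
        assert scale > 0
        # TTT->GTT: nonsynonymous transversion, proportional to omega*pi
        assert Q[idx["TTT"], idx["GTT"]] == pytest.approx(
            scale * model.omega * pi[idx["GTT"]])
        # two-position change forbidden
        assert Q[idx["TTT"], idx["GGT"]] == 0.0
        # stop codons absent from the state space
        assert "TAA" not in idx and len(codons) == 61

    def test_parameter_domain(self):
        with pytest.raises(ModelError):
            CodonModel(-1.0, 0.5)
        with pytest.raises(ModelError):
            CodonModel(2.0, -0.1)

    @pytest.mark.parametrize("case", range(4))
    def test_detailed_balance_and_unit_rate(self, case):
        Q, pi = all_models()[case]
        flow = pi[:, None] * Q
        assert np.abs(flow - flow.T).max() < 1e-12
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0, abs=1e-12)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12


class TestTransitionMatrices:
    def test_identity_at_zero(self):
        Q, pi = CodonModel(2.0, 0.3).rate_matrix()
        P = Eigensystem(Q, pi).transition(0.0)
        assert np.allclose(P, np.eye(len(pi)), atol=1e-12)

    def test_rows_stochastic(self):
        Q, pi = AminoAcidModel.jtt().rate_matrix()
        eig = Eigensystem(Q, pi)
        for t in (0.01, 0.5, 3.0):
            P = eig.transition(t)
            assert np.abs(P.sum(axis=1) - 1).max() < 1e-12
            assert P.min() >= 0

    def test_ergodic_limit(self):
        Q, pi = CodonModel(2.0, 0.3).rate_matrix()
        P = Eigensystem(Q, pi).transition(100.0)
        assert np.abs(P - pi[None, :]).max() < 1e-6

    def test_negative_time_rejected(self):
        Q, pi = AminoAcidModel.poisson().rate_matrix()
        with pytest.raises(ModelError):
            Eigensystem(Q, pi).transition(-0.1)

    def test_batch_matches_loop(self):
        Q, pi = CodonModel(1.5, 0.2).rate_matrix()
        eig = Eigensystem(Q, pi)
        ts = np.array([0.0, 0.03, 0.4, 2.0])
        batch = eig.transition_batch(ts)
        for k, t in enumerate(ts):
            assert np.allclose(batch[k], eig.transition(t), atol=1e-13)


def brute_force_loglik(tree, aln, model):
    """Exhaustive enumeration over internal-node states (test oracle)."""
    Q, pi = (model.rate_matrix() if isinstance(model, AminoAcidModel)
             else model.rate_matrix(None))
    eig = Eigensystem(Q, pi)
    P = {v: eig.transition(tree.length[v])
         for v in range(tree.n_nodes) if v != tree.root}
    S = len(pi)
    if isinstance(model, CodonModel):
        idx = {c: k for k, c in enumerate(model.code.sense_codons)}
        n_sites = aln.n_codons
        obs = {tree.node_by_name(t): [idx[aln.codon(r, s)] for s in range(n_sites)]
               for r, t in enumerate(aln.taxa)}
    else:
        idx = {a: k for k, a in enumerate(AA_ALPHABET)}
        n_sites = aln.n_sites
        obs = {tree.node_by_name(t): [idx[c] for c in aln.seqs[r]]
               for r, t in enumerate(aln.taxa)}
    internals = tree.internal_indices()
    total = 0.0
    for s in range(n_sites):
        lik = 0.0
        for assignment in itertools.product(range(S), repeat=len(internals)):
            state = dict(zip(internals, assignment))
            for leaf, seq in obs.items():
                state[leaf] = seq[s]
            term = pi[state[tree.root]]
            for v in range(tree.n_nodes):
                if v != tree.root:
                    term *= P[v][state[tree.parent[v]], state[v]]
            lik += term
        total += np.log(lik)
    return total


class TestPruning:
    def test_single_leaf_degenerates_to_prior(self):
        model = CodonModel(2.0, 0.5)
        tree = PhyloTree([-1], [[]], np.array([np.nan]), ["x"], [0], 0)
        aln = CodonAlignment(["x"], ["ATGGCTATG"])
        idx = {c: k for k, c in enumerate(model.code.sense_codons)}
        _, pi = model.rate_matrix()
        expected = sum(np.log(pi[idx[c]]) for c in ("ATG", "GCT", "ATG"))
        assert pruning_loglik(tree, aln, model) == pytest.approx(expected)

    def test_matches_enumeration_codon_quartet(self, quartet_tree):
        rng = np.random.default_rng(1)
        model = CodonModel(2.0, 0.5)
        codons = model.code.sense_codons
        aln = CodonAlignment(
            ["A", "B", "C", "D"],
            ["".join(rng.choice(codons, 3)) for _ in range(4)])
        lnL = pruning_loglik(quartet_tree, aln, model)
        lnL_bf = brute_force_loglik(quartet_tree, aln, model)
        assert abs(lnL - lnL_bf) / abs(lnL_bf) < 1e-10

    def test_matches_enumeration_protein_five_taxa(self):
        tree = read_newick(
            "((A:0.2,B:0.1):0.1,(C:0.3,D:0.15):0.05,E:0.4);")
        rng = np.random.default_rng(2)
        aln = ProteinAlignment(
            ["A", "B", "C", "D", "E"],
            ["".join(rng.choice(list(AA_ALPHABET), 6)) for _ in range(5)])
        model = AminoAcidModel.jtt()
        lnL = pruning_loglik(tree, aln, model)
        lnL_bf = brute_force_loglik(tree, aln, model)
        assert abs(lnL - lnL_bf) / abs(lnL_bf) < 1e-10

    def test_gaps_are_uninformative(self, quartet_tree):
        model = AminoAcidModel.poisson()
        with_gap = ProteinAlignment(["A", "B", "C", "D"],
                                    ["MK-A", "MKLA", "MRLA", "MKLG"])
        dropped = ProteinAlignment(["A", "B", "C", "D"],
                                   ["MKA", "MKA", "MRA", "MKG"])
        # removing the column seen only through the gap changes lnL by the
        # contribution of the three observed residues, never the gap itself
        lnL_gap = pruning_loglik(quartet_tree, with_gap, model)
        lnL_drop = pruning_loglik(quartet_tree, dropped, model)
        assert lnL_gap < lnL_drop  # the partial column still contributes

    def test_pulley_principle(self, quartet_tree):
        rng = np.random.default_rng(3)
        model = CodonModel(2.0, 0.2)
        aln = CodonAlignment(
            ["A", "B", "C", "D"],
            ["".join(rng.choice(model.code.sense_codons, 20)) for _ in range(4)])
        reference = pruning_loglik(quartet_tree, aln, model)
        for node in (1, 2, 4):
            for frac in (0.2, 0.8):
                rerooted = quartet_tree.reroot_at_edge(node, frac)
                assert pruning_loglik(rerooted, aln, model) == pytest.approx(
                    reference, abs=1e-9)

    def test_pattern_compression_invariance(self, quartet_tree):
        model = AminoAcidModel.poisson()
        aln = ProteinAlignment(["A", "B", "C", "D"],
                               ["MKMKMK", "MKMKMK", "MRMRMR", "MKMKMK"])
        total = pruning_loglik(quartet_tree, aln, model)
        per_column = sum(
            pruning_loglik(quartet_tree,
                           ProteinAlignment(aln.taxa, [s[j] for s in aln.seqs]),
                           model)
            for j in range(6))
        assert total == pytest.approx(per_column, abs=1e-10)

    def test_leaf_taxon_mismatch_raises(self, quartet_tree):
        model = AminoAcidModel.poisson()
        aln = ProteinAlignment(["A", "B", "C", "X"], ["M", "K", "L", "A"])
        with pytest.raises(ModelError, match="mismatch"):
            data = encode_alignment(aln, model)
            PruningEngine(quartet_tree, data)


class TestOptimize:
    def test_m0_parameter_recovery(self):
        tree = balanced_tree(8, seed=7, lo=0.05, hi=0.3)
        rec = simulate_alignment(tree, CodonModel(2.0, 0.2), 1500, seed=23)
        fit = fit_m0(tree, rec.alignment)
        assert 0.16 <= fit.model.omega <= 0.24
        assert 1.7 <= fit.model.kappa <= 2.3

    def test_refit_is_stable(self, small_codon_sim):
        tree, rec = small_codon_sim
        fit = fit_m0(tree, rec.alignment)
        refit = fit_m0(fit.tree, rec.alignment, kappa0=fit.model.kappa,
                       omega0=fit.model.omega)
        assert refit.lnL >= fit.lnL - 1e-6
        assert refit.lnL - fit.lnL < 0.05

    def test_protein_branch_lengths_improve_likelihood(self, small_codon_sim):
        from batvision.codonseq import translate_alignment
        tree, rec = small_codon_sim
        protein = translate_alignment(rec.alignment)
        model = AminoAcidModel.poisson()
        before = pruning_loglik(tree, protein, model)
        fitted, lnL = fit_protein_branch_lengths(tree, protein, model)
        assert lnL >= before - 1e-9
        assert pruning_loglik(fitted, protein, model) == pytest.approx(lnL, abs=1e-6)
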