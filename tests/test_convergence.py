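"""Parallel/convergent classification, expectations and the Poisson test."""

import numpy as np
import pytest
from scipy.stats import kstest

from batvision.ancestral import BranchChange, marginal_asr
from batvision.convergence import (
    BranchPair, classify_pair_changes, expected_counts, poisson_tail_test,
    resolve_pair, run_convergence_scan,
)
from batvision.errors import BatVisionError
from batvision.evomodels import AminoAcidModel, CodonModel, Eigensystem
from batvision.simulate import (
    inject_convergence, make_study_like_fixture, simulate_alignment,
)
from conftest import balanced_tree


def bc(branch, site, a, b):
    return BranchChange(branch=branch, site=site, from_state=a, to_state=b)


class TestClassification:
    def test_parallel_same_ancestor_same_derived(self):
        par, conv = classify_pair_changes([bc(1, 5, "S", "A")],
                                          [bc(2, 5, "S", "A")])
        assert par == [(5, "S", "A")] and conv == []

    def test_convergent_different_ancestors(self):
        par, conv = classify_pair_changes([bc(1, 5, "T", "A")],
                                          [bc(2, 5, "S", "A")])
        assert par == [] and conv == [(5, "T", "S", "A")]

    def test_different_derived_is_neither(self):
        par, conv = classify_pair_changes([bc(1, 5, "S", "A")],
                                          [bc(2, 5, "S", "G")])
        assert par == [] and conv == []

    def test_classification_is_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(0)
        aas = list("ACDEFGHIKL")
        for _ in range(50):
            s = int(rng.integers(1, 5))
            a1, d1 = rng.choice(aas, 2, replace=False)
            a2, d2 = rng.choice(aas, 2, replace=False)
            par, conv = classify_pair_changes([bc(1, s, a1, d1)],
                                              [bc(2, s, a2, d2)])
            n_buckets = len(par) + len(conv)
            if d1 == d2:
                assert n_buckets == 1
                assert bool(par) == (a1 == a2)
            else:
                assert n_buckets == 0

    def test_nested_pair_rejected(self):
        tree = balanced_tree(6, seed=1)
        internal = [v for v in tree.internal_indices() if v != tree.root]
        child = tree.children[internal[0]][0]
        with pytest.raises(BatVisionError, match="nested"):
            BranchPair(internal[0], child).validate(tree)
        with pytest.raises(BatVisionError):
            BranchPair(3, 3).validate(tree)


class TestExpectedCounts:
    def _setup(self, t1, t2, map_state=0, n_sites=50, seed=0):
        tree = balanced_tree(8, seed=seed)
        b1 = tree.children[tree.root][0]
        b2 = tree.children[tree.root][1]
        tree.length[b1], tree.length[b2] = t1, t2
        model = AminoAcidModel.poisson()
        rec = simulate_alignment(tree, model, n_sites, seed=seed + 1)
        asr = marginal_asr(tree, rec.alignment, model)
        # overwrite parent MAPs with a controlled state for closed forms
        p1, p2 = tree.parent[b1], tree.parent[b2]
        for p in {p1, p2}:
            asr.map_states[p] = np.full(n_sites, map_state)
        return tree, model, asr, BranchPair(b1, b2)

    def test_zero_length_branch_gives_zero_expectation(self):
        tree, model, asr, pair = self._setup(0.0, 0.3)
        e_par, e_conv = expected_counts(tree, model, asr, pair)
        assert e_par == pytest.approx(0.0, abs=1e-12)
        assert e_conv == pytest.approx(0.0, abs=1e-12)

    def test_equal_rate_closed_form(self):
        """With all ancestors equal and the equal-rate model,
        E_par = S * d1 * d2 / 19 (19 equiprobable targets per branch)."""
        t1, t2, n = 0.17, 0.29, 50
        tree, model, asr, pair = self._setup(t1, t2, n_sites=n)
        Q, pi = model.rate_matrix()
        eig = Eigensystem(Q, pi)
        d1 = 1.0 - eig.transition(t1)[0, 0]
        d2 = 1.0 - eig.transition(t2)[0, 0]
        e_par, e_conv = expected_counts(tree, model, asr, pair)
        assert e_par == pytest.approx(n * d1 * d2 / 19.0, rel=1e-10)
        assert e_conv == 0.0

    def test_monte_carlo_oracle(self):
        """E_par/E_conv match direct simulation of the two branches."""
        tree, model, asr, pair = self._setup(0.25, 0.4, n_sites=30, seed=3)
        rng = np.random.default_rng(99)
        # mixed ancestral states to exercise both the parallel and the
        # convergent branches of the formula
        n = 30
        p1, p2 = tree.parent[pair.b1], tree.parent[pair.b2]
        asr.map_states[p1] = rng.integers(0, 3, n)
        asr.map_states[p2] = rng.integers(0, 3, n)
        e_par, e_conv = expected_counts(tree, model, asr, pair)
        Q, pi = model.rate_matrix()
        eig = Eigensystem(Q, pi)
        P1 = eig.transition(tree.length[pair.b1])
        P2 = eig.transition(tree.length[pair.b2])
        n_draw = 100_000
        par = np.zeros(n_draw)
        conv = np.zeros(n_draw)
        for s in range(n):
            a1, a2 = asr.map_states[p1][s], asr.map_states[p2][s]
            y1 = rng.choice(20, size=n_draw, p=P1[a1])
            y2 = rng.choice(20, size=n_draw, p=P2[a2])
            both_changed_same = (y1 == y2) & (y1 != a1) & (y2 != a2)
            if a1 == a2:
                par += both_changed_same
            else:
                conv += both_changed_same
        for est, mc in ((e_par, par), (e_conv, conv)):
            se = mc.std(ddof=1) / np.sqrt(n_draw)
            assert abs(est - mc.mean()) < 3 * se + 1e-12

    def test_monotone_in_branch_lengths(self):
        grid = [0.05, 0.1, 0.2, 0.4]
        prev = -1.0
        for t in grid:
            tree, model, asr, pair = self._setup(t, 0.2)
            e_par, _ = expected_counts(tree, model, asr, pair)
            assert e_par > prev
            prev = e_par

    def test_additivity_over_site_partition(self):
        tree, model, asr, pair = self._setup(0.2, 0.3, n_sites=40, seed=5)
        rng = np.random.default_rng(7)
        p1, p2 = tree.parent[pair.b1], tree.parent[pair.b2]
        asr.map_states[p1] = rng.integers(0, 20, 40)
        asr.map_states[p2] = rng.integers(0, 20, 40)
        full = expected_counts(tree, model, asr, pair)
        halves = []
        for sl in (slice(0, 17), slice(17, 40)):
            part = type(asr)(
                level=asr.level, alphabet=asr.alphabet, tree=asr.tree,
                posteriors={k: v[sl] for k, v in asr.posteriors.items()},
                map_states={k: v[sl] for k, v in asr.map_states.items()},
                low_confidence=asr.low_confidence)
            halves.append(expected_counts(tree, model, part, pair))
        assert full[0] == pytest.approx(halves[0][0] + halves[1][0], rel=1e-12)
        assert full[1] == pytest.approx(halves[0][1] + halves[1][1], rel=1e-12)

    def test_posterior_weighted_option(self):
        tree, model, asr, pair = self._setup(0.2, 0.3, n_sites=20, seed=9)
        e_map = expected_counts(tree, model, asr, pair, use_map=True)
        e_int = expected_counts(tree, model, asr, pair, use_map=False)
        assert e_int[0] >= 0 and np.isfinite(e_int).all()
        assert e_int != e_map  # integration genuinely differs from plug-in


class TestPoissonTail:
    def test_zero_count_is_one(self):
        assert poisson_tail_test(0, 5.0) == 1.0
        assert poisson_tail_test(0, 0.0) == 1.0

    @pytest.mark.parametrize("n,E,expected", [
        (3, 1.0, 1 - np.exp(-1) * (1 + 1 + 0.5)),
        (1, 0.01, 1 - np.exp(-0.01)),
        (2, 0.5, 1 - np.exp(-0.5) * (1 + 0.5)),
    ])
    def test_closed_forms(self, n, E, expected):
        assert poisson_tail_test(n, E) == pytest.approx(expected, rel=1e-10)

    def test_matches_explicit_mass_enumeration(self):
        from math import exp, factorial
        for n, E in [(1, 0.3), (4, 2.2), (7, 3.0)]:
            direct = 1 - sum(exp(-E) * E ** k / factorial(k) for k in range(n))
            assert poisson_tail_test(n, E) == pytest.approx(direct, rel=1e-9)

    def test_degenerate_expectation_errors(self):
        with pytest.raises(BatVisionError):
            poisson_tail_test(2, 0.0)
        with pytest.raises(ValueError):
            poisson_tail_test(-1, 1.0)
        with pytest.raises(ValueError):
            poisson_tail_test(1.5, 1.0)


class TestScan:
    def test_injected_parallel_signal_detected(self):
        """Codon simulation in the study regime; two injected parallel
        replacements on the focal pair are flagged and significant."""
        tree, clades = make_study_like_fixture(4)
        b1 = tree.stem_branch(clades["Pteropodidae"])
        b2 = tree.stem_branch(clades["Emballonuroidea"])
        rec = simulate_alignment(tree, CodonModel(2.0, 0.08), 287, seed=77)
        rec = inject_convergence(rec, [30, 120], (b1, b2), "TGG")
        res = run_convergence_scan(tree, rec.alignment,
                                   [BranchPair(b1, b2)], model="poisson")[0]
        flagged = ({site for site, *_ in res.parallel_sites} |
                   {site for site, *_ in res.convergent_sites})
        assert {31, 121} <= flagged
        assert res.p_combined < 0.05

    def test_null_simulation_is_calibrated(self):
        """Median p over null replicates is large and the p-values are not
        anticonservative (one-sided KS against uniform)."""
        tree, clades = make_study_like_fixture(8)
        b1 = tree.stem_branch(clades["Pteropodidae"])
        b2 = tree.stem_branch(clades["Emballonuroidea"])
        pvals = []
        for seed in range(30):
            rec = simulate_alignment(tree, CodonModel(2.0, 0.08), 287,
                                     seed=1000 + seed)
            res = run_convergence_scan(tree, rec.alignment,
                                       [BranchPair(b1, b2)],
                                       model="poisson")[0]
            pvals.append(res.p_par)
        pvals = np.asarray(pvals)
        assert np.median(pvals) > 0.3
        dplus = max(np.mean(pvals <= x) - x for x in np.linspace(0.01, 1, 100))
        assert dplus < 0.25  # scaled-down replicate count, looser bound

    def test_conserved_panel_annotation(self):
        from batvision.codonseq import ProteinAlignment
        tree, clades = make_study_like_fixture(4)
        b1 = tree.stem_branch(clades["Pteropodidae"])
        b2 = tree.stem_branch(clades["Emballonuroidea"])
        rec = simulate_alignment(tree, CodonModel(2.0, 0.08), 100, seed=13)
        rec = inject_convergence(rec, [40], (b1, b2), "TGG")
        panel = ProteinAlignment(["m1", "m2"], ["P" * 100, "P" * 100])
        res = run_convergence_scan(tree, rec.alignment, [BranchPair(b1, b2)],
                                   conserved_panel=panel)[0]
        if res.parallel_sites or res.convergent_sites:
            assert all(res.conserved.values())

    def test_resolve_pair_from_clades(self, study_fixture):
        tree, clades = study_fixture
        pair = resolve_pair(tree, clades["Pteropodidae"],
                            clades["Emballonuroidea"])
        assert tree.leafset(pair.b1) == frozenset(clades["Pteropodidae"])
        assert tree.leafset(pair.b2) == frozenset(clades["Emballonuroidea"])
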