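"""Self-validation suite: oracle comparisons, closed forms, recovery and
calibration experiments.

These routines re-derive the package's key quantities from scratch —
exhaustive-enumeration likelihoods, closed-form statistics, simulation-
based parameter recovery and test calibration — and are what the
acceptance script and the acceptance tests execute.  Every routine is
deterministic given its seed.
"""

from __future__ import annotations

import itertools

import numpy as np

from .ancestral import marginal_asr
from .codonseq import CodonAlignment, ProteinAlignment
from .convergence import BranchPair, run_convergence_scan
from .distances import DistanceMatrix, nj_tree
from .evomodels import (
    AA_ALPHABET, AminoAcidModel, CodonModel, Eigensystem, fit_m0,
    pruning_loglik,
)
from .simulate import inject_convergence, make_study_like_fixture, simulate_alignment
from .trees import read_newick, robinson_foulds


def _subseed(seed: int, k: int) -> int:
    return int((seed * 100_003 + k * 7919) % (2 ** 31 - 1))


def random_tree(n_leaves: int, seed: int, lo=0.01, hi=0.3):
    """Balanced binary topology, seeded uniform branch lengths."""
    names = [f"t{i}" for i in range(n_leaves)]

    def nest(ns):
        if len(ns) == 1:
            return ns[0]
        h = len(ns) // 2
        return f"({nest(ns[:h])},{nest(ns[h:])})"

    tree = read_newick(nest(names) + ";")
    rng = np.random.default_rng(seed)
    tree.length = rng.uniform(lo, hi, tree.n_nodes)
    tree.length[tree.root] = np.nan
    return tree


def _enumeration_loglik(tree, obs, P, pi):
    internals = tree.internal_indices()
    S = len(pi)
    n_sites = len(next(iter(obs.values())))
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


def pruning_enumeration_error(seed: int) -> dict:
    """Max relative error of the pruning lnL against exhaustive
    enumeration over internal states (codon quartet + protein 5-taxon)."""
    errors = []
    # 61-state quartet, 5 sites
    tree = read_newick("((A:0.1,B:0.2):0.15,(C:0.3,D:0.05):0.08);")
    model = CodonModel(2.0, 0.5)
    rng = np.random.default_rng(_subseed(seed, 1))
    codons = model.code.sense_codons
    aln = CodonAlignment(["A", "B", "C", "D"],
                         ["".join(rng.choice(codons, 5)) for _ in range(4)])
    Q, pi = model.rate_matrix()
    eig = Eigensystem(Q, pi)
    P = {v: eig.transition(tree.length[v])
         for v in range(tree.n_nodes) if v != tree.root}
    idx = {c: k for k, c in enumerate(codons)}
    obs = {tree.node_by_name(t): [idx[aln.codon(r, s)] for s in range(5)]
           for r, t in enumerate(aln.taxa)}
    lnL = pruning_loglik(tree, aln, model)
    lnL_bf = _enumeration_loglik(tree, obs, P, pi)
    errors.append(abs(lnL - lnL_bf) / abs(lnL_bf))
    # 20-state 5-taxon unrooted, 6 sites
    tree = read_newick("((A:0.2,B:0.1):0.1,(C:0.3,D:0.15):0.05,E:0.4);")
    model = AminoAcidModel.jtt()
    rng = np.random.default_rng(_subseed(seed, 2))
    aln = ProteinAlignment(["A", "B", "C", "D", "E"],
                           ["".join(rng.choice(list(AA_ALPHABET), 6))
                            for _ in range(5)])
    Q, pi = model.rate_matrix()
    eig = Eigensystem(Q, pi)
    P = {v: eig.transition(tree.length[v])
         for v in range(tree.n_nodes) if v != tree.root}
    idx = {a: k for k, a in enumerate(AA_ALPHABET)}
    obs = {tree.node_by_name(t): [idx[c] for c in aln.seqs[r]]
           for r, t in enumerate(aln.taxa)}
    lnL = pruning_loglik(tree, aln, model)
    lnL_bf = _enumeration_loglik(tree, obs, P, pi)
    errors.append(abs(lnL - lnL_bf) / abs(lnL_bf))
    return {"value": float(max(errors)), "n": 11}


def asr_enumeration_error(seed: int) -> dict:
    """Max absolute deviation of marginal ASR posteriors from the direct
    Bayes enumeration on a 5-taxon protein tree."""
    tree = read_newick("((a:0.2,b:0.1):0.12,(c:0.3,d:0.15):0.07,e:0.25);")
    model = AminoAcidModel.poisson()
    rng = np.random.default_rng(_subseed(seed, 3))
    aln = ProteinAlignment(
        ["a", "b", "c", "d", "e"],
        ["".join(rng.choice(list(AA_ALPHABET), 5)) for _ in range(5)])
    asr = marginal_asr(tree, aln, model)
    Q, pi = model.rate_matrix()
    eig = Eigensystem(Q, pi)
    P = {v: eig.transition(tree.length[v])
         for v in range(tree.n_nodes) if v != tree.root}
    idx = {a: k for k, a in enumerate(AA_ALPHABET)}
    internals = tree.internal_indices()
    obs = {tree.node_by_name(t): [idx[c] for c in aln.seqs[r]]
           for r, t in enumerate(aln.taxa)}
    worst = 0.0
    n_sites = 5
    post = {v: np.zeros((n_sites, 20)) for v in internals}
    for s in range(n_sites):
        for assignment in itertools.product(range(20), repeat=len(internals)):
            state = dict(zip(internals, assignment))
            for leaf, seq in obs.items():
                state[leaf] = seq[s]
            term = pi[state[tree.root]]
            for v in range(tree.n_nodes):
                if v != tree.root:
                    term *= P[v][state[tree.parent[v]], state[v]]
            for v in internals:
                post[v][s, state[v]] += term
        for v in internals:
            post[v][s] /= post[v][s].sum()
    for v in internals:
        worst = max(worst, float(np.abs(asr.posteriors[v] - post[v]).max()))
    return {"value": worst, "n": n_sites * len(internals)}


def poisson_tail_closed_form() -> dict:
    from .convergence import poisson_tail_test
    return {"value": float(poisson_tail_test(3, 1.0)), "n": 1}


def chi2_quantile_anchor() -> dict:
    from scipy.stats import chi2
    return {"value": float(chi2.sf(3.841, 1)), "n": 1}


def nj_additive_recovery(seed: int) -> dict:
    """RF distance between a random 8-taxon tree and the NJ tree rebuilt
    from its exact additive path-length matrix (0 = exact recovery)."""
    tree = random_tree(8, _subseed(seed, 4), lo=0.03, hi=0.3)
    leaves = tree.leaf_indices()
    names = [tree.name[v] for v in leaves]

    def path(v):
        out = {}
        while tree.parent[v] != -1:
            out[v] = tree.length[v]
            v = tree.parent[v]
        return out

    paths = [path(v) for v in leaves]
    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = set(paths[i]) & set(paths[j])
            d[i, j] = d[j, i] = (
                sum(t for v, t in paths[i].items() if v not in shared) +
                sum(t for v, t in paths[j].items() if v not in shared))
    recovered = nj_tree(DistanceMatrix(names, d))
    return {"value": float(robinson_foulds(tree, recovered)), "n": n}


def equal_rate_expectation_error(seed: int) -> dict:
    """Relative error of E_par against the closed form S*d1*d2/19 under the
    equal-rate model with all ancestral states shared."""
    from .convergence import expected_counts
    tree = random_tree(8, _subseed(seed, 5))
    b1, b2 = tree.children[tree.root][0], tree.children[tree.root][1]
    model = AminoAcidModel.poisson()
    n_sites = 40
    rec = simulate_alignment(tree, model, n_sites, seed=_subseed(seed, 6))
    asr = marginal_asr(tree, rec.alignment, model)
    for p in {tree.parent[b1], tree.parent[b2]}:
        asr.map_states[p] = np.zeros(n_sites, dtype=int)
    e_par, _ = expected_counts(tree, model, asr, BranchPair(b1, b2))
    Q, pi = model.rate_matrix()
    eig = Eigensystem(Q, pi)
    d1 = 1.0 - eig.transition(tree.length[b1])[0, 0]
    d2 = 1.0 - eig.transition(tree.length[b2])[0, 0]
    closed = n_sites * d1 * d2 / 19.0
    return {"value": float(abs(e_par - closed) / closed), "n": n_sites}


def m0_omega_recovery(seed: int, n_taxa: int = 16, n_codons: int = 3000,
                      n_rep: int = 20, omega: float = 0.08,
                      kappa: float = 2.0) -> dict:
    """Median M0 ω̂ over seeded replicates of the study-like regime."""
    estimates = []
    for r in range(n_rep):
        tree = random_tree(n_taxa, _subseed(seed, 10 + r))
        rec = simulate_alignment(tree, CodonModel(kappa, omega), n_codons,
                                 seed=_subseed(seed, 200 + r))
        fit = fit_m0(tree, rec.alignment)
        estimates.append(fit.model.omega)
    med = float(np.median(estimates))
    return {
        "median_omega": med,
        "pct_err": 100.0 * abs(med - omega) / omega,
        "estimates": [float(x) for x in estimates],
        "true_omega": omega,
        "n": n_rep,
    }


def _scan_focal_pair(tree, clades, alignment):
    b1 = tree.stem_branch(clades["Pteropodidae"])
    b2 = tree.stem_branch(clades["Emballonuroidea"])
    res = run_convergence_scan(tree, alignment, [BranchPair(b1, b2)],
                               model="poisson")[0]
    return res


def convergence_null_calibration(seed: int, n_rep: int = 200,
                                 n_codons: int = 287) -> dict:
    """One-sided KS statistic (anticonservatism) of the parallel-site
    p-value against uniform under null codon simulations."""
    pvals = []
    for r in range(n_rep):
        tree, clades = make_study_like_fixture(_subseed(seed, 1000 + r))
        rec = simulate_alignment(tree, CodonModel(2.0, 0.08), n_codons,
                                 seed=_subseed(seed, 3000 + r))
        pvals.append(_scan_focal_pair(tree, clades, rec.alignment).p_par)
    pvals = np.sort(np.asarray(pvals))
    grid = np.unique(np.concatenate([pvals, [1.0]]))
    d_plus = max(float((pvals <= x).mean() - x) for x in grid)
    return {"ks_plus": max(d_plus, 0.0), "median_p": float(np.median(pvals)),
            "n": n_rep}


def injected_parallel_power(seed: int, n_rep: int = 100,
                            n_codons: int = 287, n_sites: int = 2) -> dict:
    """Fraction of replicates in which 2 injected parallel replacements on
    the focal pair yield p_par < 0.05."""
    import warnings
    hits = 0
    for r in range(n_rep):
        tree, clades = make_study_like_fixture(_subseed(seed, 5000 + r))
        b1 = tree.stem_branch(clades["Pteropodidae"])
        b2 = tree.stem_branch(clades["Emballonuroidea"])
        rec = simulate_alignment(tree, CodonModel(2.0, 0.08), n_codons,
                                 seed=_subseed(seed, 7000 + r))
        rng = np.random.default_rng(_subseed(seed, 9000 + r))
        sites = rng.choice(n_codons, size=n_sites, replace=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = inject_convergence(rec, [int(s) for s in sites],
                                     (b1, b2), "TGG")
        res = _scan_focal_pair(tree, clades, rec.alignment)
        hits += res.p_par < 0.05
    return {"power_pct": 100.0 * hits / n_rep, "n": n_rep}
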