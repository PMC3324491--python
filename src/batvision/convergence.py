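"""Parallel/convergent substitution detection on a designated branch pair.

Two independently evolving branches may arrive at the same amino acid by
chance; this module quantifies how surprising the observed number of such
events is.  Following the ancestral-reconstruction approach:

* a site is **parallel** when both branches change with identical
  ancestral and identical derived states (P -> A on both);
* **convergent** when the derived states agree but the ancestral states
  differ (T -> A and S -> A);

and the model-based expectation, with the parent states a1, a2 plugged in
at their MAP reconstructions, is

    E_par  = Σ_{sites: a1=a2=a}  Σ_{y≠a}        P_b1(a→y)  P_b2(a→y)
    E_conv = Σ_{sites: a1≠a2}    Σ_{y∉{a1,a2}}  P_b1(a1→y) P_b2(a2→y)

The observed count is compared to a Poisson distribution with that mean
(upper tail), the classical parallel-site test.  Both an equal-rate
(Poisson) and an empirical (JTT) amino acid model are available for the
transition probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson

from .ancestral import AncestralStates, changes_by_branch, map_substitutions, marginal_asr
from .codonseq import CodonAlignment, translate_alignment
from .errors import BatVisionError, ModelError
from .evomodels import AminoAcidModel, Eigensystem, fit_protein_branch_lengths
from .trees import PhyloTree


@dataclass(frozen=True)
class BranchPair:
    """Two focal branches, neither ancestral to the other."""

    b1: int
    b2: int

    def validate(self, tree: PhyloTree) -> "BranchPair":
        if self.b1 == self.b2:
            raise BatVisionError("branch pair must name two distinct branches")
        if tree.is_ancestor(self.b1, self.b2) or tree.is_ancestor(self.b2, self.b1):
            raise BatVisionError(
                f"branches {self.b1} and {self.b2} are nested; the test "
                "requires independent lineages")
        return self


@dataclass
class ConvergenceResult:
    """Observed/expected parallel and convergent counts and Poisson tails."""

    pair: BranchPair
    branch_names: tuple
    parallel_sites: list          # [(site, anc, derived)]
    convergent_sites: list        # [(site, anc1, anc2, derived)]
    E_par: float
    E_conv: float
    p_par: float
    p_conv: float
    p_combined: float
    model_name: str
    conserved: dict = field(default_factory=dict)  # site -> bool (reference panel)

    @property
    def n_par(self) -> int:
        return len(self.parallel_sites)

    @property
    def n_conv(self) -> int:
        return len(self.convergent_sites)

    def notation(self) -> list:
        out = [f"{anc}{site}{der}" for site, anc, der in self.parallel_sites]
        out += [f"{a1}/{a2}{site}{der}" for site, a1, a2, der in self.convergent_sites]
        return out

    def to_dict(self) -> dict:
        return {
            "branches": list(self.branch_names),
            "n_parallel": self.n_par,
            "parallel_sites": [list(x) for x in self.parallel_sites],
            "n_convergent": self.n_conv,
            "convergent_sites": [list(x) for x in self.convergent_sites],
            "E_parallel": self.E_par,
            "E_convergent": self.E_conv,
            "p_parallel": self.p_par,
            "p_convergent": self.p_conv,
            "p_combined": self.p_combined,
            "expectation_model": self.model_name,
            "conserved_in_panel": {str(k): v for k, v in self.conserved.items()},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def classify_pair_changes(changes_b1, changes_b2):
    """Split co-occurring changes into parallel and convergent sites.

    Inputs are the :class:`~batvision.ancestral.BranchChange` lists of the
    two branches.  Returns ``(parallel, convergent)`` in the
    :class:`ConvergenceResult` site-tuple formats; co-occurring changes
    with different derived states are neither.
    """
    by_site_1 = {ch.site: ch for ch in changes_b1}
    by_site_2 = {ch.site: ch for ch in changes_b2}
    parallel, convergent = [], []
    for site in sorted(set(by_site_1) & set(by_site_2)):
        c1, c2 = by_site_1[site], by_site_2[site]
        if c1.to_state != c2.to_state:
            continue
        if c1.from_state == c2.from_state:
            parallel.append((site, c1.from_state, c1.to_state))
        else:
            convergent.append((site, c1.from_state, c2.from_state, c1.to_state))
    return parallel, convergent


def expected_counts(tree: PhyloTree, model: AminoAcidModel,
                    asr: AncestralStates, pair: BranchPair,
                    use_map: bool = True):
    """Model-based expected parallel and convergent counts for a pair.

    With ``use_map`` the parent states are plugged in at their MAP values;
    otherwise the per-site expectation is averaged over the joint (assumed
    independent) parent-state posteriors — the robustness option.
    """
    pair.validate(tree)
    Q, pi = model.rate_matrix()
    eig = Eigensystem(Q, pi)
    P1 = eig.transition(tree.length[pair.b1])
    P2 = eig.transition(tree.length[pair.b2])
    S = len(pi)
    p1, p2 = tree.parent[pair.b1], tree.parent[pair.b2]
    for parent in (p1, p2):
        if parent not in asr.map_states:
            raise ModelError(f"no ancestral reconstruction at node {parent}")

    # site-independent (a1, a2) -> expectation kernels
    off1 = P1.copy(); np.fill_diagonal(off1, 0.0)
    par_kernel = (P1 * P2).sum(axis=1) - np.diag(P1) * np.diag(P2)  # a -> Σ_{y≠a}
    conv_kernel = P1 @ P2.T  # (a1,a2) -> Σ_y P1[a1,y] P2[a2,y]

    def pair_expectation(a1, a2):
        if a1 == a2:
            return float(par_kernel[a1]), 0.0
        e = conv_kernel[a1, a2] - P1[a1, a2] * P2[a2, a2] - P1[a1, a1] * P2[a2, a1]
        return 0.0, float(e)

    n_sites = asr.n_sites
    E_par = E_conv = 0.0
    if use_map:
        s1 = asr.map_states[p1]
        s2 = asr.map_states[p2]
        for site in range(n_sites):
            ep, ec = pair_expectation(int(s1[site]), int(s2[site]))
            E_par += ep
            E_conv += ec
    else:
        post1 = asr.posteriors[p1]
        post2 = asr.posteriors[p2]
        EP = np.array([[pair_expectation(a1, a2)[0] for a2 in range(S)]
                       for a1 in range(S)])
        EC = np.array([[pair_expectation(a1, a2)[1] for a2 in range(S)]
                       for a1 in range(S)])
        joint = np.einsum("si,sj->ij", post1, post2)
        E_par = float((joint * EP).sum())
        E_conv = float((joint * EC).sum())
    return E_par, E_conv


def poisson_tail_test(n: int, E: float) -> float:
    """Upper-tail probability P(X >= n) for X ~ Poisson(E); n = 0 -> 1."""
    if n < 0 or int(n) != n:
        raise ValueError(f"count must be a nonnegative integer, got {n}")
    if n == 0:
        return 1.0
    if E <= 0:
        raise BatVisionError(
            f"degenerate expectation E={E} with observed count {n}")
    return float(poisson.sf(n - 1, E))


def resolve_pair(tree: PhyloTree, clade_a, clade_b) -> BranchPair:
    """Branch pair from two clade definitions (stem branches of the MRCAs)."""
    return BranchPair(tree.stem_branch(clade_a), tree.stem_branch(clade_b)).validate(tree)


def run_convergence_scan(tree: PhyloTree, aln, pairs,
                         model: str = "poisson", use_map: bool = True,
                         fit_lengths: bool = True,
                         conserved_panel=None) -> list:
    """End-to-end convergence test: ASR -> substitution maps -> statistics.

    ``pairs`` is a list of :class:`BranchPair` (see :func:`resolve_pair`).
    ``model`` chooses the amino acid process for both reconstruction and
    expectations: "poisson" (equal-rate) or "jtt" (empirical), or a
    prebuilt :class:`AminoAcidModel`.  When ``fit_lengths`` the tree's
    branch lengths are re-estimated on the protein alignment (amino acid
    substitutions/site), which is what the expectation formulas assume.
    ``conserved_panel`` is an optional protein alignment of reference taxa
    used to annotate whether each flagged site is invariant outside the
    study group.
    """
    if isinstance(model, AminoAcidModel):
        aa_model = model
    elif model == "poisson":
        aa_model = AminoAcidModel.poisson()
    elif model == "jtt":
        aa_model = AminoAcidModel.jtt()
    else:
        raise ModelError(f"unknown expectation model {model!r}")
    protein = translate_alignment(aln) if isinstance(aln, CodonAlignment) else aln
    work = tree.copy()
    if fit_lengths:
        work, _lnL = fit_protein_branch_lengths(work, protein, aa_model)
    asr = marginal_asr(work, protein, aa_model)
    by_branch = changes_by_branch(map_substitutions(work, asr, protein))
    results = []
    for pair in pairs:
        pair.validate(work)
        parallel, convergent = classify_pair_changes(
            by_branch.get(pair.b1, []), by_branch.get(pair.b2, []))
        E_par, E_conv = expected_counts(work, aa_model, asr, pair, use_map=use_map)
        n_par, n_conv = len(parallel), len(convergent)
        p_par = poisson_tail_test(n_par, E_par) if (n_par == 0 or E_par > 0) else 0.0
        p_conv = poisson_tail_test(n_conv, E_conv) if (n_conv == 0 or E_conv > 0) else 0.0
        E_tot = E_par + E_conv
        n_tot = n_par + n_conv
        p_comb = poisson_tail_test(n_tot, E_tot) if (n_tot == 0 or E_tot > 0) else 0.0
        conserved = {}
        if conserved_panel is not None:
            for site, *_rest in parallel + convergent:
                column = {seq[site - 1] for seq in conserved_panel.seqs}
                column -= {"-", "X"}
                conserved[site] = len(column) == 1
        names = tuple(
            (work.name[b] or ",".join(sorted(work.leafset(b))[:2]) + "...")
            for b in (pair.b1, pair.b2))
        results.append(ConvergenceResult(
            pair=pair, branch_names=names,
            parallel_sites=parallel, convergent_sites=convergent,
            E_par=E_par, E_conv=E_conv,
            p_par=p_par, p_conv=p_conv, p_combined=p_comb,
            model_name=aa_model.name, conserved=conserved))
    return results
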