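"""Marginal ML ancestral reconstruction and per-branch substitution maps.

For each internal node and site, the marginal posterior over states is the
normalized product of the inside (below-node) and outside (rest-of-tree)
conditional likelihoods with the equilibrium prior — computed under a
fitted reversible model, so posteriors are invariant to the root position
away from the queried node.  The MAP state at every node then induces a
substitution map: a branch carries a change at a site whenever the MAP
state of its parent differs from the (MAP or observed) state of its child.
These branch-annotated replacements — "P133A on the Pteropodidae stem" —
are the substrate of the convergence test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codonseq import CodonAlignment, translate_alignment
from .errors import ModelError
from .evomodels import (
    AminoAcidModel, CodonModel, Eigensystem, PruningEngine, encode_alignment,
)
from .trees import PhyloTree

MISSING = ("-", "X")


@dataclass
class AncestralStates:
    """Per (node, site) posterior distribution and MAP state."""

    level: str                    # "aa" | "codon"
    alphabet: tuple
    tree: PhyloTree
    posteriors: dict              # node -> (n_sites, S)
    map_states: dict              # node -> np.ndarray of state indices
    low_confidence: dict          # node -> bool array (max posterior < 0.5)

    def map_symbol(self, node: int, site: int) -> str:
        return self.alphabet[self.map_states[node][site]]

    def map_sequence(self, node: int) -> str:
        return "".join(self.alphabet[s] for s in self.map_states[node])

    @property
    def n_sites(self) -> int:
        first = next(iter(self.map_states.values()))
        return len(first)

    def to_tsv(self, include_distribution: bool = False) -> str:
        """TSV of (node, site, MAP, posterior[, full distribution])."""
        lines = ["node\tsite\tmap_state\tposterior" +
                 ("\tdistribution" if include_distribution else "")]
        for node in sorted(self.posteriors):
            post = self.posteriors[node]
            for s in range(post.shape[0]):
                k = self.map_states[node][s]
                row = f"{node}\t{s + 1}\t{self.alphabet[k]}\t{post[s, k]:.4f}"
                if include_distribution:
                    row += "\t" + ",".join("%.4g" % v for v in post[s])
                lines.append(row)
        return "\n".join(lines) + "\n"


@dataclass
class BranchChange:
    """One inferred substitution on one branch (1-based protein site)."""

    branch: int
    site: int
    from_state: str
    to_state: str

    def __post_init__(self):
        if self.from_state == self.to_state:
            raise ValueError("a change needs distinct states")

    @property
    def notation(self) -> str:
        return f"{self.from_state}{self.site}{self.to_state}"


def marginal_asr(tree: PhyloTree, aln, model, level: str = None) -> AncestralStates:
    """Marginal posterior state distributions at every internal node.

    ``model`` must carry fitted parameters and ``tree`` fitted branch
    lengths (an unfitted tree raises).  The reconstruction level follows
    the model: amino acid for :class:`AminoAcidModel` (the default for
    protein-level replacement maps), codon for :class:`CodonModel`.
    MAP ties are broken toward the alphabetically first state.
    """
    non_root = [v for v in range(tree.n_nodes) if v != tree.root]
    if not np.isfinite(tree.length[non_root]).all():
        raise ModelError("tree has unfitted branch lengths; fit the model first")
    if isinstance(model, AminoAcidModel):
        level = "aa"
        if isinstance(aln, CodonAlignment):
            aln = translate_alignment(aln)
        Q, pi = model.rate_matrix()
        alphabet = tuple(model.alphabet)
    elif isinstance(model, CodonModel):
        level = "codon"
        Q, pi = model.rate_matrix()
        alphabet = model.code.sense_codons
    else:
        raise ModelError(f"unsupported model type {type(model).__name__}")
    data = encode_alignment(aln, model)
    engine = PruningEngine(tree, data)
    eig = Eigensystem(Q, pi)
    P = {v: eig.transition(tree.length[v]) for v in non_root}
    pattern_post = engine.node_posteriors(P, pi)
    posteriors, map_states, lowconf = {}, {}, {}
    for v in tree.internal_indices():
        post = pattern_post[v][data.site_to_pattern]
        posteriors[v] = post
        map_states[v] = post.argmax(axis=1)  # ties -> lowest index = alphabetical
        lowconf[v] = post.max(axis=1) < 0.5
    return AncestralStates(level=level, alphabet=alphabet, tree=tree,
                           posteriors=posteriors, map_states=map_states,
                           low_confidence=lowconf)


def _leaf_observed(aln, taxon: str, level: str, alphabet) -> list:
    seq = aln.sequence_of(taxon)
    if level == "codon":
        return [seq[3 * j: 3 * j + 3] for j in range(len(seq) // 3)]
    return list(seq)


def map_substitutions(tree: PhyloTree, asr: AncestralStates, aln) -> list:
    """Every branch/site where the parent MAP differs from the child state.

    For leaf branches the child state is the observed one (gaps and
    ambiguity skipped); for internal branches it is the child's MAP.
    Returns a list of :class:`BranchChange` with 1-based sites.
    """
    if isinstance(aln, CodonAlignment) and asr.level == "aa":
        aln = translate_alignment(aln)
    changes = []
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p == -1:
            continue
        parent_seq = [asr.alphabet[s] for s in asr.map_states[p]]
        if tree.is_leaf(v):
            child_seq = _leaf_observed(aln, tree.name[v], asr.level, asr.alphabet)
        else:
            child_seq = [asr.alphabet[s] for s in asr.map_states[v]]
        for s, (a, b) in enumerate(zip(parent_seq, child_seq)):
            if b in MISSING or a in MISSING:
                continue
            if a != b:
                changes.append(BranchChange(branch=v, site=s + 1,
                                            from_state=a, to_state=b))
    return changes


def changes_by_branch(changes) -> dict:
    out = {}
    for ch in changes:
        out.setdefault(ch.branch, []).append(ch)
    return out


def changes_to_tsv(changes, tree: PhyloTree = None) -> str:
    lines = ["branch\tbranch_name\tsite\tfrom\tto\tnotation"]
    for ch in changes:
        name = ""
        if tree is not None:
            name = tree.name[ch.branch] or "/".join(sorted(tree.leafset(ch.branch))[:2])
        lines.append(f"{ch.branch}\t{name}\t{ch.site}\t{ch.from_state}"
                     f"\t{ch.to_state}\t{ch.notation}")
    return "\n".join(lines) + "\n"


def annotated_newick(tree: PhyloTree, changes) -> str:
    """Newick with per-branch change strings as node comments."""
    by_branch = changes_by_branch(changes)

    def rec(v):
        label = tree.name[v] or ""
        if tree.is_leaf(v):
            s = label
        else:
            s = "(" + ",".join(rec(c) for c in tree.children[v]) + ")" + label
        if v in by_branch:
            notas = " ".join(ch.notation for ch in sorted(by_branch[v],
                                                          key=lambda c: c.site))
            s += f"[&changes={notas}]"
        if v != tree.root and np.isfinite(tree.length[v]):
            s += ":%.10g" % tree.length[v]
        return s

    return rec(tree.root) + ";"
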