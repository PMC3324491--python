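"""Synthetic data with known ground truth.

The generator evolves codon or amino acid sequences along a tree by
sampling, per branch and site, from the branch's transition distribution.
What is recorded is the *endpoint* state change on each branch — the same
granularity an ancestral-reconstruction-based analysis can see — so a
replay of the per-branch changes from the root reproduces every leaf
sequence exactly.

The study-like fixture mirrors the design of the bat dim-light-vision
analyses: ~24 taxa in five named chiropteran clades plus two outgroups,
with the Old World fruit bats (Pteropodidae) and the sheath-tailed bat
clade (Emballonuroidea) as the two non-sister focal lineages whose stem
branches carry the hypothesised convergent signal.  Default simulation
parameters follow the study regime: alignments of ~250-300 codons under a
one-ratio codon model with strong purifying selection (ω ≈ 0.08).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .codonseq import CodonAlignment, ProteinAlignment
from .errors import BatVisionError
from .evomodels import AminoAcidModel, CodonModel, Eigensystem
from .trees import PhyloTree, read_newick


@dataclass
class SimulationRecord:
    """Alignment plus the full truth that generated it."""

    seed: int
    tree: PhyloTree
    model: object
    level: str                      # "codon" | "aa"
    node_states: np.ndarray         # (n_nodes, n_sites) int state indices
    branch_changes: dict            # node -> [(site0, from_sym, to_sym)]
    alignment: object               # CodonAlignment | ProteinAlignment
    injection_log: list = field(default_factory=list)
    site_class: np.ndarray = None   # per-site class index when class-simulated

    @property
    def alphabet(self):
        return (self.model.code.sense_codons if self.level == "codon"
                else tuple(self.model.alphabet))

    def root_sequence(self) -> str:
        return "".join(self.alphabet[s] for s in self.node_states[self.tree.root])

    def replay_leaf(self, taxon: str) -> str:
        """Rebuild a leaf sequence by applying branch changes from the root."""
        tree = self.tree
        node = tree.node_by_name(taxon)
        path = [node]
        while tree.parent[path[-1]] != -1:
            path.append(tree.parent[path[-1]])
        states = list(self.node_states[tree.root])
        for v in reversed(path[:-1]):
            for site, _frm, to in self.branch_changes.get(v, []):
                states[site] = self.alphabet.index(to)
        return "".join(self.alphabet[s] for s in states)


def _transition_matrices(tree, model, site_class_spec):
    """Per-branch (and per site class) transition matrices.

    ``site_class_spec``: None for a homogeneous process, else a list of
    (proportion, omega_background, omega_foreground) tuples (codon models
    only); foreground applies to branches tagged nonzero.
    """
    if isinstance(model, AminoAcidModel):
        Q, pi = model.rate_matrix()
        eig = Eigensystem(Q, pi)
        mats = {v: [eig.transition(tree.length[v])]
                for v in range(tree.n_nodes) if v != tree.root}
        return mats, pi, [1.0]
    eig_cache = {}

    def eig_for(om):
        if om not in eig_cache:
            Q, pi = model.rate_matrix(om)
            eig_cache[om] = Eigensystem(Q, pi)
        return eig_cache[om]

    if site_class_spec is None:
        site_class_spec = [(1.0, model.omega, None)]
    props = [p for p, _, _ in site_class_spec]
    mats = {}
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        per_class = []
        for _, om_bg, om_fg in site_class_spec:
            om = om_fg if (tree.tag[v] and om_fg is not None) else om_bg
            per_class.append(eig_for(om).transition(tree.length[v]))
        mats[v] = per_class
    _, pi = model.rate_matrix(site_class_spec[0][1])
    return mats, pi, props


def simulate_alignment(tree: PhyloTree, model, n_sites: int, seed: int,
                       site_classes=None) -> SimulationRecord:
    """Evolve ``n_sites`` codon (or amino acid) sites along ``tree``.

    The root is drawn from the model's equilibrium frequencies; every
    branch is evolved by sampling each site's child state from the row of
    the branch's transition matrix.  Deterministic under ``seed``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not np.isfinite(tree.length[[v for v in range(tree.n_nodes)
                                    if v != tree.root]]).all():
        raise BatVisionError("tree must have branch lengths on every branch")
    rng = np.random.default_rng(seed)
    level = "codon" if isinstance(model, CodonModel) else "aa"
    mats, pi, props = _transition_matrices(tree, model, site_classes)
    S = len(pi)
    n_nodes = tree.n_nodes

    if site_classes is not None or len(props) > 1:
        site_class = rng.choice(len(props), size=n_sites, p=np.asarray(props) / sum(props))
    else:
        site_class = np.zeros(n_sites, dtype=int)

    states = np.empty((n_nodes, n_sites), dtype=np.int64)
    states[tree.root] = rng.choice(S, size=n_sites, p=pi)
    alphabet = (model.code.sense_codons if level == "codon" else tuple(model.alphabet))
    changes = {}
    for v in tree.preorder():
        if v == tree.root:
            continue
        parent_states = states[tree.parent[v]]
        child = np.empty(n_sites, dtype=np.int64)
        u = rng.random(n_sites)
        for k, P in enumerate(mats[v]):
            sel = site_class == k
            if not sel.any():
                continue
            cdf = np.cumsum(P[parent_states[sel]], axis=1)
            child[sel] = (u[sel, None] > cdf).sum(axis=1)
        np.clip(child, 0, S - 1, out=child)
        states[v] = child
        diff = np.nonzero(child != parent_states)[0]
        changes[v] = [(int(s), alphabet[parent_states[s]], alphabet[child[s]])
                      for s in diff]

    taxa, seqs = [], []
    for leaf in tree.leaf_indices():
        taxa.append(tree.name[leaf])
        seqs.append("".join(alphabet[s] for s in states[leaf]))
    if level == "codon":
        alignment = CodonAlignment(taxa, seqs, model.code)
    else:
        alignment = ProteinAlignment(taxa, seqs)
    return SimulationRecord(
        seed=seed, tree=tree, model=model, level=level, node_states=states,
        branch_changes=changes, alignment=alignment,
        site_class=site_class,
    )


def _subtree_nodes(tree, node):
    out, stack = [], [node]
    while stack:
        v = stack.pop()
        out.append(v)
        stack.extend(tree.children[v])
    return out


def inject_convergence(record: SimulationRecord, sites, pair,
                       derived_state: str) -> SimulationRecord:
    """Force the same derived state onto both focal lineages at ``sites``.

    ``pair`` is (node_b1, node_b2); every node at or below each focal
    branch is rewritten to carry ``derived_state`` at the chosen sites, the
    per-branch change logs are patched so the replay invariant still holds,
    and the injection is logged.  All other sites are untouched.  Sites
    where the focal branch's parent already carries the derived state are
    skipped with a warning.
    """
    b1, b2 = pair
    tree = record.tree
    if b1 == b2 or tree.is_ancestor(b1, b2) or tree.is_ancestor(b2, b1):
        raise BatVisionError("focal branches must be distinct and non-nested")
    alphabet = record.alphabet
    if derived_state not in alphabet:
        raise ValueError(f"derived state {derived_state!r} not in model alphabet")
    d_idx = alphabet.index(derived_state)
    for site in sites:
        if not 0 <= site < record.node_states.shape[1]:
            raise ValueError(f"site {site} out of range")
    for branch in (b1, b2):
        below = _subtree_nodes(tree, branch)
        parent = tree.parent[branch]
        for site in sites:
            anc = int(record.node_states[parent, site])
            if anc == d_idx:
                warnings.warn(
                    f"injection no-op: parent of branch {branch} already "
                    f"{derived_state} at site {site}")
                continue
            for v in below:
                record.node_states[v, site] = d_idx
            # patch the change logs: focal branch gains the forced change,
            # branches below it lose any change at that site
            record.branch_changes[branch] = [
                ch for ch in record.branch_changes.get(branch, []) if ch[0] != site
            ] + [(site, alphabet[anc], derived_state)]
            for v in below:
                if v == branch:
                    continue
                record.branch_changes[v] = [
                    ch for ch in record.branch_changes.get(v, []) if ch[0] != site
                ]
            record.injection_log.append(
                {"site": int(site), "branch": int(branch),
                 "from": alphabet[anc], "to": derived_state})
    # rebuild leaf sequences from node states
    taxa, seqs = [], []
    for leaf in tree.leaf_indices():
        taxa.append(tree.name[leaf])
        seqs.append("".join(alphabet[s] for s in record.node_states[leaf]))
    if record.level == "codon":
        record.alignment = CodonAlignment(taxa, seqs, record.model.code)
    else:
        record.alignment = ProteinAlignment(taxa, seqs)
    return record


STUDY_CLADES = {
    "Pteropodidae": ["Pteropus_vampyrus", "Pteropus_giganteus", "Rousettus_leschenaultii",
                     "Cynopterus_sphinx", "Eonycteris_spelaea"],
    "Rhinolophoidea": ["Rhinolophus_ferrumequinum", "Rhinolophus_pusillus",
                       "Hipposideros_armiger", "Megaderma_lyra"],
    "Emballonuroidea": ["Taphozous_melanopogon", "Taphozous_theobaldi",
                        "Emballonura_monticola", "Saccopteryx_bilineata"],
    "Noctilionoidea": ["Noctilio_leporinus", "Pteronotus_parnellii",
                       "Artibeus_jamaicensis", "Desmodus_rotundus"],
    "Vespertilionoidea": ["Myotis_lucifugus", "Myotis_ricketti", "Eptesicus_fuscus",
                          "Pipistrellus_abramus", "Miniopterus_fuliginosus"],
    "outgroups": ["Bos_taurus", "Canis_familiaris"],
}


def _ladder(names):
    if len(names) == 1:
        return names[0]
    return f"({names[0]},{_ladder(names[1:])})"


def make_study_like_fixture(seed: int):
    """A 24-leaf binary species tree shaped like the bat phylogeny.

    Yinpterochiroptera (Pteropodidae + Rhinolophoidea) is sister to
    Yangochiroptera (Emballonuroidea + (Noctilionoidea +
    Vespertilionoidea)); two laurasiatherian outgroups root the tree.
    Branch lengths are drawn uniformly from [0.01, 0.3].  Returns
    ``(tree, clades)`` where ``clades`` maps the five clade names (plus
    "outgroups") to their taxa; the focal branch pair is recovered with
    ``tree.stem_branch(clades["Pteropodidae"])`` etc.
    """
    c = STUDY_CLADES
    bats = (f"(({_ladder(c['Pteropodidae'])},{_ladder(c['Rhinolophoidea'])}),"
            f"({_ladder(c['Emballonuroidea'])},"
            f"({_ladder(c['Noctilionoidea'])},{_ladder(c['Vespertilionoidea'])})))")
    newick = f"({c['outgroups'][0]},({c['outgroups'][1]},{bats}));"
    tree = read_newick(newick)
    rng = np.random.default_rng(seed)
    lengths = rng.uniform(0.01, 0.3, size=tree.n_nodes)
    lengths[tree.root] = np.nan
    tree.length = lengths
    return tree, {k: list(v) for k, v in c.items()}
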