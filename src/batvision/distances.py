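"""Li-Wu-Luo synonymous/nonsynonymous distances and neighbor-joining.

The Li-Wu-Luo (LWL) method allocates each codon position to a 0-, 2- or
4-fold degenerate class, counts transitional (P) and transversional (Q)
difference proportions per class, applies Kimura-type corrections

    a_i = 1 / (1 - 2 P_i - Q_i)        A_i = ln(a_i)/2 - ln(b_i)/4
    b_i = 1 / (1 - 2 Q_i)              B_i = ln(b_i)/2

and combines classes with the convention that all 0-fold and two thirds of
the 2-fold sites are nonsynonymous while one third of the 2-fold and all
4-fold sites are synonymous:

    Ks = 3 [L2 A2 + L4 (A4 + B4)] / (L2 + 3 L4)
    Ka = 3 [L2 B2 + L0 (A0 + B0)] / (2 L2 + 3 L0)

Neighbor-joining (Saitou-Nei agglomeration with the rate-corrected
selection criterion) is implemented natively and returns an unrooted
binary tree; trees built from Ka or Ks matrices reproduce the
"nonsynonymous-sites" / "synonymous-sites" topologies of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .codonseq import (
    NUCLEOTIDES, CodonAlignment, GeneticCode, STANDARD_CODE,
    classify_degeneracy, is_transition,
)
from .errors import SaturationError
from .trees import PhyloTree

_CLASSES = (0, 2, 4)


@dataclass
class LwlResult:
    """Per-class site counts, difference proportions, corrected distances."""

    L0: float
    L2: float
    L4: float
    P0: float
    P2: float
    P4: float
    Q0: float
    Q2: float
    Q4: float
    A0: float
    A2: float
    A4: float
    B0: float
    B2: float
    B4: float
    Ka: float
    Ks: float
    n_codons: int

    @property
    def ka_ks(self) -> float:
        return self.Ka / self.Ks if self.Ks > 0 else float("nan")


def _is_sense(codon: str, code: GeneticCode) -> bool:
    return code.table.get(codon) is not None and code.table[codon] != "*"


def _path_steps(codon_a: str, codon_b: str, code: GeneticCode):
    """Steps (pre-codon, post-codon, position) averaged over parsimonious orderings.

    Yields (weight, X, Y, pos) for every step of every valid mutational
    ordering from codon_a to codon_b; orderings passing through a stop codon
    are discarded unless all are blocked, in which case all are kept.
    """
    diff = [p for p in range(3) if codon_a[p] != codon_b[p]]
    paths = []
    for order in permutations(diff):
        x = codon_a
        steps, blocked = [], False
        for p in order:
            y = x[:p] + codon_b[p] + x[p + 1:]
            if code.is_stop(y) and y != codon_b:
                blocked = True
            steps.append((x, y, p))
            x = y
        paths.append((steps, blocked))
    valid = [s for s, blocked in paths if not blocked]
    if not valid:
        valid = [s for s, _ in paths]
    w = 1.0 / len(valid)
    for steps in valid:
        for x, y, p in steps:
            yield w, x, y, p


def lwl_distance(seq_a: str, seq_b: str, code: GeneticCode = STANDARD_CODE,
                 require=("ka", "ks")) -> LwlResult:
    """Li-Wu-Luo Ka and Ks between two equal-length in-frame sequences.

    Codon sites containing gaps, ambiguity or stop codons in either
    sequence are skipped.  Site-class counts average the two sequences'
    per-position degeneracy classes; multi-position codon differences are
    averaged over the equally weighted parsimonious mutational orderings,
    classifying each step by the mean class of its flanking codons.

    A degeneracy class whose correction logarithm is undefined (saturated
    divergence) raises when a distance in ``require`` depends on it
    (Ks on the 2- and 4-fold classes, Ka on the 0- and 2-fold); otherwise
    the affected quantities are reported as NaN.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    if len(seq_a) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    L = dict.fromkeys(_CLASSES, 0.0)
    ts = dict.fromkeys(_CLASSES, 0.0)
    tv = dict.fromkeys(_CLASSES, 0.0)
    n_codons = 0
    for j in range(len(seq_a) // 3):
        ca, cb = seq_a[3 * j: 3 * j + 3], seq_b[3 * j: 3 * j + 3]
        if not (_is_sense(ca, code) and _is_sense(cb, code)):
            continue
        n_codons += 1
        for pos in (1, 2, 3):
            L[classify_degeneracy(ca, pos, code)] += 0.5
            L[classify_degeneracy(cb, pos, code)] += 0.5
        if ca != cb:
            for w, x, y, p in _path_steps(ca, cb, code):
                cls_x = classify_degeneracy(x, p + 1, code) if _is_sense(x, code) else None
                cls_y = classify_degeneracy(y, p + 1, code) if _is_sense(y, code) else None
                bucket = ts if is_transition(x[p], y[p]) else tv
                for cls in (cls_x, cls_y):
                    if cls is not None:
                        bucket[cls] += 0.5 * w

    require = {r.lower() for r in require}
    P, Q, A, B = {}, {}, {}, {}
    saturated = {}
    for c in _CLASSES:
        P[c] = ts[c] / L[c] if L[c] > 0 else 0.0
        Q[c] = tv[c] / L[c] if L[c] > 0 else 0.0
        arg_a = 1.0 - 2.0 * P[c] - Q[c]
        arg_b = 1.0 - 2.0 * Q[c]
        if arg_a <= 0 or arg_b <= 0:
            saturated[c] = (f"saturated {c}-fold class: "
                            f"1-2P-Q={arg_a:.4g}, 1-2Q={arg_b:.4g}")
            A[c] = B[c] = float("nan")
            continue
        A[c] = 0.5 * np.log(1.0 / arg_a) - 0.25 * np.log(1.0 / arg_b)
        B[c] = 0.5 * np.log(1.0 / arg_b)
    for c in sorted(saturated):
        needed = (("ks" in require and c in (2, 4)) or
                  ("ka" in require and c in (0, 2)))
        if needed:
            raise SaturationError(saturated[c], degeneracy_class=c)

    syn_sites = L[2] + 3.0 * L[4]
    nonsyn_sites = 2.0 * L[2] + 3.0 * L[0]
    Ks = 3.0 * (L[2] * A[2] + L[4] * (A[4] + B[4])) / syn_sites if syn_sites > 0 else float("nan")
    Ka = 3.0 * (L[2] * B[2] + L[0] * (A[0] + B[0])) / nonsyn_sites if nonsyn_sites > 0 else float("nan")
    return LwlResult(
        L0=L[0], L2=L[2], L4=L[4],
        P0=P[0], P2=P[2], P4=P[4], Q0=Q[0], Q2=Q[2], Q4=Q[4],
        A0=A[0], A2=A[2], A4=A[4], B0=B[0], B2=B[2], B4=B[4],
        Ka=Ka, Ks=Ks, n_codons=n_codons,
    )


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix over an ordered taxon list."""

    taxa: list
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} != ({n},{n})")

    def to_phylip(self) -> str:
        lines = [str(len(self.taxa))]
        for name, row in zip(self.taxa, self.d):
            lines.append(name + "\t" + "\t".join("%.6f" % v for v in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_phylip(cls, text: str) -> "DistanceMatrix":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        n = int(lines[0])
        taxa, rows = [], []
        for ln in lines[1:1 + n]:
            parts = ln.split()
            taxa.append(parts[0])
            rows.append([float(x) for x in parts[1:1 + n]])
        return cls(taxa, np.array(rows))


def _nucleotide_p(seq_a: str, seq_b: str) -> float:
    num = den = 0
    for x, y in zip(seq_a, seq_b):
        if x in NUCLEOTIDES and y in NUCLEOTIDES:
            den += 1
            num += x != y
    return num / den if den else 0.0


def pairwise_matrix(aln: CodonAlignment, which: str = "ka") -> DistanceMatrix:
    """All-pairs distance matrix: ``ka``, ``ks`` or nucleotide ``p``."""
    which = which.lower()
    if which not in ("ka", "ks", "p"):
        raise ValueError(f"unknown distance {which!r}")
    n = aln.n_taxa
    if n < 3:
        raise ValueError("need at least 3 taxa for a distance matrix")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if which == "p":
                v = _nucleotide_p(aln.seqs[i], aln.seqs[j])
            else:
                try:
                    res = lwl_distance(aln.seqs[i], aln.seqs[j], aln.code,
                                       require=(which,))
                except SaturationError as exc:
                    raise SaturationError(
                        f"pair ({aln.taxa[i]}, {aln.taxa[j]}): {exc}",
                        degeneracy_class=exc.degeneracy_class,
                        pair=(aln.taxa[i], aln.taxa[j]),
                    ) from exc
                v = res.Ka if which == "ka" else res.Ks
            d[i, j] = d[j, i] = v
    return DistanceMatrix(list(aln.taxa), d)


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor-joining tree from a distance matrix.

    Returns an unrooted binary tree represented with a trifurcating root.
    Negative branch-length estimates are clamped to zero with the deficit
    transferred to the adjacent (sibling) branch.
    """
    D = np.array(matrix.d, dtype=float)
    n = len(matrix.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")

    parent = [-1] * n
    children = [[] for _ in range(n)]
    length = [np.nan] * n
    name = list(matrix.taxa)

    active = list(range(n))  # node ids, D indexed in parallel
    idx = {node: k for k, node in enumerate(active)}

    def new_node():
        parent.append(-1)
        children.append([])
        length.append(np.nan)
        name.append(None)
        return len(parent) - 1

    def clamp_pair(li, lj):
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        ni, nj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)
        u = new_node()
        for child, ln in ((ni, li), (nj, lj)):
            parent[child] = u
            children[u].append(child)
            length[child] = ln
        # distances from u to remaining nodes
        Du = 0.5 * (D[ni] + D[nj] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[u, :u] = Du[:u]
        D[:u, u] = Du[:u]
        active = [a for a in active if a not in (ni, nj)] + [u]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    # clamp any negative star branch, moving the deficit to the longest other
    ls = {a: la, b: lb, c: lc}
    for node in (a, b, c):
        if ls[node] < 0:
            other = max((k for k in ls if k != node), key=lambda k: ls[k])
            ls[other] += -ls[node]
            ls[node] = 0.0
    root = new_node()
    for child in (a, b, c):
        parent[child] = root
        children[root].append(child)
        length[child] = ls[child]
    tag = [0] * len(parent)
    return PhyloTree(parent, children, np.asarray(length, dtype=float), name, tag, root)
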