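"""Substitution models, transition probabilities and the pruning likelihood.

Two model families are provided:

* :class:`CodonModel` — the Goldman-Yang style 61-state codon process with
  transition/transversion ratio κ, nonsynonymous/synonymous ratio ω and
  sense-codon equilibrium frequencies π (uniform, F1x4 or F3x4).  Rates are

      q_ij = 0                     more than one position differs, or stop
      q_ij = π_j                   synonymous transversion
      q_ij = κ π_j                 synonymous transition
      q_ij = ω π_j                 nonsynonymous transversion
      q_ij = ω κ π_j               nonsynonymous transition

  rescaled so the equilibrium flow is one expected substitution per codon
  site per unit branch length.

* :class:`AminoAcidModel` — a 20-state general-time-reversible process
  with fixed exchangeabilities: either the equal-rate (Poisson) model or
  the empirical JTT matrix, likewise scaled to unit mean rate.

Transition probabilities use the symmetrized spectral decomposition of the
reversible generator (cached per parameter setting); the tree likelihood is
computed by Felsenstein pruning over compressed site patterns, with
per-node rescaling against underflow, and an outside ("up") pass that
yields marginal ancestral posteriors and O(1)-per-branch likelihood curves
for branch-length optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from ._aa_data import JTT_FREQS, JTT_LOWER_TRIANGLE, JTT_ORDER
from .codonseq import (
    NUCLEOTIDES, CodonAlignment, GeneticCode, ProteinAlignment, is_transition,
)
from .errors import ModelError, OptimizationError

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"  # alphabetical one-letter codes

OMEGA_BOUNDS = (1e-4, 50.0)
KAPPA_BOUNDS = (1e-2, 100.0)
BRANCH_BOUNDS = (1e-8, 20.0)


# --------------------------------------------------------------------- models
@dataclass
class AminoAcidModel:
    """Reversible 20-state model: symmetric exchangeabilities + frequencies."""

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    name: str = "custom"

    def __post_init__(self):
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if S.shape != (20, 20) or not np.allclose(S, S.T):
            raise ModelError("exchangeabilities must be a symmetric 20x20 matrix")
        if pi.shape != (20,) or abs(pi.sum() - 1) > 1e-8 or (pi <= 0).any():
            raise ModelError("frequencies must be a positive 20-vector summing to 1")
        self.exchangeabilities = S
        self.frequencies = pi / pi.sum()

    @property
    def n_states(self) -> int:
        return 20

    @property
    def alphabet(self) -> str:
        return AA_ALPHABET

    @classmethod
    def poisson(cls) -> "AminoAcidModel":
        """Equal-rate model: every replacement equally likely, uniform π."""
        S = np.ones((20, 20)) - np.eye(20)
        return cls(S, np.full(20, 1 / 20), name="poisson")

    @classmethod
    def jtt(cls, frequencies=None) -> "AminoAcidModel":
        """Empirical JTT model, optionally with user-supplied frequencies."""
        S_jtt = np.zeros((20, 20))
        k = 0
        for col in range(19):
            for row in range(col + 1, 20):
                S_jtt[row, col] = S_jtt[col, row] = JTT_LOWER_TRIANGLE[k]
                k += 1
        # reorder from classical JTT residue order to the alphabetical one
        perm = [JTT_ORDER.index(a) for a in AA_ALPHABET]
        S = S_jtt[np.ix_(perm, perm)]
        if frequencies is None:
            pi = np.array([JTT_FREQS[JTT_ORDER.index(a)] for a in AA_ALPHABET])
        else:
            pi = np.asarray(frequencies, dtype=float)
        name = "jtt" if frequencies is None else "jtt+F"
        return cls(S, pi / pi.sum(), name=name)

    def rate_matrix(self) -> tuple:
        """(Q, π) with Q scaled to one expected substitution per site."""
        pi = self.frequencies
        Q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -(pi * np.diag(Q)).sum()
        return Q / rate, pi


def _codon_geometry(code: GeneticCode):
    """Precompute, per sense-codon pair differing at one position, the
    (i, j, is_transition, is_synonymous) quadruples."""
    codons = code.sense_codons
    n = len(codons)
    entries = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diffs = [p for p in range(3) if codons[i][p] != codons[j][p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            entries.append((
                i, j,
                is_transition(codons[i][p], codons[j][p]),
                code.table[codons[i]] == code.table[codons[j]],
            ))
    return entries


_GEOMETRY_CACHE = {}


def codon_geometry(code: GeneticCode):
    key = code.name
    if key not in _GEOMETRY_CACHE:
        _GEOMETRY_CACHE[key] = _codon_geometry(code)
    return _GEOMETRY_CACHE[key]


@dataclass
class CodonModel:
    """Goldman-Yang codon model with a single ω (per-class ω handled by
    building one rate matrix per site/branch class)."""

    kappa: float
    omega: float
    frequencies: np.ndarray = None
    code: GeneticCode = field(default_factory=GeneticCode.standard)
    freq_scheme: str = "uniform"

    def __post_init__(self):
        if self.kappa <= 0:
            raise ModelError(f"kappa must be positive, got {self.kappa}")
        if self.omega < 0:
            raise ModelError(f"omega must be nonnegative, got {self.omega}")
        n = len(self.code.sense_codons)
        if self.frequencies is None:
            self.frequencies = np.full(n, 1.0 / n)
        pi = np.asarray(self.frequencies, dtype=float)
        if pi.shape != (n,) or abs(pi.sum() - 1) > 1e-6 or (pi < 0).any():
            raise ModelError("codon frequencies must be a nonnegative "
                             f"{n}-vector summing to 1")
        self.frequencies = pi / pi.sum()

    @property
    def n_states(self) -> int:
        return len(self.code.sense_codons)

    @property
    def alphabet(self) -> tuple:
        return self.code.sense_codons

    def with_omega(self, omega: float) -> "CodonModel":
        return CodonModel(self.kappa, omega, self.frequencies, self.code, self.freq_scheme)

    def rate_matrix(self, omega: float = None) -> tuple:
        """(Q, π), scaled to one expected substitution per codon site."""
        omega = self.omega if omega is None else omega
        if omega < 0:
            raise ModelError(f"omega must be nonnegative, got {omega}")
        n = self.n_states
        pi = self.frequencies
        Q = np.zeros((n, n))
        for i, j, ts, syn in codon_geometry(self.code):
            rate = pi[j]
            if ts:
                rate *= self.kappa
            if not syn:
                rate *= omega
            Q[i, j] = rate
        np.fill_diagonal(Q, -Q.sum(axis=1))
        total = -(pi * np.diag(Q)).sum()
        if total <= 0:
            raise ModelError("degenerate codon model: zero total rate")
        return Q / total, pi

    def amino_acid_lumping(self) -> AminoAcidModel:
        """Aggregate the codon process into a 20-state amino acid model
        (equilibrium codon frequencies lumped per residue)."""
        Q, pi = self.rate_matrix()
        codons = self.code.sense_codons
        aa_idx = np.array([AA_ALPHABET.index(self.code.table[c]) for c in codons])
        pi_aa = np.zeros(20)
        flow = np.zeros((20, 20))
        for a in range(20):
            pi_aa[a] = pi[aa_idx == a].sum()
        for a in range(20):
            sel = aa_idx == a
            for b in range(20):
                if a == b:
                    continue
                flow[a, b] = (pi[sel, None] * Q[np.ix_(sel, aa_idx == b)]).sum()
        pi_aa = np.clip(pi_aa, 1e-12, None)
        pi_aa /= pi_aa.sum()
        S = (flow + flow.T) / 2.0
        S = S / np.outer(pi_aa, pi_aa)
        np.fill_diagonal(S, 0.0)
        return AminoAcidModel(S, pi_aa, name="codon-lumped")


def f1x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """Codon frequencies from overall nucleotide frequencies."""
    counts = dict.fromkeys(NUCLEOTIDES, 0)
    for seq in aln.seqs:
        for c in seq:
            if c in counts:
                counts[c] += 1
    tot = sum(counts.values()) or 1
    p = {k: v / tot for k, v in counts.items()}
    pi = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in aln.code.sense_codons])
    return _floor_frequencies(pi)


def _floor_frequencies(pi: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Keep every sense codon reachable: short alignments can miss a
    nucleotide at some position entirely, which would zero the codon's
    equilibrium frequency and break reversibility machinery."""
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


def f3x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies."""
    counts = [dict.fromkeys(NUCLEOTIDES, 0) for _ in range(3)]
    for seq in aln.seqs:
        for k, c in enumerate(seq):
            pos = k % 3
            if c in counts[pos]:
                counts[pos][c] += 1
    probs = []
    for pos in range(3):
        tot = sum(counts[pos].values()) or 1
        probs.append({k: v / tot for k, v in counts[pos].items()})
    pi = np.array([
        probs[0][c[0]] * probs[1][c[1]] * probs[2][c[2]]
        for c in aln.code.sense_codons
    ])
    if pi.sum() <= 0:
        raise ModelError("F3x4 frequencies degenerate (empty alignment?)")
    return _floor_frequencies(pi)


def empirical_codon_frequencies(aln: CodonAlignment) -> np.ndarray:
    """Observed sense-codon frequencies with a small pseudocount."""
    idx = {c: k for k, c in enumerate(aln.code.sense_codons)}
    counts = np.full(len(idx), 0.1)
    for seq in aln.seqs:
        for j in range(len(seq) // 3):
            codon = seq[3 * j: 3 * j + 3]
            if codon in idx:
                counts[idx[codon]] += 1
    return counts / counts.sum()


def codon_model_for(aln: CodonAlignment, kappa=2.0, omega=0.2,
                    freq_scheme: str = "F3x4") -> CodonModel:
    """Build a codon model with frequencies estimated from the alignment."""
    scheme = freq_scheme.lower()
    if scheme == "f3x4":
        pi = f3x4_frequencies(aln)
    elif scheme == "f1x4":
        pi = f1x4_frequencies(aln)
    elif scheme == "empirical":
        pi = empirical_codon_frequencies(aln)
    elif scheme == "uniform":
        pi = None
    else:
        raise ModelError(f"unknown frequency scheme {freq_scheme!r}")
    return CodonModel(kappa, omega, pi, aln.code, freq_scheme=freq_scheme)


# ------------------------------------------------------------- eigensystems
class Eigensystem:
    """Spectral decomposition of a reversible generator, for fast P(t).

    With D = diag(π), the symmetrized B = D^{1/2} Q D^{-1/2} has a real
    eigendecomposition B = U Λ Uᵀ, giving
    P(t) = D^{-1/2} U exp(Λ t) Uᵀ D^{1/2}.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        if (pi <= 0).any():
            raise ModelError("equilibrium frequencies must all be positive")
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = (B + B.T) / 2.0  # enforce symmetry against rounding
        lam, U = np.linalg.eigh(B)
        self.lam = lam
        self.left = U / sq[:, None] * 1.0      # D^{-1/2} U
        self.right = (U * sq[:, None]).T       # Uᵀ D^{1/2}
        self.Q = Q
        self.pi = pi

    def transition(self, t: float) -> np.ndarray:
        """Row-stochastic P(t); raises for negative t."""
        if t < 0:
            raise ModelError(f"branch length must be nonnegative, got {t}")
        P = (self.left * np.exp(self.lam * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_batch(self, ts: np.ndarray) -> np.ndarray:
        """P(t) for a vector of branch lengths in one batched product."""
        ts = np.asarray(ts, dtype=float)
        if (ts < 0).any():
            raise ModelError("branch lengths must be nonnegative")
        E = np.exp(self.lam[None, :] * ts[:, None])          # (n, S)
        P = (self.left[None, :, :] * E[:, None, :]) @ self.right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P

    def dtransition(self, t: float) -> np.ndarray:
        """dP/dt = Q P(t) through the same decomposition."""
        return (self.left * (self.lam * np.exp(self.lam * t))) @ self.right


def transition_matrix(model, t: float, omega: float = None) -> np.ndarray:
    """Convenience wrapper: P(t) for an amino acid or codon model."""
    if isinstance(model, CodonModel):
        Q, pi = model.rate_matrix(omega)
    else:
        Q, pi = model.rate_matrix()
    return Eigensystem(Q, pi).transition(t)


# ------------------------------------------------------- pattern compression
def encode_alignment(aln, model) -> "PatternData":
    """Compress an alignment into unique site patterns for a model's
    state space.  Gap/ambiguity states are encoded -1 (uninformative)."""
    if isinstance(model, CodonModel) and isinstance(aln, CodonAlignment):
        idx = {c: k for k, c in enumerate(model.code.sense_codons)}
        mat = np.empty((aln.n_taxa, aln.n_codons), dtype=np.int64)
        for r, seq in enumerate(aln.seqs):
            for j in range(aln.n_codons):
                mat[r, j] = idx.get(seq[3 * j: 3 * j + 3], -1)
        n_states = len(idx)
    elif isinstance(model, AminoAcidModel):
        if isinstance(aln, CodonAlignment):
            from .codonseq import translate_alignment
            aln = translate_alignment(aln)
        idx = {a: k for k, a in enumerate(AA_ALPHABET)}
        mat = np.empty((aln.n_taxa, aln.n_sites), dtype=np.int64)
        for r, seq in enumerate(aln.seqs):
            for j, ch in enumerate(seq):
                mat[r, j] = idx.get(ch, -1)
        n_states = 20
    else:
        raise ModelError(
            f"cannot encode {type(aln).__name__} under {type(model).__name__}")
    patterns, site_to_pattern, weights = np.unique(
        mat, axis=1, return_inverse=True, return_counts=True)
    return PatternData(list(aln.taxa), patterns, weights.astype(float),
                       site_to_pattern, n_states)


@dataclass
class PatternData:
    taxa: list
    codes: np.ndarray          # (n_taxa, n_patterns), -1 = missing
    weights: np.ndarray        # pattern multiplicities
    site_to_pattern: np.ndarray
    n_states: int

    @property
    def n_patterns(self) -> int:
        return self.codes.shape[1]

    @property
    def n_sites(self) -> int:
        return len(self.site_to_pattern)


# ----------------------------------------------------------- pruning engine
class PruningEngine:
    """Felsenstein pruning with inside (down) and outside (up) passes.

    The engine is bound to one tree shape and one pattern set; transition
    matrices are supplied per call, so one engine serves many parameter
    settings and site classes.
    """

    def __init__(self, tree, data: PatternData, dtype=np.float64):
        self.tree = tree
        self.data = data
        self.dtype = np.dtype(dtype)
        leaf_ids = tree.leaf_indices()
        names = {tree.name[i]: i for i in leaf_ids}
        missing = [t for t in data.taxa if t not in names]
        extra = [tree.name[i] for i in leaf_ids if tree.name[i] not in data.taxa]
        if missing or extra:
            raise ModelError(
                f"leaf/taxon mismatch: alignment-only {missing}, tree-only {extra}")
        self.leaf_row = {names[t]: r for r, t in enumerate(data.taxa)}
        self.postorder = tree.postorder()
        self.preorder = self.postorder[::-1]
        n_pat, S = data.n_patterns, data.n_states
        self._leaf_partials = {}
        for node, row in self.leaf_row.items():
            F = np.zeros((n_pat, S), dtype=self.dtype)
            codes = data.codes[row]
            obs = codes >= 0
            F[obs, codes[obs]] = 1.0
            F[~obs, :] = 1.0
            self._leaf_partials[node] = F

    def _cast(self, M):
        return M if M.dtype == self.dtype else M.astype(self.dtype)

    # -- inside pass ------------------------------------------------------
    def down_pass(self, P: dict):
        """Conditional likelihoods below each node.

        ``P[node]`` is the transition matrix of the branch above ``node``.
        Returns (F, cum): F[node] (n_pat, S) rescaled partials, cum[node]
        (n_pat,) log of the scale factors accumulated below node.
        """
        n_pat = self.data.n_patterns
        F = [None] * self.tree.n_nodes
        cum = [None] * self.tree.n_nodes
        self._H = [None] * self.tree.n_nodes  # child->parent messages, reused upward
        zeros = np.zeros(n_pat)
        for v in self.postorder:
            if self.tree.is_leaf(v):
                F[v] = self._leaf_partials[v]
                cum[v] = zeros
                continue
            prod = None
            c_log = zeros
            for c in self.tree.children[v]:
                msg = F[c] @ self._cast(P[c]).T
                self._H[c] = msg
                prod = msg if prod is None else prod * msg
                c_log = c_log + cum[c]
            scale = prod.max(axis=1)
            ok = scale > 0
            safe = np.where(ok, scale, 1.0)
            F[v] = prod / safe[:, None]
            with np.errstate(divide="ignore"):
                c_log = c_log + np.where(ok, np.log(safe), -np.inf)
            cum[v] = c_log
        return F, cum

    def site_logliks(self, P: dict, pi: np.ndarray, F=None, cum=None) -> np.ndarray:
        """Per-pattern log-likelihood, root weighted by π."""
        if F is None:
            F, cum = self.down_pass(P)
        root = self.tree.root
        lik = F[root] @ pi
        with np.errstate(divide="ignore"):
            out = np.log(lik) + cum[root]
        return out

    def loglik(self, P: dict, pi: np.ndarray) -> float:
        sl = self.site_logliks(P, pi)
        if np.isneginf(sl).any():
            warnings.warn("zero-probability site pattern under this model")
        return float(self.data.weights @ sl)

    # -- outside pass -----------------------------------------------------
    def up_pass(self, P: dict, F, cum):
        """Outside partials.

        Must be called with the same ``P`` (and following a call of)
        :meth:`down_pass`, whose child->parent messages it reuses.

        Returns (A, acum, G): for each non-root node c,
        A[c] = likelihood of all data outside the subtree of c, as a
        function of the state of parent(c) (edge's own P excluded);
        G[c] = A[c] @ P[c] (as a function of the state at c itself);
        acum[c] the matching log scale.  For the root, G = 1.
        """
        n_pat, S = self.data.n_patterns, self.data.n_states
        A = [None] * self.tree.n_nodes
        acum = [None] * self.tree.n_nodes
        G = [None] * self.tree.n_nodes
        G[self.tree.root] = np.ones((n_pat, S))
        gcum = [None] * self.tree.n_nodes
        gcum[self.tree.root] = np.zeros(n_pat)
        cached = getattr(self, "_H", None)
        for v in self.preorder:
            kids = self.tree.children[v]
            if not kids:
                continue
            if cached is not None and all(cached[c] is not None for c in kids):
                H = {c: cached[c] for c in kids}
            else:
                H = {c: F[c] @ self._cast(P[c]).T for c in kids}
            for c in kids:
                a = G[v].copy()
                alog = gcum[v].copy()
                for s in kids:
                    if s is c:
                        continue
                    a *= H[s]
                    alog += cum[s]
                scale = a.max(axis=1)
                safe = np.where(scale > 0, scale, 1.0)
                a = a / safe[:, None]
                with np.errstate(divide="ignore"):
                    alog = alog + np.where(scale > 0, np.log(safe), -np.inf)
                A[c] = a
                acum[c] = alog
                # reversibility: outside likelihood at c is Σ_i P_ji(t) A_i
                G[c] = a @ self._cast(P[c]).T
                gcum[c] = alog
        return A, acum, G, gcum

    def node_posteriors(self, P: dict, pi: np.ndarray):
        """Marginal posterior over states at every node, per pattern."""
        F, cum = self.down_pass(P)
        A, acum, G, gcum = self.up_pass(P, F, cum)
        post = {}
        for v in range(self.tree.n_nodes):
            unnorm = pi[None, :] * F[v] * G[v]
            tot = unnorm.sum(axis=1, keepdims=True)
            if (tot <= 0).any():
                raise ModelError("zero total likelihood at a site during "
                                 "posterior computation")
            post[v] = unnorm / tot
        return post

    # -- per-edge likelihood curves --------------------------------------
    def edge_loglik(self, node: int, P_edge: np.ndarray, pi: np.ndarray,
                    F, cum, A, acum) -> float:
        lik = ((pi[None, :] * A[node]) * (F[node] @ P_edge.T)).sum(axis=1)
        with np.errstate(divide="ignore"):
            sl = np.log(lik) + cum[node] + acum[node]
        return float(self.data.weights @ sl)

    def edge_loglik_curve(self, node: int, eig: "Eigensystem",
                          F, cum, A, acum):
        """lnL as a cheap function of this branch's length.

        Projecting the inside and outside partials onto the eigenbasis once
        reduces each evaluation to an O(patterns x states) contraction:
        lnL(t) = Σ_pat w log( Σ_k c_{pat,k} e^{λ_k t} ) + const.
        """
        # (π ⊙ A) P(t) F = [(π⊙A) D^{-1/2} U] e^{Λt} [Uᵀ D^{1/2} F]
        left_proj = (eig.pi[None, :] * A[node]) @ eig.left
        right_proj = F[node] @ eig.right.T
        coef = left_proj * right_proj
        const = cum[node] + acum[node]
        w = self.data.weights

        def lnL(t: float) -> float:
            lik = coef @ np.exp(eig.lam * t)
            np.clip(lik, 1e-300, None, out=lik)  # guard rounding at tiny t
            sl = np.log(lik) + const
            return float(w @ sl)

        return lnL


# ------------------------------------------------------------ public lnL API
def _single_matrices(tree, model, omega=None):
    if isinstance(model, CodonModel):
        Q, pi = model.rate_matrix(omega)
    else:
        Q, pi = model.rate_matrix()
    eig = Eigensystem(Q, pi)
    P = {}
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        t = tree.length[v]
        if not np.isfinite(t):
            raise ModelError("tree has branches without lengths")
        P[v] = eig.transition(t)
    return P, pi, eig


def pruning_loglik(tree, aln, model) -> float:
    """Log-likelihood of an alignment on a tree under a single-matrix model.

    ``model`` is a :class:`CodonModel` or :class:`AminoAcidModel`; branch
    lengths are read from the tree.  Gaps and ambiguity contribute flat
    partial likelihoods.  A single-leaf tree degenerates to Σ ln π(state).
    """
    data = encode_alignment(aln, model)
    if tree.n_nodes == 1:
        _, pi = (model.rate_matrix() if isinstance(model, AminoAcidModel)
                 else model.rate_matrix(None))
        codes = data.codes[0]
        with np.errstate(divide="ignore"):
            lp = np.where(codes >= 0, np.log(pi[np.clip(codes, 0, None)]), 0.0)
        return float(data.weights @ lp)
    engine = PruningEngine(tree, data)
    P, pi, _ = _single_matrices(tree, model)
    return engine.loglik(P, pi)


# ------------------------------------------------------------- optimization
def optimize_branch_lengths(engine: PruningEngine, eig: Eigensystem,
                            tree, max_sweeps: int = 10, tol: float = 1e-3) -> float:
    """Maximize lnL over all branch lengths by per-edge Brent searches.

    Each sweep computes the inside/outside partials once and optimizes
    every edge against them (the edge likelihood curve is exact for a
    single-edge move); all edges are then updated together and the global
    lnL re-evaluated.  If the simultaneous update ever decreases the
    likelihood the sweep falls back to strictly sequential coordinate
    ascent, which is monotone because the edge value at the current length
    equals the global lnL.  Mutates ``tree.length``; returns the final lnL.
    """
    pi = eig.pi
    nodes = [v for v in engine.postorder if v != tree.root]
    P = {v: eig.transition(tree.length[v]) for v in nodes}
    best = engine.loglik(P, pi)
    for _ in range(max_sweeps):
        F, cum = engine.down_pass(P)
        A, acum, _, _ = engine.up_pass(P, F, cum)
        proposal = {}
        for v in nodes:
            curve = engine.edge_loglik_curve(v, eig, F, cum, A, acum)
            res = minimize_scalar(lambda t: -curve(t), bounds=BRANCH_BOUNDS,
                                  method="bounded", options={"xatol": 1e-7})
            proposal[v] = float(res.x)
        old = tree.length.copy()
        for v in nodes:
            tree.length[v] = proposal[v]
            P[v] = eig.transition(proposal[v])
        new = engine.loglik(P, pi)
        if new < best - 1e-9:
            # simultaneous move overshot: revert and take edges one at a time
            tree.length[:] = old
            for v in nodes:
                P[v] = eig.transition(tree.length[v])
            new = best
            for v in nodes:
                F, cum = engine.down_pass(P)
                A, acum, _, _ = engine.up_pass(P, F, cum)
                curve = engine.edge_loglik_curve(v, eig, F, cum, A, acum)
                res = minimize_scalar(lambda t: -curve(t), bounds=BRANCH_BOUNDS,
                                      method="bounded", options={"xatol": 1e-7})
                if -res.fun > new:
                    new = -res.fun
                    tree.length[v] = float(res.x)
                    P[v] = eig.transition(tree.length[v])
        gain, best = new - best, new
        if gain < tol:
            break
    return best


def _brent_param(neg, lo, hi):
    """Bounded Brent in log space; returns (argmin, max value)."""
    res = minimize_scalar(lambda y: neg(float(np.exp(y))),
                          bounds=(np.log(lo), np.log(hi)), method="bounded",
                          options={"xatol": 1e-5})
    return float(np.exp(res.x)), -res.fun


def fit_m0(tree, aln, freq_scheme: str = "F3x4",
           kappa0: float = 2.0, omega0: float = 0.3, max_rounds: int = 10,
           tol: float = 1e-3, strict: bool = False):
    """Maximum-likelihood fit of the one-ratio (M0) codon model.

    Alternates branch-length sweeps with coordinate optimization of κ and
    ω (Brent in log space) until the improvement per round falls below
    ``tol`` log units.  Returns an :class:`M0Fit`.  When ``strict`` and the
    round limit is hit, raises :class:`OptimizationError` carrying the best
    fit so far.
    """
    work = tree.copy()
    work.length = np.where(np.isfinite(work.length), work.length, 0.1)
    work.length = np.clip(work.length, BRANCH_BOUNDS[0], BRANCH_BOUNDS[1])
    model = codon_model_for(aln, kappa=kappa0, omega=omega0, freq_scheme=freq_scheme)
    data = encode_alignment(aln, model)
    # single precision for the inner loops: lnL noise ~1e-7 relative, far
    # below the optimizer's convergence tolerance
    engine = PruningEngine(work, data, dtype=np.float32)

    non_root = [v for v in range(work.n_nodes) if v != work.root]

    def loglik_for(kappa, omega):
        Q, pi = CodonModel(kappa, omega, model.frequencies, model.code).rate_matrix()
        e = Eigensystem(Q, pi)
        batch = e.transition_batch(work.length[non_root])
        P = {v: batch[k] for k, v in enumerate(non_root)}
        return engine.loglik(P, pi)

    kappa, omega = float(kappa0), float(omega0)
    lnL, converged = -np.inf, False
    for rnd in range(max_rounds):
        Q, pi = CodonModel(kappa, omega, model.frequencies, model.code).rate_matrix()
        eig = Eigensystem(Q, pi)
        optimize_branch_lengths(engine, eig, work,
                                max_sweeps=5 if rnd == 0 else 3)
        # full-range search in the first round, local bracket afterwards
        if rnd == 0:
            kb, wb = KAPPA_BOUNDS, OMEGA_BOUNDS
        else:
            kb = (max(KAPPA_BOUNDS[0], kappa / 3), min(KAPPA_BOUNDS[1], kappa * 3))
            wb = (max(OMEGA_BOUNDS[0], omega / 3), min(OMEGA_BOUNDS[1], omega * 3))
        kappa, _v = _brent_param(lambda k: -loglik_for(k, omega), *kb)
        omega, new = _brent_param(lambda w: -loglik_for(kappa, w), *wb)
        if new - lnL < tol:
            lnL = max(lnL, new)
            converged = True
            break
        lnL = new
    fitted = CodonModel(kappa, omega, model.frequencies, model.code, model.freq_scheme)
    # report the final likelihood in double precision so that comparisons
    # against other fits are not perturbed by the fast inner-loop precision
    final = PruningEngine(work, data)
    Qf, pif = fitted.rate_matrix()
    ef = Eigensystem(Qf, pif)
    batch = ef.transition_batch(work.length[non_root])
    lnL = final.loglik({v: batch[k] for k, v in enumerate(non_root)}, pif)
    result = M0Fit(model=fitted, tree=work, lnL=float(lnL), converged=converged)
    if strict and not converged:
        raise OptimizationError(
            f"M0 fit did not converge in {max_rounds} rounds (lnL={lnL:.6f})",
            best=result)
    return result


@dataclass
class M0Fit:
    model: CodonModel
    tree: object
    lnL: float
    converged: bool


def fit_protein_branch_lengths(tree, protein: ProteinAlignment,
                               model: AminoAcidModel = None, n_sweeps: int = 3):
    """Fit branch lengths (amino acid substitutions/site) on a protein
    alignment under a fixed-exchangeability model. Returns (tree, lnL)."""
    model = model or AminoAcidModel.poisson()
    work = tree.copy()
    work.length = np.where(np.isfinite(work.length), work.length, 0.05)
    work.length = np.clip(work.length, BRANCH_BOUNDS[0], BRANCH_BOUNDS[1])
    data = encode_alignment(protein, model)
    engine = PruningEngine(work, data)
    Q, pi = model.rate_matrix()
    eig = Eigensystem(Q, pi)
    lnL = optimize_branch_lengths(engine, eig, work, max_sweeps=n_sweeps)
    return work, float(lnL)
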