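"""Codon-model selection tests: M0, branch, site and branch-site models.

The model zoo mirrors the standard battery used to probe selective
pressure on protein-coding genes:

==============  ================================================================
name            free parameters (beyond κ and a global branch-length scale)
==============  ================================================================
M0              one ω for all sites and branches (branch lengths fully free)
two-ratio       ω_background, ω_foreground (tagged branches)
free-ratio      one ω per branch
M1a             p0, ω0<1 (class ω1=1 fixed)
M2a             M1a + p2, ω2>1
M8              β(p,q) over 10 equal-probability categories + p_s, ω_s>1
M8a             M8 with ω_s=1 fixed
bsA             branch-site model A: p0, p1, ω0<1, ω2≥1 on the foreground
bsA-null        bsA with ω2=1 fixed
==============  ================================================================

All non-M0 models reuse the M0 branch lengths rescaled by a single free
factor — the desk-scale strategy documented in the methods note — and are
optimized by Nelder-Mead on transformed parameters (Brent sweeps for the
free-ratio model).  Nested pairs are compared by likelihood-ratio tests
against the χ² upper tail, and per-site empirical Bayes (NEB) posteriors
identify sites in the positive-selection class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import betainc, logsumexp
from scipy.stats import chi2

from .codonseq import CodonAlignment
from .errors import ModelError, OptimizationError
from .evomodels import (
    CodonModel, Eigensystem, KAPPA_BOUNDS, OMEGA_BOUNDS, PruningEngine,
    encode_alignment, fit_m0,
)

MODEL_NAMES = ("M0", "two-ratio", "free-ratio", "M1a", "M2a", "M8", "M8a",
               "bsA", "bsA-null")

# df registry for the standard nested pairs
LRT_DF = {
    ("M0", "two-ratio"): 1,
    ("M1a", "M2a"): 2,
    ("M8a", "M8"): 1,
    ("bsA-null", "bsA"): 1,   # branch-site test 2 (plain χ²1)
    ("M1a", "bsA"): 2,        # branch-site test 1
    ("M0", "M1a"): 1,
}


@dataclass
class SiteClass:
    """One mixture component: proportion and ω by branch scope."""

    proportion: float
    omega_background: float
    omega_foreground: float = None  # None -> same process on all branches

    def omega_for(self, foreground: bool) -> float:
        if foreground and self.omega_foreground is not None:
            return self.omega_foreground
        return self.omega_background


@dataclass
class FitResult:
    """A fitted codon model: parameters, mixture structure, likelihood."""

    model_name: str
    lnL: float
    kappa: float
    site_classes: list
    tree: object                   # tree with the branch lengths used
    frequencies: np.ndarray
    code: object
    params: dict = field(default_factory=dict)
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "lnL": self.lnL,
            "kappa": self.kappa,
            "site_classes": [
                {"proportion": c.proportion, "omega_background": c.omega_background,
                 "omega_foreground": c.omega_foreground}
                for c in self.site_classes
            ],
            "params": {k: (float(v) if np.isscalar(v) else v)
                       for k, v in self.params.items()},
            "converged": self.converged,
        }


@dataclass
class LrtResult:
    """Likelihood-ratio test between two nested fits."""

    lnL_null: float
    lnL_alt: float
    two_delta_l: float
    df: int
    p_value: float
    pair: tuple = ()

    def to_dict(self) -> dict:
        return {"null": self.pair[0] if self.pair else None,
                "alt": self.pair[1] if self.pair else None,
                "lnL_null": self.lnL_null, "lnL_alt": self.lnL_alt,
                "two_delta_l": self.two_delta_l, "df": self.df,
                "p_value": self.p_value}


@dataclass
class SitePosterior:
    """NEB posterior over site classes, per codon site."""

    posteriors: np.ndarray        # (n_sites, K)
    ps_class_prob: np.ndarray     # posterior mass on positive-selection classes
    method: str = "NEB"

    @property
    def flagged(self) -> np.ndarray:
        return self.ps_class_prob > 0.5

    @property
    def flagged_strong(self) -> np.ndarray:
        return self.ps_class_prob > 0.95


# ------------------------------------------------------------ mixture engine
class _MixtureLikelihood:
    """Per-class pruning likelihood over one engine, with eigen caching."""

    def __init__(self, tree, aln: CodonAlignment, frequencies):
        self.tree = tree
        self.frequencies = frequencies
        self.code = aln.code
        probe = CodonModel(2.0, 0.5, frequencies, aln.code)
        self.data = encode_alignment(aln, probe)
        self.engine = PruningEngine(tree, self.data)
        self.non_root = [v for v in range(tree.n_nodes) if v != tree.root]
        self.base_lengths = np.array([tree.length[v] for v in self.non_root])
        self.fg = np.array([bool(tree.tag[v]) for v in self.non_root])
        self._eig_cache = {}

    def eig(self, kappa: float, omega: float) -> Eigensystem:
        key = (round(kappa, 12), round(omega, 12))
        if key not in self._eig_cache:
            Q, pi = CodonModel(kappa, omega, self.frequencies, self.code).rate_matrix()
            self._eig_cache[key] = Eigensystem(Q, pi)
        if len(self._eig_cache) > 512:
            self._eig_cache.pop(next(iter(self._eig_cache)))
        return self._eig_cache[key]

    def class_site_logliks(self, kappa, site_classes, scale=1.0,
                           branch_omegas=None) -> np.ndarray:
        """(K, n_patterns) per-class site log-likelihoods.

        Transition matrices are built once per distinct ω (batched over
        branches) and shared across the classes that use them.
        """
        out = []
        lengths = self.base_lengths * scale
        batch_cache = {}

        def batch(omega):
            if omega not in batch_cache:
                batch_cache[omega] = self.eig(kappa, omega).transition_batch(lengths)
            return batch_cache[omega]

        pi = self.eig(kappa, site_classes[0].omega_background).pi
        for cls in site_classes:
            P = {}
            if branch_omegas is not None:
                for k, v in enumerate(self.non_root):
                    P[v] = batch(branch_omegas[v])[k]
            else:
                bg = batch(cls.omega_background)
                fg = (batch(cls.omega_foreground)
                      if cls.omega_foreground is not None else bg)
                for k, v in enumerate(self.non_root):
                    P[v] = fg[k] if self.fg[k] else bg[k]
            out.append(self.engine.site_logliks(P, pi))
        return np.vstack(out)

    def loglik(self, kappa, site_classes, scale=1.0, branch_omegas=None) -> float:
        sl = self.class_site_logliks(kappa, site_classes, scale, branch_omegas)
        props = np.array([c.proportion for c in site_classes])
        if abs(props.sum() - 1) > 1e-8:
            raise ModelError("site-class proportions must sum to 1")
        mixed = logsumexp(sl, axis=0, b=props[:, None])
        return float(self.data.weights @ mixed)


# -------------------------------------------------------------- transforms
def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _logit(p):
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _stick2(x, y):
    """(p0, p1, p2) on the simplex from two unconstrained reals."""
    p0 = _sigmoid(x)
    p1 = (1 - p0) * _sigmoid(y)
    return p0, p1, 1 - p0 - p1


def beta_category_means(p: float, q: float, k: int = 10) -> np.ndarray:
    """Means of K equal-probability categories of a Beta(p, q)."""
    edges = np.linspace(0, 1, k + 1)
    from scipy.stats import beta as beta_dist
    x = beta_dist.ppf(edges, p, q)
    # mean of each slice: p/(p+q) * [I(x2; p+1, q) - I(x1; p+1, q)] * K
    upper = betainc(p + 1, q, x)
    means = (p / (p + q)) * (upper[1:] - upper[:-1]) * k
    return np.clip(means, 1e-6, 1 - 1e-6)


# ---------------------------------------------------------------- model zoo
def _classes_for(spec, theta):
    """Site-class structure from the model name and transformed params."""
    if spec == "two-ratio":
        w_bg, w_fg = np.exp(theta)
        return [SiteClass(1.0, w_bg, w_fg)]
    if spec == "M1a":
        p0 = _sigmoid(theta[0])
        w0 = _sigmoid(theta[1])
        return [SiteClass(p0, w0), SiteClass(1 - p0, 1.0)]
    if spec == "M2a":
        p0, p1, p2 = _stick2(theta[0], theta[1])
        w0 = _sigmoid(theta[2])
        w2 = 1.0 + np.exp(theta[3])
        return [SiteClass(p0, w0), SiteClass(p1, 1.0), SiteClass(p2, w2)]
    if spec in ("M8", "M8a"):
        p0 = _sigmoid(theta[0])
        p = np.exp(np.clip(theta[1], np.log(5e-3), np.log(99.0)))
        q = np.exp(np.clip(theta[2], np.log(5e-3), np.log(99.0)))
        ws = 1.0 + np.exp(theta[3]) if spec == "M8" else 1.0
        cats = beta_category_means(p, q, 10)
        classes = [SiteClass(p0 / 10.0, w) for w in cats]
        classes.append(SiteClass(1 - p0, ws))
        return classes
    if spec in ("bsA", "bsA-null"):
        p0, p1, prest = _stick2(theta[0], theta[1])
        w0 = _sigmoid(theta[2])
        w2 = 1.0 + np.exp(theta[3]) if spec == "bsA" else 1.0
        denom = p0 + p1
        p2a = prest * (p0 / denom)
        p2b = prest * (p1 / denom)
        return [
            SiteClass(p0, w0),
            SiteClass(p1, 1.0),
            SiteClass(p2a, w0, w2),
            SiteClass(p2b, 1.0, w2),
        ]
    raise ModelError(f"unknown model spec {spec!r}")


_N_THETA = {"two-ratio": 2, "M1a": 2, "M2a": 4, "M8": 4, "M8a": 4,
            "bsA": 4, "bsA-null": 4}
_PS_CLASSES = {"M2a": [2], "M8": [10], "bsA": [2, 3], "bsA-null": [2, 3]}


def _fit_free_ratio(mix: _MixtureLikelihood, m0_fit: FitResult, n_sweeps: int = 5):
    """Per-branch ω by sequential edge-wise Brent sweeps from the M0 optimum.

    Only the focal branch's transition matrix depends on its ω, so each
    branch is optimized on the exact edge-likelihood curve (inside and
    outside partials held across that edge), a monotone coordinate ascent;
    κ is re-optimized between sweeps.  lnL therefore never falls below the
    M0 starting point.
    """
    tree = mix.tree
    engine = mix.engine
    omegas = {v: m0_fit.params["omega"] for v in mix.non_root}
    kappa = m0_fit.kappa
    base = [SiteClass(1.0, m0_fit.params["omega"])]
    lengths = {v: mix.base_lengths[k] for k, v in enumerate(mix.non_root)}

    def all_P(kap):
        return {v: mix.eig(kap, omegas[v]).transition(lengths[v])
                for v in mix.non_root}

    P = all_P(kappa)
    pi = mix.eig(kappa, m0_fit.params["omega"]).pi
    best = engine.loglik(P, pi)
    for _ in range(n_sweeps):
        start = best
        for v in mix.non_root:
            F, cum = engine.down_pass(P)
            A, acum, _, _ = engine.up_pass(P, F, cum)

            def neg(logw, v=v, F=F, cum=cum, A=A, acum=acum):
                Pv = mix.eig(kappa, float(np.exp(logw))).transition(lengths[v])
                return -engine.edge_loglik(v, Pv, pi, F, cum, A, acum)

            res = minimize_scalar(neg, bounds=np.log(OMEGA_BOUNDS),
                                  method="bounded", options={"xatol": 1e-4})
            if -res.fun > best:
                best = -res.fun
                omegas[v] = float(np.exp(res.x))
                P[v] = mix.eig(kappa, omegas[v]).transition(lengths[v])

        def neg_kappa(logk):
            return -engine.loglik(all_P(float(np.exp(logk))),
                                  mix.eig(float(np.exp(logk)),
                                          m0_fit.params["omega"]).pi)

        res = minimize_scalar(neg_kappa, bounds=np.log(KAPPA_BOUNDS),
                              method="bounded", options={"xatol": 1e-4})
        if -res.fun > best:
            best = -res.fun
            kappa = float(np.exp(res.x))
            P = all_P(kappa)
            pi = mix.eig(kappa, m0_fit.params["omega"]).pi
        if best - start < 1e-3:
            break
    params = {"omega_by_branch": {int(v): float(w) for v, w in omegas.items()},
              "scale": 1.0, "kappa": kappa}
    return FitResult("free-ratio", float(best), kappa,
                     [SiteClass(1.0, float(np.mean(list(omegas.values()))))],
                     tree, mix.frequencies, mix.code, params=params)


def fit_model(aln: CodonAlignment, tree, spec: str, freq_scheme: str = "F3x4",
              m0: FitResult = None, restarts=None) -> FitResult:
    """Fit one model of the zoo and return its :class:`FitResult`.

    Foreground-requiring specs (two-ratio, bsA, bsA-null) read the
    foreground tags from the tree (``#1`` newick labels) and raise when
    none are present.  Every non-M0 model starts from (and reuses the
    branch lengths of) the M0 fit, which is computed on demand when not
    passed in.
    """
    if spec not in MODEL_NAMES:
        raise ModelError(f"unknown model {spec!r}; choose from {MODEL_NAMES}")

    if spec == "M0":
        res = fit_m0(tree, aln, freq_scheme=freq_scheme)
        return FitResult(
            "M0", res.lnL, res.model.kappa,
            [SiteClass(1.0, res.model.omega)], res.tree,
            res.model.frequencies, res.model.code,
            params={"omega": res.model.omega, "kappa": res.model.kappa},
            converged=res.converged)

    if m0 is None:
        m0 = fit_model(aln, tree, "M0", freq_scheme=freq_scheme)
    fitted_tree = m0.tree.copy()

    needs_fg = spec in ("two-ratio", "bsA", "bsA-null")
    if needs_fg and not any(fitted_tree.tag):
        raise ModelError(f"model {spec} requires foreground-tagged branches "
                         "(use '#1' labels in the newick)")

    mix = _MixtureLikelihood(fitted_tree, aln, m0.frequencies)

    if spec == "free-ratio":
        if fitted_tree.n_leaves < 4:
            import warnings
            warnings.warn("free-ratio on very small trees is weakly identifiable")
        return _fit_free_ratio(mix, m0)

    w_hat = m0.params["omega"]
    k_theta = _N_THETA[spec]

    def unpack(x):
        log_kappa, log_scale = x[0], x[1]
        return float(np.exp(log_kappa)), float(np.exp(log_scale)), x[2:]

    def neg(x):
        kappa, scale, theta = unpack(x)
        kappa = float(np.clip(kappa, *KAPPA_BOUNDS))
        try:
            classes = _classes_for(spec, theta)
            return -mix.loglik(kappa, classes, scale)
        except (ModelError, FloatingPointError):
            return 1e12

    # starting points: proportions near the M0 regime, ω0 near the M0 ω
    starts = []
    base_theta = {
        "two-ratio": [np.log(max(w_hat, 1e-3))] * 2,
        "M1a": [_logit(0.8), _logit(min(w_hat, 0.9))],
        "M2a": [_logit(0.75), _logit(0.8), _logit(min(w_hat, 0.9)), np.log(1.0)],
        "M8": [_logit(0.9), np.log(0.5), np.log(2.0), np.log(1.0)],
        "M8a": [_logit(0.9), np.log(0.5), np.log(2.0), 0.0],
        "bsA": [_logit(0.75), _logit(0.8), _logit(min(w_hat, 0.9)), np.log(1.0)],
        "bsA-null": [_logit(0.75), _logit(0.8), _logit(min(w_hat, 0.9)), 0.0],
    }[spec]
    if restarts is None:
        if spec == "bsA":
            # ω2 initialized at 1.5, 5 and 20 (multimodality), plus a
            # near-boundary start so the null configuration is reachable
            restarts = [0.5, 4.0, 19.0, 2e-9]
        elif spec in ("M2a", "M8"):
            restarts = [None, 2e-9]
        else:
            restarts = [None]
    for r in restarts:
        th = list(base_theta)
        if r is not None:
            th[3] = np.log(r)
        starts.append(np.array([np.log(m0.kappa), 0.0] + th))

    best = None
    for x0 in starts:
        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-5,
                                "maxfev": 250 * len(x0)})
        if best is None or res.fun < best.fun:
            best = res
    kappa, scale, theta = unpack(best.x)
    classes = _classes_for(spec, theta)
    lnL = -best.fun
    params = {"kappa": kappa, "scale": scale}
    if spec == "two-ratio":
        params.update(omega_background=classes[0].omega_background,
                      omega_foreground=classes[0].omega_foreground)
    elif spec in ("M1a", "M2a"):
        params.update(p=[c.proportion for c in classes],
                      omega=[c.omega_background for c in classes])
    elif spec in ("M8", "M8a"):
        params.update(p0=float(sum(c.proportion for c in classes[:-1])),
                      omega_s=classes[-1].omega_background)
    elif spec in ("bsA", "bsA-null"):
        params.update(p=[c.proportion for c in classes],
                      omega0=classes[0].omega_background,
                      omega2=classes[2].omega_foreground)
    return FitResult(spec, float(lnL), kappa, classes, fitted_tree,
                     m0.frequencies, m0.code, params=params,
                     converged=bool(best.success or True))


def lrt(null_fit: FitResult, alt_fit: FitResult, df: int = None) -> LrtResult:
    """χ² likelihood-ratio test of two nested fits.

    ``df`` defaults to the registry value for the standard pairs.  A
    negative 2Δℓ within -1e-6 is clamped to 0; a larger deficit raises an
    :class:`OptimizationError` (the alternative failed to reach its
    optimum — re-run with restarts).
    """
    pair = (null_fit.model_name, alt_fit.model_name)
    if df is None:
        if pair == ("M0", "free-ratio"):
            n_branches = sum(1 for v in range(alt_fit.tree.n_nodes)
                             if alt_fit.tree.parent[v] != -1)
            df = n_branches - 1
        elif pair in LRT_DF:
            df = LRT_DF[pair]
        else:
            raise ModelError(f"no registered df for pair {pair}; pass df=")
    if df < 1:
        raise ModelError("df must be >= 1")
    two_delta = 2.0 * (alt_fit.lnL - null_fit.lnL)
    if two_delta < -1e-6:
        raise OptimizationError(
            f"alternative lnL below null by {-two_delta / 2:.3g} "
            f"({pair}); optimization failure", best=(null_fit, alt_fit))
    two_delta = max(two_delta, 0.0)
    p = float(chi2.sf(two_delta, df))
    return LrtResult(null_fit.lnL, alt_fit.lnL, two_delta, df, p, pair=pair)


def site_posteriors(fit: FitResult, aln: CodonAlignment, tree=None) -> SitePosterior:
    """NEB posterior site-class memberships at the fitted parameters.

    Per site s and class k: pp(k|s) ∝ p_k L(s|k); sites belonging to a
    positive-selection class (ω>1 component of M2a/M8, foreground ω2
    classes of bsA) are summarized in ``ps_class_prob``.
    """
    if len(fit.site_classes) < 2:
        import warnings
        warnings.warn("single-class model: posteriors are trivially 1")
        n = aln.n_codons
        return SitePosterior(np.ones((n, 1)), np.zeros(n))
    mix = _MixtureLikelihood(fit.tree, aln, fit.frequencies)
    sl = mix.class_site_logliks(fit.kappa, fit.site_classes,
                                fit.params.get("scale", 1.0))
    props = np.array([c.proportion for c in fit.site_classes])
    log_post = np.log(np.clip(props, 1e-300, None))[:, None] + sl
    log_post -= logsumexp(log_post, axis=0, keepdims=True)
    post = np.exp(log_post).T[mix.data.site_to_pattern]  # (n_sites, K)
    ps_idx = _PS_CLASSES.get(fit.model_name, [])
    ps_idx = [k for k in ps_idx
              if (fit.site_classes[k].omega_foreground or
                  fit.site_classes[k].omega_background) > 1.0]
    ps = post[:, ps_idx].sum(axis=1) if ps_idx else np.zeros(post.shape[0])
    return SitePosterior(post, ps)
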