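"""End-to-end orchestration: one config in, one consolidated report out.

Stage order: alignment summary -> distance matrices and NJ trees -> codon
model fits and LRTs -> ancestral reconstruction -> convergence test on the
configured branch pairs.  Every stage writes its artifact (JSON/TSV/newick)
into the output directory before the next stage runs, so partial failures
leave completed results on disk and every number in the report is
traceable to a file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .ancestral import annotated_newick, changes_to_tsv, map_substitutions, marginal_asr
from .codonseq import read_codon_alignment, summarize_alignment, translate_alignment
from .convergence import resolve_pair, run_convergence_scan
from .distances import nj_tree, pairwise_matrix
from .errors import ConfigError
from .evomodels import AminoAcidModel, fit_protein_branch_lengths
from .selection import LRT_DF, fit_model, lrt, site_posteriors
from .trees import read_newick_file, write_newick

logger = logging.getLogger("batvision")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    alignment: Path
    tree: Path
    out_dir: Path
    clades: dict = field(default_factory=dict)     # name -> [taxa] or file
    pairs: list = field(default_factory=list)      # [[cladeA, cladeB], ...]
    models: list = field(default_factory=lambda: ["M0"])
    freq_scheme: str = "F3x4"
    expectation_model: str = "poisson"             # poisson | jtt
    asr_level: str = "aa"
    distances: list = field(default_factory=lambda: ["ka", "ks", "p"])
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self):
        self.alignment = Path(self.alignment)
        self.tree = Path(self.tree)
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for req in ("alignment", "tree", "out_dir"):
            if req not in raw:
                raise ConfigError(f"config missing required key {req!r}")
        cfg = cls(**{**raw,
                     "alignment": Path(raw["alignment"]),
                     "tree": Path(raw["tree"]),
                     "out_dir": Path(raw["out_dir"])})
        cfg.validate()
        return cfg

    def validate(self):
        for p, what in ((self.alignment, "alignment"), (self.tree, "tree")):
            if not Path(p).exists():
                raise ConfigError(f"{what} file not found: {p}")
        clades = {}
        for name, spec in self.clades.items():
            if isinstance(spec, (str, Path)):
                p = Path(spec)
                if not p.exists():
                    raise ConfigError(f"clade file not found: {p}")
                clades[name] = [ln.strip() for ln in p.read_text().splitlines()
                                if ln.strip()]
            else:
                clades[name] = list(spec)
        self.clades = clades
        for pair in self.pairs:
            if len(pair) != 2 or any(c not in self.clades for c in pair):
                raise ConfigError(f"pair {pair} must name two defined clades")
        return self

    def semantic_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d.pop("verbosity")  # cosmetic only
        return json.loads(json.dumps(d, default=str, sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.semantic_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _setup_logging(cfg: RunConfig):
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    logger.setLevel(cfg.verbosity)
    logger.handlers = []
    fmt = logging.Formatter("%(asctime)s %(levelname)s [%(stage)s] %(message)s")
    for handler in (logging.StreamHandler(sys.stderr),
                    logging.FileHandler(cfg.out_dir / "run.log")):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


class _Stage:
    def __init__(self, name):
        self.name = name

    def log(self, msg):
        logger.info(msg, extra={"stage": self.name})


def _dump(obj, path: Path):
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".json":
        path.write_text(json.dumps(obj, indent=2, default=float) + "\n")
    else:
        path.write_text(obj)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the AnalysisReport dict (also on disk).

    Deterministic given the config (and its seed); rerunning with the same
    config produces byte-identical artifacts apart from timestamps in the
    log.  Stage failures raise with the stage name attached; artifacts of
    completed stages remain on disk.
    """
    config.validate()
    _setup_logging(config)
    out = config.out_dir
    np.random.seed(config.seed % (2 ** 31))
    report = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": config.semantic_dict(),
        },
        "artifacts": {},
    }

    def artifact(key, path):
        report["artifacts"][key] = str(path)

    stage = _Stage("summarize")
    try:
        aln = read_codon_alignment(config.alignment)
        tree = read_newick_file(config.tree)
        summary = summarize_alignment(aln)
        _dump(summary.to_dict(), out / "alignment_summary.json")
        _dump(summary.to_tsv(), out / "alignment_summary.tsv")
        artifact("alignment_summary", out / "alignment_summary.json")
        report["alignment_summary"] = summary.to_dict()
        stage.log(f"{aln.n_taxa} taxa, {aln.width} bp, "
                  f"{summary.variable_nt_sites} variable")
    except Exception as exc:
        raise type(exc)(f"[stage summarize] {exc}") from exc

    stage = _Stage("distances")
    try:
        report["nj_trees"] = {}
        for which in config.distances:
            mat = pairwise_matrix(aln, which)
            _dump(mat.to_phylip(), out / f"dist_{which}.phy")
            njt = nj_tree(mat)
            _dump(write_newick(njt) + "\n", out / f"nj_{which}.nwk")
            artifact(f"nj_{which}", out / f"nj_{which}.nwk")
            report["nj_trees"][which] = write_newick(njt)
            stage.log(f"NJ tree from {which} distances written")
    except Exception as exc:
        raise type(exc)(f"[stage distances] {exc}") from exc

    stage = _Stage("fit")
    fits = {}
    try:
        m0 = None
        for spec in config.models:
            fit = fit_model(aln, tree, spec, freq_scheme=config.freq_scheme,
                            m0=m0)
            if spec == "M0":
                m0 = fit
            fits[spec] = fit
            _dump(fit.to_dict(), out / f"fit_{spec}.json")
            artifact(f"fit_{spec}", out / f"fit_{spec}.json")
            stage.log(f"{spec}: lnL={fit.lnL:.3f}")
        lrts = []
        for (null_name, alt_name), df in LRT_DF.items():
            if null_name in fits and alt_name in fits:
                lrts.append(lrt(fits[null_name], fits[alt_name]).to_dict())
        if "M0" in fits and "free-ratio" in fits:
            lrts.append(lrt(fits["M0"], fits["free-ratio"]).to_dict())
        _dump(lrts, out / "lrt_table.json")
        artifact("lrt_table", out / "lrt_table.json")
        report["model_fits"] = {k: f.to_dict() for k, f in fits.items()}
        report["lrt_table"] = lrts
        report["flagged_sites"] = {}
        for spec, fit in fits.items():
            if len(fit.site_classes) > 1 and spec != "free-ratio":
                sp = site_posteriors(fit, aln)
                flagged = [
                    {"site": int(i) + 1, "pp": float(sp.ps_class_prob[i])}
                    for i in np.nonzero(sp.flagged)[0]
                ]
                if flagged:
                    report["flagged_sites"][spec] = flagged
    except Exception as exc:
        raise type(exc)(f"[stage fit] {exc}") from exc

    stage = _Stage("asr")
    try:
        protein = translate_alignment(aln)
        aa_model = (AminoAcidModel.jtt() if config.expectation_model == "jtt"
                    else AminoAcidModel.poisson())
        aa_tree, aa_lnL = fit_protein_branch_lengths(tree, protein, aa_model)
        asr = marginal_asr(aa_tree, protein, aa_model)
        changes = map_substitutions(aa_tree, asr, protein)
        _dump(asr.to_tsv(), out / "asr_states.tsv")
        _dump(changes_to_tsv(changes, aa_tree), out / "branch_changes.tsv")
        _dump(annotated_newick(aa_tree, changes) + "\n",
              out / "annotated_tree.nwk")
        for key in ("asr_states", "branch_changes", "annotated_tree"):
            artifact(key, out / f"{key}.{'nwk' if 'tree' in key else 'tsv'}")
        report["n_inferred_changes"] = len(changes)
        stage.log(f"ASR done (protein lnL={aa_lnL:.2f}); "
                  f"{len(changes)} branch changes")
    except Exception as exc:
        raise type(exc)(f"[stage asr] {exc}") from exc

    stage = _Stage("converge")
    try:
        results = []
        if config.pairs:
            pairs = [resolve_pair(tree, config.clades[a], config.clades[b])
                     for a, b in config.pairs]
            scan = run_convergence_scan(tree, aln, pairs,
                                        model=config.expectation_model)
            for (a, b), res in zip(config.pairs, scan):
                d = res.to_dict()
                d["clades"] = [a, b]
                results.append(d)
                stage.log(f"{a} vs {b}: n_par={res.n_par} "
                          f"E_par={res.E_par:.3f} p_par={res.p_par:.4g}")
        _dump(results, out / "convergence.json")
        artifact("convergence", out / "convergence.json")
        report["convergence"] = results
    except Exception as exc:
        raise type(exc)(f"[stage converge] {exc}") from exc

    _dump(report, out / "report.json")
    _dump(render_report(report), out / "report.md")
    return report


def render_report(report: dict) -> str:
    """Human-readable markdown mirroring the fitted-models table layout."""
    lines = ["# Analysis report", ""]
    prov = report.get("provenance", {})
    lines += ["## Provenance", "",
              f"- package version: {prov.get('package_version')}",
              f"- seed: {prov.get('seed')}",
              f"- config hash: {prov.get('config_hash')}", ""]
    if "alignment_summary" in report:
        s = report["alignment_summary"]
        lines += ["## Alignment", "",
                  f"{s['aligned_length_bp']} bp aligned, "
                  f"{s['variable_nt_sites']} variable nucleotide sites, "
                  f"{s['aa_variable_sites']} amino-acid-variable codons.", ""]
    if report.get("model_fits"):
        lines += ["## Model fits", "", "| model | lnL | parameters |",
                  "|---|---|---|"]
        for name, fit in report["model_fits"].items():
            pars = {k: v for k, v in fit["params"].items()
                    if k != "omega_by_branch"}
            par_s = ", ".join(f"{k}={np.round(v, 4) if np.isscalar(v) else v}"
                              for k, v in pars.items())
            lines.append(f"| {name} | {fit['lnL']:.3f} | {par_s} |")
        lines.append("")
    if report.get("lrt_table"):
        lines += ["## Likelihood-ratio tests", "",
                  "| null | alt | 2Δℓ | df | p |", "|---|---|---|---|---|"]
        for row in report["lrt_table"]:
            lines.append(f"| {row['null']} | {row['alt']} | "
                         f"{row['two_delta_l']:.3f} | {row['df']} | "
                         f"{row['p_value']:.4g} |")
        lines.append("")
    if report.get("flagged_sites"):
        lines += ["## Candidate positively selected sites (NEB)", ""]
        for model, sites in report["flagged_sites"].items():
            listing = ", ".join(f"site {s['site']} (pp={s['pp']:.3f})"
                                for s in sites)
            lines.append(f"- {model}: {listing}")
        lines.append("")
    if report.get("convergence"):
        lines += ["## Convergence tests", ""]
        for res in report["convergence"]:
            par = ", ".join(f"{a}{s}{d}" for s, a, d in
                            [tuple(x) for x in res["parallel_sites"]]) or "none"
            lines += [f"### {' vs '.join(res.get('clades', res['branches']))}",
                      "",
                      f"- parallel sites: {par} "
                      f"(n={res['n_parallel']}, E={res['E_parallel']:.3f}, "
                      f"p={res['p_parallel']:.4g})",
                      f"- convergent sites: n={res['n_convergent']}, "
                      f"E={res['E_convergent']:.3f}, p={res['p_convergent']:.4g}",
                      f"- combined p: {res['p_combined']:.4g}",
                      f"- expectation model: {res['expectation_model']}", ""]
    return "\n".join(lines) + "\n"
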