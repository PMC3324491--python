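# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `batvision`. It is the companion to the API documentation:
what the package computes and why, in enough detail to audit or extend it.

## Scientific setting

The package operationalizes a specific comparative question: when two
independent lineages share a phenotype (here, the large-eyed, rod-vision-
reliant bat families Pteropodidae and Emballonuroidea), do their
protein-coding genes show more *parallel* or *convergent* amino acid
replacements than a neutral substitution process predicts? The workflow
is the classical one: validate and summarize the codon alignment; build
distance trees from synonymous and nonsynonymous divergence separately;
fit codon models to measure selective pressure; reconstruct ancestral
sequences; map replacements onto branches; and test the focal branch pair
for excess shared derived changes.

## Codon alignments and site degeneracy

Alignments are in-frame, column-aligned coding sequences (FASTA). The
genetic code comes from the NCBI tables (Biopython); the standard nuclear
code is the default since the genes of interest are nuclear. Validation
rejects ragged rows, widths not divisible by three, duplicate taxa and
in-frame stop codons (codons containing gaps are exempt; ambiguity codes
are preserved but treated as missing everywhere downstream).

Each position of each sense codon is classified 0-fold, 2-fold or 4-fold
degenerate by counting its synonymous single-nucleotide mutants (0, some,
or all 3). Three-fold degenerate positions (isoleucine third positions)
are binned as 2-fold, and mutations to stop codons count as
nonsynonymous. Summary counts (variable nucleotide columns, amino-acid-
variable codon columns, gap runs) use only unambiguous residues; columns
that are partially gapped still count through their observed residues.

## Li-Wu-Luo distances

For a sequence pair, per-class site totals L0, L2, L4 average the two
sequences' class memberships (each site contributes ½ per sequence).
Transitional (P) and transversional (Q) difference proportions per class
receive Kimura-type corrections

    a_i = 1/(1 − 2P_i − Q_i)   A_i = ln(a_i)/2 − ln(b_i)/4
    b_i = 1/(1 − 2Q_i)         B_i = ln(b_i)/2

combined with the convention that all 0-fold and two-thirds of 2-fold
sites are nonsynonymous while one-third of 2-fold and all 4-fold sites
are synonymous:

    Ks = 3[L2·A2 + L4·(A4+B4)] / (L2 + 3·L4)
    Ka = 3[L2·B2 + L0·(A0+B0)] / (2·L2 + 3·L0)

Codons differing at more than one position are averaged over the equally
weighted parsimonious mutational orderings (orderings passing through a
stop codon are dropped unless all are blocked); each step is classified
by the mean degeneracy class of its flanking codons, which makes the
distance symmetric in its arguments. A saturated class (non-positive
logarithm argument) raises an error naming the class — but only when a
distance that depends on that class was requested, so a Ka matrix can
still be computed when deep synonymous divergence saturates Ks.

Neighbor joining is the Saitou–Nei agglomeration with the rate-corrected
selection criterion. Negative branch-length estimates are clamped to
zero with the deficit moved to the sibling branch (for the final
three-star, to the longest remaining branch). The "nonsynonymous-sites"
and "synonymous-sites" trees are NJ on the Ka and Ks matrices
respectively; NJ on the nucleotide p-distance is also available.

## Substitution models

**Codon model.** Goldman–Yang structure over the 61 sense codons:
off-diagonal rates are zero for multi-position changes and stops, and
otherwise π_j, κπ_j, ωπ_j or ωκπ_j according to whether the single
nucleotide change is a transversion/transition and
synonymous/nonsynonymous. Matrices are rescaled to one expected
substitution per codon site per unit branch length. Codon frequencies:
uniform, F1x4, F3x4 (default, position-specific nucleotide frequencies,
empirical and not optimized) or observed codon frequencies. Frequencies
are floored at 1e-8 and renormalized so every sense codon stays
reachable on short alignments.

**Amino acid models.** Equal-rate (Poisson, uniform frequencies) and the
empirical JTT exchangeabilities with JTT or user frequencies, both
scaled to unit mean rate; a codon-model lumping is available to derive a
20-state process consistent with a fitted codon model.

**Transition probabilities** use the symmetrized spectral decomposition
of the reversible generator (B = D^{1/2} Q D^{-1/2}, eigh), cached per
parameter setting; P(t) rows are clipped at 0 and renormalized, which
keeps them stochastic to ~1e-15. All constructed generators satisfy
detailed balance to 1e-12.

## Likelihood machinery

Felsenstein pruning over unique site patterns with per-node rescaling
(divide by the per-pattern maximum, accumulate logs), gaps/ambiguity as
flat partial likelihoods, root weighted by π. An outside ("up") pass
yields, per branch, the inside×outside decomposition whose contraction
with P(t) reproduces the tree likelihood exactly — verified against the
rerooting (pulley) invariance and used for two purposes:

* **marginal ancestral posteriors** at every node (π ⊙ inside ⊙ outside,
  normalized per site), and
* **per-branch likelihood curves**: projecting inside and outside
  partials onto the eigenbasis once reduces lnL(t) to
  Σ_pat w log(Σ_k c_k e^{λ_k t}), so Brent on one branch costs
  O(patterns × states) per evaluation.

Site-class mixtures (M1a/M2a/M8/branch-site A) compute per-class
per-pattern log-likelihoods and combine them by logsumexp with the class
proportions; transition matrices are built once per distinct ω (batched
over branches) and shared across classes.

## Optimization strategy

M0 alternates (i) branch-length sweeps — every edge Brent-optimized on
its eigenbasis curve against partials computed once per sweep, with a
monotone sequential fallback if the simultaneous update ever decreases
the likelihood — and (ii) coordinate Brent updates of log κ and log ω
(full range in round one, a ×3 bracket afterwards), until a round gains
less than 1e-3 log units (cap 10 rounds; non-convergence can raise with
the best fit attached). Bounds: ω ∈ [1e-4, 50], κ ∈ [0.01, 100],
t ∈ [1e-8, 20]. Inner loops run in single precision — lnL noise
~1e-7 relative, far below the convergence tolerance — and the reported
likelihood is re-evaluated in double precision so comparisons across
fits are clean.

All other models reuse the M0 branch lengths rescaled by one free global
factor, rather than re-estimating every branch — a deliberate desk-scale
trade-off; it makes non-M0 likelihoods very slightly conservative
relative to a full joint optimization, and is the main implementation
tolerance when comparing to full codeml-style fits. Mixture parameters
are optimized by Nelder-Mead on transformed coordinates (logit
proportions via stick-breaking, log ω, 1+exp(·) for the ω>1 classes).
The branch-site A alternative starts ω2 at 1.5, 5 and 20 (best of three,
known multimodality) plus a near-boundary start so the null
configuration is reachable; M2a/M8 likewise get a near-null start so
nesting inequalities hold in practice. The free-ratio model is fit by
monotone per-branch edge sweeps of ω from the M0 optimum with κ
refreshed between sweeps, so its likelihood never falls below M0's.

M8's β distribution is discretized into K=10 equal-probability
categories represented by their means (incomplete-beta closed form).

**LRT conventions:** two-ratio vs M0, df=1; M2a vs M1a, df=2; M8 vs M8a,
df=1; branch-site test 1 (bsA vs M1a), df=2; test 2 (bsA vs bsA-null),
df=1 with the plain χ² (not the 50:50 boundary mixture — the
conservative mixture halves these p-values; the plain χ² matches the
convention under which a branch-site 2Δℓ of 3.516 is read as P ≈ 0.06).
2Δℓ within −1e-6 of zero is clamped; larger deficits raise an
optimization-failure error. Site identification is NEB: posterior class
memberships at the MLEs, reported at the 0.5 and 0.95 thresholds. BEB
(integrating parameter uncertainty) is not implemented; NEB posteriors
are known to be anticonservative near boundary MLEs, which is a
limitation to keep in mind when reading pp values.

## Ancestral reconstruction and substitution maps

Reconstruction is marginal (per node, independently maximized), at the
amino acid level by default — replacement annotations are protein-level —
with codon-level reconstruction available. The tree is rooted as
supplied (or via an outgroup); under reversibility the posteriors at any
retained node are invariant to the rooting, which is tested. MAP ties
break toward the alphabetically first state. Gapped positions still
receive posteriors (flat leaf contributions) and are flagged when the
maximum posterior falls below 0.5. A branch carries a change at a site
when the parent's MAP state differs from the child's MAP (internal) or
observed (leaf) state; replaying all branch changes from the root MAP
sequence reproduces every leaf, which is asserted in tests.

## The convergence test

For a designated non-nested branch pair, co-occurring changes at a site
are **parallel** (same ancestral, same derived), **convergent** (different
ancestral, same derived) or neither. With parent states plugged in at
their MAP values (an option integrates over the parent posteriors
instead) and P1, P2 the branch transition matrices under the fitted
amino acid model:

    E_par  = Σ_{sites: a1=a2=a}  Σ_{y≠a}        P1[a,y]·P2[a,y]
    E_conv = Σ_{sites: a1≠a2}    Σ_{y∉{a1,a2}}  P1[a1,y]·P2[a2,y]

Observed counts are referred to Poisson upper tails with these means:
p_par, p_conv, and p_combined for the pooled count. The headline
statistic is p_par, mirroring the parallel-replacement framing of the
analyses this pipeline reproduces; the expectation model (equal-rate by
default, JTT optional) is always reported alongside so model sensitivity
is visible. Branch lengths for the expectation are re-estimated on the
protein alignment (amino acid substitutions/site). Flagged sites can be
annotated for invariance across a user-supplied reference panel
(e.g. non-bat mammals).

MAP plug-in makes E slightly conservative or anticonservative depending
on reconstruction certainty; in the study-like regime (strong purifying
selection, short branches) reconstructions are near-certain and the null
distribution of p_par is conservative relative to uniform, which the
calibration experiment checks.

## Synthetic data

The simulator draws the root from π and evolves each branch by sampling
from its transition distribution per site, recording branch *endpoint*
changes — the granularity ASR-based inference can see (within-branch
multiple hits are invisible by design). Site-class simulation assigns
sites to (proportion, ω_background, ω_foreground) classes; foreground ω
applies on tagged branches. Injection of a convergent signal rewrites
every node at or below each focal branch to the forced derived state at
the chosen sites and patches the change logs, so the replay invariant
holds and all non-focal signal is untouched.

The study-like fixture is a 24-leaf binary tree shaped like the bat
phylogeny — Yinpterochiroptera (Pteropodidae + Rhinolophoidea) sister to
Yangochiroptera (Emballonuroidea + (Noctilionoidea + Vespertilionoidea)),
two laurasiatherian outgroups — with branch lengths uniform on
[0.01, 0.3] substitutions per codon site, and default simulation
parameters in the regime the real genes show: 250–300 codons, κ = 2,
ω = 0.08 (strong purifying selection). What the generator does *not*
emulate: indels, among-site rate variation beyond the ω classes,
base-composition heterogeneity across lineages, and alignment error; a
passing pipeline on synthetic data therefore validates the inference
machinery, not robustness to those real-data complications.

## Validation suite and problem sizes

`scripts/acceptance.py` (and the mirror tests) recompute, from scratch:

* pruning lnL vs exhaustive enumeration over internal states (61-state
  quartet and 20-state 5-taxon trees) — agreement to ~1e-14 relative;
* marginal posteriors vs direct Bayes enumeration — ~1e-15 absolute;
* closed forms: P(X≥3|E=1) ≈ 0.0803, χ²(3.841, df=1) → p = 0.05, exact
  NJ recovery of an additive matrix, E_par = S·d1·d2/19 under the
  equal-rate model;
* M0 ω recovery: 20 replicates of 16 taxa × 3000 codons at true ω = 0.08
  (median ω̂ reported, expected within ±25% of truth);
* convergence-test calibration (200 null replicates of the 24-taxon
  fixture at 287 codons; one-sided KS against uniform) and power
  (100 replicates with 2 injected parallel sites; fraction with
  p_par < 0.05).

Replicate counts and alignment sizes were chosen to characterize the
estimators well at desk scale; heavier experiments (e.g. type-I error of
the branch-site LRT over hundreds of fits) run scaled-down in the test
suite with the same machinery.

## Known limitations

* Branch lengths are shared across non-M0 models up to one scale factor
  (see above); absolute lnL values differ slightly from fully joint
  optimizers, though LRT statistics of properly nested pairs are
  much less affected.
* NEB, not BEB, site posteriors.
* No indel model; gap columns are missing data.
* The LWL pathway-averaging convention for multi-hit codons (flanking-
  codon class averaging) is one of several in circulation; distances on
  highly diverged pairs differ at the percent level between conventions.
* Free-ratio ω estimates on short branches are weakly identified (few
  substitutions); they are reported as rough per-branch measures, as
  intended.
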