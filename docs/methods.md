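# Methods

This note documents the models, numerical choices and synthetic-data design
behind `amyloidvs`, in the spirit of a package methods appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Ligand database curation

Literature affinity tables are heterogeneous: *K*d values appear in pM–M
units, some only as limiting bounds ("*K*d > 1 µM"), and the same compound
recurs across sources. The curation model is:

- **Unit handling.** Every report is converted to log₁₀(*K*d/M) at parse
  time. Limiting bounds keep a direction (`gt` = *K*d above the quoted
  value, `lt` = below); a `>`/`<` prefix embedded in the value cell
  (including the fullwidth characters common in scraped tables) is honored.
- **Deduplication** merges records whose salt-stripped, neutralized parent
  structures give the same canonical SMILES. Stereochemistry is retained, so
  stereoisomers stay distinct — a deliberate choice where the looser
  alternative (ignore stereo) could silently merge *E*/*Z* probe pairs with
  different affinities.
- **Site assignment.** A ligand is tagged as binding the common FBH site iff
  at least one of its measurements is a competition assay displacing one of
  the reference radioligands (ids configurable, default `ref1`–`ref8`; the
  reference structures themselves are not machine-readable inputs). For
  FBH-tagged ligands only those qualifying measurements enter the consensus,
  since direct-assay numbers for the same compound may report other sites.
- **Consensus affinity** is the arithmetic mean of point-valued
  log₁₀(*K*d/M) reports — i.e. a geometric mean of *K*d. Averaging on the
  log scale was chosen because every downstream model, class bin and plot
  axis works in log units; averaging raw *K*d would weight weak-affinity
  outliers ~10–100×.
- **Eligibility.** Any limiting report disqualifies a ligand from
  regression. A limiting-only ligand remains classification-eligible when
  its tightest bound pins a unique class (e.g. *K*d > 1 µM ⇒
  log *K*d > −6 ⇒ weakest class); ligands with contradictory bounds are
  excluded and logged. Conservation (entries + excluded = input) is asserted
  in tests.

## Property filter

Molecular weight (RDKit average molecular weight), Crippen atom-contribution
logP, and net formal charge of the structure as drawn. Window edges are
closed — a 500.0 Da compound passes a 200–500 window — because the source
ranges are quoted without open/closed semantics and excluding boundary
compounds would be the surprising reading. No pKa/protonation model is
applied; "charged" means formal charge, and the logP estimator is recorded
in the output (`logp_method`) so windows can be recalibrated if a different
estimator is substituted.

## Descriptor panel and preprocessing

The default panel has 45 descriptors: 13 compositional, 22 topological
(including a custom aliphatic-chain count: connected components of acyclic
non-aromatic carbons), 10 conformational (inertial shape descriptors on a
3D conformer). It ships as a YAML config and can be replaced wholesale. 3D
descriptors use the lowest-MMFF-energy member of a 10-conformer seeded ETKDG
ensemble; one conformer is a pragmatic simplification (no ensemble
averaging), and embedding failures exclude the ligand from 3D-complete
tables rather than imputing.

Standardization is (X − μ)/σ with **population** σ (ddof = 0), fitted on
training rows only and applied unchanged to held-out rows; zero-variance
columns are dropped with a warning. Correlation pruning visits columns in
configured order and drops any column reaching |r| ≥ 0.9 against an
earlier-retained one — a deterministic later-listed tie-break.

## Affinity models

Class bins on log₁₀(*K*d/M): class 0 ≤ −8 < class 1 ≤ −7 < class 2 ≤ −6 <
class 3, upper edge included in each bin. Regression is scored by MAE in
log units, classification by balanced accuracy (unweighted mean per-class
recall).

Nested cross-validation uses stratified (classification) or shuffled
(regression) outer 5-folds; per outer fold, hyperparameters are chosen by a
seeded randomized search (default budget 50 parameter draws, configurable)
scored by inner 5-fold CV on the outer-training portion only, then the
winner is refit and scored once on the outer-test fold. Per-fold seeds are
spawned from the master seed, so reports reproduce bit-for-bit. A class
rarer than the fold count raises immediately with guidance to merge bins.
Supported families: random forest, extra trees, gradient boosting (plus the
histogram variant), AdaBoost, SVM (and a linear-kernel-only SVM), with
XGBoost/LightGBM backends available where installed.

Baselines: *average* predicts the training-fold mean (regression) or modal
class; *randomize* draws test predictions uniformly without replacement
from the training targets, averaged over ≥100 seeded permutations. For the
final screening model the winning family is refit on the full table with
hyperparameters chosen by one inner-CV search — the two-level protocol is
for unbiased scoring, not for producing the deployment model.

Selection keeps candidates with predicted −log₁₀(*K*d/M) strictly above a
threshold (e.g. 9.8) and/or the top-*n* by predicted affinity, ties broken
lexicographically by ligand id.

## Two-site ThT binding model

Free and fibril-bound ThT both fluoresce, so

I = ε_f φ_f · [ThT] + ε_b φ_b · ([ThT·S₁] + [ThT·S₂]),

with two site classes: S₁ binds both ThT and the competitor L, S₂ binds
ThT only, and *K*d(ThT) is assumed equal at both sites. Mass action plus the
four mass balances (ThT, L, S₁, S₂) close the system.

**Solver.** Rather than 2-D Newton iteration, the system is reduced
analytically: given free [ThT], the L/S₁ balances give free [L] as the
nonnegative root of a quadratic (evaluated in cancellation-safe form), and
the remaining ThT balance is a scalar function of free [ThT] with a
guaranteed sign change on [0, ThT_tot]. Brent's method on that bracket gives
machine-precision roots unconditionally — no damping heuristics, no
convergence failures. All states are validated against a 10⁻¹² relative
residual tolerance; the single-site limit agrees with the closed-form
quadratic isotherm to ~10⁻¹⁵.

**Identifiability and fitting.** Because *K*d(ThT) is shared, a direct
titration (no competitor) is *exactly* a one-site isotherm in S₁+S₂: the
direct phase cannot identify the S₁/S₂ split, only the total. The split is
identified by the competition phase (the depth of the displacement plateau).
The fitting API reflects this: the direct fit (ε_b φ_b, *K*d(ThT), total
sites; multi-start log-spaced *K*d initializations, log₁₀-space parameters)
takes the S₁ share as a parameter (default 0.5), and the competition fit —
one-dimensional in log₁₀ *K*d(L) with all phase-1 parameters held fixed —
can optionally float that share. `fit_global` additionally offers a joint
fit of both phases sharing all parameters; this avoids propagating phase-1
point estimates into *K*d(L) and roughly halves its error at fixed noise,
and is what the acceptance script uses for parameter-recovery statistics.
The classical sequential protocol remains available and seeds the joint fit.

Uncertainties are the dispersion across ≥3 independently fitted replicate
curves (t-based 95 % CI) when replicates exist, otherwise the asymptotic
covariance estimate, labelled as such. Degenerate data are flagged rather
than fitted: all-zero intensities (no bound-state signal) and flat
competition responses (*K*d(L) unidentifiable).

The saturating-competitor displacement fraction uses the exact limit: at
[L] → ∞, S₁ is fully occupied by L and bound ThT tends to the one-site
isotherm in S₂ alone.

## Similarity

Hashed topological-path fingerprints (paths of 1–7 bonds, 2048 bits by
default; parameters recorded in every output). Tanimoto = |A∩B|/|A∪B|; two
empty fingerprints are defined as similarity 1 with a warning. The
most-similar-database-member query breaks ties lexicographically, making it
invariant to database order.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of their spec (seed included); identical specs
give byte-identical files.

- **Ligand tables** draw structures from 20 two-slot scaffold templates
  spanning recurring amyloid-ligand motifs (benzothiazoles/benzoxazoles and
  other fused 6,5-benzoheterocycles, stilbenes, chalcones, flavones,
  aurones, bis-styryl aromatics, carbazoles …) with small neutral
  substituents; log₁₀(*K*d/M) is normal with default mean −7, SD 1,
  matching the observed micromolar-to-subnanomolar spread of fibril-ligand
  affinities. A chosen count of entries becomes limiting bounds at the
  *K*d > 1 µM level, assay kinds and reference-competitor ids are mixed so
  site assignment is exercised, and duplicate rows re-render an existing
  structure under a different SMILES. Not emulated: correlated
  affinity–structure relationships across sources, real measurement
  heterogeneity between labs, ionizable chemistry (all scaffolds are
  neutral), and billion-compound library scale. Tests passing on these
  tables validate the curation *arithmetic and plumbing*, not literature
  accuracy.
- **Descriptor tables** are iid standard-normal features with targets
  `intercept + Xβ + N(0, σ)` — a recoverability oracle. Real descriptors
  are correlated and non-Gaussian; these tables show that the CV machinery
  finds signal that is present and reports none when absent, nothing more.
- **Titration curves** follow the field's experimental template: an 8-point
  ThT dilution (0–2 µM, no fibrils), a 24-point direct titration (0–3 µM
  ThT into 500 nM monomer-equivalent fibrils), and a 24-point competition
  titration (L from 1 nM to 30 µM at 1 µM ThT) — point counts typical of
  plate-reader titrations. Default truth: log *K*d(ThT) = −6.7,
  log *K*d(L) = −7.6, two equal 250 nM site pools, and a 200-fold
  bound/free response ratio (ThT's fluorescence enhancement on amyloid
  binding is commonly 100–1000-fold). Noise is additive Gaussian with SD
  expressed as a fraction of the curve's dynamic range (default 2 %). These
  choices were fixed by an identifiability analysis at design time: sparser
  schedules or near-unity response ratios leave *K*d(ThT) poorly
  determined, which the error budget in `fit_global` then inherits. Not
  emulated: inner-filter effects, photobleaching, pipetting-volume
  correlations, or heteroscedastic detector noise.

## Problem sizes and tolerances

The test suite and acceptance script run at desk scale by design: curation
fixtures of 707/388 ligands, 1000 random solver draws against the closed
form, a 50×50 monotonicity grid, 100 seeded titration fits at 2 % noise,
120-row nested-CV tables, and a 120-candidate end-to-end screen against an
80-ligand training set with a planted lipophilicity-affinity link (the
planted subset is the top-20 % most lipophilic candidates; enrichment is
the planted fraction of the shortlist over the planted base rate). Solver
states are accepted at 10⁻¹² relative residual; standardization claims hold
to 10⁻⁹; recovery medians are judged against 0.1 log units.

## Known limitations

- The third (3D field-point) screening stage of the original workflow
  depends on proprietary software and is represented only by a plugin
  interface; the bundled `shape-neighbor` example plugin is an illustrative
  USR nearest-neighbor scorer, explicitly not a field-point QSAR.
- The high/low-affinity sub-site structure of the FBH site is not modeled
  beyond the S₁/S₂ dichotomy, and *K*d(ThT) is assumed site-independent.
- The 45-descriptor default panel is a documented, category-balanced choice,
  not a canonical list; swap in a bespoke panel via configuration for
  comparisons against other work.
- Published model scores obtained on the real curated database (e.g. an SVM
  MAE near 0.4 against a 1.1 mean baseline) depend on that database and an
  unpublished search budget; this package reproduces the scoring machinery
  and its baselines, not those numbers, which would require the original
  supplementary data as input.
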