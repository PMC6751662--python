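# Methods

This package implements a validated analysis pipeline for a cross-species
GPCR–neuropeptide pharmacology screen: synthetic data generation from an
explicit ground truth, the calling and grading procedures that turn plate
records into an interaction matrix, full concentration–response fitting,
behavioral statistics, and candidate-ligand inference. This note records the
model assumptions, parameter defaults and their reasons, known limits of the
generator's realism, numerical choices, and how ambiguities in the verbal
calling scheme were resolved.

## Generative model

**Pharmacology.** Each receptor × peptide × pathway triple carries 4PL
parameters (EC50, Emax as a fraction of the receptor's window, Hill slope,
default 1). Receptor occupancy is `c^h / (c^h + EC50^h)`, evaluated in log
space for numerical safety at extreme concentration/EC50 ratios.

**Readouts.** Stimulatory pathways (`Gs_cAMP`, `Gq_IP`, `G16_IP`,
`Dqi4myr_IP`) report accumulation over basal:
`mean = basal · (1 + (window − 1) · Emax · occ)`. The Gi/o readout
(`Gio_cAMP_fsk`) reports inhibition of forskolin-stimulated cAMP:
`mean = basal · forskolin_fold · (1 − Emax · occ)` with `forskolin_fold = 20`
(a typical forskolin stimulation magnitude; configurable).

**Noise.** Per-well multiplicative log-normal noise with unit mean and a
given coefficient of variation (default 10%, the common plate-reader scale):
`σ² = ln(1 + CV²)`, location `−σ²/2`. A per-experiment log-normal scale
factor (default CV 5%) models day-to-day assay gain; per-experiment
normalization to the control mean cancels it exactly, which is precisely why
the real assay normalizes per experiment.

**Replicate structure.** Three independent experiments × technical
triplicates per condition; buffer controls per stratum and experiment, plus a
forskolin control for the Gi/o readout.

**Behavior.** Quadrant-assay counts are multinomial per plate over
(repellent-quadrant, control-quadrant, unscored) destinations; bordering
counts are binomial. The plate is the statistical unit throughout.

### Limits of generator realism

- Wells are exchangeable within an experiment: no plate-position, edge, or
  drift effects.
- Noise is purely multiplicative; there is no additive read floor, so very
  low signals are relatively too precise.
- Pharmacology is stationary (no desensitization, depletion, or time
  dependence) and peptides act independently (no mixtures).
- Worms are independent in the behavioral model; real bordering is an
  aggregation phenotype with positive within-plate correlation, so simulated
  plate-to-plate variance is a lower bound.

## Calling procedures

**Normalization.** Per experiment, condition mean ÷ buffer-control mean
(fold of basal), or ÷ forskolin-control mean for Gi/o (fold of forskolin).
Per-well folds are pooled across experiments for significance testing;
per-experiment condition folds give the reported mean ± SEM.

**Activity call.** A condition is active iff it clears the fixed threshold
(≥ 2.0-fold of basal, or ≤ 0.8 fold of forskolin, boundaries inclusive — the
published cut numbers state no boundary convention, so the inclusive reading
is used) **and** is significant versus control by one-way ANOVA with
Dunnett's post-hoc test at α = 0.05 (`scipy.stats.dunnett`, seeded for
reproducibility). On noise-free input with zero variance everywhere the
Dunnett statistic is undefined; an exact shortcut is used instead (any mean
difference → p = 0, none → p = 1), which makes noise-free calls equal pure
threshold calls.

**Receptor window.** Worm receptors: the strongest response elicited by any
peptide at any concentration (lowest fold for Gi/o). Human receptors: the
response to the declared endogenous agonist at the top concentration.
Fraction-of-window is computed on the fold scale:
`frac = (fold − 1)/(fold_max − 1)`, and for Gi/o
`frac = (1 − fold)/(1 − fold_min)`.

**Grades.** Cutpoints FULL = 0.8, MID = 0.35, equality δ = 0.10 (all
configurable) quantify the verbal shades: `none` neither concentration
active; `i` only 10 µM active, frac < MID; `ii` only 10 µM active,
frac ≥ MID; `iii` both active, frac_high < FULL; `iv` both active, partial at
0.1 µM, frac_high ≥ FULL; `v` frac_low ≥ FULL already at 0.1 µM. Asterisk
(high-affinity partial agonism) = both active, |frac_high − frac_low| ≤ δ,
frac_high < FULL; it is an orthogonal flag, the cell keeps its shade.
Resolution of a gap in the verbal scheme: "active at 0.1 µM only" has no
slot (monotone agonism cannot produce it noise-free); it maps to grade iii.
Fractions outside [−0.2, 1.5] raise an error as a normalization fault.

**Coupling preference.** Two-way ANOVA (pathway × stimulation, type-II sums
of squares via statsmodels; type choice is moot for balanced designs) with
pooled-MSE pairwise comparisons of each condition against its pathway's
control, Bonferroni-adjusted. A pathway is active if any condition is
significant and above threshold; among active pathways the strongest signal
(max fold of basal; 1/min fold of forskolin for Gi/o) is primary.

**Curve fitting.** 4PL by nonlinear least squares on log10 concentration
(`scipy.optimize.curve_fit`), multi-start over 5 EC50 grid points × Hill
{0.5, 1, 2}, best residual kept. Convergence requires the fitted log-EC50
within the tested range ± 2 decades, positive Hill, and a non-collapsed
window; inhibition curves legitimately run downward. Emax is reported as a
percentage of the reference agonist's fitted window. Grade/EC50 band
consistency uses the bands i/ii: 10–100 µM, iii: 0.3–3 µM, iv: 30–300 nM,
v: ≤ 100 nM, and excludes partial agonists (the bands assume full agonism).

**Peptide motifs.** Last four residues of amidated peptides, precedence
NPF/Y-type (`R-x-R-[FY]`) > FMRFamide-type (`[Ω][Ψ]RF`) > short-NPF-type
(`[Ψ][Ψ]RF`), with Ω = {F, W, Y} and Ψ = {A, V, L, I, M, F, W, C}. Whether Ω
should include H, or Ψ should include G/P, is not settled; the sets are
configurable and these defaults are the conservative reading (which is why,
e.g., GLGPRPLRFa classifies as "other" despite being an RFamide).

**Behavioral statistics.** Avoidance index = (n on repellent side − n on
control side)/scored, negative when the repellent is avoided (`as_printed`
convention; a flag flips the sign, and another includes unscored worms in the
denominator). Two genotypes: unpaired two-sided t-test; more: one-way ANOVA
with Bonferroni-adjusted pairwise t-tests versus the reference genotype.
Stars at p < 0.05 (\*) and p < 0.001 (\*\*\*).

**Candidate inference.** Candidates = peptides with grade ≥ a minimum at the
target receptor AND every rescuing receptor (brute-force set intersection,
verified against an independent enumeration); optionally peptides active at
all non-rescuing specificity controls are excluded. Ranked by strongest
minimum grade, then alphabetically.

## Validation problem sizes

The simulation-study sizes (50 seeds for parameter recovery, 10,000 triples
for the grading oracle, 100 seeds for matrix recovery, 1,000 repetitions for
each type-I calibration, 1,000 random matrices for candidate inference) are
the package's own validation choices, sized so the whole suite runs in about
two minutes on one CPU while keeping Monte-Carlo error well below the checked
tolerances. The type-I checks allow two binomial Monte-Carlo standard errors
above the nominal α — an a-priori sampling allowance for an estimate whose
expectation is at α, not a widened acceptance band.

## Numerical notes

- All randomness flows from explicit seeds (`numpy.random.default_rng`;
  Dunnett's resampling seeded via its `rng` argument).
- Occupancy and the 4PL model are evaluated in log space to avoid overflow at
  extreme concentration ratios.
- Reported acceptance quantities are rounded to 6 significant digits: one
  ill-conditioned multi-start fit can flip between numerically tied starts at
  ~1e-8 relative between runs; rounding far below every tolerance makes
  reruns byte-identical.
- Plate tables store signals via `repr` (shortest round-trip float) so
  write→read→write is lossless.
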