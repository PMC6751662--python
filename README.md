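# flpnpr — cross-species neuropeptide–GPCR screen analysis

Analysis pipeline for a cross-species deorphanization screen of
RFamide/NPY-family neuropeptides against C. elegans neuropeptide receptors
(NPRs) and their human counterparts. Worm FMRFamide-like peptides (FLPs) and
human NPY-family/RFamide peptides share a C-terminal RFamide/RYamide
consensus; the pipeline asks which peptides activate which receptors, how
strongly, and — when human receptors can functionally substitute a worm
receptor in vivo — which peptides are therefore the candidate ligands
mediating the rescued behavior.

The package contains:

- a synthetic-data generator with an explicit ground truth (4PL pharmacology
  per receptor × peptide × pathway, log-normal plate noise, multinomial /
  binomial behavioral counts), so every downstream step is validated against
  a known answer;
- the calling machinery: per-experiment normalization (fold of basal, fold of
  forskolin for Gi/o), activity = fixed threshold AND Dunnett significance,
  five-shade grading with a high-affinity partial-agonist asterisk, coupling
  preference via two-way ANOVA, and the peptide × receptor interaction
  matrix;
- full concentration–response fitting (4PL, multi-start) with Emax relative
  to a reference agonist;
- C-terminal motif classification and alignment of the peptide panel;
- behavioral statistics (quadrant avoidance index, lawn bordering) with
  plate-wise group comparisons;
- candidate-ligand inference by matrix intersection over rescuing receptors.

See `docs/methods.md` for model assumptions, parameter defaults, and how
ambiguities in the verbal calling scheme were resolved.

## Worked example

The numbered scripts under `analysis/` run the pipeline on the bundled
demonstration panel (10 receptors × 13 peptides; the well-characterized
pharmacology uses published potencies, the rest is synthetic):

```sh
python analysis/01_classify_peptides.py
python analysis/02_simulate_screen.py   --seed 0
python analysis/03_call_matrix.py       --seed 0
python analysis/04_fit_curves.py        --seed 0
python analysis/05_behavior.py          --seed 0
python analysis/06_infer_candidates.py
```

`03_call_matrix.py` prints the called interaction matrix (grades i–v from
weakest to strongest, 0 inactive, `*` = high-affinity partial agonist):

```
         NPR-1 NPR-11 Y1R  Y2R Y4R  Y5R NPFF1R NPFF2R PrRPR QRFPR
FLP-14    iii*    iii   0  iii  iv  iii     iv    iii     0     0
FLP-15-2    iv     iv   0    0   0    0     iv     iv     0     0
FLP-18-5    iv      0   0    0   0    0    iii    iii     0     0
FLP-21       v      v   0   iv  iv   iv     iv     iv     0     0
FLP-27       0    iii  ii   ii   0    0      0      0     0     0
FLP-34-1     0      v  ii  iii   0    0      0      0     0     0
FLP-34-2     0      v   0   ii   0    0      0      0     0     0
NPY          0    iii   v    v   0    v      0      0     0     0
PYY          0     iv   0    0   0    0      0      0     0     0
PP           0      0   0    0   v    0      0      0     0     0
NPFF         0      0   0    0   0    0      v      v     0     0
PrRP         0      0   0    0   0    0      0      0     v     0
QRFP         0      0   0    0   0    0      0      0     0     v
```

`04_fit_curves.py` fits full 8-point curves for the characterized pairs and
recovers the generating pharmacology (EC50 in nM, Emax as % of the reference
agonist FLP-21):

```
receptor  peptide  ec50_nM  hill  emax_pct_reference reference_peptide  converged
   NPR-1   FLP-14    24.79  0.63               55.89            FLP-21       True
   NPR-1   FLP-21     0.97  0.98              100.00            FLP-21       True
  NPR-11   FLP-21    30.32  1.05              100.00            FLP-21       True
  NPR-11 FLP-34-1    20.06  1.00              102.96            FLP-21       True
  NPR-11 FLP-34-2     0.65  0.92              101.04            FLP-21       True
  NPR-11      NPY   269.44  0.92               49.40            FLP-21       True
  NPR-11      PYY    23.60  1.05               86.74            FLP-21       True
```

`05_behavior.py` compares genotypes plate-wise (avoidance index is negative
when the repellent is avoided; `***` = p < 0.001 vs the mutant):

```
avoidance index (mean over plates, vs mutant):
  mutant   -0.105
  rescue   -0.578  ***
  wt       -0.625  ***
bordering fraction (mean over plates, vs mutant):
  mutant   0.821
  rescue   0.208  ***
  wt       0.160  ***
```

`06_infer_candidates.py` intersects the matrix over the native target
receptor and every heterologous receptor that substitutes it in vivo:

```
target NPR-1; rescuers Y2R, Y4R, Y5R, NPFF1R, NPFF2R
candidate ligands (strongest minimum grade first): ['FLP-21', 'FLP-14']
after excluding peptides active at all specificity controls: ['FLP-21', 'FLP-14']
```

## Layout

```
src/flpnpr/        library (synth, screen, curves, peptides, behavior,
                   candidates, io, config, panels, studies)
analysis/          numbered pipeline drivers (the worked example above)
scripts/           acceptance.py — recompute validation quantities
tests/             unit + property + acceptance tests (pytest)
docs/methods.md    model assumptions and design decisions
results/           generated outputs (not committed; all plain text)
```
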