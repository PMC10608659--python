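# quinoscreen

Screening toolkit for the redox activity of substituted quinones — the
compound class most widely studied as organic battery electrode material.
Quinones are reversibly reduced (here by two electrons / two lithium), and
their electrode potential ΔE is tunable by substituents:
electron-withdrawing groups such as −CN and −C≡CMe raise it. `quinoscreen`
implements the full in-silico workflow for mapping that structure–potential
relationship:

1. **Derivative enumeration** — all −CN / −C≡CMe derivatives of quinone
   scaffolds, substituting one representative per atom-symmetry class of
   C–H positions and deduplicating by canonical SMILES.
2. **Molecular descriptors** — a 32-descriptor topological panel:
   electrotopological (E-state) counts/sums/extrema, Burden-matrix charge
   eigenvalue extremes (BCUT), eccentric connectivity, topological charge
   indices, Zhao van der Waals volume, TPSA, molecular weight, and a Hückel
   π-system pseudo-LUMO.
3. **Labels** — Gibbs free-energy bookkeeping and the Nernst conversion
   ΔE = −ΔG/(nF) for the reduction Q + 2 Li → Li₂Q, with
   ΔG = G(Li₂Q) − G(Q) − 2 G(Li) and G = H − TS assembled from standard
   gas-phase components.
4. **Descriptor selection** — low-variance removal (mode ≥ 60%), weak
   target correlation (|r| < 0.25), mutual correlation (|r| > 0.7, greedy
   by target relevance), and backward stepwise regression judged by 5-fold
   cross-validated R².
5. **Models** — five regressors implemented from scratch: closed-form ridge
   β = (XᵀX + λI)⁻¹Xᵀy, CART regression trees with exhaustive split
   search, random forests, extra trees, and gradient boosting
   F_m = F_{m−1} + γ·h_m. Assessment is the mean validation R² over 5-fold
   cross-validation on an 80/20 train/test split, with trendline
   (slope/intercept/R²) diagnostics on the held-out test set.

A synthetic-data module generates study-scale datasets (a real enumerated
537-derivative quinone population with linear-in-chemistry labels and
back-solved thermochemistry) so the entire workflow is testable without any
quantum-chemistry computation. See `docs/methods.md` for the models,
defaults and numerical choices in detail.

## Worked example

Run the full simulated screening campaign:

```bash
quinoscreen run --seed 1 --no-grid-search --out run/
```

prints

```
cross-validated R^2 ranking:
  ridge: 0.695
  gradient_boosting: 0.693
  extra_trees: 0.677
  cart: 0.676
  random_forest: 0.622
```

The pipeline simulated 537 quinone derivatives, split them 429/108, ran
descriptor selection on the training rows only, fitted the five model
families at the study-protocol hyperparameters (ridge λ = 0.1, tree depth
3, 10/15 forest estimators, gradient boosting γ = 0.05 with 50 stages), and
evaluated on the sealed test set. The linear model tops the ranking — the
expected outcome when the underlying structure–potential relationship is
linear, and the reason ridge regression is attractive for fast database
screening. `run/report.json` holds per-model CV and test R², trendline
slope/intercept/R² and tree feature importances; `run/predictions.csv`
holds per-molecule reference and predicted potentials, e.g.

```
canonical_smiles,E_reference,E_ridge,...
CC#CCC1=C(C)C(=O)C=C(C#N)C1=O,1.4103618084420158,1.366591252962496,...
```

Other subcommands: `quinoscreen generate` (enumerate derivatives of your
own scaffold .smi file), `describe` (descriptor CSV for any .smi),
`simulate` (write a synthetic dataset: descriptors, labels, thermochemistry
JSON, ground truth), and `select` (run the selection stages on descriptor/
label CSVs and write the audit report). Everything is importable as a
library from `quinoscreen.*`.

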