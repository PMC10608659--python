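# Methods

`quinoscreen` models the structure–redox-potential relationship of
substituted quinones, the compound class most studied as organic battery
electrode material. The workflow has five stages: derivative enumeration,
descriptor computation, label calculation, descriptor selection, and
regression modelling. This note records the models, the defaults and the
numerical choices, and what the synthetic data do and do not establish.

## Redox chemistry and labels

The label is the electrode potential of the two-electron, two-lithium
gas-phase reduction Q + 2 Li → Li₂Q,

    ΔG = G(Li₂Q) − G(Q) − 2 G(Li),        ΔE = −ΔG / (nF),   n = 2,

with F = 96485.332 C/mol. Species free energies follow standard gas-phase
statistical thermodynamics,

    H = E₀ + ZPE + H_trans + H_rot + H_vib + RT,
    S = S_trans + S_rot + S_vib + S_el,
    G = H − TS,

at T = 298 K with R = 8.31446 J/(mol·K). The quantum-chemistry calculation
that would produce these components is outside the package; `thermo`
implements only the bookkeeping, with J/mol as the single internal energy
unit and ingest-time conversion from hartree (×2 625 499.6) and eV
(×96 485.332). Entropies are always J/(mol·K). Electron count n ≥ 1 is
validated; ΔE is linear in ΔG by construction.

## Derivative enumeration

Substitution sites are carbon-bound hydrogens only — replacing O–H or N–H
would change the compound class, while C–H substitution by the
electron-withdrawing −CN and −C≡CMe groups is the design move the screening
targets. Sites are grouped into atom-symmetry classes (canonical ranking
without tie-breaking, verified in tests against exhaustive VF2 automorphism
search), and one representative per class is substituted; a brute-force
oracle that substitutes every C–H and deduplicates canonically confirms the
two routes give identical product sets. Deduplication is global across
scaffolds and substitution orders, and output is sorted by canonical SMILES
so enumeration order never depends on input order. Multiplicity is
configurable; the CLI default is monosubstitution, the synthetic generator
uses up to two substituents per molecule.

## Descriptor panel

The 32 descriptors are all topological; no 3D geometry is ever built.
Families and the choices behind them:

- **Electrotopological state.** Intrinsic state I = ((2/N)²δᵛ + 1)/δ with N
  the valence-shell principal quantum number, δᵛ the valence electrons minus
  attached hydrogens, δ the heavy-atom degree. E-state
  S_i = I_i + Σ_j (I_i − I_j)/d_ij² with d the graph distance plus one. The
  perturbation terms are pairwise antisymmetric, so Σ(S_i − I_i) = 0 — an
  exact invariant the tests assert at 1e-10. Atom types use the
  single/double/triple/aromatic bond grammar (dsCH, dssC, aasC, aaCH, tN,
  dO); counts, sums, minima and maxima over typed atoms form the panel
  entries. **Hydrogen E-state**: each hydrogen is treated as a node of the
  same formalism (N = 1, δ = δᵛ = 1, hence I_H = 5) perturbed by heavy atoms
  at their carrier distance plus one. This stays inside one formula but is
  not bit-compatible with any particular descriptor program's dialect.
- **MAXDN2 / MAXDP2.** Defined here as the extreme per-atom intrinsic-state
  variation Δᵢ = Σ_{j∼i} (I_i − I_j) over bonded neighbours:
  MAXDP2 = max(0, max Δᵢ), MAXDN2 = max(0, −min Δᵢ). A pairwise-difference
  reading is degenerate (max positive and max negative magnitudes coincide
  over unordered pairs); the per-atom form is the standard one and is zero
  for molecules with all atoms equivalent.
- **SwHBa** sums E-states over weak hydrogen-bond acceptors. The default
  acceptor set — fluorine, aromatic O/S, nitrile N — captures heteroatoms
  whose lone pairs are π-delocalized and hence weakly accepting; the
  predicate is configurable in `DescriptorConfig`.
- **BCUT.** Extreme eigenvalues of the Burden matrix: Gasteiger partial
  charges (8 equalization iterations) on the diagonal, 0.1 × bond order
  (0.15 aromatic, +0.01 for terminal bonds) for bonded pairs, 0.001
  elsewhere.
- **Topology.** ECCEN = Σ ecc(i)·deg(i); topoDiameter = max eccentricity;
  nRing is the circuit rank; JGI2 is the Galvez mean topological charge
  index of order two, G₂/(N−1) with the charge-transfer matrix from the
  adjacency and inverse-square-distance matrices; fragC is the fragment
  complexity |B² − A² + A| + H/100 over heavy atoms, bonds and heteroatoms.
- **VABC** (Å³) is the Zhao additive volume, Σ atomic contributions −
  5.92·N_bonds − 14.7·N_aromatic_rings − 3.8·N_nonaromatic_rings, hydrogens
  counted explicitly. TopoPSA is Ertl's TPSA; MW is the molecular weight.
- **Pseudo-LUMO** (eV). A simple-Hückel Hamiltonian over the conjugated
  framework (atoms in aromatic rings or multiple bonds, plus lone-pair
  donors bonded to them), with Streitwieser-style heteroatom corrections
  H_ii = α + h·β, H_ij = k·β and the default energy scale α = −6.6 eV,
  β = −2.7 eV. Orbitals fill pairwise from the bottom; the first virtual
  eigenvalue is the descriptor. It is a deterministic stand-in for a
  semi-empirical LUMO and preserves the physically expected trend — −CN
  substitution on a quinone lowers it — which is what the importance
  analysis relies on. Users with externally computed LUMO values can join
  them onto the descriptor table by canonical SMILES.

Descriptors that can be undefined (no π system, no matching atom type,
element outside the volume table, single heavy atom) are emitted as 0 with a
paired `<name>_missing` flag column rather than dropping the row; constant
flag columns are then eliminated by the selection's low-variance stage.

## Descriptor selection

Four stages, in order, with population-standard-deviation z-scoring (so the
covariance of two z-scored variables is exactly Pearson r):

1. **Low variance**: drop a column whose modal value covers ≥ 60% of rows.
2. **Target correlation**: drop columns with |r(x, y)| < 0.25 (boundary
   kept).
3. **Mutual correlation**: greedy scan in descending |target-r| order (ties
   by column order); keep a column iff |r| with every kept column ≤ 0.7.
   Greedy-by-relevance keeps the most label-relevant member of each
   correlated cluster and makes the stage deterministic.
4. **Backward stepwise**: repeatedly remove the column whose removal gives
   the best 5-fold CV R² of an OLS fit (the ridge machinery at λ = 0 with
   pseudo-inverse fallback); stop when the best removal would cost more
   than ε = 0.001 of CV R², or at a configurable survivor floor.

Thresholds apply to absolute correlations by default: a strong negative
predictor is informative and redundancy is sign-agnostic. A signed mode
exists for stages 2–3 (`use_absolute_correlations=False`) for users who
want the literal raw-covariance behaviour; under it a perfect negative
predictor is discarded, which is why it is not the default. The stepwise
stopping tolerance is the smallest rule that still reduces the panel
without hard-coding a target descriptor count.

## Models

All five regressors are implemented directly on NumPy; established ML
libraries appear only in the test suite as independent cross-checks.

- **Ridge**: β = (XᵀX + λI)⁻¹Xᵀy with a leading ones column. The penalty
  covers the intercept by default (the literal closed form);
  `penalize_intercept=False` gives the conventional variant, and optional
  standardization stores its parameters in the model. At λ = 0 a singular
  system either falls back to the minimum-norm pseudo-inverse solution or
  raises an error naming the linearly dependent columns.
- **CART**: exhaustive search over (feature, threshold) pairs, thresholds at
  midpoints of consecutive distinct sorted values, rows with x < t going
  left; cost is node MSE (a Poisson half-deviance
  mean(y·log(y/ȳ) − y + ȳ) is available for positive targets). Ties break
  deterministically: features in column order, thresholds ascending, first
  strict improvement wins. Cost decreases below 1e-12 are treated as zero
  to keep float noise from splitting pure nodes; when a midpoint rounds
  down onto the left value (adjacent floats) the threshold is pushed to the
  right value so neither child can be empty. Feature importance is the
  normalized total weighted cost decrease per feature.
- **Random forest**: size-n bootstrap per tree, fresh random feature subset
  of ⌈m/3⌉ (regression convention, configurable) at every split, exhaustive
  thresholds; prediction is the member mean.
- **Extra trees**: without-replacement subsample (default fraction 0.8,
  1.0 disables subsampling) and one uniformly random threshold per
  candidate feature.
- **Gradient boosting**: F₀ = mean(y); each stage fits a CART tree to the
  current residuals (the squared-error stagewise minimizer) and the model
  advances by γ·h_m. Training MSE is provably non-increasing for
  γ ∈ (0, 1], which the tests verify stage by stage.

All stochastic fits draw from spawned generators of a single integer seed
and are bit-reproducible. Models serialize to JSON (floats survive exactly,
so load → predict is bit-identical), and trees export as indented text.

## Evaluation protocol

Seeded 80/20 shuffle split (train size ⌊0.8n⌋); 5-fold CV by seeded shuffle
plus contiguous chunking (fold sizes differ by ≤ 1), per-fold train and
validation R² averaged across folds, not pooled. Grid search is exhaustive
with two criteria: highest mean validation R², or smallest train−validation
gap (the criterion under which weak regularization is typically selected
for ridge). Grids are ordered from the most regularized/smallest model
upward so exact ties resolve toward the simpler point. Test-set diagnostics
regress the reference potential on the model prediction; a perfect model
gives slope 1, intercept 0, R² 1. The pipeline seals test rows until the
final evaluation step and refuses outright to run with its leakage guard
lifted; the fold seed is derived from, but independent of, the split seed
and recorded in the report.

## Synthetic data

The molecular population is real: 15 built-in quinone scaffolds
(benzo-/naphtho-/anthraquinones with common ring substituents) expanded by
−CN/−C≡CMe substitution up to multiplicity 2 give 537 derivatives, all
descriptors computed by the production code. Only the labels are
synthesized:

    ΔE = b₀ + b_CN·n_CN + b_alk·n_alk + b_L·LUMO + ε,   ε ~ N(0, σ²),

with defaults b₀ = −1.2 V, b_CN = +0.30 V, b_alk = +0.10 V,
b_L = −0.30 V/eV, σ = 0.12 V, clipped to 0.3–2.8 V. The signs encode the
chemistry: electron-withdrawing −CN substitution raises the potential, and
a lower (more negative) LUMO means a stronger oxidant. The magnitudes were
calibrated once so the label distribution matches the documented
qualitative shape for this compound class — everything inside 0.3–2.8 V,
the majority between 0.75 and 1.60 V, unimodal with a right tail of
strongly substituted low-LUMO compounds, clipping < 2% — and then frozen.
Thermochemistry records are back-solved from the labels (component values
at typical gas-phase magnitudes, E₀ absorbing the remainder) so the
free-energy chain reproduces every label to well below 1e-9 V.

The ground truth is deliberately linear in descriptors, which makes the
qualitative model ordering — ridge above all tree ensembles — a recoverable
property; an interaction term can be added for contrast experiments. The
generator does not emulate quantum-chemistry error structure, conformer
effects, or scaffold classes outside the built-in library, so passing tests
establish correctness of the machinery and recoverability of a linear
signal, not predictive accuracy on any real DFT-labelled dataset.

A second generator plants ground truth for selection testing: five
informative standard-normal columns entering the label with equal unit
weight (marginal |r| ≈ 0.41 at the default noise), ten independent noise
columns of which the first is constant, and five duplicate columns.
Duplicates are exact copies by default: with jittered near-copies the
mutual-correlation filter may legitimately keep the copy instead of the
original (it ranks by target correlation), which would make
"all duplicates removed" an ill-posed success criterion; a jitter parameter
exists for that variant.

## Problem sizes and determinism

Default test and acceptance workloads: 537-molecule synthetic populations
(descriptors cached per population since molecules are seed-independent),
300×20 planted selection tables over 10 seeds, 50 random ridge instances,
100 random CART instances, and 10-seed repetitions of the five-family CV
comparison. Every random draw descends from an explicit integer seed;
rerunning any stage with the same configuration is bit-identical.

## Known limitations

- The pseudo-LUMO is a π-topology surrogate: absolute values are not
  comparable to semi-empirical or DFT orbital energies, only trends within
  a congeneric series are meaningful.
- Hydrogen E-state values follow this package's own uniform formalism and
  will not numerically match other descriptor software.
- Enumeration handles no stereochemistry (the substituents create no
  stereocenters on quinone cores) and no O–H/N–H substitution.
- Absolute cross-validated R² values on synthetic data depend on the
  synthetic noise level and selection outcome; only the relative model
  ordering and the exact arithmetic identities are meaningful claims.
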