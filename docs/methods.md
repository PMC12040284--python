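# Methods

## Molecular-graph convention

Molecules are simple, connected, undirected graphs. Two conventions are
load-bearing and deliberate:

1. **Hydrogens are explicit vertices.** Hydrogen-suppressed graphs do not
   reproduce the published amino-acid index table; hydrogen-included graphs
   reproduce every cell that is reproducible at all (see the audit below).
2. **Bond orders are collapsed.** A double bond contributes one edge, so a
   carbonyl oxygen has degree 1. This is likewise required to reproduce the
   published values (verified on the glycine and alanine rows).

The 13 amino acids are stored as frozen atom/bond lists of the neutral
(non-zwitterionic) forms, with stable 0-based atom ordering (heavy atoms
first, hydrogens appended grouped by parent). The SMILES route
(`from_smiles`, rdkit-backed) is an optional convenience; tests assert
label-preserving graph isomorphism between both routes for all 13
molecules. Heavy-atom degrees are validated against per-element caps on
*distinct neighbours* (C ≤ 4, N ≤ 4, O ≤ 2, S ≤ 2). Aromaticity,
stereochemistry, charges and 3-D geometry are out of scope.

## Index computation

All eight Gourava-family indices are edge sums of integer polynomials in
the endpoint degrees and are evaluated in exact integer arithmetic via the
edge-degree partition (the multiset of degree pairs over bonds), which is a
sufficient statistic for every degree-based edge-sum index. A registry maps
index ids to per-edge contribution functions; the classic first/second
Zagreb, Randić and sum-connectivity indices are pre-registered as extras,
and user indices can be added with `register_index`.

## The published table and the audit

The published 13 × 8 index table contains misprints. The audit
(`verify_table2`) recomputes every cell and reports 23 of 104 cells in
disagreement, including:

* glycine GO₁/GO₂ (printed 28/93 vs recomputed 93/280 — consistent with a
  column shift),
* alanine HGO₂ (printed 3364 vs 33464 — a dropped digit),
* the whole isoleucine row: under the hydrogen-included convention
  isoleucine and leucine have *identical* edge-degree partitions (every
  sp³ carbon has degree 4, the carboxyl carbon 3), so their eight index
  values must coincide; the printed isoleucine row differs from the
  printed leucine row in every cell and is unreproducible,
* lysine AGO₁ (printed 886 vs recomputed 583), plus smaller discrepancies
  in the serine, glutamine, lysine and arginine rows.

The audit reports; it never corrects silently.

## Which index table the regressions consume

Because the printed table and the recomputed table disagree, the package
exposes three regression-input variants:

* `printed` — the published table verbatim;
* `computed` — recomputed from the built-in graphs;
* `regression` (default) — the published table with exactly three cells
  replaced by their recomputed values: glycine GO₁ → 93, glutamic-acid
  GO₁ → 210, lysine AGO₁ → 583.

The default is a reconstruction of the input the original analysis
actually used, pinned by the published statistics themselves: with the two
GO₁ corrections, **all fifteen** published GO₁ curve-estimation rows
(intercept, slopes, R, SEE and F for molar mass, isoelectric point and
side-chain volume under all five forms) are reproduced **exactly** at
printed precision, while the verbatim printed column reproduces none of
them (e.g. it yields R = 0.862, SEE = 14.274, F = 31.669 for the molar-mass
linear fit against the published 0.860/14.345/31.246). The lysine AGO₁
correction is pinned the same way by the published multiple-regression R
and R² for molar mass. The analysis upstream was evidently not fully
self-consistent — the published AGO₁ curve-estimation statistics are
reproduced by the *uncorrected* column — so no single input reproduces
every published number; the package applies the three corrections
uniformly and documents the residual disagreements rather than switching
tables per stage.

## Regression details

* OLS is solved on a **column-normalized design** (each column scaled to
  unit Euclidean norm, coefficients rescaled afterwards). This is exact in
  infinite precision and numerically necessary here: a cubic in raw powers
  of an index of magnitude 10⁵ spans ~15 orders of magnitude across
  columns.
* The exactly-collinear check uses a relative singular-value cutoff of
  1e-12 on the normalized design, so genuinely ill-conditioned polynomial
  designs still fit while true duplicates (a constant predictor next to
  the intercept) raise a rank error naming the offending column.
* The **exponential** form is fitted by OLS on ln Y; R, SEE, F and p are
  reported on the log-response scale (the published exponential SEE values
  of ≈ 0.12–0.33 are only compatible with log-scale residuals), and the
  reported intercept is exp of the fitted log-intercept so the model reads
  Y = a·exp(β₁X).
* The **logarithmic** form is Y = a + β₁ ln X with a free slope (the
  published model listing omits the slope; the published tables print two
  coefficients per logarithmic row, and the a/β₁ cells of one row are
  transposed).
* **R is reported as +√R²**, matching the published tables, which print
  non-negative R throughout.
* The **multiple** model uses the Moore–Penrose pseudo-inverse
  (minimum-norm least squares) with the design's condition number recorded
  on the fit and logged above 10⁸: with n = 13 observations and k = 8
  strongly collinear predictors, coefficient estimates are unstable even
  though R² is well defined. No multiple-testing correction is applied
  across the model grid, matching the original analysis.
* A constant response is flagged `degenerate` and reported with R = 0
  rather than NaN.
* Statistic identities hold by construction and are enforced to 1e-10 in
  tests: R = √R², adjR² = 1 − (1−R²)(n−1)/(n−k−1), SEE = √(RSS/(n−k−1)),
  F = (R²/k)/((1−R²)/(n−k−1)); p is the upper tail of F(k, n−k−1).
* p-values below 0.001 are rendered "<0.001" in reports; machine output
  keeps raw values.

## Model grid

The full study is 8 indices × 11 properties × 5 forms = 440 curvilinear
records plus 11 multiple-regression records. A form whose domain constraint
fails (the exponential form on the three properties with non-positive
values: hydropathy index, logP, pH) contributes a placeholder record with a
`status` explaining the skip, so the grid cardinality is invariant and
nothing fails silently. Best-model selection maximises R (or minimises SEE)
per (index, property) with ties broken toward fewer parameters. The
pipeline has no randomness; reruns are bit-identical.

By default the curvilinear grid runs the three properties the published
per-index tables report (molar mass, isoelectric point, side-chain volume);
`--all-properties` extends to all 11. The multiple stage always runs all 11.

## Synthetic data

`random_molecular_graph` grows a random heavy-atom **tree** (elements drawn
C-majority: C 0.70, O 0.15, N 0.10, S 0.05) under the valence caps, then
fills remaining valences with hydrogens; all 13 study molecules are acyclic,
so rings are deliberately not generated. `simulate_property` adds Gaussian
noise on the scale each form is fitted on (log scale for exponential). All
randomness derives from one master seed through
`numpy.random.SeedSequence.spawn`.

`recovery_experiment` draws predictors uniformly on [25, 300] — the
magnitude range of the first Gourava index across the study molecules —
rather than generating hundreds of random graphs per replicate; this keeps
the 100-replicate Monte Carlo (n up to 400) essentially instantaneous
while testing exactly the statistical property of interest (coefficient
bias/RMSE shrinking with sample size). Graph-level properties are tested
directly on the graph generator.

What the synthetic generator does **not** emulate: rings, realistic
chemical-space composition, correlated measurement error, or the actual
joint distribution of amino-acid properties. Passing recovery tests
therefore demonstrate correctness of the fitting machinery under the
models' own assumptions, not predictive validity on new chemistry.

## Known limitations

* The regression-input reconstruction cannot be made fully consistent with
  every published statistic (see above); residual disagreements are
  documented, not patched per-table.
* With n = 13 and k = 8 the multiple model is descriptive only; adjusted
  R² and F are close to degenerate and several published adjusted-R² cells
  are themselves implausible (one is printed as "878").
* Coefficient standard errors are not reported (the study's tables do not
  print them); tests that need one derive it from SEE and the predictor
  sum of squares.
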