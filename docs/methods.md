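# Methods

This note records the modelling and numerical choices behind
`mammotriage`, in the spirit of a statistical software methods appendix:
what each stage assumes, which knobs matter, what the synthetic generators
do and do not emulate, and where the design was genuinely open.

## Fuzzy inference engine

Each expert system is a Mamdani engine with the classical operator set:
min for AND and implication, max for OR and aggregation, centroid
defuzzification. Membership functions are restricted to triangular and
trapezoidal shapes; breakpoint ties are legal and evaluate as one-sided
ramps, so shoulders (`tri(0, 0, 40)`) and spikes are expressible without
special cases.

Numerical choices:

* **Defuzzification grid.** The centroid is Σxᵢμᵢ/Σμᵢ on a uniform grid
  over the output universe, 1001 points by default (validated ≥ 101).
  Doubling the grid moves the centroid of the shipped rule bases by less
  than 0.1 on a [0, 100] universe; the test suite also checks the grid
  centroid against a brute-force 10⁵-point envelope oracle to within 0.1.
* **No-coverage behaviour.** If no rule fires, the engine raises
  `NoRuleCoverage` rather than returning a default: a silent fallback
  would propagate an arbitrary value through the cascade and contaminate
  every downstream risk. Rule-base validation additionally requires every
  universe point to have nonzero membership in at least one term of each
  variable, which catches most coverage gaps at load time.
* **Serialization.** Rule bases are JSON documents (variables with
  universes and terms, rules as antecedent/connective/consequent triples,
  mandatory version field), validated on load. This file format — not the
  shipped files — is the intended extension point for a real clinical
  knowledge base.

## Cascade and encoding

The cascade is four levels deep: three concurrent finding-group systems,
then BI-RADS, then breast composition, then history. Risks appearing as
antecedents of the next level use trapezoidal terms and the same risks as
consequents use triangular terms, reflecting the different logical role of
a premise (qualitative assessment with a certainty interval) and a
conclusion (an assigned level). Information therefore flows strictly
downstream — perturbing history can change only R4; breast composition
only {R3, R4}; BI-RADS only {R2, R3, R4} — and this is property-tested.

Categorical descriptors are mapped to crisp ordinal values by an encoding
table shipped as a JSON artifact (data, not code, so clinical teams can
re-map categories). The ordering follows the suspicion conventions of the
BI-RADS lexicon (e.g. margins circumscribed → spiculated ascending;
BI-RADS 0–6 on a 0–8 scale with 4A/4B/4C at 4/5/6). "Unknown" history
values map to the scale midpoint rather than being rejected, because
real case series contain patients with no recorded history. The level-4
system takes age, personal history and family history as three separate
antecedent variables (the alternative — a pre-combined history score —
was rejected to keep the rule base readable and each input separately
auditable).

The shipped demo rule bases (5–7 rules per system) are **illustrative**:
they encode the ordinal suspicion structure above well enough for every
pipeline stage to be exercised and tested, but they are not clinical
knowledge. Consequently the risk values printed by the original system for
its case-study patient are documentation, not targets: they were produced
by an unpublished rule base and are not reproducible by construction.

## Normalization and balancing

Z-score normalization uses the sample (n−1) standard deviation; the
per-column μ, σ are captured in a `ColumnStats` object so that a new
patient's risks are mapped with exactly the fitting statistics. Constant
columns are a hard error (`DegenerateColumn`).

Safe-Level SMOTE is implemented from its case table. The safe level
sl(·) of an instance is the number of same-class points among its k
nearest neighbours over the whole table (k = 4 by default); interpolation
neighbours are drawn from the k nearest *same-class* neighbours. With
ratio = sl(p)/sl(n), the gap of p + gap·(n−p) is: skip p when both safe
levels are 0; gap = 0 (duplicate p) when only sl(n) = 0; U(0,1) at
ratio 1; U(0, 1/ratio) when p is safer; U(1−ratio, 1) when n is safer.
Because both classes of a screening cohort may be augmented, the class
being augmented is treated as the minority for its own safe-level
computation. Distances are Euclidean on the normalized risks; ties break
by row index; the RNG is a seeded `default_rng` — no global state. Each
synthetic row is a convex combination of two same-class members, hence
stays inside the class's bounding box (property-tested).

## Factor analysis

The assumption battery (Shapiro–Wilk + skewness for normality, VIF for
multicollinearity, Mahalanobis distances for outliers, Bartlett's
sphericity test, KMO, rows-per-variable ratio) *flags* rather than blocks:
common-factor analysis of risk indices tolerates moderate normality
violations, so failed normality is logged and the analysis proceeds. Only
a singular correlation matrix is fatal. Recorded thresholds: VIF > 10
flagged, KMO acceptable ≥ 0.5, outliers at the χ²₀.₉₉₉ quantile with
p = n-variables degrees of freedom, Shapiro–Wilk α = 0.05, sample-size
rule ≥ 10 rows per variable.

Extraction is iterated Principal Axis Factoring: squared multiple
correlations initialise the communalities; each iteration
eigendecomposes the reduced correlation matrix and keeps the top-m
components; the loop stops when the largest communality change is below
1e-4. The Kaiser rule counts eigenvalues > 1 of the **full** sample
correlation matrix (the deterministic reading; the reduced-matrix variant
changes across iterations). Two numerical details deserve note:

* **Heywood handling.** A communality reaching 0.999 is pinned at that
  ceiling for the remaining iterations (with a warning). A plain
  clip-and-continue can oscillate across the clip boundary in a
  two-cycle; pinning removes the cycle at the standard boundary solution.
* **Iteration budget.** Cascade-produced risk tables are strongly
  correlated downstream (R2–R4 share most of their information), which
  makes the PAF fixed point nearly degenerate and convergence geometric
  but slow — roughly a thousand iterations is routine. The cap is
  therefore 10 000; each iteration is one 6×6 eigendecomposition, so the
  worst case costs milliseconds.

Varimax uses Kaiser's classical pairwise algorithm with row
normalization: each factor pair is rotated by the closed-form angle
φ = ¼·atan2(D − 2AB/p, C − (A² − B²)/p), sweeping until no pair moves.
The closed form matters: gradient-projection rotation has zero gradient at
symmetric loadings configurations (e.g. [[0.7, 0.7], [0.7, −0.7]]) and
returns them unrotated, whereas the pairwise angle is exactly 45° there.

Anderson–Rubin weights are W = Ψ⁻¹Λ·M^(−1/2) with
M = ΛᵀΨ⁻¹RΨ⁻¹Λ, computed from the rotated loadings and the fitting
correlation matrix, so fitting-data scores have exactly zero mean and
identity covariance and a new patient is mapped with the stored weights
and column statistics.

**Identifiability caveat.** A 6-variable, 3-factor model has zero degrees
of freedom, and the synthetic generator's structure makes two factors only
weakly identified: the two-indicator factor determines only the *product*
of its loadings (through the one inter-indicator correlation), and the
near-single-indicator factor is pinned down only by a 0.35 cross-loading.
Different extraction routines legitimately land on different points of the
same solution ridge (ours tends to the boundary, pinning the
single-indicator variable's communality). The tests therefore assert the
identified quantities — the dominant-factor block pattern, the
three-indicator factor's loadings, the two-indicator loading product —
rather than elementwise recovery of the generating matrix.

## Classifiers and evaluation

The hazard index is 100 × the model's cancer-class posterior. Weighted
KNN (k = 10, Euclidean, 1/d² weights) is written directly because its
conventions matter: all neighbours tied with the k-th distance are
included, and zero-distance neighbours decide the vote alone (the 1/d²
weight is undefined there, and an exact match is the strongest possible
evidence). Bagged trees delegate bootstrap resampling and CART growing
(Gini, minimum leaf size 1) to scikit-learn, with the 218-split cap
expressed as a 219-leaf cap; the hazard is the hard-vote fraction of the
30 trees, hence a multiple of 100/30. A single-class training set yields a
constant 0/100 hazard with a warning rather than an error.

Cross-validation is stratified 5-fold with a mandatory seed; every row is
scored exactly once out of fold. The pooled AUC comes from the
Mann–Whitney rank statistic with midranks for ties, which the tests verify
against trapezoidal integration of the empirical ROC to 1e-9.

## Triage

Both limits belong to the uncertain band: healthy on [0, limit1),
uncertain on [limit1, limit2], cancer on (limit2, 100]. Defaults (60, 65)
are configuration; no automatic derivation of the limits from ROC curves
is implemented (deliberately out of scope — the reference procedure for
choosing them is unspecified).

## Synthetic generators

`generate_patients` draws labeled records from class-conditional
categorical frequency tables at 21/130 prevalence with truncated-normal
ages (mean 55.2, sd 14, support [18, 95]). The tables are synthetic
defaults chosen once, informed by the BI-RADS suspicion ordering — the
cancer class concentrates in categories 4B+, spiculated margins, fine
pleomorphic/linear-branching calcifications, primary distortion — so that
the cohort carries a class signal a triage system can learn, comparable to
the discrimination the original system reported on its clinical data. They
are **not** fitted to any real cohort: marginal frequencies, inter-finding
correlations within a patient, and reader variability are all simplified
(findings are drawn independently given the class). Passing tests
therefore demonstrate that the pipeline's machinery works and that its
stages compose; they do not demonstrate clinical accuracy on real
mammography data.

`generate_factor_risks` draws standardized risk rows x = Λf + ε from an
explicit three-factor model (F1 → {R2: 0.70, R3: 0.75, R4: 0.75},
F2 → {R1a: 0.80, R1b: 0.80}, F3 → {R1c: 0.85, R2: 0.35}); the implied
population correlation has eigenvalues ≈ {2.10, 1.64, 1.10, 0.44, 0.36,
0.36} — exactly three above 1, so the Kaiser rule is well-posed. The 0.35
cross-loading exists precisely because a pure single-indicator factor has
a population eigenvalue ≤ 1 and would be invisible to the Kaiser rule.
`generate_labeled_risks` maps these standardized rows onto the [0, 100]
risk scale (centre 50, scale 12) with a class shift of ±12 units, giving
the labeled 20/109 table used wherever a risk table is needed without
running the cascade.

## Problem sizes

The shipped tests and the acceptance script run at the reference-cohort
scale: 130-patient cohorts for end-to-end runs, 129-row (20 + 109) risk
tables augmented to 418 rows for the balancing arithmetic, n = 1000 draws
× 10 seeds for factor-count recovery, and 10⁵-point grids for the
defuzzification oracle. These sizes were chosen to match the study
conditions the pipeline emulates while keeping any single check below a
few seconds.

## Known limitations

* The demo rule bases are illustrative; all clinical validity rests on
  replacing them through the JSON rule-base format.
* Only Mamdani inference with triangular/trapezoidal terms is supported
  (no Sugeno/TSK, no nonlinear membership shapes, no rule learning).
* Only plain Safe-Level SMOTE is offered (no ADASYN/undersampling), and
  only PAF extraction with Varimax (no maximum likelihood, no oblique
  rotations, no confirmatory models).
* Hazard calibration: the vote/weight fraction is a posterior surrogate,
  not a calibrated probability; the triage limits must be tuned to the
  deployment population.
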