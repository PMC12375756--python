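# Methods

## Model

A molecule is its hydrogen-suppressed skeleton: a simple, connected,
undirected graph with no element or bond-order attributes. All quantities
depend on topology alone. For each vertex v the neighborhood degree sum is
S(v) = Σ_{u∈N(v)} deg(u) over the *open* neighborhood (v itself excluded).
An alternative reading of "neighborhood degree" — the cardinality of the
second neighborhood |N(N(u))| — circulates in the literature; this package
uses the degree sum S(v) throughout, because it is the standard basis of the
"neighborhood degree-sum" index family and the only reading consistent with
the worked-example partition values (weights up to 8 on a bounded-degree
chemical graph).

Edges uv are partitioned by the normalized pair
(min(S(u),S(v)), max(S(u),S(v))); the class sizes m(i, j) determine both the
NM-polynomial and every index. The two computation routes — operator
calculus on NM(G; x, y) and direct summation over classes — are implemented
independently and compared by exact rational equality in the test suite
(500 random partitions per run) and at every CLI invocation.

### Numerical choices

* Polynomial coefficients are `fractions.Fraction` end to end; floats appear
  only in reports (4-decimal rounding, matching the reference tables).
* Sx/Sy on a term with zero exponent is a divergent integral and raises
  rather than silently dropping the term.
* Operator compositions are read right-to-left; since all five primitives
  act termwise on exponent pairs, pure Dx/Dy products commute — asserted as
  a property test. The scalar 2 in the NH recipe (2·Sx∘J) multiplies the
  evaluated result.

## The packaged drug dataset

The only machine-usable structural data published for the 15 drugs are the
NM-polynomials, so the fixtures store their expanded edge partitions
(cross-derived symbolically during development); structure drawings are not
parsed and partitions are not re-derived from connectivity. Properties (BP,
EV, FP, MR, SA, P, ST, MV) are stored exactly as printed, units as printed
(unstated in the source). One cell worth noting: Tamoxifen's surface area is
12 — implausibly small, but confirmed by the published random-forest error
table for that property (232.88 % against a prediction near 40), so it is
kept as printed.

Auditing the reference index table against the partitions gives a sharp
result: for every derivable drug (G1..G14) the six definition-consistent
indices — M1, FN, ND3, ND5, NH, NI — match exactly at printed rounding.
Two published surfaces are *not* reproducible and are flagged rather than
chased:

* **Actinomycin D (G0).** Its published polynomial is character-for-character
  identical to Anastrozole's (G1), yet its reference index row (M1 = 1162, …)
  is far larger. No published structure generates that row. The record is
  flagged `polynomial_duplicate_of_G1` / `table3_row_non_derivable`, and its
  reference row is retained as printed.
* **M2 (and the worked example's M2^mm).** The published M2 values
  (e.g. 17100 for the worked example) are inconsistent with the defining
  product formula, which gives 766; likewise the worked example's printed
  M2^mm = 18.9039 against a computed 0.8593. The definitions are implemented
  exactly; the printed values are excluded from verification.

## QSPR regression stage

Each property is regressed on one index by OLS with intercept on the
monomial design (1, x, x², [x³]) via statsmodels. Reported statistics:
R² = 1 − RSS/TSS, R = +√R², residual standard error √(RSS/(n−p−1)), overall
F = (R²/p)/((1−R²)/(n−p−1)) with the p-value from F(p, n−p−1). A constant
response (TSS = 0) is defined as R² = 0, F = 0, p = 1. Rank deficiency is
detected by counting distinct x values (fewer than degree+1), not by a
floating-point rank of the Vandermonde matrix, which is ill-conditioned at
raw index scales (x³ ~ 10⁹) while still mathematically full-rank.

**Index source.** The regression default is the reference column as printed.
Recomputed and printed values coincide for every derivable drug, so the
choice only matters for G0 — and the published fits demonstrably include
G0's printed row (the published BP quadratic 343.2294 + 0.6512x + 0.0002x²
with R² = 0.829 and F = 29.069 is reproduced to every printed digit with
that row, and not at all without it). A `source="recomputed"` switch exposes
the fully-derivable alternative.

Nested-model monotonicity (cubic R² ≥ quadratic R² on identical data) holds
for all 64 property–index pairs here, as it must for nested OLS with
intercept. Several published cubic rows violate it (and print 0.0000
intercepts), implying some undocumented rescaled or through-origin protocol;
the standard fit is implemented and the discrepancy left as data.

The published SE column is likewise inconsistent with any standard residual
error (0.448 for boiling-point residuals spanning hundreds of degrees); the
standard definition is reported and the printed column is not a target.

## Random-forest stage

scikit-learn `RandomForestRegressor`, 500 trees by default, all eight
indices as features (six definition-consistent recomputed columns plus M2
and M2^mm per their defining formulas; the printed-source matrix is used for
the drug analysis). The published protocol (split, tree count, seed) is
unstated, so two evaluations are produced: in-sample and leave-one-out, the
latter as headline since the nonzero published errors imply some held-out
element. Exact reproduction of the published predicted values is not
attempted. Empirically the in-sample evaluation's error profile is close to
the published tables (e.g. a maximum surface-area error of ~226 % against
the published 232.88 %, both at the Tamoxifen SA = 12 cell), consistent with
bootstrap-resampled in-sample prediction; this observation is reported by
`analysis/03_forest.py` rather than asserted. Metrics (R², MAE, RMSE,
percent error) are implemented per their defining formulas and cross-checked
against scikit-learn in tests. With only 15 samples, bootstrap resampling
leaves roughly a third of rows out of each tree, so even a target equal to
one feature column tops out near R² ≈ 0.94 in-sample.

## Synthetic generator

The generator emulates the statistical setting the regression stage assumes,
not real chemistry (no valence-by-element or ring statistics). Graphs are
grown as a random spanning tree with degree-capped uniform attachment, plus
extra edges added with probability 0.15 per feasible pair; max degree
defaults to 4 to mimic organic heavy-atom skeletons and keep neighborhood
weights in the 1–16 range seen in the drug partitions. Properties follow
y = a + bx + cx² + ε, ε ~ N(0, σ²), defaults (a, b, c) = (2, 0.5, 0.001) and
σ = 0.01 so that curvature and noise are both visible at M1 scales of a few
hundred. A single seed fans out through `SeedSequence.spawn` into per-graph
substreams and an independent noise substream, so enlarging a dataset never
reshuffles earlier draws. Passing tests on this generator shows the pipeline
recovers known coefficient structure under Gaussian noise; it does not show
that real drug properties are quadratic in any index.

## Problem sizes and determinism

The dual-route equivalence battery uses 500 random partitions (weights
1–16, up to 9 classes); parameter recovery uses 50 graphs of 10–30 vertices;
the residual-calibration check uses 500 graphs of 6–12 vertices. Forest
tests use 40–500 trees with fixed seeds; identical configuration and seed
give bit-identical predictions, and all randomness flows from explicitly
passed seeds.

## Known limitations

* Partitions come from the published polynomials, not from structures; any
  transcription error upstream of those polynomials propagates here by
  construction (the G0 row is the known instance).
* n = 15 with in-sample statistics: the regression stage reports the
  published-style fit statistics, which say nothing about generalization;
  the leave-one-out forest numbers are the honest held-out view and are
  markedly worse than in-sample.
* Property units are unstated in the source and therefore unstated here.
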