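# nmqspr

Neighborhood degree-sum topological indices and QSPR modeling for molecular
graphs, built around a 15-drug bone-cancer dataset.

## The problem

In chemical graph theory a drug molecule is modeled as its hydrogen-suppressed
skeleton: heavy atoms are vertices, covalent bonds are edges. Numerical graph
invariants ("topological indices") computed from this skeleton correlate with
physicochemical properties, so they can be used as cheap structure descriptors
in quantitative structure–property relationship (QSPR) models.

This package implements the *neighborhood degree-sum* family of indices.
Each vertex v gets the weight S(v) = Σ_{u∈N(v)} deg(u) (sum of the degrees of
its neighbors, open neighborhood), and the edges are partitioned by the
unordered pair of endpoint weights, with m(i, j) counting the edges in class
{i, j}. Everything downstream is a function of this partition:

* the **NM-polynomial** NM(G; x, y) = Σ m(i, j) xⁱyʲ, from which every index
  is derived by composing the operators Dx = x∂/∂x, Dy, Sx = ∫₀ˣ f(t,y)/t dt,
  Sy, and J: f(x,y) ↦ f(x,x), then evaluating at x = y = 1;
* the **eight indices** as direct sums over edge classes:
  M1 = Σ m(i+j), M2 = Σ m·ij, FN = Σ m(i²+j²), M2^mm = Σ m/(ij),
  ND3 = Σ m·ij(i+j), ND5 = Σ m(i/j + j/i), NH = Σ 2m/(i+j),
  NI = Σ m·ij/(i+j).

Both routes are computed with exact rational arithmetic and cross-checked by
equality, not tolerance. On top of the indices sit two modeling stages:
quadratic/cubic OLS regression of each property on each index (with R, R²,
residual SE, F and p), and random-forest regression on the full index matrix
with R², MAE, RMSE and per-drug percent errors.

## Worked example

The packaged dataset carries the edge partitions of 15 bone-cancer drugs
(transcribed from their published NM-polynomials), their physicochemical
properties, and the published reference index table. The worked-example
partition — E(2,5)=2, E(5,7)=2, E(4,7)=4, E(7,8)=2, E(6,8)=4, E(6,6)=4,
E(5,6)=2, E(4,5)=2, E(4,4)=1, 23 edges — can be run through the CLI:

```
$ nmqspr indices worked.json --out results
{
 "M1": 264.0,
 "M2": 766.0,
 "FN": 1616.0,
 "M2mm": 0.8593,
 "ND3": 9456.0,
 "ND5": 49.85,
 "NH": 4.1949,
 "NI": 63.9522
}
```

M1 = 264 says the endpoint weight sums over all 23 edges total 264; NH and NI
are the harmonic- and inverse-sum-type variants of the same partition. Every
value is computed twice (operator calculus and direct formula) and the run
aborts if the routes ever disagree.

The same numbers fall out of the library:

```python
from nmqspr import all_indices
from nmqspr.drugset import load_drugs

drugs = load_drugs()
vec = all_indices(drugs[1].partition)   # Anastrozole
print(vec.as_dict(rounded=4))           # {'M1': 264.0, ..., 'NI': 63.9522}
```

## Analysis scripts

The published study is reproduced by four numbered drivers (each writes its
tables under `results/`):

| script | what it does |
|---|---|
| `analysis/01_indices.py` | recomputes all indices for the 15 drugs and audits them against the published reference table |
| `analysis/02_qspr.py` | 112 quadratic/cubic OLS fits (7 index columns × 8 properties × 2 degrees) |
| `analysis/03_forest.py` | 500-tree random-forest prediction of each property, in-sample and leave-one-out |
| `analysis/04_synthetic_validation.py` | parameter recovery on synthetic graphs with known ground truth |

The audit in `01_indices.py` confirms that the six definition-consistent
indices (M1, FN, ND3, ND5, NH, NI) recomputed from the published polynomials
match the published table exactly for all fourteen derivable drugs, and flags
the cells that match no published structure (see `docs/methods.md`).

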