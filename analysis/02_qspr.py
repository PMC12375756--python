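#!/usr/bin/env python
"""Fit quadratic and cubic QSPR models of every property on every index.

For each of the seven reference index columns (M1, M2, FN, ND3, ND5, NH, NI)
this fits the eight physicochemical properties by OLS at degrees 2 and 3 and
writes one model table per index under results/qspr/, mirroring the published
layout (Property / Model / Equation / R / R^2 / SE / F / p).

The index source is the reference table as printed: recomputed values agree
for every derivable drug, but only the printed column carries the
Actinomycin D row, without which the published statistics are not
reproducible.  Headline check printed on stdout: the BP and MR quadratics on
M1 (published R^2 = 0.829 and 0.961).
"""

from pathlib import Path

import pandas as pd

from nmqspr.drugset import index_matrix, load_drugs, property_table
from nmqspr.qspr import model_table, round_for_report

OUT = Path("results") / "qspr"
INDEX_COLUMNS = ["M1", "M2", "FN", "ND3", "ND5", "NH", "NI"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    drugs = load_drugs()
    props = property_table(drugs)
    feats = index_matrix(drugs, source="printed")

    tables = []
    for name in INDEX_COLUMNS:
        table = model_table(props, feats[name], name)
        round_for_report(table).to_csv(OUT / f"fits_{name}.csv", index=False)
        tables.append(table)
    full = pd.concat(tables, ignore_index=True)
    round_for_report(full).to_csv(OUT / "fits_all.csv", index=False)

    quad = full.query("model == 'Quadratic'")
    cubic = full.query("model == 'Cubic'")
    print(f"{len(full)} fits written to {OUT}")
    print(f"quadratic R^2 range: {quad.R2.min():.3f} .. {quad.R2.max():.3f}")
    print(f"cubic    R^2 range: {cubic.R2.min():.3f} .. {cubic.R2.max():.3f}")
    bp = full.query("index == 'M1' and property == 'BP' and model == 'Quadratic'").iloc[0]
    mr = full.query("index == 'M1' and property == 'MR' and model == 'Quadratic'").iloc[0]
    print(f"BP ~ M1 quadratic: {bp.equation}  R^2={bp.R2:.3f} F={bp.F:.3f}")
    print(f"MR ~ M1 quadratic: {mr.equation}  R^2={mr.R2:.3f} F={mr.F:.3f}")


if __name__ == "__main__":
    main()
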