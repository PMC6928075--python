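#!/usr/bin/env python
"""Diagnostic-test statistics recomputed from the packaged confusion-count
fixtures (the reported mono- and multi-locus re-assignment tallies).

Writes results/fixture_statistics.csv; prints concordance and per-species
sensitivity/specificity for every fixture.
"""

import argparse
from pathlib import Path

import pandas as pd

from mytilus_id.assignment import SPECIES_ORDER
from mytilus_id.diagnostics import (
    CONFUSION_FIXTURES,
    concordance,
    diagnostic_stats,
    load_confusion_fixture,
)

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

rows = []
for name in CONFUSION_FIXTURES:
    matrix = load_confusion_fixture(name)
    pct = concordance(matrix)
    print(f"{name}: overall concordance {pct:.1f}%")
    for sp in SPECIES_ORDER:
        if sp not in matrix.columns:
            continue
        st = diagnostic_stats(matrix, sp)
        rows.append(
            {
                "fixture": name,
                "species": sp,
                "concordance_pct": pct,
                "sensitivity": round(st.sensitivity, 3),
                "specificity": round(st.specificity, 3),
                "lr_plus": round(st.lr_plus, 2),
                "sens_ci": f"{st.sensitivity_ci[0]:.3f}-{st.sensitivity_ci[1]:.3f}",
                "spec_ci": f"{st.specificity_ci[0]:.3f}-{st.specificity_ci[1]:.3f}",
            }
        )
        print(
            f"  {sp:>18}: S={st.sensitivity:.2f} E={st.specificity:.2f} "
            f"LR+={st.lr_plus:.2f}"
        )
pd.DataFrame(rows).to_csv(args.outdir / "fixture_statistics.csv", index=False)
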