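#!/usr/bin/env python
"""Mono-locus identification on the synthetic survey: rule-based calls for the
diagnostic markers (ITS, COI) and Bayesian leave-one-out re-allocation for the
multiallelic ones (mac-1, 16S), each scored against the Me15-16 reference.

Writes per-marker confusion matrices, row-percentage heatmaps and diagnostic
statistics under results/monolocus/; prints the concordance summary.
"""

import argparse
from pathlib import Path

from mytilus_id.pipeline import run_full_analysis, write_report
from mytilus_id.simulate import default_config

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results/monolocus"))
args = parser.parse_args()

report = run_full_analysis(default_config(seed=args.seed), outdir=args.outdir)
print("mono-locus concordance with the Me15-16 reference:")
for marker, mr in report.mono.items():
    print(f"  {marker:>6}: {mr.concordance:5.1f}%  (unassigned: {mr.unassigned})")
print("the multiallelic markers (mac-1, 16S) fall well short of the diagnostic")
print("rule-based markers, chiefly by confusing edulis/chilensis (mac-1) and")
print("assigning galloprovincialis to edulis (16S)")
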