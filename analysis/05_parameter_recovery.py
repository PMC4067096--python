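#!/usr/bin/env python
"""Parameter recovery over replicated calibrated cohorts.

Repeats the whole pipeline (simulate -> scores -> cosinor -> adjusted
models) on independent cohorts of N = 5649 and compares the mean recovered
estimate of every injected effect with its calibrated value, with
Monte-Carlo standard errors.  This is the quantitative evidence that the
pipeline is unbiased at the study's sample sizes.
"""

import argparse
import warnings
from pathlib import Path

from pigmentscore.recovery import run_recovery

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--replicates", type=int, default=200)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_recovery(n_replicates=args.replicates, seed=args.seed)

args.out_dir.mkdir(parents=True, exist_ok=True)
summary = result.summary()
summary.to_csv(args.out_dir / "recovery_summary.tsv", sep="\t")
result.replicates.to_csv(args.out_dir / "recovery_replicates.tsv", sep="\t",
                         index=False)

print(f"{args.replicates} replicate cohorts:")
print(f"{'quantity':42s} {'mean':>9s} {'MC SE':>8s} {'injected':>9s}")
for quantity, row in summary.iterrows():
    injected = "" if row.isna()["injected"] else f"{row['injected']:9.3f}"
    print(f"{quantity:42s} {row['mean']:9.3f} {row['mc_se']:8.4f} {injected:>9s}")
print(f"wrote recovery_summary.tsv under {args.out_dir}/")
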