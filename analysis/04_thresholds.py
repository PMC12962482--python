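"""Threshold analyses: where does AI assistance stop being cost-effective?

Bisects the rebuilt model for the malignancy prevalence below which the
ICER exceeds willingness-to-pay ($100k and $50k per life year), and the
clinician accuracy (malignant nodules called high-risk) above which the
added value of AI no longer justifies its fee.
"""

import argparse
from pathlib import Path

import pandas as pd

from ipn_cea import default_parameters
from ipn_cea.sensitivity import threshold

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

params = default_parameters()
analyses = [
    ("malignancy_prevalence", 100_000.0, (0.01, 0.8),
     "AI cost-effective at $100k/LY when prevalence is above"),
    ("malignancy_prevalence", 50_000.0, (0.01, 0.8),
     "AI cost-effective at $50k/LY when prevalence is above"),
    ("strat_clinician_malignant_high", 100_000.0, (0.2, 0.9),
     "AI cost-effective at $100k/LY until clinician accuracy exceeds"),
]

rows = []
for name, wtp, bracket, story in analyses:
    result = threshold(params, name, wtp, bracket)
    rows.append({"parameter": name, "wtp": wtp, "threshold": result.value,
                 "crossed": result.crossed})
    print(f"{story} {result.value:.3f}")

pd.DataFrame(rows).to_csv(args.out / "thresholds.csv", index=False)
print(f"wrote {args.out / 'thresholds.csv'}")
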