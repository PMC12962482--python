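"""Simulate the multi-reader classification study and recover the
stratification matrix the decision model consumes.

Emulates 12 readers classifying 300 nodules (150 malignant / 150 benign)
into low/intermediate/high cancer-probability groups, with and without AI
assistance, then converts counts to per-truth class frequencies and checks
they recover the packaged operating characteristics.
"""

import argparse
from pathlib import Path

import pandas as pd

from ipn_cea import default_parameters
from ipn_cea.reader_study import (
    counts_to_dataframe,
    counts_to_probs,
    simulate_reader_study,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

params = default_parameters()
true_matrix = params.stratification_matrix()
counts = simulate_reader_study(true_matrix, seed=args.seed)
recovered = counts_to_probs(counts)

counts_to_dataframe(counts).to_csv(args.out / "reader_study_counts.csv",
                                   index=False)
rows = []
for (strategy, truth), row in sorted(recovered.items()):
    rows.append({
        "strategy": strategy, "truth": truth,
        "high": row[0], "intermediate": row[1], "low": row[2],
        "true_high": true_matrix[(strategy, truth)][0],
        "true_low": true_matrix[(strategy, truth)][2],
    })
frame = pd.DataFrame(rows)
frame.to_csv(args.out / "reader_study_recovered_matrix.csv", index=False)

print(f"simulated {counts.n_readers} readers x "
      f"{sum(counts.n_nodules.values())} nodules (seed {args.seed})")
print(frame.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
worst = max(
    abs(recovered[k][i] - true_matrix[k][i])
    for k in true_matrix for i in range(3)
)
print(f"largest |recovered - true| frequency error: {worst:.4f} "
      f"(binomial noise at 1,800 reads per stratum)")
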