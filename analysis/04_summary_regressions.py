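"""Condense the run table into the headline regression summaries.

Reproduces, at scaled replication counts, the study-level summaries: how
often simulated authors committed and succeeded at publication bias, how
selection deflated the meta-analytic p-value, and the conditional
false-positive-rate and power models of the seven bias tests.
"""

import argparse
from pathlib import Path

import pandas as pd

from pubbias.experiment import summary_regressions

parser = argparse.ArgumentParser()
parser.add_argument("--runs", type=Path, default=Path("results/runs.csv"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

records = pd.read_csv(args.runs)
regs = summary_regressions(records)
args.out.mkdir(parents=True, exist_ok=True)
regs.to_csv(args.out / "regressions.csv", index=False)
print(f"wrote {args.out / 'regressions.csv'}")


def coef(table, term):
    row = regs[(regs.table == table) & (regs.term == term)]
    return float(row.coef.iloc[0])


bias = records[records.intent > 0]
print("\nPrevalence of publication bias (over all bias cells):")
print(f"  mean committed share:  {100 * bias.committed_share.mean():.1f}%")
print(f"  mean successful share: {100 * bias.successful_share.mean():.1f}%")
print(f"  success-given-committed regression constant "
      f"(N=100, beta=0, file-drawer): {100 * coef('success_given_committed', 'const'):.1f}%")
print(f"  p-value deflation: constant {coef('deflation', 'const'):.3f}, "
      f"p-hacking {coef('deflation', 'p_hacking'):+.3f}")

print("\nConditional power constants (K=100, I2=0, file-drawer, mean prevalence):")
for test in ("PU", "FAT", "TES", "CT3", "CT5", "CT10", "CT15"):
    try:
        print(f"  {test:>5}: {100 * coef(f'power_{test}', 'const'):5.1f}%   "
              f"(K=1000: {coef(f'power_{test}', 'k1000'):+.3f}, "
              f"I2/10pp: {coef(f'power_{test}', 'i2_10pp'):+.4f})")
    except IndexError:
        print(f"  {test:>5}: not estimable")

print("\nConditional false-positive-rate constants (K=100, I2=0):")
for test in ("PU", "FAT", "TES", "CT3", "CT5", "CT10", "CT15"):
    try:
        print(f"  {test:>5}: {coef(f'fpr_{test}', 'const'):.3f}   "
              f"(K=1000: {coef(f'fpr_{test}', 'k1000'):+.3f})")
    except IndexError:
        print(f"  {test:>5}: not estimable")
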