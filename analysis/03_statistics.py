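"""Factorial summaries and three-way ANOVA of the experiment table.

Reads results/experiment.csv, writes the per-cell RMS summary
(results/summary.csv), the sex x side x group ANOVA with eta-squared
effect sizes (results/anova.csv) and the per-pair scatter data
(results/scatter.csv), then prints the key findings.
"""

import argparse
from pathlib import Path

import pandas as pd

import sinusid as sd
from sinusid.experiment import BONFERRONI_ALPHA

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--results", type=Path, default=Path("results/experiment.csv"))
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

table = pd.read_csv(args.results)
args.out_dir.mkdir(parents=True, exist_ok=True)

summary = sd.summarize(table)
summary.to_csv(args.out_dir / "summary.csv", index=False)

anova = sd.three_way_anova(table)
out = anova.table.copy()
out.index.name = "term"
out.to_csv(args.out_dir / "anova.csv")

table.reset_index()[["index", "group", "rms"]].to_csv(
    args.out_dir / "scatter.csv", index=False)

print(summary.round(3).to_string(index=False))
print()
print(out[["F", "p", "eta_squared"]].round(4).to_string())
group_p = anova.table.loc["group", "p"]
print(f"\ngroup effect: p = {group_p:.3g} "
      f"({'significant' if group_p < BONFERRONI_ALPHA else 'not significant'} "
      f"at Bonferroni-corrected alpha {BONFERRONI_ALPHA:.3f}); "
      f"eta^2 = {anova.eta_squared('group'):.3f}")
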