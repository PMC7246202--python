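"""Detect a CO2 "tipping point" from verdicts across ordered categories.

The knee fixture encodes a benefit-then-harm surface: chlorophyll a
benefits mildly below 1,000 μatm and is harmed above.  The threshold is
the lower bound of the first category whose pooled effect is
significantly negative and stays negative at every higher level.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from oameta import AnalysisConfig, make_fixture_suite, run_analyze

with tempfile.TemporaryDirectory() as tmp:
    paths = make_fixture_suite(Path(tmp) / "fixtures")
    truth = json.loads(paths["knee_truth"].read_text())
    artifacts = run_analyze(paths["knee"], Path(tmp) / "out", AnalysisConfig())
    grid = pd.read_csv(artifacts["classification_level3"])
    thresholds = pd.read_csv(artifacts["thresholds_level3"])

order = ["c500_800", "c801_1000", "c1001_1500", "c1501_2000", "gt2000"]
grid["category"] = pd.Categorical(grid["category"], order, ordered=True)
grid = grid.sort_values("category")

print("verdicts across CO2 categories:")
for _, row in grid.iterrows():
    print(f"  {row['category']:>11}: {row['verdict']:>9}  "
          f"(pooled {row['pooled']:+.3f}, k={row['k']})")

row = thresholds.iloc[0]
print(f"\ndetected threshold : {row['threshold_uatm']:.0f} μatm "
      f"(displayed as the '{row['display']}' category)")
print(f"generating truth   : {truth['threshold_uatm']:.0f} μatm "
      f"({truth['knee_category']})")
# The detector names the 1,001-1,500 μatm band: harm begins above
# 1,000 μatm, matching the surface the fixture was generated from.
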