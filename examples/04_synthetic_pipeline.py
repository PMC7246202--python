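"""Run the full pipeline end-to-end on synthetic studies with known truth.

The generator draws per-study true effects around a configured surface
(here: chlorophyll a harmed by -0.4 above 1,000 μatm), emits a study
table in the exact ingest schema - including some records as boxplot
summaries and some reporting pH instead of pCO2 - and the pipeline
recovers the pooled effect.
"""

import tempfile
from pathlib import Path

import pandas as pd

from oameta import AnalysisConfig, SyntheticConfig, generate, run_analyze, write_study_table

config = SyntheticConfig(
    true_effects={
        "phytoplankton|chlorophyll_a|c801_1000": 0.15,
        "phytoplankton|chlorophyll_a|c1001_1500": -0.4,
    },
    tau2=0.02,
    n_studies_per_cell=40,
    seed=12,
)
records, truth = generate(config)
print(f"generated {len(records)} study records "
      f"({truth['truncation_events']} noise-floor truncations)")

with tempfile.TemporaryDirectory() as tmp:
    table = Path(tmp) / "studies.csv"
    write_study_table(records, table)
    artifacts = run_analyze(
        table, Path(tmp) / "out",
        AnalysisConfig(variance_mode="hedges", se_mode="corrected"),
    )
    grid = pd.read_csv(artifacts["classification_level3"])

for _, row in grid.iterrows():
    print(f"{row['category']:>11}: pooled {row['pooled']:+.3f} "
          f"[{row['ci_low']:+.3f}, {row['ci_high']:+.3f}]  "
          f"tau2={row['tau2']:.4f}  k={row['k']}  -> {row['verdict']}")
# Both cells recover their true effect (+0.15 / -0.40) within the CI,
# and tau2 lands near the generating 0.02.
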