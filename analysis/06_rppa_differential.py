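"""Protein differential expression: univariate logistic regressions.

Relates each antibody's expression to tissue status with a binomial-link
logistic model, reports odds ratios with Wald 95% intervals and
Benjamini-Hochberg q-values, and counts the proteins dysregulated at
q < 0.05.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import COHORT_DIR, OUT_DIR, require

from desilipid.msi_io import read_metadata
from desilipid.pipeline import RunConfig, stage_rppa

require(os.path.join(COHORT_DIR, "protein_table.tsv"), "01_simulate_cohort.py")
run = RunConfig(out_dir=OUT_DIR, metadata_path=os.path.join(COHORT_DIR, "metadata.tsv"))
prot = pd.read_csv(os.path.join(COHORT_DIR, "protein_table.tsv"), sep="\t", index_col=0)
meta = read_metadata(run.metadata_path)
res = stage_rppa(run, prot, meta)
sig = res[res["significant"]]
up = (sig["direction"] == "Increased").sum()
print(f"{len(sig)} of {len(res)} proteins differential at q<0.05 "
      f"({up} increased, {len(sig) - up} decreased in cancer)")
print(sig.sort_values("q_value").head(5)[
    ["protein", "odds_ratio", "ci_low", "ci_high", "q_value", "direction"]
].to_string(index=False))
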