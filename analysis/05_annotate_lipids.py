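"""Accurate-mass lipid annotation of the consensus features.

Matches every consensus m/z against the bundled [M-H]- glycerophospholipid
reference (10 ppm, up to one 13C) and joins the univariate statistics into
a report table of candidate identities with ppm errors.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import OUT_DIR, require

from desilipid.pipeline import RunConfig, load_peak_matrix, stage_annotate

require(os.path.join(OUT_DIR, "feature_stats.tsv"), "04_feature_statistics.py")
run = RunConfig(out_dir=OUT_DIR)
matrix = load_peak_matrix(OUT_DIR)
stats = pd.read_csv(os.path.join(OUT_DIR, "feature_stats.tsv"), sep="\t")
report = stage_annotate(run, matrix, stats)
named = report[report["name"] != ""]
print(f"{len(named)} of {len(report)} features annotated; top hits:")
for row in named.itertuples():
    iso = " (13C)" if row.isotope_offset else ""
    print(f"  m/z {row.mz:9.4f} -> {row.name}{iso}  {row.ppm_error:+.4f} ppm")
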