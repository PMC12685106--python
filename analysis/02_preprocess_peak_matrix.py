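"""ROI averaging, 8-ppm peak matching across patients, and PQN.

Reads the cohort imzML files and ROI masks, averages each patient's
tissue pixels into one spectrum, matches peaks across patients within
m/z 600-1000 at a maximum shift of 8 ppm, and normalizes by probabilistic
quotient.  Writes the patient x feature matrix under results/analysis.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import COHORT_DIR, OUT_DIR, ensure_out, require

from desilipid.pipeline import RunConfig, stage_preprocess

require(os.path.join(COHORT_DIR, "imzml"), "01_simulate_cohort.py")
ensure_out()
run = RunConfig(
    out_dir=OUT_DIR,
    imzml_dir=os.path.join(COHORT_DIR, "imzml"),
    masks_dir=os.path.join(COHORT_DIR, "masks"),
    metadata_path=os.path.join(COHORT_DIR, "metadata.tsv"),
)
matrix = stage_preprocess(run)
print(f"peak matrix: {len(matrix.sample_ids)} patients x "
      f"{matrix.consensus_mz.size} consensus features "
      f"({matrix.consensus_mz.min():.2f}-{matrix.consensus_mz.max():.2f} m/z)")
print(f"PQN factors span {matrix.pqn_factors.min():.3f}-{matrix.pqn_factors.max():.3f}")
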