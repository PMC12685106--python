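"""RMMC-LDA classification with leave-one-patient-out cross-validation.

Fits the maximum-margin-criterion discriminant on the normalized peak
matrix, holding out each patient in turn, and reports the confusion
matrix, sensitivity and specificity for cancer vs. benign.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import COHORT_DIR, OUT_DIR, require

from desilipid.msi_io import read_metadata
from desilipid.pipeline import RunConfig, load_peak_matrix, stage_classify

require(os.path.join(OUT_DIR, "peak_matrix.tsv"), "02_preprocess_peak_matrix.py")
run = RunConfig(out_dir=OUT_DIR, metadata_path=os.path.join(COHORT_DIR, "metadata.tsv"))
matrix = load_peak_matrix(OUT_DIR)
meta = read_metadata(run.metadata_path)
out = stage_classify(run, matrix, meta)
cm = out["confusion"]
print(f"confusion: TP={cm['tp']} FN={cm['fn']} TN={cm['tn']} FP={cm['fp']}")
print(f"sensitivity {100 * out['sensitivity']:.0f}%  "
      f"specificity {100 * out['specificity']:.0f}%  "
      f"accuracy {100 * out['accuracy']:.0f}%")
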