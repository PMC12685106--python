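"""High- vs. low-risk phenotype comparisons within each diagnosis group.

Regenerates a cohort with the within-cancer phenotype modulation enabled
(the preset plants the published high/low-risk intensity ratios on the
shared discriminatory peaks) and compares high-risk (obesity and/or
diabetes) against low-risk patients separately in the benign and cancer
cohorts with the same univariate machinery as the main contrast.
"""

import os
import sys

import numpy as np

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import OUT_DIR, SEED, ensure_out

from desilipid import SyntheticConfig, generate_cohort
from desilipid.feature_stats import feature_table, select_discriminatory
from desilipid.pipeline import build_patient_matrix
from desilipid.preprocess import PeakMatrix
from desilipid.synthetic_cohort import CANCER_PHENOTYPE_PRESET

PHENO_MZ = {mz for mz, _f, _c in CANCER_PHENOTYPE_PRESET}

ensure_out()
cfg = SyntheticConfig(phenotype_features=CANCER_PHENOTYPE_PRESET, seed=SEED)
imgs, masks, metas = generate_cohort(cfg)
matrix = build_patient_matrix(imgs, masks)
diagnosis = np.array([m.diagnosis for m in metas])
phenotype = np.array([m.phenotype for m in metas])

for cohort in ("benign", "cancer"):
    keep = diagnosis == cohort
    sub = PeakMatrix(
        sample_ids=[s for s, k in zip(matrix.sample_ids, keep) if k],
        consensus_mz=matrix.consensus_mz,
        intensities=matrix.intensities[keep],
        normalization_state=matrix.normalization_state,
    )
    stats = feature_table(sub, phenotype[keep], "high_risk", "low_risk")
    sel = select_discriminatory(stats, q_threshold=0.05)
    planted = sel[sel["mz"].map(
        lambda mz: any(abs(mz - p) / p * 1e6 <= 8.0 for p in PHENO_MZ)
    )]
    n_hi = int((phenotype[keep] == "high_risk").sum())
    print(f"{cohort}: {n_hi} high-risk vs {int(keep.sum()) - n_hi} low-risk; "
          f"{len(sel)} features at q<0.05, {len(planted)} at phenotype peaks")
    for row in planted.itertuples():
        print(f"  m/z {row.mz:9.4f}  q={row.q_value:.3f}  "
              f"high/low FC={row.fold_change:.2f}")
    stats.to_csv(os.path.join(OUT_DIR, f"phenotype_{cohort}.tsv"),
                 sep="\t", index=False)
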