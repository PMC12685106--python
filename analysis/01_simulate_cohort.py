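"""Generate the synthetic study cohort and write it to disk.

Emulates the study design: 50 endometrioid cancer and 14 benign patients,
one DESI-MSI image each (20x20 pixels, circular tissue ROI), seven
discriminatory peaks elevated in cancer at the published fold changes
(1.23-1.28), four benign-cohort phenotype peaks, 200 background peaks,
2-ppm mass jitter and per-pixel TIC scaling 0.5-2.0 — plus a 282-protein
expression table with 104 differential proteins.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import COHORT_DIR, SEED

from desilipid.pipeline import RunConfig, stage_simulate, synthetic_config
from desilipid.synthetic_cohort import generate_cohort, generate_protein_table

run = RunConfig(out_dir=COHORT_DIR, seed=SEED)
info = stage_simulate(run)
cfg = synthetic_config(run)
_imgs, _masks, metas = generate_cohort(cfg)
prot = generate_protein_table(cfg, metas)
prot.to_csv(os.path.join(COHORT_DIR, "protein_table.tsv"), sep="\t")

n_cancer = sum(m.diagnosis == "cancer" for m in metas)
print(f"wrote {info['n_patients']} patients ({n_cancer} cancer, "
      f"{len(metas) - n_cancer} benign) to {COHORT_DIR}")
print(f"protein table: {prot.shape[0]} patients x {prot.shape[1]} antibodies")
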