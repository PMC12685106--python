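"""Lipid-protein integration by cosine distance and clustering.

Takes the discriminatory lipids and the top differential proteins,
normalizes each modality (lipids by patient total, proteins by antibody
maximum), computes the full pairwise cosine-distance matrix across both
modalities, and clusters it into a dendrogram.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import COHORT_DIR, OUT_DIR, require

from desilipid.feature_stats import select_discriminatory
from desilipid.pipeline import RunConfig, load_peak_matrix, stage_integrate

require(os.path.join(OUT_DIR, "feature_stats.tsv"), "04_feature_statistics.py")
require(os.path.join(OUT_DIR, "protein_stats.tsv"), "06_rppa_differential.py")
run = RunConfig(out_dir=OUT_DIR)
matrix = load_peak_matrix(OUT_DIR)
stats = pd.read_csv(os.path.join(OUT_DIR, "feature_stats.tsv"), sep="\t")
prot_stats = pd.read_csv(os.path.join(OUT_DIR, "protein_stats.tsv"), sep="\t")
prot = pd.read_csv(os.path.join(COHORT_DIR, "protein_table.tsv"), sep="\t", index_col=0)

lipids = [f"{mz:.4f}" for mz in select_discriminatory(stats)["mz"].head(7)]
proteins = prot_stats.loc[prot_stats["significant"], "protein"].head(23).tolist()
res = stage_integrate(run, matrix, prot, lipids, proteins)
print(f"similarity matrix over {len(res.species_names)} species "
      f"({res.modality.count('lipid')} lipids + {res.modality.count('protein')} proteins)")
print(f"wrote {os.path.join(OUT_DIR, 'similarity_matrix.tsv')} and dendrogram.nwk")
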