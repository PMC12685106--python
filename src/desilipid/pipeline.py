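"""End-to-end orchestration: simulate -> preprocess -> classify -> stats ->
annotate -> rppa -> integrate, with per-stage artifacts and a run manifest.

Each stage communicates with the next only through written artifacts (TSV /
JSON / imzML), so a run is resumable per stage.  The same stage functions
back both the command-line interface and the numbered analysis drivers.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import classify as cls
from . import feature_stats as fs
from . import integration as integ
from . import lipid_annotation as ann
from . import msi_io
from . import preprocess as pp
from . import rppa_stats as rppa
from . import synthetic_cohort as synth
from .errors import DesilipidError, ValidationError


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    imzml_dir: str | None = None     # None => simulate first
    masks_dir: str | None = None
    metadata_path: str | None = None
    protein_table_path: str | None = None
    lipid_table_path: str | None = None
    mz_min: float = 600.0
    mz_max: float = 1000.0
    max_shift_ppm: float = 8.0
    pqn_quotient: str = "median"
    k: int = 1
    standardize: bool = True
    positive_class: str = "cancer"
    q_threshold: float = 0.05
    tol_ppm: float = 10.0
    max_isotope: int = 1
    linkage: str = "average"
    seed: int = 0
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides

    @classmethod
    def from_file(cls_, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls_.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"unknown config keys: {sorted(bad)}")
        return cls_(**raw)


def synthetic_config(run: RunConfig) -> synth.SyntheticConfig:
    return synth.SyntheticConfig(**{"seed": run.seed, **run.synthetic})


# ---------------------------------------------------------------- stages


def stage_simulate(run: RunConfig) -> dict:
    """Generate a synthetic cohort and write imzML, masks, metadata, proteins."""
    cfg = synthetic_config(run)
    images, masks, metas = synth.generate_cohort(cfg)
    imz_dir = os.path.join(run.out_dir, "imzml")
    msk_dir = os.path.join(run.out_dir, "masks")
    os.makedirs(imz_dir, exist_ok=True)
    os.makedirs(msk_dir, exist_ok=True)
    for img, mask in zip(images, masks):
        msi_io.write_imzml(img, os.path.join(imz_dir, f"{img.patient_id}.imzML"))
        msi_io.write_mask(mask, os.path.join(msk_dir, f"{img.patient_id}.tsv"))
    meta_path = os.path.join(run.out_dir, "metadata.tsv")
    msi_io.write_metadata(metas, meta_path)
    run.imzml_dir, run.masks_dir, run.metadata_path = imz_dir, msk_dir, meta_path
    return {"n_patients": len(images), "imzml_dir": imz_dir}


def build_patient_matrix(
    images: list[msi_io.MSImage],
    masks: list[msi_io.ROIMask],
    mz_window: tuple[float, float] = (600.0, 1000.0),
    max_shift_ppm: float = 8.0,
    pqn_quotient: str = "median",
) -> pp.PeakMatrix:
    """One PQN-normalized averaged profile per patient (in-memory path)."""
    spectra, ids = [], []
    for img, mask in zip(images, masks):
        labels = set(mask.labels.values()) - {"background"}
        if not labels:
            raise ValidationError(f"patient {img.patient_id!r}: no tissue pixels")
        label = sorted(labels)[0]
        spectra.append(
            pp.average_roi(img, mask, label, max_shift_ppm=max_shift_ppm,
                           mz_window=mz_window)
        )
        ids.append(img.patient_id)
    raw = pp.match_peaks(spectra, max_shift_ppm=max_shift_ppm,
                         mz_window=mz_window, sample_ids=ids)
    return pp.pqn_normalize(raw, quotient=pqn_quotient)


def stage_preprocess(run: RunConfig) -> pp.PeakMatrix:
    """Read imzML + masks from disk, average ROIs, match across patients, PQN."""
    if not run.imzml_dir or not run.masks_dir:
        raise ValidationError("preprocess: imzml_dir and masks_dir are required")
    spectra, ids = [], []
    for fn in sorted(os.listdir(run.imzml_dir)):
        if not fn.endswith(".imzML"):
            continue
        pid = fn[: -len(".imzML")]
        img = msi_io.read_imzml(os.path.join(run.imzml_dir, fn), patient_id=pid)
        mask = msi_io.read_mask(os.path.join(run.masks_dir, f"{pid}.tsv"))
        mask.validate_against(img)
        labels = set(mask.labels.values()) - {"background"}
        label = sorted(labels)[0]
        spectra.append(
            pp.average_roi(img, mask, label, max_shift_ppm=run.max_shift_ppm,
                           mz_window=(run.mz_min, run.mz_max))
        )
        ids.append(pid)
    raw = pp.match_peaks(spectra, max_shift_ppm=run.max_shift_ppm,
                         mz_window=(run.mz_min, run.mz_max), sample_ids=ids)
    matrix = pp.pqn_normalize(raw, quotient=run.pqn_quotient)
    save_peak_matrix(matrix, run.out_dir)
    return matrix


def save_peak_matrix(matrix: pp.PeakMatrix, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    df = pd.DataFrame(
        matrix.intensities,
        index=matrix.sample_ids,
        columns=[f"{mz:.4f}" for mz in matrix.consensus_mz],
    )
    df.index.name = "sample_id"
    df.to_csv(os.path.join(out_dir, "peak_matrix.tsv"), sep="\t")
    sidecar = {
        "normalization_state": matrix.normalization_state,
        "pqn_factors": None
        if matrix.pqn_factors is None
        else dict(zip(matrix.sample_ids, matrix.pqn_factors.tolist())),
        "n_features": int(matrix.consensus_mz.size),
    }
    with open(os.path.join(out_dir, "peak_matrix.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_peak_matrix(out_dir: str) -> pp.PeakMatrix:
    df = pd.read_csv(os.path.join(out_dir, "peak_matrix.tsv"), sep="\t",
                     index_col="sample_id")
    with open(os.path.join(out_dir, "peak_matrix.json")) as fh:
        sidecar = json.load(fh)
    factors = sidecar.get("pqn_factors")
    return pp.PeakMatrix(
        sample_ids=[str(i) for i in df.index],
        consensus_mz=np.array([float(c) for c in df.columns]),
        intensities=df.to_numpy(dtype=np.float64),
        normalization_state=sidecar["normalization_state"],
        pqn_factors=None if factors is None
        else np.array([factors[str(i)] for i in df.index]),
    )


def diagnosis_labels(matrix: pp.PeakMatrix, meta_df: pd.DataFrame) -> np.ndarray:
    lookup = dict(zip(meta_df["patient_id"], meta_df["diagnosis"]))
    missing = [s for s in matrix.sample_ids if s not in lookup]
    if missing:
        raise ValidationError(f"metadata missing for samples: {missing[:5]}")
    return np.array([lookup[s] for s in matrix.sample_ids])


def stage_classify(run: RunConfig, matrix: pp.PeakMatrix, meta_df: pd.DataFrame) -> dict:
    labels = diagnosis_labels(matrix, meta_df)
    cm, preds = cls.lopo_cv(
        matrix.intensities, labels, matrix.sample_ids, k=run.k,
        standardize=run.standardize, positive_label=run.positive_class,
    )
    m = cls.metrics(cm)
    out = {"confusion": {"tp": cm.tp, "fn": cm.fn, "tn": cm.tn, "fp": cm.fp}, **m}
    os.makedirs(run.out_dir, exist_ok=True)
    with open(os.path.join(run.out_dir, "classification.json"), "w") as fh:
        json.dump(out, fh, indent=2)
    pd.DataFrame(preds).to_csv(
        os.path.join(run.out_dir, "patient_scores.tsv"), sep="\t", index=False
    )
    return out


def stage_stats(run: RunConfig, matrix: pp.PeakMatrix, meta_df: pd.DataFrame) -> pd.DataFrame:
    labels = diagnosis_labels(matrix, meta_df)
    df = fs.feature_table(matrix, labels, group_a="cancer", group_b="benign")
    os.makedirs(run.out_dir, exist_ok=True)
    df.to_csv(os.path.join(run.out_dir, "feature_stats.tsv"), sep="\t", index=False)
    return df


def stage_annotate(run: RunConfig, matrix: pp.PeakMatrix,
                   stats_df: pd.DataFrame | None = None) -> pd.DataFrame:
    table = ann.load_reference_table(run.lipid_table_path)
    report = ann.annotate_matrix(matrix, table, tol_ppm=run.tol_ppm,
                                 max_isotope=run.max_isotope, stats_df=stats_df)
    os.makedirs(run.out_dir, exist_ok=True)
    report.to_csv(os.path.join(run.out_dir, "annotations.tsv"), sep="\t", index=False)
    return report


def stage_rppa(run: RunConfig, protein_df: pd.DataFrame, meta_df: pd.DataFrame) -> pd.DataFrame:
    lookup = dict(zip(meta_df["patient_id"], meta_df["diagnosis"]))
    labels = [lookup[p] for p in protein_df.index]
    res = rppa.rppa_pipeline(protein_df, labels, q_threshold=run.q_threshold)
    os.makedirs(run.out_dir, exist_ok=True)
    res.to_csv(os.path.join(run.out_dir, "protein_stats.tsv"), sep="\t", index=False)
    return res


def stage_integrate(
    run: RunConfig,
    matrix: pp.PeakMatrix,
    protein_df: pd.DataFrame,
    lipids: list | None = None,
    proteins: list | None = None,
) -> integ.CrossCorrResult:
    lipid_df = pd.DataFrame(
        matrix.intensities,
        index=matrix.sample_ids,
        columns=[f"{mz:.4f}" for mz in matrix.consensus_mz],
    )
    res = integ.cosine_distance_matrix(lipid_df, protein_df,
                                       lipids=lipids, proteins=proteins)
    _Z, order, newick = integ.hierarchical_cluster(
        res.distance_matrix, res.species_names, linkage=run.linkage
    )
    os.makedirs(run.out_dir, exist_ok=True)
    pd.DataFrame(res.similarity_matrix, index=res.species_names,
                 columns=res.species_names).to_csv(
        os.path.join(run.out_dir, "similarity_matrix.tsv"), sep="\t"
    )
    with open(os.path.join(run.out_dir, "dendrogram.nwk"), "w") as fh:
        fh.write(newick + "\n")
    return res


def run_pipeline(run: RunConfig) -> dict:
    """Execute all stages; write artifacts and a manifest under out_dir.

    Stage failures leave earlier artifacts in place and re-raise with the
    failing stage named.
    """
    os.makedirs(run.out_dir, exist_ok=True)
    manifest: dict = {"config": asdict(run), "stages": {}}
    report: dict = {}

    def timed(name, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kw)
        except DesilipidError as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_manifest(run, manifest)
            raise DesilipidError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "status": "ok",
            "seconds": round(time.perf_counter() - t0, 3),
        }
        return out

    metas = None
    if run.imzml_dir is None:
        timed("simulate", stage_simulate, run)
        cfg = synthetic_config(run)
        _, _, metas = synth.generate_cohort(cfg)
    matrix = timed("preprocess", stage_preprocess, run)
    meta_df = msi_io.read_metadata(run.metadata_path)
    report["classification"] = timed("classify", stage_classify, run, matrix, meta_df)
    stats_df = timed("stats", stage_stats, run, matrix, meta_df)
    report["n_discriminatory"] = int(
        len(fs.select_discriminatory(stats_df, run.q_threshold))
    )
    annotations = timed("annotate", stage_annotate, run, matrix, stats_df)
    report["n_annotated"] = int((annotations["name"] != "").sum())

    if run.protein_table_path:
        protein_df = pd.read_csv(run.protein_table_path, sep="\t", index_col=0)
    elif metas is None:
        raise ValidationError(
            "protein_table_path is required when running on pre-existing imzML data"
        )
    else:
        cfg = synthetic_config(run)
        lipid_df = pd.DataFrame(
            matrix.intensities, index=matrix.sample_ids,
            columns=[f"{mz:.4f}" for mz in matrix.consensus_mz],
        )
        protein_df = synth.generate_protein_table(cfg, metas, lipid_profiles=lipid_df)
        protein_df.to_csv(os.path.join(run.out_dir, "protein_table.tsv"), sep="\t")
    prot_stats = timed("rppa", stage_rppa, run, protein_df, meta_df)
    report["n_proteins_significant"] = int(prot_stats["significant"].sum())

    sel = fs.select_discriminatory(stats_df, run.q_threshold)
    lipid_names = [f"{mz:.4f}" for mz in sel["mz"].head(7)]
    prot_names = prot_stats.loc[prot_stats["significant"], "protein"].head(23).tolist()
    if lipid_names and prot_names:
        timed("integrate", stage_integrate, run, matrix, protein_df,
              lipid_names, prot_names)

    manifest["report"] = report
    _write_manifest(run, manifest)
    return report


def _write_manifest(run: RunConfig, manifest: dict) -> None:
    import desilipid

    manifest.setdefault("versions", {"desilipid": desilipid.__version__,
                                     "numpy": np.__version__,
                                     "pandas": pd.__version__})
    with open(os.path.join(run.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
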