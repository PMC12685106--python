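"""Synthetic DESI-MSI cohorts with the statistical structure of a two-class
tissue study.

The generator emulates a cohort of cancer and benign patients whose tissue
spectra carry a set of planted discriminatory peaks (elevated in cancer by
configurable fold changes), phenotype-linked peaks modulated only in
high-risk patients of one cohort, and non-discriminatory background peaks.
Pixel intensities follow a log-normal law with a configurable coefficient
of variation around the patient's expected level; each patient carries an
independent log-normal between-patient effect per feature; each pixel's
spectrum is scaled by a uniform TIC factor (exercising PQN) and each peak's
m/z is jittered in ppm (exercising the matching window).  A companion
protein table plants standardized mean differences and, optionally,
proteins correlated with realized lipid levels.

All randomness flows from one seeded NumPy generator consumed in a fixed,
documented order: background m/z, background intensities, phenotype
assignment, grade/stage draws, then per-patient effects and pixels in
patient order.  Identical configs therefore give identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .msi_io import MSImage, ROIMask

# Planted cancer-vs-benign features: (mz, fold_change, base_intensity, cv).
# m/z values and fold changes follow the study's discriminatory peak list;
# base intensities and the per-pixel CV are free generator parameters.
DEFAULT_PLANTED = (
    (688.4921, 1.24, 120.0, 0.25),
    (699.5014, 1.27, 150.0, 0.25),
    (714.5123, 1.28, 140.0, 0.25),
    (740.5229, 1.27, 110.0, 0.25),
    (864.5707, 1.24, 90.0, 0.25),
    (913.5778, 1.23, 80.0, 0.25),
    (915.5901, 1.27, 85.0, 0.25),
)

# Phenotype-linked features: (mz, fold_change of high-risk over low-risk
# patients, cohort in {"benign", "cancer"}).  The modulation is
# mean-preserving within its cohort, so it never leaks into the
# cancer-vs-benign contrast.  The default plants the benign-cohort
# high-risk signature on four peaks of its own; the within-cancer
# modulation of shared discriminatory peaks (elevated in the LOW-risk
# group, folds below 1) is a separate preset for subgroup analyses because
# it deliberately inflates within-cancer variance at those peaks.
DEFAULT_PHENOTYPE = (
    (753.5636, 4.03, "benign"),
    (813.5425, 3.09, "benign"),
    (839.5628, 10.97, "benign"),
    (890.5829, 5.06, "benign"),
)

CANCER_PHENOTYPE_PRESET = DEFAULT_PHENOTYPE + (
    (714.5123, 1.0 / 1.84, "cancer"),
    (740.5229, 1.0 / 1.63, "cancer"),
    (753.5636, 1.0 / 1.69, "cancer"),
)

GRADE_PROBS = {"1": 15 / 50, "2": 19 / 50, "3": 15 / 50, "unknown": 1 / 50}
STAGE_PROBS = {"IA": 20 / 50, "IB": 16 / 50, "II": 4 / 50, "III": 8 / 50, "IV": 2 / 50}


@dataclass(frozen=True)
class PatientMeta:
    patient_id: str
    diagnosis: str                 # {"benign", "cancer"}
    grade: str | None = None       # {"1","2","3","unknown"}; None for benign
    stage: str | None = None       # {"IA","IB","II","III","IV"}; None for benign
    phenotype: str = "low_risk"    # high_risk = obesity and/or diabetes


@dataclass(frozen=True)
class SyntheticConfig:
    n_cancer: int = 50
    n_benign: int = 14
    image_shape: tuple[int, int] = (20, 20)   # (rows, cols)
    planted_features: tuple = DEFAULT_PLANTED
    n_background_peaks: int = 200
    mz_range: tuple[float, float] = (600.0, 1000.0)
    ppm_jitter_sd: float = 2.0
    tic_scale_range: tuple[float, float] = (0.5, 2.0)
    fraction_high_risk_cancer: float = 26 / 50
    fraction_high_risk_benign: float = 5 / 14
    phenotype_features: tuple = DEFAULT_PHENOTYPE
    phenotype_base_intensity: float = 50.0
    patient_cv: float = 0.10       # between-patient log-normal CV per feature
    background_intensity_range: tuple[float, float] = (20.0, 200.0)
    background_cv: float = 0.25
    n_proteins: int = 282
    n_differential_proteins: int = 104
    protein_effect_size: float = 1.5   # standardized mean difference
    protein_base_mean: float = 1.0
    protein_base_sd: float = 0.25
    protein_lipid_links: tuple = (("protein_001", 699.5014, 0.9),)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cancer < 1:
            raise ConfigurationError("n_cancer must be >= 1")
        if self.n_benign < 1:
            raise ConfigurationError("n_benign must be >= 1")
        if self.mz_range[0] >= self.mz_range[1]:
            raise ConfigurationError("mz_range must satisfy low < high")
        for mz, fold, base, cv in self.planted_features:
            if not (self.mz_range[0] <= mz <= self.mz_range[1]):
                raise ConfigurationError(f"planted_features: m/z {mz} outside mz_range")
            if fold <= 0:
                raise ConfigurationError("planted_features: fold_change must be > 0")
            if base <= 0:
                raise ConfigurationError("planted_features: base_intensity must be > 0")
            if cv < 0:
                raise ConfigurationError("planted_features: cv must be >= 0")
        for mz, fold, cohort in self.phenotype_features:
            if cohort not in ("benign", "cancer"):
                raise ConfigurationError("phenotype_features: cohort must be benign or cancer")
            if fold <= 0:
                raise ConfigurationError("phenotype_features: fold_change must be > 0")
        if self.ppm_jitter_sd < 0:
            raise ConfigurationError("ppm_jitter_sd must be >= 0")
        if self.tic_scale_range[0] >= self.tic_scale_range[1] or self.tic_scale_range[0] <= 0:
            raise ConfigurationError("tic_scale_range must satisfy 0 < low < high")
        for name, frac in (
            ("fraction_high_risk_cancer", self.fraction_high_risk_cancer),
            ("fraction_high_risk_benign", self.fraction_high_risk_benign),
        ):
            if not (0.0 <= frac <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.patient_cv < 0:
            raise ConfigurationError("patient_cv must be >= 0")
        if self.n_background_peaks < 0:
            raise ConfigurationError("n_background_peaks must be >= 0")
        if self.n_proteins < 0:
            raise ConfigurationError("n_proteins must be >= 0")
        if self.n_differential_proteins > self.n_proteins:
            raise ConfigurationError(
                "n_differential_proteins must not exceed n_proteins"
            )


def _lognormal(rng: np.random.Generator, mean, cv: float, size) -> np.ndarray:
    """Log-normal draws parameterized by arithmetic mean and CV."""
    mean = np.broadcast_to(np.asarray(mean, dtype=np.float64), size)
    if cv == 0:
        return mean.copy()
    sigma2 = math.log(1.0 + cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return np.exp(rng.normal(mu, math.sqrt(sigma2), size=size))


def _background_mz(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform background m/z with >= 50 ppm separation from every planted,
    phenotype and previously drawn background peak."""
    fixed = [mz for mz, *_ in cfg.planted_features]
    fixed += [mz for mz, _, _ in cfg.phenotype_features]
    taken = sorted(set(fixed))
    out = []
    lo, hi = cfg.mz_range
    attempts = 0
    while len(out) < cfg.n_background_peaks:
        attempts += 1
        if attempts > 100000:
            raise ConfigurationError(
                "n_background_peaks: cannot place peaks 50 ppm apart in mz_range"
            )
        cand = float(rng.uniform(lo, hi))
        if all(abs(cand - m) / m * 1e6 >= 50.0 for m in taken):
            out.append(cand)
            taken.append(cand)
    return np.array(sorted(out))


def _tissue_pixels(shape: tuple[int, int]) -> set[tuple[int, int]]:
    rows, cols = shape
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    radius = 0.35 * min(rows, cols)
    return {
        (x, y)
        for y in range(rows)
        for x in range(cols)
        if (x - cx) ** 2 + (y - cy) ** 2 <= radius**2
    }


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[MSImage], list[ROIMask], list[PatientMeta]]:
    """Generate one MSImage + ROIMask + PatientMeta per patient.

    Tissue-pixel spectra contain every planted, phenotype and background
    peak; cancer tissue carries planted peaks at base x fold intensity.
    Non-tissue pixels carry the same peak list at near-zero (1%) intensity.
    m/z jitter is Gaussian in ppm, truncated at 3 sigma so that a feature's
    within-cohort spread stays inside the matching window.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    bg_mz = _background_mz(config, rng)
    bg_base = rng.uniform(*config.background_intensity_range, size=bg_mz.size)

    planted_mz = np.array([f[0] for f in config.planted_features])
    planted_fold = np.array([f[1] for f in config.planted_features])
    planted_base = np.array([f[2] for f in config.planted_features])
    planted_cv = np.array([f[3] for f in config.planted_features])

    # phenotype m/z that coincide with a planted peak modulate that peak;
    # only the remainder introduce new peaks at the phenotype base intensity
    pheno_all = sorted({mz for mz, _, _ in config.phenotype_features})
    planted_set = set(float(m) for m in planted_mz)
    pheno_mz = [mz for mz in pheno_all if float(mz) not in planted_set]
    pheno_folds = {  # (mz, cohort) -> fold on high-risk patients
        (mz, cohort): fold for mz, fold, cohort in config.phenotype_features
    }

    all_mz = np.concatenate([planted_mz, np.array(pheno_mz, dtype=float), bg_mz])
    order = np.argsort(all_mz)
    all_mz = all_mz[order]
    n_feat = all_mz.size

    # per-feature base intensity / cv, aligned to sorted all_mz
    base = np.concatenate(
        [planted_base, np.full(len(pheno_mz), config.phenotype_base_intensity), bg_base]
    )[order]
    cv = np.concatenate(
        [planted_cv,
         np.full(len(pheno_mz), config.background_cv),
         np.full(bg_mz.size, config.background_cv)]
    )[order]
    kind = np.concatenate(  # 0 planted, 1 phenotype, 2 background
        [np.zeros(planted_mz.size), np.ones(len(pheno_mz)), np.full(bg_mz.size, 2)]
    )[order]
    planted_idx = {float(all_mz[j]): j for j in range(n_feat) if kind[j] == 0}
    col_of = {float(all_mz[j]): j for j in range(n_feat)}
    pheno_idx = {float(mz): col_of[float(mz)] for mz in pheno_all}
    fold_by_mz = {float(mz): float(f) for mz, f in zip(planted_mz, planted_fold)}

    # patient roster: cancers first, then benign controls
    metas: list[PatientMeta] = []
    n_hr_cancer = int(round(config.fraction_high_risk_cancer * config.n_cancer))
    n_hr_benign = int(round(config.fraction_high_risk_benign * config.n_benign))
    hr_cancer = set(rng.permutation(config.n_cancer)[:n_hr_cancer].tolist())
    hr_benign = set(rng.permutation(config.n_benign)[:n_hr_benign].tolist())
    grades = rng.choice(list(GRADE_PROBS), size=config.n_cancer, p=list(GRADE_PROBS.values()))
    stages = rng.choice(list(STAGE_PROBS), size=config.n_cancer, p=list(STAGE_PROBS.values()))
    for i in range(config.n_cancer):
        metas.append(
            PatientMeta(
                patient_id=f"cancer_{i + 1:03d}",
                diagnosis="cancer",
                grade=str(grades[i]),
                stage=str(stages[i]),
                phenotype="high_risk" if i in hr_cancer else "low_risk",
            )
        )
    for i in range(config.n_benign):
        metas.append(
            PatientMeta(
                patient_id=f"benign_{i + 1:03d}",
                diagnosis="benign",
                phenotype="high_risk" if i in hr_benign else "low_risk",
            )
        )

    tissue = sorted(_tissue_pixels(config.image_shape))
    rows, cols = config.image_shape
    all_pixels = [(x, y) for y in range(rows) for x in range(cols)]
    n_tissue = len(tissue)
    tissue_set = set(tissue)
    jitter_cap = 3.0 * config.ppm_jitter_sd

    images, masks = [], []
    for meta in metas:
        expected = base.copy()
        if meta.diagnosis == "cancer":
            for mz, j in planted_idx.items():
                expected[j] *= fold_by_mz[mz]
        # phenotype contrast is mean-preserving within its cohort: the
        # high/low intensity ratio equals the configured fold while the
        # cohort mean is unchanged, so cohort-level planted folds survive
        n_coh = config.n_cancer if meta.diagnosis == "cancer" else config.n_benign
        n_hi = n_hr_cancer if meta.diagnosis == "cancer" else n_hr_benign
        for mz, j in pheno_idx.items():
            fold = pheno_folds.get((mz, meta.diagnosis))
            if fold is None:
                continue
            scale = n_coh / ((n_coh - n_hi) + n_hi * fold)
            expected[j] *= scale * (fold if meta.phenotype == "high_risk" else 1.0)

        patient_effect = _lognormal(rng, 1.0, config.patient_cv, (n_feat,))
        level = expected * patient_effect

        # tissue pixels first in RNG order, then near-zero background pixels
        sigma2 = np.log(1.0 + cv * cv)
        mu = np.log(level) - sigma2 / 2.0
        z = rng.normal(size=(n_tissue, n_feat))
        inten_t = np.exp(mu + z * np.sqrt(sigma2))
        tic = rng.uniform(*config.tic_scale_range, size=n_tissue)
        inten_t = inten_t * tic[:, None]
        bg_pix = [xy for xy in all_pixels if xy not in tissue_set]
        inten_b = _lognormal(rng, level * 0.01, config.background_cv,
                             (len(bg_pix), n_feat))

        jit_t = rng.normal(0.0, config.ppm_jitter_sd or 1.0, size=(n_tissue, n_feat))
        jit_b = rng.normal(0.0, config.ppm_jitter_sd or 1.0, size=(len(bg_pix), n_feat))
        if config.ppm_jitter_sd == 0:
            jit_t = np.zeros_like(jit_t)
            jit_b = np.zeros_like(jit_b)
        else:
            jit_t = np.clip(jit_t, -jitter_cap, jitter_cap)
            jit_b = np.clip(jit_b, -jitter_cap, jitter_cap)

        img = MSImage(patient_id=meta.patient_id, mode="processed",
                      spatial_resolution_um=100.0)
        mask = ROIMask()
        tissue_label = "cancer_tissue" if meta.diagnosis == "cancer" else "benign_tissue"
        for r, xy in enumerate(tissue):
            mz_px = all_mz * (1.0 + jit_t[r] * 1e-6)
            img.pixels[xy] = (mz_px, inten_t[r].copy())
            mask.labels[xy] = tissue_label
        for r, xy in enumerate(bg_pix):
            mz_px = all_mz * (1.0 + jit_b[r] * 1e-6)
            img.pixels[xy] = (mz_px, inten_b[r].copy())
            mask.labels[xy] = "background"
        images.append(img)
        masks.append(mask)
    return images, masks, metas


def differential_protein_names(config: SyntheticConfig) -> list[str]:
    return [f"protein_{j + 1:03d}" for j in range(config.n_differential_proteins)]


def generate_protein_table(
    config: SyntheticConfig,
    meta: list[PatientMeta],
    lipid_profiles: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Patients x proteins expression table.

    The first ``n_differential_proteins`` carry a class-mean difference of
    ``protein_effect_size`` standard deviations (higher in cancer); the rest
    are exchangeable between classes.  When ``lipid_profiles`` (patients x
    lipid m/z columns, e.g. realized planted-feature intensities) is given,
    each configured link replaces a protein's draw with a construction
    correlated at the requested coefficient with the named lipid.
    """
    config.validate()
    if not meta:
        raise ConfigurationError("meta must be non-empty")
    rng = np.random.default_rng([config.seed, 104729])  # independent substream
    n = len(meta)
    names = [f"protein_{j + 1:03d}" for j in range(config.n_proteins)]
    is_cancer = np.array([m.diagnosis == "cancer" for m in meta], dtype=float)
    Z = rng.normal(size=(n, config.n_proteins))
    X = config.protein_base_mean + config.protein_base_sd * Z
    shift = config.protein_effect_size * config.protein_base_sd
    X[:, : config.n_differential_proteins] += shift * is_cancer[:, None]

    df = pd.DataFrame(X, index=[m.patient_id for m in meta], columns=names)
    if lipid_profiles is not None:
        for prot, lipid_mz, rho in config.protein_lipid_links:
            if prot not in df.columns:
                raise ConfigurationError(f"protein_lipid_links: unknown protein {prot!r}")
            if not (-1.0 <= rho <= 1.0):
                raise ConfigurationError("protein_lipid_links: correlation outside [-1, 1]")
            col = _nearest_column(lipid_profiles, lipid_mz)
            v = lipid_profiles[col].reindex(df.index).to_numpy(dtype=np.float64)
            z = (v - v.mean()) / v.std(ddof=0)
            eps = rng.normal(size=n)
            df[prot] = config.protein_base_mean + config.protein_base_sd * (
                rho * z + math.sqrt(max(0.0, 1.0 - rho * rho)) * eps
            )
    return df


def _nearest_column(lipid_profiles: pd.DataFrame, mz: float):
    cols = list(lipid_profiles.columns)
    vals = np.array([float(c) for c in cols])
    j = int(np.argmin(np.abs(vals - mz)))
    if abs(vals[j] - mz) / mz * 1e6 > 50.0:
        raise ConfigurationError(
            f"protein_lipid_links: no lipid column within 50 ppm of m/z {mz}"
        )
    return cols[j]


def null_config(config: SyntheticConfig | None = None) -> SyntheticConfig:
    """A copy of a config with all planted effects removed (for calibration)."""
    cfg = config or SyntheticConfig()
    flat_planted = tuple((mz, 1.0, base, cv) for mz, _f, base, cv in cfg.planted_features)
    flat_pheno = tuple((mz, 1.0, cohort) for mz, _f, cohort in cfg.phenotype_features)
    return replace(
        cfg,
        planted_features=flat_planted,
        phenotype_features=flat_pheno,
        protein_effect_size=0.0,
    )
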