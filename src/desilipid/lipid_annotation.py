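"""Lipid annotation of consensus m/z features by accurate-mass lookup.

Candidates are deprotonated ([M-H]-) glycerophospholipids from a bundled
reference table (extensible TSV); each observed m/z is matched against
every record's monoisotopic mass and its 13C isotopologues, and hits are
ranked by absolute ppm error.  MS/MS notes ride along as opaque metadata
and are never interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import ConfigurationError, ValidationError
from .preprocess import PeakMatrix

#: 13C - 12C mass difference, Da (to 7 d.p.)
C13_MASS_SHIFT = 1.0033548

DEFAULT_TOL_PPM = 10.0
DEFAULT_MAX_ISOTOPE = 1


@dataclass(frozen=True)
class LipidRecord:
    name: str
    lipid_class: str
    adduct: str
    theoretical_mz: float  # monoisotopic adduct ion mass
    msms_note: str = ""


@dataclass(frozen=True)
class AnnotationHit:
    observed_mz: float
    record: LipidRecord
    isotope_offset: int
    matched_theoretical_mz: float
    ppm_error: float
    rank: int


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """(observed - theoretical) / theoretical x 1e6."""
    if theoretical_mz <= 0:
        raise ValidationError("theoretical m/z must be positive")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


def isotope_mz(mono_mz: float, k: int) -> float:
    """m/z of the k-fold 13C isotopologue of a monoisotopic ion."""
    if k < 0:
        raise ConfigurationError("isotope count k must be >= 0")
    return mono_mz + k * C13_MASS_SHIFT


def load_reference_table(path: str | None = None) -> list[LipidRecord]:
    """Load a lipid reference TSV; the bundled table when no path is given."""
    if path is None:
        src = resources.files("desilipid.data") / "lipid_reference.tsv"
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"name", "lipid_class", "adduct", "theoretical_mz"}
    if not required <= set(df.columns):
        raise ValidationError(f"reference table missing columns {required - set(df.columns)}")
    if df.duplicated(subset=["name", "adduct"]).any():
        raise ValidationError("duplicate (name, adduct) in reference table")
    return [
        LipidRecord(
            name=r["name"],
            lipid_class=r["lipid_class"],
            adduct=r["adduct"],
            theoretical_mz=float(r["theoretical_mz"]),
            msms_note=str(r.get("msms_note", "") or ""),
        )
        for r in df.to_dict("records")
    ]


def annotate_feature(
    observed_mz: float,
    table: list[LipidRecord],
    tol_ppm: float = DEFAULT_TOL_PPM,
    max_isotope: int = DEFAULT_MAX_ISOTOPE,
) -> list[AnnotationHit]:
    """All candidate identities within a ppm tolerance, ranked by |ppm error|.

    Ties break toward the lower isotope offset, then lexicographic name.
    An empty list is a valid result.
    """
    if not table:
        raise ValidationError("reference table is empty")
    if tol_ppm <= 0:
        raise ConfigurationError("tol_ppm must be positive")
    raw = []
    for rec in table:
        for k in range(max_isotope + 1):
            theo = isotope_mz(rec.theoretical_mz, k)
            err = ppm_error(observed_mz, theo)
            if abs(err) <= tol_ppm:
                raw.append((rec, k, theo, err))
    raw.sort(key=lambda t: (abs(t[3]), t[1], t[0].name))
    return [
        AnnotationHit(
            observed_mz=observed_mz,
            record=rec,
            isotope_offset=k,
            matched_theoretical_mz=theo,
            ppm_error=err,
            rank=i + 1,
        )
        for i, (rec, k, theo, err) in enumerate(raw)
    ]


def annotate_matrix(
    matrix: PeakMatrix,
    table: list[LipidRecord] | None = None,
    tol_ppm: float = DEFAULT_TOL_PPM,
    max_isotope: int = DEFAULT_MAX_ISOTOPE,
    stats_df: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Top-hit annotation report for every consensus feature.

    One row per feature (unannotated features keep empty name fields); when
    a feature-statistics table is supplied its p/q/fold-change columns are
    joined on m/z.
    """
    table = table if table is not None else load_reference_table()
    rows = []
    for mz in matrix.consensus_mz:
        hits = annotate_feature(float(mz), table, tol_ppm=tol_ppm, max_isotope=max_isotope)
        top = hits[0] if hits else None
        rows.append(
            {
                "mz": float(mz),
                "name": top.record.name if top else "",
                "lipid_class": top.record.lipid_class if top else "",
                "adduct": top.record.adduct if top else "",
                "isotope_offset": top.isotope_offset if top else pd.NA,
                "theoretical_mz": top.matched_theoretical_mz if top else pd.NA,
                "ppm_error": round(top.ppm_error, 4) if top else pd.NA,
                "msms_note": top.record.msms_note if top else "",
                "n_candidates": len(hits),
            }
        )
    report = pd.DataFrame(rows)
    if stats_df is not None and not stats_df.empty:
        report = report.merge(
            stats_df[["mz", "p_value", "q_value", "fold_change", "direction"]],
            on="mz",
            how="left",
        )
    return report
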