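"""Mass-spectrometry-imaging I/O: imzML spectra, ROI label masks, metadata tables.

Pixel coordinates are 0-based throughout the package, ``x`` = column,
``y`` = row, origin top-left.  The on-disk imzML convention is 1-based, so
coordinates are shifted on read/write.  Intensities are stored as 32-bit
floats and m/z as 64-bit floats in the binary container, preserving
ppm-level mass precision at the usual file size.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

ROI_LABELS = ("background", "benign_tissue", "cancer_tissue")

Spectrum = tuple[np.ndarray, np.ndarray]  # (mz ascending, intensity >= 0)


@dataclass
class MSImage:
    """One patient's pixel grid of centroided spectra.

    ``pixels`` maps (x, y) to a (mz, intensity) pair of 1-D arrays with m/z
    strictly ascending.  ``mode`` records whether every pixel shares one m/z
    axis ("continuous") or carries its own peak list ("processed").
    """

    patient_id: str
    pixels: dict[tuple[int, int], Spectrum] = field(default_factory=dict)
    mode: str = "processed"
    spatial_resolution_um: float = 100.0

    def validate(self) -> None:
        if self.mode not in ("continuous", "processed"):
            raise FormatError(f"unknown mode {self.mode!r}")
        shared = None
        for (x, y), (mz, inten) in self.pixels.items():
            mz = np.asarray(mz)
            inten = np.asarray(inten)
            if mz.shape != inten.shape or mz.ndim != 1:
                raise FormatError(f"pixel ({x},{y}): mz/intensity shape mismatch")
            if mz.size > 1 and not np.all(np.diff(mz) > 0):
                raise FormatError(f"pixel ({x},{y}): m/z axis not strictly ascending")
            if np.any(inten < 0):
                raise FormatError(f"pixel ({x},{y}): negative intensity")
            if self.mode == "continuous":
                if shared is None:
                    shared = mz
                elif mz.shape != shared.shape or not np.allclose(mz, shared):
                    raise FormatError(
                        f"continuous mode but pixel ({x},{y}) has its own m/z axis"
                    )


@dataclass
class ROIMask:
    """Per-pixel tissue label aligned to MSImage coordinates."""

    labels: dict[tuple[int, int], str] = field(default_factory=dict)

    def pixels_with(self, label: str) -> list[tuple[int, int]]:
        return sorted(xy for xy, lab in self.labels.items() if lab == label)

    def validate_against(self, img: MSImage) -> None:
        for xy, lab in self.labels.items():
            if lab not in ROI_LABELS:
                raise FormatError(f"unknown ROI label {lab!r} at pixel {xy}")
            if xy not in img.pixels:
                raise ValidationError(
                    f"mask pixel {xy} absent from image {img.patient_id!r}"
                )


def write_imzml(img: MSImage, path: str, mode: str | None = None) -> None:
    """Write an imzML + ibd pair; ``mode`` defaults to the image's own."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    mode = mode or img.mode
    if mode not in ("continuous", "processed"):
        raise FormatError(f"unknown imzML mode {mode!r}")
    if mode == "continuous":
        axes = [np.asarray(mz) for mz, _ in img.pixels.values()]
        if axes and any(
            a.shape != axes[0].shape or not np.allclose(a, axes[0]) for a in axes[1:]
        ):
            raise FormatError(
                "continuous mode requested but pixels have ragged m/z axes"
            )
    with ImzMLWriter(path, mode=mode, mz_dtype=np.float64, intensity_dtype=np.float32) as w:
        for (x, y) in sorted(img.pixels):
            mz, inten = img.pixels[(x, y)]
            w.addSpectrum(np.asarray(mz, float), np.asarray(inten, float), (x + 1, y + 1, 1))


def read_imzml(path: str, patient_id: str | None = None) -> MSImage:
    """Read an imzML file into an :class:`MSImage`.

    Mode is detected from the file's cvParams; a missing .ibd companion is
    reported as an I/O error before parsing starts.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    ibd = os.path.splitext(path)[0] + ".ibd"
    if not os.path.exists(path):
        raise IOError(f"imzML file not found: {path}")
    if not os.path.exists(ibd):
        raise IOError(f"binary companion (.ibd) missing for {path}")
    try:
        parser = ImzMLParser(path)
    except Exception as exc:
        raise FormatError(f"cannot parse imzML file {path}: {exc}") from exc
    mode = (
        "continuous"
        if "continuous" in parser.metadata.file_description.param_by_name
        else "processed"
    )
    pid = patient_id or os.path.splitext(os.path.basename(path))[0]
    img = MSImage(patient_id=pid, mode=mode)
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=np.float64)
        inten = np.asarray(inten, dtype=np.float64)
        if mz.size > 1 and not np.all(np.diff(mz) > 0):
            raise FormatError(f"pixel ({x - 1},{y - 1}) in {path}: m/z not ascending")
        img.pixels[(x - 1, y - 1)] = (mz, inten)
    img.validate()
    return img


def write_mask(mask: ROIMask, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# ROI mask: 0-based pixel coordinates, x = column, y = row, origin top-left\n")
        fh.write("x\ty\tlabel\n")
        for (x, y) in sorted(mask.labels):
            fh.write(f"{x}\t{y}\t{mask.labels[(x, y)]}\n")


def read_mask(path: str) -> ROIMask:
    mask = ROIMask()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("x\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"mask row {line!r}: expected 3 tab-separated fields")
            x, y, lab = parts
            if lab not in ROI_LABELS:
                raise FormatError(f"mask label {lab!r} outside vocabulary {ROI_LABELS}")
            mask.labels[(int(x), int(y))] = lab
    return mask


def write_metadata(meta: list, path: str) -> None:
    """Write patient metadata as TSV (patient_id, diagnosis, grade, stage, phenotype)."""
    rows = [
        {
            "patient_id": m.patient_id,
            "diagnosis": m.diagnosis,
            "grade": "" if m.grade is None else m.grade,
            "stage": "" if m.stage is None else m.stage,
            "phenotype": m.phenotype,
        }
        for m in meta
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_metadata(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"patient_id", "diagnosis", "phenotype"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata table missing columns: {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        raise FormatError("duplicate patient_id in metadata table")
    return df
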