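"""Spectral preprocessing: ppm-constrained peak matching, ROI averaging, PQN.

The unit of analysis is one averaged spectrum per patient per tissue class:
peaks are matched across a region's pixels first, each consensus feature is
averaged over the labeled pixel count (absent peaks count as zero), and the
per-patient averages are then matched across patients into a
:class:`PeakMatrix` and normalized by probabilistic quotient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyROIError, FormatError, NormalizationError
from .msi_io import MSImage, ROIMask, Spectrum

DEFAULT_MZ_WINDOW = (600.0, 1000.0)
DEFAULT_MAX_SHIFT_PPM = 8.0


@dataclass
class PeakMatrix:
    """Samples x consensus-feature intensity matrix after ppm matching."""

    sample_ids: list[str]
    consensus_mz: np.ndarray  # strictly ascending
    intensities: np.ndarray  # (n_samples, n_features), non-negative
    normalization_state: str = "raw"  # {"raw", "pqn"}
    pqn_factors: np.ndarray | None = None

    def copy(self) -> "PeakMatrix":
        return PeakMatrix(
            sample_ids=list(self.sample_ids),
            consensus_mz=self.consensus_mz.copy(),
            intensities=self.intensities.copy(),
            normalization_state=self.normalization_state,
            pqn_factors=None if self.pqn_factors is None else self.pqn_factors.copy(),
        )


def _check_spectrum(mz: np.ndarray, who: str) -> None:
    if mz.size > 1 and not np.all(np.diff(mz) > 0):
        raise FormatError(f"{who}: input spectrum m/z not strictly ascending")


def match_peaks(
    spectra: list[Spectrum],
    max_shift_ppm: float = DEFAULT_MAX_SHIFT_PPM,
    mz_window: tuple[float, float] | None = DEFAULT_MZ_WINDOW,
    sample_ids: list[str] | None = None,
) -> PeakMatrix:
    """Cluster peaks across spectra into consensus features within a ppm bound.

    All peaks are pooled and sorted by m/z; a single-linkage-style sweep
    closes a feature when the ppm gap between the next peak and the running
    intensity-weighted consensus exceeds ``max_shift_ppm``.  A refinement
    pass enforces per-spectrum uniqueness: where one spectrum lands several
    peaks in a feature, the nearest-ppm peak stays (ties broken toward the
    higher intensity) and each loser re-opens its own feature.  Consensus
    m/z is the intensity-weighted mean of member m/z; absent peaks are 0.
    The result is independent of the order of input spectra.
    """
    if not spectra:
        raise FormatError("match_peaks: need at least one spectrum")
    if max_shift_ppm <= 0:
        raise FormatError("match_peaks: max_shift_ppm must be positive")
    ids = sample_ids if sample_ids is not None else [f"s{i}" for i in range(len(spectra))]

    mzs, intens, sidx = [], [], []
    for i, (mz, inten) in enumerate(spectra):
        mz = np.asarray(mz, dtype=np.float64)
        inten = np.asarray(inten, dtype=np.float64)
        _check_spectrum(mz, f"spectrum {i}")
        keep = np.ones(mz.size, dtype=bool)
        if mz_window is not None:
            keep = (mz >= mz_window[0]) & (mz <= mz_window[1])
        mzs.append(mz[keep])
        intens.append(inten[keep])
        sidx.append(np.full(int(keep.sum()), i, dtype=np.int64))
    mz_all = np.concatenate(mzs)
    in_all = np.concatenate(intens)
    sx_all = np.concatenate(sidx)
    order = np.argsort(mz_all, kind="stable")
    mz_all, in_all, sx_all = mz_all[order], in_all[order], sx_all[order]

    # sweep pass
    clusters: list[list[int]] = []
    if mz_all.size:
        cur = [0]
        wsum = in_all[0] * mz_all[0]
        w = in_all[0]
        consensus = mz_all[0]
        for j in range(1, mz_all.size):
            gap_ppm = (mz_all[j] - consensus) / consensus * 1e6
            if gap_ppm > max_shift_ppm:
                clusters.append(cur)
                cur = [j]
                wsum, w = in_all[j] * mz_all[j], in_all[j]
                consensus = mz_all[j]
            else:
                cur.append(j)
                wsum += in_all[j] * mz_all[j]
                w += in_all[j]
                consensus = wsum / w if w > 0 else float(np.mean(mz_all[cur]))
        clusters.append(cur)

    def _consensus(members: list[int]) -> float:
        m = mz_all[members]
        wt = in_all[members]
        tot = wt.sum()
        return float((m * wt).sum() / tot) if tot > 0 else float(m.mean())

    # refinement: one peak per spectrum per feature
    refined: list[list[int]] = []
    for members in clusters:
        cons = _consensus(members)
        by_spec: dict[int, list[int]] = {}
        for j in members:
            by_spec.setdefault(int(sx_all[j]), []).append(j)
        kept: list[int] = []
        for js in by_spec.values():
            if len(js) == 1:
                kept.append(js[0])
                continue
            # nearest ppm wins; tie -> higher intensity, then lower m/z
            js_sorted = sorted(
                js,
                key=lambda j: (abs(mz_all[j] - cons) / cons, -in_all[j], mz_all[j]),
            )
            kept.append(js_sorted[0])
            refined.extend([[j] for j in js_sorted[1:]])  # losers open new features
        refined.append(kept)

    feats = sorted(refined, key=_consensus)
    consensus_mz = np.array([_consensus(m) for m in feats])
    matrix = np.zeros((len(spectra), len(feats)))
    for f, members in enumerate(feats):
        for j in members:
            matrix[sx_all[j], f] += in_all[j]
    return PeakMatrix(sample_ids=ids, consensus_mz=consensus_mz, intensities=matrix)


def average_roi(
    img: MSImage,
    mask: ROIMask,
    label: str,
    max_shift_ppm: float = DEFAULT_MAX_SHIFT_PPM,
    mz_window: tuple[float, float] | None = None,
) -> Spectrum:
    """Mean spectrum over a region's pixels.

    Pixel peak lists are pooled and matched first so the mean is a single
    peak list; a feature's averaged intensity is its summed intensity over
    contributing pixels divided by the labeled pixel count (missing = 0).
    """
    pix = mask.pixels_with(label)
    pix = [xy for xy in pix if xy in img.pixels]
    if not pix:
        raise EmptyROIError(
            f"patient {img.patient_id!r}: no pixels labeled {label!r}"
        )
    spectra = [img.pixels[xy] for xy in pix]
    pm = match_peaks(spectra, max_shift_ppm=max_shift_ppm, mz_window=mz_window)
    mean_int = pm.intensities.sum(axis=0) / len(pix)
    return pm.consensus_mz, mean_int


def pqn_normalize(matrix: PeakMatrix, quotient: str = "median") -> PeakMatrix:
    """Probabilistic quotient normalization against the mean reference spectrum.

    The reference is the element-wise mean of the total-normalized sample
    spectra, rescaled to the mean total, so that a sample's own global
    scale cannot distort the reference shape.  Each sample's quotients are
    its intensities divided by the reference at features where the
    reference is positive; the per-sample factor is the median (default)
    or mean of those quotients, and the sample is divided by its factor.
    """
    if quotient not in ("median", "mean"):
        raise NormalizationError(f"unknown quotient rule {quotient!r}")
    X = matrix.intensities
    row_pos = (X > 0).any(axis=1)
    if not row_pos.all():
        bad = matrix.sample_ids[int(np.argmin(row_pos))]
        raise NormalizationError(f"sample {bad!r} is all-zero; cannot normalize")
    totals = X.sum(axis=1)
    reference = (X / totals[:, None]).mean(axis=0) * totals.mean()
    pos = reference > 0
    if not pos.any():
        raise NormalizationError("reference spectrum has no positive feature")
    q = X[:, pos] / reference[pos]
    factors = np.median(q, axis=1) if quotient == "median" else q.mean(axis=1)
    if np.any(factors <= 0):
        bad = matrix.sample_ids[int(np.argmin(factors))]
        raise NormalizationError(f"sample {bad!r}: non-positive quotient factor")
    out = matrix.copy()
    out.intensities = X / factors[:, None]
    out.normalization_state = "pqn"
    out.pqn_factors = factors
    return out
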