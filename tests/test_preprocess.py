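"""Peak matching, ROI averaging and PQN: examples and invariants."""

import numpy as np
import pytest

from desilipid import (
    MSImage,
    ROIMask,
    SyntheticConfig,
    average_roi,
    generate_cohort,
    match_peaks,
    pqn_normalize,
)
from desilipid.errors import EmptyROIError, FormatError, NormalizationError
from desilipid.preprocess import PeakMatrix
from tests.conftest import PLANTED_MZ


def _spec(*pairs):
    mz, inten = zip(*pairs)
    return np.array(mz, float), np.array(inten, float)


class TestMatchPeaks:
    def test_peaks_4ppm_apart_merge(self):
        pm = match_peaks([_spec((700.0000, 1.0)), _spec((700.0028, 2.0))])
        assert pm.consensus_mz.size == 1
        np.testing.assert_allclose(pm.intensities, [[1.0], [2.0]])

    def test_peaks_25ppm_apart_split(self):
        pm = match_peaks([_spec((700.0000, 1.0)), _spec((700.0175, 2.0))])
        assert pm.consensus_mz.size == 2

    def test_window_filters_out_of_range_peaks(self):
        pm = match_peaks([_spec((550.0, 1.0), (700.0, 2.0), (1100.0, 3.0))])
        assert pm.consensus_mz.size == 1

    def test_consensus_is_intensity_weighted_mean(self):
        pm = match_peaks([_spec((700.0000, 1.0)), _spec((700.0028, 3.0))])
        assert pm.consensus_mz[0] == pytest.approx((700.0 * 1 + 700.0028 * 3) / 4)

    def test_order_invariance(self, rng):
        spectra = []
        for _ in range(6):
            mz = np.sort(rng.uniform(600, 1000, 40))
            spectra.append((mz, rng.uniform(1, 100, 40)))
        a = match_peaks(spectra)
        perm = [3, 0, 5, 1, 4, 2]
        b = match_peaks([spectra[i] for i in perm])
        np.testing.assert_allclose(np.sort(a.consensus_mz), np.sort(b.consensus_mz))

    def test_members_within_window_and_per_spectrum_unique(self, rng):
        spectra = []
        for _ in range(5):
            mz = np.sort(rng.uniform(600, 1000, 60))
            spectra.append((mz, rng.uniform(1, 100, 60)))
        pm = match_peaks(spectra, max_shift_ppm=8.0)
        # re-match each input peak to its nearest consensus: must be <= 8 ppm
        for mz, _ in spectra:
            for m in mz:
                j = int(np.argmin(np.abs(pm.consensus_mz - m)))
                assert abs(m - pm.consensus_mz[j]) / pm.consensus_mz[j] * 1e6 <= 8.0 + 1e-9

    def test_non_ascending_spectrum_rejected(self):
        with pytest.raises(FormatError, match="ascending"):
            match_peaks([(np.array([700.0, 650.0]), np.array([1.0, 1.0]))])

    def test_synthetic_cohort_feature_count_is_exact(self):
        """7 planted + 200 background peaks with 2-ppm jitter match into
        exactly 207 cohort features, each within 8 ppm of its true m/z."""
        cfg = SyntheticConfig(n_cancer=3, n_benign=2, image_shape=(10, 10),
                              phenotype_features=(), seed=21)
        imgs, masks, _metas = generate_cohort(cfg)
        spectra = [
            average_roi(img, mask, sorted(set(mask.labels.values()) - {"background"})[0])
            for img, mask in zip(imgs, masks)
        ]
        pm = match_peaks(spectra)
        assert pm.consensus_mz.size == 207
        for true_mz in PLANTED_MZ:
            err = np.min(np.abs(pm.consensus_mz - true_mz)) / true_mz * 1e6
            assert err <= 8.0


class TestAverageROI:
    def _image(self, pixels):
        img = MSImage(patient_id="p")
        mask = ROIMask()
        for i, spec in enumerate(pixels):
            img.pixels[(i, 0)] = spec
            mask.labels[(i, 0)] = "cancer_tissue"
        return img, mask

    def test_single_pixel_is_identity(self):
        img, mask = self._image([_spec((700.0, 5.0), (800.0, 7.0))])
        mz, inten = average_roi(img, mask, "cancer_tissue")
        np.testing.assert_allclose(mz, [700.0, 800.0])
        np.testing.assert_allclose(inten, [5.0, 7.0])

    def test_identical_pixels_idempotent(self):
        spec = _spec((700.0, 5.0), (800.0, 7.0))
        img, mask = self._image([spec, spec])
        _mz, inten = average_roi(img, mask, "cancer_tissue")
        np.testing.assert_allclose(inten, [5.0, 7.0])

    def test_missing_peak_counts_as_zero(self):
        img, mask = self._image([_spec((700.0, 10.0)), _spec((900.0, 4.0))])
        _mz, inten = average_roi(img, mask, "cancer_tissue")
        np.testing.assert_allclose(inten, [5.0, 2.0])

    def test_empty_roi_names_patient_and_label(self):
        img, mask = self._image([_spec((700.0, 1.0))])
        with pytest.raises(EmptyROIError, match="benign_tissue"):
            average_roi(img, mask, "benign_tissue")


class TestPQN:
    def test_multiplicative_invariance_between_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        pm = PeakMatrix(["a", "b"], np.array([601.0, 700.0, 800.0, 900.0]),
                        np.vstack([a, 3 * a]))
        out = pqn_normalize(pm)
        np.testing.assert_allclose(out.intensities[0], out.intensities[1])

    def test_single_sample_factor_is_one(self):
        pm = PeakMatrix(["a"], np.array([700.0, 800.0]), np.array([[2.0, 5.0]]))
        out = pqn_normalize(pm)
        assert out.pqn_factors[0] == pytest.approx(1.0)
        np.testing.assert_allclose(out.intensities, pm.intensities)

    def test_row_scale_invariance(self, rng):
        """A sample's global intensity scale is removed: rescaling one row
        changes every normalized row only by a single cohort-wide scalar
        (the mean-total reference scale), never any sample's profile."""
        X = rng.uniform(1, 10, size=(5, 20))
        mz = np.sort(rng.uniform(600, 1000, 20))
        out1 = pqn_normalize(PeakMatrix([f"s{i}" for i in range(5)], mz, X.copy()))
        X2 = X.copy()
        X2[2] *= 7.5
        out2 = pqn_normalize(PeakMatrix([f"s{i}" for i in range(5)], mz, X2))
        scalar = out2.intensities[0, 0] / out1.intensities[0, 0]
        np.testing.assert_allclose(out2.intensities, scalar * out1.intensities,
                                   rtol=1e-10)
        profiles1 = out1.intensities / out1.intensities.sum(axis=1, keepdims=True)
        profiles2 = out2.intensities / out2.intensities.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(profiles1, profiles2, rtol=1e-10)

    def test_idempotence_on_proportional_rows(self):
        base = np.array([1.0, 4.0, 2.0, 8.0])
        X = np.vstack([c * base for c in (0.5, 1.0, 2.0)])
        mz = np.array([650.0, 700.0, 750.0, 800.0])
        once = pqn_normalize(PeakMatrix(["a", "b", "c"], mz, X))
        twice = pqn_normalize(once)
        np.testing.assert_allclose(twice.intensities, once.intensities)
        np.testing.assert_allclose(twice.pqn_factors, np.ones(3))

    def test_all_zero_sample_is_named(self):
        pm = PeakMatrix(["good", "dead"], np.array([700.0]),
                        np.array([[1.0], [0.0]]))
        with pytest.raises(NormalizationError, match="dead"):
            pqn_normalize(pm)

    def test_mean_quotient_variant(self):
        a = np.array([1.0, 2.0, 3.0])
        pm = PeakMatrix(["a", "b"], np.array([650.0, 700.0, 750.0]),
                        np.vstack([a, 2 * a]))
        out = pqn_normalize(pm, quotient="mean")
        np.testing.assert_allclose(out.intensities[0], out.intensities[1])

    def test_recovers_fold_change_under_tic_scaling(self, small_matrix, small_cohort):
        """TIC factors drawn from (0.5, 2) are removed by PQN: the planted
        fold at m/z 688.49 survives at the patient level."""
        _imgs, _masks, metas = small_cohort
        labels = np.array([m.diagnosis for m in metas])
        j = int(np.argmin(np.abs(small_matrix.consensus_mz - 688.4921)))
        v = small_matrix.intensities[:, j]
        fc = v[labels == "cancer"].mean() / v[labels == "benign"].mean()
        # 14 patients only: generous band around the configured 1.24
        assert fc == pytest.approx(1.24, rel=0.15)
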