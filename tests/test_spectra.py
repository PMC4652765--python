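"""Emission-spectrum processing, centroid classification, CD rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gqfold.spectra import (
    CDSpectrum,
    ClusterModel,
    EmissionSpectrum,
    LigandReadout,
    classify_cd_spectrum,
    classify_point,
    fit_centroids,
    normalize_to_reference,
    peak_intensity,
    pearson_correlation,
    subtract_background,
)


def make_spectrum(w, y, ligand="NMM", excitation=393.0, sample_id="s"):
    return EmissionSpectrum(
        wavelengths=np.asarray(w, float),
        intensities=np.asarray(y, float),
        excitation_nm=excitation,
        ligand=ligand,
        sample_id=sample_id,
    )


class TestPeakIntensity:
    def test_gaussian_peak_read(self):
        w = np.arange(550.0, 751.0)
        y = 100.0 * np.exp(-0.5 * ((w - 610.0) / 10.0) ** 2)
        val = peak_intensity(make_spectrum(w, y), 610.0, half_window=2.0)
        assert val == pytest.approx(100.0, rel=0.02)
        assert peak_intensity(make_spectrum(w, y), 610.0, half_window=0.0) == 100.0

    def test_all_zero_spectrum(self):
        w = np.arange(550.0, 751.0)
        assert peak_intensity(make_spectrum(w, np.zeros_like(w)), 640.0) == 0.0

    def test_linear_ramp_window_mean_is_center_value(self):
        # exact oracle: the window mean of a linear function a + b*x over
        # [c-h, c+h] is a + b*c, for any sampling grid
        w = np.arange(550.0, 755.0, 5.0)
        a, b = -3.0, 0.25
        y = a + b * w
        val = peak_intensity(make_spectrum(w, y), 612.0, half_window=2.0)
        assert val == pytest.approx(a + b * 612.0, abs=1e-9)

    def test_window_outside_coverage_raises(self):
        w = np.arange(600.0, 651.0)
        spec = make_spectrum(w, np.ones_like(w))
        with pytest.raises(ValueError, match="coverage"):
            peak_intensity(spec, 649.5, half_window=2.0)

    def test_strictly_increasing_grid_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            make_spectrum([600, 600, 601], [1, 1, 1])


class TestBackgroundSubtraction:
    def test_self_subtraction_is_zero(self):
        w = np.arange(550.0, 751.0)
        spec = make_spectrum(w, np.random.default_rng(0).random(w.size))
        out = subtract_background(spec, spec)
        assert np.all(out.intensities == 0.0)

    def test_flat_control_subtracts_and_floors(self):
        w = np.arange(550.0, 751.0)
        peak = 100.0 * np.exp(-0.5 * ((w - 610.0) / 10.0) ** 2)
        out = subtract_background(
            make_spectrum(w, peak), make_spectrum(w, np.full(w.size, 10.0))
        )
        assert peak_intensity(out, 610.0) == pytest.approx(90.0, rel=0.03)
        assert np.all(out.intensities >= 0.0)

    def test_shifted_grid_interpolation(self):
        # control on a 2.5 nm-offset grid; hand-computed interpolation oracle
        w = np.array([600.0, 605.0, 610.0])
        control_w = np.array([597.5, 602.5, 607.5, 612.5])
        control_y = np.array([10.0, 20.0, 30.0, 40.0])
        # linear interp of the control at 600/605/610 is 15/25/35 by hand
        out = subtract_background(
            make_spectrum(w, [100.0, 100.0, 100.0]),
            make_spectrum(control_w, control_y),
        )
        assert out.intensities == pytest.approx([85.0, 75.0, 65.0])

    def test_ligand_mismatch_rejected(self):
        w = np.arange(550.0, 751.0)
        a = make_spectrum(w, np.ones_like(w), ligand="NMM")
        b = make_spectrum(w, np.ones_like(w), ligand="CV", excitation=540.0)
        with pytest.raises(ValueError, match="ligand mismatch"):
            subtract_background(a, b)


class TestNormalization:
    def panel(self):
        return [
            LigandReadout("1-1-1", nmm_610=400.0, nmm_670=240.0, cv_640=50.0),
            LigandReadout("half", nmm_610=200.0, nmm_670=120.0, cv_640=100.0),
            LigandReadout("tta3", nmm_610=40.0, nmm_670=24.0, cv_640=200.0),
        ]

    def test_reference_maps_to_100(self):
        out = normalize_to_reference(self.panel(), "1-1-1")
        ref = next(r for r in out if r.sample_id == "1-1-1")
        assert ref.nmm_percent == 100.0 and ref.cv_percent == 100.0

    def test_half_intensity_gives_50_percent(self):
        out = normalize_to_reference(self.panel(), "1-1-1")
        half = next(r for r in out if r.sample_id == "half")
        assert half.nmm_percent == pytest.approx(50.0)
        assert half.cv_percent == pytest.approx(200.0)

    def test_rank_preservation(self):
        panel = self.panel()
        out = normalize_to_reference(panel, "1-1-1")
        raw_rank = np.argsort([r.nmm_610 for r in panel])
        pct_rank = np.argsort([r.nmm_percent for r in out])
        assert np.array_equal(raw_rank, pct_rank)

    def test_idempotence_on_percent_scale(self):
        out = normalize_to_reference(self.panel(), "1-1-1")
        again = normalize_to_reference(
            [
                LigandReadout(r.sample_id, r.nmm_percent, r.nmm_percent, r.cv_percent)
                for r in out
            ],
            "1-1-1",
        )
        for r1, r2 in zip(out, again):
            assert r2.nmm_percent == pytest.approx(r1.nmm_percent)
            assert r2.cv_percent == pytest.approx(r1.cv_percent)

    def test_zero_reference_rejected(self):
        panel = [LigandReadout("ref", 0.0, 0.0, 10.0)] + self.panel()[1:]
        with pytest.raises(ValueError, match="positive"):
            normalize_to_reference(panel, "ref")

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="not found"):
            normalize_to_reference(self.panel(), "nope")


BLOB_MEANS = {
    "parallel": (100.0, 10.0),
    "antiparallel": (15.0, 85.0),
    "unfolded": (5.0, 5.0),
}


def blob_panel(rng, n_per_class=40, sd=4.0):
    points = []
    for label, (mx, my) in BLOB_MEANS.items():
        xs = rng.normal(mx, sd, n_per_class)
        ys = rng.normal(my, sd, n_per_class)
        points += [(x, y, label) for x, y in zip(xs, ys)]
    return points


class TestCentroidClassifier:
    def test_single_point_per_class_centroids(self):
        pts = [(100.0, 10.0, "parallel"), (15.0, 85.0, "antiparallel"), (5.0, 5.0, "unfolded")]
        model = fit_centroids(pts)
        for x, y, label in pts:
            assert model.centroids[label] == pytest.approx((x, y))

    def test_duplicated_points_idempotent(self):
        pts = [(100.0, 10.0, "parallel"), (15.0, 85.0, "antiparallel"), (5.0, 5.0, "unfolded")]
        assert fit_centroids(pts).centroids == fit_centroids(pts * 3).centroids

    def test_blob_centroids_near_generating_means(self, rng):
        model = fit_centroids(blob_panel(rng, n_per_class=200))
        for label, mean in BLOB_MEANS.items():
            assert model.centroids[label] == pytest.approx(mean, abs=1.5)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="no calibration points"):
            fit_centroids([(1.0, 2.0, "parallel"), (3.0, 4.0, "unfolded")])

    def test_point_at_centroid_classified(self, rng):
        model = fit_centroids(blob_panel(rng))
        for label in BLOB_MEANS:
            got, dists = classify_point(model.centroids[label], model)
            assert got == label
            assert dists[label] == pytest.approx(0.0, abs=1e-12)

    def test_equidistant_tie_prefers_parallel(self):
        model = ClusterModel(
            centroids={
                "parallel": (100.0, 0.0),
                "antiparallel": (0.0, 100.0),
                "unfolded": (200.0, 200.0),
            },
            metric="euclidean",
        )
        label, dists = classify_point((50.0, 50.0), model)
        assert dists["parallel"] == pytest.approx(dists["antiparallel"])
        assert label == "parallel"

    def test_well_separated_blobs_fully_recovered(self, rng):
        train = blob_panel(rng, n_per_class=50)
        model = fit_centroids(train)
        test = blob_panel(rng, n_per_class=100)
        assert all(classify_point((x, y), model)[0] == lab for x, y, lab in test)

    def test_common_rescaling_invariance_standardized(self, rng):
        pts = blob_panel(rng, n_per_class=30)
        model = fit_centroids(pts, metric="standardized_euclidean")
        for c in (0.1, 3.0, 40.0):
            scaled = [(c * x, c * y, lab) for x, y, lab in pts]
            model_c = fit_centroids(scaled, metric="standardized_euclidean")
            for x, y, lab in pts:
                assert (
                    classify_point((c * x, c * y), model_c)[0]
                    == classify_point((x, y), model)[0]
                )


class TestPearson:
    def test_identity_and_negation(self):
        x = [1.0, 2.0, 5.0, 7.0]
        assert pearson_correlation(x, x) == pytest.approx(1.0)
        assert pearson_correlation(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov = 1.0, var_x = var_y = 1.25 -> r = 0.8
        assert pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_preconditions(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_correlation([1, 2], [3, 4])
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100),
            min_size=4,
            max_size=20,
            unique=True,
        ),
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=-50, max_value=50),
    )
    def test_symmetry_and_positive_affine_invariance(self, x, slope, offset):
        rng = np.random.default_rng(1)
        y = list(rng.permutation(x))
        if np.std(y) == 0:
            return
        r = pearson_correlation(x, y)
        assert pearson_correlation(y, x) == pytest.approx(r, abs=1e-9)
        y_aff = [slope * v + offset for v in y]
        assert pearson_correlation(x, y_aff) == pytest.approx(r, abs=1e-6)


class TestCDClassifier:
    grid = np.arange(200.0, 321.0)

    def gaussian(self, center, amp, sd):
        return amp * np.exp(-0.5 * ((self.grid - center) / sd) ** 2)

    def test_parallel_signature(self):
        y = self.gaussian(260, 4.0, 8.0) - self.gaussian(240, 3.0, 6.0)
        spec = CDSpectrum(self.grid, y)
        assert classify_cd_spectrum(spec) == "parallel"

    def test_antiparallel_signature(self):
        spec = CDSpectrum(self.grid, self.gaussian(290, 3.0, 10.0))
        assert classify_cd_spectrum(spec) == "antiparallel"

    def test_broad_duplex_band_indeterminate(self):
        y = np.minimum(self.gaussian(275, 3.0, 25.0), 2.0)  # flat-topped, broad
        spec = CDSpectrum(self.grid, y)
        assert classify_cd_spectrum(spec) == "indeterminate"

    def test_flat_spectrum_indeterminate(self):
        spec = CDSpectrum(self.grid, np.zeros_like(self.grid))
        assert classify_cd_spectrum(spec) == "indeterminate"

    def test_insufficient_coverage_rejected(self):
        w = np.arange(250.0, 321.0)
        with pytest.raises(ValueError, match="cover"):
            classify_cd_spectrum(CDSpectrum(w, np.zeros_like(w)))
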