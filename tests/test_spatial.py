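"""Spatial statistics: map assembly, phase labels, weights, spatial lag,
Moran's I (against a brute-force O(n^2) oracle), permutation inference and
sigmoid transect fits."""

import numpy as np
import pytest

from nanorheo.forward_model import FieldSpec, MembraneModel, RampSpec, generate_curve, generate_field
from nanorheo.lockin import ShearDrive
from nanorheo.pipeline import process_curve
from nanorheo.spatial import (
    DiffusivityMap, SpatialError, build_map, classify_phases,
    contiguity_weights, morans_I, per_phase_moran, sigmoid_profile_fit,
    spatial_lag,
)


def brute_force_moran(values: np.ndarray, w_dense: np.ndarray) -> float:
    """Independent O(n^2) double-loop Moran implementation."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    z = v - v.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w_dense[i, j] * z[i] * z[j]
            s0 += w_dense[i, j]
    return n / s0 * num / np.sum(z**2)


def simple_map(d, height=None, phase=None, pixel=5e-9):
    d = np.asarray(d, dtype=float)
    if height is None:
        height = np.zeros_like(d)
    return DiffusivityMap(d=d, height=height, pixel_size=pixel, phase=phase)


class TestBuildMap:
    def _grid(self, field_seed=0, shape=(4, 4), noiseless=True):
        model = MembraneModel()
        drive = ShearDrive()
        ramp = RampSpec(velocity=120e-9, sample_rate=6250.0)
        spec = FieldSpec(shape=shape, seed=field_seed, roughness=0.0)
        bundle = generate_field(spec)
        rows, cols = shape
        grid = np.empty(shape, dtype=object)
        for r in range(rows):
            for c in range(cols):
                m = model.with_(d_true=float(bundle.d_true[r, c]))
                grid[r, c] = process_curve(generate_curve(m, drive, ramp))
        return grid, bundle

    def test_noiseless_band_map_equals_truth(self):
        grid, bundle = self._grid()
        dmap = build_map(grid, pixel_size=5e-9, mode="band")
        assert np.allclose(dmap.d, bundle.d_true, rtol=1e-6)

    def test_band_and_plateau_agree_on_flat_plateau(self):
        grid, _ = self._grid()
        d_band = build_map(grid, pixel_size=5e-9, mode="band").d
        d_plat = build_map(grid, pixel_size=5e-9, mode="plateau").d
        assert np.allclose(d_band, d_plat, rtol=1e-6)

    def test_all_failed_grid_masked_with_warning(self):
        grid = np.full((3, 3), None, dtype=object)
        with pytest.warns(UserWarning, match="masked"):
            dmap = build_map(grid, pixel_size=5e-9)
        assert np.all(np.isnan(dmap.d))

    def test_non_rectangular_grid_rejected(self):
        with pytest.raises(SpatialError, match="2-D grid"):
            build_map(np.array([None, None], dtype=object), pixel_size=5e-9)


class TestClassifyPhases:
    def test_exact_two_level_map_perfect(self):
        h = np.zeros((10, 10))
        h[:, 5:] = 1e-9
        labels = classify_phases(h)
        assert np.all(labels[:, 5:] == "LO")
        assert np.all(labels[:, :5] == "LD")

    def test_noisy_bimodal_accuracy(self):
        """1.0 nm offset, 0.15 nm roughness: >99% pixel accuracy."""
        accs = []
        for seed in range(30):
            bundle = generate_field(FieldSpec(shape=(32, 32), seed=seed))
            labels = classify_phases(bundle.height)
            accs.append(np.mean(labels == bundle.phase))
        assert np.mean(accs) > 0.99

    def test_constant_height_single_phase_warning(self):
        with pytest.warns(UserWarning, match="single-phase"):
            labels = classify_phases(np.zeros((8, 8)))
        assert np.all(labels == "LD")

    def test_manual_threshold_override(self):
        h = np.zeros((4, 4))
        h[2:] = 0.4e-9
        labels = classify_phases(h, threshold=0.2e-9)
        assert np.all(labels[2:] == "LO")


class TestContiguityWeights:
    def test_interior_rook_four_quarter_neighbors(self):
        w = contiguity_weights((5, 5), scheme="rook")
        center = 12  # (2,2)
        row = w.w[center].toarray().ravel()
        assert np.count_nonzero(row) == 4
        assert np.allclose(row[row > 0], 0.25)

    def test_corner_rook_two_half_neighbors(self):
        w = contiguity_weights((5, 5), scheme="rook")
        row = w.w[0].toarray().ravel()
        assert np.count_nonzero(row) == 2
        assert np.allclose(row[row > 0], 0.5)

    def test_row_sums_exactly_one(self):
        for scheme in ("rook", "queen"):
            w = contiguity_weights((6, 7), scheme=scheme)
            sums = np.asarray(w.w.sum(axis=1)).ravel()
            assert np.all(sums[~w.isolated] == 1.0)

    def test_phase_surrounded_pixel_isolated(self):
        phase = np.full((3, 3), "LD", dtype=object)
        phase[1, 1] = "LO"
        w = contiguity_weights((3, 3), scheme="queen", phase=phase,
                               within_phase=True)
        assert w.isolated[4]  # center pixel has no same-phase neighbor

    def test_diagonal_zero(self):
        w = contiguity_weights((4, 4), scheme="queen")
        assert w.w.diagonal().sum() == 0.0


class TestSpatialLag:
    def test_constant_field_lag_is_constant(self):
        w = contiguity_weights((4, 4), scheme="queen")
        lag = spatial_lag(np.full(16, 3.3), w)
        assert np.allclose(lag, 3.3)

    def test_two_by_two_hand_computed(self):
        """2x2 rook: every pixel has the two orthogonal neighbors."""
        w = contiguity_weights((2, 2), scheme="rook")
        lag = spatial_lag(np.array([1.0, 2.0, 3.0, 4.0]), w)
        # pixel (0,0): neighbors (0,1)=2 and (1,0)=3 -> 2.5, etc.
        assert np.allclose(lag, [2.5, 2.5, 2.5, 2.5])

    def test_isolated_pixel_lag_undefined(self):
        valid = np.ones((3, 3), dtype=bool)
        phase = np.full((3, 3), "LD", dtype=object)
        phase[1, 1] = "LO"
        w = contiguity_weights((3, 3), scheme="rook", phase=phase,
                               within_phase=True)
        lag = spatial_lag(np.arange(9.0), w)
        assert np.isnan(lag[4])


class TestMoransI:
    def test_checkerboard_is_exactly_minus_one(self):
        v = np.indices((8, 8)).sum(axis=0) % 2
        w = contiguity_weights((8, 8), scheme="rook")
        res = morans_I(v.ravel().astype(float), w, permutations=99, seed=0)
        assert res.i == -1.0

    @pytest.mark.parametrize("scheme", ["rook", "queen"])
    @pytest.mark.parametrize("shape", [(4, 4), (5, 6), (6, 6)])
    def test_equals_brute_force_oracle(self, scheme, shape, rng):
        v = rng.normal(size=shape).ravel()
        w = contiguity_weights(shape, scheme=scheme)
        res = morans_I(v, w, permutations=0)
        assert res.i == pytest.approx(
            brute_force_moran(v, w.w.toarray()), rel=1e-12)

    def test_permutation_mean_matches_expectation(self, rng):
        v = rng.normal(size=(8, 8)).ravel()
        w = contiguity_weights((8, 8), scheme="queen")
        res = morans_I(v, w, permutations=10000, seed=5)
        n = res.n
        assert res.perm_mean == pytest.approx(-1.0 / (n - 1), abs=4 * res.perm_sd / 100)

    def test_affine_invariance(self, rng):
        v = rng.normal(size=(6, 6)).ravel()
        w = contiguity_weights((6, 6), scheme="queen")
        r1 = morans_I(v, w, permutations=199, seed=1)
        r2 = morans_I(2.5 * v + 7.0, w, permutations=199, seed=1)
        assert r1.i == pytest.approx(r2.i, rel=1e-12)
        assert r1.p_value == r2.p_value

    def test_zero_variance_rejected(self):
        w = contiguity_weights((4, 4), scheme="rook")
        with pytest.raises(SpatialError, match="variance"):
            morans_I(np.ones(16), w, permutations=9)

    def test_too_few_pixels_rejected(self):
        w = contiguity_weights((3, 3), scheme="rook")
        with pytest.raises(SpatialError, match="non-isolated"):
            morans_I(np.arange(9.0), w)


class TestPerPhaseMoran:
    def test_single_phase_map_matches_whole_map(self, rng):
        d = np.abs(rng.normal(5e-12, 5e-13, (8, 8)))
        dmap = simple_map(d, phase=np.full((8, 8), "LD", dtype=object))
        res = per_phase_moran(dmap, permutations=99, seed=2)
        assert res["LD"].i == pytest.approx(res["all"].i, rel=1e-12)

    def test_correlated_field_detected(self):
        hits = 0
        for seed in range(20):
            bundle = generate_field(FieldSpec(shape=(32, 32), ell=20e-9, seed=seed))
            dmap = simple_map(bundle.d_true, bundle.height, bundle.phase)
            res = per_phase_moran(dmap, permutations=999, seed=seed)
            if res["all"].i > 0 and res["all"].p_value < 0.01:
                hits += 1
        assert hits >= 19

    def test_tiny_phase_skipped_with_warning(self, rng):
        d = np.abs(rng.normal(5e-12, 5e-13, (6, 6)))
        phase = np.full((6, 6), "LD", dtype=object)
        phase[0, 0] = "LO"
        dmap = simple_map(d, phase=phase)
        with pytest.warns(UserWarning, match="skipped"):
            res = per_phase_moran(dmap, permutations=49, seed=0)
        assert "LO" not in res

    def test_mean_i_nondecreasing_in_correlation_length(self):
        means = []
        for ell in (0.0, 10e-9, 20e-9, 40e-9):
            vals = []
            for seed in range(15):
                bundle = generate_field(FieldSpec(shape=(24, 24), ell=ell,
                                                  lo_fraction=0.0, seed=seed))
                w = contiguity_weights((24, 24), scheme="queen")
                vals.append(morans_I(bundle.d_true.ravel(), w, permutations=0).i)
            means.append(np.mean(vals))
        assert np.all(np.diff(means) > -0.02)


class TestSigmoidFit:
    @staticmethod
    def logistic(x, a, b, x0, w):
        return a + (b - a) / (1 + np.exp(-(x - x0) / w))

    def test_exact_samples_recovered(self):
        x = np.linspace(0, 150e-9, 30)
        y = self.logistic(x, 1e-12, 8e-12, 70e-9, 12e-9)
        fit = sigmoid_profile_fit(x, y)
        assert fit.lower == pytest.approx(1e-12, rel=1e-6)
        assert fit.upper == pytest.approx(8e-12, rel=1e-6)
        assert fit.midpoint == pytest.approx(70e-9, rel=1e-6)
        assert fit.width == pytest.approx(12e-9, rel=1e-6)

    def test_noisy_midpoint_within_two_stderr(self):
        """8 transect positions over 150 nm with a 20 nm-wide transition and
        10% per-point noise, as in lens-membrane line scans: the midpoint is
        covered by 2 se of the weighted fit in >=95% of seeds."""
        x = np.linspace(0, 150e-9, 8)
        y0 = self.logistic(x, 1e-12, 8e-12, 70e-9, 20e-9)
        hits, total = 0, 500
        for seed in range(total):
            rng = np.random.default_rng(seed)
            y = y0 * (1 + 0.1 * rng.normal(size=8))
            try:
                fit = sigmoid_profile_fit(x, y, sigma=0.1 * y0)
            except SpatialError:
                continue
            se = fit.stderr["midpoint"]
            if np.isfinite(se) and abs(fit.midpoint - 70e-9) <= 2 * se:
                hits += 1
        assert hits / total >= 0.95

    def test_constant_data_degenerate_warning(self):
        x = np.linspace(0, 1e-7, 10)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = sigmoid_profile_fit(x, np.full(10, 3e-12))
        assert fit.degenerate

    def test_too_few_points_rejected(self):
        with pytest.raises(SpatialError, match=">= 5"):
            sigmoid_profile_fit(np.arange(4.0), np.arange(4.0))
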