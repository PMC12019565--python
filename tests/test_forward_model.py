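"""Forward-model physics: normal/shear responses, curve synthesis, random
fields and maps, all validated against closed-form oracles or recovery."""

import numpy as np
import pytest

import nanorheo as nr
from nanorheo.forward_model import (
    ChannelNoise, FieldSpec, MembraneModel, RampSpec, gaussian_random_field,
    generate_curve, generate_field, generate_map, normal_response,
    shear_response, shear_velocity_rms,
)
from nanorheo.lockin import ShearDrive


class TestNormalResponse:
    def test_zero_at_contact_reference(self, model):
        assert normal_response(0.0, model) == 0.0
        assert normal_response(-1e-9, model) == 0.0

    def test_monotone_compression_pre_rupture(self, model):
        dh = np.linspace(0.1e-9, model.dh_rupture * 0.99, 50)
        f = normal_response(dh, model)
        assert np.all(np.diff(f) > 0)

    def test_rupture_jump_advances_remaining_thickness(self, drive):
        """At breakthrough the tip jumps forward by t_mem - dh_rupture."""
        model = MembraneModel(f_rup=1e-9)
        ramp = RampSpec()
        curve = generate_curve(model, drive, ramp)
        dh = curve.meta["truth"]["dh"]
        i_rup = curve.meta["truth"]["rupture_index"]
        jump = dh[i_rup] - dh[i_rup - 1]
        expected = model.t_mem - model.dh_rupture
        assert jump == pytest.approx(expected, rel=1e-2)
        # stiff substrate branch afterwards: indentation stays capped
        assert np.all(dh[i_rup:] == model.t_mem)


class TestShearResponse:
    def test_zero_velocity_means_no_force_and_undefined_phase(self, model):
        f_s, _, defined = shear_response(2e-9, 0.0, model)
        assert f_s == 0.0
        assert not defined

    def test_linear_in_velocity(self, model):
        f1, _, _ = shear_response(2e-9, 1e-4, model)
        f2, _, _ = shear_response(2e-9, 2e-4, model)
        assert f2 == pytest.approx(2 * f1, rel=1e-12)

    def test_lipid_branch_matches_algebraic_inversion(self):
        """F_S from D = 5.8 um^2/s at dh = 2 nm: one-line SI oracle."""
        model = MembraneModel(d_true=5.8e-12, r_tip=5e-9, a_lipid=0.70e-18,
                              temperature=298.0)
        drive = ShearDrive(f_s=25e3, a_s=5e-9)
        # independent oracle: F_S = kB*T*2*pi*R*dh*f*A/(sqrt(2)*A_lip*D)
        expected = (1.380649e-23 * 298.0 * 2 * np.pi * 5e-9 * 2e-9 * 25e3 * 5e-9
                    / (np.sqrt(2) * 0.70e-18 * 5.8e-12))
        f_s, _, _ = shear_response(2e-9, shear_velocity_rms(drive), model)
        assert f_s == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(5.6e-12, rel=0.02)  # ~5.6 pN

    def test_drag_continuous_across_hydration_boundary(self, model):
        eps = 1e-15
        lo, _, _ = shear_response(model.h_hyd - eps, 1e-4, model)
        hi, _, _ = shear_response(model.h_hyd + eps, 1e-4, model)
        assert lo == pytest.approx(hi, rel=1e-5)

    def test_phase_monotone_toward_viscous_asymptote(self, model):
        dh = np.linspace(0.1e-9, 4e-9, 40)
        _, theta, _ = shear_response(dh, 1e-4, model)
        assert np.all(np.diff(theta) > 0)
        assert theta[-1] < model.theta_inf


class TestGenerateCurve:
    def test_precontact_forces_are_zero_noiseless(self, model, drive, ramp):
        curve = generate_curve(model, drive, ramp)
        pre = curve.z < ramp.z_contact
        assert np.all(curve.f_n[pre] == 0)
        assert np.all(curve.f_s[pre] == 0)

    def test_seeded_determinism_bitwise(self, noisy_model, drive, ramp):
        c1 = generate_curve(noisy_model, drive, ramp)
        c2 = generate_curve(noisy_model, drive, ramp)
        assert c1.f_n.tobytes() == c2.f_n.tobytes()
        assert c1.f_s.tobytes() == c2.f_s.tobytes()
        assert c1.theta.tobytes() == c2.theta.tobytes()

    def test_ramp_never_reaching_contact_is_flagged(self, model, drive):
        ramp = RampSpec(z_start=0.0, z_end=10e-9, z_contact=20e-9)
        curve = generate_curve(model, drive, ramp)
        assert curve.meta["no_contact"]

    @pytest.mark.parametrize("d_true", [0.5e-12, 3e-12, 50e-12])
    def test_roundtrip_through_pipeline(self, drive, ramp, d_true):
        """Noiseless generated curve -> plateau D equals D_true to 1e-6."""
        model = MembraneModel(d_true=d_true)
        curve = generate_curve(model, drive, ramp)
        p = nr.process_curve(curve)
        assert p.d_plateau == pytest.approx(d_true, rel=1e-6)

    def test_raw_mode_returns_carrier_series(self, model, ramp):
        drive = ShearDrive(sample_rate=200e3, f_s=25e3)
        curve = generate_curve(model, drive, ramp, raw=True)
        assert curve.raw is not None
        assert curve.meta["raw_sample_rate"] == drive.sample_rate
        assert np.max(np.abs(curve.raw)) == pytest.approx(np.max(curve.f_s), rel=0.05)


class TestInvariants:
    def test_loglog_linearity_of_fs_vs_vs(self, model):
        """Slope 1 +/- 0.02 across the f_S x A_S grid at fixed dh."""
        fs_grid = np.array([1, 2, 5, 10, 25, 50]) * 1e3
        as_grid = np.array([1, 2, 3, 5, 7]) * 1e-9
        v, f = [], []
        for f_s in fs_grid:
            for a_s in as_grid:
                drive = ShearDrive(f_s=f_s, a_s=a_s)
                vs = shear_velocity_rms(drive)
                force, _, _ = shear_response(2e-9, vs, model)
                v.append(vs)
                f.append(force)
        slope = np.polyfit(np.log(v), np.log(f), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.02)

    def test_fs_decreasing_in_temperature_for_increasing_d(self, drive):
        """Arrhenius-fluid membrane: warmer -> faster lipids -> less drag."""
        temps = np.array([295.0, 300.0, 305.0, 310.0, 315.0])
        e_act = 35e3  # J/mol, typical lipid diffusion activation energy
        d_of_t = 5.8e-12 * np.exp(-e_act / 8.314 * (1 / temps - 1 / 298.0))
        forces = []
        for t, d_t in zip(temps, d_of_t):
            m = MembraneModel(d_true=float(d_t), temperature=float(t))
            f_s, _, _ = shear_response(2e-9, 1e-4, m)
            forces.append(f_s)
        assert np.all(np.diff(forces) < 0)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            MembraneModel(d_true=-1e-12)
        with pytest.raises(ValueError):
            MembraneModel(h_hyd=5e-9, t_mem=4e-9)
        with pytest.raises(ValueError):
            ChannelNoise(sigma_fn=-1.0)
        with pytest.raises(ValueError):
            RampSpec(z_start=10e-9, z_end=0.0)


class TestGaussianRandomField:
    def test_zero_length_gives_white_field(self):
        """lag-1 autocorrelation ~ 0 within Monte-Carlo error, 100 seeds."""
        acs = []
        for seed in range(100):
            g = gaussian_random_field((32, 32), 0.0, np.random.default_rng(seed))
            ac = np.mean(g[:, :-1] * g[:, 1:]) / np.var(g)
            acs.append(ac)
        assert abs(np.mean(acs)) < 3.0 / np.sqrt(100 * 31 * 32)

    def test_autocorrelation_matches_kernel_at_one_length(self):
        """ell = 4 px: empirical correlation at lag 4 ~ exp(-1/2), 100 seeds."""
        ell = 4.0
        num, den = 0.0, 0.0
        for seed in range(100):
            g = gaussian_random_field((32, 32), ell, np.random.default_rng(seed))
            num += np.mean(g[:, :-4] * g[:, 4:])
            den += np.mean(g * g)  # uncentered: the ensemble mean is 0 exactly
        assert num / den == pytest.approx(np.exp(-0.5), abs=0.03)

    def test_unit_variance(self):
        var = np.mean([
            np.var(gaussian_random_field((32, 32), 4.0, np.random.default_rng(s)))
            for s in range(50)
        ])
        assert var == pytest.approx(1.0, abs=0.1)


class TestGenerateField:
    def test_height_histogram_bimodal_with_stated_offset(self):
        spec = FieldSpec(shape=(48, 48), height_offset=1.0e-9, roughness=0.15e-9, seed=3)
        bundle = generate_field(spec)
        lo = bundle.height[bundle.phase == "LO"]
        ld = bundle.height[bundle.phase == "LD"]
        assert np.mean(lo) - np.mean(ld) == pytest.approx(1.0e-9, abs=0.1e-9)

    def test_phase_means_respected(self):
        spec = FieldSpec(shape=(64, 64), sd_rel=0.1, seed=5)
        bundle = generate_field(spec)
        d_lo = bundle.d_true[bundle.phase == "LO"].mean()
        d_ld = bundle.d_true[bundle.phase == "LD"].mean()
        assert d_ld > d_lo
        assert d_ld == pytest.approx(spec.d_mean_ld, rel=0.15)

    def test_truncation_warns_and_keeps_positive(self):
        spec = FieldSpec(shape=(16, 16), sd_rel=1.5, seed=0)
        with pytest.warns(UserWarning, match="truncated"):
            bundle = generate_field(spec)
        assert np.all(bundle.d_true > 0)

    def test_constant_field_flagged_degenerate(self):
        spec = FieldSpec(shape=(8, 8), sd_rel=0.0, lo_fraction=0.0,
                         roughness=0.0, seed=0)
        with pytest.warns(UserWarning, match="degenerate"):
            bundle = generate_field(spec)
        assert bundle.constant_field

    def test_explicit_phase_mask(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[:4] = True
        spec = FieldSpec(shape=(8, 8), phase_mask=mask, seed=0)
        bundle = generate_field(spec)
        assert np.all(bundle.phase[:4] == "LO")
        assert np.all(bundle.phase[4:] == "LD")


class TestGenerateMap:
    def test_per_pixel_curves_carry_local_d(self, model, drive):
        ramp = RampSpec(velocity=120e-9, sample_rate=6250.0)
        spec = FieldSpec(shape=(3, 3), seed=1)
        bundle = generate_map(spec, model, drive, ramp, curves=True)
        assert len(bundle.curves) == 9
        for curve, d_pix in zip(bundle.curves, bundle.d_true.ravel()):
            assert curve.meta["truth"]["d_true"] == pytest.approx(d_pix)

    def test_curves_false_skips_generation(self, model, drive, ramp):
        bundle = generate_map(FieldSpec(shape=(4, 4)), model, drive, ramp,
                              curves=False)
        assert bundle.curves is None
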