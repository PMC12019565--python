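"""Forward model of the AFM shear-spectroscopy measurement.

Synthesizes physically structured nano-rheology data — single approach
curves, velocity sweeps and force-map grids — with known ground truth, so
that every downstream analysis stage can be validated by recovery.

The measurement being emulated: a sharp tip (spherical apex, radius
``R_tip``) is pressed into a supported lipid bilayer while the sample is
sheared laterally at frequency ``f_S`` and amplitude ``A_S``.  The lateral
drag on the tip is linear in the shear velocity; in the lipid-dominated
regime the drag coefficient follows an Einstein / Evans-Sackmann law, so
that the local lipid diffusion coefficient can be read back from the
measured shear force.  At shallow indentation the tip shears the bound
hydration-water layer instead, whose drag is independent of the lipid
mobility.

Normal-force phenomenology on approach: zero force in the bulk, a
compressive membrane branch, a sudden rupture (breakthrough) event once a
threshold load is reached, and a stiff substrate branch with the tip pinned
on the support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ETA_WATER, K_B
from .lockin import ShearDrive

__all__ = [
    "ChannelNoise",
    "MembraneModel",
    "RampSpec",
    "FieldSpec",
    "MapBundle",
    "shear_velocity_rms",
    "contact_area",
    "normal_response",
    "shear_response",
    "generate_curve",
    "generate_field",
    "generate_map",
    "gaussian_random_field",
]


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelNoise:
    """Additive Gaussian noise amplitudes per measured channel (SI units).

    ``sigma_fs_rel`` adds noise proportional to the local shear force on top
    of the absolute floor ``sigma_fs``; phase noise is inflated where the
    shear force drops below 3x the absolute noise floor (the phase of a
    vanishing phasor is ill-determined).
    """

    sigma_fn: float = 0.0        # N, normal-force channel
    sigma_fs: float = 0.0        # N, shear-amplitude channel (absolute)
    sigma_fs_rel: float = 0.0    # dimensionless, relative shear noise
    sigma_theta: float = 0.0     # degrees
    sigma_defl: float = 0.0      # m, deflection-distance channel

    def __post_init__(self) -> None:
        for name in ("sigma_fn", "sigma_fs", "sigma_fs_rel", "sigma_theta", "sigma_defl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def is_zero(self) -> bool:
        return (
            self.sigma_fn == 0
            and self.sigma_fs == 0
            and self.sigma_fs_rel == 0
            and self.sigma_theta == 0
            and self.sigma_defl == 0
        )


@dataclass(frozen=True)
class MembraneModel:
    """Ground truth for a supported-membrane measurement site.

    Parameters
    ----------
    d_true : float
        Lipid diffusion coefficient under the tip (m^2/s).
    t_mem : float
        Membrane thickness (m); the tip advances by the remaining thickness
        at rupture.
    h_hyd : float
        Hydration-layer thickness (m); below this indentation the shear
        response is dominated by bound interfacial water.
    k_mem : float
        Membrane compression stiffness (N/m) of the pre-rupture branch.
    f_rup : float
        Rupture (breakthrough) force (N).
    a_lipid : float
        Mean area per lipid (m^2).
    r_tip : float
        Tip apex radius (m).
    k_flex : float
        Flexural stiffness of the cantilever (N/m), used to solve the
        quasistatic base-position/deflection balance.
    theta_inf, lambda_theta :
        Shear-phase saturation value (deg) and indentation decay length (m)
        of the empirical phase evolution theta(dh) = theta_inf*(1 - exp(-dh/lambda)).
    hyd_drag_scale : float
        Dimensionless drag enhancement of the hydration layer relative to a
        bulk-water Couette film of thickness ``h_hyd``.
    temperature : float
        Absolute temperature (K).
    noise : ChannelNoise
    seed : int
    """

    d_true: float = 5.8e-12
    t_mem: float = 4.5e-9
    h_hyd: float = 1.5e-9
    k_mem: float = 0.3
    f_rup: float = 1.0e-9
    a_lipid: float = 0.70e-18
    r_tip: float = 5.0e-9
    k_flex: float = 0.6
    theta_inf: float = 75.0
    lambda_theta: float = 1.0e-9
    hyd_drag_scale: float = 1000.0
    temperature: float = 298.0
    noise: ChannelNoise = field(default_factory=ChannelNoise)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_true <= 0:
            raise ValueError("d_true must be > 0")
        if not (0 < self.h_hyd < self.t_mem):
            raise ValueError("need 0 < h_hyd < t_mem")
        if self.f_rup <= 0:
            raise ValueError("f_rup must be > 0")
        if self.a_lipid <= 0:
            raise ValueError("a_lipid must be > 0")
        if self.r_tip <= 0 or self.k_mem <= 0 or self.k_flex <= 0:
            raise ValueError("r_tip, k_mem and k_flex must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def dh_rupture(self) -> float:
        """Indentation at which the breakthrough occurs (m)."""
        return self.f_rup / self.k_mem

    def with_(self, **kwargs) -> "MembraneModel":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RampSpec:
    """Approach-ramp geometry: tip-base positions with z increasing toward
    the sample surface."""

    z_start: float = 0.0          # m
    z_end: float = 30e-9          # m
    velocity: float = 30e-9       # m/s  (static-mode approach speed)
    sample_rate: float = 2000.0   # Hz
    z_contact: float = 20e-9      # m, true contact position

    def __post_init__(self) -> None:
        if self.z_end <= self.z_start:
            raise ValueError("z grid must be strictly monotone (z_end > z_start)")
        if self.velocity <= 0 or self.sample_rate <= 0:
            raise ValueError("velocity and sample_rate must be > 0")

    def z_grid(self) -> np.ndarray:
        n = max(2, int(round((self.z_end - self.z_start) / self.velocity * self.sample_rate)))
        return np.linspace(self.z_start, self.z_end, n)


# ---------------------------------------------------------------------------
# point-wise physics
# ---------------------------------------------------------------------------


def shear_velocity_rms(drive: ShearDrive) -> float:
    """RMS shear velocity of a sinusoidal drive: v_S = 2*pi*f_S*A_S/sqrt(2)."""
    return 2.0 * np.pi * drive.f_s * drive.a_s / np.sqrt(2.0)


def contact_area(dh, r_tip: float):
    """Tip-membrane contact area A = 2*pi*R_tip*dh for a spherical apex."""
    return 2.0 * np.pi * r_tip * np.asarray(dh, dtype=float)


def normal_response(dh, model: MembraneModel):
    """Quasistatic normal force as a function of tip indentation.

    Piecewise: zero out of contact, linear spring compression
    ``F_N = k_mem*dh`` up to the rupture force, then a hard-wall substrate
    branch once the membrane has broken through (the tip is pinned; any
    further base advance loads the substrate).  The function is evaluated
    against the *tip* indentation coordinate; the discontinuous jump of the
    tip at rupture is realized in :func:`generate_curve`, which solves the
    base-position force balance.
    """
    dh = np.asarray(dh, dtype=float)
    f = np.where(dh > 0, model.k_mem * dh, 0.0)
    return np.clip(f, 0.0, None) if f.ndim else float(max(f, 0.0))


def _drag_coefficient(dh, model: MembraneModel):
    """Shear drag zeta(dh) (N s/m against the RMS shear velocity).

    Lipid branch (dh >= h_hyd): exactly the Einstein / Evans-Sackmann drag,
    zeta = kB*T*R_tip*dh/(A_lipid*D), so that the diffusion-coefficient
    inversion is an identity.  Hydration branch: Couette-like film drag
    zeta_hyd = hyd_drag_scale * eta_w * A(dh)/h_hyd, independent of D.  The
    two are blended with a smooth weight w = (1 - dh/h_hyd)^2 over
    [0, h_hyd] so zeta is continuous and equals the lipid drag identically
    beyond the hydration layer.
    """
    dh = np.asarray(dh, dtype=float)
    dh_pos = np.clip(dh, 0.0, None)
    zeta_lip = (
        K_B * model.temperature * model.r_tip * dh_pos / (model.a_lipid * model.d_true)
    )
    zeta_hyd = (
        model.hyd_drag_scale * ETA_WATER * contact_area(dh_pos, model.r_tip) / model.h_hyd
    )
    w = np.clip(1.0 - dh_pos / model.h_hyd, 0.0, 1.0) ** 2
    return w * zeta_hyd + (1.0 - w) * zeta_lip


def shear_response(dh, v_s, model: MembraneModel):
    """Shear-force amplitude, phase and a defined-flag at indentation ``dh``.

    Parameters
    ----------
    dh : array_like
        Indentation (m), >= 0 relative to contact.
    v_s : float or array_like
        RMS shear velocity (m/s), >= 0.

    Returns
    -------
    f_s : ndarray or float
        Shear-force amplitude, ``zeta(dh) * v_s`` (N).
    theta : ndarray or float
        Shear phase (deg), saturating with indentation toward its viscous
        asymptote.
    defined : ndarray or bool
        False where the phase is physically undefined (no shear force above
        the configured noise floor).
    """
    dh = np.asarray(dh, dtype=float)
    v = np.asarray(v_s, dtype=float)
    if np.any(v < 0):
        raise ValueError("v_s must be >= 0")
    f_s = _drag_coefficient(dh, model) * v
    theta = model.theta_inf * (1.0 - np.exp(-np.clip(dh, 0.0, None) / model.lambda_theta))
    floor = 3.0 * (model.noise.sigma_fs if model.noise.sigma_fs > 0 else 0.0)
    defined = (f_s > floor) & (v > 0) & (dh > 0)
    if f_s.ndim == 0:
        return float(f_s), float(theta), bool(defined)
    return f_s, np.asarray(theta), defined


# ---------------------------------------------------------------------------
# curve synthesis
# ---------------------------------------------------------------------------


def _solve_quasistatic(zeta_base: np.ndarray, model: MembraneModel):
    """Solve the base-advance / deflection balance along the approach.

    ``zeta_base`` is the tip-base advance past the contact position.  On the
    membrane branch the cantilever spring and the membrane spring are in
    series: dh = k_flex*zb/(k_flex + k_mem).  Once the load reaches f_rup
    the membrane breaks; the tip jumps forward by the remaining thickness
    and is pinned on the substrate (hard wall): dh = t_mem, deflection
    zb - t_mem.

    Returns (dh, deflection, ruptured-mask).
    """
    kf, km = model.k_flex, model.k_mem
    dh = np.where(zeta_base > 0, kf * zeta_base / (kf + km), 0.0)
    f_n = km * np.clip(dh, 0.0, None)
    ruptured = f_n >= model.f_rup
    if ruptured.any():
        i0 = int(np.argmax(ruptured))
        ruptured[:] = False
        ruptured[i0:] = True
        dh = dh.copy()
        dh[ruptured] = model.t_mem
    defl = np.where(ruptured, np.clip(zeta_base - model.t_mem, 0.0, None), zeta_base - dh)
    return dh, np.clip(defl, 0.0, None), ruptured


def generate_curve(
    model: MembraneModel,
    drive: ShearDrive,
    ramp: RampSpec,
    rng: np.random.Generator | None = None,
    raw: bool = False,
):
    """Synthesize one approach force curve.

    Returns a :class:`nanorheo.pipeline.ForceCurve` carrying per-point z,
    normal force, shear-force amplitude and shear phase, plus metadata with
    everything the analysis pipeline needs (drive, tip radius, area per
    lipid, temperature, flexural stiffness) and, for validation, the
    ground-truth contact position and indentation.

    With ``raw=True`` the returned curve additionally carries a synthesized
    torsional-channel voltage-like time series (carrier at ``drive.f_s``
    with the per-point amplitude/phase), sampled at ``drive.sample_rate``,
    for exercising the lock-in demodulator.

    Bitwise reproducible for a fixed ``model.seed`` (or supplied ``rng``).
    """
    from .pipeline import ForceCurve  # local import to avoid a cycle

    if rng is None:
        rng = np.random.default_rng(model.seed)
    z = ramp.z_grid()
    zb = z - ramp.z_contact
    no_contact = bool(zb[-1] <= 0)
    dh, defl, ruptured = _solve_quasistatic(zb, model)
    f_n = model.k_flex * defl
    v_s = shear_velocity_rms(drive)
    f_s, theta, defined = shear_response(dh, v_s, model)
    f_s = np.asarray(f_s, dtype=float)
    theta = np.asarray(theta, dtype=float)

    noise = model.noise
    if not noise.is_zero:
        f_n = f_n + rng.normal(0.0, noise.sigma_fn, z.shape) if noise.sigma_fn else f_n
        sig = np.hypot(noise.sigma_fs, noise.sigma_fs_rel * f_s)
        if np.any(sig > 0):
            f_s = f_s + rng.normal(0.0, 1.0, z.shape) * sig
        if noise.sigma_theta:
            infl = np.where(f_s < 3.0 * max(noise.sigma_fs, 1e-30), 5.0, 1.0)
            theta = theta + rng.normal(0.0, 1.0, z.shape) * noise.sigma_theta * infl
        if noise.sigma_defl:
            defl_noise = rng.normal(0.0, noise.sigma_defl, z.shape)
            f_n = f_n + model.k_flex * defl_noise

    meta = {
        "drive": drive,
        "r_tip": model.r_tip,
        "a_lipid": model.a_lipid,
        "temperature": model.temperature,
        "k_flex": model.k_flex,
        "seed": model.seed,
        "no_contact": no_contact,
        "truth": {
            "z_contact": ramp.z_contact,
            "d_true": model.d_true,
            "dh": dh,
            "rupture_index": int(np.argmax(ruptured)) if ruptured.any() else None,
            "t_mem": model.t_mem,
        },
    }
    raw_series = None
    if raw:
        raw_series = _raw_torsional_series(f_s, theta, drive, rng)
        meta["raw_sample_rate"] = drive.sample_rate
    theta = np.where(defined, theta, np.nan)
    return ForceCurve(z=z, f_n=f_n, f_s=f_s, theta=theta, meta=meta, raw=raw_series)


def _raw_torsional_series(f_s, theta, drive: ShearDrive, rng) -> np.ndarray:
    """Carrier at f_S with piecewise per-point amplitude/phase (one carrier
    block per ramp sample), in force units; a lock-in recovers f_s/theta."""
    block = max(4, int(drive.sample_rate / 1000))
    n = block * len(f_s)
    t = np.arange(n) / drive.sample_rate
    amp = np.repeat(f_s, block)
    ph = np.deg2rad(np.repeat(np.nan_to_num(theta), block))
    return amp * np.sin(2.0 * np.pi * drive.f_s * t + ph)


# ---------------------------------------------------------------------------
# gridded fields and maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldSpec:
    """Two-phase membrane map geometry and diffusivity-field statistics.

    The diffusivity field is a squared-exponential Gaussian random field
    with correlation length ``ell`` (m), scaled per phase:
    D = mean_phase*(1 + sd_rel*g), truncated below at 5% of the phase mean.
    The liquid-ordered (L_O) phase sits ``height_offset`` higher in
    topography than the liquid-disordered (L_D) phase and is slower.
    """

    shape: tuple[int, int] = (32, 32)
    pixel_size: float = 5e-9          # m
    ell: float = 20e-9                # m, correlation length of the D field
    d_mean_ld: float = 5.8e-12        # m^2/s
    d_mean_lo: float = 2.0e-12        # m^2/s
    sd_rel: float = 0.2               # relative spread of D around the phase mean
    lo_fraction: float = 0.35         # areal fraction of the L_O phase
    domain_ell: float = 60e-9         # m, length scale of the phase geometry
    phase_mask: np.ndarray | None = None  # optional explicit L_O mask
    height_offset: float = 1.0e-9     # m, L_O above L_D
    roughness: float = 0.15e-9        # m, topographic roughness sigma
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ell < 0:
            raise ValueError("ell must be >= 0")
        if self.d_mean_ld <= 0 or self.d_mean_lo <= 0:
            raise ValueError("per-phase mean D must be > 0")
        if self.shape[0] < 2 or self.shape[1] < 2:
            raise ValueError("grid must be at least 2x2")


@dataclass
class MapBundle:
    """Ground truth (and optionally per-pixel curves) for a synthetic map."""

    d_true: np.ndarray          # (rows, cols) m^2/s
    height: np.ndarray          # (rows, cols) m
    phase: np.ndarray           # (rows, cols) str labels "LO"/"LD"
    pixel_size: float           # m
    curves: list | None = None  # row-major list of ForceCurve, if generated
    constant_field: bool = False


def gaussian_random_field(
    shape: tuple[int, int],
    ell_pixels: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance Gaussian random field with squared-exponential
    correlation C(r) = exp(-r^2 / (2*ell^2)), by circulant spectral synthesis.

    ``ell_pixels = 0`` degenerates to i.i.d. standard normals.
    """
    rows, cols = shape
    if ell_pixels <= 0:
        return rng.standard_normal(shape)
    # embed on a doubled torus so the kernel wraps smoothly
    m, n = 2 * rows, 2 * cols
    ky = np.minimum(np.arange(m), m - np.arange(m))
    kx = np.minimum(np.arange(n), n - np.arange(n))
    r2 = ky[:, None] ** 2 + kx[None, :] ** 2
    cov = np.exp(-r2 / (2.0 * ell_pixels**2))
    lam = np.clip(np.fft.fft2(cov).real, 0.0, None)
    # x = IFFT(sqrt(lam) * FFT(white)) has circulant covariance exactly `cov`
    # (FFT of i.i.d. N(0,1) noise has E|.|^2 = m*n, matching the 1/(m*n) of
    # the inverse transform); Hermitian symmetry makes x real.
    w = rng.standard_normal((m, n))
    x = np.fft.ifft2(np.sqrt(lam) * np.fft.fft2(w)).real
    return x[:rows, :cols]


def generate_field(spec: FieldSpec, rng: np.random.Generator | None = None) -> MapBundle:
    """Draw the ground-truth D field, height map and phase labels."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    ell_px = spec.ell / spec.pixel_size
    g = gaussian_random_field(spec.shape, ell_px, rng)

    if spec.phase_mask is not None:
        lo_mask = np.asarray(spec.phase_mask, dtype=bool)
        if lo_mask.shape != tuple(spec.shape):
            raise ValueError("phase_mask shape mismatch")
    elif spec.lo_fraction <= 0:
        lo_mask = np.zeros(spec.shape, dtype=bool)
    elif spec.lo_fraction >= 1:
        lo_mask = np.ones(spec.shape, dtype=bool)
    else:
        dom = gaussian_random_field(spec.shape, spec.domain_ell / spec.pixel_size, rng)
        thr = np.quantile(dom, 1.0 - spec.lo_fraction)
        lo_mask = dom > thr

    mean = np.where(lo_mask, spec.d_mean_lo, spec.d_mean_ld)
    d = mean * (1.0 + spec.sd_rel * g)
    floor = 0.05 * mean
    n_trunc = int(np.sum(d < floor))
    if n_trunc:
        warnings.warn(
            f"{n_trunc} diffusivity pixels truncated at 5% of the phase mean",
            stacklevel=2,
        )
    d = np.maximum(d, floor)

    height = np.where(lo_mask, spec.height_offset, 0.0)
    if spec.roughness > 0:
        height = height + rng.normal(0.0, spec.roughness, spec.shape)
    phase = np.where(lo_mask, "LO", "LD")
    constant = bool(np.ptp(d) == 0)
    if constant:
        warnings.warn("degenerate (constant) diffusivity field", stacklevel=2)
    return MapBundle(
        d_true=d, height=height, phase=phase, pixel_size=spec.pixel_size,
        constant_field=constant,
    )


def generate_map(
    field: FieldSpec,
    model: MembraneModel,
    drive: ShearDrive,
    ramp: RampSpec,
    curves: bool = True,
) -> MapBundle:
    """Generate a force-map grid: ground truth plus (optionally) a full
    approach curve per pixel, each with the pixel's local D_true."""
    rng = np.random.default_rng(field.seed)
    bundle = generate_field(field, rng)
    if curves:
        curve_list = []
        for d_pix in bundle.d_true.ravel():
            m = model.with_(d_true=float(d_pix))
            curve_list.append(generate_curve(m, drive, ramp, rng=rng))
        bundle.curves = curve_list
    return bundle
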