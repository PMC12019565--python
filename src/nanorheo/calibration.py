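"""Cantilever force calibration.

Converts raw photodiode signals to forces:

* **Torsional thermal calibration** — fit a simple-harmonic-oscillator
  (Lorentzian) line plus a white floor to the torsional thermal power
  spectral density, then convert the fitted ``(f_0, Q, P_DC)`` to the
  torsional optical sensitivity

      gamma_tors = h_tip * sqrt(2*kB*T / (pi * k_phi * f_0 * P_DC * Q)).

  ``P_DC`` is the zero-frequency plateau of the SHO line (the fit's DC
  amplitude parameter).  Evaluating the expression verbatim — including the
  ``h_tip`` prefactor — yields a sensitivity in metres of lateral tip
  displacement per volt; the force expression below is then dimensionally
  consistent with a lateral stiffness in N/m.

* **Lateral force** — with the lateral stiffness
  ``k_L = k_phi * L / ((L - dL) * h_tip^2)`` built from the torsional
  stiffness and the lever geometry,

      F_L = k_L * gamma_tors * dV_L.

* **Flexural sensitivity (invOLS)** — slope of deflection volts versus
  z-piezo extension in hard contact, inverted to m/V.

* **Equipartition stiffness** — k = kB*T / <x^2> with the mean-square
  thermal displacement integrated from the fitted SHO line; provided as the
  in-package route to a flexural (or, in air, torsional) stiffness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize, signal as sps

from .constants import K_B

__all__ = [
    "CantileverSpec",
    "ThermalSpectrum",
    "CalibrationError",
    "sho_psd",
    "fit_thermal_psd",
    "PsdFitResult",
    "torsional_sensitivity",
    "lateral_stiffness",
    "lateral_force",
    "fit_invols",
    "stiffness_equipartition",
]


class CalibrationError(RuntimeError):
    """Raised when a calibration fit fails or inputs are unusable."""


@dataclass
class CantileverSpec:
    """Geometric and mechanical calibration constants of one lever.

    Lengths in metres, stiffnesses in N/m (flexural, lateral) and
    N m/rad (torsional); ``gamma_tors`` in m/V, ``invols`` in m/V.
    """

    length: float = 7.0e-6        # L, cantilever length
    setback: float = 0.5e-6       # dL, tip setback from the free end
    h_tip: float = 2.5e-6         # tip height
    k_flex: float = 0.6           # N/m
    k_phi: float = 1.0e-9         # N m/rad
    gamma_tors: float | None = None   # m/V, set by calibration
    invols: float | None = None       # m/V, set by calibration
    temperature: float = 298.0
    _k_lat: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.setback < self.length):
            raise ValueError("need 0 <= setback < length")
        if self.h_tip <= 0:
            raise ValueError("h_tip must be > 0")

    @property
    def k_lat(self) -> float:
        """Lateral stiffness k_L (N/m), computed once and cached."""
        if self._k_lat is None:
            self._k_lat = lateral_stiffness(self)
        return self._k_lat


@dataclass(frozen=True)
class ThermalSpectrum:
    """Thermal power spectral density of one cantilever mode."""

    frequency: np.ndarray              # Hz, strictly increasing
    psd: np.ndarray                    # V^2/Hz (or m^2/Hz, rad^2/Hz)
    medium: Literal["air", "liquid"] = "liquid"
    n_averages: int = 100

    def __post_init__(self) -> None:
        f = np.asarray(self.frequency, dtype=float)
        p = np.asarray(self.psd, dtype=float)
        if f.shape != p.shape:
            raise ValueError("frequency and psd must be congruent")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("PSD must be >= 0")
        object.__setattr__(self, "frequency", f)
        object.__setattr__(self, "psd", p)


def sho_psd(f, f0: float, q: float, p_dc: float, white: float = 0.0):
    """Simple-harmonic-oscillator (Lorentzian) thermal PSD with white floor.

    P(f) = P_DC * f0^4 / ((f0^2 - f^2)^2 + (f*f0/Q)^2) + white;
    P(0) = P_DC + white, peak ~ P_DC*Q^2 near f0.
    """
    f = np.asarray(f, dtype=float)
    return p_dc * f0**4 / ((f0**2 - f**2) ** 2 + (f * f0 / q) ** 2) + white


@dataclass(frozen=True)
class PsdFitResult:
    f0: float
    q: float
    p_dc: float
    white_floor: float
    stderr: dict[str, float]

    def as_dict(self) -> dict[str, float]:
        return {"f0": self.f0, "q": self.q, "p_dc": self.p_dc, "white_floor": self.white_floor}


def fit_thermal_psd(
    spectrum: ThermalSpectrum,
    window: tuple[float, float] | None = None,
    prominence_factor: float = 3.0,
) -> PsdFitResult:
    """Least-squares SHO + white-floor fit to a thermal PSD.

    Parameters
    ----------
    window : (f_lo, f_hi), optional
        Frequency band containing exactly one resonance; defaults to the
        full grid.
    prominence_factor :
        Minimum peak prominence, in units of the median PSD, for a
        resonance to be considered detectable.

    Raises
    ------
    CalibrationError
        If no sufficiently prominent peak is found in the window, or the
        fit does not converge.
    """
    f, p = spectrum.frequency, spectrum.psd
    if window is not None:
        sel = (f >= window[0]) & (f <= window[1])
        if sel.sum() < 8:
            raise CalibrationError("fit window contains too few PSD points")
        f, p = f[sel], p[sel]
    baseline = float(np.median(p))
    peaks, props = sps.find_peaks(p, prominence=prominence_factor * max(baseline, 1e-300))
    if len(peaks) == 0:
        raise CalibrationError(
            "no detectable resonance peak in window "
            f"(prominence threshold {prominence_factor} x median PSD)"
        )
    ipk = peaks[np.argmax(props["prominences"])]
    f0_guess = float(f[ipk])
    peak = float(p[ipk])
    # half-power width -> Q guess
    above = p > (peak + baseline) / 2.0
    width = max(float(np.ptp(f[above])) if above.sum() > 1 else f0_guess / 10.0, f[1] - f[0])
    q_guess = max(f0_guess / width, 0.6)
    p_dc_guess = peak / q_guess**2
    # optimize dimensionless multipliers of the guess: the raw parameters
    # span ~16 orders of magnitude, which defeats the optimizer's step
    # control if fitted directly
    scale = np.array([f0_guess, q_guess, p_dc_guess,
                      max(baseline, 1e-3 * p_dc_guess)])

    # chi^2 (multiplicative) noise on an averaged periodogram has sd
    # proportional to the model value: weight by the model prediction.
    def residuals(u):
        f0, q, p_dc, white = np.abs(u) * scale
        model = sho_psd(f, f0, q, p_dc, white)
        return (p - model) / np.maximum(model, 1e-300)

    # bounds keep the resonance inside the window and the quality factor
    # physical: without them a needle-thin Lorentzian on a single noisy
    # sample is a spurious minimum of the relative-residual cost
    df = f[1] - f[0]
    q_max = max(10.0 * f0_guess / df, 10.0) / scale[1]
    lower = [f[0] / scale[0], 0.25 / scale[1], 1e-8, 0.0]
    upper = [f[-1] / scale[0], q_max, 1e8, 1e8]
    try:
        res = optimize.least_squares(
            residuals, [1.0, 1.0, 1.0, 1e-6], method="trf",
            bounds=(lower, upper), max_nfev=20000,
        )
    except Exception as exc:  # pragma: no cover - scipy internal failures
        raise CalibrationError(f"SHO PSD fit failed: {exc}") from exc
    if not res.success:
        raise CalibrationError(f"SHO PSD fit did not converge: {res.message}")
    f0, q, p_dc, white = np.abs(res.x) * scale
    if not (f[0] <= f0 <= f[-1]) or p_dc <= 0:
        raise CalibrationError(
            f"SHO PSD fit landed outside the window (f0={f0:.4g} Hz, p_dc={p_dc:.4g})"
        )
    # standard errors from the Jacobian at the solution
    try:
        _, s, vt = np.linalg.svd(res.jac, full_matrices=False)
        threshold = np.finfo(float).eps * max(res.jac.shape) * s[0]
        s = s[s > threshold]
        vt = vt[: s.size]
        cov = vt.T / s**2 @ vt
        dof = max(len(f) - 4, 1)
        cov *= 2.0 * res.cost / dof
        err = np.sqrt(np.abs(np.diag(cov))) * scale  # back to physical units
    except np.linalg.LinAlgError:  # pragma: no cover
        err = np.full(4, np.nan)
    stderr = dict(zip(("f0", "q", "p_dc", "white_floor"), map(float, err)))
    return PsdFitResult(float(f0), float(q), float(p_dc), float(white), stderr)


def torsional_sensitivity(
    spec: CantileverSpec, f0: float, p_dc: float, q: float
) -> float:
    """Torsional optical sensitivity from the thermal-spectrum fit,

        gamma_tors = h_tip * sqrt(2*kB*T / (pi * k_phi * f0 * P_DC * Q)),

    evaluated verbatim; with ``P_DC`` in V^2/Hz the result is in m/V.
    """
    for name, val in (("k_phi", spec.k_phi), ("f0", f0), ("p_dc", p_dc),
                      ("q", q), ("temperature", spec.temperature)):
        if val is None or val <= 0:
            raise ValueError(f"{name} must be positive, got {val!r}")
    return spec.h_tip * np.sqrt(
        2.0 * K_B * spec.temperature / (np.pi * spec.k_phi * f0 * p_dc * q)
    )


def lateral_stiffness(spec: CantileverSpec) -> float:
    """k_L = k_phi * L / ((L - dL) * h_tip^2) in N/m."""
    if spec.setback >= spec.length:
        raise ValueError("tip setback must be smaller than the lever length")
    return spec.k_phi * spec.length / ((spec.length - spec.setback) * spec.h_tip**2)


def lateral_force(dv_l, spec: CantileverSpec):
    """Lateral force on the tip from the lateral photodiode voltage,
    F_L = k_L * gamma_tors * dV_L (N).  ``dv_l`` may be an array."""
    if spec.gamma_tors is None:
        raise CalibrationError("gamma_tors is not calibrated on this CantileverSpec")
    k_l = spec.k_lat
    return k_l * spec.gamma_tors * np.asarray(dv_l, dtype=float)


def fit_invols(deflection_v, z, contact_slice: slice | None = None):
    """Flexural inverse optical lever sensitivity from a hard-contact fit.

    Ordinary least squares of deflection volts against z-piezo extension
    over the hard-contact branch; the slope (V/m) is inverted to m/V.

    Returns ``(invols, invols_stderr)``.

    Raises
    ------
    CalibrationError
        If the region has fewer than 10 points or a non-positive slope
        (wrong branch selected).
    """
    d = np.asarray(deflection_v, dtype=float)
    zz = np.asarray(z, dtype=float)
    if contact_slice is not None:
        d, zz = d[contact_slice], zz[contact_slice]
    if len(d) < 10:
        raise CalibrationError("hard-contact region shorter than 10 points")
    slope, intercept = np.polyfit(zz, d, 1)
    if slope <= 0:
        raise CalibrationError(
            f"non-positive deflection-vs-z slope ({slope:.4g} V/m): "
            "selected region is not the hard-contact branch"
        )
    resid = d - (slope * zz + intercept)
    dof = max(len(d) - 2, 1)
    s2 = float(resid @ resid) / dof
    sxx = float(np.sum((zz - zz.mean()) ** 2))
    slope_se = np.sqrt(s2 / sxx) if sxx > 0 else np.inf
    invols = 1.0 / slope
    return float(invols), float(slope_se / slope**2)


def stiffness_equipartition(f0: float, q: float, p_dc: float, temperature: float) -> float:
    """Stiffness from equipartition on the fitted SHO line.

    The mean-square thermal displacement of the SHO PSD is
    <x^2> = pi * f0 * Q * P_DC / 2 (one-sided), so
    k = kB*T / <x^2>.  Units follow the PSD: a displacement PSD in m^2/Hz
    gives N/m; an angular PSD in rad^2/Hz gives N m/rad.
    """
    if min(f0, q, p_dc, temperature) <= 0:
        raise ValueError("all equipartition inputs must be positive")
    msd = np.pi * f0 * q * p_dc / 2.0
    return K_B * temperature / msd
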