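"""Indentation-resolved analysis of calibrated shear-spectroscopy curves.

Takes one approach force curve — height ``z``, normal force ``F_N``, shear
force amplitude ``F_S`` and shear phase ``theta_S`` — and produces the
deflection-corrected indentation ``dh``, the per-point local diffusion
coefficient

    D = kB*T * (2*pi*R_tip*dh / A_lipid) * (f_S*A_S / (sqrt(2)*F_S)),

the viscoelastic shear (storage) and loss moduli, and a plateau estimate of
D over the indentation window where ``|dD/ddh|`` is minimal (robust
tip-membrane contact without significant deformation or rupture).

Masking policy: D is reported only where the shear force exceeds the
per-curve noise floor, the tip is indenting (dh > 0) and the membrane has
not ruptured; the shear phase is undefined wherever there is no shear force
to measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .constants import K_B

__all__ = [
    "ForceCurve",
    "ProcessedCurve",
    "PipelineError",
    "NoContactError",
    "zero_baseline",
    "detect_contact",
    "indentation",
    "detect_rupture",
    "noise_floor",
    "diffusion_profile",
    "select_plateau",
    "moduli",
    "aggregate_curves",
    "process_curve",
    "diffusion_coefficient",
]


class PipelineError(RuntimeError):
    """Raised when a curve cannot be processed."""


class NoContactError(PipelineError):
    """Raised when no tip-sample contact is found on the approach."""


@dataclass
class ForceCurve:
    """One approach curve with calibrated channels (SI units).

    ``theta`` is in degrees with NaN where undefined.  ``meta`` carries the
    measurement context: ``drive`` (ShearDrive), ``r_tip`` (m), ``a_lipid``
    (m^2), ``temperature`` (K) and ``k_flex`` (N/m), plus free-form
    provenance.  ``raw`` optionally holds the undemodulated torsional
    time series.
    """

    z: np.ndarray
    f_n: np.ndarray
    f_s: np.ndarray
    theta: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)
    raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.f_n = np.asarray(self.f_n, dtype=float)
        self.f_s = np.asarray(self.f_s, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        n = len(self.z)
        if not (len(self.f_n) == len(self.f_s) == len(self.theta) == n):
            raise ValueError("all channels must have the same length")

    def copy(self) -> "ForceCurve":
        return ForceCurve(
            z=self.z.copy(), f_n=self.f_n.copy(), f_s=self.f_s.copy(),
            theta=self.theta.copy(), meta=dict(self.meta),
            raw=None if self.raw is None else self.raw.copy(),
        )


@dataclass
class ProcessedCurve:
    """Analysis result for one curve (SI units; D in m^2/s)."""

    curve: ForceCurve
    z_contact: float
    contact_index: int
    rupture_index: int | None
    dh: np.ndarray
    d: np.ndarray                 # local diffusion coefficient, NaN where masked
    d_mask: np.ndarray            # True where D is defined
    g_storage: np.ndarray
    g_loss: np.ndarray
    noise_floor: float
    plateau: np.ndarray | None = None   # indices of the plateau window points
    d_plateau: float = float("nan")
    d_plateau_sd: float = float("nan")


# ---------------------------------------------------------------------------
# baseline / events
# ---------------------------------------------------------------------------


def zero_baseline(
    curve: ForceCurve, baseline_fraction: float = 0.2, detrend: bool = False
) -> ForceCurve:
    """Remove the far-field force reference (F_N = F_S = 0 in the bulk).

    Subtracts the median of the first ``baseline_fraction`` of the approach
    from both force channels; with ``detrend=True`` a linear fit to the
    baseline segment of ``F_N`` is removed instead (hydrodynamic drift).
    Idempotent on already-zeroed noiseless curves.
    """
    n = len(curve.z)
    nb = int(np.floor(n * baseline_fraction))
    if nb < 2:
        raise PipelineError(
            f"no usable pre-contact segment ({nb} points at fraction {baseline_fraction})"
        )
    out = curve.copy()
    if detrend:
        coef = np.polyfit(curve.z[:nb], curve.f_n[:nb], 1)
        out.f_n = curve.f_n - np.polyval(coef, curve.z)
    else:
        out.f_n = curve.f_n - np.median(curve.f_n[:nb])
    out.f_s = curve.f_s - np.median(curve.f_s[:nb])
    out.meta["baseline_points"] = nb
    return out


def detect_contact(
    curve: ForceCurve,
    k_sigma: float = 3.0,
    sustain: int = 5,
    baseline_fraction: float = 0.2,
) -> tuple[float, int]:
    """Locate the contact point on a zeroed approach curve.

    Scans from the bulk side for the first excursion of ``F_N`` above
    ``k_sigma`` times the baseline noise that is sustained for ``sustain``
    samples, then refines ``z_c`` by intersecting a local linear fit of the
    rising flank with zero force.

    Returns ``(z_contact, contact_index)`` where ``contact_index`` is the
    first sample at or past contact.
    """
    n = len(curve.z)
    nb = int(np.floor(n * baseline_fraction))
    sigma = float(np.std(curve.f_n[:nb])) if nb >= 2 else 0.0
    thresh = k_sigma * sigma if sigma > 0 else max(1e-15, k_sigma * 1e-15)
    above = curve.f_n > thresh
    # sustained crossing: `sustain` consecutive samples above threshold
    idx = None
    run = 0
    for i in range(n):
        run = run + 1 if above[i] else 0
        if run >= sustain:
            idx = i - sustain + 1
            break
    if idx is None:
        raise NoContactError("no sustained force excursion above the noise threshold")
    # refine: fit the rising flank past the crossing and intersect zero force.
    # The flank extends until the force has grown well clear of the noise
    # (10x threshold), so the intercept is averaged over many samples.
    lo = idx
    past = np.flatnonzero(curve.f_n[lo:] > 10.0 * thresh)
    hi = lo + (int(past[0]) + 1 if len(past) else max(sustain, 8))
    hi = min(max(hi, lo + max(sustain, 8)), n)
    if hi - lo >= 3:
        slope, intercept = np.polyfit(curve.z[lo:hi], curve.f_n[lo:hi], 1)
        if slope > 0:
            z_c = -intercept / slope
            # keep the refinement inside a sane window around the crossing
            if curve.z[max(lo - 4 * sustain, 0)] <= z_c <= curve.z[hi - 1]:
                i_c = int(np.searchsorted(curve.z, z_c))
                return float(z_c), min(i_c, n - 1)
    return float(curve.z[idx]), idx


def indentation(
    curve: ForceCurve, z_c: float, t_mem: float | None = None
) -> np.ndarray:
    """Deflection-corrected indentation dh = (z - z_c) - F_N/k_flex.

    Clipped at zero before contact; optionally capped at the membrane
    thickness ``t_mem`` (the tip cannot indent past the substrate).
    """
    k_flex = curve.meta.get("k_flex")
    if k_flex is None or k_flex <= 0:
        raise PipelineError("k_flex missing from curve metadata")
    dh = (curve.z - z_c) - curve.f_n / k_flex
    dh = np.clip(dh, 0.0, None)
    if t_mem is not None:
        dh = np.minimum(dh, t_mem)
    return dh


def detect_rupture(
    curve: ForceCurve,
    dh: np.ndarray,
    jump_threshold: float = 1.0e-9,
    min_load: float = 100e-12,
    half_window: int = 5,
) -> int | None:
    """Find the membrane breakthrough event, if any.

    The rupture is the largest discontinuity in tip-sample separation
    (equivalently in ``dh``) exceeding ``jump_threshold`` while the normal
    force immediately before the jump exceeds ``min_load``.  The jump is
    measured between medians of ``half_window`` samples on either side, so
    single-sample noise cannot fake a breakthrough.  Returns the index of
    the first post-rupture sample, or None.
    """
    n = len(dh)
    if n < 2 * half_window + 2:
        return None
    # rolling medians on either side of each candidate boundary
    win = np.lib.stride_tricks.sliding_window_view(dh, half_window)
    med = np.median(win, axis=1)                  # med[i] = median(dh[i:i+hw])
    med_before = med[: n - 2 * half_window + 1]   # window ending at boundary
    med_after = med[half_window:]                 # window starting at boundary
    jumps = med_after - med_before                # boundary index = i + hw
    order = np.argsort(jumps)[::-1]
    for j in order:
        if jumps[j] < jump_threshold:
            return None
        boundary = j + half_window
        pre = curve.f_n[max(boundary - half_window, 0):boundary + 1]
        if pre.size == 0 or pre.max() < min_load:
            continue
        # refine to the largest single-sample step near the boundary
        lo = max(boundary - half_window, 1)
        hi = min(boundary + half_window, n - 1)
        step = np.diff(dh[lo - 1:hi + 1])
        return int(lo + np.argmax(step))
    return None


def noise_floor(curve: ForceCurve, multiplier: float = 3.0,
                baseline_fraction: float = 0.2) -> float:
    """Per-curve shear noise floor: ``multiplier`` x the baseline F_S sd."""
    nb = int(np.floor(len(curve.z) * baseline_fraction))
    if nb < 2:
        return 0.0
    return multiplier * float(np.std(curve.f_s[:nb]))


# ---------------------------------------------------------------------------
# diffusion and moduli
# ---------------------------------------------------------------------------


def diffusion_coefficient(dh, f_s, r_tip, a_lipid, temperature, f_drive, a_drive):
    """Local diffusion coefficient (m^2/s),

        D = kB*T * (2*pi*R_tip*dh / A_lipid) * (f_S*A_S / (sqrt(2)*F_S)),

    evaluated elementwise with no masking (callers guard F_S > 0)."""
    dh = np.asarray(dh, dtype=float)
    f_s = np.asarray(f_s, dtype=float)
    return (
        K_B * temperature
        * (2.0 * np.pi * r_tip * dh / a_lipid)
        * (f_drive * a_drive / (np.sqrt(2.0) * f_s))
    )


def diffusion_profile(
    curve: ForceCurve,
    dh: np.ndarray,
    floor: float,
    rupture_index: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point D(dh) with validity mask.

    Masked (NaN) where F_S is at or below the noise floor, where the tip is
    not indenting, and at/after rupture.
    """
    drive = curve.meta.get("drive")
    r_tip = curve.meta.get("r_tip")
    a_lipid = curve.meta.get("a_lipid")
    temperature = curve.meta.get("temperature")
    if drive is None or r_tip is None or a_lipid is None or temperature is None:
        missing = [k for k in ("drive", "r_tip", "a_lipid", "temperature")
                   if curve.meta.get(k) is None]
        raise PipelineError(f"curve metadata missing {missing} for Eq.-of-motion inversion")
    mask = (curve.f_s > max(floor, 0.0)) & (dh > 0)
    if rupture_index is not None:
        mask[rupture_index:] = False
    d = np.full_like(dh, np.nan)
    d[mask] = diffusion_coefficient(
        dh[mask], curve.f_s[mask], r_tip, a_lipid, temperature, drive.f_s, drive.a_s
    )
    return d, mask


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    width = max(1, min(width, 5) | 1)  # odd, <= 5
    if width == 1 or len(x) < width:
        return x
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def select_plateau(
    dh: np.ndarray,
    d: np.ndarray,
    mask: np.ndarray,
    window_width: float = 1.0e-9,
    smooth_points: int = 3,
) -> tuple[slice, float, float]:
    """Choose the plateau window of the D(dh) profile.

    Slides a window of ``window_width`` metres of indentation over the
    valid region (points ordered by indentation) and picks the one
    minimizing the window-mean |dD/ddh|, estimated as the least-squares
    slope of the lightly smoothed profile within the window — an average of
    the local central differences that stays finite when measurement noise
    on the deflection locally scrambles the dh ordering.  Ties are broken
    toward the deepest indentation — the plateau follows the
    hydration-layer crossover, it does not precede it.

    Returns ``(index_array_of_window_points, d_plateau, sd)`` where the
    indices refer to the original arrays.
    """
    valid = np.flatnonzero(mask & np.isfinite(d))
    if len(valid) < 5:
        raise PipelineError(
            f"only {len(valid)} valid D points; need >= 5 for plateau selection"
        )
    order = np.argsort(dh[valid], kind="stable")
    valid = valid[order]
    x = dh[valid]
    y = _smooth(d[valid], smooth_points)
    spacing = float(np.median(np.diff(x))) if len(x) > 1 else window_width
    w_pts = max(3, int(round(window_width / max(spacing, 1e-15))))
    w_pts = min(w_pts, len(valid))
    # windowed OLS slope via cumulative sums: O(n) over all windows
    cx, cy = np.concatenate(([0.0], np.cumsum(x))), np.concatenate(([0.0], np.cumsum(y)))
    cxx = np.concatenate(([0.0], np.cumsum(x * x)))
    cxy = np.concatenate(([0.0], np.cumsum(x * y)))
    i0 = np.arange(len(x) - w_pts + 1)
    i1 = i0 + w_pts
    sx, sy = cx[i1] - cx[i0], cy[i1] - cy[i0]
    sxx, sxy = cxx[i1] - cxx[i0], cxy[i1] - cxy[i0]
    denom = w_pts * sxx - sx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.where(denom > 0, (w_pts * sxy - sx * sy) / denom, np.inf)
    scores = np.abs(slopes)
    best = float(np.min(scores))
    tol = best * 1e-9 + 1e-30
    start = int(np.flatnonzero(scores <= best + tol)[-1])  # deepest tie
    sel = valid[start:start + w_pts]
    d_win = d[sel]
    return sel, float(np.mean(d_win)), float(np.std(d_win))


def moduli(
    f_s: np.ndarray,
    theta_deg: np.ndarray,
    dh: np.ndarray,
    a_drive: float,
    r_tip: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Shear storage and loss moduli (Pa) from amplitude and phase.

    Stress over the cylindrical contact band sigma = F_S/(2*pi*R_tip*dh),
    strain gamma = A_S/dh; G' = (sigma/gamma)*cos(theta),
    G'' = (sigma/gamma)*sin(theta).  Masked (NaN) where dh <= 0 or the
    phase is undefined.
    """
    dh = np.asarray(dh, dtype=float)
    f_s = np.asarray(f_s, dtype=float)
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = f_s / (2.0 * np.pi * r_tip * dh) / (a_drive / dh)
        g1 = ratio * np.cos(th)
        g2 = ratio * np.sin(th)
    bad = ~(dh > 0) | ~np.isfinite(th)
    g1 = np.where(bad, np.nan, g1)
    g2 = np.where(bad, np.nan, g2)
    return g1, g2


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def process_curve(
    curve: ForceCurve,
    baseline_fraction: float = 0.2,
    k_sigma: float = 3.0,
    noise_multiplier: float = 3.0,
    plateau_width: float = 1.0e-9,
    jump_threshold: float = 1.0e-9,
    t_mem: float | None = None,
    detrend: bool = False,
) -> ProcessedCurve:
    """Full single-curve pipeline: baseline, contact, indentation, rupture,
    D(dh), plateau selection and moduli."""
    zc_curve = zero_baseline(curve, baseline_fraction, detrend=detrend)
    z_c, i_c = detect_contact(zc_curve, k_sigma=k_sigma,
                              baseline_fraction=baseline_fraction)
    dh = indentation(zc_curve, z_c, t_mem=t_mem)
    rupture = detect_rupture(zc_curve, dh, jump_threshold=jump_threshold)
    floor = noise_floor(zc_curve, multiplier=noise_multiplier,
                        baseline_fraction=baseline_fraction)
    d, mask = diffusion_profile(zc_curve, dh, floor, rupture_index=rupture)
    drive = zc_curve.meta["drive"]
    g1, g2 = moduli(zc_curve.f_s, zc_curve.theta, dh, drive.a_s, zc_curve.meta["r_tip"])
    out = ProcessedCurve(
        curve=zc_curve, z_contact=z_c, contact_index=i_c, rupture_index=rupture,
        dh=dh, d=d, d_mask=mask, g_storage=g1, g_loss=g2, noise_floor=floor,
    )
    try:
        window, d_pl, d_sd = select_plateau(dh, d, mask, window_width=plateau_width)
        out.plateau, out.d_plateau, out.d_plateau_sd = window, d_pl, d_sd
    except PipelineError:
        warnings.warn("plateau selection failed: too few valid D points", stacklevel=2)
    return out


def aggregate_curves(
    processed: list[ProcessedCurve], n_grid: int = 200
) -> dict[str, np.ndarray]:
    """Mean +/- sd profiles of a set of processed curves on a common dh grid.

    Interpolates each curve's F_N, F_S and D onto a shared indentation grid
    spanning the intersection...union of supports; returns pointwise mean,
    sd and per-point curve count (points outside a curve's support do not
    contribute).
    """
    if len(processed) < 2:
        raise PipelineError("need at least 2 curves to aggregate")
    los, his = [], []
    for p in processed:
        valid = np.flatnonzero(p.d_mask)
        if len(valid) == 0:
            continue
        los.append(p.dh[valid[0]])
        his.append(p.dh[valid[-1]])
    if not los or max(los) >= min(his):
        raise PipelineError("curves have disjoint indentation supports")
    grid = np.linspace(max(los), min(his), n_grid)
    stacks = {"f_n": [], "f_s": [], "d": []}
    for p in processed:
        sel = p.d_mask & np.isfinite(p.d)
        order = np.argsort(p.dh[sel])
        x = p.dh[sel][order]
        stacks["f_n"].append(np.interp(grid, x, p.curve.f_n[sel][order]))
        stacks["f_s"].append(np.interp(grid, x, p.curve.f_s[sel][order]))
        stacks["d"].append(np.interp(grid, x, p.d[sel][order]))
    out: dict[str, np.ndarray] = {"dh": grid, "n": np.full(n_grid, len(stacks["d"]))}
    for key, arrs in stacks.items():
        a = np.vstack(arrs)
        out[f"{key}_mean"] = a.mean(axis=0)
        out[f"{key}_sd"] = a.std(axis=0)
    return out
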