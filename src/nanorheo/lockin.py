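"""Digital lock-in amplifier.

Demodulates the amplitude and phase of a reference-frequency component from
a raw time series: in-phase/quadrature mixing against the reference
followed by a cascade of identical first-order exponential low-pass stages
with time constant ``tau`` (order 4 by default, matching common lock-in
hardware roll-off settings).

Conventions
-----------
* The reference is ``sin(2*pi*f_s*t)`` with ``t = n/sample_rate`` starting
  at the first sample.
* Amplitude is reported as the *peak* sinusoid amplitude, not RMS, because
  the shear drive amplitude it calibrates against is a displacement
  amplitude.
* Phase is reported relative to the reference, wrapped to (-180, 180]
  degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "ShearDrive",
    "demodulate",
    "steady_state",
    "lowpass_gain",
    "equivalent_noise_bandwidth",
    "TAU_FAST",
    "TAU_SLOW",
]

#: Lock-in time constant used at shear frequencies >= 25 kHz (s)
TAU_FAST = 199.8e-6
#: Lock-in time constant used at a 1 kHz shear frequency (s)
TAU_SLOW = 1.973e-3


@dataclass(frozen=True)
class ShearDrive:
    """Shear excitation and demodulation settings.

    f_s : shear frequency (Hz); a_s : shear displacement amplitude (m);
    tau : lock-in time constant (s); filter_order : number of cascaded
    first-order low-pass stages; sample_rate : digitizer rate (Hz).
    """

    f_s: float = 25e3
    a_s: float = 5e-9
    tau: float = TAU_FAST
    filter_order: int = 4
    sample_rate: float = 1e6

    def __post_init__(self) -> None:
        if not (0 < self.f_s < self.sample_rate / 2):
            raise ValueError("need 0 < f_s < sample_rate/2 (Nyquist)")
        if self.a_s <= 0:
            raise ValueError("a_s must be > 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")

    @property
    def settle_time(self) -> float:
        """Default settling window: 10 time constants per filter stage."""
        return 10.0 * self.tau * self.filter_order


def _stage_pole(tau: float, sample_rate: float) -> float:
    return float(np.exp(-1.0 / (tau * sample_rate)))


def _cascaded_lowpass(x: np.ndarray, tau: float, sample_rate: float, order: int) -> np.ndarray:
    a = _stage_pole(tau, sample_rate)
    b, den = [1.0 - a], [1.0, -a]
    for _ in range(order):
        x = sps.lfilter(b, den, x)
    return x


def lowpass_gain(f_offset, tau: float, sample_rate: float, order: int = 4):
    """Magnitude of the cascaded low-pass transfer function at a frequency
    offset from the reference (exact discrete-time expression)."""
    a = _stage_pole(tau, sample_rate)
    w = 2.0 * np.pi * np.asarray(f_offset, dtype=float) / sample_rate
    h1 = (1.0 - a) / np.abs(1.0 - a * np.exp(-1j * w))
    return h1**order


def equivalent_noise_bandwidth(tau: float, sample_rate: float, order: int = 4) -> float:
    """One-sided equivalent noise bandwidth (Hz) of the cascade,
    ENBW = integral |H(f)|^2 df over [0, Nyquist]."""
    f = np.linspace(0.0, sample_rate / 2.0, 200001)
    h = lowpass_gain(f, tau, sample_rate, order)
    return float(np.trapezoid(h**2, f))


def _iq(x: np.ndarray, drive: ShearDrive):
    """Mixed-and-filtered in-phase / quadrature components."""
    if drive.f_s >= drive.sample_rate / 2:
        raise ValueError("reference frequency above Nyquist")
    if drive.tau * drive.sample_rate < 5:
        warnings.warn("tau*sample_rate < 5: low-pass filter barely resolved", stacklevel=2)
    t = np.arange(len(x)) / drive.sample_rate
    ref_i = np.sin(2.0 * np.pi * drive.f_s * t)
    ref_q = np.cos(2.0 * np.pi * drive.f_s * t)
    xi = _cascaded_lowpass(2.0 * x * ref_i, drive.tau, drive.sample_rate, drive.filter_order)
    xq = _cascaded_lowpass(2.0 * x * ref_q, drive.tau, drive.sample_rate, drive.filter_order)
    return xi, xq


def demodulate(x, drive: ShearDrive):
    """Demodulate amplitude and phase time series at ``drive.f_s``.

    Returns ``(amplitude, phase_deg)`` arrays of the same length as ``x``.
    The first ~``drive.settle_time`` seconds are filter transient.
    """
    x = np.asarray(x, dtype=float)
    xi, xq = _iq(x, drive)
    amp = np.hypot(xi, xq)
    phase = np.degrees(np.arctan2(xq, xi))
    # wrap to (-180, 180]
    phase = np.where(phase <= -180.0, phase + 360.0, phase)
    return amp, phase


def steady_state(x, drive: ShearDrive, settle: float | None = None):
    """Settled amplitude and phase of a stationary input.

    Averages the demodulated output over the tail after the settling window
    (default ``drive.settle_time``).  Returns
    ``(amplitude, phase_deg, amp_sd, phase_sd)``; the phase is NaN
    (undefined) when the settled amplitude is consistent with zero.
    """
    x = np.asarray(x, dtype=float)
    if settle is None:
        settle = drive.settle_time
    n_settle = int(np.ceil(settle * drive.sample_rate))
    if len(x) <= n_settle + 1:
        raise ValueError(
            f"signal duration {len(x)/drive.sample_rate:.4g} s does not exceed "
            f"the settle window {settle:.4g} s"
        )
    xi, xq = _iq(x, drive)
    zi, zq = xi[n_settle:], xq[n_settle:]
    a_tail = np.hypot(zi, zq)
    a_mean = float(np.mean(a_tail))
    a_sd = float(np.std(a_tail))
    if a_mean <= 3.0 * a_sd or a_mean == 0.0:
        return a_mean, float("nan"), a_sd, float("nan")
    ph = np.degrees(np.arctan2(np.mean(zq), np.mean(zi)))
    if ph <= -180.0:
        ph += 360.0
    ph_sd = float(np.degrees(np.std(np.arctan2(zq, zi) - np.deg2rad(ph))))
    return a_mean, float(ph), a_sd, ph_sd
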