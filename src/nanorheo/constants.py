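"""Physical constants and unit helpers (SI internally; pretty units at the edges)."""

from __future__ import annotations

#: Boltzmann constant (J/K)
K_B = 1.380649e-23

#: Dynamic viscosity of bulk water at ~25 degC (Pa s)
ETA_WATER = 0.89e-3

# -- presentation-boundary converters (SI <-> reporting units) --------------


def m2s_to_um2s(d: float) -> float:
    """Diffusion coefficient m^2/s -> um^2/s."""
    return d * 1e12


def um2s_to_m2s(d: float) -> float:
    """Diffusion coefficient um^2/s -> m^2/s."""
    return d * 1e-12


def n_to_pn(f: float) -> float:
    """Force N -> pN."""
    return f * 1e12


def pn_to_n(f: float) -> float:
    """Force pN -> N."""
    return f * 1e-12


def m_to_nm(x: float) -> float:
    return x * 1e9


def nm_to_m(x: float) -> float:
    return x * 1e-9
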