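"""Nucleus kinds, spectrometer base frequencies and ppm/Hz conversion.

The package works at a fixed (virtual) field corresponding to a 600 MHz
spectrometer: 599.6 MHz for 1H, 150.8 MHz for 13C and 60.8 MHz for 15N.
Chemical-shift coordinates are carried in ppm; time-domain simulation and
Fourier processing work in Hz offsets from a per-dimension carrier.
"""

from __future__ import annotations

# Shift-table nucleus kinds (per residue)
SHIFT_KINDS = ("HN", "N", "CO", "CA", "CB", "HA", "HB")

# element class of each shift kind, used for tolerances and base frequencies
KIND_CLASS = {
    "HN": "H",
    "HA": "H",
    "HB": "H",
    "N": "N",
    "CO": "C",
    "CA": "C",
    "CB": "C",
}

# base (Larmor) frequencies in MHz
BASE_MHZ = {"H": 599.6, "C": 150.8, "N": 60.8}

#: default chemical-shift matching tolerances in ppm, per element class
DEFAULT_TOLERANCES_PPM = {"C": 0.05, "N": 0.1, "H": 0.01}


def ppm_to_hz(ppm: float, carrier_ppm: float, element: str) -> float:
    """Offset in Hz of a resonance at ``ppm`` from a carrier, for an element class."""
    return (ppm - carrier_ppm) * BASE_MHZ[element]


def hz_to_ppm(hz: float, carrier_ppm: float, element: str) -> float:
    """Inverse of :func:`ppm_to_hz`."""
    return carrier_ppm + hz / BASE_MHZ[element]


def tolerance_for(kind_or_class: str, tolerances: dict | None = None) -> float:
    """Matching tolerance (ppm) for a shift kind ('CO', 'HN', ...) or class ('C', ...)."""
    tol = dict(DEFAULT_TOLERANCES_PPM)
    if tolerances:
        tol.update(tolerances)
    cls = KIND_CLASS.get(kind_or_class, kind_or_class)
    return tol[cls]
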