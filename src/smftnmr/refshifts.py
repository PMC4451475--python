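"""Random-coil reference chemical shifts for the twenty amino acids.

The values are typical random-coil compilations (ppm) for the seven backbone /
near-backbone nuclei handled by the pipeline: HN, N, CO, CA, CB, HA, HB.
Prolines have no amide proton; glycines have no CB and (here) a single HA
entry standing for their two alpha protons.  Standard deviations express the
spread that unstructured polypeptides show around the random-coil mean; they
are used both to bound the synthetic shift draw (+-4 SD) and for
amino-acid-type recognition (default +-3 SD).
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# per-kind standard deviations (ppm)
REFERENCE_SD = {
    "CA": 0.8,
    "CB": 0.9,
    "CO": 0.7,
    "N": 2.0,
    "HN": 0.25,
    "HA": 0.15,
    "HB": 0.20,
}

# random-coil means, ppm: aa -> {kind: mean}; missing key = nucleus absent
REFERENCE_MEANS = {
    "A": {"CA": 52.5, "CB": 19.1, "CO": 177.8, "N": 123.8, "HN": 8.24, "HA": 4.32, "HB": 1.39},
    "R": {"CA": 56.0, "CB": 30.9, "CO": 176.3, "N": 120.5, "HN": 8.23, "HA": 4.34, "HB": 1.79},
    "N": {"CA": 53.1, "CB": 38.9, "CO": 175.2, "N": 118.7, "HN": 8.40, "HA": 4.74, "HB": 2.83},
    "D": {"CA": 54.2, "CB": 41.1, "CO": 176.3, "N": 120.4, "HN": 8.34, "HA": 4.64, "HB": 2.72},
    "C": {"CA": 58.2, "CB": 28.0, "CO": 174.6, "N": 118.8, "HN": 8.32, "HA": 4.55, "HB": 2.93},
    "Q": {"CA": 55.7, "CB": 29.4, "CO": 176.0, "N": 119.8, "HN": 8.32, "HA": 4.34, "HB": 2.08},
    "E": {"CA": 56.6, "CB": 29.9, "CO": 176.6, "N": 120.2, "HN": 8.42, "HA": 4.35, "HB": 2.01},
    "G": {"CA": 45.1, "CO": 174.9, "N": 108.8, "HN": 8.33, "HA": 3.96},
    "H": {"CA": 55.0, "CB": 29.0, "CO": 174.1, "N": 118.2, "HN": 8.42, "HA": 4.73, "HB": 3.18},
    "I": {"CA": 61.1, "CB": 38.8, "CO": 176.4, "N": 119.9, "HN": 8.00, "HA": 4.17, "HB": 1.87},
    "L": {"CA": 55.1, "CB": 42.4, "CO": 177.6, "N": 121.8, "HN": 8.16, "HA": 4.32, "HB": 1.62},
    "K": {"CA": 56.2, "CB": 33.1, "CO": 176.6, "N": 120.4, "HN": 8.29, "HA": 4.32, "HB": 1.81},
    "M": {"CA": 55.4, "CB": 32.9, "CO": 176.3, "N": 119.6, "HN": 8.28, "HA": 4.48, "HB": 2.05},
    "F": {"CA": 57.7, "CB": 39.6, "CO": 175.8, "N": 120.3, "HN": 8.30, "HA": 4.62, "HB": 3.11},
    "P": {"CA": 63.3, "CB": 32.1, "CO": 177.3, "N": 136.5, "HA": 4.42, "HB": 2.05},
    "S": {"CA": 58.3, "CB": 63.8, "CO": 174.6, "N": 115.7, "HN": 8.31, "HA": 4.47, "HB": 3.87},
    "T": {"CA": 61.8, "CB": 69.8, "CO": 174.7, "N": 113.6, "HN": 8.15, "HA": 4.35, "HB": 4.24},
    "W": {"CA": 57.5, "CB": 29.6, "CO": 176.1, "N": 121.3, "HN": 8.25, "HA": 4.66, "HB": 3.26},
    "Y": {"CA": 57.9, "CB": 38.8, "CO": 175.9, "N": 120.3, "HN": 8.12, "HA": 4.55, "HB": 2.98},
    "V": {"CA": 62.2, "CB": 32.9, "CO": 176.3, "N": 119.2, "HN": 8.03, "HA": 4.12, "HB": 2.13},
}


def reference_mean(aa: str, kind: str) -> float | None:
    """Random-coil mean for amino acid ``aa`` and nucleus ``kind``; None if absent."""
    return REFERENCE_MEANS[aa].get(kind)


def reference_sd(kind: str) -> float:
    return REFERENCE_SD[kind]


def has_nucleus(aa: str, kind: str) -> bool:
    return kind in REFERENCE_MEANS[aa]


def kind_range(kind: str, k_sd: float = 4.0) -> tuple[float, float]:
    """Global [min, max] ppm range of ``kind`` over all amino acids, +- k_sd SDs."""
    vals = [m[kind] for m in REFERENCE_MEANS.values() if kind in m]
    sd = REFERENCE_SD[kind]
    return min(vals) - k_sd * sd, max(vals) + k_sd * sd
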