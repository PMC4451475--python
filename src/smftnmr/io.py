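"""Text formats: Sparky peak lists, NUS schedules, basis tables, pick sets.

Sparky lists follow the conventional layout::

      Assignment         w1         w2   Data Height
      ?-?            174.523    118.204     -1.23e+05

Basis peak lists are tab-separated tables with the four labelled frequency
columns of the 4D basis experiment (CO_i, N_i+1, N_i, CO_i-1).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fixing_catalog import BasisPeak
from .peak_analysis import PickedPeak2D


def write_sparky_list(path, peaks: list[PickedPeak2D], labels: list[str] | None = None):
    lines = [f"{'Assignment':>12s} {'w1':>10s} {'w2':>10s}  Data Height"]
    for k, p in enumerate(peaks):
        label = labels[k] if labels else "?-?"
        lines.append(f"{label:>12s} {p.x_ppm:10.4f} {p.y_ppm:10.4f}  {p.intensity:12.4e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sparky_list(path) -> list[PickedPeak2D]:
    peaks = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) < 4 or parts[0] == "Assignment":
            continue
        peaks.append(
            PickedPeak2D(
                x_ppm=float(parts[1]), y_ppm=float(parts[2]), intensity=float(parts[3])
            )
        )
    return peaks


def write_basis_table(path, peaks: list[BasisPeak]) -> None:
    df = pd.DataFrame(
        [
            {
                "id": p.id,
                "CO_i": p.co_i,
                "N_i+1": p.n_ip1,
                "N_i": p.n_i,
                "CO_i-1": p.co_im1,
                "intensity": p.intensity,
                "sign": p.sign,
            }
            for p in peaks
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.5f")


def read_basis_table(path) -> list[BasisPeak]:
    df = pd.read_csv(path, sep="\t")
    return [
        BasisPeak(
            id=str(r["id"]),
            co_i=float(r["CO_i"]),
            n_ip1=float(r["N_i+1"]),
            n_i=float(r["N_i"]),
            co_im1=float(r["CO_i-1"]),
            intensity=float(r["intensity"]),
            sign=int(r["sign"]),
        )
        for _, r in df.iterrows()
    ]


def write_picks_json(path, picks: dict[str, dict[str, list[PickedPeak2D]]]) -> None:
    out = {
        bid: {
            vid: [
                {
                    "x_ppm": p.x_ppm,
                    "y_ppm": p.y_ppm,
                    "intensity": p.intensity,
                    "experiment": p.experiment,
                    "variant": p.variant,
                    "basis_peak_id": p.basis_peak_id,
                }
                for p in plist
            ]
            for vid, plist in by_variant.items()
        }
        for bid, by_variant in picks.items()
    }
    Path(path).write_text(json.dumps(out, indent=1))


def read_picks_json(path) -> dict[str, dict[str, list[PickedPeak2D]]]:
    raw = json.loads(Path(path).read_text())
    return {
        bid: {vid: [PickedPeak2D(**p) for p in plist] for vid, plist in by_variant.items()}
        for bid, by_variant in raw.items()
    }


def export_plane(path_prefix, plane) -> None:
    """A cross-section as a .npy matrix plus a small text axis header."""
    prefix = Path(path_prefix)
    np.save(prefix.with_suffix(".npy"), plane.data)
    hdr = [
        f"experiment {plane.experiment}",
        f"variant {plane.variant}",
        f"basis_peak {plane.basis_peak_id}",
    ]
    for k, ax in enumerate(plane.axes, start=1):
        hdr.append(
            f"w{k} {ax.label} {ax.element} npts {len(ax)} "
            f"first_ppm {ax.ppm[0]:.5f} step_ppm {ax.step_ppm:.6f}"
        )
    for d, ppm in sorted(plane.fixed_ppm.items()):
        hdr.append(f"fixed dim{d + 1} {ppm:.5f}")
    prefix.with_suffix(".hdr").write_text("\n".join(hdr) + "\n")
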