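"""Synthetic ground-truth chemical shifts and theoretical peak enumeration.

This module fabricates the statistical structure of an intrinsically
disordered protein at the level the processing and assignment stack needs:
per-residue shifts for HN, N, CO, CA, CB, HA and HB drawn tightly around
random-coil means (narrow dispersion), prolines without amide protons,
glycines without CB/HB, and the exact multidimensional peak families -- with
their signs -- that the 4D (HACA)CON(CA)NCO and the two 5D experiments
produce from a given shift table.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nuclei import KIND_CLASS, SHIFT_KINDS
from .refshifts import AMINO_ACIDS, REFERENCE_MEANS, reference_mean, reference_sd

#: per-element scaling of the user jitter parameter, reflecting the very
#: different absolute dispersions of 1H, 13C and 15N shifts (amide 15N has
#: by far the strongest sequence-context sensitivity in disordered chains)
JITTER_SCALE = {"C": 1.0, "N": 4.5, "H": 0.08}


@dataclass
class ShiftTable:
    """Ground-truth chemical shifts: residue index (1-based) -> kind -> ppm."""

    sequence: str
    shifts: dict[int, dict[str, float]]

    def __len__(self) -> int:
        return len(self.sequence)

    def aa(self, i: int) -> str:
        return self.sequence[i - 1]

    def get(self, i: int, kind: str) -> float | None:
        """Shift of nucleus ``kind`` of residue ``i``; None if absent/out of range."""
        if i < 1 or i > len(self.sequence):
            return None
        return self.shifts.get(i, {}).get(kind)

    def has(self, i: int, kind: str) -> bool:
        return self.get(i, kind) is not None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(1, len(self.sequence) + 1):
            row = {"residue": i, "aa": self.sequence[i - 1]}
            for kind in SHIFT_KINDS:
                row[kind] = self.shifts.get(i, {}).get(kind, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, sep="\t", index=False, float_format="%.4f")

    @classmethod
    def from_tsv(cls, path_or_buf) -> "ShiftTable":
        df = pd.read_csv(path_or_buf, sep="\t")
        sequence = "".join(df["aa"].tolist())
        shifts: dict[int, dict[str, float]] = {}
        for _, row in df.iterrows():
            entry = {k: float(row[k]) for k in SHIFT_KINDS if pd.notna(row[k])}
            shifts[int(row["residue"])] = entry
        return cls(sequence=sequence, shifts=shifts)

    def validate(self) -> None:
        """Check the structural invariants of a synthetic IDP shift table."""
        if len(self.sequence) < 3:
            raise ValueError("at least 3 residues are needed for any experiment")
        for i, aa in enumerate(self.sequence, start=1):
            entry = self.shifts.get(i, {})
            if aa == "P" and "HN" in entry:
                raise ValueError(f"proline at {i} must not carry an HN shift")
            if aa == "G" and ("CB" in entry or "HB" in entry):
                raise ValueError(f"glycine at {i} must not carry CB/HB shifts")
            for kind, val in entry.items():
                mean = reference_mean(aa, kind)
                if mean is None:
                    raise ValueError(f"{aa}{i} has a {kind} shift but lacks that nucleus")
                if abs(val - mean) > 4.0 * reference_sd(kind):
                    raise ValueError(
                        f"{aa}{i} {kind}={val:.3f} is outside +-4 SD of the "
                        f"random-coil mean {mean:.3f}"
                    )


@dataclass(frozen=True)
class TheoreticalPeak:
    """One multidimensional peak an experiment produces from a shift table.

    ``coords`` follows the experiment's dimension order; each entry is
    (nucleus kind, residue index, ppm).  ``family`` tags the coherence
    pathway: 'sequential' / 'diagonal' for the CO-detected backbone peaks,
    'alpha' / 'beta' for the aliphatic 5D families.
    """

    experiment: str
    residue: int
    coords: tuple[tuple[str, int, float], ...]
    sign: int
    family: str

    @property
    def ppms(self) -> tuple[float, ...]:
        return tuple(c[2] for c in self.coords)


def _check_sequence(sequence: str) -> None:
    if len(sequence) < 3:
        raise ValueError("sequence must have length >= 3")
    for pos, aa in enumerate(sequence, start=1):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"unknown amino-acid code {aa!r} at position {pos}")


def generate_shift_table(
    sequence: str,
    seed: int,
    jitter_sd: float = 0.3,
    ensure_pair_separation: tuple[float, float] | None = None,
    max_redraws: int = 200,
) -> ShiftTable:
    """Draw a synthetic IDP shift table.

    Each present shift is drawn from Normal(random-coil mean, jitter_sd *
    per-element scale), truncated to +-4 reference SDs.  Deterministic for a
    fixed seed.

    ``ensure_pair_separation=(co_tol, n_tol)`` enforces the "collision-free"
    study condition under which assignment is exact: no two distinct
    sequential CO-N anchor pairs (CO_{i-1}, N_i) coincide within those
    tolerances, and the two carbonyls fixed from one basis peak (CO_{i-1}
    and CO_i) stay separated at spectral-resolution scale (0.15 ppm, about
    one linewidth) so that the different fixing variants of a basis peak
    address distinct planes.  Offending residues are redrawn individually
    (deterministically) until the condition holds.
    """
    _check_sequence(sequence)
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))

    def draw_entry(aa: str) -> dict[str, float]:
        entry = {}
        for kind in SHIFT_KINDS:
            mean = reference_mean(aa, kind)
            if mean is None:
                continue
            sd = jitter_sd * JITTER_SCALE[KIND_CLASS[kind]]
            bound = 4.0 * reference_sd(kind)
            val = rng.normal(mean, sd) if sd > 0 else mean
            # truncate to +-4 reference SDs by redrawing (bounded)
            for _ in range(100):
                if abs(val - mean) <= bound:
                    break
                val = rng.normal(mean, sd)
            else:
                val = mean
            entry[kind] = float(val)
        return entry

    shifts = {i: draw_entry(aa) for i, aa in enumerate(sequence, start=1)}
    table = ShiftTable(sequence=sequence, shifts=shifts)
    if ensure_pair_separation is not None:
        for _ in range(max_redraws):
            bad = _collision_residues(table, *ensure_pair_separation)
            if not bad:
                break
            for i in sorted(bad):
                shifts[i] = draw_entry(sequence[i - 1])
        else:
            raise RuntimeError(
                "could not draw a collision-free shift table within the redraw "
                "budget; loosen ensure_pair_separation or increase jitter_sd"
            )
    return table


ADJACENT_CO_SEPARATION = 0.2  # ppm; below ~one indirect 13C linewidth the
# fixing variants of a basis peak stop addressing distinct planes

#: CO-N anchor-pair separations (ppm) defining the collision-free study
#: condition: twice the matching tolerances, so that distinct anchor pairs
#: stay resolvable after measurement error.  (Partial overlaps above this
#: scale but below the point-spread widths are handled downstream by the
#: cross-check fixing variants.)
PAIR_SEPARATION_CO = 0.1
PAIR_SEPARATION_N = 0.2


def _collision_residues(table: ShiftTable, co_tol: float, n_tol: float) -> set[int]:
    """Residues participating in a shift collision (to be redrawn)."""
    bad: set[int] = set()
    pairs = []
    for i in range(2, len(table.sequence) + 1):
        co, n = table.get(i - 1, "CO"), table.get(i, "N")
        if co is not None and n is not None:
            pairs.append((i, co, n))
    for a in range(len(pairs)):
        for b in range(a + 1, len(pairs)):
            ia, coa, na = pairs[a]
            ib, cob, nb = pairs[b]
            if abs(coa - cob) < co_tol and abs(na - nb) < n_tol:
                bad.update({ib, ib - 1} if ib > 1 else {ib})
    for i in range(2, len(table.sequence) + 1):
        co_prev, co = table.get(i - 1, "CO"), table.get(i, "CO")
        if co_prev is not None and co is not None:
            if abs(co - co_prev) < ADJACENT_CO_SEPARATION:
                bad.add(i)
    return bad


# ---------------------------------------------------------------------------
# peak enumeration


def _peak(table, experiment, i, spec_coords, sign, family):
    """Build a TheoreticalPeak if every required shift exists, else None."""
    coords = []
    for kind, idx in spec_coords:
        val = table.get(idx, kind)
        if val is None:
            return None
        coords.append((kind, idx, val))
    return TheoreticalPeak(
        experiment=experiment, residue=i, coords=tuple(coords), sign=sign, family=family
    )


def enumerate_peaks(experiment_id: str, table: ShiftTable) -> list[TheoreticalPeak]:
    """All theoretical peaks of an experiment for a ground-truth shift table.

    Peak families and sign rules (i indexes the residue the pathway starts
    on; G = glycine):

    * ``basis4d``: sequential CO_i-N_{i+1}-N_i-CO_{i-1} (sign -1, +1 if
      G_i) and diagonal CO_i-N_{i+1}-N_{i+1}-CO_i (+1, -1 if G_i); both
      pathways start on HA_i/CA_i, which every residue type possesses.
    * ``habcab5d``: HA_i-CA_i-CO_i-N_i-CO_{i-1} and
      HA_i-CA_i-CO_i-N_{i+1}-CO_i (+1, -1 if G_i);
      HB_i-CB_i-CO_i-N_i-CO_{i-1} and HB_i-CB_i-CO_i-N_{i+1}-CO_i
      (always +1; absent for glycine, which has no CB/HB).
    * ``hn5d``: HN_i-N_i-CO_{i-1}-N_{i-1}-CO_{i-2} and
      HN_i-N_i-CO_{i-1}-N_i-CO_{i-1} (+1, -1 if residue i-1 is G; absent
      for prolines, which have no HN).

    Peaks whose any coordinate is undefined (termini, proline HN, glycine
    CB/HB) are omitted.
    """
    if experiment_id not in ("basis4d", "habcab5d", "hn5d"):
        raise KeyError(f"unknown experiment {experiment_id!r}")
    L = len(table.sequence)
    peaks: list[TheoreticalPeak] = []

    def gly(i):
        return 1 <= i <= L and table.aa(i) == "G"

    for i in range(1, L + 1):
        if experiment_id == "basis4d":
            if not (table.has(i, "HA") and table.has(i, "CA")):
                continue
            s = +1 if gly(i) else -1
            p = _peak(table, experiment_id, i,
                      [("CO", i), ("N", i + 1), ("N", i), ("CO", i - 1)], s, "sequential")
            if p:
                peaks.append(p)
            p = _peak(table, experiment_id, i,
                      [("CO", i), ("N", i + 1), ("N", i + 1), ("CO", i)], -s, "diagonal")
            if p:
                peaks.append(p)
        elif experiment_id == "habcab5d":
            s = -1 if gly(i) else +1
            for coords, fam, sign in [
                ([("HA", i), ("CA", i), ("CO", i), ("N", i), ("CO", i - 1)], "alpha", s),
                ([("HA", i), ("CA", i), ("CO", i), ("N", i + 1), ("CO", i)], "alpha", s),
                ([("HB", i), ("CB", i), ("CO", i), ("N", i), ("CO", i - 1)], "beta", +1),
                ([("HB", i), ("CB", i), ("CO", i), ("N", i + 1), ("CO", i)], "beta", +1),
            ]:
                p = _peak(table, experiment_id, i, coords, sign, fam)
                if p:
                    peaks.append(p)
        else:  # hn5d
            s = -1 if gly(i - 1) else +1
            p = _peak(table, experiment_id, i,
                      [("HN", i), ("N", i), ("CO", i - 1), ("N", i - 1), ("CO", i - 2)],
                      s, "sequential")
            if p:
                peaks.append(p)
            p = _peak(table, experiment_id, i,
                      [("HN", i), ("N", i), ("CO", i - 1), ("N", i), ("CO", i - 1)],
                      s, "diagonal")
            if p:
                peaks.append(p)
    return peaks
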