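"""Synthetic shift tables and theoretical peak enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smftnmr.refshifts import AMINO_ACIDS, reference_mean, reference_sd
from smftnmr.shift_synth import (
    ShiftTable,
    enumerate_peaks,
    generate_shift_table,
)

sequences = st.text(alphabet=AMINO_ACIDS, min_size=3, max_size=14)


class TestGenerateShiftTable:
    def test_glycine_lacks_cb_hb(self):
        t = generate_shift_table("GAS", seed=1)
        assert t.get(1, "CB") is None and t.get(1, "HB") is None
        assert t.get(1, "CA") is not None

    def test_proline_lacks_hn(self):
        t = generate_shift_table("APG", seed=1)
        assert t.get(2, "HN") is None
        assert t.get(2, "N") is not None  # proline keeps its nitrogen

    def test_deterministic(self):
        a = generate_shift_table("MDSKA", seed=11)
        b = generate_shift_table("MDSKA", seed=11)
        assert a.shifts == b.shifts

    def test_rejects_unknown_code(self):
        with pytest.raises(ValueError, match="position 2"):
            generate_shift_table("AZA", seed=1)

    def test_rejects_short_sequence(self):
        with pytest.raises(ValueError):
            generate_shift_table("AA", seed=1)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seq=sequences, seed=st.integers(0, 2**20))
    def test_shifts_within_four_sd_of_reference(self, seq, seed):
        t = generate_shift_table(seq, seed=seed, jitter_sd=1.0)
        t.validate()
        for i, aa in enumerate(seq, start=1):
            for kind, val in t.shifts[i].items():
                assert abs(val - reference_mean(aa, kind)) <= 4 * reference_sd(kind)

    def test_collision_free_condition(self):
        t = generate_shift_table("KAKAKAKAKA", seed=2, ensure_pair_separation=(0.1, 0.2))
        pairs = [(t.get(i - 1, "CO"), t.get(i, "N")) for i in range(2, 11)]
        for a in range(len(pairs)):
            for b in range(a + 1, len(pairs)):
                assert (
                    abs(pairs[a][0] - pairs[b][0]) >= 0.1
                    or abs(pairs[a][1] - pairs[b][1]) >= 0.2
                )

    def test_tsv_roundtrip(self, tmp_path):
        t = generate_shift_table("MDPSKG", seed=4)
        path = tmp_path / "shifts.tsv"
        t.to_tsv(path)
        back = ShiftTable.from_tsv(path)
        assert back.sequence == t.sequence
        for i in range(1, 7):
            for kind, val in t.shifts[i].items():
                assert back.get(i, kind) == pytest.approx(val, abs=1e-3)


def brute_force_counts(table, experiment_id):
    """Independent oracle: count peaks by direct index-bound enumeration."""
    L = len(table.sequence)
    n = 0
    reqs = {
        "basis4d": [
            [("HA", 0), ("CA", 0), ("CO", 0), ("N", 1), ("N", 0), ("CO", -1)],
            [("HA", 0), ("CA", 0), ("CO", 0), ("N", 1)],
        ],
        "habcab5d": [
            [("HA", 0), ("CA", 0), ("CO", 0), ("N", 0), ("CO", -1)],
            [("HA", 0), ("CA", 0), ("CO", 0), ("N", 1)],
            [("HB", 0), ("CB", 0), ("CO", 0), ("N", 0), ("CO", -1)],
            [("HB", 0), ("CB", 0), ("CO", 0), ("N", 1)],
        ],
        "hn5d": [
            [("HN", 0), ("N", 0), ("CO", -1), ("N", -1), ("CO", -2)],
            [("HN", 0), ("N", 0), ("CO", -1)],
        ],
    }[experiment_id]
    for i in range(1, L + 1):
        for req in reqs:
            if all(table.get(i + off, kind) is not None for kind, off in req):
                n += 1
    return n


class TestEnumeratePeaks:
    def test_three_residue_peptide_counts(self):
        # sequential CO_i-N_{i+1}-N_i-CO_{i-1} exists only for i=2 in a
        # 3-mer; the diagonal needs only CO_i and N_{i+1} (i = 1, 2)
        t = generate_shift_table("AAA", seed=1)
        peaks = enumerate_peaks("basis4d", t)
        assert sum(p.family == "sequential" for p in peaks) == 1
        assert sum(p.family == "diagonal" for p in peaks) == 2

    def test_glycine_sign_flip_4d(self):
        t = generate_shift_table("AAGAA", seed=1)
        seq = {p.residue: p for p in enumerate_peaks("basis4d", t) if p.family == "sequential"}
        assert seq[3].sign == +1  # glycine flips the (otherwise negative) sequential peak
        assert seq[2].sign == -1
        diag = {p.residue: p for p in enumerate_peaks("basis4d", t) if p.family == "diagonal"}
        assert diag[3].sign == -1 and diag[2].sign == +1

    def test_glycine_habcab(self):
        t = generate_shift_table("AAGAA", seed=1)
        peaks = enumerate_peaks("habcab5d", t)
        g = [p for p in peaks if p.residue == 3]
        assert all(p.family == "alpha" for p in g)  # no HB-CB peaks for glycine
        assert all(p.sign == -1 for p in g)
        beta = [p for p in peaks if p.family == "beta"]
        assert beta and all(p.sign == +1 for p in beta)

    def test_hn_experiment_glycine_rule_and_proline(self):
        t = generate_shift_table("AAGAPA", seed=1)
        peaks = enumerate_peaks("hn5d", t)
        assert all(p.residue != 5 for p in peaks)  # proline has no amide proton
        by_res = {}
        for p in peaks:
            by_res.setdefault(p.residue, []).append(p)
        assert all(p.sign == -1 for p in by_res[4])  # residue i-1 = G flips
        assert all(p.sign == +1 for p in by_res[3])

    def test_no_gly_pro_4d_count_formula(self):
        t = generate_shift_table("ASKLVEDTRM", seed=2)
        peaks = enumerate_peaks("basis4d", t)
        L = 10
        assert sum(p.family == "sequential" for p in peaks) == L - 2
        assert sum(p.family == "diagonal" for p in peaks) == L - 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seq=sequences)
    def test_counts_match_brute_force(self, seq):
        t = generate_shift_table(seq, seed=9)
        for e in ("basis4d", "habcab5d", "hn5d"):
            assert len(enumerate_peaks(e, t)) == brute_force_counts(t, e)

    def test_enumeration_idempotent(self):
        t = generate_shift_table("MDGSPKA", seed=5)
        a = enumerate_peaks("basis4d", t)
        b = enumerate_peaks("basis4d", t)
        assert a == b

    def test_coordinate_dimensionality(self):
        t = generate_shift_table("MDSKA", seed=5)
        assert all(len(p.coords) == 4 for p in enumerate_peaks("basis4d", t))
        assert all(len(p.coords) == 5 for p in enumerate_peaks("habcab5d", t))
        assert all(len(p.coords) == 5 for p in enumerate_peaks("hn5d", t))
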