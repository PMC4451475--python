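"""Plane picking, 4D basis picking, overlap resolution."""

import numpy as np
import pytest

from smftnmr.fixing_catalog import BasisPeak
from smftnmr.ft_engine import CrossSection2D, PlaneAxis
from smftnmr.peak_analysis import (
    PickedPeak2D,
    group_overlapping_basis_peaks,
    pick_peaks_2d,
    resolve_plane_overlap,
)


def make_plane(data, step=0.1):
    n0, n1 = data.shape
    ax0 = PlaneAxis("CO", "C", 170.0 + step * np.arange(n0), step * np.arange(n0))
    ax1 = PlaneAxis("N", "N", 110.0 + step * np.arange(n1), step * np.arange(n1))
    return CrossSection2D(
        data=data, axes=(ax0, ax1), experiment="basis4d", variant="1i",
        basis_peak_id="b0", fixed_ppm={},
    )


def gaussian_bump(shape, center, sigma=1.6, amp=1.0):
    y, x = np.indices(shape)
    return amp * np.exp(-(((y - center[0]) ** 2 + (x - center[1]) ** 2) / (2 * sigma**2)))


class TestPickPeaks2D:
    def test_single_peak_within_half_grid_step(self):
        data = gaussian_bump((41, 41), (20.3, 17.6)) + 1e-4 * np.random.default_rng(0).normal(size=(41, 41))
        plane = make_plane(data)
        peaks = pick_peaks_2d(plane, threshold_sigma=6)
        assert len(peaks) == 1
        assert abs(peaks[0].x_ppm - (170.0 + 0.1 * 20.3)) <= 0.05
        assert abs(peaks[0].y_ppm - (110.0 + 0.1 * 17.6)) <= 0.05

    def test_negated_plane_flips_signs_keeps_positions(self):
        data = gaussian_bump((31, 31), (12, 22)) - gaussian_bump((31, 31), (25, 5), amp=0.7)
        data += 1e-3 * np.random.default_rng(1).normal(size=data.shape)
        p = pick_peaks_2d(make_plane(data), threshold_sigma=6)
        n = pick_peaks_2d(make_plane(-data), threshold_sigma=6)
        assert len(p) == len(n) == 2
        for a, b in zip(p, n):
            assert a.x_ppm == pytest.approx(b.x_ppm) and a.y_ppm == pytest.approx(b.y_ppm)
            assert a.intensity == pytest.approx(-b.intensity)

    def test_pure_noise_false_peak_rate(self):
        """At 6 sigma, pure-noise planes should essentially never yield picks
        (< 0.05 false peaks per plane on average over 100 seeds)."""
        total = 0
        for seed in range(100):
            data = np.random.default_rng(seed).normal(size=(60, 60))
            total += len(pick_peaks_2d(make_plane(data), threshold_sigma=6))
        assert total / 100 < 0.05

    def test_all_zero_plane_empty(self):
        assert pick_peaks_2d(make_plane(np.zeros((20, 20)))) == []

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            pick_peaks_2d(make_plane(np.ones((5, 5))), threshold_sigma=0)

    def test_ordered_by_decreasing_magnitude(self):
        data = gaussian_bump((41, 41), (10, 10)) + 0.5 * gaussian_bump((41, 41), (30, 30))
        data += 1e-3 * np.random.default_rng(2).normal(size=data.shape)
        peaks = pick_peaks_2d(make_plane(data), threshold_sigma=6)
        mags = [abs(p.intensity) for p in peaks]
        assert mags == sorted(mags, reverse=True)


class TestBuildBasisPeaklist:
    def test_counts_match_enumerated_sequential_family(self, small4d):
        expected = sum(p.family == "sequential" for p in small4d["peaks"])
        assert len(small4d["basis"]) == expected

    def test_diagonal_peaks_excluded(self, small4d):
        # no returned quadruple may look diagonal (dim1~dim4 and dim2~dim3)
        for bp in small4d["basis"]:
            assert not (abs(bp.co_i - bp.co_im1) <= 0.1 and abs(bp.n_ip1 - bp.n_i) <= 0.25)
        assert small4d["info"]["n_diagonal"] > 0

    def test_signs_follow_glycine_rule(self, small4d):
        table = small4d["table"]
        truth = {
            p.residue: p for p in small4d["peaks"] if p.family == "sequential"
        }
        for bp in small4d["basis"]:
            res = min(
                truth,
                key=lambda i: abs(truth[i].coords[2][2] - bp.n_i)
                + abs(truth[i].coords[3][2] - bp.co_im1),
            )
            assert bp.sign == truth[res].sign

    def test_positions_accurate(self, small4d):
        truth = {p.residue: p.ppms for p in small4d["peaks"] if p.family == "sequential"}
        tols = (0.05, 0.1, 0.1, 0.02)  # CO(ind), N, N, CO(direct, fine axis)
        for bp in small4d["basis"]:
            best = min(truth.values(), key=lambda c: abs(c[2] - bp.n_i) + abs(c[3] - bp.co_im1))
            for got, want, tol in zip(bp.ppms, best, tols):
                assert abs(got - want) <= tol

    def test_rejects_non_basis_experiment(self, small4d):
        from dataclasses import replace

        from smftnmr.ft_engine import HybridDataset
        from smftnmr.peak_analysis import build_basis_peaklist

        hyb = small4d["hybrid"]
        wrong_exp = replace(hyb.experiment, id="habcab5d")
        bad = HybridDataset(
            experiment=wrong_exp, schedule=hyb.schedule, acq=hyb.acq, data=hyb.data
        )
        with pytest.raises(ValueError):
            build_basis_peaklist(bad)


def pick(x, y, inten=1.0):
    return PickedPeak2D(x_ppm=x, y_ppm=y, intensity=inten)


class TestOverlapResolution:
    def test_grouping_by_fixed_pair(self):
        peaks = [
            BasisPeak("a", 175.0, 119.0, 121.0, 174.0),
            BasisPeak("b", 176.0, 118.0, 121.02, 174.01),  # same (N_i, CO_{i-1})
            BasisPeak("c", 177.0, 117.0, 125.0, 176.0),
        ]
        groups = group_overlapping_basis_peaks(peaks)
        assert len(groups) == 1
        assert {p.id for p in groups[0]} == {"a", "b"}

    def test_disambiguation_via_1iv(self):
        # both (1i) planes show three peaks; each member's own (1iv) plane
        # confirms only its two
        shared = pick(174.0, 121.0)  # the common CO_{i-1}-N_i peak
        a_own = pick(175.0, 119.0)
        b_own = pick(176.0, 118.0)
        picks_1i = [shared, a_own, b_own]
        a_1iv = [pick(121.0, 174.0), pick(119.0, 175.0)]  # (N, CO) axes
        b_1iv = [pick(121.0, 174.0), pick(118.0, 176.0)]
        members = [
            (BasisPeak("a", 175.0, 119.0, 121.0, 174.0), picks_1i, a_1iv),
            (BasisPeak("b", 176.0, 118.0, 121.0, 174.0), picks_1i, b_1iv),
        ]
        res = resolve_plane_overlap(members)
        assert not res.ambiguous
        assert {(p.x_ppm, p.y_ppm) for p in res.kept["a"]} == {(174.0, 121.0), (175.0, 119.0)}
        assert {(p.x_ppm, p.y_ppm) for p in res.kept["b"]} == {(174.0, 121.0), (176.0, 118.0)}
        assert res.removed["a"] == [b_own] and res.removed["b"] == [a_own]

    def test_no_overlap_passthrough(self):
        a = [pick(175.0, 119.0), pick(174.0, 121.0)]
        a_iv = [pick(119.0, 175.0), pick(121.0, 174.0)]
        b = [pick(176.0, 118.0), pick(174.5, 120.0)]
        b_iv = [pick(118.0, 176.0), pick(120.0, 174.5)]
        members = [
            (BasisPeak("a", 175.0, 119.0, 121.0, 174.0), a, a_iv),
            (BasisPeak("b", 176.0, 118.0, 121.0, 174.0), b, b_iv),
        ]
        res = resolve_plane_overlap(members)
        assert res.kept["a"] == a and res.kept["b"] == b

    def test_fully_degenerate_flagged_ambiguous(self):
        picks_1i = [pick(174.0, 121.0), pick(175.0, 119.0), pick(176.0, 118.0)]
        same_iv = [pick(121.0, 174.0), pick(119.0, 175.0), pick(118.0, 176.0)]
        members = [
            (BasisPeak("a", 175.0, 119.0, 121.0, 174.0), picks_1i, same_iv),
            (BasisPeak("b", 176.0, 118.0, 121.0, 174.0), picks_1i, same_iv),
        ]
        res = resolve_plane_overlap(members)
        assert res.ambiguous
        assert res.kept["a"] == picks_1i  # no guessing: picks returned intact

    def test_group_needs_two_members(self):
        with pytest.raises(ValueError):
            resolve_plane_overlap([(BasisPeak("a", 1, 2, 3, 4), [], [])])
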