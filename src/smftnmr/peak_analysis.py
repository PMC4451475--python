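"""Peak picking on 2D cross-sections and on the 4D basis spectrum.

The basis spectrum is picked by brute-force MFT evaluation of 3D indirect
cubes at candidate direct-dimension bins, restricted to frequency windows
around the plausible chemical-shift ranges (full four-dimensional grids are
deliberately avoided: high-dimensional spectra are mostly empty and far too
large to evaluate everywhere).  Picked 4D extrema are refined by pointwise
re-evaluation of the Fourier sum, classified into sequential
(CO_i-N_{i+1}-N_i-CO_{i-1}) and diagonal (CO_i-N_{i+1}-N_{i+1}-CO_i) peaks,
and only the sequential ones enter the basis peak list.

Plane picking finds signed 3x3 local extrema above a robust
median-absolute-deviation noise threshold and refines positions by per-axis
parabolic interpolation.  Overlapping cross-sections (two basis peaks whose
(N_i, CO_{i-1}) pairs coincide) are resolved by comparing the (1i) plane of
each member against its (1iv) plane, where identical peaks are expected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fixing_catalog import BasisPeak
from .ft_engine import NFFT, CrossSection2D, HybridDataset, mft, mft_point
from .refshifts import kind_range

logger = logging.getLogger(__name__)

MAD_TO_SIGMA = 1.4826


@dataclass(frozen=True)
class PickedPeak2D:
    """A picked plane peak: two frequencies (ppm) and a signed intensity."""

    x_ppm: float
    y_ppm: float
    intensity: float
    experiment: str = ""
    variant: str = ""
    basis_peak_id: str = ""


def trim_intensity_gap(picks: list["PickedPeak2D"], factor: float = 2.0):
    """Keep the leading picks of comparable amplitude: the ranked list is
    cut at the first > ``factor`` drop between consecutive |intensities|.

    Genuine peaks of one cross-section have similar amplitudes, while peaks
    leaking from nearby cross-sections (and the artifact ridges of planes
    whose direct dimension is free) are strongly attenuated.
    """
    ranked = sorted(picks, key=lambda p: -abs(p.intensity))
    for k in range(1, len(ranked)):
        if abs(ranked[k - 1].intensity) > factor * abs(ranked[k].intensity):
            return ranked[:k]
    return ranked


def plane_noise(data: np.ndarray) -> float:
    """Robust noise level: median absolute deviation x 1.4826."""
    med = np.median(data)
    return MAD_TO_SIGMA * float(np.median(np.abs(data - med)))


def _parabolic_delta(vm: float, v0: float, vp: float) -> float:
    denom = vm - 2 * v0 + vp
    if denom == 0:
        return 0.0
    delta = 0.5 * (vm - vp) / denom
    return float(np.clip(delta, -0.5, 0.5))


def pick_peaks_2d(
    plane: CrossSection2D, threshold_sigma: float = 6.0, noise: float | None = None
) -> list[PickedPeak2D]:
    """Signed local extrema of a cross-section above a robust threshold.

    A point is picked when it is the extremum of its 3x3 neighbourhood and
    |value| > threshold_sigma x (MAD-based noise estimate).  Positions are
    refined by per-axis parabolic interpolation; the sign is preserved.
    Returns peaks ordered by decreasing |intensity|.
    """
    if threshold_sigma <= 0:
        raise ValueError("threshold_sigma must be > 0")
    data = plane.data
    if not np.any(data):
        return []
    sigma = plane_noise(data) if noise is None else noise
    thr = threshold_sigma * sigma
    if thr == 0:  # pathological noiseless constant plane
        thr = 1e-12 * np.max(np.abs(data))

    is_max = (data == ndimage.maximum_filter(data, size=3, mode="nearest")) & (data > thr)
    is_min = (data == ndimage.minimum_filter(data, size=3, mode="nearest")) & (data < -thr)
    peaks = []
    for i, j in zip(*np.nonzero(is_max | is_min)):
        v0 = data[i, j]
        di = dj = 0.0
        if 0 < i < data.shape[0] - 1:
            di = _parabolic_delta(data[i - 1, j], v0, data[i + 1, j])
        if 0 < j < data.shape[1] - 1:
            dj = _parabolic_delta(data[i, j - 1], v0, data[i, j + 1])
        ax0, ax1 = plane.axes
        x = float(ax0.ppm[i]) + di * ax0.step_ppm
        y = float(ax1.ppm[j]) + dj * ax1.step_ppm
        peaks.append(
            PickedPeak2D(
                x_ppm=x,
                y_ppm=y,
                intensity=float(v0),
                experiment=plane.experiment,
                variant=plane.variant,
                basis_peak_id=plane.basis_peak_id,
            )
        )
    peaks.sort(key=lambda p: -abs(p.intensity))
    return peaks


def refine_plane_picks(
    hybrid: HybridDataset,
    variant,
    basis_peak: BasisPeak,
    picks: list[PickedPeak2D],
    rounds: int = 2,
    max_picks: int = 12,
) -> list[PickedPeak2D]:
    """Refine picked plane positions by pointwise re-evaluation of the
    sparse Fourier sum on a shrinking three-point stencil.

    Grid-parabola positions on coarse indirect axes inherit bias from
    asymmetric backgrounds; re-evaluating the transform at sub-grid
    frequencies removes it.  Free indirect coordinates are refined (one
    half-grid-step stencil per round); a free direct coordinate already
    sits on the fine 2048-bin axis and is left as is.
    """
    from .fixing_catalog import fixed_frequencies
    from .ft_engine import _bit_axes, _reduce_fixed

    exp = hybrid.experiment
    nind = exp.n_indirect
    direct = exp.n_dims - 1
    fixed = fixed_frequencies(variant, basis_peak)
    free = sorted(d for d in variant.free if d != direct)
    axis_of = {d: "xy"[variant.free.index(d)] for d in free}
    # stencil scale ~ half a natural resolution element per dimension
    steps = {d: 1.0 / (2 * exp.dims[d].t_max) / exp.dims[d].base_mhz for d in free}
    t = hybrid.schedule.times()

    fixed_w = {}
    for d, ppm in fixed.items():
        if d == direct:
            continue
        arg = 2 * np.pi * float(exp.dims[d].to_hz(ppm)) * t[:, d]
        fixed_w[d] = (np.cos(arg), np.sin(arg))

    red_cache: dict[int, np.ndarray] = {}

    def reduced(direct_bin):
        if direct_bin not in red_cache:
            B = _bit_axes(hybrid.data[:, :, direct_bin], nind)
            red_cache[direct_bin] = _reduce_fixed(B, fixed_w)  # (K, 2[, 2])
        return red_cache[direct_bin]

    def point_factory(direct_bin):
        red = reduced(direct_bin)

        def point(c):
            ws = []
            for d in free:
                arg = 2 * np.pi * float(exp.dims[d].to_hz(c[d])) * t[:, d]
                ws.append(np.stack([np.cos(arg), np.sin(arg)]))
            if len(free) == 1:
                return float(np.einsum("ka,ak->", red, ws[0]))
            return float(np.einsum("kab,ak,bk->", red, ws[0], ws[1]))

        return point

    # only the leading picks are ever used downstream; the long tail of
    # ridge-artifact picks on direct-free planes is passed through as is
    todo = sorted(picks, key=lambda q: -abs(q.intensity))
    todo, rest = todo[:max_picks], todo[max_picks:]
    out = list(rest)
    for p in todo:
        coords = {d: (p.x_ppm if axis_of[d] == "x" else p.y_ppm) for d in free}
        if variant.fixes_direct:
            direct_bin = hybrid.nearest_bin(fixed[direct])
        else:
            direct_ppm = p.x_ppm if variant.free[0] == direct else p.y_ppm
            direct_bin = hybrid.nearest_bin(direct_ppm)
        point = point_factory(direct_bin)
        val = point(coords)
        for r in range(rounds):
            for d in free:
                s = steps[d] / (2 ** (r + 1))
                lo = {**coords, d: coords[d] - s}
                hi = {**coords, d: coords[d] + s}
                vm, vp = point(lo), point(hi)
                delta = _parabolic_delta(vm if val > 0 else -vm,
                                         abs(val),
                                         vp if val > 0 else -vp)
                coords[d] += delta * s
            val = point(coords)
        x, y = p.x_ppm, p.y_ppm
        for d in free:
            if axis_of[d] == "x":
                x = coords[d]
            else:
                y = coords[d]
        out.append(
            PickedPeak2D(
                x_ppm=x, y_ppm=y, intensity=float(val),
                experiment=p.experiment, variant=p.variant,
                basis_peak_id=p.basis_peak_id,
            )
        )
    out.sort(key=lambda q: -abs(q.intensity))
    return out


# ---------------------------------------------------------------------------
# 4D basis-spectrum picking


def default_windows() -> dict[str, tuple[float, float]]:
    """Plausible CO and N shift windows from the random-coil reference table."""
    return {"CO": kind_range("CO", 4.0), "N": kind_range("N", 4.0)}


def windows_from_table(table, margin_ppm=None) -> dict[str, tuple[float, float]]:
    """Shift windows spanning a synthetic table's actual CO / N ranges."""
    margin = {"CO": 0.5, "N": 1.0}
    if margin_ppm:
        margin.update(margin_ppm)
    out = {}
    for kind in ("CO", "N"):
        vals = [
            v
            for i in range(1, len(table.sequence) + 1)
            if (v := table.get(i, kind)) is not None
        ]
        out[kind] = (min(vals) - margin[kind], max(vals) + margin[kind])
    return out


def _grid(dim, window_ppm, divisor=2):
    lo, hi = sorted(float(dim.to_hz(p)) for p in window_ppm)
    lo = max(lo, -dim.sw_hz / 2)
    hi = min(hi, dim.sw_hz / 2)
    step = 1.0 / (divisor * dim.t_max)
    hz = np.arange(lo, hi + step / 2, step)
    return np.asarray(dim.to_ppm(hz))


def _candidate_direct_bins(hybrid, window_ppm, rel_threshold, stride_hz):
    """Direct bins worth a 3D cube: local maxima of the direct-power
    projection plus a strided fill of the above-threshold region."""
    proj = np.sqrt(np.mean(hybrid.data**2, axis=(0, 1)))
    axis_ppm = hybrid.direct_axis_ppm()
    lo, hi = sorted(window_ppm)
    in_win = (axis_ppm >= lo) & (axis_ppm <= hi)
    thr = rel_threshold * proj[in_win].max()
    above = in_win & (proj > thr)
    local_max = above & (proj == ndimage.maximum_filter(proj, size=5, mode="nearest"))
    bins = set(np.nonzero(local_max)[0].tolist())
    stride = max(1, int(round(stride_hz / (hybrid.direct_dim.sw_hz / NFFT))))
    idx = np.nonzero(above)[0]
    bins.update(idx[::stride].tolist())
    return sorted(bins), proj


def refine_4d_peak(
    hybrid: HybridDataset,
    ppms: list[float],
    direct_bin: int,
    steps_ppm: list[float],
    rounds: int = 2,
    direct_halfwidth_bins: int = 18,
):
    """Refine a 4D extremum by pointwise re-evaluation of the Fourier sum.

    Per round, each indirect coordinate is updated from a three-point
    parabola at +-step (step halved every round); finally the direct
    coordinate is re-located on its (fine) frequency axis.
    Returns (indirect ppms, direct ppm, intensity).
    """
    ppms = list(ppms)
    for r in range(rounds):
        for d in range(len(ppms)):
            s = steps_ppm[d] / (2**r)
            trial = [list(ppms) for _ in range(3)]
            trial[0][d] -= s
            trial[2][d] += s
            vals = [mft_point(hybrid, tuple(tr), direct_bin) for tr in trial]
            delta = _parabolic_delta(vals[0], vals[1], vals[2])
            ppms[d] += delta * s
    b0 = direct_bin
    lo = max(0, b0 - direct_halfwidth_bins)
    hi = min(NFFT, b0 + direct_halfwidth_bins + 1)
    bins = np.arange(lo, hi)
    vals = mft_point(hybrid, tuple(ppms), bins)
    k = int(np.argmax(np.abs(vals)))
    delta = 0.0
    if 0 < k < len(bins) - 1:
        v = vals if vals[k] > 0 else -vals
        delta = _parabolic_delta(v[k - 1], v[k], v[k + 1])
    axis = hybrid.direct_axis_ppm()
    step = float(axis[1] - axis[0])
    direct_ppm = float(axis[bins[k]]) + delta * step
    return ppms, direct_ppm, float(vals[k])


def build_basis_peaklist(
    hybrid: HybridDataset,
    windows: dict[str, tuple[float, float]] | None = None,
    rel_threshold: float = 0.25,
    stride_hz: float = 12.0,
    step_divisor: int = 2,
    diag_tol=(0.1, 0.25),
    dedupe_tol=(0.12, 0.35),
) -> tuple[list[BasisPeak], dict]:
    """Pick the 4D basis spectrum and return its sequential peak list.

    ``windows`` maps 'CO'/'N' to (lo, hi) ppm search windows (defaults to
    the random-coil plausible ranges).  ``rel_threshold`` is the picking
    floor relative to the strongest 4D extremum -- on sparse NUS data the
    off-peak background is sampling artifacts, whose level is reported in
    the returned info dict rather than asserted.  Diagonal peaks
    (dim1 ~ dim4 and dim2 ~ dim3 within ``diag_tol`` = (13C, 15N) ppm) are
    classified and excluded; only sequential peaks are returned, with sign.
    """
    if hybrid.experiment.id != "basis4d":
        raise ValueError("basis picking expects the 4D basis experiment")
    windows = windows or default_windows()
    exp = hybrid.experiment
    grids = [
        _grid(exp.dims[0], windows["CO"], step_divisor),
        _grid(exp.dims[1], windows["N"], step_divisor),
        _grid(exp.dims[2], windows["N"], step_divisor),
    ]
    steps_ppm = [abs(float(g[1] - g[0])) for g in grids]
    bins, proj = _candidate_direct_bins(hybrid, windows["CO"], 0.2, stride_hz)
    logger.info("basis picking: %d direct candidate bins, cube %s", len(bins),
                tuple(len(g) for g in grids))

    candidates = []
    global_max = 0.0
    floors = []
    for b in bins:
        cube = mft(hybrid, grids, b)
        global_max = max(global_max, float(np.max(np.abs(cube))))
        floors.append(plane_noise(cube))
        is_max = (cube == ndimage.maximum_filter(cube, size=3, mode="nearest"))
        is_min = (cube == ndimage.minimum_filter(cube, size=3, mode="nearest"))
        mask = (is_max | is_min) & (np.abs(cube) > rel_threshold * np.max(np.abs(cube)))
        for idx in zip(*np.nonzero(mask)):
            candidates.append((b, idx, float(cube[idx])))

    # refine and keep candidates above the global relative threshold
    refined = []
    for b, idx, v in candidates:
        if abs(v) < rel_threshold * global_max:
            continue
        ppms = [float(grids[d][idx[d]]) for d in range(3)]
        ind_ppms, direct_ppm, inten = refine_4d_peak(hybrid, ppms, b, steps_ppm)
        if abs(inten) < rel_threshold * global_max:
            continue
        refined.append((ind_ppms + [direct_ppm], inten))

    # dedupe across cubes / adjacent direct bins
    tol_c, tol_n = dedupe_tol
    tols = np.array([tol_c, tol_n, tol_n, tol_c])
    kept: list[tuple[list[float], float]] = []
    for coords, inten in sorted(refined, key=lambda r: -abs(r[1])):
        if any(np.all(np.abs(np.array(coords) - np.array(kc)) < tols) for kc, _ in kept):
            continue
        kept.append((coords, inten))

    sequential, diagonal = [], []
    for coords, inten in kept:
        co1, n2, n3, co4 = coords
        if abs(co1 - co4) <= diag_tol[0] and abs(n2 - n3) <= diag_tol[1]:
            diagonal.append((coords, inten))
        else:
            sequential.append((coords, inten))

    sequential.sort(key=lambda r: (r[0][2], r[0][3]))  # by (N_i, CO_{i-1})
    peaks = [
        BasisPeak(
            id=f"b{k:03d}",
            co_i=c[0],
            n_ip1=c[1],
            n_i=c[2],
            co_im1=c[3],
            intensity=v,
            sign=int(np.sign(v)),
        )
        for k, (c, v) in enumerate(sequential, start=1)
    ]
    info = {
        "n_direct_bins": len(bins),
        "n_candidates": len(candidates),
        "n_sequential": len(peaks),
        "n_diagonal": len(diagonal),
        "global_max": global_max,
        "artifact_floor": float(np.median(floors)) if floors else 0.0,
        "peak_to_floor": global_max / (MAD_TO_SIGMA * np.median(floors))
        if floors and np.median(floors) > 0
        else np.inf,
    }
    logger.info(
        "basis picking: %d sequential, %d diagonal peaks; peak/artifact floor ~ %.1f",
        len(peaks), len(diagonal), info["peak_to_floor"],
    )
    return peaks, info


# ---------------------------------------------------------------------------
# overlapping cross-section resolution


def group_overlapping_basis_peaks(
    peaks: list[BasisPeak], tol_c: float = 0.05, tol_n: float = 0.1
) -> list[list[BasisPeak]]:
    """Groups of basis peaks whose (N_i, CO_{i-1}) fixed pairs coincide."""
    n = len(peaks)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(n):
        for b in range(a + 1, n):
            if (
                abs(peaks[a].n_i - peaks[b].n_i) < tol_n
                and abs(peaks[a].co_im1 - peaks[b].co_im1) < tol_c
            ):
                parent[find(a)] = find(b)
    groups: dict[int, list[BasisPeak]] = {}
    for a in range(n):
        groups.setdefault(find(a), []).append(peaks[a])
    return [g for g in groups.values() if len(g) > 1]


@dataclass
class OverlapResolution:
    """Result of a 1i/1iv cross-check for one overlap group."""

    kept: dict[str, list[PickedPeak2D]]  # basis peak id -> retained 1i picks
    removed: dict[str, list[PickedPeak2D]]  # attributed to overlapping partners
    ambiguous: bool = False


def _match_1i_1iv(p_1i: PickedPeak2D, p_1iv: PickedPeak2D, tol_c, tol_n) -> bool:
    # 1i planes are (CO, N); 1iv planes are (N, CO-direct)
    return (
        abs(p_1i.x_ppm - p_1iv.y_ppm) <= tol_c and abs(p_1i.y_ppm - p_1iv.x_ppm) <= tol_n
    )


def resolve_plane_overlap(
    members: list[tuple[BasisPeak, list[PickedPeak2D], list[PickedPeak2D]]],
    tol_c: float = 0.05,
    tol_n: float = 0.1,
) -> OverlapResolution:
    """Disambiguate overlapping (1i) cross-sections via (1iv) planes.

    ``members`` holds, per basis peak of one overlap group, its picked (1i)
    and (1iv) plane peaks.  A (1i) peak is kept for a member only when a
    matching peak is present on that member's own (1iv) plane; peaks present
    on only one fixing are attributed to the overlapping partner.  If every
    member retains an identical excess peak set the group cannot be resolved
    and is flagged ambiguous (no guessing).
    """
    if len(members) < 2:
        raise ValueError("an overlap group needs at least two basis peaks")
    kept, removed = {}, {}
    for peak, picks_1i, picks_1iv in members:
        # drop the weak artifact-ridge picks of the direct-free (1iv) plane
        confirm = trim_intensity_gap(picks_1iv, factor=3.0)
        k = [p for p in picks_1i if any(_match_1i_1iv(p, q, tol_c, tol_n) for q in confirm)]
        r = [p for p in picks_1i if p not in k]
        kept[peak.id] = k
        removed[peak.id] = r

    def same(a: list[PickedPeak2D], b: list[PickedPeak2D]) -> bool:
        if len(a) != len(b):
            return False
        used = set()
        for p in a:
            hit = next(
                (
                    j
                    for j, q in enumerate(b)
                    if j not in used
                    and abs(p.x_ppm - q.x_ppm) <= tol_c
                    and abs(p.y_ppm - q.y_ppm) <= tol_n
                ),
                None,
            )
            if hit is None:
                return False
            used.add(hit)
        return True

    ids = list(kept)
    n_expected = 2  # a clean (1i) plane carries exactly two peak types
    identical = all(same(kept[ids[0]], kept[i]) for i in ids[1:])
    ambiguous = identical and any(len(kept[i]) > n_expected for i in ids)
    if ambiguous:
        # no information gained: hand the original picks back unmodified
        kept = {m[0].id: list(m[1]) for m in members}
        removed = {m[0].id: [] for m in members}
    return OverlapResolution(kept=kept, removed=removed, ambiguous=ambiguous)
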