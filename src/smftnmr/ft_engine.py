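"""IPAP virtual decoupling, direct-dimension processing, MFT and SMFT.

Processing chain for the carbon-detected NUS experiments:

1. :func:`combine_ipap` removes the CA-CO doublet in the direct dimension by
   recombining the in-phase and (90deg phase-rotated) anti-phase components,
   frequency-shifting them by -J/2 and +J/2 and summing ("virtual
   decoupling").
2. :func:`process_direct` applies a cosine-square weighting over the
   acquisition time, zero-fills to 2048 complex points, Fourier-transforms
   the direct dimension and keeps the absorptive (real) part.  The result is
   a *hybrid* dataset: frequency along the direct axis, NUS evolution times
   along the indirect ones.
3. :func:`mft` evaluates the multidimensional Fourier sum of the NUS data on
   arbitrary indirect frequency grids (unit weights, absorptive part) -- the
   brute-force transform used for the 4D basis spectrum.
4. :func:`smft_plane` computes a 2D cross-section of the full spectrum by
   pinning the fixed dimensions of a fixing variant to the frequencies of a
   basis peak (sparse MFT).  No apodization is applied in indirect
   dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .experiments import Dimension, Experiment
from .fid_simulator import NUSDataset
from .fixing_catalog import BasisPeak, FixingVariant, fixed_frequencies

NFFT = 2048  # direct-dimension zero-fill size (complex points)

#: default free-grid step divisors: step = 1 / (divisor * t_max) per element
DEFAULT_STEP_DIVISORS = {"C": 2, "N": 2, "H": 2}


@dataclass(frozen=True)
class PlaneAxis:
    """One frequency axis of a cross-section (ppm ascending)."""

    label: str
    element: str
    ppm: np.ndarray
    hz: np.ndarray  # offsets from the carrier

    def __len__(self) -> int:
        return len(self.ppm)

    @property
    def step_ppm(self) -> float:
        return float(self.ppm[1] - self.ppm[0]) if len(self.ppm) > 1 else 0.0


@dataclass
class CrossSection2D:
    """A real 2D cross-section with full provenance.

    ``data[i, j]`` corresponds to ``axes[0].ppm[i]`` x ``axes[1].ppm[j]``.
    """

    data: np.ndarray
    axes: tuple[PlaneAxis, PlaneAxis]
    experiment: str
    variant: str
    basis_peak_id: str
    fixed_ppm: dict[int, float]

    def __post_init__(self):
        if self.data.shape != (len(self.axes[0]), len(self.axes[1])):
            raise ValueError("plane shape does not match its axes")


@dataclass
class HybridDataset:
    """Schedule-indexed hypercomplex components after direct-dimension FT.

    ``data`` has shape (n schedule points, 2^(D-1) components, 2048) and is
    real (absorptive part); the direct axis maps bin m to
    carrier + sw * (m/2048 - 1/2).
    """

    experiment: Experiment
    schedule: object
    acq: object
    data: np.ndarray

    def __post_init__(self):
        if self.data.shape[-1] != NFFT:
            raise ValueError(f"direct axis must hold exactly {NFFT} bins")

    @property
    def direct_dim(self) -> Dimension:
        return self.experiment.direct_dim

    def direct_axis_hz(self) -> np.ndarray:
        sw = self.direct_dim.sw_hz
        return sw * (np.arange(NFFT) / NFFT - 0.5)

    def direct_axis_ppm(self) -> np.ndarray:
        return np.asarray(self.direct_dim.to_ppm(self.direct_axis_hz()))

    def nearest_bin(self, ppm: float) -> int:
        sw = self.direct_dim.sw_hz
        off = float(self.direct_dim.to_hz(ppm))
        m = int(round((off / sw + 0.5) * NFFT))
        return min(max(m, 0), NFFT - 1)

    def bin_ppm(self, m: int) -> float:
        return float(self.direct_axis_ppm()[m])


# ---------------------------------------------------------------------------
# IPAP virtual decoupling


def combine_ipap(dataset: NUSDataset) -> NUSDataset:
    """Collapse the CA-CO doublet by IP/AP recombination.

    The anti-phase part is phase-rotated by 90deg (x i), the sum IP + iAP and
    difference IP - iAP are frequency-shifted by -J/2 and +J/2 through
    time-domain multiplication by e^(-+ i pi J t), and averaged.  For the
    ideal signal model the doublet collapses exactly to a single line at the
    chemical-shift position with twice the amplitude of one doublet
    component.
    """
    if dataset.ip is None or dataset.ap is None:
        raise ValueError(
            "dataset lacks IP and/or AP components; virtual decoupling "
            "requires the interleaved IPAP acquisition"
        )
    if dataset.acq.j_caco <= 0:
        raise ValueError("J(CA-CO) must be > 0")
    t = dataset.direct_times()
    ph = np.exp(-1j * np.pi * dataset.acq.j_caco * t)  # shift by -J/2
    s = dataset.ip + 1j * dataset.ap
    d = dataset.ip - 1j * dataset.ap
    data = 0.5 * (s * ph + d * np.conj(ph))
    return NUSDataset(
        experiment=dataset.experiment,
        schedule=dataset.schedule,
        acq=dataset.acq,
        data=data,
    )


# ---------------------------------------------------------------------------
# direct-dimension processing


def process_direct(dataset: NUSDataset) -> HybridDataset:
    """Weight, zero-fill to 2048, FT and take the real part of the direct dim."""
    if not dataset.is_decoupled:
        raise ValueError("run combine_ipap before direct-dimension processing")
    dim = dataset.experiment.direct_dim
    t = dataset.direct_times()
    w = np.cos(np.pi * t / (2 * dim.t_acq)) ** 2
    K = dataset.data.shape[0]
    out = np.empty(dataset.data.shape[:2] + (NFFT,), dtype=np.float64)
    chunk = max(1, int(2**24 // (dataset.data.shape[1] * NFFT)))
    for k0 in range(0, K, chunk):
        x = dataset.data[k0 : k0 + chunk] * w
        x[..., 0] *= 0.5  # half first point: removes the DC baseline offset
        spec = np.fft.fftshift(np.fft.fft(x, n=NFFT, axis=-1), axes=-1)
        out[k0 : k0 + chunk] = spec.real
    return HybridDataset(
        experiment=dataset.experiment,
        schedule=dataset.schedule,
        acq=dataset.acq,
        data=out,
    )


# ---------------------------------------------------------------------------
# hypercomplex NUS Fourier evaluation


def _bit_axes(A: np.ndarray, nind: int) -> np.ndarray:
    """Reshape the component axis (axis 1) into nind binary axes so that
    axis 1+d corresponds to the cos/sin bit of indirect dimension d."""
    K = A.shape[0]
    rest = A.shape[2:]
    B = A.reshape((K,) + (2,) * nind + rest)
    # after reshape, axis 1 is the *highest* bit; reorder to bit order
    order = [0] + [1 + (nind - 1 - d) for d in range(nind)] + list(
        range(1 + nind, B.ndim)
    )
    return np.transpose(B, order)


def _reduce_fixed(B: np.ndarray, weights: dict[int, tuple[np.ndarray, np.ndarray]]):
    """Collapse fixed indirect dimensions: cos-part * cos + sin-part * sin.

    ``B`` comes from :func:`_bit_axes`; ``weights[d] = (cos(2 pi w t_d),
    sin(2 pi w t_d))``, each of shape (K,).  Processing in descending d keeps
    the axis numbering of the remaining (smaller-d) bits valid.
    """
    for d in sorted(weights, reverse=True):
        c, s = weights[d]
        ax = 1 + d
        b0 = np.take(B, 0, axis=ax)
        b1 = np.take(B, 1, axis=ax)
        shape = (B.shape[0],) + (1,) * (b0.ndim - 1)
        B = b0 * c.reshape(shape) + b1 * s.reshape(shape)
    return B


def _trig_matrices(t: np.ndarray, grid_hz: np.ndarray):
    arg = 2 * np.pi * np.outer(t, grid_hz)  # (K, G)
    return np.cos(arg), np.sin(arg)


def mft(
    hybrid: HybridDataset,
    grids_ppm: list[np.ndarray],
    direct_bin: int,
) -> np.ndarray:
    """Brute-force NUS Fourier sum on indirect frequency grids.

    For every indirect frequency tuple the hypercomplex components are
    demodulated dimension by dimension (cosine part x cos + sine part x sin,
    i.e. the absorptive part of e^(-i 2 pi w t) applied hypercomplexly) and
    summed over the schedule with unit weights.  Returns a real array of
    shape (len(grid_1), ..., len(grid_{D-1})).  Complexity is
    O(n_points x grid size).
    """
    exp = hybrid.experiment
    nind = exp.n_indirect
    if len(grids_ppm) != nind:
        raise ValueError(f"expected {nind} grids, got {len(grids_ppm)}")
    t = hybrid.schedule.times()
    A = hybrid.data[:, :, direct_bin]  # (K, ncomp)
    B = _bit_axes(A, nind)  # (K, 2, ..., 2)
    mats = []
    for d in range(nind):
        g_hz = np.asarray(exp.dims[d].to_hz(np.asarray(grids_ppm[d], dtype=float)))
        mats.append(_trig_matrices(t[:, d], g_hz))

    shape = tuple(len(g) for g in grids_ppm)
    out = np.zeros(shape)
    K = t.shape[0]
    for b in range(2**nind):
        Ab = B[(slice(None),) + tuple((b >> d) & 1 for d in range(nind))]  # (K,)
        term = Ab
        # successive expansion over all but the last dim, contraction on the last
        if nind == 1:
            M = mats[0][(b >> 0) & 1]
            out += Ab @ M
            continue
        T = Ab[:, None] * mats[0][(b >> 0) & 1]  # (K, G1)
        for d in range(1, nind - 1):
            M = mats[d][(b >> d) & 1]  # (K, Gd)
            T = T[..., None] * M.reshape((K,) + (1,) * (T.ndim - 1) + (M.shape[1],))
        M = mats[nind - 1][(b >> (nind - 1)) & 1]
        out += np.tensordot(T, M, axes=(0, 0))
    return out


def mft_point(
    hybrid: HybridDataset,
    ppms: tuple[float, ...],
    direct_bins: np.ndarray | int,
) -> np.ndarray:
    """Evaluate the NUS Fourier sum at a single indirect frequency tuple for
    one or more direct bins (used for peak-position refinement)."""
    exp = hybrid.experiment
    nind = exp.n_indirect
    bins = np.atleast_1d(np.asarray(direct_bins, dtype=int))
    t = hybrid.schedule.times()
    A = hybrid.data[:, :, bins]  # (K, ncomp, B)
    B = _bit_axes(A, nind)
    weights = {}
    for d in range(nind):
        w_hz = float(exp.dims[d].to_hz(ppms[d]))
        arg = 2 * np.pi * w_hz * t[:, d]
        weights[d] = (np.cos(arg), np.sin(arg))
    red = _reduce_fixed(B, weights)  # (K, B)
    vals = red.sum(axis=0)
    return vals if np.ndim(direct_bins) else float(vals[0])


# ---------------------------------------------------------------------------
# SMFT cross-sections


def default_grid(dim: Dimension, step_divisor: int | None = None) -> np.ndarray:
    """Full-window ppm grid at step 1/(divisor * t_max) (divisor default 2)."""
    if step_divisor is None:
        step_divisor = DEFAULT_STEP_DIVISORS.get(dim.element, 2)
    step = 1.0 / (step_divisor * dim.t_max)
    half = dim.sw_hz / 2
    hz = np.arange(-half, half + step / 2, step)
    return np.asarray(dim.to_ppm(hz))


def smft_plane(
    hybrid: HybridDataset,
    variant: FixingVariant,
    basis_peak: BasisPeak,
    grids_ppm: dict[int, np.ndarray] | None = None,
    step_divisors: dict[str, int] | None = None,
    direct_window_ppm: tuple[float, float] | None = None,
) -> CrossSection2D:
    """A 2D cross-section with the variant's fixed dimensions pinned.

    Evaluates exactly the same hypercomplex sum as :func:`mft`, restricted to
    the plane spanned by the variant's two free dimensions.  A fixed direct
    dimension is read at the nearest of the 2048 bins; a free direct
    dimension contributes its (optionally windowed) frequency axis.  Free
    indirect grids default to the full spectral window at a step of
    1/(divisor x t_max).
    """
    exp = hybrid.experiment
    if variant.experiment != exp.id:
        raise ValueError(
            f"variant {variant.id} belongs to {variant.experiment}, dataset is {exp.id}"
        )
    nind = exp.n_indirect
    direct = exp.n_dims - 1
    fixed = fixed_frequencies(variant, basis_peak)
    for d, ppm in fixed.items():
        if not exp.dims[d].contains_ppm(ppm):
            raise ValueError(
                f"fixed frequency {ppm:.3f} ppm lies outside the spectral "
                f"window of dimension {d + 1} ({exp.dims[d].label})"
            )

    t = hybrid.schedule.times()
    # data along the direct axis: a single fixed bin, or the free window
    if variant.fixes_direct:
        bin_sel = np.array([hybrid.nearest_bin(fixed[direct])])
        direct_axis = None
    else:
        axis_ppm = hybrid.direct_axis_ppm()
        axis_hz = hybrid.direct_axis_hz()
        if direct_window_ppm is not None:
            lo, hi = sorted(direct_window_ppm)
            sel = np.nonzero((axis_ppm >= lo) & (axis_ppm <= hi))[0]
        else:
            sel = np.arange(NFFT)
        bin_sel = sel
        direct_axis = PlaneAxis(
            label=exp.direct_dim.label,
            element=exp.direct_dim.element,
            ppm=axis_ppm[sel],
            hz=axis_hz[sel],
        )

    A = hybrid.data[:, :, bin_sel]  # (K, ncomp, B)
    B = _bit_axes(A, nind)
    weights = {}
    for d, ppm in fixed.items():
        if d == direct:
            continue
        w_hz = float(exp.dims[d].to_hz(ppm))
        arg = 2 * np.pi * w_hz * t[:, d]
        weights[d] = (np.cos(arg), np.sin(arg))
    red = _reduce_fixed(B, weights)  # (K, 2, ..., 2 [free indirect bits], B)

    free_ind = [d for d in variant.free if d != direct]
    # axis order of red's bit axes follows ascending dimension index
    free_sorted = sorted(free_ind)

    axes_grids = {}
    sd = step_divisors or {}
    for d in free_ind:
        if grids_ppm is not None and d in grids_ppm:
            g = np.asarray(grids_ppm[d], dtype=float)
        else:
            dim = exp.dims[d]
            g = default_grid(dim, sd.get(dim.label, sd.get(dim.element)))
        axes_grids[d] = g

    mats = {
        d: _trig_matrices(t[:, d], np.asarray(exp.dims[d].to_hz(axes_grids[d])))
        for d in free_ind
    }

    nf = len(free_ind)
    shape = tuple(len(axes_grids[d]) for d in free_sorted) + (len(bin_sel),)
    acc = np.zeros(shape)
    for b in range(2**nf):
        idx = (slice(None),) + tuple((b >> i) & 1 for i in range(nf))
        Ab = red[idx]  # (K, B)
        if nf == 1:
            d0 = free_sorted[0]
            M = mats[d0][(b >> 0) & 1]
            acc += np.tensordot(M, Ab, axes=(0, 0))  # (G, B)
        else:  # nf == 2; the direct dimension is fixed here, so Ab is (K, 1)
            d0, d1 = free_sorted
            M0 = mats[d0][(b >> 0) & 1]  # (K, G0)
            M1 = mats[d1][(b >> 1) & 1]  # (K, G1)
            acc[..., 0] += M0.T @ (M1 * Ab[:, 0][:, None])
    # assemble plane with axes in the variant's declared free order
    plane_axes = []
    slices = acc
    if variant.fixes_direct:
        slices = acc[..., 0]
        for d in variant.free:
            dim = exp.dims[d]
            g = axes_grids[d]
            plane_axes.append(
                PlaneAxis(dim.label, dim.element, g, np.asarray(dim.to_hz(g)))
            )
        if variant.free != tuple(free_sorted):
            slices = slices.T
        data = slices
    else:
        # one free indirect axis + the direct axis
        d0 = free_ind[0]
        dim = exp.dims[d0]
        g = axes_grids[d0]
        ind_axis = PlaneAxis(dim.label, dim.element, g, np.asarray(dim.to_hz(g)))
        data = slices  # (G, B)
        if variant.free[0] == direct:
            data = data.T
            plane_axes = [direct_axis, ind_axis]
        else:
            plane_axes = [ind_axis, direct_axis]

    return CrossSection2D(
        data=np.ascontiguousarray(data),
        axes=tuple(plane_axes),
        experiment=exp.id,
        variant=variant.id,
        basis_peak_id=basis_peak.id,
        fixed_ppm=fixed,
    )
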