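"""IPAP decoupling, direct processing, MFT and SMFT cross-sections."""

import numpy as np
import pytest

from smftnmr.experiments import BASIS_4D, Dimension, Experiment
from smftnmr.fid_simulator import AcquisitionConfig, NUSDataset, simulate
from smftnmr.fixing_catalog import BasisPeak, get_variant
from smftnmr.ft_engine import (
    NFFT,
    combine_ipap,
    default_grid,
    mft,
    mft_point,
    process_direct,
    smft_plane,
)
from smftnmr.nus_schedule import SamplingConfig, generate_schedule
from smftnmr.shift_synth import TheoreticalPeak

# a minimal 2D experiment (one indirect CO dim + direct CO) for oracles
EXP2D = Experiment(
    id="test2d",
    name="2D test",
    dims=(
        Dimension("CO", "C", 175.5, 500.0, t_max=0.064),
        Dimension("CO", "C", 175.5, 2200.0, t_acq=0.106),
    ),
    default_increments=33,
)


def peak2d(co_ind_ppm, co_dir_ppm, sign=1):
    return TheoreticalPeak(
        experiment="test2d",
        residue=1,
        coords=(("CO", 1, co_ind_ppm), ("CO", 0, co_dir_ppm)),
        sign=sign,
        family="sequential",
    )


def full_grid_2d():
    return generate_schedule(SamplingConfig.for_experiment(EXP2D, n=33, seed=0))


@pytest.fixture(scope="module")
def hybrid2d():
    sch = full_grid_2d()
    peaks = [peak2d(175.9, 175.0), peak2d(175.1, 176.2, sign=-1)]
    ds = simulate(peaks, sch, AcquisitionConfig(), EXP2D)
    return process_direct(combine_ipap(ds))


class TestCombineIpap:
    def _one_peak_spec(self, r2_direct=10.0, kill_ap=False, j=53.0):
        sch = full_grid_2d()
        ds = simulate([peak2d(175.5, 175.8)], sch, AcquisitionConfig(j_caco=j, r2_direct=r2_direct), EXP2D)
        if kill_ap:
            ds = NUSDataset(
                experiment=ds.experiment, schedule=ds.schedule, acq=ds.acq,
                ip=ds.ip, ap=np.zeros_like(ds.ap),
            )
        hyb = process_direct(combine_ipap(ds))
        k0 = int(np.nonzero((sch.indices == 0).all(axis=1))[0][0])
        return hyb, hyb.data[k0, 0], hyb.direct_axis_hz()

    def test_doublet_collapses_to_single_line(self):
        hyb, spec, axis = self._one_peak_spec()
        nu = float(EXP2D.direct_dim.to_hz(175.8))
        i0 = np.argmin(np.abs(axis - nu))
        assert np.argmax(spec) == i0
        for off in (-53.0 / 2, 53.0 / 2):
            i = np.argmin(np.abs(axis - (nu + off)))
            assert abs(spec[i]) < 0.05 * spec[i0]  # residual < 5 %

    def test_collapsed_amplitude_twice_doublet_component(self):
        hyb, spec, axis = self._one_peak_spec()
        # reference: in-phase-only processing shows the J-split doublet
        sch = full_grid_2d()
        ds = simulate([peak2d(175.5, 175.8)], sch, AcquisitionConfig(), EXP2D)
        ip_only = NUSDataset(experiment=ds.experiment, schedule=ds.schedule, acq=ds.acq, data=ds.ip)
        hyb_ip = process_direct(ip_only)
        k0 = int(np.nonzero((sch.indices == 0).all(axis=1))[0][0])
        spec_ip = hyb_ip.data[k0, 0]
        nu = float(EXP2D.direct_dim.to_hz(175.8))
        comp = spec_ip[np.argmin(np.abs(axis - (nu - 53.0 / 2)))]
        assert spec.max() / comp == pytest.approx(2.0, rel=0.1)

    def test_zero_antiphase_leaves_doublet(self):
        hyb, spec, axis = self._one_peak_spec(kill_ap=True)
        nu = float(EXP2D.direct_dim.to_hz(175.8))
        peak = np.max(np.abs(spec))
        for off in (-53.0, 53.0):  # satellites remain when AP carries no signal
            i = np.argmin(np.abs(axis - (nu + off)))
            assert abs(spec[i]) > 0.2 * peak

    def test_missing_ap_refused(self):
        sch = full_grid_2d()
        ds = simulate([peak2d(175.5, 175.8)], sch, AcquisitionConfig(), EXP2D)
        broken = NUSDataset(experiment=ds.experiment, schedule=ds.schedule, acq=ds.acq, ip=ds.ip)
        with pytest.raises(ValueError, match="AP"):
            combine_ipap(broken)


class TestProcessDirect:
    def test_zero_input_zero_output(self):
        sch = full_grid_2d()
        ds = simulate([], sch, AcquisitionConfig(), EXP2D)
        hyb = process_direct(combine_ipap(ds))
        assert not np.any(hyb.data)

    def test_peak_at_carrier_maps_to_center_bin(self):
        sch = full_grid_2d()
        ds = simulate([peak2d(175.5, 175.5)], sch, AcquisitionConfig(), EXP2D)
        hyb = process_direct(combine_ipap(ds))
        k0 = int(np.nonzero((sch.indices == 0).all(axis=1))[0][0])
        assert np.argmax(hyb.data[k0, 0]) == NFFT // 2

    def test_off_carrier_peak_within_one_bin_of_mapping(self):
        ppm = 176.23
        sch = full_grid_2d()
        ds = simulate([peak2d(175.5, ppm)], sch, AcquisitionConfig(), EXP2D)
        hyb = process_direct(combine_ipap(ds))
        k0 = int(np.nonzero((sch.indices == 0).all(axis=1))[0][0])
        assert abs(int(np.argmax(hyb.data[k0, 0])) - hyb.nearest_bin(ppm)) <= 1

    def test_requires_decoupled_input(self):
        sch = full_grid_2d()
        ds = simulate([peak2d(175.5, 175.5)], sch, AcquisitionConfig(), EXP2D)
        with pytest.raises(ValueError, match="combine_ipap"):
            process_direct(ds)


class TestMFT:
    def test_matches_fft_on_uniform_data(self, hybrid2d):
        """On a fully sampled grid the NUS Fourier sum must equal the FFT."""
        sch = hybrid2d.schedule
        order = np.argsort(sch.indices[:, 0])
        b = hybrid2d.nearest_bin(175.0)
        z = hybrid2d.data[order, 0, b] + 1j * hybrid2d.data[order, 1, b]
        ref = np.real(np.fft.fft(z))
        N = len(z)
        freqs_hz = np.arange(N) * EXP2D.dims[0].sw_hz / N
        grid_ppm = np.asarray(EXP2D.dims[0].to_ppm(freqs_hz))
        out = mft(hybrid2d, [grid_ppm], b)
        assert np.max(np.abs(out - ref)) <= 1e-9 * np.max(np.abs(ref))

    def test_zero_data_zero_spectrum(self):
        sch = full_grid_2d()
        hyb = process_direct(combine_ipap(simulate([], sch, AcquisitionConfig(), EXP2D)))
        out = mft(hyb, [np.linspace(175.0, 176.0, 11)], 1000)
        assert not np.any(out)

    def test_single_peak_located_within_grid_step(self, hybrid2d):
        truth = 175.9
        g = default_grid(EXP2D.dims[0], 2)
        out = mft(hybrid2d, [g], hybrid2d.nearest_bin(175.0))
        step = abs(g[1] - g[0])
        assert abs(g[int(np.argmax(out))] - truth) <= step

    def test_amplitude_scales_linearly(self):
        sch = full_grid_2d()
        acq = AcquisitionConfig()
        g = [np.array([175.9])]
        vals = []
        for amp_sign in (1, -1):
            ds = simulate([peak2d(175.9, 175.0, sign=amp_sign)], sch, acq, EXP2D)
            hyb = process_direct(combine_ipap(ds))
            vals.append(mft(hyb, g, hyb.nearest_bin(175.0))[0])
        assert vals[0] == pytest.approx(-vals[1], rel=1e-12)

    def test_mft_point_matches_mft(self, hybrid2d):
        b = hybrid2d.nearest_bin(175.0)
        v_grid = mft(hybrid2d, [np.array([175.82])], b)[0]
        v_point = mft_point(hybrid2d, (175.82,), b)
        assert v_point == pytest.approx(v_grid, rel=1e-12)


class TestSMFTPlane:
    def test_fixed_frequency_outside_window_refused(self, small4d):
        bp = BasisPeak("x", co_i=175.0, n_ip1=120.0, n_i=170.0, co_im1=175.0)
        with pytest.raises(ValueError, match="dimension 3"):
            smft_plane(small4d["hybrid"], get_variant("1i"), bp)

    def test_plane_carries_provenance_and_axes(self, small4d):
        bp = small4d["basis"][0]
        plane = smft_plane(small4d["hybrid"], get_variant("1i"), bp)
        assert plane.variant == "1i" and plane.basis_peak_id == bp.id
        assert plane.data.shape == (len(plane.axes[0]), len(plane.axes[1]))
        assert plane.axes[0].label == "CO" and plane.axes[1].label == "N"
        assert set(plane.fixed_ppm) == {2, 3}

    def test_free_direct_plane_axes(self, small4d):
        bp = small4d["basis"][0]
        plane = smft_plane(
            small4d["hybrid"], get_variant("1iv"), bp, direct_window_ppm=(173.0, 178.0)
        )
        assert plane.axes[0].label == "N" and plane.axes[1].label == "CO"
        assert plane.axes[1].ppm.min() >= 173.0 and plane.axes[1].ppm.max() <= 178.0

    def test_default_grid_step_bound(self):
        dim = BASIS_4D.dims[0]
        g = default_grid(dim)
        step_hz = abs(float(dim.to_hz(g[1]) - dim.to_hz(g[0])))
        assert step_hz <= 1.0 / (2 * dim.t_max) + 1e-9
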