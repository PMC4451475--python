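import numpy as np
import pytest

from smftnmr.assigner import CSSS, Slot
from smftnmr.experiments import BASIS_4D
from smftnmr.fid_simulator import AcquisitionConfig, simulate
from smftnmr.ft_engine import combine_ipap, process_direct
from smftnmr.nus_schedule import SamplingConfig, generate_schedule
from smftnmr.peak_analysis import build_basis_peaklist, windows_from_table
from smftnmr.pipeline import PipelineConfig, run_pipeline
from smftnmr.shift_synth import enumerate_peaks, generate_shift_table

TEN_MER = "ASKLGVEDTR"


@pytest.fixture(scope="session")
def small4d():
    """A 10-residue noiseless 4D basis dataset, processed and picked."""
    table = generate_shift_table(TEN_MER, seed=3, ensure_pair_separation=(0.1, 0.2))
    schedule = generate_schedule(SamplingConfig.for_experiment(BASIS_4D, seed=7))
    peaks = enumerate_peaks("basis4d", table)
    acq = AcquisitionConfig(seed=5)
    hybrid = process_direct(combine_ipap(simulate(peaks, schedule, acq, BASIS_4D)))
    basis, info = build_basis_peaklist(hybrid, windows=windows_from_table(table))
    return {
        "table": table,
        "schedule": schedule,
        "peaks": peaks,
        "hybrid": hybrid,
        "basis": basis,
        "info": info,
    }


@pytest.fixture(scope="session")
def full_run():
    """The bundled 60-residue synthetic IDP, noiseless, all experiments."""
    return run_pipeline(PipelineConfig(seed=1))


def csss_from_truth(table, i, bid=None) -> CSSS:
    """A CSSS whose slots hold the ground-truth shifts the experiment suite
    can theoretically deliver for basis residue i (test scaffolding)."""
    from smftnmr.fixing_catalog import BasisPeak

    L = len(table.sequence)
    bp = BasisPeak(
        id=bid or f"t{i:03d}",
        co_i=table.get(i, "CO"),
        n_ip1=table.get(i + 1, "N"),
        n_i=table.get(i, "N"),
        co_im1=table.get(i - 1, "CO"),
        intensity=-1.0,
        sign=+1 if table.aa(i) == "G" else -1,
    )
    c = CSSS(id=bp.id, basis=bp)

    def put(kind, off, src="test"):
        v = table.get(i + off, kind)
        if v is not None:
            c.slots[(kind, off)] = Slot(value=v, source=src, intensity=1.0)

    put("CO", -1, "basis")
    put("CO", 0, "basis")
    put("N", 0, "basis")
    put("N", 1, "basis")
    if i + 1 <= L - 1:  # the 1ii plane needs the successor's basis peak
        put("CO", 1)
        put("N", 2)
    if i - 1 >= 2:  # the 1iii plane needs the predecessor's basis peak
        put("CO", -2)
        put("N", -1)
    for kind in ("CA", "CB", "HA", "HB"):
        put(kind, -1)
        put(kind, 0)
    put("HN", 0)
    put("HN", 1)
    return c
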