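"""End-to-end pipeline: simulate -> process -> pick -> assign -> evaluate.

Every stage is a plain function over explicit artifacts so that the CLI, the
tests and the acceptance script can re-run any part in isolation;``
run_pipeline`` chains them and optionally persists the intermediates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as sio
from .assigner import (
    CSSS,
    build_csss,
    evaluate_assignment,
    form_chains,
    join_chains_over_gaps,
    link_csss,
    map_chains,
    true_positions,
)
from .experiments import EXPERIMENTS, get_experiment
from .fid_simulator import AcquisitionConfig, NUSDataset, simulate
from .fixing_catalog import BasisPeak, list_variants
from .ft_engine import HybridDataset, combine_ipap, process_direct, smft_plane
from .nus_schedule import SamplingConfig, Schedule, generate_schedule
from .peak_analysis import (
    build_basis_peaklist,
    group_overlapping_basis_peaks,
    pick_peaks_2d,
    refine_plane_picks,
    resolve_plane_overlap,
    windows_from_table,
)
from .shift_synth import ShiftTable, enumerate_peaks, generate_shift_table

logger = logging.getLogger(__name__)

#: bundled worked example: a 60-residue synthetic IDP with 10% proline and
#: 10% glycine scattered through an otherwise mixed hydrophilic sequence
EXAMPLE_SEQUENCE = "MDSKAGQVTPELNGKAYSEGRFDQPLMTVKPNEDGALPIRQSTGKFVPYHPNADLSGKQM"

ALL_EXPERIMENTS = ("basis4d", "habcab5d", "hn5d")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, with acquisition-table defaults."""

    sequence: str = EXAMPLE_SEQUENCE
    seed: int = 1
    jitter_sd: float = 0.3
    noise_sd: float = 0.0
    collision_free: bool = True  # redraw shifts until CO-N anchor pairs separate
    experiments: tuple[str, ...] = ALL_EXPERIMENTS
    increments: dict = field(default_factory=dict)  # experiment id -> n
    tolerances: dict = field(default_factory=dict)  # element class -> ppm
    threshold_sigma: float = 6.0
    basis_rel_threshold: float = 0.25
    # free-grid step = 1/(divisor * t_max), keyed by dimension label (with
    # element-class fallback); the proton and aliphatic-carbon axes need
    # finer-than-2x sampling for sub-tolerance position interpolation
    step_divisors: dict = field(
        default_factory=lambda: {"Hab": 6, "Cab": 4, "HN": 4, "N": 4, "CO": 2}
    )
    k_sd: float = 3.0
    j_caco: float = 53.0
    r2_indirect: float = 47.0
    r2_direct: float = 10.0
    family_scale: dict = field(default_factory=dict)
    save_fids: bool = False

    def n_for(self, experiment_id: str) -> int:
        return int(self.increments.get(experiment_id) or get_experiment(experiment_id).default_increments)

    def validate(self) -> None:
        if "basis4d" not in self.experiments:
            raise ValueError("the 4D basis experiment is mandatory")
        for e in self.experiments:
            exp = get_experiment(e)
            n = self.n_for(e)
            cfg = SamplingConfig.for_experiment(exp, n=n, seed=0)
            cfg.validate()
            if n > 4 * exp.default_increments:
                warnings.warn(
                    f"{e}: {n} increments is far above the published "
                    f"acquisition scale ({exp.default_increments})",
                    stacklevel=2,
                )

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["experiments"] = list(self.experiments)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "experiments" in d:
            d["experiments"] = tuple(d["experiments"])
        return cls(**d)


@dataclass
class PipelineResult:
    config: PipelineConfig
    table: ShiftTable
    schedules: dict
    hybrids: dict
    basis_peaks: list[BasisPeak]
    basis_info: dict
    picks: dict  # basis id -> variant id -> [PickedPeak2D]
    overlap_groups: list
    cssss: list[CSSS]
    chains: list
    assignment: object
    report: object  # DataFrame
    summary: dict


# ---------------------------------------------------------------------------
# stages


def stage_shifts(config: PipelineConfig) -> ShiftTable:
    sep = None
    if config.collision_free:
        from .shift_synth import PAIR_SEPARATION_CO, PAIR_SEPARATION_N

        sep = (PAIR_SEPARATION_CO, PAIR_SEPARATION_N)
    return generate_shift_table(
        config.sequence, seed=config.seed, jitter_sd=config.jitter_sd,
        ensure_pair_separation=sep,
    )


def stage_schedules(config: PipelineConfig) -> dict[str, Schedule]:
    out = {}
    for k, e in enumerate(config.experiments):
        cfg = SamplingConfig.for_experiment(
            get_experiment(e), n=config.n_for(e), seed=(config.seed * 7919 + k) % (2**31)
        )
        out[e] = generate_schedule(cfg)
        logger.info("schedule %s: %d points, final radius %.4f", e, out[e].n, out[e].final_radius)
    return out


def _acq(config: PipelineConfig, k: int) -> AcquisitionConfig:
    return AcquisitionConfig(
        j_caco=config.j_caco,
        r2_indirect=config.r2_indirect,
        r2_direct=config.r2_direct,
        noise_sd=config.noise_sd,
        seed=(config.seed * 104729 + k) % (2**31),
        family_scale=config.family_scale,
    )


def stage_datasets(
    config: PipelineConfig, table: ShiftTable, schedules: dict[str, Schedule]
) -> dict[str, NUSDataset]:
    out = {}
    for k, e in enumerate(config.experiments):
        peaks = enumerate_peaks(e, table)
        out[e] = simulate(peaks, schedules[e], _acq(config, k), get_experiment(e))
        logger.info("simulated %s: %d peaks", e, len(peaks))
    return out


def stage_process(datasets: dict[str, NUSDataset]) -> dict[str, HybridDataset]:
    return {e: process_direct(combine_ipap(ds)) for e, ds in datasets.items()}


def stage_basis(
    config: PipelineConfig, hybrid4d: HybridDataset, table: ShiftTable | None = None
):
    windows = windows_from_table(table) if table is not None else None
    return build_basis_peaklist(
        hybrid4d, windows=windows, rel_threshold=config.basis_rel_threshold
    )


def compute_plane(hybrids, variant, basis_peak, config, direct_window=None):
    hybrid = hybrids[variant.experiment]
    return smft_plane(
        hybrid,
        variant,
        basis_peak,
        step_divisors=config.step_divisors,
        direct_window_ppm=direct_window,
    )


def stage_planes_and_picks(
    config: PipelineConfig,
    hybrids: dict[str, HybridDataset],
    basis_peaks: list[BasisPeak],
    direct_window: tuple[float, float] | None = None,
):
    """Compute all cross-sections of every basis peak and pick them.

    The free direct axis of the (1iii)/(1iv) planes is restricted to
    ``direct_window`` (ppm) when given, which keeps those planes to the
    populated CO region.
    """
    picks: dict[str, dict[str, list]] = {}
    for bp in basis_peaks:
        picks[bp.id] = {}
        for e in config.experiments:
            if e not in hybrids:
                continue
            for variant in list_variants(e):
                plane = compute_plane(
                    hybrids, variant, bp, config,
                    direct_window=direct_window if variant.direct_is_free else None,
                )
                raw = pick_peaks_2d(plane, threshold_sigma=config.threshold_sigma)
                picks[bp.id][variant.id] = refine_plane_picks(
                    hybrids[variant.experiment], variant, bp, raw
                )
    return picks


def stage_overlap_resolution(
    config: PipelineConfig, basis_peaks: list[BasisPeak], picks: dict
):
    """Disambiguate coinciding (1i) planes via the (1iv) cross-check."""
    from .nuclei import tolerance_for

    tol_c = tolerance_for("C", config.tolerances)
    tol_n = tolerance_for("N", config.tolerances)
    groups = group_overlapping_basis_peaks(basis_peaks, tol_c, tol_n)
    resolutions = []
    for group in groups:
        members = [(bp, picks[bp.id].get("1i", []), picks[bp.id].get("1iv", [])) for bp in group]
        res = resolve_plane_overlap(members, tol_c, tol_n)
        resolutions.append((group, res))
        if not res.ambiguous:
            for bp in group:
                picks[bp.id]["1i"] = res.kept[bp.id]
        else:
            logger.warning(
                "overlap group %s is fully degenerate; left unresolved",
                [bp.id for bp in group],
            )
    return groups, resolutions


def stage_assign(config: PipelineConfig, basis_peaks: list[BasisPeak], picks: dict):
    from .assigner import plane_interference

    interference = plane_interference(basis_peaks)
    cssss = [
        build_csss(
            bp, picks.get(bp.id, {}), tolerances=config.tolerances,
            k_sd=config.k_sd, interference=interference.get(bp.id),
        )
        for bp in basis_peaks
    ]
    graph = link_csss(cssss, tolerances=config.tolerances)
    chains = form_chains(graph)
    by_id = {c.id: c for c in cssss}
    for ch in chains:
        ch.members = [by_id[m] if isinstance(m, str) else m for m in ch.members]
    chains = join_chains_over_gaps(chains, tolerances=config.tolerances)
    assignment = map_chains(chains, config.sequence, k_sd=config.k_sd)
    return cssss, graph, chains, assignment


def stage_evaluate(config, assignment, cssss, table):
    report = evaluate_assignment(assignment, cssss, table, tolerances=config.tolerances)
    truth = true_positions(cssss, table, tolerances=config.tolerances)
    n_correct_csss = sum(
        1 for cid, pos in assignment.positions.items() if truth.get(cid) == pos
    )
    n_incorrect_csss = sum(
        1 for cid, pos in assignment.positions.items() if truth.get(cid) not in (None, pos)
    )
    total = report[report["nucleus"] == "total"].iloc[0]
    summary = {
        "n_basis_peaks": len(cssss),
        "n_assigned_csss": len(assignment.positions),
        "n_correct_csss": n_correct_csss,
        "n_incorrect_csss": n_incorrect_csss,
        "pct_correct": float(total["pct_correct"]),
        "pct_incorrect": float(total["pct_incorrect"]),
    }
    return report, summary


# ---------------------------------------------------------------------------
# driver


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    table: ShiftTable | None = None,
    resume: bool = False,
) -> PipelineResult:
    """Run the whole pipeline; optionally persist / resume intermediates.

    A pre-made ``table`` overrides the synthetic shift draw (used e.g. for
    engineered degeneracy studies).  With ``resume=True`` and an ``outdir``
    holding ``basis.tsv`` + ``picks.json`` from an earlier run, the
    expensive simulation / transform stages are skipped.
    """
    config.validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if table is None:
        table = stage_shifts(config)
    table.validate()
    if out is not None:
        table.to_tsv(out / "shifts.tsv")

    if resume and out is not None and (out / "basis.tsv").exists() and (out / "picks.json").exists():
        logger.info("resuming from %s", out)
        basis_peaks = sio.read_basis_table(out / "basis.tsv")
        picks = sio.read_picks_json(out / "picks.json")
        schedules, hybrids, basis_info = {}, {}, {"resumed": True}
        overlap_groups = group_overlapping_basis_peaks(basis_peaks)
    else:
        schedules = stage_schedules(config)
        if out is not None:
            for e, sch in schedules.items():
                sch.write(out / f"schedule_{e}.txt")
        datasets = stage_datasets(config, table, schedules)
        if out is not None and config.save_fids:
            for e, ds in datasets.items():
                ds.save(out / f"fid_{e}.h5")
        hybrids = stage_process(datasets)
        del datasets
        basis_peaks, basis_info = stage_basis(config, hybrids["basis4d"], table)
        if out is not None:
            sio.write_basis_table(out / "basis.tsv", basis_peaks)
        windows = windows_from_table(table)
        picks = stage_planes_and_picks(
            config, hybrids, basis_peaks, direct_window=windows["CO"]
        )
        overlap_groups, _ = stage_overlap_resolution(config, basis_peaks, picks)
        if out is not None:
            sio.write_picks_json(out / "picks.json", picks)

    cssss, graph, chains, assignment = stage_assign(config, basis_peaks, picks)
    report, summary = stage_evaluate(config, assignment, cssss, table)
    summary["n_chains"] = len(chains)
    summary["chain_lengths"] = sorted((len(c) for c in chains), reverse=True)
    summary.update({f"basis_{k}": v for k, v in basis_info.items() if np.isscalar(v)})

    if out is not None:
        by_id = {c.id: c for c in cssss}
        assignment.to_frame(by_id).to_csv(out / "assignment.tsv", sep="\t", index=False)
        report.to_csv(out / "report.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))

    return PipelineResult(
        config=config,
        table=table,
        schedules=schedules,
        hybrids=hybrids,
        basis_peaks=basis_peaks,
        basis_info=basis_info,
        picks=picks,
        overlap_groups=overlap_groups,
        cssss=cssss,
        chains=chains,
        assignment=assignment,
        report=report,
        summary=summary,
    )


def repick_with_fraction(
    config: PipelineConfig,
    hybrids: dict[str, HybridDataset],
    basis_peaks: list[BasisPeak],
    experiment_id: str,
    fraction: float,
    direct_window=None,
):
    """Re-transform one experiment's planes from the first ``fraction`` of
    schedule points and re-pick them (the increment-reduction study)."""
    h = hybrids[experiment_id]
    n = int(round(fraction * h.data.shape[0]))
    sub = HybridDataset(
        experiment=h.experiment,
        schedule=h.schedule.head(n),
        acq=h.acq,
        data=h.data[:n],
    )
    picks = {}
    for bp in basis_peaks:
        picks[bp.id] = {}
        for variant in list_variants(experiment_id):
            plane = smft_plane(
                sub, variant, bp,
                step_divisors=config.step_divisors,
                direct_window_ppm=direct_window if variant.direct_is_free else None,
            )
            raw = pick_peaks_2d(plane, threshold_sigma=config.threshold_sigma)
            picks[bp.id][variant.id] = refine_plane_picks(sub, variant, bp, raw)
    return picks
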