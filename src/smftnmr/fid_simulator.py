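"""Synthetic hypercomplex NUS time-domain data (IP and AP components).

The signal model is a sum of exponentially decaying (Lorentzian) resonances
under States-style quadrature in every indirect dimension: a peak of
amplitude a = sign x family scale contributes, at indirect evolution times
(t_1 ... t_{D-1}) and direct acquisition time t,

    a * prod_d mod_d(2 pi nu_d t_d) e^(-R2_d t_d)        (indirect dims)
      * e^(i 2 pi nu_D t) e^(-R2_D t)                    (direct dim)
      * cos(pi J t)  [in-phase]   /   sin(pi J t)  [anti-phase]

where mod_d is cos for the cosine component and sin for the sine component
of dimension d, and J is the one-bond CA-CO scalar coupling that splits the
detected carbonyl line.  The 2^(D-1) cos/sin combinations are stored per
schedule point, IP and AP interleaved conceptually as separate arrays of
identical shape.  Complex Gaussian noise of a stated SD is added
independently to every stored value.  No pulse-sequence physics is modelled
beyond this (no transfer efficiencies, no phase cycling).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .experiments import Dimension, Experiment
from .nus_schedule import SamplingConfig, Schedule
from .shift_synth import TheoreticalPeak

#: default indirect-dimension transverse relaxation rate, s^-1 (~15 Hz
#: Lorentzian linewidth, typical of the narrow lines of a disordered protein)
DEFAULT_R2 = 47.0

#: default direct (carbonyl) relaxation rate, s^-1; IDP CO lines are a few
#: Hz wide, which is what the 106 ms acquisition time is meant to resolve
DEFAULT_R2_DIRECT = 10.0


@dataclass(frozen=True)
class AcquisitionConfig:
    """Physics knobs of the simulation.

    ``r2_indirect`` may be a scalar (applied to every indirect dimension) or
    a sequence per indirect dimension, in s^-1.  ``family_scale`` rescales
    whole peak families (e.g. to de-balance sequential vs diagonal
    transfers); unlisted families default to 1.
    """

    j_caco: float = 53.0
    r2_indirect: float | tuple[float, ...] = DEFAULT_R2
    r2_direct: float = DEFAULT_R2_DIRECT
    noise_sd: float = 0.0
    seed: int = 0
    family_scale: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.j_caco <= 0:
            raise ValueError("J(CA-CO) must be > 0")

    def r2_for(self, experiment: Experiment) -> np.ndarray:
        r2 = self.r2_indirect
        if np.isscalar(r2):
            return np.full(experiment.n_indirect, float(r2))
        r2 = np.asarray(r2, dtype=float)
        if r2.shape != (experiment.n_indirect,):
            raise ValueError("r2_indirect length must match the indirect dimensions")
        return r2

    def to_json(self) -> str:
        return json.dumps(
            {
                "j_caco": self.j_caco,
                "r2_indirect": np.asarray(self.r2_indirect).tolist(),
                "r2_direct": self.r2_direct,
                "noise_sd": self.noise_sd,
                "seed": self.seed,
                "family_scale": self.family_scale,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "AcquisitionConfig":
        d = json.loads(s)
        r2 = d["r2_indirect"]
        if isinstance(r2, list):
            r2 = tuple(r2) if len(r2) > 1 else r2[0]
        return cls(
            j_caco=d["j_caco"],
            r2_indirect=r2,
            r2_direct=d["r2_direct"],
            noise_sd=d["noise_sd"],
            seed=d["seed"],
            family_scale=d["family_scale"],
        )


@dataclass
class NUSDataset:
    """Hypercomplex NUS time-domain data for one experiment.

    ``ip``/``ap`` have shape (n schedule points, 2^(D-1) components,
    n direct points), complex.  Component c uses the sine modulation in
    indirect dimension d iff bit d of c is set ((c >> d) & 1 == 1), cosine
    otherwise.  After virtual decoupling a single combined component set is
    held in ``data`` instead.
    """

    experiment: Experiment
    schedule: Schedule
    acq: AcquisitionConfig
    ip: np.ndarray | None = None
    ap: np.ndarray | None = None
    data: np.ndarray | None = None

    @property
    def is_decoupled(self) -> bool:
        return self.data is not None

    @property
    def n_components(self) -> int:
        return self.experiment.n_components

    def direct_times(self) -> np.ndarray:
        dim = self.experiment.direct_dim
        return np.arange(dim.n_direct_points) / dim.sw_hz

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["experiment"] = _experiment_json(self.experiment)
            f.attrs["acq"] = self.acq.to_json()
            f.attrs["schedule_config"] = json.dumps(
                {
                    "dims": list(map(list, self.schedule.config.dims)),
                    "n": self.schedule.config.n,
                    "seed": self.schedule.config.seed,
                    "final_radius": self.schedule.final_radius,
                }
            )
            f.create_dataset("schedule", data=self.schedule.indices)
            for name in ("ip", "ap", "data"):
                arr = getattr(self, name)
                if arr is not None:
                    f.create_dataset(name, data=arr)

    @classmethod
    def load(cls, path) -> "NUSDataset":
        with h5py.File(path, "r") as f:
            experiment = _experiment_from_json(f.attrs["experiment"])
            acq = AcquisitionConfig.from_json(f.attrs["acq"])
            sc = json.loads(f.attrs["schedule_config"])
            config = SamplingConfig(
                dims=tuple(tuple(d) for d in sc["dims"]), n=sc["n"], seed=sc["seed"]
            )
            schedule = Schedule(
                indices=f["schedule"][...], config=config, final_radius=sc["final_radius"]
            )
            kw = {
                name: (f[name][...] if name in f else None) for name in ("ip", "ap", "data")
            }
        return cls(experiment=experiment, schedule=schedule, acq=acq, **kw)


def _experiment_json(e: Experiment) -> str:
    return json.dumps(
        {
            "id": e.id,
            "name": e.name,
            "default_increments": e.default_increments,
            "dims": [
                {
                    "label": d.label,
                    "element": d.element,
                    "carrier_ppm": d.carrier_ppm,
                    "sw_hz": d.sw_hz,
                    "t_max": d.t_max,
                    "t_acq": d.t_acq,
                }
                for d in e.dims
            ],
        }
    )


def _experiment_from_json(s: str) -> Experiment:
    d = json.loads(s)
    dims = tuple(Dimension(**dd) for dd in d["dims"])
    return Experiment(
        id=d["id"], name=d["name"], dims=dims, default_increments=d["default_increments"]
    )


def simulate(
    peaks: list[TheoreticalPeak],
    schedule: Schedule,
    acq: AcquisitionConfig,
    experiment: Experiment,
) -> NUSDataset:
    """Simulate IP/AP hypercomplex NUS data from a theoretical peak list.

    The dataset is linear in the peak list; an empty list yields pure noise.
    Deterministic for a fixed ``acq.seed``.
    """
    K = schedule.n
    nind = experiment.n_indirect
    ncomp = experiment.n_components
    dim_dir = experiment.direct_dim
    ndir = dim_dir.n_direct_points
    t_ind = schedule.times()  # (K, nind)
    t_dir = np.arange(ndir) / dim_dir.sw_hz
    r2_ind = acq.r2_for(experiment)

    ip = np.zeros((K, ncomp, ndir), dtype=np.complex128)
    ap = np.zeros_like(ip)

    if peaks:
        P = len(peaks)
        offs = np.empty((P, len(experiment.dims)))
        amps = np.empty(P)
        for p, peak in enumerate(peaks):
            if len(peak.coords) != len(experiment.dims):
                raise ValueError(
                    f"peak has {len(peak.coords)} coordinates, experiment "
                    f"{experiment.id} has {len(experiment.dims)} dimensions"
                )
            for d, (kind, idx, ppm) in enumerate(peak.coords):
                off = experiment.dims[d].to_hz(ppm)
                if abs(off) > experiment.dims[d].sw_hz / 2:
                    warnings.warn(
                        f"peak {peak.residue} {kind}{idx} at {ppm:.2f} ppm lies "
                        f"outside the window of dimension {d + 1}",
                        stacklevel=2,
                    )
                offs[p, d] = off
            amps[p] = peak.sign * acq.family_scale.get(peak.family, 1.0)

        # common indirect decay (peak-independent)
        decay_ind = np.exp(-(t_ind @ r2_ind))  # (K,)
        bits = (np.arange(ncomp)[None, :] >> np.arange(nind)[:, None]) & 1  # (nind, ncomp)

        # W[p, k, c] = prod_d mod_d(2 pi nu_d t_kd)
        W = np.ones((P, K, ncomp))
        for d in range(nind):
            arg = 2 * np.pi * np.outer(offs[:, d], t_ind[:, d])  # (P, K)
            mods = np.stack([np.cos(arg), np.sin(arg)], axis=-1)  # (P, K, 2)
            W *= mods[:, :, bits[d]]
        W *= (amps[:, None] * decay_ind[None, :])[:, :, None]

        direct = np.exp((2j * np.pi * offs[:, -1][:, None] - acq.r2_direct) * t_dir[None, :])
        jmod_c = np.cos(np.pi * acq.j_caco * t_dir)
        jmod_s = np.sin(np.pi * acq.j_caco * t_dir)

        Wm = W.reshape(P, K * ncomp).T  # (K*ncomp, P)
        ip += (Wm @ (direct * jmod_c)).reshape(K, ncomp, ndir)
        ap += (Wm @ (direct * jmod_s)).reshape(K, ncomp, ndir)

    if acq.noise_sd > 0:
        rng = np.random.default_rng(acq.seed)
        shape = ip.shape
        for arr in (ip, ap):
            arr += rng.normal(scale=acq.noise_sd, size=shape)
            arr += 1j * rng.normal(scale=acq.noise_sd, size=shape)

    return NUSDataset(experiment=experiment, schedule=schedule, acq=acq, ip=ip, ap=ap)
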