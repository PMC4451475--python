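"""Experiment definitions: dimension layouts and acquisition defaults.

Three carbon-detected experiments form the assignment suite:

* ``basis4d``  -- 4D (HACA)CON(CA)NCO, dimension order CO(1) N(2) N(3) CO(4),
  dimension 4 directly detected.  Serves as the basis spectrum for SMFT.
* ``habcab5d`` -- 5D HabCabCO(CA)NCO, Hab(1) Cab(2) CO(3) N(4) CO(5).
* ``hn5d``     -- 5D HNCO(CA)NCO, HN(1) N(2) CO(3) N(4) CO(5).

Default spectral widths, maximum evolution times and increment counts follow
the acquisition-parameter table of the underlying method (28 ms / 2.2 kHz for
CO, 28 ms / 2.8 kHz for N, 10 ms / 6 kHz for Hab, 7.1 ms / 15 kHz for Cab,
10 ms / 5.2 kHz for HN; 2400 increments for the 4D and 1800 for each 5D);
the direct CO dimension is acquired for 106 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .nuclei import BASE_MHZ, KIND_CLASS, hz_to_ppm, ppm_to_hz


@dataclass(frozen=True)
class Dimension:
    """One spectral dimension.

    ``label`` is the dimension's nucleus role ('CO', 'N', 'Cab', 'Hab', 'HN');
    ``element`` the element class ('C', 'N', 'H'); ``t_max`` the maximum
    evolution time in seconds (None for the directly detected dimension,
    which uses ``t_acq`` instead).
    """

    label: str
    element: str
    carrier_ppm: float
    sw_hz: float
    t_max: float | None = None
    t_acq: float | None = None

    @property
    def is_direct(self) -> bool:
        return self.t_max is None

    @property
    def base_mhz(self) -> float:
        return BASE_MHZ[self.element]

    @property
    def grid_size(self) -> int:
        """Number of on-grid evolution-time increments (indirect dims only)."""
        if self.t_max is None:
            raise ValueError("direct dimension has no indirect sampling grid")
        return int(np.floor(self.t_max * self.sw_hz)) + 1

    @property
    def n_direct_points(self) -> int:
        if self.t_acq is None:
            raise ValueError("not a direct dimension")
        return int(round(self.t_acq * self.sw_hz))

    def to_hz(self, ppm):
        return ppm_to_hz(np.asarray(ppm, dtype=float), self.carrier_ppm, self.element)

    def to_ppm(self, hz):
        return hz_to_ppm(np.asarray(hz, dtype=float), self.carrier_ppm, self.element)

    def contains_ppm(self, ppm: float) -> bool:
        return abs(self.to_hz(ppm)) <= self.sw_hz / 2


@dataclass(frozen=True)
class Experiment:
    """An experiment's ordered dimension layout (last dimension = direct)."""

    id: str
    name: str
    dims: tuple[Dimension, ...]
    default_increments: int

    @property
    def n_dims(self) -> int:
        return len(self.dims)

    @property
    def n_indirect(self) -> int:
        return len(self.dims) - 1

    @property
    def direct_dim(self) -> Dimension:
        return self.dims[-1]

    @property
    def indirect_dims(self) -> tuple[Dimension, ...]:
        return self.dims[:-1]

    @property
    def n_components(self) -> int:
        """Hypercomplex component count, 2^(D-1)."""
        return 2 ** self.n_indirect


T_ACQ = 0.106  # direct-dimension acquisition time, s

_CO_IND = dict(label="CO", element="C", carrier_ppm=175.5, sw_hz=2200.0, t_max=0.028)
_N_IND = dict(label="N", element="N", carrier_ppm=122.0, sw_hz=2800.0, t_max=0.028)
_CO_DIRECT = Dimension("CO", "C", carrier_ppm=175.5, sw_hz=2200.0, t_acq=T_ACQ)

BASIS_4D = Experiment(
    id="basis4d",
    name="4D (HACA)CON(CA)NCO",
    dims=(
        Dimension(**_CO_IND),
        Dimension(**_N_IND),
        Dimension(**_N_IND),
        _CO_DIRECT,
    ),
    default_increments=2400,
)

HABCAB_5D = Experiment(
    id="habcab5d",
    name="5D HabCabCO(CA)NCO",
    dims=(
        Dimension("Hab", "H", carrier_ppm=4.0, sw_hz=6000.0, t_max=0.010),
        Dimension("Cab", "C", carrier_ppm=45.0, sw_hz=15000.0, t_max=0.0071),
        Dimension(**_CO_IND),
        Dimension(**_N_IND),
        _CO_DIRECT,
    ),
    default_increments=1800,
)

HN_5D = Experiment(
    id="hn5d",
    name="5D HNCO(CA)NCO",
    dims=(
        Dimension("HN", "H", carrier_ppm=8.3, sw_hz=5200.0, t_max=0.010),
        Dimension(**_N_IND),
        Dimension(**_CO_IND),
        Dimension(**_N_IND),
        _CO_DIRECT,
    ),
    default_increments=1800,
)

EXPERIMENTS = {e.id: e for e in (BASIS_4D, HABCAB_5D, HN_5D)}


def get_experiment(experiment_id: str) -> Experiment:
    try:
        return EXPERIMENTS[experiment_id]
    except KeyError:
        raise KeyError(
            f"unknown experiment {experiment_id!r}; known: {sorted(EXPERIMENTS)}"
        ) from None
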