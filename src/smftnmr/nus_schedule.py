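"""On-grid Poisson-disk non-uniform sampling schedules with Gaussian density.

Schedules are generated by dart throwing on the Nyquist grid of the indirect
evolution times: a candidate grid point t is accepted with probability
prod_d exp(-(t_d / (0.5 t_max,d))^2) -- the Gaussian density decay, expressed
relative to the maximum evolution time -- and rejected if it falls closer
than a disk radius (in t_max-normalised Euclidean distance) to any point
already in the schedule.  The first increment (all-zero evolution times) is
always included.  When the dart-throwing budget for the requested point
count is exhausted, the radius is relaxed geometrically (x0.9) and the final
radius is reported on the schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .experiments import Experiment


@dataclass(frozen=True)
class SamplingConfig:
    """Per-dimension (sw_hz, t_max_s) plus total increment count and seed."""

    dims: tuple[tuple[float, float], ...]  # (sw in Hz, t_max in s) per indirect dim
    n: int
    seed: int

    @classmethod
    def for_experiment(cls, experiment: Experiment, n: int | None = None, seed: int = 0):
        dims = tuple((d.sw_hz, d.t_max) for d in experiment.indirect_dims)
        return cls(dims=dims, n=int(n or experiment.default_increments), seed=seed)

    @property
    def grid_sizes(self) -> tuple[int, ...]:
        return tuple(int(np.floor(t * sw)) + 1 for sw, t in self.dims)

    @property
    def n_grid(self) -> int:
        return int(np.prod(self.grid_sizes))

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.n > self.n_grid:
            raise ValueError(
                f"n={self.n} exceeds the sampling grid size {self.n_grid}"
            )


@dataclass(frozen=True)
class Schedule:
    """A list of n distinct grid-index tuples plus its provenance."""

    indices: np.ndarray  # (n, D) int
    config: SamplingConfig
    final_radius: float

    @property
    def n(self) -> int:
        return self.indices.shape[0]

    @property
    def n_dims(self) -> int:
        return self.indices.shape[1]

    def times(self) -> np.ndarray:
        """Evolution times in seconds, shape (n, D)."""
        steps = np.array([1.0 / sw for sw, _ in self.config.dims])
        return self.indices * steps

    def normalized_times(self) -> np.ndarray:
        tmax = np.array([t for _, t in self.config.dims])
        return self.times() / tmax

    def head(self, n: int) -> "Schedule":
        """The first ``n`` increments (used for the subsampling re-transform)."""
        return Schedule(self.indices[:n].copy(), self.config, self.final_radius)

    def write(self, path) -> None:
        np.savetxt(path, self.indices, fmt="%d")

    @classmethod
    def read(cls, path, config: SamplingConfig) -> "Schedule":
        idx = np.loadtxt(path, dtype=int, ndmin=2)
        return cls(indices=idx, config=config, final_radius=np.nan)


def _density(tau: np.ndarray) -> np.ndarray:
    """Gaussian sampling density exp(-(tau/0.5)^2), tau = t/t_max per dim."""
    return np.exp(-np.sum((tau / 0.5) ** 2, axis=-1))


def initial_radius(config: SamplingConfig) -> float:
    """Dart-throwing heuristic: radius so n disks roughly cover the
    density-weighted volume of the normalised sampling cube."""
    D = len(config.dims)
    # 0.441 = integral of exp(-(u/0.5)^2) on [0, 1]: the effective covered
    # length of the Gaussian envelope per normalised dimension
    v_eff = 0.441**D
    return 0.7 * (v_eff / config.n) ** (1.0 / D)


def generate_schedule(
    config: SamplingConfig,
    radius: float | None = None,
    max_tries_per_radius: int | None = None,
) -> Schedule:
    """Generate an on-grid Poisson-disk schedule (deterministic per seed).

    ``radius`` overrides the initial disk radius (0 disables the minimum-
    distance constraint; duplicates are still excluded).  If ``n`` equals the
    full grid size the complete Cartesian grid is returned.
    """
    config.validate()
    sizes = config.grid_sizes
    D = len(sizes)

    if config.n == config.n_grid:
        grids = np.meshgrid(*[np.arange(s) for s in sizes], indexing="ij")
        idx = np.stack([g.ravel() for g in grids], axis=1)
        return Schedule(indices=idx, config=config, final_radius=0.0)

    rng = np.random.default_rng(config.seed)
    r = initial_radius(config) if radius is None else float(radius)
    budget = max_tries_per_radius or max(20000, 500 * config.n)

    # index -> normalised time: tau_d = idx_d / (sw_d * t_max_d)
    scale = np.array([1.0 / (sw * t) for sw, t in config.dims])

    accepted = np.zeros((config.n, D), dtype=int)
    accepted_tau = np.zeros((config.n, D))
    n_acc = 1  # origin always included
    seen = {tuple(np.zeros(D, dtype=int))}
    tries = 0
    final_r = r
    while n_acc < config.n:
        m = 4096
        cand = np.stack([rng.integers(0, s, size=m) for s in sizes], axis=1)
        tau = cand * scale
        keep = rng.random(m) < _density(tau)
        cand, tau = cand[keep], tau[keep]
        for c, ct in zip(cand, tau):
            tries += 1
            key = tuple(int(x) for x in c)
            if key in seen:
                continue
            if final_r > 0:
                d2 = np.sum((accepted_tau[:n_acc] - ct) ** 2, axis=1)
                if d2.min() < final_r**2:
                    continue
            accepted[n_acc] = c
            accepted_tau[n_acc] = ct
            seen.add(key)
            n_acc += 1
            if n_acc == config.n:
                break
        if tries > budget and n_acc < config.n:
            final_r *= 0.9
            tries = 0
            if final_r < 1e-12:
                final_r = 0.0
    return Schedule(indices=accepted, config=config, final_radius=final_r)
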