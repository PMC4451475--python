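"""The multiple-fixing scheme: which dimensions each SMFT variant pins.

Every 2D cross-section of a high-dimensional spectrum is obtained by fixing
all but two dimensions at frequencies taken from one peak of the 4D basis
spectrum (a CO_i - N_{i+1} - N_i - CO_{i-1} quadruple).  Because those four
frequencies can be distributed over the fixed dimensions in several ways,
each basis peak yields a family of different cross-sections ("multiple
fixing").  This module is the declarative catalog of the ten variants:

* 4D basis spectrum (CO1 N2 N3 CO4, dim 4 direct):
  1i, 1ii (direct dimension fixed), 1iii, 1iv (direct dimension free)
* 5D HabCabCO(CA)NCO: 2i, 2ii, 2iii
* 5D HNCO(CA)NCO:     3i, 3ii, 3iii

Each variant also declares the peak types expected on its plane as
templates (nucleus kind + residue offset relative to the basis peak's
residue i, with the glycine sign rule), which later drives the routing of
picked peaks into cross-section spin systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .experiments import EXPERIMENTS, get_experiment


@dataclass(frozen=True)
class BasisPeak:
    """One sequential peak of the 4D basis spectrum (frequencies in ppm)."""

    id: str
    co_i: float
    n_ip1: float
    n_i: float
    co_im1: float
    intensity: float = 0.0
    sign: int = -1

    #: dimension order of the basis experiment
    FIELDS = ("co_i", "n_ip1", "n_i", "co_im1")

    def field_ppm(self, name: str) -> float:
        if name not in self.FIELDS:
            raise KeyError(f"basis peak has no field {name!r}")
        return getattr(self, name)

    @property
    def ppms(self) -> tuple[float, float, float, float]:
        return (self.co_i, self.n_ip1, self.n_i, self.co_im1)


@dataclass(frozen=True)
class PeakTemplate:
    """An expected 2D peak: (x, y) nucleus kinds and residue offsets.

    ``sign`` is the base intensity sign; it is flipped when the residue at
    ``gly_flip_offset`` (relative to the basis residue i) is a glycine.
    ``gly_flip_offset`` None means the sign never flips (the always-positive
    HB-CB family).
    """

    x_kind: str
    x_off: int
    y_kind: str
    y_off: int
    sign: int = 1
    gly_flip_offset: int | None = None

    def slots(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (self.x_kind, self.x_off), (self.y_kind, self.y_off)

    def expected_sign(self, sequence: str, basis_residue: int) -> int:
        """Theoretical sign for a known sequence (1-based basis residue)."""
        if self.gly_flip_offset is None:
            return self.sign
        j = basis_residue + self.gly_flip_offset
        if 1 <= j <= len(sequence) and sequence[j - 1] == "G":
            return -self.sign
        return self.sign


@dataclass(frozen=True)
class FixingVariant:
    """One way of fixing frequencies for SMFT processing.

    ``fixed`` maps 0-based dimension index -> basis-peak field name;
    ``free`` is the ordered pair of free dimension indices (plane x, y).
    """

    id: str
    experiment: str
    fixed: tuple[tuple[int, str], ...]
    free: tuple[int, int]
    templates: tuple[PeakTemplate, ...]

    def __post_init__(self):
        exp = get_experiment(self.experiment)
        dims = set(d for d, _ in self.fixed) | set(self.free)
        if dims != set(range(exp.n_dims)):
            raise ValueError(f"variant {self.id}: fixed+free do not partition dimensions")
        if not self.templates:
            raise ValueError(f"variant {self.id}: expected templates must be non-empty")

    @property
    def fixes_direct(self) -> bool:
        direct = get_experiment(self.experiment).n_dims - 1
        return any(d == direct for d, _ in self.fixed)

    @property
    def direct_is_free(self) -> bool:
        return not self.fixes_direct


def _t(x_kind, x_off, y_kind, y_off, sign=1, gly=None):
    return PeakTemplate(x_kind, x_off, y_kind, y_off, sign, gly)


_HABCAB_I_TEMPLATES = (
    _t("HA", 0, "CA", 0, +1, gly=0),
    _t("HB", 0, "CB", 0, +1, gly=None),
)
_HN_IP1_TEMPLATE = (_t("HN", +1, "N", +1, +1, gly=0),)

CATALOG: dict[str, FixingVariant] = {
    v.id: v
    for v in [
        # --- 4D basis spectrum: four ways of fixing two of four dimensions
        FixingVariant(
            "1i", "basis4d", fixed=((2, "n_i"), (3, "co_im1")), free=(0, 1),
            templates=(_t("CO", -1, "N", 0, +1, gly=-1), _t("CO", 0, "N", +1, -1, gly=0)),
        ),
        FixingVariant(
            "1ii", "basis4d", fixed=((2, "n_ip1"), (3, "co_i")), free=(0, 1),
            templates=(_t("CO", 0, "N", +1, +1, gly=0), _t("CO", +1, "N", +2, -1, gly=+1)),
        ),
        FixingVariant(
            "1iii", "basis4d", fixed=((1, "n_i"), (0, "co_im1")), free=(2, 3),
            templates=(_t("N", -1, "CO", -2, -1, gly=-1), _t("N", 0, "CO", -1, +1, gly=-1)),
        ),
        FixingVariant(
            "1iv", "basis4d", fixed=((1, "n_ip1"), (0, "co_i")), free=(2, 3),
            templates=(_t("N", 0, "CO", -1, -1, gly=0), _t("N", +1, "CO", 0, +1, gly=0)),
        ),
        # --- 5D HabCabCO(CA)NCO: three ways
        FixingVariant(
            "2i", "habcab5d",
            fixed=((2, "co_i"), (3, "n_i"), (4, "co_im1")), free=(0, 1),
            templates=_HABCAB_I_TEMPLATES,
        ),
        FixingVariant(
            "2ii", "habcab5d",
            fixed=((2, "co_im1"), (3, "n_i"), (4, "co_im1")), free=(0, 1),
            templates=(_t("HA", -1, "CA", -1, +1, gly=-1), _t("HB", -1, "CB", -1, +1, gly=None)),
        ),
        FixingVariant(
            "2iii", "habcab5d",
            fixed=((2, "co_i"), (3, "n_ip1"), (4, "co_i")), free=(0, 1),
            templates=_HABCAB_I_TEMPLATES,
        ),
        # --- 5D HNCO(CA)NCO: three ways
        FixingVariant(
            "3i", "hn5d",
            fixed=((2, "co_i"), (3, "n_i"), (4, "co_im1")), free=(0, 1),
            templates=_HN_IP1_TEMPLATE,
        ),
        FixingVariant(
            "3ii", "hn5d",
            fixed=((2, "co_im1"), (3, "n_i"), (4, "co_im1")), free=(0, 1),
            templates=(_t("HN", 0, "N", 0, +1, gly=-1),),
        ),
        FixingVariant(
            "3iii", "hn5d",
            fixed=((2, "co_i"), (3, "n_ip1"), (4, "co_i")), free=(0, 1),
            templates=_HN_IP1_TEMPLATE,
        ),
    ]
}

_ORDER = {
    "basis4d": ("1i", "1ii", "1iii", "1iv"),
    "habcab5d": ("2i", "2ii", "2iii"),
    "hn5d": ("3i", "3ii", "3iii"),
}


def list_variants(experiment_id: str) -> list[FixingVariant]:
    """Ordered fixing variants of an experiment (4D -> 4, each 5D -> 3)."""
    if experiment_id not in _ORDER:
        raise KeyError(f"unknown experiment {experiment_id!r}")
    return [CATALOG[v] for v in _ORDER[experiment_id]]


def get_variant(variant_id: str) -> FixingVariant:
    try:
        return CATALOG[variant_id]
    except KeyError:
        raise KeyError(f"unknown fixing variant {variant_id!r}") from None


def fixed_frequencies(variant: FixingVariant, peak: BasisPeak) -> dict[int, float]:
    """Resolve a variant's fixed dimensions to ppm values of a basis peak."""
    return {dim: peak.field_ppm(name) for dim, name in variant.fixed}


# ---------------------------------------------------------------------------
# serialisation: the catalog round-trips through a structured config file so
# that new experiments can be added without code changes


def catalog_to_yaml(path, catalog: dict[str, FixingVariant] | None = None) -> None:
    catalog = catalog or CATALOG
    out = {}
    for vid, v in catalog.items():
        out[vid] = {
            "experiment": v.experiment,
            "fixed": {int(d): name for d, name in v.fixed},
            "free": list(v.free),
            "templates": [
                {
                    "x_kind": t.x_kind, "x_off": t.x_off,
                    "y_kind": t.y_kind, "y_off": t.y_off,
                    "sign": t.sign, "gly_flip_offset": t.gly_flip_offset,
                }
                for t in v.templates
            ],
        }
    with open(path, "w") as f:
        yaml.safe_dump(out, f, sort_keys=True)


def catalog_from_yaml(path) -> dict[str, FixingVariant]:
    with open(path) as f:
        raw = yaml.safe_load(f)
    catalog = {}
    for vid, d in raw.items():
        catalog[vid] = FixingVariant(
            id=vid,
            experiment=d["experiment"],
            fixed=tuple(sorted((int(k), v) for k, v in d["fixed"].items())),
            free=tuple(d["free"]),
            templates=tuple(PeakTemplate(**t) for t in d["templates"]),
        )
    return catalog
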