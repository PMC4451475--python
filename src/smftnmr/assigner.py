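"""Automatic sequence-specific assignment from cross-section peak lists.

Four-stage strategy operating on the planes of every basis peak:

1. *CSSS formation* -- the picked peaks of all fixing variants of one basis
   peak are routed into a cross-section spin system (CSSS) holding the
   chemical shifts of residues i-2 ... i+2: CO_{i-2..i+1}, N_{i-1..i+2},
   CA/CB/HA/HB of i-1 and i, HN of i and i+1 (18 slots for a complete
   internal residue).
2. *Sequential linking* -- candidate successor links are scored by how many
   of the three shared CO-N pairs match (plus shared aliphatic/amide
   slots); links need >= 2 matching CO-N pairs, no contradiction, and
   mutual-best uniqueness.
3. *Amino-acid recognition* -- CA/CB (and HA/HB) slots against the
   random-coil reference statistics give per-CSSS candidate amino-acid sets.
4. *Mapping* -- chains of CSSSs are placed on the sequence where every
   member's candidate sets admit the corresponding residue letters; chains
   with a unique admissible position are assigned, longest first.

A missing basis peak leaves a one-residue gap; flanking chains are joined
when the outer two CO-N pairs still match, and all seven shifts of the
lacking residue are recovered from the adjacent CSSSs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .fixing_catalog import BasisPeak, get_variant
from .nuclei import KIND_CLASS, tolerance_for
from .peak_analysis import PickedPeak2D, trim_intensity_gap
from .refshifts import AMINO_ACIDS, REFERENCE_MEANS, reference_mean, reference_sd

logger = logging.getLogger(__name__)

#: the 18 CSSS shift slots: (nucleus kind, residue offset relative to i)
CSSS_SLOTS: tuple[tuple[str, int], ...] = tuple(
    [("CO", o) for o in (-2, -1, 0, 1)]
    + [("N", o) for o in (-1, 0, 1, 2)]
    + [(k, o) for k in ("CA", "CB", "HA", "HB") for o in (-1, 0)]
    + [("HN", o) for o in (0, 1)]
)

#: variant processing order: basis-confirming planes first, then the planes
#: that extend the spin system, then the aliphatic and amide planes
VARIANT_ORDER = ("1i", "1iv", "1ii", "1iii", "2i", "2iii", "2ii", "3ii", "3i", "3iii")


@dataclass
class Slot:
    value: float
    source: str  # variant id or 'basis'
    intensity: float
    penalty: float = 0.0  # interference of the source plane (0 = clean)


#: approximate point-spread half-widths (ppm) of the fixed dimensions, used
#: to estimate how strongly foreign cross-sections leak into a plane
PSF_SIGMA_C_IND = 0.151  # indirect 13C, Gaussian-weighted 28 ms evolution
PSF_SIGMA_N_IND = 0.374  # indirect 15N
PSF_SIGMA_C_DIR = 0.08  # direct 13C, window-limited (~15 Hz)


def plane_interference(basis_peaks: list[BasisPeak]) -> dict[str, dict[str, float]]:
    """Per basis peak and 5D fixing variant: how much foreign peak families
    leak into the plane through the point spread of the fixed dimensions.

    The two aliphatic/amide peak families of a residue share the fixed
    coordinate triples (CO_i, N_i, CO_{i-1}) and (CO_i, N_{i+1}, CO_i), both
    of which are available from the basis peak list; the penalty of a plane
    is the summed attenuation-kernel overlap with every *other* basis peak's
    triples.  A plane's own legitimate content is not interference: for
    (2i)/(3i) and (2iii)/(3iii) that content belongs to the basis peak
    itself (excluded via identity); for (2ii)/(3ii) it is the predecessor's
    family, structurally an exact match, so the single largest foreign
    contribution is dropped -- if a *second* exact match remains (two basis
    peaks with coinciding anchors) it counts in full.  The redundant variant
    pairs (2i)/(2iii) and (3i)/(3iii) expect identical peak types, so the
    cleaner plane of each pair can be preferred when their picks disagree --
    the cross-check the multiple fixing scheme provides for overlapping
    planes.
    """
    from .fixing_catalog import fixed_frequencies

    out: dict[str, dict[str, float]] = {b.id: {} for b in basis_peaks}

    def families(b: BasisPeak):
        return ((b.co_i, b.n_i, b.co_im1), (b.co_i, b.n_ip1, b.co_i))

    for vid in ("2i", "2ii", "2iii", "3i", "3ii", "3iii"):
        var = get_variant(vid)
        legit_is_predecessor = vid in ("2ii", "3ii")
        for b in basis_peaks:
            F = fixed_frequencies(var, b)
            f = (F[2], F[3], F[4])
            ks = []
            for b2 in basis_peaks:
                if b2.id == b.id:
                    continue
                for T in families(b2):
                    ks.append(
                        float(
                            np.exp(
                                -(((T[0] - f[0]) / PSF_SIGMA_C_IND) ** 2)
                                - ((T[1] - f[1]) / PSF_SIGMA_N_IND) ** 2
                                - ((T[2] - f[2]) / PSF_SIGMA_C_DIR) ** 2
                            )
                        )
                    )
            if legit_is_predecessor and ks:
                ks.remove(max(ks))
            out[b.id][vid] = float(sum(ks))
    return out


@dataclass
class CSSS:
    """Cross-section spin system of one basis peak."""

    id: str
    basis: BasisPeak
    slots: dict[tuple[str, int], Slot] = field(default_factory=dict)

    def get(self, kind: str, off: int) -> float | None:
        s = self.slots.get((kind, off))
        return None if s is None else s.value

    def n_filled(self) -> int:
        return len(self.slots)

    def co_n_pairs(self) -> list[tuple[float | None, float | None]]:
        """The four consecutive CO-N pairs q0..q3: (CO_{i-2+j}, N_{i-1+j})."""
        return [(self.get("CO", j - 2), self.get("N", j - 1)) for j in range(4)]

    def residue_observation(self, off: int) -> dict[str, float]:
        """CA/CB/HA/HB observations of residue i+off (off in {-1, 0})."""
        obs = {}
        for kind in ("CA", "CB", "HA", "HB"):
            v = self.get(kind, off)
            if v is not None:
                obs[kind] = v
        return obs


# ---------------------------------------------------------------------------
# stage 1: CSSS formation


def _axis_tol(kind: str, tolerances) -> float:
    return tolerance_for(kind, tolerances)


def classify_aliphatic(
    h_ppm: float, c_ppm: float, intensity: float, k_sd: float = 3.0
) -> set[str]:
    """Is an (H, C) aliphatic peak compatible with an alpha and/or beta pair?

    Compatibility means some amino acid's (HA, CA) -- or (HB, CB) --
    random-coil statistics cover the observation within k_sd SDs.  Negative
    intensity implies an alpha peak (only glycine alpha peaks are negative
    on these planes).
    """
    out = set()
    for aa, means in REFERENCE_MEANS.items():
        if (
            "CA" in means
            and abs(c_ppm - means["CA"]) <= k_sd * reference_sd("CA")
            and abs(h_ppm - means["HA"]) <= k_sd * reference_sd("HA")
        ):
            out.add("alpha")
        if (
            "CB" in means
            and abs(c_ppm - means["CB"]) <= k_sd * reference_sd("CB")
            and abs(h_ppm - means["HB"]) <= k_sd * reference_sd("HB")
        ):
            out.add("beta")
    if intensity < 0:
        out &= {"alpha"}
    return out


def _fill(
    csss: CSSS, kind: str, off: int, value: float, source: str, intensity: float,
    penalty: float = 0.0,
):
    """Fill a slot; conflicting candidates are resolved by plane cleanliness
    (interference penalty, in coarse buckets) and then by |intensity| rank.
    The basis peak's own frequencies are inviolable."""
    cur = csss.slots.get((kind, off))
    if cur is not None:
        if cur.source == "basis":
            return
        new_rank = (round(penalty / 0.05), -abs(intensity))
        cur_rank = (round(cur.penalty / 0.05), -abs(cur.intensity))
        if cur_rank <= new_rank:
            return
    csss.slots[(kind, off)] = Slot(value=value, source=source, intensity=intensity,
                                   penalty=penalty)


#: point-spread-scale exclusion radii (ppm) per element class: leftover
#: picks this close to an already-consumed peak are its shoulders or ridge
#: artifacts, not independent resonances
PSF_EXCLUSION = {"C": 0.15, "N": 0.4, "H": 0.06}


def _route_templated(csss, variant, picks, tolerances, penalty=0.0):
    """Route picks of a 4D or HN plane using the variant's templates:
    templates are matched on whichever axes are already predictable from
    filled slots, then fill their unknown axes from the pick position."""
    remaining = sorted(picks, key=lambda p: -abs(p.intensity))
    claimed: list[tuple[float, float]] = []  # (x, y) of known/consumed peaks
    templates = sorted(
        variant.templates,
        key=lambda t: -sum(csss.get(k, o) is not None for k, o in t.slots()),
    )
    for t in templates:
        (xk, xo), (yk, yo) = t.slots()
        known = {}
        for axis, (k, o) in zip("xy", t.slots()):
            v = csss.get(k, o)
            if v is not None:
                known[axis] = (v, _axis_tol(k, tolerances))
        if len(known) == 2:
            # a fully predicted peak position is claimed even if no pick
            # matches it (overlap can pull the apparent maximum away)
            claimed.append((known["x"][0], known["y"][0]))
        ex_x = PSF_EXCLUSION[KIND_CLASS[xk]]
        ex_y = PSF_EXCLUSION[KIND_CLASS[yk]]
        # slots already filled: a match merely consumes the pick, so the
        # tolerance may be loosened to the hysteresis band (2x)
        consume_factor = 2.0 if len(known) == 2 else 1.0
        candidates = []
        for p in remaining:
            ok = True
            for axis, (v, tol) in known.items():
                obs = p.x_ppm if axis == "x" else p.y_ppm
                if abs(obs - v) > consume_factor * tol:
                    ok = False
                    break
            if ok and not known:
                # a fully unknown template must not pick up the shoulder of
                # a known or already-assigned peak
                for qx, qy in claimed:
                    if abs(p.x_ppm - qx) < ex_x and abs(p.y_ppm - qy) < ex_y:
                        ok = False
                        break
            if ok:
                candidates.append(p)
        if not candidates:
            continue
        best = max(candidates, key=lambda p: abs(p.intensity))
        if len(known) < 2:
            # the template fills at least one slot from the pick position;
            # two comparable-intensity candidates (exactly overlapping
            # cross-sections put the partner's peak on this plane at full
            # amplitude) cannot be told apart: no guessing
            contenders = [
                p for p in candidates if abs(p.intensity) >= abs(best.intensity) / 2
            ]
            if len(contenders) > 1:
                continue
        remaining.remove(best)
        claimed.append((best.x_ppm, best.y_ppm))
        _fill(csss, xk, xo, best.x_ppm, variant.id, best.intensity, penalty)
        _fill(csss, yk, yo, best.y_ppm, variant.id, best.intensity, penalty)


def _route_aliphatic(csss, variant, picks, k_sd, penalty=0.0):
    """Route HabCab plane picks into alpha (HA, CA) / beta (HB, CB) slots.

    Picks below the first large intensity gap are discarded as leakage from
    overlapping cross-sections.  A lone peak whose statistics fit both the
    alpha and the beta ranges is left out entirely (no guessing which one it
    is); when both peaks are present, an unambiguous one resolves the other
    by elimination.
    """
    off = variant.templates[0].x_off  # both templates share the residue offset
    picks = trim_intensity_gap(picks)
    classed = [
        (p, classify_aliphatic(p.x_ppm, p.y_ppm, p.intensity, k_sd)) for p in picks
    ]
    classed = [(p, c) for p, c in classed if c]
    # choose the (alpha, beta) pick combination with the largest summed
    # |intensity| among all class-compatible combinations; ties between
    # different contents mean the data cannot decide, and the disputed slot
    # is left empty (a lone both-ways-compatible peak ties with itself)
    combos = [((None, None), 0.0)]
    for p, c in classed:
        if "alpha" in c:
            combos.append(((p, None), abs(p.intensity)))
        if "beta" in c:
            combos.append(((None, p), abs(p.intensity)))
    for pa, ca in classed:
        for pb, cb in classed:
            if pa is not pb and "alpha" in ca and "beta" in cb:
                combos.append(((pa, pb), abs(pa.intensity) + abs(pb.intensity)))
    best_score = max(s for _, s in combos)
    # combinations within 15 % of the best are indistinguishable (exactly
    # overlapping planes carry the partner residue's pair at full amplitude)
    best = [pair for pair, s in combos if s >= best_score * 0.85]
    alphas = {pair[0] for pair in best}
    betas = {pair[1] for pair in best}
    alpha = alphas.pop() if len(alphas) == 1 else None
    beta = betas.pop() if len(betas) == 1 else None
    if alpha is not None:
        _fill(csss, "HA", off, alpha.x_ppm, variant.id, alpha.intensity, penalty)
        _fill(csss, "CA", off, alpha.y_ppm, variant.id, alpha.intensity, penalty)
    if beta is not None:
        _fill(csss, "HB", off, beta.x_ppm, variant.id, beta.intensity, penalty)
        _fill(csss, "CB", off, beta.y_ppm, variant.id, beta.intensity, penalty)


def build_csss(
    basis_peak: BasisPeak,
    picks_by_variant: dict[str, list[PickedPeak2D]],
    tolerances: dict | None = None,
    k_sd: float = 3.0,
    interference: dict[str, float] | None = None,
) -> CSSS:
    """Form the cross-section spin system of one basis peak.

    ``picks_by_variant`` maps fixing-variant ids to the picked peaks of the
    corresponding plane of this basis peak; ``interference`` optionally maps
    variant ids to the plane-interference penalty of
    :func:`plane_interference`.  Slots are only ever filled from this peak's
    own planes; conflicting candidates for one slot are resolved by plane
    cleanliness, then by |intensity|.
    """
    csss = CSSS(id=basis_peak.id, basis=basis_peak)
    for (kind, off), val in (
        (("CO", -1), basis_peak.co_im1),
        (("N", 0), basis_peak.n_i),
        (("CO", 0), basis_peak.co_i),
        (("N", 1), basis_peak.n_ip1),
    ):
        csss.slots[(kind, off)] = Slot(value=val, source="basis", intensity=np.inf)
    interference = interference or {}
    for vid in VARIANT_ORDER:
        picks = picks_by_variant.get(vid)
        if not picks:
            continue
        variant = get_variant(vid)
        penalty = interference.get(vid, 0.0)
        if variant.experiment == "habcab5d":
            _route_aliphatic(csss, variant, picks, k_sd, penalty)
        else:
            _route_templated(csss, variant, picks, tolerances, penalty)
    return csss


# ---------------------------------------------------------------------------
# stage 2: sequential linking


def _pair_state(pa, pb, tol_c, tol_n):
    """'match' / 'mismatch' / None (not comparable) for two (CO, N) pairs.

    A hysteresis band separates matching from contradicting: shifts within
    the tolerance match, shifts beyond twice the tolerance contradict, the
    zone in between is treated as uninformative (measurement precision on
    coarse indirect grids does not support a hard veto there).
    """
    if None in pa or None in pb:
        return None
    dc, dn = abs(pa[0] - pb[0]), abs(pa[1] - pb[1])
    if dc <= tol_c and dn <= tol_n:
        return "match"
    if dc > 2 * tol_c or dn > 2 * tol_n:
        return "mismatch"
    return None


def score_link(a: CSSS, b: CSSS, tolerances=None, offset: int = 1):
    """Score the hypothesis that b's residue index is a's plus ``offset``.

    Returns (co_n_matches, aux_matches) or None when any comparable shared
    shift contradicts the hypothesis.  For offset 1 the three shared CO-N
    pairs and the shared i-level aliphatic/amide slots are compared; for
    offset 2 (a single-residue gap) only the outer two CO-N pairs remain.
    """
    tol_c, tol_n = tolerance_for("C", tolerances), tolerance_for("N", tolerances)
    qa, qb = a.co_n_pairs(), b.co_n_pairs()
    matches = 0
    for j in range(4 - offset):
        st = _pair_state(qa[j + offset], qb[j], tol_c, tol_n)
        if st == "mismatch":
            return None
        if st == "match":
            matches += 1
    aux = 0
    if offset == 1:
        shared = [(k, 0, k, -1) for k in ("CA", "CB", "HA", "HB")] + [("HN", 1, "HN", 0)]
        for ka, oa, kb, ob in shared:
            va, vb = a.get(ka, oa), b.get(kb, ob)
            if va is None or vb is None:
                continue
            d = abs(va - vb)
            tol = _axis_tol(ka, tolerances)
            if d <= tol:
                aux += 1
            elif d > 2 * tol:
                return None
    return matches, aux


def link_csss(
    cssss: list[CSSS], tolerances: dict | None = None, min_pair_matches: int = 2
) -> nx.DiGraph:
    """Directed successor graph over CSSSs (mutual-best links only).

    An edge a -> b means residue(b) = residue(a) + 1, accepted when at
    least ``min_pair_matches`` of the three shared CO-N pairs match, no
    comparable shared shift contradicts, and a and b are each other's
    unique best partners.
    """
    if len(cssss) < 2:
        g = nx.DiGraph()
        g.add_nodes_from(c.id for c in cssss)
        return g
    by_id = {c.id: c for c in cssss}
    candidates = {}
    for a, b in itertools.permutations(cssss, 2):
        s = score_link(a, b, tolerances, offset=1)
        if s is not None and s[0] >= min_pair_matches:
            candidates[(a.id, b.id)] = s

    def best_unique(pairs):
        """id -> partner, only where a strictly best candidate exists."""
        by_src: dict[str, list] = {}
        for (x, y), s in pairs.items():
            by_src.setdefault(x, []).append((s, y))
        out = {}
        for x, lst in by_src.items():
            lst.sort(reverse=True)
            if len(lst) == 1 or lst[0][0] > lst[1][0]:
                out[x] = lst[0][1]
        return out

    succ = best_unique(candidates)
    pred = best_unique({(b, a): s for (a, b), s in candidates.items()})
    g = nx.DiGraph()
    g.add_nodes_from(by_id)
    for a, b in succ.items():
        if pred.get(b) == a:
            g.add_edge(a, b, score=candidates[(a, b)])
    return g


# ---------------------------------------------------------------------------
# stage 2b: chains and gap joining


@dataclass
class GapResidue:
    """A residue bridged between two chains after a basis-peak gap; all its
    shifts are recovered from the adjacent CSSSs."""

    shifts: dict[str, float]


@dataclass
class Chain:
    id: int
    members: list  # CSSS | GapResidue, in sequence order

    def __len__(self) -> int:
        return len(self.members)

    @property
    def csss_members(self) -> list[CSSS]:
        return [m for m in self.members if isinstance(m, CSSS)]


def form_chains(graph: nx.DiGraph) -> list[Chain]:
    """Maximal simple paths of unambiguous links.

    Only edges that are the unique out-edge of their source and the unique
    in-edge of their target are followed; branch points terminate chains.
    """
    good = {
        (a, b)
        for a, b in graph.edges
        if graph.out_degree(a) == 1 and graph.in_degree(b) == 1
    }
    succ = dict(good)
    pred = {b: a for a, b in good}
    chains = []
    nodes = sorted(graph.nodes)
    seen = set()
    for n in nodes:
        if n in seen or n in pred:
            continue
        path = [n]
        seen.add(n)
        while path[-1] in succ:
            nxt = succ[path[-1]]
            if nxt in seen:
                break
            path.append(nxt)
            seen.add(nxt)
        chains.append(path)
    for n in nodes:  # nodes stuck in cycles (should not occur) or leftovers
        if n not in seen:
            chains.append([n])
            seen.add(n)
    id2csss = nx.get_node_attributes(graph, "csss")
    out = []
    for k, path in enumerate(chains):
        out.append(Chain(id=k, members=[id2csss.get(i, i) for i in path]))
    return out


def _materialise_chains(graph: nx.DiGraph, cssss: list[CSSS]) -> list[Chain]:
    by_id = {c.id: c for c in cssss}
    chains = form_chains(graph)
    for ch in chains:
        ch.members = [by_id[m] if isinstance(m, str) else m for m in ch.members]
    return chains


def recover_gap_shifts(a: CSSS, b: CSSS) -> dict[str, float]:
    """All seven shifts of the lacking residue r between chains ...a] [b...

    With residue(b) = residue(a) + 2 = r + 1: CO_r and N_r sit in both
    neighbours (averaged when doubly present); the aliphatic shifts come
    from b's i-1 slots and HN_r from a's i+1 slot.
    """
    out = {}
    for kind, src in [
        ("CO", [(a, "CO", 1), (b, "CO", -1)]),
        ("N", [(a, "N", 1), (b, "N", -1)]),
        ("CA", [(b, "CA", -1)]),
        ("CB", [(b, "CB", -1)]),
        ("HA", [(b, "HA", -1)]),
        ("HB", [(b, "HB", -1)]),
        ("HN", [(a, "HN", 1)]),
    ]:
        vals = [v for c, k, o in src if (v := c.get(k, o)) is not None]
        if vals:
            out[kind] = float(np.mean(vals))
    return out


def join_chains_over_gaps(
    chains: list[Chain], tolerances: dict | None = None
) -> list[Chain]:
    """Join chain pairs separated by exactly one missing basis peak.

    The end of one chain and the start of another are linked when both
    remaining CO-N pair comparisons (offset 2) match with no contradiction
    and the pairing is mutually unique; the bridged residue is inserted as a
    :class:`GapResidue` carrying its recovered shifts.
    """
    ends = {ch.id: ch.members[-1] for ch in chains if isinstance(ch.members[-1], CSSS)}
    starts = {ch.id: ch.members[0] for ch in chains if isinstance(ch.members[0], CSSS)}
    cand = {}
    for ia, a in ends.items():
        for ib, b in starts.items():
            if ia == ib:
                continue
            s = score_link(a, b, tolerances, offset=2)
            if s is not None and s[0] >= 2:
                cand[(ia, ib)] = s

    def unique(d):
        best = {}
        for (x, y), s in d.items():
            best.setdefault(x, []).append((s, y))
        out = {}
        for x, lst in best.items():
            lst.sort(reverse=True)
            if len(lst) == 1 or lst[0][0] > lst[1][0]:
                out[x] = lst[0][1]
        return out

    succ = unique(cand)
    pred = unique({(b, a): s for (a, b), s in cand.items()})
    links = [(a, b) for a, b in succ.items() if pred.get(b) == a]

    by_id = {ch.id: ch for ch in chains}
    merged_into: dict[int, int] = {}
    for ia, ib in links:
        ra = merged_into.get(ia, ia)
        rb = merged_into.get(ib, ib)
        if ra == rb:
            continue
        a_chain, b_chain = by_id[ra], by_id[rb]
        gap = GapResidue(shifts=recover_gap_shifts(a_chain.members[-1], b_chain.members[0]))
        a_chain.members = a_chain.members + [gap] + b_chain.members
        for cid, tgt in list(merged_into.items()):
            if tgt == rb:
                merged_into[cid] = ra
        merged_into[rb] = ra
        del by_id[rb]
    return list(by_id.values())


# ---------------------------------------------------------------------------
# stage 3: amino-acid recognition


def candidates_for_observation(obs: dict[str, float], k_sd: float = 3.0) -> set[str]:
    """Amino acids compatible with observed CA/CB/HA/HB shifts.

    Every observed nucleus must exist for the amino acid and lie within
    k_sd reference SDs of its random-coil mean; an empty observation admits
    all twenty amino acids (no information).
    """
    if not obs:
        return set(AMINO_ACIDS)
    out = set()
    for aa in AMINO_ACIDS:
        ok = True
        for kind, val in obs.items():
            mean = reference_mean(aa, kind)
            if mean is None or abs(val - mean) > k_sd * reference_sd(kind):
                ok = False
                break
        if ok:
            out.add(aa)
    return out


def recognize_aa(csss: CSSS, k_sd: float = 3.0) -> tuple[set[str], set[str]]:
    """Candidate amino-acid sets for residues i-1 and i of a CSSS."""
    return (
        candidates_for_observation(csss.residue_observation(-1), k_sd),
        candidates_for_observation(csss.residue_observation(0), k_sd),
    )


# ---------------------------------------------------------------------------
# stage 4: mapping chains on the sequence


@dataclass
class Assignment:
    """Mapping result plus the assembled shift table."""

    sequence: str
    positions: dict[str, int]  # csss id -> residue index i
    chain_of: dict[str, tuple[int, int]]  # csss id -> (chain id, chain length)
    gap_shifts: dict[int, dict[str, float]]  # residue index -> recovered shifts
    unassigned_chains: dict[int, str]  # chain id -> reason

    def assembled_shifts(self, cssss: dict[str, "CSSS"]) -> dict[tuple[int, str], float]:
        """Consensus shift per (residue, kind): cleanest source plane first
        (interference penalty), then nearest offset, then |intensity|."""
        best: dict[tuple[int, str], tuple] = {}
        for cid, i in self.positions.items():
            c = cssss[cid]
            for (kind, off), slot in c.slots.items():
                key = (i + off, kind)
                rank = (round(slot.penalty / 0.05), abs(off), -abs(slot.intensity))
                if key not in best or rank < best[key][0]:
                    best[key] = (rank, slot.value)
        for r, shifts in self.gap_shifts.items():
            for kind, v in shifts.items():
                key = (r, kind)
                rank = (0, 0.5, 0.0)
                if key not in best or rank < best[key][0]:
                    best[key] = (rank, v)
        return {k: v for k, (_, v) in best.items()}

    def to_frame(self, cssss: dict[str, "CSSS"]) -> pd.DataFrame:
        rows = []
        for (r, kind), v in sorted(self.assembled_shifts(cssss).items()):
            if 1 <= r <= len(self.sequence):
                rows.append(
                    {"residue": r, "aa": self.sequence[r - 1], "nucleus": kind, "ppm": v}
                )
        return pd.DataFrame(rows)


def _chain_constraints(chain: Chain, k_sd: float):
    """Per-member (cand_i, cand_im1) sets; gap members constrain only i."""
    cons = []
    for m in chain.members:
        if isinstance(m, GapResidue):
            obs = {k: v for k, v in m.shifts.items() if k in ("CA", "CB", "HA", "HB")}
            cons.append((candidates_for_observation(obs, k_sd), None))
        else:
            cand_im1, cand_i = recognize_aa(m, k_sd)
            cons.append((cand_i, cand_im1))
    return cons


def admissible_positions(chain: Chain, sequence: str, k_sd: float = 3.0) -> list[int]:
    """Sequence positions p (residue index of the first member) at which
    every member's candidate sets contain the corresponding letters.

    A basis peak requires both CO_{i-1} and N_{i+1}, so member residues are
    confined to 2 .. L-1.
    """
    L = len(sequence)
    cons = _chain_constraints(chain, k_sd)
    M = len(cons)
    out = []
    for p in range(2, L - M + 2):  # member k sits at residue p + k <= L - 1
        ok = True
        for k, (cand_i, cand_im1) in enumerate(cons):
            q = p + k
            if not (2 <= q <= L - 1):
                ok = False
                break
            if sequence[q - 1] not in cand_i:
                ok = False
                break
            if cand_im1 is not None and sequence[q - 2] not in cand_im1:
                ok = False
                break
        if ok:
            out.append(p)
    return out


def map_chains(
    chains: list[Chain], sequence: str, k_sd: float = 3.0
) -> Assignment:
    """Place chains on the sequence (longest first, unique positions only).

    A chain is assigned iff it admits exactly one position and none of its
    residues is already occupied by a longer chain; otherwise it is left
    unassigned with a reason ('ambiguous', 'no position', 'conflict').
    """
    positions: dict[str, int] = {}
    chain_of: dict[str, tuple[int, int]] = {}
    gap_shifts: dict[int, dict[str, float]] = {}
    unassigned: dict[int, str] = {}
    occupied: set[int] = set()
    for chain in sorted(chains, key=lambda c: (-len(c), c.id)):
        adm = admissible_positions(chain, sequence, k_sd)
        if len(adm) == 0:
            unassigned[chain.id] = "no position"
            continue
        if len(adm) > 1:
            unassigned[chain.id] = "ambiguous"
            continue
        p = adm[0]
        span = set(range(p, p + len(chain)))
        if span & occupied:
            unassigned[chain.id] = "conflict"
            continue
        occupied |= span
        for k, m in enumerate(chain.members):
            if isinstance(m, GapResidue):
                gap_shifts[p + k] = m.shifts
            else:
                positions[m.id] = p + k
                chain_of[m.id] = (chain.id, len(chain))
    return Assignment(
        sequence=sequence,
        positions=positions,
        chain_of=chain_of,
        gap_shifts=gap_shifts,
        unassigned_chains=unassigned,
    )


# ---------------------------------------------------------------------------
# evaluation against ground truth

#: per-kind evaluation tolerances (ppm).  CO, N and the protons are judged
#: at the matching tolerances of their element class; CA/CB are measured on
#: the wide aliphatic-carbon dimension (7.1 ms evolution, 0.47 ppm
#: resolution element), whose achievable position precision is ~0.1 ppm.
EVAL_TOLERANCES_PPM = {"CA": 0.1, "CB": 0.1}


def eval_tolerance(kind: str, tolerances: dict | None = None) -> float:
    if kind in EVAL_TOLERANCES_PPM:
        return EVAL_TOLERANCES_PPM[kind]
    return tolerance_for(kind, tolerances)


def theoretical_slot_coverage(table) -> set[tuple[int, str]]:
    """(residue, kind) pairs the experiment suite can observe at all.

    Derived from the existence conditions of the underlying peak families:
    basis peaks exist for i = 2..L-1; the 1ii/1iii planes extend CO/N
    coverage by one residue where the neighbouring basis peak exists; the
    aliphatic planes cover residues i-1 and i; the amide planes cover HN of
    i (if not proline) and i+1.
    """
    L = len(table.sequence)
    cov = set()
    for i in range(2, L):
        cov.update({(i - 1, "CO"), (i, "N"), (i, "CO"), (i + 1, "N")})
        if i + 1 <= L - 1:
            cov.update({(i + 1, "CO"), (i + 2, "N")})
        if i - 1 >= 2:
            cov.update({(i - 2, "CO"), (i - 1, "N")})
        for off in (-1, 0):
            for kind in ("CA", "CB", "HA", "HB"):
                if table.has(i + off, kind):
                    cov.add((i + off, kind))
        for off in (0, 1):
            if table.has(i + off, "HN"):
                cov.add((i + off, "HN"))
    return {(r, k) for (r, k) in cov if table.has(r, k)}


def evaluate_assignment(
    assignment: Assignment,
    cssss: list[CSSS],
    table,
    tolerances: dict | None = None,
) -> pd.DataFrame:
    """Per-nucleus correct / incorrect / unassigned fractions.

    The denominator per nucleus kind is the set of resonances the
    experiments can observe (see :func:`theoretical_slot_coverage`).  An
    assembled shift is correct when it matches the ground truth within the
    per-kind evaluation tolerance (:func:`eval_tolerance`), incorrect
    otherwise; observable resonances without an assembled value count as
    unassigned.
    """
    by_id = {c.id: c for c in cssss}
    values = assignment.assembled_shifts(by_id)
    cov = theoretical_slot_coverage(table)
    kinds = ("HN", "N", "CO", "CA", "CB", "HA", "HB")
    rows = []
    totals = {"observable": 0, "correct": 0, "incorrect": 0, "unassigned": 0}
    for kind in kinds:
        n_obs = n_ok = n_bad = n_un = 0
        for r, k in sorted(cov):
            if k != kind:
                continue
            n_obs += 1
            v = values.get((r, k))
            if v is None:
                n_un += 1
            elif abs(v - table.get(r, k)) <= eval_tolerance(k, tolerances):
                n_ok += 1
            else:
                n_bad += 1
        rows.append(
            {
                "nucleus": kind,
                "observable": n_obs,
                "correct": n_ok,
                "incorrect": n_bad,
                "unassigned": n_un,
            }
        )
        for key, v in zip(("observable", "correct", "incorrect", "unassigned"),
                          (n_obs, n_ok, n_bad, n_un)):
            totals[key] += v
    rows.append({"nucleus": "total", **totals})
    df = pd.DataFrame(rows)
    df["pct_correct"] = 100.0 * df["correct"] / df["observable"].replace(0, np.nan)
    df["pct_incorrect"] = 100.0 * df["incorrect"] / df["observable"].replace(0, np.nan)
    return df


def true_positions(cssss: list[CSSS], table, tolerances: dict | None = None) -> dict[str, int]:
    """Ground-truth residue index of each CSSS, from its basis quadruple."""
    tol_c, tol_n = tolerance_for("C", tolerances), tolerance_for("N", tolerances)
    out = {}
    L = len(table.sequence)
    for c in cssss:
        best = None
        for i in range(2, L):
            coords = (
                table.get(i, "CO"),
                table.get(i + 1, "N"),
                table.get(i, "N"),
                table.get(i - 1, "CO"),
            )
            if any(v is None for v in coords):
                continue
            d = (
                abs(coords[0] - c.basis.co_i) / tol_c
                + abs(coords[1] - c.basis.n_ip1) / tol_n
                + abs(coords[2] - c.basis.n_i) / tol_n
                + abs(coords[3] - c.basis.co_im1) / tol_c
            )
            if best is None or d < best[1]:
                best = (i, d)
        if best is not None and best[1] <= 4.0:  # each coordinate within ~1 tol
            out[c.id] = best[0]
    return out
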