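"""Four-bead coarse-grained peptide model.

Each residue is represented by three backbone beads (NH, CA, CO) and one
sidechain center-of-mass bead (SC).  Configurations live in a periodic cubic
box; geometry is maintained through pseudo-bond length constraints with a
fractional tolerance, hard-sphere excluded volume, and square-well attractive
interactions between hydrogen-bonding backbone groups and between sidechain
beads.  The dimensionless configuration energy is

    E = -w_bb * N_backbone - w_sc * N_sidechain

where the counts are saturated (at most one bond per donor/acceptor bead)
square-well contacts.

Numeric defaults (bead diameters, well widths, bond references) follow the
published parameterization of the four-bead model for glutamine; every value
can be overridden through :class:`InteractionParams` or a YAML parameter file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "BEAD_KINDS",
    "BeadSpec",
    "CGResidue",
    "CGChain",
    "CGSystem",
    "InteractionParams",
    "InteractionCount",
    "Violation",
    "PlacementError",
    "build_system",
    "build_chain_coords",
    "minimum_image_displacement",
    "wrap_positions",
    "unwrap_chain",
    "count_interactions",
    "p20_energy",
    "validate_constraints",
    "interaction_delta",
    "apply_proposal",
    "default_params",
    "get_topology",
]

BEAD_KINDS = ("NH", "CA", "CO", "SC")
KIND_INDEX = {k: i for i, k in enumerate(BEAD_KINDS)}
BEADS_PER_RESIDUE = 4

# Internal backbone geometry used by the extended-chain builder (planar,
# all-trans).  Bond lengths in Angstrom, angles in degrees.
_BOND_NH_CA = 1.46
_BOND_CA_CO = 1.51
_BOND_CO_NH = 1.33
_BOND_CA_SC = 2.56
_ANG_NH_CA_CO = 111.0
_ANG_CA_CO_NH = 116.0
_ANG_CO_NH_CA = 122.0


class PlacementError(RuntimeError):
    """Raised when chains cannot be placed without constraint violations."""


@dataclass(frozen=True)
class BeadSpec:
    """Hard-sphere bead: kind, diameter (A) and mass (amu)."""

    kind: str
    diameter: float
    mass: float

    def __post_init__(self) -> None:
        if self.kind not in BEAD_KINDS:
            raise ValueError(f"unknown bead kind {self.kind!r}")
        if not self.diameter > 0:
            raise ValueError("bead diameter must be > 0")
        if not self.mass > 0:
            raise ValueError("bead mass must be > 0")


# Diameters follow the published four-bead parameterization; masses are the
# united-atom group masses (glutamine sidechain = C3H6NO).
DEFAULT_BEAD_SPECS = {
    "NH": BeadSpec("NH", 3.3, 15.015),
    "CA": BeadSpec("CA", 3.7, 13.019),
    "CO": BeadSpec("CO", 3.5, 28.010),
    "SC": BeadSpec("SC", 4.7, 72.086),
}


@dataclass
class CGResidue:
    """One residue: index, one-letter code, and its four bead positions."""

    index: int
    aa: str
    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.positions) != set(BEAD_KINDS):
            raise ValueError("residue needs exactly one position per bead kind")
        for kind, pos in self.positions.items():
            pos = np.asarray(pos, dtype=float)
            if pos.shape != (3,) or not np.all(np.isfinite(pos)):
                raise ValueError(f"non-finite or malformed position for bead {kind}")
            self.positions[kind] = pos


@dataclass
class CGChain:
    """An ordered chain of residues."""

    chain_id: str
    residues: list[CGResidue]

    def __post_init__(self) -> None:
        for i, res in enumerate(self.residues):
            if res.index != i:
                raise ValueError("residue indices must be consecutive from 0")

    @property
    def sequence(self) -> str:
        return "".join(res.aa for res in self.residues)


class CGSystem:
    """Chains of four-bead residues in a periodic cubic box.

    Coordinates are stored as a flat ``(n_beads, 3)`` array wrapped into
    ``[0, L)``; beads are ordered chain-major, residue-major, with bead kinds
    in the order NH, CA, CO, SC.  Structured :class:`CGChain` views are built
    on demand via :attr:`chains`.
    """

    def __init__(
        self,
        chain_ids: Sequence[str],
        sequences: Sequence[str],
        coords: np.ndarray,
        box_length: float,
        periodic: bool = True,
    ) -> None:
        if not box_length > 0:
            raise ValueError("box length must be > 0")
        if len(chain_ids) != len(sequences):
            raise ValueError("chain_ids and sequences must have equal length")
        n_expected = sum(len(s) for s in sequences) * BEADS_PER_RESIDUE
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (n_expected, 3):
            raise ValueError(f"expected coords of shape ({n_expected}, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        self.chain_ids = list(chain_ids)
        self.sequences = [str(s) for s in sequences]
        self.box_length = float(box_length)
        self.periodic = bool(periodic)
        self.coords = wrap_positions(coords, self.box_length) if periodic else coords
        # Per-bead bookkeeping arrays.
        chain_index, residue_index, kind_index = [], [], []
        chain_start = []
        start = 0
        for ci, seq in enumerate(self.sequences):
            chain_start.append(start)
            for ri in range(len(seq)):
                for ki in range(BEADS_PER_RESIDUE):
                    chain_index.append(ci)
                    residue_index.append(ri)
                    kind_index.append(ki)
            start += len(seq) * BEADS_PER_RESIDUE
        self.chain_index = np.asarray(chain_index, dtype=np.int64)
        self.residue_index = np.asarray(residue_index, dtype=np.int64)
        self.kind_index = np.asarray(kind_index, dtype=np.int64)
        self._chain_start = chain_start
        self._topo_cache: tuple[object, object] | None = None

    # -- construction / views -------------------------------------------------

    @classmethod
    def from_chains(cls, chains: Iterable[CGChain], box_length: float,
                    periodic: bool = True) -> "CGSystem":
        chains = list(chains)
        coords = []
        for chain in chains:
            for res in chain.residues:
                for kind in BEAD_KINDS:
                    coords.append(res.positions[kind])
        return cls(
            [c.chain_id for c in chains],
            [c.sequence for c in chains],
            np.asarray(coords, dtype=float),
            box_length,
            periodic,
        )

    @property
    def n_chains(self) -> int:
        return len(self.chain_ids)

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def chain_slice(self, chain: int) -> slice:
        start = self._chain_start[chain]
        return slice(start, start + len(self.sequences[chain]) * BEADS_PER_RESIDUE)

    def bead_index(self, chain: int, residue: int, kind: str) -> int:
        return self._chain_start[chain] + residue * BEADS_PER_RESIDUE + KIND_INDEX[kind]

    @property
    def chains(self) -> list[CGChain]:
        out = []
        for ci, (cid, seq) in enumerate(zip(self.chain_ids, self.sequences)):
            residues = []
            for ri, aa in enumerate(seq):
                pos = {
                    kind: self.coords[self.bead_index(ci, ri, kind)].copy()
                    for kind in BEAD_KINDS
                }
                residues.append(CGResidue(ri, aa, pos))
            out.append(CGChain(cid, residues))
        return out

    def copy(self) -> "CGSystem":
        return CGSystem(
            list(self.chain_ids), list(self.sequences), self.coords.copy(),
            self.box_length, self.periodic,
        )

    def invalidate_cache(self) -> None:
        self._topo_cache = None


def wrap_positions(x: np.ndarray, box_length: float) -> np.ndarray:
    """Wrap coordinates into ``[0, L)``."""
    x = np.asarray(x, dtype=float)
    return x - box_length * np.floor(x / box_length)


def minimum_image_displacement(a, b, box_length: float) -> np.ndarray:
    """Minimum-image displacement ``b - a``, components in ``[-L/2, L/2)``."""
    if not box_length > 0:
        raise ValueError("box length must be > 0")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("positions must be finite")
    d = b - a
    return d - box_length * np.floor(d / box_length + 0.5)


# -- interaction parameters ---------------------------------------------------


def _pair_key(kind_a: str, kind_b: str) -> tuple[str, str]:
    return tuple(sorted((kind_a, kind_b)))  # type: ignore[return-value]


@dataclass
class InteractionParams:
    """All tunable model parameters (see module docstring for provenance).

    ``hb_well`` is the backbone NH...CO square-well distance band; ``sc_wells``
    maps sorted bead-kind pairs involving SC to their bands.  ``bond_lengths``
    holds pseudo-bond references; a trailing ``+`` in a key means "next
    residue".  Excluded volume applies between beads of different chains and
    between intra-chain beads at least two residues apart; the contact
    distance is the mean of the two bead diameters unless overridden.
    """

    bead_specs: dict[str, BeadSpec] = field(
        default_factory=lambda: dict(DEFAULT_BEAD_SPECS))
    w_bb: float = 1.0
    w_sc: float = 0.08
    hb_well: tuple[float, float] | None = (3.4, 4.5)
    sc_wells: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: {
            ("SC", "SC"): (4.7, 6.1),
            ("NH", "SC"): (4.0, 5.0),
            ("CO", "SC"): (4.1, 5.1),
        })
    bond_lengths: dict[str, float] = field(default_factory=dict)
    bond_tolerance: float = 0.02375
    min_residue_separation: int = 3
    excluded_overrides: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.w_bb < 0 or self.w_sc < 0:
            raise ValueError("interaction weights must be >= 0")
        if not (0 < self.bond_tolerance < 0.2):
            raise ValueError("bond tolerance must be in (0, 0.2)")
        if self.hb_well is not None:
            lo, hi = self.hb_well
            if not (0 < lo < hi):
                raise ValueError("hydrogen-bond well needs 0 < d_min < d_max")
        for key, (lo, hi) in self.sc_wells.items():
            if not (0 < lo < hi):
                raise ValueError(f"sidechain well {key} needs 0 < d_min < d_max")
        if not self.bond_lengths:
            self.bond_lengths = _default_bond_lengths()

    def excluded_diameter(self, kind_a: str, kind_b: str) -> float:
        key = _pair_key(kind_a, kind_b)
        if key in self.excluded_overrides:
            return self.excluded_overrides[key]
        return 0.5 * (self.bead_specs[kind_a].diameter
                      + self.bead_specs[kind_b].diameter)

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "beads": {k: {"diameter": s.diameter, "mass": s.mass}
                      for k, s in self.bead_specs.items()},
            "w_bb": self.w_bb,
            "w_sc": self.w_sc,
            "hb_well": list(self.hb_well) if self.hb_well else None,
            "sc_wells": {"-".join(k): list(v) for k, v in self.sc_wells.items()},
            "bond_lengths": dict(self.bond_lengths),
            "bond_tolerance": self.bond_tolerance,
            "min_residue_separation": self.min_residue_separation,
            "excluded_overrides": {"-".join(k): v
                                   for k, v in self.excluded_overrides.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "InteractionParams":
        data = dict(data)
        kwargs: dict = {}
        if "beads" in data:
            kwargs["bead_specs"] = {
                k: BeadSpec(k, v["diameter"], v["mass"])
                for k, v in data.pop("beads").items()
            }
        if "hb_well" in data:
            well = data.pop("hb_well")
            kwargs["hb_well"] = tuple(well) if well is not None else None
        if "sc_wells" in data:
            kwargs["sc_wells"] = {
                tuple(k.split("-")): tuple(v)
                for k, v in data.pop("sc_wells").items()
            }
        if "excluded_overrides" in data:
            kwargs["excluded_overrides"] = {
                tuple(k.split("-")): float(v)
                for k, v in data.pop("excluded_overrides").items()
            }
        for key in ("w_bb", "w_sc", "bond_lengths", "bond_tolerance",
                    "min_residue_separation"):
            if key in data:
                kwargs[key] = data.pop(key)
        if data:
            raise ValueError(f"unknown parameter keys: {sorted(data)}")
        return cls(**kwargs)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "InteractionParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def replace(self, **kwargs) -> "InteractionParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class InteractionCount:
    n_backbone: int
    n_sidechain: int

    def __post_init__(self) -> None:
        if self.n_backbone < 0 or self.n_sidechain < 0:
            raise ValueError("interaction counts must be >= 0")

    def as_tuple(self) -> tuple[int, int]:
        return (self.n_backbone, self.n_sidechain)


def default_params() -> InteractionParams:
    return InteractionParams()


def p20_energy(counts: InteractionCount | tuple[int, int],
               params: InteractionParams | None = None) -> float:
    """Dimensionless energy ``-w_bb * N_backbone - w_sc * N_sidechain``."""
    if params is None:
        params = default_params()
    if isinstance(counts, InteractionCount):
        nb, ns = counts.n_backbone, counts.n_sidechain
    else:
        nb, ns = counts
    return -params.w_bb * nb - params.w_sc * ns


# -- chain builder ------------------------------------------------------------


def build_chain_coords(sequence: str) -> np.ndarray:
    """Planar all-trans extended chain; returns ``(4 * n_res, 3)`` coords.

    The backbone zig-zags in the xy-plane with the canonical bond lengths and
    angles; the SC bead sits above the plane at the CA-SC reference length.
    All pseudo-bond constraints of :func:`_default_bond_lengths` are satisfied
    exactly by construction.
    """
    n_res = len(sequence)
    if n_res < 1:
        raise ValueError("sequence must have at least one residue")
    backbone = []  # NH0, CA0, CO0, NH1, ...
    pos = np.zeros(3)
    direction = np.array([1.0, 0.0, 0.0])
    backbone.append(pos.copy())
    bonds = [_BOND_NH_CA, _BOND_CA_CO, _BOND_CO_NH]
    angles = [_ANG_NH_CA_CO, _ANG_CA_CO_NH, _ANG_CO_NH_CA]
    sign = 1.0
    step = 0
    for _ in range(3 * n_res - 1):
        bond = bonds[step % 3]
        pos = pos + bond * direction
        backbone.append(pos.copy())
        turn = sign * math.radians(180.0 - angles[step % 3])
        c, s = math.cos(turn), math.sin(turn)
        direction = np.array([c * direction[0] - s * direction[1],
                              s * direction[0] + c * direction[1], 0.0])
        sign = -sign
        step += 1
    backbone = np.asarray(backbone)
    coords = np.empty((BEADS_PER_RESIDUE * n_res, 3))
    z = np.array([0.0, 0.0, 1.0])
    for ri in range(n_res):
        nh, ca, co = backbone[3 * ri], backbone[3 * ri + 1], backbone[3 * ri + 2]
        u_n = (nh - ca) / np.linalg.norm(nh - ca)
        u_c = (co - ca) / np.linalg.norm(co - ca)
        bisector = -(u_n + u_c)
        bisector /= np.linalg.norm(bisector)
        sc_dir = bisector + z
        sc_dir /= np.linalg.norm(sc_dir)
        base = BEADS_PER_RESIDUE * ri
        coords[base + KIND_INDEX["NH"]] = nh
        coords[base + KIND_INDEX["CA"]] = ca
        coords[base + KIND_INDEX["CO"]] = co
        coords[base + KIND_INDEX["SC"]] = ca + _BOND_CA_SC * sc_dir
    return coords


def _default_bond_lengths() -> dict[str, float]:
    """Bond/pseudo-bond references measured from the canonical extended chain."""
    coords = build_chain_coords("QQ")

    def d(i, j):
        return float(np.linalg.norm(coords[i] - coords[j]))

    nh0, ca0, co0, sc0 = 0, 1, 2, 3
    nh1, ca1 = 4, 5
    return {
        "NH-CA": d(nh0, ca0),
        "CA-CO": d(ca0, co0),
        "CA-SC": d(ca0, sc0),
        "NH-CO": d(nh0, co0),
        "CO-NH+": d(co0, nh1),
        "CA-NH+": d(ca0, nh1),
        "CA-CA+": d(ca0, ca1),
    }


def build_system(
    sequence: str,
    n_chains: int,
    box_length: float,
    seed: int,
    params: InteractionParams | None = None,
    max_retries: int = 1000,
) -> CGSystem:
    """Place ``n_chains`` extended copies of ``sequence`` in a periodic box.

    Each chain is rotated by a uniformly random rotation and translated to a
    uniformly random box position; placements are retried until the full
    system passes :func:`validate_constraints`.  Deterministic for fixed seed.
    """
    if len(sequence) < 1:
        raise ValueError("sequence must have at least one residue")
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if params is None:
        params = default_params()
    rng = np.random.default_rng(seed)
    template = build_chain_coords(sequence)
    template = template - template.mean(axis=0)
    chain_ids = [chr(ord("A") + i) if i < 26 else f"X{i}" for i in range(n_chains)]
    sequences = [sequence] * n_chains

    placed: list[np.ndarray] = []
    for ci in range(n_chains):
        last_violation = None
        for _ in range(max_retries):
            quat = rng.normal(size=4)
            quat /= np.linalg.norm(quat)
            rot = _quat_to_matrix(quat)
            shift = rng.uniform(0.0, box_length, size=3)
            candidate = template @ rot.T + shift
            trial = CGSystem(chain_ids[: ci + 1], sequences[: ci + 1],
                             np.concatenate(placed + [candidate]), box_length)
            violations = validate_constraints(trial, params)
            if not violations:
                placed.append(wrap_positions(candidate, box_length))
                break
            last_violation = violations[0]
        else:
            raise PlacementError(
                f"could not place chain {ci} after {max_retries} attempts; "
                f"last failing constraint: {last_violation}")
    return CGSystem(chain_ids, sequences, np.concatenate(placed), box_length)


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def unwrap_chain(system: CGSystem, chain: int) -> np.ndarray:
    """Continuous (unwrapped) coordinates for one chain.

    Walks the bond tree (NH->CA->CO->NH..., CA->SC) taking minimum-image
    steps, then snaps each bead to ``wrapped + k * L`` for the integer image
    shift ``k``; beads with ``k == 0`` keep their stored bits exactly.
    """
    sl = system.chain_slice(chain)
    wrapped = system.coords[sl]
    L = system.box_length
    n_res = len(system.sequences[chain])
    n = wrapped.shape[0]
    # Parent of each bead in the bond tree (NH of residue 0 is the root).
    parent = np.empty(n, dtype=np.int64)
    for ri in range(n_res):
        base = ri * BEADS_PER_RESIDUE
        parent[base + KIND_INDEX["NH"]] = (
            base - BEADS_PER_RESIDUE + KIND_INDEX["CO"] if ri > 0 else -1)
        parent[base + KIND_INDEX["CA"]] = base + KIND_INDEX["NH"]
        parent[base + KIND_INDEX["CO"]] = base + KIND_INDEX["CA"]
        parent[base + KIND_INDEX["SC"]] = base + KIND_INDEX["CA"]
    d = wrapped - wrapped[np.maximum(parent, 0)]
    d -= L * np.floor(d / L + 0.5)
    est = np.empty_like(wrapped)
    est[0] = wrapped[0]
    for k in range(1, n):
        est[k] = est[parent[k]] + d[k]
    shifts = np.rint((est - wrapped) / L)
    out = wrapped.copy()
    nonzero = np.any(shifts != 0.0, axis=1)
    out[nonzero] = wrapped[nonzero] + shifts[nonzero] * L
    return out


# -- topology: precomputed pair lists for constraints and counting ------------


@dataclass(frozen=True)
class Violation:
    """A single constraint violation (bond stretch or hard-sphere overlap)."""

    kind: str  # "bond" | "excluded_volume"
    beads: tuple[int, int]
    labels: tuple[str, str]
    distance: float
    limit: float

    def __str__(self) -> str:
        if self.kind == "bond":
            return (f"bond {self.labels[0]}--{self.labels[1]}: length "
                    f"{self.distance:.4f} A outside tolerance of reference "
                    f"{self.limit:.4f} A")
        return (f"excluded volume {self.labels[0]}--{self.labels[1]}: distance "
                f"{self.distance:.4f} A < contact {self.limit:.4f} A")


class Topology:
    """Static pair lists derived from system composition and parameters."""

    def __init__(self, system: CGSystem, params: InteractionParams) -> None:
        self.params = params
        self.box_length = system.box_length
        n = system.n_beads
        chain = system.chain_index
        res = system.residue_index
        kind = system.kind_index
        self.bead_labels = [
            f"{system.chain_ids[chain[i]]}/{res[i]}/{BEAD_KINDS[kind[i]]}"
            for i in range(n)
        ]

        # Bonds.
        bonds_i, bonds_j, bonds_ref = [], [], []
        intra = [("NH", "CA"), ("CA", "CO"), ("CA", "SC"), ("NH", "CO")]
        inter = [("CO-NH+", "CO", "NH"), ("CA-NH+", "CA", "NH"),
                 ("CA-CA+", "CA", "CA")]
        for ci in range(system.n_chains):
            n_res = len(system.sequences[ci])
            for ri in range(n_res):
                for a, b in intra:
                    bonds_i.append(system.bead_index(ci, ri, a))
                    bonds_j.append(system.bead_index(ci, ri, b))
                    bonds_ref.append(params.bond_lengths[f"{a}-{b}"])
                if ri + 1 < n_res:
                    for name, a, b in inter:
                        bonds_i.append(system.bead_index(ci, ri, a))
                        bonds_j.append(system.bead_index(ci, ri + 1, b))
                        bonds_ref.append(params.bond_lengths[name])
        self.bonds_i = np.asarray(bonds_i, dtype=np.int64)
        self.bonds_j = np.asarray(bonds_j, dtype=np.int64)
        self.bonds_ref = np.asarray(bonds_ref, dtype=float)

        # All-pairs upper triangle.
        iu, ju = np.triu_indices(n, k=1)
        same_chain = chain[iu] == chain[ju]
        res_sep = np.abs(res[iu] - res[ju])

        # Excluded volume: skip intra-chain pairs closer than two residues
        # (their geometry is governed by the bond constraints instead).
        ev_mask = ~(same_chain & (res_sep <= 1))
        self.ev_i = iu[ev_mask]
        self.ev_j = ju[ev_mask]
        diam = np.array([[params.excluded_diameter(a, b) for b in BEAD_KINDS]
                         for a in BEAD_KINDS])
        self.ev_dmin = diam[kind[self.ev_i], kind[self.ev_j]]

        # Counting pairs share the residue-separation exclusion.
        count_ok = ~(same_chain & (res_sep < params.min_residue_separation))

        nh_k, co_k, sc_k = KIND_INDEX["NH"], KIND_INDEX["CO"], KIND_INDEX["SC"]
        if params.hb_well is not None:
            hb = count_ok & (((kind[iu] == nh_k) & (kind[ju] == co_k))
                             | ((kind[iu] == co_k) & (kind[ju] == nh_k)))
            self.hb_i = iu[hb]
            self.hb_j = ju[hb]
            self.hb_lo, self.hb_hi = params.hb_well
        else:
            self.hb_i = np.empty(0, dtype=np.int64)
            self.hb_j = np.empty(0, dtype=np.int64)
            self.hb_lo = self.hb_hi = 0.0

        sc_i, sc_j, sc_lo, sc_hi = [], [], [], []
        wells = {tuple(sorted(k)): v for k, v in params.sc_wells.items()}
        pair_kinds = np.stack([kind[iu], kind[ju]], axis=1)
        for (ka, kb), (lo, hi) in wells.items():
            ia, ib = KIND_INDEX[ka], KIND_INDEX[kb]
            m = count_ok & (((pair_kinds[:, 0] == ia) & (pair_kinds[:, 1] == ib))
                            | ((pair_kinds[:, 0] == ib) & (pair_kinds[:, 1] == ia)))
            sc_i.append(iu[m])
            sc_j.append(ju[m])
            sc_lo.append(np.full(m.sum(), lo))
            sc_hi.append(np.full(m.sum(), hi))
        self.sc_i = np.concatenate(sc_i) if sc_i else np.empty(0, dtype=np.int64)
        self.sc_j = np.concatenate(sc_j) if sc_j else np.empty(0, dtype=np.int64)
        self.sc_lo = np.concatenate(sc_lo) if sc_lo else np.empty(0)
        self.sc_hi = np.concatenate(sc_hi) if sc_hi else np.empty(0)

        # Fused index arrays so one distance pass serves bonds, excluded
        # volume and both square-well counters (hot path of the sampler).
        self._all_i = np.concatenate([self.bonds_i, self.ev_i,
                                      self.hb_i, self.sc_i])
        self._all_j = np.concatenate([self.bonds_j, self.ev_j,
                                      self.hb_j, self.sc_j])
        n_b, n_ev, n_hb = len(self.bonds_i), len(self.ev_i), len(self.hb_i)
        self._sl_bonds = slice(0, n_b)
        self._sl_ev = slice(n_b, n_b + n_ev)
        self._sl_hb = slice(n_b + n_ev, n_b + n_ev + n_hb)
        self._sl_sc = slice(n_b + n_ev + n_hb, None)
        self._bond_tol_abs = params.bond_tolerance * self.bonds_ref

    # -- distance helpers -----------------------------------------------------

    def _dist(self, coords: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        d = coords[j] - coords[i]
        L = self.box_length
        d -= L * np.floor(d / L + 0.5)
        return np.sqrt(np.einsum("ij,ij->i", d, d))

    # -- evaluation -----------------------------------------------------------

    def bond_ok(self, coords: np.ndarray) -> bool:
        d = self._dist(coords, self.bonds_i, self.bonds_j)
        return bool(np.all(np.abs(d - self.bonds_ref)
                           <= self.params.bond_tolerance * self.bonds_ref))

    def overlap_ok(self, coords: np.ndarray) -> bool:
        d = self._dist(coords, self.ev_i, self.ev_j)
        return bool(np.all(d >= self.ev_dmin))

    def is_valid(self, coords: np.ndarray) -> bool:
        return self.bond_ok(coords) and self.overlap_ok(coords)

    def evaluate(self, coords: np.ndarray) -> tuple[bool, int, int]:
        """One-pass (valid, n_backbone, n_sidechain); counts are only
        computed when the configuration is constraint-valid."""
        d = self._dist(coords, self._all_i, self._all_j)
        db = d[self._sl_bonds]
        if np.any(np.abs(db - self.bonds_ref) > self._bond_tol_abs):
            return False, 0, 0
        if np.any(d[self._sl_ev] < self.ev_dmin):
            return False, 0, 0
        nb = self._matched_d(d[self._sl_hb], self.hb_i, self.hb_j,
                             self.hb_lo, self.hb_hi)
        ns = self._matched_d(d[self._sl_sc], self.sc_i, self.sc_j,
                             self.sc_lo, self.sc_hi)
        return True, nb, ns

    def violations(self, coords: np.ndarray) -> list[Violation]:
        out: list[Violation] = []
        d = self._dist(coords, self.bonds_i, self.bonds_j)
        bad = np.abs(d - self.bonds_ref) > self.params.bond_tolerance * self.bonds_ref
        for k in np.nonzero(bad)[0]:
            i, j = int(self.bonds_i[k]), int(self.bonds_j[k])
            out.append(Violation("bond", (i, j),
                                 (self.bead_labels[i], self.bead_labels[j]),
                                 float(d[k]), float(self.bonds_ref[k])))
        d = self._dist(coords, self.ev_i, self.ev_j)
        bad = d < self.ev_dmin
        for k in np.nonzero(bad)[0]:
            i, j = int(self.ev_i[k]), int(self.ev_j[k])
            out.append(Violation("excluded_volume", (i, j),
                                 (self.bead_labels[i], self.bead_labels[j]),
                                 float(d[k]), float(self.ev_dmin[k])))
        return out

    def count(self, coords: np.ndarray) -> tuple[int, int]:
        nb = self._matched(coords, self.hb_i, self.hb_j,
                           self.hb_lo, self.hb_hi)
        ns = self._matched(coords, self.sc_i, self.sc_j,
                           self.sc_lo, self.sc_hi)
        return nb, ns

    def _matched(self, coords, pi, pj, lo, hi) -> int:
        if len(pi) == 0:
            return 0
        return self._matched_d(self._dist(coords, pi, pj), pi, pj, lo, hi)

    def _matched_d(self, d, pi, pj, lo, hi) -> int:
        """Greedy distance-ascending matching: one bond per bead, ties by index."""
        if len(pi) == 0:
            return 0
        inside = (d >= lo) & (d <= hi)
        if not np.any(inside):
            return 0
        cand = np.nonzero(inside)[0]
        order = sorted(cand, key=lambda k: (d[k], int(pi[k]), int(pj[k])))
        used: set[int] = set()
        n = 0
        for k in order:
            i, j = int(pi[k]), int(pj[k])
            if i in used or j in used:
                continue
            used.add(i)
            used.add(j)
            n += 1
        return n


def get_topology(system: CGSystem, params: InteractionParams) -> Topology:
    cache = system._topo_cache
    if cache is not None and cache[0] is params:
        return cache[1]  # type: ignore[return-value]
    topo = Topology(system, params)
    system._topo_cache = (params, topo)
    return topo


# -- public operations --------------------------------------------------------


def count_interactions(system: CGSystem,
                       params: InteractionParams | None = None) -> InteractionCount:
    """Saturated square-well contact counts (backbone, sidechain)."""
    if params is None:
        params = default_params()
    nb, ns = get_topology(system, params).count(system.coords)
    return InteractionCount(nb, ns)


def validate_constraints(system: CGSystem,
                         params: InteractionParams | None = None) -> list[Violation]:
    """Every bond-length and excluded-volume violation, empty if none."""
    if params is None:
        params = default_params()
    return get_topology(system, params).violations(system.coords)


def apply_proposal(system: CGSystem, proposal) -> None:
    """Write a move proposal's new positions into the system (in place)."""
    system.coords[proposal.bead_indices] = wrap_positions(
        proposal.new_positions, system.box_length)


def interaction_delta(system: CGSystem, proposal,
                      params: InteractionParams | None = None) -> tuple[int, int]:
    """Signed count change if ``proposal`` were applied.

    Guaranteed consistent with a from-scratch recount: the trial counts are
    recomputed with the full (global) matching on the proposed coordinates.
    """
    if params is None:
        params = default_params()
    topo = get_topology(system, params)
    old_nb, old_ns = topo.count(system.coords)
    trial = system.coords.copy()
    trial[proposal.bead_indices] = wrap_positions(
        np.asarray(proposal.new_positions, dtype=float), system.box_length)
    new_nb, new_ns = topo.count(trial)
    return (new_nb - old_nb, new_ns - old_ns)
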