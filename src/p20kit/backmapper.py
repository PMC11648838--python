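"""Inverse coarse-graining: rebuild all-atom peptides from CG bead snapshots.

Backbone N, CA and C atoms are taken directly from the NH, CA and CO beads.
Carbonyl oxygens and amide protons are constructed in the peptide plane
(planar trans arrangement); each sidechain is placed as a rigid equilibrium
template whose mass-weighted center of mass is pinned to the SC bead and
whose internal CA->COM axis is aligned with the actual CA->SC direction.  The
torsion about that axis, which the CG representation leaves free, is resolved
by sampling K candidate rotations and keeping the one with the fewest steric
clashes against already-placed atoms.  Both termini are built charged (NH3+
and COO-).  Structures are written as PDB v3.3 or GRO via biotite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.gro import GROFile
from biotite.structure.io.pdb import PDBFile

from .prime20_model import (
    BEADS_PER_RESIDUE,
    KIND_INDEX,
    CGSystem,
    unwrap_chain,
)

__all__ = [
    "ResidueTemplate",
    "AtomRecord",
    "AtomisticStructure",
    "ClashRecord",
    "ClashReport",
    "GeometryConfig",
    "BackmapError",
    "GLN_TEMPLATE",
    "ATOM_MASSES",
    "VDW_RADII",
    "place_atom",
    "dihedral",
    "complete_backbone",
    "reconstruct_sidechain",
    "torsion_candidates",
    "backmap",
    "project_to_cg",
    "detect_clashes",
    "write_structure",
    "read_structure",
]

ATOM_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}
VDW_RADII = {"H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52}


class BackmapError(RuntimeError):
    pass


@dataclass
class GeometryConfig:
    """Standard geometry used to complete the backbone and termini."""

    c_o_length: float = 1.23        # carbonyl C=O
    n_h_length: float = 1.01        # amide N-H
    c_n_h_angle: float = 119.0      # deg, at the amide N
    ca_ha_length: float = 1.09
    c_oxt_length: float = 1.25      # carboxylate C-O
    oxt_angle: float = 117.0        # deg, CA-C-O at the C-terminus
    n_h3_length: float = 1.03       # ammonium N-H
    n_h3_angle: float = 109.5       # deg, from the CA->N axis
    n_h3_reference_torsion: float = 60.0  # deg, first H relative to CA->C
    torsion_samples: int = 36       # K candidate sidechain torsions
    clash_fraction: float = 0.6     # cutoff = fraction * (vdw_i + vdw_j)


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    if norm < 1e-10:
        raise BackmapError("degenerate (zero-length) direction vector")
    return v / norm


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place X bonded to ``a`` with angle X-a-b and dihedral X-a-b-c."""
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    ba = _unit(a - b)
    n = np.cross(b - c, ba)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        raise BackmapError("collinear reference atoms for placement")
    n /= norm
    m = np.cross(n, ba)
    d = (-math.cos(theta) * ba
         + math.sin(theta) * math.cos(phi) * m
         + math.sin(theta) * math.sin(phi) * n)
    return a + bond * d


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in radians."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    return math.atan2(np.dot(np.cross(b1u, v), w), np.dot(v, w))


# -- residue template ---------------------------------------------------------


@dataclass
class ResidueTemplate:
    """Rigid equilibrium conformation of one residue type.

    ``coords`` holds the template frame positions of ``atom_names``; the
    sidechain members define the mass-weighted COM that anchors placement.
    """

    name: str
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray
    sidechain_atoms: list[str]
    ca_atom: str = "CA"
    first_sidechain_atom: str = "CB"
    bonds: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atom_names), 3):
            raise ValueError("template coords must match the atom list")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("template coords must be finite")
        backbone_like = {self.ca_atom}
        if not set(self.sidechain_atoms).isdisjoint(backbone_like):
            raise ValueError("sidechain COM must use sidechain atoms only")
        self._index = {n: i for i, n in enumerate(self.atom_names)}

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOM_MASSES[e] for e in self.elements])

    def sidechain_indices(self) -> np.ndarray:
        return np.array([self.index(n) for n in self.sidechain_atoms])

    def sidechain_com(self) -> np.ndarray:
        idx = self.sidechain_indices()
        m = self.masses[idx]
        return (self.coords[idx] * m[:, None]).sum(axis=0) / m.sum()


def _build_gln_template() -> ResidueTemplate:
    """Glutamine equilibrium conformation from ideal internal coordinates."""
    ca = np.zeros(3)
    n = np.array([-1.46, 0.0, 0.0])
    alpha = math.radians(69.0)  # so that angle N-CA-C = 111 deg
    c = 1.51 * np.array([math.cos(alpha), math.sin(alpha), 0.0])
    pos = {"CA": ca, "N": n, "C": c}
    pos["CB"] = place_atom(ca, n, c, 1.53, 110.5, -122.0)
    pos["CG"] = place_atom(pos["CB"], ca, n, 1.53, 111.0, 180.0)
    pos["CD"] = place_atom(pos["CG"], pos["CB"], ca, 1.52, 111.0, 180.0)
    pos["OE1"] = place_atom(pos["CD"], pos["CG"], pos["CB"], 1.23, 121.0, 0.0)
    pos["NE2"] = place_atom(pos["CD"], pos["CG"], pos["CB"], 1.335, 116.5, 180.0)
    pos["HE21"] = place_atom(pos["NE2"], pos["CD"], pos["CG"], 1.01, 120.0, 0.0)
    pos["HE22"] = place_atom(pos["NE2"], pos["CD"], pos["CG"], 1.01, 120.0, 180.0)
    pos["HB2"] = place_atom(pos["CB"], pos["CG"], pos["CD"], 1.09, 109.4, 60.0)
    pos["HB3"] = place_atom(pos["CB"], pos["CG"], pos["CD"], 1.09, 109.4, -60.0)
    pos["HG2"] = place_atom(pos["CG"], pos["CB"], ca, 1.09, 109.4, 60.0)
    pos["HG3"] = place_atom(pos["CG"], pos["CB"], ca, 1.09, 109.4, -60.0)
    names = ["CA", "CB", "HB2", "HB3", "CG", "HG2", "HG3", "CD", "OE1",
             "NE2", "HE21", "HE22"]
    elements = [nm[0] for nm in names]  # C/H/N/O from the leading letter
    coords = np.array([pos[nm] for nm in names])
    sidechain = names[1:]
    bonds = [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
             ("CG", "HG2"), ("CG", "HG3"), ("CG", "CD"), ("CD", "OE1"),
             ("CD", "NE2"), ("NE2", "HE21"), ("NE2", "HE22")]
    return ResidueTemplate("GLN", names, elements, coords, sidechain,
                           bonds=bonds)


GLN_TEMPLATE = _build_gln_template()
DEFAULT_TEMPLATES = {"Q": GLN_TEMPLATE}
THREE_LETTER = {"Q": "GLN"}


# -- atomistic structure ------------------------------------------------------


@dataclass
class AtomRecord:
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be a finite 3-vector")


@dataclass
class AtomisticStructure:
    atoms: list[AtomRecord]
    sequences: list[str]
    chain_ids: list[str]
    termini_charged: bool = True
    provenance: str = ""
    bonds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]


def expected_atom_count(sequences: list[str],
                        templates: dict[str, ResidueTemplate] | None = None,
                        termini_charged: bool = True) -> int:
    """Template-derived atom count: per residue N,H,CA,HA,C,O plus sidechain;
    charged termini add two extra H at the N-terminus and one OXT."""
    if templates is None:
        templates = DEFAULT_TEMPLATES
    total = 0
    for seq in sequences:
        for aa in seq:
            if aa not in templates:
                raise BackmapError(f"no residue template for type {aa!r}")
            total += 6 + len(templates[aa].sidechain_atoms)
        if termini_charged:
            total += 3  # 2 extra ammonium H + OXT
    return total


# -- backbone completion ------------------------------------------------------


def _carbonyl_oxygen(ca: np.ndarray, c: np.ndarray, n_next: np.ndarray,
                     length: float) -> np.ndarray:
    """O in the CA-C-N plane, anti to the bisector of the two bonds."""
    u_ca = _unit(ca - c)
    u_n = _unit(n_next - c)
    bis = u_ca + u_n
    if np.linalg.norm(bis) < 1e-10:
        raise BackmapError("collinear backbone triplet at carbonyl placement")
    return c + length * _unit(-bis)


def _amide_hydrogen(o_prev: np.ndarray, c_prev: np.ndarray, n: np.ndarray,
                    geo: GeometryConfig) -> np.ndarray:
    """H on the amide N, in the O-C-N plane and exactly trans to O."""
    u = _unit(n - c_prev)
    oc = o_prev - c_prev
    perp = oc - np.dot(oc, u) * u
    d = _unit(perp)
    theta = math.radians(geo.c_n_h_angle)
    direction = math.cos(theta) * (-u) + math.sin(theta) * (-d)
    return n + geo.n_h_length * _unit(direction)


def complete_backbone(n_pos: np.ndarray, ca_pos: np.ndarray, c_pos: np.ndarray,
                      geo: GeometryConfig | None = None,
                      ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Carbonyl O and amide H positions for every peptide bond of a chain.

    Inputs are per-residue backbone positions (n residues each).  Returns
    (oxygens, hydrogens): ``oxygens[i]`` completes residue ``i`` for
    ``i < n-1``; ``hydrogens[i]`` sits on residue ``i+1``'s nitrogen.  Raises
    on chains shorter than 2 residues or degenerate triplets.
    """
    if geo is None:
        geo = GeometryConfig()
    n_res = len(ca_pos)
    if n_res < 2:
        raise BackmapError("backbone completion needs at least 2 residues")
    oxygens, hydrogens = [], []
    for i in range(n_res - 1):
        try:
            o = _carbonyl_oxygen(ca_pos[i], c_pos[i], n_pos[i + 1],
                                 geo.c_o_length)
        except BackmapError as err:
            raise BackmapError(f"residue {i}: {err}") from None
        h = _amide_hydrogen(o, c_pos[i], n_pos[i + 1], geo)
        oxygens.append(o)
        hydrogens.append(h)
    return oxygens, hydrogens


# -- sidechain placement ------------------------------------------------------


def _align_rotation(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Rotation matrix taking direction v_from to direction v_to."""
    a = _unit(v_from)
    b = _unit(v_to)
    c = float(np.dot(a, b))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # pick any axis perpendicular to a
        helper = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = _unit(np.cross(a, helper))
        return _axis_rotation(axis, math.pi)
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    axis = axis / s
    angle = math.atan2(s, c)
    return _axis_rotation(axis, angle)


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def torsion_candidates(template: ResidueTemplate, ca_pos: np.ndarray,
                       com_pos: np.ndarray, k: int) -> list[np.ndarray]:
    """The K rigid placements of the sidechain atoms that pin the COM to
    ``com_pos`` and align the template CA->COM axis with ``ca_pos->com_pos``,
    differing only by torsion about that axis."""
    ca_pos = np.asarray(ca_pos, dtype=float)
    com_pos = np.asarray(com_pos, dtype=float)
    axis = com_pos - ca_pos
    if np.linalg.norm(axis) < 1e-10:
        raise BackmapError("zero-length CA->COM vector")
    com_t = template.sidechain_com()
    ca_t = template.coords[template.index(template.ca_atom)]
    r0 = _align_rotation(com_t - ca_t, axis)
    axis_u = _unit(axis)
    sc = template.coords[template.sidechain_indices()]
    local = sc - com_t
    out = []
    for i in range(k):
        rot = _axis_rotation(axis_u, 2.0 * math.pi * i / k) @ r0
        out.append(com_pos + local @ rot.T)
    return out


def reconstruct_sidechain(template: ResidueTemplate, ca_pos: np.ndarray,
                          com_pos: np.ndarray,
                          placed_coords: np.ndarray | None = None,
                          placed_elements: list[str] | None = None,
                          geo: GeometryConfig | None = None) -> np.ndarray:
    """Rigidly place the template sidechain; returns coords for
    ``template.sidechain_atoms`` in order.

    Among K sampled torsions about the CA->COM axis the placement with the
    fewest clashes against ``placed_coords`` is returned (ties broken by the
    lowest torsion index).
    """
    if geo is None:
        geo = GeometryConfig()
    candidates = torsion_candidates(template, ca_pos, com_pos,
                                    geo.torsion_samples)
    if placed_coords is None or len(placed_coords) == 0:
        return candidates[0]
    placed_coords = np.asarray(placed_coords, dtype=float)
    sc_elements = [template.elements[i] for i in template.sidechain_indices()]
    cut = np.array([
        [geo.clash_fraction * (VDW_RADII[a] + VDW_RADII[b])
         for b in placed_elements] for a in sc_elements])
    best_idx, best_clashes = 0, None
    for i, cand in enumerate(candidates):
        d = np.linalg.norm(cand[:, None, :] - placed_coords[None, :, :], axis=2)
        n_clash = int(np.sum(d < cut))
        if best_clashes is None or n_clash < best_clashes:
            best_idx, best_clashes = i, n_clash
    return candidates[best_idx]


# -- full backmapping ---------------------------------------------------------


def _nterm_hydrogens(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                     geo: GeometryConfig) -> list[np.ndarray]:
    """Three ammonium hydrogens, tetrahedral about the CA->N axis."""
    u = _unit(n - ca)
    ref = c - ca
    perp = ref - np.dot(ref, u) * u
    p = _unit(perp)
    q = np.cross(u, p)
    theta = math.radians(geo.n_h3_angle)
    out = []
    for k in range(3):
        tor = math.radians(geo.n_h3_reference_torsion + 120.0 * k)
        direction = (math.cos(theta) * u
                     + math.sin(theta) * (math.cos(tor) * p + math.sin(tor) * q))
        out.append(n + geo.n_h3_length * direction)
    return out


def _cterm_oxygens(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                   geo: GeometryConfig) -> tuple[np.ndarray, np.ndarray]:
    """Carboxylate O/OXT, symmetric about the CA->C axis in the N-CA-C plane."""
    w = _unit(c - ca)
    normal = np.cross(ca - n, w)
    if np.linalg.norm(normal) < 1e-10:
        raise BackmapError("collinear backbone triplet at the C-terminus")
    p = _unit(np.cross(_unit(normal), w))
    theta = math.radians(geo.oxt_angle)
    a = -math.cos(theta)
    b = math.sin(theta)
    o = c + geo.c_oxt_length * (a * w + b * p)
    oxt = c + geo.c_oxt_length * (a * w - b * p)
    return o, oxt


def backmap(system: CGSystem,
            templates: dict[str, ResidueTemplate] | None = None,
            geo: GeometryConfig | None = None,
            provenance: str = "") -> AtomisticStructure:
    """Reconstruct an all-atom structure (charged termini) from a CG system."""
    if templates is None:
        templates = DEFAULT_TEMPLATES
    if geo is None:
        geo = GeometryConfig()
    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int]] = []
    placed_coords: list[np.ndarray] = []
    placed_elements: list[str] = []

    def add_atom(name, element, res_idx, res_name, chain_id, pos) -> int:
        atoms.append(AtomRecord(name, element, res_idx, res_name, chain_id, pos))
        placed_coords.append(np.asarray(pos, dtype=float))
        placed_elements.append(element)
        return len(atoms) - 1

    for ci, (chain_id, seq) in enumerate(zip(system.chain_ids, system.sequences)):
        for aa in seq:
            if aa not in templates:
                raise BackmapError(f"no residue template for type {aa!r}")
        unwrapped = unwrap_chain(system, ci)

        def bead(res, kind):
            return unwrapped[res * BEADS_PER_RESIDUE + KIND_INDEX[kind]]

        n_res = len(seq)
        n_pos = [bead(r, "NH") for r in range(n_res)]
        ca_pos = [bead(r, "CA") for r in range(n_res)]
        c_pos = [bead(r, "CO") for r in range(n_res)]
        sc_pos = [bead(r, "SC") for r in range(n_res)]
        if n_res >= 2:
            oxygens, hydrogens = complete_backbone(n_pos, ca_pos, c_pos, geo)
        else:
            oxygens, hydrogens = [], []

        prev_c_index: int | None = None
        for r in range(n_res):
            template = templates[seq[r]]
            res_name = template.name
            index_of: dict[str, int] = {}
            index_of["N"] = add_atom("N", "N", r, res_name, chain_id, n_pos[r])
            if r == 0:
                for k, h in enumerate(_nterm_hydrogens(n_pos[r], ca_pos[r],
                                                       c_pos[r], geo)):
                    index_of[f"H{k + 1}"] = add_atom(
                        f"H{k + 1}", "H", r, res_name, chain_id, h)
            else:
                index_of["H"] = add_atom("H", "H", r, res_name, chain_id,
                                         hydrogens[r - 1])
            index_of["CA"] = add_atom("CA", "C", r, res_name, chain_id, ca_pos[r])
            sc_coords = reconstruct_sidechain(
                template, ca_pos[r], sc_pos[r],
                np.asarray(placed_coords), placed_elements, geo)
            sc_names = template.sidechain_atoms
            sc_elements = [template.elements[i]
                           for i in template.sidechain_indices()]
            # HA from the tetrahedral complement of N, C and CB around CA.
            cb = sc_coords[sc_names.index(template.first_sidechain_atom)]
            ha_dir = -( _unit(n_pos[r] - ca_pos[r])
                        + _unit(c_pos[r] - ca_pos[r])
                        + _unit(cb - ca_pos[r]))
            ha = ca_pos[r] + geo.ca_ha_length * _unit(ha_dir)
            index_of["HA"] = add_atom("HA", "H", r, res_name, chain_id, ha)
            for name, element, pos in zip(sc_names, sc_elements, sc_coords):
                index_of[name] = add_atom(name, element, r, res_name,
                                          chain_id, pos)
            index_of["C"] = add_atom("C", "C", r, res_name, chain_id, c_pos[r])
            if r < n_res - 1:
                index_of["O"] = add_atom("O", "O", r, res_name, chain_id,
                                         oxygens[r])
            else:
                o, oxt = _cterm_oxygens(n_pos[r], ca_pos[r], c_pos[r], geo)
                index_of["O"] = add_atom("O", "O", r, res_name, chain_id, o)
                index_of["OXT"] = add_atom("OXT", "O", r, res_name, chain_id, oxt)

            # Covalent bonds for the clash-exclusion graph.
            if r == 0:
                for k in range(3):
                    bonds.append((index_of["N"], index_of[f"H{k + 1}"]))
            else:
                bonds.append((index_of["N"], index_of["H"]))
                assert prev_c_index is not None
                bonds.append((prev_c_index, index_of["N"]))
            bonds.append((index_of["N"], index_of["CA"]))
            bonds.append((index_of["CA"], index_of["HA"]))
            bonds.append((index_of["CA"], index_of["C"]))
            bonds.append((index_of["C"], index_of["O"]))
            if "OXT" in index_of:
                bonds.append((index_of["C"], index_of["OXT"]))
            for a, b in template.bonds:
                bonds.append((index_of[a], index_of[b]))
            prev_c_index = index_of["C"]

    structure = AtomisticStructure(atoms, list(system.sequences),
                                   list(system.chain_ids), True, provenance,
                                   bonds)
    expected = expected_atom_count(list(system.sequences), templates, True)
    if structure.n_atoms != expected:
        raise BackmapError(
            f"internal error: built {structure.n_atoms} atoms, expected {expected}")
    return structure


def project_to_cg(structure: AtomisticStructure,
                  templates: dict[str, ResidueTemplate] | None = None,
                  ) -> dict[str, dict[str, np.ndarray]]:
    """Project an atomistic structure back to CG beads.

    Returns per-chain arrays for keys "NH", "CA", "CO" (backbone atom
    positions) and "SC" (mass-weighted sidechain COM per residue).
    """
    if templates is None:
        templates = DEFAULT_TEMPLATES
    per_chain: dict[str, dict[int, dict[str, list]]] = {}
    for i, atom in enumerate(structure.atoms):
        res = per_chain.setdefault(atom.chain_id, {}).setdefault(
            atom.residue_index, {"sc_pos": [], "sc_mass": []})
        if atom.name == "N":
            res["N"] = atom.position
        elif atom.name == "CA":
            res["CA"] = atom.position
        elif atom.name == "C":
            res["C"] = atom.position
    # Sidechain members per residue name.
    sc_members = {t.name: set(t.sidechain_atoms) for t in templates.values()}
    for atom in structure.atoms:
        members = sc_members.get(atom.residue_name, set())
        if atom.name in members:
            res = per_chain[atom.chain_id][atom.residue_index]
            res["sc_pos"].append(atom.position)
            res["sc_mass"].append(ATOM_MASSES[atom.element])
    out: dict[str, dict[str, np.ndarray]] = {}
    for chain_id, residues in per_chain.items():
        order = sorted(residues)
        nh = np.array([residues[r]["N"] for r in order])
        ca = np.array([residues[r]["CA"] for r in order])
        co = np.array([residues[r]["C"] for r in order])
        sc = []
        for r in order:
            pos = np.asarray(residues[r]["sc_pos"])
            mass = np.asarray(residues[r]["sc_mass"])
            sc.append((pos * mass[:, None]).sum(axis=0) / mass.sum())
        out[chain_id] = {"NH": nh, "CA": ca, "CO": co, "SC": np.array(sc)}
    return out


# -- clash detection ----------------------------------------------------------


@dataclass(frozen=True)
class ClashRecord:
    atom_i: int
    atom_j: int
    distance: float
    cutoff: float


@dataclass
class ClashReport:
    clashes: list[ClashRecord]

    def __post_init__(self) -> None:
        for c in self.clashes:
            if not c.distance < c.cutoff:
                raise ValueError("clash report entries must have distance < cutoff")

    def __len__(self) -> int:
        return len(self.clashes)


def _excluded_pairs(structure: AtomisticStructure) -> set[tuple[int, int]]:
    """Atom pairs within two covalent bonds (1-2 and 1-3)."""
    adjacency: dict[int, set[int]] = {}
    for a, b in structure.bonds:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    excluded: set[tuple[int, int]] = set()
    for a, nbrs in adjacency.items():
        for b in nbrs:
            excluded.add((min(a, b), max(a, b)))
            for c in adjacency.get(b, ()):  # 1-3
                if c != a:
                    excluded.add((min(a, c), max(a, c)))
    return excluded


def detect_clashes(structure: AtomisticStructure,
                   cutoff_rule=None,
                   geo: GeometryConfig | None = None) -> ClashReport:
    """All non-bonded atom pairs closer than their cutoff.

    ``cutoff_rule(element_i, element_j)`` overrides the default fraction-of-
    van-der-Waals rule.  Pairs within two covalent bonds are skipped.
    """
    if geo is None:
        geo = GeometryConfig()
    if cutoff_rule is None:
        frac = geo.clash_fraction

        def cutoff_rule(a, b, _frac=frac):
            return _frac * (VDW_RADII[a] + VDW_RADII[b])

    coords = structure.coords
    elements = structure.elements
    max_cut = max((cutoff_rule(a, b)
                   for a in set(elements) for b in set(elements)), default=0.0)
    excluded = _excluded_pairs(structure)
    records: list[ClashRecord] = []
    if max_cut > 0 and len(coords) > 1:
        from scipy.spatial import cKDTree

        tree = cKDTree(coords)
        for i, j in sorted(tree.query_pairs(max_cut)):
            if (i, j) in excluded:
                continue
            cut = cutoff_rule(elements[i], elements[j])
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d < cut:
                records.append(ClashRecord(i, j, d, cut))
    return ClashReport(records)


def write_clash_report(report: ClashReport, structure: AtomisticStructure,
                       path) -> None:
    with open(path, "w") as fh:
        fh.write("atom_i\tatom_j\tname_i\tname_j\tdistance_A\tcutoff_A\n")
        for c in report.clashes:
            ai = structure.atoms[c.atom_i]
            aj = structure.atoms[c.atom_j]
            fh.write(f"{c.atom_i}\t{c.atom_j}\t"
                     f"{ai.chain_id}/{ai.residue_index}/{ai.name}\t"
                     f"{aj.chain_id}/{aj.residue_index}/{aj.name}\t"
                     f"{c.distance:.4f}\t{c.cutoff:.4f}\n")


# -- file output --------------------------------------------------------------


def _to_biotite(structure: AtomisticStructure) -> struc.AtomArray:
    n = structure.n_atoms
    array = struc.AtomArray(n)
    array.coord = structure.coords
    array.chain_id = np.array([a.chain_id for a in structure.atoms])
    array.res_id = np.array([a.residue_index + 1 for a in structure.atoms])
    array.res_name = np.array([a.residue_name for a in structure.atoms])
    array.atom_name = np.array([a.name for a in structure.atoms])
    array.element = np.array([a.element for a in structure.atoms])
    array.hetero = np.zeros(n, dtype=bool)
    return array


def write_structure(structure: AtomisticStructure, path, format: str = "pdb",
                    ) -> None:
    """Write PDB v3.3 or GRO (coordinates in nm) via biotite."""
    array = _to_biotite(structure)
    fmt = format.lower()
    if fmt == "pdb":
        pdb = PDBFile()
        pdb.set_structure(array)
        pdb.write(str(path))
    elif fmt == "gro":
        gro = GROFile()
        gro.set_structure(array)
        gro.write(str(path))
    else:
        raise ValueError(f"unsupported structure format {format!r}")


def read_structure(path, format: str | None = None) -> struc.AtomArray:
    """Read a written structure back (for round-trip checks)."""
    path = str(path)
    fmt = format or ("gro" if path.endswith(".gro") else "pdb")
    if fmt == "pdb":
        return PDBFile.read(path).get_structure(model=1)
    if fmt == "gro":
        return GROFile.read(path).get_structure(model=1)
    raise ValueError(f"unsupported structure format {format!r}")
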