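"""Structural comparison of ligand/receptor co-crystal complexes.

Groups of receptor structures solved with the same bound ligand are
compared by (i) rigid-body superposition on the backbone of the shared
binding-pocket residues, (ii) heavy-atom RMSD of the bound ligands
without further fitting — capturing both relative orientation and
position inside the pocket, (iii) heavy-atom RMSD of matched pocket
residues, (iv) seven-class protein–ligand interaction fingerprints, and
(v) model-quality flags from per-residue real-space correlation (RSCC)
and B-factor tables.

The binding pocket is the union, over all compared complexes, of
residues with any heavy atom within 5 Å of any ligand heavy atom; the
docking box uses a tighter 4 Å shell.  Ligand RMSD minimizes over the
element-labeled graph automorphisms of the ligand so topologically
equivalent atoms (e.g. the two oxygens of a carboxylate) never inflate
the deviation.
"""

from __future__ import annotations

import io
import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

__all__ = [
    "Atom",
    "Residue",
    "Ligand",
    "ComplexStructure",
    "PocketDefinition",
    "IfpMatrix",
    "QualityReport",
    "IfpCutoffs",
    "StructureError",
    "load_complex",
    "define_pocket",
    "docking_box_residues",
    "superpose_group",
    "kabsch",
    "ligand_rmsd",
    "pocket_rmsd",
    "compute_ifp",
    "ifp_heatmap",
    "quality_report",
    "find_disulfides",
    "INTERACTION_TYPES",
]

WATER_NAMES = {"HOH", "WAT", "DOD"}
BACKBONE_ATOMS = ("N", "CA", "C", "O")

INTERACTION_TYPES = (
    "hydrophobic",
    "hbond_donor",
    "hbond_acceptor",
    "weak_hbond_donor",
    "weak_hbond_acceptor",
    "ionic",
    "aromatic",
)

#: Fig-style color legend for IFP heatmaps.
INTERACTION_COLORS = {
    "hydrophobic": "#3b6fb6",  # blue
    "hbond_donor": "#c0392b",  # red
    "hbond_acceptor": "#c0392b",
    "weak_hbond_donor": "#e67e22",  # orange
    "weak_hbond_acceptor": "#e67e22",
    "ionic": "#8e44ad",  # purple
    "aromatic": "#27ae60",  # green
}

DAMAGE_PRONE_ALWAYS = {"ASP", "GLU", "MET", "TYR"}

COVALENT_RADII = {
    "C": 0.77, "N": 0.75, "O": 0.73, "S": 1.02, "P": 1.06,
    "F": 0.71, "CL": 0.99, "BR": 1.14, "I": 1.33, "B": 0.82,
}
BOND_TOLERANCE = 0.45  # Å added to the radius sum when inferring bonds


class StructureError(ValueError):
    """Raised for unusable structural input."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) in Å

    def __post_init__(self):
        self.coord = np.asarray(self.coord, float)
        if not np.isfinite(self.coord).all():
            raise StructureError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    chain: str
    resnum: int
    icode: str
    resname: str
    atoms: list[Atom]

    @property
    def key(self) -> tuple[int, str]:
        """Residue identity used to match residues across complexes."""
        return (self.resnum, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])


@dataclass
class Ligand:
    code: str  # 3-letter chemical component code
    atoms: list[Atom]
    bonds: list[tuple[int, int]]  # indices into atoms

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for i, a in enumerate(self.atoms):
            g.add_node(i, element=a.element)
        g.add_edges_from(self.bonds)
        return g


@dataclass
class ComplexStructure:
    complex_id: str
    residues: list[Residue]
    ligand: Ligand

    def residue_by_key(self, key: tuple[int, str]) -> Residue | None:
        for r in self.residues:
            if r.key == key:
                return r
        return None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ComplexStructure":
        """Apply a rigid motion x -> R x + t to every atom (ligand included)."""

        def move(atom: Atom) -> Atom:
            return Atom(atom.name, atom.element, rotation @ atom.coord + translation)

        residues = [replace(r, atoms=[move(a) for a in r.atoms]) for r in self.residues]
        ligand = replace(self.ligand, atoms=[move(a) for a in self.ligand.atoms])
        return ComplexStructure(self.complex_id, residues, ligand)


@dataclass
class PocketDefinition:
    radius: float
    residues: set[tuple[int, str]]  # (resnum, icode)
    scope: str  # "single_complex" | "group_union"


@dataclass
class IfpCutoffs:
    """Geometric rules defining each interaction class (Å / degrees)."""

    hydrophobic: float = 4.5  # apolar C/S pair
    hbond: float = 3.5  # donor–acceptor heavy-atom distance
    hbond_angle: float = 90.0  # antecedent–donor–acceptor minimum angle
    weak_hbond: float = 3.8  # C–H donor to acceptor
    ionic: float = 4.0  # opposite formal charges
    aromatic: float = 5.0  # ring-centroid distance

    @property
    def max_shell(self) -> float:
        return max(self.hydrophobic, self.hbond, self.weak_hbond, self.ionic, self.aromatic)


@dataclass
class IfpMatrix:
    complex_id: str
    bits: pd.DataFrame  # index "RES123", columns INTERACTION_TYPES, bool
    residue_info: pd.DataFrame  # resnum, icode, resname, segment label


@dataclass
class QualityReport:
    table: pd.DataFrame  # resnum, resname, rscc, bfactor, flags
    pocket_median_b: float


# ---------------------------------------------------------------------------
# loading


def _infer_bonds(atoms: Sequence[Atom]) -> list[tuple[int, int]]:
    """Bond perception from covalent radii (heavy atoms only)."""
    bonds = []
    for i, j in itertools.combinations(range(len(atoms)), 2):
        cutoff = (
            COVALENT_RADII.get(atoms[i].element, 0.77)
            + COVALENT_RADII.get(atoms[j].element, 0.77)
            + BOND_TOLERANCE
        )
        if np.linalg.norm(atoms[i].coord - atoms[j].coord) <= cutoff:
            bonds.append((i, j))
    return bonds


def load_complex(
    pdb_source: str | Path | io.IOBase,
    ligand_code: str,
    chain_selection: Sequence[str] | None = None,
    complex_id: str | None = None,
    ligand_bonds: Sequence[tuple[int, int]] | None = None,
) -> ComplexStructure:
    """Read one receptor/ligand complex from a PDB file.

    Keeps heavy atoms of amino-acid residues in the selected chain(s)
    (all chains when ``chain_selection`` is None) plus the named ligand;
    waters and every other heteroatom entity are stripped.  Author
    residue numbering and insertion codes are preserved.  Alternate
    locations resolve to the highest-occupancy conformer (Biopython's
    default altloc policy).  Ligand bonds are taken from ``ligand_bonds``
    when supplied, else inferred from covalent radii.
    """
    parser = PDBParser(QUIET=True)
    if isinstance(pdb_source, io.IOBase):
        handle = pdb_source
    else:
        text = str(pdb_source)
        if "\n" in text:
            handle = io.StringIO(text)
        else:
            path = Path(text)
            if not path.exists():
                raise StructureError(f"cannot read PDB source {pdb_source!r}")
            handle = open(path)
    structure = parser.get_structure("complex", handle)
    model = next(iter(structure))

    wanted = set(chain_selection) if chain_selection else None
    residues: list[Residue] = []
    ligand: Ligand | None = None
    chains_seen = set()
    for chain in model:
        chains_seen.add(chain.id)
        if wanted is not None and chain.id not in wanted:
            continue
        for res in chain:
            hetflag, resnum, icode = res.id
            resname = res.get_resname().strip()
            if resname in WATER_NAMES:
                continue
            atoms = [
                Atom(a.get_name(), (a.element or "C").upper(), a.get_coord())
                for a in res.get_atoms()
                if (a.element or "").upper() != "H"
            ]
            if not atoms:
                continue
            if hetflag.strip() == "":
                residues.append(Residue(chain.id, resnum, icode.strip(), resname, atoms))
            elif resname == ligand_code and ligand is None:
                bonds = list(ligand_bonds) if ligand_bonds is not None else _infer_bonds(atoms)
                ligand = Ligand(ligand_code, atoms, bonds)

    if wanted is not None and not wanted & chains_seen:
        raise StructureError(f"chain(s) {sorted(wanted)} absent; file has {sorted(chains_seen)}")
    if ligand is None:
        raise StructureError(f"ligand {ligand_code!r} not found in selected chains")
    if not residues:
        raise StructureError("no amino-acid residues in selection")
    if not nx.is_connected(ligand.graph()):
        warnings.warn(f"ligand {ligand_code} atom graph is not connected", stacklevel=2)
    cid = complex_id or f"{getattr(pdb_source, 'name', 'complex')}:{ligand_code}"
    return ComplexStructure(cid, residues, ligand)


# ---------------------------------------------------------------------------
# pocket definition and superposition


def _pocket_keys_single(complex_: ComplexStructure, radius: float) -> set[tuple[int, str]]:
    lig = complex_.ligand.coords()
    keys = set()
    for res in complex_.residues:
        d = np.linalg.norm(res.coords()[:, None, :] - lig[None, :, :], axis=2)
        if d.min() <= radius:
            keys.add(res.key)
    return keys


def define_pocket(
    complexes: ComplexStructure | Sequence[ComplexStructure], radius: float = 5.0
) -> PocketDefinition:
    """Residues with any heavy atom within ``radius`` Å of the ligand.

    For a group, the pocket is the union over complexes (residues matched
    across complexes by author residue number + insertion code), so a
    residue contacting the ligand in any one member belongs to the shared
    pocket.
    """
    if isinstance(complexes, ComplexStructure):
        complexes = [complexes]
    if not complexes:
        raise StructureError("no complexes given")
    if radius <= 0:
        raise StructureError("radius must be positive")
    keys: set[tuple[int, str]] = set()
    for c in complexes:
        keys |= _pocket_keys_single(c, radius)
    if not keys:
        raise StructureError(
            f"empty pocket at {radius} Å — check ligand code and chain selection"
        )
    scope = "single_complex" if len(complexes) == 1 else "group_union"
    return PocketDefinition(radius=radius, residues=keys, scope=scope)


def docking_box_residues(complex_: ComplexStructure, radius: float = 4.0) -> PocketDefinition:
    """Docking-box residue selection: the 4 Å shell around the crystal ligand."""
    return define_pocket(complex_, radius=radius)


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition: returns (R, t) with R@x+t ≈ ref."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if len(mobile) < 3:
        raise StructureError("need at least 3 matched atoms for superposition")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    return rot, trans


def superpose_group(
    complexes: Sequence[ComplexStructure],
    reference: int = 0,
    pocket_radius: float = 5.0,
) -> tuple[list[ComplexStructure], list[float]]:
    """Rigid-body superposition of each complex onto the reference.

    The fit uses backbone heavy atoms (N, CA, C, O) of the group
    pocket-union residues shared (by residue number) between each complex
    and the reference; the resulting transform is applied to all atoms
    including the ligand.  Returns the transformed complexes (reference
    returned unchanged) and per-complex backbone fit RMSDs.
    """
    if not complexes:
        raise StructureError("no complexes given")
    pocket = define_pocket(complexes, radius=pocket_radius)
    ref = complexes[reference]
    out: list[ComplexStructure] = []
    fit_rmsds: list[float] = []
    for idx, mob in enumerate(complexes):
        if idx == reference:
            out.append(mob)
            fit_rmsds.append(0.0)
            continue
        mob_pts, ref_pts = [], []
        for key in sorted(pocket.residues):
            r_ref, r_mob = ref.residue_by_key(key), mob.residue_by_key(key)
            if r_ref is None or r_mob is None:
                continue
            for name in BACKBONE_ATOMS:
                a_ref, a_mob = r_ref.atom(name), r_mob.atom(name)
                if a_ref is not None and a_mob is not None:
                    ref_pts.append(a_ref.coord)
                    mob_pts.append(a_mob.coord)
        rot, trans = kabsch(np.array(mob_pts), np.array(ref_pts))
        moved = mob.transformed(rot, trans)
        fitted = np.array(mob_pts) @ rot.T + trans
        fit_rmsds.append(float(np.sqrt(((fitted - np.array(ref_pts)) ** 2).sum(axis=1).mean())))
        out.append(moved)
    return out, fit_rmsds


# ---------------------------------------------------------------------------
# RMSD


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


MAX_AUTOMORPHISMS = 10_000


def ligand_rmsd(
    complex_a: ComplexStructure,
    complex_b: ComplexStructure,
    symmetry: bool = True,
) -> float:
    """Heavy-atom RMSD between the two bound ligands, no refitting.

    Computed in the frame established by the group superposition, so the
    value reflects both the ligands' internal conformation and their
    placement in the pocket.  The atom correspondence is the
    element-labeled graph isomorphism minimizing the RMSD (exhaustive up
    to ``MAX_AUTOMORPHISMS`` mappings); with ``symmetry=False`` atoms are
    matched by name instead.
    """
    la, lb = complex_a.ligand, complex_b.ligand
    ca, cb = la.coords(), lb.coords()
    if not symmetry:
        return _name_matched_rmsd(la, lb)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        la.graph(), lb.graph(), node_match=lambda x, y: x["element"] == y["element"]
    )
    best = None
    for count, mapping in enumerate(matcher.isomorphisms_iter()):
        if count >= MAX_AUTOMORPHISMS:
            warnings.warn(
                "too many ligand automorphisms; falling back to name matching", stacklevel=2
            )
            return _name_matched_rmsd(la, lb)
        idx_a = np.fromiter(mapping.keys(), int)
        idx_b = np.fromiter(mapping.values(), int)
        r = _rmsd(ca[idx_a], cb[idx_b])
        best = r if best is None else min(best, r)
    if best is None:
        raise StructureError(
            f"ligand graphs of {complex_a.complex_id} and {complex_b.complex_id} "
            "are not isomorphic"
        )
    return best


def _name_matched_rmsd(la: Ligand, lb: Ligand) -> float:
    names_b = {a.name: a.coord for a in lb.atoms}
    pairs = [(a.coord, names_b[a.name]) for a in la.atoms if a.name in names_b]
    if not pairs:
        raise StructureError("no ligand atoms share names")
    pa, pb = map(np.array, zip(*pairs))
    return _rmsd(pa, pb)


def pocket_rmsd(
    complex_a: ComplexStructure,
    complex_b: ComplexStructure,
    pocket: PocketDefinition,
) -> float:
    """Heavy-atom RMSD over matched pocket residues, no refitting.

    Atoms are matched by residue number + atom name; atoms present in
    only one complex (e.g. unmodeled side-chains) are skipped, so
    truncated residues still contribute their shared atoms.
    """
    pa, pb = [], []
    for key in sorted(pocket.residues):
        ra, rb = complex_a.residue_by_key(key), complex_b.residue_by_key(key)
        if ra is None or rb is None:
            continue
        for atom in ra.atoms:
            other = rb.atom(atom.name)
            if other is not None:
                pa.append(atom.coord)
                pb.append(other.coord)
    if not pa:
        raise StructureError("no matched pocket atoms")
    return _rmsd(np.array(pa), np.array(pb))


# ---------------------------------------------------------------------------
# interaction fingerprints

# Side-chain functional atom sets per residue type.  Donors map atom ->
# antecedent heavy atom (for the angle test).  Backbone N/O handled
# separately for every residue.
RESIDUE_DONORS: dict[str, dict[str, str]] = {
    "SER": {"OG": "CB"}, "THR": {"OG1": "CB"}, "TYR": {"OH": "CZ"},
    "CYS": {"SG": "CB"},
    "ASN": {"ND2": "CG"}, "GLN": {"NE2": "CD"},
    "LYS": {"NZ": "CE"}, "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
    "TRP": {"NE1": "CD1"},
}
RESIDUE_ACCEPTORS: dict[str, list[str]] = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"],
    "ASN": ["OD1"], "GLN": ["OE1"],
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"],
    "HIS": ["ND1", "NE2"], "MET": ["SD"],
}
RESIDUE_CATIONIC: dict[str, list[str]] = {"LYS": ["NZ"], "ARG": ["NH1", "NH2", "NE"]}
RESIDUE_ANIONIC: dict[str, list[str]] = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}
RESIDUE_AROMATIC_RINGS: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TRP": [["CG", "CD1", "CD2", "NE1", "CE2"], ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
}
# Apolar side-chain carbons/sulfurs (no N/O neighbors).
RESIDUE_APOLAR: dict[str, list[str]] = {
    "ALA": ["CB"], "VAL": ["CB", "CG1", "CG2"], "LEU": ["CB", "CG", "CD1", "CD2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"], "PRO": ["CB", "CG"],
    "MET": ["CB", "CG", "SD", "CE"], "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2"], "LYS": ["CB", "CG", "CD"],
    "ARG": ["CB", "CG"], "GLU": ["CB", "CG"], "GLN": ["CB", "CG"],
    "ASP": ["CB"], "ASN": ["CB"], "THR": ["CG2"], "CYS": ["CB"], "HIS": ["CB"],
}


@dataclass
class _LigandTyping:
    donors: list[tuple[int, int]]  # (donor atom, antecedent atom)
    acceptors: list[int]
    cationic: list[int]
    anionic: list[int]
    apolar: list[int]
    weak_donors: list[tuple[int, int]]  # carbon C–H donors with an antecedent
    ring_centroids: list[np.ndarray]


def _ligand_rings(lig: Ligand, planarity_tol: float = 0.15) -> list[list[int]]:
    """5/6-membered planar rings of C/N/O/S, taken as aromatic."""
    g = lig.graph()
    rings = []
    for cycle in nx.cycle_basis(g):
        if len(cycle) not in (5, 6):
            continue
        if any(lig.atoms[i].element not in {"C", "N", "O", "S"} for i in cycle):
            continue
        pts = np.array([lig.atoms[i].coord for i in cycle])
        centered = pts - pts.mean(axis=0)
        # deviation from the best-fit plane = smallest singular value direction
        _, s, vt = np.linalg.svd(centered)
        dev = np.abs(centered @ vt[2])
        if dev.max() <= planarity_tol:
            rings.append(cycle)
    return rings


def _type_ligand(lig: Ligand) -> _LigandTyping:
    """Rule-based typing of a hydrogen-free ligand heavy-atom graph.

    pH-7 conventions: amine nitrogens (only carbon neighbors, ≤3 heavy
    neighbors, not in an aromatic ring) are cationic donors; carboxylate
    oxygens (terminal O on a carbon bearing two terminal oxygens) are
    anionic acceptors.  Any N/O that can still carry a hydrogen is a
    donor; any O, and any non-cationic N with ≤2 heavy neighbors, is an
    acceptor.  Carbons with no N/O neighbor are apolar; every carbon with
    an implied hydrogen is a weak (C–H) donor.
    """
    g = lig.graph()
    elems = [a.element for a in lig.atoms]
    nbrs = {i: sorted(g.neighbors(i)) for i in g.nodes}
    rings = _ligand_rings(lig)
    ring_atoms = {i for ring in rings for i in ring}

    cationic, anionic, donors, acceptors = [], [], [], []
    for i, el in enumerate(elems):
        nn = nbrs[i]
        if el == "N":
            if i not in ring_atoms and len(nn) <= 3 and all(elems[j] == "C" for j in nn):
                cationic.append(i)
            if len(nn) <= 2:
                acceptors.append(i)
            if len(nn) <= 3:
                donors.append((i, nn[0] if nn else i))
        elif el == "O":
            acceptors.append(i)
            if len(nn) <= 1:
                # terminal O: hydroxyl-like donor unless part of a carboxylate
                donors.append((i, nn[0] if nn else i))
    # carboxylates: carbon with exactly two terminal oxygens
    for i, el in enumerate(elems):
        if el != "C":
            continue
        term_o = [j for j in nbrs[i] if elems[j] == "O" and len(nbrs[j]) == 1]
        if len(term_o) == 2:
            anionic.extend(term_o)
            donors = [d for d in donors if d[0] not in term_o]
    apolar = [
        i
        for i, el in enumerate(elems)
        if (el == "S")
        or (el == "C" and all(elems[j] not in {"N", "O"} for j in nbrs[i]))
    ]
    weak_donors = [
        (i, nbrs[i][0])
        for i, el in enumerate(elems)
        if el == "C" and len(nbrs[i]) < 4 and nbrs[i]
    ]
    centroids = [np.mean([lig.atoms[i].coord for i in ring], axis=0) for ring in rings]
    return _LigandTyping(donors, acceptors, cationic, anionic, apolar, weak_donors, centroids)


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def _min_dist(res: Residue, lig: Ligand) -> float:
    d = np.linalg.norm(res.coords()[:, None, :] - lig.coords()[None, :, :], axis=2)
    return float(d.min())


def compute_ifp(
    complex_: ComplexStructure,
    pocket: PocketDefinition,
    cutoffs: IfpCutoffs | None = None,
    segment_labels: Mapping[tuple[int, str], str] | None = None,
) -> IfpMatrix:
    """Seven-class interaction fingerprint of one complex over a pocket.

    Columns (residue perspective): hydrophobic contact, hydrogen-bond
    donor / acceptor, weak (C–H) hydrogen-bond donor / acceptor, ionic,
    aromatic.  The geometric rules are distance (and, for H-bonds, an
    antecedent–donor–acceptor angle ≥ ``hbond_angle``) cutoffs — the
    fingerprint flags likely interactions rather than asserting their
    absolute presence, and every cutoff is configurable.  Residues with
    no heavy atom inside the largest cutoff get an all-false row.
    """
    cut = cutoffs or IfpCutoffs()
    lig = complex_.ligand
    lt = _type_ligand(lig)
    lcoords = lig.coords()

    rows = {}
    info = []
    for key in sorted(pocket.residues):
        res = complex_.residue_by_key(key)
        if res is None:
            continue
        label = f"{res.resname}{res.resnum}{res.icode}"
        info.append(
            {
                "residue": label,
                "resnum": res.resnum,
                "icode": res.icode,
                "resname": res.resname,
                "segment": (segment_labels or {}).get(key, ""),
            }
        )
        bits = dict.fromkeys(INTERACTION_TYPES, False)
        if _min_dist(res, lig) <= cut.max_shell:
            _fill_bits(res, lig, lcoords, lt, cut, bits)
        rows[label] = bits

    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(INTERACTION_TYPES))
    return IfpMatrix(complex_.complex_id, frame.astype(bool), pd.DataFrame(info))


def _fill_bits(res, lig, lcoords, lt, cut, bits) -> None:
    rn = res.resname

    def d(atom: Atom, j: int) -> float:
        return float(np.linalg.norm(atom.coord - lcoords[j]))

    # hydrophobic: apolar residue C/S near apolar ligand C/S
    for name in RESIDUE_APOLAR.get(rn, []):
        a = res.atom(name)
        if a and any(d(a, j) <= cut.hydrophobic for j in lt.apolar):
            bits["hydrophobic"] = True
            break

    # residue as H-bond donor (side-chain + backbone N)
    donor_map = dict(RESIDUE_DONORS.get(rn, {}))
    donor_map["N"] = "CA"
    for dn, ante in donor_map.items():
        a, b = res.atom(dn), res.atom(ante)
        if a is None or b is None:
            continue
        for j in lt.acceptors:
            if d(a, j) <= cut.hbond and _angle(b.coord, a.coord, lcoords[j]) >= cut.hbond_angle:
                bits["hbond_donor"] = True
                break
        if bits["hbond_donor"]:
            break

    # residue as H-bond acceptor (side-chain + backbone O), ligand donates
    acceptor_names = list(RESIDUE_ACCEPTORS.get(rn, [])) + ["O"]
    for an in acceptor_names:
        a = res.atom(an)
        if a is None:
            continue
        for dn, ante in lt.donors:
            if (
                d(a, dn) <= cut.hbond
                and _angle(lcoords[ante], lcoords[dn], a.coord) >= cut.hbond_angle
            ):
                bits["hbond_acceptor"] = True
                break
        if bits["hbond_acceptor"]:
            break

    # weak H-bonds: residue C–H to ligand acceptor / ligand C–H to residue acceptor
    for name in RESIDUE_APOLAR.get(rn, []) + ["CA"]:
        a = res.atom(name)
        if a and a.element == "C" and any(d(a, j) <= cut.weak_hbond for j in lt.acceptors):
            bits["weak_hbond_donor"] = True
            break
    for an in acceptor_names:
        a = res.atom(an)
        if a and any(d(a, dn) <= cut.weak_hbond for dn, _ in lt.weak_donors):
            bits["weak_hbond_acceptor"] = True
            break

    # ionic: opposite formal charges
    for names, partners in (
        (RESIDUE_ANIONIC.get(rn, []), lt.cationic),
        (RESIDUE_CATIONIC.get(rn, []), lt.anionic),
    ):
        for name in names:
            a = res.atom(name)
            if a and any(d(a, j) <= cut.ionic for j in partners):
                bits["ionic"] = True
                break
        if bits["ionic"]:
            break

    # aromatic: ring centroid distance
    for ring in RESIDUE_AROMATIC_RINGS.get(rn, []):
        atoms = [res.atom(n) for n in ring]
        if any(a is None for a in atoms):
            continue
        centroid = np.mean([a.coord for a in atoms], axis=0)
        if any(np.linalg.norm(centroid - c) <= cut.aromatic for c in lt.ring_centroids):
            bits["aromatic"] = True
            break


def ifp_heatmap(
    matrices: Sequence[IfpMatrix],
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Residue-aligned IFP grid for a group of complexes.

    All matrices must share the same residue row set (build them from the
    group pocket union).  Returns the long-format bit table; when
    ``path`` is given, also renders the color-coded heatmap (one row
    block per complex, interaction classes colored per the standard
    legend).
    """
    if not matrices:
        raise StructureError("empty group")
    rows0 = list(matrices[0].bits.index)
    for m in matrices[1:]:
        if list(m.bits.index) != rows0:
            raise StructureError("IFP row sets are not aligned across the group")

    long = pd.concat(
        [m.bits.assign(complex_id=m.complex_id).reset_index(names="residue") for m in matrices],
        ignore_index=True,
    )

    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        types = list(INTERACTION_TYPES)
        ncols = len(rows0) * len(types)
        grid = np.zeros((len(matrices), ncols), int)
        for mi, m in enumerate(matrices):
            for ri, res in enumerate(rows0):
                for ti, t in enumerate(types):
                    if m.bits.loc[res, t]:
                        grid[mi, ri * len(types) + ti] = ti + 1
        cmap = ListedColormap(["white"] + [INTERACTION_COLORS[t] for t in types])
        fig, ax = plt.subplots(figsize=(max(6, ncols * 0.12), 1 + 0.5 * len(matrices)))
        ax.imshow(grid, cmap=cmap, vmin=0, vmax=len(types), aspect="auto", interpolation="none")
        ax.set_yticks(range(len(matrices)), [m.complex_id for m in matrices])
        ax.set_xticks(
            [ri * len(types) + len(types) / 2 for ri in range(len(rows0))],
            rows0,
            rotation=90,
            fontsize=6,
        )
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return long


# ---------------------------------------------------------------------------
# model quality


def find_disulfides(complex_: ComplexStructure, cutoff: float = 2.5) -> set[tuple[int, str]]:
    """Residue keys of cysteines whose SG is within ``cutoff`` of another SG."""
    sgs = [
        (r.key, r.atom("SG").coord)
        for r in complex_.residues
        if r.resname == "CYS" and r.atom("SG") is not None
    ]
    out = set()
    for (ka, ca), (kb, cb) in itertools.combinations(sgs, 2):
        if np.linalg.norm(ca - cb) <= cutoff:
            out |= {ka, kb}
    return out


def quality_report(
    rscc_table: pd.DataFrame,
    pocket: PocketDefinition,
    disulfide_cys: Iterable[tuple[int, str]] = (),
    rscc_cutoff: float = 0.8,
    plot_path: str | Path | None = None,
) -> QualityReport:
    """Model-quality flags for pocket residues from RSCC / B-factor data.

    ``rscc_table`` columns: chain, resnum, resname, rscc, bfactor (an
    optional icode column defaults to "").  Flags per residue:

    - ``low_rscc``: RSCC < 0.8 — poor fit to electron density;
    - ``damage_prone``: ASP/GLU/MET/TYR, or CYS in ``disulfide_cys`` —
      residue types whose density degrades under radiation damage, so a
      low RSCC there is not evidence against the model and conclusions
      should not rest on it;
    - ``low_rscc_high_b``: low RSCC together with a B-factor above the
      pocket median — corroborated poor fit;
    - ``missing_data``: pocket residue absent from the table.
    """
    t = rscc_table.copy()
    if "icode" not in t.columns:
        t["icode"] = ""
    t["icode"] = t["icode"].fillna("").astype(str)
    by_key = {
        (int(row.resnum), row.icode): row for row in t.itertuples(index=False)
    }

    disulfides = set(disulfide_cys)
    present = [k for k in sorted(pocket.residues) if k in by_key]
    median_b = float(np.median([by_key[k].bfactor for k in present])) if present else float("nan")

    rows = []
    for key in sorted(pocket.residues):
        if key not in by_key:
            rows.append(
                {
                    "resnum": key[0], "icode": key[1], "resname": "",
                    "rscc": np.nan, "bfactor": np.nan,
                    "low_rscc": False, "damage_prone": False,
                    "low_rscc_high_b": False, "missing_data": True,
                }
            )
            continue
        row = by_key[key]
        resname = str(row.resname)
        rscc, bfac = float(row.rscc), float(row.bfactor)
        low = rscc < rscc_cutoff
        damage = resname in DAMAGE_PRONE_ALWAYS or (resname == "CYS" and key in disulfides)
        rows.append(
            {
                "resnum": key[0], "icode": key[1], "resname": resname,
                "rscc": rscc, "bfactor": bfac,
                "low_rscc": low, "damage_prone": damage,
                "low_rscc_high_b": low and bfac > median_b,
                "missing_data": False,
            }
        )
    table = pd.DataFrame(rows)

    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ok = table[~table["missing_data"]]
        fig, ax1 = plt.subplots(figsize=(8, 3))
        x = np.arange(len(ok))
        ax1.plot(x, ok["rscc"], color="green", marker="o", ms=3, label="RSCC")
        ax1.axhline(rscc_cutoff, ls=":", color="black")
        ax1.set_ylabel("RSCC", color="green")
        ax1.set_ylim(0, 1.05)
        ax2 = ax1.twinx()
        ax2.plot(x, ok["bfactor"], color="red", marker="s", ms=3, label="B-factor")
        ax2.set_ylabel("B-factor", color="red")
        ax1.set_xticks(x, [f"{r.resname}{r.resnum}" for r in ok.itertuples()], rotation=90, fontsize=6)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return QualityReport(table=table, pocket_median_b=median_b)
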