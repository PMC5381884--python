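"""Synthetic inputs with the statistical and structural properties the
analysis pipeline assumes.

Three generators stand in for data this package deliberately does not
produce itself:

* :func:`simulate_scores` — docking-score tables emulating the output of
  a stochastic docking engine: per-ligand score repeated over independent
  runs, actives shifted toward better (lower) scores by a tunable effect
  size, and the screening-library convention of 39 property-matched
  decoys per known ligand.
* :func:`simulate_library` — an SDF ligand library built from distinct
  scaffold families (to exercise chemotype clustering), with a tunable
  fraction of stereocenter-bearing molecules and injected
  enantiomer-double pairs (to exercise racemic deduplication).
* :func:`build_toy_complex` — miniature receptor/ligand complexes with
  each intended interaction realized at an exact target distance,
  serializable to valid PDB.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .struct_compare import Atom, ComplexStructure, Ligand, Residue, StructureError

__all__ = [
    "ScoreSimConfig",
    "LibrarySimConfig",
    "ResiduePlacement",
    "ToyComplexSpec",
    "simulate_scores",
    "simulate_pockets",
    "simulate_library",
    "build_toy_complex",
    "default_ligand",
    "complex_to_pdb",
    "RESIDUE_TEMPLATES",
]


# ---------------------------------------------------------------------------
# docking-score tables


@dataclass
class ScoreSimConfig:
    """Gaussian score model for a retrospective screen.

    Decoy scores are N(base_score, score_sd²); actives are shifted by
    ``effect_size`` toward better scores plus a per-chemotype extra
    shift; each docking repeat adds N(0, repeat_noise_sd²).  Lower is
    better throughout (energy-like scores).  The default 39 decoys per
    active follows the property-matched decoy-set convention of GPCR
    benchmark libraries.
    """

    n_actives: int = 50
    decoys_per_active: int = 39
    n_repeats: int = 3
    effect_size: float = 2.0
    score_sd: float = 1.0
    repeat_noise_sd: float = 0.3
    base_score: float = -20.0
    agonist_fraction: float = 0.5
    chemotype_profile: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "A": (0.4, 0.0),
            "B": (0.3, 0.0),
            "C": (0.2, 0.0),
            "D": (0.1, 0.0),
        }
    )
    seed: int = 0

    @property
    def n_decoys(self) -> int:
        return self.n_actives * self.decoys_per_active

    def validate(self) -> None:
        if self.n_actives <= 0 or self.decoys_per_active <= 0 or self.n_repeats <= 0:
            raise ValueError("counts must be positive")
        total = sum(f for f, _ in self.chemotype_profile.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"chemotype fractions sum to {total}, expected 1")


def _chemotype_assignment(config: ScoreSimConfig) -> list[str]:
    """Deterministic largest-remainder apportionment of actives to chemotypes."""
    items = list(config.chemotype_profile.items())
    raw = [f * config.n_actives for _, (f, _) in items]
    counts = [int(x) for x in raw]
    short = config.n_actives - sum(counts)
    remainders = sorted(range(len(items)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in remainders[:short]:
        counts[i] += 1
    out: list[str] = []
    for (name, _), c in zip(items, counts):
        out.extend([name] * c)
    return out


def simulate_scores(
    config: ScoreSimConfig,
    pocket_id: str = "pocket1",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one pocket's score table (long format, lower-is-better).

    Columns: ligand_id, pocket_id, repeat, score, class_label,
    pharmacology, chemotype.  Reproducible given ``config.seed`` (or an
    externally supplied generator).
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    chemotypes = _chemotype_assignment(config)
    shifts = {name: s for name, (_, s) in config.chemotype_profile.items()}

    rows = []
    n_agonists = round(config.agonist_fraction * config.n_actives)
    for i in range(config.n_actives):
        chem = chemotypes[i]
        mean = config.base_score - config.effect_size - shifts[chem]
        base = rng.normal(mean, config.score_sd)
        pharm = "agonist" if i < n_agonists else "inhibitor"
        for rep in range(1, config.n_repeats + 1):
            rows.append(
                (f"act{i:04d}", pocket_id, rep, base + rng.normal(0, config.repeat_noise_sd),
                 "active", pharm, chem)
            )
    for i in range(config.n_decoys):
        base = rng.normal(config.base_score, config.score_sd)
        for rep in range(1, config.n_repeats + 1):
            rows.append(
                (f"dec{i:05d}", pocket_id, rep, base + rng.normal(0, config.repeat_noise_sd),
                 "decoy", "unknown", "other")
            )
    return pd.DataFrame(
        rows,
        columns=["ligand_id", "pocket_id", "repeat", "score", "class_label",
                 "pharmacology", "chemotype"],
    )


def simulate_pockets(
    effect_sizes: Mapping[str, float],
    config: ScoreSimConfig | None = None,
) -> pd.DataFrame:
    """Simulate several pockets screening the same library.

    ``effect_sizes`` maps pocket_id → active/decoy mean-score separation;
    all other parameters come from ``config``.  Each pocket draws its own
    scores (independent dockings of a shared library).
    """
    config = config or ScoreSimConfig()
    rng = np.random.default_rng(config.seed)
    frames = []
    for pocket_id, effect in effect_sizes.items():
        cfg = ScoreSimConfig(**{**config.__dict__, "effect_size": effect})
        frames.append(simulate_scores(cfg, pocket_id=pocket_id, rng=rng))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# ligand libraries

# substituent R always attaches through its first atom
SCAFFOLDS = (
    "O=C(N{R})c1ccc2ccccc2c1",     # naphthalene carboxamides
    "O=S(=O)(N{R})c1ccncc1",       # pyridine-4-sulfonamides
    "O=C(O{R})C1CCCCC1",           # cyclohexanecarboxylate esters
    "c1ccc2c(c1)c({R})c[nH]2",     # 3-substituted indoles
)
PLAIN_SUBSTITUENTS = ("C", "CC", "CCC", "CCO", "CCN", "CCCC", "CC(C)C", "CCCO")
STEREO_SUBSTITUENTS = ("C(C)CC", "C(C)CCO", "C(CC)CO")  # one undetermined stereocenter
ENANTIOMER_TEMPLATES = (
    ("N[C@@H]({R})c1ccc2ccccc2c1", "N[C@H]({R})c1ccc2ccccc2c1"),
)


@dataclass
class LibrarySimConfig:
    """Scaffold-family library emulating a known-ligand screening library."""

    family_sizes: Sequence[int] = (4, 3, 3, 2)
    stereo_fraction: float = 0.25
    n_enantiomer_pairs: int = 0
    agonist_fraction: float = 0.5
    seed: int = 0


def simulate_library(config: LibrarySimConfig) -> tuple[str, pd.DataFrame]:
    """Generate an SDF library plus a label sidecar table.

    Molecules come from well-separated scaffold families (within-family
    Tanimoto dissimilarity far below between-family) so hierarchical
    chemotype clustering can recover the family structure.  A
    ``stereo_fraction`` of molecules carries one unassigned stereocenter;
    ``n_enantiomer_pairs`` pairs of records share a constitution in the
    two enantiomeric states, emulating duplicate deposits that must be
    counted once after racemic processing.

    Returns ``(sdf_text, labels)`` with labels columns
    ligand_id,label,pharmacology.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    rng = np.random.default_rng(config.seed)
    total = sum(config.family_sizes)
    n_stereo = round(config.stereo_fraction * total)
    stereo_slots = set(rng.choice(total, size=n_stereo, replace=False).tolist())

    entries: list[tuple[str, str]] = []  # (ligand_id, smiles)
    mol_index = 0
    for fam, size in enumerate(config.family_sizes):
        scaffold = SCAFFOLDS[fam % len(SCAFFOLDS)]
        n_stereo_in_family = 0  # distinct substituents within a family
        for k in range(size):
            if mol_index in stereo_slots:
                sub = STEREO_SUBSTITUENTS[n_stereo_in_family % len(STEREO_SUBSTITUENTS)]
                n_stereo_in_family += 1
            else:
                sub = PLAIN_SUBSTITUENTS[k % len(PLAIN_SUBSTITUENTS)]
            entries.append((f"fam{fam}_{k:02d}", scaffold.format(R=sub)))
            mol_index += 1
    for p in range(config.n_enantiomer_pairs):
        tpl_r, tpl_s = ENANTIOMER_TEMPLATES[0]
        sub = PLAIN_SUBSTITUENTS[p % len(PLAIN_SUBSTITUENTS)]
        entries.append((f"pair{p}_R", tpl_r.format(R=sub)))
        entries.append((f"pair{p}_S", tpl_s.format(R=sub)))

    buf = io.StringIO()
    writer = Chem.SDWriter(buf)
    labels = []
    for i, (lid, smi) in enumerate(entries):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # pragma: no cover - templates are valid by construction
            raise ValueError(f"bad template SMILES {smi!r}")
        AllChem.Compute2DCoords(mol)
        mol.SetProp("_Name", lid)
        pharm = "agonist" if i % 2 == 0 else "inhibitor"
        mol.SetProp("class", "active")
        mol.SetProp("pharmacology", pharm)
        writer.write(mol)
        labels.append({"ligand_id": lid, "label": "active", "pharmacology": pharm})
    writer.close()
    return buf.getvalue(), pd.DataFrame(labels)


# ---------------------------------------------------------------------------
# toy complexes

# Minimal ideal-geometry residue templates (heavy atoms, local frame with
# CA at the origin and the side chain extending toward +x).  These are
# fixtures for exact interaction distances, not rotamer-realistic models.
_BB = [("N", "N", (-1.20, 0.90, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
       ("C", "C", (-0.60, -1.30, 0.0)), ("O", "O", (-1.80, -1.50, 0.0))]

_PHE_RING = [
    ("CG", "C", (2.255, 1.306, 0.0)), ("CD1", "C", (3.645, 1.306, 0.0)),
    ("CE1", "C", (4.340, 2.510, 0.0)), ("CZ", "C", (3.645, 3.714, 0.0)),
    ("CE2", "C", (2.255, 3.714, 0.0)), ("CD2", "C", (1.565, 2.510, 0.0)),
]

RESIDUE_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "ALA": _BB + [("CB", "C", (1.50, 0.0, 0.0))],
    "SER": _BB + [("CB", "C", (1.50, 0.0, 0.0)), ("OG", "O", (2.20, 1.20, 0.0))],
    "CYS": _BB + [("CB", "C", (1.50, 0.0, 0.0)), ("SG", "S", (2.40, 1.40, 0.0))],
    "LEU": _BB + [
        ("CB", "C", (1.50, 0.0, 0.0)), ("CG", "C", (2.30, 1.20, 0.0)),
        ("CD1", "C", (3.80, 1.10, 0.0)), ("CD2", "C", (1.80, 2.55, 0.30)),
    ],
    "MET": _BB + [
        ("CB", "C", (1.50, 0.0, 0.0)), ("CG", "C", (2.30, 1.25, 0.0)),
        ("SD", "S", (3.90, 1.25, 0.0)), ("CE", "C", (4.60, 2.60, 0.0)),
    ],
    "ASP": _BB + [
        ("CB", "C", (1.50, 0.0, 0.0)), ("CG", "C", (2.20, 1.30, 0.0)),
        ("OD1", "O", (3.43, 1.40, 0.0)), ("OD2", "O", (1.55, 2.40, 0.0)),
    ],
    "ASN": _BB + [
        ("CB", "C", (1.50, 0.0, 0.0)), ("CG", "C", (2.20, 1.30, 0.0)),
        ("OD1", "O", (3.43, 1.40, 0.0)), ("ND2", "N", (1.55, 2.40, 0.0)),
    ],
    "LYS": _BB + [
        ("CB", "C", (1.50, 0.0, 0.0)), ("CG", "C", (2.30, 1.25, 0.0)),
        ("CD", "C", (3.80, 1.25, 0.0)), ("CE", "C", (4.60, 2.50, 0.0)),
        ("NZ", "N", (6.00, 2.50, 0.0)),
    ],
    "PHE": _BB + [("CB", "C", (1.50, 0.0, 0.0))] + _PHE_RING,
    "TYR": _BB + [("CB", "C", (1.50, 0.0, 0.0))] + _PHE_RING
    + [("OH", "O", (4.335, 4.909, 0.0))],
}


def default_ligand(code: str = "LIG") -> Ligand:
    """A small probe ligand: benzene ring with a benzylic aminium arm and
    a phenolic hydroxyl — cationic donor N, donor/acceptor O, apolar ring
    carbons, and one planar aromatic ring."""
    atoms = [
        Atom("C1", "C", (1.390, 0.0, 0.0)),
        Atom("C2", "C", (0.695, 1.204, 0.0)),
        Atom("C3", "C", (-0.695, 1.204, 0.0)),
        Atom("C4", "C", (-1.390, 0.0, 0.0)),
        Atom("C5", "C", (-0.695, -1.204, 0.0)),
        Atom("C6", "C", (0.695, -1.204, 0.0)),
        Atom("C7", "C", (2.890, 0.0, 0.0)),
        Atom("N1", "N", (3.630, 1.250, 0.0)),
        Atom("O1", "O", (-2.750, 0.0, 0.0)),
    ]
    bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0), (0, 6), (6, 7), (3, 8)]
    return Ligand(code, atoms, bonds)


@dataclass
class ResiduePlacement:
    """Place one residue so a named atom sits at an exact distance from a
    named ligand atom, along ``direction`` (unit vector pointing from the
    ligand atom outward; the residue body extends further outward)."""

    resname: str
    resnum: int
    residue_atom: str
    ligand_atom: str
    distance: float
    direction: tuple[float, float, float]
    interaction: str = ""  # intended interaction type, informational


@dataclass
class ToyComplexSpec:
    complex_id: str
    placements: list[ResiduePlacement]
    ligand: Ligand | None = None  # defaults to default_ligand()


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


MIN_UNINTENDED_CONTACT = 1.5  # Å between atoms of different entities


def build_toy_complex(spec: ToyComplexSpec) -> ComplexStructure:
    """Realize a miniature pocket around the ligand.

    Each placement positions its residue rigidly so that the contact atom
    lies exactly ``distance`` Å from the chosen ligand atom along
    ``direction``, with the rest of the residue oriented further away
    from the ligand.  Any unintended inter-entity atom pair closer than
    1.5 Å is a fatal steric clash.
    """
    ligand = spec.ligand or default_ligand()
    lig_atoms = {a.name: a for a in ligand.atoms}

    residues: list[Residue] = []
    for pl in spec.placements:
        if pl.resname not in RESIDUE_TEMPLATES:
            raise StructureError(f"no template for residue type {pl.resname!r}")
        template = RESIDUE_TEMPLATES[pl.resname]
        names = [n for n, _, _ in template]
        if pl.residue_atom not in names:
            raise StructureError(f"{pl.resname} has no atom {pl.residue_atom!r}")
        if pl.ligand_atom not in lig_atoms:
            raise StructureError(f"ligand has no atom {pl.ligand_atom!r}")
        local = np.array([xyz for _, _, xyz in template])
        contact_local = local[names.index(pl.residue_atom)]
        centroid = local.mean(axis=0)
        outward = centroid - contact_local
        if np.linalg.norm(outward) < 1e-9:
            outward = np.array([1.0, 0.0, 0.0])
        direction = np.asarray(pl.direction, float)
        direction /= np.linalg.norm(direction)
        rot = _rotation_between(outward, direction)
        anchor = lig_atoms[pl.ligand_atom].coord + pl.distance * direction
        placed = (local - contact_local) @ rot.T + anchor
        residues.append(
            Residue(
                chain="A",
                resnum=pl.resnum,
                icode="",
                resname=pl.resname,
                atoms=[
                    Atom(n, el, xyz) for (n, el, _), xyz in zip(template, placed)
                ],
            )
        )

    # verify realized distances and check sterics
    for pl, res in zip(spec.placements, residues):
        realized = float(
            np.linalg.norm(res.atom(pl.residue_atom).coord - lig_atoms[pl.ligand_atom].coord)
        )
        if abs(realized - pl.distance) > 0.01:  # pragma: no cover - exact by construction
            raise StructureError(
                f"{pl.resname}{pl.resnum}: realized {realized:.3f} Å vs target {pl.distance} Å"
            )
    entities = [ligand.coords()] + [r.coords() for r in residues]
    for i in range(len(entities)):
        for j in range(i + 1, len(entities)):
            d = np.linalg.norm(entities[i][:, None, :] - entities[j][None, :, :], axis=2)
            if d.min() < MIN_UNINTENDED_CONTACT:
                raise StructureError(
                    f"steric clash: entities {i} and {j} at {d.min():.2f} Å"
                )

    return ComplexStructure(spec.complex_id, residues, ligand)


def complex_to_pdb(complex_: ComplexStructure) -> str:
    """Serialize a complex as PDB text (ATOM records + HETATM ligand)."""

    def fmt(serial, name, resname, chain, resnum, atom, record):
        pdb_name = name if len(name) >= 4 else f" {name:<3s}"
        return (
            f"{record:<6s}{serial:>5d} {pdb_name}{'':1s}{resname:>3s} {chain}"
            f"{resnum:>4d}{'':1s}   "
            f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
        )

    lines = []
    serial = 1
    for res in complex_.residues:
        for atom in res.atoms:
            lines.append(fmt(serial, atom.name, res.resname, res.chain, res.resnum, atom, "ATOM"))
            serial += 1
    for atom in complex_.ligand.atoms:
        lines.append(fmt(serial, atom.name, complex_.ligand.code, "A", 900, atom, "HETATM"))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
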