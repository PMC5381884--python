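"""Structure loading, pocket definition, superposition, RMSD, IFP, quality."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pocketscreen import struct_compare as sc
from pocketscreen import synthetic_data as sd

from conftest import random_rotation


def pdb_line(record, serial, name, resname, chain, resnum, xyz, occ=1.0, alt=" ", element=None):
    el = element or name[0]
    pdb_name = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:>5d} {pdb_name}{alt}{resname:>3s} {chain}{resnum:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{0.0:6.2f}          {el:>2s}"
    )


@pytest.fixture
def two_chain_pdb():
    """Two-chain toy receptor with waters, an altloc CA, and a bound ligand."""
    lines = [
        pdb_line("ATOM", 1, "N", "ALA", "A", 1, (0, 0, 0)),
        pdb_line("ATOM", 2, "CA", "ALA", "A", 1, (1.0, 0, 0), occ=0.6, alt="A"),
        pdb_line("ATOM", 3, "CA", "ALA", "A", 1, (9.0, 9, 9), occ=0.4, alt="B"),
        pdb_line("ATOM", 4, "C", "ALA", "A", 1, (2.0, 1.0, 0)),
        pdb_line("ATOM", 5, "O", "ALA", "A", 1, (3.0, 1.0, 0)),
        pdb_line("ATOM", 6, "N", "GLY", "B", 1, (10, 0, 0)),
        pdb_line("ATOM", 7, "CA", "GLY", "B", 1, (11, 0, 0)),
        pdb_line("ATOM", 8, "C", "GLY", "B", 1, (12, 1, 0)),
        pdb_line("HETATM", 9, "O", "HOH", "A", 101, (5, 5, 5)),
        pdb_line("HETATM", 10, "C1", "LIG", "A", 200, (1.0, 3.0, 0)),
        pdb_line("HETATM", 11, "C2", "LIG", "A", 200, (2.4, 3.0, 0)),
        "END",
    ]
    return "\n".join(lines) + "\n"


class TestLoadComplex:
    def test_chain_selection(self, two_chain_pdb):
        cx = sc.load_complex(two_chain_pdb, "LIG", chain_selection=["A"])
        assert {r.chain for r in cx.residues} == {"A"}

    def test_waters_removed(self, two_chain_pdb):
        cx = sc.load_complex(two_chain_pdb, "LIG")
        assert all(r.resname != "HOH" for r in cx.residues)

    def test_altloc_highest_occupancy(self, two_chain_pdb):
        cx = sc.load_complex(two_chain_pdb, "LIG")
        ca = cx.residues[0].atom("CA")
        assert np.allclose(ca.coord, (1.0, 0, 0))

    def test_missing_ligand_fatal(self, two_chain_pdb):
        with pytest.raises(sc.StructureError, match="XYZ"):
            sc.load_complex(two_chain_pdb, "XYZ")

    def test_missing_chain_fatal(self, two_chain_pdb):
        with pytest.raises(sc.StructureError, match="absent"):
            sc.load_complex(two_chain_pdb, "LIG", chain_selection=["Q"])

    def test_ligand_bonds_inferred(self, two_chain_pdb):
        cx = sc.load_complex(two_chain_pdb, "LIG")
        assert cx.ligand.bonds == [(0, 1)]  # C1-C2 at 1.4 Å


def single_residue_complex(resname, resnum, atom, lig_atom, distance, direction):
    return sd.build_toy_complex(
        sd.ToyComplexSpec(
            f"{resname}{resnum}",
            [sd.ResiduePlacement(resname, resnum, atom, lig_atom, distance, direction)],
        )
    )


class TestDefinePocket:
    def test_distance_threshold(self):
        cx = sd.build_toy_complex(
            sd.ToyComplexSpec(
                "thresh",
                [
                    sd.ResiduePlacement("ALA", 1, "CB", "C2", 4.9, (0.5, 1.0, 0.3)),
                    sd.ResiduePlacement("ALA", 2, "CB", "C5", 5.1, (-0.5, -1.0, 0.3)),
                ],
            )
        )
        pocket = sc.define_pocket(cx, radius=5.0)
        assert (1, "") in pocket.residues
        assert (2, "") not in pocket.residues

    def test_group_union_includes_single_member_contacts(self):
        near = single_residue_complex("ALA", 7, "CB", "C2", 4.0, (0.5, 1.0, 0.3))
        far = single_residue_complex("ALA", 7, "CB", "C2", 8.0, (0.5, 1.0, 0.3))
        union = sc.define_pocket([near, far], radius=5.0)
        assert (7, "") in union.residues
        assert union.scope == "group_union"

    def test_group_pocket_superset_of_members(self, toy_complex):
        other = single_residue_complex("SER", 99, "OG", "O1", 4.5, (-1.0, 0.5, 0.0))
        group = sc.define_pocket([toy_complex, other], radius=5.0)
        for member in (toy_complex, other):
            assert sc.define_pocket(member, radius=5.0).residues <= group.residues

    def test_empty_pocket_is_error(self):
        cx = single_residue_complex("ALA", 1, "CB", "C2", 20.0, (0.5, 1.0, 0.3))
        with pytest.raises(sc.StructureError, match="empty pocket"):
            sc.define_pocket(cx, radius=5.0)

    def test_docking_box_uses_four_angstroms(self, toy_complex):
        box = sc.docking_box_residues(toy_complex)
        assert box.radius == 4.0
        assert box.residues <= sc.define_pocket(toy_complex, 5.0).residues


class TestSuperposeGroup:
    def test_recovers_rigid_motion(self, toy_complex):
        rng = np.random.default_rng(1)
        moved = toy_complex.transformed(random_rotation(rng), np.array([4.0, -2.0, 7.0]))
        out, fits = sc.superpose_group([toy_complex, moved])
        assert fits[1] < 1e-6
        assert sc.ligand_rmsd(out[0], out[1]) < 1e-6

    def test_fit_invariant_under_input_rigid_motion(self, toy_complex):
        rng = np.random.default_rng(2)
        jittered = toy_complex.transformed(np.eye(3), np.array([0.3, 0.0, 0.0]))
        _, fits0 = sc.superpose_group([toy_complex, jittered])
        for seed in range(3):
            r = random_rotation(np.random.default_rng(seed))
            removed = jittered.transformed(r, np.array([1.0, 2.0, 3.0]))
            _, fits1 = sc.superpose_group([toy_complex, removed])
            assert fits1[1] == pytest.approx(fits0[1], abs=1e-9)

    def test_side_chain_motion_does_not_affect_backbone_fit(self, toy_complex):
        from dataclasses import replace

        residues = []
        for r in toy_complex.residues:
            if r.resname == "LEU":
                atoms = [
                    sc.Atom(a.name, a.element, a.coord + (1.0 if a.name == "CD1" else 0.0))
                    for a in r.atoms
                ]
                residues.append(replace(r, atoms=atoms))
            else:
                residues.append(r)
        bent = sc.ComplexStructure("bent", residues, toy_complex.ligand)
        _, fits = sc.superpose_group([toy_complex, bent])
        assert fits[1] < 1e-9

    def test_too_few_atoms_fatal(self, toy_complex):
        lonely = sc.ComplexStructure("x", toy_complex.residues[:1], toy_complex.ligand)
        stripped = sc.ComplexStructure(
            "y",
            [sc.Residue("A", 10, "", "ASP", toy_complex.residues[0].atoms[:2])],
            toy_complex.ligand,
        )
        with pytest.raises(sc.StructureError):
            sc.superpose_group([lonely, stripped])


def ligand_only_complex(ligand, cid="x"):
    res = sc.Residue("A", 1, "", "ALA", [sc.Atom("CA", "C", (50.0, 50.0, 50.0))])
    return sc.ComplexStructure(cid, [res], ligand)


def brute_force_min_rmsd(lig_a, lig_b):
    """Oracle: exhaustive minimum RMSD over all element- and
    adjacency-preserving bijections between the two ligand graphs."""
    elems_a = [a.element for a in lig_a.atoms]
    elems_b = [a.element for a in lig_b.atoms]
    adj_a = {frozenset(b) for b in lig_a.bonds}
    adj_b = {frozenset(b) for b in lig_b.bonds}
    ca, cb = lig_a.coords(), lig_b.coords()
    groups = {}
    for j, e in enumerate(elems_b):
        groups.setdefault(e, []).append(j)
    order = [i for e in sorted(groups) for i in range(len(elems_a)) if elems_a[i] == e]
    best = None
    pools = [itertools.permutations(groups[e]) for e in sorted(groups)]
    for combo in itertools.product(*pools):
        mapping = dict(zip(order, itertools.chain(*combo)))
        if {frozenset((mapping[i], mapping[j])) for i, j in adj_a} != adj_b:
            continue
        idx = [mapping[i] for i in range(len(elems_a))]
        r = float(np.sqrt(((ca - cb[idx]) ** 2).sum(axis=1).mean()))
        best = r if best is None else min(best, r)
    return best


def benzene(names):
    coords = [
        (1.39, 0, 0), (0.695, 1.204, 0), (-0.695, 1.204, 0),
        (-1.39, 0, 0), (-0.695, -1.204, 0), (0.695, -1.204, 0),
    ]
    atoms = [sc.Atom(n, "C", c) for n, c in zip(names, coords)]
    return sc.Ligand("BNZ", atoms, [(i, (i + 1) % 6) for i in range(6)])


class TestLigandRmsd:
    def test_identical_is_zero(self, toy_complex):
        assert sc.ligand_rmsd(toy_complex, toy_complex) == pytest.approx(0.0)

    def test_pure_translation(self, toy_complex):
        moved = toy_complex.transformed(np.eye(3), np.array([3.0, 0.0, 0.0]))
        assert sc.ligand_rmsd(toy_complex, moved) == pytest.approx(3.0)

    def test_symmetry_equivalent_relabeling_is_zero(self):
        a = ligand_only_complex(benzene(["C1", "C2", "C3", "C4", "C5", "C6"]))
        b = ligand_only_complex(benzene(["C2", "C3", "C4", "C5", "C6", "C1"]))
        assert sc.ligand_rmsd(a, b, symmetry=False) > 1.0  # name matching is fooled
        assert sc.ligand_rmsd(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_non_isomorphic_fatal(self):
        chain = sc.Ligand(
            "CHN",
            [sc.Atom(f"C{i}", "C", (1.5 * i, 0, 0)) for i in range(6)],
            [(i, i + 1) for i in range(5)],
        )
        with pytest.raises(sc.StructureError, match="isomorphic"):
            sc.ligand_rmsd(ligand_only_complex(benzene(["C%d" % i for i in range(6)])),
                           ligand_only_complex(chain))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_and_bounds_name_matching(self, seed):
        rng = np.random.default_rng(seed)
        base = sd.default_ligand()
        jittered = sc.Ligand(
            base.code,
            [sc.Atom(a.name, a.element, a.coord + rng.normal(0, 0.3, 3)) for a in base.atoms],
            base.bonds,
        )
        a, b = ligand_only_complex(base), ligand_only_complex(jittered)
        sym = sc.ligand_rmsd(a, b)
        assert sym == pytest.approx(brute_force_min_rmsd(base, jittered), abs=1e-9)
        assert sym <= sc.ligand_rmsd(a, b, symmetry=False) + 1e-12

    def test_symmetric_in_arguments(self, toy_complex):
        rng = np.random.default_rng(9)
        moved = toy_complex.transformed(random_rotation(rng), np.array([0.5, 0.2, -0.1]))
        assert sc.ligand_rmsd(toy_complex, moved) == pytest.approx(
            sc.ligand_rmsd(moved, toy_complex)
        )


class TestPocketRmsd:
    def test_identical_is_zero(self, toy_complex):
        pocket = sc.define_pocket(toy_complex, 6.5)
        assert sc.pocket_rmsd(toy_complex, toy_complex, pocket) == pytest.approx(0.0)

    def test_uniform_displacement(self, toy_complex):
        pocket = sc.define_pocket(toy_complex, 6.5)
        moved = toy_complex.transformed(np.eye(3), np.array([2.0, 0.0, 0.0]))
        assert sc.pocket_rmsd(toy_complex, moved, pocket) == pytest.approx(2.0)

    def test_missing_side_chain_atoms_skipped(self, toy_complex):
        from dataclasses import replace

        residues = []
        for r in toy_complex.residues:
            atoms = [a for a in r.atoms if not (r.resname == "LEU" and a.name.startswith("CD"))]
            residues.append(replace(r, atoms=atoms))
        truncated = sc.ComplexStructure("trunc", residues, toy_complex.ligand)
        pocket = sc.define_pocket(toy_complex, 6.5)
        assert sc.pocket_rmsd(toy_complex, truncated, pocket) == pytest.approx(0.0)


class TestIfp:
    def test_constructed_interaction_bits(self, toy_complex):
        pocket = sc.define_pocket(toy_complex, 6.5)
        ifp = sc.compute_ifp(toy_complex, pocket)
        asp = ifp.bits.loc["ASP10"]
        assert asp["ionic"] and asp["hbond_acceptor"]
        assert ifp.bits.loc["LEU20", "hydrophobic"]
        assert ifp.bits.loc["SER30", "hbond_donor"]
        assert ifp.bits.loc["PHE40", "aromatic"]

    def test_hydrophobic_within_cutoff(self):
        cx = single_residue_complex("LEU", 5, "CD1", "C5", 4.0, (-0.4, -1.0, 0.3))
        ifp = sc.compute_ifp(cx, sc.define_pocket(cx, 5.0))
        assert ifp.bits.loc["LEU5", "hydrophobic"]

    def test_distant_residue_all_false(self, toy_spec):
        spec = sd.ToyComplexSpec(
            "far",
            toy_spec.placements
            + [sd.ResiduePlacement("ALA", 90, "CB", "C5", 10.0, (0.0, -1.0, -0.4))],
        )
        cx = sd.build_toy_complex(spec)
        pocket = sc.PocketDefinition(5.0, {(90, "")} | sc.define_pocket(cx, 6.5).residues,
                                     "single_complex")
        ifp = sc.compute_ifp(cx, pocket)
        assert not ifp.bits.loc["ALA90"].any()

    def test_invariant_under_rigid_motion(self, toy_complex):
        pocket = sc.define_pocket(toy_complex, 6.5)
        base = sc.compute_ifp(toy_complex, pocket).bits
        rng = np.random.default_rng(4)
        moved = toy_complex.transformed(random_rotation(rng), np.array([-3.0, 8.0, 1.0]))
        assert sc.compute_ifp(moved, pocket).bits.equals(base)

    def test_heatmap_identical_complexes_identical_rows(self, toy_complex, tmp_path):
        pocket = sc.define_pocket(toy_complex, 6.5)
        m1 = sc.compute_ifp(toy_complex, pocket)
        m2 = sc.compute_ifp(toy_complex, pocket)
        m2.complex_id = "copy"
        bits = sc.ifp_heatmap([m1, m2], path=tmp_path / "ifp.png")
        wide = bits.set_index(["complex_id", "residue"])
        assert wide.loc["toy1"].equals(wide.loc["copy"])
        assert (tmp_path / "ifp.png").exists()

    def test_one_lost_contact_changes_exactly_one_cell(self, toy_spec):
        placements = [
            p if p.resname != "LEU"
            else sd.ResiduePlacement("LEU", 20, "CD1", "C5", 5.2, p.direction)
            for p in toy_spec.placements
        ]
        variant = sd.build_toy_complex(sd.ToyComplexSpec("variant", placements))
        base = sd.build_toy_complex(toy_spec)
        pocket = sc.define_pocket([base, variant], 6.5)
        b1 = sc.compute_ifp(base, pocket).bits
        b2 = sc.compute_ifp(variant, pocket).bits
        assert int((b1 != b2).to_numpy().sum()) == 1
        assert bool(b1.loc["LEU20", "hydrophobic"]) and not bool(b2.loc["LEU20", "hydrophobic"])

    def test_empty_group_is_error(self):
        with pytest.raises(sc.StructureError, match="empty"):
            sc.ifp_heatmap([])

    def test_mismatched_rows_fatal(self, toy_complex):
        pocket_full = sc.define_pocket(toy_complex, 6.5)
        pocket_small = sc.PocketDefinition(5.0, set(list(sorted(pocket_full.residues))[:2]),
                                           "single_complex")
        m1 = sc.compute_ifp(toy_complex, pocket_full)
        m2 = sc.compute_ifp(toy_complex, pocket_small)
        with pytest.raises(sc.StructureError, match="aligned"):
            sc.ifp_heatmap([m1, m2])


class TestQualityReport:
    @pytest.fixture
    def pocket(self):
        return sc.PocketDefinition(5.0, {(10, ""), (20, ""), (30, ""), (40, "")},
                                   "single_complex")

    def make_table(self, rows):
        return pd.DataFrame(rows, columns=["chain", "resnum", "resname", "rscc", "bfactor"])

    def test_flags(self, pocket, tmp_path):
        table = self.make_table(
            [("A", 10, "SER", 0.75, 30.0), ("A", 20, "LEU", 0.90, 20.0),
             ("A", 30, "MET", 0.70, 80.0), ("A", 40, "PHE", 0.95, 10.0)]
        )
        report = sc.quality_report(table, pocket, plot_path=tmp_path / "q.png")
        t = report.table.set_index("resnum")
        assert t.loc[10, "low_rscc"] and not t.loc[10, "damage_prone"]
        assert not t.loc[20, "low_rscc"]
        assert t.loc[30, "low_rscc"] and t.loc[30, "damage_prone"]
        assert t.loc[30, "low_rscc_high_b"]  # B 80 above pocket median
        assert (tmp_path / "q.png").exists()

    def test_missing_residue_flagged(self, pocket):
        table = self.make_table([("A", 10, "SER", 0.9, 30.0)])
        report = sc.quality_report(table, pocket)
        t = report.table.set_index("resnum")
        assert t.loc[40, "missing_data"]
        assert not t.loc[10, "missing_data"]

    def test_disulfide_cys_damage_prone(self, pocket):
        table = self.make_table([("A", 10, "CYS", 0.7, 30.0), ("A", 20, "CYS", 0.7, 30.0)])
        with_ss = sc.quality_report(table, pocket, disulfide_cys={(10, "")})
        t = with_ss.table.set_index("resnum")
        assert t.loc[10, "damage_prone"]
        assert not t.loc[20, "damage_prone"]  # free cysteine

    def test_find_disulfides_distance_rule(self):
        spec = sd.ToyComplexSpec(
            "ss",
            [
                sd.ResiduePlacement("CYS", 50, "SG", "C3", 4.0, (0.0, 1.0, 0.0)),
                sd.ResiduePlacement("CYS", 51, "SG", "C3", 4.0, (-0.485, 0.875, 0.0)),
                sd.ResiduePlacement("CYS", 60, "SG", "C6", 6.0, (0.4, -1.0, 0.0)),
            ],
        )
        cx = sd.build_toy_complex(spec)
        assert sc.find_disulfides(cx) == {(50, ""), (51, "")}
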