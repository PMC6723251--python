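"""Alignment-tree configuration, anchoring, set execution, tree execution."""

from __future__ import annotations

import numpy as np
import pytest
import yaml

from poltree.fixtures import (
    FamilySpec,
    folded_template,
    random_transforms,
    synth_family,
    synth_tree,
)
from poltree.msa import MotifRegionSet
from poltree.pdbio import (
    AtomRecord,
    RigidTransform,
    StructureModel,
    read_structure,
    write_structure,
)
from poltree.superpose import kabsch_fit, ml_superpose, rmsd
from poltree.tree import (
    SetRunError,
    TreeConfigError,
    anchor_to_parent,
    load_tree,
    run_set,
    run_tree,
)

MINI_TREE = {
    "sets": [
        {"name": "base", "parent": "ROOT", "seed": {"pdb": "a001", "chain": "A"},
         "region": "FULL",
         "members": [{"pdb": "a001", "chain": "A", "file": "a001.pdb"},
                     {"pdb": "a002", "chain": "A", "file": "a002.pdb"}]},
        {"name": "midl", "parent": "base", "seed": {"pdb": "a002", "chain": "A"},
         "region": "FULL",
         "members": [{"pdb": "a002", "chain": "A", "file": "a002.pdb"},
                     {"pdb": "a003", "chain": "A", "file": "a003.pdb"}]},
        {"name": "leaf", "parent": "midl", "seed": {"pdb": "a003", "chain": "A"},
         "region": "FULL",
         "members": [{"pdb": "a003", "chain": "A", "file": "a003.pdb"},
                     {"pdb": "a004", "chain": "A", "file": "a004.pdb"}]},
    ]
}


def _write_config(tmp_path, doc):
    path = tmp_path / "tree.yaml"
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


class TestLoadTree:
    def test_topological_order(self, tmp_path):
        tree = load_tree(_write_config(tmp_path, MINI_TREE))
        assert tree.order == ["base", "midl", "leaf"]

    def test_cycle_rejected(self, tmp_path):
        doc = yaml.safe_load(yaml.safe_dump(MINI_TREE))
        doc["sets"][0]["parent"] = "leaf"
        doc["sets"][0]["seed"] = {"pdb": "a001", "chain": "A"}
        doc["sets"][2]["members"].append({"pdb": "a001", "chain": "A",
                                          "file": "a001.pdb"})
        with pytest.raises(TreeConfigError, match="cycle|ROOT"):
            load_tree(_write_config(tmp_path, doc))

    def test_duplicate_set_name_rejected(self, tmp_path):
        doc = yaml.safe_load(yaml.safe_dump(MINI_TREE))
        doc["sets"][2]["name"] = "midl"
        doc["sets"][2]["parent"] = "base"
        doc["sets"][2]["seed"] = {"pdb": "a002", "chain": "A"}
        doc["sets"][2]["members"][0] = {"pdb": "a002", "chain": "A",
                                        "file": "a002.pdb"}
        with pytest.raises(TreeConfigError, match="duplicate"):
            load_tree(_write_config(tmp_path, doc))

    def test_seed_must_be_member(self, tmp_path):
        doc = yaml.safe_load(yaml.safe_dump(MINI_TREE))
        doc["sets"][0]["seed"] = {"pdb": "zzzz", "chain": "A"}
        with pytest.raises(TreeConfigError, match="seed"):
            load_tree(_write_config(tmp_path, doc))

    def test_unknown_parent_rejected(self, tmp_path):
        doc = yaml.safe_load(yaml.safe_dump(MINI_TREE))
        doc["sets"][2]["parent"] = "gone"
        with pytest.raises(TreeConfigError, match="unknown parent"):
            load_tree(_write_config(tmp_path, doc))

    def test_pivot_handoff_child_seeded_by_non_seed_member(self, tmp_path):
        """An opcl-style pivot: the child's seed is a parent member that is not
        the parent's own seed (open vs closed conformation handoff)."""
        doc = yaml.safe_load(yaml.safe_dump(MINI_TREE))
        # midl is seeded by a002 while base's seed is a001 - already the case
        tree = load_tree(_write_config(tmp_path, doc))
        assert tree.get("midl").seed == ("a002", "A")
        assert tree.get("base").seed == ("a001", "A")


class TestAnchorToParent:
    def _result(self):
        fam = synth_family(FamilySpec(4, 30, 0.05, seed=21))
        res = ml_superpose(fam.correspondence(), [t.coords for t in fam.traces])
        return res

    def test_identity_when_parent_frame_equals_ml_frame(self):
        res = self._result()
        transforms, g = anchor_to_parent(res, 0, res.member_fitted(0))
        assert np.allclose(g.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(g.translation, 0, atol=1e-9)
        for a, b in zip(transforms, res.member_transforms):
            assert np.allclose(a.rotation, b.rotation, atol=1e-9)

    def test_rotated_parent_frame_preserves_relative_geometry(self):
        res = self._result()
        rot = RigidTransform.about_axis((0, 1, 1), 25.0, (3, 1, -2))
        parent_coords = rot.apply(res.member_fitted(0))
        transforms, g = anchor_to_parent(res, 0, parent_coords)
        assert np.allclose(g.rotation, rot.rotation, atol=1e-8)
        fitted = [t.apply(c) for t, c in zip(
            transforms,
            [res.member_fitted(i) for i in range(4)],
        )]
        # relative geometry: pairwise RMSDs unchanged
        before = [rmsd(res.member_fitted(i), res.member_fitted(j))
                  for i in range(4) for j in range(i + 1, 4)]
        # recompute member coords both ways through original coordinates
        after = []
        orig = [res.member_transforms[i].inverse().apply(res.member_fitted(i))
                for i in range(4)]
        moved = [t.apply(o) for t, o in zip(transforms, orig)]
        after = [rmsd(moved[i], moved[j]) for i in range(4)
                 for j in range(i + 1, 4)]
        assert np.allclose(before, after, atol=1e-9)

    def test_column_mismatch_rejected(self):
        res = self._result()
        with pytest.raises(ValueError, match="mismatch"):
            anchor_to_parent(res, 0, res.member_fitted(0)[:10])


def _write_family_set(tmp_path, n_entries=4, two_chain_entry=True, seed=33):
    """Synthetic set on disk: identical-sequence entries; first entry carries
    two polymerase chains when requested."""
    fam = synth_family(FamilySpec(n_entries + (1 if two_chain_entry else 0),
                                  40, 0.02, seed=seed))
    pdb_dir = tmp_path / "in"
    pdb_dir.mkdir(exist_ok=True)
    members = []
    traces = iter(fam.traces)
    for e in range(n_entries):
        pdb_id = f"e{e:03d}"
        chains = ["A", "B"] if (two_chain_entry and e == 0) else ["A"]
        atoms = []
        for chain in chains:
            tr = next(traces)
            for j in range(len(tr)):
                atoms.append(AtomRecord(
                    serial=len(atoms) + 1, name="CA", altloc="",
                    residue_name=tr.residues[j][2], chain_id=chain,
                    residue_seq=j + 1, insertion_code="",
                    position=tr.coords[j], occupancy=1.0, b_factor=10.0,
                    element="C"))
            members.append({"pdb": pdb_id, "chain": chain,
                            "file": f"in/{pdb_id}.pdb"})
        write_structure(StructureModel(pdb_id, f"ENTRY {pdb_id.upper()}", atoms),
                        pdb_dir / f"{pdb_id}.pdb")
    return members


class TestRunSet:
    def test_entry_with_two_chains_yields_one_output_per_chain(self, tmp_path):
        members = _write_family_set(tmp_path)
        doc = {"sets": [{"name": "fams", "parent": "ROOT",
                         "seed": {"pdb": "e000", "chain": "A"},
                         "region": "FULL", "members": members}]}
        tree = load_tree(_write_config(tmp_path, doc))
        res = run_set(tree.get("fams"), out_root=tmp_path / "out")
        assert len(res.output_paths) == 5
        names = sorted(p.name for p in res.output_paths)
        assert "e000_A-fams.pdb" in names and "e000_B-fams.pdb" in names

    def test_copies_of_seed_stay_in_seed_frame(self, tmp_path):
        fam = synth_family(FamilySpec(2, 40, 0.0, seed=3))
        pdb_dir = tmp_path / "in"
        pdb_dir.mkdir()
        # three exact copies of one structure under different entry ids
        tr = fam.traces[0]
        members = []
        for pdb_id in ("c001", "c002", "c003"):
            atoms = [AtomRecord(j + 1, "CA", "", tr.residues[j][2], "A", j + 1,
                                "", tr.coords[j], 1.0, 10.0, "C")
                     for j in range(len(tr))]
            write_structure(StructureModel(pdb_id, "COPY", atoms),
                            pdb_dir / f"{pdb_id}.pdb")
            members.append({"pdb": pdb_id, "chain": "A",
                            "file": f"in/{pdb_id}.pdb"})
        doc = {"sets": [{"name": "copy", "parent": "ROOT",
                         "seed": {"pdb": "c001", "chain": "A"},
                         "region": "FULL", "members": members}]}
        tree = load_tree(_write_config(tmp_path, doc))
        res = run_set(tree.get("copy"), out_root=tmp_path / "out")
        seed_coords = res.traces[("c001", "A")].coords
        for m in res.members:
            out = res.transforms[m.key].apply(res.traces[m.key].coords)
            assert rmsd(out, seed_coords) < 1e-6

    def test_region_column_count_reported_in_readme(self, tmp_path):
        members = _write_family_set(tmp_path, two_chain_entry=False)
        doc = {"sets": [{"name": "regn", "parent": "ROOT",
                         "seed": {"pdb": "e000", "chain": "A"},
                         "region": {"motif_A": [[3, 15]], "motif_C": [[20, 32]]},
                         "members": members}]}
        tree = load_tree(_write_config(tmp_path, doc))
        res = run_set(tree.get("regn"), out_root=tmp_path / "out")
        assert len(res.superposition.columns_used) == 26
        assert res.readme_text.count("(26 atoms)") == len(res.members)
        # two region segments -> two residue ranges printed
        assert "3-15, 20-32" in res.readme_text

    def test_unreadable_member_skipped_and_listed(self, tmp_path):
        members = _write_family_set(tmp_path, two_chain_entry=False)
        members.append({"pdb": "gone", "chain": "A", "file": "in/gone.pdb"})
        doc = {"sets": [{"name": "skip", "parent": "ROOT",
                         "seed": {"pdb": "e000", "chain": "A"},
                         "region": "FULL", "members": members}]}
        tree = load_tree(_write_config(tmp_path, doc))
        res = run_set(tree.get("skip"), out_root=tmp_path / "out")
        assert len(res.skipped) == 1
        assert "SKIPPED gone_A" in res.readme_text
        with pytest.raises(SetRunError):
            run_set(tree.get("skip"), out_root=tmp_path / "out2", strict=True)

    def test_unreadable_seed_is_fatal(self, tmp_path):
        members = [{"pdb": "gone", "chain": "A", "file": "in/gone.pdb"},
                   {"pdb": "alsg", "chain": "A", "file": "in/alsg.pdb"}]
        doc = {"sets": [{"name": "fatl", "parent": "ROOT",
                         "seed": {"pdb": "gone", "chain": "A"},
                         "region": "FULL", "members": members}]}
        tree = load_tree(_write_config(tmp_path, doc))
        with pytest.raises(SetRunError, match="seed"):
            run_set(tree.get("fatl"), out_root=tmp_path / "out")


class TestRunTree:
    def test_two_level_recovery_and_seed_anchoring(self, tmp_path):
        fix = synth_tree(2, 3, seed=5, out_dir=tmp_path / "fix")
        results = run_tree(fix.tree, tmp_path / "out",
                           root_seed_frame=fix.root_seed_frame)
        assert [r.name for r in results] == fix.tree.order
        for r in results:
            assert r.seed_anchor_rmsd < 1e-6
            for m in r.members:
                out = r.transforms[m.key].apply(r.traces[m.key].coords)
                err = rmsd(out, fix.ground_truth[m.key])
                assert err <= 3 * fix.noise

    def test_frame_composition_consistency(self, tmp_path):
        """A child member's coordinates computed through its final transform
        equal the parent-anchoring composition applied to its within-set fit."""
        fix = synth_tree(2, 3, seed=8, out_dir=tmp_path / "fix")
        results = run_tree(fix.tree, tmp_path / "out",
                           root_seed_frame=fix.root_seed_frame)
        child = results[1]
        for i, m in enumerate(child.members):
            direct = child.transforms[m.key].apply(child.traces[m.key].coords)
            via_result = child.superposition.member_transforms[i].apply(
                child.traces[m.key].coords
            )
            assert rmsd(direct, via_result) < 1e-8

    def test_outputs_pooled_into_all_pdbs(self, tmp_path):
        fix = synth_tree(2, 3, seed=2, out_dir=tmp_path / "fix")
        results = run_tree(fix.tree, tmp_path / "out",
                           root_seed_frame=fix.root_seed_frame)
        pooled = {p.name for p in (tmp_path / "out" / "_All_PDBs").iterdir()}
        produced = {p.name for r in results for p in r.output_paths}
        assert pooled == produced

    def test_single_node_tree_equals_run_set(self, tmp_path):
        fix = synth_tree(1, 3, seed=4, out_dir=tmp_path / "fix")
        results = run_tree(fix.tree, tmp_path / "out1",
                           root_seed_frame=fix.root_seed_frame)
        solo = run_set(fix.tree.get(fix.tree.order[0]),
                       root_seed_frame=fix.root_seed_frame,
                       out_root=tmp_path / "out2")
        for m in solo.members:
            a = results[0].transforms[m.key]
            b = solo.transforms[m.key]
            assert np.allclose(a.rotation, b.rotation, atol=1e-12)
            assert np.allclose(a.translation, b.translation, atol=1e-12)

    def test_rerun_is_byte_identical(self, tmp_path):
        fix = synth_tree(2, 3, seed=6, out_dir=tmp_path / "fix")
        run_tree(fix.tree, tmp_path / "o1", root_seed_frame=fix.root_seed_frame)
        run_tree(fix.tree, tmp_path / "o2", root_seed_frame=fix.root_seed_frame)
        files1 = sorted(p.relative_to(tmp_path / "o1")
                        for p in (tmp_path / "o1").rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(tmp_path / "o2")
                        for p in (tmp_path / "o2").rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (tmp_path / "o1" / rel).read_bytes() == \
                (tmp_path / "o2" / rel).read_bytes()
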