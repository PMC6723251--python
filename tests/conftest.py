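"""Shared fixtures: small synthetic structures built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from poltree.fixtures import EntryLayout, synth_pdb_entry
from poltree.pdbio import AtomRecord, StructureModel


def make_ca_model(coords, pdb_id="test", chain="A", resname="ALA",
                  title="TEST MODEL") -> StructureModel:
    """A minimal Cα-only model from a coordinate array."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    atoms = [
        AtomRecord(
            serial=i + 1, name="CA", altloc="", residue_name=resname,
            chain_id=chain, residue_seq=i + 1, insertion_code="",
            position=coords[i], occupancy=1.0, b_factor=10.0, element="C",
        )
        for i in range(len(coords))
    ]
    return StructureModel(pdb_id, title, atoms)


@pytest.fixture
def active_site_entry():
    """Entry with catalytic aspartates exactly at the anchor points."""
    return synth_pdb_entry(EntryLayout(), seed=0)


@pytest.fixture
def ion_entry():
    """Entry carrying 2 Mg + 1 Zn metals and one water."""
    layout = EntryLayout(
        ions=[("MG", "meA", (0, 0, 0)), ("MG", "meB", (0, 0, 0)),
              ("ZN", "meB'", (0, 0, 0))],
        waters=1,
    )
    return synth_pdb_entry(layout, seed=0)
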