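"""Execute a miniature alignment tree with orientation inheritance.

Builds a two-level synthetic tree (root set aligned on a 13-column core,
child set on 40 columns; the child is seeded by a non-seed member of the
root, like the open/closed pivot), runs it, and compares every output to the
generator's true common-frame coordinates.
"""

import tempfile
from pathlib import Path

from poltree.fixtures import synth_tree
from poltree.superpose import rmsd
from poltree.tree import run_tree

with tempfile.TemporaryDirectory() as tmp:
    work = Path(tmp)
    fix = synth_tree(levels=2, members_per_set=3, seed=7, out_dir=work / "fix")
    results = run_tree(fix.tree, work / "out", root_seed_frame=fix.root_seed_frame)

    for r in results:
        region = fix.tree.get(r.name).region
        cols = region.total_columns if region else "FULL"
        print(f"set {r.name}: {len(r.members)} members, region columns: {cols}, "
              f"seed anchor RMSD {r.seed_anchor_rmsd:.2e} A")
        for m in r.members:
            out = r.transforms[m.key].apply(r.traces[m.key].coords)
            err = rmsd(out, fix.ground_truth[m.key])
            print(f"  {m.label}: {err:.3f} A from true common frame "
                  f"(planted noise {fix.noise} A)")

    n_out = len(list((work / "out" / "_All_PDBs").glob("*.pdb")))
    print(f"\n_All_PDBs/ pools {n_out} reoriented structures.")
    print("Seed anchor RMSD ~1e-14 A means each set exactly kept the")
    print("orientation handed down by its parent; member errors near the")
    print("planted noise mean the whole tree shares one coordinate frame.")
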