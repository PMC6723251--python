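"""Ground-truth synthetic inputs for the superposition pipeline.

Real polymerase structures are bulky and curated; the generators here produce
miniature stand-ins with *known* answers so that every stage of the pipeline can
be verified against planted ground truth:

* Cα families related by known rigid transforms with position-dependent
  Gaussian noise and optional deletions — the statistical structure the
  maximum-likelihood model assumes (tight cores, divergent loops);
* single PDB entries with catalytic aspartate Cα atoms placed at the canonical
  common-frame anchor positions, optional nucleic-acid and decoy chains, and
  metal HETATM records at the ion-site centroids;
* miniature alignment trees (files + configuration + true common-frame
  coordinates) whose region sizes grow down the tree, emulating how aligned
  regions expand as structural similarity increases.

Geometry is idealised (α-helical Cα spirals with the canonical ~3.8 Å Cα–Cα
spacing) rather than physically realistic; every generator is a pure function
of its specification and seed, so regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from Bio.SeqUtils import seq3
from scipy.spatial.transform import Rotation

from .analysis import BASE_PAIR_ANCHOR, MOTIF_A_ANCHOR, MOTIF_C_ANCHOR, IonSiteModel
from .msa import MISSING, CorrespondenceTable
from .pdbio import (
    AtomRecord,
    CaTrace,
    RigidTransform,
    StructureModel,
    write_structure,
)
from .tree import AlignmentTreeConfig, load_tree

__all__ = [
    "FamilySpec",
    "SyntheticFamily",
    "EntryLayout",
    "TreeFixture",
    "ideal_helix",
    "folded_template",
    "random_transforms",
    "standard_family_spec",
    "transform_recovery_errors",
    "synth_family",
    "synth_pdb_entry",
    "synth_tree",
    "DD_ANCHOR_DISTANCE",
]

#: Distance between the motif A and motif C anchor points (Å).
DD_ANCHOR_DISTANCE = float(np.linalg.norm(MOTIF_A_ANCHOR - MOTIF_C_ANCHOR))

_AA = "ACDEFGHIKLMNPQRSTVWY"


def ideal_helix(n: int, center: bool = True) -> np.ndarray:
    """Cα positions of an ideal α-helix: rise 1.5 Å and 100° twist per residue,
    radius 2.3 Å.  Consecutive Cα–Cα distances are the canonical ≈3.8 Å."""
    if n < 1:
        raise ValueError("need at least one residue")
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    coords = np.column_stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i]
    )
    if center:
        coords -= coords.mean(0)
    return coords


def folded_template(n: int) -> np.ndarray:
    """A compact three-segment fold of helical Cα segments with distinct axis
    orientations, centred at the origin.

    A single straight helix is nearly a rod, which leaves rotation about its
    axis weakly determined; real polymerase domains extend in all directions.
    Splitting the trace into three mutually rotated helical segments gives the
    synthetic families comparable leverage about every rotation axis.
    """
    if n < 1:
        raise ValueError("need at least one residue")
    thirds = [n - 2 * (n // 3), n // 3, n // 3]
    # antiparallel bundle: helix axes alternate direction, packed ~10 A apart
    placements = [
        RigidTransform.about_axis((0, 0, 1), 0.0, (0.0, 0.0, 0.0)),
        RigidTransform.about_axis((1, 0, 0), 180.0, (10.0, 0.0, 0.0)),
        RigidTransform.about_axis((0, 0, 1), 0.0, (5.0, 8.7, 0.0)),
    ]
    segs = [
        placement.apply(ideal_helix(length))
        for length, placement in zip(thirds, placements)
        if length >= 1
    ]
    coords = np.vstack(segs)
    return coords - coords.mean(0)


def random_transforms(n: int, rng: np.random.Generator,
                      translation_range: float = 20.0) -> list[RigidTransform]:
    """Uniformly random proper rotations with uniform box translations."""
    Rs = Rotation.random(n, random_state=rng).as_matrix()
    ts = rng.uniform(-translation_range, translation_range, size=(n, 3))
    return [RigidTransform(Rs[i], ts[i]) for i in range(n)]


def _random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(_AA[k] for k in rng.integers(0, len(_AA), size=n))


@dataclass
class FamilySpec:
    """A family of Cα traces: template + per-position noise + planted transforms.

    ``sigma`` is either a scalar (uniform per-coordinate Gaussian noise, Å) or a
    per-position profile of length ``template_length``.  ``deletions`` are
    (member, start, length) spans removed from that member's trace.  The seed is
    mandatory: families are reproducible by construction.
    """

    n_members: int
    template_length: int = 60
    sigma: float | np.ndarray = 0.1
    transforms: list[RigidTransform] | None = None
    deletions: list[tuple[int, int, int]] = field(default_factory=list)
    seed: int = 0

    def sigma_profile(self) -> np.ndarray:
        s = np.asarray(self.sigma, dtype=float)
        if s.ndim == 0:
            s = np.full(self.template_length, float(s))
        if s.shape != (self.template_length,):
            raise ValueError("sigma profile length must equal template length")
        if np.any(s < 0):
            raise ValueError("negative noise sigma")
        return s

    def validate(self) -> None:
        if self.n_members < 2:
            raise ValueError("need at least 2 members")
        self.sigma_profile()
        for m, start, length in self.deletions:
            if not (0 <= m < self.n_members):
                raise ValueError(f"deletion names member {m} out of range")
            if not (0 <= start and start + length <= self.template_length):
                raise ValueError("deletion outside template")


@dataclass
class SyntheticFamily:
    """Generated traces plus the ground truth that produced them."""

    spec: FamilySpec
    template: np.ndarray                 # (L, 3), common frame
    sequence: str
    traces: list[CaTrace]                # member coordinates in their own frames
    transforms: list[RigidTransform]     # planted: original = T_i(template+noise)
    true_coords: list[np.ndarray]        # template+noise per member (common frame)
    kept_indices: list[np.ndarray]       # template positions present per member

    def correspondence(self) -> CorrespondenceTable:
        """Ground-truth correspondence (columns = template positions)."""
        L = self.spec.template_length
        n = len(self.traces)
        indices = np.full((n, L), MISSING, dtype=int)
        for i, kept in enumerate(self.kept_indices):
            indices[i, kept] = np.arange(len(kept))
        present = indices >= 0
        keep = present.sum(0) >= 2
        return CorrespondenceTable(
            members=[t.source for t in self.traces],
            indices=indices[:, keep],
            alignment_columns=np.nonzero(keep)[0],
            alignment_length=L,
        )


def synth_family(spec: FamilySpec) -> SyntheticFamily:
    """Generate a Cα family: member i = T_i(template + noise_i), deletions applied."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.template_length
    template = folded_template(L)
    sequence = _random_sequence(L, rng)
    sigma = spec.sigma_profile()
    transforms = spec.transforms or random_transforms(spec.n_members, rng)
    if len(transforms) != spec.n_members:
        raise ValueError("one planted transform required per member")

    deleted: dict[int, set[int]] = {}
    for m, start, length in spec.deletions:
        deleted.setdefault(m, set()).update(range(start, start + length))

    traces, true_coords, kept_list = [], [], []
    for i in range(spec.n_members):
        noise = rng.normal(0.0, 1.0, size=(L, 3)) * sigma[:, None]
        truth = template + noise
        kept = np.array(
            [j for j in range(L) if j not in deleted.get(i, set())], dtype=int
        )
        coords = transforms[i].apply(truth[kept])
        residues = [
            (int(j) + 1, "", seq3(sequence[j]).upper()) for j in kept
        ]
        traces.append(CaTrace(f"f{i:03d}", "A", residues, coords))
        true_coords.append(truth)
        kept_list.append(kept)

    return SyntheticFamily(
        spec=spec,
        template=template,
        sequence=sequence,
        traces=traces,
        transforms=list(transforms),
        true_coords=true_coords,
        kept_indices=kept_list,
    )


def standard_family_spec(seed: int, n_members: int = 20) -> FamilySpec:
    """The package's reference recovery conditions: 20 members, σ = 0.1 Å over
    the two 'core' bundle segments and σ = 1.5 Å over the middle 'loop'
    segment, random planted transforms."""
    sigma = np.full(60, 0.1)
    sigma[20:40] = 1.5
    return FamilySpec(n_members=n_members, template_length=60, sigma=sigma,
                      seed=seed)


def transform_recovery_errors(family: SyntheticFamily, result) -> tuple[np.ndarray, np.ndarray]:
    """Per-member rotation (deg) and translation (Å) recovery errors.

    A multiple superposition recovers the planted transforms only up to one
    global rigid gauge; it is estimated by fitting the template onto the
    recovered mean structure with the estimated precision weights.  The
    translation error is evaluated at the precision-weighted template centroid
    (the fit's centre of mass), the pivot about which rotation and translation
    components are naturally decoupled.
    """
    from .superpose import kabsch_fit

    w = 1.0 / result.column_variances
    cols = result.columns_used
    template = family.template[cols]
    gauge = kabsch_fit(template, result.mean_coords, w)
    centroid = (w[:, None] * template).sum(0) / w.sum()
    rot_err, trans_err = [], []
    for M, T in zip(result.member_transforms, family.transforms):
        E = gauge.inverse().compose(M.compose(T))  # identity for perfect recovery
        cosang = (np.trace(E.rotation) - 1.0) / 2.0
        rot_err.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        trans_err.append(float(np.linalg.norm(E.apply(centroid) - centroid)))
    return np.asarray(rot_err), np.asarray(trans_err)


# ---------------------------------------------------------------------------
# single-entry generator
# ---------------------------------------------------------------------------


@dataclass
class EntryLayout:
    """Layout of a synthetic PDB entry in the common superposed frame.

    The polymerase-like chain is a Cα helix near the base-pair anchor with two
    ASP residues whose Cα atoms sit at the motif C anchor and at ``dd`` Å from
    it along the direction of the motif A anchor (``dd=None`` puts both exactly
    at their anchors).  Optional extras: an RNA-like chain starting at
    ``rna_distance`` from the base-pair anchor, a decoy protein chain at
    ``second_protein_distance``, metal HETATMs at ion-site centroids plus
    offsets, and waters.
    """

    pdb_id: str = "synt"
    n_residues: int = 40
    dd: float | None = None
    asp_offset_a: Sequence[float] = (0.0, 0.0, 0.0)
    asp_offset_c: Sequence[float] = (0.0, 0.0, 0.0)
    use_asn: bool = False
    rna_distance: float | None = None
    rna_length: int = 4
    second_protein_distance: float | None = None
    ions: list[tuple[str, str, Sequence[float]]] = field(default_factory=list)
    #: each ion: (element, site in {"meA","meB","meB'"} or "custom", offset/position)
    waters: int = 0
    title: str = "SYNTHETIC POLYMERASE-LIKE ENTRY"


def synth_pdb_entry(
    layout: EntryLayout, path: str | Path | None = None, seed: int = 0
) -> StructureModel:
    """Build (and optionally write) a synthetic entry per the layout.

    Atom pairs closer than 0.5 Å are rejected as collisions.
    """
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    serial = 0

    def add(name, resname, chain, resseq, pos, kind="ATOM", element=None):
        nonlocal serial
        serial += 1
        atoms.append(
            AtomRecord(
                serial=serial,
                name=name,
                altloc="",
                residue_name=resname,
                chain_id=chain,
                residue_seq=resseq,
                insertion_code="",
                position=np.asarray(pos, dtype=float),
                occupancy=1.0,
                b_factor=10.0,
                element=element or name[0],
                record_kind=kind,
            )
        )

    # polymerase-like chain: helix along z through the base-pair anchor
    helix = ideal_helix(layout.n_residues) + BASE_PAIR_ANCHOR
    seq = _random_sequence(layout.n_residues, rng)
    for j in range(layout.n_residues):
        add("CA", seq3(seq[j]).upper(), "A", j + 1, helix[j], element="C")

    # catalytic aspartates
    asp_c = MOTIF_C_ANCHOR + np.asarray(layout.asp_offset_c, dtype=float)
    if layout.dd is None:
        asp_a = MOTIF_A_ANCHOR + np.asarray(layout.asp_offset_a, dtype=float)
    else:
        u = (MOTIF_A_ANCHOR - MOTIF_C_ANCHOR) / DD_ANCHOR_DISTANCE
        asp_a = asp_c + layout.dd * u + np.asarray(layout.asp_offset_a, dtype=float)
    resname = "ASN" if layout.use_asn else "ASP"
    add("CA", resname, "A", layout.n_residues + 10, asp_a, element="C")
    add("CA", resname, "A", layout.n_residues + 20, asp_c, element="C")

    # RNA-like chain walking outward from the base-pair anchor
    if layout.rna_distance is not None:
        direction = np.array([0.0, 1.0, 0.0])
        for j in range(layout.rna_length):
            pos = BASE_PAIR_ANCHOR + (layout.rna_distance + 5.0 * j) * direction
            add("P", "U", "R", j + 1, pos, element="P")

    # decoy second protein chain
    if layout.second_protein_distance is not None:
        decoy = ideal_helix(10) + BASE_PAIR_ANCHOR + np.array(
            [layout.second_protein_distance, 0.0, 0.0]
        )
        for j in range(10):
            add("CA", "GLY", "B", j + 1, decoy[j], element="C")

    # metal ions and waters
    site_model = IonSiteModel()
    site_pos = dict(site_model.centroids())
    for k, (element, site, offset) in enumerate(layout.ions):
        if site == "custom":
            pos = np.asarray(offset, dtype=float)
        else:
            pos = site_pos[site] + np.asarray(offset, dtype=float)
        add(element.upper(), element.upper(), "I", k + 1, pos,
            kind="HETATM", element=element.upper())
    for k in range(layout.waters):
        pos = BASE_PAIR_ANCHOR + np.array([6.0 + 2.0 * k, 6.0, 6.0])
        add("O", "HOH", "W", k + 1, pos, kind="HETATM", element="O")

    # collision check
    pos = np.array([a.position for a in atoms])
    if len(pos) > 1:
        d2 = ((pos[:, None] - pos[None]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        if d2.min() < 0.5 ** 2:
            i, j = np.unravel_index(int(d2.argmin()), d2.shape)
            raise ValueError(
                f"colliding atoms {i} and {j} at {np.sqrt(d2.min()):.2f} A"
            )

    model = StructureModel(layout.pdb_id, layout.title, atoms)
    if path is not None:
        write_structure(model, path)
    return model


# ---------------------------------------------------------------------------
# miniature alignment tree
# ---------------------------------------------------------------------------


@dataclass
class TreeFixture:
    """A generated tree: input files, configuration, and true common frames."""

    config_path: Path
    tree: AlignmentTreeConfig
    ground_truth: dict[tuple[str, str], np.ndarray]  # (pdb_id, chain) -> (L, 3)
    root_seed_frame: np.ndarray
    noise: float


def synth_tree(
    levels: int,
    members_per_set: int,
    seed: int,
    out_dir: str | Path,
    noise: float = 0.05,
    template_length: int = 60,
) -> TreeFixture:
    """Generate a linear chain of superposition sets with planted frames.

    The root set aligns a short shared core (13 columns); deeper sets use
    progressively larger regions (40 columns, then the full trace), emulating
    how aligned regions grow with structural similarity.  Each child is seeded
    by its parent's second member, so orientation handoff through a non-seed
    member is exercised.  True common-frame coordinates are returned for every
    member, along with the root seed's frame.
    """
    if levels < 1:
        raise ValueError("need at least one level")
    if members_per_set < 2:
        raise ValueError("need at least two members per set")
    out_dir = Path(out_dir)
    input_dir = out_dir / "input"
    input_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    template = folded_template(template_length)
    sequence = _random_sequence(template_length, rng)

    # root region: 13 columns in short stretches near the ends of all three
    # bundle segments, so the small root fit has leverage about every axis;
    # mid level: 40 contiguous columns; deeper levels: full traces.
    core13 = {
        "core_A": [[1, 2], [19, 20]],
        "core_B": [[21, 22], [39, 40]],
        "core_C": [[41, 42], [58, 60]],
    }
    mid40 = {"core": [[6, 45]]}
    region_for_level = lambda lv: core13 if lv == 1 else (mid40 if lv == 2 else "FULL")  # noqa: E731

    ground_truth: dict[tuple[str, str], np.ndarray] = {}
    file_coords: dict[str, np.ndarray] = {}
    entry_counter = 0

    def make_entry() -> tuple[str, np.ndarray]:
        nonlocal entry_counter
        entry_counter += 1
        pdb_id = f"t{entry_counter:03d}"
        eps = rng.normal(0.0, noise, size=(template_length, 3))
        truth = template + eps
        t = random_transforms(1, rng, translation_range=30.0)[0]
        coords = t.apply(truth)
        file_coords[pdb_id] = np.round(coords, 3)  # what the PDB file will carry
        residues = [(j + 1, "", seq3(sequence[j]).upper()) for j in range(template_length)]
        trace = CaTrace(pdb_id, "A", residues, coords)
        atoms = [
            AtomRecord(
                serial=j + 1, name="CA", altloc="",
                residue_name=residues[j][2], chain_id="A", residue_seq=j + 1,
                insertion_code="", position=coords[j], occupancy=1.0,
                b_factor=10.0, element="C", record_kind="ATOM",
            )
            for j in range(template_length)
        ]
        model = StructureModel(pdb_id, f"SYNTHETIC TREE ENTRY {pdb_id.upper()}", atoms)
        write_structure(model, input_dir / f"{pdb_id}.pdb")
        ground_truth[(pdb_id, "A")] = truth
        return pdb_id, trace.coords

    sets_yaml = []
    prev_members: list[str] = []
    for lv in range(1, levels + 1):
        name = f"st{lv:02d}"
        members: list[str] = []
        if lv == 1:
            members = [make_entry()[0] for _ in range(members_per_set)]
            seed_id = members[0]
            parent = "ROOT"
        else:
            seed_id = prev_members[1 if len(prev_members) > 1 else 0]
            members = [seed_id] + [make_entry()[0] for _ in range(members_per_set - 1)]
            parent = f"st{lv - 1:02d}"
        sets_yaml.append(
            {
                "name": name,
                "parent": parent,
                "seed": {"pdb": seed_id, "chain": "A"},
                "alignment": "auto",
                "region": region_for_level(lv),
                "members": [
                    {"pdb": m, "chain": "A", "file": f"input/{m}.pdb"}
                    for m in members
                ],
            }
        )
        prev_members = members

    config_path = out_dir / "tree.yaml"
    config_path.write_text(yaml.safe_dump({"sets": sets_yaml}, sort_keys=False))
    tree = load_tree(config_path)
    root_seed = tree.get(tree.order[0]).seed

    # The root frame must be a rigid image of the coordinates actually stored
    # in the seed's file (which are rounded to PDB precision), or exact frame
    # retention would be impossible; fit the file coordinates onto the true
    # template frame and use that image as the inherited root orientation.
    from .superpose import kabsch_fit

    seed_file = file_coords[root_seed[0]]
    g0 = kabsch_fit(seed_file, ground_truth[(root_seed[0], root_seed[1])])
    root_seed_frame = g0.apply(seed_file)

    return TreeFixture(
        config_path=config_path,
        tree=tree,
        ground_truth=ground_truth,
        root_seed_frame=root_seed_frame,
        noise=noise,
    )
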