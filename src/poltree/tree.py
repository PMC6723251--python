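"""Hierarchical alignment-tree execution with orientation inheritance.

A superposition *set* is one multiple structure alignment: a named group of
member chains, an equivalence source (automatic MSA or a curated alignment
file), and a column region (conserved motifs for divergent families, FULL for
close homologues).  Sets form a tree: each child inherits its orientation from
its parent through a shared *seed* structure — after the child's own
maximum-likelihood superposition, the whole family is rigidly re-anchored so
that the seed exactly retains the coordinates it was given by the parent set.
Executing the tree root-to-leaves therefore places every member of every set
into one common coordinate space, while each set's internal fit is driven only
by its own, most-appropriate region.

Special "pivot" sets (e.g. an open/closed conformational bridge) need no extra
machinery: they are ordinary FULL-region sets whose children simply name a
different member than the parent's seed as their own seed.

Outputs replicate a fixed directory layout per set: ``<set>/pdb/`` with one
reoriented full-entry file per polymerase chain (``<pdbid>_<chain>-<set>.pdb``,
uppercase basenames for representatives), ``<set>/super/`` with the average
structure and per-column variances, a ``_readme.txt`` inventory, and a
top-level ``_All_PDBs/`` pooling every output file.

Frames are inherited through in-memory transforms, not by re-reading written
files, so seed anchoring is exact to numerical precision rather than to the
0.001 Å precision of the PDB format.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, replace as dc_replace
from pathlib import Path

import numpy as np
import yaml

from .msa import (
    MotifRegionSet,
    SequenceAlignment,
    build_correspondence,
    parse_alignment,
    progressive_msa,
    restrict_regions,
)
from .pdbio import (
    CaTrace,
    RigidTransform,
    StructureModel,
    apply_transform,
    extract_ca_trace,
    output_filename,
    read_structure,
    write_structure,
)
from .superpose import (
    MLOptions,
    SuperpositionResult,
    kabsch_fit,
    ml_superpose,
    mean_structure,
    rmsd,
    write_variances,
)

__all__ = [
    "MemberRef",
    "AlignmentSetConfig",
    "AlignmentTreeConfig",
    "SetResult",
    "TreeConfigError",
    "SetRunError",
    "load_tree",
    "anchor_to_parent",
    "run_set",
    "run_tree",
    "write_set_readme",
]

logger = logging.getLogger("poltree")

ROOT = "ROOT"


class TreeConfigError(ValueError):
    """Invalid alignment-tree configuration."""


class SetRunError(RuntimeError):
    """Fatal failure while executing a superposition set."""


@dataclass(frozen=True)
class MemberRef:
    """One member chain of a set: PDB entry id, chain, and source file."""

    pdb_id: str
    chain: str
    path: Path
    representative: str | None = None  # uppercase basename when this member seeds children

    @property
    def key(self) -> tuple[str, str]:
        return (self.pdb_id.lower(), self.chain)

    @property
    def label(self) -> str:
        return f"{self.pdb_id}_{self.chain}"


@dataclass
class AlignmentSetConfig:
    """Configuration of one superposition set."""

    name: str
    parent: str
    seed: tuple[str, str]  # (pdb_id, chain)
    members: list[MemberRef]
    region: MotifRegionSet | None  # None means FULL
    alignment_source: Path | None  # None means automatic MSA
    prefix: str | None = None

    @property
    def dirname(self) -> str:
        return f"{self.prefix}-{self.name}" if self.prefix else self.name

    @property
    def seed_key(self) -> tuple[str, str]:
        return (self.seed[0].lower(), self.seed[1])


@dataclass
class AlignmentTreeConfig:
    """Validated tree of superposition sets, with a topological execution order."""

    sets: list[AlignmentSetConfig]
    order: list[str]

    def get(self, name: str) -> AlignmentSetConfig:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass
class SetResult:
    """Everything produced by executing one set."""

    name: str
    config: AlignmentSetConfig
    members: list[MemberRef]                      # successfully processed
    transforms: dict[tuple[str, str], RigidTransform]  # final (anchored) frames
    superposition: SuperpositionResult            # in the final anchored frame
    traces: dict[tuple[str, str], CaTrace]
    used_residue_indices: dict[tuple[str, str], np.ndarray]
    output_paths: list[Path]
    skipped: list[tuple[MemberRef, str]]
    readme_text: str
    seed_anchor_rmsd: float


# ---------------------------------------------------------------------------
# configuration loading
# ---------------------------------------------------------------------------


def _parse_member(raw: dict, base: Path) -> MemberRef:
    try:
        pdb = str(raw["pdb"])
        chain = str(raw["chain"])
    except KeyError as exc:
        raise TreeConfigError(f"member entry missing field {exc}") from exc
    file = raw.get("file", f"{pdb}.pdb")
    rep = raw.get("representative")
    return MemberRef(pdb, chain, (base / file), str(rep) if rep else None)


def load_tree(path: str | Path) -> AlignmentTreeConfig:
    """Load and validate a tree configuration (YAML, one document per tree).

    Validation: unique 4-letter set names, a single ROOT, acyclic parent edges,
    every seed among its own set's members, and every child's seed present in
    its parent (directly or as a designated representative).
    """
    path = Path(path)
    base = path.parent
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise TreeConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict) or "sets" not in doc:
        raise TreeConfigError(f"{path}: expected a mapping with a 'sets' list")

    sets: list[AlignmentSetConfig] = []
    for raw in doc["sets"]:
        name = str(raw.get("name", ""))
        if len(name) != 4 or not name.isalnum():
            raise TreeConfigError(f"set name must be 4 alphanumeric characters: {name!r}")
        members = [_parse_member(m, base) for m in raw.get("members", [])]
        if not members:
            raise TreeConfigError(f"set {name}: no members")
        seed_raw = raw.get("seed")
        if not seed_raw:
            raise TreeConfigError(f"set {name}: missing seed")
        seed = (str(seed_raw["pdb"]), str(seed_raw["chain"]))
        region_raw = raw.get("region", "FULL")
        if isinstance(region_raw, str) and region_raw.upper() == "FULL":
            region = None
        elif isinstance(region_raw, dict):
            region = MotifRegionSet.from_config(region_raw)
        else:
            raise TreeConfigError(f"set {name}: bad region specification")
        aln_raw = raw.get("alignment", "auto")
        alignment = None if str(aln_raw).lower() == "auto" else (base / str(aln_raw))
        sets.append(
            AlignmentSetConfig(
                name=name,
                parent=str(raw.get("parent", ROOT)),
                seed=seed,
                members=members,
                region=region,
                alignment_source=alignment,
                prefix=str(raw["prefix"]) if raw.get("prefix") is not None else None,
            )
        )

    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        dup = next(n for n in names if names.count(n) > 1)
        raise TreeConfigError(f"duplicate set name: {dup}")
    by_name = {s.name: s for s in sets}

    roots = [s for s in sets if s.parent == ROOT]
    if len(roots) != 1:
        raise TreeConfigError(f"exactly one ROOT set required, found {len(roots)}")
    for s in sets:
        if s.parent != ROOT and s.parent not in by_name:
            raise TreeConfigError(f"set {s.name}: unknown parent {s.parent!r}")
        member_keys = {m.key for m in s.members}
        if s.seed_key not in member_keys:
            raise TreeConfigError(f"set {s.name}: seed {s.seed} not among members")
        if s.parent != ROOT:
            parent = by_name[s.parent]
            pkeys = {m.key for m in parent.members}
            reps = {
                (m.representative.lower(), m.chain)
                for m in parent.members
                if m.representative
            }
            if s.seed_key not in pkeys and s.seed_key not in reps:
                raise TreeConfigError(
                    f"set {s.name}: seed {s.seed} does not appear in parent "
                    f"{s.parent} (as member or representative)"
                )

    # Kahn topological order, stable in input order; leftovers indicate a cycle
    order: list[str] = []
    placed: set[str] = set()
    remaining = list(sets)
    while remaining:
        progressed = False
        for s in list(remaining):
            if s.parent == ROOT or s.parent in placed:
                order.append(s.name)
                placed.add(s.name)
                remaining.remove(s)
                progressed = True
        if not progressed:
            cyc = ", ".join(s.name for s in remaining)
            raise TreeConfigError(f"cycle in tree configuration involving: {cyc}")

    return AlignmentTreeConfig(sets=sets, order=order)


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------


def anchor_to_parent(
    result: SuperpositionResult,
    seed_index: int,
    seed_parent_coords: np.ndarray,
) -> tuple[list[RigidTransform], RigidTransform]:
    """Re-anchor a superposition so the seed retains its parent-frame coordinates.

    Computes the rigid transform G mapping the seed's fitted (ML-frame) region
    coordinates onto ``seed_parent_coords`` by unweighted Kabsch — an exact
    match exists because both are rigid images of the same atoms — and returns
    ``G ∘ T_i`` for every member together with G.  Relative geometry among
    members is unchanged.
    """
    fitted = result.member_fitted(seed_index)
    parent = np.asarray(seed_parent_coords, dtype=float).reshape(-1, 3)
    if len(parent) != len(fitted):
        raise ValueError(
            f"seed column mismatch: fitted {len(fitted)} vs parent {len(parent)}"
        )
    if len(parent) < 3:
        raise ValueError("fewer than 3 shared columns for anchoring")
    G = kabsch_fit(fitted, parent)
    return [G.compose(t) for t in result.member_transforms], G


def _curated_rows(
    aln: SequenceAlignment, members: list[MemberRef]
) -> SequenceAlignment:
    """Select the curated-alignment rows belonging to the processed members."""
    by_name = {n: r for n, r in zip(aln.names, aln.rows)}
    names, rows = [], []
    for m in members:
        row = by_name.get(m.label)
        if row is None and m.representative:
            row = by_name.get(m.representative)
        if row is None:
            raise SetRunError(
                f"curated alignment has no row named {m.label!r}"
            )
        names.append(m.label)
        rows.append(row)
    return SequenceAlignment(names, rows)


def run_set(
    config: AlignmentSetConfig,
    parent_result: SetResult | None = None,
    root_seed_frame: np.ndarray | None = None,
    out_root: str | Path = ".",
    strict: bool = False,
    ml_options: MLOptions | None = None,
) -> SetResult:
    """Execute one superposition set and write its output directory.

    Pipeline: read each member entry and extract the member chain's Cα trace;
    obtain residue equivalences (curated file or automatic MSA); restrict to the
    configured region (FULL skips restriction); run the maximum-likelihood
    superposition initialised on the seed; re-anchor the family onto the seed's
    parent-frame coordinates; apply the final transform to each *complete*
    original entry (one output per polymerase chain) and write the set
    directory.

    Unreadable non-seed members are skipped with a logged warning (escalated to
    an error under ``strict``); an unreadable seed is fatal.
    """
    out_root = Path(out_root)
    loaded: list[tuple[MemberRef, StructureModel, CaTrace]] = []
    skipped: list[tuple[MemberRef, str]] = []
    for m in config.members:
        try:
            model = read_structure(m.path)
            trace = extract_ca_trace(model, m.chain)
        except Exception as exc:  # noqa: BLE001 - skip policy is per-member
            if m.key == config.seed_key:
                raise SetRunError(f"set {config.name}: seed member failed: {exc}") from exc
            if strict:
                raise SetRunError(f"set {config.name}: member {m.label} failed: {exc}") from exc
            logger.warning("set %s: skipping member %s: %s", config.name, m.label, exc)
            skipped.append((m, str(exc)))
            continue
        loaded.append((m, model, trace))

    if len(loaded) < 2:
        raise SetRunError(f"set {config.name}: fewer than 2 readable members")

    members = [m for m, _, _ in loaded]
    traces = [t for _, _, t in loaded]
    if config.alignment_source is not None:
        aln = _curated_rows(parse_alignment(config.alignment_source), members)
    else:
        aln = progressive_msa([t.sequence for t in traces], [m.label for m in members])

    table = build_correspondence(aln, traces)
    if config.region is not None:
        table = restrict_regions(table, config.region)

    seed_idx = next(i for i, m in enumerate(members) if m.key == config.seed_key)
    opts = ml_options or MLOptions()
    opts = dc_replace(opts, init_member=seed_idx)
    result = ml_superpose(table, [t.coords for t in traces], opts)

    # residue indices actually used per member (columns kept by the ML stage)
    kept_in_table = np.isin(table.alignment_columns, result.columns_used)
    used_idx: dict[tuple[str, str], np.ndarray] = {}
    for i, m in enumerate(members):
        idx = table.indices[i][kept_in_table]
        used_idx[m.key] = idx[idx >= 0]

    # --- orientation inheritance
    seed_member = members[seed_idx]
    seed_trace = traces[seed_idx]
    seed_cols = used_idx[seed_member.key]
    seed_orig = seed_trace.coords[seed_cols]
    if parent_result is not None:
        parent_t = parent_result.transforms.get(seed_member.key)
        if parent_t is None:
            raise SetRunError(
                f"set {config.name}: seed {seed_member.label} has no frame in "
                f"parent {config.parent}"
            )
        seed_parent_coords = parent_t.apply(seed_orig)
    elif root_seed_frame is not None:
        frame = np.asarray(root_seed_frame, dtype=float).reshape(-1, 3)
        if len(frame) != len(seed_trace):
            raise SetRunError(
                f"set {config.name}: root frame has {len(frame)} positions but the "
                f"seed trace has {len(seed_trace)}"
            )
        seed_parent_coords = frame[seed_cols]
    else:
        seed_parent_coords = seed_orig  # keep the seed's own input orientation

    final_transforms, G = anchor_to_parent(result, seed_idx, seed_parent_coords)
    anchored = dc_replace(
        result,
        member_transforms=final_transforms,
        mean_coords=G.apply(result.mean_coords),
        fitted_coords=np.where(
            result.present[:, :, None], G.apply(result.fitted_coords.reshape(-1, 3)).reshape(result.fitted_coords.shape), np.nan
        ),
    )
    seed_anchor = rmsd(anchored.member_fitted(seed_idx), seed_parent_coords)

    # --- outputs
    set_dir = out_root / config.dirname
    pdb_dir = set_dir / "pdb"
    super_dir = set_dir / "super"
    pdb_dir.mkdir(parents=True, exist_ok=True)
    super_dir.mkdir(parents=True, exist_ok=True)

    transforms: dict[tuple[str, str], RigidTransform] = {}
    output_paths: list[Path] = []
    for i, (m, model, _) in enumerate(loaded):
        t = final_transforms[i]
        transforms[m.key] = t
        moved = apply_transform(model, t)
        fname = output_filename(m.pdb_id, m.chain, config.name)
        out = write_structure(moved, pdb_dir / fname)
        output_paths.append(out)
        if m.representative:
            rep_title = (
                f"{moved.title} [REPRESENTATIVE {m.representative.upper()} "
                f"FROM PDB {m.pdb_id.upper()} CHAIN {m.chain}]"
            ).strip()
            rep_model = StructureModel(moved.pdb_id, rep_title, moved.atoms)
            rep_name = output_filename(m.representative, m.chain, config.name,
                                       representative=True)
            output_paths.append(write_structure(rep_model, pdb_dir / rep_name))

    write_structure(mean_structure(anchored), super_dir / "theseus_ave.pdb")
    write_variances(anchored, super_dir / "theseus_variances.txt")

    res = SetResult(
        name=config.name,
        config=config,
        members=members,
        transforms=transforms,
        superposition=anchored,
        traces={m.key: t for m, _, t in loaded},
        used_residue_indices=used_idx,
        output_paths=output_paths,
        skipped=skipped,
        readme_text="",
        seed_anchor_rmsd=seed_anchor,
    )
    res.readme_text = _readme_text(res, {m.key: mod.title for m, mod, _ in loaded})
    (set_dir / "_readme.txt").write_text(res.readme_text)
    return res


def _ranges(residue_seqs: list[int]) -> str:
    """Compress an increasing residue-number list into 'a-b, c-d' range text."""
    if not residue_seqs:
        return "none"
    parts = []
    start = prev = residue_seqs[0]
    for r in residue_seqs[1:]:
        if r == prev + 1:
            prev = r
            continue
        parts.append(f"{start}-{prev}" if prev != start else f"{start}")
        start = prev = r
    parts.append(f"{start}-{prev}" if prev != start else f"{start}")
    return ", ".join(parts)


def _readme_text(result: SetResult, titles: dict[tuple[str, str], str]) -> str:
    cfg = result.config
    lines = [
        f"Superposition set: {cfg.name} (parent: {cfg.parent})",
        f"Alignment source: "
        + (str(cfg.alignment_source) if cfg.alignment_source else "automatic MSA"),
        f"Columns used for superposition: {len(result.superposition.columns_used)}",
        "",
    ]
    for m in result.members:
        trace = result.traces[m.key]
        used = result.used_residue_indices[m.key]
        seqs = [trace.residues[k][0] for k in used]
        lines.append(output_filename(m.pdb_id, m.chain, cfg.name))
        lines.append(f"  TITLE: {titles.get(m.key, '')}")
        lines.append(
            f"  Residues used (chain {m.chain}): {_ranges(seqs)}  ({len(used)} atoms)"
        )
        lines.append("")
    for m, reason in result.skipped:
        lines.append(f"SKIPPED {m.label}: {reason}")
        lines.append("")
    return "\n".join(lines).rstrip() + "\n"


def write_set_readme(result: SetResult, path: str | Path) -> Path:
    """Write the set inventory: one block per member with TITLE, residue ranges
    and atom count used; skipped members are listed with their reason."""
    path = Path(path)
    path.write_text(result.readme_text)
    return path


def run_tree(
    tree: AlignmentTreeConfig,
    out_root: str | Path,
    root_seed_frame: np.ndarray | None = None,
    strict: bool = False,
    ml_options: MLOptions | None = None,
) -> list[SetResult]:
    """Execute every set in topological order and pool outputs in ``_All_PDBs/``.

    Each child consumes its seed's frame from its parent's in-memory result.
    ``root_seed_frame`` optionally fixes the root seed's full-trace coordinates
    in a caller-chosen frame; by default the root seed keeps its input
    orientation.  Fatal errors name the failing set.
    """
    out_root = Path(out_root)
    results: dict[str, SetResult] = {}
    ordered: list[SetResult] = []
    for name in tree.order:
        cfg = tree.get(name)
        parent_result = results.get(cfg.parent)
        res = run_set(
            cfg,
            parent_result=parent_result,
            root_seed_frame=root_seed_frame if parent_result is None else None,
            out_root=out_root,
            strict=strict,
            ml_options=ml_options,
        )
        logger.info(
            "set %s: %d members, %d columns, seed anchor RMSD %.2e A",
            name, len(res.members), len(res.superposition.columns_used),
            res.seed_anchor_rmsd,
        )
        results[name] = res
        ordered.append(res)

    all_dir = out_root / "_All_PDBs"
    all_dir.mkdir(parents=True, exist_ok=True)
    for res in ordered:
        for p in res.output_paths:
            shutil.copyfile(p, all_dir / p.name)
    return ordered
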