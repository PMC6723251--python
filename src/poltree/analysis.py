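"""Spatial analyses over superposed structures.

Because every file produced by the alignment tree lives in one common
coordinate frame, fixed points in that frame ("pseudoatom anchors") select the
same functional location in every structure.  Three anchors are central:

* the motif A catalytic aspartate Cα, near (3.5, −17.0, −11.5) Å;
* the motif C catalytic aspartate Cα (first Asp of the GDD motif), near
  (10.0, −16.3, −13.8) Å;
* the centre of the nascent base pair in a positive-strand RdRP active site,
  near (14.5, −4.5, −15.5) Å.

On these anchors the module builds: radius selections with optional by-chain
closure ("expand" semantics, closed boundary); catalytic-aspartate location
(2.5 Å tolerance for motif A, whose Cα moves between open and closed active
sites; 2.0 Å for motif C); the DD distance — the Cα–Cα distance between the two
catalytic aspartates, a scalar readout of active-site open/closed conformation —
surveyed over whole file collections with histogram and per-class summaries;
monomer trimming; and metal-ion pooling with nearest-centroid assignment to the
meA / meB / meB′ binding sites.

All distances are computed in double precision and reported to 2 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .pdbio import (
    DEFAULT_METALS,
    AtomRecord,
    IonRecord,
    StructureModel,
    extract_metal_ions,
    format_atom_line,
    read_structure,
)

__all__ = [
    "AnchorPoint",
    "DDRecord",
    "DDSurvey",
    "IonSiteModel",
    "LabeledIon",
    "NoActiveSiteError",
    "MOTIF_A_ANCHOR",
    "MOTIF_C_ANCHOR",
    "BASE_PAIR_ANCHOR",
    "select_within",
    "locate_catalytic_aspartates",
    "dd_distance",
    "survey_dd",
    "trim_to_monomer",
    "pool_ions",
    "assign_ion_sites",
]

MOTIF_A_ANCHOR = np.array([3.5, -17.0, -11.5])
MOTIF_C_ANCHOR = np.array([10.0, -16.3, -13.8])
BASE_PAIR_ANCHOR = np.array([14.5, -4.5, -15.5])

MOTIF_A_RADIUS = 2.5   # accommodates motif A movement between open/closed states
MOTIF_C_RADIUS = 2.0


class NoActiveSiteError(ValueError):
    """No qualifying catalytic aspartate near an anchor point."""


@dataclass(frozen=True)
class AnchorPoint:
    """A fixed position in the common frame with a selection radius."""

    label: str
    position: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )
        if self.radius <= 0:
            raise ValueError("anchor radius must be positive")


@dataclass(frozen=True)
class DDRecord:
    """DD distance measured in one superposed file."""

    source_file: str
    set_label: str
    polymerase_class: str
    motif_a_residue: tuple[str, int, str]  # (chain, residue_seq, insertion code)
    motif_c_residue: tuple[str, int, str]
    dd: float

    def __post_init__(self) -> None:
        if not self.dd > 0:
            raise ValueError("DD distance must be positive")


@dataclass
class DDSurvey:
    """DD records, skipped files, histogram, and per-class summaries."""

    records: pd.DataFrame
    skipped: list[tuple[str, str]]
    bin_edges: np.ndarray
    counts: np.ndarray
    class_summary: pd.DataFrame


@dataclass(frozen=True)
class IonSiteModel:
    """Nearest-centroid model of the three active-site metal positions.

    The centroids ship as package defaults estimated from superposed synthetic
    active sites (meA between the aspartates and the NTP, meB beside the motif A
    aspartate, meB′ offset outward from the active site) and are explicitly
    user-overridable; ions farther than ``cutoff`` from every centroid are
    labeled OTHER.
    """

    me_a: np.ndarray = field(default_factory=lambda: np.array([7.0, -14.5, -15.5]))
    me_b: np.ndarray = field(default_factory=lambda: np.array([4.5, -18.0, -14.0]))
    me_b_prime: np.ndarray = field(default_factory=lambda: np.array([0.5, -20.5, -12.0]))
    cutoff: float = 3.0

    def __post_init__(self) -> None:
        for name in ("me_a", "me_b", "me_b_prime"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float).reshape(3)
            )
        cents = self.centroids()
        for i in range(3):
            for j in range(i + 1, 3):
                if np.allclose(cents[i][1], cents[j][1]):
                    raise ValueError("ion site centroids must be pairwise distinct")

    def centroids(self) -> list[tuple[str, np.ndarray]]:
        return [("meA", self.me_a), ("meB", self.me_b), ("meB'", self.me_b_prime)]


@dataclass(frozen=True)
class LabeledIon:
    ion: IonRecord
    site: str       # meA | meB | meB' | OTHER
    distance: float


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def select_within(
    model: StructureModel,
    anchor: AnchorPoint,
    predicate: Callable[[AtomRecord], bool] | None = None,
    by_chain: bool = False,
) -> list[int]:
    """Indices of atoms within ``anchor.radius`` of the anchor (closed boundary).

    ``predicate`` further filters candidate atoms.  With ``by_chain=True`` the
    selection closes over chains: all atoms of any chain with at least one
    selected atom are returned.
    """
    pos = np.array([a.position for a in model.atoms], dtype=float)
    if len(pos) == 0:
        return []
    dist = np.linalg.norm(pos - anchor.position, axis=1)
    hit = dist <= anchor.radius
    if predicate is not None:
        hit &= np.array([predicate(a) for a in model.atoms], dtype=bool)
    idx = np.nonzero(hit)[0]
    if not by_chain:
        return idx.tolist()
    chains = {model.atoms[i].chain_id for i in idx}
    return [i for i, a in enumerate(model.atoms) if a.chain_id in chains]


def _nearest_asp_ca(
    model: StructureModel, anchor: AnchorPoint
) -> tuple[AtomRecord, float]:
    is_asp_ca = lambda a: (  # noqa: E731
        a.record_kind == "ATOM" and a.residue_name == "ASP" and a.name == "CA"
    )
    idx = select_within(model, anchor, predicate=is_asp_ca)
    if not idx:
        raise NoActiveSiteError(
            f"no ASP CA within {anchor.radius} A of anchor {anchor.label} "
            f"at {tuple(anchor.position)}"
        )
    best = min(
        idx, key=lambda i: float(np.linalg.norm(model.atoms[i].position - anchor.position))
    )
    return model.atoms[best], float(
        np.linalg.norm(model.atoms[best].position - anchor.position)
    )


def locate_catalytic_aspartates(
    model: StructureModel,
) -> tuple[AtomRecord, AtomRecord]:
    """The motif A and motif C catalytic aspartate Cα atoms.

    Requires the model to be in the common superposed frame: the motif A Asp Cα
    must lie within 2.5 Å of the motif A anchor and the motif C Asp Cα within
    2.0 Å of the motif C anchor; the nearest qualifying aspartate wins when
    several are in range.
    """
    asp_a, _ = _nearest_asp_ca(
        model, AnchorPoint("PolAspA", MOTIF_A_ANCHOR, MOTIF_A_RADIUS)
    )
    asp_c, _ = _nearest_asp_ca(
        model, AnchorPoint("PolAspC", MOTIF_C_ANCHOR, MOTIF_C_RADIUS)
    )
    return asp_a, asp_c


def dd_distance(model: StructureModel) -> float:
    """DD: the Cα–Cα distance (Å) between the motif A and C catalytic aspartates."""
    asp_a, asp_c = locate_catalytic_aspartates(model)
    return float(np.linalg.norm(asp_a.position - asp_c.position))


def survey_dd(
    paths: Sequence[str | Path],
    labels: dict[str, str] | None = None,
    bin_width: float = 0.1,
    bin_range: tuple[float, float] = (5.0, 9.0),
) -> DDSurvey:
    """Measure DD in every file; histogram plus per-class summaries.

    Files without a qualifying active site are listed under ``skipped`` with the
    reason rather than failing the survey.  ``labels`` maps file names to
    polymerase classes (e.g. RdRP/RdDP/DdRP/DdDP) for the per-class breakdown.
    """
    labels = labels or {}
    rows = []
    skipped: list[tuple[str, str]] = []
    for p in paths:
        p = Path(p)
        try:
            model = read_structure(p)
            asp_a, asp_c = locate_catalytic_aspartates(model)
            dd = float(np.linalg.norm(asp_a.position - asp_c.position))
            rec = DDRecord(
                source_file=p.name,
                set_label=p.stem.split("-")[-1] if "-" in p.stem else "",
                polymerase_class=labels.get(p.name, "unlabeled"),
                motif_a_residue=(asp_a.chain_id, asp_a.residue_seq, asp_a.insertion_code),
                motif_c_residue=(asp_c.chain_id, asp_c.residue_seq, asp_c.insertion_code),
                dd=round(dd, 2),
            )
            rows.append(
                {
                    "source_file": rec.source_file,
                    "set_label": rec.set_label,
                    "class": rec.polymerase_class,
                    "motif_a_chain": rec.motif_a_residue[0],
                    "motif_a_resseq": rec.motif_a_residue[1],
                    "motif_c_chain": rec.motif_c_residue[0],
                    "motif_c_resseq": rec.motif_c_residue[1],
                    "dd": rec.dd,
                }
            )
        except Exception as exc:  # noqa: BLE001 - per-file skip policy
            skipped.append((p.name, str(exc)))

    records = pd.DataFrame(
        rows,
        columns=[
            "source_file", "set_label", "class", "motif_a_chain", "motif_a_resseq",
            "motif_c_chain", "motif_c_resseq", "dd",
        ],
    )
    lo, hi = bin_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(records["dd"].to_numpy(dtype=float), bins=edges) if len(records) else (
        np.zeros(len(edges) - 1, dtype=int), edges,
    )
    if len(records):
        summary = (
            records.groupby("class")["dd"]
            .agg(["min", "max", "mean", "count"])
            .rename(columns={"count": "n"})
            .reset_index()
        )
    else:
        summary = pd.DataFrame(columns=["class", "min", "max", "mean", "n"])
    return DDSurvey(records, skipped, edges, counts, summary)


def trim_to_monomer(model: StructureModel, radius: float = 22.0) -> StructureModel:
    """Keep only chains with an atom within ``radius`` of the base-pair anchor.

    In the common frame this trims a superposed file down to the polymerase
    chain used for the superposition plus any bound nucleic acid; neighbouring
    polymerase chains in multi-copy entries fall outside the default 22 Å.
    """
    if not model.atoms:
        raise ValueError("empty model")
    anchor = AnchorPoint("PseudoBP", BASE_PAIR_ANCHOR, radius)
    idx = select_within(model, anchor, by_chain=True)
    if not idx:
        raise NoActiveSiteError("no monomer at the base-pair anchor")
    keep = set(idx)
    atoms = [a for i, a in enumerate(model.atoms) if i in keep]
    return StructureModel(model.pdb_id, model.title, atoms, model.model_number)


# ---------------------------------------------------------------------------
# ions
# ---------------------------------------------------------------------------


def pool_ions(
    paths: Sequence[str | Path],
    set_name: str,
    out_dir: str | Path = ".",
    metals: Iterable[str] = DEFAULT_METALS,
) -> tuple[Path, list[IonRecord]]:
    """Pool all metal ions from all files into ``IONS-<set>.pdb``.

    Every HETATM line in the output is appended (after column 80) with the name
    of the source PDB file so each ion's provenance stays identifiable.  Ion
    count and positions are conserved exactly; duplicate input files contribute
    duplicate ions (no deduplication, mirroring the no-NCS-check policy).
    Unreadable files are skipped with a warning.
    """
    import logging

    log = logging.getLogger("poltree")
    records: list[IonRecord] = []
    for p in paths:
        p = Path(p)
        try:
            model = read_structure(p)
        except Exception as exc:  # noqa: BLE001
            log.warning("pool_ions: skipping %s: %s", p.name, exc)
            continue
        records.extend(extract_metal_ions(model, p.name, metals))

    out = Path(out_dir) / f"IONS-{set_name}.pdb"
    lines = []
    for i, ion in enumerate(records, start=1):
        atom = AtomRecord(
            serial=i,
            name=ion.element,
            altloc="",
            residue_name=ion.element,
            chain_id=ion.source_chain or "I",
            residue_seq=ion.residue_seq,
            insertion_code="",
            position=ion.position,
            occupancy=1.0,
            b_factor=0.0,
            element=ion.element,
            record_kind="HETATM",
        )
        lines.append(format_atom_line(atom).ljust(80) + " " + ion.source_file)
    lines.append("END")
    out.write_text("\n".join(lines) + "\n")
    return out, records


def assign_ion_sites(
    ions: Sequence[IonRecord],
    sites: IonSiteModel | None = None,
    labels: dict[str, str] | None = None,
) -> tuple[list[LabeledIon], pd.DataFrame]:
    """Label each ion with its nearest site centroid (meA/meB/meB′) within cutoff.

    Ions beyond the cutoff from every centroid are labeled OTHER.  Returns the
    labeled ions (input order preserved) and a per-site count table, broken down
    by polymerase class when ``labels`` maps source files to classes.
    """
    sites = sites or IonSiteModel()
    labels = labels or {}
    cents = sites.centroids()
    labeled: list[LabeledIon] = []
    for ion in ions:
        dists = [(name, float(np.linalg.norm(ion.position - c))) for name, c in cents]
        name, d = min(dists, key=lambda nd: nd[1])
        if d > sites.cutoff:
            name = "OTHER"
        labeled.append(LabeledIon(ion, name, round(d, 2)))

    rows = [
        {
            "site": li.site,
            "element": li.ion.element,
            "class": labels.get(li.ion.source_file, "unlabeled"),
        }
        for li in labeled
    ]
    if rows:
        counts = (
            pd.DataFrame(rows)
            .groupby(["site", "class"])
            .size()
            .rename("n")
            .reset_index()
        )
    else:
        counts = pd.DataFrame(columns=["site", "class", "n"])
    return labeled, counts
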