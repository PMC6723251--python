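"""Residue equivalence across set members.

Structure superposition needs a one-to-one mapping of equivalent residues before
any coordinates are fit.  This module establishes that mapping either
automatically — a built-in progressive multiple sequence alignment (k-mer
distances, UPGMA guide tree, affine-gap profile alignment with BLOSUM62) — or
from a curated CLUSTAL-format alignment file, and restricts it to named motif
regions (the conserved polymerase motifs A, C, F, B) when a set aligns only its
structurally conserved core.

Minor misassignments by the automatic aligner are tolerated by design: the
maximum-likelihood superposition down-weights columns that are structurally
divergent, so residual alignment errors do not propagate into the fit.
Curated alignments may contain "non-overlapping sections" — blocks where a
divergent segment of one member occupies columns gapped in all other rows — and
these parse as ordinary columns; they simply never contribute usable
correspondences for the other members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage

__all__ = [
    "GAP_CHARS",
    "AlignParams",
    "SequenceAlignment",
    "CorrespondenceTable",
    "MotifRegionSet",
    "AlignmentFormatError",
    "SequenceMismatchError",
    "pairwise_align",
    "progressive_msa",
    "parse_alignment",
    "write_alignment",
    "read_fasta_sequences",
    "build_correspondence",
    "restrict_regions",
]

GAP_CHARS = "-."
MISSING = -1

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class AlignmentFormatError(ValueError):
    """Bad alignment file or inconsistent alignment."""


class SequenceMismatchError(ValueError):
    """Alignment row disagrees with the structure's residue sequence."""


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for the global aligner (affine gap costs)."""

    gap_open: float = 10.0
    gap_extend: float = 0.5
    matrix: str = "BLOSUM62"


@dataclass
class SequenceAlignment:
    """Named, equal-length gapped rows over the amino-acid alphabet."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise AlignmentFormatError("name/row count mismatch")
        if len(set(self.names)) != len(self.names):
            dup = next(n for n in self.names if self.names.count(n) > 1)
            raise AlignmentFormatError(f"duplicate row name: {dup}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            bad = next(n for n, r in zip(self.names, self.rows)
                       if len(r) != len(self.rows[0]))
            raise AlignmentFormatError(f"inconsistent row length for {bad}")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return "".join(c for c in self.rows[i] if c not in GAP_CHARS)


@dataclass
class CorrespondenceTable:
    """Structures × columns map of equivalent residues.

    ``indices[i, j]`` is the residue index (into member i's Cα trace) equivalent
    at column j, or ``MISSING`` (-1).  Columns present in fewer than two members
    carry no superposition information and are dropped at construction;
    ``alignment_columns`` records each kept column's index in the source
    alignment so motif regions can still be addressed in alignment coordinates.
    """

    members: list[tuple[str, str]]
    indices: np.ndarray           # (n_members, n_columns) int, MISSING = -1
    alignment_columns: np.ndarray  # (n_columns,) int
    alignment_length: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.alignment_columns = np.asarray(self.alignment_columns, dtype=int)
        for i in range(self.indices.shape[0]):
            present = self.indices[i][self.indices[i] >= 0]
            if len(present) and np.any(np.diff(present) <= 0):
                raise ValueError(
                    f"correspondence for member {self.members[i]} is not colinear"
                )

    @property
    def n_columns(self) -> int:
        return self.indices.shape[1]


@dataclass
class MotifRegionSet:
    """Named, disjoint sets of alignment-column ranges (0-based, half-open)."""

    regions: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for name, ranges in self.regions.items():
            for start, stop in ranges:
                if stop <= start or start < 0:
                    raise ValueError(f"bad range {start}:{stop} in region {name}")
                cols = set(range(start, stop))
                if cols & seen:
                    raise ValueError(f"region {name} overlaps another region")
                seen |= cols

    @classmethod
    def from_config(cls, spec: dict[str, list[Sequence[int]]]) -> "MotifRegionSet":
        """Build from 1-based inclusive ranges as written in configuration files."""
        regions = {
            name: [(int(a) - 1, int(b)) for a, b in ranges]
            for name, ranges in spec.items()
        }
        return cls(regions)

    def columns(self) -> list[int]:
        """All region columns, in region order."""
        out: list[int] = []
        for ranges in self.regions.values():
            for start, stop in ranges:
                out.extend(range(start, stop))
        return out

    @property
    def total_columns(self) -> int:
        return len(self.columns())

    @property
    def max_column(self) -> int:
        return max((stop for rs in self.regions.values() for _, stop in rs), default=0)


# ---------------------------------------------------------------------------
# scoring machinery
# ---------------------------------------------------------------------------


def _load_matrix(name: str) -> tuple[np.ndarray, dict[str, int]]:
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    idx = {c: i for i, c in enumerate(alphabet)}
    return np.asarray(mat, dtype=float), idx


def _sanitize(seq: str) -> str:
    """Uppercase; map non-standard residue letters to 'X' with a warning."""
    s = seq.upper()
    if not s:
        raise ValueError("empty sequence")
    bad = sorted({c for c in s if c not in _STANDARD_AA and c != "X"})
    if bad:
        warnings.warn(
            f"non-standard residue letters mapped to X: {''.join(bad)}",
            stacklevel=3,
        )
        s = "".join(c if c in _STANDARD_AA or c == "X" else "X" for c in s)
    return s


def _profile_counts(rows: list[str], idx: dict[str, int]) -> np.ndarray:
    """Per-column residue counts over the substitution-matrix alphabet."""
    L = len(rows[0])
    counts = np.zeros((L, len(idx)), dtype=float)
    for row in rows:
        for j, c in enumerate(row):
            if c not in GAP_CHARS:
                counts[j, idx.get(c, idx.get("X", 0))] += 1.0
    return counts


def _align_profiles(
    rows_a: list[str],
    rows_b: list[str],
    params: AlignParams,
    matrix: np.ndarray,
    idx: dict[str, int],
) -> tuple[list[str], list[str]]:
    """Global affine-gap (Gotoh) alignment of two gapped profiles.

    Column-pair score is the average substitution score over all residue pairs
    drawn one from each profile column (gap entries contribute zero).
    """
    ca = _profile_counts(rows_a, idx)
    cb = _profile_counts(rows_b, idx)
    na, nb = len(rows_a), len(rows_b)
    S = (ca @ matrix @ cb.T) / (na * nb)
    La, Lb = S.shape
    go, ge = params.gap_open, params.gap_extend
    NEG = -1e30

    M = np.full((La + 1, Lb + 1), NEG)
    Ix = np.full((La + 1, Lb + 1), NEG)  # gap in B (consume A column)
    Iy = np.full((La + 1, Lb + 1), NEG)  # gap in A (consume B column)
    M[0, 0] = 0.0
    for i in range(1, La + 1):
        Ix[i, 0] = -go - (i - 1) * ge
    for j in range(1, Lb + 1):
        Iy[0, j] = -go - (j - 1) * ge

    for i in range(1, La + 1):
        for j in range(1, Lb + 1):
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + S[i - 1, j - 1]
            Ix[i, j] = max(M[i - 1, j] - go, Ix[i - 1, j] - ge, Iy[i - 1, j] - go)
            Iy[i, j] = max(M[i, j - 1] - go, Iy[i, j - 1] - ge, Ix[i, j - 1] - go)

    # traceback
    i, j = La, Lb
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    path: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            path.append("D")
            prev = [M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1:
            path.append("U")
            cands = [M[i - 1, j] - go, Ix[i - 1, j] - ge, Iy[i - 1, j] - go]
            i -= 1
            state = int(np.argmax(cands))
        else:
            path.append("L")
            cands = [M[i, j - 1] - go, Ix[i, j - 1] - go, Iy[i, j - 1] - ge]
            j -= 1
            state = int(np.argmax(cands))
    path.reverse()

    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = jb = 0
    for step in path:
        if step == "D":
            for r, row in enumerate(rows_a):
                out_a[r] += row[ia]
            for r, row in enumerate(rows_b):
                out_b[r] += row[jb]
            ia += 1
            jb += 1
        elif step == "U":
            for r, row in enumerate(rows_a):
                out_a[r] += row[ia]
            for r in range(nb):
                out_b[r] += "-"
            ia += 1
        else:
            for r in range(na):
                out_a[r] += "-"
            for r, row in enumerate(rows_b):
                out_b[r] += row[jb]
            jb += 1
    return out_a, out_b


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def pairwise_align(
    seq_a: str,
    seq_b: str,
    params: AlignParams | None = None,
    names: tuple[str, str] = ("seq_a", "seq_b"),
) -> SequenceAlignment:
    """Needleman–Wunsch global alignment with affine gap costs."""
    params = params or AlignParams()
    a = _sanitize(seq_a)
    b = _sanitize(seq_b)
    matrix, idx = _load_matrix(params.matrix)
    rows_a, rows_b = _align_profiles([a], [b], params, matrix, idx)
    return SequenceAlignment(list(names), [rows_a[0], rows_b[0]])


def _kmer_distance(a: str, b: str, k: int) -> float:
    """1 − fractional shared k-mer count; crude but adequate for a guide tree."""
    from collections import Counter

    ka = Counter(a[i:i + k] for i in range(len(a) - k + 1))
    kb = Counter(b[i:i + k] for i in range(len(b) - k + 1))
    shared = sum(min(ka[key], kb[key]) for key in ka)
    denom = max(1, min(len(a), len(b)) - k + 1)
    return 1.0 - shared / denom


def progressive_msa(
    seqs: Sequence[str],
    names: Sequence[str] | None = None,
    params: AlignParams | None = None,
) -> SequenceAlignment:
    """Progressive multiple sequence alignment.

    k-mer distances (k = 3, shortened for very short inputs) feed a UPGMA guide
    tree; profiles are merged up the tree with the affine-gap profile aligner.
    Row order matches input order.
    """
    params = params or AlignParams()
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    clean = [_sanitize(s) for s in seqs]
    if names is None:
        names = [f"seq{i + 1}" for i in range(len(clean))]
    matrix, idx = _load_matrix(params.matrix)

    n = len(clean)
    if n == 2:
        rows_a, rows_b = _align_profiles([clean[0]], [clean[1]], params, matrix, idx)
        return SequenceAlignment(list(names), [rows_a[0], rows_b[0]])

    k = max(1, min(3, min(len(s) for s in clean)))
    dist = []
    for i in range(n):
        for j in range(i + 1, n):
            dist.append(_kmer_distance(clean[i], clean[j], k))
    Z = linkage(np.asarray(dist), method="average")

    # cluster id -> (member input indices, gapped rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [clean[i]]) for i in range(n)
    }
    for step, (left, right, _, _) in enumerate(Z):
        ia, rows_a = clusters.pop(int(left))
        ib, rows_b = clusters.pop(int(right))
        out_a, out_b = _align_profiles(rows_a, rows_b, params, matrix, idx)
        clusters[n + step] = (ia + ib, out_a + out_b)

    order, rows = clusters.popitem()[1]
    by_input = {inp: row for inp, row in zip(order, rows)}
    return SequenceAlignment(list(names), [by_input[i] for i in range(n)])


def parse_alignment(path: str | Path) -> SequenceAlignment:
    """Read a CLUSTAL-dialect alignment (interleaved blocks).

    Conservation/consensus lines are ignored.  Duplicate names within a block and
    row-length inconsistencies raise :class:`AlignmentFormatError` naming the row.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].upper().startswith("CLUSTAL"):
        raise AlignmentFormatError(f"{path}: missing CLUSTAL header line")

    acc: dict[str, str] = {}
    order: list[str] = []
    block_seen: set[str] = set()
    for line in lines[1:]:
        if not line.strip():
            block_seen = set()
            continue
        if line[0] in " \t":  # conservation line
            continue
        parts = line.split()
        if len(parts) < 2:
            continue
        name, chunk = parts[0], parts[1]
        if not set(chunk) <= set("ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz-."):
            raise AlignmentFormatError(f"{path}: unexpected characters in row {name}")
        if name in block_seen:
            raise AlignmentFormatError(f"{path}: duplicate row name {name}")
        block_seen.add(name)
        if name not in acc:
            acc[name] = ""
            order.append(name)
        acc[name] += chunk.upper()

    if not order:
        raise AlignmentFormatError(f"{path}: no alignment rows")
    lengths = {len(acc[n]) for n in order}
    if len(lengths) > 1:
        ref = len(acc[order[0]])
        bad = next(n for n in order if len(acc[n]) != ref)
        raise AlignmentFormatError(f"{path}: row length mismatch for {bad}")
    return SequenceAlignment(order, [acc[n] for n in order])


def write_alignment(aln: SequenceAlignment, path: str | Path, width: int = 60) -> Path:
    """Write CLUSTAL format with interleaved fixed-width blocks."""
    path = Path(path)
    name_w = max(len(n) for n in aln.names) + 2
    out = ["CLUSTAL multiple sequence alignment", ""]
    for start in range(0, aln.length, width):
        for name, row in zip(aln.names, aln.rows):
            out.append(f"{name:<{name_w}}{row[start:start + width]}")
        out.append("")
    path.write_text("\n".join(out) + "\n")
    return path


def read_fasta_sequences(path: str | Path) -> tuple[list[str], list[str]]:
    """Names and sequences from a FASTA file (convenience input route)."""
    from Bio import SeqIO

    names, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs.append(str(rec.seq))
    return names, seqs


def build_correspondence(
    aln: SequenceAlignment,
    traces: Sequence,
) -> CorrespondenceTable:
    """Map alignment columns to residue indices of each member's Cα trace.

    Each alignment row's ungapped content must equal the corresponding trace's
    one-letter sequence exactly; a disagreement raises
    :class:`SequenceMismatchError` naming the member and the first mismatching
    position.  Gaps become MISSING.  Columns with fewer than two present members
    are dropped (their original alignment indices remain addressable through
    ``alignment_columns``).
    """
    if len(aln.rows) != len(traces):
        raise ValueError("one trace per alignment row required")
    members = [t.source for t in traces]
    L = aln.length
    indices = np.full((len(traces), L), MISSING, dtype=int)
    for i, (row, trace) in enumerate(zip(aln.rows, traces)):
        seq = trace.sequence
        ungapped = aln.ungapped(i)
        if len(ungapped) != len(seq):
            raise SequenceMismatchError(
                f"member {members[i]}: alignment row has {len(ungapped)} residues, "
                f"trace has {len(seq)}"
            )
        r = 0
        for j, c in enumerate(row):
            if c in GAP_CHARS:
                continue
            if c != seq[r] and not (c == "X" or seq[r] == "X"):
                raise SequenceMismatchError(
                    f"member {members[i]}: alignment says {c!r} but trace has "
                    f"{seq[r]!r} at residue index {r}"
                )
            indices[i, j] = r
            r += 1

    present = indices >= 0
    keep = present.sum(0) >= 2
    return CorrespondenceTable(
        members=members,
        indices=indices[:, keep],
        alignment_columns=np.nonzero(keep)[0],
        alignment_length=L,
    )


def restrict_regions(
    table: CorrespondenceTable, regions: MotifRegionSet
) -> CorrespondenceTable:
    """Keep only motif-region columns, in region order; members unchanged."""
    if regions.max_column > table.alignment_length:
        raise ValueError(
            f"region extends to column {regions.max_column} but alignment has "
            f"{table.alignment_length} columns"
        )
    pos = {int(c): k for k, c in enumerate(table.alignment_columns)}
    sel = [pos[c] for c in regions.columns() if c in pos]
    if not sel:
        raise ValueError("no usable columns after region restriction")
    return CorrespondenceTable(
        members=list(table.members),
        indices=table.indices[:, sel],
        alignment_columns=table.alignment_columns[sel],
        alignment_length=table.alignment_length,
    )
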