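"""Rigid-body fitting and maximum-likelihood multiple structure superposition.

Two fitting regimes are provided:

* :func:`kabsch_fit` — the classical weighted least-squares rotation (Kabsch/SVD),
  which treats every position with a fixed weight; and
* :func:`ml_superpose` — an iterative maximum-likelihood multiple superposition in
  the spirit of Theseus: every alignment column carries its own isotropic variance
  σ²ⱼ estimated from the data, and members are refit with weights 1/σ²ⱼ, so
  structurally divergent columns are automatically down-weighted while the fit
  converges about the conserved core.

The per-column variances are the package's measure of structural heterogeneity;
:func:`pseudo_b` converts them to crystallographic-style B-values (B = 8π²σ²)
which are written into the B-factor field of the average structure so that
flexibility can be visualised by colouring in any molecular-graphics program.

The variance model here is deliberately a simplified isotropic estimator with a
small variance floor rather than a full hierarchical-prior treatment: it
reproduces the observable outputs (orientations, per-column variances, pseudo-B)
that downstream analyses consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .msa import CorrespondenceTable
from .pdbio import AtomRecord, RigidTransform, StructureModel

__all__ = [
    "DegenerateFitError",
    "MLOptions",
    "SuperpositionResult",
    "kabsch_fit",
    "rmsd",
    "ml_superpose",
    "pseudo_b",
    "mean_structure",
    "write_variances",
]

EIGHT_PI_SQUARED = 8.0 * math.pi ** 2


class DegenerateFitError(ValueError):
    """Point sets too degenerate (collinear/coincident) to define a rotation."""


def kabsch_fit(
    moving: np.ndarray,
    fixed: np.ndarray,
    weights: np.ndarray | None = None,
) -> RigidTransform:
    """Weighted least-squares rigid fit of ``moving`` onto ``fixed``.

    Returns the proper rotation R and translation t minimising
    ``sum_i w_i |R m_i + t - f_i|^2``.  A reflection in the SVD solution is
    corrected by flipping the sign of the smallest singular direction, so the
    result is always a proper rotation.

    Raises
    ------
    DegenerateFitError
        fewer than 3 (positively weighted) points, or point sets whose
        cross-covariance is rank-deficient (collinear/coincident points).
    """
    m = np.asarray(moving, dtype=float).reshape(-1, 3)
    f = np.asarray(fixed, dtype=float).reshape(-1, 3)
    if m.shape != f.shape:
        raise ValueError(f"point count mismatch: {m.shape[0]} vs {f.shape[0]}")
    if weights is None:
        w = np.ones(len(m))
    else:
        w = np.asarray(weights, dtype=float).reshape(-1)
        if len(w) != len(m):
            raise ValueError("weight count mismatch")
        if np.any(w < 0):
            raise ValueError("negative weights")
    if np.count_nonzero(w > 0) < 3:
        raise DegenerateFitError("need at least 3 positively weighted points")

    wsum = w.sum()
    cm = (w[:, None] * m).sum(0) / wsum
    cf = (w[:, None] * f).sum(0) / wsum
    mc = m - cm
    fc = f - cf
    A = (mc * w[:, None]).T @ fc  # 3x3 cross-covariance
    U, S, Vt = np.linalg.svd(A)
    scale = max(S[0], 1e-300)
    if S[1] / scale < 1e-10:
        raise DegenerateFitError("degenerate point set (collinear or coincident)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    return RigidTransform(R, t)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two equal-length coordinate lists.

    No fitting is performed; the inputs are compared as given.
    """
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    if len(a) == 0:
        raise ValueError("empty coordinate lists")
    return float(np.sqrt(((a - b) ** 2).sum(1).mean()))


@dataclass
class MLOptions:
    """Tunables for :func:`ml_superpose`.

    tol:
        relative change in the objective below which iteration stops.
    variance_floor:
        lower bound on σ²ⱼ (Å²); prevents zero-variance columns from acquiring
        infinite weight in the zero-noise limit.
    fixed_variance:
        when set, all column variances are pinned to this constant, which makes
        the procedure equivalent to iterated unweighted least squares.
    init_member:
        index of the member whose original frame initialises (and therefore
        gauges) the superposition; conventionally the set's seed.
    """

    tol: float = 1e-8
    max_iter: int = 200
    variance_floor: float = 1e-4
    fixed_variance: float | None = None
    init_member: int = 0


@dataclass
class SuperpositionResult:
    """Outcome of a maximum-likelihood multiple superposition."""

    members: list[tuple[str, str]]
    member_transforms: list[RigidTransform]
    mean_coords: np.ndarray          # (m, 3)
    column_variances: np.ndarray     # (m,) sigma^2 in A^2
    iterations: int
    objective_trace: list[float]
    columns_used: np.ndarray         # alignment-column provenance, (m,)
    present: np.ndarray              # (n_members, m) bool mask
    converged: bool
    fitted_coords: np.ndarray        # (n_members, m, 3); NaN where absent

    def member_fitted(self, i: int) -> np.ndarray:
        """Fitted coordinates of member ``i`` over its present columns."""
        return self.fitted_coords[i][self.present[i]]


def _member_column_coords(
    table: CorrespondenceTable, traces: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """(n, m, 3) coordinate tensor and presence mask from a correspondence table."""
    n, m = table.indices.shape
    X = np.full((n, m, 3), np.nan)
    present = table.indices >= 0
    for i in range(n):
        coords = np.asarray(traces[i], dtype=float).reshape(-1, 3)
        idx = table.indices[i]
        X[i, present[i]] = coords[idx[present[i]]]
    return X, present


def ml_superpose(
    table: CorrespondenceTable,
    traces: Sequence[np.ndarray],
    options: MLOptions | None = None,
) -> SuperpositionResult:
    """Maximum-likelihood multiple superposition over a correspondence table.

    EM-style alternation: initialise every member by an unweighted Kabsch fit onto
    the ``init_member``; then repeat (i) per-column mean over present members,
    (ii) isotropic per-column variance σ²ⱼ = mean squared deviation from the mean
    (over present members and the 3 coordinates), floored, (iii) refit each member
    to the mean with per-column weights 1/σ²ⱼ, until the objective

        sum_j [ 3 n_j log σ²ⱼ + S_j / σ²ⱼ ],   S_j = sum_i |x_ij − μ_j|²

    changes by less than ``tol`` (relative) or ``max_iter`` is reached.  Missing
    entries are excluded from mean, variance, and fits.  Non-convergence is
    reported via the ``converged`` flag, not an exception.
    """
    opts = options or MLOptions()
    if len(traces) != len(table.members):
        raise ValueError("one coordinate trace required per table member")
    if len(table.members) < 2:
        raise ValueError("need at least 2 members")

    X, present = _member_column_coords(table, traces)
    # columns informative for superposition need >= 2 present members
    keep = present.sum(0) >= 2
    X = X[:, keep]
    present = present[:, keep]
    columns_used = table.alignment_columns[keep]
    n, m = present.shape

    for i in range(n):
        if present[i].sum() < 3:
            raise ValueError(
                f"member {table.members[i]} has fewer than 3 usable columns"
            )

    # --- initialisation: unweighted Kabsch onto the init member
    ref = opts.init_member
    transforms: list[RigidTransform] = []
    for i in range(n):
        if i == ref:
            transforms.append(RigidTransform.identity())
            continue
        shared = present[i] & present[ref]
        if shared.sum() < 3:
            raise ValueError(
                f"member {table.members[i]} shares fewer than 3 columns with the seed"
            )
        transforms.append(kabsch_fit(X[i][shared], X[ref][shared]))

    objective_trace: list[float] = []
    converged = False
    it = 0
    n_j = present.sum(0)  # members present per column
    variances = np.full(m, np.nan)
    mean = np.full((m, 3), np.nan)
    Y = np.full_like(X, np.nan)

    for it in range(1, opts.max_iter + 1):
        for i in range(n):
            Y[i, present[i]] = transforms[i].apply(X[i][present[i]])
        mean = np.nansum(np.where(present[:, :, None], Y, 0.0), axis=0) / n_j[:, None]
        dev = np.where(present[:, :, None], Y - mean[None], 0.0)
        S_j = (dev ** 2).sum(axis=(0, 2))
        if opts.fixed_variance is not None:
            variances = np.full(m, float(opts.fixed_variance))
        else:
            variances = np.maximum(S_j / (3.0 * n_j), opts.variance_floor)
        objective = float(np.sum(3.0 * n_j * np.log(variances) + S_j / variances))
        objective_trace.append(objective)
        if len(objective_trace) >= 2:
            prev = objective_trace[-2]
            if abs(objective - prev) <= opts.tol * max(1.0, abs(prev)):
                converged = True
                break
        weights = 1.0 / variances
        for i in range(n):
            mask = present[i]
            transforms[i] = kabsch_fit(X[i][mask], mean[mask], weights[mask])

    for i in range(n):
        Y[i, present[i]] = transforms[i].apply(X[i][present[i]])

    return SuperpositionResult(
        members=list(table.members),
        member_transforms=transforms,
        mean_coords=mean,
        column_variances=variances,
        iterations=it,
        objective_trace=objective_trace,
        columns_used=columns_used,
        present=present,
        converged=converged,
        fitted_coords=Y,
    )


def pseudo_b(variances: np.ndarray) -> np.ndarray:
    """Pseudo B-factors: B_j = 8 pi^2 sigma^2_j (A^2).

    The conventional crystallographic relation between an isotropic positional
    variance and its temperature factor, applied to the per-column variances of a
    superposition so that structural heterogeneity displays like thermal motion.
    """
    v = np.asarray(variances, dtype=float)
    if np.any(v < 0):
        raise ValueError("negative variance")
    return EIGHT_PI_SQUARED * v


def mean_structure(result: SuperpositionResult, chain_id: str = "A") -> StructureModel:
    """Average structure: one Cα pseudo-residue per column, B = 8π²σ²ⱼ.

    Residues are numbered sequentially; loading this model and colouring by the
    B-factor field visualises per-position structural heterogeneity.
    """
    b = pseudo_b(result.column_variances)
    atoms = [
        AtomRecord(
            serial=j + 1,
            name="CA",
            altloc="",
            residue_name="ALA",
            chain_id=chain_id,
            residue_seq=j + 1,
            insertion_code="",
            position=result.mean_coords[j],
            occupancy=1.0,
            b_factor=float(b[j]),
            element="C",
            record_kind="ATOM",
        )
        for j in range(len(result.mean_coords))
    ]
    return StructureModel(pdb_id="AVRG", title="AVERAGE STRUCTURE OF SUPERPOSITION", atoms=atoms)


def write_variances(result: SuperpositionResult, path: str | Path) -> Path:
    """Per-column variance listing: column, mean x/y/z, sigma^2, pseudo-B."""
    path = Path(path)
    b = pseudo_b(result.column_variances)
    lines = ["# column    mean_x     mean_y     mean_z     variance   pseudoB"]
    for j in range(len(result.mean_coords)):
        x, y, z = result.mean_coords[j]
        lines.append(
            f"{int(result.columns_used[j]):>8} {x:>10.3f} {y:>10.3f} {z:>10.3f} "
            f"{result.column_variances[j]:>10.5f} {b[j]:>9.3f}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
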