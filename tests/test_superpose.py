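"""Rigid fitting and maximum-likelihood superposition."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from poltree.fixtures import (
    FamilySpec,
    folded_template,
    random_transforms,
    standard_family_spec,
    synth_family,
    transform_recovery_errors,
)
from poltree.msa import CorrespondenceTable
from poltree.pdbio import RigidTransform, read_structure, write_structure
from poltree.superpose import (
    DegenerateFitError,
    EIGHT_PI_SQUARED,
    MLOptions,
    kabsch_fit,
    mean_structure,
    ml_superpose,
    pseudo_b,
    rmsd,
    write_variances,
)


def brute_force_best_residual(moving, fixed, n_trials, seed, weights=None):
    """Independent oracle: best weighted residual over random rotations, with
    the optimal translation (weighted-centroid match) applied analytically."""
    m = np.asarray(moving, float)
    f = np.asarray(fixed, float)
    w = np.ones(len(m)) if weights is None else np.asarray(weights, float)
    cm = (w[:, None] * m).sum(0) / w.sum()
    cf = (w[:, None] * f).sum(0) / w.sum()
    mc, fc = m - cm, f - cf
    Rs = Rotation.random(n_trials, random_state=np.random.default_rng(seed)).as_matrix()
    rotated = np.einsum("kij,nj->kni", Rs, mc)
    resid = (w[None, :, None] * (rotated - fc[None]) ** 2).sum(axis=(1, 2))
    return float(resid.min())


def fit_residual(t: RigidTransform, moving, fixed, weights=None) -> float:
    w = np.ones(len(moving)) if weights is None else np.asarray(weights, float)
    d = t.apply(moving) - np.asarray(fixed, float)
    return float((w[:, None] * d ** 2).sum())


class TestKabsch:
    def test_self_fit_is_identity(self):
        pts = folded_template(20)
        t = kabsch_fit(pts, pts)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, 0, atol=1e-12)

    def test_recovers_constructed_transform(self):
        pts = folded_template(25)
        planted = RigidTransform.about_axis((1, 1, 0), 37.0, (4, -2, 9))
        t = kabsch_fit(pts, planted.apply(pts))
        assert rmsd(t.apply(pts), planted.apply(pts)) < 1e-9

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_beats_random_rotation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        moving = rng.normal(0, 3, size=(15, 3))
        fixed = rng.normal(0, 3, size=(15, 3))
        weights = rng.uniform(0.2, 2.0, size=15)
        t = kabsch_fit(moving, fixed, weights)
        ours = fit_residual(t, moving, fixed, weights)
        best = brute_force_best_residual(moving, fixed, 20000, seed, weights)
        assert ours <= best + 1e-9

    def test_weight_two_equals_duplicated_point(self):
        rng = np.random.default_rng(7)
        moving = rng.normal(0, 3, size=(8, 3))
        fixed = rng.normal(0, 3, size=(8, 3))
        w = np.ones(8)
        w[3] = 2.0
        t1 = kabsch_fit(moving, fixed, w)
        t2 = kabsch_fit(
            np.vstack([moving, moving[3]]), np.vstack([fixed, fixed[3]])
        )
        assert np.allclose(t1.rotation, t2.rotation, atol=1e-10)
        assert np.allclose(t1.translation, t2.translation, atol=1e-10)

    def test_collinear_points_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateFitError):
            kabsch_fit(line, line + 1.0)

    def test_too_few_weighted_points_rejected(self):
        pts = folded_template(5)
        with pytest.raises(DegenerateFitError):
            kabsch_fit(pts, pts, weights=[1, 1, 0, 0, 0])


class TestRmsd:
    def test_identical_and_single_point(self):
        pts = folded_template(10)
        assert rmsd(pts, pts) == 0.0
        assert rmsd([[0, 0, 0]], [[0, 3, 0]]) == pytest.approx(3.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        expected = np.sqrt((((a - b) ** 2).sum(1)).mean())
        assert rmsd(a, b) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmsd(folded_template(4), folded_template(5))


def _full_table(n_members, length):
    indices = np.tile(np.arange(length), (n_members, 1))
    return CorrespondenceTable(
        members=[(f"m{i}", "A") for i in range(n_members)],
        indices=indices,
        alignment_columns=np.arange(length),
        alignment_length=length,
    )


class TestMlSuperpose:
    def test_zero_noise_members_coincide_and_variances_floor(self):
        fam = synth_family(FamilySpec(3, 40, 0.0, seed=1))
        res = ml_superpose(fam.correspondence(), [t.coords for t in fam.traces])
        for i in range(1, 3):
            assert (
                rmsd(res.member_fitted(0), res.member_fitted(i)) < 1e-6
            )
        assert np.all(res.column_variances == MLOptions().variance_floor)

    def test_standard_family_recovery(self):
        fam = synth_family(standard_family_spec(seed=11))
        res = ml_superpose(fam.correspondence(), [t.coords for t in fam.traces])
        rot_err, trans_err = transform_recovery_errors(fam, res)
        assert rot_err.max() < 1.0
        assert trans_err.max() < 0.1
        core = np.r_[res.column_variances[:20], res.column_variances[40:]]
        loops = res.column_variances[20:40]
        assert loops.mean() / core.mean() > 10.0

    def test_uniform_variance_limit_matches_iterated_least_squares(self):
        fam = synth_family(FamilySpec(6, 40, 0.1, seed=4))
        coords = [t.coords for t in fam.traces]
        table = fam.correspondence()
        res = ml_superpose(
            table, coords, MLOptions(fixed_variance=1.0, tol=1e-15, max_iter=500)
        )

        # independent oracle: plain alternating mean / unweighted Kabsch
        transforms = [RigidTransform.identity()]
        transforms += [kabsch_fit(coords[i], coords[0]) for i in range(1, 6)]
        for _ in range(500):
            Y = np.stack([t.apply(c) for t, c in zip(transforms, coords)])
            mean = Y.mean(axis=0)
            new = [kabsch_fit(c, mean) for c in coords]
            delta = max(
                np.max(np.abs(a.rotation - b.rotation)) for a, b in zip(new, transforms)
            )
            transforms = new
            if delta < 1e-15:
                break

        for ours, ref in zip(res.member_transforms, transforms):
            assert np.max(np.abs(ours.rotation - ref.rotation)) < 1e-8
            assert np.max(np.abs(ours.translation - ref.translation)) < 1e-8

    def test_objective_non_increasing(self):
        for seed in (1, 2, 3):
            fam = synth_family(standard_family_spec(seed=seed, n_members=8))
            res = ml_superpose(
                fam.correspondence(), [t.coords for t in fam.traces]
            )
            obj = np.asarray(res.objective_trace)
            assert np.all(np.diff(obj) <= 1e-9 * np.maximum(1.0, np.abs(obj[:-1])))

    def test_member_order_invariance_of_relative_geometry(self):
        fam = synth_family(FamilySpec(5, 40, 0.05, seed=9))
        coords = [t.coords for t in fam.traces]
        table = fam.correspondence()
        opts = MLOptions(tol=1e-14, max_iter=1000)
        res1 = ml_superpose(table, coords, opts)

        perm = [2, 0, 4, 1, 3]
        table2 = CorrespondenceTable(
            members=[table.members[i] for i in perm],
            indices=table.indices[perm],
            alignment_columns=table.alignment_columns,
            alignment_length=table.alignment_length,
        )
        res2 = ml_superpose(table2, [coords[i] for i in perm], opts)

        def pairwise(res, order):
            out = {}
            for a in range(5):
                for b in range(a + 1, 5):
                    ia, ib = order.index(a), order.index(b)
                    out[(a, b)] = rmsd(res.member_fitted(ia), res.member_fitted(ib))
            return out

        p1 = pairwise(res1, [0, 1, 2, 3, 4])
        p2 = pairwise(res2, perm)
        for key in p1:
            assert abs(p1[key] - p2[key]) < 1e-6

    def test_ml_downweights_corrupted_column_more_than_ls(self):
        fam = synth_family(FamilySpec(8, 40, 0.05, seed=6))
        coords = [t.coords.copy() for t in fam.traces]
        table = fam.correspondence()
        base_ml = ml_superpose(table, coords)
        base_ls = ml_superpose(table, coords, MLOptions(fixed_variance=1.0))

        coords[3][17] += 10.0  # corrupt one column of one member
        ml = ml_superpose(table, coords)
        ls = ml_superpose(table, coords, MLOptions(fixed_variance=1.0))

        def max_rot_change(a, b):
            return max(
                ta.compose(tb.inverse()).rotation_angle_deg()
                for ta, tb in zip(a.member_transforms, b.member_transforms)
            )

        assert max_rot_change(ml, base_ml) < max_rot_change(ls, base_ls)

    def test_variance_estimate_consistent(self):
        fam = synth_family(FamilySpec(20, 40, 0.5, seed=13))
        res = ml_superpose(fam.correspondence(), [t.coords for t in fam.traces])
        mean_var = res.column_variances.mean()
        assert 0.5 * 0.25 <= mean_var <= 1.5 * 0.25

    def test_member_with_too_few_columns_rejected(self):
        fam = synth_family(FamilySpec(3, 10, 0.0, seed=1, deletions=[(1, 0, 8)]))
        with pytest.raises(ValueError, match="fewer than 3"):
            ml_superpose(fam.correspondence(), [t.coords for t in fam.traces])

    def test_non_convergence_flagged_not_raised(self):
        fam = synth_family(FamilySpec(4, 40, 0.3, seed=2))
        res = ml_superpose(
            fam.correspondence(),
            [t.coords for t in fam.traces],
            MLOptions(max_iter=2, tol=1e-30),
        )
        assert res.converged is False


class TestPseudoB:
    def test_unit_variance_is_eight_pi_squared(self):
        assert pseudo_b(np.array([1.0]))[0] == pytest.approx(78.9568, abs=1e-4)
        assert EIGHT_PI_SQUARED == pytest.approx(78.95683520871486)

    def test_zero_and_linear_scaling(self):
        assert pseudo_b(np.array([0.0]))[0] == 0.0
        assert pseudo_b(np.array([0.25]))[0] == pytest.approx(19.7392, abs=1e-4)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            pseudo_b(np.array([-0.1]))


class TestMeanStructure:
    def _result(self, seed=1, sigma=0.2):
        fam = synth_family(FamilySpec(6, 30, sigma, seed=seed))
        return ml_superpose(fam.correspondence(), [t.coords for t in fam.traces])

    def test_two_identical_members_mean_equals_member(self):
        fam = synth_family(FamilySpec(2, 30, 0.0, seed=3))
        res = ml_superpose(fam.correspondence(), [t.coords for t in fam.traces])
        assert rmsd(res.mean_coords, res.member_fitted(0)) < 1e-6

    def test_written_b_column_matches_pseudo_b(self, tmp_path):
        res = self._result()
        model = mean_structure(res)
        path = tmp_path / "ave.pdb"
        write_structure(model, path)
        back = read_structure(path)
        expected = pseudo_b(res.column_variances)
        written = np.array([a.b_factor for a in back.atoms])
        assert np.allclose(written, expected, atol=1e-2)

    def test_b_rank_follows_variance_rank(self, tmp_path):
        res = self._result(seed=8, sigma=0.4)
        path = tmp_path / "ave.pdb"
        write_structure(mean_structure(res), path)
        written = np.array([a.b_factor for a in read_structure(path).atoms])
        v = res.column_variances
        # format precision can tie neighbours; require Spearman-like agreement
        assert np.corrcoef(np.argsort(np.argsort(written)),
                           np.argsort(np.argsort(v)))[0, 1] > 0.99

    def test_variance_file_lists_all_columns(self, tmp_path):
        res = self._result()
        path = write_variances(res, tmp_path / "theseus_variances.txt")
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == len(res.mean_coords)
        first = lines[0].split()
        assert len(first) == 6  # column, x, y, z, variance, pseudo-B
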