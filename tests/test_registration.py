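"""NGF distance, curvature regularizer and masking against brute-force
oracles; landmark transforms; mask plumbing."""

import numpy as np
import pytest

from iusreg.evaluation import dice
from iusreg.grids import BinaryMask, DeformationField, LandmarkSet, Volume3D
from iusreg.registration import (RegistrationConfig, RigidTransform,
                                 combine_masks, curvature_energy,
                                 estimate_beam_mask, ngf_distance,
                                 transform_landmarks, _diff, _diff_adjoint)


def ngf_oracle(R, T, mask, sp, eps):
    """Straight-loop evaluation of the masked NGF formula."""
    n = R.shape

    def grad(f):
        g = np.zeros((3,) + f.shape)
        for ax in range(3):
            for i in range(n[ax]):
                ip, im = min(i + 1, n[ax] - 1), max(i - 1, 0)
                sl = [slice(None)] * 3
                slp, slm = list(sl), list(sl)
                sl[ax], slp[ax], slm[ax] = i, ip, im
                g[ax][tuple(sl)] = (f[tuple(slp)] - f[tuple(slm)]) \
                    / (2 * sp[ax])
        return g

    gR, gT = grad(R), grad(T)
    h = np.prod(sp)
    val = 0.0
    for idx in np.ndindex(*n):
        if not mask[idx]:
            continue
        a = np.array([gR[k][idx] for k in range(3)])
        b = np.array([gT[k][idx] for k in range(3)])
        r = (a @ b + eps ** 2) / (np.sqrt(a @ a + eps ** 2)
                                  * np.sqrt(b @ b + eps ** 2))
        val += 0.5 * h * (1 - r ** 2)
    return val


def curvature_oracle(u, sp):
    """Straight-loop interior Laplacian energy."""
    h = np.prod(sp)
    n = u.shape[1:]
    val = 0.0
    for l in range(3):
        for idx in np.ndindex(*n):
            if any(idx[a] in (0, n[a] - 1) for a in range(3)):
                continue
            lap = 0.0
            for ax in range(3):
                ip = list(idx)
                ip[ax] += 1
                im = list(idx)
                im[ax] -= 1
                lap += (u[l][tuple(ip)] - 2 * u[l][idx]
                        + u[l][tuple(im)]) / sp[ax] ** 2
            val += 0.5 * h * lap ** 2
    return val


SPACING = np.array([0.7, 1.0, 1.3])


class TestNgfDistance:
    def test_difference_operator_adjointness(self, rng):
        f = rng.standard_normal((6, 6, 6))
        w = rng.standard_normal((6, 6, 6))
        for ax in range(3):
            lhs = (_diff(f, ax, 0.7) * w).sum()
            rhs = (f * _diff_adjoint(w, ax, 0.7)).sum()
            assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_identical_images_zero(self, rng):
        v = Volume3D(rng.random((6, 6, 6)), SPACING)
        mask = BinaryMask.on_grid(v, np.ones(v.shape, bool))
        assert ngf_distance(v, v, mask, 0.5)["value"] == pytest.approx(
            0.0, abs=1e-10)

    def test_constant_images_zero(self):
        a = Volume3D(np.full((6, 6, 6), 3.0), SPACING)
        b = Volume3D(np.full((6, 6, 6), 7.0), SPACING)
        mask = BinaryMask.on_grid(a, np.ones(a.shape, bool))
        assert ngf_distance(a, b, mask, 0.5)["value"] == pytest.approx(
            0.0, abs=1e-12)

    def test_orthogonal_ramps_match_oracle(self):
        x = np.indices((6, 6, 6)).astype(float)
        slope = 2.0
        R = slope * x[0] * SPACING[0]
        T = slope * x[1] * SPACING[1]
        eps = 0.1 * slope
        vR, vT = Volume3D(R, SPACING), Volume3D(T, SPACING)
        mask = np.ones((6, 6, 6), bool)
        got = ngf_distance(vR, vT, BinaryMask.on_grid(vR, mask), eps)["value"]
        want = ngf_oracle(vR.data.astype(float), vT.data.astype(float),
                          mask, SPACING, eps)
        assert got == pytest.approx(want, rel=1e-10)

    def test_random_instance_matches_oracle(self, rng):
        R = rng.standard_normal((6, 6, 6))
        T = rng.standard_normal((6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.3
        vR, vT = Volume3D(R, SPACING), Volume3D(T, SPACING)
        got = ngf_distance(vR, vT, BinaryMask.on_grid(vR, mask), 0.5)["value"]
        want = ngf_oracle(vR.data.astype(float), vT.data.astype(float),
                          mask, SPACING, 0.5)
        assert got == pytest.approx(want, rel=1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        R = rng.standard_normal((6, 6, 6))
        T64 = rng.standard_normal((6, 6, 6))
        vR = Volume3D(R, SPACING)
        mask = BinaryMask.on_grid(vR, rng.random((6, 6, 6)) > 0.3)
        g = ngf_distance(vR, Volume3D(T64, SPACING), mask, 0.5)["gradient"]
        e = 1e-5
        for _ in range(25):
            idx = tuple(rng.integers(0, 6, 3))
            Tp, Tm = T64.copy(), T64.copy()
            Tp[idx] += e
            Tm[idx] -= e
            vp, vm = Volume3D(Tp, SPACING), Volume3D(Tm, SPACING)
            # measure the step actually applied after float32 storage
            step = float(vp.data[idx]) - float(vm.data[idx])
            num = (ngf_distance(vR, vp, mask, 0.5)["value"]
                   - ngf_distance(vR, vm, mask, 0.5)["value"]) / step
            assert num == pytest.approx(g[idx], rel=1e-4, abs=1e-9)

    def test_symmetric_in_images(self, rng):
        R = Volume3D(rng.standard_normal((6, 6, 6)), SPACING)
        T = Volume3D(rng.standard_normal((6, 6, 6)), SPACING)
        mask = BinaryMask.on_grid(R, rng.random((6, 6, 6)) > 0.4)
        assert ngf_distance(R, T, mask, 0.4)["value"] == pytest.approx(
            ngf_distance(T, R, mask, 0.4)["value"], rel=1e-12)

    def test_mask_shrink_never_increases(self, rng):
        R = Volume3D(rng.standard_normal((6, 6, 6)), SPACING)
        T = Volume3D(rng.standard_normal((6, 6, 6)), SPACING)
        big = rng.random((6, 6, 6)) > 0.2
        small = big & (rng.random((6, 6, 6)) > 0.5)
        v_big = ngf_distance(R, T, BinaryMask.on_grid(R, big), 0.4)["value"]
        v_small = ngf_distance(R, T, BinaryMask.on_grid(R, small),
                               0.4)["value"]
        assert v_small <= v_big + 1e-12

    def test_empty_mask_warns_zero(self, rng):
        R = Volume3D(rng.standard_normal((4, 4, 4)))
        with pytest.warns(UserWarning, match="empty mask"):
            out = ngf_distance(R, R, BinaryMask.on_grid(
                R, np.zeros(R.shape, bool)), 0.5)
        assert out["value"] == 0.0


class TestCurvatureEnergy:
    def test_zero_field(self):
        assert curvature_energy(DeformationField(
            np.zeros((3, 5, 5, 5)), SPACING))["value"] == 0.0

    def test_affine_null_space(self, rng):
        A = rng.standard_normal((3, 3))
        b = rng.standard_normal(3)
        x = np.indices((6, 6, 6)).astype(float) \
            * SPACING[:, None, None, None]
        u = np.einsum("ab,b...->a...", A, x) + b[:, None, None, None]
        assert curvature_energy(DeformationField(u, SPACING))["value"] \
            == pytest.approx(0.0, abs=1e-18)

    def test_quadratic_matches_oracle(self):
        u = np.zeros((3, 5, 5, 5))
        u[0] = (np.arange(5.0)[:, None, None] ** 2) * np.ones((5, 5, 5))
        sp = np.ones(3)
        got = curvature_energy(DeformationField(u, sp))["value"]
        assert got == pytest.approx(curvature_oracle(u, sp), rel=1e-10)

    def test_random_instance_matches_oracle(self, rng):
        u = rng.standard_normal((3, 5, 5, 5))
        got = curvature_energy(DeformationField(u, SPACING))["value"]
        assert got == pytest.approx(curvature_oracle(u, SPACING), rel=1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        u = rng.standard_normal((3, 5, 5, 5))
        g = curvature_energy(DeformationField(u, SPACING))["gradient"]
        e = 1e-6
        for _ in range(20):
            l = int(rng.integers(0, 3))
            idx = tuple(rng.integers(0, 5, 3))
            up, um = u.copy(), u.copy()
            up[(l,) + idx] += e
            um[(l,) + idx] -= e
            num = (curvature_energy(DeformationField(up, SPACING))["value"]
                   - curvature_energy(DeformationField(um, SPACING))["value"]
                   ) / (2 * e)
            assert num == pytest.approx(g[(l,) + idx], rel=1e-4, abs=1e-8)


class TestMasks:
    def test_beam_mask_recovers_cone(self, small_pair):
        est = estimate_beam_mask(small_pair.fixed)
        assert dice(est, small_pair.beam_mask) > 0.98

    def test_strictly_positive_volume_full_mask(self):
        v = Volume3D(np.ones((5, 5, 5)))
        assert estimate_beam_mask(v).data.all()

    def test_all_zero_volume_empty_mask(self):
        v = Volume3D(np.zeros((5, 5, 5)))
        with pytest.warns(UserWarning, match="zero"):
            assert estimate_beam_mask(v).count() == 0

    def test_combine_intersection_and_cavity(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[:2] = True   # 32 voxels
        b[1:3] = True  # 32 voxels, overlap rows 1 only
        out = combine_masks(BinaryMask(a), BinaryMask(b))
        assert out.count() == 16
        cav = np.zeros((4, 4, 4), bool)
        cav[1, :2] = True
        out2 = combine_masks(BinaryMask(a), BinaryMask(b), BinaryMask(cav))
        assert out2.count() == 8

    def test_cavity_covering_beam_raises(self):
        full = BinaryMask(np.ones((3, 3, 3), bool))
        with pytest.raises(ValueError, match="no overlap"):
            combine_masks(full, full, full)

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="grid"):
            combine_masks(BinaryMask(np.ones((3, 3, 3), bool)),
                          BinaryMask(np.ones((4, 4, 4), bool)))


class TestTransformLandmarks:
    def test_zero_field_identity(self):
        lm = LandmarkSet([[1, 2, 3], [4, 5, 6]], [[0, 0, 0], [0, 0, 0]])
        field = DeformationField(np.zeros((3, 8, 8, 8)))
        out = transform_landmarks(lm, field)
        np.testing.assert_allclose(out.points_fixed, lm.points_fixed)

    def test_constant_field_shifts(self):
        lm = LandmarkSet([[1, 2, 3]], [[0, 0, 0]])
        field = DeformationField(np.ones((3, 8, 8, 8)))
        out = transform_landmarks(lm, field)
        np.testing.assert_allclose(out.points_fixed[0], [2, 3, 4])

    def test_exact_at_grid_nodes(self, rng):
        u = rng.standard_normal((3, 6, 6, 6))
        field = DeformationField(u, spacing=(2.0, 2.0, 2.0))
        nodes = np.array([[1, 2, 3], [4, 0, 5]])
        lm = LandmarkSet(nodes * 2.0, np.zeros((2, 3)))
        out = transform_landmarks(lm, field)
        for k, n in enumerate(nodes):
            np.testing.assert_allclose(
                out.points_fixed[k] - lm.points_fixed[k],
                u[:, n[0], n[1], n[2]], atol=1e-12)

    def test_out_of_domain_listed(self):
        lm = LandmarkSet([[100, 0, 0]], [[0, 0, 0]], labels=["far"])
        field = DeformationField(np.zeros((3, 8, 8, 8)))
        with pytest.raises(ValueError, match="far"):
            transform_landmarks(lm, field)


class TestConfigs:
    def test_invalid_tolerances_rejected(self):
        with pytest.raises(ValueError):
            RegistrationConfig(min_progress=0.0)
        with pytest.raises(ValueError):
            RegistrationConfig(levels_deformable=0)

    def test_rigid_transform_determinant_check(self):
        with pytest.raises(ValueError, match="determinant"):
            RigidTransform(rotation=np.diag([1.0, 1.0, -1.0]))
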