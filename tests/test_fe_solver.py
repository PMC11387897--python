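"""Finite-element solver: stiffness, solution, recovery, invariants."""

import numpy as np
import pytest

import skullfea as sf
from skullfea.fe_solver import LoadCase, SolverError, element_stiffness
from skullfea.verification import (
    cantilever_benchmark,
    face_traction_loads,
    patch_test,
    tet_box,
)

from conftest import random_rotation


def oracle_element_stiffness(coords, E, nu):
    """Independent stiffness construction: shape-function coefficients from
    the 4x4 Vandermonde system [1 x y z], exact constant-strain integration."""
    coords = np.asarray(coords, float)
    M = np.column_stack([np.ones(4), coords])  # rows: [1, x_i, y_i, z_i]
    C = np.linalg.inv(M)  # column i: coefficients of N_i
    grads = C[1:, :].T  # (4,3) gradient of each shape function
    vol = abs(np.linalg.det(M)) / 6.0
    B = np.zeros((6, 12))
    for i in range(4):
        gx, gy, gz = grads[i]
        B[:, 3 * i: 3 * i + 3] = [
            [gx, 0, 0], [0, gy, 0], [0, 0, gz],
            [gy, gx, 0], [0, gz, gy], [gz, 0, gx],
        ]
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = lam * np.outer([1, 1, 1, 0, 0, 0], [1, 1, 1, 0, 0, 0]) + mu * np.diag(
        [2, 2, 2, 1, 1, 1]
    )
    return vol * B.T @ D @ B


class TestElementStiffness:
    COORDS = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)

    def test_symmetry_and_rigid_body_modes(self, material):
        K = element_stiffness(self.COORDS, material)
        assert np.allclose(K, K.T, atol=1e-12)
        w = np.linalg.eigvalsh(K)
        assert (w > -1e-8 * w.max()).all()  # positive semidefinite
        assert (np.abs(w) < 1e-8 * w.max()).sum() == 6  # 6 rigid-body modes

    def test_rigid_translation_in_nullspace(self, material):
        K = element_stiffness(self.COORDS, material)
        for d in range(3):
            t = np.zeros(12)
            t[d::3] = 1.0
            assert np.abs(K @ t).max() < 1e-9 * np.abs(K).max()

    def test_matches_independent_oracle_unit_tet(self):
        mat = sf.MaterialProperties(youngs_modulus=1.0, poisson_ratio=0.0)
        K = element_stiffness(self.COORDS, mat)
        K_oracle = oracle_element_stiffness(self.COORDS, 1.0, 0.0)
        np.testing.assert_allclose(K, K_oracle, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_oracle_random_tet(self, seed, material):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(4, 3)) * 10
        K = element_stiffness(coords, material)
        K_oracle = oracle_element_stiffness(
            coords, material.youngs_modulus, material.poisson_ratio
        )
        np.testing.assert_allclose(K, K_oracle, rtol=1e-9, atol=1e-6)

    def test_degenerate_tet_rejected(self, material):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        with pytest.raises(SolverError):
            element_stiffness(flat, material)


class TestMaterial:
    @pytest.mark.parametrize("E,nu", [(-1, 0.3), (0, 0.3), (1, 0.5), (1, -1.0)])
    def test_invalid_properties(self, E, nu):
        with pytest.raises(ValueError):
            sf.MaterialProperties(E, nu)


class TestSolve:
    def test_zero_loads_zero_field(self, cranium, material):
        lc = LoadCase(constraints={int(n): (0, 1, 2)
                                   for n in cranium.joint_nodes})
        fld = sf.solve(cranium.mesh, material, lc)
        assert np.abs(fld.displacements).max() == 0.0
        assert np.abs(fld.von_mises).max() == 0.0

    def test_unconstrained_system_rejected(self, unit_tet, material):
        lc = LoadCase(point_loads={0: np.array([1.0, 0, 0])})
        with pytest.raises(SolverError):
            sf.solve(unit_tet, material, lc)

    def test_constrained_displacements_exactly_zero(self, cranium, material,
                                                    cranium_field, cranium_loads):
        for node in cranium_loads.constraints:
            assert np.all(cranium_field.displacements[node] == 0.0)

    def test_global_equilibrium(self, cranium, cranium_loads, cranium_field):
        applied = cranium_loads.total_nodal_forces(cranium.mesh.n_nodes).sum(axis=0)
        reactions = sum(cranium_field.reactions.values())
        scale = np.abs(applied).max()
        assert np.abs(applied + reactions).max() < 1e-6 * scale

    def test_linearity(self, cranium, material, cranium_loads):
        f1 = sf.solve(cranium.mesh, material, cranium_loads)
        lc2 = sf.perturb_loads(cranium_loads, 3.0, "global")
        f2 = sf.solve(cranium.mesh, material, lc2)
        np.testing.assert_allclose(f2.displacements, 3.0 * f1.displacements,
                                   rtol=1e-9, atol=1e-15)
        np.testing.assert_allclose(f2.von_mises, 3.0 * f1.von_mises,
                                   rtol=1e-9, atol=1e-15)

    def test_superposition(self, cranium, material):
        spec = sf.MuscleSpec(adductor_area=cranium.adductor_area)
        lc_m = sf.build_load_case(cranium, spec=spec)
        lc_b = sf.build_load_case(cranium, muscles=[],
                                  bite=sf.BiteConfig(magnitude=250.0))
        lc_both = sf.build_load_case(cranium, spec=spec,
                                     bite=sf.BiteConfig(magnitude=250.0))
        fm = sf.solve(cranium.mesh, material, lc_m)
        fb = sf.solve(cranium.mesh, material, lc_b)
        fboth = sf.solve(cranium.mesh, material, lc_both)
        np.testing.assert_allclose(
            fboth.displacements, fm.displacements + fb.displacements,
            rtol=1e-8, atol=1e-12,
        )

    def test_frame_indifference(self, cranium, material, cranium_loads,
                                cranium_field):
        R = random_rotation(11)
        mesh2 = sf.TetMesh(cranium.mesh.nodes @ R.T, cranium.mesh.tets.copy(),
                           {k: v.copy() for k, v in cranium.mesh.node_sets.items()})
        lc2 = LoadCase(
            constraints={k: (0, 1, 2) for k in cranium_loads.constraints},
            point_loads={k: R @ v for k, v in cranium_loads.point_loads.items()},
            muscle_loads={
                g: {k: R @ v for k, v in grp.items()}
                for g, grp in cranium_loads.muscle_loads.items()
            },
        )
        fld2 = sf.solve(mesh2, material, lc2)
        np.testing.assert_allclose(
            fld2.displacements, cranium_field.displacements @ R.T,
            rtol=1e-7, atol=1e-10,
        )
        ref = np.abs(cranium_field.von_mises).max()
        assert np.abs(fld2.von_mises - cranium_field.von_mises).max() < 1e-8 * ref


class TestPatchTest:
    def test_uniform_uniaxial_state(self):
        r = patch_test(force=1000.0)
        assert r.max_rel_err_stress < 1e-8
        assert r.max_rel_err_vm < 1e-8


class TestCantilever:
    def test_tip_deflection_and_convergence(self, material):
        errs = [cantilever_benchmark(refinement=r, material=material).rel_err
                for r in (1, 2, 3)]
        assert errs[0] > errs[1] > errs[2]  # monotone mesh convergence
        packaged = cantilever_benchmark(material=material)
        assert packaged.rel_err < 0.05


class TestVonMises:
    def test_uniaxial(self):
        s = np.diag([10.0, 0, 0])
        assert sf.von_mises_from_tensor(s) == pytest.approx(10.0)

    def test_hydrostatic(self):
        assert sf.von_mises_from_tensor(np.eye(3) * 7.0) == pytest.approx(0.0)

    def test_pure_shear(self):
        s = np.zeros((3, 3))
        s[0, 1] = s[1, 0] = 5.0
        assert sf.von_mises_from_tensor(s) == pytest.approx(5 * np.sqrt(3))

    @pytest.mark.parametrize("seed", range(3))
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(3, 3))
        s = (a + a.T) / 2
        R = random_rotation(seed + 100)
        v1 = sf.von_mises_from_tensor(s)
        v2 = sf.von_mises_from_tensor(R @ s @ R.T)
        assert v2 == pytest.approx(v1, rel=1e-10)


class TestPrincipalStrains:
    def test_diagonal(self):
        e = np.diag([3e-4, 2e-4, 1e-4])
        np.testing.assert_allclose(sf.principal_strains(e),
                                   [3e-4, 2e-4, 1e-4])

    def test_zero(self):
        np.testing.assert_array_equal(sf.principal_strains(np.zeros((3, 3))),
                                      np.zeros(3))

    def test_rotation_invariance(self):
        e = np.diag([5e-4, -1e-4, 2e-4])
        R = random_rotation(42)
        np.testing.assert_allclose(
            sf.principal_strains(R @ e @ R.T),
            sorted([5e-4, 2e-4, -1e-4], reverse=True), atol=1e-12,
        )


class TestFaceLoads:
    def test_consistent_loads_sum_to_traction_times_area(self):
        mesh = tet_box(4.0, 2.0, 3.0, 2, 2, 2)
        loads = face_traction_loads(mesh, "x1", np.array([2.0, 0, 0]))
        total = sum(loads.values())
        np.testing.assert_allclose(total, [2.0 * 2.0 * 3.0, 0, 0], atol=1e-12)
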