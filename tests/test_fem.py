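"""FEM assembly, dipole sources, sensor mappings and transfer matrices."""

import numpy as np
import pytest
import scipy.sparse as sp

from sensmap.conductivity import ConductivityField
from sensmap.fem import (
    assemble_stiffness,
    compute_leadfield,
    compute_transfer_matrix,
    eeg_restriction,
    meg_integration_rows,
    partial_integration_rhs,
    primary_b_field,
    rhs_matrix,
)
from sensmap.meshing import LabeledTetMesh
from sensmap.sensors import SensorSet

_MU0 = 4e-7 * np.pi


def single_tet_mesh(scale_mm=1000.0):
    """One reference tetrahedron; default scale makes coordinates 1 m in SI."""
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]) * scale_mm
    return LabeledTetMesh(nodes, np.array([[0, 1, 2, 3]]), np.array([0]), {0: "t"})


def iso_field(mesh, sigma=1.0):
    return ConductivityField(
        np.tile(sigma * np.eye(3), (mesh.n_elements, 1, 1)), "homogeneous"
    )


class TestStiffness:
    def test_reference_tet_hand_integrated(self):
        # vol = 1/6 m^3; gradients: g0 = (-1,-1,-1), g1 = e_x, g2 = e_y,
        # g3 = e_z; K = vol * G G^T for sigma = I
        mesh = single_tet_mesh()
        K = assemble_stiffness(mesh, iso_field(mesh)).matrix.toarray()
        G = np.array([[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        np.testing.assert_allclose(K, (G @ G.T) / 6.0, atol=1e-14)

    def test_constant_nullspace(self, four_layer_mesh, four_layer_cond):
        K = assemble_stiffness(four_layer_mesh, four_layer_cond).matrix
        ones = np.ones(K.shape[0])
        scale = np.abs(K.data).max()
        assert np.abs(K @ ones).max() < 1e-10 * scale
        # symmetry
        assert abs(K - K.T).max() < 1e-14 * scale

    def test_linear_in_sigma(self):
        mesh = single_tet_mesh()
        k1 = assemble_stiffness(mesh, iso_field(mesh, 1.0)).matrix.toarray()
        k3 = assemble_stiffness(mesh, iso_field(mesh, 3.0)).matrix.toarray()
        np.testing.assert_allclose(k3, 3.0 * k1, rtol=1e-12)

    def test_degenerate_element_rejected(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0],
                          [0, 0, 1.0]])
        mesh = LabeledTetMesh(nodes, np.array([[0, 1, 2, 3], [0, 1, 2, 4]]),
                              np.array([0, 0]), {0: "t"})
        with pytest.raises(ValueError, match="degenerate"):
            assemble_stiffness(mesh, iso_field(mesh))


class TestPartialIntegration:
    def test_entries_sum_to_zero(self, four_layer_mesh):
        f = partial_integration_rhs(four_layer_mesh, [5.0, 6.0, 7.0],
                                    [0.0, 0.0, 1.0])
        assert f.nnz <= 4
        assert abs(f.sum()) < 1e-12 * np.abs(f.data).max()

    def test_reference_tet_x_moment_gives_gradient_x_components(self):
        mesh = single_tet_mesh()
        f = partial_integration_rhs(
            mesh, [250.0, 250.0, 250.0], [1.0, 0.0, 0.0], moment=1.0
        ).toarray().ravel()
        np.testing.assert_allclose(f, [-1.0, 1.0, 0.0, 0.0], atol=1e-12)

    def test_linear_in_moment(self, four_layer_mesh):
        f1 = partial_integration_rhs(four_layer_mesh, [1.0, 2.0, 3.0],
                                     [1.0, 0, 0], moment=1e-9)
        f2 = partial_integration_rhs(four_layer_mesh, [1.0, 2.0, 3.0],
                                     [1.0, 0, 0], moment=2e-9)
        np.testing.assert_allclose(f2.toarray(), 2 * f1.toarray(), rtol=1e-12)

    def test_outside_position_rejected(self, four_layer_mesh):
        with pytest.raises(ValueError, match="outside"):
            partial_integration_rhs(four_layer_mesh, [0.0, 0.0, 200.0], [1, 0, 0])


class TestEegRestriction:
    def test_one_unit_entry_per_row(self, four_layer_mesh, four_layer_sensors):
        R = eeg_restriction(four_layer_mesh, four_layer_sensors)
        assert R.shape == (32, four_layer_mesh.n_nodes)
        assert R.nnz == 32
        np.testing.assert_allclose(R.data, 1.0)
        # constant potential reads constant
        u = np.full(four_layer_mesh.n_nodes, 3.7)
        np.testing.assert_allclose(R @ u, 3.7)

    def test_unsnapped_electrode_rejected(self, four_layer_mesh,
                                          four_layer_sensors):
        bad = SensorSet(
            four_layer_sensors.electrode_positions + 0.5,
            four_layer_sensors.electrode_labels,
            four_layer_sensors.coil_positions,
            four_layer_sensors.coil_orientations,
            four_layer_sensors.coil_labels,
        )
        with pytest.raises(ValueError, match="coincide"):
            eeg_restriction(four_layer_mesh, bad)


class TestMegRows:
    def test_constant_potential_reads_zero(self, homogeneous_sphere):
        mesh, cond = homogeneous_sphere
        sens = _coil_ring(n=6)
        M = meg_integration_rows(mesh, cond, sens)
        u = np.ones(mesh.n_nodes)
        np.testing.assert_allclose(M @ u, 0.0, atol=1e-10 * np.abs(M).max())

    def test_direct_biot_savart_oracle_small_mesh(self):
        # independent element-loop quadrature of sigma grad(u) x kernel
        mesh = LabeledTetMesh(
            np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10],
                      [10, 10, 10.0]]),
            np.array([[0, 1, 2, 3], [4, 1, 2, 3]]),
            np.array([0, 0]), {0: "t"},
        )
        cond = iso_field(mesh, 0.5)
        coil_p = np.array([[60.0, -40.0, 80.0]])
        coil_o = np.array([[0.0, 1.0, 0.0]])
        sens = SensorSet(np.zeros((1, 3)), ["E1"], coil_p, coil_o, ["M1"])
        M = meg_integration_rows(mesh, cond, sens)
        rng = np.random.default_rng(0)
        u = rng.normal(size=mesh.n_nodes)

        from sensmap.fem import _QUAD_BARY, _QUAD_W, _element_geometry
        verts, vol, grads = _element_geometry(mesh)
        b = np.zeros(3)
        for e in range(mesh.n_elements):
            gu = sum(u[mesh.elements[e][i]] * grads[e, i] for i in range(4))
            j = 0.5 * gu  # sigma grad u
            for q in range(4):
                x = _QUAD_BARY[q] @ verts[e]
                r = coil_p[0] * 1e-3 - x
                w = vol[e] * _QUAD_W[q]
                b += -(_MU0 / (4 * np.pi)) * w * np.cross(j, r) / np.linalg.norm(r) ** 3
        assert M[0] @ u == pytest.approx(b @ coil_o[0], rel=1e-10)

    def test_linearity(self, homogeneous_sphere):
        mesh, cond = homogeneous_sphere
        sens = _coil_ring(n=3)
        M = meg_integration_rows(mesh, cond, sens)
        rng = np.random.default_rng(1)
        u1, u2 = rng.normal(size=(2, mesh.n_nodes))
        np.testing.assert_allclose(M @ (u1 + u2), M @ u1 + M @ u2, rtol=1e-9)

    def test_coil_inside_or_too_close_rejected(self, homogeneous_sphere):
        mesh, cond = homogeneous_sphere
        inside = SensorSet(np.zeros((1, 3)), ["E"], np.array([[0.0, 0.0, 40.0]]),
                           np.array([[0.0, 0.0, 1.0]]), ["M"])
        with pytest.raises(ValueError, match="inside|closer"):
            meg_integration_rows(mesh, cond, inside)


def _coil_ring(n, radius=130.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pos = np.column_stack([radius * np.cos(th), radius * np.sin(th), np.zeros(n)])
    ori = pos / radius
    return SensorSet(np.zeros((1, 3)), ["E"], pos, ori,
                     [f"M{i}" for i in range(n)])


class TestPrimaryField:
    def test_parallel_moment_zero(self):
        assert primary_b_field([0, 0, 0], [0, 0, 1.0], [0, 0, 50.0],
                               [0, 1.0, 0]) == 0.0

    def test_inverse_square_of_kernel(self):
        b1 = primary_b_field([0, 0, 0], [1.0, 0, 0], [0, 0, 50.0], [0, 1, 0.0])
        b2 = primary_b_field([0, 0, 0], [1.0, 0, 0], [0, 0, 100.0], [0, 1, 0.0])
        assert b1 == pytest.approx(4 * b2, rel=1e-12)

    def test_independent_numeric_evaluation(self):
        # q = 10 nAm x_hat at origin, r = (0, 0, 0.1) m, o = y_hat
        got = primary_b_field([0, 0, 0], [1.0, 0, 0], [0, 0, 100.0],
                              [0, 1.0, 0], moment=10e-9)
        q = np.array([10e-9, 0, 0])
        r = np.array([0, 0, 0.1])
        expected = (_MU0 / (4 * np.pi) * np.cross(q, r) / 0.1 ** 3) @ [0, 1, 0]
        assert got == pytest.approx(expected, rel=1e-12)


class TestTransferMatrix:
    def test_matches_direct_solve_every_pair(self, small_three_layer):
        """Transfer path equals a direct regularized solve for all pairs."""
        mesh, cond = small_three_layer
        from sensmap.sensors import place_sensors

        sens = place_sensors(mesh, 8, 6, coil_offset=15.0, seed=0)
        system = assemble_stiffness(mesh, cond)
        R = eeg_restriction(mesh, sens)
        T = compute_transfer_matrix(system, R, "eeg")
        rng = np.random.default_rng(0)
        for _ in range(5):
            p = rng.normal(size=3) * 5
            f = partial_integration_rhs(mesh, p, [0.0, 0.0, 1.0]).toarray().ravel()
            u = system.solve(f)
            direct = R @ u - (R @ u).mean()
            via_transfer = T.values @ f
            via_transfer = via_transfer - via_transfer.mean()
            np.testing.assert_allclose(via_transfer, direct,
                                       atol=1e-10 * np.abs(direct).max())

    def test_cg_agrees_with_direct(self, small_three_layer):
        mesh, cond = small_three_layer
        from sensmap.sensors import place_sensors

        sens = place_sensors(mesh, 4, 4, coil_offset=15.0, seed=1)
        R = eeg_restriction(mesh, sens)
        Td = compute_transfer_matrix(
            assemble_stiffness(mesh, cond, solver="direct"), R, "eeg")
        Tc = compute_transfer_matrix(
            assemble_stiffness(mesh, cond, solver="cg", rtol=1e-10), R, "eeg")
        f = partial_integration_rhs(mesh, [2.0, 1.0, 3.0], [1, 0, 0.0])
        a, b = Td.values @ f.toarray().ravel(), Tc.values @ f.toarray().ravel()
        np.testing.assert_allclose(a - a.mean(), b - b.mean(),
                                   atol=1e-7 * np.abs(a).max())

    def test_zero_sensor_row_gives_zero_transfer_row(self, small_three_layer):
        mesh, cond = small_three_layer
        system = assemble_stiffness(mesh, cond)
        rows = sp.csr_matrix((2, mesh.n_nodes))
        T = compute_transfer_matrix(system, rows, "meg")
        assert T.shape == (2, mesh.n_nodes)
        np.testing.assert_allclose(T.values, 0.0, atol=1e-15)


class TestLeadfield:
    def test_eeg_columns_average_referenced(self, small_three_layer):
        mesh, cond = small_three_layer
        from sensmap.sensors import place_sensors

        sens = place_sensors(mesh, 8, 4, coil_offset=15.0, seed=0)
        system = assemble_stiffness(mesh, cond)
        T = compute_transfer_matrix(system, eeg_restriction(mesh, sens), "eeg")
        pos = np.array([[0, 0, 5.0], [3.0, 0, 8.0]])
        ori = np.array([[0, 0, 1.0], [1.0, 0, 0]])
        lf, _ = compute_leadfield(T, None, mesh, cond, pos, ori)
        np.testing.assert_allclose(lf.values.mean(axis=0), 0.0, atol=1e-12)

    def test_flipped_orientation_negates_column(self, small_three_layer):
        mesh, cond = small_three_layer
        from sensmap.sensors import place_sensors

        sens = place_sensors(mesh, 8, 4, coil_offset=15.0, seed=0)
        system = assemble_stiffness(mesh, cond)
        T = compute_transfer_matrix(system, eeg_restriction(mesh, sens), "eeg")
        pos = np.array([[0, 0, 5.0]])
        a, _ = compute_leadfield(T, None, mesh, cond, pos, np.array([[0, 0, 1.0]]))
        b, _ = compute_leadfield(T, None, mesh, cond, pos, np.array([[0, 0, -1.0]]))
        np.testing.assert_allclose(b.values, -a.values, rtol=1e-12)

    def test_potentials_scale_inversely_with_sigma(self, small_three_layer):
        mesh, cond = small_three_layer
        from sensmap.sensors import place_sensors

        sens = place_sensors(mesh, 8, 4, coil_offset=15.0, seed=0)
        scaled = ConductivityField(2.0 * cond.tensors, cond.variant)
        pos, ori = np.array([[0, 0, 5.0]]), np.array([[1.0, 0, 0]])
        lf1, _ = compute_leadfield(
            compute_transfer_matrix(assemble_stiffness(mesh, cond),
                                    eeg_restriction(mesh, sens), "eeg"),
            None, mesh, cond, pos, ori)
        lf2, _ = compute_leadfield(
            compute_transfer_matrix(assemble_stiffness(mesh, scaled),
                                    eeg_restriction(mesh, sens), "eeg"),
            None, mesh, scaled, pos, ori)
        np.testing.assert_allclose(lf2.values, lf1.values / 2.0, rtol=1e-9)
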