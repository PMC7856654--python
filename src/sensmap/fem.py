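"""First-order Lagrangian FEM for the EEG/MEG forward problem.

Piecewise-linear basis on tetrahedra, partial-integration dipole right-hand
sides, and the transfer-matrix approach: one adjoint solve per sensor makes
every additional dipole a sparse dot product.  The EEG potential system is a
pure-Neumann problem; its constant nullspace is handled by zero-mean right-
hand sides plus either a grounded direct factorization (default) or a
projected Jacobi-preconditioned conjugate-gradient solver.

All computation here is in SI units (m, S/m, A m, V, T); mesh coordinates
arrive in mm and are converted on entry.  Leadfields are returned in the
reporting units uV/nAm (EEG, average-referenced) and fT/nAm (MEG).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .analytic import _MU0
from .conductivity import ConductivityField
from .meshing import LabeledTetMesh
from .sensors import SensorSet

__all__ = [
    "StiffnessSystem",
    "TransferMatrix",
    "Leadfield",
    "assemble_stiffness",
    "partial_integration_rhs",
    "rhs_matrix",
    "eeg_restriction",
    "meg_integration_rows",
    "primary_b_field",
    "compute_transfer_matrix",
    "compute_leadfield",
]

_MM = 1e-3  # mm -> m

# 4-point Gauss rule on the reference tetrahedron (degree-2 exact),
# barycentric coordinates; weights sum to 1 (scaled by element volume).
_QUAD_BARY = np.array(
    [
        [0.5854101966249685, 0.1381966011250105, 0.1381966011250105, 0.1381966011250105],
        [0.1381966011250105, 0.5854101966249685, 0.1381966011250105, 0.1381966011250105],
        [0.1381966011250105, 0.1381966011250105, 0.5854101966249685, 0.1381966011250105],
        [0.1381966011250105, 0.1381966011250105, 0.1381966011250105, 0.5854101966249685],
    ]
)
_QUAD_W = np.full(4, 0.25)


def _element_geometry(mesh: LabeledTetMesh):
    """Vertices (m), signed volumes (m^3) and basis gradients (1/m).

    Gradients: (n_elements, 4, 3); row i is the constant gradient of the
    barycentric (hat) function of local vertex i.
    """
    verts = mesh.element_vertices() * _MM
    e = np.stack(
        [verts[:, 1] - verts[:, 0], verts[:, 2] - verts[:, 0], verts[:, 3] - verts[:, 0]],
        axis=1,
    )  # (E, 3, 3) rows are edge vectors
    vol = np.linalg.det(e) / 6.0
    bad = np.nonzero(np.abs(vol) < 1e-12 * np.max(np.abs(vol), initial=0.0))[0]
    if len(bad):
        raise ValueError(f"degenerate (zero-volume) element(s): {bad[:10].tolist()}")
    inv = np.linalg.inv(e)  # columns of inv are gradients of lambda_1..3
    grads = np.empty((len(verts), 4, 3))
    grads[:, 1:, :] = np.transpose(inv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    return verts, vol, grads


@dataclass
class StiffnessSystem:
    """Sparse FEM stiffness matrix with cached factorization/solver state."""

    matrix: sp.csr_matrix               # (n_nodes, n_nodes), S m
    solver: str = "direct"              # "direct" | "cg"
    rtol: float = 1e-8
    max_iter: int = 5000

    _lu: object = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def _grounded_lu(self):
        if self._lu is None:
            k = self.matrix.tocsc()[1:, 1:]
            self._lu = spla.splu(k)
        return self._lu

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Solve K u = rhs for zero-sum rhs; solution returned zero-mean.

        ``rhs`` may be (n,) or (n, k).
        """
        rhs = np.asarray(rhs, dtype=float)
        one_d = rhs.ndim == 1
        b = rhs[:, None] if one_d else rhs
        if self.solver == "direct":
            x = np.zeros_like(b)
            x[1:] = self._grounded_lu().solve(b[1:])
        elif self.solver == "cg":
            x = np.empty_like(b)
            d = self.matrix.diagonal()
            d[d <= 0] = 1.0
            M = sp.diags(1.0 / d)
            for j in range(b.shape[1]):
                rj = b[:, j] - b[:, j].mean()
                xj, info = spla.cg(
                    self.matrix, rj, M=M, rtol=self.rtol, maxiter=self.max_iter
                )
                if info != 0:
                    res = np.linalg.norm(self.matrix @ xj - rj) / np.linalg.norm(rj)
                    raise RuntimeError(
                        f"CG failed to converge (info={info}, rel residual {res:.2e})"
                    )
                x[:, j] = xj
        else:
            raise ValueError(f"unknown solver {self.solver!r}")
        x = x - x.mean(axis=0, keepdims=True)
        return x[:, 0] if one_d else x


@dataclass
class TransferMatrix:
    """Dense sensors x nodes matrix mapping nodal potentials to readings."""

    values: np.ndarray  # (n_sensors, n_nodes)
    modality: str       # "eeg" | "meg"

    @property
    def shape(self):
        return self.values.shape


@dataclass
class Leadfield:
    """Sensors x sources forward solutions per unit (1 nAm) dipole moment.

    EEG in uV/nAm, average-referenced over channels; MEG in fT/nAm for
    orientation-projected point coils.
    """

    values: np.ndarray  # (n_sensors, n_dipoles)
    modality: str

    @property
    def n_sensors(self) -> int:
        return self.values.shape[0]

    @property
    def n_sources(self) -> int:
        return self.values.shape[1]


def assemble_stiffness(
    mesh: LabeledTetMesh,
    conductivity: ConductivityField,
    solver: str = "direct",
    rtol: float = 1e-8,
) -> StiffnessSystem:
    """Assemble K_ij = sum_E vol(E) grad(phi_i) . sigma_E grad(phi_j)."""
    if len(conductivity.tensors) != mesh.n_elements:
        raise ValueError("conductivity field does not match the mesh")
    _, vol, grads = _element_geometry(mesh)
    sigma_g = np.einsum("eab,eib->eia", conductivity.tensors, grads)
    ke = np.einsum("e,eia,eja->eij", vol, grads, sigma_g)  # (E, 4, 4)

    conn = mesh.elements
    rows = np.repeat(conn, 4, axis=1).ravel()
    cols = np.tile(conn, (1, 4)).ravel()
    K = sp.coo_matrix(
        (ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()
    K = (K + K.T) * 0.5  # enforce exact symmetry against round-off
    return StiffnessSystem(K, solver=solver, rtol=rtol)


def partial_integration_rhs(
    mesh: LabeledTetMesh,
    position,
    orientation,
    moment: float = 1e-9,
) -> sp.csr_matrix:
    """Partial-integration source vector for one dipole (sparse (n_nodes, 1)).

    ``position`` mm, ``orientation`` unit vector, ``moment`` in A m
    (default 1 nAm).  Entries are q . grad(phi_i) over the host element's
    vertices and sum to zero.
    """
    return rhs_matrix(mesh, np.atleast_2d(position), np.atleast_2d(orientation), moment)


def rhs_matrix(
    mesh: LabeledTetMesh,
    positions: np.ndarray,
    orientations: np.ndarray,
    moment: float = 1e-9,
) -> sp.csr_matrix:
    """Sparse (n_nodes, n_dipoles) partial-integration right-hand sides."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    orientations = np.atleast_2d(np.asarray(orientations, dtype=float))
    if positions.shape != orientations.shape:
        raise ValueError("positions and orientations must match")
    _, _, grads = _element_geometry(mesh)

    outside = []
    hosts = np.empty(len(positions), dtype=np.int64)
    for i, p in enumerate(positions):
        try:
            hosts[i] = mesh.locate_element(p)
        except ValueError:
            outside.append(i)
    if outside:
        raise ValueError(f"dipole(s) outside the mesh: {outside[:10]}")

    q = moment * orientations  # (D, 3) A m
    vals = np.einsum("dj,dij->di", q, grads[hosts])  # (D, 4)
    rows = mesh.elements[hosts].ravel()
    cols = np.repeat(np.arange(len(positions)), 4)
    return sp.coo_matrix(
        (vals.ravel(), (rows, cols)), shape=(mesh.n_nodes, len(positions))
    ).tocsr()


def eeg_restriction(
    mesh: LabeledTetMesh, sensors: SensorSet, tol: float = 1e-6
) -> sp.csr_matrix:
    """Sparse (n_electrodes x n_nodes) point-evaluation map (one 1 per row).

    Electrodes must coincide with mesh nodes (the snapping contract of the
    sensor placement); a non-matching electrode raises.
    """
    from scipy.spatial import cKDTree

    tree = cKDTree(mesh.nodes)
    d, idx = tree.query(sensors.electrode_positions)
    bad = np.nonzero(d > tol)[0]
    if len(bad):
        raise ValueError(
            f"electrode(s) {bad[:10].tolist()} do not coincide with mesh nodes "
            f"(max offset {d.max():.3g} mm)"
        )
    n = sensors.n_eeg
    return sp.coo_matrix(
        (np.ones(n), (np.arange(n), idx)), shape=(n, mesh.n_nodes)
    ).tocsr()


def meg_integration_rows(
    mesh: LabeledTetMesh,
    conductivity: ConductivityField,
    sensors: SensorSet,
) -> np.ndarray:
    """Dense (n_coils x n_nodes) map from nodal potentials to secondary field.

    Row for an oriented coil (r, o) evaluates o . B_sec(r) with

        B_sec(r) = -(mu0 / 4 pi) sum_E  (sigma_E grad u|_E) x W_E(r),
        W_E(r)   = integral_E (r - x) / |r - x|^3 dx,

    the element integrals by a fixed 4-point quadrature.  Coils must lie
    strictly outside the mesh, farther than one local element diameter
    (kernel near-singularity guard).
    """
    verts, vol, grads = _element_geometry(mesh)  # SI
    sigma_g = np.einsum("eab,eib->eia", conductivity.tensors, grads)  # (E,4,3)
    qpts = np.einsum("qi,eij->eqj", _QUAD_BARY, verts)  # (E, 4, 3) m

    coils = np.asarray(sensors.coil_positions, dtype=float) * _MM
    orient = np.asarray(sensors.coil_orientations, dtype=float)

    # per-element diameters for the near-singularity guard
    diam = np.max(
        np.linalg.norm(verts[:, :, None, :] - verts[:, None, :, :], axis=-1),
        axis=(1, 2),
    )  # (E,)

    conn = mesh.elements
    n_nodes = mesh.n_nodes
    rows = np.zeros((len(coils), n_nodes))
    wq = vol[:, None] * _QUAD_W[None, :]  # (E, 4)
    for ci, (c, o) in enumerate(zip(coils, orient)):
        d = c[None, None, :] - qpts  # (E, 4, 3)
        dist = np.linalg.norm(d, axis=-1)  # (E, 4)
        # guard: a coil closer to an element than that element's diameter
        # makes the fixed-order quadrature unreliable (kernel near-singular)
        if np.any(dist.min(axis=1) < diam):
            inside = True
            try:
                mesh.locate_element(c / _MM)
            except ValueError:
                inside = False
            if inside:
                raise ValueError(f"coil {ci} lies inside the mesh")
            raise ValueError(
                f"coil {ci} closer than one element diameter to the mesh "
                f"(min distance {dist.min():.4g} m)"
            )
        r3 = dist ** 3
        W = np.einsum("eq,eqj->ej", wq / r3, d)  # (E, 3)
        Wxo = np.cross(W, o)  # (E, 3)
        # o . (v x W) = v . (W x o)
        contrib = -(_MU0 / (4.0 * np.pi)) * np.einsum("eia,ea->ei", sigma_g, Wxo)
        np.add.at(rows[ci], conn.ravel(), contrib.ravel())
    return rows


def primary_b_field(
    dipole_position,
    dipole_orientation,
    point,
    orientation,
    moment: float = 1e-9,
) -> float:
    """Infinite-medium dipole field reading o . B_p(r) in tesla.

    Positions mm; ``moment`` A m.  Needed to total the MEG forward solution
    (secondary field from the FEM potential plus this primary term).
    """
    r0 = np.asarray(dipole_position, dtype=float) * _MM
    r = np.asarray(point, dtype=float) * _MM
    q = moment * np.asarray(dipole_orientation, dtype=float)
    o = np.asarray(orientation, dtype=float)
    d = r - r0
    dist = np.linalg.norm(d)
    if dist < 1e-12:
        raise ValueError("field point coincides with the dipole")
    B = _MU0 / (4.0 * np.pi) * np.cross(q, d) / dist ** 3
    return float(B @ o)


def _primary_b_matrix(
    positions: np.ndarray,
    orientations: np.ndarray,
    coils_mm: np.ndarray,
    coil_orient: np.ndarray,
    moment: float,
) -> np.ndarray:
    """(n_coils, n_dipoles) primary-field readings in tesla, vectorized."""
    r0 = np.asarray(positions, dtype=float) * _MM       # (D, 3)
    r = np.asarray(coils_mm, dtype=float) * _MM          # (C, 3)
    q = moment * np.asarray(orientations, dtype=float)   # (D, 3)
    d = r[:, None, :] - r0[None, :, :]                   # (C, D, 3)
    dist3 = np.linalg.norm(d, axis=-1) ** 3
    qxd = np.cross(np.broadcast_to(q[None, :, :], d.shape), d)
    return _MU0 / (4.0 * np.pi) * np.einsum(
        "cdj,cj->cd", qxd / dist3[..., None], coil_orient
    )


def compute_transfer_matrix(
    system: StiffnessSystem,
    sensor_rows,
    modality: str,
) -> TransferMatrix:
    """Adjoint transfer matrix: solve K t_k = r_k^T per sensor row.

    EEG rows (point evaluations) are shifted to zero mean, which is absorbed
    by the average reference later; MEG rows already annihilate constants.
    """
    R = np.asarray(
        sensor_rows.todense() if sp.issparse(sensor_rows) else sensor_rows, dtype=float
    )
    if R.shape[1] != system.n_nodes:
        raise ValueError("sensor row length does not match node count")
    rhs = R.T - R.T.mean(axis=0, keepdims=True)
    T = system.solve(rhs).T
    return TransferMatrix(np.ascontiguousarray(T), modality)


def compute_leadfield(
    transfer_eeg: TransferMatrix | None,
    transfer_meg: TransferMatrix | None,
    mesh: LabeledTetMesh,
    conductivity: ConductivityField,
    positions: np.ndarray,
    orientations: np.ndarray,
    sensors: SensorSet | None = None,
) -> tuple[Leadfield | None, Leadfield | None]:
    """EEG and/or MEG leadfields for a dipole set, per 1 nAm moment.

    EEG columns are average-referenced and reported in uV/nAm; MEG columns
    are the FEM secondary field plus the infinite-medium primary field at the
    coils, reported in fT/nAm.
    """
    moment = 1e-9  # 1 nAm in A m
    F = rhs_matrix(mesh, positions, orientations, moment=moment)

    lf_eeg = lf_meg = None
    if transfer_eeg is not None:
        u = transfer_eeg.values @ F  # volts
        u = u - u.mean(axis=0, keepdims=True)  # average reference
        lf_eeg = Leadfield(np.asarray(u) * 1e6, "eeg")  # V -> uV, per nAm
    if transfer_meg is not None:
        if sensors is None:
            raise ValueError("MEG leadfield needs the sensor set for primary fields")
        b_sec = transfer_meg.values @ F  # tesla
        b_pri = _primary_b_matrix(
            positions, orientations, sensors.coil_positions,
            sensors.coil_orientations, moment,
        )
        lf_meg = Leadfield((np.asarray(b_sec) + b_pri) * 1e15, "meg")  # T -> fT
    return lf_eeg, lf_meg
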