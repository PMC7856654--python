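"""FEM-vs-oracle validation on concentric-sphere models.

EEG: FEM potentials on a 4-layer sphere mesh against the multilayer
Legendre-series solution, for radial and tangential dipoles at a range of
eccentricities.  MEG: FEM total fields on a homogeneous sphere against the
Sarvas closed form, plus the radial-source null check.  Errors are reported
as RDM (topography) and lnMAG (magnitude).
"""

from __future__ import annotations

import numpy as np

from .analytic import SphereModel, eeg_sphere_potential, lnmag, meg_sphere_field, rdm
from .conductivity import ConductivityField, assign_conductivities
from .fem import (
    assemble_stiffness,
    compute_leadfield,
    compute_transfer_matrix,
    eeg_restriction,
    meg_integration_rows,
)
from .meshing import build_layered_sphere_mesh
from .sensors import place_sensors

__all__ = ["validate_eeg_against_sphere", "validate_meg_against_sarvas"]

FOUR_LAYER_RADII = (78.0, 80.0, 86.0, 92.0)
FOUR_LAYER_SIGMA = (0.33, 1.79, 0.01, 0.43)
DEFAULT_ECCENTRICITIES = (0.3, 0.5, 0.7, 0.8)


def validate_eeg_against_sphere(
    target_edge_length: float = 6.0,
    n_electrodes: int = 71,
    eccentricities=DEFAULT_ECCENTRICITIES,
    seed: int = 0,
    rtol: float = 1e-8,
    solver: str = "direct",
) -> list[dict]:
    """RDM/lnMAG of FEM EEG vs the 4-layer sphere series, per dipole case."""
    mesh = build_layered_sphere_mesh(FOUR_LAYER_RADII, target_edge_length, seed=seed)
    cond = assign_conductivities(mesh, "4CI")
    sensors = place_sensors(mesh, n_electrodes, 8, coil_offset=20.0, seed=seed + 1)
    system = assemble_stiffness(mesh, cond, solver=solver, rtol=rtol)
    T = compute_transfer_matrix(system, eeg_restriction(mesh, sensors), "eeg")

    model = SphereModel(list(FOUR_LAYER_RADII), list(FOUR_LAYER_SIGMA))
    elec = sensors.electrode_positions
    rows = []
    for ecc in eccentricities:
        pos = np.array([0.0, 0.0, FOUR_LAYER_RADII[0] * ecc])
        for name, ori in (("radial", [0.0, 0.0, 1.0]), ("tangential", [1.0, 0.0, 0.0])):
            ori = np.asarray(ori)
            lf, _ = compute_leadfield(T, None, mesh, cond, pos[None, :], ori[None, :])
            ana = eeg_sphere_potential(model, pos, ori, elec)
            ana = ana - ana.mean()
            rows.append({
                "modality": "eeg", "eccentricity": ecc, "orientation": name,
                "rdm": rdm(lf.values[:, 0], ana),
                "lnmag": lnmag(lf.values[:, 0], ana),
                "n_elements": mesh.n_elements,
            })
    return rows


def validate_meg_against_sarvas(
    target_edge_length: float = 7.0,
    n_coils: int = 64,
    sphere_radius: float = 92.0,
    sigma: float = 0.33,
    eccentricities=DEFAULT_ECCENTRICITIES,
    seed: int = 0,
    rtol: float = 1e-8,
    solver: str = "direct",
) -> list[dict]:
    """RDM/lnMAG of FEM MEG vs Sarvas (tangential) and the radial null ratio.

    The radial rows carry the ratio of the radial dipole's total-field norm
    to the co-located tangential one in the ``radial_ratio`` column.
    """
    mesh = build_layered_sphere_mesh(
        [sphere_radius], target_edge_length, seed=seed, label_names=["brain"]
    )
    cond = ConductivityField(
        np.tile(sigma * np.eye(3), (mesh.n_elements, 1, 1)), "homogeneous"
    )
    sensors = place_sensors(mesh, 16, n_coils, coil_offset=20.0, seed=seed + 1)
    system = assemble_stiffness(mesh, cond, solver=solver, rtol=rtol)
    T = compute_transfer_matrix(
        system, meg_integration_rows(mesh, cond, sensors), "meg"
    )

    rows = []
    for ecc in eccentricities:
        pos = np.array([0.0, 0.0, sphere_radius * ecc])
        _, lf_tan = compute_leadfield(
            None, T, mesh, cond, pos[None, :], np.array([[1.0, 0.0, 0.0]]),
            sensors=sensors,
        )
        _, lf_rad = compute_leadfield(
            None, T, mesh, cond, pos[None, :], np.array([[0.0, 0.0, 1.0]]),
            sensors=sensors,
        )
        ana = np.array([
            meg_sphere_field([0.0, 0.0, 0.0], pos, [1.0, 0.0, 0.0], c) @ o
            for c, o in zip(sensors.coil_positions, sensors.coil_orientations)
        ])
        tan_norm = np.linalg.norm(lf_tan.values[:, 0])
        rows.append({
            "modality": "meg", "eccentricity": ecc, "orientation": "tangential",
            "rdm": rdm(lf_tan.values[:, 0], ana),
            "lnmag": lnmag(lf_tan.values[:, 0], ana),
            "radial_ratio": np.nan,
            "n_elements": mesh.n_elements,
        })
        rows.append({
            "modality": "meg", "eccentricity": ecc, "orientation": "radial",
            "rdm": np.nan, "lnmag": np.nan,
            "radial_ratio": float(np.linalg.norm(lf_rad.values[:, 0]) / tan_norm),
            "n_elements": mesh.n_elements,
        })
    return rows
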