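"""Compartment conductivities for the three head-model variants.

Values in S/m.  The three variants share one mesh and differ only in how the
elements are labeled/valued:

* ``3CI`` — scalp, skull, brain (isotropic)
* ``4CI`` — scalp, skull, CSF, brain (isotropic)
* ``6CA`` — scalp, skull compacta, skull spongiosa, CSF, gray matter and
  anisotropic white matter; the white-matter tensors are constrained so the
  mean of their eigenvalues equals the isotropic reference value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meshing import LabeledTetMesh

__all__ = [
    "CONDUCTIVITY_TABLE",
    "ConductivityField",
    "assign_conductivities",
    "make_anisotropic_tensor",
    "variant_sigma",
]

#: isotropic conductivity (S/m) per compartment and variant
CONDUCTIVITY_TABLE: dict[str, dict[str, float]] = {
    "3CI": {"brain": 0.33, "skull": 0.01, "scalp": 0.43},
    "4CI": {"brain": 0.33, "csf": 1.79, "skull": 0.01, "scalp": 0.43},
    "6CA": {
        "white_matter": 0.14,  # mean eigenvalue of the anisotropic tensor
        "gray_matter": 0.33,
        "csf": 1.79,
        "skull_spongiosa": 0.025,
        "skull_compacta": 0.008,
        "scalp": 0.43,
    },
}

#: compartments with anisotropic tensors, per variant
ANISOTROPIC_COMPARTMENTS = {"6CA": ("white_matter",)}


@dataclass
class ConductivityField:
    """Per-element 3x3 symmetric positive-definite conductivity tensors (S/m)."""

    tensors: np.ndarray  # (n_elements, 3, 3)
    variant: str

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 3 or self.tensors.shape[1:] != (3, 3):
            raise ValueError("tensors must be (n, 3, 3)")

    def is_spd(self, tol: float = 1e-12) -> bool:
        sym = np.allclose(self.tensors, np.transpose(self.tensors, (0, 2, 1)))
        eig = np.linalg.eigvalsh(self.tensors)
        return sym and bool(np.all(eig > tol))


def variant_sigma(variant: str, compartment: str) -> float:
    """Isotropic (or mean-eigenvalue) conductivity of one compartment."""
    try:
        return CONDUCTIVITY_TABLE[variant][compartment]
    except KeyError as exc:
        raise KeyError(f"no conductivity for {compartment!r} in variant {variant!r}") from exc


def make_anisotropic_tensor(
    fiber_direction,
    reference_sigma: float,
    anisotropy_ratio: float = 10.0,
) -> np.ndarray:
    """Axially symmetric conductivity tensor aligned with a fiber direction.

    The longitudinal eigenvalue (along the fiber) and the two transversal
    eigenvalues satisfy ``lam_l / lam_t = anisotropy_ratio`` and
    ``(lam_l + 2 lam_t) / 3 = reference_sigma`` (tensor eigenvalue mean fits
    the isotropic reference).
    """
    d = np.asarray(fiber_direction, dtype=float)
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise ValueError("fiber_direction must be nonzero")
    if reference_sigma <= 0:
        raise ValueError("reference_sigma must be positive")
    if anisotropy_ratio < 1:
        raise ValueError("anisotropy_ratio must be >= 1")
    d = d / nrm
    lam_t = 3.0 * reference_sigma / (anisotropy_ratio + 2.0)
    lam_l = anisotropy_ratio * lam_t
    outer = np.outer(d, d)
    return lam_t * np.eye(3) + (lam_l - lam_t) * outer


def assign_conductivities(
    mesh: LabeledTetMesh,
    variant: str,
    anisotropy_ratio: float = 10.0,
) -> ConductivityField:
    """Per-element tensors for a labeled mesh under one model variant.

    Isotropic compartments get ``sigma * I``.  For 6CA the white-matter
    elements get tensors from :func:`make_anisotropic_tensor` with a locally
    radial fiber direction — the synthetic stand-in for diffusion-derived
    fiber fields on the sphere phantom.
    """
    if variant not in CONDUCTIVITY_TABLE:
        raise ValueError(f"unknown variant {variant!r}")
    table = CONDUCTIVITY_TABLE[variant]
    names = set(mesh.label_names.values())
    missing = set(table) - names
    if missing:
        raise ValueError(
            f"mesh lacks compartments required by {variant}: {sorted(missing)}"
        )

    tensors = np.zeros((mesh.n_elements, 3, 3))
    aniso = ANISOTROPIC_COMPARTMENTS.get(variant, ())
    centroids = None
    for label, name in mesh.label_names.items():
        sel = mesh.labels == label
        if not np.any(sel):
            continue
        sigma = variant_sigma(variant, name)
        if name in aniso:
            if centroids is None:
                centroids = mesh.element_centroids()
            c = centroids[sel]
            r = np.linalg.norm(c, axis=1, keepdims=True)
            fibers = np.where(r > 1e-9, c / np.maximum(r, 1e-30), [0.0, 0.0, 1.0])
            lam_t = 3.0 * sigma / (anisotropy_ratio + 2.0)
            lam_l = anisotropy_ratio * lam_t
            tensors[sel] = lam_t * np.eye(3) + (lam_l - lam_t) * np.einsum(
                "ni,nj->nij", fibers, fibers
            )
        else:
            tensors[sel] = sigma * np.eye(3)
    return ConductivityField(tensors, variant)


def relabel_for_variant(mesh: LabeledTetMesh, variant: str) -> LabeledTetMesh:
    """Merge/rename the 6-shell reference labeling down to a coarser variant.

    The same geometric mesh serves all variants: only element labels change.
    Expects the 6-shell naming (white/gray matter, csf, spongiosa/compacta,
    scalp); 4CI merges brain and skull sublayers, 3CI additionally merges CSF
    into brain.
    """
    name_of = mesh.label_names
    inv = {v: k for k, v in name_of.items()}
    required = set(CONDUCTIVITY_TABLE["6CA"])
    if set(name_of.values()) == set(CONDUCTIVITY_TABLE[variant]):
        return mesh
    if not required <= set(name_of.values()):
        raise ValueError("relabeling requires the 6-shell reference labeling")

    if variant == "6CA":
        return mesh
    if variant == "4CI":
        merge = {
            "white_matter": "brain", "gray_matter": "brain", "csf": "csf",
            "skull_spongiosa": "skull", "skull_compacta": "skull", "scalp": "scalp",
        }
        order = ["brain", "csf", "skull", "scalp"]
    elif variant == "3CI":
        merge = {
            "white_matter": "brain", "gray_matter": "brain", "csf": "brain",
            "skull_spongiosa": "skull", "skull_compacta": "skull", "scalp": "scalp",
        }
        order = ["brain", "skull", "scalp"]
    else:
        raise ValueError(f"unknown variant {variant!r}")

    new_id = {name: i for i, name in enumerate(order)}
    labels = np.empty_like(mesh.labels)
    for old_name, new_name in merge.items():
        labels[mesh.labels == inv[old_name]] = new_id[new_name]
    return LabeledTetMesh(
        mesh.nodes, mesh.elements, labels, {i: n for n, i in new_id.items()}
    )
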