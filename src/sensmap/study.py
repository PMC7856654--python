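"""Full sensitivity-study orchestration.

One 6-shell reference mesh is built and then *relabeled* for each head-model
variant (3CI/4CI/6CA) — the geometry never changes between variants, only
the tissue labels and tensors.  Cortical dipoles are derived once from the
6-shell gray-matter labeling and reused everywhere, so SNR differences
between variants reflect conductivity modeling alone.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field as dc_field, fields as dc_fields, asdict
from pathlib import Path

import numpy as np

from .conductivity import assign_conductivities, relabel_for_variant
from .fem import (
    assemble_stiffness,
    compute_leadfield,
    compute_transfer_matrix,
    eeg_restriction,
    meg_integration_rows,
)
from .meshing import LabeledTetMesh, build_ball_mesh, build_layered_sphere_mesh
from .noise import estimate_noise_variance, synth_noise_baseline
from .sensors import place_sensors
from .snr import (
    SnrConfig,
    differential_snr,
    heatmap_by_column,
    project_subcortical,
    snr_map,
    summarize_by_bins,
)
from .sources import (
    DipoleSet,
    cortical_dipoles_from_surface,
    source_angles,
    source_depths,
    subcortical_dipoles_from_regions,
)
from .surfaces import sphere_surface, synth_cortex_surface

log = logging.getLogger("sensmap")

__all__ = ["StudyConfig", "StudyResults", "VariantResults", "run_sensitivity_study",
           "stage_seed", "DEFAULT_SUBCORTICAL_REGIONS"]

#: nine subcortical regions as balls (center mm, radius mm) inside the brain
#: shell of the sphere phantom; sizes roughly ordered like the anatomical ones
DEFAULT_SUBCORTICAL_REGIONS: dict[str, tuple[tuple[float, float, float], float]] = {
    "cerebellum": ((0.0, -30.0, -25.0), 14.0),
    "thalamus": ((0.0, -8.0, 8.0), 8.0),
    "caudate": ((12.0, 12.0, 8.0), 6.0),
    "putamen": ((-20.0, 5.0, 0.0), 6.0),
    "pallidum": ((16.0, -2.0, 0.0), 5.0),
    "hippocampus": ((-24.0, -18.0, -8.0), 6.0),
    "amygdala": ((22.0, -14.0, -10.0), 5.0),
    "accumbens_area": ((-8.0, 16.0, -6.0), 4.0),
    "ventral_diencephalon": ((6.0, -4.0, -12.0), 6.0),
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed; adding stages never shifts existing ones."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) & 0x7FFFFFFF


@dataclass
class StudyConfig:
    """All knobs of the synthetic sphere study (lengths mm, S/m, nAm)."""

    # 6-shell reference geometry: white|gray at 60, gray|csf 78, csf|skull 80,
    # spongiosa|compacta 83, compacta|scalp 86, scalp|air 92
    radii: tuple = (60.0, 78.0, 80.0, 83.0, 86.0, 92.0)
    target_edge_length: float = 6.0
    variants: tuple = ("3CI", "4CI", "6CA")
    anisotropy_ratio: float = 10.0

    n_electrodes: int = 71
    n_coils: int = 271
    coil_offset: float = 20.0

    cortex_base_radius: float = 60.0
    cortex_fold_amplitude: float = 14.0
    cortex_fold_frequency: int = 8
    cortex_resolution: int = 4

    subcortical_regions: dict = dc_field(
        default_factory=lambda: {
            k: (list(v[0]), v[1]) for k, v in DEFAULT_SUBCORTICAL_REGIONS.items()
        }
    )
    subcortical_edge_factor: float = 1.2  # region mesh edge = radius / factor

    eeg_noise_variance: float = 10.0     # uV^2
    meg_noise_variance: float = 1.0e4    # fT^2
    noise_samples: int = 10_000
    noise_channel_jitter: float = 0.2

    amplitude: float = 10.0              # nAm

    solver: str = "direct"
    solver_tol: float = 1e-8

    depth_range: tuple = (0.0, 50.0)
    angle_range: tuple = (0.0, 180.0)
    n_bins: int = 5
    snr_bins: int = 20
    inner_skull_resolution: int = 6      # icosphere subdivision, <= 2 mm spacing

    seed: int = 0

    def validate(self) -> None:
        radii = tuple(self.radii)
        if any(b <= a for a, b in zip(radii, radii[1:])) or radii[0] <= 0:
            raise ValueError("radii must be positive and strictly increasing")
        if len(radii) != 6:
            raise ValueError("the reference geometry needs six shell radii")
        for v in self.variants:
            if v not in ("3CI", "4CI", "6CA"):
                raise ValueError(f"unknown variant {v!r}")
        if self.cortex_base_radius + self.cortex_fold_amplitude >= radii[1]:
            raise ValueError("cortex surface would escape the brain compartment")
        for name, (center, radius) in self.subcortical_regions.items():
            if np.linalg.norm(center) + radius >= radii[1]:
                raise ValueError(f"subcortical region {name!r} leaves the brain")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.eeg_noise_variance <= 0 or self.meg_noise_variance <= 0:
            raise ValueError("noise variances must be positive")
        if self.target_edge_length <= 0:
            raise ValueError("target_edge_length must be positive")

    def to_dict(self) -> dict:
        def listify(x):
            if isinstance(x, (tuple, list)):
                return [listify(v) for v in x]
            if isinstance(x, dict):
                return {k: listify(v) for k, v in x.items()}
            return x

        return {k: listify(v) for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        for name in ("radii", "variants", "depth_range", "angle_range"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        cfg.validate()
        return cfg


@dataclass
class VariantResults:
    """Leadfields, SNR maps and summaries for one head-model variant."""

    variant: str
    lf_eeg_cortical: np.ndarray      # (N_eeg, n_cort) uV/nAm
    lf_meg_cortical: np.ndarray      # (N_meg, n_cort) fT/nAm
    lf_eeg_subcortical: np.ndarray
    lf_meg_subcortical: np.ndarray
    snr_eeg_cortical: np.ndarray     # dB
    snr_meg_cortical: np.ndarray
    diff_snr_cortical: np.ndarray
    # subcortical, SVD-projected: per component ("radial", "tangential1",
    # "tangential2"), SNR per source node (group)
    snr_subcortical: dict            # comp -> {"eeg": arr, "meg": arr}
    subcortical_group_region: np.ndarray  # region name per source node
    summaries: dict                  # name -> BinnedSummary
    heatmaps: dict                   # name -> Heatmap2D
    solve_seconds: float = 0.0


@dataclass
class StudyResults:
    config: StudyConfig
    mesh: LabeledTetMesh
    cortex_surface: object
    inner_skull: object
    sensors: object
    noise: object
    cortical: DipoleSet
    subcortical: DipoleSet
    depths: np.ndarray
    angles: np.ndarray
    variants: dict                   # variant -> VariantResults


def _build_sources(cfg: StudyConfig, mesh6: LabeledTetMesh):
    """Cortical + subcortical dipole sets on the 6-shell reference labeling."""
    cortex = synth_cortex_surface(
        cfg.cortex_base_radius,
        cfg.cortex_fold_amplitude,
        cfg.cortex_fold_frequency,
        mesh_resolution=cfg.cortex_resolution,
        seed=stage_seed(cfg.seed, "cortex"),
        max_radius=cfg.radii[1],
    )
    gray_label = {v: k for k, v in mesh6.label_names.items()}["gray_matter"]
    cortical = cortical_dipoles_from_surface(cortex, mesh6, gray_label)

    regions = []
    for name, (center, radius) in cfg.subcortical_regions.items():
        edge = max(radius / cfg.subcortical_edge_factor, 2.0)
        regions.append(
            (name, build_ball_mesh(center, radius, edge,
                                   seed=stage_seed(cfg.seed, f"region:{name}"),
                                   label_name=name))
        )
    subcortical = subcortical_dipoles_from_regions(regions)
    return cortex, cortical, subcortical


def run_sensitivity_study(cfg: StudyConfig) -> StudyResults:
    """Run the full pipeline for every requested head-model variant."""
    cfg.validate()
    t_start = time.time()

    mesh6 = build_layered_sphere_mesh(
        cfg.radii, cfg.target_edge_length, seed=stage_seed(cfg.seed, "mesh")
    )
    log.info("mesh: %d nodes, %d elements", mesh6.n_nodes, mesh6.n_elements)

    sensors = place_sensors(
        mesh6, cfg.n_electrodes, cfg.n_coils, cfg.coil_offset,
        seed=stage_seed(cfg.seed, "sensors"),
    )
    baseline = synth_noise_baseline(
        sensors, cfg.eeg_noise_variance, cfg.meg_noise_variance,
        cfg.noise_samples, seed=stage_seed(cfg.seed, "noise"),
        channel_jitter=cfg.noise_channel_jitter,
    )
    noise = estimate_noise_variance(baseline)
    noise.validate_positive()

    cortex, cortical, subcortical = _build_sources(cfg, mesh6)
    log.info("sources: %d cortical, %d subcortical dipoles",
             len(cortical), len(subcortical))

    # csf|skull interface of the sphere phantom = inner skull surface
    inner_skull = sphere_surface(cfg.radii[2], subdivisions=cfg.inner_skull_resolution)
    depths = source_depths(cortical, inner_skull)
    angles = source_angles(cortical, inner_skull)

    all_pos = np.vstack([cortical.positions, subcortical.positions])
    all_ori = np.vstack([cortical.orientations, subcortical.orientations])
    n_cort = len(cortical)

    snr_cfg = SnrConfig(cfg.amplitude)
    results: dict[str, VariantResults] = {}
    for variant in cfg.variants:
        t0 = time.time()
        vmesh = relabel_for_variant(mesh6, variant)
        cond = assign_conductivities(vmesh, variant, cfg.anisotropy_ratio)
        system = assemble_stiffness(vmesh, cond, solver=cfg.solver, rtol=cfg.solver_tol)
        T_eeg = compute_transfer_matrix(system, eeg_restriction(vmesh, sensors), "eeg")
        T_meg = compute_transfer_matrix(
            system, meg_integration_rows(vmesh, cond, sensors), "meg"
        )
        lf_eeg, lf_meg = compute_leadfield(
            T_eeg, T_meg, vmesh, cond, all_pos, all_ori, sensors=sensors
        )
        solve_s = time.time() - t0
        log.info("variant %s: forward done in %.1f s", variant, solve_s)

        ec, es = lf_eeg.values[:, :n_cort], lf_eeg.values[:, n_cort:]
        mc, ms = lf_meg.values[:, :n_cort], lf_meg.values[:, n_cort:]

        snr_eeg = snr_map(ec, noise.eeg_variance, snr_cfg)
        snr_meg = snr_map(mc, noise.meg_variance, snr_cfg)
        diff = differential_snr(snr_meg, snr_eeg)

        projected = project_subcortical(es, ms, subcortical.group)
        groups = sorted(projected)
        comp_names = ("tangential1", "tangential2", "radial")
        snr_sub = {
            c: {"eeg": np.empty(len(groups)), "meg": np.empty(len(groups))}
            for c in comp_names
        }
        group_region = np.empty(len(groups), dtype=object)
        g_to_region = {}
        for g, reg in zip(subcortical.group, subcortical.region):
            g_to_region[int(g)] = reg
        for gi, g in enumerate(groups):
            group_region[gi] = g_to_region[g]
            p = projected[g]
            for ci, c in enumerate(comp_names):
                snr_sub[c]["eeg"][gi] = snr_map(
                    p.eeg[:, ci:ci + 1], noise.eeg_variance, snr_cfg
                )[0]
                snr_sub[c]["meg"][gi] = snr_map(
                    p.meg[:, ci:ci + 1], noise.meg_variance, snr_cfg
                )[0]

        summaries = {
            "snr_eeg_by_depth": summarize_by_bins(
                snr_eeg, depths, cfg.n_bins, cfg.depth_range),
            "snr_meg_by_depth": summarize_by_bins(
                snr_meg, depths, cfg.n_bins, cfg.depth_range),
            "snr_eeg_by_angle": summarize_by_bins(
                snr_eeg, angles, cfg.n_bins, cfg.angle_range),
            "snr_meg_by_angle": summarize_by_bins(
                snr_meg, angles, cfg.n_bins, cfg.angle_range),
            "diff_by_depth": summarize_by_bins(
                diff, depths, cfg.n_bins, cfg.depth_range),
            "diff_by_angle": summarize_by_bins(
                diff, angles, cfg.n_bins, cfg.angle_range),
        }
        heatmaps = {
            "eeg_depth": heatmap_by_column(snr_eeg, depths, cfg.snr_bins, cfg.n_bins,
                                           covariate_range=cfg.depth_range),
            "eeg_angle": heatmap_by_column(snr_eeg, angles, cfg.snr_bins, cfg.n_bins,
                                           covariate_range=cfg.angle_range),
            "meg_depth": heatmap_by_column(snr_meg, depths, cfg.snr_bins, cfg.n_bins,
                                           covariate_range=cfg.depth_range),
            "meg_angle": heatmap_by_column(snr_meg, angles, cfg.snr_bins, cfg.n_bins,
                                           covariate_range=cfg.angle_range),
        }

        results[variant] = VariantResults(
            variant=variant,
            lf_eeg_cortical=ec, lf_meg_cortical=mc,
            lf_eeg_subcortical=es, lf_meg_subcortical=ms,
            snr_eeg_cortical=snr_eeg, snr_meg_cortical=snr_meg,
            diff_snr_cortical=diff,
            snr_subcortical=snr_sub,
            subcortical_group_region=group_region,
            summaries=summaries, heatmaps=heatmaps,
            solve_seconds=solve_s,
        )

    log.info("study complete in %.1f s", time.time() - t_start)
    return StudyResults(
        config=cfg, mesh=mesh6, cortex_surface=cortex, inner_skull=inner_skull,
        sensors=sensors, noise=noise, cortical=cortical, subcortical=subcortical,
        depths=depths, angles=angles, variants=results,
    )


def export_results(res: StudyResults, out_dir) -> None:
    """Write the results bundle (HDF5 leadfields, CSV summaries, VTK maps)."""
    import pandas as pd

    from .fem import Leadfield
    from .io import (
        config_hash, save_config, write_dipoles_tsv, write_leadfield_h5,
        write_msh, write_sensors_tsv, write_surface_map, write_vtu,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_d = res.config.to_dict()
    chash = config_hash(cfg_d)
    save_config(cfg_d, out / "config.yaml")
    write_msh(res.mesh, out / "mesh.msh")
    write_vtu(res.mesh, out / "mesh.vtu")
    write_sensors_tsv(res.sensors, out / "sensors.tsv")
    write_dipoles_tsv(DipoleSet.concatenate([res.cortical, res.subcortical]),
                      out / "dipoles.tsv")

    for variant, vr in res.variants.items():
        write_leadfield_h5(
            out / f"leadfield_{variant}.h5",
            Leadfield(np.hstack([vr.lf_eeg_cortical, vr.lf_eeg_subcortical]), "eeg"),
            Leadfield(np.hstack([vr.lf_meg_cortical, vr.lf_meg_subcortical]), "meg"),
            attrs={"config_hash": chash, "variant": variant},
        )
        # cortical map on the cortex surface (one value per vertex/dipole)
        finite = np.nan_to_num(vr.diff_snr_cortical, neginf=-99.0)
        write_surface_map(
            res.cortex_surface,
            {
                "snr_eeg": np.nan_to_num(vr.snr_eeg_cortical, neginf=-99.0),
                "snr_meg": np.nan_to_num(vr.snr_meg_cortical, neginf=-99.0),
                "diff_snr": finite,
            },
            out / f"cortical_map_{variant}.vtk",
        )
        rows = []
        for name, s in vr.summaries.items():
            for b in range(s.n_bins):
                rows.append({
                    "summary": name, "bin": b,
                    "lo": s.edges[b], "hi": s.edges[b + 1], "count": s.counts[b],
                    "min": s.five_number[b, 0], "q1": s.five_number[b, 1],
                    "median": s.five_number[b, 2], "q3": s.five_number[b, 3],
                    "max": s.five_number[b, 4], "config_hash": chash,
                })
        pd.DataFrame(rows).to_csv(out / f"summaries_{variant}.csv", index=False)

        rows = []
        for comp, d in vr.snr_subcortical.items():
            for gi, reg in enumerate(vr.subcortical_group_region):
                rows.append({
                    "component": comp, "region": reg,
                    "snr_eeg": d["eeg"][gi], "snr_meg": d["meg"][gi],
                    "config_hash": chash,
                })
        pd.DataFrame(rows).to_csv(out / f"subcortical_snr_{variant}.csv", index=False)

        for name, hm in vr.heatmaps.items():
            pd.DataFrame(hm.matrix).to_csv(
                out / f"heatmap_{variant}_{name}.csv", index=False
            )
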