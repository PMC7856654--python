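# sensmap

FEM-based EEG/MEG sensitivity (SNR) mapping on layered volume-conductor head
models.

## What this is for

Whether a cortical or subcortical current source is visible in EEG, in MEG,
in both or in neither depends on its location, orientation and depth, and on
how faithfully the head's conductive anatomy — in particular the highly
conductive cerebrospinal fluid (CSF) — is modeled.  `sensmap` computes
per-source signal-to-noise-ratio maps for both modalities on tetrahedral
volume-conductor models of increasing detail (3-compartment isotropic,
4-compartment isotropic with CSF, 6-compartment with anisotropic white
matter), and the analyses that summarize them: differential SNR maps,
depth/angle-binned boxplot statistics, column-normalized heat maps, and an
SVD-based split of subcortical sources into radial and tangential
components.

Everything runs on synthetic layered-sphere head phantoms with a folded
synthetic cortex, so the whole pipeline is testable against quasi-analytic
sphere solutions without any external data.  The intended users are
methods-oriented EEG/MEG researchers who want reproducible sensitivity
simulations or a validated, self-contained FEM forward stack to build on.

## The model

The electric potential `u` in the head obeys the quasi-static equation
`∇·(σ∇u) = ∇·j_p` with a point-dipole primary current `j_p` and a no-flux
scalp boundary.  `sensmap` solves it with first-order Lagrangian FEM on a
labeled tetrahedral mesh, the partial-integration right-hand side for the
dipole, and the transfer-matrix approach (one adjoint solve per sensor, so
each additional dipole costs a sparse dot product).  MEG readings add the
analytic primary (infinite-medium) field to the secondary field computed
from the FEM potential by volume-current integration.

For each source `i` the SNR in dB is

    SNR_i = 10 log10( (a² / N) Σ_k  b_ki² / s_k² )

with `a = 10 nAm` the source amplitude, `N` the channel count, `b_ki` the
forward solution at sensor `k` per unit moment and `s_k²` the channel noise
variance estimated from baseline recordings.  The differential map is
`D_i = SNR_MEG,i − SNR_EEG,i`.  For subcortical sources with Cartesian
orientation triplets, the n×3 MEG leadfield `L = U S Vᵀ` is decomposed per
source node; the right singular vector of the smallest singular value is the
(near-)radial direction, and both modalities' leadfields are projected onto
`V` to yield one radial and two tangential components.

Accuracy is established against the multilayer concentric-sphere Legendre
series (EEG) and the Sarvas closed form (MEG), using the standard RDM
(topography) and lnMAG (magnitude) error measures.

## Worked example

```python
import numpy as np
from sensmap import StudyConfig, run_sensitivity_study

cfg = StudyConfig(variants=("3CI", "4CI"), n_electrodes=32, n_coils=64, seed=1)
res = run_sensitivity_study(cfg)

sup = res.depths < 15.0                     # superficial cortical sources
for v in ("3CI", "4CI"):
    m = np.median(res.variants[v].snr_eeg_cortical[sup])
    print(f"{v}: median superficial EEG SNR {m:+.2f} dB")
```

prints

```
3CI: median superficial EEG SNR -15.78 dB
4CI: median superficial EEG SNR -17.60 dB
```

— the 3-compartment model, which ignores CSF, overestimates superficial EEG
SNR by ~1.8 dB relative to the 4-compartment model: omitting the conductive
CSF layer suppresses the current shunting that in reality weakens scalp
potentials.  `res.variants[v]` also carries the MEG SNR map, the
differential map with its depth/angle summaries, and the SVD-projected
subcortical component SNRs per region.

The same pipeline is scriptable from the shell:

```bash
sensmap generate --out out/            # phantom, sensors, sources, noise
sensmap validate --out out/            # FEM vs sphere-oracle RDM/MAG report
sensmap report   --out out/            # full study: HDF5 + CSV + VTK maps
```

## Layout

- `sensmap.meshing` / `sensmap.surfaces` — layered-sphere tetrahedral
  phantoms, folded synthetic cortex, subcortical ball regions
- `sensmap.conductivity` — per-variant tissue conductivities, anisotropic
  white-matter tensors
- `sensmap.sensors` / `sensmap.noise` — point electrodes/coils, baseline
  noise generation and variance estimation
- `sensmap.analytic` — multilayer sphere EEG series, Sarvas MEG field,
  RDM/lnMAG
- `sensmap.fem` — stiffness assembly, partial-integration sources, transfer
  matrices, leadfields
- `sensmap.sources` / `sensmap.snr` — dipole spaces, depth/angle covariates,
  SNR/differential maps, SVD projection, summaries
- `sensmap.study` / `sensmap.cli` / `sensmap.io` — orchestration, CLI, file
  formats (MSH/VTU/PLY/VTK/TSV/HDF5/CSV/YAML)

See `docs/methods.md` for the modeling choices, defaults and limitations.
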