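"""SNR maps, differential maps, and the radial/tangential SVD projection.

The per-dipole signal-to-noise ratio in dB is

    SNR_i = 10 log10( (a^2 / N) * sum_k  b_ki^2 / s_k^2 )

with a the source amplitude (nAm), N the channel count, b_ki the forward
solution at sensor k per 1 nAm, and s_k^2 the channel noise variance.  The
differential map is D_i = SNR_MEG_i - SNR_EEG_i (positive where MEG is the
more sensitive modality).

For subcortical Cartesian triplets the n x 3 MEG leadfield L of each source
node is decomposed as L = U S V^T; the right singular vector of the smallest
singular value is the (near-)radial direction, and both modalities' triplet
leadfields are projected onto V's columns to give one radial and two
tangential component columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import Leadfield
from .sources import BinnedSummary, bin_values

__all__ = [
    "SnrConfig",
    "snr_map",
    "differential_snr",
    "svd_project",
    "ProjectedLeadfield",
    "project_subcortical",
    "summarize_by_bins",
    "heatmap_by_column",
    "Heatmap2D",
]

NEG_INF = -np.inf  # sentinel for zero leadfield columns


@dataclass
class SnrConfig:
    """Amplitude convention of the SNR maps: source strength a in nAm."""

    amplitude: float = 10.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


def snr_map(
    leadfield: Leadfield | np.ndarray,
    noise_variance: np.ndarray,
    config: SnrConfig | None = None,
) -> np.ndarray:
    """Per-dipole SNR in dB; zero columns map to -inf (kept as sentinel)."""
    config = config or SnrConfig()
    b = leadfield.values if isinstance(leadfield, Leadfield) else np.asarray(leadfield)
    b = np.atleast_2d(np.asarray(b, dtype=float))
    s2 = np.asarray(noise_variance, dtype=float).ravel()
    if len(s2) != b.shape[0]:
        raise ValueError("noise channel count does not match leadfield rows")
    if np.any(s2 <= 0):
        raise ValueError("noise variances must be strictly positive")
    n = b.shape[0]
    power = (config.amplitude ** 2 / n) * np.sum(b ** 2 / s2[:, None], axis=0)
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(power)


def differential_snr(snr_meg: np.ndarray, snr_eeg: np.ndarray) -> np.ndarray:
    """D_i = SNR_MEG_i - SNR_EEG_i, elementwise."""
    snr_meg = np.asarray(snr_meg, dtype=float)
    snr_eeg = np.asarray(snr_eeg, dtype=float)
    if snr_meg.shape != snr_eeg.shape:
        raise ValueError("SNR vectors must have equal length")
    return snr_meg - snr_eeg


@dataclass
class ProjectedLeadfield:
    """SVD split of one source node's Cartesian-triplet leadfields.

    ``v`` columns are ordered by descending singular value; column 3 is the
    (near-)radial direction.  ``meg``/``eeg`` hold the projected component
    columns [tangential-1, tangential-2, radial].
    """

    singular_values: np.ndarray  # (3,), descending
    v: np.ndarray                # (3, 3), orthonormal, sign-fixed
    meg: np.ndarray              # (n_meg, 3) projected columns
    eeg: np.ndarray              # (n_eeg, 3)

    @property
    def radial_direction(self) -> np.ndarray:
        return self.v[:, 2]


def svd_project(
    leadfield_meg_group: np.ndarray,
    leadfield_eeg_group: np.ndarray,
    meg_noise_std: np.ndarray | None = None,
) -> ProjectedLeadfield:
    """SVD of an n x 3 MEG leadfield; project both modalities onto V.

    By default the SVD is taken on the raw leadfield.  Passing
    ``meg_noise_std`` whitens the rows (divides by per-channel noise std)
    before the SVD, which makes the component split conserve the
    noise-weighted energy sum_k b^2/s^2 exactly even for heterogeneous
    noise; the projected component columns stay in raw (unwhitened) units.
    The sign of each V column is fixed so its largest-magnitude entry is
    positive.  Raises for a rank-0 MEG matrix.
    """
    L = np.asarray(leadfield_meg_group, dtype=float)
    E = np.asarray(leadfield_eeg_group, dtype=float)
    if L.ndim != 2 or L.shape[1] != 3:
        raise ValueError("MEG group leadfield must be n x 3")
    if not np.any(L):
        raise ValueError("rank-0 MEG leadfield group")
    Lw = L
    if meg_noise_std is not None:
        Lw = L / np.asarray(meg_noise_std, dtype=float).reshape(-1, 1)
    _, s, vt = np.linalg.svd(Lw, full_matrices=False)
    v = vt.T
    flip = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(3)])
    flip[flip == 0] = 1.0
    v = v * flip
    return ProjectedLeadfield(s, v, L @ v, E @ v)


def project_subcortical(
    lf_eeg: np.ndarray,
    lf_meg: np.ndarray,
    group: np.ndarray,
) -> dict[int, ProjectedLeadfield]:
    """Per-group SVD projection of subcortical triplet leadfields.

    ``group`` labels columns; each group must have exactly 3 columns (the
    Cartesian orientations of one source node).
    """
    out: dict[int, ProjectedLeadfield] = {}
    group = np.asarray(group)
    for g in np.unique(group):
        cols = np.nonzero(group == g)[0]
        if len(cols) != 3:
            raise ValueError(f"group {g} has {len(cols)} columns, expected 3")
        out[int(g)] = svd_project(lf_meg[:, cols], lf_eeg[:, cols])
    return out


def summarize_by_bins(
    values: np.ndarray,
    covariate: np.ndarray,
    n_bins: int = 5,
    covariate_range: tuple[float, float] | None = None,
) -> BinnedSummary:
    """Five-number summary of ``values`` per equal-width covariate bin.

    Non-finite values (the -inf sentinel of dead MEG columns) are excluded
    from the summaries but their covariates still define the binning range.
    """
    values = np.asarray(values, dtype=float).ravel()
    covariate = np.asarray(covariate, dtype=float).ravel()
    if len(values) != len(covariate):
        raise ValueError("values and covariate must have equal length")
    idx, summary = bin_values(covariate, n_bins=n_bins, value_range=covariate_range)
    counts = np.zeros(summary.n_bins, dtype=int)
    five = np.full((summary.n_bins, 5), np.nan)
    finite = np.isfinite(values)
    for b in range(summary.n_bins):
        sel = (idx == b) & finite
        counts[b] = int(np.sum(idx == b))
        if np.any(sel):
            five[b] = np.percentile(values[sel], [0, 25, 50, 75, 100], method="linear")
    return BinnedSummary(summary.edges, counts, five)


@dataclass
class Heatmap2D:
    """Column-normalized bidimensional histogram (SNR bins x covariate bins)."""

    matrix: np.ndarray           # (n_snr_bins, n_cov_bins), columns sum to 1 or 0
    snr_edges: np.ndarray
    covariate_edges: np.ndarray


def heatmap_by_column(
    snr: np.ndarray,
    covariate: np.ndarray,
    snr_bins: int | np.ndarray = 20,
    covariate_bins: int | np.ndarray = 5,
    snr_range: tuple[float, float] | None = None,
    covariate_range: tuple[float, float] | None = None,
) -> Heatmap2D:
    """Joint histogram of (SNR, covariate), each covariate column normalized.

    Empty columns stay all-zero.  Non-finite SNR sentinels are dropped.
    """
    snr = np.asarray(snr, dtype=float).ravel()
    covariate = np.asarray(covariate, dtype=float).ravel()
    if len(snr) != len(covariate):
        raise ValueError("snr and covariate must have equal length")
    finite = np.isfinite(snr)
    h, snr_edges, cov_edges = np.histogram2d(
        snr[finite], covariate[finite],
        bins=[snr_bins, covariate_bins],
        range=None if (snr_range is None and covariate_range is None)
        else [snr_range, covariate_range],
    )
    colsum = h.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(colsum > 0, h / np.where(colsum == 0, 1.0, colsum), 0.0)
    return Heatmap2D(h, snr_edges, cov_edges)
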