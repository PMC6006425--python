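"""Psychophysiological interaction (PPI) mapping.

The seed's BOLD series is extracted from a sphere, deconvolved to a neural
series on a microtime grid (ridge-regularised inversion of the HRF
convolution operator in a discrete-cosine basis), multiplied by the
contrast-coded psychological envelope, re-convolved with the HRF and
downsampled — giving the interaction regressor.  A whole-brain GLM with
psychological, physiological, interaction and confound columns then tests
which voxels carry task-dependent coupling with the seed, thresholded with
the voxel-p + 270 mm^3 cluster-extent rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import AcquisitionSpec, TaskDesign
from .geometry import GeometryError, sphere_mask
from .glm import DesignMatrix, contrast_map, dct_highpass_basis, fit_glm, threshold_map
from .hrf import canonical_hrf, hrf_convolve
from .volumes import Run, StatMap

__all__ = [
    "SeedSeries",
    "PPIDesign",
    "PPIResult",
    "extract_seed",
    "deconvolve",
    "build_ppi_design",
    "ppi_map",
]

MICROTIME_FACTOR = 16


@dataclass
class SeedSeries:
    centre_mm: np.ndarray
    radius_mm: float
    bold: np.ndarray                      # per volume
    tr_s: float
    neural: np.ndarray | None = None      # per microtime step
    microtime_factor: int = MICROTIME_FACTOR


def extract_seed(run: Run, centre_mm, radius_mm: float = 6.0) -> SeedSeries:
    """Mean BOLD over voxels whose centre lies within the seed sphere."""
    mask = sphere_mask(run.data.shape[:3], run.affine, centre_mm, radius_mm)
    if not mask.any():
        raise GeometryError(f"seed sphere at {tuple(centre_mm)} contains no voxels")
    bold = run.data[mask].mean(axis=0)
    return SeedSeries(np.asarray(centre_mm, float), radius_mm, bold, run.tr_s)


def _convolution_operator(n_volumes: int, tr_s: float, factor: int, hrf_kernel=None):
    """Matrix mapping microtime neural activity to BOLD at mid-volume times."""
    dtm = tr_s / factor
    n_micro = n_volumes * factor
    if hrf_kernel is None:
        hrf_kernel = canonical_hrf(dtm)
    t_vol = (np.arange(n_volumes) + 0.5) * tr_s
    tau = np.arange(n_micro) * dtm
    lag = t_vol[:, None] - tau[None, :]
    h = np.zeros_like(lag)
    inside = (lag >= 0) & (lag < len(hrf_kernel) * dtm)
    idx = np.clip((lag[inside] / dtm).astype(int), 0, len(hrf_kernel) - 1)
    h[inside] = hrf_kernel[idx]
    return h * dtm


def deconvolve(
    bold: np.ndarray,
    tr_s: float,
    microtime_factor: int = MICROTIME_FACTOR,
    ridge_lambda: float = 1e-2,
    hrf_kernel: np.ndarray | None = None,
) -> np.ndarray:
    """Estimate the neural series generating a BOLD series.

    Solves the Toeplitz convolution system at microtime resolution in a
    discrete-cosine basis of dimension n_volumes, with ridge penalty
    ``ridge_lambda`` scaled by the leading eigenvalue of the normal matrix.
    Returns the neural estimate at microtime resolution
    (length n_volumes * microtime_factor).
    """
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be >= 0")
    bold = np.asarray(bold, dtype=float)
    n_vol = len(bold)
    n_micro = n_vol * microtime_factor
    h = _convolution_operator(n_vol, tr_s, microtime_factor, hrf_kernel)
    j = np.arange(n_micro)
    basis = np.cos(np.pi * np.outer(j + 0.5, np.arange(n_vol)) / n_micro)
    g = h @ basis
    gtg = g.T @ g
    lam = ridge_lambda * float(np.linalg.eigvalsh(gtg).max())
    w = np.linalg.solve(gtg + lam * np.eye(n_vol), g.T @ bold)
    return basis @ w


@dataclass
class PPIDesign:
    psychological: np.ndarray
    physiological: np.ndarray
    interaction: np.ndarray
    tr_s: float
    contrast: dict[str, float]
    confounds: np.ndarray | None = None

    def __post_init__(self) -> None:
        cols = [self.psychological, self.physiological, self.interaction]
        for i in range(3):
            for j in range(i + 1, 3):
                a, b = cols[i], cols[j]
                if np.allclose(a, b) and np.any(a != 0):
                    raise ValueError("PPI columns must be mutually non-identical")


def build_ppi_design(
    seed: SeedSeries,
    design: TaskDesign,
    contrast: dict[str, float],
    acquisition: AcquisitionSpec,
    ridge_lambda: float = 1e-2,
    hrf_kernel: np.ndarray | None = None,
    include_condition_confounds: bool = True,
) -> PPIDesign:
    """Construct psychological, physiological and interaction regressors.

    ``contrast`` maps condition labels to weights and must sum to zero over
    the contrasted conditions (e.g. colour +1, semantic -1).  The
    psychological envelope is mean-centred over microtime steps where any
    contrasted condition is active; the interaction is the product of the
    deconvolved neural seed series with that envelope, re-convolved with the
    HRF and sampled at mid-volume times.

    By default the per-condition main-effect regressors are attached as
    confounds so that purely task-evoked voxel responses cannot masquerade
    as interaction effects.
    """
    missing = [c for c in contrast if c not in design.conditions]
    if missing:
        raise KeyError(f"contrast names absent from design: {missing}")
    if abs(sum(contrast.values())) > 1e-9:
        raise ValueError("contrast weights must sum to zero")
    factor = seed.microtime_factor
    dtm = acquisition.tr_s / factor
    n_micro = acquisition.n_volumes * factor
    if hrf_kernel is None:
        hrf_kernel = canonical_hrf(dtm)
    t_vol = acquisition.volume_times

    psych_micro = np.zeros(n_micro)
    on_any = np.zeros(n_micro, dtype=bool)
    for cond, w in contrast.items():
        u = design.condition_boxcar(cond, dtm, n_micro)
        psych_micro += w * u
        on_any |= u > 0
    if on_any.any() and np.any(psych_micro != 0):
        psych_micro = psych_micro - psych_micro[on_any].mean() * on_any

    def to_volumes(micro: np.ndarray) -> np.ndarray:
        conv = hrf_convolve(micro, hrf_kernel, dtm)
        t = np.arange(n_micro) * dtm
        return np.interp(t_vol, t, conv)

    psychological = to_volumes(psych_micro)

    if seed.neural is None:
        seed.neural = deconvolve(
            seed.bold, acquisition.tr_s, factor, ridge_lambda=ridge_lambda
        )
    neural = seed.neural
    if len(neural) != n_micro:
        raise ValueError("seed neural series length does not match the acquisition")
    interaction = to_volumes(neural * psych_micro)
    confounds = None
    if include_condition_confounds:
        cols = [
            to_volumes(design.condition_boxcar(c, dtm, n_micro)) for c in design.conditions
        ]
        if cols:
            confounds = np.column_stack(cols)
    return PPIDesign(
        psychological=psychological,
        physiological=np.asarray(seed.bold, float),
        interaction=interaction,
        tr_s=acquisition.tr_s,
        contrast=dict(contrast),
        confounds=confounds,
    )


@dataclass
class PPIResult:
    t_map: StatMap
    mask: np.ndarray
    clusters: list[dict]
    design: DesignMatrix


def ppi_map(
    run: Run,
    ppi: PPIDesign,
    hp_cutoff_s: float = 128.0,
    p_voxel: float = 0.005,
    extent_mm3: float = 270.0,
    extra_confounds: np.ndarray | None = None,
) -> PPIResult:
    """Whole-brain interaction t map with voxel-p + cluster-extent threshold."""
    n_vol = run.n_volumes
    if len(ppi.interaction) != n_vol:
        raise ValueError("PPI design length does not match the run")
    names = ["interaction", "psychological", "physiological"]
    cols = [ppi.interaction, ppi.psychological, ppi.physiological]
    if ppi.confounds is not None:
        for j in range(ppi.confounds.shape[1]):
            names.append(f"confound_{j}")
            cols.append(ppi.confounds[:, j])
    if extra_confounds is not None:
        for j in range(extra_confounds.shape[1]):
            names.append(f"extra_{j}")
            cols.append(extra_confounds[:, j])
    hp = dct_highpass_basis(n_vol, ppi.tr_s, hp_cutoff_s)
    for k in range(hp.shape[1]):
        names.append(f"dct_{k + 1}")
        cols.append(hp[:, k])
    names.append("constant")
    cols.append(np.ones(n_vol))
    dm = DesignMatrix(names, np.column_stack(cols), ppi.tr_s, hp_cutoff_s)
    fit = fit_glm(run, dm)
    tmap = contrast_map(fit, {"interaction": 1.0}, label="ppi-interaction")
    mask, clusters = threshold_map(tmap, p_voxel=p_voxel, extent_mm3=extent_mm3)
    return PPIResult(tmap, mask, clusters, dm)
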