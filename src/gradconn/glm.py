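"""First-level mass-univariate GLM.

Condition regressors are boxcars convolved with the canonical HRF on a
microtime grid and sampled at mid-volume acquisition times.  Nuisance terms
comprise a mean-centred reaction-time parametric modulator, optional motion
series, a discrete-cosine high-pass basis up to the 128-s cutoff, and a
constant; rest is modelled implicitly.  Estimation is ordinary least squares
per voxel (the generator produces white noise, so no prewhitening), followed
by contrast effect/t maps, Gaussian smoothing, and the operational
suprathreshold rule used throughout: a voxel-level p threshold plus a
cluster-extent constraint of 270 mm^3 (10 voxels at 3 mm isotropic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .design import AcquisitionSpec, TaskDesign
from .hrf import canonical_hrf, hrf_convolve, sample_at
from .volumes import Run, StatMap, Volume

__all__ = [
    "MulticollinearityError",
    "DesignMatrix",
    "GLMFit",
    "build_design_matrix",
    "dct_highpass_basis",
    "smooth_volume",
    "fit_glm",
    "contrast",
    "contrast_map",
    "threshold_map",
    "one_sample_t_map",
]


class MulticollinearityError(ValueError):
    """Raised when the design matrix is rank deficient."""


def dct_highpass_basis(n_volumes: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine regressors spanning fluctuations slower than the cutoff.

    Component k has frequency k / (2 * T); all k with frequency below
    1/cutoff are included (k = 1 .. floor(2T / cutoff)).
    """
    total = n_volumes * tr_s
    k_max = int(math.floor(2.0 * total / cutoff_s))
    n = np.arange(n_volumes)
    cols = [np.cos(np.pi * k * (n + 0.5) / n_volumes) for k in range(1, k_max + 1)]
    if not cols:
        return np.zeros((n_volumes, 0))
    basis = np.column_stack(cols)
    return basis / np.linalg.norm(basis, axis=0)


@dataclass
class DesignMatrix:
    names: list[str]
    x: np.ndarray
    tr_s: float
    hp_cutoff_s: float
    condition_names: list[str] = field(default_factory=list)

    @property
    def n_volumes(self) -> int:
        return self.x.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.x[:, self.names.index(name)]

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        c = np.zeros(self.x.shape[1])
        for name, w in weights.items():
            if name not in self.names:
                raise KeyError(f"no design column named {name!r}")
            c[self.names.index(name)] = w
        return c


def _find_dependent_columns(x: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(x.shape[1]):
        others = np.delete(x, j, axis=1)
        proj, *_ = np.linalg.lstsq(others, x[:, j], rcond=None)
        resid = x[:, j] - others @ proj
        denom = np.linalg.norm(x[:, j]) + 1e-30
        if np.linalg.norm(resid) / denom < 1e-8:
            bad.append(names[j])
    return bad


def build_design_matrix(
    design: TaskDesign,
    acquisition: AcquisitionSpec,
    rt_s: np.ndarray | None = None,
    motion: np.ndarray | None = None,
    hp_cutoff_s: float = 128.0,
    dt: float = 0.1,
    hrf_kernel: np.ndarray | None = None,
    rt_per_condition: bool = False,
) -> DesignMatrix:
    """Assemble the first-level design matrix for one run.

    ``rt_s`` is the per-trial reaction-time covariate; by default it enters
    as a single pooled mean-centred parametric modulator spanning all
    conditions (set ``rt_per_condition`` for one modulator per condition).
    ``motion`` is an (n_volumes, 6) array of realignment series.
    """
    if hrf_kernel is None:
        hrf_kernel = canonical_hrf(dt)
    times = acquisition.volume_times
    n_vol = acquisition.n_volumes
    n_steps = max(int(round(acquisition.duration_s / dt)), 1)

    names: list[str] = []
    cols: list[np.ndarray] = []
    condition_names: list[str] = []
    for cond in design.conditions:
        if not any(b.condition == cond for b in design.blocks):
            continue
        u = design.condition_boxcar(cond, dt, n_steps)
        cols.append(sample_at(hrf_convolve(u, hrf_kernel, dt), dt, times))
        names.append(cond)
        condition_names.append(cond)

    if rt_s is not None and len(design.trials) > 0:
        rt_s = np.asarray(rt_s, dtype=float)
        if len(rt_s) != len(design.trials):
            raise ValueError(
                f"rt covariate length {len(rt_s)} != {len(design.trials)} trials"
            )
        groups = (
            {c: [i for i, t in enumerate(design.trials) if t.condition == c]
             for c in condition_names}
            if rt_per_condition
            else {"all": list(range(len(design.trials)))}
        )
        for label, idx in groups.items():
            centred = rt_s[idx] - rt_s[idx].mean()
            u = np.zeros(n_steps)
            tgrid = np.arange(n_steps) * dt
            for a, i in zip(centred, idx):
                trial = design.trials[i]
                on = trial.onset_s + trial.fixation_s
                u[(tgrid >= on - 1e-9) & (tgrid < on + trial.stimulus_s - 1e-9)] = a
            col = sample_at(hrf_convolve(u, hrf_kernel, dt), dt, times)
            cols.append(col - col.mean())
            names.append(f"rt_{label}")

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_vol:
            raise ValueError(
                f"motion covariates have {motion.shape[0]} rows, expected {n_vol}"
            )
        for j in range(motion.shape[1]):
            cols.append(motion[:, j] - motion[:, j].mean())
            names.append(f"motion_{j}")

    hp = dct_highpass_basis(n_vol, acquisition.tr_s, hp_cutoff_s)
    for k in range(hp.shape[1]):
        cols.append(hp[:, k])
        names.append(f"dct_{k + 1}")

    cols.append(np.ones(n_vol))
    names.append("constant")

    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _find_dependent_columns(x, names)
        raise MulticollinearityError(
            f"design matrix is rank deficient; offending columns: {bad}"
        )
    return DesignMatrix(names, x, acquisition.tr_s, hp_cutoff_s, condition_names)


@dataclass
class GLMFit:
    design: DesignMatrix
    beta: np.ndarray          # (n_regressors, n_voxels)
    resvar: np.ndarray        # residual variance per voxel
    df: int
    xtx_inv: np.ndarray
    row_projection: np.ndarray  # projector onto the design's row space
    shape: tuple[int, int, int] | None = None
    affine: np.ndarray | None = None

    @property
    def names(self) -> list[str]:
        return self.design.names


def fit_glm(run: Run | np.ndarray, design: DesignMatrix) -> GLMFit:
    """Ordinary-least-squares fit per voxel.

    ``run`` may be a 4-D :class:`Run` or a 2-D (n_volumes, n_voxels) array.
    """
    if isinstance(run, Run):
        y = run.timeseries()
        shape, affine = run.data.shape[:3], run.affine
    else:
        y = np.asarray(run, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        shape, affine = None, None
    x = design.x
    if y.shape[0] != x.shape[0]:
        raise ValueError(f"run has {y.shape[0]} volumes but design has {x.shape[0]} rows")
    rank = np.linalg.matrix_rank(x)
    df = y.shape[0] - rank
    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    resvar = rss / max(df, 1)
    xtx_inv = pinv @ pinv.T
    row_projection = pinv @ x
    return GLMFit(design, beta, resvar, df, xtx_inv, row_projection, shape, affine)


def contrast(fit: GLMFit, weights: dict[str, float] | np.ndarray):
    """Per-voxel contrast effect c'beta and its t statistic.

    Returns (effect, t, se) flat arrays of length n_voxels.
    """
    c = (
        fit.design.contrast_vector(weights)
        if isinstance(weights, dict)
        else np.asarray(weights, dtype=float)
    )
    if c.shape[0] != fit.beta.shape[0]:
        raise ValueError(f"contrast length {c.shape[0]} != {fit.beta.shape[0]} betas")
    effect = c @ fit.beta
    # a contrast outside the design's row space is not estimable: its unique
    # variance is fully shared with other columns and the t is reported as 0
    c_norm = np.linalg.norm(c)
    if c_norm > 0 and np.linalg.norm(fit.row_projection @ c - c) > 1e-8 * c_norm:
        zero = np.zeros_like(effect)
        return zero, zero, np.full_like(effect, np.inf)
    var_c = float(c @ fit.xtx_inv @ c)
    se = np.sqrt(np.maximum(fit.resvar * var_c, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    return effect, t, se


def contrast_map(
    fit: GLMFit, weights: dict[str, float] | np.ndarray, label: str = "", kind: str = "t"
) -> StatMap:
    """Contrast statistic reshaped into a :class:`StatMap` (t or beta)."""
    if fit.shape is None:
        raise ValueError("fit was not computed on a spatial run; use contrast()")
    effect, t, _ = contrast(fit, weights)
    data = (t if kind == "t" else effect).reshape(fit.shape)
    return StatMap(data, fit.affine, kind=kind, label=label, df=fit.df)


def smooth_volume(volume: Volume, fwhm_mm: float) -> Volume:
    """Gaussian smoothing with sigma = FWHM / (2 sqrt(2 ln 2)) per axis."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return Volume(volume.data.copy(), volume.affine)
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = sigma_mm / volume.voxel_size_mm
    return Volume(ndimage.gaussian_filter(volume.data.astype(float), sigma_vox), volume.affine)


def smooth_run(run: Run, fwhm_mm: float) -> Run:
    """Apply :func:`smooth_volume` to every frame of a run."""
    if fwhm_mm == 0:
        return Run(run.data.copy(), run.affine, run.tr_s)
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = list(sigma_mm / np.sqrt(np.sum(run.affine[:3, :3] ** 2, axis=0))) + [0.0]
    return Run(ndimage.gaussian_filter(run.data.astype(float), sigma_vox), run.affine, run.tr_s)


# 18-connectivity (faces + edges), the usual cluster-forming neighbourhood
_CLUSTER_STRUCTURE = ndimage.generate_binary_structure(3, 2)


def threshold_map(
    stat_map: StatMap,
    p_voxel: float = 0.005,
    extent_mm3: float = 270.0,
    two_sided: bool = False,
) -> tuple[np.ndarray, list[dict]]:
    """Voxel-p + cluster-extent thresholding.

    Returns a boolean mask of surviving voxels and a list of cluster records
    (size in voxels and mm^3, peak value, peak index).
    """
    if stat_map.kind == "t":
        if stat_map.df is None:
            raise ValueError("t map lacks degrees of freedom")
        crit = stats.t.isf(p_voxel / (2 if two_sided else 1), stat_map.df)
    elif stat_map.kind == "z":
        crit = stats.norm.isf(p_voxel / (2 if two_sided else 1))
    else:
        raise ValueError("threshold_map requires a t or z map")
    above = (np.abs(stat_map.data) if two_sided else stat_map.data) > crit
    min_vox = int(math.ceil(extent_mm3 / stat_map.voxel_volume_mm3 - 1e-9))
    labels, n_lab = ndimage.label(above, structure=_CLUSTER_STRUCTURE)
    mask = np.zeros_like(above)
    clusters = []
    for lab in range(1, n_lab + 1):
        sel = labels == lab
        size = int(sel.sum())
        if size < min_vox:
            continue
        mask |= sel
        vals = np.where(sel, stat_map.data, -np.inf)
        peak = np.unravel_index(np.argmax(np.abs(np.where(sel, stat_map.data, 0))), sel.shape)
        clusters.append(
            {
                "n_voxels": size,
                "volume_mm3": size * stat_map.voxel_volume_mm3,
                "peak_value": float(stat_map.data[peak]),
                "peak_ijk": tuple(int(v) for v in peak),
            }
        )
    clusters.sort(key=lambda c: -c["n_voxels"])
    return mask, clusters


def z_from_t(stat_map: StatMap) -> StatMap:
    """Convert a t map to the equivalent z map (monotone at fixed df)."""
    if stat_map.kind != "t" or stat_map.df is None:
        raise ValueError("z_from_t requires a t map with degrees of freedom")
    logp = stats.t.logsf(stat_map.data, stat_map.df)
    z = stats.norm.isf(np.exp(logp))
    small = np.exp(logp) < 1e-300
    z = np.where(small, stats.norm.isf(1e-300), z)
    return StatMap(z, stat_map.affine, kind="z", label=stat_map.label, df=stat_map.df)


def one_sample_t_map(maps: list[StatMap], label: str = "") -> StatMap:
    """Across-subject one-sample t of per-subject contrast-value maps."""
    if len(maps) < 2:
        raise ValueError("need at least two subjects")
    data = np.stack([m.data for m in maps], axis=-1)
    n = data.shape[-1]
    mean = data.mean(axis=-1)
    sd = data.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return StatMap(t, maps[0].affine, kind="t", label=label, df=n - 1)
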