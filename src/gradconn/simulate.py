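"""Synthetic subject generation: network activity embedded into 4-D BOLD runs.

A simulated subject is produced in three steps: (i) build a counterbalanced
task design; (ii) integrate the ground-truth bilinear network driven by the
design's condition boxcars; (iii) spatialise the result — each node's
HRF-convolved activity is written into a Gaussian blob around its coordinate,
strip voxels receive condition-weighted mixtures that vary monotonically with
y (the injected gradient), zone voxels receive fixed condition mixtures —
then add cosine drift and white measurement noise.

Everything is driven by a single integer seed; regenerating a subject with
the same seed reproduces the run bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import AcquisitionSpec, TaskDesign, build_main_task_design
from .geometry import GeometryError, GeometrySpec, default_geometry
from .hrf import canonical_hrf, hrf_convolve, sample_at
from .network import NetworkModel, simulate_network, top_down_model
from .volumes import Run

__all__ = [
    "SimulatedSubject",
    "embed_volumes",
    "generate_rt",
    "observe_nodes",
    "simulate_subject",
]

# Mean per-condition response times (s), matching the observed direction of
# task difficulty: slowest for arbitrary colour pairing.
RT_MEANS_S = {
    "colour": 1.569,
    "semantic": 1.387,
    "control": 1.354,
    "coloured": 1.123,
    "greyscale": 1.144,
}
RT_SD_S = 0.15

# Maximum number of cosine drift components; components are restricted to
# frequencies below the 1/128 Hz high-pass cutoff so the GLM's
# discrete-cosine basis removes them by construction for any run length.
N_DRIFT_COMPONENTS = 3
DRIFT_CUTOFF_S = 128.0


def generate_rt(design: TaskDesign, seed: int = 0) -> np.ndarray:
    """Per-trial reaction times: condition mean + Gaussian jitter, >= 0.3 s."""
    rng = np.random.default_rng(seed)
    rt = np.array(
        [RT_MEANS_S.get(tr.condition, 1.4) + rng.normal(0.0, RT_SD_S) for tr in design.trials]
    )
    return np.clip(rt, 0.3, None)


def drift_basis(
    n_volumes: int,
    tr_s: float = 2.8,
    cutoff_s: float = DRIFT_CUTOFF_S,
    max_components: int = N_DRIFT_COMPONENTS,
) -> np.ndarray:
    """Low-order cosine drift regressors, all slower than the cutoff period.

    Component k has frequency k / (2 * T); only k with frequency below
    1/cutoff are kept (at most ``max_components``), so a matching
    discrete-cosine high-pass basis spans them exactly.
    """
    total = n_volumes * tr_s
    k_max = min(max_components, int(np.floor(2.0 * total / cutoff_s)))
    n = np.arange(n_volumes)
    cols = [np.cos(np.pi * k * (n + 0.5) / n_volumes) for k in range(1, k_max + 1)]
    return np.column_stack(cols) if cols else np.zeros((n_volumes, 0))


def embed_volumes(
    node_series: np.ndarray,
    dt: float,
    geometry: GeometrySpec,
    acquisition: AcquisitionSpec,
    hrf_kernel: np.ndarray | None = None,
    condition_series: dict[str, np.ndarray] | None = None,
    noise_sd: float = 1.0,
    drift_amplitude: float = 1.0,
    amplitude: float = 1.0,
    node_amplitude: float = 1.0,
    seed: int = 0,
) -> Run:
    """Write node and condition signals into a 4-D grid and add noise/drift.

    ``node_series`` is (n_steps, n_nodes) neural activity on the microtime
    grid; ``condition_series`` maps condition labels to microtime envelopes
    (typically the design boxcars) used for the strip/zone signal mixtures.
    """
    if hrf_kernel is None:
        hrf_kernel = canonical_hrf(dt)
    times = acquisition.volume_times
    n_vol = acquisition.n_volumes
    shape = geometry.shape
    data = np.zeros(shape + (n_vol,), dtype=np.float64)

    # -- network nodes -> Gaussian blobs --------------------------------
    node_labels = list(geometry.node_coords)
    for idx, label in enumerate(node_labels):
        z = node_series[:, idx]
        bold = sample_at(hrf_convolve(z, hrf_kernel, dt), dt, times)
        mask, w = geometry.node_blob(label)
        if not mask.any():
            raise GeometryError(f"node {label} has empty blob support")
        data[mask] += node_amplitude * amplitude * w[:, None] * bold[None, :]

    # -- condition-weighted strip gradients and zone mixtures ------------
    if condition_series:
        cond_bold = {
            c: sample_at(hrf_convolve(u, hrf_kernel, dt), dt, times)
            for c, u in condition_series.items()
        }
        for strip, weights in geometry.strip_weights.items():
            mask = geometry.sectors[strip]
            frac = geometry.strip_fraction(strip)
            sig = np.zeros((int(mask.sum()), n_vol))
            for cond, (w0, w1) in weights.items():
                if cond not in cond_bold:
                    continue
                w = w0 + (w1 - w0) * frac
                sig += w[:, None] * cond_bold[cond][None, :]
            data[mask] += amplitude * sig
        for zone, weights in geometry.zone_weights.items():
            mask = geometry.zones[zone]
            sig = np.zeros(n_vol)
            for cond, w in weights.items():
                if cond not in cond_bold:
                    continue
                sig += w * cond_bold[cond]
            data[mask] += amplitude * sig[None, :]

    # -- drift and measurement noise -------------------------------------
    rng = np.random.default_rng(seed)
    n_voxels = int(np.prod(shape))
    if drift_amplitude > 0:
        basis = drift_basis(n_vol, acquisition.tr_s)
        if basis.shape[1]:
            coef = rng.normal(0.0, drift_amplitude, size=(n_voxels, basis.shape[1]))
            data += (coef @ basis.T).reshape(shape + (n_vol,))
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)
    return Run(data, geometry.affine, acquisition.tr_s)


def observe_nodes(
    node_series: np.ndarray,
    dt: float,
    acquisition: AcquisitionSpec,
    hrf_kernel: np.ndarray | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Per-node BOLD observations at volume times, shape (n_volumes, n_nodes).

    This is the observation model the network-fitting stage inverts: each
    node's neural series convolved with the HRF, sampled at mid-volume times,
    plus white noise.
    """
    if hrf_kernel is None:
        hrf_kernel = canonical_hrf(dt)
    times = acquisition.volume_times
    bold = np.column_stack(
        [
            sample_at(hrf_convolve(node_series[:, i], hrf_kernel, dt), dt, times)
            for i in range(node_series.shape[1])
        ]
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        bold = bold + rng.normal(0.0, noise_sd, size=bold.shape)
    return bold


@dataclass
class SimulatedSubject:
    seed: int
    design: TaskDesign
    acquisition: AcquisitionSpec
    geometry: GeometrySpec
    model: NetworkModel
    dt: float
    node_series: np.ndarray      # (n_steps, n_nodes) ground-truth neural
    run: Run                     # 4-D BOLD
    rt_s: np.ndarray             # per-trial reaction times


def simulate_subject(
    seed: int,
    design: TaskDesign | None = None,
    geometry: GeometrySpec | None = None,
    model: NetworkModel | None = None,
    tr_s: float = 2.8,
    dt: float = 0.1,
    state_noise_sd: float = 0.8,
    noise_sd: float = 1.0,
    drift_amplitude: float = 1.0,
    amplitude: float = 1.0,
    node_amplitude: float = 1.0,
) -> SimulatedSubject:
    """Generate one complete synthetic subject from a single seed."""
    ss = np.random.SeedSequence(seed)
    seed_order, seed_state, seed_embed, seed_rt = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )
    if design is None:
        design = build_main_task_design(order_seed=seed_order)
    if geometry is None:
        geometry = default_geometry()
    if model is None:
        model = top_down_model()
    acquisition = AcquisitionSpec.for_design(
        design, tr_s=tr_s, shape=geometry.shape, voxel_size_mm=tuple(geometry.voxel_size_mm)
    )
    node_series = simulate_network(
        model, design, dt=dt, state_noise_sd=state_noise_sd, seed=seed_state
    )
    condition_series = {
        c: design.condition_boxcar(c, dt, node_series.shape[0]) for c in design.conditions
    }
    run = embed_volumes(
        node_series,
        dt,
        geometry,
        acquisition,
        condition_series=condition_series,
        noise_sd=noise_sd,
        drift_amplitude=drift_amplitude,
        amplitude=amplitude,
        node_amplitude=node_amplitude,
        seed=seed_embed,
    )
    rt = generate_rt(design, seed=seed_rt)
    return SimulatedSubject(
        seed=seed,
        design=design,
        acquisition=acquisition,
        geometry=geometry,
        model=model,
        dt=dt,
        node_series=node_series,
        run=run,
        rt_s=rt,
    )
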