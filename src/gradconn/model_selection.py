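"""Bilinear network model fitting and Bayesian model selection.

Each candidate architecture (top-down vs bottom-up) is fitted to observed
per-node BOLD series by bounded nonlinear least squares over the free A/B/C
entries: candidate parameters are integrated forward through the bilinear
state equation, convolved with the canonical HRF, sampled at volume times,
and compared to the observations.  Model evidence is approximated by -BIC/2,
and the candidates are adjudicated with fixed-effects (summed evidence /
softmax posterior) and random-effects (variational Dirichlet over model
frequencies, Monte-Carlo exceedance probabilities) Bayesian selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .design import AcquisitionSpec, TaskDesign
from .hrf import canonical_hrf, hrf_convolve, sample_at
from .network import NetworkModel, build_inputs, simulate_network

__all__ = [
    "OptimisationError",
    "ModelFit",
    "SelectionResult",
    "fit_bilinear",
    "ffx_select",
    "rfx_select",
    "exceedance_2model_exact",
]


class OptimisationError(RuntimeError):
    pass


@dataclass
class ModelFit:
    model: NetworkModel           # estimated parameters in a copy of the template
    rss: float
    n_params: int
    n_obs: int
    log_evidence: float           # -BIC/2
    n_starts_used: int = 1

    @property
    def bic(self) -> float:
        return -2.0 * self.log_evidence


def _unpack(theta: np.ndarray, template: NetworkModel) -> NetworkModel:
    m = template.copy()
    pos = 0
    for idx in np.argwhere(template.a_free):
        m.a[idx[0], idx[1]] = theta[pos]
        pos += 1
    for name in template.b:
        for idx in np.argwhere(template.b_free[name]):
            m.b[name][idx[0], idx[1]] = theta[pos]
            pos += 1
    for name in template.c:
        for (i,) in np.argwhere(template.c_free[name]):
            m.c[name][i] = theta[pos]
            pos += 1
    return m


def _pack(model: NetworkModel) -> np.ndarray:
    vals = list(model.a[model.a_free])
    for name in model.b:
        vals.extend(model.b[name][model.b_free[name]])
    for name in model.c:
        vals.extend(model.c[name][model.c_free[name]])
    return np.array(vals)


def predict_bold(
    model: NetworkModel,
    design: TaskDesign,
    acquisition: AcquisitionSpec,
    dt: float = 0.1,
    hrf_kernel: np.ndarray | None = None,
) -> np.ndarray:
    """Noise-free forward prediction: (n_volumes, n_nodes) BOLD."""
    if hrf_kernel is None:
        hrf_kernel = canonical_hrf(dt)
    z = simulate_network(model, design, dt=dt)
    times = acquisition.volume_times
    return np.column_stack(
        [sample_at(hrf_convolve(z[:, i], hrf_kernel, dt), dt, times) for i in range(z.shape[1])]
    )


def _linear_init(
    observed: np.ndarray,
    design: TaskDesign,
    template: NetworkModel,
    acquisition: AcquisitionSpec,
    dt: float,
) -> np.ndarray | None:
    """Two-stage warm start: deconvolve each node's BOLD to a neural estimate,
    then regress the Euler increments on states/inputs — the free parameters
    enter that regression linearly."""
    from .ppi import deconvolve  # local import to avoid a cycle

    try:
        factor = max(int(round(acquisition.tr_s / dt)), 1)
        n_nodes = len(template.nodes)
        z = np.column_stack(
            [
                deconvolve(observed[:, i], acquisition.tr_s, microtime_factor=factor)
                for i in range(n_nodes)
            ]
        )
        u = build_inputs(template, design, acquisition.tr_s / factor, z.shape[0])
        dz = np.diff(z, axis=0) / (acquisition.tr_s / factor)
        zt, ut = z[:-1], u[:-1]
        names = template.input_names
        theta = []
        # decompose per target node: dz_i - diag term = sum over free params
        cols_per_node: dict[int, list] = {i: [] for i in range(n_nodes)}
        order = []
        for i, j in np.argwhere(template.a_free):
            cols_per_node[i].append(zt[:, j])
            order.append(("a", i))
        for name in template.b:
            m = names.index(name)
            for i, j in np.argwhere(template.b_free[name]):
                cols_per_node[i].append(ut[:, m] * zt[:, j])
                order.append(("b", i))
        for name in template.c:
            m = names.index(name)
            for (i,) in np.argwhere(template.c_free[name]):
                cols_per_node[i].append(ut[:, m])
                order.append(("c", i))
        est_per_node = {}
        for i in range(n_nodes):
            if not cols_per_node[i]:
                continue
            x = np.column_stack(cols_per_node[i])
            y = dz[:, i] - template.a[i, i] * zt[:, i]
            coef, *_ = np.linalg.lstsq(x, y, rcond=None)
            est_per_node[i] = list(coef)
        for kind, i in order:
            theta.append(est_per_node[i].pop(0))
        return np.array(theta)
    except Exception:
        return None


def fit_bilinear(
    observed: np.ndarray,
    design: TaskDesign,
    template: NetworkModel,
    acquisition: AcquisitionSpec,
    dt: float = 0.1,
    hrf_kernel: np.ndarray | None = None,
    n_starts: int = 8,
    seed: int = 0,
    bound: float = 3.0,
    tol: float = 1e-6,
    max_nfev: int | None = 3000,
    early_stop_rtol: float = 1e-3,
    early_stop_stale: int = 1,
) -> ModelFit:
    """Bounded nonlinear least squares over the template's free entries.

    Runs up to ``n_starts`` seeded starts — a deconvolution-based linear
    warm start, a structured small-value start, then random perturbations —
    and stops early once ``early_stop_stale`` consecutive starts fail to
    improve the best residual sum of squares by more than
    ``early_stop_rtol`` relatively.  The diagonal self-decay stays fixed.
    """
    observed = np.asarray(observed, dtype=float)
    if hrf_kernel is None:
        hrf_kernel = canonical_hrf(dt)
    if observed.shape != (acquisition.n_volumes, len(template.nodes)):
        raise ValueError(
            f"observed series shape {observed.shape} != "
            f"({acquisition.n_volumes}, {len(template.nodes)})"
        )
    n_free = template.n_free
    times = acquisition.volume_times
    u = build_inputs(template, design, dt)

    def residuals(theta: np.ndarray) -> np.ndarray:
        m = _unpack(theta, template)
        # smooth penalty for unstable candidates keeps a usable gradient
        max_re = float(np.linalg.eigvals(m.a).real.max())
        if max_re >= -1e-6:
            return np.full(observed.size, 1e3 * (1.0 + max_re))
        z = simulate_network(m, design, dt=dt, n_steps=u.shape[0], check_stability=False)
        pred = np.column_stack(
            [
                sample_at(hrf_convolve(z[:, i], hrf_kernel, dt), dt, times)
                for i in range(z.shape[1])
            ]
        )
        return (pred - observed).ravel()

    rng = np.random.default_rng(seed)
    x0_list = []
    warm = _linear_init(observed, design, template, acquisition, dt)
    if warm is not None and np.all(np.isfinite(warm)):
        warm = np.clip(warm, -bound + 1e-6, bound - 1e-6)
        # shrink an unstable warm start towards zero until stable
        for _ in range(32):
            if np.linalg.eigvals(_unpack(warm, template).a).real.max() < -1e-3:
                break
            warm = warm * 0.8
        x0_list.append(warm)
    x0_list.append(np.full(n_free, 0.1))
    while len(x0_list) < n_starts:
        x0_list.append(rng.uniform(-0.5, 0.5, n_free))
    x0_list = x0_list[:n_starts]

    best = None
    stale = 0
    used = 0
    for x0 in x0_list:
        used += 1
        try:
            res = optimize.least_squares(
                residuals,
                x0,
                bounds=(-bound, bound),
                method="trf",
                xtol=tol,
                ftol=tol,
                gtol=tol,
                max_nfev=max_nfev,
            )
        except Exception:
            continue
        rss = float(2.0 * res.cost)
        if best is None or rss < best[0] * (1.0 - early_stop_rtol):
            best = (rss, res.x)
            stale = 0
        else:
            stale += 1
            if stale >= early_stop_stale:
                break
    if best is None:
        raise OptimisationError(
            f"no start converged after {used} attempts for model {template.name!r}"
        )
    rss, theta = best
    n_obs = observed.size
    rss = max(rss, 1e-300)
    bic = n_obs * np.log(rss / n_obs) + n_free * np.log(n_obs)
    fitted = _unpack(theta, template)
    fitted.name = template.name
    return ModelFit(
        model=fitted,
        rss=rss,
        n_params=n_free,
        n_obs=n_obs,
        log_evidence=-0.5 * float(bic),
        n_starts_used=used,
    )


@dataclass
class SelectionResult:
    models: tuple[str, ...]
    ffx_posterior: np.ndarray | None = None
    alpha: np.ndarray | None = None           # RFX Dirichlet concentrations
    exceedance: np.ndarray | None = None


def _evidence_matrix(log_evidence: dict[str, np.ndarray]):
    models = tuple(log_evidence)
    lengths = {len(np.asarray(v)) for v in log_evidence.values()}
    if len(lengths) != 1:
        raise ValueError("every model needs a log evidence for every subject")
    lme = np.column_stack([np.asarray(log_evidence[m], dtype=float) for m in models])
    if not np.all(np.isfinite(lme)):
        raise ValueError("log evidences must be finite for all subject x model cells")
    return models, lme


def ffx_select(log_evidence: dict[str, np.ndarray]) -> SelectionResult:
    """Fixed-effects selection: posterior ∝ exp(summed log evidence)."""
    models, lme = _evidence_matrix(log_evidence)
    total = lme.sum(axis=0)
    post = np.exp(total - special.logsumexp(total))
    post /= post.sum()
    return SelectionResult(models=models, ffx_posterior=post)


def rfx_select(
    log_evidence: dict[str, np.ndarray],
    n_samples: int = 10_000,
    seed: int = 0,
    max_iter: int = 64,
    tol: float = 1e-6,
    alpha0: float = 1.0,
    strict: bool = False,
) -> SelectionResult:
    """Random-effects selection via the variational Dirichlet scheme.

    Updates Dirichlet concentrations over model frequencies from per-subject
    evidences (uniform prior, concentration ``alpha0`` per model), then
    estimates exceedance probabilities — the posterior probability that each
    model is the most frequent — by Monte-Carlo sampling from the fitted
    Dirichlet.
    """
    models, lme = _evidence_matrix(log_evidence)
    if len(models) < 2:
        raise ValueError("need at least two models")
    if n_samples < 10_000:
        msg = f"n_samples={n_samples} < 10^4 gives imprecise exceedance probabilities"
        if strict:
            raise ValueError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
    k = len(models)
    alpha = np.full(k, alpha0)
    for _ in range(max_iter):
        log_u = lme + special.psi(alpha) - special.psi(alpha.sum())
        g = np.exp(log_u - special.logsumexp(log_u, axis=1, keepdims=True))
        new_alpha = alpha0 + g.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    rng = np.random.default_rng(seed)
    samples = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(samples, axis=1)
    counts = np.bincount(winners, minlength=k).astype(float)
    exceedance = counts / counts.sum()
    return SelectionResult(models=models, alpha=alpha, exceedance=exceedance)


def exceedance_2model_exact(alpha: np.ndarray) -> np.ndarray:
    """Exact two-model exceedance: P(x1 > 1/2) for x1 ~ Beta(a1, a2)."""
    if len(alpha) != 2:
        raise ValueError("exact form applies to two models only")
    p1 = 1.0 - special.betainc(alpha[0], alpha[1], 0.5)
    return np.array([p1, 1.0 - p1])
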