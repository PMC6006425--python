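"""Bilinear five-node neural network: state equation, factory models, simulation.

The neural dynamics follow the standard bilinear state equation used in
effective-connectivity modelling,

    dz/dt = (A + sum_j u_j(t) B_j) z + C u(t),

where A holds the endogenous (context-independent) coupling in Hz with a
fixed self-decay on the diagonal, each B_j is the additive change in coupling
induced by modulatory input j, and C routes driving inputs into nodes.  The
five nodes are the left inferior frontal gyrus (control centre), the ventral
and lateral anterior temporal lobe (hub), and occipital "concept" and
"percept" regions (spokes).

Two candidate architectures are provided: a *top-down* model in which the
task input enters via IFG and ventral ATL and the colour condition modulates
the IFG -> occipital-concept connection, and a *bottom-up* model in which the
input enters via the occipital percept node and colour modulates
occipital-concept -> IFG instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .design import TaskDesign

__all__ = [
    "NODES",
    "StabilityError",
    "NetworkModel",
    "top_down_model",
    "bottom_up_model",
    "build_inputs",
    "simulate_network",
]

NODES = ("IFG", "vATL", "lATL", "OCC-C", "OCC-P")

SELF_DECAY_HZ = -1.0  # fixed self-connection; not a fitted parameter


class StabilityError(ValueError):
    """Raised when the endogenous matrix has an eigenvalue with Re >= 0."""


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


@dataclass
class NetworkModel:
    """Named-node bilinear connectivity model.

    ``a[i, j]`` is the influence of node j on node i (Hz).  ``b`` maps a
    modulatory input name to its additive coupling-change matrix, ``c`` maps
    a driving input name to per-node input weights.  ``input_conditions``
    states which task conditions make up each input's boxcar.  The ``*_free``
    masks declare which entries are estimated when the model is fitted.
    """

    nodes: tuple[str, ...] = NODES
    a: np.ndarray = None
    b: dict[str, np.ndarray] = field(default_factory=dict)
    c: dict[str, np.ndarray] = field(default_factory=dict)
    input_conditions: dict[str, tuple[str, ...]] = field(default_factory=dict)
    a_free: np.ndarray = None
    b_free: dict[str, np.ndarray] = field(default_factory=dict)
    c_free: dict[str, np.ndarray] = field(default_factory=dict)
    name: str = "model"

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if self.a is None:
            self.a = np.eye(n) * SELF_DECAY_HZ
        self.a = np.asarray(self.a, dtype=float)
        if self.a_free is None:
            self.a_free = _offdiag_mask(n)
        for name in self.b:
            self.b[name] = np.asarray(self.b[name], dtype=float)
            self.b_free.setdefault(name, self.b[name] != 0)
        for name in self.c:
            self.c[name] = np.asarray(self.c[name], dtype=float)
            self.c_free.setdefault(name, self.c[name] != 0)

    # -- parameter bookkeeping ------------------------------------------
    @property
    def input_names(self) -> tuple[str, ...]:
        names = list(self.c) + [n for n in self.b if n not in self.c]
        return tuple(names)

    @property
    def n_endogenous(self) -> int:
        return int(np.sum(self.a_free))

    @property
    def n_modulatory(self) -> int:
        return int(sum(np.sum(m) for m in self.b_free.values()))

    @property
    def n_driving(self) -> int:
        return int(sum(np.sum(m) for m in self.c_free.values()))

    @property
    def n_free(self) -> int:
        return self.n_endogenous + self.n_modulatory + self.n_driving

    def check_stable(self) -> None:
        eig = np.linalg.eigvals(self.a)
        if np.any(eig.real >= 0):
            raise StabilityError(
                f"endogenous matrix is unstable (max Re eig = {eig.real.max():.3f} Hz)"
            )

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            nodes=self.nodes,
            a=self.a.copy(),
            b={k: v.copy() for k, v in self.b.items()},
            c={k: v.copy() for k, v in self.c.items()},
            input_conditions={k: tuple(v) for k, v in self.input_conditions.items()},
            a_free=self.a_free.copy(),
            b_free={k: v.copy() for k, v in self.b_free.items()},
            c_free={k: v.copy() for k, v in self.c_free.items()},
            name=self.name,
        )


# Fixed, mildly heterogeneous endogenous couplings (Hz); all excitatory,
# Gershgorin-stable with the -1 Hz self-decay.
_A_TRUE = np.array(
    [
        [-1.00, 0.20, 0.10, 0.15, 0.05],
        [0.25, -1.00, 0.25, 0.10, 0.10],
        [0.10, 0.30, -1.00, 0.05, 0.05],
        [0.20, 0.10, 0.05, -1.00, 0.25],
        [0.05, 0.10, 0.05, 0.30, -1.00],
    ]
)

_IFG, _VATL, _LATL, _OCC_C, _OCC_P = range(5)


def _base_modulation(strength: float = 0.2) -> np.ndarray:
    """Shared modulatory skeleton: colour modulates vATL<->IFG and vATL<->lATL."""
    b = np.zeros((5, 5))
    b[_IFG, _VATL] = strength   # vATL -> IFG
    b[_VATL, _IFG] = strength   # IFG -> vATL
    b[_LATL, _VATL] = strength  # vATL -> lATL
    b[_VATL, _LATL] = strength  # lATL -> vATL
    return b


def top_down_model(
    modulation: float = 0.2, ppi_modulation: float = 0.8, drive: float = 0.8
) -> NetworkModel:
    """Task input enters IFG and ventral ATL; colour additionally boosts the
    top-down IFG -> occipital-concept connection."""
    b = _base_modulation(modulation)
    b[_OCC_C, _IFG] = ppi_modulation
    c = np.zeros(5)
    c[_IFG] = drive
    c[_VATL] = drive
    return NetworkModel(
        a=_A_TRUE.copy(),
        b={"colour": b},
        c={"task": c},
        input_conditions={"task": ("colour", "semantic", "control"), "colour": ("colour",)},
        name="top-down",
    )


def bottom_up_model(
    modulation: float = 0.2, ppi_modulation: float = 0.8, drive: float = 1.0
) -> NetworkModel:
    """Task input enters via the occipital percept node; colour boosts the
    feed-forward occipital-concept -> IFG connection."""
    b = _base_modulation(modulation)
    b[_IFG, _OCC_C] = ppi_modulation
    c = np.zeros(5)
    c[_OCC_P] = drive
    return NetworkModel(
        a=_A_TRUE.copy(),
        b={"colour": b},
        c={"task": c},
        input_conditions={"task": ("colour", "semantic", "control"), "colour": ("colour",)},
        name="bottom-up",
    )


def build_inputs(
    model: NetworkModel, design: TaskDesign, dt: float, n_steps: int | None = None
) -> np.ndarray:
    """Stack the model's input boxcars, shape (n_steps, n_inputs)."""
    if n_steps is None:
        n_steps = int(round(design.total_s / dt))
    cols = []
    for name in model.input_names:
        conds = model.input_conditions.get(name, (name,))
        cols.append(design.condition_boxcar(tuple(conds), dt, n_steps))
    return np.column_stack(cols) if cols else np.zeros((n_steps, 0))


@njit(cache=False)
def _euler(a, b_stack, c_mat, u, dt, noise):  # pragma: no cover - jitted
    n_steps, n_inputs = u.shape
    n = a.shape[0]
    z = np.zeros((n_steps, n))
    for t in range(n_steps - 1):
        m = a.copy()
        for j in range(n_inputs):
            uj = u[t, j]
            if uj != 0.0:
                m = m + uj * b_stack[j]
        dz = m @ z[t] + c_mat @ u[t]
        z[t + 1] = z[t] + dt * dz + noise[t]
    return z


def simulate_network(
    model: NetworkModel,
    design: TaskDesign,
    dt: float = 0.1,
    state_noise_sd: float = 0.0,
    seed: int = 0,
    n_steps: int | None = None,
    check_stability: bool = True,
) -> np.ndarray:
    """Forward-Euler integration of the bilinear state equation.

    Returns node activity of shape (n_steps, n_nodes) on the microtime grid
    t = k*dt.  With ``state_noise_sd`` > 0, i.i.d. Gaussian innovations of
    standard deviation ``state_noise_sd * sqrt(dt)`` are added per step
    (an Euler-Maruyama discretisation); with 0 the output is deterministic.
    """
    if check_stability:
        model.check_stable()
    n = len(model.nodes)
    u = build_inputs(model, design, dt, n_steps)
    n_steps = u.shape[0]
    names = model.input_names
    b_stack = np.zeros((len(names), n, n))
    c_mat = np.zeros((n, len(names)))
    for j, name in enumerate(names):
        if name in model.b:
            b_stack[j] = model.b[name]
        if name in model.c:
            c_mat[:, j] = model.c[name]
    if state_noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal((n_steps, n)) * state_noise_sd * np.sqrt(dt)
    else:
        noise = np.zeros((n_steps, n))
    return _euler(model.a, b_stack, c_mat, u, dt, noise)
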