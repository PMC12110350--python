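"""Coupled astrocyte-neuron network dynamics.

Each node holds an excitatory population ``Ex``, an inhibitory population
``In``, an astrocytic glutamate concentration ``Glu`` and a recovery
variable ``h``.  Calcium tracks the excitatory firing rate linearly
(``Ca = k_ca * f(Ex)``); when it exceeds the threshold ``ca_th`` the
astrocyte releases glutamate, which feeds back onto the excitatory
population as the current ``I_astro = 10 * lambda_a * Glu``.  Nodes are
coupled through the binary adjacency matrix via the firing rates of their
neighbours' excitatory populations.  The model is dimensionless; time
labels are nominal milliseconds.

The four discharge modes are single-parameter overrides of the baseline
parameter set:

====  =================  =========================================
mode  override           regime
====  =================  =========================================
1     ``tau_in = 0.001`` quiescent (inhibition frozen, Ex settles)
2     ``h_ex  = -0.6``   large-amplitude high-frequency seizure
3     ``tau_ex = 0.6``   smaller, slower intermittent discharge
4     ``kappa = 1``      saturated discharge, glutamate plateaus
====  =================  =========================================
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import default_config
from .errors import BlowUpError, InvalidParameterError
from .network import AdjacencyNetwork, ModeAssignment

__all__ = [
    "ModelParams",
    "NodeParams",
    "Trajectory",
    "MODE_OVERRIDES",
    "sigmoid",
    "astrocyte_current",
    "calcium",
    "rectified_drive",
    "apply_mode",
    "build_node_params",
    "derivatives",
    "step",
    "simulate",
]

_CAL = default_config()["model"]

#: discharge mode -> (field, value) single-parameter override
MODE_OVERRIDES: dict[int, tuple[str, float]] = {
    1: ("tau_in", 0.001),
    2: ("h_ex", -0.6),
    3: ("tau_ex", 0.6),
    4: ("kappa", 1.0),
}


@dataclass(frozen=True)
class ModelParams:
    """All model constants.

    The neuronal constants carry their standard values; the astrocyte and
    coupling constants (``k_ca`` through ``c_net``) default to the
    calibrated values shipped in ``data/default_config.yaml``.
    """

    tau_ex: float = 1.97
    tau_in: float = 3.0
    h_ex: float = -0.5
    h_in: float = -1.4
    c1: float = 1.0
    c2: float = 15.0
    c3: float = 6.1
    cu: float = 6.0
    lambda_a: float = _CAL["lambda_a"]
    k_ca: float = _CAL["k_ca"]
    ca_th: float = _CAL["ca_th"]
    kappa: float = _CAL["kappa"]
    mu_glu: float = _CAL["mu_glu"]
    eta_h: float = _CAL["eta_h"]
    eps: float = 1000.0
    c_net: float = _CAL["c_net"]
    dt: float = 0.05
    t_total: float = 100.0

    def __post_init__(self) -> None:
        for name in ("tau_ex", "tau_in", "mu_glu", "eta_h", "dt"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.eps <= 1:
            raise InvalidParameterError("eps must be > 1")
        if self.t_total < self.dt:
            raise InvalidParameterError("t_total must be >= dt")

    @classmethod
    def from_config(cls, model_cfg: dict) -> "ModelParams":
        return cls(**{k: float(v) for k, v in model_cfg.items()})

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)


def apply_mode(params: ModelParams, mode: int) -> ModelParams:
    """Return a copy of ``params`` with the mode's single override applied."""
    if mode not in MODE_OVERRIDES:
        raise InvalidParameterError(f"unknown discharge mode {mode}")
    name, value = MODE_OVERRIDES[mode]
    return params.replace(**{name: value})


# ---------------------------------------------------------------------------
# elementary pieces


def sigmoid(x, eps: float = 1000.0):
    """``1 / (1 + eps**(-x))``, overflow-safe, strictly increasing."""
    return expit(np.asarray(x, dtype=float) * np.log(eps))


def astrocyte_current(glu, lambda_a: float):
    """Astrocytic feedback current ``10 * lambda_a * Glu``."""
    return 10.0 * lambda_a * np.asarray(glu, dtype=float)


def calcium(ex, k_ca: float, eps: float = 1000.0):
    """Calcium level: linear in the excitatory firing rate ``f(Ex)``."""
    return k_ca * sigmoid(ex, eps)


def rectified_drive(ca, ca_th: float):
    """Suprathreshold calcium ``max(0, Ca - ca_th)`` driving glutamate."""
    return np.maximum(0.0, np.asarray(ca, dtype=float) - ca_th)


# ---------------------------------------------------------------------------
# per-node parameter arrays

_PER_NODE_FIELDS = (
    "tau_ex",
    "tau_in",
    "h_ex",
    "h_in",
    "c1",
    "c2",
    "c3",
    "cu",
    "lambda_a",
    "k_ca",
    "ca_th",
    "kappa",
    "mu_glu",
    "eta_h",
)


@dataclass
class NodeParams:
    """Model constants broadcast to (N,) arrays, with global scalars."""

    arrays: dict[str, np.ndarray]
    eps: float
    c_net: float
    dt: float
    t_total: float
    base: ModelParams

    def __getattr__(self, name: str):
        try:
            return self.arrays[name]
        except KeyError:
            raise AttributeError(name) from None


def build_node_params(
    base: ModelParams, n_nodes: int, modes: ModeAssignment | None = None
) -> NodeParams:
    """Broadcast the base constants to every node and apply mode overrides."""
    arrays = {
        f: np.full(n_nodes, getattr(base, f), dtype=float) for f in _PER_NODE_FIELDS
    }
    if modes is not None:
        if len(modes.mode_of_node) != n_nodes:
            raise InvalidParameterError("mode assignment does not match network size")
        for mode, (field_name, value) in MODE_OVERRIDES.items():
            arrays[field_name][modes.mode_of_node == mode] = value
    return NodeParams(
        arrays, base.eps, base.c_net, base.dt, base.t_total, base
    )


# ---------------------------------------------------------------------------
# right-hand side and stepping


def derivatives(
    state: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    np_: NodeParams,
    adjacency: np.ndarray,
    active: np.ndarray,
    s_now: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Time derivative of ``(Ex, In, Glu, h)`` at one instant.

    The external stimulus ``s_now`` enters the excitatory equation
    additively, outside the time-scale factor.  Inactive nodes get zero
    derivative.
    """
    ex, inh, glu, h = state
    if not (len(ex) == len(inh) == len(glu) == len(h) == adjacency.shape[0] == len(s_now)):
        raise InvalidParameterError("state/stimulus dimensions do not match network")
    a = np_.arrays
    f_ex = sigmoid(ex, np_.eps)
    f_in = sigmoid(inh, np_.eps)
    i_astro = 10.0 * a["lambda_a"] * glu
    coupling = np_.c_net * (adjacency @ f_ex)
    d_ex = (
        a["tau_ex"]
        * (
            a["h_ex"]
            - ex
            + a["c1"] * f_ex
            - a["c2"] * f_in
            + coupling
            + a["cu"] * sigmoid(i_astro, np_.eps)
        )
        + s_now
    )
    d_in = a["tau_in"] * (a["h_in"] - inh + a["c3"] * ex)
    ca = a["k_ca"] * f_ex
    z = np.maximum(0.0, ca - a["ca_th"])
    # below threshold z = 0 and the decay branch -Glu - kappa*h applies;
    # the single expression covers both branches of the piecewise equation
    d_glu = (-glu + z - a["kappa"] * h) / a["mu_glu"]
    d_h = (-h + glu) / a["eta_h"]
    if not active.all():
        inactive = ~active
        for d in (d_ex, d_in, d_glu, d_h):
            d[inactive] = 0.0
    return d_ex, d_in, d_glu, d_h


def step(
    state,
    np_: NodeParams,
    adjacency: np.ndarray,
    active: np.ndarray,
    s_fn,
    t: float,
    dt: float,
    method: str = "euler",
):
    """Advance one integration step (forward Euler or classical RK4).

    ``s_fn(t)`` returns the per-node stimulus vector at a stage time.
    """
    if method == "euler":
        d = derivatives(state, np_, adjacency, active, s_fn(t))
        return tuple(x + dt * dx for x, dx in zip(state, d))
    if method == "rk4":
        k1 = derivatives(state, np_, adjacency, active, s_fn(t))
        s2 = tuple(x + 0.5 * dt * dx for x, dx in zip(state, k1))
        k2 = derivatives(s2, np_, adjacency, active, s_fn(t + 0.5 * dt))
        s3 = tuple(x + 0.5 * dt * dx for x, dx in zip(state, k2))
        k3 = derivatives(s3, np_, adjacency, active, s_fn(t + 0.5 * dt))
        s4 = tuple(x + dt * dx for x, dx in zip(state, k3))
        k4 = derivatives(s4, np_, adjacency, active, s_fn(t + dt))
        return tuple(
            x + dt / 6.0 * (a + 2 * b + 2 * c + d)
            for x, a, b, c, d in zip(state, k1, k2, k3, k4)
        )
    raise InvalidParameterError(f"unknown integration method {method!r}")


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """Simulated time course of the network state plus the stimulus record."""

    times: np.ndarray          # (T+1,)
    ex: np.ndarray             # (T+1, N)
    inh: np.ndarray
    glu: np.ndarray
    h: np.ndarray
    stim: np.ndarray           # (T+1, N) applied stimulus record
    node_params: NodeParams
    net: AdjacencyNetwork
    seed: int
    method: str
    stim_targets: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def ca(self) -> np.ndarray:
        """Calcium level per sample and node (derived)."""
        return self.node_params.arrays["k_ca"] * sigmoid(self.ex, self.node_params.eps)

    @property
    def z_drive(self) -> np.ndarray:
        """Rectified suprathreshold calcium (derived)."""
        return np.maximum(0.0, self.ca - self.node_params.arrays["ca_th"])

    @property
    def i_astro(self) -> np.ndarray:
        """Astrocyte feedback current (derived)."""
        return 10.0 * self.node_params.arrays["lambda_a"] * self.glu

    def summed_glu(self) -> np.ndarray:
        """Across-active-node sum of glutamate per sample (headline series)."""
        return self.glu[:, self.net.active_mask].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: time, node, Ex, In, Glu, h, S."""
        n = self.net.n_nodes
        t_rep = np.repeat(self.times, n)
        node = np.tile(np.arange(n), self.n_samples)
        return pd.DataFrame(
            {
                "time": t_rep,
                "node": node,
                "Ex": self.ex.ravel(),
                "In": self.inh.ravel(),
                "Glu": self.glu.ravel(),
                "h": self.h.ravel(),
                "S": self.stim.ravel(),
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def summary(self) -> dict:
        g = self.summed_glu()
        q = max(1, self.n_samples // 4)
        return {
            "n_nodes": int(self.net.n_nodes),
            "n_active": int(self.net.n_active),
            "seed": int(self.seed),
            "method": self.method,
            "dt": float(self.node_params.dt),
            "t_total": float(self.node_params.t_total),
            "glu_peak": float(g.max()),
            "glu_plateau": float(g[-q:].mean()),
            "stim_targets": (
                [int(i) for i in self.stim_targets]
                if self.stim_targets is not None
                else []
            ),
        }


def simulate(
    net: AdjacencyNetwork,
    base_params: ModelParams | None = None,
    modes: ModeAssignment | None = None,
    stimulus=None,
    seed: int = 0,
    method: str = "euler",
    init: str = "random",
) -> Trajectory:
    """Integrate the network from a seeded initial condition.

    Parameters
    ----------
    stimulus : StimulusSpec, Stimulus or None
        External drive wired to the top-degree nodes (see the stimulation
        module).  ``None`` means no stimulus.
    init : 'random' draws Ex and In i.i.d. uniform on [-0.1, 0.1] and the
        concentration-like Glu and h uniform on [0, 0.1], all from
        ``seed``; 'zeros' starts at the origin.

    The run is bitwise reproducible for a fixed seed, method and stimulus.
    """
    from .stimulation import Stimulus, StimulusSpec, build_stimulus

    params = base_params if base_params is not None else ModelParams()
    n = net.n_nodes
    np_ = build_node_params(params, n, modes)
    dt, t_total = params.dt, params.t_total
    n_steps = int(round(t_total / dt))
    times = np.arange(n_steps + 1) * dt

    if isinstance(stimulus, StimulusSpec):
        stimulus = build_stimulus(stimulus, net)
    if stimulus is not None and not isinstance(stimulus, Stimulus):
        raise InvalidParameterError("stimulus must be a StimulusSpec or Stimulus")

    target_vec = np.zeros(n)
    targets = None
    if stimulus is not None:
        targets = stimulus.targets
        target_vec[targets] = 1.0
        svals = stimulus.series(times)
    else:
        svals = np.zeros(n_steps + 1)

    rng = np.random.default_rng(seed)
    if init == "random":
        # Ex/In start anywhere in [-0.1, 0.1]; Glu/h are concentration-like
        # and start non-negative in [0, 0.1]
        state = (
            rng.uniform(-0.1, 0.1, n),
            rng.uniform(-0.1, 0.1, n),
            rng.uniform(0.0, 0.1, n),
            rng.uniform(0.0, 0.1, n),
        )
    elif init == "zeros":
        state = tuple(np.zeros(n) for _ in range(4))
    else:
        raise InvalidParameterError(f"unknown init {init!r}")
    active = net.active_mask
    if not active.all():
        state = tuple(np.where(active, x, 0.0) for x in state)

    adjacency = net.adjacency.astype(float)
    rec = [np.empty((n_steps + 1, n)) for _ in range(4)]
    for arr, x in zip(rec, state):
        arr[0] = x
    stim_rec = svals[:, None] * target_vec[None, :]

    for i in range(n_steps):
        t = times[i]
        if stimulus is not None and method == "rk4":
            def s_fn(tt, _i=i):
                return stimulus.stage_value(tt, _i, svals) * target_vec
        else:
            def s_fn(tt, _i=i):
                return svals[_i] * target_vec
        state = step(state, np_, adjacency, active, s_fn, t, dt, method)
        if not all(np.isfinite(x).all() for x in state):
            raise BlowUpError(i + 1, times[i + 1])
        for arr, x in zip(rec, state):
            arr[i + 1] = x

    return Trajectory(
        times, rec[0], rec[1], rec[2], rec[3], stim_rec, np_, net, seed, method,
        stim_targets=targets,
    )
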