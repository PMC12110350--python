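"""Synchronization and glutamate metrics.

Phases come from the Hilbert analytic signal of each node's mean-removed
excitatory trace.  Pairwise synchrony is the phase-locking value (PLV):
the modulus of the time-averaged unit phasor of the phase difference,

    PLV_ij = | (1/T) sum_t exp(j * (phi_i(t) - phi_j(t))) |,

1 for perfect locking, 0 for no consistent phase relation.  Instantaneous
network synchrony is the Kuramoto order parameter
``R(t) = | mean_i exp(j * phi_i(t)) |``, and its coefficient of variation
(population standard deviation over mean) measures how unsteady the
synchrony is: lower CV, steadier post-treatment network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import hilbert

from .dynamics import Trajectory
from .errors import DegenerateSignalError, InvalidParameterError, UndefinedCVError

__all__ = [
    "SyncReport",
    "hilbert_phase",
    "plv_matrix",
    "network_plv",
    "order_parameter",
    "coefficient_of_variation",
    "glutamate_summary",
    "sync_report",
]


def hilbert_phase(signal: np.ndarray) -> np.ndarray:
    """Instantaneous phase (principal value) of a real time series."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise DegenerateSignalError("need a 1-D series of length >= 4")
    mean = x.mean()
    x = x - mean
    if np.abs(x).max() <= 1e-12 * max(1.0, abs(mean)):
        raise DegenerateSignalError("constant signal has no phase")
    return np.angle(hilbert(x))


def plv_matrix(phases: np.ndarray) -> np.ndarray:
    """Pairwise phase-locking values from an (N, T) phase array."""
    phases = np.asarray(phases, dtype=float)
    if phases.ndim != 2:
        raise InvalidParameterError("phases must be an (N, T) array")
    t_len = phases.shape[1]
    if t_len < 1:
        raise InvalidParameterError("need at least one sample")
    z = np.exp(1j * phases)
    plv = np.abs(z @ z.conj().T) / t_len
    # guard rounding just above 1
    np.clip(plv, 0.0, 1.0, out=plv)
    np.fill_diagonal(plv, 1.0)
    return plv


def network_plv(plv: np.ndarray, active_mask: np.ndarray | None = None) -> float:
    """Mean PLV over distinct active node pairs (upper triangle)."""
    plv = np.asarray(plv, dtype=float)
    if active_mask is not None:
        idx = np.flatnonzero(np.asarray(active_mask, dtype=bool))
        plv = plv[np.ix_(idx, idx)]
    n = plv.shape[0]
    if n < 2:
        raise InvalidParameterError("need at least 2 active nodes")
    iu = np.triu_indices(n, k=1)
    return float(plv[iu].mean())


def order_parameter(phases: np.ndarray) -> np.ndarray:
    """Kuramoto order parameter R(t) of an (N, T) phase array."""
    phases = np.asarray(phases, dtype=float)
    if phases.ndim != 2 or phases.shape[0] < 2:
        raise InvalidParameterError("need phases for at least 2 nodes")
    return np.abs(np.exp(1j * phases).mean(axis=0))


def coefficient_of_variation(series: np.ndarray) -> float:
    """Population standard deviation divided by the mean."""
    x = np.asarray(series, dtype=float)
    mu = x.mean()
    if mu == 0.0:
        raise UndefinedCVError("series has zero mean; CV undefined")
    return float(x.std() / mu)


def glutamate_summary(traj: Trajectory) -> tuple[float, float]:
    """Peak and late-time plateau of the summed-glutamate series.

    The series is the across-active-node sum of Glu; the plateau is its
    mean over the final quarter of samples.
    """
    g = traj.summed_glu()
    quarter = max(1, len(g) // 4)
    return float(g.max()), float(g[-quarter:].mean())


@dataclass
class SyncReport:
    """Synchronization metrics of one trajectory (active nodes only)."""

    plv: np.ndarray            # (N, N); NaN rows/cols for inactive nodes
    network_plv: float
    order_series: np.ndarray   # R(t) on the post-transient window
    cv: float
    glu_peak: float
    glu_plateau: float
    transient_frac: float
    cv_source: str

    def to_dict(self) -> dict:
        return {
            "network_plv": self.network_plv,
            "cv": self.cv,
            "glu_peak": self.glu_peak,
            "glu_plateau": self.glu_plateau,
            "transient_frac": self.transient_frac,
            "cv_source": self.cv_source,
        }

    def write(self, out_dir: str | Path, stem: str = "sync") -> dict:
        """JSON scalars plus CSVs for the PLV matrix and R(t) series."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        plv_path = out / f"{stem}_plv.csv"
        order_path = out / f"{stem}_order.csv"
        np.savetxt(plv_path, self.plv, delimiter=",", fmt="%.8g")
        np.savetxt(order_path, self.order_series, delimiter=",", fmt="%.8g")
        payload = self.to_dict() | {
            "plv_csv": plv_path.name,
            "order_csv": order_path.name,
        }
        json_path = out / f"{stem}.json"
        json_path.write_text(json.dumps(payload, indent=2))
        return payload


def sync_report(
    traj: Trajectory,
    transient_frac: float = 0.1,
    cv_source: str = "order_parameter",
) -> SyncReport:
    """Full synchronization report for a trajectory.

    The first ``transient_frac`` of samples is dropped before phase
    extraction so that initial-condition decay does not deflate the PLV.
    ``cv_source`` selects the series the CV is computed on: the Kuramoto
    order parameter (default) or the across-node mean Ex signal.
    """
    if not 0 <= transient_frac < 1:
        raise InvalidParameterError("transient_frac must lie in [0, 1)")
    start = int(round(transient_frac * traj.n_samples))
    active = traj.net.active_nodes
    if len(active) < 2:
        raise InvalidParameterError("need at least 2 active nodes")
    ex = traj.ex[start:, active].T  # (n_active, T)
    phases = np.vstack([hilbert_phase(row) for row in ex])

    plv_active = plv_matrix(phases)
    n = traj.net.n_nodes
    plv = np.full((n, n), np.nan)
    plv[np.ix_(active, active)] = plv_active
    net_plv = network_plv(plv_active)

    order = order_parameter(phases)
    if cv_source == "order_parameter":
        cv = coefficient_of_variation(order)
    elif cv_source == "mean_ex":
        cv = coefficient_of_variation(ex.mean(axis=0))
    else:
        raise InvalidParameterError(f"unknown cv_source {cv_source!r}")

    glu_peak, glu_plateau = glutamate_summary(traj)
    return SyncReport(
        plv, net_plv, order, cv, glu_peak, glu_plateau, transient_frac, cv_source
    )
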