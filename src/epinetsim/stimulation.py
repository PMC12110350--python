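"""External stimulation of high-degree nodes.

Three waveform families model deep-brain-stimulation drive added to the
excitatory equation of the targeted nodes: per-step random noise (uniform
on [-z, z], zero mean), a sinusoid ``z * sin(2*pi*t/period)``, and a
unipolar square wave taking the values 0 or ``+z``.  One shared waveform
is applied to all targets; targets are the top-``n`` nodes of the degree
ranking (an alternative selector ranks nodes by their baseline PLV row
sums).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .network import AdjacencyNetwork, degree_rank

__all__ = ["StimulusSpec", "Stimulus", "waveform_value", "build_stimulus"]

_KINDS = ("none", "random", "sine", "square")


@dataclass(frozen=True)
class StimulusSpec:
    """Waveform kind, amplitude ``intensity`` (z), target count and timing."""

    kind: str = "none"
    intensity: float = 0.0
    n_targets: int = 0
    period: float = 10.0
    duty: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidParameterError(
                f"unknown stimulus kind {self.kind!r}; expected one of {_KINDS}"
            )
        if self.intensity < 0:
            raise InvalidParameterError("intensity must be >= 0")
        if self.n_targets < 0:
            raise InvalidParameterError("n_targets must be >= 0")
        if self.kind in ("sine", "square") and self.period <= 0:
            raise InvalidParameterError("period must be > 0 for periodic waveforms")
        if self.kind == "square" and not 0 < self.duty < 1:
            raise InvalidParameterError("duty must lie in (0, 1)")


def waveform_value(spec: StimulusSpec, t, rng: np.random.Generator | None = None):
    """Waveform amplitude at time(s) ``t``.

    The random kind draws a fresh uniform value on [-z, z] per call (one
    per integration step in a simulation); pass the generator that owns
    the stimulus seed.
    """
    t = np.asarray(t, dtype=float)
    if spec.kind == "none":
        return np.zeros_like(t)
    if spec.kind == "random":
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        return rng.uniform(-spec.intensity, spec.intensity, size=t.shape)
    if spec.kind == "sine":
        return spec.intensity * np.sin(2.0 * np.pi * t / spec.period)
    if spec.kind == "square":
        phase = np.mod(t / spec.period, 1.0)
        return np.where(phase < spec.duty, spec.intensity, 0.0)
    raise InvalidParameterError(f"unknown stimulus kind {spec.kind!r}")


@dataclass(frozen=True)
class Stimulus:
    """A waveform wired to a fixed set of target nodes."""

    spec: StimulusSpec
    targets: np.ndarray

    def series(self, times: np.ndarray) -> np.ndarray:
        """Waveform value at every sample time (random: one draw per step,
        reproducible from the spec seed)."""
        rng = np.random.default_rng(self.spec.seed)
        return np.asarray(waveform_value(self.spec, times, rng), dtype=float)

    def stage_value(self, t: float, step_index: int, svals: np.ndarray) -> float:
        """Waveform value at an RK4 stage time.

        Deterministic kinds are evaluated exactly; the random kind holds
        the step's drawn value across its stages.
        """
        if self.spec.kind == "random":
            return float(svals[step_index])
        return float(waveform_value(self.spec, t))


def build_stimulus(
    spec: StimulusSpec,
    net: AdjacencyNetwork,
    selector: str = "degree",
    plv_row_sums: np.ndarray | None = None,
) -> Stimulus:
    """Wire a waveform to the top-``n_targets`` nodes of the ranking.

    ``selector='degree'`` ranks by structural degree (the default);
    ``selector='plv'`` ranks active nodes by descending ``plv_row_sums``
    from a baseline run.
    """
    if spec.n_targets > net.n_active:
        raise InvalidParameterError(
            f"n_targets={spec.n_targets} exceeds {net.n_active} active nodes"
        )
    if selector == "degree":
        ranked = degree_rank(net)
    elif selector == "plv":
        if plv_row_sums is None:
            raise InvalidParameterError("selector='plv' needs plv_row_sums")
        nodes = net.active_nodes
        order = np.lexsort((nodes, -np.asarray(plv_row_sums, dtype=float)[nodes]))
        ranked = nodes[order]
    else:
        raise InvalidParameterError(f"unknown selector {selector!r}")
    targets = np.asarray(ranked[: spec.n_targets], dtype=int)
    return Stimulus(spec, targets)
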