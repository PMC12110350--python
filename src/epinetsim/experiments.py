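"""End-to-end computational experiments.

Three studies mirror the treatment-strategy questions the simulator was
built for: a gallery of the four single-population discharge modes, PLV
sweeps over stimulated-node count and stimulation intensity for the three
waveforms, and the comparison of surgical resection plans via glutamate
load, PLV and CV.  Every experiment is reproducible bit-for-bit from its
seed; per-run seeds are spawned deterministically from the experiment seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import sync_report
from .dynamics import ModelParams, Trajectory, apply_mode, simulate
from .errors import InvalidParameterError
from .network import AdjacencyNetwork, assign_modes, generate_ws_network, resect
from .stimulation import StimulusSpec

__all__ = [
    "run_mode_gallery",
    "run_stimulation_sweep",
    "run_resection_experiment",
    "write_report",
    "spawn_seeds",
]

#: classifier thresholds for the mode gallery (post-transient Ex trace)
QUIESCENT_EX_RANGE = 0.5      # final-quarter Ex range below this = quiescent
OSCILLATORY_SIGN_CHANGES = 3  # mean-removed Ex sign changes at least this
SATURATED_GLU_LEVEL = 0.5     # final-quarter mean Glu above this = elevated


def spawn_seeds(seed: int, n: int) -> list[int]:
    """n reproducible child seeds (< 2**31) from one experiment seed."""
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


# ---------------------------------------------------------------------------
# discharge-mode gallery


def _classify(traj: Trajectory) -> dict:
    ex = traj.ex[:, 0]
    glu = traj.glu[:, 0]
    post = slice(traj.n_samples // 10, None)
    quarter = traj.n_samples // 4
    centered = ex[post] - ex[post].mean()
    sign_changes = int(np.sum(np.sign(centered[:-1]) * np.sign(centered[1:]) < 0))
    q4_range = float(np.ptp(ex[-quarter:]))
    glu_q1_std = float(glu[:quarter].std())
    glu_q4_std = float(glu[-quarter:].std())
    glu_q4_mean = float(glu[-quarter:].mean())
    return {
        "ex_amplitude": float(np.ptp(ex[post])),
        "ex_q4_range": q4_range,
        "sign_changes": sign_changes,
        "dominant_freq_proxy": sign_changes / 2.0,
        "glu_range": float(np.ptp(glu[post])),
        "glu_abs_max": float(np.abs(glu[post]).max()),
        "glu_q4_mean": glu_q4_mean,
        "quiescent": q4_range < QUIESCENT_EX_RANGE
        and abs(glu_q4_mean) < QUIESCENT_EX_RANGE,
        "oscillatory": sign_changes >= OSCILLATORY_SIGN_CHANGES,
        "saturated": glu_q4_std < glu_q1_std and glu_q4_mean > SATURATED_GLU_LEVEL,
    }


def run_mode_gallery(
    base_params: ModelParams | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict[int, dict]:
    """Simulate a single uncoupled population under each discharge mode.

    Returns per-mode trajectories with qualitative classifier flags:
    mode 1 quiescent (settled Ex, glutamate near zero), modes 2-3
    oscillatory with mode 2 the larger and faster, mode 4 with glutamate
    rising to a stable elevated plateau.
    """
    params = base_params if base_params is not None else ModelParams()
    single = AdjacencyNetwork(np.zeros((1, 1), dtype=np.int8))
    out: dict[int, dict] = {}
    for mode in (1, 2, 3, 4):
        traj = simulate(single, apply_mode(params, mode), seed=seed)
        entry = {"trajectory": traj, **_classify(traj)}
        if out_dir is not None:
            path = Path(out_dir)
            path.mkdir(parents=True, exist_ok=True)
            traj.write_csv(path / f"mode{mode}_trajectory.csv")
        out[mode] = entry
    return out


# ---------------------------------------------------------------------------
# stimulation sweeps


def _one_run(
    n_nodes: int,
    params: ModelParams,
    kind: str,
    intensity: float,
    n_targets: int,
    net_seed: int,
    run_seed: int,
    stim_seed: int,
    scheme: str = "stimulation",
) -> float:
    net = generate_ws_network(n_nodes, 2, 0.5, seed=net_seed)
    modes = assign_modes(net, scheme)
    spec = None
    if n_targets > 0 and kind != "none" and intensity > 0:
        spec = StimulusSpec(
            kind=kind, intensity=intensity, n_targets=n_targets, seed=stim_seed
        )
    traj = simulate(net, params, modes, stimulus=spec, seed=run_seed)
    return sync_report(traj).network_plv


def run_stimulation_sweep(
    axis: str,
    n_nodes: int = 50,
    kinds: tuple[str, ...] = ("random", "sine", "square"),
    grid: np.ndarray | None = None,
    replicates: int = 10,
    seed: int = 0,
    base_params: ModelParams | None = None,
    fixed_intensity: float = 0.1,
    fixed_n_targets: int = 20,
) -> pd.DataFrame:
    """PLV as a function of stimulated-node count or stimulation intensity.

    ``axis='n_targets'`` sweeps the number of stimulated top-degree nodes
    (default grid 0..30 step 2) at intensity ``fixed_intensity``;
    ``axis='intensity'`` sweeps the amplitude (default 0.01..0.3 in 30
    steps) with ``fixed_n_targets`` stimulated nodes.  Each (kind, grid
    point) is replicated over fresh network/initial-condition seeds.
    """
    params = base_params if base_params is not None else ModelParams()
    if axis == "n_targets":
        grid = np.arange(0, 31, 2) if grid is None else np.asarray(grid)
    elif axis == "intensity":
        grid = np.linspace(0.01, 0.3, 30) if grid is None else np.asarray(grid)
    else:
        raise InvalidParameterError(f"unknown sweep axis {axis!r}")
    if np.any(np.diff(grid) <= 0):
        raise InvalidParameterError("sweep grid must be strictly increasing")

    rep_seeds = spawn_seeds(seed, replicates)
    rows = []
    for kind in kinds:
        for value in grid:
            for rep, rs in enumerate(rep_seeds):
                child = spawn_seeds(rs, 3)
                if axis == "n_targets":
                    n_t, z = int(round(value)), fixed_intensity
                else:
                    n_t, z = fixed_n_targets, float(value)
                plv = _one_run(
                    n_nodes, params, kind, z, n_t,
                    net_seed=child[0], run_seed=child[1], stim_seed=child[2],
                )
                rows.append(
                    {
                        "kind": kind,
                        "grid_value": float(value),
                        "replicate": rep,
                        "seed": rs,
                        "network_plv": plv,
                    }
                )
    df = pd.DataFrame(rows)
    df.attrs["axis"] = axis
    df.attrs["replicates"] = replicates
    return df


# ---------------------------------------------------------------------------
# resection comparison


def run_resection_experiment(
    n_nodes: int = 50,
    plans: tuple[int, ...] = (0, 1, 2, 3, 4),
    replicates: int = 10,
    seed: int = 0,
    base_params: ModelParams | None = None,
) -> pd.DataFrame:
    """Simulate the surgery-scheme network under each resection plan.

    Plan 0 is the pre-surgical baseline.  Each row reports the summed
    glutamate peak and plateau, network PLV, and the CV of the Kuramoto
    order-parameter series for one (plan, replicate).
    """
    if not set(plans) <= {0, 1, 2, 3, 4}:
        raise InvalidParameterError("plans must be a subset of {0,...,4}")
    params = base_params if base_params is not None else ModelParams()
    rep_seeds = spawn_seeds(seed, replicates)
    rows = []
    for rep, rs in enumerate(rep_seeds):
        child = spawn_seeds(rs, 2)
        net = generate_ws_network(n_nodes, 2, 0.5, seed=child[0])
        modes = assign_modes(net, "surgery")
        for plan in plans:
            resected = net if plan == 0 else resect(net, modes, plan)
            traj = simulate(resected, params, modes, seed=child[1])
            rep_out = sync_report(traj)
            rows.append(
                {
                    "plan": plan,
                    "replicate": rep,
                    "seed": rs,
                    "n_active": resected.n_active,
                    "glu_peak": rep_out.glu_peak,
                    "glu_plateau": rep_out.glu_plateau,
                    "network_plv": rep_out.network_plv,
                    "cv": rep_out.cv,
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["replicates"] = replicates
    return df


# ---------------------------------------------------------------------------
# reporting


def write_report(
    results: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Write tidy CSVs plus a JSON manifest; deterministic file naming."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out}: {exc}") from exc
    import epinetsim

    manifest: dict = {
        "version": epinetsim.__version__,
        "seed": seed,
        "config": config or {},
        "files": {},
    }
    for name in sorted(results):
        df = results[name]
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        manifest["files"][name] = path.name
        if "seed" in df.columns:
            manifest.setdefault("seeds", {})[name] = sorted(
                int(s) for s in df["seed"].unique()
            )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out / "manifest.json"
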