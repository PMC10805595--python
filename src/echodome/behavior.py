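"""Linking echoes to behaviour: choice summaries, trajectory averaging and
per-pulse LSD along walking approaches.

The per-pulse analysis mirrors the trajectory study: for selected pulse
emissions along a walk, both targets are simulated at the pulse's
source-target distance, impulse responses extracted by baseline
subtraction, and the surface-/occlusion-component LSD computed.  Component
gates shift with distance (the surface echo arrives at the two-way delay
2 d / c), keeping the same gate geometry relative to the echo as in the
static starting-point analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .fixtures import ChoiceTrialTable, TrajectoryFixture
from .geometry import DomeSpec
from .scenario import SceneCache, target_impulse_response
from .spectral import component_lsd


@dataclass
class ChoiceSummary:
    per_bat: pd.DataFrame  # bat_id, condition, n_trials, n_correct, accuracy
    per_condition: pd.DataFrame  # condition, n_trials, n_correct, accuracy, p_value, p_holm


@dataclass
class MeanPath:
    """Pointwise mean and standard deviation of normalized trajectories."""

    arclength: np.ndarray  # common normalized arc-length grid in [0, 1]
    mean: np.ndarray  # (n, 2)
    sd: np.ndarray  # (n, 2)


@dataclass
class PulseLSDSeries:
    df: pd.DataFrame  # pulse_time_s, x_mm, y_mm, distance_mm, surface_lsd, occlusion_lsd
    probe_target_id: str
    reference_target_id: str


def summarize_choices(trials: ChoiceTrialTable) -> ChoiceSummary:
    """Per-bat and per-condition accuracy with exact binomial tests.

    The pooled per-condition accuracy is tested two-sided against chance
    (0.5); Holm-adjusted p-values are reported alongside the raw ones for
    the four planned comparisons.
    """
    df = trials.df
    if len(df) == 0:
        raise ValueError("empty trial table")
    per_bat = (
        df.groupby(["bat_id", "condition"], as_index=False)
        .agg(n_trials=("correct", "size"), n_correct=("correct", "sum"))
        .assign(accuracy=lambda d: d.n_correct / d.n_trials)
    )
    rows = []
    for cond, grp in df.groupby("condition"):
        n, k = len(grp), int(grp["correct"].sum())
        if n == 0:
            warnings.warn(f"condition {cond} has no trials; omitted")
            continue
        rows.append(
            {
                "condition": cond,
                "n_trials": n,
                "n_correct": k,
                "accuracy": k / n,
                "p_value": binomtest(k, n, 0.5, alternative="two-sided").pvalue,
            }
        )
    per_cond = pd.DataFrame(rows)
    per_cond["p_holm"] = _holm(per_cond["p_value"].to_numpy())
    return ChoiceSummary(per_bat=per_bat, per_condition=per_cond)


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def normalize_trajectories(fixtures: list[TrajectoryFixture], n_points: int = 100) -> MeanPath:
    """Mirror, resample and average walking paths.

    Trials with T1 on the RIGHT are mirrored laterally so T1 is always on
    the LEFT (as in the trajectory figure); each path is resampled onto a
    common normalized arc-length grid, then averaged pointwise.
    """
    if not fixtures:
        raise ValueError("need at least one trajectory")
    s_grid = np.linspace(0.0, 1.0, n_points)
    resampled = []
    for f in fixtures:
        pos = f.positions.copy()
        if f.side_of_t1 == "RIGHT":
            pos[:, 1] = -pos[:, 1]
        seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1] if s[-1] > 0 else 1.0
        s /= total
        resampled.append(
            np.stack([np.interp(s_grid, s, pos[:, 0]), np.interp(s_grid, s, pos[:, 1])], axis=1)
        )
    arr = np.stack(resampled)
    return MeanPath(arclength=s_grid, mean=arr.mean(axis=0), sd=arr.std(axis=0))


def pulse_lsd_series(
    fixture: TrajectoryFixture,
    probe_spec: DomeSpec,
    reference_spec: DomeSpec,
    dx: float = 2.0,
    pulse_subset: list[int] | None = None,
    cache: SceneCache | None = None,
    min_distance: float = 80.0,
    max_distance: float = 450.0,
    gate_offsets_ms: tuple[float, float, float] = (-0.3, 0.5, 1.3),
    mesh_resolution: float | None = None,
    **lsd_kwargs,
) -> PulseLSDSeries:
    """Surface/occlusion LSD of probe vs reference at each selected pulse.

    The corridor walls are not simulated: each pulse maps to a scene by its
    source-target distance alone (domain length adapts to the distance).
    The target sits in the T1 corridor; distances are measured from the
    pulse position to the target front-face centre.  Pulses outside the
    simulable distance range are skipped with a warning.

    ``gate_offsets_ms`` = (pre, split, post) places the surface gate at
    [t0+pre, t0+split) and the occlusion gate at [t0+split, t0+post) around
    the two-way surface delay t0 = 2 d / c.
    """
    cache = cache if cache is not None else SceneCache()
    pulse_pos = fixture.pulse_positions()
    idx = list(range(len(pulse_pos))) if pulse_subset is None else list(pulse_subset)
    sgn = -1.0 if fixture.side_of_t1 == "LEFT" else 1.0
    from .fixtures import ARENA

    target_xy = np.array([0.0, sgn * ARENA["corridor_offset"]])
    rows = []
    for i in idx:
        p = pulse_pos[i]
        d = float(np.linalg.norm(p - target_xy))
        d = round(d / dx) * dx  # snap to the lattice
        if not min_distance <= d <= max_distance:
            warnings.warn(
                f"pulse {i} at distance {d:.0f} mm is outside the simulable range "
                f"[{min_distance}, {max_distance}]; skipped"
            )
            continue
        c = 340.0
        t0 = 2.0 * d * 1e-3 / c * 1e3  # two-way surface delay, ms
        pre, split, post = gate_offsets_ms
        gates = {
            "SURFACE": (t0 + pre, t0 + split),
            "OCCLUSION": (t0 + split, t0 + post),
        }
        duration = t0 + post + 0.25
        common = dict(dx=dx, distance=d, duration_ms=duration, cache=cache)
        if mesh_resolution is not None:
            common["mesh_resolution"] = mesh_resolution
        ir_probe = target_impulse_response(probe_spec, **common)
        ir_ref = target_impulse_response(reference_spec, **common)
        res = component_lsd(ir_probe, ir_ref, gates=gates, **lsd_kwargs)
        rows.append(
            {
                "pulse_index": i,
                "pulse_time_s": fixture.pulse_times[i],
                "x_mm": p[0],
                "y_mm": p[1],
                "distance_mm": d,
                "surface_lsd": res.surface_lsd,
                "occlusion_lsd": res.occlusion_lsd,
            }
        )
    return PulseLSDSeries(
        df=pd.DataFrame(rows),
        probe_target_id=probe_spec.target_id,
        reference_target_id=reference_spec.target_id,
    )
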