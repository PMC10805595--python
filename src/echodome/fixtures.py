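"""Synthetic behavioural fixtures: walking trajectories and choice trials.

The two-alternative forced-choice arena is a box whose far end is split by
a central wall into two 100 mm wide corridors; the trained target T1 sits
in one corridor (pseudo-random side per trial) and a comparison target in
the other.  These generators stand in for the motion-capture trajectories
and trial logs of the behavioural experiment: smooth walking paths with
jittered pulse-emission times, and Bernoulli choice outcomes at a
prescribed per-condition accuracy (15 test trials per condition in the
study design).

Coordinates: the target line is at x = 0, the bat starts near
``start_distance`` (mm) and walks toward the targets; y is lateral with
the corridor centres at +/- ``corridor_offset``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("T1vT2", "T1vT3", "T1vT4", "T1vT5")

#: Mean choice accuracy per condition observed in the discrimination tests
#: (T2 and T5 at 100%, T3 near chance, T4 intermediate).
DEFAULT_CONDITION_ACCURACY: dict[str, float] = {
    "T1vT2": 1.0,
    "T1vT3": 0.557,
    "T1vT4": 0.68,
    "T1vT5": 1.0,
}

ARENA = {
    "start_distance": 600.0,  # mm from target line to release point
    "corridor_width": 100.0,  # aisle width (10 cm)
    "corridor_offset": 60.0,  # lateral centre of each corridor
    "half_width": 110.0,  # arena lateral half extent
}


class FixtureError(ValueError):
    pass


@dataclass
class TrajectoryFixture:
    """One walking approach with pulse-emission times."""

    times: np.ndarray  # s, strictly increasing
    positions: np.ndarray  # (n, 2) floor coordinates, mm
    head_directions: np.ndarray  # (n, 2) unit vectors
    pulse_times: np.ndarray  # s
    side_of_t1: str  # LEFT / RIGHT
    outcome: str  # CORRECT / INCORRECT
    condition: str = "T1vT4"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.head_directions = np.asarray(self.head_directions, dtype=float).reshape(-1, 2)
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise FixtureError("times must be strictly increasing")
        if len(self.times) != len(self.positions):
            raise FixtureError("times and positions must have equal length")
        if self.pulse_times.size and (
            self.pulse_times.min() < self.times[0] or self.pulse_times.max() > self.times[-1]
        ):
            raise FixtureError("pulse_times must lie within the trajectory time span")
        if self.side_of_t1 not in ("LEFT", "RIGHT"):
            raise FixtureError(f"side_of_t1 must be LEFT or RIGHT, got {self.side_of_t1}")
        if self.outcome not in ("CORRECT", "INCORRECT"):
            raise FixtureError(f"outcome must be CORRECT or INCORRECT, got {self.outcome}")

    def pulse_positions(self) -> np.ndarray:
        """(k, 2) interpolated positions at the pulse-emission times."""
        return np.stack(
            [np.interp(self.pulse_times, self.times, self.positions[:, i]) for i in (0, 1)],
            axis=1,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_s": self.times,
                "x_mm": self.positions[:, 0],
                "y_mm": self.positions[:, 1],
                "head_x": self.head_directions[:, 0],
                "head_y": self.head_directions[:, 1],
            }
        )
        df["is_pulse"] = np.isin(df["time_s"], self.pulse_times)
        return df


@dataclass
class ChoiceTrialTable:
    """Per-trial outcomes of the two-alternative forced-choice tests."""

    df: pd.DataFrame

    REQUIRED = ("bat_id", "condition", "side_of_t1", "chosen_side", "correct")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.df.columns)
        if missing:
            raise FixtureError(f"trial table is missing columns {sorted(missing)}")
        ok = (self.df["chosen_side"] == self.df["side_of_t1"]) == self.df["correct"]
        if not ok.all():
            raise FixtureError("'correct' must equal (chosen_side == side_of_t1)")

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ChoiceTrialTable":
        return cls(pd.read_csv(path))


def _balanced_sides(n: int, rng: np.random.Generator) -> np.ndarray:
    """Pseudo-random but balanced LEFT/RIGHT sequence."""
    sides = np.array(["LEFT", "RIGHT"] * (n // 2 + 1))[:n]
    rng.shuffle(sides)
    return sides


def gen_trajectories(
    n_trials: int,
    condition: str = "T1vT4",
    decision_profile: str = "DECISIVE",
    seed: int = 0,
    sample_rate: float = 100.0,
    speed: float = 300.0,
    pulse_interval: float = 0.08,
    pulse_jitter: float = 0.02,
) -> list[TrajectoryFixture]:
    """Smooth approach paths with jittered pulse emissions.

    ``DECISIVE`` paths veer into the T1 corridor over the second half of
    the approach (mirroring correct trials); ``UNSURE`` paths wander near
    the centreline and end undecided (mirroring incorrect trials).
    ``speed`` is the walking speed in mm/s.
    """
    if n_trials < 1:
        raise FixtureError("n_trials must be >= 1")
    if decision_profile not in ("DECISIVE", "UNSURE"):
        raise FixtureError(f"unknown decision profile {decision_profile!r}")
    if condition not in CONDITIONS:
        raise FixtureError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    sides = _balanced_sides(n_trials, rng)
    fixtures = []
    x0 = ARENA["start_distance"]
    for trial in range(n_trials):
        duration = x0 / speed
        t = np.arange(0.0, duration + 1e-9, 1.0 / sample_rate)
        x = x0 - speed * t
        sgn = -1.0 if sides[trial] == "LEFT" else 1.0
        if decision_profile == "DECISIVE":
            # logistic veer into the T1 corridor, committed halfway in
            centre = 0.45 * x0
            width = 0.12 * x0
            y = sgn * ARENA["corridor_offset"] / (1.0 + np.exp((x - centre) / width))
        else:
            y = np.zeros_like(x)
        # small smooth wander, stronger for the unsure profile
        n_w = 4
        amp = 8.0 if decision_profile == "DECISIVE" else 18.0
        for h in range(1, n_w + 1):
            y = y + amp / h * rng.standard_normal() * np.sin(
                np.pi * h * t / duration + rng.uniform(0, 2 * np.pi)
            ) * np.sin(np.pi * t / duration)
        y = np.clip(y, -ARENA["half_width"] + 5, ARENA["half_width"] - 5)
        pos = np.stack([x, y], axis=1)
        tang = np.gradient(pos, t, axis=0)
        norm = np.linalg.norm(tang, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        head = tang / norm
        pulses = []
        tp = rng.uniform(0, pulse_interval)
        while tp <= duration:
            pulses.append(tp)
            tp += pulse_interval + rng.uniform(-pulse_jitter, pulse_jitter)
        pulse_times = np.interp(np.asarray(pulses), t, t)  # snap inside span
        outcome = "CORRECT" if decision_profile == "DECISIVE" else "INCORRECT"
        fixtures.append(
            TrajectoryFixture(
                times=t,
                positions=pos,
                head_directions=head,
                pulse_times=pulse_times,
                side_of_t1=str(sides[trial]),
                outcome=outcome,
                condition=condition,
            )
        )
    return fixtures


def gen_choice_trials(
    accuracy_per_condition: dict[str, float] | None = None,
    n_per_condition: int = 15,
    n_bats: int = 3,
    seed: int = 0,
) -> ChoiceTrialTable:
    """Bernoulli trial outcomes at the prescribed per-condition accuracy,
    with balanced pseudo-random T1 side assignment."""
    acc = DEFAULT_CONDITION_ACCURACY if accuracy_per_condition is None else accuracy_per_condition
    for cond, p in acc.items():
        if not 0.0 <= p <= 1.0:
            raise FixtureError(f"accuracy for {cond} must lie in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    rows = []
    for cond, p in acc.items():
        for bat in range(n_bats):
            sides = _balanced_sides(n_per_condition, rng)
            correct = rng.random(n_per_condition) < p
            for s, ok in zip(sides, correct):
                chosen = s if ok else ("RIGHT" if s == "LEFT" else "LEFT")
                rows.append(
                    {
                        "bat_id": chr(ord("A") + bat),
                        "condition": cond,
                        "side_of_t1": s,
                        "chosen_side": chosen,
                        "correct": bool(ok),
                    }
                )
    return ChoiceTrialTable(pd.DataFrame(rows))
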