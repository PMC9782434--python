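"""Platform yaw-perturbation trajectories and the randomized trial schedule.

The support surface rotates sinusoidally about the vertical (yaw) axis at one
of three intensity levels.  Each steady-state sinusoid is bracketed by smooth
sigmoidal on/off ramps so that the platform never starts or stops abruptly.
A recording session consists of 18 trials: 3 levels x 2 starting sides x 3
repetitions, delivered in seeded random order.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PerturbationLevel",
    "StartSide",
    "PerturbationSpec",
    "PlatformTrajectory",
    "TrialSchedule",
    "STANDARD_SPECS",
    "make_trajectory",
    "make_schedule",
]


class PerturbationLevel(str, enum.Enum):
    LP = "LP"
    MP = "MP"
    HP = "HP"


class StartSide(str, enum.Enum):
    RIGHT = "right"
    LEFT = "left"


#: (frequency Hz, peak amplitude deg) of the three platform conditions.
_LEVEL_PARAMS: dict[PerturbationLevel, tuple[float, float]] = {
    PerturbationLevel.LP: (0.2, 55.0),
    PerturbationLevel.MP: (0.3, 55.0),
    PerturbationLevel.HP: (0.5, 35.0),
}


@dataclass(frozen=True)
class PerturbationSpec:
    """One platform condition: intensity level, frequency and peak amplitude.

    The three standard levels are LP (0.2 Hz, +/-55 deg), MP (0.3 Hz,
    +/-55 deg) and HP (0.5 Hz, +/-35 deg).  ``start_side`` selects the sign
    of the initial half-wave (right = +sin, left = -sin).
    """

    level: PerturbationLevel
    frequency: float
    peak_amplitude: float
    start_side: StartSide = StartSide.RIGHT

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"frequency must be positive, got {self.frequency}")
        if self.peak_amplitude < 0:
            raise ValueError(
                f"peak_amplitude must be non-negative, got {self.peak_amplitude}"
            )

    @classmethod
    def standard(
        cls,
        level: PerturbationLevel | str,
        start_side: StartSide | str = StartSide.RIGHT,
    ) -> "PerturbationSpec":
        """Return the standard condition for *level* (LP, MP or HP)."""
        level = PerturbationLevel(level)
        f, amp = _LEVEL_PARAMS[level]
        return cls(level=level, frequency=f, peak_amplitude=amp,
                   start_side=StartSide(start_side))

    @property
    def test_type(self) -> str:
        """Identifier of the (level, side) test type, e.g. ``'LP_right'``."""
        return f"{self.level.value}_{self.start_side.value}"


#: All six standard test types (3 levels x 2 sides).
STANDARD_SPECS: tuple[PerturbationSpec, ...] = tuple(
    PerturbationSpec.standard(level, side)
    for level in PerturbationLevel
    for side in StartSide
)


@dataclass
class PlatformTrajectory:
    """Sampled platform yaw-angle trajectory with ramp bookkeeping.

    ``steady_start_index``/``steady_end_index`` delimit the un-ramped,
    purely sinusoidal portion (half-open interval, python slice semantics).
    """

    time: np.ndarray          # s, uniform grid
    yaw_angle: np.ndarray     # deg
    fs: float                 # Hz
    ramp_duration: float      # s
    steady_start_index: int
    steady_end_index: int
    spec: PerturbationSpec | None = None

    @property
    def steady_slice(self) -> slice:
        return slice(self.steady_start_index, self.steady_end_index)

    @property
    def steady_yaw(self) -> np.ndarray:
        return self.yaw_angle[self.steady_slice]

    def to_csv(self, path: str | Path) -> None:
        """Write the trajectory as a two-column CSV (time_s, yaw_deg)."""
        arr = np.column_stack([self.time, self.yaw_angle])
        np.savetxt(path, arr, delimiter=",", header="time_s,yaw_deg",
                   comments="", fmt="%.9g")


def _smoothstep(u: np.ndarray) -> np.ndarray:
    """C1 sigmoidal envelope 3u^2 - 2u^3 on [0, 1], clipped outside."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def make_trajectory(
    spec: PerturbationSpec,
    duration: float = 34.0,
    fs: float = 100.0,
    ramp_duration: float = 2.0,
) -> PlatformTrajectory:
    """Generate a ramped sinusoidal platform yaw trajectory.

    The steady segment is ``A * sin(2*pi*f*t)`` (sign flipped for a left
    start), multiplied by a sigmoidal amplitude envelope rising over the
    first ``ramp_duration`` seconds and falling over the last, so the
    platform starts and ends at 0 deg with continuous velocity.

    Parameters
    ----------
    spec
        Perturbation condition (frequency, amplitude, start side).
    duration
        Total trajectory length in s, ramps included.  The steady portion
        must cover at least 5 full periods of ``spec.frequency``.
    fs
        Sampling rate in Hz; must be at least 20x the perturbation frequency.
    ramp_duration
        Length of each sigmoidal on/off ramp, s.
    """
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if ramp_duration < 0:
        raise ValueError("ramp_duration must be non-negative")
    steady = duration - 2.0 * ramp_duration
    min_steady = 5.0 / spec.frequency
    if steady < min_steady - 1e-12:
        raise ValueError(
            f"duration {duration} s leaves {steady:.2f} s of steady state; "
            f"at least 5 periods ({min_steady:.2f} s) of {spec.frequency} Hz "
            f"are required after the two {ramp_duration} s ramps"
        )
    if fs < 20.0 * spec.frequency:
        raise ValueError(
            f"fs {fs} Hz is below 20x the perturbation frequency "
            f"({spec.frequency} Hz)"
        )

    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    sign = 1.0 if spec.start_side is StartSide.RIGHT else -1.0
    carrier = sign * spec.peak_amplitude * np.sin(2.0 * np.pi * spec.frequency * t)

    env = np.ones(n)
    if ramp_duration > 0:
        env *= _smoothstep(t / ramp_duration)
        env *= _smoothstep((duration - t) / ramp_duration)
    yaw = env * carrier

    start = int(np.ceil(ramp_duration * fs - 1e-9))
    end = n - start  # symmetric: last steady sample is n-1-start, slice end-exclusive
    return PlatformTrajectory(
        time=t, yaw_angle=yaw, fs=fs, ramp_duration=ramp_duration,
        steady_start_index=start, steady_end_index=end, spec=spec,
    )


@dataclass
class TrialSchedule:
    """Seeded random ordering of the 18 trials of one recording session."""

    trials: list[tuple[int, PerturbationSpec]] = field(default_factory=list)
    rng_seed: int = 0

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "trial_index": i,
                "level": s.level.value,
                "frequency_hz": s.frequency,
                "peak_amplitude_deg": s.peak_amplitude,
                "start_side": s.start_side.value,
            }
            for i, s in self.trials
        ]
        Path(path).write_text(json.dumps(
            {"rng_seed": self.rng_seed, "trials": payload}, indent=2))


def make_schedule(rng_seed: int, n_repetitions: int = 3) -> TrialSchedule:
    """Build the randomized trial order: 3 levels x 2 sides x repetitions.

    The same seed always yields the same permutation; different seeds
    permute the same multiset of trials.
    """
    pool = [spec for spec in STANDARD_SPECS for _ in range(n_repetitions)]
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(pool))
    trials = [(i, pool[j]) for i, j in enumerate(order)]
    return TrialSchedule(trials=trials, rng_seed=rng_seed)
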