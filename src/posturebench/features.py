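"""Kinematic feature extraction from IMU streams.

For each trial the pipeline derives, per body segment (head, trunk, pelvis):

* **ROM-ML / ROM-AP** — range of motion (max - min displacement, mm) in the
  medio-lateral and antero-posterior directions.  Body-frame accelerations
  are rotated to the world frame with the quaternion-derived rotation
  matrix, gravity is subtracted, and displacement is obtained by double
  integration with a zero-lag first-order Butterworth high-pass (0.2 Hz)
  after each integration stage to suppress integration drift.
* **Gain Ratio (G) / Phase Shift (phi)** — inter-segment yaw coupling at the
  perturbation frequency, computed in the Fourier domain: G is the ratio of
  the distal to proximal spectral amplitude at the proximal fundamental,
  phi the phase difference there (degrees, positive = distal lags).

Coupling is chained pelvis<-platform, trunk<-pelvis, head<-trunk, so each
segment owns one (G, phi) pair.  Over the six test types (3 perturbation
levels x 2 start sides) this yields 4 features x 3 segments x 6 tests = 72
features per subject-state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.transform import Rotation

from .cohort import GRAVITY, SEGMENTS, RecordingSession, Segment, SensorStream
from .protocol import PerturbationLevel, StartSide

__all__ = [
    "FEATURE_BASES",
    "FEATURE_NAMES",
    "FeatureVector",
    "world_linear_acceleration",
    "displacement_from_acceleration",
    "zero_lag_highpass_gain",
    "range_of_motion",
    "dominant_frequency",
    "coupling_indices",
    "CouplingIndices",
    "yaw_angle_from_stream",
    "static_heading_offset",
    "extract_session_features",
    "assemble_features",
]

HIGHPASS_CUTOFF_HZ = 0.2
#: Fundamental-frequency search band for the FFT argmax, Hz (DC excluded).
FUNDAMENTAL_BAND_HZ = (0.05, 2.0)
#: Seconds trimmed from each side of the steady window (filter edge guard).
#: The 0.2 Hz first-order high-pass has a ~0.8 s time constant; two seconds
#: lets both stages' edge transients decay below the ROM tolerance.
EDGE_GUARD_S = 2.0

FEATURE_BASES = ("rom_ml", "rom_ap", "gain", "phase")

#: Stable ordering of the 72 feature names: base x segment x level x side.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{base}_{seg.value}_{level.value}_{side.value}"
    for base in FEATURE_BASES
    for seg in SEGMENTS
    for level in PerturbationLevel
    for side in StartSide
)


@dataclass
class FeatureVector:
    """The named kinematic features of one subject-state, plus its label."""

    subject_id: str
    state: str
    group: str
    features: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.features)
        if missing:
            raise ValueError(f"missing features: {sorted(missing)[:5]}...")
        bad = [k for k, v in self.features.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite features: {bad[:5]}")

    def as_series(self) -> pd.Series:
        return pd.Series({name: self.features[name] for name in FEATURE_NAMES})


@dataclass(frozen=True)
class CouplingIndices:
    """Fourier-domain yaw coupling of one kinematic link."""

    distal: str
    proximal: str
    gain_ratio: float
    phase_shift_deg: float   # in (-180, 180], positive = distal lags
    fundamental_hz: float


# --------------------------------------------------------------------------
# Signal primitives


def world_linear_acceleration(stream: SensorStream,
                              norm_tol: float = 1e-3) -> np.ndarray:
    """Rotate body accelerations to the world frame and remove gravity.

    Returns an (n, 3) array of free acceleration in m/s^2 (X = AP,
    Y = ML, Z = vertical).  Quaternions whose norm deviates from 1 by more
    than *norm_tol* are rejected.
    """
    norms = np.linalg.norm(stream.quaternion, axis=1)
    worst = float(np.max(np.abs(norms - 1.0)))
    if worst > norm_tol:
        raise ValueError(
            f"non-unit quaternion in stream (max |norm-1| = {worst:.2e})")
    rot = Rotation.from_quat(stream.quaternion, scalar_first=True)
    a_world = rot.apply(stream.accel_body)
    a_world[:, 2] -= GRAVITY
    return a_world


def _zero_lag_highpass(x: np.ndarray, fs: float,
                       cutoff: float) -> np.ndarray:
    b, a = signal.butter(1, cutoff, btype="highpass", fs=fs)
    # even-reflection padding over many filter time constants keeps the
    # start-up transient of the slow high-pass out of the series proper
    padlen = min(x.size - 1, int(10.0 * fs / cutoff))
    return signal.filtfilt(b, a, x, padtype="even", padlen=padlen)


def zero_lag_highpass_gain(freq_hz: float, fs: float,
                           cutoff: float = HIGHPASS_CUTOFF_HZ) -> float:
    """Magnitude response of one forward-backward high-pass pass at *freq_hz*.

    The forward-backward (zero-lag) application squares the single-pass
    Butterworth magnitude; this exact digital response is what the ROM
    amplitude correction and the analytic test oracles use.
    """
    b, a = signal.butter(1, cutoff, btype="highpass", fs=fs)
    _, h = signal.freqz(b, a, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]) ** 2)


def displacement_from_acceleration(
    accel: np.ndarray,
    fs: float,
    cutoff: float = HIGHPASS_CUTOFF_HZ,
) -> np.ndarray:
    """Double-integrate a free-acceleration axis into displacement (mm).

    Each cumulative-trapezoid integration is followed by the zero-lag
    first-order Butterworth high-pass at *cutoff*, which bounds the
    low-frequency drift both integrations would otherwise accumulate.  The
    returned displacement is attenuated by the filter's passband response;
    callers that need absolute amplitudes correct with
    :func:`zero_lag_highpass_gain`.
    """
    accel = np.asarray(accel, dtype=float)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    warmup = 3.0 / cutoff
    if accel.shape[0] / fs < warmup:
        raise ValueError(
            f"series of {accel.shape[0] / fs:.1f} s is shorter than the "
            f"{warmup:.0f} s filter warm-up at cutoff {cutoff} Hz")
    vel = cumulative_trapezoid(accel, dx=1.0 / fs, initial=0.0)
    vel = _zero_lag_highpass(vel, fs, cutoff)
    disp = cumulative_trapezoid(vel, dx=1.0 / fs, initial=0.0)
    disp = _zero_lag_highpass(disp, fs, cutoff)
    return disp * 1000.0


def range_of_motion(displacement: np.ndarray,
                    window: slice | None = None) -> float:
    """Peak-to-peak excursion (max - min) of *displacement* over *window*."""
    seg = displacement[window] if window is not None else displacement
    if seg.size == 0:
        raise ValueError("empty steady-state window")
    return float(np.max(seg) - np.min(seg))


def dominant_frequency(series: np.ndarray, fs: float,
                       band: tuple[float, float] = FUNDAMENTAL_BAND_HZ,
                       ) -> tuple[float, int]:
    """Frequency (Hz) and rFFT bin of the maximum-magnitude component.

    The search excludes DC and is restricted to *band*; ties break toward
    the lower frequency (``argmax`` keeps the first maximum).
    """
    series = np.asarray(series, dtype=float)
    spec = np.fft.rfft(series - series.mean())
    freqs = np.fft.rfftfreq(series.size, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    if not mask.any():
        raise ValueError(f"no FFT bins inside band {band} Hz")
    mags = np.abs(spec)
    if np.all(mags[mask] == 0):
        raise ValueError("spectrum is identically zero inside the band")
    idx = np.flatnonzero(mask)
    k = int(idx[np.argmax(mags[idx])])
    return float(freqs[k]), k


def _wrap_phase_deg(phi: float) -> float:
    """Wrap to (-180, 180]."""
    w = (phi + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else float(w)


def coupling_indices(
    distal: np.ndarray,
    proximal: np.ndarray,
    fs: float,
    distal_name: str = "distal",
    proximal_name: str = "proximal",
    band: tuple[float, float] = FUNDAMENTAL_BAND_HZ,
) -> CouplingIndices:
    """Gain ratio and phase shift of *distal* relative to *proximal*.

    Both series are mean-detrended; the fundamental bin is the
    maximum-magnitude bin of the *proximal* spectrum within *band*.  The
    gain ratio is the distal/proximal magnitude ratio there; the phase
    shift is the proximal-minus-distal phase difference wrapped to
    (-180, 180] degrees, so a distal delay gives a positive shift.
    """
    distal = np.asarray(distal, dtype=float)
    proximal = np.asarray(proximal, dtype=float)
    if distal.shape != proximal.shape:
        raise ValueError("distal and proximal series must have equal length")
    f_star, k = dominant_frequency(proximal, fs, band=band)
    spec_d = np.fft.rfft(distal - distal.mean())
    spec_p = np.fft.rfft(proximal - proximal.mean())
    gain = float(np.abs(spec_d[k]) / np.abs(spec_p[k]))
    phase = _wrap_phase_deg(
        np.degrees(np.angle(spec_p[k]) - np.angle(spec_d[k])))
    return CouplingIndices(distal=distal_name, proximal=proximal_name,
                           gain_ratio=gain, phase_shift_deg=phase,
                           fundamental_hz=f_star)


def yaw_angle_from_stream(stream: SensorStream) -> np.ndarray:
    """Unwrapped yaw angle (deg) of the segment from its quaternions."""
    rot = Rotation.from_quat(stream.quaternion, scalar_first=True)
    yaw = rot.as_euler("zyx", degrees=True)[:, 0]
    return np.unwrap(yaw, period=360.0)


def static_heading_offset(stream: SensorStream,
                          static_window: slice) -> float:
    """Mean yaw (deg) over a static standing pose.

    A minimal stand-in for a full functional sensor-to-segment calibration:
    the constant heading misalignment estimated from a quiet-standing window
    can be subtracted from the segment's yaw before coupling analysis.
    (Mean-detrending inside :func:`coupling_indices` removes any constant
    offset as well, so this matters only for reporting absolute headings.)
    """
    return float(np.mean(yaw_angle_from_stream(stream)[static_window]))


# --------------------------------------------------------------------------
# Session-level extraction


def _periodic_window(start: int, stop: int, fs: float, f0: float) -> slice:
    """Crop [start, stop) to the largest integer number of f0-periods.

    An integer-period window makes the fundamental fall exactly on an rFFT
    bin, eliminating spectral leakage in the coupling estimates.
    """
    n_avail = stop - start
    # smallest block of whole periods that is also a whole number of samples
    for m in range(1, 1001):
        n_block = m * fs / f0
        if abs(n_block - round(n_block)) < 1e-9:
            n_block = int(round(n_block))
            break
    else:  # pragma: no cover - unreachable for rational fs/f0
        n_block = n_avail
    n_use = (n_avail // n_block) * n_block
    if n_use == 0:
        n_use = n_avail  # fall back to the full window
    return slice(start, start + n_use)


def extract_session_features(session: RecordingSession) -> dict[str, float]:
    """Extract the 12 per-trial features (4 per segment) of one session.

    Returns a dict keyed ``{base}_{segment}`` (e.g. ``rom_ml_trunk``,
    ``gain_pelvis``); the caller appends the test-type suffix.
    """
    traj = session.trajectory
    fs = traj.fs
    guard = int(round(EDGE_GUARD_S * fs))
    start = traj.steady_start_index + guard
    stop = traj.steady_end_index - guard
    if stop <= start:
        raise ValueError("steady-state window vanished after edge guard")
    window = slice(start, stop)

    f_pert = session.spec.frequency
    coupling_win = _periodic_window(start, stop, fs, f_pert)

    feats: dict[str, float] = {}
    proximal_yaw = traj.yaw_angle
    for seg in (Segment.PELVIS, Segment.TRUNK, Segment.HEAD):
        stream = session.streams[seg]
        a_world = world_linear_acceleration(stream)
        for base, axis in (("rom_ap", 0), ("rom_ml", 1)):
            disp = displacement_from_acceleration(a_world[:, axis], fs)
            rom = range_of_motion(disp, window)
            # undo the known two-stage zero-lag attenuation at the sway
            # fundamental so ROM is reported on the physical scale
            f_dom, _ = dominant_frequency(disp[window], fs)
            stage_gain = zero_lag_highpass_gain(f_dom, fs)
            feats[f"{base}_{seg.value}"] = rom / stage_gain**2

        yaw = yaw_angle_from_stream(stream)
        ci = coupling_indices(yaw[coupling_win], proximal_yaw[coupling_win],
                              fs, distal_name=seg.value)
        feats[f"gain_{seg.value}"] = ci.gain_ratio
        feats[f"phase_{seg.value}"] = ci.phase_shift_deg
        proximal_yaw = yaw
    return feats


def assemble_features(
    sessions: list[RecordingSession],
    subject_id: str | None = None,
    group: str = "",
    state: str | None = None,
) -> FeatureVector:
    """Average per-trial features over repetitions into the 72-entry vector.

    All six test types (3 levels x 2 start sides) must be present;
    repetitions of the same test type are averaged.  The result is invariant
    to the order in which sessions are supplied.
    """
    if not sessions:
        raise ValueError("no sessions supplied")
    subject_id = subject_id or sessions[0].subject_id
    state = state if state is not None else sessions[0].state.value

    by_type: dict[str, list[dict[str, float]]] = {}
    for s in sessions:
        by_type.setdefault(s.spec.test_type, []).append(
            extract_session_features(s))

    expected = {f"{lvl.value}_{side.value}"
                for lvl in PerturbationLevel for side in StartSide}
    missing = expected - set(by_type)
    if missing:
        raise ValueError(
            f"missing test types for {subject_id}/{state}: {sorted(missing)}")

    features: dict[str, float] = {}
    for test_type, reps in by_type.items():
        keys = reps[0].keys()
        for key in keys:
            features[f"{key}_{test_type}"] = float(
                np.mean([r[key] for r in reps]))
    return FeatureVector(subject_id=subject_id, state=state, group=group,
                         features=features)


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into the analysis table (one row per vector)."""
    rows = []
    for v in vectors:
        row = {"subject_id": v.subject_id, "group": v.group, "state": v.state}
        row.update({name: v.features[name] for name in FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)
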