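"""Virtual cohort: simulated subjects, segment kinematics and IMU streams.

Stands in for an instrumented-posturography recording of real participants.
Each subject is a small parametric model of reactive postural behaviour
during yaw platform rotations:

* the axial segments (pelvis, trunk, head) follow the platform's yaw through
  a chain of per-link gains and phase lags (pelvis<-platform, trunk<-pelvis,
  head<-trunk), the standard way inter-segment yaw coupling is summarized;
* each segment additionally sways sinusoidally in the medio-lateral (ML) and
  antero-posterior (AP) directions;
* a virtual IMU on each segment reports its orientation quaternion,
  body-frame specific force (gravity included) and body-frame angular rate,
  with optional Gaussian sensor noise.

Group structure mirrors the clinical contrast the pipeline is meant to
detect: parkinsonian subjects (PD) sway more in ML and transmit less of the
platform rotation through the pelvis link than healthy controls (HC); PD
subjects carry paired medication-OFF and medication-ON parameter sets, with
ON only partially normalized toward HC (axial postural control is largely
refractory to dopaminergic therapy).

World frame: Z up (gravity +9.81 m/s^2 on Z), X antero-posterior,
Y medio-lateral.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .protocol import PerturbationSpec, PlatformTrajectory

__all__ = [
    "Group",
    "MedState",
    "Segment",
    "SEGMENTS",
    "GRAVITY",
    "SubjectProfile",
    "SegmentKinematics",
    "SensorStream",
    "RecordingSession",
    "EffectConfig",
    "CohortParams",
    "simulate_segment_kinematics",
    "render_imu",
    "simulate_session",
    "sample_cohort",
]

GRAVITY = 9.81  # m/s^2, +Z in the world frame


class Group(str, enum.Enum):
    PD = "PD"
    HC = "HC"


class MedState(str, enum.Enum):
    ON = "ON"
    OFF = "OFF"
    NONE = "none"


class Segment(str, enum.Enum):
    HEAD = "head"
    TRUNK = "trunk"
    PELVIS = "pelvis"


SEGMENTS: tuple[Segment, ...] = (Segment.HEAD, Segment.TRUNK, Segment.PELVIS)

#: Kinematic chain: segment -> its proximal reference.
LINKS: dict[Segment, str] = {
    Segment.PELVIS: "platform",
    Segment.TRUNK: Segment.PELVIS.value,
    Segment.HEAD: Segment.TRUNK.value,
}


@dataclass
class SubjectProfile:
    """Ground-truth kinematic parameters of one simulated subject-state.

    ``link_gain``/``link_phase_deg`` parameterize the yaw transmission of
    each link (dimensionless gain, phase lag in degrees at the perturbation
    frequency, positive = distal segment lags).  ``sway_amp_ml_mm`` /
    ``sway_amp_ap_mm`` give each segment's sway amplitude; sway is sinusoidal
    at ``sway_freq_ml_hz`` / ``sway_freq_ap_hz``.
    """

    subject_id: str
    group: Group
    state: MedState
    link_gain: dict[Segment, float]
    link_phase_deg: dict[Segment, float]
    sway_amp_ml_mm: dict[Segment, float]
    sway_amp_ap_mm: dict[Segment, float]
    sway_freq_ml_hz: float = 0.6
    sway_freq_ap_hz: float = 0.5
    accel_noise_ms2: float = 0.0
    orient_noise_deg: float = 0.0

    def __post_init__(self) -> None:
        if (self.group is Group.HC) != (self.state is MedState.NONE):
            raise ValueError("state must be 'none' iff group is HC")
        for seg in SEGMENTS:
            if self.link_gain[seg] < 0:
                raise ValueError(f"negative link gain for {seg.value}")
            if self.sway_amp_ml_mm[seg] < 0 or self.sway_amp_ap_mm[seg] < 0:
                raise ValueError(f"negative sway amplitude for {seg.value}")
        for f in (self.sway_freq_ml_hz, self.sway_freq_ap_hz):
            if f <= 0.2:
                raise ValueError(
                    f"sway frequency {f} Hz must exceed the 0.2 Hz high-pass "
                    "cutoff or the simulated sway is unrecoverable"
                )


@dataclass
class SegmentKinematics:
    """Noise-free ground-truth motion of one segment on the trial grid."""

    segment: Segment
    time: np.ndarray
    yaw_deg: np.ndarray
    disp_ml_mm: np.ndarray
    disp_ap_mm: np.ndarray
    acc_ml_ms2: np.ndarray   # analytic second derivative of ML displacement
    acc_ap_ms2: np.ndarray
    fs: float


@dataclass
class SensorStream:
    """One virtual IMU's output: quaternions, body accelerations, body rates."""

    segment: Segment
    time: np.ndarray               # s
    quaternion: np.ndarray         # (n, 4) scalar-first (w, x, y, z), unit
    accel_body: np.ndarray         # (n, 3) m/s^2, gravity included
    gyro_body: np.ndarray          # (n, 3) deg/s

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (self.quaternion.shape == (n, 4)
                and self.accel_body.shape == (n, 3)
                and self.gyro_body.shape == (n, 3)):
            raise ValueError("channel lengths differ within the stream")

    def to_frame(self):
        """Return the stream as a pandas DataFrame in the session CSV schema."""
        import pandas as pd

        return pd.DataFrame({
            "time_s": self.time,
            "qw": self.quaternion[:, 0], "qx": self.quaternion[:, 1],
            "qy": self.quaternion[:, 2], "qz": self.quaternion[:, 3],
            "ax": self.accel_body[:, 0], "ay": self.accel_body[:, 1],
            "az": self.accel_body[:, 2],
            "gx": self.gyro_body[:, 0], "gy": self.gyro_body[:, 1],
            "gz": self.gyro_body[:, 2],
        })

    @classmethod
    def from_frame(cls, segment: Segment | str, frame) -> "SensorStream":
        """Rebuild a stream from a DataFrame in the session CSV schema."""
        return cls(
            segment=Segment(segment),
            time=frame["time_s"].to_numpy(float),
            quaternion=frame[["qw", "qx", "qy", "qz"]].to_numpy(float),
            accel_body=frame[["ax", "ay", "az"]].to_numpy(float),
            gyro_body=frame[["gx", "gy", "gz"]].to_numpy(float),
        )


@dataclass
class RecordingSession:
    """One trial: three sensor streams plus the platform trajectory."""

    subject_id: str
    state: MedState
    spec: PerturbationSpec
    streams: dict[Segment, SensorStream]
    trajectory: PlatformTrajectory
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if set(self.streams) != set(SEGMENTS):
            raise ValueError("a session needs exactly one stream per segment")


def _delayed(time: np.ndarray, signal: np.ndarray, delay_s: float) -> np.ndarray:
    """Signal shifted later by *delay_s* (zero-held outside the record)."""
    if delay_s == 0.0:
        return signal.copy()
    return np.interp(time - delay_s, time, signal, left=0.0, right=0.0)


def simulate_segment_kinematics(
    profile: SubjectProfile,
    trajectory: PlatformTrajectory,
    sway_phases: dict[Segment, tuple[float, float]] | None = None,
) -> dict[Segment, SegmentKinematics]:
    """Propagate the platform yaw up the kinematic chain and add sway.

    Each link applies its gain and converts its phase lag (degrees at the
    perturbation frequency) into a pure time delay, so the chain composes
    multiplicatively: yaw_pelvis = g1 * platform delayed by phi1, yaw_trunk =
    g2 * pelvis delayed by phi2, yaw_head = g3 * trunk delayed by phi3.
    ML/AP displacements are sinusoids of the profile's amplitudes and
    frequencies; *sway_phases* (radians per segment, default 0) decorrelates
    repetitions.
    """
    spec = trajectory.spec
    f_pert = spec.frequency if spec is not None else None
    t = trajectory.time

    def delay_of(phase_deg: float) -> float:
        if phase_deg == 0.0:
            return 0.0
        if f_pert is None or f_pert == 0.0:
            raise ValueError("phase lag requires a perturbation frequency")
        return (phase_deg / 360.0) / f_pert

    proximal_yaw = trajectory.yaw_angle
    out: dict[Segment, SegmentKinematics] = {}
    for seg in (Segment.PELVIS, Segment.TRUNK, Segment.HEAD):
        g = profile.link_gain[seg]
        yaw = g * _delayed(t, proximal_yaw, delay_of(profile.link_phase_deg[seg]))
        ph_ml, ph_ap = (sway_phases or {}).get(seg, (0.0, 0.0))
        w_ml = 2.0 * np.pi * profile.sway_freq_ml_hz
        w_ap = 2.0 * np.pi * profile.sway_freq_ap_hz
        a_ml = profile.sway_amp_ml_mm[seg]
        a_ap = profile.sway_amp_ap_mm[seg]
        disp_ml = a_ml * np.sin(w_ml * t + ph_ml)
        disp_ap = a_ap * np.sin(w_ap * t + ph_ap)
        out[seg] = SegmentKinematics(
            segment=seg, time=t, yaw_deg=yaw,
            disp_ml_mm=disp_ml, disp_ap_mm=disp_ap,
            # analytic d2/dt2 of the sway sinusoids, in m/s^2
            acc_ml_ms2=-(a_ml / 1000.0) * w_ml**2 * np.sin(w_ml * t + ph_ml),
            acc_ap_ms2=-(a_ap / 1000.0) * w_ap**2 * np.sin(w_ap * t + ph_ap),
            fs=trajectory.fs,
        )
        proximal_yaw = yaw
    return out


def render_imu(
    kin: SegmentKinematics,
    accel_noise_ms2: float = 0.0,
    orient_noise_deg: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> SensorStream:
    """Render one segment's kinematics as a virtual IMU stream.

    The orientation is a pure yaw rotation (plus orientation noise as small
    random extra rotations).  The body-frame accelerometer reports
    ``R^-1 (a_world + g)`` with g = +9.81 m/s^2 on world Z; the gyroscope
    reports the angular rate of the (noisy) orientation sequence.
    """
    dt = np.diff(kin.time)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
        raise ValueError("kinematics must be sampled on a uniform time grid")
    rng = np.random.default_rng(rng)

    yaw = kin.yaw_deg.astype(float)
    if orient_noise_deg > 0:
        yaw = yaw + rng.normal(0.0, orient_noise_deg, size=yaw.shape)
    rot = Rotation.from_euler("z", yaw[:, np.newaxis], degrees=True)

    a_world = np.column_stack([
        kin.acc_ap_ms2,                       # X: antero-posterior
        kin.acc_ml_ms2,                       # Y: medio-lateral
        np.zeros_like(kin.acc_ml_ms2),
    ])
    g_vec = np.array([0.0, 0.0, GRAVITY])
    accel_body = rot.inv().apply(a_world + g_vec)
    if accel_noise_ms2 > 0:
        accel_body = accel_body + rng.normal(
            0.0, accel_noise_ms2, size=accel_body.shape)

    # angular rate about Z from the rendered yaw sequence, deg/s
    gyro_z = np.gradient(yaw, kin.time)
    gyro_body = np.column_stack(
        [np.zeros_like(gyro_z), np.zeros_like(gyro_z), gyro_z])

    quat = rot.as_quat(scalar_first=True)
    # canonical sign (w >= 0) keeps the stored stream reproducible
    quat = np.where(quat[:, [0]] < 0, -quat, quat)
    return SensorStream(segment=kin.segment, time=kin.time,
                        quaternion=quat, accel_body=accel_body,
                        gyro_body=gyro_body)


def simulate_session(
    profile: SubjectProfile,
    spec: PerturbationSpec,
    duration: float = 34.0,
    fs: float = 100.0,
    ramp_duration: float = 2.0,
    rng: np.random.Generator | int | None = None,
) -> RecordingSession:
    """Simulate one full trial of *profile* under perturbation *spec*."""
    from .protocol import make_trajectory

    rng = np.random.default_rng(rng)
    traj = make_trajectory(spec, duration=duration, fs=fs,
                           ramp_duration=ramp_duration)
    phases = {seg: (rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi))
              for seg in SEGMENTS}
    kins = simulate_segment_kinematics(profile, traj, sway_phases=phases)
    streams = {
        seg: render_imu(kins[seg], profile.accel_noise_ms2,
                        profile.orient_noise_deg, rng)
        for seg in SEGMENTS
    }
    return RecordingSession(subject_id=profile.subject_id, state=profile.state,
                            spec=spec, streams=streams, trajectory=traj)


# --------------------------------------------------------------------------
# Cohort sampling


@dataclass
class EffectConfig:
    """Standardized group contrasts between PD and HC parameter distributions.

    ``ml_amp_sd``: PD medio-lateral sway amplitude mean is shifted up by this
    many within-group SDs.  ``pelvis_gain_sd``: PD pelvis-link yaw gain mean
    is shifted down by this many SDs (reduced transmission through the
    lumbo-sacral link).  ``on_normalization``: fraction by which ON-state
    parameters move back from the OFF values toward the HC means; the default
    is small because axial postural abnormalities respond poorly to L-Dopa.
    """

    ml_amp_sd: float = 1.5
    pelvis_gain_sd: float = 1.5
    on_normalization: float = 0.3


@dataclass
class CohortParams:
    """Population-level means/SDs shared by both groups unless contrasted."""

    # per-segment HC mean ML sway amplitude, mm
    ml_amp_mean: dict[Segment, float] = field(default_factory=lambda: {
        Segment.HEAD: 9.0, Segment.TRUNK: 8.0, Segment.PELVIS: 6.0})
    ml_amp_sd: float = 1.5
    ap_amp_mean: dict[Segment, float] = field(default_factory=lambda: {
        Segment.HEAD: 11.0, Segment.TRUNK: 10.0, Segment.PELVIS: 8.0})
    ap_amp_sd: float = 1.5
    link_gain_mean: dict[Segment, float] = field(default_factory=lambda: {
        Segment.PELVIS: 0.85, Segment.TRUNK: 0.80, Segment.HEAD: 0.90})
    link_gain_sd: float = 0.05
    link_phase_mean_deg: dict[Segment, float] = field(default_factory=lambda: {
        Segment.PELVIS: 8.0, Segment.TRUNK: 12.0, Segment.HEAD: 10.0})
    link_phase_sd_deg: float = 3.0
    sway_freq_ml_hz: float = 0.6
    sway_freq_ap_hz: float = 0.5
    accel_noise_ms2: float = 0.05
    orient_noise_deg: float = 0.2


def _draw_profile(
    subject_id: str,
    group: Group,
    state: MedState,
    params: CohortParams,
    rng: np.random.Generator,
    ml_shift_sd: float = 0.0,
    pelvis_gain_shift_sd: float = 0.0,
) -> SubjectProfile:
    ml = {
        seg: max(0.0, rng.normal(
            params.ml_amp_mean[seg] + ml_shift_sd * params.ml_amp_sd,
            params.ml_amp_sd))
        for seg in SEGMENTS
    }
    ap = {seg: max(0.0, rng.normal(params.ap_amp_mean[seg], params.ap_amp_sd))
          for seg in SEGMENTS}
    gains = {}
    for seg in SEGMENTS:
        mean = params.link_gain_mean[seg]
        if seg is Segment.PELVIS:
            mean = mean + pelvis_gain_shift_sd * params.link_gain_sd
        gains[seg] = max(0.0, rng.normal(mean, params.link_gain_sd))
    phases = {
        seg: rng.normal(params.link_phase_mean_deg[seg],
                        params.link_phase_sd_deg)
        for seg in SEGMENTS
    }
    return SubjectProfile(
        subject_id=subject_id, group=group, state=state,
        link_gain=gains, link_phase_deg=phases,
        sway_amp_ml_mm=ml, sway_amp_ap_mm=ap,
        sway_freq_ml_hz=params.sway_freq_ml_hz,
        sway_freq_ap_hz=params.sway_freq_ap_hz,
        accel_noise_ms2=params.accel_noise_ms2,
        orient_noise_deg=params.orient_noise_deg,
    )


def _normalize_toward(profile: SubjectProfile, params: CohortParams,
                      frac: float, state: MedState) -> SubjectProfile:
    """Move *profile*'s contrasted parameters a fraction toward HC means."""
    ml = {seg: a + frac * (params.ml_amp_mean[seg] - a)
          for seg, a in profile.sway_amp_ml_mm.items()}
    gains = dict(profile.link_gain)
    gains[Segment.PELVIS] = gains[Segment.PELVIS] + frac * (
        params.link_gain_mean[Segment.PELVIS] - gains[Segment.PELVIS])
    return replace(profile, state=state, sway_amp_ml_mm=ml, link_gain=gains)


def sample_cohort(
    n_pd: int = 20,
    n_hc: int = 15,
    effect: EffectConfig | float | None = None,
    rng_seed: int | np.random.Generator = 0,
    params: CohortParams | None = None,
) -> list[SubjectProfile]:
    """Draw a virtual cohort: paired OFF/ON profiles per PD subject, one per HC.

    *effect* may be an :class:`EffectConfig` or a single standardized effect
    size applied to both contrasted parameters (ML sway amplitude up,
    pelvis-link gain down, in the PD group).
    """
    if n_pd < 0 or n_hc < 0:
        raise ValueError("cohort sizes must be non-negative")
    if effect is None:
        effect = EffectConfig()
    elif not isinstance(effect, EffectConfig):
        effect = EffectConfig(ml_amp_sd=float(effect),
                              pelvis_gain_sd=float(effect))
    params = params or CohortParams()
    rng = np.random.default_rng(rng_seed)

    profiles: list[SubjectProfile] = []
    for i in range(n_pd):
        off = _draw_profile(
            f"PD{i + 1:02d}", Group.PD, MedState.OFF, params, rng,
            ml_shift_sd=effect.ml_amp_sd,
            pelvis_gain_shift_sd=-effect.pelvis_gain_sd,
        )
        on = _normalize_toward(off, params, effect.on_normalization,
                               MedState.ON)
        profiles.extend([off, on])
    for i in range(n_hc):
        profiles.append(_draw_profile(
            f"HC{i + 1:02d}", Group.HC, MedState.NONE, params, rng))
    return profiles
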