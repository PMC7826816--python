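"""Seeded synthetic multimodal subjects for end-to-end pipeline testing.

No public recordings of the clinical sessions exist, so this module
fabricates complete subjects: all five sensor streams (7-IMU body
motion at 15 Hz, blood volume pulse at 64 Hz, electrodermal activity at
4 Hz, wrist acceleration at 32 Hz, head rotations plus discrete facial
scores at 10 Hz), a protocol-valid behavior event log per session, and
the latent ground truth that produced them.

The generative model is intentionally simple and fully invented --
sinusoid-plus-noise limb motion, template-pulse photoplethysmogram,
exponential-decay skin-conductance responses, categorical facial
scores -- and makes no claim of physiological realism beyond what the
downstream features can sense.  What it does honor are the study
conditions the pipeline is built around: a CTCTT visit with ~10-12 min
sessions, roughly 26 precursor episodes per visit, 26.9% face-tracking
dropout, <0.3% corrupted IMU rows, and an escalation signature that
begins (by default) 90 s before each precursor, ramping from a 0.3
floor at onset to full intensity at the event.  During escalation,
limb-motion amplitude, heart rate, skin-conductance response rate and
head motion rise by per-subject gains while happy/engaged facial scores
fall.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from . import fsm_protocol
from .fsm_protocol import (
    CTCTT,
    DEFAULT_SESSION_MINUTES,
    BehaviorPolicy,
    SessionTimeline,
    run_protocol,
)
from .streams_io import (
    EventLog,
    SensorStream,
    SessionManifest,
    StreamSchema,
    write_event_log,
    write_manifest,
    write_stream,
)

IMU_NAMES = (
    "l_forearm", "l_upperarm", "r_forearm", "r_upperarm",
    "back_upper", "back_mid", "back_lower",
)
IMU_CHANNELS = ("acclx", "accly", "acclz", "magx", "magy", "magz")
WINGS_CHANNELS = tuple(f"{imu}_{c}" for imu in IMU_NAMES for c in IMU_CHANNELS)

KINECT_NUMERIC = ("head_roll", "head_pitch", "head_yaw")  # degrees
KINECT_FACIAL = ("happy", "eyes_closed", "mouth_open", "looking_away", "engaged")
KINECT_CHANNELS = KINECT_NUMERIC + KINECT_FACIAL

FACIAL_LEVELS = np.array([0.0, 0.5, 1.0])

#: Local magnetic field in the room frame (north, 0, down), arbitrary units.
MAG_FIELD = np.array([0.5, 0.0, -0.4])

SCHEMAS: dict[str, StreamSchema] = {
    "wings": StreamSchema("wings", WINGS_CHANNELS, 15.0),
    "bvp": StreamSchema("bvp", ("bvp",), 64.0),
    "eda": StreamSchema("eda", ("eda_us",), 4.0),
    "e4acc": StreamSchema("e4acc", ("acc_x", "acc_y", "acc_z"), 32.0),
    "kinect": StreamSchema("kinect", KINECT_CHANNELS, 10.0),
}

#: P(score) over {0, 0.5, 1} per facial channel, per latent state.
FACIAL_TABLES: dict[str, dict[str, tuple[float, float, float]]] = {
    "calm": {
        "happy": (0.05, 0.15, 0.80), "engaged": (0.05, 0.10, 0.85),
        "looking_away": (0.80, 0.15, 0.05), "eyes_closed": (0.85, 0.10, 0.05),
        "mouth_open": (0.70, 0.20, 0.10),
    },
    "neutral": {
        "happy": (0.30, 0.50, 0.20), "engaged": (0.30, 0.40, 0.30),
        "looking_away": (0.50, 0.30, 0.20), "eyes_closed": (0.80, 0.15, 0.05),
        "mouth_open": (0.60, 0.25, 0.15),
    },
    "escalating": {
        "happy": (0.55, 0.30, 0.15), "engaged": (0.50, 0.30, 0.20),
        "looking_away": (0.35, 0.30, 0.35), "eyes_closed": (0.75, 0.18, 0.07),
        "mouth_open": (0.45, 0.30, 0.25),
    },
}


class ProfileError(ValueError):
    pass


@dataclass
class SubjectProfile:
    """Everything that makes one synthetic subject who they are."""

    subject_id: str = "subject_01"
    seed: int = 0
    # session structure
    schedule: tuple[str, ...] = CTCTT
    session_minutes: tuple[float, ...] = DEFAULT_SESSION_MINUTES
    duration_scale: float = 1.0
    calm_threshold_s: float = 90.0
    policy: BehaviorPolicy = field(default_factory=BehaviorPolicy)
    # escalation signature
    escalation_lead_s: float = 90.0
    escalation_floor: float = 0.3
    # body motion
    baseline_angles_deg: np.ndarray | None = None  # (7, 3) roll/pitch/yaw
    motion_amp_deg: float = 12.0
    motion_freq_hz: float = 0.9
    motion_gain: float = 2.0
    imu_escalation_weights: np.ndarray | None = None  # (7,), mean ~1
    dyn_accel_std_g: float = 0.08
    dominant_side: str = "right"
    # physiology
    hr_base_bpm: float = 95.0
    hr_rise_bpm: float = 25.0
    scl_base_us: float = 2.0
    scr_rate_base_per_min: float = 2.0
    scr_rate_gain: float = 4.0
    scr_amp_us: float = 0.4
    wrist_motion_gain: float = 2.0
    # face / head
    head_motion_base_deg: float = 4.0
    head_gain: float = 2.0
    # data quality
    missingness_rate: float = 0.269
    missing_burst_s: float = 1.5
    corruption_rate: float = 0.003

    def __post_init__(self) -> None:
        for name in ("missingness_rate", "corruption_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ProfileError(f"{name} must be in [0, 1], got {v}")
        if self.escalation_lead_s <= 0:
            raise ProfileError("escalation_lead_s must be > 0")
        for name in ("motion_gain", "hr_rise_bpm", "scr_rate_gain",
                     "head_gain", "wrist_motion_gain"):
            if getattr(self, name) < 0:
                raise ProfileError(f"{name} must be >= 0")
        if self.baseline_angles_deg is None:
            self.baseline_angles_deg = np.zeros((len(IMU_NAMES), 3))
        self.baseline_angles_deg = np.asarray(self.baseline_angles_deg, float)
        if self.imu_escalation_weights is None:
            self.imu_escalation_weights = np.ones(len(IMU_NAMES))
        self.imu_escalation_weights = np.asarray(self.imu_escalation_weights, float)

    @property
    def scaled_session_minutes(self) -> tuple[float, ...]:
        return tuple(m * self.duration_scale for m in self.session_minutes)


@dataclass
class GroundTruth:
    """Latent process behind one generated session."""

    timeline: SessionTimeline
    lead_s: float
    floor: float
    gains: dict[str, float]
    #: latent driver series on a 1 s grid (pre-noise "clean signals")
    driver_times_ms: np.ndarray
    drivers: dict[str, np.ndarray]
    clean_streams: dict[str, SensorStream] = field(default_factory=dict)

    @property
    def precursor_times_ms(self) -> np.ndarray:
        return self.timeline.precursor_times_ms

    def env_at(self, t_ms) -> np.ndarray:
        """Escalation intensity in [0, 1]; ramps from ``floor`` at
        lead-time onset to 1 at each precursor, 0 elsewhere."""
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        env = np.zeros(len(t))
        lead = self.lead_s * 1000.0
        for p in self.precursor_times_ms:
            m = (t >= p - lead) & (t <= p)
            if m.any():
                frac = 1.0 - (p - t[m]) / lead
                env[m] = np.maximum(env[m], self.floor + (1 - self.floor) * frac)
        return env

    def state_at(self, t_ms) -> np.ndarray:
        """Latent state label per instant: escalating / calm / neutral."""
        t = np.atleast_1d(np.asarray(t_ms, dtype=np.int64))
        out = np.full(len(t), "neutral", dtype=object)
        for t0, t1 in self.timeline.calm_intervals:
            out[(t >= t0) & (t < t1)] = "calm"
        out[self.env_at(t) > 0] = "escalating"
        return out


@dataclass
class SessionRecording:
    """One generated session: raw streams + observer log + ground truth."""

    session_id: str
    streams: dict[str, SensorStream]
    log: EventLog
    truth: GroundTruth


@dataclass
class Subject:
    subject_id: str
    profile: SubjectProfile
    sessions: list[SessionRecording]

    @property
    def logs(self) -> list[EventLog]:
        return [s.log for s in self.sessions]

    @property
    def n_precursors(self) -> int:
        return int(sum(len(s.truth.precursor_times_ms) for s in self.sessions))


# ---------------------------------------------------------------------------
# Per-modality generators
# ---------------------------------------------------------------------------


def _grid_ms(dur_ms: int, rate_hz: float) -> np.ndarray:
    n = int(np.floor(dur_ms * rate_hz / 1000.0))
    return np.round(np.arange(n) * 1000.0 / rate_hz).astype(np.int64)


def _rotation_entries(roll, pitch, yaw):
    """Vectorized body-to-room rotation matrix entries (Rz@Ry@Rx)."""
    sr, cr = np.sin(roll), np.cos(roll)
    sp, cp = np.sin(pitch), np.cos(pitch)
    sy, cy = np.sin(yaw), np.cos(yaw)
    return np.stack([
        cy * cp, cy * sp * sr - sy * cr, sy * sr + cy * sp * cr,
        sy * cp, sy * sp * sr + cy * cr, sy * sp * cr - cy * sr,
        -sp, cp * sr, cp * cr,
    ]).reshape(3, 3, -1)


def _readings_from_angles(angles: np.ndarray, rng, dyn_scale, dyn_std,
                          noise_g=0.01, noise_mag=0.005):
    """(n,3) roll/pitch/yaw -> (accel (n,3) in g, mag (n,3)).

    Gravity reaction +1 g opposite gravity, rotated into the body frame,
    plus band-limited dynamic acceleration scaled by ``dyn_scale`` (this
    is what drives the activity-level feature up during escalation).
    """
    n = len(angles)
    R = _rotation_entries(angles[:, 0], angles[:, 1], angles[:, 2])
    # a_body = R^T @ (0,0,1) = third row of R
    accel = np.column_stack([R[2, 0], R[2, 1], R[2, 2]])
    # m_body = R^T @ MAG_FIELD
    mag = np.einsum("ijn,i->nj", R, MAG_FIELD)
    dyn = uniform_filter1d(rng.normal(0.0, 1.0, (n, 3)), size=3, axis=0)
    accel = accel + dyn * (dyn_std * dyn_scale)[:, None]
    accel += rng.normal(0.0, noise_g, (n, 3))
    mag += rng.normal(0.0, noise_mag, (n, 3))
    return accel, mag


def _gen_wings(p: SubjectProfile, truth: GroundTruth, dur_ms: int,
               rng: np.random.Generator) -> SensorStream:
    ts = _grid_ms(dur_ms, 15.0)
    t_s = ts / 1000.0
    env = truth.env_at(ts)
    n = len(ts)
    values = np.empty((n, len(WINGS_CHANNELS)))
    amp0 = np.deg2rad(p.motion_amp_deg)
    angle_scale = np.array([1.0, 1.0, 0.6])  # yaw wanders less
    for i, imu in enumerate(IMU_NAMES):
        w = p.imu_escalation_weights[i]
        scale = 1.0 + p.motion_gain * w * env
        base = np.deg2rad(p.baseline_angles_deg[i])
        angles = np.empty((n, 3))
        for a in range(3):
            f = p.motion_freq_hz * float(rng.uniform(0.7, 1.3))
            phase = float(rng.uniform(0, 2 * np.pi))
            amp = np.minimum(amp0 * angle_scale[a] * scale, np.deg2rad(60.0))
            angles[:, a] = (
                base[a]
                + amp * np.sin(2 * np.pi * f * t_s + phase)
                + rng.normal(0.0, np.deg2rad(1.0), n)  # ~1 deg IMU precision
            )
        accel, mag = _readings_from_angles(
            angles, rng, dyn_scale=scale, dyn_std=p.dyn_accel_std_g)
        values[:, 6 * i:6 * i + 3] = accel
        values[:, 6 * i + 3:6 * i + 6] = mag
    # wireless corruption: a random channel of an unlucky row goes wild
    bad = np.nonzero(rng.random(n) < p.corruption_rate)[0]
    if bad.size:
        ch = rng.integers(0, len(WINGS_CHANNELS), size=bad.size)
        kind = rng.random(bad.size)
        vals = np.where(kind < 0.5, np.inf,
                        500.0 * np.sign(rng.normal(size=bad.size)))
        values[bad, ch] = vals
    return SensorStream("wings", WINGS_CHANNELS, 15.0, ts, values)


def _gen_bvp(p: SubjectProfile, truth: GroundTruth, dur_ms: int,
             rng: np.random.Generator) -> SensorStream:
    ts = _grid_ms(dur_ms, 64.0)
    dur_s = dur_ms / 1000.0
    x = rng.normal(0.0, 0.02, len(ts))
    # beat train with instantaneous rate driven by the escalation envelope
    beats = []
    t_b = float(rng.uniform(0.0, 0.8))
    while t_b < dur_s:
        beats.append(t_b)
        hr = (p.hr_base_bpm
              + p.hr_rise_bpm * float(truth.env_at(t_b * 1000.0)[0])
              + 1.5 * np.sin(2 * np.pi * 0.08 * t_b))  # slow HRV wander
        ibi = 60.0 / hr * (1.0 + float(rng.normal(0.0, 0.01)))
        t_b += max(ibi, 0.25)
    tau = np.arange(-0.10, 0.45, 1.0 / 64.0)
    template = (np.exp(-0.5 * ((tau - 0.08) / 0.05) ** 2)
                + 0.30 * np.exp(-0.5 * ((tau - 0.33) / 0.07) ** 2))
    fs = 64.0
    for t_beat in beats:
        i0 = int(round((t_beat - 0.10) * fs))
        sl = slice(max(i0, 0), min(i0 + len(tau), len(x)))
        x[sl] += template[sl.start - i0:sl.stop - i0]
    return SensorStream("bvp", ("bvp",), 64.0, ts, x[:, None])


def _scr_kernel(rate_hz: float = 4.0) -> np.ndarray:
    tau = np.arange(0, 20.0, 1.0 / rate_hz)
    k = (1.0 - np.exp(-tau / 0.75)) * np.exp(-tau / 4.0)
    return k / k.max()


def _gen_eda(p: SubjectProfile, truth: GroundTruth, dur_ms: int,
             rng: np.random.Generator) -> SensorStream:
    ts = _grid_ms(dur_ms, 4.0)
    t_s = ts / 1000.0
    n = len(ts)
    env = truth.env_at(ts)
    scl = (p.scl_base_us
           + 0.2 * np.sin(2 * np.pi * t_s / 600.0 + rng.uniform(0, 2 * np.pi))
           + np.cumsum(rng.normal(0.0, 2e-4, n)))  # slow tonic drift
    rate_per_s = p.scr_rate_base_per_min * (1.0 + p.scr_rate_gain * env) / 60.0
    events = rng.random(n) < rate_per_s / 4.0
    amps = np.where(events, p.scr_amp_us * rng.lognormal(0.0, 0.4, n), 0.0)
    phasic = np.convolve(amps, _scr_kernel(4.0))[:n]
    x = np.maximum(scl + phasic + rng.normal(0.0, 0.005, n), 0.01)
    return SensorStream("eda", ("eda_us",), 4.0, ts, x[:, None])


def _gen_e4acc(p: SubjectProfile, truth: GroundTruth, dur_ms: int,
               rng: np.random.Generator) -> SensorStream:
    ts = _grid_ms(dur_ms, 32.0)
    n = len(ts)
    env = truth.env_at(ts)
    scale = 1.0 + p.wrist_motion_gain * env
    # slowly wandering wrist attitude around level, plus scaled movement
    tilt = uniform_filter1d(rng.normal(0.0, 1.0, (n, 2)), size=64, axis=0) * 0.3
    grav = np.column_stack([
        np.sin(tilt[:, 0]), np.sin(tilt[:, 1]) * np.cos(tilt[:, 0]),
        np.cos(tilt[:, 1]) * np.cos(tilt[:, 0]),
    ])
    dyn = uniform_filter1d(rng.normal(0.0, 1.0, (n, 3)), size=4, axis=0)
    x = grav + dyn * (p.dyn_accel_std_g * 1.5 * scale)[:, None]
    x += rng.normal(0.0, 0.01, (n, 3))
    return SensorStream("e4acc", ("acc_x", "acc_y", "acc_z"), 32.0, ts, x)


def _missing_runs(n: int, rate: float, mean_burst: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Two-state Markov dropout mask with stationary probability ``rate``
    and mean missing-burst length ``mean_burst`` samples."""
    if rate <= 0:
        return np.zeros(n, dtype=bool)
    mean_ok = mean_burst * (1.0 - rate) / rate
    mask = np.zeros(n, dtype=bool)
    pos = 0
    missing = rng.random() < rate
    while pos < n:
        mean = mean_burst if missing else mean_ok
        run = int(rng.geometric(1.0 / max(mean, 1.001)))
        mask[pos:pos + run] = missing
        pos += run
        missing = not missing
    return mask


def _gen_kinect(p: SubjectProfile, truth: GroundTruth, dur_ms: int,
                rng: np.random.Generator) -> SensorStream:
    ts = _grid_ms(dur_ms, 10.0)
    t_s = ts / 1000.0
    n = len(ts)
    env = truth.env_at(ts)
    state = truth.state_at(ts)
    values = np.empty((n, len(KINECT_CHANNELS)))
    amp = p.head_motion_base_deg * (1.0 + p.head_gain * env)
    for a in range(3):  # head roll/pitch/yaw in degrees
        f = float(rng.uniform(0.2, 0.6))
        phase = float(rng.uniform(0, 2 * np.pi))
        values[:, a] = (amp * np.sin(2 * np.pi * f * t_s + phase)
                        + rng.normal(0.0, 1.0, n))
    for j, chan in enumerate(KINECT_FACIAL):
        col = np.empty(n)
        for s in ("calm", "neutral", "escalating"):
            m = state == s
            if m.any():
                col[m] = rng.choice(FACIAL_LEVELS, size=int(m.sum()),
                                    p=FACIAL_TABLES[s][chan])
        values[:, 3 + j] = col
    # the sensor loses the whole face at once: row-wise dropout bursts
    burst = p.missing_burst_s * 10.0
    mask = _missing_runs(n, p.missingness_rate, burst, rng)
    values[mask, :] = np.nan
    return SensorStream("kinect", KINECT_CHANNELS, 10.0, ts, values)


# ---------------------------------------------------------------------------
# Subject / cohort assembly
# ---------------------------------------------------------------------------


def _build_truth(p: SubjectProfile, tl: SessionTimeline) -> GroundTruth:
    gains = {
        "motion_gain": p.motion_gain,
        "hr_rise_bpm": p.hr_rise_bpm,
        "scr_rate_gain": p.scr_rate_gain,
        "head_gain": p.head_gain,
    }
    truth = GroundTruth(
        timeline=tl, lead_s=p.escalation_lead_s, floor=p.escalation_floor,
        gains=gains, driver_times_ms=np.empty(0, dtype=np.int64), drivers={},
    )
    t1s = np.arange(0, tl.duration_ms, 1000, dtype=np.int64)
    env = truth.env_at(t1s)
    truth.driver_times_ms = t1s
    truth.drivers = {
        "escalation_env": env,
        "hr_bpm": p.hr_base_bpm + p.hr_rise_bpm * env,
        "motion_amp_scale": 1.0 + p.motion_gain * env,
        "scr_rate_per_min": p.scr_rate_base_per_min * (1.0 + p.scr_rate_gain * env),
    }
    return truth


def generate_subject(profile: SubjectProfile) -> Subject:
    """Generate one complete, seeded subject (five-session visit)."""
    rng = np.random.default_rng(profile.seed)
    logs, timelines = run_protocol(
        schedule=profile.schedule,
        policy=profile.policy,
        seed=rng,
        session_minutes=profile.scaled_session_minutes,
        calm_threshold_s=profile.calm_threshold_s,
        session_id_prefix=f"{profile.subject_id}_s",
    )
    sessions = []
    for log, tl in zip(logs, timelines):
        truth = _build_truth(profile, tl)
        dur = tl.duration_ms
        streams = {
            "wings": _gen_wings(profile, truth, dur, rng),
            "bvp": _gen_bvp(profile, truth, dur, rng),
            "eda": _gen_eda(profile, truth, dur, rng),
            "e4acc": _gen_e4acc(profile, truth, dur, rng),
            "kinect": _gen_kinect(profile, truth, dur, rng),
        }
        sessions.append(SessionRecording(log.session_id, streams, log, truth))
    return Subject(profile.subject_id, profile, sessions)


def generate_cohort(
    n: int,
    heterogeneity: float = 1.0,
    seed: int = 0,
    **profile_overrides,
) -> list[Subject]:
    """Generate ``n`` subjects whose profiles scatter around a population
    mean with spread proportional to ``heterogeneity``.

    At heterogeneity 0 every subject shares the population profile and
    differs only through the stream-noise seeds.  At the default 1,
    subjects differ in which body segments express escalation, in
    dominant side, baseline posture, and physiological baselines/gains
    -- the between-subject variation that separates individualized from
    group (leave-one-subject-out) model performance.
    """
    if n < 1:
        raise ProfileError(f"cohort size must be >= 1, got {n}")
    h = float(heterogeneity)
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(1, n + 1):
        side = "right" if (h == 0 or rng.random() < 0.7) else "left"
        w = np.exp(h * rng.normal(0.0, 1.2, len(IMU_NAMES)))
        side_boost = np.array([
            1.5 if name.startswith(side[0] + "_") else 1.0 for name in IMU_NAMES
        ])
        w = w * side_boost
        w *= len(w) / w.sum()
        params = dict(
            subject_id=f"subject_{i:02d}",
            seed=int(rng.integers(0, 2**31 - 1)),
            baseline_angles_deg=h * rng.normal(0.0, 15.0, (len(IMU_NAMES), 3)),
            motion_amp_deg=12.0 * float(np.exp(h * rng.normal(0.0, 0.2))),
            motion_freq_hz=0.9 * float(np.exp(h * rng.normal(0.0, 0.2))),
            motion_gain=min(2.0 * float(np.exp(h * rng.normal(0.0, 0.3))), 3.5),
            imu_escalation_weights=w,
            dominant_side=side,
            hr_base_bpm=95.0 + h * float(rng.normal(0.0, 12.0)),
            hr_rise_bpm=25.0 * float(np.exp(h * rng.normal(0.0, 0.4))),
            scr_rate_gain=4.0 * float(np.exp(h * rng.normal(0.0, 0.4))),
            head_gain=2.0 * float(np.exp(h * rng.normal(0.0, 0.4))),
        )
        params.update(profile_overrides)
        subjects.append(generate_subject(SubjectProfile(**params)))
    return subjects


# ---------------------------------------------------------------------------
# On-disk export (drop-in replacement for real recordings)
# ---------------------------------------------------------------------------


def write_subject(subject: Subject, out_dir) -> None:
    """Write a subject's sessions in the standard stream/log TSV formats."""
    from pathlib import Path

    out = Path(out_dir) / subject.subject_id
    manifests = []
    for rec in subject.sessions:
        files = {}
        for modality, stream in rec.streams.items():
            fname = f"{rec.session_id}_{modality}.tsv"
            write_stream(stream, out / fname)
            files[modality] = fname
        ev = f"{rec.session_id}_events.tsv"
        write_event_log(rec.log, out / ev)
        manifests.append(SessionManifest(
            session_id=rec.session_id, session_type=rec.log.session_type,
            subject_id=subject.subject_id, stream_files=files, events_file=ev,
        ))
    write_manifest(manifests, out / "manifest.yaml",
                   subject_id=subject.subject_id)


def load_subject(subject_dir) -> Subject:
    """Read a written subject back (streams+logs only; no ground truth)."""
    from pathlib import Path

    from .streams_io import read_event_log, read_manifest, read_stream

    subject_dir = Path(subject_dir)
    manifests = read_manifest(subject_dir / "manifest.yaml")
    sessions = []
    for m in manifests:
        streams = {
            modality: read_stream(subject_dir / fname, SCHEMAS[modality])
            for modality, fname in m.stream_files.items()
        }
        log = read_event_log(subject_dir / m.events_file)
        tl = SessionTimeline(duration_ms=log.duration_ms,
                             precursor_times_ms=log.precursor_times)
        truth = GroundTruth(
            timeline=tl, lead_s=90.0, floor=0.3, gains={},
            driver_times_ms=np.empty(0, dtype=np.int64), drivers={},
        )
        sessions.append(SessionRecording(m.session_id, streams, log, truth))
    profile = SubjectProfile(subject_id=manifests[0].subject_id)
    return Subject(manifests[0].subject_id, profile, sessions)
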