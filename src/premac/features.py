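"""Per-modality feature extraction and nearest-in-time fusion.

The fused feature vector (32 columns in the default, paper-strict
configuration) combines, per instant of the 15 Hz body-motion timeline:

* 20 body-motion features: roll, pitch, yaw and activity level for the
  left/right forearm, left/right upper arm, and torso (the torso angles
  average the three back IMUs);
* 1 heart rate in bpm, from inter-beat intervals of the band-passed
  blood volume pulse;
* 2 skin-conductance features: tonic level (SCL) and phasic response
  (SCR), microsiemens;
* 3 wrist accelerations (g), low-passed;
* 6 face/head features: head roll/pitch/yaw (degrees) and the discrete
  happy / engaged / looking-away scores.

Fusion takes the body-motion timeline as the basis and, for every other
modality, copies the value of its timestamp-closest sample (ties go to
the earlier sample); no interpolation happens at the fusion stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinematics, preprocess
from .streams_io import SensorStream

SEGMENTS = ("l_forearm", "l_upperarm", "r_forearm", "r_upperarm", "torso")
BACK_IMUS = ("back_upper", "back_mid", "back_lower")
ANGLE_NAMES = ("roll", "pitch", "yaw")


class FeatureError(ValueError):
    pass


@dataclass
class FeatureConfig:
    """Feature-set and preprocessing knobs of the extraction stage."""

    paper_strict: bool = True  # exactly the 32-column feature set
    al_window_s: float = 1.0  # activity-level averaging window
    hr_window_s: float = 10.0  # sliding IBI window for heart rate
    hr_step_s: float = 1.0
    lowpass_cutoff_hz: float = 10.0  # wrist accelerations (32 Hz stream)
    bvp_band_hz: tuple[float, float] = (1.0, 8.0)
    scl_cutoff_hz: float = 0.05  # tonic/phasic split
    impute_k: int = 20
    al_strict_divisor: int | None = None  # fixed divisor instead of n
    require_all_modalities: bool = True

    @property
    def facial_channels(self) -> tuple[str, ...]:
        if self.paper_strict:
            return ("happy", "engaged", "looking_away")
        return ("happy", "engaged", "looking_away", "eyes_closed", "mouth_open")


@dataclass
class FeatureMatrix:
    """Fused per-instant features on the body-motion timeline."""

    timestamps: np.ndarray  # ms
    values: pd.DataFrame  # one named column per feature

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        if len(self.values.columns) != len(set(self.values.columns)):
            raise FeatureError("duplicate feature column names")

    @property
    def n_rows(self) -> int:
        return len(self.timestamps)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        df = self.values.copy()
        df.insert(0, "timestamp_ms", self.timestamps)
        from .streams_io import _atomic_write
        from pathlib import Path
        _atomic_write(Path(path), df.to_csv(sep="\t", index=False))

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        ts = df.pop("timestamp_ms").to_numpy(dtype=np.int64)
        return cls(ts, df)


def modality_of(column: str) -> str:
    """Map a feature column to its sensing modality group."""
    if column.startswith(("l_forearm", "l_upperarm", "r_forearm",
                          "r_upperarm", "torso")):
        return "body_motion"
    if column in ("hr_bpm", "scl_us", "scr_us"):
        return "physiology"
    if column.startswith("wrist_acc"):
        return "wrist_acceleration"
    if column.startswith("head_"):
        return "head_rotation"
    return "facial_expression"


def modality_map(columns) -> dict[str, str]:
    return {c: modality_of(c) for c in columns}


# ---------------------------------------------------------------------------
# Activity level
# ---------------------------------------------------------------------------


def activity_level(window: np.ndarray, divisor: int | None = None) -> float:
    """Average acceleration magnitude over a window of (n, 3) samples.

    ``divisor`` overrides the averaging denominator with a constant
    (strict mode); by default the sample count is used.
    """
    w = np.atleast_2d(np.asarray(window, float))
    if w.size == 0:
        raise FeatureError("activity level of an empty window")
    mags = np.linalg.norm(w, axis=1)
    return float(mags.sum() / (divisor if divisor else len(mags)))


def rolling_activity_level(values3: np.ndarray, rate_hz: float,
                           window_s: float = 1.0,
                           divisor: int | None = None) -> np.ndarray:
    """Centered moving-average acceleration magnitude, one value per sample."""
    mags = np.linalg.norm(np.asarray(values3, float), axis=1)
    w = max(int(round(window_s * rate_hz)), 1)
    s = pd.Series(mags).rolling(w, center=True, min_periods=1)
    if divisor:
        return (s.sum() / divisor).to_numpy()
    return s.mean().to_numpy()


# ---------------------------------------------------------------------------
# Physiology
# ---------------------------------------------------------------------------


def detect_beats(bvp: SensorStream) -> np.ndarray:
    """Systolic peak times (seconds) in a band-passed BVP stream."""
    from scipy.signal import find_peaks

    x = bvp.values[:, 0]
    fs = bvp.nominal_rate
    prom = 0.8 * float(np.std(x))
    peaks, _ = find_peaks(x, distance=max(int(0.3 * fs), 1), prominence=prom)
    return bvp.timestamps[peaks] / 1000.0


def heart_rate_from_bvp(
    bvp: SensorStream, window_s: float = 10.0, step_s: float = 1.0
) -> SensorStream:
    """Heart rate (bpm) series from inter-beat intervals.

    Beats are detected on the band-passed pulse waveform; HR at grid
    time t is 60 / mean(IBI) over beats in the trailing ``window_s``
    seconds.  Windows with fewer than two beats yield a missing value.
    Downstream fusion holds each value until the next update.
    """
    beat_s = detect_beats(bvp)
    t_end = bvp.timestamps[-1] / 1000.0 if bvp.n_samples else 0.0
    grid = np.arange(0.0, t_end + step_s / 2, step_s)
    hr = np.full(len(grid), np.nan)
    for i, g in enumerate(grid):
        in_win = beat_s[(beat_s >= g - window_s) & (beat_s <= g)]
        if len(in_win) >= 2:
            hr[i] = 60.0 / float(np.mean(np.diff(in_win)))
    return SensorStream("hr", ("hr_bpm",), 1.0 / step_s,
                        np.round(grid * 1000).astype(np.int64), hr[:, None])


def eda_decompose(
    eda: SensorStream, scl_cutoff_hz: float = 0.05
) -> tuple[SensorStream, SensorStream]:
    """Split electrodermal activity into tonic (SCL) and phasic (SCR).

    SCL is a zero-phase low-pass of the conductance; SCR is the exact
    residual, so SCL + SCR reconstructs the input to machine precision.
    Deconvolution-based decompositions are deliberately out of scope.
    """
    x = eda.values[:, 0]
    if np.isnan(x).any():
        raise FeatureError("EDA stream has missing values; scrub first")
    if (x < 0).any():
        raise FeatureError("negative skin conductance after scrubbing")
    scl_stream = preprocess.lowpass_filter(eda, scl_cutoff_hz)
    scr = eda.copy()
    scr.values = eda.values - scl_stream.values
    scl_stream.modality, scr.modality = "scl", "scr"
    scl_stream.channel_names, scr.channel_names = ("scl_us",), ("scr_us",)
    return scl_stream, scr


# ---------------------------------------------------------------------------
# Per-modality preprocessing + feature streams
# ---------------------------------------------------------------------------


def wings_features(wings: SensorStream, cfg: FeatureConfig
                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Body-motion features on the (scrubbed) 15 Hz timeline.

    Corrupted rows are scrubbed, gaps of up to two samples bridged, and
    any row still missing is excluded.  The 15 Hz stream is below the
    Nyquist frequency of the nominal 10 Hz acceleration low-pass, so no
    additional filtering is applied to it.
    """
    scrubbed, _ = preprocess.scrub_corrupted(wings)
    bridged = preprocess.bridge_short_gaps(scrubbed, max_gap=2)
    keep = ~np.isnan(bridged.values).any(axis=1)
    ts = bridged.timestamps[keep]
    vals = bridged.values[keep]
    from .synthetic_data import IMU_NAMES  # canonical IMU ordering

    per_imu_angles = {}
    per_imu_al = {}
    for i, imu in enumerate(IMU_NAMES):
        accel = vals[:, 6 * i:6 * i + 3]
        mag = vals[:, 6 * i + 3:6 * i + 6]
        per_imu_angles[imu] = kinematics.orientations_from_stream(accel, mag)
        per_imu_al[imu] = rolling_activity_level(
            accel, wings.nominal_rate, cfg.al_window_s, cfg.al_strict_divisor)
    cols = {}
    for seg in SEGMENTS:
        if seg == "torso":
            ang = np.mean([per_imu_angles[b] for b in BACK_IMUS], axis=0)
            al = np.mean([per_imu_al[b] for b in BACK_IMUS], axis=0)
        else:
            ang, al = per_imu_angles[seg], per_imu_al[seg]
        for a, name in enumerate(ANGLE_NAMES):
            cols[f"{seg}_{name}"] = ang[:, a]
        cols[f"{seg}_al"] = al
    return ts, pd.DataFrame(cols)


def _prepare_streams(streams: dict[str, SensorStream],
                     cfg: FeatureConfig) -> dict[str, SensorStream]:
    """Run the per-modality cleaning/feature recipe; returns streams of
    feature channels ready for nearest-in-time fusion."""
    out: dict[str, SensorStream] = {}
    if "bvp" in streams:
        band = preprocess.bandpass_filter(streams["bvp"], *cfg.bvp_band_hz)
        out["hr"] = heart_rate_from_bvp(band, cfg.hr_window_s, cfg.hr_step_s)
    if "eda" in streams:
        scl, scr = eda_decompose(streams["eda"], cfg.scl_cutoff_hz)
        merged = scl.copy()
        merged.modality = "eda_features"
        merged.channel_names = ("scl_us", "scr_us")
        merged.values = np.column_stack([scl.values, scr.values])
        out["eda_features"] = merged
    if "e4acc" in streams:
        filt = preprocess.lowpass_filter(streams["e4acc"], cfg.lowpass_cutoff_hz)
        filt.channel_names = ("wrist_acc_x", "wrist_acc_y", "wrist_acc_z")
        out["wrist"] = filt
    if "kinect" in streams:
        kin = preprocess.impute_numeric(
            streams["kinect"], cfg.impute_k,
            channels=["head_roll", "head_pitch", "head_yaw"])
        kin = preprocess.impute_categorical(
            kin, cfg.impute_k, channels=list(cfg.facial_channels))
        wanted = ("head_roll", "head_pitch", "head_yaw") + cfg.facial_channels
        idx = [kin.channel_names.index(c) for c in wanted]
        kin.values = kin.values[:, idx]
        kin.channel_names = wanted
        out["kinect"] = kin
    return out


def _nearest_rows(src_ts: np.ndarray, basis_ts: np.ndarray) -> np.ndarray:
    """Index of the timestamp-closest source sample for every basis
    instant; ties resolve to the earlier sample."""
    if len(src_ts) == 1:
        return np.zeros(len(basis_ts), dtype=int)
    j = np.searchsorted(src_ts, basis_ts)
    j = np.clip(j, 1, len(src_ts) - 1)
    left, right = src_ts[j - 1], src_ts[j]
    use_left = (basis_ts - left) <= (right - basis_ts)  # tie -> earlier
    idx = np.where(use_left, j - 1, j)
    idx[basis_ts <= src_ts[0]] = 0
    idx[basis_ts >= src_ts[-1]] = len(src_ts) - 1
    return idx


EXPECTED_MODALITIES = ("bvp", "eda", "e4acc", "kinect")


def build_feature_matrix(
    streams: dict[str, SensorStream],
    cfg: FeatureConfig | None = None,
) -> FeatureMatrix:
    """Fuse all modalities onto the body-motion timeline.

    One output row per (valid) body-motion instant; every other feature
    takes the value of its timestamp-closest sample, verbatim.  In the
    default paper-strict configuration the result has exactly 32
    columns and no missing entries.
    """
    cfg = cfg or FeatureConfig()
    if "wings" not in streams:
        raise FeatureError("body-motion (wings) stream is required as the "
                           "fusion basis")
    absent = [m for m in EXPECTED_MODALITIES if m not in streams]
    if absent and cfg.require_all_modalities:
        raise FeatureError(
            f"missing modalities {absent}; pass require_all_modalities=False "
            "to drop their columns"
        )
    ts, df = wings_features(streams["wings"], cfg)
    prepared = _prepare_streams(streams, cfg)
    for stream in prepared.values():
        # a sensor that warms up late (e.g. first HR window) holds its
        # first valid value backwards so fusion leaves no gaps
        vals = pd.DataFrame(stream.values).ffill().bfill().to_numpy()
        idx = _nearest_rows(stream.timestamps, ts)
        for c, name in enumerate(stream.channel_names):
            df[name] = vals[idx, c]
    fm = FeatureMatrix(ts, df)
    if cfg.paper_strict and not absent and fm.values.shape[1] != 32:
        raise FeatureError(
            f"paper-strict mode produced {fm.values.shape[1]} columns, "
            "expected 32"
        )
    if fm.values.isna().any().any():
        raise FeatureError("fused feature matrix contains missing entries")
    return fm
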