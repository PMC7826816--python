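"""Tabular I/O and validation for multimodal session recordings.

Every modality of a recording session is stored as one UTF-8,
tab-separated file with a header row: a ``timestamp_ms`` column of
integer milliseconds since session start followed by one column per
channel.  Missing values are the literal string ``NA``.  The behavior
observer's event log is a second TSV (``timestamp_ms``, ``event_kind``)
preceded by two comment lines carrying the session id and type.  A YAML
manifest ties the per-modality files of a session together.

These formats are deliberately diff-able and independently replaceable:
a synthetic session written by :mod:`premac.synthetic_data` is
indistinguishable on disk from a converted clinical recording.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MISSING_MARKER = "NA"

#: Recognised behavior-log event kinds (tablet button presses plus the
#: implicit session bracket events).
EVENT_KINDS = (
    "session_start",
    "SR_on",
    "EO_on",
    "calm_on",
    "calm_off",
    "precursor",
    "problem_behavior",
    "session_end",
)

SESSION_TYPES = ("control", "test")


class StreamFormatError(ValueError):
    """Raised when a stream file violates the documented dialect."""


class SchemaError(StreamFormatError):
    """Raised when a stream file does not match the expected schema."""


class EventLogError(ValueError):
    """Raised when an event log violates the session-protocol invariants."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class StreamSchema:
    """Expected layout of one modality's stream file."""

    modality: str
    channels: tuple[str, ...]
    rate_hz: float
    units: tuple[str, ...] | None = None


@dataclass
class SensorStream:
    """One modality's timestamped multichannel samples.

    ``values`` is an ``(n_samples, n_channels)`` float array; missing
    entries are ``NaN`` (serialized as ``NA``).  Timestamps are integer
    milliseconds since session start and strictly increasing.
    """

    modality: str
    channel_names: tuple[str, ...]
    nominal_rate: float
    timestamps: np.ndarray
    values: np.ndarray
    units: tuple[str, ...] | None = None
    #: rows of the source file that could not be parsed (counted, not dropped)
    n_bad_rows: int = 0

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channel_names.index(name)]

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def copy(self) -> "SensorStream":
        return dataclasses.replace(
            self, timestamps=self.timestamps.copy(), values=self.values.copy()
        )

    def validate(self, check_rate: bool = True) -> "SensorStream":
        """Check the stream invariants, raising :class:`StreamFormatError`."""
        if self.nominal_rate <= 0:
            raise StreamFormatError(
                f"{self.modality}: nominal_rate must be > 0, got {self.nominal_rate}"
            )
        if self.values.shape != (self.n_samples, self.n_channels):
            raise StreamFormatError(
                f"{self.modality}: values shape {self.values.shape} does not match "
                f"{self.n_samples} samples x {self.n_channels} channels"
            )
        if self.n_samples > 1:
            dt = np.diff(self.timestamps)
            bad = np.nonzero(dt <= 0)[0]
            if bad.size:
                i = int(bad[0])
                raise StreamFormatError(
                    f"{self.modality}: timestamps not strictly increasing at row "
                    f"{i + 1} (t={self.timestamps[i]} -> t={self.timestamps[i + 1]})"
                )
            if check_rate:
                expected = 1000.0 / self.nominal_rate
                med = float(np.median(dt))
                if not (0.8 * expected <= med <= 1.2 * expected):
                    raise StreamFormatError(
                        f"{self.modality}: median inter-sample interval {med:.2f} ms "
                        f"is outside 20% of nominal {expected:.2f} ms"
                    )
        return self


@dataclass
class EventLog:
    """Ordered behavior-observation events of one session."""

    session_id: str
    session_type: str
    entries: list[tuple[int, str]] = field(default_factory=list)

    def validate(self) -> "EventLog":
        errs = validate_event_log_entries(self.entries, self.session_type)
        if errs:
            raise EventLogError(
                f"event log '{self.session_id}': " + "; ".join(errs)
            )
        return self

    def times_of(self, kind: str) -> np.ndarray:
        return np.array(
            [t for t, k in self.entries if k == kind], dtype=np.int64
        )

    @property
    def precursor_times(self) -> np.ndarray:
        return self.times_of("precursor")

    @property
    def duration_ms(self) -> int:
        return self.entries[-1][0] - self.entries[0][0] if self.entries else 0


def validate_event_log_entries(
    entries: list[tuple[int, str]], session_type: str
) -> list[str]:
    """Structural invariant checks; returns human-readable error strings.

    Deeper protocol semantics (90-s calm gating etc.) live in
    :mod:`premac.fsm_protocol`; this checks only what the file format
    itself promises.
    """
    errs: list[str] = []
    if session_type not in SESSION_TYPES:
        errs.append(f"unknown session_type '{session_type}'")
    if not entries:
        errs.append("log is empty")
        return errs
    for i, (t, kind) in enumerate(entries):
        if kind not in EVENT_KINDS:
            errs.append(f"line {i + 1}: unknown event kind '{kind}'")
    times = [t for t, _ in entries]
    for i in range(1, len(times)):
        if times[i] < times[i - 1]:
            errs.append(
                f"line {i + 1}: timestamp {times[i]} decreases "
                f"(previous {times[i - 1]})"
            )
    if entries[0][1] != "session_start":
        errs.append(f"first entry is '{entries[0][1]}', expected session_start")
    if entries[-1][1] != "session_end":
        errs.append(f"last entry is '{entries[-1][1]}', expected session_end")
    # calm_on / calm_off strictly alternate
    calm = [(t, k) for t, k in entries if k in ("calm_on", "calm_off")]
    expect = "calm_on"
    for t, k in calm:
        if k != expect:
            errs.append(f"'{k}' at t={t} without preceding "
                        f"'{'calm_on' if k == 'calm_off' else 'calm_off'}'")
            break
        expect = "calm_off" if k == "calm_on" else "calm_on"
    # condition events: first must be SR_on, then strict EO/SR alternation
    cond = [(t, k) for t, k in entries if k in ("SR_on", "EO_on")]
    if cond:
        if cond[0][1] != "SR_on":
            errs.append(
                f"first condition at t={cond[0][0]} is EO_on; sessions start "
                "under the reinforcement (S^R) condition"
            )
        for (t0, k0), (t1, k1) in zip(cond, cond[1:]):
            if k1 == k0:
                errs.append(
                    f"condition '{k1}' at t={t1} repeats '{k0}' at t={t0}; "
                    "EO and S^R must alternate"
                )
    if session_type == "control":
        eo = [t for t, k in entries if k == "EO_on"]
        if eo:
            errs.append(
                f"control session contains EO_on at t={eo[0]}; control "
                "sessions contain only S^R conditions"
            )
    return errs


# ---------------------------------------------------------------------------
# Stream files
# ---------------------------------------------------------------------------


def read_stream(path: str | Path, schema: StreamSchema | None = None) -> SensorStream:
    """Read one modality's TSV stream file.

    Unparseable rows are counted on ``stream.n_bad_rows`` and logged;
    unparseable value cells become missing.  Rows whose timestamp cannot
    be parsed are dropped (and counted).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(
            path, sep="\t", dtype=str, comment="#",
            keep_default_na=False, na_values=[],
        )
    except pd.errors.EmptyDataError:
        raise StreamFormatError(f"{path}: file is empty") from None
    if df.shape[1] < 2 or df.columns[0] != "timestamp_ms":
        raise StreamFormatError(
            f"{path}: expected a header starting with 'timestamp_ms', got "
            f"{list(df.columns)[:4]}"
        )
    channels = tuple(df.columns[1:])
    if schema is not None:
        missing = [c for c in schema.channels if c not in channels]
        if missing:
            raise SchemaError(
                f"{path}: missing expected channels {missing} "
                f"(found {list(channels)})"
            )
        channels = tuple(schema.channels)

    ts = pd.to_numeric(df["timestamp_ms"], errors="coerce")
    bad_ts = ts.isna()
    n_bad = int(bad_ts.sum())
    vals = np.full((len(df), len(channels)), np.nan)
    for j, c in enumerate(channels):
        col = df[c].to_numpy()
        na = col == MISSING_MARKER
        try:
            # numpy's parser round-trips float64 exactly
            vals[~na, j] = np.asarray(col[~na], dtype=float)
        except ValueError:
            coerced = pd.to_numeric(df[c], errors="coerce").to_numpy()
            cell_bad = np.isnan(coerced) & ~na
            n_bad += int(np.sum(cell_bad & ~bad_ts.to_numpy()))
            good = ~na & ~cell_bad
            vals[good, j] = np.asarray(col[good], dtype=float)
    keep = ~bad_ts.to_numpy()
    if n_bad:
        logger.warning("%s: %d unparseable rows/cells", path, n_bad)
    modality = schema.modality if schema else path.stem.split("_")[-1]
    rate = schema.rate_hz if schema else _infer_rate(ts[keep].to_numpy())
    stream = SensorStream(
        modality=modality,
        channel_names=channels,
        nominal_rate=rate,
        timestamps=ts[keep].to_numpy(dtype=np.int64),
        values=vals[keep],
        units=schema.units if schema else None,
        n_bad_rows=n_bad,
    )
    return stream.validate(check_rate=schema is not None)


def _infer_rate(ts_ms: np.ndarray) -> float:
    if len(ts_ms) < 2:
        return 1.0
    med = float(np.median(np.diff(ts_ms)))
    return 1000.0 / med if med > 0 else 1.0


def write_stream(stream: SensorStream, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(stream.values, columns=list(stream.channel_names))
    df.insert(0, "timestamp_ms", stream.timestamps)
    # %.17g round-trips float64 exactly, keeping read/write lossless
    _atomic_write(path, df.to_csv(sep="\t", index=False, na_rep=MISSING_MARKER,
                                  float_format="%.17g"))


# ---------------------------------------------------------------------------
# Event-log files
# ---------------------------------------------------------------------------


def read_event_log(path: str | Path) -> EventLog:
    """Read and validate a behavior event-log TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    session_id, session_type = path.stem.replace("_events", ""), "test"
    entries: list[tuple[int, str]] = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                key, val = key.strip(), val.strip()
                if key == "session_id":
                    session_id = val
                elif key == "session_type":
                    session_type = val
                continue
            parts = line.split("\t")
            if not header_seen:
                if parts[:2] != ["timestamp_ms", "event_kind"]:
                    raise StreamFormatError(
                        f"{path}:{lineno}: expected header "
                        f"'timestamp_ms\\tevent_kind', got {parts[:2]}"
                    )
                header_seen = True
                continue
            if len(parts) < 2:
                raise StreamFormatError(f"{path}:{lineno}: malformed row {parts}")
            try:
                t = int(parts[0])
            except ValueError:
                raise StreamFormatError(
                    f"{path}:{lineno}: bad timestamp '{parts[0]}'"
                ) from None
            entries.append((t, parts[1]))
    if not header_seen:
        raise StreamFormatError(f"{path}: file is empty")
    log = EventLog(session_id=session_id, session_type=session_type,
                   entries=entries)
    return log.validate()


def write_event_log(log: EventLog, path: str | Path) -> None:
    lines = [
        f"# session_id: {log.session_id}",
        f"# session_type: {log.session_type}",
        "timestamp_ms\tevent_kind",
    ]
    lines += [f"{t}\t{k}" for t, k in log.entries]
    _atomic_write(Path(path), "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Session manifests
# ---------------------------------------------------------------------------


@dataclass
class SessionManifest:
    """Names the on-disk pieces of one recorded session."""

    session_id: str
    session_type: str
    subject_id: str
    stream_files: dict[str, str]  # modality -> relative path
    events_file: str


def write_manifest(manifests: list[SessionManifest], path: str | Path,
                   subject_id: str | None = None) -> None:
    doc = {
        "subject_id": subject_id or (manifests[0].subject_id if manifests else ""),
        "sessions": [dataclasses.asdict(m) for m in manifests],
    }
    _atomic_write(Path(path), yaml.safe_dump(doc, sort_keys=False))


def read_manifest(path: str | Path) -> list[SessionManifest]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return [SessionManifest(**m) for m in doc["sessions"]]


def _atomic_write(path: Path, text: str) -> None:
    """Write-then-rename so partial failures never leave half files."""
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)
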