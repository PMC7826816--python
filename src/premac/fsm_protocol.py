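"""Finite state machine of the IISCA session protocol.

A visit comprises five sessions in the fixed multielement order CTCTT
(control, test, control, test, test).  Control sessions run entirely
under the reinforcing condition (S^R); test sessions alternate between
S^R and the evocative establishing-operation condition (EO).  The
protocol gate: EO may begin only after the child has been continuously
calm for at least 90 s under S^R.  Any precursor, problem behavior or
loss of calm restarts that timer.

The same machine serves two purposes: replay-validation of observer
event logs, and driving the synthetic-session generator (whose output
must replay with zero violations).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .streams_io import EventLog

CTCTT = ("control", "test", "control", "test", "test")

DEFAULT_CALM_THRESHOLD_S = 90.0

PHASES = ("INIT", "SR", "EO", "SUMMARY", "END")


class ProtocolViolation(ValueError):
    """An event illegal in the current protocol state."""


@dataclass
class ProtocolState:
    """Mutable-by-replacement protocol state of one session."""

    phase: str = "INIT"
    calm: bool = False
    calm_elapsed: float = 0.0  # s of *continuous* calm under S^R
    eo_ready: bool = False
    session_index: int = 1
    session_type: str = "control"
    calm_threshold_s: float = DEFAULT_CALM_THRESHOLD_S
    time_ms: int = 0


def _advance_clock(state: ProtocolState, t_ms: int) -> ProtocolState:
    if t_ms < state.time_ms:
        raise ProtocolViolation(
            f"time moved backwards ({state.time_ms} -> {t_ms} ms)"
        )
    dt_s = (t_ms - state.time_ms) / 1000.0
    new = dataclasses.replace(state, time_ms=t_ms)
    if state.phase == "SR" and state.calm:
        new.calm_elapsed = state.calm_elapsed + dt_s
        if new.calm_elapsed >= new.calm_threshold_s:
            new.eo_ready = True
    return new


def fsm_step(state: ProtocolState, event_kind: str, t_ms: int) -> ProtocolState:
    """One deterministic transition.

    ``event_kind`` is a log event kind, or ``"tick"`` for a pure clock
    advance (calm time accumulates only while calm under S^R).  Raises
    :class:`ProtocolViolation` on illegal events.
    """
    s = _advance_clock(state, t_ms)
    k = event_kind
    if k == "tick":
        return s
    if s.phase in ("SUMMARY", "END"):
        raise ProtocolViolation(f"event '{k}' at t={t_ms} after session end")
    if k == "session_start":
        if s.phase != "INIT":
            raise ProtocolViolation(f"session_start at t={t_ms} after start")
        s.phase = "SR"
        return s
    if s.phase == "INIT":
        raise ProtocolViolation(f"event '{k}' at t={t_ms} before session_start")

    if k == "SR_on":
        # condition marker: legal at session start and when leaving EO
        if s.phase == "SR" and t_ms > 0:
            raise ProtocolViolation(f"SR_on at t={t_ms} while already under S^R")
        s.phase = "SR"
        s.calm_elapsed = 0.0
        s.eo_ready = False
        return s
    if k == "EO_on":
        if s.session_type == "control":
            raise ProtocolViolation(
                f"EO_on at t={t_ms} in a control session (control sessions "
                "contain only S^R conditions)"
            )
        if s.phase != "SR":
            raise ProtocolViolation(f"EO_on at t={t_ms} outside S^R")
        if not s.eo_ready:
            raise ProtocolViolation(
                f"EO_on at t={t_ms} without {s.calm_threshold_s:.0f} s of "
                f"continuous calm (elapsed {s.calm_elapsed:.1f} s)"
            )
        s.phase = "EO"
        s.calm_elapsed = 0.0
        s.eo_ready = False
        return s
    if k == "calm_on":
        if s.calm:
            raise ProtocolViolation(f"calm_on at t={t_ms} while already calm")
        s.calm = True
        s.calm_elapsed = 0.0
        return s
    if k == "calm_off":
        if not s.calm:
            raise ProtocolViolation(f"calm_off at t={t_ms} while not calm")
        s.calm = False
        s.calm_elapsed = 0.0
        s.eo_ready = False
        return s
    if k in ("precursor", "problem_behavior"):
        # behavior during S^R restarts the calm requirement; during EO it
        # is simply recorded
        s.calm_elapsed = 0.0
        s.eo_ready = False
        return s
    if k == "session_end":
        s.phase = "SUMMARY"
        return s
    raise ProtocolViolation(f"unknown event kind '{k}' at t={t_ms}")


# ---------------------------------------------------------------------------
# Log replay / validation
# ---------------------------------------------------------------------------


@dataclass
class SessionTimeline:
    """Latent condition/calm timeline recovered from (or generating) a log.

    Intervals are ``(t0_ms, t1_ms)`` half-open; resolution is the
    millisecond timestamps themselves.
    """

    duration_ms: int
    condition_intervals: list[tuple[int, int, str]] = field(default_factory=list)
    calm_intervals: list[tuple[int, int]] = field(default_factory=list)
    precursor_times_ms: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))

    def condition_at(self, t_ms: np.ndarray) -> np.ndarray:
        out = np.full(len(t_ms), "SR", dtype=object)
        for t0, t1, kind in self.condition_intervals:
            out[(t_ms >= t0) & (t_ms < t1)] = kind
        return out

    def eo_time_ms(self) -> int:
        return sum(t1 - t0 for t0, t1, k in self.condition_intervals if k == "EO")


def replay_log(
    log: EventLog,
    calm_threshold_s: float = DEFAULT_CALM_THRESHOLD_S,
    session_index: int = 1,
) -> tuple[list[str], SessionTimeline]:
    """Replay an event log through the FSM.

    Returns the list of violations (empty for a protocol-valid log) and
    the reconstructed latent condition/calm timeline.
    """
    state = ProtocolState(
        session_type=log.session_type,
        session_index=session_index,
        calm_threshold_s=calm_threshold_s,
    )
    violations: list[str] = []
    cond_start, cond_kind = 0, "SR"
    cond_intervals: list[tuple[int, int, str]] = []
    calm_start: int | None = None
    calm_intervals: list[tuple[int, int]] = []
    for t, k in log.entries:
        try:
            state = fsm_step(state, k, t)
        except ProtocolViolation as exc:
            violations.append(str(exc))
            # resynchronise clock so later checks stay meaningful
            state.time_ms = max(state.time_ms, t)
            continue
        if k == "EO_on":
            cond_intervals.append((cond_start, t, cond_kind))
            cond_start, cond_kind = t, "EO"
        elif k == "SR_on" and t > 0:
            cond_intervals.append((cond_start, t, cond_kind))
            cond_start, cond_kind = t, "SR"
        elif k == "calm_on":
            calm_start = t
        elif k == "calm_off" and calm_start is not None:
            calm_intervals.append((calm_start, t))
            calm_start = None
    end = log.entries[-1][0] if log.entries else 0
    cond_intervals.append((cond_start, end, cond_kind))
    if calm_start is not None:
        calm_intervals.append((calm_start, end))
    timeline = SessionTimeline(
        duration_ms=end,
        condition_intervals=cond_intervals,
        calm_intervals=calm_intervals,
        precursor_times_ms=log.precursor_times,
    )
    return violations, timeline


def validate_visit(
    logs: list[EventLog],
    schedule: tuple[str, ...] = CTCTT,
    calm_threshold_s: float = DEFAULT_CALM_THRESHOLD_S,
) -> list[str]:
    """Replay every session of a visit and check the CTCTT schedule."""
    violations: list[str] = []
    if len(logs) != len(schedule):
        violations.append(
            f"visit has {len(logs)} sessions, schedule requires {len(schedule)}"
        )
    for i, log in enumerate(logs):
        if i < len(schedule) and log.session_type != schedule[i]:
            violations.append(
                f"session {i + 1} is '{log.session_type}', schedule says "
                f"'{schedule[i]}'"
            )
        v, _ = replay_log(log, calm_threshold_s, session_index=i + 1)
        violations += [f"session {i + 1}: {m}" for m in v]
    return violations


# ---------------------------------------------------------------------------
# Protocol-driven session generation
# ---------------------------------------------------------------------------


@dataclass
class BehaviorPolicy:
    """Stochastic latencies of the simulated child/therapist loop.

    Defaults are set so a five-session visit at the default session
    durations produces roughly 26 precursor episodes and spends about
    40% of test-session time inside a 90-s pre-precursor window.
    All times in seconds.
    """

    calm_latency_mean_s: float = 12.0  # S^R onset -> observable calm
    calm_hold_extra_mean_s: float = 5.0  # beyond the 90-s gate before EO
    eo_precursor_latency_mean_s: float = 15.0  # EO onset -> first precursor
    burst_extra_precursors_mean: float = 1.5  # Poisson extras per EO bout
    intra_burst_gap_mean_s: float = 28.0
    intra_burst_gap_min_s: float = 5.0
    post_burst_sr_delay_s: float = 5.0
    calm_break_mean_s: float = 150.0  # control sessions: calm bout length
    calm_gap_mean_s: float = 20.0

    def draw_calm_latency(self, rng: np.random.Generator) -> float:
        return float(rng.gamma(4.0, self.calm_latency_mean_s / 4.0))

    def draw_calm_hold_extra(self, rng: np.random.Generator) -> float:
        return float(rng.exponential(self.calm_hold_extra_mean_s))

    def draw_eo_latency(self, rng: np.random.Generator) -> float:
        return float(rng.gamma(4.0, self.eo_precursor_latency_mean_s / 4.0))

    def draw_burst(self, rng: np.random.Generator) -> int:
        return 1 + int(rng.poisson(self.burst_extra_precursors_mean))

    def draw_burst_gap(self, rng: np.random.Generator) -> float:
        return self.intra_burst_gap_min_s + float(
            rng.exponential(self.intra_burst_gap_mean_s - self.intra_burst_gap_min_s)
        )


#: Per-session durations (minutes) matching typical visit structure.
DEFAULT_SESSION_MINUTES = (12.05, 11.37, 10.02, 10.71, 10.05)


def run_protocol(
    schedule: tuple[str, ...] = CTCTT,
    policy: BehaviorPolicy | None = None,
    seed: int | np.random.Generator = 0,
    session_minutes: tuple[float, ...] = DEFAULT_SESSION_MINUTES,
    calm_threshold_s: float = DEFAULT_CALM_THRESHOLD_S,
    session_id_prefix: str = "session",
) -> tuple[list[EventLog], list[SessionTimeline]]:
    """Generate a protocol-valid visit: event logs + latent timelines.

    The policy supplies the stochastic behavior latencies; the returned
    logs replay through :func:`fsm_step` with zero violations by
    construction (asserted in tests, not here).
    """
    policy = policy or BehaviorPolicy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    logs: list[EventLog] = []
    timelines: list[SessionTimeline] = []
    for i, stype in enumerate(schedule):
        dur_ms = int(round(session_minutes[i % len(session_minutes)] * 60_000))
        if stype == "control":
            log, tl = _gen_control(dur_ms, policy, rng)
        else:
            log, tl = _gen_test(dur_ms, policy, rng, calm_threshold_s)
        log.session_id = f"{session_id_prefix}_{i + 1}"
        log.session_type = stype
        logs.append(log)
        timelines.append(tl)
    return logs, timelines


def _ms(t_s: float) -> int:
    return int(round(t_s * 1000.0))


def _gen_control(
    dur_ms: int, policy: BehaviorPolicy, rng: np.random.Generator
) -> tuple[EventLog, SessionTimeline]:
    entries: list[tuple[int, str]] = [(0, "session_start"), (0, "SR_on")]
    calm_intervals: list[tuple[int, int]] = []
    t = policy.draw_calm_latency(rng)
    calm = False
    calm_t0 = 0
    while _ms(t) < dur_ms:
        if not calm:
            entries.append((_ms(t), "calm_on"))
            calm, calm_t0 = True, _ms(t)
            t += rng.exponential(policy.calm_break_mean_s)
        else:
            entries.append((_ms(t), "calm_off"))
            calm_intervals.append((calm_t0, _ms(t)))
            calm = False
            t += rng.exponential(policy.calm_gap_mean_s)
    if calm:
        calm_intervals.append((calm_t0, dur_ms))
        entries.append((dur_ms, "calm_off"))
    entries.append((dur_ms, "session_end"))
    tl = SessionTimeline(
        duration_ms=dur_ms,
        condition_intervals=[(0, dur_ms, "SR")],
        calm_intervals=calm_intervals,
    )
    return EventLog("", "control", entries), tl


def _gen_test(
    dur_ms: int,
    policy: BehaviorPolicy,
    rng: np.random.Generator,
    calm_threshold_s: float,
) -> tuple[EventLog, SessionTimeline]:
    entries: list[tuple[int, str]] = [(0, "session_start"), (0, "SR_on")]
    cond_intervals: list[tuple[int, int, str]] = []
    calm_intervals: list[tuple[int, int]] = []
    precursors: list[int] = []
    t = 0.0
    sr_start = 0
    while True:
        # --- S^R: wait for calm, hold it through the gate ---
        calm_on = t + policy.draw_calm_latency(rng)
        eo_start = calm_on + calm_threshold_s + policy.draw_calm_hold_extra(rng)
        first_prec = eo_start + policy.draw_eo_latency(rng)
        if _ms(first_prec) + 10_000 > dur_ms:
            # not enough session left for another full EO cycle
            if calm_on < dur_ms / 1000.0 - 5.0:
                entries.append((_ms(calm_on), "calm_on"))
                calm_intervals.append((_ms(calm_on), dur_ms))
                entries.append((dur_ms, "calm_off"))
            break
        entries.append((_ms(calm_on), "calm_on"))
        entries.append((_ms(eo_start), "EO_on"))
        cond_intervals.append((sr_start, _ms(eo_start), "SR"))
        # the child stops looking calm shortly after the EO begins, and
        # certainly by the first precursor
        calm_off = min(eo_start + 1.0 + rng.exponential(1.0), first_prec - 0.1)
        entries.append((_ms(calm_off), "calm_off"))
        calm_intervals.append((_ms(calm_on), _ms(calm_off)))
        # --- EO: precursor burst, then reinforcement resumes ---
        n_prec = policy.draw_burst(rng)
        tp = first_prec
        for j in range(n_prec):
            if _ms(tp) >= dur_ms - 2000:
                break
            entries.append((_ms(tp), "precursor"))
            precursors.append(_ms(tp))
            if j < n_prec - 1:
                tp += policy.draw_burst_gap(rng)
        sr_on = tp + policy.post_burst_sr_delay_s
        if _ms(sr_on) >= dur_ms:
            cond_intervals.append((_ms(eo_start), dur_ms, "EO"))
            sr_start = dur_ms
            break
        entries.append((_ms(sr_on), "SR_on"))
        cond_intervals.append((_ms(eo_start), _ms(sr_on), "EO"))
        sr_start = _ms(sr_on)
        t = sr_on
    if sr_start < dur_ms:
        cond_intervals.append((sr_start, dur_ms, "SR"))
    entries.append((dur_ms, "session_end"))
    entries.sort(key=lambda e: e[0])
    tl = SessionTimeline(
        duration_ms=dur_ms,
        condition_intervals=cond_intervals,
        calm_intervals=calm_intervals,
        precursor_times_ms=np.array(precursors, dtype=np.int64),
    )
    return EventLog("", "test", entries), tl
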