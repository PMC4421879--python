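"""On-the-fly tomographic acquisition scheduling.

The sample rotates continuously while the analyser grating performs an
N-step phase-stepping series per projection; the camera is triggered at a
fixed cadence (exposure + readout + G2 settle).  The rotation stage speed
in motor pulses per second is chosen so that each stepping series completes
within one projection's angular span.  Direct (no-sample) frames for
flat-field correction are inserted as blocks at a fixed angular interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Literal, NamedTuple, Optional

__all__ = ["ScanProtocol", "ScheduleEvent", "Schedule", "step_period",
           "rotation_speed", "build_schedule", "total_time"]


@dataclass(frozen=True)
class ScanProtocol:
    """Acquisition parameters for one tomographic scan.

    Defaults reproduce a fresh-specimen protocol: 600 projections over
    180° with five-step phase stepping, 500 ms exposure, 50 ms camera
    readout, 30 ms G2 settle, a 90000-pulse rotation stage at 0.002° per
    pulse, and flat-field blocks every 36°.
    """

    n_projections: int = 600
    n_steps: int = 5
    exposure_s: float = 0.5
    readout_s: float = 0.05
    settle_s: float = 0.03
    pulses_per_180: int = 90000
    pulse_resolution_deg: float = 0.002
    flat_interval_deg: float = 36.0
    flat_frames: Optional[int] = None  # defaults to n_steps (a full series)
    flat_overhead_s: float = 0.0  # stage translation time per flat block
    initial_flat: bool = True

    def __post_init__(self) -> None:
        if self.n_projections < 0:
            raise ValueError("n_projections must be >= 0")
        if self.n_steps < 3:
            raise ValueError("phase stepping needs at least 3 steps")
        if min(self.exposure_s, self.readout_s, self.settle_s) < 0:
            raise ValueError("times must be non-negative")
        if not math.isclose(self.pulses_per_180 * self.pulse_resolution_deg, 180.0,
                            rel_tol=1e-9):
            raise ValueError("pulses_per_180 × pulse_resolution_deg must equal 180°")

    @property
    def frame_interval_s(self) -> float:
        """Trigger cadence: exposure + readout + G2 settle."""
        return self.exposure_s + self.readout_s + self.settle_s

    @property
    def n_flat_frames(self) -> int:
        return self.n_steps if self.flat_frames is None else self.flat_frames

    @property
    def pulses_per_projection(self) -> float:
        return self.pulses_per_180 / self.n_projections


class ScheduleEvent(NamedTuple):
    time_s: float
    kind: Literal["trigger", "g2_step", "flat_block_start", "flat_frame"]
    projection: int  # -1 for flat events
    step: int


@dataclass
class Schedule:
    events: List[ScheduleEvent]
    total_time_s: float
    rotation_speed_pps: int

    @property
    def trigger_count(self) -> int:
        return sum(1 for e in self.events if e.kind in ("trigger", "flat_frame"))

    def flat_blocks(self) -> int:
        return sum(1 for e in self.events if e.kind == "flat_block_start")

    def to_frame(self):
        """Event list as a pandas DataFrame (time_s, kind, proj, step)."""
        import pandas as pd

        return pd.DataFrame(self.events, columns=["time_s", "kind", "proj", "step"])


def step_period(protocol: ScanProtocol) -> float:
    """Duration T of one N-step stepping series: N × (exposure+readout+settle)."""
    return protocol.n_steps * protocol.frame_interval_s


def rotation_speed(protocol: ScanProtocol) -> int:
    """Rotation speed in integer motor pulses per second.

    The stage must advance exactly one projection's worth of pulses
    (X_proj = X_total/Y) during one stepping period T, so the speed is
    X_proj/T truncated to an integer — the truncation is the documented
    convention (150/2.9 s → 51 pulses s⁻¹).
    """
    T = step_period(protocol)
    if T <= 0:
        raise ValueError("stepping period must be positive")
    x_proj = protocol.pulses_per_projection
    return int(x_proj / T)


def total_time(protocol: ScanProtocol, include_flats: bool = False) -> float:
    """Scan duration in seconds.

    Rotation-limited: X_total divided by the integer pulse rate.  With
    ``include_flats`` the flat blocks (frames at the trigger cadence plus
    the per-block overhead) are added on top.
    """
    if protocol.n_projections == 0:
        return 0.0
    T = step_period(protocol)
    if T == 0:
        return 0.0
    speed = rotation_speed(protocol)
    if speed == 0:
        # stepping slower than one pulse per second: time is stepping-limited
        t_rot = protocol.n_projections * T
    else:
        t_rot = protocol.pulses_per_180 / speed
    if not include_flats:
        return t_rot
    blocks = _n_flat_blocks(protocol)
    per_block = protocol.n_flat_frames * protocol.frame_interval_s + protocol.flat_overhead_s
    return t_rot + blocks * per_block


def _n_flat_blocks(protocol: ScanProtocol) -> int:
    """Initial block (if enabled) plus one per completed flat interval."""
    n = 1 if protocol.initial_flat else 0
    if protocol.flat_interval_deg > 0:
        ratio = 180.0 / protocol.flat_interval_deg
        if not math.isclose(ratio, round(ratio), rel_tol=1e-9):
            warnings.warn(
                f"flat interval {protocol.flat_interval_deg}° does not divide 180°; "
                "the last partial interval gets no flat block",
                stacklevel=3,
            )
        n += int(math.floor(ratio + 1e-9))
    return n


def build_schedule(protocol: ScanProtocol) -> Schedule:
    """Expand a protocol into the ordered trigger/step/flat event timeline.

    Per projection the G2 stage moves, then the camera is triggered, N_step
    times at the fixed cadence.  A flat block of ``flat_frames`` frames is
    placed at t=0 (configurable) and after every completed
    ``flat_interval_deg`` of rotation; the block at the 180° endpoint is
    included.  Event times are a uniform grid of the trigger cadence.
    """
    dt = protocol.frame_interval_s
    events: List[ScheduleEvent] = []
    t = 0.0
    if protocol.n_projections == 0:
        return Schedule(events, 0.0, 0)

    speed = rotation_speed(protocol)

    def flat_block(t0: float) -> float:
        events.append(ScheduleEvent(t0, "flat_block_start", -1, -1))
        for k in range(protocol.n_flat_frames):
            events.append(ScheduleEvent(t0 + k * dt, "flat_frame", -1, k))
        return t0 + protocol.n_flat_frames * dt + protocol.flat_overhead_s

    if protocol.initial_flat:
        t = flat_block(t)

    projs_per_interval = (
        protocol.flat_interval_deg / (180.0 / protocol.n_projections)
        if protocol.flat_interval_deg > 0
        else math.inf
    )
    _n_flat_blocks(protocol)  # emits the divisibility warning once
    next_flat_at = projs_per_interval
    for proj in range(protocol.n_projections):
        for step in range(protocol.n_steps):
            events.append(ScheduleEvent(t, "g2_step", proj, step))
            events.append(ScheduleEvent(t + protocol.settle_s, "trigger", proj, step))
            t += dt
        if proj + 1 >= next_flat_at - 1e-9 and math.isfinite(next_flat_at):
            t = flat_block(t)
            next_flat_at += projs_per_interval
    return Schedule(events, t, speed)
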