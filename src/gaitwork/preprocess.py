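"""Signal conditioning, gait-event detection, stride segmentation and
time normalization.

The conditioning pipeline follows standard overground gait practice: kinematic
channels are low-pass filtered at 6 Hz and force channels at 15 Hz with
4th-order zero-phase Butterworth filters, foot contacts are detected with a
40 N threshold on the vertical ground reaction force, and per-stride curves
are linearly resampled onto 101 points (0–100 % of the gait cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "FilterSpec",
    "Stride",
    "ContactEvent",
    "lowpass_zero_phase",
    "detect_contacts",
    "segment_strides",
    "bin_speed",
    "time_normalize",
    "ensemble_average",
]

#: default speed-bin edges, m/s; [0.6, 1.1) is slow, [1.1, 1.6] is fast
SLOW_BIN = (0.6, 1.1)
FAST_BIN = (1.1, 1.6)


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth design applied forward-backward (zero phase)."""

    order: int = 4
    cutoff: float = 6.0  # Hz
    kind: str = "lowpass"
    zero_phase: bool = True

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.kind != "lowpass":
            raise ValueError("only lowpass filters are supported")


@dataclass(frozen=True)
class ContactEvent:
    """One foot contact: strike and toe-off sample indices."""

    strike: int
    toe_off: int


@dataclass
class Stride:
    """One gait cycle of one limb: ipsilateral strike to next ipsilateral strike."""

    limb: str
    i_start: int
    i_end: int
    rate: float
    speed: float = float("nan")
    speed_bin: str = "excluded"
    force_covered: bool = True

    def __post_init__(self):
        if self.i_end <= self.i_start:
            raise ValueError("stride must end after it starts")

    @property
    def duration(self) -> float:
        return (self.i_end - self.i_start) / self.rate


def lowpass_zero_phase(x: np.ndarray, rate: float, spec: FilterSpec) -> np.ndarray:
    """Apply a zero-phase low-pass Butterworth filter.

    Designs a filter of ``spec.order`` and runs it forward then backward
    (``filtfilt``), doubling the magnitude roll-off and cancelling phase.
    DC gain is exactly 1.
    """
    x = np.asarray(x, dtype=float)
    nyq = rate / 2.0
    if spec.cutoff >= nyq:
        raise ValueError(f"cutoff {spec.cutoff} Hz >= Nyquist {nyq} Hz")
    if x.shape[-1] < 3 * spec.order:
        raise ValueError("signal too short for the requested filter order")
    sos = signal.butter(spec.order, spec.cutoff, btype="low", fs=rate, output="sos")
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


def detect_contacts(
    vgrf: np.ndarray,
    rate: float,
    threshold: float = 40.0,
    min_phase: float = 0.05,
) -> list[ContactEvent]:
    """Detect foot contacts from a vertical GRF channel.

    Foot strike is the first sample at/above ``threshold`` after a
    below-threshold interval; toe-off the first subsequent sample below it.
    Stance or swing intervals shorter than ``min_phase`` seconds are merged
    (debounce), suppressing threshold chatter. An unterminated final contact
    is dropped. No crossings is not an error: returns [].
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    v = np.asarray(vgrf, dtype=float)
    v = np.where(v < 0, 0.0, v)  # clamp small negative plate noise
    above = v >= threshold
    d = np.diff(above.astype(np.int8))
    strikes = list(np.nonzero(d == 1)[0] + 1)
    offs = list(np.nonzero(d == -1)[0] + 1)
    if above[0]:
        # signal starts mid-stance; there is no strike for the first off
        if offs and (not strikes or offs[0] < strikes[0]):
            offs.pop(0)
    events = []
    for s in strikes:
        nxt = [o for o in offs if o > s]
        if not nxt:
            break
        events.append([s, nxt[0]])
    if not events:
        return []
    # debounce: merge contacts separated by a swing shorter than min_phase,
    # then drop stances shorter than min_phase
    min_samp = int(round(min_phase * rate))
    merged = [events[0]]
    for s, o in events[1:]:
        if s - merged[-1][1] < min_samp:
            merged[-1][1] = o
        else:
            merged.append([s, o])
    merged = [(s, o) for s, o in merged if o - s >= min_samp]
    return [ContactEvent(s, o) for s, o in merged]


def segment_strides(
    events: list[ContactEvent],
    com_vel_ap: np.ndarray,
    rate: float,
    limb: str = "right",
    force_coverage: list[bool] | None = None,
) -> list[Stride]:
    """Build strides from consecutive ipsilateral foot strikes.

    Each stride's speed is the mean anteroposterior whole-body COM velocity
    over [i_start, i_end); its speed bin follows :func:`bin_speed`. Strides
    whose force-coverage flag is false are dropped.
    """
    strikes = [e.strike for e in events]
    if len(strikes) < 2:
        return []
    if force_coverage is None:
        force_coverage = [True] * (len(strikes) - 1)
    v = np.asarray(com_vel_ap, dtype=float)
    strides = []
    for k, (i0, i1) in enumerate(zip(strikes[:-1], strikes[1:])):
        if not force_coverage[k]:
            continue
        speed = float(v[i0:i1].mean())
        strides.append(
            Stride(
                limb=limb,
                i_start=i0,
                i_end=i1,
                rate=rate,
                speed=speed,
                speed_bin=bin_speed(speed),
            )
        )
    return strides


def bin_speed(speed: float) -> str:
    """Assign a stride speed to the slow/fast bins.

    slow ⇔ 0.6 ≤ v < 1.1 m/s; fast ⇔ 1.1 ≤ v ≤ 1.6 m/s; otherwise excluded.
    The shared 1.1 m/s edge goes to the fast bin (half-open convention).
    """
    if not np.isfinite(speed):
        raise ValueError("speed must be finite")
    if SLOW_BIN[0] <= speed < SLOW_BIN[1]:
        return "slow"
    if FAST_BIN[0] <= speed <= FAST_BIN[1]:
        return "fast"
    return "excluded"


def time_normalize(x: np.ndarray, stride: Stride, n_points: int = 101) -> np.ndarray:
    """Resample one stride of a channel onto ``n_points`` equally spaced
    fractions of the gait cycle (0–100 %), by linear interpolation.

    The first point equals ``x[stride.i_start]`` and the last point
    ``x[stride.i_end]`` (the next ipsilateral strike).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    x = np.asarray(x, dtype=float)
    if stride.i_end >= x.shape[-1]:
        raise ValueError("stride extends beyond the channel")
    src = np.arange(stride.i_start, stride.i_end + 1)
    tgt = stride.i_start + (stride.i_end - stride.i_start) * np.linspace(0, 1, n_points)
    return np.interp(tgt, src, x[stride.i_start : stride.i_end + 1])


def ensemble_average(
    curves_by_participant: dict[str, list[np.ndarray]],
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage ensemble average of normalized gait curves.

    Curves are first averaged within each participant, then the mean and
    sample s.d. are taken across participants, so every participant carries
    equal weight regardless of stride count. Returns ``(mean, sd)``; with a
    single participant the s.d. is 0.
    """
    if not curves_by_participant:
        raise ValueError("no participants to average")
    per_participant = []
    for pid, curves in curves_by_participant.items():
        if not curves:
            raise ValueError(f"participant {pid!r} has no curves")
        per_participant.append(np.mean(np.asarray(curves, dtype=float), axis=0))
    stack = np.asarray(per_participant)
    mean = stack.mean(axis=0)
    sd = (
        stack.std(axis=0, ddof=1)
        if stack.shape[0] > 1
        else np.zeros_like(mean)
    )
    return mean, sd
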