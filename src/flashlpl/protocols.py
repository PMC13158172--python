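"""Dose-rate histories: constant pulses and explicit pulse trains.

A delivery protocol is a piecewise-constant dose rate Ḋ(t).  The solvers
integrate segment by segment so the discontinuous rate is never sampled
across a boundary; the history therefore exposes exact segment edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["Segment", "DoseRateHistory", "constant_pulse", "pulse_train", "rate_at"]


@dataclass(frozen=True)
class Segment:
    """One constant-rate interval [t_start, t_end) at ``rate`` Gy/s."""

    t_start: float
    t_end: float
    rate: float

    def __post_init__(self) -> None:
        if self.t_start < 0:
            raise ValueError(f"segment start must be >= 0, got {self.t_start!r}")
        if not self.t_end > self.t_start:
            raise ValueError(
                f"segment end ({self.t_end!r}) must exceed start ({self.t_start!r})"
            )
        if self.rate < 0:
            raise ValueError(f"dose rate must be >= 0, got {self.rate!r}")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def dose(self) -> float:
        return self.rate * self.duration


@dataclass(frozen=True)
class DoseRateHistory:
    """Ordered, non-overlapping constant-rate segments (gaps carry zero rate)."""

    segments: tuple[Segment, ...]

    def __init__(self, segments: Sequence[Segment] = ()) -> None:
        segs = tuple(segments)
        for prev, cur in zip(segs, segs[1:]):
            if cur.t_start < prev.t_end:
                raise ValueError(
                    f"segments overlap or are out of order near t = {cur.t_start!r}"
                )
        object.__setattr__(self, "segments", segs)

    @property
    def total_dose(self) -> float:
        """Σ rate·duration over all segments, in Gy."""
        return sum(s.dose for s in self.segments)

    @property
    def tau_pulse(self) -> float:
        """End time of the last segment with nonzero rate (0 if none)."""
        ends = [s.t_end for s in self.segments if s.rate > 0]
        return max(ends) if ends else 0.0

    def boundaries(self) -> list[float]:
        """Sorted unique segment edge times (integration split points)."""
        edges: set[float] = set()
        for s in self.segments:
            edges.update((s.t_start, s.t_end))
        return sorted(edges)


def constant_pulse(dose: float, dose_rate: float) -> DoseRateHistory:
    """Single continuous pulse of ``dose`` Gy at constant ``dose_rate`` Gy/s.

    The pulse occupies [0, dose/dose_rate]; this is the mean-dose-rate
    representation of delivery, Ḋ = D/τ_pulse.
    """
    if not dose > 0:
        raise ValueError(f"dose must be positive, got {dose!r}")
    if not dose_rate > 0:
        raise ValueError(f"dose_rate must be positive, got {dose_rate!r}")
    return DoseRateHistory([Segment(0.0, dose / dose_rate, dose_rate)])


def pulse_train(
    n_pulses: int, pulse_dose: float, in_pulse_rate: float, gap: float
) -> DoseRateHistory:
    """``n_pulses`` identical pulses separated by zero-rate gaps of ``gap`` s.

    Interpulse oxygen recovery is controlled by gap/τ_reox; with n_pulses = 1
    this reduces to :func:`constant_pulse`.
    """
    if not (isinstance(n_pulses, int) and n_pulses >= 1):
        raise ValueError(f"n_pulses must be an integer >= 1, got {n_pulses!r}")
    if not pulse_dose > 0:
        raise ValueError(f"pulse_dose must be positive, got {pulse_dose!r}")
    if not in_pulse_rate > 0:
        raise ValueError(f"in_pulse_rate must be positive, got {in_pulse_rate!r}")
    if not gap > 0:
        raise ValueError(f"gap must be positive, got {gap!r}")
    width = pulse_dose / in_pulse_rate
    segments = []
    t = 0.0
    for _ in range(n_pulses):
        segments.append(Segment(t, t + width, in_pulse_rate))
        t += width + gap
    return DoseRateHistory(segments)


def rate_at(history: DoseRateHistory, t: float) -> float:
    """Dose rate at time ``t`` (Gy/s); right-continuous at segment edges.

    Zero outside every segment (including beyond the last one).
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t!r}")
    for s in history.segments:
        if s.t_start <= t < s.t_end:
            return s.rate
    return 0.0
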