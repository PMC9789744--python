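"""Cuff-occlusion acquisition protocol.

A recording session consists of five contiguous phases, each nominally one
minute long: a resting baseline, a minimal venous occlusion (thigh cuff
inflated to 60 mmHg and held), a recovery minute after rapid deflation, a
partial occlusion (cuff at 100 mmHg), and a final recovery minute.  Cuff
inflation takes roughly ten seconds; deflation is treated as instantaneous.
Each inflate-hold-deflate-recover cycle is one *trial*; the analysis window
of a trial runs from inflation onset to the end of the following recovery
phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

DEFAULT_PHASE_DURATION_S = 60.0
DEFAULT_RAMP_S = 10.0
DEFAULT_PRESSURES_MMHG = (60.0, 100.0)


class ProtocolError(ValueError):
    """Invalid acquisition-protocol configuration."""


@dataclass(frozen=True)
class TrialWindow:
    """Analysis window of one inflation trial."""

    pressure_mmhg: float
    inflation_onset_s: float   # cuff starts inflating
    inflation_end_s: float     # ramp complete, hold begins
    deflation_s: float         # rapid deflation instant
    window_end_s: float        # end of post-deflation recovery phase

    @property
    def duration_s(self) -> float:
        return self.window_end_s - self.inflation_onset_s


@dataclass(frozen=True)
class ProtocolSchedule:
    """Five ordered phases with two inflation trials.

    ``phase_bounds_s`` holds the six boundaries of the five contiguous
    phases; ``pressures_mmhg`` the cuff pressure of each inflation trial
    (phases 2 and 4).
    """

    phase_bounds_s: tuple[float, ...]
    pressures_mmhg: tuple[float, ...] = DEFAULT_PRESSURES_MMHG
    ramp_s: float = DEFAULT_RAMP_S
    trials: tuple[TrialWindow, ...] = field(init=False)

    def __post_init__(self) -> None:
        b = self.phase_bounds_s
        if len(b) != 6:
            raise ProtocolError(f"expected 6 phase boundaries, got {len(b)}")
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ProtocolError("phase boundaries must be strictly increasing")
        if len(self.pressures_mmhg) != 2:
            raise ProtocolError("exactly two inflation trials are required")
        if any(p <= 0 for p in self.pressures_mmhg):
            raise ProtocolError("cuff pressures must be positive")
        if self.ramp_s < 0:
            raise ProtocolError("inflation ramp must be non-negative")
        trials = []
        # trials occupy phases 2 and 4 (0-based 1 and 3), each followed by
        # a post-deflation recovery phase
        for k, phase in enumerate((1, 3)):
            onset, deflate = b[phase], b[phase + 1]
            ramp_end = min(onset + self.ramp_s, deflate)
            trials.append(
                TrialWindow(
                    pressure_mmhg=self.pressures_mmhg[k],
                    inflation_onset_s=onset,
                    inflation_end_s=ramp_end,
                    deflation_s=deflate,
                    window_end_s=b[phase + 2],
                )
            )
        object.__setattr__(self, "trials", tuple(trials))

    @property
    def total_duration_s(self) -> float:
        return self.phase_bounds_s[-1] - self.phase_bounds_s[0]

    @property
    def baseline_window_s(self) -> tuple[float, float]:
        """Phase-1 resting baseline interval."""
        return self.phase_bounds_s[0], self.phase_bounds_s[1]


def build_protocol(
    phase_durations_s: Sequence[float] | None = None,
    pressures_mmhg: Sequence[float] = DEFAULT_PRESSURES_MMHG,
    ramp_s: float = DEFAULT_RAMP_S,
) -> ProtocolSchedule:
    """Build the five-phase cuff schedule.

    Parameters
    ----------
    phase_durations_s:
        Durations of the five phases in seconds.  Defaults to 60 s each
        (baseline, 60 mmHg hold, recovery, 100 mmHg hold, recovery).
    pressures_mmhg:
        Cuff pressures of the two inflation trials, in order.
    ramp_s:
        Time the cuff takes to reach the hold pressure.
    """
    if phase_durations_s is None:
        phase_durations_s = [DEFAULT_PHASE_DURATION_S] * 5
    durations = [float(d) for d in phase_durations_s]
    if len(durations) != 5:
        raise ProtocolError(f"expected 5 phase durations, got {len(durations)}")
    if any(d <= 0 for d in durations):
        raise ProtocolError("phase durations must be positive")
    bounds = [0.0]
    for d in durations:
        bounds.append(bounds[-1] + d)
    return ProtocolSchedule(
        phase_bounds_s=tuple(bounds),
        pressures_mmhg=tuple(float(p) for p in pressures_mmhg),
        ramp_s=float(ramp_s),
    )
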