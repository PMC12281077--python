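"""Stimulus-block schedules for the three pain-modulation paradigms.

Each paradigm delivers eight noxious heat stimuli per recording series,
separated by non-painful interstimulus intervals (ISI), while the subject
rates pain continuously on a 0-100 visual analogue scale (VAS) sampled
every 0.5 s.  Placebo and conditioned-pain-modulation (CPM) blocks last
15 s (including ~2.5 s thermode ramps at 4 degC/s); offset-analgesia
blocks last 14.4 s with effectively instantaneous ramps and an internal
T1 / T2 / T3 temperature structure (4 s moderate, 4 s at +1 degC, 6.4 s
back at moderate).
"""

from __future__ import annotations

from enum import Enum

import numpy as np
from pydantic import BaseModel, model_validator


class Paradigm(str, Enum):
    PLACEBO = "placebo"
    CPM = "cpm"
    OFFSET = "offset"


class UnknownParadigmError(ValueError):
    """Raised when a paradigm name is not one of placebo / cpm / offset."""


class ParadigmTiming(BaseModel, frozen=True):
    """Block/window schedule for one paradigm variant.

    All durations are in seconds.  ``t1``/``t2``/``t3`` are set only for
    the offset paradigm and tile the stimulus block exactly.
    """

    paradigm: Paradigm
    n_blocks: int = 8
    stimulus_duration: float
    isi_duration: float
    sample_interval: float = 0.5
    ramp_rate: float | None = None  # degC/s; None = effectively instantaneous
    t1: float | None = None
    t2: float | None = None
    t3: float | None = None

    @model_validator(mode="after")
    def _check_schedule(self) -> "ParadigmTiming":
        if self.n_blocks != 8:
            raise ValueError("schedule is fixed at 8 stimulus blocks")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.stimulus_duration <= 0 or self.isi_duration < 0:
            raise ValueError("durations must be positive")
        if self.paradigm is Paradigm.OFFSET:
            if self.t1 is None or self.t2 is None or self.t3 is None:
                raise ValueError("offset timing requires t1, t2, t3")
            if min(self.t1, self.t2, self.t3) <= 0:
                raise ValueError("offset sub-windows must have positive length")
            if abs(self.t1 + self.t2 + self.t3 - self.stimulus_duration) > 1e-9:
                raise ValueError("t1 + t2 + t3 must equal stimulus_duration")
        return self

    @property
    def block_period(self) -> float:
        return self.stimulus_duration + self.isi_duration

    @property
    def total_duration(self) -> float:
        return self.n_blocks * self.block_period

    def block_start(self, block: int) -> float:
        """Start time (s) of stimulus block ``block`` (0-based)."""
        if not 0 <= block < self.n_blocks:
            raise IndexError(f"block index {block} out of range")
        return block * self.block_period

    def sample_times(self) -> np.ndarray:
        """The canonical rating-sample grid: every 0.5 s from t=0 to the
        end of the last ISI (exclusive)."""
        n = int(round(self.total_duration / self.sample_interval))
        return np.arange(n) * self.sample_interval


def build_timing(paradigm: str | Paradigm) -> ParadigmTiming:
    """Return the fixed stimulus schedule for a paradigm.

    Placebo and CPM use 15 s stimuli and 15 s ISIs with 4 degC/s ramps;
    offset uses 14.4 s stimuli/ISIs partitioned into T1=4 s, T2=4 s
    (+1 degC) and T3=6.4 s.
    """
    try:
        paradigm = Paradigm(paradigm)
    except ValueError:
        raise UnknownParadigmError(f"unknown paradigm: {paradigm!r}") from None
    if paradigm in (Paradigm.PLACEBO, Paradigm.CPM):
        return ParadigmTiming(
            paradigm=paradigm,
            stimulus_duration=15.0,
            isi_duration=15.0,
            ramp_rate=4.0,
        )
    return ParadigmTiming(
        paradigm=Paradigm.OFFSET,
        stimulus_duration=14.4,
        isi_duration=14.4,
        ramp_rate=None,
        t1=4.0,
        t2=4.0,
        t3=6.4,
    )
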