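"""Reduce continuous VAS traces to per-stimulus-block summaries.

All downstream statistics consume the eight per-block mean VAS values of
a recording series.  Three windowings are supported:

* ``full_block`` — the whole stimulus period (placebo and CPM);
* ``offset_T3`` — the T3 return-to-moderate window of the offset series;
* ``control_last_6.4s`` — the final 6.4 s of each block of the offset
  control series, the duration-matched comparison for T3.

Windows are half-open ``[start, end)``: a sample on an exact boundary
belongs to the later window, so the offset T1/T2/T3 windows tile the
block with no overlap and no double counting.  Because the offset block
period (28.8 s) is not a multiple of the 0.5 s sampling interval, window
membership is evaluated with a 1e-9 s tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .timing import Paradigm, ParadigmTiming

_TOL = 1e-9

WINDOW_FULL = "full_block"
WINDOW_T3 = "offset_T3"
WINDOW_CONTROL_TAIL = "control_last_6.4s"


class TraceError(ValueError):
    """Raised for traces that do not cover the schedule or contain gaps."""


@dataclass(frozen=True)
class VasTrace:
    """One continuous 0-100 VAS rating series for one recording."""

    subject_id: str
    series: int  # 1 = control recording, 2 = modulation recording
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.series not in (1, 2):
            raise ValueError("series must be 1 or 2")
        if times.shape != values.shape or times.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if times.size >= 2:
            steps = np.diff(times)
            if np.any(steps <= 0) or np.ptp(steps) > _TOL:
                raise ValueError("times must increase in uniform steps")
        if not np.all(np.isfinite(values)):
            raise TraceError("trace contains non-finite ratings")
        if values.size and (values.min() < -_TOL or values.max() > 100 + _TOL):
            raise ValueError("VAS values must lie in [0, 100]")


@dataclass(frozen=True)
class StimulusBlockSeries:
    """The eight per-block mean VAS values of one recording series."""

    subject_id: str
    series: int
    block_means: np.ndarray
    window_label: str = WINDOW_FULL

    def __post_init__(self) -> None:
        means = np.asarray(self.block_means, dtype=float)
        object.__setattr__(self, "block_means", means)
        if means.shape != (8,):
            raise ValueError("exactly 8 block means are required")
        if not np.all(np.isfinite(means)):
            raise ValueError("block means must be finite")
        if means.min() < -_TOL or means.max() > 100 + _TOL:
            raise ValueError("block means must lie in [0, 100]")


@dataclass(frozen=True)
class VariabilitySummary:
    """Rating variability of one series: sample SD of its 8 block means."""

    subject_id: str
    series: int
    sd_of_block_means: float = field(default=0.0)


def _window_means(
    trace: VasTrace,
    timing: ParadigmTiming,
    window_offset: float,
    window_length: float,
    label: str,
) -> StimulusBlockSeries:
    """Mean VAS over ``[block_start + offset, block_start + offset + length)``
    for each of the 8 blocks."""
    end_required = (
        timing.block_start(timing.n_blocks - 1) + window_offset + window_length
    )
    if trace.times.size == 0 or trace.times[-1] < end_required - timing.sample_interval - _TOL:
        raise TraceError(
            f"trace for {trace.subject_id!r} series {trace.series} ends at "
            f"{trace.times[-1] if trace.times.size else 'n/a'} s but the "
            f"schedule requires coverage to {end_required} s"
        )
    expected = _expected_samples(timing, window_offset, window_length)
    means = np.empty(8)
    for b in range(timing.n_blocks):
        start = timing.block_start(b) + window_offset
        stop = start + window_length
        mask = (trace.times >= start - _TOL) & (trace.times < stop - _TOL)
        n_in = int(mask.sum())
        if n_in != expected[b]:
            raise TraceError(
                f"block {b + 1} window [{start}, {stop}) holds {n_in} samples, "
                f"expected {expected[b]}: missing samples are not imputed"
            )
        means[b] = trace.values[mask].mean()
    return StimulusBlockSeries(
        subject_id=trace.subject_id,
        series=trace.series,
        block_means=means,
        window_label=label,
    )


def _expected_samples(
    timing: ParadigmTiming, window_offset: float, window_length: float
) -> list[int]:
    """Sample count the canonical grid puts in each block's window."""
    h = timing.sample_interval
    counts = []
    for b in range(timing.n_blocks):
        start = timing.block_start(b) + window_offset
        stop = start + window_length
        first = int(np.ceil((start - _TOL) / h))
        last = int(np.ceil((stop - _TOL) / h))  # exclusive
        counts.append(last - first)
    return counts


def block_means(trace: VasTrace, timing: ParadigmTiming) -> StimulusBlockSeries:
    """Average the whole stimulus period of each of the 8 blocks.

    Ramp-up/ramp-down seconds are included: ratings over each full pain
    period are averaged.  Missing in-window samples are an error, not
    imputed.
    """
    return _window_means(trace, timing, 0.0, timing.stimulus_duration, WINDOW_FULL)


def offset_t3_means(trace: VasTrace, timing: ParadigmTiming) -> StimulusBlockSeries:
    """Average the T3 (return-to-moderate) window of each offset block.

    Applies to series 2 of the offset paradigm: the analysed window is
    ``[block_start + t1 + t2, block_start + stimulus_duration)``.
    """
    if timing.paradigm is not Paradigm.OFFSET:
        raise ValueError("T3 windows exist only for the offset paradigm")
    return _window_means(trace, timing, timing.t1 + timing.t2, timing.t3, WINDOW_T3)


def control_tail_means(trace: VasTrace, timing: ParadigmTiming) -> StimulusBlockSeries:
    """Average the last 6.4 s of each block of the offset control series.

    This is the duration-matched comparison window for the T3 period.
    """
    if timing.paradigm is not Paradigm.OFFSET:
        raise ValueError("control-tail windows exist only for the offset paradigm")
    tail = timing.t3
    return _window_means(
        trace, timing, timing.stimulus_duration - tail, tail, WINDOW_CONTROL_TAIL
    )


def analysis_block_means(
    trace: VasTrace, timing: ParadigmTiming
) -> StimulusBlockSeries:
    """The windowing the classification analysis uses for this trace.

    Placebo/CPM: full-block means for both series.  Offset: last-6.4 s
    means for the control series (1), T3 means for the offset series (2).
    """
    if timing.paradigm is not Paradigm.OFFSET:
        return block_means(trace, timing)
    if trace.series == 1:
        return control_tail_means(trace, timing)
    return offset_t3_means(trace, timing)


def series_variability(series: StimulusBlockSeries) -> VariabilitySummary:
    """Sample SD (n-1 denominator) of the eight block means."""
    sd = float(np.std(series.block_means, ddof=1))
    return VariabilitySummary(
        subject_id=series.subject_id, series=series.series, sd_of_block_means=sd
    )
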