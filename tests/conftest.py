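import numpy as np
import pytest

from painmod.preprocess import VasTrace
from painmod.timing import ParadigmTiming, build_timing

_TOL = 1e-9


@pytest.fixture(scope="session")
def placebo_timing() -> ParadigmTiming:
    return build_timing("placebo")


@pytest.fixture(scope="session")
def offset_timing() -> ParadigmTiming:
    return build_timing("offset")


def make_trace(
    timing: ParadigmTiming,
    block_value,
    subject_id: str = "s",
    series: int = 1,
    isi_value: float = 0.0,
) -> VasTrace:
    """Build a trace whose in-block samples come from ``block_value``.

    ``block_value`` is either a constant or a callable ``(block, t_rel) ->
    VAS`` evaluated per sample; ISI samples are set to ``isi_value``.
    """
    times = timing.sample_times()
    values = np.full_like(times, float(isi_value))
    for b in range(timing.n_blocks):
        start = timing.block_start(b)
        mask = (times >= start - _TOL) & (
            times < start + timing.stimulus_duration - _TOL
        )
        if callable(block_value):
            values[mask] = [block_value(b, t - start) for t in times[mask]]
        else:
            values[mask] = block_value
    return VasTrace(subject_id=subject_id, series=series, times=times, values=values)


def brute_force_window_means(
    trace: VasTrace, timing: ParadigmTiming, offset: float, length: float
) -> np.ndarray:
    """Independent re-average: plain loop over samples with explicit window
    membership tests.  Oracle for the vectorised windowing code."""
    sums = [0.0] * timing.n_blocks
    counts = [0] * timing.n_blocks
    for t, v in zip(trace.times.tolist(), trace.values.tolist()):
        for b in range(timing.n_blocks):
            lo = b * (timing.stimulus_duration + timing.isi_duration) + offset
            hi = lo + length
            if lo - _TOL <= t < hi - _TOL:
                sums[b] += v
                counts[b] += 1
    return np.array([s / c for s, c in zip(sums, counts)])
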