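"""Bootstrap responder classification: inhibitor / nonresponder / facilitator.

Each subject contributes two recording series, summarised as eight
per-block mean VAS ratings each.  The classifier draws ``n_resamples``
bootstrap means (means of 8 draws with replacement) independently from
each series, pairs them by replicate, and measures the tail proportions
of the paired difference ``test - control``:

* ``p_inhibit``    = fraction of differences >= 0 (evidence the test
  series is *lower* is a small upper tail);
* ``p_facilitate`` = fraction of differences <= 0.

A subject is an *inhibitor* if ``p_inhibit < alpha`` (one-tailed),
a *facilitator* if ``p_facilitate < alpha``, otherwise a *nonresponder*.
Ties (difference exactly zero) count toward both tails, so
``p_inhibit + p_facilitate >= 1`` and the two significant labels are
mutually exclusive for any ``alpha < 0.5``.

``exact_bootstrap_p`` provides the exact finite-sample version by
enumerating all C(15,7) = 6435 bootstrap multisets per series with their
multinomial weights; it is the verification oracle for the Monte-Carlo
procedure and for its calibration.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from math import factorial
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .preprocess import StimulusBlockSeries

LABEL_INHIBITOR = "inhibitor"
LABEL_NONRESPONDER = "nonresponder"
LABEL_FACILITATOR = "facilitator"
LABELS = (LABEL_INHIBITOR, LABEL_NONRESPONDER, LABEL_FACILITATOR)


class BootstrapConfig(BaseModel, frozen=True):
    """Resampling parameters of the classification test."""

    n_resamples: int = Field(default=10_000, ge=1)
    alpha: float = Field(default=0.05, gt=0.0, lt=0.5)
    seed: int = 0


@dataclass(frozen=True)
class ClassificationResult:
    subject_id: str
    label: str
    p_inhibit: float
    p_facilitate: float
    mean_diff: float  # series-2 mean minus series-1 mean, VAS points
    config: BootstrapConfig


def subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    """Independent, stable RNG stream for one subject.

    The stream is keyed by a CRC of the subject id, so adding or removing
    subjects never perturbs the draws of the others.
    """
    key = zlib.crc32(subject_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _validated_means(values: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("block means must be a non-empty 1-D array")
    if arr.size != 8:
        raise ValueError(f"expected 8 block means, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("block means must be finite")
    return arr


def bootstrap_mean_samples(
    block_means: Sequence[float] | np.ndarray,
    n_resamples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """``n_resamples`` means of 8 draws with replacement from the input."""
    arr = _validated_means(block_means)
    idx = rng.integers(0, arr.size, size=(n_resamples, arr.size))
    return arr[idx].mean(axis=1)


def classify_subject(
    control: StimulusBlockSeries,
    test: StimulusBlockSeries,
    config: BootstrapConfig,
) -> ClassificationResult:
    """Label one subject from its two block-mean series.

    Both series must belong to the same subject.  The result is
    reproducible: the resampling stream is derived from ``config.seed``
    and the subject id only.
    """
    if control.subject_id != test.subject_id:
        raise ValueError(
            f"series belong to different subjects: "
            f"{control.subject_id!r} vs {test.subject_id!r}"
        )
    c = _validated_means(control.block_means)
    t = _validated_means(test.block_means)
    rng = subject_rng(config.seed, control.subject_id)
    control_means = bootstrap_mean_samples(c, config.n_resamples, rng)
    test_means = bootstrap_mean_samples(t, config.n_resamples, rng)
    diffs = test_means - control_means
    p_inhibit = float(np.mean(diffs >= 0.0))
    p_facilitate = float(np.mean(diffs <= 0.0))
    return ClassificationResult(
        subject_id=control.subject_id,
        label=_label(p_inhibit, p_facilitate, config.alpha),
        p_inhibit=p_inhibit,
        p_facilitate=p_facilitate,
        mean_diff=float(t.mean() - c.mean()),
        config=config,
    )


def _label(p_inhibit: float, p_facilitate: float, alpha: float) -> str:
    if p_inhibit < alpha:
        return LABEL_INHIBITOR
    if p_facilitate < alpha:
        return LABEL_FACILITATOR
    return LABEL_NONRESPONDER


# ---------------------------------------------------------------------------
# Exact enumeration oracle
# ---------------------------------------------------------------------------

_N_BLOCKS = 8


def _compositions(n: int, k: int) -> np.ndarray:
    """All length-k vectors of non-negative ints summing to n (stars/bars)."""
    if k == 1:
        return np.array([[n]], dtype=np.int64)
    rows = []
    for first in range(n + 1):
        rest = _compositions(n - first, k - 1)
        block = np.empty((rest.shape[0], k), dtype=np.int64)
        block[:, 0] = first
        block[:, 1:] = rest
        rows.append(block)
    return np.vstack(rows)


_COMP_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _bootstrap_support(k: int = _N_BLOCKS) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicity matrix (C(2k-1,k-1) x k) and multinomial weights of all
    bootstrap multisets of k draws from k values."""
    if k not in _COMP_CACHE:
        comps = _compositions(k, k)
        logw = np.full(comps.shape[0], float(np.log(factorial(k))) - k * np.log(k))
        # subtract log(prod m_i!) per composition
        log_fact = np.log([factorial(i) for i in range(k + 1)])
        logw -= log_fact[comps].sum(axis=1)
        w = np.exp(logw)
        _COMP_CACHE[k] = (comps, w / w.sum())  # exact unit mass despite rounding
    return _COMP_CACHE[k]


def exact_bootstrap_p(
    control: Sequence[float] | np.ndarray,
    test: Sequence[float] | np.ndarray,
) -> tuple[float, float]:
    """Exact P(diff >= 0) and P(diff <= 0) under the bootstrap-of-means law.

    Enumerates the 6435 bootstrap multisets of each series with their
    multinomial weights and accumulates the two tail masses of the
    independent paired difference.  Swapping the arguments swaps the two
    returned probabilities exactly.
    """
    c = _validated_means(control)
    t = _validated_means(test)
    comps, weights = _bootstrap_support(c.size)
    c_means = comps @ c / c.size
    t_means = comps @ t / t.size
    order = np.argsort(c_means, kind="stable")
    c_sorted = c_means[order]
    c_cum = np.concatenate([[0.0], np.cumsum(weights[order])])
    total = c_cum[-1]
    # tolerance for float ties between resampled means
    tol = 1e-9 * (1.0 + max(np.abs(c).max(), np.abs(t).max()))
    # P(diff >= 0) = sum_t w_t * P(c_mean <= t_mean)
    le_idx = np.searchsorted(c_sorted, t_means + tol, side="right")
    p_inhibit = float(np.dot(weights, c_cum[le_idx]) / total)
    # P(diff <= 0) = sum_t w_t * P(c_mean >= t_mean)
    lt_idx = np.searchsorted(c_sorted, t_means - tol, side="left")
    p_facilitate = float(np.dot(weights, total - c_cum[lt_idx]) / total)
    return min(p_inhibit, 1.0), min(p_facilitate, 1.0)


def classify_subject_exact(
    control: StimulusBlockSeries,
    test: StimulusBlockSeries,
    alpha: float = 0.05,
) -> str:
    """Label a subject using the exact enumeration oracle."""
    p_i, p_f = exact_bootstrap_p(control.block_means, test.block_means)
    return _label(p_i, p_f, alpha)


# ---------------------------------------------------------------------------
# Cohort-level classification
# ---------------------------------------------------------------------------


def classify_cohort(
    pairs: Iterable[tuple[StimulusBlockSeries, StimulusBlockSeries]],
    config: BootstrapConfig,
    metadata: pd.DataFrame | None = None,
) -> tuple[list[ClassificationResult], pd.DataFrame]:
    """Classify every subject and tabulate label proportions.

    ``metadata`` (optional, indexed or keyed by ``subject_id``) may carry
    ``site`` and ``sex`` columns; proportions are then also stratified by
    those factors.  Returns the per-subject results and a tidy proportion
    table with columns stratum / stratum_level / label / count / percent.
    """
    results: list[ClassificationResult] = []
    seen: set[str] = set()
    for control, test in pairs:
        if control.subject_id in seen:
            raise ValueError(f"duplicate subject_id: {control.subject_id!r}")
        seen.add(control.subject_id)
        results.append(classify_subject(control, test, config))
    if not results:
        raise ValueError("cohort must contain at least one subject")

    frame = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in results],
            "label": [r.label for r in results],
        }
    )
    if metadata is not None:
        meta = metadata.reset_index() if metadata.index.name == "subject_id" else metadata
        frame = frame.merge(meta, on="subject_id", how="left")

    tables = [_proportion_rows(frame, "overall", "all")]
    for factor in ("site", "sex"):
        if factor in frame.columns:
            for level, sub in frame.groupby(factor, observed=True):
                tables.append(_proportion_rows(sub, factor, str(level)))
    return results, pd.concat(tables, ignore_index=True)


def _proportion_rows(frame: pd.DataFrame, stratum: str, level: str) -> pd.DataFrame:
    counts = frame["label"].value_counts()
    n = len(frame)
    return pd.DataFrame(
        {
            "stratum": stratum,
            "stratum_level": level,
            "label": LABELS,
            "count": [int(counts.get(lbl, 0)) for lbl in LABELS],
            "percent": [100.0 * counts.get(lbl, 0) / n for lbl in LABELS],
        }
    )


def results_frame(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Per-subject classification table (one row per subject)."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in results],
            "label": [r.label for r in results],
            "p_inhibit": [r.p_inhibit for r in results],
            "p_facilitate": [r.p_facilitate for r in results],
            "mean_diff": [r.mean_diff for r in results],
            "n_resamples": [r.config.n_resamples for r in results],
            "seed": [r.config.seed for r in results],
        }
    )
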