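"""Benchmark experiments for the classification procedure.

Three experiments quantify how trustworthy the bootstrap responder
classification is, plus a worked-example check that the paired effect
arithmetic reproduces published summary rows:

* ``worked_effect_examples`` — rebuild a difference vector with a
  published row's n/mean/SD and recompute Cohen's D and paired t;
* ``null_calibration`` — type-I-error rate of the classifier on
  simulated exchangeable (delta = 0) subjects, measured for the
  Monte-Carlo test and for the exact enumeration oracle on the same
  subjects;
* ``oracle_agreement`` — how often the Monte-Carlo tail probability at
  B resamples falls within 3 binomial standard errors of the exact
  probability;
* ``recovery_experiment`` — classify a simulated cohort with known
  class mix and published-magnitude deltas and compare recovered
  proportions with the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import (
    LABELS,
    BootstrapConfig,
    classify_subject,
    classify_subject_exact,
    exact_bootstrap_p,
)
from .preprocess import analysis_block_means
from .simulate import ClassParams, CohortSpec, diffs_with_mean_sd, simulate_cohort
from .stats import paired_effect
from .timing import build_timing

#: Published paired-effect rows whose printed Cohen's D and t are
#: arithmetically consistent with their printed n / mean / SD at 2 dp.
#: Columns: key, n, mean_diff, sd_diff, cohens_d, t.
PUBLISHED_EFFECT_ROWS: list[tuple[str, int, float, float, float, float]] = [
    ("placebo_arm", 77, -3.48, 11.26, 0.31, -2.71),
    ("placebo_face", 23, -4.38, 9.31, 0.47, -2.26),
    ("placebo_inhibitors_face", 10, -13.02, 5.36, 2.43, -7.68),
    ("placebo_nonresponders_all", 34, 0.41, 3.75, 0.11, 0.64),
    ("placebo_nonresponders_arm", 24, 0.44, 3.98, 0.11, 0.54),
    ("placebo_facilitators_all", 17, 13.27, 6.98, 1.90, 7.84),
    ("placebo_facilitators_face", 3, 8.65, 5.94, 1.46, 2.52),
    ("cpm_all", 135, -2.89, 11.75, 0.25, -2.86),
    ("cpm_face", 107, -2.72, 12.60, 0.22, -2.23),
    ("cpm_inhibitors_all", 45, -14.67, 10.04, 1.46, -9.80),
    ("cpm_inhibitors_face", 34, -15.48, 11.20, 1.38, -8.06),
    ("cpm_nonresponders_arm", 15, 0.35, 2.60, 0.13, 0.52),
    ("cpm_nonresponders_face", 53, -0.48, 4.49, 0.11, -0.78),
    ("cpm_facilitators_all", 23, 12.50, 6.46, 1.93, 9.28),
    ("offset_all", 36, -2.30, 17.64, 0.13, -0.78),
    ("offset_inhibitors", 12, -21.39, 10.79, 1.98, -6.87),
    ("offset_facilitators", 7, 20.40, 11.89, 1.72, 4.54),
]


def worked_effect_examples() -> dict[str, dict[str, float]]:
    """Recompute each published row's Cohen's D and paired t from a
    difference vector carrying exactly that row's n, mean and SD."""
    out = {}
    for key, n, mean, sd, _d, _t in PUBLISHED_EFFECT_ROWS:
        eff = paired_effect(diffs_with_mean_sd(n, mean, sd), group=key)
        out[key] = {"n": n, "cohens_d": eff.cohens_d, "t": eff.t_value}
    return out


@dataclass(frozen=True)
class CalibrationResult:
    n_subjects: int
    mc_rejection_rate: float  # fraction labelled inhibitor or facilitator
    exact_rejection_rate: float  # same subjects, exact enumeration oracle


def _cohort_block_mean_pairs(spec: CohortSpec):
    timing = build_timing(spec.paradigm)
    for profile, s1, s2 in simulate_cohort(spec):
        yield (
            profile,
            analysis_block_means(s1, timing),
            analysis_block_means(s2, timing),
        )


def null_calibration(
    n_subjects: int = 2000,
    seed: int = 0,
    n_resamples: int = 10_000,
    alpha: float = 0.05,
    block_noise_sd: float = 5.0,
) -> CalibrationResult:
    """Type-I-error rate on exchangeable (delta = 0) simulated subjects.

    The nominal two-tail rate is about 2*alpha; the bootstrap-of-means
    test on 8 blocks is mildly conservative or liberal depending on the
    noise law, so the exact oracle's rate on the same subjects is the
    reference the Monte-Carlo rate is compared against.
    """
    spec = CohortSpec(
        n_subjects=n_subjects,
        paradigm="placebo",
        class_mix={"nonresponder": 1.0},
        delta_distributions={"nonresponder": ClassParams(mean=0.0, sd=0.0)},
        block_noise_sd=ClassParams(mean=block_noise_sd, sd=0.0),
        seed=seed,
    )
    config = BootstrapConfig(n_resamples=n_resamples, alpha=alpha, seed=seed)
    mc_hits = 0
    exact_hits = 0
    for _, s1, s2 in _cohort_block_mean_pairs(spec):
        mc_hits += classify_subject(s1, s2, config).label != "nonresponder"
        exact_hits += classify_subject_exact(s1, s2, alpha) != "nonresponder"
    return CalibrationResult(
        n_subjects=n_subjects,
        mc_rejection_rate=mc_hits / n_subjects,
        exact_rejection_rate=exact_hits / n_subjects,
    )


def oracle_agreement(
    n_pairs: int = 50,
    seed: int = 0,
    n_resamples: int = 10_000,
) -> float:
    """Fraction of random series pairs whose Monte-Carlo p_inhibit falls
    within 3 binomial standard errors of the exact value."""
    rng = np.random.default_rng(seed)
    config = BootstrapConfig(n_resamples=n_resamples, seed=seed)
    from .preprocess import StimulusBlockSeries

    hits = 0
    for i in range(n_pairs):
        delta = rng.uniform(-10, 10)
        c = rng.normal(45, 5, 8)
        t = rng.normal(45 + delta, 5, 8)
        p_exact, _ = exact_bootstrap_p(c, t)
        r = classify_subject(
            StimulusBlockSeries(f"pair{i}", 1, np.clip(c, 0, 100)),
            StimulusBlockSeries(f"pair{i}", 2, np.clip(t, 0, 100)),
            config,
        )
        se = np.sqrt(max(p_exact * (1 - p_exact), 1.0 / n_resamples) / n_resamples)
        hits += abs(r.p_inhibit - p_exact) <= 3 * se
    return hits / n_pairs


@dataclass(frozen=True)
class RecoveryResult:
    n_subjects: int
    true_mix: dict[str, float]
    recovered: dict[str, float]  # fraction of subjects per label
    ci_halfwidth: dict[str, float]  # 95% binomial half-widths at the true mix


def recovery_experiment(
    n_subjects: int = 300,
    seed: int = 0,
    n_resamples: int = 10_000,
    mix: dict[str, float] | None = None,
    deltas: dict[str, float] | None = None,
    block_noise_sd: float = 4.0,
) -> RecoveryResult:
    """Classify a simulated cohort with known structure and compare the
    recovered label proportions with the generating mix."""
    mix = mix or {"inhibitor": 0.49, "nonresponder": 0.34, "facilitator": 0.17}
    deltas = deltas or {"inhibitor": -12.4, "nonresponder": 0.0, "facilitator": 13.3}
    spec = CohortSpec(
        n_subjects=n_subjects,
        paradigm="placebo",
        class_mix=mix,
        delta_distributions={
            lbl: ClassParams(mean=deltas[lbl], sd=0.0) for lbl in mix
        },
        block_noise_sd=ClassParams(mean=block_noise_sd, sd=0.0),
        seed=seed,
    )
    config = BootstrapConfig(n_resamples=n_resamples, seed=seed)
    counts = {lbl: 0 for lbl in LABELS}
    for _, s1, s2 in _cohort_block_mean_pairs(spec):
        counts[classify_subject(s1, s2, config).label] += 1
    recovered = {lbl: counts[lbl] / n_subjects for lbl in LABELS}
    ci = {
        lbl: 1.96 * np.sqrt(mix[lbl] * (1 - mix[lbl]) / n_subjects) for lbl in mix
    }
    return RecoveryResult(
        n_subjects=n_subjects, true_mix=mix, recovered=recovered, ci_halfwidth=ci
    )
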