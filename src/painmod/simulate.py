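"""Synthetic cohorts of continuous VAS pain-rating traces.

No behavioural data are deposited with the study this package analyses,
so the generator emulates the statistical structure the analysis
assumes: per subject, two recording series of eight stimulus blocks with

* a latent in-block level = calibrated baseline (moderate pain,
  40-50 VAS) + the subject's modulation effect (series 2 only),
* a per-block Gaussian deviation (SD ``block_noise_sd``) driving the
  between-block rating variability,
* per-sample Gaussian jitter (SD ``within_block_sd``),
* clamping of every emitted rating to [0, 100],
* ratings decaying linearly to 0 over the first 5 s of each ISI (the
  ISI thermode temperature is non-painful, and no analysed window
  overlaps the ISI).

Variance decomposition: a block mean over ``m`` in-window samples has
variance ``block_noise_sd**2 + within_block_sd**2 / m`` (before
clamping), so the SD of the 8 block means converges to
``sqrt(block_noise_sd**2 + within_block_sd**2 / m)`` over replicates.

Class allocation is stratified (largest-remainder rounding of the
requested mix), so small cohorts hit the mix exactly; each subject's
noise comes from a stable sub-seeded stream, so adding a subject never
perturbs the others.
"""

from __future__ import annotations

import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .classify import LABELS, subject_rng
from .preprocess import VasTrace
from .timing import Paradigm, ParadigmTiming, build_timing

ISI_DECAY_SECONDS = 5.0
OFFSET_T2_BUMP = 15.0  # VAS rise during the +1 degC T2 period (series 2)

ALLOWED_TEMPS = np.arange(44.0, 48.51, 0.5)

# questionnaire score ranges (min, max) for plausibility checks
QUESTIONNAIRE_RANGES: dict[str, tuple[float, float]] = {
    "LOT-R": (0, 24),
    "STAI-S": (20, 80),
    "STAI-T": (20, 80),
    "PCS": (0, 52),
    "BIS": (7, 28),
    "BAS": (13, 52),
}


class SubjectProfile(BaseModel, frozen=True):
    subject_id: str
    paradigm: Paradigm
    site: str = "arm"  # test-stimulus site: arm | face
    conditioning_site: str = "none"  # arm | leg | none (CPM only)
    sex: str = "female"
    age: float = 25.0
    true_class: str = "nonresponder"
    baseline_vas: float = Field(default=45.0, ge=0.0, le=100.0)
    modulation_delta: float = 0.0  # VAS points added to series 2 (neg = inhibition)
    block_noise_sd: float = Field(default=4.0, ge=0.0)
    within_block_sd: float = Field(default=3.0, ge=0.0)
    calibrated_temp: float = 46.5  # degC, one of 44.0..48.5 in 0.5 steps
    questionnaires: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "SubjectProfile":
        if self.true_class not in LABELS:
            raise ValueError(f"unknown true_class {self.true_class!r}")
        if not np.all(np.isfinite([self.baseline_vas, self.modulation_delta,
                                   self.block_noise_sd, self.within_block_sd])):
            raise ValueError("profile parameters must be finite")
        if not np.any(np.isclose(self.calibrated_temp, ALLOWED_TEMPS)):
            raise ValueError(
                "calibrated_temp must lie on the 44.0-48.5 degC grid in 0.5 steps"
            )
        for name, score in self.questionnaires.items():
            lo, hi = QUESTIONNAIRE_RANGES.get(name, (-np.inf, np.inf))
            if not lo <= score <= hi:
                raise ValueError(f"{name} score {score} outside [{lo}, {hi}]")
        return self


class ClassParams(BaseModel, frozen=True):
    """Normal distribution of modulation deltas within one response class."""

    mean: float
    sd: float = Field(default=0.0, ge=0.0)


class CohortSpec(BaseModel, frozen=True):
    """Everything needed to simulate one cohort reproducibly."""

    n_subjects: int = Field(ge=0)
    paradigm: Paradigm = Paradigm.PLACEBO
    class_mix: dict[str, float] = Field(
        default={"inhibitor": 0.48, "nonresponder": 0.34, "facilitator": 0.18}
    )
    delta_distributions: dict[str, ClassParams] = Field(
        # Table-1-scale modulation magnitudes per class
        default={
            "inhibitor": ClassParams(mean=-12.4, sd=4.8),
            "nonresponder": ClassParams(mean=0.0, sd=0.0),
            "facilitator": ClassParams(mean=13.3, sd=7.0),
        }
    )
    block_noise_sd: ClassParams = ClassParams(mean=5.0, sd=1.5)
    within_block_sd: ClassParams = ClassParams(mean=3.0, sd=0.0)
    baseline_vas: ClassParams = ClassParams(mean=45.0, sd=3.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if set(self.class_mix) - set(LABELS):
            raise ValueError(f"class_mix keys must be among {LABELS}")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1 (tolerance 1e-9)")
        if set(self.class_mix) - set(self.delta_distributions):
            raise ValueError("every class in class_mix needs a delta distribution")
        return self

    def to_yaml(self) -> str:
        return yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortSpec":
        return cls.model_validate(yaml.safe_load(text))


def allocate_classes(mix: Mapping[str, float], n: int) -> list[str]:
    """Deterministic stratified allocation: largest-remainder rounding of
    ``mix`` over ``n`` subjects, ordered inhibitor/nonresponder/facilitator."""
    labels = [lbl for lbl in LABELS if lbl in mix]
    raw = {lbl: mix[lbl] * n for lbl in labels}
    counts = {lbl: int(np.floor(raw[lbl])) for lbl in labels}
    short = n - sum(counts.values())
    by_remainder = sorted(labels, key=lambda l: (-(raw[l] - counts[l]), labels.index(l)))
    for lbl in by_remainder[:short]:
        counts[lbl] += 1
    out: list[str] = []
    for lbl in labels:
        out.extend([lbl] * counts[lbl])
    return out


def simulate_trace(
    profile: SubjectProfile,
    timing: ParadigmTiming,
    series_index: int,
    rng: np.random.Generator,
) -> VasTrace:
    """One continuous VAS trace for one recording series.

    Series 1 is the control recording; series 2 carries the subject's
    modulation delta on every block.  For the offset paradigm, series 2
    additionally rates higher during the +1 degC T2 period and expresses
    the delta during T3 (the analysed window), while T1 sits at baseline.
    """
    if series_index not in (1, 2):
        raise ValueError("series_index must be 1 or 2")
    times = timing.sample_times()
    values = np.zeros_like(times)
    delta = profile.modulation_delta if series_index == 2 else 0.0
    tol = 1e-9
    period = timing.block_period
    for b in range(timing.n_blocks):
        start = timing.block_start(b)
        stop = start + timing.stimulus_duration
        block_dev = rng.normal(0.0, profile.block_noise_sd)
        in_block = (times >= start - tol) & (times < stop - tol)
        level = np.full(int(in_block.sum()), profile.baseline_vas + delta)
        if timing.paradigm is Paradigm.OFFSET and series_index == 2:
            t_rel = times[in_block] - start
            level = np.where(t_rel < timing.t1 - tol, profile.baseline_vas, level)
            in_t2 = (t_rel >= timing.t1 - tol) & (t_rel < timing.t1 + timing.t2 - tol)
            level = np.where(in_t2, profile.baseline_vas + OFFSET_T2_BUMP, level)
        jitter = rng.normal(0.0, profile.within_block_sd, size=level.size)
        values[in_block] = level + block_dev + jitter
        # ISI: ratings fall linearly to 0 over the first seconds off-stimulus
        isi = (times >= stop - tol) & (times < start + period - tol)
        t_isi = times[isi] - stop
        last = values[in_block][-1] if level.size else 0.0
        values[isi] = np.clip(last * (1.0 - t_isi / ISI_DECAY_SECONDS), 0.0, None)
    values = np.clip(values, 0.0, 100.0)
    return VasTrace(
        subject_id=profile.subject_id, series=series_index, times=times, values=values
    )


def simulate_subject(
    profile: SubjectProfile,
    timing: ParadigmTiming,
    seed: int,
) -> tuple[VasTrace, VasTrace]:
    """Both recording series of one subject from its own stable stream."""
    rng = subject_rng(seed, profile.subject_id)
    return (
        simulate_trace(profile, timing, 1, rng),
        simulate_trace(profile, timing, 2, rng),
    )


def simulate_cohort(
    spec: CohortSpec,
) -> list[tuple[SubjectProfile, VasTrace, VasTrace]]:
    """Simulate a full cohort: profiles plus both rating series each.

    Reproducible: the same spec (including seed) yields byte-identical
    cohorts.  Class labels follow stratified allocation of ``class_mix``;
    per-class modulation deltas are drawn from ``delta_distributions``.
    """
    timing = build_timing(spec.paradigm)
    classes = allocate_classes(spec.class_mix, spec.n_subjects)
    profile_rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(0xC0F0,))
    )
    out = []
    for i, true_class in enumerate(classes):
        sid = f"{spec.paradigm.value}-{i + 1:04d}"
        dist = spec.delta_distributions[true_class]
        delta = dist.mean + dist.sd * profile_rng.standard_normal()
        profile = SubjectProfile(
            subject_id=sid,
            paradigm=spec.paradigm,
            site="arm" if spec.paradigm is Paradigm.OFFSET
            else ("face" if profile_rng.random() < 0.25 else "arm"),
            conditioning_site=(
                "none" if spec.paradigm is not Paradigm.CPM
                else ("arm" if profile_rng.random() < 0.5 else "leg")
            ),
            sex="female" if profile_rng.random() < 0.5 else "male",
            age=float(np.round(profile_rng.uniform(18, 45), 1)),
            true_class=true_class,
            baseline_vas=float(
                np.clip(
                    spec.baseline_vas.mean
                    + spec.baseline_vas.sd * profile_rng.standard_normal(),
                    5.0,
                    95.0,
                )
            ),
            modulation_delta=float(delta),
            block_noise_sd=float(
                max(0.5, spec.block_noise_sd.mean
                    + spec.block_noise_sd.sd * profile_rng.standard_normal())
            ),
            within_block_sd=float(
                max(0.0, spec.within_block_sd.mean
                    + spec.within_block_sd.sd * profile_rng.standard_normal())
            ),
            calibrated_temp=float(
                ALLOWED_TEMPS[profile_rng.integers(0, ALLOWED_TEMPS.size)]
            ),
            questionnaires=_draw_questionnaires(profile_rng),
        )
        s1, s2 = simulate_subject(profile, timing, spec.seed)
        out.append((profile, s1, s2))
    return out


def _draw_questionnaires(rng: np.random.Generator) -> dict[str, float]:
    """Plausible questionnaire scores (population-typical means/SDs)."""
    draws = {
        "LOT-R": rng.normal(14.5, 4.0),
        "STAI-S": rng.normal(36.0, 9.0),
        "STAI-T": rng.normal(36.0, 9.0),
        "PCS": rng.normal(13.0, 8.0),
        "BIS": rng.normal(20.0, 3.5),
        "BAS": rng.normal(40.0, 4.0),
    }
    return {
        name: float(np.clip(round(v), *QUESTIONNAIRE_RANGES[name]))
        for name, v in draws.items()
    }


# ---------------------------------------------------------------------------
# Long-format writers / readers
# ---------------------------------------------------------------------------


def ratings_frame(
    cohort: Sequence[tuple[SubjectProfile, VasTrace, VasTrace]]
) -> pd.DataFrame:
    """Long-format ratings table: subject_id, series, time_s, vas."""
    parts = []
    for _, s1, s2 in cohort:
        for tr in (s1, s2):
            parts.append(
                pd.DataFrame(
                    {
                        "subject_id": tr.subject_id,
                        "series": tr.series,
                        "time_s": tr.times,
                        "vas": tr.values,
                    }
                )
            )
    if not parts:
        return pd.DataFrame(columns=["subject_id", "series", "time_s", "vas"])
    return pd.concat(parts, ignore_index=True)


def metadata_frame(
    cohort: Sequence[tuple[SubjectProfile, VasTrace, VasTrace]]
) -> pd.DataFrame:
    """One row per subject: profile fields plus questionnaire columns."""
    rows = []
    for profile, _, _ in cohort:
        row = profile.model_dump(exclude={"questionnaires"})
        row["paradigm"] = profile.paradigm.value
        row.update(profile.questionnaires)
        rows.append(row)
    return pd.DataFrame(rows)


def traces_from_frame(ratings: pd.DataFrame) -> dict[str, dict[int, VasTrace]]:
    """Rebuild VasTrace objects from a long-format ratings table."""
    out: dict[str, dict[int, VasTrace]] = {}
    for (sid, series), grp in ratings.groupby(["subject_id", "series"], sort=True):
        grp = grp.sort_values("time_s")
        out.setdefault(str(sid), {})[int(series)] = VasTrace(
            subject_id=str(sid),
            series=int(series),
            times=grp["time_s"].to_numpy(float),
            values=grp["vas"].to_numpy(float),
        )
    return out


def diffs_with_mean_sd(
    n: int, mean: float, sd: float, rng: np.random.Generator | None = None
) -> np.ndarray:
    """A length-``n`` vector whose sample mean and sample SD (ddof=1) equal
    ``mean`` and ``sd`` exactly (up to float rounding).

    Used to reconstruct within-subject difference vectors from published
    summary rows.  Deterministic when ``rng`` is omitted.
    """
    if n < 2:
        raise ValueError("need n >= 2 to fix both mean and SD")
    base = (
        rng.standard_normal(n) if rng is not None
        else np.linspace(-1.0, 1.0, n)
    )
    base = base - base.mean()
    s = base.std(ddof=1)
    if s == 0:
        raise ValueError("degenerate base vector")
    return mean + sd * base / s
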