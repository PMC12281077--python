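"""Shared study-scale cohort definitions for the analysis drivers.

One spec per paradigm, sized and parameterised at the magnitudes the
published cohorts showed: class mixes from the per-class sample sizes
(placebo 49/34/17 of 100, CPM 45/68/23 of 136, offset 12/17/7 of 36),
modulation deltas and their spreads from the per-class paired-difference
summaries, and between-block rating noise at the observed control-scan
variability scale (mean SD ~5-10 VAS points).
"""

from painmod.simulate import ClassParams, CohortSpec

BOOTSTRAP_RESAMPLES = 10_000


def cohort_specs(seed: int) -> dict[str, CohortSpec]:
    noise = ClassParams(mean=6.5, sd=2.0)
    return {
        "placebo": CohortSpec(
            n_subjects=100,
            paradigm="placebo",
            class_mix={"inhibitor": 0.49, "nonresponder": 0.34, "facilitator": 0.17},
            delta_distributions={
                "inhibitor": ClassParams(mean=-12.42, sd=4.83),
                "nonresponder": ClassParams(mean=0.41, sd=3.75),
                "facilitator": ClassParams(mean=13.27, sd=6.98),
            },
            block_noise_sd=noise,
            seed=seed,
        ),
        "cpm": CohortSpec(
            n_subjects=136,
            paradigm="cpm",
            class_mix={
                "inhibitor": 45 / 136,
                "nonresponder": 68 / 136,
                "facilitator": 23 / 136,
            },
            delta_distributions={
                "inhibitor": ClassParams(mean=-14.67, sd=10.04),
                "nonresponder": ClassParams(mean=-0.30, sd=4.14),
                "facilitator": ClassParams(mean=12.50, sd=6.46),
            },
            block_noise_sd=noise,
            seed=seed + 1,
        ),
        "offset": CohortSpec(
            n_subjects=36,
            paradigm="offset",
            class_mix={
                "inhibitor": 12 / 36,
                "nonresponder": 17 / 36,
                "facilitator": 7 / 36,
            },
            delta_distributions={
                "inhibitor": ClassParams(mean=-21.39, sd=10.79),
                "nonresponder": ClassParams(mean=1.83, sd=5.52),
                "facilitator": ClassParams(mean=20.40, sd=11.89),
            },
            block_noise_sd=ClassParams(mean=8.0, sd=2.5),
            seed=seed + 2,
        ),
    }
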