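"""Simulate the three study-scale cohorts and write their raw data.

Produces, per paradigm, a long-format continuous-ratings table
(subject_id, series, time_s, vas at 0.5 s resolution) and a subject
metadata table, under results/cohorts/<paradigm>/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from paradigm_specs import cohort_specs

from painmod.simulate import metadata_frame, ratings_frame, simulate_cohort

SEED = 20250929


def main() -> None:
    for name, spec in cohort_specs(SEED).items():
        out = Path("results/cohorts") / name
        out.mkdir(parents=True, exist_ok=True)
        cohort = simulate_cohort(spec)
        ratings = ratings_frame(cohort)
        ratings.to_csv(out / "ratings.csv", index=False, float_format="%.17g")
        metadata_frame(cohort).to_csv(out / "metadata.csv", index=False,
                                      float_format="%.17g")
        (out / "cohort_spec.yaml").write_text(spec.to_yaml())
        n_samples = len(ratings)
        print(
            f"{name:8s}: {spec.n_subjects:3d} subjects, "
            f"{n_samples:7d} rating samples -> {out}/"
        )


if __name__ == "__main__":
    main()
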