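"""Classify every simulated subject and compare response proportions.

Ingests the cohorts written by 01_simulate_cohorts.py, runs the full
pipeline (block means -> bootstrap classification -> summary tables)
per paradigm, then tests the pairwise differences in inhibitor /
nonresponder / facilitator proportions between paradigms with the
pooled two-proportion z test.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from paradigm_specs import BOOTSTRAP_RESAMPLES

from painmod.classify import BootstrapConfig
from painmod.pipeline import RunConfig, run_pipeline
from painmod.stats import two_proportion_test

SEED = 20250929


def main() -> None:
    counts: dict[str, dict[str, int]] = {}
    for name in ("placebo", "cpm", "offset"):
        src = Path("results/cohorts") / name
        if not src.exists():
            raise SystemExit(f"run 01_simulate_cohorts.py first ({src} missing)")
        config = RunConfig(
            mode="ingest",
            ratings_path=str(src / "ratings.csv"),
            metadata_path=str(src / "metadata.csv"),
            bootstrap=BootstrapConfig(n_resamples=BOOTSTRAP_RESAMPLES, seed=SEED),
            out_dir=str(Path("results/classified") / name),
        )
        report = run_pipeline(config)
        overall = {
            p["label"]: p for p in report["proportions"] if p["stratum"] == "overall"
        }
        counts[name] = {lbl: overall[lbl]["count"] for lbl in overall}
        pretty = ", ".join(
            f"{lbl} {overall[lbl]['percent']:.0f}%" for lbl in overall
        )
        print(f"{name:8s} (n={report['n_subjects']}): {pretty}")

    print("\npairwise two-proportion z tests (inhibitor share):")
    rows = []
    names = list(counts)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            n_a, n_b = sum(counts[a].values()), sum(counts[b].values())
            for lbl in ("inhibitor", "nonresponder", "facilitator"):
                z, p = two_proportion_test(
                    counts[a][lbl], n_a, counts[b][lbl], n_b
                )
                rows.append(
                    {"label": lbl, "a": a, "b": b, "z": round(z, 3), "p": round(p, 4)}
                )
    table = pd.DataFrame(rows)
    table.to_csv("results/proportion_tests.csv", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
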