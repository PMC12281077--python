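"""Effect sizes, rating variability and questionnaire contrasts.

Reads the per-paradigm outputs of 02_classify_responders.py and reports:

* paired effect summaries (Cohen's D, mean/SD of differences, t) per
  response class (already written as effects_by_class.csv by the pipeline);
* control-scan rating variability (SD of the 8 block means) compared
  between response classes with the KS-normality-gated t / Mann-Whitney
  tests, Bonferroni-corrected over the three pairwise contrasts;
* one-way ANOVA with post hoc t-tests on the questionnaire scores.
"""

from pathlib import Path

import pandas as pd

from painmod.stats import compare_groups

LABELS = ("inhibitor", "nonresponder", "facilitator")


def control_variability(classified: Path) -> pd.DataFrame:
    """Per-subject control-series SD of block means, labelled."""
    blocks = pd.read_csv(classified / "block_means.csv")
    labels = pd.read_csv(classified / "classification.csv")[["subject_id", "label"]]
    control = blocks[blocks["series"] == 1]
    sd = (
        control.groupby("subject_id")["mean_vas"]
        .std(ddof=1)
        .rename("control_sd")
        .reset_index()
    )
    return sd.merge(labels, on="subject_id")


def main() -> None:
    for name in ("placebo", "cpm", "offset"):
        classified = Path("results/classified") / name
        if not classified.exists():
            raise SystemExit(f"run 02_classify_responders.py first ({classified})")
        print(f"\n=== {name} ===")
        effects = pd.read_csv(classified / "effects_by_class.csv")
        main_rows = effects[effects["site"] == "all"][
            ["group", "n", "cohens_d", "mean_diff", "sd_diff", "t_value", "p_value"]
        ]
        print(main_rows.round(2).to_string(index=False))

        var = control_variability(classified)
        groups = {
            lbl: var.loc[var["label"] == lbl, "control_sd"].to_numpy()
            for lbl in LABELS
        }
        groups = {k: v for k, v in groups.items() if v.size >= 4}
        if len(groups) >= 2:
            print("\ncontrol-scan variability contrasts (Bonferroni m=3):")
            rows = [
                {
                    "pair": f"{c.group_a} vs {c.group_b}",
                    "test": c.test_used,
                    "stat": round(c.statistic, 3),
                    "p_bonf": round(c.bonferroni_p, 4),
                }
                for c in compare_groups("control_sd", groups)
            ]
            frame = pd.DataFrame(rows)
            frame.to_csv(classified / "variability_contrasts.csv", index=False)
            print(frame.to_string(index=False))

        quest = pd.read_csv(classified / "questionnaires.csv")
        if "F" in quest.columns:
            cols = ["measure", "F", "p"] + [
                c for c in quest.columns if c.startswith("p_")
            ]
            print("\nquestionnaire ANOVA (post hoc p uncorrected where present):")
            print(quest[cols].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
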