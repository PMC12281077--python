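"""End-to-end orchestration: simulate/ingest -> block means -> classify ->
cohort statistics -> tables and a machine-readable report.

Every artefact is reproducible from the run config and seed; the report
embeds a hash of the config so outputs can be traced back to it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from . import __version__
from .classify import (
    LABELS,
    BootstrapConfig,
    ClassificationResult,
    classify_cohort,
    results_frame,
)
from .preprocess import analysis_block_means, series_variability
from .simulate import (
    CohortSpec,
    metadata_frame,
    ratings_frame,
    simulate_cohort,
    traces_from_frame,
)
from .stats import anova_with_posthoc, mean_sem, paired_effect, percent_change
from .timing import build_timing

QUESTIONNAIRES = ("LOT-R", "STAI-S", "STAI-T", "PCS", "BIS", "BAS")


class RunConfig(BaseModel, frozen=True):
    mode: Literal["simulate", "ingest"] = "simulate"
    cohort: CohortSpec | None = None
    ratings_path: str | None = None
    metadata_path: str | None = None
    bootstrap: BootstrapConfig = BootstrapConfig()
    out_dir: str = "results"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.mode == "simulate" and self.cohort is None:
            raise ValueError("simulate mode requires a cohort spec")
        if self.mode == "ingest":
            if self.cohort is not None:
                raise ValueError("ingest mode must not carry a cohort spec")
            if not self.ratings_path:
                raise ValueError("ingest mode requires ratings_path")
        return self

    def config_hash(self) -> str:
        # hash the scientific configuration only: where the artefacts land
        # must not change what they contain
        payload = self.model_dump_json(exclude={"out_dir"})
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and subject ids."""

    def __init__(self, stage: str, detail: str, subjects: list[str] | None = None):
        self.stage = stage
        self.subjects = subjects or []
        suffix = f" (subjects: {', '.join(self.subjects)})" if subjects else ""
        super().__init__(f"stage {stage!r} failed: {detail}{suffix}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write CSV artefacts plus a JSON report.

    Returns the report as a dict.  Idempotent given the config (which
    includes every seed involved).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: acquire traces -------------------------------------------
    if config.mode == "simulate":
        cohort = simulate_cohort(config.cohort)
        paradigm = config.cohort.paradigm.value
        ratings = ratings_frame(cohort)
        metadata = metadata_frame(cohort)
    else:
        # round_trip parsing keeps ingested ratings bit-identical to the
        # floats that were written
        ratings = pd.read_csv(config.ratings_path, float_precision="round_trip")
        metadata = (
            pd.read_csv(config.metadata_path)
            if config.metadata_path
            else pd.DataFrame(columns=["subject_id", "paradigm"])
        )
        paradigms = (
            metadata["paradigm"].unique()
            if "paradigm" in metadata.columns and len(metadata)
            else ["placebo"]
        )
        if len(paradigms) != 1:
            raise StageError("ingest", f"expected one paradigm, got {list(paradigms)}")
        paradigm = str(paradigms[0])
        cohort = None
    # %.17g keeps float64 ratings lossless, so a written-then-ingested run
    # reproduces the in-memory analysis bit for bit
    ratings.to_csv(out / "ratings.csv", index=False, float_format="%.17g")
    metadata.to_csv(out / "metadata.csv", index=False, float_format="%.17g")

    timing = build_timing(paradigm)
    traces = traces_from_frame(ratings)

    # --- stage: preprocess ------------------------------------------------
    pairs = []
    block_rows = []
    failed: list[str] = []
    for sid in sorted(traces):
        try:
            s1 = analysis_block_means(traces[sid][1], timing)
            s2 = analysis_block_means(traces[sid][2], timing)
        except (KeyError, ValueError) as exc:
            failed.append(sid)
            detail = str(exc)
            continue
        pairs.append((s1, s2))
        for s in (s1, s2):
            for b, m in enumerate(s.block_means, start=1):
                block_rows.append(
                    {
                        "subject_id": sid,
                        "series": s.series,
                        "window_label": s.window_label,
                        "block": b,
                        "mean_vas": m,
                    }
                )
    if failed:
        raise StageError("preprocess", detail, failed)
    pd.DataFrame(block_rows).to_csv(out / "block_means.csv", index=False)

    # --- stage: classify --------------------------------------------------
    results, proportions = classify_cohort(pairs, config.bootstrap, metadata)
    res_frame = results_frame(results)
    res_frame.to_csv(out / "classification.csv", index=False)
    proportions.to_csv(out / "proportions.csv", index=False)

    # --- stage: statistics ------------------------------------------------
    effects = effects_table(results, metadata, paradigm)
    effects.to_csv(out / "effects_by_class.csv", index=False)
    summary = group_summary_table(results, pairs, metadata, paradigm)
    summary.to_csv(out / "group_summary.csv", index=False)
    quest = questionnaire_table(results, metadata, paradigm)
    quest.to_csv(out / "questionnaires.csv", index=False)

    report = {
        "paradigm": paradigm,
        "n_subjects": len(pairs),
        "proportions": proportions.to_dict(orient="records"),
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.bootstrap.seed,
            "painmod_version": __version__,
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def _label_map(results: list[ClassificationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in results],
            "label": [r.label for r in results],
            "mean_diff": [r.mean_diff for r in results],
        }
    )


def effects_table(
    results: list[ClassificationResult],
    metadata: pd.DataFrame,
    paradigm: str,
) -> pd.DataFrame:
    """Paired effect summaries by response class and stimulation site.

    Rows ordered main effect -> inhibitors -> nonresponders ->
    facilitators, each split all / arm / face.  Strata with fewer than
    two subjects are kept as explicit empty rows, never dropped.
    """
    frame = _label_map(results)
    if "site" in metadata.columns:
        frame = frame.merge(metadata[["subject_id", "site"]], on="subject_id", how="left")
    else:
        frame["site"] = "all"
    rows = []
    strata = [("main_effect", frame)] + [
        (lbl + "s", frame[frame["label"] == lbl]) for lbl in LABELS
    ]
    sites = ["all"] + sorted(s for s in frame["site"].unique() if s != "all")
    for stratum, sub in strata:
        for site in sites:
            sel = sub if site == "all" else sub[sub["site"] == site]
            row = {"paradigm": paradigm, "group": stratum, "site": site, "n": len(sel)}
            if len(sel) >= 2:
                eff = paired_effect(sel["mean_diff"].to_numpy(), group=stratum)
                row.update(
                    cohens_d=eff.cohens_d,
                    mean_diff=eff.mean_diff,
                    sd_diff=eff.sd_diff,
                    t_value=eff.t_value,
                    p_value=eff.p_value,
                    degenerate=eff.degenerate,
                )
            else:
                row.update(
                    cohens_d=np.nan, mean_diff=np.nan, sd_diff=np.nan,
                    t_value=np.nan, p_value=np.nan, degenerate=False,
                )
            rows.append(row)
    return pd.DataFrame(rows)



def group_summary_table(
    results: list[ClassificationResult],
    pairs,
    metadata: pd.DataFrame,
    paradigm: str,
) -> pd.DataFrame:
    """Percent pain change, age, temperature and rating variability
    (mean +/- SEM) per response class, overall and by sex."""
    frame = _label_map(results)
    control = {s1.subject_id: s1 for s1, _ in pairs}
    test = {s1.subject_id: s2 for s1, s2 in pairs}
    frame["pct_change"] = [
        percent_change(control[sid].block_means.mean(), test[sid].block_means.mean())
        for sid in frame["subject_id"]
    ]
    frame["control_sd"] = [
        series_variability(control[sid]).sd_of_block_means for sid in frame["subject_id"]
    ]
    frame["test_sd"] = [
        series_variability(test[sid]).sd_of_block_means for sid in frame["subject_id"]
    ]
    cols = [c for c in ("sex", "age", "calibrated_temp") if c in metadata.columns]
    if cols:
        frame = frame.merge(metadata[["subject_id", *cols]], on="subject_id", how="left")
    measures = ["pct_change", "control_sd", "test_sd"] + (
        ["age", "calibrated_temp"] if "age" in frame.columns else []
    )
    rows = []
    for lbl in LABELS:
        sub = frame[frame["label"] == lbl]
        splits = [("all", sub)]
        if "sex" in sub.columns:
            splits += [(sx, sub[sub["sex"] == sx]) for sx in ("female", "male")]
        for sex, sel in splits:
            row = {"paradigm": paradigm, "group": lbl, "sex": sex, "n": len(sel)}
            for m in measures:
                if len(sel) >= 2:
                    mu, sem = mean_sem(sel[m].to_numpy(float))
                else:
                    mu, sem = np.nan, np.nan
                row[f"{m}_mean"], row[f"{m}_sem"] = mu, sem
            rows.append(row)
    return pd.DataFrame(rows)


def questionnaire_table(
    results: list[ClassificationResult],
    metadata: pd.DataFrame,
    paradigm: str,
) -> pd.DataFrame:
    """Per-questionnaire one-way ANOVA over response classes with
    uncorrected post hoc t-tests where the main effect is significant."""
    frame = _label_map(results).merge(metadata, on="subject_id", how="left")
    rows = []
    for q in QUESTIONNAIRES:
        if q not in frame.columns:
            continue
        groups = {
            lbl: frame.loc[frame["label"] == lbl, q].dropna().to_numpy(float)
            for lbl in LABELS
        }
        groups = {k: v for k, v in groups.items() if v.size >= 2}
        row: dict = {"paradigm": paradigm, "measure": q}
        for lbl in LABELS:
            vals = groups.get(lbl, np.array([]))
            if vals.size >= 2:
                mu, sem = mean_sem(vals)
            else:
                mu, sem = np.nan, np.nan
            row[f"{lbl}_mean"], row[f"{lbl}_sem"] = mu, sem
        if len(groups) >= 2:
            res = anova_with_posthoc(q, groups)
            row.update(F=res.f_value, df_between=res.df_between,
                       df_within=res.df_within, p=res.p_value)
            for cmp_ in res.posthoc:
                row[f"p_{cmp_.group_a}_vs_{cmp_.group_b}"] = cmp_.raw_p
        rows.append(row)
    return pd.DataFrame(rows)
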