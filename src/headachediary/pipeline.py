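"""End-to-end pipeline: read -> classify -> aggregate -> group -> select
cohort -> analyze, with all report files written to an output directory."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import aggregate as agg
from . import stats
from .classifier import classify_collection
from .config import PipelineConfig
from .model import DiaryCollection

logger = logging.getLogger("headachediary")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and context."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


def _subset(collection: DiaryCollection, user_ids: set[str]) -> DiaryCollection:
    return DiaryCollection(
        users=[u for u in collection.users if u.user_id in user_ids],
        attacks=[a for a in collection.attacks if a.user_id in user_ids],
        medications=[m for m in collection.medications
                     if m.user_id in user_ids],
        entries=[e for e in collection.entries if e.user_id in user_ids],
    )


def _rows_to_frame(rows: list[stats.OutcomeTableRow]) -> pd.DataFrame:
    recs = []
    for r in rows:
        rec = {"subgroup": r.subgroup, "outcome": r.outcome_name}
        if r.result is not None:
            rec.update(dataclasses.asdict(r.result))
            rec.pop("outcome_name")
        rec["note"] = r.note
        recs.append(rec)
    return pd.DataFrame(recs)


def run_pipeline(collection: DiaryCollection, config: PipelineConfig,
                 out_dir, seed: Optional[int] = None) -> dict[str, Path]:
    """Run all analysis stages and write report files.

    Writes monthly_outcomes.tsv, diagnosis_groups.tsv, demographics.json,
    outcome_table.{tsv,json}, anova.json and run_log.json.  An empty
    selected cohort is reported, not an error.  Returns name -> path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    months = config.analysis.followup_month

    try:
        cohort_ids = set(agg.select_regular_users(collection, months))
    except Exception as exc:
        raise PipelineError("select_cohort", exc) from exc
    logger.info("cohort: %d of %d users adherent for %d months",
                len(cohort_ids), len(collection.users), months)
    cohort = _subset(collection, cohort_ids)

    try:
        classifications = classify_collection(
            cohort, config.classifier.to_classifier_config())
    except Exception as exc:
        raise PipelineError("classify", exc) from exc

    try:
        outcomes = agg.compute_monthly_outcomes(cohort, classifications,
                                                months=months)
    except Exception as exc:
        raise PipelineError("aggregate", exc) from exc

    groups: list[agg.DiagnosisGroup] = []
    if cohort.users:
        try:
            groups = agg.assign_diagnosis_group(
                cohort, classifications,
                chronic_headache_days=config.aggregation.chronic_headache_days,
                chronic_migraine_days=config.aggregation.chronic_migraine_days,
                episodic_min_attacks=config.aggregation.episodic_min_attacks,
                window_days=config.aggregation.diagnosis_window_days)
        except Exception as exc:
            raise PipelineError("diagnosis_groups", exc) from exc

    try:
        demographics = stats.summarize_demographics(cohort.users, groups)
        table_rows = stats.build_outcome_table(
            outcomes, groups, config.analysis.baseline_month,
            config.analysis.followup_month, alpha=config.analysis.alpha)
    except Exception as exc:
        raise PipelineError("analyze", exc) from exc

    anova_results = _anova_stage(outcomes, config)

    paths = {}
    paths["monthly_outcomes"] = out_dir / "monthly_outcomes.tsv"
    agg.write_monthly_outcomes(outcomes, paths["monthly_outcomes"])
    paths["diagnosis_groups"] = out_dir / "diagnosis_groups.tsv"
    agg.write_diagnosis_groups(groups, paths["diagnosis_groups"])

    paths["demographics"] = out_dir / "demographics.json"
    paths["demographics"].write_text(json.dumps(
        {k: dataclasses.asdict(v) for k, v in demographics.items()},
        indent=2))

    frame = _rows_to_frame(table_rows)
    paths["outcome_table_tsv"] = out_dir / "outcome_table.tsv"
    frame.to_csv(paths["outcome_table_tsv"], sep="\t", index=False,
                 float_format="%.6g")
    paths["outcome_table_json"] = out_dir / "outcome_table.json"
    paths["outcome_table_json"].write_text(
        frame.to_json(orient="records", indent=2))

    paths["anova"] = out_dir / "anova.json"
    paths["anova"].write_text(json.dumps(anova_results, indent=2))

    paths["run_log"] = out_dir / "run_log.json"
    paths["run_log"].write_text(json.dumps({
        "config_hash": config.config_hash(),
        "seed": seed,
        "n_users_input": len(collection.users),
        "n_users_cohort": len(cohort_ids),
        "n_attacks_cohort": len(cohort.attacks),
        "followup_month": months,
    }, indent=2))
    logger.info("pipeline outputs written to %s", out_dir)
    return paths


def _anova_stage(outcomes, config: PipelineConfig) -> list[dict]:
    """Repeated-measures ANOVA over baseline / month 7 / month 13 (or the
    available subset) for the three count outcomes."""
    timepoints = [m for m in (config.analysis.baseline_month, 7, 13)
                  if m <= config.analysis.followup_month]
    timepoints = sorted(set(timepoints))
    if len(timepoints) < 2:
        return []
    by_user_month = {(o.user_id, o.month_index): o for o in outcomes}
    user_ids = sorted({o.user_id for o in outcomes})
    results = []
    for outcome in ("mhd", "mmd", "amd"):
        matrix = []
        for uid in user_ids:
            row = [by_user_month.get((uid, m)) for m in timepoints]
            if any(o is None for o in row):
                continue
            matrix.append([getattr(o, outcome) for o in row])
        try:
            res = stats.repeated_measures_anova(matrix, outcome_name=outcome)
            results.append({"timepoints": timepoints,
                            **dataclasses.asdict(res)})
        except ValueError as exc:
            results.append({"timepoints": timepoints, "outcome_name": outcome,
                            "note": str(exc)})
    return results
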