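"""End-to-end cohort evaluation and report rendering.

``run_evaluation`` drives a whole cohort from a manifest: per-case
overlap metrics for each compartment, per-case semi-quantitative scores
with their decision path, cohort summaries (median and P25-P75 whole
tumor Dice, overall and per subgroup), Mann-Whitney subgroup tests on
Dice and chi-square tests on the score distributions. Cases that fail to
load or validate are skipped with a warning and counted, since clinical
cohorts routinely contain broken files.

``render_crosstab`` / ``render_subgroup_table`` format count tables the
way the clinical literature prints them: "count (percent)" cells with
marginal totals, percentages taken within each column.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort_stats import (
    CrossTab,
    DegenerateTableError,
    ScoreTable,
    score_summary,
    subgroup_compare,
)
from .mask_model import (
    CaseRecord,
    Compartment,
    load_case,
    read_manifest,
)
from .overlap_metrics import case_overlaps
from .semiquant import ScoringConfig, score_case

logger = logging.getLogger("segqa")

__all__ = [
    "RunConfig",
    "RunArtifacts",
    "evaluate_cases",
    "run_evaluation",
    "render_crosstab",
    "render_subgroup_table",
]


@dataclass
class RunConfig:
    manifest_path: str
    output_dir: str
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        scoring = ScoringConfig.from_dict(raw.pop("scoring", {}))
        return cls(scoring=scoring, **raw)

    def to_dict(self) -> dict:
        return {
            "manifest_path": str(self.manifest_path),
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "scoring": self.scoring.to_dict(),
        }


@dataclass
class RunArtifacts:
    metrics: pd.DataFrame
    scores: pd.DataFrame
    summary: dict
    n_skipped: int
    skipped: List[str]


def evaluate_cases(
    cases: Sequence[CaseRecord], cfg: Optional[ScoringConfig] = None
):
    """Per-case metric and score tables for an in-memory cohort."""
    cfg = cfg or ScoringConfig()
    metric_rows, score_rows = [], []
    for case in cases:
        overlaps = case_overlaps(case)
        for comp, res in overlaps.items():
            metric_rows.append(
                {
                    "case_id": case.case_id,
                    "compartment": comp.name,
                    "dice": res.dice,
                    "missing_fraction": res.missing_fraction,
                    "false_inclusion_fraction": res.false_inclusion_fraction,
                    "ref_volume_mm3": res.ref_volume_mm3,
                    "cand_volume_mm3": res.cand_volume_mm3,
                }
            )
        sq = score_case(case, cfg)
        score_rows.append(
            {
                "case_id": case.case_id,
                "status": case.status,
                "focality": case.focality,
                "score": sq.score,
                "pre_penalty_score": sq.pre_penalty_score,
                "initially_consistent": sq.initially_consistent,
                "penalty_applied": sq.penalty_applied,
                "wt_dice": sq.wt_dice,
                "false_inclusion": sq.false_inclusion,
                **{
                    f"missing_{k.lower()}": v
                    for k, v in sq.per_sequence_missing.items()
                },
            }
        )
    return pd.DataFrame(metric_rows), pd.DataFrame(score_rows)


def summarize_cohort(scores: pd.DataFrame) -> dict:
    """Cohort summary: WT Dice distribution overall and per subgroup,
    subgroup tests on Dice and on the ordinal scores."""
    wt = scores["wt_dice"].to_numpy(float)
    summary: dict = {
        "n_cases": int(len(scores)),
        "wt_dice": {
            "median": float(np.median(wt)),
            "sd": float(np.std(wt, ddof=1)) if len(wt) > 1 else 0.0,
            "p25": float(np.percentile(wt, 25)),
            "p75": float(np.percentile(wt, 75)),
        },
        "score_distribution": {
            int(s): int(c)
            for s, c in scores["score"].value_counts().sort_index().items()
        },
        "subgroups": {},
        "warnings": [],
    }
    if len(scores) >= 2:
        tab = ScoreTable.from_scores(scores["score"])
        summary["score_summary"] = score_summary(tab)
    for factor in ("status", "focality"):
        if scores[factor].nunique() < 2:
            summary["warnings"].append(f"single {factor} level; tests skipped")
            continue
        entry: dict = {}
        entry["dsc"] = subgroup_compare(scores, factor, "dsc")
        try:
            res = subgroup_compare(scores, factor, "semiquant")
            entry["semiquant"] = {
                k: v for k, v in res.items() if k != "table"
            }
        except DegenerateTableError as exc:
            summary["warnings"].append(f"{factor} score table degenerate: {exc}")
        summary["subgroups"][factor] = entry
    return summary


def run_evaluation(cfg: RunConfig) -> RunArtifacts:
    """Evaluate every case in the manifest and write all artifacts."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(cfg.manifest_path)
    cases, skipped = [], []
    for _, row in manifest.iterrows():
        try:
            cases.append(load_case(row))
        except Exception as exc:  # noqa: BLE001 - warn-and-continue policy
            logger.warning("skipping case %s: %s", row["case_id"], exc)
            skipped.append(str(row["case_id"]))
    if not cases:
        raise ValueError("no loadable cases in manifest")
    metrics, scores = evaluate_cases(cases, cfg.scoring)
    summary = summarize_cohort(scores)
    summary["n_skipped"] = len(skipped)
    summary["skipped_cases"] = skipped

    metrics.to_csv(out / "case_metrics.csv", index=False)
    scores.to_csv(out / "case_scores.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)
    with open(out / "config_used.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)
    return RunArtifacts(metrics, scores, summary, len(skipped), skipped)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _fmt_cell(count: int, denom: int) -> str:
    pct = 100.0 * count / denom if denom else 0.0
    return f"{count} ({pct:.2f})"


def render_crosstab(ct: CrossTab, row_name: str = "a", col_name: str = "b") -> pd.DataFrame:
    """Format a cross-tab as 'count (percent)' cells: cell percentages
    within each column, marginal Total row/column as percent of the
    grand total."""
    col_tot = ct.col_totals
    grand = ct.n
    data = {}
    for j, col in enumerate(ct.cols):
        data[str(col)] = [
            _fmt_cell(int(ct.cells[i, j]), int(col_tot[j]))
            for i in range(len(ct.rows))
        ] + [str(int(col_tot[j]))]
    data["Total"] = [
        _fmt_cell(int(t), grand) for t in ct.row_totals
    ] + [str(grand)]
    index = [str(r) for r in ct.rows] + ["Total"]
    df = pd.DataFrame(data, index=index)
    df.index.name = f"{row_name} \\ {col_name}"
    return df


def render_subgroup_table(ct: CrossTab, p_value: Optional[float] = None) -> pd.DataFrame:
    """Score-by-level table with column percentages and totals; optionally
    annotates the chi-square p value."""
    df = render_crosstab(ct, row_name="score", col_name="level")
    if p_value is not None:
        star = "*" if p_value < 0.05 else ""
        df["P value"] = [f"{p_value:.3f}{star}"] + [""] * (len(df) - 1)
    return df


def frame_to_markdown(df: pd.DataFrame) -> str:
    """Minimal GitHub-style markdown table (index included)."""
    header = [df.index.name or ""] + [str(c) for c in df.columns]
    lines = ["| " + " | ".join(header) + " |",
             "|" + "|".join(["---"] * len(header)) + "|"]
    for idx, row in df.iterrows():
        lines.append("| " + " | ".join([str(idx)] + [str(v) for v in row]) + " |")
    return "\n".join(lines) + "\n"
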