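"""End-to-end orchestration: ingest or simulate, score, categorize, analyze.

:func:`run_pipeline` runs the whole workflow and writes a result bundle:

* ``ei_results.csv`` — per participant: subindices, EI, category;
* ``category_summary.csv`` — per-category descriptive statistics;
* ``univariate.csv`` — the univariate screen (both test branches);
* ``model_full.csv`` / ``model_reduced.csv`` — regression tables;
* ``trend_table.csv`` — cohort-mean per-period components;
* ``run_metadata.json`` — config echo, seed, conventions (loyalty
  convention, percentile rule, boundary rule), cut-points, row counts.

Every convention that shaped the numbers is recorded in the metadata so a
run is auditable and exactly repeatable.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import data_model
from .determinants import (DEFAULT_VARIABLES, RETAIN_ALPHA, SCREEN_ALPHA,
                           dichotomize, fit_full_model, fit_reduced_model,
                           screened_variables, summarize_by_category,
                           univariate_screen, univariate_table)
from .engagement_index import (PERCENTILE_METHOD, Cutpoints, categorize_frame,
                               cohort_cutpoints, combine_frame)
from .subindices import DEFAULT_SCORING_KEY, EngagementConfig, score_cohort
from .synthetic_cohort import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["participant_id", "ci", "li", "ii", "ri", "fi",
                  "n_subindices_used", "ei", "category"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; exactly one input source."""

    output_dir: str | Path = "results"
    seed: int = 0
    simulation: SimulationConfig | None = None
    input_paths: Mapping[str, str] | None = None  # registry/sessions/messages/surveys
    schema_config: Mapping[str, Mapping[str, str]] | None = None
    engagement: EngagementConfig = field(default_factory=EngagementConfig)
    screen_alpha: float = SCREEN_ALPHA
    retain_alpha: float = RETAIN_ALPHA
    cutpoints_override: tuple[float, float] | None = None

    def validate(self) -> "RunConfig":
        if (self.simulation is None) == (self.input_paths is None):
            raise ValueError("provide exactly one of simulation or input_paths")
        for name in ("screen_alpha", "retain_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        return self


def trend_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Cohort-mean per-period components (the attrition/decay profile)."""
    if len(scores) == 0:
        raise ValueError("cannot compute trends for an empty cohort")
    rows = []
    for j in (1, 2, 3):
        rows.append({
            "period": j,
            "mean_click_depth": float(scores[f"c{j}"].mean()),
            "mean_loyalty": float(scores[f"l{j}"].mean()),
            "mean_interaction": float(scores[f"i{j}"].mean()),
            "mean_recency": float(scores[f"r{j}"].mean()),
        })
    return pd.DataFrame(rows)


def _load_dataset(cfg: RunConfig):
    if cfg.simulation is not None:
        sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        dataset, truth = simulate_cohort(sim)
        return dataset, truth
    paths = cfg.input_paths
    dataset = data_model.read_cohort(
        paths["registry"], paths["sessions"], paths["messages"],
        paths["surveys"], cfg.schema_config)
    return dataset, None


def run_pipeline(run_config: RunConfig) -> dict:
    """Run the full workflow; returns the in-memory results and writes files."""
    cfg = run_config.validate()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    dataset, truth = _load_dataset(cfg)
    scores = score_cohort(dataset, cfg.engagement, DEFAULT_SCORING_KEY)
    results = combine_frame(scores)

    if cfg.cutpoints_override is not None:
        cutpoints = Cutpoints(*cfg.cutpoints_override)
    else:
        cutpoints = cohort_cutpoints(results["ei"])
    results = categorize_frame(results, cutpoints)

    analysis = dichotomize(dataset.participants)
    analysis = analysis.merge(
        results[["participant_id", "ei", "category"]], on="participant_id")
    screen = univariate_screen(analysis)
    screened = [v for v in screened_variables(screen, cfg.screen_alpha)]
    full = fit_full_model(analysis, screened)
    reduced = fit_reduced_model(analysis, full, alpha=cfg.retain_alpha)
    summary = summarize_by_category(analysis, screen=screen)
    trends = trend_table(scores)

    data_model.write_table(results[RESULT_COLUMNS], out_dir / "ei_results.csv")
    data_model.write_table(summary, out_dir / "category_summary.csv")
    data_model.write_table(univariate_table(screen), out_dir / "univariate.csv")
    data_model.write_table(full.to_frame(), out_dir / "model_full.csv")
    data_model.write_table(reduced.to_frame(), out_dir / "model_reduced.csv")
    data_model.write_table(trends, out_dir / "trend_table.csv")
    if truth is not None:
        data_model.write_table(truth.frame, out_dir / "ground_truth.csv")

    metadata = {
        "seed": cfg.seed,
        "n_participants": int(len(dataset.participants)),
        "rows": {name: int(len(getattr(dataset, name)))
                 for name in ("participants", "sessions", "messages", "surveys")},
        "read_report": dataset.report.to_dict() if dataset.report else None,
        "engagement_config": {
            "page_threshold": cfg.engagement.page_threshold,
            "loyalty_convention": cfg.engagement.loyalty_convention,
            "interaction_channels": sorted(cfg.engagement.interaction_channels),
            "recency_zero_day_value": cfg.engagement.recency_zero_day_value,
            "period_boundaries_weeks": list(cfg.engagement.period_boundaries_weeks),
        },
        "conventions": {
            "percentile_method": PERCENTILE_METHOD,
            "category_boundaries": "poor: ei <= q1; high: ei >= q3",
            "normalization": "ei = 100 * mean(available subindices)",
        },
        "cutpoints": {"q1": cutpoints.q1, "q3": cutpoints.q3,
                      "overridden": cfg.cutpoints_override is not None},
        "screen_alpha": cfg.screen_alpha,
        "retain_alpha": cfg.retain_alpha,
        "screened_variables": screened,
        "reduced_model_variables": reduced.variables,
        "simulation": (dataclasses.asdict(
            dataclasses.replace(cfg.simulation, seed=cfg.seed))
            if cfg.simulation is not None else None),
    }
    (out_dir / "run_metadata.json").write_text(
        json.dumps(metadata, indent=2, default=str))
    logger.info("pipeline complete: %d participants scored, cutpoints "
                "(%.2f, %.2f)", len(results), cutpoints.q1, cutpoints.q3)
    return {
        "dataset": dataset, "truth": truth, "scores": scores,
        "results": results, "cutpoints": cutpoints, "screen": screen,
        "full_model": full, "reduced_model": reduced, "summary": summary,
        "trends": trends, "metadata": metadata,
    }
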