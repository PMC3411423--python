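"""End-to-end audit pipeline: simulate/load -> score -> concordance -> psychometrics."""

from __future__ import annotations

import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .bank import load_banks
from .cohort import (Cohort, read_cohort, summarize_cohort, validate_cohort,
                     write_cohort)
from .concordance import (apply_exclusions, classify_concordance,
                          em_impute_goals, fit_treatment_model, univariate_screen)
from .psychometrics import (content_validity, discriminant_validity,
                            feasibility_report, predictive_validity,
                            preference_gradient, retest_report)
from .scoring import item_diagnostics, score_cohort
from .simulate import GeneratorConfig, generate_cohort, generate_retest

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one audit run."""

    out_dir: str = "dq_audit"
    cohort_path: Optional[str] = None     # None -> simulate
    retest_path: Optional[str] = None
    bank_path: Optional[str] = None
    seed: int = 0
    item_set: str = "reduced"
    include_stage: bool = True
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    write_cohort_files: bool = False


def _jsonify(obj):
    """Make results JSON-serialisable; floats kept to 6 significant digits."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if np.isnan(f):
            return None
        return float(f"{f:.6g}")
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonify(obj.to_dict())
    return obj


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonify(obj), indent=2, sort_keys=True) + "\n")


def run_concordance(cohort: Cohort, *, include_stage: bool = True) -> dict:
    """Exclusions -> EM imputation -> logistic fit -> concordance classification."""
    analyzable, excluded = apply_exclusions(cohort)
    goal_ids = [g.goal_id for g in cohort.goal_bank if g.in_concordance_model]
    raw = np.array([[r.goal_ratings.get(g, np.nan) for g in goal_ids]
                    for r in analyzable], dtype=float)
    completed, em = em_impute_goals(raw)
    model = fit_treatment_model(analyzable, goal_ids, goal_matrix=completed,
                                include_stage=include_stage)
    result = classify_concordance(model, analyzable, excluded)
    screen = univariate_screen(analyzable, goal_ids, goal_matrix=raw)
    return {"analyzable": analyzable, "goal_ids": goal_ids, "goal_matrix": completed,
            "em": em, "model": model, "result": result, "univariate": screen}


def run_audit(config: PipelineConfig) -> dict:
    """Run the full audit and write the report bundle under ``config.out_dir``.

    Any stage failure aborts with the stage name and removes partial outputs.
    Returns the in-memory bundle (score set, diagnostics, concordance,
    psychometric report, manifest).
    """
    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    stage = "setup"
    warnings_seen: list = []
    try:
        stage = "load"
        if config.cohort_path:
            banks = load_banks(config.bank_path) if config.bank_path else (None, None)
            cohort = read_cohort(config.cohort_path, *banks)
            retest = (read_cohort(config.retest_path, cohort.item_bank, cohort.goal_bank)
                      if config.retest_path else None)
        else:
            cohort = generate_cohort(config.generator, config.seed)
            retest = generate_retest(cohort, config.generator, config.seed + 1)
            if config.write_cohort_files:
                write_cohort(cohort, out / "cohort.csv")
                write_cohort(retest, out / "cohort_retest.csv")
        validation = validate_cohort(cohort)
        if validation.orphan_retests:
            warnings_seen.append(f"{len(validation.orphan_retests)} orphan retest records")

        stage = "score"
        scores = {s: score_cohort(cohort, s) for s in ("reduced", "screener")}
        diagnostics = item_diagnostics(cohort)

        stage = "concordance"
        conc = run_concordance(cohort, include_stage=config.include_stage)
        if conc["model"].separation_flag:
            warnings_seen.append("treatment model flagged possible separation")

        stage = "psychometrics"
        provider_ratings = [r.demographics.get("coverage_rating")
                            for r in cohort.providers()]
        psych = {
            "content": content_validity(provider_ratings, cohort.patients("test"),
                                        cohort.goal_bank),
            "discriminant": discriminant_validity(scores["reduced"], cohort),
            "preference_gradient": preference_gradient(
                conc["result"],
                [r.preference for r in conc["analyzable"]]),
            "predictive": predictive_validity(conc["result"], cohort),
            "feasibility": feasibility_report(cohort),
        }
        if retest is not None:
            psych["reliability"] = retest_report(cohort, retest)

        stage = "report"
        summary = summarize_cohort(cohort)
        model = conc["model"]
        bundle = {
            "summary": summary,
            "scores": {s: {"group_summary": ss.group_summary,
                           "histograms": {g: {"edges": e, "counts": c}
                                          for g, (e, c) in ss.histograms.items()}}
                       for s, ss in scores.items()},
            "item_diagnostics": {"table": diagnostics.table,
                                 "floor_pct": diagnostics.floor_pct,
                                 "ceiling_pct": diagnostics.ceiling_pct,
                                 "recommended_reduced_set": diagnostics.recommended_reduced_set},
            "concordance": {
                "overall_pct": conc["result"].overall_pct,
                "by_arm_pct": conc["result"].by_arm_pct,
                "n_analyzable": conc["result"].n_analyzable,
                "excluded": conc["result"].excluded,
                "c_statistic": model.c_statistic,
                "or_table": model.or_table(),
                "univariate": conc["univariate"],
            },
            "psychometrics": psych,
        }
        dump_json(bundle, out / "report.json")
        diagnostics.table.to_csv(out / "item_diagnostics.csv", index=False)
        model.or_table().to_csv(out / "model_or_table.csv")
        scores["reduced"].scores.to_csv(out / "scores_reduced.csv", index=False)
        manifest = {
            "package_version": __version__,
            "generator_version": cohort.provenance.get("generator_version"),
            "seed": config.seed,
            "source": cohort.provenance.get("source"),
            "n_records": len(cohort.records),
            "warnings": warnings_seen,
            "elapsed_seconds": round(time.perf_counter() - t0, 3),
        }
        dump_json(manifest, out / "manifest.json")
        bundle["manifest"] = manifest
        return bundle
    except Exception as exc:
        # remove partial outputs so a failed run leaves nothing misleading
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for f in ("report.json", "manifest.json", "item_diagnostics.csv",
                      "model_or_table.csv", "scores_reduced.csv"):
                (out / f).unlink(missing_ok=True)
        raise RuntimeError(f"audit failed during stage {stage!r}: {exc}") from exc
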