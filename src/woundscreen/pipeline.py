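"""End-to-end glue: photograph → staples → ROI → redness → triage.

`analyze_image` runs the image-side pipeline (detect staples, inpaint or
mask them, score redness over the peri-wound band); `analyze_visit` adds
the questionnaire and triage fusion; `evaluate_cohort` batches the image
pipeline over a synthetic cohort and computes the diagnostic statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .evalstats import (
    ConfusionTable,
    DiagnosticMetrics,
    RocCurve,
    cohens_kappa,
    confusion,
    roc_and_cutoff,
    sensitivity_specificity,
)
from .errors import MetricError
from .imaging import WoundImage
from .questionnaire import QuestionnaireScore, score, validate_record
from .redness import RednessResult, score_redness
from .staples import StapleDetection, detect_staples, inpaint_staples
from .synth import CohortBundle
from .triage import TriageDecision, decide

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImageAnalysis:
    detection: StapleDetection
    redness: RednessResult
    roi_source: str            # "wound_band" | "whole_image"
    notes: list[str]


@dataclass(frozen=True)
class VisitAnalysis:
    image: ImageAnalysis
    qscore: QuestionnaireScore
    decision: TriageDecision


def analyze_image(image: WoundImage, config: RunConfig | None = None) -> ImageAnalysis:
    """Image-side screening: staples, ROI, redness proportion and call."""
    config = config or RunConfig()
    notes: list[str] = []
    if image.undersized:
        notes.append("image smaller than 500×500; analysed anyway")
        logger.warning("[%s] image below the 500×500 intake rule", image.source_id)

    detection = detect_staples(image, config.staples)
    if detection.roi_mask is not None:
        roi = detection.roi_mask
        roi_source = "wound_band"
    else:
        roi = np.ones(image.pixels.shape[:2], dtype=bool)
        roi_source = "whole_image"
        notes.append("axis undeterminable; fell back to whole-image ROI")

    scored = image
    if config.scoring_order == "inpaint" and detection.staple_mask.any():
        scored = inpaint_staples(
            image,
            detection.staple_mask,
            max_iterations=config.inpaint_max_iterations,
            tol=config.inpaint_tol,
        )
    elif config.scoring_order == "mask":
        roi = roi & ~detection.staple_mask
        if not roi.any():
            roi = np.ones(image.pixels.shape[:2], dtype=bool) & ~detection.staple_mask

    redness = score_redness(
        scored,
        roi,
        params=config.red,
        method=config.redness_method,
        threshold=config.redness_threshold,
    )
    return ImageAnalysis(detection=detection, redness=redness, roi_source=roi_source, notes=notes)


def analyze_visit(
    image: WoundImage, questionnaire_raw, config: RunConfig | None = None
) -> VisitAnalysis:
    """Full visit screening: image analysis plus questionnaire fusion."""
    config = config or RunConfig()
    record = validate_record(questionnaire_raw)
    qscore = score(record)
    img = analyze_image(image, config)
    decision = decide(img.redness, qscore, config.triage)
    return VisitAnalysis(image=img, qscore=qscore, decision=decision)


@dataclass(frozen=True)
class CohortEvaluation:
    table: ConfusionTable
    metrics: DiagnosticMetrics
    roc: RocCurve | None
    results: pd.DataFrame     # per image: id, score, prediction, truth

    def to_dict(self) -> dict:
        out = {
            "confusion": self.table.to_dict(),
            "metrics": self.metrics.to_dict(),
        }
        if self.roc is not None:
            out["roc"] = {
                "auc": self.roc.auc,
                "optimal_threshold": self.roc.optimal_threshold,
                "criterion": self.roc.criterion,
            }
        return out


def evaluate_cohort(
    bundle: CohortBundle,
    config: RunConfig | None = None,
    decision_level: str = "triage",
) -> CohortEvaluation:
    """Run the pipeline over a cohort and score it against ground truth.

    ``decision_level`` selects the prediction compared with truth:
    "triage" uses the fused decision, "image" the redness call alone.
    """
    config = config or RunConfig()
    records = []
    for row in bundle.rows:
        image, _ = row.render()
        if decision_level == "image":
            analysis = analyze_image(image, config)
            pred = int(analysis.redness.positive)
            proportion = analysis.redness.proportion
        else:
            visit = analyze_visit(image, row.questionnaire, config)
            pred = int(visit.decision.review_needed)
            proportion = visit.image.redness.proportion
        records.append(
            {
                "image_id": row.image_id,
                "patient_code": row.patient_code,
                "score": proportion,
                "prediction": pred,
                "truth": row.infected,
            }
        )
    df = pd.DataFrame(records)
    table = confusion(df["prediction"], df["truth"])
    try:
        metrics = sensitivity_specificity(table, ci=config.ci_method)
    except MetricError as exc:
        # single-class truth: emit the defined margin, flag the other
        from .evalstats import clopper_pearson

        pos, neg = table.tp + table.fn, table.tn + table.fp
        metrics = DiagnosticMetrics(
            sensitivity=table.tp / pos if pos else float("nan"),
            sensitivity_ci=clopper_pearson(table.tp, pos) if pos else (float("nan"),) * 2,
            specificity=table.tn / neg if neg else float("nan"),
            specificity_ci=clopper_pearson(table.tn, neg) if neg else (float("nan"),) * 2,
            notes=str(exc),
        )
    try:
        kappa = cohens_kappa(df["prediction"].to_numpy(), df["truth"].to_numpy())
        metrics = DiagnosticMetrics(
            sensitivity=metrics.sensitivity,
            sensitivity_ci=metrics.sensitivity_ci,
            specificity=metrics.specificity,
            specificity_ci=metrics.specificity_ci,
            kappa=kappa,
            notes=metrics.notes,
        )
    except MetricError:
        pass
    roc = None
    try:
        roc = roc_and_cutoff(df["score"], df["truth"], criterion=config.roc_criterion)
    except MetricError as exc:
        logger.warning("ROC skipped: %s", exc)
    return CohortEvaluation(table=table, metrics=metrics, roc=roc, results=df)
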