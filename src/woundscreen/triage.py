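"""Decision fusion: image redness + questionnaire → triage decision.

The patient-facing output is binary: "needs in-person review" versus
"satisfactory evolution".  The default fusion is disjunctive (OR) with
hard clinical flags — the screening is deliberately sensitivity-first, so
any single trigger (positive image, an alarming symptom, high pain or a
symptom burden) sends the patient to review.  The symptom-count and VAS
cutoffs are artifact calibration constants, not clinically validated
values; they are surfaced in the policy for exactly that reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .questionnaire import BINARY_ITEMS, QuestionnaireScore
from .redness import RednessResult

#: Symptoms that alone mandate review under the default policy.
DEFAULT_HARD_FLAGS = ("opening", "secretion", "fever")


@dataclass(frozen=True)
class TriagePolicy:
    mode: str = "OR"  # "OR" | "image_only" | "questionnaire_only"
    hard_flags: tuple[str, ...] = DEFAULT_HARD_FLAGS
    symptom_count_cutoff: int = 3
    vas_cutoff: int = 7

    def __post_init__(self) -> None:
        if self.mode not in ("OR", "image_only", "questionnaire_only"):
            raise ValueError(f"unknown triage mode {self.mode!r}")
        bad = set(self.hard_flags) - set(BINARY_ITEMS)
        if bad:
            raise ValueError(f"hard flags not questionnaire items: {sorted(bad)}")
        if not (0 <= self.symptom_count_cutoff <= 6):
            raise ValueError("symptom_count_cutoff must lie in 0..6")
        if not (0 <= self.vas_cutoff <= 10):
            raise ValueError("vas_cutoff must lie in 0..10")


@dataclass(frozen=True)
class TriageDecision:
    review_needed: bool
    reasons: list[str]
    inputs_summary: dict

    def to_dict(self) -> dict:
        return {
            "review_needed": self.review_needed,
            "decision": "needs in-person review"
            if self.review_needed
            else "satisfactory evolution",
            "reasons": list(self.reasons),
            "inputs_summary": dict(self.inputs_summary),
        }


def decide(
    redness: RednessResult,
    qscore: QuestionnaireScore,
    policy: TriagePolicy | None = None,
) -> TriageDecision:
    """Fuse the image call and questionnaire into the triage decision.

    Under "OR" mode, review is needed iff the redness call is positive, or
    any hard-flag symptom is present, or the symptom count or VAS reach
    their cutoffs; ``reasons`` enumerates every trigger.  The restricted
    modes consider only the image or only the questionnaire.
    """
    policy = policy or TriagePolicy()
    if redness.positive is None:
        raise ValueError("redness result is unclassified; apply a threshold first")

    image_reasons: list[str] = []
    if redness.positive:
        image_reasons.append("redness ≥ threshold")

    q_reasons: list[str] = []
    for flag in policy.hard_flags:
        if qscore.items.get(flag, 0) == 1:
            q_reasons.append(f"hard flag: {flag}")
    if qscore.symptom_count >= policy.symptom_count_cutoff:
        q_reasons.append(
            f"symptom count {qscore.symptom_count} ≥ {policy.symptom_count_cutoff}"
        )
    if qscore.vas >= policy.vas_cutoff:
        q_reasons.append(f"VAS {qscore.vas} ≥ {policy.vas_cutoff}")

    if policy.mode == "image_only":
        reasons = image_reasons
    elif policy.mode == "questionnaire_only":
        reasons = q_reasons
    else:
        reasons = image_reasons + q_reasons

    return TriageDecision(
        review_needed=bool(reasons),
        reasons=reasons,
        inputs_summary={
            "redness_proportion": redness.proportion,
            "redness_threshold": redness.threshold,
            "symptom_count": qscore.symptom_count,
            "vas": qscore.vas,
            "fever_flag": qscore.fever_flag,
        },
    )
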