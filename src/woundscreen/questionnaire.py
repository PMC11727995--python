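"""Symptom questionnaire validation and scoring.

Each visit records a pain VAS (0–10) and six binary items: redness,
burning, wound opening, swelling, liquid secretion and fever.  Fever may
arrive as a 0/1 answer or as a raw temperature in °C, coded 1 strictly
above 37.7 °C.  The screening gate is hard: every item must be answered,
and nothing is imputed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping

from .errors import CodingError, IncompleteQuestionnaireError

logger = logging.getLogger(__name__)

#: The six binary symptom items, in reporting order.
BINARY_ITEMS = ("redness", "burning", "opening", "swelling", "secretion", "fever")

FEVER_THRESHOLD_C = 37.7
_TEMP_SANITY = (30.0, 45.0)
_INT_RE = re.compile(r"^[+-]?\d+$")

_ALLOWED_KEYS = frozenset(BINARY_ITEMS) | {
    "vas",
    "temperature_c",
    "timestamp",
    "patient_code",
}


@dataclass(frozen=True)
class QuestionnaireRecord:
    """A validated per-visit questionnaire."""

    vas: int
    redness: int
    burning: int
    opening: int
    swelling: int
    secretion: int
    fever: int
    temperature_c: float | None = None
    timestamp: str | None = None
    patient_code: str = ""

    def items(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in BINARY_ITEMS}


@dataclass(frozen=True)
class QuestionnaireScore:
    """Coded summary: symptom count, pain VAS and the fever flag."""

    symptom_count: int
    vas: int
    fever_flag: int
    items: dict[str, int]


def fever_from_temperature(temp_c: float) -> int:
    """Fever coding from a raw temperature: 1 iff strictly above 37.7 °C."""
    temp_c = float(temp_c)
    if not (_TEMP_SANITY[0] <= temp_c <= _TEMP_SANITY[1]):
        raise CodingError(
            f"temperature {temp_c} °C outside sanity window {_TEMP_SANITY}"
        )
    return int(temp_c > FEVER_THRESHOLD_C)


def _coerce_int(name: str, value) -> int:
    if isinstance(value, bool):
        return int(value)
    if isinstance(value, int):
        return value
    if isinstance(value, float) and value.is_integer():
        return int(value)
    if isinstance(value, str) and _INT_RE.match(value.strip()):
        return int(value.strip())
    raise CodingError(f"{name}: expected an integer code, got {value!r}")


def validate_record(raw: Mapping) -> QuestionnaireRecord:
    """Validate a raw key→answer mapping into a QuestionnaireRecord.

    Raises :class:`IncompleteQuestionnaireError` when any of the seven
    required answers is missing (fever counts as answered when a raw
    temperature is supplied), and :class:`CodingError` for out-of-range or
    non-binary values and for unknown keys.  When both a fever answer and
    a temperature are given and disagree, the temperature wins (the coding
    rule is temperature-defined) and a warning is logged.
    """
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        raise CodingError(f"unknown questionnaire keys: {sorted(unknown)}")

    if "vas" not in raw or raw["vas"] is None:
        raise IncompleteQuestionnaireError("incomplete questionnaire: missing 'vas'")
    vas = _coerce_int("vas", raw["vas"])
    if not (0 <= vas <= 10):
        raise CodingError(f"vas {vas} outside the 0-10 scale")

    values: dict[str, int] = {}
    for item in BINARY_ITEMS[:-1]:
        if item not in raw or raw[item] is None:
            raise IncompleteQuestionnaireError(
                f"incomplete questionnaire: missing {item!r}"
            )
        v = _coerce_int(item, raw[item])
        if v not in (0, 1):
            raise CodingError(f"{item}: expected 0/1, got {v}")
        values[item] = v

    temp = raw.get("temperature_c")
    fever_answer = raw.get("fever")
    if temp is None and fever_answer is None:
        raise IncompleteQuestionnaireError("incomplete questionnaire: missing 'fever'")
    if temp is not None:
        temp = float(temp)
        fever = fever_from_temperature(temp)
        if fever_answer is not None:
            declared = _coerce_int("fever", fever_answer)
            if declared not in (0, 1):
                raise CodingError(f"fever: expected 0/1, got {declared}")
            if declared != fever:
                logger.warning(
                    "fever answer %d inconsistent with temperature %.1f °C; "
                    "temperature rule applied",
                    declared,
                    temp,
                )
    else:
        fever = _coerce_int("fever", fever_answer)
        if fever not in (0, 1):
            raise CodingError(f"fever: expected 0/1, got {fever}")

    return QuestionnaireRecord(
        vas=vas,
        temperature_c=temp,
        timestamp=raw.get("timestamp"),
        patient_code=str(raw.get("patient_code", "")),
        fever=fever,
        **{k: values[k] for k in BINARY_ITEMS[:-1]},
    )


def score(record: QuestionnaireRecord) -> QuestionnaireScore:
    """Summarise a validated record: symptom count, VAS, fever flag."""
    items = record.items()
    return QuestionnaireScore(
        symptom_count=sum(items.values()),
        vas=record.vas,
        fever_flag=record.fever,
        items=items,
    )
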