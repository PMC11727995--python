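"""Run configuration: one resolvable object covering every module default.

Every command emits the fully-resolved configuration next to its outputs
so that any run can be reproduced from the emitted config plus the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .redness import DEFAULT_THRESHOLD, RedMembershipParams
from .staples import StapleParams
from .triage import TriagePolicy


@dataclass(frozen=True)
class RunConfig:
    staples: StapleParams = field(default_factory=StapleParams)
    red: RedMembershipParams = field(default_factory=RedMembershipParams)
    triage: TriagePolicy = field(default_factory=TriagePolicy)
    redness_threshold: float = DEFAULT_THRESHOLD
    redness_method: str = "crisp"          # "crisp" | "weighted"
    scoring_order: str = "inpaint"         # "inpaint" | "mask"
    roi_fallback: str = "whole_image"      # when no wound axis is found
    inpaint_max_iterations: int = 500
    inpaint_tol: float = 1e-5
    ci_method: str = "clopper-pearson"
    roc_criterion: str = "youden"
    seed: int = 0

    def resolved(self) -> dict:
        """Plain-dict view of every effective parameter."""
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.resolved(), fh, indent=2, default=str)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a YAML (or JSON, a YAML subset) config file.

        Top-level keys mirror the dataclass fields; the nested ``staples``,
        ``red`` and ``triage`` blocks take those dataclasses' field names.
        """
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {}
        if "staples" in data:
            kwargs["staples"] = StapleParams(**data.pop("staples"))
        if "red" in data:
            kwargs["red"] = RedMembershipParams(**data.pop("red"))
        if "triage" in data:
            block = data.pop("triage")
            if "hard_flags" in block:
                block["hard_flags"] = tuple(block["hard_flags"])
            kwargs["triage"] = TriagePolicy(**block)
        kwargs.update(data)
        return cls(**kwargs)
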