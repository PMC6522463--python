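"""Delimitation report objects and their JSON round-trip.

A :class:`DelimitationReport` holds, for every candidate species label, the
verdict on each of the five recognition criteria together with the evidence
consulted, plus any merge recommendations produced by the lumping
recommender and the parameters of the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional

CRITERIA = (
    "monophyly",
    "genealogical",
    "distinctness",
    "minimal_sampling",
    "polygenic_differentiation",
)

PASS, FAIL, NOT_ASSESSABLE = "pass", "fail", "not_assessable"


@dataclass
class CriterionResult:
    """Verdict of one criterion for one candidate, with evidence.

    ``evidence`` is a JSON-serializable dict that always names the loci or
    trees consulted.
    """

    criterion: str
    verdict: str
    evidence: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.verdict not in (PASS, FAIL, NOT_ASSESSABLE):
            raise ValueError(f"unknown verdict {self.verdict!r}")

    def to_dict(self) -> Dict[str, Any]:
        return {
            "criterion": self.criterion,
            "verdict": self.verdict,
            "evidence": self.evidence,
        }

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "CriterionResult":
        return cls(d["criterion"], d["verdict"], d.get("evidence", {}))


@dataclass
class CandidateReport:
    """All five criterion results for one candidate label."""

    label: str
    members: List[str]
    comparator: Optional[str]  # sister or nearest candidate used
    criteria: List[CriterionResult]

    @property
    def overall(self) -> str:
        """``pass`` iff every assessable criterion passes.

        ``not_assessable`` criteria are listed but do not block a pass.
        """
        verdicts = [c.verdict for c in self.criteria]
        if FAIL in verdicts:
            return FAIL
        if PASS in verdicts:
            return PASS
        return NOT_ASSESSABLE

    @property
    def failed_criteria(self) -> List[str]:
        return [c.criterion for c in self.criteria if c.verdict == FAIL]

    def criterion(self, name: str) -> CriterionResult:
        for c in self.criteria:
            if c.criterion == name:
                return c
        raise KeyError(name)

    def to_dict(self) -> Dict[str, Any]:
        return {
            "label": self.label,
            "members": sorted(self.members),
            "comparator": self.comparator,
            "overall": self.overall,
            "criteria": [c.to_dict() for c in self.criteria],
        }

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "CandidateReport":
        return cls(
            d["label"],
            list(d["members"]),
            d.get("comparator"),
            [CriterionResult.from_dict(c) for c in d["criteria"]],
        )


@dataclass
class DelimitationReport:
    """Per-candidate verdicts plus merge recommendations and parameters."""

    candidates: List[CandidateReport]
    merge_recommendations: List[List[str]] = field(default_factory=list)
    parameters: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.merge_recommendations = [
            sorted(set(g)) for g in self.merge_recommendations
        ]
        for group in self.merge_recommendations:
            if len(group) < 2:
                raise ValueError("merge recommendation needs >= 2 labels")

    def candidate(self, label: str) -> CandidateReport:
        for c in self.candidates:
            if c.label == label:
                return c
        raise KeyError(label)

    @property
    def labels(self) -> List[str]:
        return [c.label for c in self.candidates]

    def to_dict(self) -> Dict[str, Any]:
        return {
            "candidates": [c.to_dict() for c in self.candidates],
            "merge_recommendations": self.merge_recommendations,
            "parameters": self.parameters,
        }

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "DelimitationReport":
        return cls(
            [CandidateReport.from_dict(c) for c in d["candidates"]],
            [list(g) for g in d.get("merge_recommendations", [])],
            d.get("parameters", {}),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DelimitationReport":
        return cls.from_dict(json.loads(text))

    def summary(self) -> str:
        """Human-readable text summary, one block per candidate."""
        lines: List[str] = []
        lines.append("Phylospecies delimitation report")
        lines.append(f"  candidates: {len(self.candidates)}")
        for cand in self.candidates:
            lines.append("")
            lines.append(
                f"candidate {cand.label}  (n={len(cand.members)}, "
                f"comparator={cand.comparator or 'none'})  "
                f"overall: {cand.overall.upper()}"
            )
            for c in cand.criteria:
                lines.append(f"  {c.criterion:28s} {c.verdict}")
            if cand.failed_criteria:
                lines.append(
                    "  failed: " + ", ".join(cand.failed_criteria)
                )
        lines.append("")
        if self.merge_recommendations:
            for group in self.merge_recommendations:
                lines.append("recommend merging: " + " + ".join(group))
        else:
            lines.append("no merges recommended")
        return "\n".join(lines) + "\n"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DelimitationReport)
            and self.to_dict() == other.to_dict()
        )
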