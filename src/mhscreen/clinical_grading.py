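"""Clinical grading of a suspected malignant-hyperthermia episode.

A point-based grading scale maps observed clinical indicators (muscle
rigidity, muscle breakdown, respiratory acidosis, temperature rise,
metabolic acidosis, ...) to a score and a qualitative likelihood rank.
Both the indicator->points table and the rank boundaries are
configuration: the shipped default carries only five well-anchored
indicators, each in its own physiological process category, and the
conventional six qualitative ranks with "almost certain" starting at 50
points.  Fuller published scales can be supplied as a YAML config file.

Under the ``max_per_category`` rule only the highest-scoring observed
indicator in each process category contributes (double counting within a
process is avoided); under ``sum_all`` every observed indicator counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import yaml


class CategoryRule(str, Enum):
    sum_all = "sum_all"
    max_per_category = "max_per_category"


@dataclass(frozen=True)
class Indicator:
    id: str
    category: str
    points: int

    def __post_init__(self) -> None:
        if self.points < 0:
            raise ValueError(f"indicator {self.id}: points must be >= 0")


@dataclass
class GradingScale:
    indicators: list[Indicator]
    rank_boundaries: list[tuple[int, str]]
    category_rule: CategoryRule = CategoryRule.sum_all

    def __post_init__(self) -> None:
        ids = [i.id for i in self.indicators]
        if len(set(ids)) != len(ids):
            raise ValueError("indicator ids must be unique")
        if not self.rank_boundaries:
            raise ValueError("rank table is empty")
        self.rank_boundaries = sorted(
            [(int(s), str(l)) for s, l in self.rank_boundaries])
        scores = [s for s, _ in self.rank_boundaries]
        if len(set(scores)) != len(scores):
            raise ValueError("rank boundaries must be strictly increasing")
        self.category_rule = CategoryRule(self.category_rule)

    def indicator_ids(self) -> set[str]:
        return {i.id for i in self.indicators}


@dataclass
class CaseIndicators:
    observed: set[str]


def default_scale() -> GradingScale:
    """Five-indicator default scale with conventional rank boundaries.

    The indicator points (15 points each for masseter spasm, creatine-
    kinase elevation, respiratory acidosis and inappropriate temperature
    increase, 10 points for metabolic acidosis) cover the classic
    presentation; each sits in its own process category, so the
    ``sum_all`` and ``max_per_category`` rules agree on this default.
    """
    return GradingScale(
        indicators=[
            Indicator("masseter_spasm", "muscle_rigidity", 15),
            Indicator("ck_elevation", "muscle_breakdown", 15),
            Indicator("respiratory_acidosis", "carbon_dioxide", 15),
            Indicator("inappropriate_temperature_increase", "temperature", 15),
            Indicator("metabolic_acidosis", "acid_base", 10),
        ],
        rank_boundaries=[
            (0, "almost never"),
            (3, "unlikely"),
            (10, "somewhat less than likely"),
            (20, "somewhat greater than likely"),
            (35, "very likely"),
            (50, "almost certain"),
        ],
        category_rule=CategoryRule.sum_all,
    )


def grade_case(case: CaseIndicators, scale: GradingScale) -> tuple[int, str]:
    """Score a case against a grading scale and map the score to a rank."""
    unknown = case.observed - scale.indicator_ids()
    if unknown:
        raise ValueError(f"unknown indicator ids: {sorted(unknown)}")
    observed = [i for i in scale.indicators if i.id in case.observed]
    if scale.category_rule is CategoryRule.sum_all:
        score = sum(i.points for i in observed)
    else:
        best: dict[str, int] = {}
        for ind in observed:
            best[ind.category] = max(best.get(ind.category, 0), ind.points)
        score = sum(best.values())
    rank = scale.rank_boundaries[0][1]
    for min_score, label in scale.rank_boundaries:
        if score >= min_score:
            rank = label
    return score, rank


def load_scale(path: str | Path) -> GradingScale:
    """Load a grading scale from a YAML config file.

    Expected structure::

        category_rule: sum_all            # or max_per_category
        indicators:
          - {id: masseter_spasm, category: muscle_rigidity, points: 15}
        rank_boundaries:
          - {min_score: 0, rank: almost never}
    """
    payload = yaml.safe_load(Path(path).read_text())
    return GradingScale(
        indicators=[
            Indicator(d["id"], d["category"], int(d["points"]))
            for d in payload["indicators"]
        ],
        rank_boundaries=[
            (int(d["min_score"]), str(d["rank"]))
            for d in payload["rank_boundaries"]
        ],
        category_rule=CategoryRule(payload.get("category_rule", "sum_all")),
    )


def save_scale(scale: GradingScale, path: str | Path) -> None:
    payload = {
        "category_rule": scale.category_rule.value,
        "indicators": [
            {"id": i.id, "category": i.category, "points": i.points}
            for i in scale.indicators
        ],
        "rank_boundaries": [
            {"min_score": s, "rank": l} for s, l in scale.rank_boundaries
        ],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
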