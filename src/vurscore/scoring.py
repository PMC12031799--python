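"""From screened associations to the integer risk score.

Variable selection first applies the significance gate (p < alpha), then
collapses each *collinearity group* -- a set of logically nested variables
that measure the same clinical axis -- to its single highest-OR member.
The default groups are:

* ``ultrasound``: abnormal USG > hydronephrosis > UTD-P3 dilatation
* ``scintigraphy``: any scar > multiple scars (both require a DMSA scan)
* ``infection``: UTI > recurrent UTI / non-E. coli uropathogen

Weights are the selected odds ratios divided by the smallest selected OR,
rounded half-up and clamped to {1, ..., ceiling} (ceiling 2 by default), so
the score of a patient is a small integer sum; a predictor that is undefined
for a patient (scar variables without DMSA) contributes 0, capping the
achievable maximum for that patient.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import AssociationResult
from .cohort import Cohort, PatientRecord
from .errors import ModelDegenerateError, ParameterError

#: Which availability flag each predictor needs (missing flag => predictor NA).
MODALITY_REQUIREMENTS: Mapping[str, str] = {
    "any_scar": "dmsa_done",
    "multiple_scars": "dmsa_done",
}


@dataclass(frozen=True)
class CollinearityGroups:
    """Named, disjoint sets of interchangeable candidate variables.

    Candidates not listed in any group act as singletons.
    """

    groups: Mapping[str, tuple[str, ...]]

    def __post_init__(self):
        seen: dict[str, str] = {}
        for name, members in self.groups.items():
            for v in members:
                if v in seen:
                    raise ParameterError(
                        f"variable {v!r} appears in groups {seen[v]!r} and {name!r}"
                    )
                seen[v] = name

    def group_of(self, variable: str) -> str:
        """Group name containing *variable* (its own name if a singleton)."""
        for name, members in self.groups.items():
            if variable in members:
                return name
        return variable


DEFAULT_GROUPS = CollinearityGroups(
    {
        "infection": ("uti", "recurrent_uti", "non_ecoli"),
        "ultrasound": ("usg_abnormal", "hydronephrosis", "utd_p3"),
        "scintigraphy": ("any_scar", "multiple_scars"),
    }
)


def select_variables(
    results: Sequence[AssociationResult],
    groups: CollinearityGroups = DEFAULT_GROUPS,
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Significance gate, then one highest-OR variable per collinearity group.

    Returns the retained results in input order. Ties inside a group keep the
    variable listed first. An empty selection raises
    :class:`ModelDegenerateError`.
    """
    significant = [r for r in results if r.p_value < alpha]
    best: dict[str, AssociationResult] = {}
    for r in significant:
        g = groups.group_of(r.variable)
        if g not in best or r.or_point > best[g].or_point:
            best[g] = r
    kept = {r.variable for r in best.values()}
    selected = [r for r in results if r.variable in kept]
    if not selected:
        raise ModelDegenerateError(
            f"no variable passed the screen at alpha={alpha}"
        )
    return selected


@dataclass(frozen=True)
class WeightSpec:
    """The fitted scoring model: ordered variable -> integer weight."""

    entries: Mapping[str, int]
    ors: Mapping[str, float]
    min_or_anchor: float
    ceiling: int = 2

    @property
    def max_score(self) -> int:
        return sum(self.entries.values())

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def capped_max_score(self, missing_flag: str) -> int:
        """Maximum achievable score when *missing_flag* modality is absent."""
        lost = sum(
            w
            for v, w in self.entries.items()
            if MODALITY_REQUIREMENTS.get(v) == missing_flag
        )
        return self.max_score - lost

    def to_json(self, path) -> None:
        payload = {
            "entries": {v: int(w) for v, w in self.entries.items()},
            "ors": {v: float(o) for v, o in self.ors.items()},
            "min_or_anchor": float(self.min_or_anchor),
            "ceiling": int(self.ceiling),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "WeightSpec":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            entries=dict(payload["entries"]),
            ors=dict(payload["ors"]),
            min_or_anchor=float(payload["min_or_anchor"]),
            ceiling=int(payload.get("ceiling", 2)),
        )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def assign_weights(
    selected: Sequence[AssociationResult] | Mapping[str, float],
    ceiling: int = 2,
) -> WeightSpec:
    """OR-ratio weights: ``w_i = clamp(round_half_up(OR_i / min OR), 1, ceiling)``.

    Accepts either screened results or a plain ``{variable: OR}`` mapping.
    """
    if isinstance(selected, Mapping):
        ors = dict(selected)
    else:
        ors = {r.variable: r.or_point for r in selected}
    if not ors:
        raise ModelDegenerateError("cannot assign weights to an empty selection")
    if ceiling < 1:
        raise ParameterError(f"weight ceiling must be >= 1, got {ceiling}")
    for v, o in ors.items():
        if not (o > 0) or not np.isfinite(o):
            raise ParameterError(f"odds ratio for {v!r} must be positive, got {o}")
    anchor = min(ors.values())
    entries = {
        v: max(1, min(ceiling, _round_half_up(o / anchor))) for v, o in ors.items()
    }
    return WeightSpec(entries=entries, ors=ors, min_or_anchor=anchor, ceiling=ceiling)


def compute_score(record: PatientRecord, spec: WeightSpec) -> int:
    """Weighted sum of the record's selected predictors; missing counts 0."""
    total = 0
    for variable, weight in spec.entries.items():
        value = record.get(variable)  # SchemaError if unknown
        if value:
            total += weight
    return total


@dataclass(frozen=True)
class ScoreDistribution:
    """Per-score counts split by outcome: ``n0[s]`` negatives, ``n1[s]`` positives."""

    n0: tuple[int, ...]
    n1: tuple[int, ...]

    def __post_init__(self):
        if len(self.n0) != len(self.n1) or len(self.n0) == 0:
            raise ParameterError("n0 and n1 must be equal-length, non-empty")
        if any(v < 0 for v in self.n0 + self.n1):
            raise ParameterError("score counts must be non-negative")

    @property
    def max_score(self) -> int:
        return len(self.n0) - 1

    @property
    def n_neg(self) -> int:
        return int(sum(self.n0))

    @property
    def n_pos(self) -> int:
        return int(sum(self.n1))

    @property
    def total(self) -> int:
        return self.n_neg + self.n_pos

    @classmethod
    def from_counts(
        cls, counts: Mapping[int, tuple[int, int]], max_score: int | None = None
    ) -> "ScoreDistribution":
        """Build from ``{score: (negatives, positives)}``."""
        if max_score is None:
            max_score = max(counts)
        n0 = [0] * (max_score + 1)
        n1 = [0] * (max_score + 1)
        for s, (neg, pos) in counts.items():
            n0[s] = int(neg)
            n1[s] = int(pos)
        return cls(tuple(n0), tuple(n1))

    @classmethod
    def from_scores(
        cls, scores: Sequence[int], outcomes: Sequence[int], max_score: int
    ) -> "ScoreDistribution":
        n0 = [0] * (max_score + 1)
        n1 = [0] * (max_score + 1)
        for s, y in zip(scores, outcomes, strict=True):
            (n1 if y else n0)[int(s)] += 1
        return cls(tuple(n0), tuple(n1))

    def event_rate(self, score: int) -> float:
        """P(outcome | score) among patients at exactly *score* (NaN if empty)."""
        n = self.n0[score] + self.n1[score]
        return self.n1[score] / n if n else float("nan")

    def to_frame(self) -> pd.DataFrame:
        """Display table: one row per score, highest first."""
        rows = []
        for s in range(self.max_score, -1, -1):
            n = self.n0[s] + self.n1[s]
            rows.append(
                {
                    "score": s,
                    "n_no_severe_vur": self.n0[s],
                    "n_severe_vur": self.n1[s],
                    "severe_vur_rate_pct": round(100 * self.n1[s] / n, 1) if n else float("nan"),
                }
            )
        return pd.DataFrame(rows)


def score_cohort(
    cohort: Cohort, spec: WeightSpec, outcome: str = "severe_vur"
) -> tuple[pd.Series, ScoreDistribution]:
    """Score every record; returns (per-patient scores, score distribution)."""
    ids = [r.patient_id for r in cohort]
    scores = [compute_score(r, spec) for r in cohort]
    outcomes = [r.get(outcome) for r in cohort]
    dist = ScoreDistribution.from_scores(scores, outcomes, spec.max_score)
    return pd.Series(scores, index=pd.Index(ids, name="patient_id"), name="score"), dist
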