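"""Packaged reference counts and their accessors.

``data/printed_tables.json`` carries the reference cross-tabulations the
scoring model was reported with: per-variable exposure counts by outcome
group (Table-1 style, with the reduced denominators for the scintigraphy
variables), the per-score outcome distribution (Table-2 style), the three
risk bands, and the no-DMSA subgroup counts. :func:`load_fixtures` checks
their internal consistency before handing them out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

from .association import ContingencyTable2x2
from .errors import FixtureIntegrityError, SchemaError
from .scoring import ScoreDistribution


@dataclass(frozen=True)
class Table1Row:
    """One screened variable: exposed counts and group denominators, plus the
    reference display strings (metadata only, never used in computation)."""

    variable: str
    exposed_no_mild: int
    denom_no_mild: int
    exposed_severe: int
    denom_severe: int
    printed_p: str
    printed_or: Optional[str]
    assigned_score: Optional[int]

    def contingency(self) -> ContingencyTable2x2:
        """2x2 with severe-VUR patients as cases."""
        return ContingencyTable2x2(
            a=self.exposed_severe,
            b=self.denom_severe - self.exposed_severe,
            c=self.exposed_no_mild,
            d=self.denom_no_mild - self.exposed_no_mild,
        )


@dataclass(frozen=True)
class BandCounts:
    label: str
    score_lo: int
    score_hi: int
    absent: int
    present: int


@dataclass(frozen=True)
class NoDmsaCounts:
    """The no-DMSA subgroup split at the capped top score (5)."""

    severe_score5: int
    no_mild_score5: int
    severe_le4: int
    no_mild_le4: int

    @property
    def n(self) -> int:
        return (
            self.severe_score5 + self.no_mild_score5
            + self.severe_le4 + self.no_mild_le4
        )

    @property
    def n_severe(self) -> int:
        return self.severe_score5 + self.severe_le4

    def contingency(self) -> ContingencyTable2x2:
        """Score-5 (capped top) vs. score <= 4, severe vs. not."""
        return ContingencyTable2x2(
            a=self.severe_score5,
            b=self.severe_le4,
            c=self.no_mild_score5,
            d=self.no_mild_le4,
        )


@dataclass(frozen=True)
class FixtureSet:
    table1: Mapping[str, Table1Row]
    table2: ScoreDistribution
    table3: tuple[BandCounts, ...]
    nodmsa: NoDmsaCounts

    def table1_contingency(self, variable: str) -> ContingencyTable2x2:
        if variable not in self.table1:
            raise SchemaError(f"no reference counts for variable {variable!r}")
        return self.table1[variable].contingency()

    def table1_contingencies(self) -> dict[str, ContingencyTable2x2]:
        return {v: row.contingency() for v, row in self.table1.items()}


def load_fixtures() -> FixtureSet:
    """Load and integrity-check the packaged reference counts."""
    raw = json.loads(
        resources.files("vurscore.data").joinpath("printed_tables.json").read_text()
    )
    table1 = {
        v: Table1Row(
            variable=v,
            exposed_no_mild=row["no_mild"][0],
            denom_no_mild=row["no_mild"][1],
            exposed_severe=row["severe"][0],
            denom_severe=row["severe"][1],
            printed_p=row["p"],
            printed_or=row["or"],
            assigned_score=row["score"],
        )
        for v, row in raw["table1"].items()
    }
    table2 = ScoreDistribution.from_counts(
        {int(s): (neg, pos) for s, (neg, pos) in raw["table2"].items()}
    )
    table3 = tuple(
        BandCounts(b["label"], b["range"][0], b["range"][1], b["absent"], b["present"])
        for b in raw["table3"]
    )
    nd = raw["nodmsa"]
    nodmsa = NoDmsaCounts(
        severe_score5=nd["score5"]["severe"],
        no_mild_score5=nd["score5"]["no_mild"],
        severe_le4=nd["score_le4"]["severe"],
        no_mild_le4=nd["score_le4"]["no_mild"],
    )

    if table2.n_neg != 958 or table2.n_pos != 86:
        raise FixtureIntegrityError(
            f"score-table outcome totals {table2.n_neg}/{table2.n_pos} != 958/86"
        )
    if nodmsa.n != 537 or nodmsa.n_severe != 18:
        raise FixtureIntegrityError(
            f"no-DMSA subgroup totals {nodmsa.n}/{nodmsa.n_severe} != 537/18"
        )
    band_total = sum(b.absent + b.present for b in table3)
    if band_total != table2.total:
        raise FixtureIntegrityError(
            f"band counts sum to {band_total}, score table to {table2.total}"
        )
    for row in table1.values():
        if not (0 <= row.exposed_no_mild <= row.denom_no_mild) or not (
            0 <= row.exposed_severe <= row.denom_severe
        ):
            raise FixtureIntegrityError(f"impossible counts for {row.variable!r}")
    return FixtureSet(table1=table1, table2=table2, table3=table3, nodmsa=nodmsa)
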