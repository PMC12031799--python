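"""Univariable association screening on 2x2 exposure-outcome tables.

The screening stage compares children with severe reflux against the rest,
one binary predictor at a time: Pearson chi-square for significance and the
cross-product odds ratio with a Woolf (log-normal) 95% interval for effect
size. Records in which a predictor is undefined (the scar variables when no
DMSA scan was done) are excluded pairwise, table by table, which is what
produces the reduced scintigraphy denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import Table2x2

from .cohort import Cohort, PREDICTOR_VARIABLES
from .errors import DegenerateTableError, SchemaError, UndefinedStatisticError


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure x outcome counts.

    ``a``: exposed cases, ``b``: unexposed cases, ``c``: exposed controls,
    ``d``: unexposed controls.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise DegenerateTableError(
                    f"cell {name}={v!r} must be a non-negative integer"
                )
        if self.total == 0:
            raise DegenerateTableError("empty 2x2 table (no observations)")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def swap_exposure(self) -> "ContingencyTable2x2":
        """Relabel exposed <-> unexposed (inverts the odds ratio)."""
        return ContingencyTable2x2(self.b, self.a, self.d, self.c)

    def transpose(self) -> "ContingencyTable2x2":
        """Swap the roles of exposure and outcome."""
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)


@dataclass(frozen=True)
class AssociationResult:
    """One screened variable: test, effect size and significance flag."""

    variable: str
    table: ContingencyTable2x2
    chi2: float
    p_value: float
    or_point: float
    ci_low: float
    ci_high: float
    haldane_applied: bool
    significant: bool


def build_2x2(
    cohort: Cohort, predictor: str, outcome: str = "severe_vur"
) -> ContingencyTable2x2:
    """Cross-tabulate *predictor* against *outcome*.

    Records whose predictor value is missing are excluded (pairwise
    deletion); an empty cohort or an all-missing predictor raises
    :class:`DegenerateTableError`.
    """
    from .cohort import CSV_COLUMNS

    for name in (predictor, outcome):
        if name not in CSV_COLUMNS[1:]:
            raise SchemaError(f"unknown variable {name!r}")
    a = b = c = d = 0
    for rec in cohort:
        x = rec.get(predictor)
        y = rec.get(outcome)
        if x is None or y is None:
            continue
        if y == 1:
            a, b = (a + 1, b) if x == 1 else (a, b + 1)
        else:
            c, d = (c + 1, d) if x == 1 else (c, d + 1)
    if a + b + c + d == 0:
        raise DegenerateTableError(
            f"no observations for predictor {predictor!r} x outcome {outcome!r}"
        )
    return ContingencyTable2x2(a, b, c, d)


def chi_square_test(
    table: ContingencyTable2x2, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 (1 df), optionally Yates-corrected.

    A zero row or column margin makes the statistic undefined and raises
    :class:`DegenerateTableError`.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero margin in 2x2 table")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=continuity_correction)
    return float(chi2), float(p)


def odds_ratio(
    table: ContingencyTable2x2, zero_cell_rule: bool = True
) -> tuple[float, float, float, bool]:
    """Cross-product OR with Woolf 95% CI.

    OR = (a*d)/(b*c); the interval is the normal approximation on the log
    scale with SE sqrt(1/a + 1/b + 1/c + 1/d). A zero cell triggers the
    Haldane-Anscombe correction (+0.5 to every cell) when ``zero_cell_rule``
    is on, otherwise :class:`UndefinedStatisticError`.

    Returns ``(or_point, ci_low, ci_high, haldane_applied)``.
    """
    arr = table.as_array()
    haldane = False
    if (arr == 0).any():
        if not zero_cell_rule:
            raise UndefinedStatisticError(
                "odds ratio undefined: zero cell and Haldane correction disabled"
            )
        arr = arr + 0.5
        haldane = True
    t = Table2x2(arr, shift_zeros=False)
    lo, hi = t.oddsratio_confint(0.05)
    return float(t.oddsratio), float(lo), float(hi), haldane


def assess_table(
    variable: str,
    table: ContingencyTable2x2,
    alpha: float = 0.05,
    continuity_correction: bool = False,
    zero_cell_rule: bool = True,
) -> AssociationResult:
    """Chi-square + OR for one named table (the per-variable screen step)."""
    chi2, p = chi_square_test(table, continuity_correction=continuity_correction)
    orp, lo, hi, haldane = odds_ratio(table, zero_cell_rule=zero_cell_rule)
    return AssociationResult(
        variable=variable,
        table=table,
        chi2=chi2,
        p_value=p,
        or_point=orp,
        ci_low=lo,
        ci_high=hi,
        haldane_applied=haldane,
        significant=bool(p < alpha),
    )


def screen_counts(
    tables: Mapping[str, ContingencyTable2x2],
    alpha: float = 0.05,
    continuity_correction: bool = False,
    zero_cell_rule: bool = True,
) -> list[AssociationResult]:
    """Screen pre-built 2x2 tables (e.g. the packaged reference counts)."""
    return [
        assess_table(v, t, alpha, continuity_correction, zero_cell_rule)
        for v, t in tables.items()
    ]


def screen_variables(
    cohort: Cohort,
    variables: Sequence[str] | None = None,
    outcome: str = "severe_vur",
    alpha: float = 0.05,
    continuity_correction: bool = False,
    zero_cell_rule: bool = True,
) -> list[AssociationResult]:
    """Screen each candidate variable in order against the outcome.

    Default candidates are the ten reference predictors. Each result carries
    ``significant = (p < alpha)``.
    """
    if variables is None:
        variables = PREDICTOR_VARIABLES
    for v in variables:
        if v not in PREDICTOR_VARIABLES:
            raise SchemaError(f"unknown candidate variable {v!r}")
    tables = {v: build_2x2(cohort, v, outcome) for v in variables}
    return screen_counts(
        tables,
        alpha=alpha,
        continuity_correction=continuity_correction,
        zero_cell_rule=zero_cell_rule,
    )


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (display convention for ORs/percentages)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def screen_report_frame(results: Sequence[AssociationResult]):
    """Screen results as a display table mirroring the reference layout."""
    import pandas as pd

    rows = []
    for r in results:
        n_case = r.table.a + r.table.b
        n_ctrl = r.table.c + r.table.d
        rows.append(
            {
                "variable": r.variable,
                "control_exposed": r.table.c,
                "control_pct": round_half_away(100.0 * r.table.c / n_ctrl, 1),
                "case_exposed": r.table.a,
                "case_pct": round_half_away(100.0 * r.table.a / n_case, 1),
                "chi2": r.chi2,
                "p_value": r.p_value,
                "odds_ratio": round_half_away(r.or_point, 1),
                "ci_low": round_half_away(r.ci_low, 1),
                "ci_high": round_half_away(r.ci_high, 1),
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)
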