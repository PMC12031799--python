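"""Diagnostic evaluation of the discrete risk score.

Everything here operates on a :class:`~vurscore.scoring.ScoreDistribution`
(per-score counts split by outcome), because the score takes a handful of
integer values and ties carry all the information:

* AUC is the tie-aware Mann-Whitney probability of correct ranking
  (a positive-negative pair with equal scores counts 1/2), identical to the
  trapezoid area under the empirical ROC over integer thresholds.
* The Youden index J(t) = Se(t) + Sp(t) - 1 picks the lower cutoff
  (smallest maximizer); the upper cutoff -- the high-risk boundary -- is the
  smallest threshold above it whose specificity reaches a configurable floor
  (default 0.97), since a single J maximization yields only one cutpoint.
* Band and threshold diagnostics (Se/Sp/PPV/NPV, OR vs. the rest) come
  straight from the 2x2 identities.
* Patients lacking a scored modality (no DMSA scan) are analysed separately
  against their capped maximum achievable score.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import stats

from .association import ContingencyTable2x2, odds_ratio
from .cohort import Cohort
from .errors import (
    BandConstructionError,
    DegenerateTableError,
    ParameterError,
    UndefinedStatisticError,
)
from .scoring import (
    MODALITY_REQUIREMENTS,
    ScoreDistribution,
    WeightSpec,
    compute_score,
)


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class RocResult:
    """AUC with 95% CI and the ROC polyline over integer thresholds."""

    auc: float
    ci_low: float
    ci_high: float
    points: tuple[tuple[float, float], ...]  # (1 - Sp, Se), threshold high -> low
    ci_method: str


def _counts_at_threshold(dist: ScoreDistribution, t: int) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) for the rule ``test positive iff score >= t``."""
    tp = sum(dist.n1[t:])
    fp = sum(dist.n0[t:])
    fn = dist.n_pos - tp
    tn = dist.n_neg - fp
    return tp, fp, fn, tn


def roc_auc(dist: ScoreDistribution, ci_method: str = "hanley") -> RocResult:
    """Tie-aware AUC with a normal-approximation CI.

    ``ci_method``: ``"hanley"`` (Hanley-McNeil variance, default) or
    ``"delong"`` (DeLong structural-component variance). Raises
    :class:`UndefinedStatisticError` if either outcome class is empty.
    """
    n1, n0 = dist.n_pos, dist.n_neg
    if n1 == 0 or n0 == 0:
        raise UndefinedStatisticError("ROC undefined: an outcome class is empty")
    pos = np.asarray(dist.n1, dtype=float)
    neg = np.asarray(dist.n0, dtype=float)
    neg_below = np.concatenate([[0.0], np.cumsum(neg)[:-1]])
    # placement of each positive score level among negatives (ties count 1/2)
    placement = (neg_below + 0.5 * neg) / n0
    auc = float(np.dot(pos, placement) / n1)

    if ci_method == "hanley":
        q1 = auc / (2 - auc)
        q2 = 2 * auc * auc / (1 + auc)
        var = (
            auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
        ) / (n1 * n0)
    elif ci_method == "delong":
        pos_below = np.concatenate([[0.0], np.cumsum(pos)[:-1]])
        # structural components: for a negative at level s, the fraction of
        # positives ranked above it (ties 1/2) has mean equal to the AUC
        v01 = (pos_below + 0.5 * pos) / n1
        s10 = float(np.dot(pos, (placement - auc) ** 2) / (n1 - 1)) if n1 > 1 else 0.0
        s01 = (
            float(np.dot(neg, ((1 - v01) - auc) ** 2) / (n0 - 1)) if n0 > 1 else 0.0
        )
        var = s10 / n1 + s01 / n0
    else:
        raise ParameterError(f"unknown ci_method {ci_method!r}")
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.975)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)

    points = []
    for t in range(dist.max_score + 1, -1, -1):
        tp, fp, fn, tn = _counts_at_threshold(dist, t)
        points.append((fp / n0, tp / n1))
    return RocResult(auc, lo, hi, tuple(points), ci_method)


def pairwise_auc(dist: ScoreDistribution) -> float:
    """Brute-force all-pairs AUC (concordant + half ties); O(S^2) oracle-style
    reference kept in the public API because it is occasionally the clearer
    statement of what AUC means on a discrete score."""
    n1, n0 = dist.n_pos, dist.n_neg
    if n1 == 0 or n0 == 0:
        raise UndefinedStatisticError("ROC undefined: an outcome class is empty")
    total = 0.0
    for sp in range(dist.max_score + 1):
        for sn in range(dist.max_score + 1):
            pairs = dist.n1[sp] * dist.n0[sn]
            if sp > sn:
                total += pairs
            elif sp == sn:
                total += 0.5 * pairs
    return total / (n1 * n0)


# ---------------------------------------------------------------------------
# Risk bands


@dataclass(frozen=True)
class RiskBands:
    """Three-band partition of the score range.

    ``lower_cut`` is the smallest moderate-band score, ``upper_cut`` the
    smallest high-band score.
    """

    lower_cut: int
    upper_cut: int
    max_score: int

    def __post_init__(self):
        if not (0 < self.lower_cut < self.upper_cut <= self.max_score):
            raise ParameterError(
                f"bands need 0 < lower_cut < upper_cut <= max_score, got "
                f"{self.lower_cut}, {self.upper_cut}, {self.max_score}"
            )

    @property
    def bands(self) -> tuple[tuple[str, int, int], ...]:
        return (
            ("low", 0, self.lower_cut - 1),
            ("moderate", self.lower_cut, self.upper_cut - 1),
            ("high", self.upper_cut, self.max_score),
        )

    def label_for(self, score: int) -> str:
        for label, lo, hi in self.bands:
            if lo <= score <= hi:
                return label
        raise ParameterError(f"score {score} outside 0..{self.max_score}")


def youden_bands(
    dist: ScoreDistribution, high_specificity_floor: float = 0.97
) -> RiskBands:
    """Two cutoffs from the threshold sweep.

    ``lower_cut`` maximizes J = Se + Sp - 1 (ties -> smallest threshold);
    ``upper_cut`` is the smallest threshold above it with specificity >= the
    floor. Raises :class:`BandConstructionError` when no threshold clears the
    floor, with the sweep attached for diagnosis.
    """
    if not (0 < high_specificity_floor < 1):
        raise ParameterError("high_specificity_floor must be in (0, 1)")
    n1, n0 = dist.n_pos, dist.n_neg
    if n1 == 0 or n0 == 0:
        raise UndefinedStatisticError("bands undefined: an outcome class is empty")
    sweep = []
    for t in range(1, dist.max_score + 1):
        tp, fp, fn, tn = _counts_at_threshold(dist, t)
        se, sp = tp / n1, tn / n0
        sweep.append((t, se, sp, se + sp - 1))
    lower_cut = max(sweep, key=lambda row: (row[3], -row[0]))[0]
    upper_candidates = [
        t for t, se, sp, j in sweep if t > lower_cut and sp >= high_specificity_floor
    ]
    if not upper_candidates:
        detail = ", ".join(f"t={t}: Se={se:.3f} Sp={sp:.3f}" for t, se, sp, _ in sweep)
        raise BandConstructionError(
            f"no threshold above {lower_cut} reaches specificity "
            f">= {high_specificity_floor} ({detail})"
        )
    return RiskBands(lower_cut, min(upper_candidates), dist.max_score)


# ---------------------------------------------------------------------------
# Diagnostic metrics


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Se/Sp/PPV/NPV plus OR vs. the rest for one test-positive definition."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    or_point: float
    or_ci_low: float
    or_ci_high: float
    undefined: tuple[str, ...] = ()

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _metrics_from_counts(
    tp: int, fp: int, fn: int, tn: int, zero_cell_rule: bool = True
) -> DiagnosticMetrics:
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    se = ratio(tp, tp + fn, "sensitivity")
    sp = ratio(tn, tn + fp, "specificity")
    ppv = ratio(tp, tp + fp, "ppv")
    npv = ratio(tn, tn + fn, "npv")
    try:
        orp, lo, hi, _ = odds_ratio(
            ContingencyTable2x2(tp, fn, fp, tn), zero_cell_rule=zero_cell_rule
        )
    except (DegenerateTableError, UndefinedStatisticError):
        undefined.append("odds_ratio")
        orp = lo = hi = float("nan")
    return DiagnosticMetrics(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=se, specificity=sp, ppv=ppv, npv=npv,
        or_point=orp, or_ci_low=lo, or_ci_high=hi,
        undefined=tuple(undefined),
    )


def threshold_metrics(
    dist: ScoreDistribution, threshold: int, zero_cell_rule: bool = True
) -> DiagnosticMetrics:
    """Diagnostics for ``test positive iff score >= threshold``.

    Degenerate margins yield NaN metrics flagged in ``undefined`` rather
    than silent zeros.
    """
    if not (0 < threshold <= dist.max_score):
        raise ParameterError(
            f"threshold must be in 1..{dist.max_score}, got {threshold}"
        )
    tp, fp, fn, tn = _counts_at_threshold(dist, threshold)
    return _metrics_from_counts(tp, fp, fn, tn, zero_cell_rule)


@dataclass(frozen=True)
class BandReport:
    """One risk band: occupancy, event rate, and band-as-test diagnostics."""

    label: str
    score_lo: int
    score_hi: int
    n: int
    events: int
    event_rate: float
    metrics: DiagnosticMetrics


@dataclass(frozen=True)
class BandEvaluation:
    reports: tuple[BandReport, ...]
    chi2: float
    p_value: float


def band_metrics(dist: ScoreDistribution, bands: RiskBands) -> BandEvaluation:
    """Per-band event rates and diagnostics (band membership = test positive),
    plus the chi-square of outcome across the three bands."""
    if bands.max_score != dist.max_score:
        raise ParameterError("bands and distribution disagree on max score")
    reports = []
    table = []
    for label, lo, hi in bands.bands:
        pos = sum(dist.n1[lo : hi + 1])
        neg = sum(dist.n0[lo : hi + 1])
        n = pos + neg
        tp, fn = pos, dist.n_pos - pos
        fp, tn = neg, dist.n_neg - neg
        m = _metrics_from_counts(tp, fp, fn, tn)
        rate = pos / n if n else float("nan")
        reports.append(BandReport(label, lo, hi, n, pos, rate, m))
        table.append([neg, pos])
    arr = np.asarray(table, dtype=float)
    keep = arr.sum(axis=1) > 0
    chi2, p, _, _ = stats.chi2_contingency(arr[keep])
    return BandEvaluation(tuple(reports), float(chi2), float(p))


# ---------------------------------------------------------------------------
# Capped-score subgroup (patients lacking a scored modality)


@dataclass(frozen=True)
class CappedSubgroupReport:
    """Evaluation of patients missing *modality*, against the capped maximum."""

    modality: str
    n: int
    n_events: int
    prevalence: float
    capped_max_score: int
    threshold: int
    distribution: ScoreDistribution
    metrics: DiagnosticMetrics


def capped_subgroup_analysis(
    cohort: Cohort,
    spec: WeightSpec,
    modality: str = "dmsa_done",
    outcome: str = "severe_vur",
) -> CappedSubgroupReport:
    """Rescore and evaluate the records lacking *modality*.

    Their achievable maximum drops by the weight of every modality-dependent
    variable; the top achievable score serves as the test threshold
    (reported as ``score >= threshold``, which here means ``== capped max``).
    """
    dependent = [v for v, f in MODALITY_REQUIREMENTS.items() if f == modality]
    if not any(v in spec.entries for v in dependent):
        raise ParameterError(
            f"{modality!r} is not the availability flag of any weighted variable"
        )
    subset = [r for r in cohort if r.get(modality) == 0]
    if not subset:
        raise DegenerateTableError(
            f"empty subgroup: every record has {modality} = 1"
        )
    capped = spec.capped_max_score(modality)
    scores = [compute_score(r, spec) for r in subset]
    outcomes = [r.get(outcome) for r in subset]
    dist = ScoreDistribution.from_scores(scores, outcomes, capped)
    metrics = threshold_metrics(dist, capped)
    n = len(subset)
    events = int(sum(outcomes))
    return CappedSubgroupReport(
        modality=modality,
        n=n,
        n_events=events,
        prevalence=events / n,
        capped_max_score=capped,
        threshold=capped,
        distribution=dist,
        metrics=metrics,
    )
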