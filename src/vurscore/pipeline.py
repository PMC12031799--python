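"""End-to-end orchestration: screen -> select -> weight -> score -> bands -> report.

The pipeline is deterministic: identical cohort + config produce
byte-identical output files (no timestamps inside report artifacts; wall-clock
logging goes to stderr only).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .association import (
    AssociationResult,
    screen_report_frame,
    screen_variables,
    round_half_away,
)
from .cohort import Cohort, read_cohort_csv, validate_cohort
from .errors import ParameterError, PipelineError, VurScoreError
from .evaluate import (
    BandEvaluation,
    CappedSubgroupReport,
    RiskBands,
    RocResult,
    band_metrics,
    capped_subgroup_analysis,
    roc_auc,
    youden_bands,
)
from .scoring import (
    CollinearityGroups,
    DEFAULT_GROUPS,
    ScoreDistribution,
    WeightSpec,
    assign_weights,
    score_cohort,
    select_variables,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the full run; defaults reproduce the reference model."""

    alpha: float = 0.05
    groups: CollinearityGroups = field(default_factory=lambda: DEFAULT_GROUPS)
    weight_ceiling: int = 2
    high_specificity_floor: float = 0.97
    continuity_correction: bool = False
    zero_cell_rule: bool = True
    seed: int = 0
    outdir: Optional[str] = None

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ParameterError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (0 < self.high_specificity_floor < 1):
            raise ParameterError(
                f"high_specificity_floor must be in (0, 1), got {self.high_specificity_floor}"
            )
        if self.weight_ceiling < 1:
            raise ParameterError(f"weight_ceiling must be >= 1, got {self.weight_ceiling}")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "groups": {k: list(v) for k, v in self.groups.groups.items()},
            "weight_ceiling": self.weight_ceiling,
            "high_specificity_floor": self.high_specificity_floor,
            "continuity_correction": self.continuity_correction,
            "zero_cell_rule": self.zero_cell_rule,
            "seed": self.seed,
            "version": __version__,
        }

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Read a JSON key-value config; unknown keys are rejected."""
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        raw.pop("version", None)
        groups = raw.pop("groups", None)
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw) if groups is None else cls(
            groups=CollinearityGroups({k: tuple(v) for k, v in groups.items()}), **raw
        )
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class PipelineReport:
    """Everything a full run produced, pre-serialization."""

    cohort_provenance: str
    n: int
    n_events: int
    screen: tuple[AssociationResult, ...]
    weights: WeightSpec
    scores: pd.Series
    distribution: ScoreDistribution
    roc: RocResult
    bands: RiskBands
    band_evaluation: BandEvaluation
    subgroup: Optional[CappedSubgroupReport]
    config: PipelineConfig


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except VurScoreError as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_full_pipeline(cohort, config: PipelineConfig | None = None) -> PipelineReport:
    """Run the whole workflow on *cohort* (a Cohort or a CSV path).

    Writes report tables, the serialized weight spec, and a run log under
    ``config.outdir`` when set. Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    config = config or PipelineConfig()
    config.validate()
    if not isinstance(cohort, Cohort):
        cohort = read_cohort_csv(cohort)
    violations = validate_cohort(cohort)
    if violations:
        raise PipelineError(
            f"stage 'validate' failed: {len(violations)} invariant violation(s), "
            f"first: {violations[0]}"
        )

    screen = _stage("screen")(screen_variables)(
        cohort,
        alpha=config.alpha,
        continuity_correction=config.continuity_correction,
        zero_cell_rule=config.zero_cell_rule,
    )
    selected = _stage("select")(select_variables)(
        screen, groups=config.groups, alpha=config.alpha
    )
    weights = _stage("weight")(assign_weights)(selected, ceiling=config.weight_ceiling)
    scores, dist = _stage("score")(score_cohort)(cohort, weights)
    roc = _stage("roc")(roc_auc)(dist)
    bands = _stage("bands")(youden_bands)(
        dist, high_specificity_floor=config.high_specificity_floor
    )
    band_eval = _stage("band-metrics")(band_metrics)(dist, bands)
    subgroup = None
    if any(rec.dmsa_done == 0 for rec in cohort) and any(
        v in weights.entries for v in ("any_scar", "multiple_scars")
    ):
        subgroup = _stage("subgroup")(capped_subgroup_analysis)(cohort, weights)

    report = PipelineReport(
        cohort_provenance=cohort.provenance,
        n=len(cohort),
        n_events=sum(r.severe_vur for r in cohort),
        screen=tuple(screen),
        weights=weights,
        scores=scores,
        distribution=dist,
        roc=roc,
        bands=bands,
        band_evaluation=band_eval,
        subgroup=subgroup,
        config=config,
    )
    if config.outdir is not None:
        write_report(report, config.outdir)
    return report


def _bands_frame(report: PipelineReport) -> pd.DataFrame:
    rows = []
    for b in report.band_evaluation.reports:
        rows.append(
            {
                "band": b.label,
                "scores": f"{b.score_lo}-{b.score_hi}",
                "n": b.n,
                "severe_vur_absent": b.n - b.events,
                "severe_vur_present": b.events,
                "event_rate_pct": round_half_away(100 * b.event_rate, 1),
            }
        )
    return pd.DataFrame(rows)


def _metrics_frame(report: PipelineReport) -> pd.DataFrame:
    rows = []
    for b in report.band_evaluation.reports:
        m = b.metrics
        rows.append(
            {
                "band": b.label,
                "scores": f"{b.score_lo}-{b.score_hi}",
                "sensitivity_pct": round_half_away(100 * m.sensitivity, 1),
                "specificity_pct": round_half_away(100 * m.specificity, 1),
                "ppv_pct": round_half_away(100 * m.ppv, 1),
                "npv_pct": round_half_away(100 * m.npv, 1),
                "odds_ratio": round_half_away(m.or_point, 2),
                "or_ci_low": round_half_away(m.or_ci_low, 2),
                "or_ci_high": round_half_away(m.or_ci_high, 2),
            }
        )
    return pd.DataFrame(rows)


def report_payload(report: PipelineReport) -> dict:
    """The structured (machine-readable) report; numbers identical to the
    delimited tables."""
    be = report.band_evaluation
    payload = {
        "cohort": {
            "provenance": report.cohort_provenance,
            "n": report.n,
            "events": report.n_events,
            "prevalence": report.n_events / report.n if report.n else None,
        },
        "screen": [
            {
                "variable": r.variable,
                "table": [r.table.a, r.table.b, r.table.c, r.table.d],
                "chi2": r.chi2,
                "p_value": r.p_value,
                "odds_ratio": r.or_point,
                "ci": [r.ci_low, r.ci_high],
                "haldane_applied": r.haldane_applied,
                "significant": r.significant,
            }
            for r in report.screen
        ],
        "weights": {
            "entries": dict(report.weights.entries),
            "min_or_anchor": report.weights.min_or_anchor,
            "max_score": report.weights.max_score,
        },
        "score_distribution": {
            "n0": list(report.distribution.n0),
            "n1": list(report.distribution.n1),
        },
        "roc": {
            "auc": report.roc.auc,
            "ci": [report.roc.ci_low, report.roc.ci_high],
            "ci_method": report.roc.ci_method,
        },
        "bands": {
            "lower_cut": report.bands.lower_cut,
            "upper_cut": report.bands.upper_cut,
            "chi2": be.chi2,
            "p_value": be.p_value,
            "per_band": [
                {
                    "band": b.label,
                    "scores": [b.score_lo, b.score_hi],
                    "n": b.n,
                    "events": b.events,
                    "event_rate": b.event_rate,
                    "sensitivity": b.metrics.sensitivity,
                    "specificity": b.metrics.specificity,
                    "ppv": b.metrics.ppv,
                    "npv": b.metrics.npv,
                    "odds_ratio": b.metrics.or_point,
                    "or_ci": [b.metrics.or_ci_low, b.metrics.or_ci_high],
                }
                for b in be.reports
            ],
        },
        "config": report.config.to_dict(),
    }
    if report.subgroup is not None:
        s = report.subgroup
        payload["no_modality_subgroup"] = {
            "modality": s.modality,
            "n": s.n,
            "events": s.n_events,
            "prevalence": s.prevalence,
            "capped_max_score": s.capped_max_score,
            "threshold": s.threshold,
            "sensitivity": s.metrics.sensitivity,
            "specificity": s.metrics.specificity,
            "ppv": s.metrics.ppv,
            "npv": s.metrics.npv,
            "odds_ratio": s.metrics.or_point,
            "or_ci": [s.metrics.or_ci_low, s.metrics.or_ci_high],
        }
    return payload


def write_report(report: PipelineReport, outdir) -> None:
    """Delimited tables + structured report + weight spec + run log."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    screen_report_frame(report.screen).to_csv(out / "screen.tsv", sep="\t", index=False)
    report.distribution.to_frame().to_csv(out / "scores.tsv", sep="\t", index=False)
    _bands_frame(report).to_csv(out / "bands.tsv", sep="\t", index=False)
    _metrics_frame(report).to_csv(out / "band_metrics.tsv", sep="\t", index=False)
    report.weights.to_json(out / "weights.json")
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report_payload(report), fh, indent=2, allow_nan=True)
        fh.write("\n")
    with open(out / "run.log", "w", encoding="utf-8") as fh:
        fh.write(f"vurscore {__version__}\n")
        fh.write(f"cohort: {report.cohort_provenance} (n={report.n})\n")
        fh.write("config: " + json.dumps(report.config.to_dict(), sort_keys=True) + "\n")
    logger.info("report written to %s", out)


def apply_model(
    cohort, spec: WeightSpec, bands: RiskBands
) -> pd.DataFrame:
    """Score a (possibly new) cohort with a fitted spec and label the bands.

    Returns one row per patient: score, band label, and whether the score was
    capped by a missing modality. Schema mismatches raise with the missing
    variable names.
    """
    if not isinstance(cohort, Cohort):
        cohort = read_cohort_csv(cohort)
    from .scoring import MODALITY_REQUIREMENTS, compute_score

    rows = []
    for rec in cohort:
        score = compute_score(rec, spec)
        capped = any(
            rec.get(flag) == 0
            for v, flag in MODALITY_REQUIREMENTS.items()
            if v in spec.entries
        )
        rows.append(
            {
                "patient_id": rec.patient_id,
                "score": score,
                "band": bands.label_for(score),
                "capped": capped,
            }
        )
    columns = ["patient_id", "score", "band", "capped"]
    return pd.DataFrame(rows, columns=columns)
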