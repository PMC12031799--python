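"""Synthetic cohorts and the deterministic reference reconstruction.

Two distinct sources of test data:

:func:`generate_cohort`
    A calibrated stochastic generator. The outcome is drawn first
    (severe-VUR probability ``prevalence``), then each predictor chain is
    drawn conditional on the outcome group: the most specific member first
    (UTD-P3; multiple scars; non-E. coli and recurrent UTI), with implied
    ancestors forced and residual probabilities chosen so every marginal
    frequency matches the calibration exactly in expectation. Outside the
    forced implications, predictors are conditionally independent given the
    outcome -- the simplest joint distribution consistent with all the
    marginal calibration targets. DMSA availability is sampled independently
    of outcome by default.

:func:`reconstruct_reference_cohort`
    A fixed 1044-record cohort expanded from a frozen predictor-pattern
    table (plain-text package data). Under the reference weights
    {1,1,1,2,2} its per-score outcome counts equal the packaged score table
    exactly, its no-DMSA subgroup reproduces the packaged subgroup counts,
    and its per-variable margins equal the packaged screening counts with
    one documented exception: the severe-group margins as printed are
    arithmetically inconsistent with the printed score distribution (their
    weighted sum is 337 against a required 365), so the reconstruction
    carries 57 rather than 43 severe UTD-P3 patients -- the unique minimal
    adjustment confined to a single margin. See docs/methods.md.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping, Optional

import numpy as np

from .cohort import Cohort, PatientRecord
from .errors import ParameterError
from .fixtures import load_fixtures

#: Severe UTD-P3 count carried by the reconstruction (printed value is 43;
#: see the module docstring for why they cannot coincide).
RECONSTRUCTED_SEVERE_UTD_P3 = 57


@dataclass(frozen=True)
class SyntheticParams:
    """Calibration of the stochastic generator.

    ``predictor_marginals`` maps each predictor to its exposure probability
    ``(P[x=1 | no/mild VUR], P[x=1 | severe VUR])``; the scar probabilities
    are conditional on a DMSA scan having been performed.
    ``dmsa_missing_rate_severe`` optionally makes DMSA availability depend
    on the outcome (for sensitivity studies); by default missingness is
    outcome-independent.
    """

    n: int
    prevalence: float
    predictor_marginals: Mapping[str, tuple[float, float]]
    dmsa_missing_rate: float
    seed: int = 0
    dmsa_missing_rate_severe: Optional[float] = None

    def validate(self) -> None:
        if self.n < 0:
            raise ParameterError(f"n must be >= 0, got {self.n}")
        probs = {"prevalence": self.prevalence, "dmsa_missing_rate": self.dmsa_missing_rate}
        if self.dmsa_missing_rate_severe is not None:
            probs["dmsa_missing_rate_severe"] = self.dmsa_missing_rate_severe
        for v, (p0, p1) in self.predictor_marginals.items():
            probs[f"{v}|no_mild"] = p0
            probs[f"{v}|severe"] = p1
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ParameterError(f"probability {name} = {p} outside [0, 1]")
        required = {
            "age_lt2", "male", "uti", "recurrent_uti", "non_ecoli",
            "usg_abnormal", "hydronephrosis", "utd_p3", "any_scar", "multiple_scars",
        }
        missing = required - set(self.predictor_marginals)
        if missing:
            raise ParameterError(f"missing marginals for: {sorted(missing)}")
        m = self.predictor_marginals
        for g in (0, 1):
            if not m["utd_p3"][g] <= m["hydronephrosis"][g] <= m["usg_abnormal"][g]:
                raise ParameterError(
                    "infeasible imaging marginals: need P(utd_p3) <= "
                    "P(hydronephrosis) <= P(usg_abnormal) in each outcome group"
                )
            if not m["multiple_scars"][g] <= m["any_scar"][g]:
                raise ParameterError(
                    "infeasible scar marginals: need P(multiple_scars) <= P(any_scar)"
                )
            forced = 1.0 - (1.0 - m["non_ecoli"][g]) * (1.0 - m["recurrent_uti"][g])
            if m["uti"][g] < forced - 1e-12:
                raise ParameterError(
                    "infeasible infection marginals: P(uti) below the rate forced "
                    "by non_ecoli and recurrent_uti under conditional independence"
                )

    def replace(self, **kwargs) -> "SyntheticParams":
        return replace(self, **kwargs)


def default_calibration(seed: int = 0) -> SyntheticParams:
    """Calibration read from the packaged reference counts.

    n = 1044, severe-VUR prevalence 86/1044 (8.2%), DMSA missing in
    537/1044, and per-group exposure probabilities equal to the reference
    frequencies (scar variables conditional on DMSA done).
    """
    fix = load_fixtures()
    marginals = {
        v: (
            row.exposed_no_mild / row.denom_no_mild,
            row.exposed_severe / row.denom_severe,
        )
        for v, row in fix.table1.items()
    }
    return SyntheticParams(
        n=1044,
        prevalence=86 / 1044,
        predictor_marginals=marginals,
        dmsa_missing_rate=537 / 1044,
        seed=seed,
    )


def _residual(p_target: np.ndarray, p_forced: np.ndarray) -> np.ndarray:
    """P(extra draw) so that forced | extra has marginal p_target."""
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (p_target - p_forced) / (1.0 - p_forced)
    return np.clip(np.nan_to_num(r), 0.0, 1.0)


def generate_cohort(params: SyntheticParams) -> Cohort:
    """Draw a cohort of ``params.n`` records; same params + seed => identical
    cohort, and every record satisfies the hierarchy invariants."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n
    m = params.predictor_marginals

    def p(var: str, y: np.ndarray) -> np.ndarray:
        return np.where(y, m[var][1], m[var][0])

    y = rng.random(n) < params.prevalence

    # imaging chain: most specific first, ancestors forced
    utd = rng.random(n) < p("utd_p3", y)
    hn = utd | (rng.random(n) < _residual(p("hydronephrosis", y), p("utd_p3", y)))
    usg = hn | (rng.random(n) < _residual(p("usg_abnormal", y), p("hydronephrosis", y)))

    # infection chain: two specific flags, UTI forced by either
    non_ecoli = rng.random(n) < p("non_ecoli", y)
    recurrent = rng.random(n) < p("recurrent_uti", y)
    forced = 1.0 - (1.0 - p("non_ecoli", y)) * (1.0 - p("recurrent_uti", y))
    uti = non_ecoli | recurrent | (rng.random(n) < _residual(p("uti", y), forced))

    # DMSA availability, then the scar chain among scanned patients
    miss = np.full(n, params.dmsa_missing_rate)
    if params.dmsa_missing_rate_severe is not None:
        miss = np.where(y, params.dmsa_missing_rate_severe, miss)
    dmsa = rng.random(n) >= miss
    mult = dmsa & (rng.random(n) < p("multiple_scars", y))
    scar = mult | (
        dmsa & (rng.random(n) < _residual(p("any_scar", y), p("multiple_scars", y)))
    )

    age = rng.random(n) < p("age_lt2", y)
    male = rng.random(n) < p("male", y)

    width = max(4, len(str(max(n, 1))))
    records = []
    for i in range(n):
        done = bool(dmsa[i])
        records.append(
            PatientRecord(
                patient_id=f"S{i:0{width}d}",
                age_lt2=int(age[i]),
                male=int(male[i]),
                uti=int(uti[i]),
                recurrent_uti=int(recurrent[i]),
                non_ecoli=int(non_ecoli[i]),
                usg_abnormal=int(usg[i]),
                hydronephrosis=int(hn[i]),
                utd_p3=int(utd[i]),
                dmsa_done=int(done),
                any_scar=int(scar[i]) if done else None,
                multiple_scars=int(mult[i]) if done else None,
                severe_vur=int(y[i]),
            )
        )
    return Cohort(tuple(records), provenance=f"synthetic:seed={params.seed}")


def reconstruct_reference_cohort() -> Cohort:
    """Deterministically expand the frozen pattern table into 1044 records."""
    text = resources.files("vurscore.data").joinpath("reference_patterns.csv").read_text()
    reader = csv.DictReader(text.splitlines())
    records = []
    i = 0
    for row in reader:
        count = int(row.pop("count"))
        dmsa = int(row["dmsa_done"])

        def cell(col: str):
            v = row[col].strip()
            return None if v == "" else int(v)

        for _ in range(count):
            i += 1
            records.append(
                PatientRecord(
                    patient_id=f"R{i:04d}",
                    age_lt2=int(row["age_lt2"]),
                    male=int(row["male"]),
                    uti=int(row["uti"]),
                    recurrent_uti=int(row["recurrent_uti"]),
                    non_ecoli=int(row["non_ecoli"]),
                    usg_abnormal=int(row["usg_abnormal"]),
                    hydronephrosis=int(row["hydronephrosis"]),
                    utd_p3=int(row["utd_p3"]),
                    dmsa_done=dmsa,
                    any_scar=cell("any_scar"),
                    multiple_scars=cell("multiple_scars"),
                    severe_vur=int(row["severe_vur"]),
                )
            )
    return Cohort(tuple(records), provenance="fixture:table2")
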