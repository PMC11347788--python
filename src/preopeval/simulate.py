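"""Synthetic cohort and paired-decision simulation.

The study's patient-level data are not publicly deposited, so this module
generates stand-ins: (i) cohorts whose marginal summaries match a published
baseline-characteristics profile (elderly high-comorbidity elective surgical
patients: median age 73, ~49% female, ASA 3 in 98%, mostly intermediate-risk
procedures), with rule-engine-ready observation answers; and (ii) paired
binary clearance decisions with controlled marginals and a target Cohen's
kappa, obtained by analytically inverting the kappa definition into four
cell probabilities.

Continuous summaries given as median (IQR) are modelled log-normally by the
method of quantiles: ``log X ~ Normal(log m, (log q3 − log q1)/(2·z_{0.75}))``.
A single root seed spawns independent sub-streams per output so the
generators can be tested in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .observations import (
    MISSING,
    ObservationDictionary,
    PatientRecord,
    SurgicalContext,
)
from .scores import RCRI_ITEMS

__all__ = [
    "CohortProfile",
    "PairedRatingSpec",
    "DEFAULT_PROFILE",
    "generate_cohort",
    "cohort_frame",
    "generate_paired_ratings",
    "paired_cells",
    "generate_exam_requests",
    "InfeasibleSpecError",
]

_Z75 = 0.6744897501960817  # standard normal 0.75 quantile


class InfeasibleSpecError(ValueError):
    """Requested marginals/kappa imply a negative cell probability."""


@dataclass(frozen=True)
class CohortProfile:
    """Marginal profile of the simulated cohort (defaults: the study cohort)."""

    n: int = 204
    age_quartiles: tuple[float, float, float] = (64.0, 73.0, 79.0)
    female_fraction: float = 0.485
    bmi_quartiles: tuple[float, float, float] = (22.0, 25.0, 29.0)
    asa3_fraction: float = 0.980
    risk_fractions: tuple[float, float, float] = (0.103, 0.642, 0.255)  # low/int/high
    charlson_fractions: tuple[float, float, float, float, float] = (
        0.225,  # 0
        0.544,  # 1-2
        0.108,  # 3-4
        0.015,  # >=5
        0.108,  # unknown
    )
    pospom_quartiles: tuple[float, float, float] = (26.0, 29.0, 32.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n < 0:
            raise InfeasibleSpecError("n must be non-negative")
        for name, frac in (("female_fraction", self.female_fraction), ("asa3_fraction", self.asa3_fraction)):
            if not 0 <= frac <= 1:
                raise InfeasibleSpecError(f"{name} outside [0,1]")
        for name, fracs in (("risk_fractions", self.risk_fractions), ("charlson_fractions", self.charlson_fractions)):
            if any(f < 0 for f in fracs):
                raise InfeasibleSpecError(f"{name} has negative entries")
            if abs(sum(fracs) - 1) > 1e-9:
                raise InfeasibleSpecError(f"{name} must sum to 1")
        for name, q in (
            ("age_quartiles", self.age_quartiles),
            ("bmi_quartiles", self.bmi_quartiles),
            ("pospom_quartiles", self.pospom_quartiles),
        ):
            if not (0 < q[0] <= q[1] <= q[2]):
                raise InfeasibleSpecError(f"{name} must be positive and ordered")


DEFAULT_PROFILE = CohortProfile()

CHARLSON_STRATA = ("0", "1-2", "3-4", ">=5", "unknown")

# comorbidity flag combinations realising each Charlson stratum
# (weight-1 ids, then a weight-2 and a weight-3 id for the higher strata)
_W1 = ["5.1", "5.2", "5.3", "5.4", "5.6", "5.10"]
_W2 = ["5.13", "5.14", "5.12"]
_W3 = ["5.17"]
_ALL_CHARLSON = [f"5.{i}" for i in range(1, 20)]


def _lognormal_from_quartiles(rng: np.ndarray, q: tuple[float, float, float], size: int) -> np.ndarray:
    q1, med, q3 = q
    mu = np.log(med)
    sigma = (np.log(q3) - np.log(q1)) / (2 * _Z75)
    return np.exp(rng.normal(mu, sigma, size=size))


def _charlson_flags(rng, stratum: str) -> dict[str, object]:
    """Flag assignment whose Charlson sum falls inside the stratum band."""
    flags: dict[str, object] = {i: "no" for i in _ALL_CHARLSON}
    if stratum == "unknown":
        return {i: MISSING for i in _ALL_CHARLSON}
    if stratum == "0":
        return flags
    if stratum == "1-2":
        for i in rng.choice(_W1, size=rng.integers(1, 3), replace=False):
            flags[i] = "yes"
    elif stratum == "3-4":
        flags[rng.choice(_W2)] = "yes"
        for i in rng.choice(_W1, size=rng.integers(1, 3), replace=False):
            flags[i] = "yes"
    else:  # >=5
        flags[_W3[0]] = "yes"
        flags[rng.choice(_W2)] = "yes"
        for i in rng.choice(_W1, size=1, replace=False):
            flags[i] = "yes"
    return flags


def generate_cohort(
    profile: CohortProfile = DEFAULT_PROFILE,
    dictionary: ObservationDictionary | None = None,
) -> list[PatientRecord]:
    """Deterministically generate ``profile.n`` validated patient records.

    Observation answers are populated for the demonstrator dictionary:
    cardiac risk-factor counts increase with the Charlson stratum, poor
    functional capacity is more likely with cardiac risk factors, and
    observation 1.1.3 (high-risk surgical conditions) tracks the surgical
    risk class — enough correlation for rules and scores to exercise their
    full range, not an emulation of true clinical joint distributions.
    """
    profile.validate()
    if dictionary is None:
        from .observations import load_dictionary
        from .scores import _data_path

        dictionary = load_dictionary(_data_path("observations.yaml"))
    root = np.random.SeedSequence(profile.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    n = profile.n
    ages = np.clip(np.rint(_lognormal_from_quartiles(rng, profile.age_quartiles, n)), 18, 100).astype(int)
    bmis = np.round(np.clip(_lognormal_from_quartiles(rng, profile.bmi_quartiles, n), 13, 60), 1)
    pospoms = np.rint(_lognormal_from_quartiles(rng, profile.pospom_quartiles, n)).astype(int)
    female = rng.random(n) < profile.female_fraction
    asa3 = rng.random(n) < profile.asa3_fraction
    risk = rng.choice(["low", "intermediate", "high"], size=n, p=profile.risk_fractions)
    strata = rng.choice(CHARLSON_STRATA, size=n, p=profile.charlson_fractions)

    records = []
    for i in range(n):
        stratum = strata[i]
        stratum_idx = 0 if stratum == "unknown" else CHARLSON_STRATA.index(stratum)
        answers: dict[str, object] = {}
        answers.update(_charlson_flags(rng, stratum))
        # cardiac risk factors: probability grows with comorbidity stratum
        p_rf = (0.08, 0.22, 0.45, 0.6)[min(stratum_idx, 3)]
        rf = rng.random(len(RCRI_ITEMS)) < p_rf
        answers["2.2"] = "yes" if rf.any() else "no"
        if rf.any():
            for obs_id, flag in zip(RCRI_ITEMS, rf):
                answers[obs_id] = "yes" if flag else "no"
        # functional capacity: poorer when cardiac risk factors present
        p_limited = 0.55 if rf.sum() >= 2 else 0.25
        limited = rng.random() < p_limited
        answers["2.1"] = "yes" if limited else "no"
        if limited:
            met = rng.random(3) < 0.6
            if not met.any():
                met[rng.integers(3)] = True
            for obs_id, flag in zip(("2.1.4", "2.1.5", "2.1.6"), met):
                answers[obs_id] = "yes" if flag else "no"
        answers["1.1.3"] = "yes" if risk[i] == "high" else "no"
        # sleep-apnoea screening items
        for obs_id, p in (("3.1.1", 0.35), ("3.1.2", 0.3), ("3.1.3", 0.1), ("3.1.4", 0.55), ("3.1.5", 0.3)):
            answers[obs_id] = "yes" if rng.random() < p else "no"
        # renal/abdominal factors
        for obs_id, p in (("4.1", 0.4), ("4.2", 0.05), ("4.3", 0.2), ("4.4", 0.2)):
            answers[obs_id] = "yes" if rng.random() < p else "no"
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:04d}",
                age=int(ages[i]),
                sex="female" if female[i] else "male",
                bmi=float(bmis[i]),
                asa=3 if asa3[i] else 4,
                context=SurgicalContext(risk_class=str(risk[i]), elective=True),
                answers=answers,
            )
        )
    # attach sampled summaries for cohort_frame without widening the record type
    for rec, stratum, pospom_val in zip(records, strata, pospoms):
        object.__setattr__(rec, "_charlson_stratum", str(stratum))
        object.__setattr__(rec, "_pospom", int(pospom_val))
    return records


def cohort_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Tabular per-patient summary of a generated cohort."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "bmi": [r.bmi for r in records],
            "asa": [r.asa for r in records],
            "risk_class": [r.context.risk_class for r in records],
            "charlson_stratum": [getattr(r, "_charlson_stratum", None) for r in records],
            "pospom": [getattr(r, "_pospom", None) for r in records],
        }
    )


@dataclass(frozen=True)
class PairedRatingSpec:
    """Paired binary decisions with marginals (p, q) and target kappa."""

    n: int = 204
    p: float = 0.5  # rater 1 "clear" marginal
    q: float = 0.5  # rater 2 "clear" marginal
    kappa: float = 0.0
    seed: int = 0


def paired_cells(spec: PairedRatingSpec) -> np.ndarray:
    """Cell probabilities (p11, p10, p01, p00) realising the spec exactly.

    Inverts the kappa definition: with chance agreement
    ``p_e = pq + (1−p)(1−q)`` the excess ``delta = kappa·(1−p_e)/2`` is added
    to both diagonal cells. Infeasible combinations raise, never clip.
    """
    p, q, k = spec.p, spec.q, spec.kappa
    if not (0 <= p <= 1 and 0 <= q <= 1):
        raise InfeasibleSpecError("marginals must lie in [0,1]")
    p_e = p * q + (1 - p) * (1 - q)
    delta = k * (1 - p_e) / 2
    cells = np.array(
        [
            p * q + delta,
            p * (1 - q) - delta,
            (1 - p) * q - delta,
            (1 - p) * (1 - q) + delta,
        ]
    )
    if np.any(cells < -1e-12) or np.any(cells > 1 + 1e-12):
        raise InfeasibleSpecError(
            f"kappa={k} infeasible with marginals p={p}, q={q}: cells {cells}"
        )
    return np.clip(cells, 0.0, 1.0)


def generate_paired_ratings(spec: PairedRatingSpec) -> tuple[list[str], list[str]]:
    """Draw ``spec.n`` i.i.d. decision pairs from the implied cell distribution."""
    cells = paired_cells(spec)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
    draws = rng.choice(4, size=spec.n, p=cells)
    rater1 = ["clear" if d in (0, 1) else "reject" for d in draws]
    rater2 = ["clear" if d in (0, 2) else "reject" for d in draws]
    return rater1, rater2


def generate_exam_requests(
    cohort: Sequence[PatientRecord],
    exam_rates: dict[str, tuple[float, float, float]],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-exam binary request indicators for an approach and the reference.

    ``exam_rates`` maps exam name → (approach rate, reference rate, target
    percent agreement p_o); joint request probabilities are solved from the
    marginals and agreement, with feasibility checked. Returns a long table
    with columns patient_id, exam, approach_request, reference_request.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    rows = []
    for exam, (p, q, p_o) in exam_rates.items():
        p11 = (p_o - 1 + p + q) / 2
        cells = np.array([p11, p - p11, q - p11, 1 - p - q + p11])
        if np.any(cells < -1e-12):
            raise InfeasibleSpecError(
                f"exam {exam!r}: agreement {p_o} infeasible with rates ({p}, {q})"
            )
        cells = np.clip(cells, 0, 1)
        draws = rng.choice(4, size=len(cohort), p=cells / cells.sum())
        for rec, d in zip(cohort, draws):
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "exam": exam,
                    "approach_request": int(d in (0, 1)),
                    "reference_request": int(d in (0, 2)),
                }
            )
    return pd.DataFrame(rows)
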