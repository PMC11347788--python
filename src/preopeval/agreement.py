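"""Inter-rater agreement statistics for paired binary clearance decisions.

Two chance-corrected coefficients are implemented for a 2×2
cross-classification of one evaluation approach against a reference rater:

* **Cohen's kappa** — chance agreement from the product of the raters'
  marginals, ``kappa = (p_o − p_e) / (1 − p_e)``; the large-sample standard
  error uses the Fleiss–Cohen–Everitt variance of the estimator.
* **Gwet's AC1** — robust to skewed marginals; with ``pi`` the mean of the
  two raters' "clear" proportions, chance agreement is ``2·pi·(1 − pi)``.
  The variance is Gwet's unconditional (subject-level) estimator.

Interpretation uses a Landis–Koch-style band scale (≥0.8 very good, ≥0.6
good, ≥0.4 moderate, ≥0.2 fair, else poor); each interval includes its upper
breakpoint, so a coefficient sitting exactly on a boundary takes the higher
band. Confidence intervals are Wald on the coefficient scale, clipped to
[−1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "TwoByTwo",
    "AgreementEstimate",
    "BandScale",
    "DEFAULT_BANDS",
    "crosstab",
    "percent_agreement",
    "cohen_kappa",
    "gwet_ac1",
    "compare_kappas_z",
    "interpret",
    "classify_decision",
    "two_proportion_test",
    "DegenerateTableError",
]

CLEAR, REJECT = "clear", "reject"


class DegenerateTableError(ValueError):
    """Chance agreement is 1, so the coefficient is undefined."""


@dataclass(frozen=True)
class TwoByTwo:
    """Cross-classification of an approach's decisions against the reference.

    a: both clear; b: approach clear / reference reject ("not followed");
    c: approach reject / reference clear ("incorrectly rejected");
    d: both reject.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n == 0:
            raise ValueError("table must contain at least one pair")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "TwoByTwo":
        """The table with the two raters' roles exchanged (b and c swap)."""
        return TwoByTwo(self.a, self.c, self.b, self.d)


@dataclass(frozen=True)
class AgreementEstimate:
    method: str  # kappa | ac1
    p_o: float
    p_e: float
    coef: float
    se: float
    ci: tuple[float, float]
    band: str
    degenerate: bool = False


@dataclass(frozen=True)
class BandScale:
    """Ordered (lower bound, label) pairs; intervals closed at the top."""

    bounds: tuple[tuple[float, str], ...]

    def label(self, coef: float) -> str:
        out = self.bounds[-1][1]
        for lo, lab in self.bounds:
            if coef >= lo:
                return lab
        return out


DEFAULT_BANDS = BandScale(
    bounds=(
        (0.8, "very good"),
        (0.6, "good"),
        (0.4, "moderate"),
        (0.2, "fair"),
        (-np.inf, "poor"),
    )
)

_Z95 = float(stats.norm.ppf(0.975))


def _as_binary(vec: Sequence[str]) -> np.ndarray:
    arr = np.asarray(vec)
    bad = set(np.unique(arr)) - {CLEAR, REJECT}
    if bad:
        raise ValueError(f"decisions must be clear/reject, got {sorted(bad)}")
    return arr == CLEAR


def crosstab(approach: Sequence[str], reference: Sequence[str]) -> TwoByTwo:
    """Count the four agreement cells from paired clear/reject decisions."""
    x = _as_binary(approach)
    y = _as_binary(reference)
    if len(x) != len(y) or len(x) == 0:
        raise ValueError("decision vectors must have equal positive length")
    return TwoByTwo(
        a=int(np.sum(x & y)),
        b=int(np.sum(x & ~y)),
        c=int(np.sum(~x & y)),
        d=int(np.sum(~x & ~y)),
    )


def decisions_from_table(t: TwoByTwo) -> tuple[list[str], list[str]]:
    """Expand cell counts back into paired per-patient decision vectors.

    Ordered deterministically: both-clear pairs first, then approach-clear /
    reference-reject, then approach-reject / reference-clear, then
    both-reject. ``crosstab`` of the result reproduces ``t`` exactly.
    """
    approach = [CLEAR] * (t.a + t.b) + [REJECT] * (t.c + t.d)
    reference = (
        [CLEAR] * t.a + [REJECT] * t.b + [CLEAR] * t.c + [REJECT] * t.d
    )
    return approach, reference


def percent_agreement(t: TwoByTwo) -> float:
    """Raw proportion of concordant pairs, (a + d) / N."""
    return (t.a + t.d) / t.n


def classify_decision(approach: str, reference: str) -> str:
    """Four-way primary-outcome category for one patient."""
    key = (approach, reference)
    mapping = {
        (CLEAR, CLEAR): "correctly_cleared",
        (REJECT, REJECT): "correctly_rejected",
        (CLEAR, REJECT): "not_followed",
        (REJECT, CLEAR): "incorrectly_rejected",
    }
    if key not in mapping:
        raise ValueError(f"decisions must be clear/reject, got {key}")
    return mapping[key]


def cohen_kappa(t: TwoByTwo, bands: BandScale = DEFAULT_BANDS) -> AgreementEstimate:
    """Cohen's kappa with Fleiss–Cohen–Everitt SE and Wald 95% CI."""
    n = t.n
    p = np.array([[t.a, t.b], [t.c, t.d]], dtype=float) / n
    p_o = p[0, 0] + p[1, 1]
    row = p.sum(axis=1)  # approach marginals (clear, reject)
    col = p.sum(axis=0)  # reference marginals
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-12:
        raise DegenerateTableError("chance agreement is 1; kappa undefined")
    coef = (p_o - p_e) / (1 - p_e)
    # Fleiss, Cohen & Everitt large-sample variance of kappa-hat
    term1 = sum(
        p[i, i] * ((1 - p_e) - (row[i] + col[i]) * (1 - p_o)) ** 2 for i in range(2)
    )
    term2 = (1 - p_o) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2 for i in range(2) for j in range(2) if i != j
    )
    term3 = (p_o * p_e - 2 * p_e + p_o) ** 2
    var = (term1 + term2 - term3) / (n * (1 - p_e) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    lo, hi = np.clip([coef - _Z95 * se, coef + _Z95 * se], -1.0, 1.0)
    return AgreementEstimate(
        method="kappa",
        p_o=float(p_o),
        p_e=p_e,
        coef=float(coef),
        se=se,
        ci=(float(lo), float(hi)),
        band=bands.label(float(coef)),
    )


def gwet_ac1(t: TwoByTwo, bands: BandScale = DEFAULT_BANDS) -> AgreementEstimate:
    """Gwet's first-order coefficient with the unconditional variance.

    Degenerate marginals (a rater always or never decides "clear") do not
    make AC1 undefined; the estimate is flagged ``degenerate`` instead.
    """
    n = t.n
    p_o = (t.a + t.d) / n
    p1 = (t.a + t.b) / n  # approach "clear" marginal
    p2 = (t.a + t.c) / n  # reference "clear" marginal
    pi = (p1 + p2) / 2
    p_e = 2 * pi * (1 - pi)
    coef = (p_o - p_e) / (1 - p_e)
    # subject-level linearisation: each cell contributes identical subjects
    cells = {
        (1, 1): t.a,
        (1, 0): t.b,
        (0, 1): t.c,
        (0, 0): t.d,
    }
    devs = []
    for (r1, r2), count in cells.items():
        if count == 0:
            continue
        agree = 1.0 if r1 == r2 else 0.0
        pi_s = (r1 + r2) / 2  # subject-level "clear" proportion
        pe_s = 2 * pi_s * (1 - pi_s)
        gamma_s = (agree - p_e) / (1 - p_e)
        gamma_star = gamma_s - 2 * (1 - coef) * (pe_s - p_e) / (1 - p_e)
        devs.append((count, gamma_star))
    if n > 1:
        var = sum(c * (g - coef) ** 2 for c, g in devs) / (n * (n - 1))
    else:
        var = 0.0
    se = float(np.sqrt(max(var, 0.0)))
    lo, hi = np.clip([coef - _Z95 * se, coef + _Z95 * se], -1.0, 1.0)
    degenerate = p1 in (0.0, 1.0) or p2 in (0.0, 1.0)
    return AgreementEstimate(
        method="ac1",
        p_o=float(p_o),
        p_e=float(p_e),
        coef=float(coef),
        se=se,
        ci=(float(lo), float(hi)),
        band=bands.label(float(coef)),
        degenerate=degenerate,
    )


def compare_kappas_z(e1: AgreementEstimate, e2: AgreementEstimate) -> tuple[float, float]:
    """Two-sided z-test comparing two agreement coefficients.

    The coefficients are treated as independent; for two approaches rated on
    the same patients this ignores the pairing and is a documented
    approximation.
    """
    denom = np.hypot(e1.se, e2.se)
    if denom == 0:
        if e1.coef == e2.coef:
            return 0.0, 1.0
        raise ValueError("both standard errors are zero with unequal coefficients")
    z = (e1.coef - e2.coef) / denom
    p = 2 * float(stats.norm.sf(abs(z)))
    return float(z), p


def interpret(coef: float, scale: BandScale = DEFAULT_BANDS) -> str:
    """Map a coefficient to its agreement band label."""
    return scale.label(coef)


def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int, continuity: bool = False
) -> tuple[float, float]:
    """Two-sample proportion z-test (pooled), continuity-uncorrected by default."""
    if continuity:
        p1, p2 = x1 / n1, x2 / n2
        pooled = (x1 + x2) / (n1 + n2)
        se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        if se == 0:
            return 0.0, 1.0
        corr = 0.5 * (1 / n1 + 1 / n2)
        diff = abs(p1 - p2) - corr
        z = max(diff, 0.0) / se * (1 if p1 >= p2 else -1)
        return float(z), 2 * float(stats.norm.sf(abs(z)))
    if x1 * n2 == x2 * n1:  # identical proportions: z = 0 exactly
        return 0.0, 1.0
    z, p = proportions_ztest([x1, x2], [n1, n2])
    return float(z), float(p)
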