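"""End-to-end study reporting.

Runs two evaluation approaches against a reference rater and produces:

* the primary-outcome agreement report (four-way classification counts with
  percentages, percent agreement, Cohen's kappa, Gwet's AC1 and the
  between-approach z-comparison, plus clearance rates);
* a per-examination agreement report (AC1 per exam type with not-followed /
  unnecessary request frequencies);
* the GRADE-stratum adherence arithmetic.

Rendered percentages are rounded half-up to one decimal; coefficients to two
decimals in markdown, full precision in the JSON structure.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .agreement import (
    AgreementEstimate,
    TwoByTwo,
    classify_decision,
    cohen_kappa,
    compare_kappas_z,
    crosstab,
    gwet_ac1,
    percent_agreement,
)

__all__ = [
    "round_half_up",
    "table2_report",
    "exam_agreement_report",
    "grade_stratum_summary",
    "render_table2_markdown",
]

GRADE_CLASSES = ("1A", "1B", "1C", "2A", "2B", "2C")

#: Row labels of the primary-outcome report, keyed by classification category.
CATEGORY_LABELS = {
    "correctly_cleared": "Correctly cleared for surgery",
    "correctly_rejected": "Correctly rejected",
    "not_followed": "Not followed recommendations",
    "incorrectly_rejected": "Incorrectly rejected",
}


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 18.05 → 18.1, not banker's 18.0)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _estimate_dict(e: AgreementEstimate) -> dict:
    return {
        "method": e.method,
        "p_o": e.p_o,
        "p_e": e.p_e,
        "coef": e.coef,
        "se": e.se,
        "ci": list(e.ci),
        "band": e.band,
        "degenerate": e.degenerate,
    }


def _approach_block(approach: Sequence[str], reference: Sequence[str]) -> dict:
    t = crosstab(approach, reference)
    n = t.n
    counts = {
        "correctly_cleared": t.a,
        "not_followed": t.b,
        "incorrectly_rejected": t.c,
        "correctly_rejected": t.d,
    }
    kappa = cohen_kappa(t)
    return {
        "n": n,
        "table": {"a": t.a, "b": t.b, "c": t.c, "d": t.d},
        "classification": {
            cat: {"count": c, "percent": round_half_up(100 * c / n)}
            for cat, c in counts.items()
        },
        "percent_agreement": round_half_up(100 * percent_agreement(t)),
        "clearance_rate": round_half_up(100 * (t.a + t.b) / n),
        "kappa": _estimate_dict(kappa),
        "ac1": _estimate_dict(gwet_ac1(t)),
        "_kappa_estimate": kappa,
    }


def table2_report(
    approach_a: Sequence[str],
    approach_b: Sequence[str],
    reference: Sequence[str],
    labels: tuple[str, str] = ("digital", "standard"),
) -> dict:
    """Primary-outcome agreement report for two approaches vs one reference.

    Decisions are ``clear``/``reject`` vectors of equal length, one entry per
    patient. Returns a JSON-serialisable dict; the kappa z-comparison between
    the approaches is included.
    """
    if not (len(approach_a) == len(approach_b) == len(reference)):
        raise ValueError("decision vectors must have equal length")
    block_a = _approach_block(approach_a, reference)
    block_b = _approach_block(approach_b, reference)
    z, p = compare_kappas_z(block_a.pop("_kappa_estimate"), block_b.pop("_kappa_estimate"))
    n = len(reference)
    ref_clear = sum(d == "clear" for d in reference)
    return {
        "n": n,
        "approaches": {labels[0]: block_a, labels[1]: block_b},
        "reference_clearance_rate": round_half_up(100 * ref_clear / n),
        "kappa_comparison": {"z": z, "p": p},
    }


def exam_agreement_report(requests: pd.DataFrame) -> pd.DataFrame:
    """Per-exam agreement table from long-format request indicators.

    ``requests`` columns: patient_id, exam, approach_request,
    reference_request (0/1). For each exam: Gwet's AC1 with CI and band (a
    rater who never or always requests yields a flagged degenerate estimate,
    not NaN), plus the not-followed frequency (reference requested, approach
    did not) and unnecessary frequency (approach requested, reference did
    not) as fractions of all patients.
    """
    required = {"patient_id", "exam", "approach_request", "reference_request"}
    missing = required - set(requests.columns)
    if missing:
        raise ValueError(f"requests table missing columns {sorted(missing)}")
    rows = []
    for exam, grp in requests.groupby("exam", sort=True):
        appr = ["clear" if v else "reject" for v in grp["approach_request"]]
        ref = ["clear" if v else "reject" for v in grp["reference_request"]]
        t = crosstab(appr, ref)
        est = gwet_ac1(t)
        n = t.n
        rows.append(
            {
                "exam": exam,
                "n": n,
                "ac1": est.coef,
                "ac1_ci_lo": est.ci[0],
                "ac1_ci_hi": est.ci[1],
                "band": est.band,
                "degenerate": est.degenerate,
                "not_followed": t.c / n,
                "unnecessary": t.b / n,
            }
        )
    return pd.DataFrame(rows)


def grade_stratum_summary(
    strata_counts: Mapping[str, int], adhered: int | None = None
) -> dict:
    """Totals and shares over GRADE strata of triggered recommendations.

    ``strata_counts`` maps GRADE class → number of recommendations; returns
    the stratum total, the adherence percentage (``adhered`` of total,
    rounded half-up to the integer) and the strong-recommendation share
    (classes 1A–1C, one decimal).
    """
    unknown = set(strata_counts) - set(GRADE_CLASSES)
    if unknown:
        raise ValueError(f"unknown GRADE classes {sorted(unknown)}")
    total = sum(strata_counts.values())
    if total == 0:
        raise ValueError("no recommendations in any GRADE stratum")
    strong = sum(strata_counts.get(g, 0) for g in ("1A", "1B", "1C"))
    out = {
        "total": total,
        "strata": dict(strata_counts),
        "strong_count": strong,
        "strong_share_percent": round_half_up(100 * strong / total),
    }
    if adhered is not None:
        if not 0 <= adhered <= total:
            raise ValueError("adhered count outside [0, total]")
        out["adhered"] = adhered
        out["adherence_percent"] = round_half_up(100 * adhered / total, 0)
    return out


def triplets_from_tables(
    t_a: "TwoByTwo", t_b: "TwoByTwo", rng=None
) -> tuple[list[str], list[str], list[str]]:
    """Per-patient decision triplets realising two published 2×2 tables.

    Both tables must share the reference marginal (same count of
    reference-clear patients). Within each reference block, each approach's
    clear decisions are assigned from the start of the block; the joint
    distribution of the two approaches is otherwise unconstrained, exactly as
    in a report that prints only the two pairwise tables. Pass a numpy
    ``Generator`` to shuffle patient order (pairwise tables are invariant).
    """
    if t_a.a + t_a.c != t_b.a + t_b.c or t_a.n != t_b.n:
        raise ValueError("tables disagree on the reference marginal")
    ref_clear, n = t_a.a + t_a.c, t_a.n
    reference = ["clear"] * ref_clear + ["reject"] * (n - ref_clear)

    def approach(t: TwoByTwo) -> list[str]:
        block_clear = ["clear"] * t.a + ["reject"] * t.c
        block_reject = ["clear"] * t.b + ["reject"] * t.d
        return block_clear + block_reject

    a_vec, b_vec = approach(t_a), approach(t_b)
    if rng is not None:
        order = rng.permutation(n)
        a_vec = [a_vec[i] for i in order]
        b_vec = [b_vec[i] for i in order]
        reference = [reference[i] for i in order]
    return a_vec, b_vec, reference


def render_table2_markdown(report: dict) -> str:
    """Markdown rendering of the primary-outcome report (Table-2 layout)."""
    labels = list(report["approaches"])
    lines = [
        "| | " + " | ".join(labels) + " |",
        "|---|" + "---|" * len(labels),
    ]
    kappa_cells = []
    for lab in labels:
        k = report["approaches"][lab]["kappa"]
        kappa_cells.append(
            f"{k['coef']:.2f} ({k['ci'][0]:.2f}–{k['ci'][1]:.2f})"
        )
    lines.append("| Cohen's kappa | " + " | ".join(kappa_cells) + " |")
    for cat in ("correctly_cleared", "correctly_rejected", "not_followed", "incorrectly_rejected"):
        cells = []
        for lab in labels:
            c = report["approaches"][lab]["classification"][cat]
            cells.append(f"{c['count']} ({c['percent']})")
        lines.append(f"| {CATEGORY_LABELS[cat]} | " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def classification_counts(approach: Sequence[str], reference: Sequence[str]) -> dict[str, int]:
    """Four-way category counts over a cohort (equals the crosstab cells)."""
    counts = {cat: 0 for cat in CATEGORY_LABELS}
    for a, r in zip(approach, reference):
        counts[classify_decision(a, r)] += 1
    return counts
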