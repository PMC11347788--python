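"""Risk-score calculators exposed to the rule engine by name.

All clinical point tables (Charlson weights, POSPOM points, STOP-BANG items
and cutoff, AKI factor list and class map) ship as versioned YAML data files;
the code implements only *weighted sum*, *count* and *lookup*. Missing inputs
yield :data:`~preopeval.observations.MISSING` (unknown) — never an imputed
zero — mirroring how cohort tables report an explicit "Unknown" comorbidity
stratum.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path
from typing import Any, Callable, Mapping

import yaml

from .observations import (
    MISSING,
    ObservationDictionary,
    PatientRecord,
    pending_inputs,
    resolved_value,
)

__all__ = [
    "load_table",
    "rcri_clinical_factors",
    "rcri_total",
    "charlson",
    "pospom",
    "stop_bang",
    "aki_risk_index",
    "default_bindings",
    "RCRI_ITEMS",
]

#: The five clinical cardiac risk factors counted by the revised cardiac risk
#: index (the sixth published item, high-risk surgery, is observation 1.1.3).
RCRI_ITEMS = ("2.2.1", "2.2.2", "2.2.3", "2.2.4", "2.2.5")
RCRI_SURGERY_ITEM = "1.1.3"


class TableError(ValueError):
    """Malformed or checksum-failing score table."""


def _data_path(name: str) -> Path:
    return Path(str(resources.files("preopeval").joinpath("data", name)))


def load_table(name_or_path: str | Path, verify_checksum: bool = False) -> dict:
    """Load a score table; with ``verify_checksum`` a ``.sha256`` sidecar
    must match the file bytes (guards against silent transcription drift)."""
    path = Path(name_or_path)
    if not path.exists():
        path = _data_path(str(name_or_path))
    raw = path.read_bytes()
    if verify_checksum:
        sidecar = path.with_suffix(path.suffix + ".sha256")
        if not sidecar.exists():
            raise TableError(f"checksum sidecar missing for {path.name}")
        expected = sidecar.read_text().strip()
        actual = hashlib.sha256(raw).hexdigest()
        if actual != expected:
            raise TableError(f"{path.name}: checksum mismatch")
    table = yaml.safe_load(raw.decode("utf-8"))
    if not isinstance(table, dict) or "name" not in table:
        raise TableError(f"{path.name}: not a score table")
    return table


def _item_value(record: PatientRecord, dictionary: ObservationDictionary, item: Mapping) -> Any:
    """Resolve one table item to True/False/MISSING.

    Items either reference an observation (``obs``) or a record field
    (``field``: age_gt/age_ge/bmi_gt/sex_male/emergency).
    """
    if "obs" in item:
        v = resolved_value(record, dictionary, item["obs"])
        if v is MISSING:
            return MISSING
        return v == "yes"
    kind = item["field"]
    if kind == "age_gt":
        return record.age > item["value"]
    if kind == "age_ge":
        return record.age >= item["value"]
    if kind == "bmi_gt":
        return record.bmi > item["value"]
    if kind == "sex_male":
        return record.sex == "male"
    if kind == "emergency":
        return not record.context.elective
    raise TableError(f"unknown item field kind {item['field']!r}")


def _count_items(record, dictionary, items) -> int | Any:
    count = 0
    for item in items:
        v = _item_value(record, dictionary, item)
        if v is MISSING:
            return MISSING
        count += bool(v)
    return count


def rcri_clinical_factors(record: PatientRecord, dictionary: ObservationDictionary):
    """Count of the five clinical cardiac risk factors (0..5), or MISSING."""
    return _count_items(record, dictionary, [{"obs": i} for i in RCRI_ITEMS])


def rcri_total(record: PatientRecord, dictionary: ObservationDictionary):
    """Published six-item total: clinical factors plus high-risk surgery."""
    clinical = rcri_clinical_factors(record, dictionary)
    surgery = resolved_value(record, dictionary, RCRI_SURGERY_ITEM)
    if clinical is MISSING or surgery is MISSING:
        return MISSING
    return clinical + (surgery == "yes")


def charlson(record: PatientRecord, dictionary: ObservationDictionary, table: dict | None = None):
    """Weighted comorbidity sum over the shipped condition table.

    A condition whose severe form is flagged does not also count its milder
    form (``supersedes`` links). Any required flag that cannot be resolved
    makes the whole score unknown.
    """
    if table is None:
        table = load_table("charlson_weights.yaml")
    values = {}
    for item in table["items"]:
        v = _item_value(record, dictionary, item)
        if v is MISSING:
            return MISSING
        values[item["obs"]] = bool(v)
    superseded = {
        item["supersedes"]
        for item in table["items"]
        if item.get("supersedes") and values[item["obs"]]
    }
    return sum(
        item["weight"]
        for item in table["items"]
        if values[item["obs"]] and item["obs"] not in superseded
    )


def pospom(record: PatientRecord, dictionary: ObservationDictionary, table: dict | None = None):
    """Additive mortality-risk points from a configurable table.

    The default table (``pospom_points_synthetic.yaml``) is a *synthetic*
    stand-in with the published table's structure (age bands + comorbidity
    points + procedure-group points) but demonstrator point values; it is
    loaded with checksum verification.
    """
    if table is None:
        table = load_table("pospom_points_synthetic.yaml", verify_checksum=True)
    points = 0
    age_points = None
    for band in sorted(table["age_bands"], key=lambda b: b["min"]):
        if record.age >= band["min"]:
            age_points = band["points"]
    if age_points is None:
        raise TableError("pospom: age below every age band")
    points += age_points
    for item in table["comorbidities"]:
        v = _item_value(record, dictionary, item)
        if v is MISSING:
            return MISSING
        points += item["points"] if v else 0
    points += table["procedure_points"][record.context.risk_class]
    return points


def stop_bang(record: PatientRecord, dictionary: ObservationDictionary, table: dict | None = None):
    """Eight-item sleep-apnoea screen: (count 0..8, risk band) or MISSING."""
    if table is None:
        table = load_table("stop_bang.yaml")
    count = _count_items(record, dictionary, table["items"])
    if count is MISSING:
        return MISSING
    band = None
    for b in sorted(table["bands"], key=lambda b: b["min"]):
        if count >= b["min"]:
            band = b["label"]
    return count, band


def aki_risk_index(record: PatientRecord, dictionary: ObservationDictionary, table: dict | None = None):
    """(risk-factor count, risk class) from the configurable count→class map."""
    if table is None:
        table = load_table("aki_index.yaml")
    count = _count_items(record, dictionary, table["factors"])
    if count is MISSING:
        return MISSING
    for cls in table["classes"]:
        if cls["max"] is None or count <= cls["max"]:
            return count, cls["label"]
    raise TableError("aki_risk_index: class map does not cover the count")


def _table_obs_ids(table: dict, keys=("items", "factors", "comorbidities")) -> list[str]:
    ids = []
    for key in keys:
        for item in table.get(key, []):
            if "obs" in item:
                ids.append(item["obs"])
    return ids


def default_bindings(
    declared: list[str], dictionary: ObservationDictionary
) -> tuple[dict[str, Callable], dict[str, Callable]]:
    """Score bindings for the rule engine.

    Returns ``(scores, requirements)``: callables ``record -> value`` (MISSING
    when undecidable) and ``record -> set of observation ids`` still needed.
    Besides the clinical scores, the demographic/context values ``age``,
    ``bmi``, ``asa``, ``sex`` and ``surgical_risk`` are exposed as read-only
    named targets so rule files never embed arithmetic.
    """
    stop_bang_table = load_table("stop_bang.yaml")
    aki_table = load_table("aki_index.yaml")
    charlson_table = load_table("charlson_weights.yaml")
    pospom_table = load_table("pospom_points_synthetic.yaml", verify_checksum=True)

    def _req(ids):
        def req(record: PatientRecord) -> set[str]:
            return pending_inputs(record, dictionary, ids)

        return req

    def _first(f):
        def g(record):
            v = f(record)
            return v if v is MISSING else v[0]

        return g

    scores: dict[str, Callable] = {
        "rcri_clinical_factors": lambda r: rcri_clinical_factors(r, dictionary),
        "rcri_total": lambda r: rcri_total(r, dictionary),
        "charlson": lambda r: charlson(r, dictionary, charlson_table),
        "pospom": lambda r: pospom(r, dictionary, pospom_table),
        "stop_bang": _first(lambda r: stop_bang(r, dictionary, stop_bang_table)),
        "aki_factor_count": _first(lambda r: aki_risk_index(r, dictionary, aki_table)),
        "surgical_risk": lambda r: r.context.risk_class,
        "age": lambda r: r.age,
        "bmi": lambda r: r.bmi,
        "asa": lambda r: r.asa,
        "sex": lambda r: r.sex,
    }
    requirements: dict[str, Callable] = {
        "rcri_clinical_factors": _req(RCRI_ITEMS),
        "rcri_total": _req(RCRI_ITEMS + (RCRI_SURGERY_ITEM,)),
        "charlson": _req(_table_obs_ids(charlson_table)),
        "pospom": _req(_table_obs_ids(pospom_table)),
        "stop_bang": _req(_table_obs_ids(stop_bang_table)),
        "aki_factor_count": _req(_table_obs_ids(aki_table)),
    }
    unknown = [name for name in declared if name not in scores]
    if unknown:
        raise TableError(f"undeclared score bindings requested: {unknown}")
    if declared:
        keep = set(declared)
        scores = {k: v for k, v in scores.items() if k in keep}
        requirements = {k: v for k, v in requirements.items() if k in keep}
    return scores, requirements
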