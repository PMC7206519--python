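"""Rule-based patient profiling: evaluate a patient record into an integer
severity vector over the term space.

Each rule targets one term and carries a declarative condition over record
fields, a severity value in {0..3} (0 = no need, 3 = worst) and a priority.
For every term, the matching rule of highest priority wins; ties at the top
priority resolve to the maximum value; a term with no matching rule — or
whose fields are missing from the record — stays 0.  This fail-soft
semantics means an empty record produces the zero vector, never an error.

The default ruleset encodes standard clinical reference ranges: BP below
140/90 mm Hg is severity 0, with grades 1/2/3 at 140-159/90-99,
160-179/100-109 and >=180/>=110 (max of the systolic and diastolic grades);
laboratory values are graded by their fold over the reference limit
(<=1.2x -> 1, <=1.5x -> 2, else 3, symmetric below the lower limit); PHQ-9
uses the standard 0-4/5-9/10-14/>=15 depression bands; everything is
overridable from YAML configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .vectorspace import VectorSpace, default_space

#: operators usable in rule conditions
_OPS = {
    "ge": lambda a, b: a >= b,
    "gt": lambda a, b: a > b,
    "le": lambda a, b: a <= b,
    "lt": lambda a, b: a < b,
    "eq": lambda a, b: a == b,
    "in": lambda a, b: a in b,
    "contains": lambda a, b: b in a,
}

#: reference ranges (lower, upper) for laboratory tests, mmol/L unless noted
LAB_RANGES: dict[str, tuple[float, float]] = {
    "glucose": (3.9, 6.1),
    "total_cholesterol": (2.9, 5.2),
    "triglyceride": (0.56, 1.70),
    "hdl": (1.20, 1.68),
    "ldl": (2.07, 3.12),
}

#: uric acid (umol/L) by (sex, age band): men/women, under/over 60
URIC_ACID_RANGES: dict[tuple[str, str], tuple[float, float]] = {
    ("male", "under60"): (149.0, 416.0),
    ("female", "under60"): (89.0, 357.0),
    ("male", "over60"): (250.0, 476.0),
    ("female", "over60"): (190.0, 434.0),
}

BMI_RANGE = (18.5, 23.9)  # kg/m^2, Chinese adult reference


@dataclass
class PatientRecord:
    """One patient's data; every field may be missing (None / empty)."""

    patient_id: str
    sex: str | None = None                   # "male" | "female"
    age: float | None = None                 # years
    height: float | None = None              # m
    weight: float | None = None              # kg
    bmi: float | None = None                 # kg/m^2 (derived if absent)
    pregnant: bool | None = None
    history: set[str] = field(default_factory=set)
    labs: dict[str, float] = field(default_factory=dict)
    monitoring: dict[str, object] = field(default_factory=dict)
    questionnaires: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("age", "height", "weight", "bmi"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative")
        for k, v in self.labs.items():
            if v is not None and v < 0:
                raise ValueError(f"lab {k!r} must be nonnegative")
        phq9 = self.questionnaires.get("phq9")
        if phq9 is not None and not 0 <= phq9 <= 27:
            raise ValueError("PHQ-9 total must lie in 0..27")

    def effective_bmi(self) -> float | None:
        if self.bmi is not None:
            return self.bmi
        if self.height and self.weight:
            return self.weight / self.height**2
        return None


#: field name -> accessor; the closed namespace rules may reference
FIELD_ACCESSORS = {
    "sex": lambda r: r.sex,
    "age": lambda r: r.age,
    "bmi": lambda r: r.effective_bmi(),
    "pregnant": lambda r: r.pregnant,
    "history": lambda r: r.history,
    "systolic_bp": lambda r: r.monitoring.get("systolic_bp"),
    "diastolic_bp": lambda r: r.monitoring.get("diastolic_bp"),
    "cigarettes_per_day": lambda r: r.monitoring.get("cigarettes_per_day"),
    "drinks_per_week": lambda r: r.monitoring.get("drinks_per_week"),
    "diet": lambda r: r.monitoring.get("diet"),
    "medications": lambda r: r.monitoring.get("medications") or set(),
    "adherence": lambda r: r.monitoring.get("adherence"),
    "sleep": lambda r: r.monitoring.get("sleep"),
    "phq9": lambda r: r.questionnaires.get("phq9"),
    "ipaq": lambda r: r.questionnaires.get("ipaq"),
    **{lab: (lambda r, _lab=lab: r.labs.get(_lab))
       for lab in (*LAB_RANGES, "uric_acid")},
}


@dataclass(frozen=True)
class SeverityRule:
    target_term: str
    condition: dict
    value: int
    priority: int = 0

    def __post_init__(self) -> None:
        if self.value not in (0, 1, 2, 3):
            raise ValueError(f"rule value must be in 0..3, got {self.value}")
        _validate_condition(self.condition)


def _validate_condition(cond: dict) -> None:
    if "all" in cond or "any" in cond:
        key = "all" if "all" in cond else "any"
        for sub in cond[key]:
            _validate_condition(sub)
        return
    missing = {"field", "op", "value"} - set(cond)
    if missing:
        raise ValueError(f"malformed condition {cond!r}: missing {sorted(missing)}")
    if cond["field"] not in FIELD_ACCESSORS:
        raise ValueError(f"unknown record field {cond['field']!r}")
    if cond["op"] not in _OPS:
        raise ValueError(f"unknown operator {cond['op']!r}")


def _matches(cond: dict, record: PatientRecord) -> bool:
    if "all" in cond:
        return all(_matches(c, record) for c in cond["all"])
    if "any" in cond:
        return any(_matches(c, record) for c in cond["any"])
    actual = FIELD_ACCESSORS[cond["field"]](record)
    if actual is None:
        return False  # missing data never matches
    try:
        return bool(_OPS[cond["op"]](actual, cond["value"]))
    except TypeError:
        return False


@dataclass
class PatientVector:
    patient_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if np.any((self.values < 0) | (self.values > 3)):
            raise ValueError("severity entries must lie in {0, 1, 2, 3}")


def evaluate_rules(record: PatientRecord, ruleset: list[SeverityRule],
                   space: VectorSpace | None = None) -> PatientVector:
    """Evaluate a record into its severity vector (total: always succeeds)."""
    space = space or default_space()
    for rule in ruleset:
        if rule.target_term not in space:
            raise ValueError(f"rule targets unknown term {rule.target_term!r}")
    best: dict[str, tuple[int, int]] = {}  # term -> (priority, value)
    for rule in ruleset:
        if _matches(rule.condition, record):
            cur = best.get(rule.target_term)
            cand = (rule.priority, rule.value)
            if cur is None or cand > cur:
                best[rule.target_term] = cand
    values = [best.get(t, (0, 0))[1] for t in space.terms]
    return PatientVector(record.patient_id, np.array(values))


def load_ruleset(text: str, space: VectorSpace | None = None) -> list[SeverityRule]:
    """Parse a YAML ruleset (list of ``{term, when, value, priority}``)."""
    space = space or default_space()
    data = yaml.safe_load(text)
    if not isinstance(data, list):
        raise ValueError("ruleset must be a YAML list of rules")
    rules = []
    for i, raw in enumerate(data, start=1):
        try:
            rule = SeverityRule(raw["term"], raw["when"], int(raw["value"]),
                                int(raw.get("priority", 0)))
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"rule #{i}: {exc}") from exc
        if rule.target_term not in space:
            raise ValueError(f"rule #{i}: term {rule.target_term!r} not in the vector space")
        rules.append(rule)
    return rules


def ruleset_to_yaml(rules: list[SeverityRule]) -> str:
    return yaml.safe_dump([{"term": r.target_term, "when": r.condition,
                            "value": r.value, "priority": r.priority}
                           for r in rules], sort_keys=False, allow_unicode=True)


def _fold_band_rules(term: str, field_name: str, lower: float, upper: float,
                     extra: list[dict] | None = None) -> list[SeverityRule]:
    """Severity 1/2/3 by fold over the reference limit, symmetric below it."""
    def cond(leaf: dict) -> dict:
        return {"all": [*extra, leaf]} if extra else leaf

    rules = []
    for sev, fold in ((1, 1.0), (2, 1.2), (3, 1.5)):
        rules.append(SeverityRule(term, cond({"field": field_name, "op": "gt",
                                              "value": round(upper * fold, 6)}),
                                  sev, priority=sev))
        rules.append(SeverityRule(term, cond({"field": field_name, "op": "lt",
                                              "value": round(lower / fold, 6)}),
                                  sev, priority=sev))
    return rules


def default_ruleset(space: VectorSpace | None = None) -> list[SeverityRule]:
    """The shipped ruleset over the default 33-term space (clinical cut-points)."""
    rules: list[SeverityRule] = []

    # blood pressure: graded on the worse of systolic / diastolic
    bp_bands = [(1, 140, 90), (2, 160, 100), (3, 180, 110)]
    for sev, sys_lo, dia_lo in bp_bands:
        rules.append(SeverityRule("blood pressure",
                                  {"any": [{"field": "systolic_bp", "op": "ge", "value": sys_lo},
                                           {"field": "diastolic_bp", "op": "ge", "value": dia_lo}]},
                                  sev, priority=sev))

    # laboratory tests graded by fold over the reference range
    for term, fld in (("blood glucose", "glucose"),
                      ("total cholesterol", "total_cholesterol"),
                      ("triglyceride", "triglyceride"),
                      ("hdl", "hdl"), ("ldl", "ldl")):
        lo, hi = LAB_RANGES[fld]
        rules += _fold_band_rules(term, fld, lo, hi)
    for (sex, band), (lo, hi) in URIC_ACID_RANGES.items():
        age_leaf = ({"field": "age", "op": "lt", "value": 60} if band == "under60"
                    else {"field": "age", "op": "ge", "value": 60})
        rules += _fold_band_rules("uric acid", "uric_acid", lo, hi,
                                  extra=[{"field": "sex", "op": "eq", "value": sex}, age_leaf])

    rules += _fold_band_rules("bmi", "bmi", *BMI_RANGE)
    for sev, bmi_lo in ((1, 24.0), (2, 28.0)):
        rules.append(SeverityRule("weight control",
                                  {"field": "bmi", "op": "ge", "value": bmi_lo},
                                  sev, priority=sev))

    # disease history: presence signals an education need
    for term, label in (("hypertension", "hypertension"), ("diabetes", "diabetes"),
                        ("stroke", "stroke"), ("hyperlipidemia", "hyperlipidemia"),
                        ("coronary artery disease", "coronary artery disease"),
                        ("copd", "copd"), ("other disease", "other")):
        rules.append(SeverityRule(term, {"field": "history", "op": "contains",
                                         "value": label}, 2))

    # smoking / drinking graded by quantity
    for sev, cigs in ((1, 1), (2, 10), (3, 20)):
        rules.append(SeverityRule("smoking", {"field": "cigarettes_per_day",
                                              "op": "ge", "value": cigs}, sev, priority=sev))
    for sev, drinks in ((1, 1), (2, 8), (3, 15)):
        rules.append(SeverityRule("drinking", {"field": "drinks_per_week",
                                               "op": "ge", "value": drinks}, sev, priority=sev))

    # ordinal self-ratings
    for term, fld in (("diet", "diet"), ("medication adherence", "adherence"),
                      ("sleep", "sleep")):
        for sev, level in ((1, "medium"), (2, "poor")):
            rules.append(SeverityRule(term, {"field": fld, "op": "eq", "value": level},
                                      sev, priority=sev))
    rules.append(SeverityRule("salt intake", {"field": "diet", "op": "eq",
                                              "value": "poor"}, 1))

    # questionnaires: PHQ-9 depression bands, IPAQ activity level
    for sev, total in ((1, 5), (2, 10), (3, 15)):
        rules.append(SeverityRule("depression", {"field": "phq9", "op": "ge",
                                                 "value": total}, sev, priority=sev))
    rules.append(SeverityRule("mental health", {"field": "phq9", "op": "ge",
                                                "value": 10}, 1))
    for term in ("physical activity", "exercise"):
        for sev, level in ((1, "moderate"), (2, "low")):
            rules.append(SeverityRule(term, {"field": "ipaq", "op": "eq",
                                             "value": level}, sev, priority=sev))

    # demographics: sex terms fire only with a sex-specific education need,
    # so a patient with no abnormal finding keeps a zero vector
    rules.append(SeverityRule("pregnancy", {"field": "pregnant", "op": "eq",
                                            "value": True}, 2))
    rules.append(SeverityRule("female", {"all": [{"field": "sex", "op": "eq", "value": "female"},
                                                 {"field": "pregnant", "op": "eq", "value": True}]}, 1))
    rules.append(SeverityRule("male", {"all": [{"field": "sex", "op": "eq", "value": "male"},
                                               {"field": "cigarettes_per_day", "op": "ge", "value": 1}]}, 1))
    for sev, age in ((1, 60), (2, 75)):
        rules.append(SeverityRule("age", {"field": "age", "op": "ge", "value": age},
                                  sev, priority=sev))

    # current medication signals relevance of that drug-topic education
    for term, med in (("antihypertensive drug", "antihypertensive"),
                      ("hypoglycemic drug", "hypoglycemic"),
                      ("hypolipidemic drug", "hypolipidemic")):
        rules.append(SeverityRule(term, {"field": "medications", "op": "contains",
                                         "value": med}, 1))

    space = space or default_space()
    for r in rules:
        if r.target_term not in space:
            raise ValueError(f"default rule targets term {r.target_term!r} outside the space")
    return rules


def record_to_dict(record: PatientRecord) -> dict:
    return {
        "patient_id": record.patient_id, "sex": record.sex, "age": record.age,
        "height": record.height, "weight": record.weight, "bmi": record.bmi,
        "pregnant": record.pregnant, "history": sorted(record.history),
        "labs": dict(record.labs),
        "monitoring": {k: (sorted(v) if isinstance(v, set) else v)
                       for k, v in record.monitoring.items()},
        "questionnaires": dict(record.questionnaires),
    }


def record_from_dict(data: dict) -> PatientRecord:
    monitoring = dict(data.get("monitoring", {}))
    if "medications" in monitoring and monitoring["medications"] is not None:
        monitoring["medications"] = set(monitoring["medications"])
    return PatientRecord(
        patient_id=data["patient_id"], sex=data.get("sex"), age=data.get("age"),
        height=data.get("height"), weight=data.get("weight"), bmi=data.get("bmi"),
        pregnant=data.get("pregnant"), history=set(data.get("history", [])),
        labs=dict(data.get("labs", {})), monitoring=monitoring,
        questionnaires=dict(data.get("questionnaires", {})),
    )


def write_patients_json(records: list[PatientRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([record_to_dict(r) for r in records], fh, indent=1)


def read_patients_json(path) -> list[PatientRecord]:
    with open(path, encoding="utf-8") as fh:
        return [record_from_dict(d) for d in json.load(fh)]
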