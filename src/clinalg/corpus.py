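"""Line-delimited JSON case corpus and expectation files."""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import yaml

from .engine import PatientCase
from .qa import Expectation


def case_to_dict(case: PatientCase) -> dict:
    return {
        "id": case.id,
        "age_days": case.age_days,
        "sex": case.sex,
        "weight_kg": case.weight_kg,
        "answers": dict(case.answers),
        "estimated": sorted(case.estimated),
        "label": case.label,
    }


def case_from_dict(d: dict) -> PatientCase:
    return PatientCase(
        id=str(d["id"]),
        age_days=int(d["age_days"]),
        sex=str(d.get("sex", "")),
        weight_kg=float(d["weight_kg"]),
        answers=dict(d.get("answers", {})),
        estimated=set(d.get("estimated", [])),
        label=d.get("label"),
    )


def write_cases(cases: Iterable[PatientCase], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in cases:
            fh.write(json.dumps(case_to_dict(c), sort_keys=True) + "\n")


def read_cases(path: str) -> list[PatientCase]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(case_from_dict(json.loads(line)))
    return out


def read_expectations(path: str) -> list[Expectation]:
    """Expectations as a YAML/JSON list of mappings."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    out = []
    for d in data:
        drugs = d.get("expected_drugs")
        out.append(
            Expectation(
                case_id=str(d["case_id"]),
                expected_diagnoses=frozenset(d.get("expected_diagnoses", [])),
                expected_referral=bool(d["expected_referral"]),
                expected_drugs=None if drugs is None else frozenset(drugs),
            )
        )
    return out
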