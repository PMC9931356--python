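"""Reading and writing algorithm documents.

One schema, two dialects: a human-readable YAML authoring form and a
canonical, key-sorted JSON exchange form.  Both carry a ``format_version``
field.  ``deserialize(serialize(alg))`` is the identity on every valid
algorithm, and serialization is canonical — two serializations of equal
algorithms are byte-identical.
"""

from __future__ import annotations

import json
from typing import Any, Mapping

import yaml

from .conditions import Condition, condition_from_dict
from .model import (
    AlgorithmMeta,
    Answer,
    ClinicalAlgorithm,
    Diagnosis,
    DosingRule,
    DrugDefinition,
    Finding,
    Formulation,
    Management,
    Node,
    TreatmentSpec,
    assign_terminology,
    validate_algorithm,
)

FORMAT_VERSION = "1.0"


class ParseError(ValueError):
    """The document does not parse as the declared format."""


class ValidationError(ValueError):
    """The document parsed but violates structural invariants."""

    def __init__(self, findings: list[Finding]):
        self.findings = findings
        lines = [f"[{f.code}] {f.subject}: {f.message}" for f in findings]
        super().__init__(
            f"{len(findings)} validation finding(s):\n" + "\n".join(lines)
        )


# -- to_dict ----------------------------------------------------------------

def _opt(d: dict, key: str, value: Any, default: Any = None) -> None:
    if value != default:
        d[key] = value


def _node_to_dict(n: Node) -> dict:
    d: dict[str, Any] = {
        "id": n.id,
        "stage": n.stage,
        "kind": n.kind,
        "label": n.label,
        "answer_type": n.answer_type,
        "answers": [_answer_to_dict(a) for a in n.answers],
    }
    _opt(d, "unit", n.unit)
    _opt(d, "admissible_lo", None if n.admissible_lo is None else float(n.admissible_lo))
    _opt(d, "admissible_hi", None if n.admissible_hi is None else float(n.admissible_hi))
    if n.display_condition is not None:
        d["display_condition"] = n.display_condition.to_dict()
    _opt(d, "referral_triggering", n.referral_triggering, False)
    _opt(d, "estimable", n.estimable, False)
    _opt(d, "emergency_relevant", n.emergency_relevant, False)
    _opt(d, "help", n.help)
    _opt(d, "auto_from", n.auto_from)
    return d


def _answer_to_dict(a: Answer) -> dict:
    d: dict[str, Any] = {"id": a.id, "label": a.label}
    _opt(d, "lo", None if a.lo is None else float(a.lo))
    _opt(d, "hi", None if a.hi is None else float(a.hi))
    return d


def _diagnosis_to_dict(dx: Diagnosis) -> dict:
    d: dict[str, Any] = {
        "id": dx.id,
        "label": dx.label,
        "severity_tier": dx.severity_tier,
        "condition": dx.condition.to_dict(),
    }
    _opt(d, "managements", list(dx.managements), [])
    if dx.treatments:
        d["treatments"] = [
            {"drug": t.drug_id, "alternatives": list(t.alternative_drug_ids)}
            for t in dx.treatments
        ]
    _opt(d, "excludes", list(dx.excludes), [])
    return d


def to_dict(alg: ClinicalAlgorithm) -> dict:
    """Plain-data document form (registries as authoring-ordered lists)."""
    return {
        "format_version": FORMAT_VERSION,
        "meta": {
            "name": alg.meta.name,
            "country": alg.meta.country,
            "version_id": alg.meta.version_id,
            "age_min_days": alg.meta.age_min_days,
            "age_max_days": alg.meta.age_max_days,
        },
        "stages": list(alg.stages),
        "nodes": [_node_to_dict(n) for n in alg.nodes.values()],
        "diagnoses": [_diagnosis_to_dict(d) for d in alg.diagnoses.values()],
        "managements": [
            {
                "id": m.id,
                "label": m.label,
                "kind": m.kind,
                **({"emergency_guidance": True} if m.emergency_guidance else {}),
            }
            for m in alg.managements.values()
        ],
        "drugs": [
            {
                "id": dr.id,
                "name": dr.name,
                "formulations": [
                    {
                        "form": f.form,
                        "strength_mg": float(f.strength_mg),
                        "increment": float(f.increment),
                    }
                    for f in dr.formulations
                ],
            }
            for dr in alg.drugs.values()
        ],
        "dosing_rules": [
            {
                "id": r.id,
                "drug": r.drug_id,
                "indication": r.indication,
                "age_lo_days": float(r.age_lo_days),
                "age_hi_days": float(r.age_hi_days),
                "weight_lo_kg": float(r.weight_lo_kg),
                "weight_hi_kg": float(r.weight_hi_kg),
                "target_mg_per_kg": float(r.target_mg_per_kg),
                "min_mg_per_kg": float(r.min_mg_per_kg),
                "max_mg_per_kg": float(r.max_mg_per_kg),
                "max_mg_per_dose": float(r.max_mg_per_dose),
                "frequency_per_day": r.frequency_per_day,
                "duration_days": r.duration_days,
            }
            for r in alg.dosing_rules.values()
        ],
        "terminology": dict(sorted(alg.terminology.items())),
    }


# -- from_dict --------------------------------------------------------------

def _require(d: Mapping, key: str, subject: str) -> Any:
    if key not in d:
        raise ParseError(f"{subject}: missing required field {key!r}")
    return d[key]


def _parse_condition(d: Any, subject: str) -> Condition:
    try:
        return condition_from_dict(d)
    except Exception as e:
        raise ParseError(f"{subject}: bad condition: {e}") from e


def from_dict(doc: Mapping) -> ClinicalAlgorithm:
    """Parse a document into an (unvalidated) :class:`ClinicalAlgorithm`."""
    if not isinstance(doc, Mapping):
        raise ParseError("document is not a mapping")
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise ParseError(
            f"unsupported format_version {version!r} (expected {FORMAT_VERSION!r})"
        )
    md = _require(doc, "meta", "document")
    meta = AlgorithmMeta(
        name=str(_require(md, "name", "meta")),
        country=str(_require(md, "country", "meta")),
        version_id=str(_require(md, "version_id", "meta")),
        age_min_days=int(_require(md, "age_min_days", "meta")),
        age_max_days=int(_require(md, "age_max_days", "meta")),
    )
    nodes: dict[str, Node] = {}
    for nd in doc.get("nodes", []):
        nid = str(_require(nd, "id", "node"))
        answers = [
            Answer(
                id=str(_require(ad, "id", f"answer of {nid}")),
                label=str(ad.get("label", ad["id"])),
                lo=None if ad.get("lo") is None else float(ad["lo"]),
                hi=None if ad.get("hi") is None else float(ad["hi"]),
            )
            for ad in nd.get("answers", [])
        ]
        cond = nd.get("display_condition")
        nodes[nid] = Node(
            id=nid,
            stage=str(_require(nd, "stage", nid)),
            kind=str(_require(nd, "kind", nid)),
            label=str(nd.get("label", nid)),
            answer_type=str(_require(nd, "answer_type", nid)),
            answers=answers,
            unit=nd.get("unit"),
            admissible_lo=None if nd.get("admissible_lo") is None else float(nd["admissible_lo"]),
            admissible_hi=None if nd.get("admissible_hi") is None else float(nd["admissible_hi"]),
            display_condition=None if cond is None else _parse_condition(cond, nid),
            referral_triggering=bool(nd.get("referral_triggering", False)),
            estimable=bool(nd.get("estimable", False)),
            emergency_relevant=bool(nd.get("emergency_relevant", False)),
            help=nd.get("help"),
            auto_from=nd.get("auto_from"),
        )
    diagnoses: dict[str, Diagnosis] = {}
    for dd in doc.get("diagnoses", []):
        did = str(_require(dd, "id", "diagnosis"))
        diagnoses[did] = Diagnosis(
            id=did,
            label=str(dd.get("label", did)),
            severity_tier=str(_require(dd, "severity_tier", did)),
            condition=_parse_condition(_require(dd, "condition", did), did),
            managements=[str(x) for x in dd.get("managements", [])],
            treatments=[
                TreatmentSpec(
                    drug_id=str(_require(td, "drug", did)),
                    alternative_drug_ids=[str(x) for x in td.get("alternatives", [])],
                )
                for td in dd.get("treatments", [])
            ],
            excludes=[str(x) for x in dd.get("excludes", [])],
        )
    managements = {
        str(md_["id"]): Management(
            id=str(md_["id"]),
            label=str(md_.get("label", md_["id"])),
            kind=str(_require(md_, "kind", md_["id"])),
            emergency_guidance=bool(md_.get("emergency_guidance", False)),
        )
        for md_ in doc.get("managements", [])
    }
    drugs = {
        str(dr["id"]): DrugDefinition(
            id=str(dr["id"]),
            name=str(dr.get("name", dr["id"])),
            formulations=[
                Formulation(
                    form=str(fd["form"]),
                    strength_mg=float(fd["strength_mg"]),
                    increment=float(fd["increment"]),
                )
                for fd in dr.get("formulations", [])
            ],
        )
        for dr in doc.get("drugs", [])
    }
    dosing_rules = {
        str(rd["id"]): DosingRule(
            id=str(rd["id"]),
            drug_id=str(_require(rd, "drug", rd["id"])),
            indication=str(_require(rd, "indication", rd["id"])),
            age_lo_days=float(rd["age_lo_days"]),
            age_hi_days=float(rd["age_hi_days"]),
            weight_lo_kg=float(rd["weight_lo_kg"]),
            weight_hi_kg=float(rd["weight_hi_kg"]),
            target_mg_per_kg=float(rd["target_mg_per_kg"]),
            min_mg_per_kg=float(rd["min_mg_per_kg"]),
            max_mg_per_kg=float(rd["max_mg_per_kg"]),
            max_mg_per_dose=float(rd["max_mg_per_dose"]),
            frequency_per_day=int(rd["frequency_per_day"]),
            duration_days=int(rd["duration_days"]),
        )
        for rd in doc.get("dosing_rules", [])
    }
    return ClinicalAlgorithm(
        meta=meta,
        stages=[str(s) for s in doc.get("stages", [])],
        nodes=nodes,
        diagnoses=diagnoses,
        managements=managements,
        drugs=drugs,
        dosing_rules=dosing_rules,
        terminology={str(k): str(v) for k, v in doc.get("terminology", {}).items()},
    )


# -- public API -------------------------------------------------------------

def build_algorithm(document: str | Mapping) -> ClinicalAlgorithm:
    """Parse, validate and finalize an algorithm document.

    ``document`` may be YAML or JSON text (JSON is a YAML subset) or an
    already-parsed mapping.  Terminology codes are auto-assigned to any
    node/diagnosis lacking one.  Raises :class:`ParseError` on malformed
    input and :class:`ValidationError` listing *every* violated invariant.
    """
    if isinstance(document, str):
        try:
            data = yaml.safe_load(document)
        except yaml.YAMLError as e:
            raise ParseError(f"document does not parse: {e}") from e
    else:
        data = document
    alg = from_dict(data)
    findings = [f for f in validate_algorithm(alg) if f.severity == "error"]
    if findings:
        raise ValidationError(findings)
    assign_terminology(alg)
    return alg


def serialize(alg: ClinicalAlgorithm, dialect: str = "json") -> str:
    """Canonical document text ("json" exchange or "yaml" authoring)."""
    d = to_dict(alg)
    if dialect == "json":
        return json.dumps(d, sort_keys=True, indent=2) + "\n"
    if dialect == "yaml":
        return yaml.safe_dump(d, sort_keys=False, allow_unicode=True)
    raise ValueError(f"unknown dialect {dialect!r}")


def deserialize(text: str) -> ClinicalAlgorithm:
    """Inverse of :func:`serialize` (validating, either dialect)."""
    return build_algorithm(text)


def load_algorithm(path: str) -> ClinicalAlgorithm:
    with open(path, "r", encoding="utf-8") as fh:
        return build_algorithm(fh.read())


def save_algorithm(alg: ClinicalAlgorithm, path: str) -> None:
    dialect = "yaml" if path.endswith((".yml", ".yaml")) else "json"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize(alg, dialect=dialect))
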