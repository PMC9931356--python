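"""Three-valued Boolean condition expressions over questionnaire atoms.

Conditions gate the display of questions and define diagnoses in a
decision-tree clinical algorithm.  An atom is a (node, answer) pair —
"the MUAC question was answered '<12.5 cm'".  During a consultation an
atom may be *true*, *false*, or *unknown* (the question has not been
asked yet), so connectives follow Kleene's strong three-valued logic:
a condition only commits to true or false once enough answers are in,
which prevents questions from being pruned prematurely.

Besides AND / OR / NOT, an ``AT_LEAST(k, atoms)`` counting connective is
provided for composite clinical-impression items and "any k of n danger
signs" logic, which plain AND/OR cannot express compactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, Iterator, Mapping


class Tri(Enum):
    """Kleene truth value."""

    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"


def tri_of(value: bool | None) -> Tri:
    if value is None:
        return Tri.UNKNOWN
    return Tri.TRUE if value else Tri.FALSE


def tri_not(v: Tri) -> Tri:
    if v is Tri.TRUE:
        return Tri.FALSE
    if v is Tri.FALSE:
        return Tri.TRUE
    return Tri.UNKNOWN


def tri_and(values: Iterable[Tri]) -> Tri:
    out = Tri.TRUE
    for v in values:
        if v is Tri.FALSE:
            return Tri.FALSE
        if v is Tri.UNKNOWN:
            out = Tri.UNKNOWN
    return out


def tri_or(values: Iterable[Tri]) -> Tri:
    out = Tri.FALSE
    for v in values:
        if v is Tri.TRUE:
            return Tri.TRUE
        if v is Tri.UNKNOWN:
            out = Tri.UNKNOWN
    return out


# Lookup signature: (node_id, answer_id) -> Tri
AtomLookup = Callable[[str, str], Tri]


class ConditionError(ValueError):
    """Raised for a malformed condition expression."""


@dataclass(frozen=True)
class Condition:
    """Abstract base for condition expression nodes."""

    def evaluate(self, lookup: AtomLookup) -> Tri:  # pragma: no cover
        raise NotImplementedError

    def atoms(self) -> Iterator["Atom"]:  # pragma: no cover
        raise NotImplementedError

    def to_dict(self) -> dict:  # pragma: no cover
        raise NotImplementedError

    def node_ids(self) -> set[str]:
        return {a.node_id for a in self.atoms()}


@dataclass(frozen=True)
class Atom(Condition):
    node_id: str
    answer_id: str

    def evaluate(self, lookup: AtomLookup) -> Tri:
        return lookup(self.node_id, self.answer_id)

    def atoms(self) -> Iterator["Atom"]:
        yield self

    def to_dict(self) -> dict:
        return {"atom": {"node": self.node_id, "answer": self.answer_id}}


@dataclass(frozen=True)
class And(Condition):
    terms: tuple[Condition, ...]

    def evaluate(self, lookup: AtomLookup) -> Tri:
        return tri_and(t.evaluate(lookup) for t in self.terms)

    def atoms(self) -> Iterator[Atom]:
        for t in self.terms:
            yield from t.atoms()

    def to_dict(self) -> dict:
        return {"all": [t.to_dict() for t in self.terms]}


@dataclass(frozen=True)
class Or(Condition):
    terms: tuple[Condition, ...]

    def evaluate(self, lookup: AtomLookup) -> Tri:
        return tri_or(t.evaluate(lookup) for t in self.terms)

    def atoms(self) -> Iterator[Atom]:
        for t in self.terms:
            yield from t.atoms()

    def to_dict(self) -> dict:
        return {"any": [t.to_dict() for t in self.terms]}


@dataclass(frozen=True)
class Not(Condition):
    term: Condition

    def evaluate(self, lookup: AtomLookup) -> Tri:
        return tri_not(self.term.evaluate(lookup))

    def atoms(self) -> Iterator[Atom]:
        yield from self.term.atoms()

    def to_dict(self) -> dict:
        return {"not": self.term.to_dict()}


@dataclass(frozen=True)
class AtLeast(Condition):
    """True when at least ``k`` of the listed atoms hold.

    Three-valued semantics: true once k atoms are true; false once so many
    atoms are false that k can no longer be reached; unknown otherwise.
    """

    k: int
    items: tuple[Atom, ...]

    def __post_init__(self) -> None:
        if self.k < 1 or self.k > len(self.items):
            raise ConditionError(
                f"AT_LEAST k={self.k} must be in 1..{len(self.items)}"
            )

    def evaluate(self, lookup: AtomLookup) -> Tri:
        n_true = n_unknown = 0
        for a in self.items:
            v = a.evaluate(lookup)
            if v is Tri.TRUE:
                n_true += 1
            elif v is Tri.UNKNOWN:
                n_unknown += 1
        if n_true >= self.k:
            return Tri.TRUE
        if n_true + n_unknown < self.k:
            return Tri.FALSE
        return Tri.UNKNOWN

    def atoms(self) -> Iterator[Atom]:
        yield from self.items

    def to_dict(self) -> dict:
        return {"at_least": {"k": self.k, "atoms": [a.to_dict() for a in self.items]}}


# -- construction helpers ---------------------------------------------------

def atom(node_id: str, answer_id: str) -> Atom:
    return Atom(node_id, answer_id)


def all_of(*terms: Condition) -> And:
    return And(tuple(terms))


def any_of(*terms: Condition) -> Or:
    return Or(tuple(terms))


def not_(term: Condition) -> Not:
    return Not(term)


def at_least(k: int, *items: Atom) -> AtLeast:
    return AtLeast(k, tuple(items))


def condition_from_dict(d: Mapping) -> Condition:
    """Parse the serialized form produced by :meth:`Condition.to_dict`."""
    if not isinstance(d, Mapping) or len(d) != 1:
        raise ConditionError(f"malformed condition: {d!r}")
    (key, body), = d.items()
    if key == "atom":
        return Atom(str(body["node"]), str(body["answer"]))
    if key == "all":
        return And(tuple(condition_from_dict(t) for t in body))
    if key == "any":
        return Or(tuple(condition_from_dict(t) for t in body))
    if key == "not":
        return Not(condition_from_dict(body))
    if key == "at_least":
        items = tuple(condition_from_dict(t) for t in body["atoms"])
        if not all(isinstance(i, Atom) for i in items):
            raise ConditionError("at_least items must be atoms")
        return AtLeast(int(body["k"]), items)
    raise ConditionError(f"unknown condition operator {key!r}")


def minimal_support(
    cond: Condition, value_of: Callable[[Atom], bool | None]
) -> list[tuple[Atom, bool]]:
    """A minimal partial atom assignment under which ``cond`` is true.

    Starting from the full assignment restricted to the condition's atoms,
    atoms are greedily dropped (reverting them to unknown) while the
    condition still evaluates true under Kleene semantics.  The result is
    an irreducible explanation: replaying only these atoms suffices to
    satisfy the condition.  Deterministic for a given condition/assignment.
    """
    seen: dict[Atom, bool] = {}
    for a in cond.atoms():
        if a in seen:
            continue
        v = value_of(a)
        if v is not None:
            seen[a] = v

    def eval_with(sub: Mapping[Atom, bool]) -> Tri:
        def lookup(node_id: str, answer_id: str) -> Tri:
            return tri_of(sub.get(Atom(node_id, answer_id)))

        return cond.evaluate(lookup)

    if eval_with(seen) is not Tri.TRUE:
        raise ConditionError("condition is not satisfied by the assignment")

    support = dict(seen)
    for a in list(seen):
        trial = dict(support)
        del trial[a]
        if eval_with(trial) is Tri.TRUE:
            support = trial
    return sorted(support.items(), key=lambda kv: (kv[0].node_id, kv[0].answer_id))
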