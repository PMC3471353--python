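"""SADI-style service registry matchmaking.

SADI services consume OWL instances of a declared input class and attach a
declared predicate to them; a registry indexes services by the property they
attach.  During query composition that index answers two questions:

* which predicates are *serviceable* for a clause whose subject has known
  semantic types (those suggestions get highlighted); and
* what semantic type the object variable of a serviceable clause will hold
  at execution time (propagated forward so later clauses can be matched too).

Matchmaking is by exact class IRI; OWL subsumption over class expressions is
deliberately out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Optional

from .parser import CompletionContext

if TYPE_CHECKING:  # pragma: no cover
    from .engine import Suggestion


class RegistryError(Exception):
    """Raised for malformed registry documents."""


@dataclass(frozen=True)
class ServiceRecord:
    """One service: consumes instances of ``input_class`` and attaches
    ``attached_property``; ``output_class`` (may be empty) is the type of the
    generated values."""

    service_id: str
    input_class: str
    attached_property: str
    output_class: str = ""

    def __post_init__(self) -> None:
        if not self.input_class or not self.attached_property:
            raise ValueError("service records need an input class and a property")


class Registry:
    """Queryable collection of :class:`ServiceRecord` with deterministic
    iteration order."""

    def __init__(self, records: Iterable[ServiceRecord] = ()) -> None:
        self.records: list[ServiceRecord] = list(records)
        self._by_property: dict[str, list[ServiceRecord]] = {}
        self._by_input: dict[str, list[ServiceRecord]] = {}
        for rec in self.records:
            self._by_property.setdefault(rec.attached_property, []).append(rec)
            self._by_input.setdefault(rec.input_class, []).append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def by_property(self, prop: str) -> list[ServiceRecord]:
        return self._by_property.get(prop, [])

    def by_input(self, input_class: str) -> list[ServiceRecord]:
        return self._by_input.get(input_class, [])

    def properties(self) -> list[str]:
        """All attached properties, deterministically ordered."""
        return sorted(self._by_property)

    @classmethod
    def from_json(cls, document: str) -> "Registry":
        """Load ``{"services": [{"id":…, "input_class":…, "property":…,
        "output_class":…}]}``."""
        try:
            doc = json.loads(document)
        except json.JSONDecodeError as exc:
            raise RegistryError(f"invalid registry JSON: {exc}") from exc
        if not isinstance(doc, dict) or not isinstance(doc.get("services", []), list):
            raise RegistryError('registry JSON must be {"services": [...]}')
        records = []
        for i, svc in enumerate(doc.get("services", [])):
            if not isinstance(svc, dict):
                raise RegistryError(f"services[{i}]: expected an object")
            try:
                records.append(
                    ServiceRecord(
                        service_id=str(svc.get("id", f"service-{i}")),
                        input_class=svc.get("input_class", ""),
                        attached_property=svc.get("property", ""),
                        output_class=svc.get("output_class", "") or "",
                    )
                )
            except ValueError as exc:
                raise RegistryError(f"services[{i}]: {exc}") from exc
        return cls(records)

    def to_json(self) -> str:
        return json.dumps(
            {
                "services": [
                    {
                        "id": r.service_id,
                        "input_class": r.input_class,
                        "property": r.attached_property,
                        "output_class": r.output_class,
                    }
                    for r in self.records
                ]
            },
            indent=2,
        )


@dataclass
class TypeAssignment:
    """Map from query variable to the set of class IRIs it is known to carry
    at execution time.  Sets only ever grow during propagation."""

    classes: dict[str, set[str]] = field(default_factory=dict)

    def get(self, var: str) -> set[str]:
        return self.classes.get(var, set())

    def add(self, var: str, cls: str) -> bool:
        existing = self.classes.setdefault(var, set())
        if cls in existing:
            return False
        existing.add(cls)
        return True


def available_properties(input_classes: set[str], registry: Registry) -> set[str]:
    """Properties attached by at least one service whose input class is in
    ``input_classes`` (exact IRI match)."""
    out: set[str] = set()
    for cls in input_classes:
        for rec in registry.by_input(cls):
            out.add(rec.attached_property)
    return out


def _subject_classes(
    node, assignment: TypeAssignment, individual_types: Mapping[str, set[str]]
) -> set[str]:
    if node is None:
        return set()
    if node.is_iri():
        return set(individual_types.get(node.value, set()))
    if node.is_var():
        return assignment.get(node.value)
    return set()


def propagate_types(
    context: CompletionContext,
    registry: Registry,
    individual_types: Mapping[str, set[str]],
) -> TypeAssignment:
    """Fixpoint of forward type propagation over the query's triple patterns.

    For each complete pattern ``(s, p, o)`` with ``o`` a variable: if ``s`` is
    an individual of type ``T`` (or a variable already assigned ``T``) and a
    record ``(T, p, O)`` with non-empty output exists, ``O`` is added to the
    types of ``o``.  Terminates because assignments only grow within a finite
    class universe.
    """
    assignment = TypeAssignment()
    query_vars = set(context.variables)
    for t in context.triples:
        query_vars |= t.variables()
    changed = True
    while changed:
        changed = False
        for t in context.triples:
            if t.predicate is None or t.object is None:
                continue
            if not t.predicate.is_iri() or not t.object.is_var():
                continue
            if t.object.value not in query_vars:
                continue
            subject_classes = _subject_classes(t.subject, assignment, individual_types)
            for rec in registry.by_property(t.predicate.value):
                if rec.output_class and rec.input_class in subject_classes:
                    if assignment.add(t.object.value, rec.output_class):
                        changed = True
    return assignment


def annotate_predicates(
    suggestions: list["Suggestion"],
    context: CompletionContext,
    registry: Registry,
    assignment: TypeAssignment,
    individual_types: Mapping[str, set[str]],
    registry_only: Optional[set[str]] = None,
) -> list["Suggestion"]:
    """Highlight serviceable predicate suggestions and filter unserviceable
    registry-only ones.

    The current clause's subject classes are looked up (from the individual
    type map for IRIs, from the propagated assignment for variables).  A
    suggestion whose target is serviceable for those classes is marked
    ``highlighted``.  A property known *only* from the registry (never seen in
    a loaded ontology, as listed in ``registry_only``) is dropped when not
    serviceable; ontology-indexed properties are always retained, merely left
    unhighlighted.  With no subject type information nothing is highlighted
    and nothing filtered.
    """
    clause = context.current_clause
    subject = clause.subject if clause is not None else None
    classes = _subject_classes(subject, assignment, individual_types)
    registry_only = registry_only or set()
    if not classes:
        return list(suggestions)
    serviceable = available_properties(classes, registry)
    out = []
    for s in suggestions:
        if s.target_uri in serviceable:
            out.append(s.replace(highlighted=True))
        elif s.target_uri in registry_only:
            continue  # a service exists somewhere, but not for this input
        else:
            out.append(s)
    return out
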