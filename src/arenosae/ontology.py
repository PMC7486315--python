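"""Controlled vocabulary for structured plant descriptions.

A description in this model is a sequence of descriptive elements, each
tying a *structure* (an anatomical part such as ``calyx`` or ``anthophore``)
to a *property* (``length``, ``shape``, ``pubescence`` ...) and a score.
The base ontology declares which structures, properties and states exist;
a description template ("pro-forma" ontology) is an ordered selection of
(structure, property) slots that a set of descriptions must conform to,
and whose order drives rendering.

Structures form a part-of tree (``flower/pedicel``).  A *specifier*
singles out one instance from a collection of like structures — the
uppermost internode, the first flower's pedicel, the longer class of
calyx teeth — and is written in square brackets in a structure path::

    internode[position=uppermost]
    flower[order=first]/pedicel
    tooth[class=shorter]
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import (
    DanglingReferenceError,
    DuplicateTermError,
    OntologyError,
    StructurePathError,
    UnknownTermError,
)

#: Specifier values that are always understood, even without a SpecifierDef.
ORDINAL_KEYWORDS = frozenset(
    {"first", "uppermost", "next-upper", "lower-part", "upper-part"}
)

PROPERTY_KINDS = ("qualitative", "quantitative", "count", "relative")


def _norm(name: str) -> str:
    return unicodedata.normalize("NFC", name).strip()


@dataclass(frozen=True)
class StructureTerm:
    name: str
    parent: str | None = None
    synonyms: tuple[str, ...] = ()
    note: str = ""


@dataclass(frozen=True)
class PropertyTerm:
    """A property and, for qualitative properties, its permitted states.

    ``units`` maps unit tokens to the factor converting them into the
    canonical unit (e.g. ``{"mm": 1.0, "cm": 10.0}`` with canonical mm).
    """

    name: str
    kind: str
    states: tuple[str, ...] = ()
    canonical_unit: str | None = None
    units: Mapping[str, float] = field(default_factory=dict)
    applicable_structures: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in PROPERTY_KINDS:
            raise OntologyError(f"unknown property kind {self.kind!r}")
        if self.kind == "qualitative" and not self.states:
            raise OntologyError(
                f"qualitative property {self.name!r} declares no states"
            )
        if self.kind == "quantitative":
            if not self.canonical_unit:
                raise OntologyError(
                    f"quantitative property {self.name!r} has no canonical unit"
                )
            if self.canonical_unit not in self.units:
                raise OntologyError(
                    f"canonical unit {self.canonical_unit!r} of {self.name!r} "
                    "missing from its unit registry"
                )

    def convert(self, value: float, from_unit: str, to_unit: str) -> float:
        from .descriptions import convert_unit  # local import, shared helper

        return convert_unit(value, from_unit, to_unit, self)


@dataclass(frozen=True)
class SpecifierDef:
    """Declares which discriminator=value pairs a structure accepts."""

    base_structure: str
    discriminator: str
    allowed_values: tuple[str, ...] = ()


@dataclass(frozen=True)
class PathSegment:
    structure: str
    specifiers: tuple[tuple[str, str], ...] = ()

    def __str__(self) -> str:
        if not self.specifiers:
            return self.structure
        spec = ",".join(f"{k}={v}" for k, v in self.specifiers)
        return f"{self.structure}[{spec}]"


@dataclass(frozen=True)
class StructureRef:
    """A resolved structure path, possibly qualified by specifiers."""

    segments: tuple[PathSegment, ...]

    def __str__(self) -> str:
        return "/".join(str(s) for s in self.segments)

    @property
    def structure(self) -> str:
        """Name of the innermost structure the ref points at."""
        return self.segments[-1].structure


_SEGMENT_RE = re.compile(r"^(?P<name>[^\[\]/]+)(\[(?P<spec>[^\[\]]*)\])?$")


def parse_structure_path(path: str) -> StructureRef:
    """Parse the textual path syntax without touching any ontology."""
    segments = []
    for raw in _norm(path).split("/"):
        m = _SEGMENT_RE.match(raw.strip())
        if not m or not m.group("name").strip():
            raise StructurePathError(f"malformed path segment {raw!r} in {path!r}")
        specifiers = []
        if m.group("spec"):
            for pair in m.group("spec").split(","):
                if "=" not in pair:
                    raise StructurePathError(
                        f"malformed specifier {pair!r} in {path!r}"
                    )
                k, v = pair.split("=", 1)
                specifiers.append((_norm(k), _norm(v)))
        segments.append(
            PathSegment(_norm(m.group("name")), tuple(sorted(specifiers)))
        )
    return StructureRef(tuple(segments))


class Ontology:
    """Closed vocabulary of structures, properties, states and specifiers."""

    def __init__(
        self,
        structures: Iterable[StructureTerm] = (),
        properties: Iterable[PropertyTerm] = (),
        specifier_defs: Iterable[SpecifierDef] = (),
        version: str = "0",
        provenance: str = "",
    ):
        self.version = version
        self.provenance = provenance
        self.structures: dict[str, StructureTerm] = {}
        self.properties: dict[str, PropertyTerm] = {}
        self.specifier_defs: list[SpecifierDef] = []
        self._synonyms: dict[str, str] = {}
        for s in structures:
            self._add_structure(s)
        for p in properties:
            self._add_property(p)
        for d in specifier_defs:
            self._add_specifier_def(d)
        self._check_closure()

    # -- construction -----------------------------------------------------

    def _add_structure(self, term: StructureTerm) -> None:
        name = _norm(term.name)
        if name in self.structures or name in self._synonyms:
            raise DuplicateTermError("structure", name)
        self.structures[name] = term
        for syn in term.synonyms:
            syn = _norm(syn)
            if syn in self.structures or syn in self._synonyms:
                raise DuplicateTermError("structure synonym", syn)
            self._synonyms[syn] = name

    def _add_property(self, term: PropertyTerm) -> None:
        name = _norm(term.name)
        if name in self.properties:
            raise DuplicateTermError("property", name)
        seen_states = set()
        for st in term.states:
            if st in seen_states:
                raise DuplicateTermError(f"state of {name!r}", st)
            seen_states.add(st)
        self.properties[name] = term

    def _add_specifier_def(self, d: SpecifierDef) -> None:
        self.specifier_defs.append(d)

    def _check_closure(self) -> None:
        for s in self.structures.values():
            if s.parent is not None and self.canonical_structure(s.parent) is None:
                raise DanglingReferenceError(
                    "structure", s.parent, f"parent of {s.name!r}"
                )
        # part-of graph must be acyclic
        for name in self.structures:
            seen = set()
            cur: str | None = name
            while cur is not None:
                if cur in seen:
                    raise OntologyError(f"part-of cycle through {name!r}")
                seen.add(cur)
                cur = self.structures[self.canonical_structure(cur)].parent
                if cur is not None:
                    cur = self.canonical_structure(cur)
        for p in self.properties.values():
            for s in p.applicable_structures:
                if self.canonical_structure(s) is None:
                    raise DanglingReferenceError(
                        "structure", s, f"applicable_structures of {p.name!r}"
                    )
        for d in self.specifier_defs:
            if self.canonical_structure(d.base_structure) is None:
                raise DanglingReferenceError(
                    "structure", d.base_structure, "specifier definition"
                )
            if (
                d.discriminator not in self.properties
                and not (set(d.allowed_values) & ORDINAL_KEYWORDS)
                and not d.allowed_values
            ):
                raise DanglingReferenceError(
                    "property", d.discriminator, "specifier discriminator"
                )

    # -- lookups ----------------------------------------------------------

    def canonical_structure(self, name: str) -> str | None:
        name = _norm(name)
        if name in self.structures:
            return name
        return self._synonyms.get(name)

    def ancestors(self, name: str) -> list[str]:
        out = []
        cur = self.structures[name].parent
        while cur is not None:
            cur = self.canonical_structure(cur)
            out.append(cur)
            cur = self.structures[cur].parent
        return out

    def specifier_values(self, structure: str, discriminator: str) -> set[str]:
        vals: set[str] = set()
        for d in self.specifier_defs:
            if (
                self.canonical_structure(d.base_structure) == structure
                and d.discriminator == discriminator
            ):
                vals.update(d.allowed_values)
        return vals

    def property_applicable(self, prop: str, structure: str) -> bool:
        p = self.properties[prop]
        if not p.applicable_structures:
            return True
        allowed = {self.canonical_structure(s) for s in p.applicable_structures}
        return structure in allowed

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "provenance": self.provenance,
            "structures": [
                {
                    "name": s.name,
                    "parent": s.parent,
                    "synonyms": list(s.synonyms),
                    "note": s.note,
                }
                for s in self.structures.values()
            ],
            "properties": [
                {
                    "name": p.name,
                    "kind": p.kind,
                    "states": list(p.states),
                    "canonical_unit": p.canonical_unit,
                    "units": dict(p.units),
                    "applicable_structures": list(p.applicable_structures),
                }
                for p in self.properties.values()
            ],
            "specifiers": [
                {
                    "base_structure": d.base_structure,
                    "discriminator": d.discriminator,
                    "allowed_values": list(d.allowed_values),
                }
                for d in self.specifier_defs
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1, ensure_ascii=False, sort_keys=True)
            + "\n",
            encoding="utf-8",
        )


def load_ontology(source) -> Ontology:
    """Load an ontology from a JSON document (path, JSON text, or dict)."""
    doc = _load_json(source)
    structures = [
        StructureTerm(
            name=_norm(s["name"]),
            parent=s.get("parent"),
            synonyms=tuple(_norm(x) for x in s.get("synonyms", ())),
            note=s.get("note", ""),
        )
        for s in doc.get("structures", ())
    ]
    properties = [
        PropertyTerm(
            name=_norm(p["name"]),
            kind=p["kind"],
            states=tuple(_norm(x) for x in p.get("states", ())),
            canonical_unit=p.get("canonical_unit"),
            units={k: float(v) for k, v in p.get("units", {}).items()},
            applicable_structures=tuple(p.get("applicable_structures", ())),
        )
        for p in doc.get("properties", ())
    ]
    specifiers = [
        SpecifierDef(
            base_structure=d["base_structure"],
            discriminator=d["discriminator"],
            allowed_values=tuple(d.get("allowed_values", ())),
        )
        for d in doc.get("specifiers", ())
    ]
    return Ontology(
        structures,
        properties,
        specifiers,
        version=str(doc.get("version", "0")),
        provenance=doc.get("provenance", ""),
    )


def _load_json(source) -> dict:
    if isinstance(source, dict):
        return source
    if isinstance(source, Path):
        return json.loads(source.read_text(encoding="utf-8"))
    if isinstance(source, str):
        text = source.lstrip()
        if text.startswith("{"):
            return json.loads(source)
        return json.loads(Path(source).read_text(encoding="utf-8"))
    return json.load(source)


# -- structure references -------------------------------------------------


def resolve_structure_ref(ontology: Ontology, path: str | StructureRef) -> StructureRef:
    """Resolve a structure path against an ontology.

    Each segment's structure must exist (synonyms are canonicalized), each
    inner segment must be a part-of ancestor of the next, and every
    specifier must either use a declared discriminator/value or an
    ordinal keyword such as ``uppermost`` or ``first``.
    """
    ref = parse_structure_path(path) if isinstance(path, str) else path
    resolved = []
    prev: str | None = None
    for seg in ref.segments:
        canon = ontology.canonical_structure(seg.structure)
        if canon is None:
            raise UnknownTermError(f"unknown structure {seg.structure!r} in {path!r}")
        if prev is not None and prev not in ontology.ancestors(canon):
            raise StructurePathError(
                f"{canon!r} is not part of {prev!r} (path {path!r})"
            )
        for disc, value in seg.specifiers:
            allowed = ontology.specifier_values(canon, disc)
            if value not in allowed and value not in ORDINAL_KEYWORDS:
                raise UnknownTermError(
                    f"specifier {disc}={value} not declared for {canon!r}"
                )
        resolved.append(PathSegment(canon, seg.specifiers))
        prev = canon
    return StructureRef(tuple(resolved))


# -- description templates ------------------------------------------------


@dataclass(frozen=True)
class TemplateSlot:
    """One (structure path, property) position of a template.

    ``label`` is the heading used when rendering the slot group
    (e.g. ``Calyx``); ``precision`` the number of decimals for
    quantitative scores; ``unit`` the unit to render in.
    """

    path: str
    property: str
    label: str = ""
    precision: int = 1
    unit: str | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.path, self.property)


class DescriptionTemplate:
    def __init__(self, ontology: Ontology, slots: Sequence[TemplateSlot],
                 name: str = ""):
        self.ontology = ontology
        self.name = name
        self.slots: list[TemplateSlot] = []
        self._index: dict[tuple[str, str], int] = {}
        for slot in slots:
            ref = resolve_structure_ref(ontology, slot.path)
            if slot.property not in ontology.properties:
                raise UnknownTermError(f"unknown property {slot.property!r}")
            if not ontology.property_applicable(slot.property, ref.structure):
                raise OntologyError(
                    f"property {slot.property!r} not applicable to "
                    f"{ref.structure!r}"
                )
            canon = TemplateSlot(
                str(ref), slot.property, slot.label, slot.precision, slot.unit
            )
            if canon.key in self._index:
                raise DuplicateTermError("template slot", f"{canon.key}")
            self._index[canon.key] = len(self.slots)
            self.slots.append(canon)

    def slot_order(self, path: str, prop: str) -> int | None:
        ref = resolve_structure_ref(self.ontology, path)
        return self._index.get((str(ref), prop))

    def __len__(self) -> int:
        return len(self.slots)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "slots": [
                {
                    "path": s.path,
                    "property": s.property,
                    "label": s.label,
                    "precision": s.precision,
                    "unit": s.unit,
                }
                for s in self.slots
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1, ensure_ascii=False) + "\n",
            encoding="utf-8",
        )


def derive_template(
    ontology: Ontology, selection: Sequence, name: str = ""
) -> DescriptionTemplate:
    """Build a template from an ordered slot selection.

    Selection entries may be ``(path, property)`` tuples or dicts with
    optional ``label``, ``precision`` and ``unit`` keys.  Order is
    preserved and becomes the rendering order.
    """
    slots = []
    for entry in selection:
        if isinstance(entry, TemplateSlot):
            slots.append(entry)
        elif isinstance(entry, dict):
            slots.append(
                TemplateSlot(
                    path=entry["path"],
                    property=entry["property"],
                    label=entry.get("label", ""),
                    precision=int(entry.get("precision", 1)),
                    unit=entry.get("unit"),
                )
            )
        else:
            path, prop = entry
            slots.append(TemplateSlot(path=path, property=prop))
    return DescriptionTemplate(ontology, slots, name=name)


def load_template(ontology: Ontology, source) -> DescriptionTemplate:
    doc = _load_json(source)
    return derive_template(ontology, doc["slots"], name=doc.get("name", ""))
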