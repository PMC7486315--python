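"""Descriptive elements and taxon descriptions.

A taxon description is an ordered set of descriptive elements (DEs).
Each DE scores one property of one structure: a quantitative range
(``Calyx 10.0-14.0 mm``), a set of alternative states (``oblong or
ellipsoid``), a count (``2-3 distinct internodes``) or a relation to
another structure (``obviously longer than the next upper internode``).
Modifiers qualify a DE by frequency (``usually``), time (``at
anthesis`` / ``in fruit``) or position on the organ (``in lower part``).

Absence of a slot means *not recorded*, never *organ absent*: queries
return ``None`` and downstream key evaluation treats the value as
unknown (three-valued logic).

The module also implements the redundancy-avoiding algebra used for the
section account: :func:`intersect_constant` collects the features shared
by a set of taxa, :func:`factor` strips from each child every element
already stated identically by the parent, and :func:`expand` restores a
self-contained description (child elements win on conflict).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ArenosaeError, UnitError, UnknownTermError, StructurePathError
from .ontology import (
    DescriptionTemplate,
    Ontology,
    PropertyTerm,
    parse_structure_path,
    resolve_structure_ref,
)

RANKS = ("section", "species", "subspecies")

MODIFIER_VALUES = {
    "frequency": frozenset({"usually", "sometimes", "rarely", "often"}),
    "temporal": frozenset({"at-anthesis", "in-fruit", "in-flower", "in-bud"}),
    "spatial": frozenset(
        {"in-lower-part", "in-upper-part", "in-central-part", "throughout",
         "at-base", "at-apex", "at-margin"}
    ),
    "relative": frozenset({"less-than", "equal-to", "more-than"}),
}

RELATIONS = (
    "longer-than",
    "obviously-longer-than",
    "equal-to",
    "shorter-than",
)


def convert_unit(value: float, from_unit: str, to_unit: str,
                 prop: PropertyTerm) -> float:
    units = prop.units
    if from_unit not in units:
        raise UnitError(f"unknown unit {from_unit!r} for property {prop.name!r}")
    if to_unit not in units:
        raise UnitError(f"unknown unit {to_unit!r} for property {prop.name!r}")
    return value * units[from_unit] / units[to_unit]


# -- scores ---------------------------------------------------------------


@dataclass(frozen=True)
class QuantRange:
    """A main range with optional parenthetical extremes.

    The printed form ``(8.0-)9.0-13.0(-14.0) mm`` maps to
    ``QuantRange(9.0, 13.0, extreme_low=8.0, extreme_high=14.0, unit="mm")``.
    A single printed value such as ``Capsule 12.0 mm`` is the degenerate
    range ``12.0-12.0``.
    """

    main_low: float
    main_high: float
    extreme_low: float | None = None
    extreme_high: float | None = None
    unit: str = "mm"

    @property
    def wellformed(self) -> bool:
        seq = [
            v
            for v in (self.extreme_low, self.main_low, self.main_high,
                      self.extreme_high)
            if v is not None
        ]
        return all(a <= b for a, b in zip(seq, seq[1:]))

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.main_low + self.main_high)

    def convert(self, to_unit: str, prop: PropertyTerm) -> "QuantRange":
        c = lambda v: None if v is None else convert_unit(v, self.unit, to_unit, prop)
        return QuantRange(
            c(self.main_low), c(self.main_high), c(self.extreme_low),
            c(self.extreme_high), to_unit,
        )

    def to_dict(self) -> dict:
        d: dict = {"type": "range", "main": [self.main_low, self.main_high],
                   "unit": self.unit}
        if self.extreme_low is not None:
            d["extreme_low"] = self.extreme_low
        if self.extreme_high is not None:
            d["extreme_high"] = self.extreme_high
        return d


@dataclass(frozen=True)
class CountRange:
    """Integer count, possibly a printed range (``with 2-3 internodes``)."""

    low: int
    high: int

    @property
    def wellformed(self) -> bool:
        return 0 <= self.low <= self.high

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)

    def to_dict(self) -> dict:
        return {"type": "count", "low": self.low, "high": self.high}


@dataclass(frozen=True)
class QualScore:
    """Alternative states, connected by "or" (``oblong or ellipsoid``)."""

    states: frozenset[str]

    def __init__(self, states: Iterable[str]):
        object.__setattr__(self, "states", frozenset(states))
        if not self.states:
            raise ArenosaeError("qualitative score needs at least one state")

    def to_dict(self) -> dict:
        return {"type": "states", "states": sorted(self.states)}


@dataclass(frozen=True)
class RelativeScore:
    """Comparison against another structure of the same plant."""

    relation: str
    reference: str  # structure path

    def __post_init__(self):
        if self.relation not in RELATIONS:
            raise ArenosaeError(f"unknown relation {self.relation!r}")

    def to_dict(self) -> dict:
        return {"type": "relative", "relation": self.relation,
                "reference": self.reference}


Score = QuantRange | CountRange | QualScore | RelativeScore

_SCORE_KIND = {
    QuantRange: "quantitative",
    CountRange: "count",
    QualScore: "qualitative",
    RelativeScore: "relative",
}


def score_from_dict(d: dict) -> Score:
    t = d.get("type")
    if t == "range":
        return QuantRange(
            float(d["main"][0]), float(d["main"][1]),
            None if d.get("extreme_low") is None else float(d["extreme_low"]),
            None if d.get("extreme_high") is None else float(d["extreme_high"]),
            d.get("unit", "mm"),
        )
    if t == "count":
        return CountRange(int(d["low"]), int(d["high"]))
    if t == "states":
        return QualScore(d["states"])
    if t == "relative":
        return RelativeScore(d["relation"], d["reference"])
    raise ArenosaeError(f"unknown score type {t!r}")


# -- descriptive elements -------------------------------------------------


@dataclass(frozen=True)
class Modifier:
    kind: str
    value: str

    def __post_init__(self):
        if self.kind not in MODIFIER_VALUES:
            raise ArenosaeError(f"unknown modifier kind {self.kind!r}")

    @property
    def permitted(self) -> bool:
        return self.value in MODIFIER_VALUES[self.kind]


@dataclass(frozen=True)
class DescriptiveElement:
    """structure + property + score (+ modifiers)."""

    structure: str
    property: str
    score: Score
    modifiers: tuple[Modifier, ...] = ()
    supplemented: bool = False  # recorded from notes/key rather than the account

    @property
    def context(self) -> frozenset[tuple[str, str]]:
        """Modifier context for slot identity.

        Temporal and spatial modifiers split a slot into distinct
        contexts (``cylindrical at anthesis`` vs ``clavate in fruit``);
        frequency modifiers do not.
        """
        return frozenset(
            (m.kind, m.value) for m in self.modifiers
            if m.kind in ("temporal", "spatial")
        )

    @property
    def slot(self) -> tuple[str, str, frozenset]:
        return (self.structure, self.property, self.context)

    def same_statement(self, other: "DescriptiveElement") -> bool:
        """True when both elements state the same fact (modifiers included)."""
        return (
            self.slot == other.slot
            and self.score == other.score
            and set(self.modifiers) == set(other.modifiers)
        )

    def to_dict(self) -> dict:
        d: dict = {
            "structure": self.structure,
            "property": self.property,
            "score": self.score.to_dict(),
        }
        if self.modifiers:
            d["modifiers"] = [
                {"kind": m.kind, "value": m.value} for m in self.modifiers
            ]
        if self.supplemented:
            d["supplemented"] = True
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DescriptiveElement":
        return cls(
            structure=d["structure"],
            property=d["property"],
            score=score_from_dict(d["score"]),
            modifiers=tuple(
                Modifier(m["kind"], m["value"]) for m in d.get("modifiers", ())
            ),
            supplemented=bool(d.get("supplemented", False)),
        )


# -- taxon descriptions ---------------------------------------------------


@dataclass
class TaxonDescription:
    taxon_name: str
    rank: str
    elements: list[DescriptiveElement] = field(default_factory=list)
    parent: str | None = None

    def __post_init__(self):
        if self.rank not in RANKS:
            raise ArenosaeError(f"unknown rank {self.rank!r}")

    # -- access -----------------------------------------------------------

    def element_map(self) -> dict[tuple, DescriptiveElement]:
        return {e.slot: e for e in self.elements}

    def find(self, structure: str, prop: str,
             context: frozenset | None = None) -> list[DescriptiveElement]:
        ref = str(parse_structure_path(structure))
        out = [
            e for e in self.elements
            if e.structure == ref and e.property == prop
            and (context is None or e.context == context)
        ]
        return out

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "taxon": self.taxon_name,
            "rank": self.rank,
            "elements": [e.to_dict() for e in self.elements],
        }
        if self.parent:
            d["parent"] = self.parent
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaxonDescription":
        return cls(
            taxon_name=d["taxon"],
            rank=d["rank"],
            elements=[DescriptiveElement.from_dict(e) for e in d["elements"]],
            parent=d.get("parent"),
        )

    def canonical(self, template: DescriptionTemplate) -> "TaxonDescription":
        """Return a copy with elements in template slot order.

        Elements outside the template sort after all template slots, by
        path.  Within a slot, contexts sort lexicographically.  This is
        the order used for canonical (byte-stable) serialization.
        """
        n = len(template)

        def sort_key(e: DescriptiveElement):
            idx = template.slot_order(e.structure, e.property)
            return (
                n if idx is None else idx,
                e.structure,
                e.property,
                sorted(e.context),
            )

        return replace_elements(self, sorted(self.elements, key=sort_key))

    def canonical_json(self, template: DescriptionTemplate) -> str:
        return json.dumps(
            self.canonical(template).to_dict(),
            indent=1, sort_keys=True, ensure_ascii=False,
        ) + "\n"

    def save(self, path: str | Path, template: DescriptionTemplate) -> None:
        Path(path).write_text(self.canonical_json(template), encoding="utf-8")


def replace_elements(desc: TaxonDescription,
                     elements: Sequence[DescriptiveElement]) -> TaxonDescription:
    return TaxonDescription(
        taxon_name=desc.taxon_name, rank=desc.rank,
        elements=list(elements), parent=desc.parent,
    )


def load_description(source) -> TaxonDescription:
    if isinstance(source, dict):
        return TaxonDescription.from_dict(source)
    if isinstance(source, (str, Path)) and str(source).lstrip().startswith("{"):
        return TaxonDescription.from_dict(json.loads(str(source)))
    return TaxonDescription.from_dict(
        json.loads(Path(source).read_text(encoding="utf-8"))
    )


# -- validation -----------------------------------------------------------


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    slot: str
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    def add(self, severity: str, slot: str, message: str) -> None:
        self.findings.append(Finding(severity, slot, message))

    def __bool__(self) -> bool:  # truthy when something was found
        return bool(self.findings)


def validate_description(desc: TaxonDescription,
                         template: DescriptionTemplate) -> ValidationReport:
    """Check a description against a template and its ontology.

    Findings are data, not exceptions: unknown terms, inapplicable
    properties, unit mismatches, malformed ranges, slots missing from
    the template, and duplicated (slot, modifier-context) pairs are all
    reported together.
    """
    onto = template.ontology
    report = ValidationReport()
    seen: set[tuple] = set()
    for e in desc.elements:
        label = f"{e.structure}:{e.property}"
        try:
            ref = resolve_structure_ref(onto, e.structure)
        except (UnknownTermError, StructurePathError) as exc:
            report.add("error", label, f"unknown structure: {exc}")
            continue
        prop = onto.properties.get(e.property)
        if prop is None:
            report.add("error", label, f"unknown property {e.property!r}")
            continue
        if not onto.property_applicable(e.property, ref.structure):
            report.add("error", label,
                       f"property {e.property!r} not applicable to "
                       f"{ref.structure!r}")
        if template.slot_order(e.structure, e.property) is None:
            report.add("error", label, "slot not in template")
        expected = _SCORE_KIND[type(e.score)]
        if expected != prop.kind:
            report.add("error", label,
                       f"{expected} score on {prop.kind} property")
        if isinstance(e.score, QuantRange):
            if e.score.unit not in prop.units:
                report.add("error", label,
                           f"unit not permitted: {e.score.unit!r}")
            if not e.score.wellformed:
                report.add("error", label, "malformed range")
        if isinstance(e.score, CountRange) and not e.score.wellformed:
            report.add("error", label, "malformed count")
        if isinstance(e.score, QualScore):
            bad = e.score.states - set(prop.states)
            if bad:
                report.add("error", label,
                           f"states not in property: {sorted(bad)}")
        if isinstance(e.score, RelativeScore):
            try:
                resolve_structure_ref(onto, e.score.reference)
            except (UnknownTermError, StructurePathError) as exc:
                report.add("error", label, f"relative reference: {exc}")
        for m in e.modifiers:
            if not m.permitted:
                report.add("error", label,
                           f"modifier value {m.value!r} not permitted "
                           f"for kind {m.kind!r}")
        if e.slot in seen:
            report.add("error", label,
                       "duplicate element for slot and modifier context")
        seen.add(e.slot)
    return report


# -- set algebra ----------------------------------------------------------


def intersect_constant(descs: Sequence[TaxonDescription],
                       policy: str = "strict",
                       taxon_name: str = "constant features",
                       rank: str = "section") -> TaxonDescription:
    """Collect the features constant across all input descriptions.

    A slot contributes iff every input records it.  Under ``strict``
    the scores (and modifiers) must be identical; under ``enclosing``,
    quantitative ranges may differ and the enclosing hull is emitted
    with a ``hull`` frequency-free marker (a ``sometimes`` modifier is
    *not* used: the hull element carries ``supplemented=True`` to show
    it was derived, not observed).
    """
    if policy not in ("strict", "enclosing"):
        raise ArenosaeError(f"unknown policy {policy!r}")
    if len(descs) < 2:
        raise ArenosaeError("need at least two descriptions to intersect")
    maps = [d.element_map() for d in descs]
    common = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
    out: list[DescriptiveElement] = []
    for slot in sorted(common, key=lambda s: (s[0], s[1], sorted(s[2]))):
        elems = [m[slot] for m in maps]
        first = elems[0]
        if all(e.same_statement(first) for e in elems[1:]):
            out.append(first)
            continue
        if policy == "enclosing" and all(
            isinstance(e.score, QuantRange) for e in elems
        ) and len({e.score.unit for e in elems}) == 1:
            lows = [e.score.main_low for e in elems]
            highs = [e.score.main_high for e in elems]
            elows = [e.score.extreme_low for e in elems
                     if e.score.extreme_low is not None]
            ehighs = [e.score.extreme_high for e in elems
                      if e.score.extreme_high is not None]
            hull = QuantRange(
                min(lows), max(highs),
                min(elows) if elows else None,
                max(ehighs) if ehighs else None,
                first.score.unit,
            )
            out.append(replace(first, score=hull, modifiers=(),
                               supplemented=True))
    return TaxonDescription(taxon_name=taxon_name, rank=rank, elements=out)


def factor(parent: TaxonDescription,
           children: Sequence[TaxonDescription]) -> list[TaxonDescription]:
    """Strip from each child every element the parent states identically."""
    pmap = parent.element_map()
    out = []
    for child in children:
        kept = [
            e for e in child.elements
            if not (e.slot in pmap and e.same_statement(pmap[e.slot]))
        ]
        out.append(replace_elements(child, kept))
    return out


def expand(child: TaxonDescription,
           parent: TaxonDescription) -> TaxonDescription:
    """Merge parent elements into a child; the child wins on conflict."""
    have = {e.slot for e in child.elements}
    merged = list(child.elements) + [
        e for e in parent.elements if e.slot not in have
    ]
    return replace_elements(child, merged)


# -- diff -----------------------------------------------------------------


@dataclass
class DiffReport:
    equal: list[tuple] = field(default_factory=list)
    only_a: list[tuple] = field(default_factory=list)
    only_b: list[tuple] = field(default_factory=list)
    conflict: list[tuple] = field(default_factory=list)

    @property
    def identical(self) -> bool:
        return not (self.only_a or self.only_b or self.conflict)


def diff(a: TaxonDescription, b: TaxonDescription) -> DiffReport:
    amap, bmap = a.element_map(), b.element_map()
    report = DiffReport()
    for slot in sorted(set(amap) | set(bmap),
                       key=lambda s: (s[0], s[1], sorted(s[2]))):
        if slot not in bmap:
            report.only_a.append(slot)
        elif slot not in amap:
            report.only_b.append(slot)
        elif amap[slot].same_statement(bmap[slot]):
            report.equal.append(slot)
        else:
            report.conflict.append(slot)
    return report


# -- query ----------------------------------------------------------------


def query(desc: TaxonDescription, structure: str, prop: str,
          unit: str | None = None, ontology: Ontology | None = None,
          context: frozenset | None = None):
    """Look up a score; ``None`` means the slot is not recorded.

    When several modifier contexts record the slot (``in flower`` vs
    ``in fruit``) and no context is given, an unmodified element is
    preferred, otherwise the first element in description order is
    returned.  Quantitative scores are converted to ``unit`` when one
    is requested (an ontology is then required for the unit registry).
    """
    hits = desc.find(structure, prop, context)
    if not hits:
        return None
    bare = [e for e in hits if not e.context]
    e = bare[0] if bare and context is None else hits[0]
    score = e.score
    if unit is not None:
        if not isinstance(score, QuantRange):
            raise UnitError(f"{prop!r} score of {structure!r} has no unit")
        if ontology is None:
            raise ArenosaeError("unit conversion requires an ontology")
        score = score.convert(unit, ontology.properties[prop])
    return score
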