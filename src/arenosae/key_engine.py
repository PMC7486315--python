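"""Dichotomous identification keys: parsing, evaluation, audit.

A key is a numbered set of couplets, each with exactly two leads; a
lead is a conjunction of predicates over a taxon description and routes
either to another couplet or to a taxon.  Evaluation is three-valued:
a predicate over a slot the description does not record is *unknown*,
and the policy decides what happens when neither lead of a couplet is
satisfied outright.

Because printed thresholds often sit exactly on a range bound
(``anthophore 3.0–5.0 mm`` against ``> 4 mm``), quantitative
satisfaction is policy-driven: ``strict-range`` demands the whole main
range satisfy the comparison, ``midpoint`` tests the main-range
midpoint, ``overlap`` asks for at least one satisfying point.  The
default policy is midpoint with both-branches handling of unresolved
couplets, which keeps evaluation deterministic while preserving
correctness at boundaries.

A predicate marked ``soft`` mirrors a hedged lead ("calyx *usually*
< 13 mm"): when unsatisfied it yields unknown instead of false, so a
taxon that sits in the acknowledged exception is not excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .errors import ArenosaeError, KeyDocumentError
from .descriptions import (
    CountRange,
    QualScore,
    QuantRange,
    RelativeScore,
    TaxonDescription,
    query,
)
from .ontology import Ontology

COMPARATORS = ("<", ">", "<=", ">=", "state-in", "range-within", "relative-is")

#: a stated relation satisfies a predicate relation when equal or stronger
_RELATION_ENTAILS = {
    "obviously-longer-than": {"obviously-longer-than", "longer-than"},
    "longer-than": {"longer-than"},
    "equal-to": {"equal-to"},
    "shorter-than": {"shorter-than"},
}


@dataclass(frozen=True)
class SatisfactionPolicy:
    mode: str = "midpoint"  # strict-range | midpoint | overlap
    include_extremes: bool = False
    unknown_handling: str = "both-branches"  # both-branches | fail

    def __post_init__(self):
        if self.mode not in ("strict-range", "midpoint", "overlap"):
            raise ArenosaeError(f"unknown policy mode {self.mode!r}")
        if self.unknown_handling not in ("both-branches", "fail"):
            raise ArenosaeError(
                f"unknown unknown_handling {self.unknown_handling!r}"
            )


DEFAULT_POLICY = SatisfactionPolicy()


@dataclass(frozen=True)
class Predicate:
    structure: str
    property: str
    comparator: str
    value: float | None = None
    unit: str | None = None
    low: float | None = None
    high: float | None = None
    states: frozenset[str] = frozenset()
    relation: str | None = None
    soft: bool = False
    note: str = ""

    def __post_init__(self):
        if self.comparator not in COMPARATORS:
            raise KeyDocumentError(f"unknown comparator {self.comparator!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "Predicate":
        comp = {"lt": "<", "gt": ">", "le": "<=", "ge": ">="}.get(
            d["comparator"], d["comparator"]
        )
        return cls(
            structure=d["structure"],
            property=d["property"],
            comparator=comp,
            value=None if d.get("value") is None else float(d["value"]),
            unit=d.get("unit"),
            low=None if d.get("low") is None else float(d["low"]),
            high=None if d.get("high") is None else float(d["high"]),
            states=frozenset(d.get("states", ())),
            relation=d.get("relation"),
            soft=bool(d.get("soft", False)),
            note=d.get("note", ""),
        )

    def to_dict(self) -> dict:
        d: dict = {"structure": self.structure, "property": self.property,
                   "comparator": self.comparator}
        if self.value is not None:
            d["value"] = self.value
        if self.unit:
            d["unit"] = self.unit
        if self.low is not None:
            d["low"] = self.low
        if self.high is not None:
            d["high"] = self.high
        if self.states:
            d["states"] = sorted(self.states)
        if self.relation:
            d["relation"] = self.relation
        if self.soft:
            d["soft"] = True
        if self.note:
            d["note"] = self.note
        return d


@dataclass(frozen=True)
class Lead:
    predicates: tuple[Predicate, ...]
    goto: int | None = None
    taxon: str | None = None
    notes: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.predicates:
            raise KeyDocumentError("lead without predicates")
        if (self.goto is None) == (self.taxon is None):
            raise KeyDocumentError(
                "lead must have exactly one outcome (goto or taxon)"
            )


@dataclass(frozen=True)
class Couplet:
    id: int
    leads: tuple[Lead, Lead]

    def __post_init__(self):
        if self.id <= 0:
            raise KeyDocumentError("couplet ids must be positive")
        if len(self.leads) != 2:
            raise KeyDocumentError(
                f"couplet {self.id} must have exactly 2 leads"
            )


class Key:
    """A validated dichotomous key."""

    def __init__(self, couplets: Sequence[Couplet], name: str = "",
                 preamble: str = ""):
        self.name = name
        self.preamble = preamble
        self.couplets: dict[int, Couplet] = {}
        for c in couplets:
            if c.id in self.couplets:
                raise KeyDocumentError(f"duplicate couplet id {c.id}")
            self.couplets[c.id] = c
        if not self.couplets:
            raise KeyDocumentError("key without couplets")
        self.start = min(self.couplets)
        self._validate_graph()

    def _validate_graph(self) -> None:
        for c in self.couplets.values():
            for lead in c.leads:
                if lead.goto is not None and lead.goto not in self.couplets:
                    raise KeyDocumentError(
                        f"couplet {c.id} points to missing couplet {lead.goto}"
                    )
        # DFS from the start couplet: detect cycles, demand reachability
        colors: dict[int, int] = {}

        def visit(cid: int) -> None:
            colors[cid] = 1
            for lead in self.couplets[cid].leads:
                if lead.goto is None:
                    continue
                state = colors.get(lead.goto, 0)
                if state == 1:
                    raise KeyDocumentError(
                        f"cycle through couplet {lead.goto}"
                    )
                if state == 0:
                    visit(lead.goto)
            colors[cid] = 2

        visit(self.start)
        unreachable = set(self.couplets) - set(colors)
        if unreachable:
            raise KeyDocumentError(
                f"couplets unreachable from {self.start}: {sorted(unreachable)}"
            )

    @property
    def terminal_taxa(self) -> list[str]:
        out = []
        for cid in sorted(self.couplets):
            for lead in self.couplets[cid].leads:
                if lead.taxon is not None and lead.taxon not in out:
                    out.append(lead.taxon)
        return out

    def __len__(self) -> int:
        return len(self.couplets)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "preamble": self.preamble,
            "couplets": [
                {
                    "id": cid,
                    "leads": [
                        {
                            "predicates": [p.to_dict() for p in lead.predicates],
                            **({"goto": lead.goto} if lead.goto is not None
                               else {"taxon": lead.taxon}),
                            **({"notes": list(lead.notes)} if lead.notes else {}),
                        }
                        for lead in self.couplets[cid].leads
                    ],
                }
                for cid in sorted(self.couplets)
            ],
        }


def parse_key(source) -> Key:
    """Load and validate a key document (path, JSON text, or dict)."""
    if isinstance(source, dict):
        doc = source
    elif isinstance(source, (str, Path)) and str(source).lstrip().startswith("{"):
        doc = json.loads(str(source))
    else:
        doc = json.loads(Path(source).read_text(encoding="utf-8"))
    couplets = []
    for c in doc["couplets"]:
        leads = tuple(
            Lead(
                predicates=tuple(
                    Predicate.from_dict(p) for p in lead["predicates"]
                ),
                goto=lead.get("goto"),
                taxon=lead.get("taxon"),
                notes=tuple(lead.get("notes", ())),
            )
            for lead in c["leads"]
        )
        if len(leads) != 2:
            raise KeyDocumentError(
                f"couplet {c.get('id')} must have exactly 2 leads"
            )
        couplets.append(Couplet(id=int(c["id"]), leads=leads))
    return Key(couplets, name=doc.get("name", ""),
               preamble=doc.get("preamble", ""))


# -- predicate evaluation -------------------------------------------------


def _compare(lo: float, hi: float, mid: float, comparator: str, value: float,
             mode: str) -> bool:
    if comparator == "<":
        return {"strict-range": hi < value, "midpoint": mid < value,
                "overlap": lo < value}[mode]
    if comparator == ">":
        return {"strict-range": lo > value, "midpoint": mid > value,
                "overlap": hi > value}[mode]
    if comparator == "<=":
        return {"strict-range": hi <= value, "midpoint": mid <= value,
                "overlap": lo <= value}[mode]
    if comparator == ">=":
        return {"strict-range": lo >= value, "midpoint": mid >= value,
                "overlap": hi >= value}[mode]
    raise ArenosaeError(f"non-numeric comparator {comparator!r}")


def eval_predicate(desc: TaxonDescription, p: Predicate,
                   policy: SatisfactionPolicy = DEFAULT_POLICY,
                   ontology: Ontology | None = None) -> bool | None:
    """Three-valued predicate evaluation (``None`` is unknown)."""
    score = query(desc, p.structure, p.property)
    if score is None:
        return None
    result: bool
    if p.comparator == "state-in":
        if not isinstance(score, QualScore):
            raise KeyDocumentError(
                f"state-in predicate on non-qualitative slot "
                f"{p.structure}:{p.property}"
            )
        result = bool(score.states & p.states)
    elif p.comparator == "relative-is":
        if not isinstance(score, RelativeScore):
            raise KeyDocumentError(
                f"relative-is predicate on non-relative slot "
                f"{p.structure}:{p.property}"
            )
        result = p.relation in _RELATION_ENTAILS.get(score.relation, set())
    elif isinstance(score, (QuantRange, CountRange)):
        if isinstance(score, QuantRange):
            if p.unit and score.unit != p.unit:
                if ontology is None:
                    raise ArenosaeError(
                        "unit conversion in predicates requires an ontology"
                    )
                score = score.convert(p.unit, ontology.properties[p.property])
            lo, hi = score.main_low, score.main_high
            if policy.include_extremes:
                lo = score.extreme_low if score.extreme_low is not None else lo
                hi = score.extreme_high if score.extreme_high is not None else hi
        else:
            lo, hi = float(score.low), float(score.high)
        mid = 0.5 * (score.main_low + score.main_high) if isinstance(
            score, QuantRange) else score.midpoint
        if p.comparator == "range-within":
            if p.low is None or p.high is None:
                raise KeyDocumentError("range-within predicate needs low/high")
            result = {
                "strict-range": p.low <= lo and hi <= p.high,
                "midpoint": p.low <= mid <= p.high,
                "overlap": hi >= p.low and lo <= p.high,
            }[policy.mode]
        else:
            if p.value is None:
                raise KeyDocumentError(
                    f"comparator {p.comparator!r} needs a value"
                )
            result = _compare(lo, hi, mid, p.comparator, p.value, policy.mode)
    else:
        raise KeyDocumentError(
            f"comparator {p.comparator!r} incompatible with score "
            f"{type(score).__name__} at {p.structure}:{p.property}"
        )
    if p.soft and not result:
        return None
    return result


def _lead_truth(desc, lead: Lead, policy, ontology) -> bool | None:
    """Three-valued conjunction over the lead's predicates."""
    saw_unknown = False
    for p in lead.predicates:
        v = eval_predicate(desc, p, policy, ontology)
        if v is False:
            return False
        if v is None:
            saw_unknown = True
    return None if saw_unknown else True


# -- evaluation trace -----------------------------------------------------


@dataclass
class EvaluationTrace:
    visited: list[tuple[int, str]] = field(default_factory=list)
    outcomes: set[str] = field(default_factory=set)
    terminal_couplets: dict[str, int] = field(default_factory=dict)
    lead_truths: dict[int, tuple[bool | None, bool | None]] = field(
        default_factory=dict
    )
    #: one (couplet id, lead index) path per reached taxon outcome
    paths: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def unique(self) -> bool:
        return len(self.outcomes) == 1


def evaluate(desc: TaxonDescription, key: Key,
             policy: SatisfactionPolicy = DEFAULT_POLICY,
             ontology: Ontology | None = None) -> EvaluationTrace:
    """Run a description through the key.

    A lead is followed iff all its predicates are true.  When neither
    lead of a couplet is true (any mix of false and unknown),
    ``both-branches`` handling explores both continuations and unions
    the outcomes; ``fail`` handling records a dead end.
    """
    trace = EvaluationTrace()

    def walk(cid: int, path: list[tuple[int, int]]) -> None:
        couplet = key.couplets[cid]
        if cid not in trace.lead_truths:
            trace.lead_truths[cid] = tuple(
                _lead_truth(desc, lead, policy, ontology)
                for lead in couplet.leads
            )
        ta, tb = trace.lead_truths[cid]
        if ta is True and tb is True:
            chosen, label = [0, 1], "both"
        elif ta is True:
            chosen, label = [0], "a"
        elif tb is True:
            chosen, label = [1], "b"
        elif policy.unknown_handling == "both-branches":
            chosen, label = [0, 1], "both"
        else:
            chosen, label = [], "dead-end"
        trace.visited.append((cid, label))
        for idx in chosen:
            lead = couplet.leads[idx]
            step = path + [(cid, idx)]
            if lead.taxon is not None:
                trace.outcomes.add(lead.taxon)
                trace.terminal_couplets.setdefault(lead.taxon, cid)
                trace.paths.setdefault(lead.taxon, step)
            else:
                walk(lead.goto, step)

    walk(key.start, [])
    return trace


# -- audit ----------------------------------------------------------------


@dataclass
class TaxonAudit:
    taxon: str
    member: bool
    terminal_couplet: int | None
    #: couplets on this taxon's path where the sibling lead is true/unknown
    weak_discriminations: list[int]


@dataclass
class ConsistencyReport:
    audits: list[TaxonAudit]

    @property
    def all_members(self) -> bool:
        return all(a.member for a in self.audits)

    def to_dict(self) -> dict:
        return {
            "all_members": self.all_members,
            "taxa": [
                {
                    "taxon": a.taxon,
                    "member": a.member,
                    "terminal_couplet": a.terminal_couplet,
                    "weak_discriminations": a.weak_discriminations,
                }
                for a in self.audits
            ],
        }

    def to_markdown(self) -> str:
        lines = ["| taxon | member | terminal | weak couplets |",
                 "| --- | --- | --- | --- |"]
        for a in self.audits:
            weak = ", ".join(map(str, a.weak_discriminations)) or "-"
            lines.append(
                f"| {a.taxon} | {'yes' if a.member else 'NO'} | "
                f"{a.terminal_couplet if a.terminal_couplet is not None else '-'}"
                f" | {weak} |"
            )
        return "\n".join(lines) + "\n"


def check_consistency(key: Key, descs: Mapping[str, TaxonDescription],
                      policy: SatisfactionPolicy = DEFAULT_POLICY,
                      ontology: Ontology | None = None) -> ConsistencyReport:
    """Audit a key against one description per terminal taxon.

    For each taxon: (a) membership — the taxon appears in the outcome
    set of its own description; (b) discrimination — couplets on its
    path where the sibling lead is also true or unknown, i.e. where the
    key does not cleanly separate it.
    """
    audits = []
    for taxon in key.terminal_taxa:
        if taxon not in descs:
            raise KeyDocumentError(f"no description for terminal {taxon!r}")
        trace = evaluate(descs[taxon], key, policy, ontology)
        member = taxon in trace.outcomes
        weak: list[int] = []
        if member:
            for cid, idx in trace.paths[taxon]:
                sibling = trace.lead_truths[cid][1 - idx]
                if sibling is not False:
                    weak.append(cid)
        audits.append(
            TaxonAudit(
                taxon=taxon,
                member=member,
                terminal_couplet=trace.terminal_couplets.get(taxon),
                weak_discriminations=weak,
            )
        )
    return ConsistencyReport(audits)
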