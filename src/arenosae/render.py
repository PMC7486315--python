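"""Telegraphic rendering and parsing of description text.

Quantitative scores use the conventional range notation of taxonomic
accounts: a main range flanked by optional parenthetical extremes, as
in ``(8.0–)9.0–13.0(–14.0) mm``.  Dimension pairs join a length and a
width with a multiplication sign (``10.0–40.0 × 2.0–4.0 mm``).

Rendering a whole description walks the template slots in order and
emits one fragment per label group.  Full-sentence equality with a
printed account is not the goal (accounts contain free-text asides);
the contract is slot-wise phrase equality for scores, which is what
the fixture audits check.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ArenosaeError
from .descriptions import (
    CountRange,
    DescriptiveElement,
    QualScore,
    QuantRange,
    RelativeScore,
    TaxonDescription,
)
from .ontology import DescriptionTemplate, parse_structure_path

EN_DASH = "–"
TIMES = "×"


class RenderParseError(ArenosaeError):
    def __init__(self, text: str, position: int):
        self.position = position
        super().__init__(
            f"cannot parse quantitative range {text!r} at position {position}"
        )


@dataclass(frozen=True)
class RenderStyle:
    """Typography knobs.  ``ascii_safe`` falls back to ``-`` and ``x``."""

    dash: str = EN_DASH
    times: str = TIMES
    ascii_safe: bool = False
    decimals: dict = field(default_factory=dict)  # property name -> precision
    #: suffix appended after a quantitative phrase, per property
    suffixes: dict = field(
        default_factory=lambda: {"length": "long", "height": "tall"}
    )

    @property
    def dash_glyph(self) -> str:
        return "-" if self.ascii_safe else self.dash

    @property
    def times_glyph(self) -> str:
        return "x" if self.ascii_safe else self.times


DEFAULT_STYLE = RenderStyle()


def _num(value: float, precision: int) -> str:
    return f"{value:.{precision}f}"


def format_quant(r: QuantRange, style: RenderStyle = DEFAULT_STYLE,
                 precision: int = 1, with_unit: bool = True) -> str:
    """``(EL-)ML-MH(-EH) unit``; parentheses omitted when extremes absent."""
    d = style.dash_glyph
    parts = []
    if r.extreme_low is not None:
        parts.append(f"({_num(r.extreme_low, precision)}{d})")
    if r.main_low == r.main_high:
        parts.append(_num(r.main_low, precision))
    else:
        parts.append(f"{_num(r.main_low, precision)}{d}{_num(r.main_high, precision)}")
    if r.extreme_high is not None:
        parts.append(f"({d}{_num(r.extreme_high, precision)})")
    text = "".join(parts)
    if with_unit and r.unit:
        text += f" {r.unit}"
    return text


def format_dimension_pair(length: QuantRange, width: QuantRange,
                          style: RenderStyle = DEFAULT_STYLE,
                          precision: int = 1) -> str:
    if length.unit != width.unit:
        raise ArenosaeError("dimension pair must share a unit")
    return (
        f"{format_quant(length, style, precision, with_unit=False)} "
        f"{style.times_glyph} "
        f"{format_quant(width, style, precision, with_unit=True)}"
    )


def format_count(c: CountRange, style: RenderStyle = DEFAULT_STYLE) -> str:
    if c.low == c.high:
        return str(c.low)
    return f"{c.low}{style.dash_glyph}{c.high}"


_NUM = r"\d+(?:\.\d+)?"
_DASH = f"[{EN_DASH}-]"
_RANGE_RE = re.compile(
    rf"^\s*(?:ca\.?\s+)?"
    rf"(?:\(\s*(?P<el>{_NUM})\s*{_DASH}\s*\)\s*)?"
    rf"(?P<ml>{_NUM})"
    rf"(?:\s*{_DASH}\s*(?P<mh>{_NUM}))?"
    rf"(?:\s*\(\s*{_DASH}\s*(?P<eh>{_NUM})\s*\))?"
    rf"\s*(?P<unit>[a-zA-Zµ]+)?\s*$"
)


def parse_quant(text: str, default_unit: str = "mm"):
    """Parse the range notation; the inverse of :func:`format_quant`.

    A dimension pair (``10.0–30.0 × 2.0–4.0 mm``) yields a
    ``(length, width)`` tuple sharing the trailing unit.  En dash and
    ASCII hyphen are both accepted.
    """
    parts = re.split(rf"\s*[{TIMES}x]\s+", text.strip())
    if len(parts) == 2:
        width = parse_quant(parts[1], default_unit)
        length = parse_quant(parts[0], width.unit)
        return (length, width)
    m = _RANGE_RE.match(text)
    if not m:
        # report the first offending character for diagnostics
        allowed = set("0123456789.()–- ") | {EN_DASH}
        pos = next(
            (i for i, ch in enumerate(text) if ch not in allowed and
             not ch.isalpha()),
            0,
        )
        raise RenderParseError(text, pos)
    ml = float(m.group("ml"))
    mh = float(m.group("mh")) if m.group("mh") else ml
    r = QuantRange(
        ml, mh,
        float(m.group("el")) if m.group("el") else None,
        float(m.group("eh")) if m.group("eh") else None,
        m.group("unit") or default_unit,
    )
    if not r.wellformed:
        raise RenderParseError(text, 0)
    return r


# -- whole-description rendering ------------------------------------------


def _ref_phrase(path: str) -> str:
    """Noun phrase for a structure path: ``internode[position=next-upper]``
    becomes ``next upper internode``."""
    seg = parse_structure_path(path).segments[-1]
    words = [v.replace("-", " ") for _, v in seg.specifiers]
    words.append(seg.structure.replace("-", " "))
    return " ".join(words)


_MODIFIER_PHRASES = {
    "at-anthesis": "at anthesis",
    "in-fruit": "in fruit",
    "in-flower": "in flower",
    "in-bud": "in bud",
    "in-lower-part": "in lower part",
    "in-upper-part": "in upper part",
    "in-central-part": "in central part",
}

_RELATION_PHRASES = {
    "obviously-longer-than": "obviously longer than",
    "longer-than": "longer than",
    "equal-to": "equal to",
    "shorter-than": "shorter than",
}


def _score_phrase(e: DescriptiveElement, precision: int,
                  style: RenderStyle) -> str:
    if isinstance(e.score, QuantRange):
        text = format_quant(e.score, style, precision)
        suffix = style.suffixes.get(e.property, "")
        if suffix:
            text += f" {suffix}"
    elif isinstance(e.score, CountRange):
        text = format_count(e.score, style)
    elif isinstance(e.score, QualScore):
        text = " or ".join(s.replace("-", " ") for s in sorted(e.score.states))
    elif isinstance(e.score, RelativeScore):
        text = (f"{_RELATION_PHRASES[e.score.relation]} the "
                f"{_ref_phrase(e.score.reference)}")
    else:  # pragma: no cover
        raise ArenosaeError(f"cannot render score {e.score!r}")
    freq = [m.value for m in e.modifiers if m.kind == "frequency"]
    if freq:
        text = f"{' '.join(freq)} {text}"
    temporal = [
        _MODIFIER_PHRASES.get(m.value, m.value)
        for m in e.modifiers if m.kind == "temporal"
    ]
    if temporal:
        text = f"{text} {' '.join(temporal)}"
    spatial = [
        _MODIFIER_PHRASES.get(m.value, m.value)
        for m in e.modifiers if m.kind == "spatial"
    ]
    if spatial:
        text = f"{text} {' '.join(spatial)}"
    return text


def render_fragments(desc: TaxonDescription, template: DescriptionTemplate,
                     style: RenderStyle = DEFAULT_STYLE) -> list[str]:
    """One text fragment per template label group, in slot order.

    Consecutive template slots sharing a label form a group; the label
    is emitted once, followed by the slot phrases.  A length slot
    immediately followed by a width slot of the same structure is fused
    into a dimension pair.  Phrases join with a comma, except before a
    relative phrase, which reads better after ``and``.
    """
    emap: dict[tuple, list[DescriptiveElement]] = {}
    for e in desc.elements:
        emap.setdefault((e.structure, e.property), []).append(e)

    fragments: list[str] = []
    current_label: str | None = None
    phrases: list[str] = []
    pending_length: tuple[DescriptiveElement, int] | None = None

    def flush():
        nonlocal phrases, current_label, pending_length
        if pending_length is not None:
            e, prec = pending_length
            phrases.append(_score_phrase(e, prec, style))
            pending_length = None
        if current_label is not None and phrases:
            text = current_label
            for i, p in enumerate(phrases):
                if i == 0:
                    text += f" {p}"
                elif p.startswith(tuple(_RELATION_PHRASES.values())):
                    text += f" and {p}"
                else:
                    text += f", {p}"
            if text[:1].isupper():
                text += "."
            fragments.append(text)
        phrases = []

    for slot in template.slots:
        elems = emap.get((slot.path, slot.property), [])
        if not elems:
            continue
        label = slot.label or _ref_phrase(slot.path).capitalize()
        if label != current_label:
            flush()
            current_label = label
        precision = style.decimals.get(slot.property, slot.precision)
        # fuse length x width pairs of the same structure
        if pending_length is not None:
            le, lp = pending_length
            if (slot.property == "width" and le.structure == slot.path
                    and len(elems) == 1
                    and isinstance(elems[0].score, QuantRange)):
                phrases.append(
                    format_dimension_pair(le.score, elems[0].score, style, lp)
                )
                pending_length = None
                continue
            phrases.append(_score_phrase(le, lp, style))
            pending_length = None
        if (slot.property == "length" and len(elems) == 1
                and isinstance(elems[0].score, QuantRange)
                and not elems[0].modifiers):
            pending_length = (elems[0], precision)
            continue
        group = [_score_phrase(e, precision, style) for e in elems]
        if len(group) > 1 and all(
            any(m.kind == "temporal" for m in e.modifiers) for e in elems
        ):
            phrases.append(" and ".join(group))
        else:
            phrases.extend(group)
    flush()
    return fragments


def render_description(desc: TaxonDescription, template: DescriptionTemplate,
                       style: RenderStyle = DEFAULT_STYLE) -> str:
    return " ".join(render_fragments(desc, template, style))


def render_markdown(desc: TaxonDescription, template: DescriptionTemplate,
                    style: RenderStyle = DEFAULT_STYLE) -> str:
    body = render_description(desc, template, style)
    return f"#### {desc.taxon_name}\n\n{body}\n"


_TOKEN_RE = re.compile(_NUM)


def numeric_tokens(text: str) -> list[float]:
    """All numbers occurring in a text, for fixture audits."""
    return [float(t) for t in _TOKEN_RE.findall(text)]
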