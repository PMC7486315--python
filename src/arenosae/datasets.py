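"""Packaged descriptive dataset for *Silene* sect. *Arenosae*.

The data directory ships the reconstructed base ontology, the section
description template, one structured description per taxon (the
section, eight species and the four subspecies of *S. microsperma*),
the dichotomous key to the section, and the published telegraphic
account text for each taxon.

Taxon descriptions are stored factored against the section
description — an element stated identically at section level is not
repeated in a species file — mirroring how the accounts were databased
without redundancy.  :func:`load_description` with ``expanded=True``
(the default for key work) merges the section back in.

Elements flagged ``supplemented`` were not part of the formal account
but are recorded from the section preamble, the key, or the
morphological notes (flowering time, leaf succulence, calyx-tooth
dimorphism, tooth margin width); the flag preserves that provenance.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from .descriptions import TaxonDescription, expand, load_description as _load_desc
from .key_engine import Key, parse_key
from .ontology import DescriptionTemplate, Ontology, load_ontology, load_template

SECTION = "Silene sect. Arenosae"

#: file slug -> accepted taxon name
TAXA = {
    "arenosa": "Silene arenosa",
    "leyseroides": "Silene leyseroides",
    "linearis": "Silene linearis",
    "austroiranica": "Silene austroiranica",
    "georgievskyi": "Silene georgievskyi",
    "chaetodonta": "Silene chaetodonta",
    "striata": "Silene striata",
    "microsperma": "Silene microsperma subsp. microsperma",
    "cypria": "Silene microsperma subsp. cypria",
    "maritima": "Silene microsperma subsp. maritima",
    "modesta": "Silene microsperma subsp. modesta",
    "exsudans": "Silene exsudans",
}

_NAME_TO_SLUG = {v: k for k, v in TAXA.items()}


def _data(name: str) -> str:
    return (
        resources.files("arenosae").joinpath("data", name).read_text("utf-8")
    )


@lru_cache(maxsize=1)
def load_base_ontology() -> Ontology:
    return load_ontology(_data("ontology.json"))


@lru_cache(maxsize=1)
def load_section_template() -> DescriptionTemplate:
    return load_template(load_base_ontology(), _data("template.json"))


@lru_cache(maxsize=1)
def load_section_description() -> TaxonDescription:
    return _load_desc(_data("descriptions/section.json"))


def load_taxon_description(name: str, expanded: bool = True) -> TaxonDescription:
    """Load one taxon description by slug or accepted name.

    With ``expanded=True`` the section-level elements are merged in, so
    the result is self-contained (what key evaluation needs); with
    ``expanded=False`` the stored, redundancy-free form is returned.
    """
    slug = _NAME_TO_SLUG.get(name, name)
    if slug not in TAXA:
        raise KeyError(f"unknown taxon {name!r}")
    desc = _load_desc(_data(f"descriptions/{slug}.json"))
    if expanded:
        desc = expand(desc, load_section_description())
    return desc


def load_all_descriptions(expanded: bool = True) -> dict[str, TaxonDescription]:
    """All terminal taxa, keyed by accepted name."""
    return {
        name: load_taxon_description(slug, expanded=expanded)
        for slug, name in TAXA.items()
    }


@lru_cache(maxsize=1)
def load_key() -> Key:
    return parse_key(_data("key.json"))


def load_account_text(name: str) -> str:
    """The published telegraphic account for a taxon (plain text)."""
    slug = _NAME_TO_SLUG.get(name, name)
    return _data(f"accounts/{slug}.txt")


def species_names() -> list[str]:
    """Accepted species of the section.

    Species with their own account plus species implied as parents of
    packaged subspecies (*S. microsperma* is described only through its
    four subspecies).
    """
    names: list[str] = []
    implied: list[str] = []
    for slug, name in TAXA.items():
        desc = load_taxon_description(slug, expanded=False)
        if desc.rank == "species" and name not in names:
            names.append(name)
        elif desc.rank == "subspecies" and desc.parent:
            if desc.parent not in implied:
                implied.append(desc.parent)
    for name in implied:
        if name not in names:
            names.append(name)
    return names


def subspecies_names(parent: str = "Silene microsperma") -> list[str]:
    out = []
    for slug, name in TAXA.items():
        desc = load_taxon_description(slug, expanded=False)
        if desc.rank == "subspecies" and desc.parent == parent:
            out.append(name)
    return out
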