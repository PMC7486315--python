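"""Synthetic descriptions, keys and posterior tree samples.

The generators make every other module testable without external data.
They draw from a single explicitly seeded pseudo-random source per
call; the same seed reproduces byte-identical output.

``gen_posterior`` emulates the structure of a species-tree posterior
sample around a known truth: a fixed true partition of individuals
into populations, a per-tip reassignment ("flip") probability *q* that
blurs it, coalescence of same-population tips well below the collapse
height and of populations well above it.  It does not simulate the
multispecies-coalescent likelihood itself — only the cluster geometry
a delimitation summary consumes — so co-clustering probabilities are
known in closed form (:func:`expected_cocluster`) and matrix estimates
can be checked against them.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .delimit import Partition, TreeSampleSet, UltrametricTree, _Node
from .descriptions import (
    DescriptiveElement,
    QualScore,
    QuantRange,
    TaxonDescription,
)
from .errors import ArenosaeError
from .ontology import (
    DescriptionTemplate,
    Ontology,
    PropertyTerm,
    StructureTerm,
    TemplateSlot,
)

#: collapse height the posterior generator is calibrated around
COLLAPSE_HEIGHT = 1e-4


def _default_partition() -> dict[str, list[str]]:
    # 12 individuals in 6 populations of 3/2/2/2/2/1, echoing a sampling
    # design of two-to-three specimens per putative species
    return {
        "A": ["A1", "A2", "A3"],
        "B": ["B1", "B2"],
        "C": ["C1", "C2"],
        "D": ["D1", "D2"],
        "E": ["E1", "E2"],
        "F": ["F1"],
    }


@dataclass
class SynthConfig:
    seed: int = 0
    # description generator
    n_taxa: int = 5
    n_chars: int = 20
    constant_fraction: float = 0.4
    # posterior generator
    true_partition: dict[str, list[str]] = field(
        default_factory=_default_partition
    )
    flip_prob: float = 0.1
    n_samples: int = 400
    within_height: float = 5e-5
    between_height: float = 1e-2

    def __post_init__(self):
        if not (0 <= self.flip_prob <= 1):
            raise ArenosaeError("flip_prob must be in [0, 1]")
        if not (0 < self.within_height < self.between_height):
            raise ArenosaeError(
                "need 0 < within_height < between_height"
            )
        if not (0 <= self.constant_fraction <= 1):
            raise ArenosaeError("constant_fraction must be in [0, 1]")


# -- synthetic descriptions -----------------------------------------------

_SYN_STATES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta")


@dataclass
class SynthDescriptions:
    parent: TaxonDescription        # exactly the constant slots
    descriptions: list[TaxonDescription]
    ontology: Ontology
    template: DescriptionTemplate
    constant_slots: list[tuple[str, str]]


def _synth_vocabulary(n_chars: int) -> tuple[Ontology, DescriptionTemplate]:
    structures = [StructureTerm("organism")]
    slots = []
    props = [
        PropertyTerm("length", "quantitative", canonical_unit="mm",
                     units={"mm": 1.0, "cm": 10.0}),
        PropertyTerm("form", "qualitative", states=_SYN_STATES),
    ]
    for i in range(n_chars):
        name = f"organ{i:02d}"
        structures.append(StructureTerm(name, parent="organism"))
        prop = "length" if i % 2 == 0 else "form"
        slots.append(TemplateSlot(path=name, property=prop,
                                  label=name.capitalize()))
    onto = Ontology(structures, props, version="synthetic")
    return onto, DescriptionTemplate(onto, slots, name="synthetic")


def _draw_score(rng: random.Random, prop: str):
    if prop == "length":
        low = round(rng.uniform(1.0, 15.0), 1)
        high = round(low + rng.uniform(0.5, 10.0), 1)
        return QuantRange(low, high, unit="mm")
    k = rng.randint(1, 2)
    return QualScore(rng.sample(_SYN_STATES, k))


def _different_score(rng: random.Random, prop: str, base):
    while True:
        alt = _draw_score(rng, prop)
        if alt != base:
            return alt


def gen_descriptions(cfg: SynthConfig) -> SynthDescriptions:
    """Generate ``n_taxa`` descriptions over ``n_chars`` slots.

    Exactly ``round(constant_fraction * n_chars)`` slots carry an
    identical element in every taxon; each remaining slot differs in at
    least one taxon.  The returned parent truth holds exactly the
    constant elements, so ``intersect_constant`` (strict) must recover
    it and ``factor``/``expand`` against it must round-trip.
    """
    if cfg.n_taxa < 2:
        raise ArenosaeError("need at least two taxa")
    rng = random.Random(cfg.seed)
    onto, template = _synth_vocabulary(cfg.n_chars)
    n_const = round(cfg.constant_fraction * cfg.n_chars)
    constant_idx = set(rng.sample(range(cfg.n_chars), n_const))

    parent_elems: list[DescriptiveElement] = []
    per_taxon: list[list[DescriptiveElement]] = [[] for _ in range(cfg.n_taxa)]
    constant_slots: list[tuple[str, str]] = []
    for i, slot in enumerate(template.slots):
        base = _draw_score(rng, slot.property)
        if i in constant_idx:
            e = DescriptiveElement(slot.path, slot.property, base)
            parent_elems.append(e)
            constant_slots.append(slot.key)
            for elems in per_taxon:
                elems.append(e)
        else:
            deviant = rng.randrange(cfg.n_taxa)
            for t, elems in enumerate(per_taxon):
                score = (_different_score(rng, slot.property, base)
                         if t == deviant else base)
                elems.append(
                    DescriptiveElement(slot.path, slot.property, score)
                )
    parent = TaxonDescription("synthetic-parent", "section",
                              elements=parent_elems)
    descs = [
        TaxonDescription(f"synthetic-taxon-{t:02d}", "species",
                         elements=elems, parent="synthetic-parent")
        for t, elems in enumerate(per_taxon)
    ]
    return SynthDescriptions(parent, descs, onto, template, constant_slots)


# -- synthetic posteriors -------------------------------------------------


def _join_caterpillar(nodes: list[_Node], heights: list[float]) -> _Node:
    """Join subtrees pairwise at the given ascending heights."""
    assert len(heights) == len(nodes) - 1
    current = nodes[0]
    for node, h in zip(nodes[1:], heights):
        current = _Node(height=h, children=[current, node])
    return current


def gen_posterior(cfg: SynthConfig) -> TreeSampleSet:
    """Sample ``n_samples`` ultrametric trees around the true partition.

    Per sample, each tip is reassigned with probability ``flip_prob``
    to a uniformly chosen *other* population; tips sharing a (possibly
    perturbed) population coalesce at heights uniform in
    ``(0, within_height)`` and populations join at heights in
    ``(between_height, 2 * between_height)``, so the collapse partition
    at any epsilon between the two scales equals the perturbed
    assignment.
    """
    classes = sorted(cfg.true_partition)
    if not classes:
        raise ArenosaeError("empty partition")
    tips = [t for c in classes for t in cfg.true_partition[c]]
    if len(set(tips)) != len(tips):
        raise ArenosaeError("duplicate tips in partition")
    if len(classes) < 2 and cfg.flip_prob > 0:
        raise ArenosaeError(
            "reassignment needs at least two classes (no flip target)"
        )
    rng = random.Random(cfg.seed)
    trees = []
    for _ in range(cfg.n_samples):
        assign: dict[str, str] = {}
        for c in classes:
            for t in sorted(cfg.true_partition[c]):
                if cfg.flip_prob > 0 and rng.random() < cfg.flip_prob:
                    others = [x for x in classes if x != c]
                    assign[t] = others[rng.randrange(len(others))]
                else:
                    assign[t] = c
        groups: dict[str, list[str]] = {}
        for t in sorted(assign):
            groups.setdefault(assign[t], []).append(t)
        subtrees = []
        for c in sorted(groups):
            members = [_Node(height=0.0, label=t) for t in groups[c]]
            heights = sorted(
                rng.uniform(0.0, cfg.within_height)
                for _ in range(len(members) - 1)
            )
            subtrees.append(_join_caterpillar(members, heights))
        if len(subtrees) == 1:
            root = subtrees[0]
        else:
            heights = sorted(
                rng.uniform(cfg.between_height, 2 * cfg.between_height)
                for _ in range(len(subtrees) - 1)
            )
            root = _join_caterpillar(subtrees, heights)
        trees.append(UltrametricTree(root))
    return TreeSampleSet(trees, source=f"synthetic(seed={cfg.seed})")


def true_partition_of(cfg: SynthConfig) -> Partition:
    return Partition(
        frozenset(frozenset(v) for v in cfg.true_partition.values())
    )


def expected_cocluster(cfg: SynthConfig, a: str, b: str) -> float:
    """Closed-form construction probability that two tips co-cluster.

    With K classes and flip probability q, two tips of the same class
    stay together with probability (1-q)^2 + q^2/(K-1) (neither moves,
    or both move to the same other class); tips of different classes
    meet with probability 2q(1-q)/(K-1) + q^2(K-2)/(K-1)^2.
    """
    if a == b:
        return 1.0
    k = len(cfg.true_partition)
    q = cfg.flip_prob
    same = any(
        a in members and b in members
        for members in cfg.true_partition.values()
    )
    if k == 1:
        return 1.0
    if same:
        return (1 - q) ** 2 + q ** 2 / (k - 1)
    return 2 * q * (1 - q) / (k - 1) + q ** 2 * (k - 2) / (k - 1) ** 2
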