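import random

import pytest
from hypothesis import given, settings, strategies as st_hyp

from arenosae.descriptions import (
    DescriptiveElement,
    QuantRange,
    TaxonDescription,
)
from arenosae.errors import KeyDocumentError
from arenosae.key_engine import (
    Predicate,
    SatisfactionPolicy,
    check_consistency,
    eval_predicate,
    evaluate,
    parse_key,
)


def _minimal_key(goto_target=2):
    return {
        "couplets": [
            {"id": 1, "leads": [
                {"predicates": [{"structure": "calyx", "property": "length",
                                 "comparator": "<", "value": 10}],
                 "taxon": "A"},
                {"predicates": [{"structure": "calyx", "property": "length",
                                 "comparator": ">", "value": 10}],
                 "goto": goto_target},
            ]},
            {"id": 2, "leads": [
                {"predicates": [{"structure": "calyx", "property": "length",
                                 "comparator": "<", "value": 20}],
                 "taxon": "B"},
                {"predicates": [{"structure": "calyx", "property": "length",
                                 "comparator": ">", "value": 20}],
                 "taxon": "C"},
            ]},
        ]
    }


def test_packaged_key_structure(key):
    assert len(key) == 11
    assert sorted(key.couplets) == list(range(1, 12))
    assert len(key.terminal_taxa) == 12


def test_missing_goto_target_is_an_error():
    with pytest.raises(KeyDocumentError):
        parse_key(_minimal_key(goto_target=99))


def test_cycle_is_an_error():
    doc = _minimal_key()
    doc["couplets"][1]["leads"][1] = {
        "predicates": [{"structure": "calyx", "property": "length",
                        "comparator": ">", "value": 20}],
        "goto": 1,
    }
    with pytest.raises(KeyDocumentError, match="cycle"):
        parse_key(doc)


def test_single_lead_couplet_is_an_error():
    doc = _minimal_key()
    doc["couplets"][0]["leads"] = doc["couplets"][0]["leads"][:1]
    with pytest.raises(KeyDocumentError):
        parse_key(doc)


# -- predicate semantics --------------------------------------------------


def _desc_with(lo, hi):
    return TaxonDescription("x", "species", [
        DescriptiveElement("anthophore", "length", QuantRange(lo, hi)),
    ])


def test_predicate_true_in_every_mode_when_range_clear(descriptions):
    p = Predicate("calyx", "length", ">", value=20, unit="mm")
    d = descriptions["Silene georgievskyi"]  # calyx 25-30 mm
    for mode in ("strict-range", "midpoint", "overlap"):
        assert eval_predicate(d, p, SatisfactionPolicy(mode=mode)) is True


def test_predicate_false_when_range_entirely_outside():
    p = Predicate("anthophore", "length", "<", value=1, unit="mm")
    for mode in ("strict-range", "midpoint", "overlap"):
        assert eval_predicate(_desc_with(12.0, 13.0), p,
                              SatisfactionPolicy(mode=mode)) is False


def test_boundary_range_splits_by_policy():
    # 5.0-6.0 mm against "< 6 mm": strict no, midpoint/overlap yes
    p = Predicate("anthophore", "length", "<", value=6, unit="mm")
    d = _desc_with(5.0, 6.0)
    assert eval_predicate(d, p, SatisfactionPolicy(mode="strict-range")) is False
    assert eval_predicate(d, p, SatisfactionPolicy(mode="midpoint")) is True
    assert eval_predicate(d, p, SatisfactionPolicy(mode="overlap")) is True


def test_missing_slot_is_unknown():
    p = Predicate("calyx", "length", "<", value=10, unit="mm")
    assert eval_predicate(_desc_with(1.0, 2.0), p) is None


def test_soft_predicate_fails_to_unknown():
    p = Predicate("anthophore", "length", "<", value=3, unit="mm", soft=True)
    assert eval_predicate(_desc_with(5.0, 6.0), p) is None


def test_incompatible_comparator_raises():
    p = Predicate("anthophore", "length", "state-in",
                  states=frozenset({"glabrous"}))
    with pytest.raises(KeyDocumentError):
        eval_predicate(_desc_with(5.0, 6.0), p)


@settings(max_examples=200, deadline=None)
@given(
    bounds=st_hyp.tuples(
        st_hyp.integers(0, 300).map(lambda v: v / 10),
        st_hyp.integers(0, 300).map(lambda v: v / 10)),
    value=st_hyp.integers(0, 300).map(lambda v: v / 10),
    comparator=st_hyp.sampled_from(["<", ">"]),
)
def test_policy_monotonicity(bounds, value, comparator):
    """overlap-true includes midpoint-true includes strict-true."""
    lo, hi = sorted(bounds)
    d = _desc_with(lo, hi)
    p = Predicate("anthophore", "length", comparator, value=value, unit="mm")
    results = {
        mode: eval_predicate(d, p, SatisfactionPolicy(mode=mode))
        for mode in ("strict-range", "midpoint", "overlap")
    }
    if results["strict-range"]:
        assert results["midpoint"]
    if results["midpoint"]:
        assert results["overlap"]


# -- evaluation -----------------------------------------------------------


def test_georgievskyi_resolves_uniquely_at_couplet_3(
        key, descriptions, ontology):
    trace = evaluate(descriptions["Silene georgievskyi"], key,
                     ontology=ontology)
    assert trace.outcomes == {"Silene georgievskyi"}
    assert trace.terminal_couplets["Silene georgievskyi"] == 3


def test_exsudans_resolves_uniquely_at_couplet_1(key, descriptions, ontology):
    trace = evaluate(descriptions["Silene exsudans"], key, ontology=ontology)
    assert trace.outcomes == {"Silene exsudans"}
    assert trace.terminal_couplets["Silene exsudans"] == 1


def test_every_terminal_contains_its_own_taxon(key, descriptions, ontology):
    for name, desc in descriptions.items():
        trace = evaluate(desc, key, ontology=ontology)
        assert name in trace.outcomes, name


def test_fully_unknown_description_reaches_all_terminals(key):
    empty = TaxonDescription("mystery", "species")
    trace = evaluate(empty, key)
    assert trace.outcomes == set(key.terminal_taxa)
    assert len(trace.outcomes) == 12


def test_fail_handling_dead_ends_instead_of_branching(key):
    empty = TaxonDescription("mystery", "species")
    policy = SatisfactionPolicy(unknown_handling="fail")
    trace = evaluate(empty, key, policy)
    assert trace.outcomes == set()
    assert trace.visited == [(1, "dead-end")]


def test_unambiguous_trace_visits_at_most_all_couplets(
        key, descriptions, ontology):
    trace = evaluate(descriptions["Silene georgievskyi"], key,
                     ontology=ontology)
    assert len(trace.visited) <= len(key)


def test_outcomes_invariant_under_couplet_renumbering(
        key, descriptions, ontology):
    doc = key.to_dict()
    mapping = {cid: cid * 10 + 3 for cid in key.couplets}
    for c in doc["couplets"]:
        c["id"] = mapping[c["id"]]
        for lead in c["leads"]:
            if "goto" in lead:
                lead["goto"] = mapping[lead["goto"]]
    # the id map is monotonic, so the entry couplet stays first
    renumbered = parse_key(doc)
    assert renumbered.start == mapping[1]
    for name in ("Silene georgievskyi", "Silene chaetodonta"):
        a = evaluate(descriptions[name], key, ontology=ontology)
        b = evaluate(descriptions[name], renumbered, ontology=ontology)
        assert a.outcomes == b.outcomes


# -- audit ----------------------------------------------------------------


def test_full_consistency_audit_membership(key, descriptions, ontology):
    report = check_consistency(key, descriptions, ontology=ontology)
    assert report.all_members
    assert len(report.audits) == 12


def test_contradicting_lead_reported_as_nonmember():
    doc = _minimal_key()
    key = parse_key(doc)
    descs = {
        "A": _calyx(15.0, 16.0),  # violates its own lead (calyx < 10)
        "B": _calyx(15.0, 16.0),
        "C": _calyx(25.0, 30.0),
    }
    report = check_consistency(key, descs)
    by_taxon = {a.taxon: a for a in report.audits}
    assert not by_taxon["A"].member
    assert by_taxon["B"].member and by_taxon["C"].member


def test_identical_leads_flagged_as_weak_discrimination():
    pred = {"structure": "calyx", "property": "length",
            "comparator": ">", "value": 1}
    doc = {"couplets": [{"id": 1, "leads": [
        {"predicates": [dict(pred)], "taxon": "A"},
        {"predicates": [dict(pred)], "taxon": "B"},
    ]}]}
    key = parse_key(doc)
    report = check_consistency(key, {"A": _calyx(5.0, 6.0),
                                     "B": _calyx(5.0, 6.0)})
    assert all(a.weak_discriminations == [1] for a in report.audits)


def _calyx(lo, hi):
    return TaxonDescription("x", "species", [
        DescriptiveElement("calyx", "length", QuantRange(lo, hi)),
    ])
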