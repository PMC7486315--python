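# Methods

## The description model

A taxon description is an ordered set of descriptive elements (DEs).
Each DE scores one property of one structure:

* **quantitative** — a main range with optional parenthetical extremes,
  `(8.0–)9.0–13.0(–14.0) mm`; units live in a per-property registry
  (mm and cm, factor 10), and all comparisons happen after conversion
  to the property's canonical unit (mm);
* **qualitative** — a non-empty set of alternative states joined by
  "or" (`oblong or ellipsoid`);
* **count** — a non-negative integer range (`with 2–3 distinct
  internodes`); the rare parenthetical count extreme is not modelled;
* **relative** — a relation to another structure
  (`obviously longer than the next upper internode`), with
  *obviously-longer-than* entailing *longer-than*.

Modifiers qualify a DE by frequency (`usually`), time (`at anthesis`,
`in fruit`) or position (`in lower part`). Temporal and spatial
modifiers define the *slot context*: a calyx that is "cylindrical at
anthesis and clavate in fruit" is two DEs on the same slot in different
contexts, and the at-most-one-DE invariant keys on (structure, property,
context). Frequency modifiers do not split contexts, but they do count
for element identity: "rarely erect" is not the same statement as
"erect".

The base ontology fixes structures (a single-parent part-of tree),
properties, states and units. It is a reconstruction: it covers every
term used in the packaged accounts, not the full vocabulary of the
original database. Specifiers single out one instance of a structure
collection and are written into the path —
`internode[position=uppermost]`, `flower[order=first]/pedicel`,
`tooth[class=shorter]`, `limb[surface=upper]`, `leaf[type=basal]`.
Calyx-tooth heteromorphism (three longer vs two shorter teeth) is
encoded as parallel DE sets on the two tooth classes. Synonyms resolve
to canonical names at load time; all names are NFC-normalized.

A description template is an ordered slot list over the ontology; slot
order drives both canonical serialization and rendering. Canonical
serialization (template order, sorted keys, one decimal for lengths) is
what makes the factoring round-trip byte-identical.

**Unknowns.** Absence of a slot means *not recorded*, never "organ
absent" (*S. striata*: "Seeds unknown"). Queries return `None` and key
predicates evaluate to *unknown*.

## Factoring and the packaged fixtures

The section account states the features constant across its species; the
species accounts then need not repeat them. The algebra:

* `intersect_constant(descs)` keeps a slot iff every input records it
  with an identical statement (strict) or, for quantitative slots under
  the `enclosing` policy, emits the interval hull flagged as derived;
* `factor(parent, children)` removes from each child every DE identical
  to a parent DE; `expand(child, parent)` merges parent DEs in, the
  child winning on conflict. `factor(expand(c)) == c` always;
  `expand(factor(c)) == c` whenever the child records every parent slot.

The 12 terminal fixtures are stored factored against the section
description; the loader expands them by default. A handful of elements
carry `supplemented: true`: they are recorded from the section preamble,
the key, or the morphological notes rather than the formal account —
per-taxon flowering time (diurnal for *S. exsudans*, *S. leyseroides*
and subsp. *cypria*), leaf succulence, calyx-papillae absence, tooth
margin width for *S. linearis*, and tooth dimorphism (clear for
*S. chaetodonta* and *S. georgievskyi*, whose longer teeth exceed 4 mm;
obscure otherwise).

## Rendering

Rendering walks the template slots in order, groups consecutive slots
sharing a label into one fragment, fuses an adjacent length+width pair
into `10.0–40.0 × 2.0–4.0 mm`, joins temporal variants with "and", and
renders relations through a phrase table. Full-sentence equality with
the published accounts is *not* the contract — the prose contains
asides — but every number the renderer emits must appear in the
corresponding printed account; the fixture audit compares parsed numeric
values, so `1–2 cm` in print and `1.0–2.0 cm` rendered agree. The
parenthetical-extreme grammar accepts en dash or ASCII hyphen, and an
ASCII output mode (`-`, `x`) exists for terminals without U+2013/U+00D7.

## Key evaluation

A key is a set of numbered couplets with exactly two leads each; the
couplet graph must be acyclic and fully reachable from the lowest id.
A lead is a conjunction of predicates; evaluation is three-valued.
Quantitative satisfaction is a policy because printed thresholds sit on
range bounds (anthophore `3.0–5.0 mm` against "> 4 mm"):

* `strict-range` — the whole main range must satisfy the comparison;
* `midpoint` (default) — the main-range midpoint decides;
* `overlap` — one satisfying point suffices.

For ">"/"<" predicates, overlap-true ⊇ midpoint-true ⊇ strict-true.
A lead is taken iff all its predicates are true; when neither lead is
true, the default `both-branches` handling explores both continuations
and unions the outcomes (the `fail` alternative records a dead end).
State predicates are satisfied by set intersection, since the key tests
single representative states against "A or B" descriptions. Geographic
qualifiers in leads are carried as notes, not evaluated.

Two encoding conventions deserve mention. Hedged leads ("calyx
*usually* < 13 mm", "flowers *usually* nocturnal") are marked `soft`:
when unsatisfied they yield unknown rather than false, so a taxon in
the acknowledged exception (subsp. *modesta*, calyx 13–15 mm; the
diurnal subsp. *cypria*) is not excluded at its own lead. And couplet
8's "calyx teeth 1.5–2 mm" names no tooth class; it is scored against
the shorter class, with the choice flagged in the predicate note.

Under the default policy every packaged terminal reaches its own name;
*S. georgievskyi* and *S. exsudans* resolve uniquely (couplets 3 and 1).
The consistency audit reports, per taxon, membership and the couplets on
its path where the sibling lead is not cleanly false.

## Delimitation summaries

Trees are read with dendropy (NEXUS translate tables and bracketed
BEAST-style annotations handled); node heights are derived from branch
lengths. A tree is accepted as ultrametric when every tip depth is
within τ = 1e-8 of the root height (relative); offending trees are
rejected, not repaired. Burn-in removes the first ⌊fraction·N⌋ samples,
so results are reproducible bit-for-bit.

The collapse partition at height ε clusters tips whose MRCA height is
strictly below ε; equality at ε does not cluster (ε approximates zero
height, so boundary mass is measure-zero). Because heights decrease
rootward-to-tipward in an ultrametric tree, the maximal sub-ε nodes
induce a valid partition; the implementation is a single traversal,
checked in tests against an O(n²) all-pairs MRCA thresholding oracle.
Each tip is its own minimal cluster — every specimen's assignment is
under test. The similarity matrix averages the co-clustering indicator
over the retained samples (symmetric, unit diagonal, entries in [0,1],
invariant to sample order); the frequency table counts distinct
partitions. Row/column order for display follows the ladderized
left-to-right tip order of a supplied summary tree (smaller clades
first, ties by smallest tip label) — the exact ordering convention of
heatmap scripts in circulation is not standardized, so this one is
documented and deterministic. Reference settings are 10% burn-in and
ε = 1e-4.

## Synthetic data

`gen_descriptions` builds a disposable ontology of n_chars slots
(alternating quantitative and qualitative) and n_taxa descriptions in
which exactly round(constant_fraction·n_chars) slots are identical
across taxa and every other slot differs in at least one taxon; the
returned parent truth holds exactly the constant slots, so strict
intersection must recover it and factoring must round-trip.

`gen_posterior` emulates the cluster geometry of a species-tree
posterior, not the multispecies-coalescent likelihood: a fixed true
partition; per sample, each tip reassigned with probability q to a
uniformly chosen other population; same-population tips coalescing at
heights uniform in (0, within_height) and populations joining in
(between_height, 2·between_height). With within < ε < between, the
collapse partition of each sample equals its perturbed assignment, so
co-clustering probabilities are closed-form: with K populations,
p_same = (1−q)² + q²/(K−1) and
p_diff = 2q(1−q)/(K−1) + q²(K−2)/(K−1)².
Defaults are chosen as realistic study-scale conditions: 12 individuals
in 6 populations (3/2/2/2/2/1, mirroring two-to-three specimens per
putative species), q = 0.1, N = 400 samples, within = 5e-5 and
between = 1e-2 around ε = 1e-4. Each generator call draws from a single
explicitly seeded source; the same seed reproduces byte-identical
output.

What the generator does not emulate: topology and height uncertainty
beyond the flip process, per-locus gene-tree conflict, correlated
reassignment (hybrids move jointly, not independently), and MCMC
autocorrelation. Passing the recovery test therefore shows the summary
pipeline is correct and well-calibrated against its own sampling noise —
not that real posteriors are this well behaved.

## Numerical choices and limitations

* Ultrametricity tolerance τ = 1e-8 relative to root height; burn-in is
  floor-based; collapse uses strict inequality.
* Quantitative key comparisons convert to the predicate's unit via the
  ontology registry; midpoints are exact in binary for the 0.1-step
  values used throughout.
* Canonical serialization relies on Python's shortest-repr floats; all
  fixture values are one-decimal and round-trip exactly.
* The rendered prose is telegraphic and deterministic, not a facsimile
  of the published accounts; idiosyncratic modifier merges in the prose
  ("rarely glabrous, or pubescent") are flattened into state sets.
* The base ontology is a minimal reconstruction; extending it to new
  taxa will usually require new terms (this is by design — the ontology
  is closed under reference, and loaders fail loudly on unknown terms).
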