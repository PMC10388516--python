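# Methods

## The grammar

`uds` treats a systematic diagnosis as a string generated by concatenating
typed variables in a single fixed order:

```
d := Dur Seg Reg Site Prog e o S p Deg
```

Concatenation is the only combining operation; it is associative,
non-commutative, and has the empty string as identity, so empty slots
vanish without trace and adding an empty binding never changes the output.
The disorder `o` decomposes per body-part level X ∈ {P, T, S, I, L, C, O}
(parenchyma, tube, slit/cavity, tissue, cell line, cell, organelle) as
`O_X^Y := N_X S_V K L Dir_X^Y Y_X^Z`, a morphology series (Y = M) followed
by a function series (Y = F).  The engine renders a part as: body-part
name, per-part suffix, metabolite (direction + substance), regulator name,
direction, outcome.  The worked regulator example (*β-cell insulin
hyposecretion*) places the regulator name plain and its direction directly
before the outcome, so the part's direction slot falls back to the
regulator direction when unset — we follow the worked example rather than
the abstract `L := Dir & N_H` reading.

A binding is immutable; `bind` returns an updated copy after type-checking
the surface against the lexicon category the slot requires.  Generation is
therefore a pure function of (binding, lexicon) and bind-order invariance
holds by construction; the test suite still verifies it over permuted bind
sequences because the property is part of the engine's contract.

## Lexicon encoding

The packaged lexicon (`data/uds_lexicon.tsv`, ~290 entries) compiles the
term lists for every variable.  Printed clinical term lists often mark fusion by ad-hoc
leading/trailing spaces inside quoted terms; that typography is
inconsistent, so surfaces are stored trimmed and NFC-normalized and the
attachment behaviour is made explicit in a `join` column:

* `FUSE_PREV` — suffixes and localizers (`itis`, `osis`, `aemia`, `oma`):
  attach to the previous token with no space;
* `FUSE_NEXT` — direction prefixes (`hypo`, `dys`, `a`) and o-final
  combining forms (`myelo`, `arterio`, `hydro`, `nephro`): attach the next
  token with no space;
* `SPACE` — free words.

A junction between two tokens fuses iff the left token is `FUSE_NEXT` or
the right one is `FUSE_PREV`.  Word-like members of prefix/suffix
categories (`Elevated`, `deficiency`, `intake`, `vulnus`) carry the flag
`WORD`, which exempts them from the category join convention; `intake`
additionally carries `NUT`, licensing it inside the etiology segment.
Etiology and pathogenesis class membership (infectious, allergic,
radiation, …; immune reaction, hemostasis, …) is carried as `CLASS:<code>`
flags and drives the suffix-agreement check.  A surface may be
multi-categorial (`itis` is both an etiology-driven and a
pathogenesis-driven suffix; `oma` is a morphology term, a suffix and a
localizer); all candidates are kept and disambiguated by position.

## Rewrite rules

Four token-level rules run after slot assembly and before joining, in a
fixed order chosen so that category information is still visible when each
rule fires: cell-line neoplasia → fusion swap → slit reorder → euphonic
a/an, then join and whitespace normalization.

* *cell-line neoplasia*: `<hematopoietic cell> neo plasia` →
  `<cell> leukemia`; the cell set ships in `data/rewrite_config.json` and
  is extensible without code change.
* *fusion swap*: `hypo` before a `FUSION_SWAP`-flagged term renders the
  term + `deficiency` (`immunodeficiency`).  The behaviour of other
  directions before such terms is not fixed by clinical usage;
  plain concatenation (`hyperimmuno`) was chosen.
* *slit reorder*: a slit/cavity body part followed by a slit morphology
  term swaps and fuses (`hydrothorax`, `hematopericard`).
* *euphonic a/an*: direction `a` before an ASCII vowel becomes `an`
  (`anosmia` but `afunction`); Greek initials (`β`) do not count.

Each rule's output pattern is not a trigger of any rule, so the pipeline is
idempotent; this is property-tested on 1000 seeded random token streams.

## Parsing

Segmentation is exact dynamic programming over character positions:
matches may be multiword lexicon surfaces or fused morphemes; a word with
no viable analysis is skipped whole as an unknown span (never an
exception).  Optimality is lexicographic — maximize characters covered by
known surfaces, then minimize token count — and *all* optimal
segmentations are returned up to a cap (default 32); more than one
surviving decomposition sets the `ambiguous` flag.

Label assignment is a depth-first search over a ten-stage order template
(Dur→Seg→Reg→Site→Prog→etiology→disorder→suffix→pathogenesis→Deg) with
memoized dead states.  Body-part/morphology/function tokens are admitted
inside the pathogenesis only after a connective or pathogenesis term
('with pulmonary metastasis', 'causing hepatic hypofunction'), which is
what makes exactly one of the six (e, o, p) orderings derivable.  The
connectives `causes`/`and` may alternatively reset the machine, handling
chained diagnoses ('diagnosis 1 causes diagnosis 2 and diagnosis 3');
the non-reset reading is always preferred when both succeed.
Re-generation from a parse rejoins the labeled tokens with their lexicon
join behaviour and re-runs the rewrite pipeline; for violation-free parses
this reproduces the normalized input, the round-trip property tested over
200+ random bindings.

Inflectional variants are handled lexically, not by a stemming algorithm:
`bacteria`/`bacterial` and `conjunctiva`/`conjunctiv` are separate stored
surfaces.  Spans are 0-based half-open character offsets.

## Validation

Classification is purely structural: presence of etiology, disorder and
pathogenesis (the suffix counts towards the pathogenesis) maps to disease,
syndrome, disorder, the two unknown-localization classes, or invalid.
Suffix agreement compares the suffix set demanded by the etiology class
with the set demanded by the pathogenesis class; disjoint sets are
reported as a conflict (radiation demands `osis`, an immune reaction
demands `itis`), never silently fixed.  An `itis` suffix without an
immune-reaction type yields a completeness warning.  Clinical findings
(symptom terms such as `algia`, `phagia`) are excluded by lexicon design —
their morphemes simply do not exist — rather than by a blocklist.

## Random bindings and enumeration

`random_binding` draws from curated per-category pools: body parts at the
parenchyma/tube/cell levels, directions {hypo, hyper, dys, a, brady,
tachy}, suffixes {itis, osis, ism}, any morphology/function outcome, any
etiology, single-word pathogenesis terms.  These are the study conditions
for the property tests; the generator emulates well-typed clinical
bindings, not the marginal distribution of real diagnoses, so passing
round trips show grammatical invertibility, not coverage of free-text
clinical language.  Sizes used: 500 bindings for bind-order invariance
(all permutations when ≤ 4 slots, 8 sampled otherwise), 200 for round
trips, chosen to keep the whole suite under a few seconds while exercising
every pool.

`enumerate_diagnoses` realizes the combinatorial-classification view: the
etiology pool × body-part pool × (suffix ∪ pathogenesis) pool in
lexicographic order, so the emitted count equals the product of pool
sizes; this is checked against a brute-force product oracle on all
sub-lexicons with ≤ 5 terms per category.

## Numerical/degenerate-input choices

* Comparisons are case-sensitive; proper-name agents keep capitalization.
* Site recursion is capped at depth 5.
* Degree vocabulary is fixed to `degree 0` … `degree 4`.
* A compound with one empty side omits the `causing` connector.
* Whitespace normalization collapses any Unicode whitespace to single
  ASCII spaces and is idempotent.
* Generic function entries are stored as the bare term `function`; the
  organelle name variable goes by several notations in the field and is
  treated as a single subcategory `O`.

## Known limitations

* The lexicon is a representative compilation, not a complete clinical
  vocabulary; coverage of real-world diagnoses is bounded by it.
* No semantics: validation checks derivability and suffix agreement, not
  biological plausibility, and there is no mapping to ICD-10, ICPC-2,
  SNOMED or UMLS.
* Nerve names for neural pathways are an open-ended vocabulary; only
  placeholder entries ship.
* Parsing of deeply chained diagnoses keeps only the first sub-diagnosis
  in the structured components (the full token sequence is retained).
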