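# uds — a grammar engine for systematic medical diagnoses

Clinical diagnoses such as *E.coli cystitis* or *deep vein thrombosis with
embolus to lung and lung infarction* are compositional: they name an
etiological agent, a disorder of a body part, and a pathogenetic mechanism,
always in that order, built from a small vocabulary of medical morphemes,
prefixes and suffixes.  `uds` implements that compositional syntax as an
executable grammar.  It is aimed at medical-informatics developers and
terminology researchers who need to **generate** systematic diagnosis
strings from typed component bindings, **parse** diagnosis strings back
into their components, and **validate/classify** them — rejecting
misnomers such as *itiscys* that no derivation can produce.

## The model

Diagnoses are generated by concatenation (`&`) of typed variables:

```
d := e & o & p                      # etiology, disorder, pathogenesis
d := Dur Seg Reg Site Prog e o S p Deg       # full component order
O_X^Y := N_X S_V K L Dir_X^Y Y_X^Z           # one body-part disorder
o := O^M & ' causing ' & O^F                 # compound cause/effect disorder
```

* `e` — etiological agent (microorganism, mutation, trauma, radiation,
  social problem; empty = idiopathic), or `Dir_E & substance & 'intake'`
  for nutrition.
* `o` — the affected body part `N_X` at level X ∈ {parenchyma, tube,
  slit/cavity, tissue, cell line, cell, organelle} plus a direction of
  change (`hypo`, `hyper`, `dys`, `a/an`, …) and a morphology or function
  outcome term.
* `S` — suffix (`itis`, `osis`, `ism`, …) fused onto the body-part name.
* `p` — pathogenesis: immune reaction types IR1–IR5, hemostasis,
  metabolic (`Dir & substance & localizer`, e.g. *hyperglycaemia*),
  metastasis, embolism, spread with the blood stream, or neural pathways.

Completeness classifies a diagnosis: all of e, o, p present → **disease**;
o alone → **disorder**; o + p → **syndrome**; e alone is invalid
(etiological agents alone do not give rise to diagnoses).  A handful of
surface rewrite rules make the output clinically idiomatic: euphonic
`a → an` before vowels (*anosmia*), slit/cavity reordering (*hydrothorax*,
not *thorax hydro*), the hypo/deficiency swap (*immunodeficiency*), and
the leukemia rule (*promyelocyte leukemia* for hematopoietic neoplasia).

The parser inverts generation: dynamic-programming segmentation undoes
fusion (`cystitis → cyst + itis`, `myelodysplasia → myelo + dys + plasia`),
every morpheme keeps all of its candidate categories, and an order-template
automaton picks a label assignment consistent with the component order —
exactly one of the six permutations of (e, o, p) is derivable.

## Worked example

```python
import uds

lex = uds.load_packaged_lexicon()            # ~290 typed morphemes (TSV)

b = uds.Binding()
for var, value in [("e", "E.coli"), ("N_S", "cyst"), ("S", "itis")]:
    b = uds.bind(b, var, value, lex)         # any bind order works
print(uds.generate(b, lex).text)             # -> E.coli cystitis

res = uds.parse("bacterial conjunctivitis", lex)
print(res.best.etiology, res.best.disorder, res.best.suffix)
#      bacterial ['conjunctiv'] itis
print(res.best.kindhint)                     # -> disease  (e, o and suffix present)

print(uds.is_well_formed("itiscys", lex))
# -> (False, ['unknown term at 0:7', 'components do not form a valid diagnosis'])
```

`uds.bind` type-checks every assignment: binding `'Staphylococcus aureus'`
to the disorder slot raises `CategoryError`, because the surface exists
only as an etiological agent — an agent is not a tissue.

The same operations are available from the shell:

```
uds generate --set e=E.coli --set N_S=cyst --set S=itis
uds parse "E.coli cystitis" --json
uds validate --batch diagnoses.txt          # exit 0 well-formed, 1 violations
uds enumerate --limit 10
uds fixtures
```

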