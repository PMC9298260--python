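# The dendrimer linear-notation dialect

One line encodes one branched peptide. Example (a G3 dendrimer):

```
(KA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2
```

Segments are written outermost first with multiplicity subscripts; the core
segment is unparenthesized and has implicit multiplicity 1. Multiplicities
must strictly halve down to the core (8/4/2/1, 4/2/1, ..., or a single core
segment for a linear peptide): each copy of an inner segment carries two
copies of the next-outer segment, one on the alpha- and one on the
epsilon-amine of its leading (branching) lysine.

## Grammar (EBNF)

```ebnf
notation     = [ "sr-" ], ( monomer | dimer ) ;
dimer        = "(", monomer, ")", subscript2 ;        (* disulfide homodimer *)
monomer      = { segment }, core, terminus ;
segment      = "(", [ cap ], residues, ")", subscript ;
core         = [ cap (* linear peptides only *) ], residues ;
residues     = residue, { residue } ;
residue      = ( [ "*" ], letter, [ "*" ] ), [ label ] ;
letter       = "A" | "C" | "E" | "K" | "Y" | "G"
             | "a" | "c" | "e" | "k" | "y" | "g" ;    (* lowercase = D *)
cap          = "Ac" | "ClAc" | "Fum" ;
label        = "(", "Fl", ")" ;
terminus     = hyphen, ( "OH" | "NH_2" | "NH2" ) ;
subscript    = [ "_" ], digits ;
subscript2   = [ "_" ], "2" ;
hyphen       = "-" | "‐" ;                            (* ASCII or U+2010 *)
```

Whitespace is ignored everywhere. Any hyphen-like codepoint (U+2010, U+2011,
en/em dash, minus sign) is accepted for the terminus separator.

## Semantic rules

- **Branching is positional.** The first residue of every non-outermost
  segment (including the core of a multi-segment dendrimer) must be a
  lysine and is a branching unit, star-marked or not; `(KKAKE)_4` and
  `(*K*KAKE)_4` are the same segment. Star marks anywhere else, including
  anywhere in the outermost segment or in a linear peptide, are rejected.
- **Stereochemistry.** Uppercase = L, lowercase = D; `sr-` marks a
  stereorandomized preparation (every center racemic, composition
  unchanged). Case never changes topology or composition.
- **Caps** apply uniformly to every N-terminus of the outermost segment
  (`(AcKA)_8` acetylates all eight chain ends); caps on inner segments are
  rejected. A linear peptide may carry a cap on its single N-terminus.
- **Labels** attach to the preceding residue (`C(Fl)` = labelled cysteine)
  and apply to every copy of that segment.
- **Dimers** require exactly one cysteine per monomer; the two monomers are
  joined by one disulfide bridge.

## Canonical form

`write_notation` emits ASCII hyphens, `_n` subscripts, explicit `*K*`
stars on every inner leading lysine and a single space before the core.
Parsing then writing is idempotent; writing then parsing is the identity.

## Position ids

Residue positions are 0-based, depth-first from the core: a segment copy
emits its residues in written (N-to-C) order, then recurses into child
copies `2c` and `2c + 1` of the next-outer segment; a dimer's second
monomer follows the first.

## CSV dialect

Compound tables are plain CSV with columns `name`, `notation`, `activity`
(`+`, `-` or `NA`) and free-text `notes`; extra columns pass through
untouched.
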