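# dendrimap

Peptide-dendrimer sequence notation, property calculus, virtual-library
enumeration and MinHash chemical-space tree maps.

## What it is for

Glatiramer acetate (GA) — a random Ala/Lys/Glu/Tyr copolymer in a
4.2/3.4/1.4/1.0 ratio, 5–9 kDa — is a multiple-sclerosis drug whose
polymeric nature makes it hard to replicate. One route to a precisely
defined alternative is the *peptide dendrimer*: a tree-shaped peptide in
which branching lysines, acylated on both their α- and ε-amines, double
the number of chains at each generation. Such compounds are written in a
compact linear notation, e.g. the G3 dendrimer

```
(KA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2
```

(eight KA arms on four *K*AK branches on two *K*EKA branches on one core,
carboxamide C-terminus). `dendrimap` is a toolkit for people designing
and characterizing these molecules:

- **notation** — parse/write the linear notation (branch stars, D-residue
  lowercase, `Ac`/`ClAc`/`Fum` caps, `C(Fl)` labels, `sr-` prefix,
  disulfide-dimer wrapper) into validated topology trees
  (`docs/NOTATION.md` has the grammar);
- **chemistry** — molecular formula, monoisotopic/average mass, formal
  net charge at neutral pH (free Lys +1, Glu −1, carboxyl C-terminus −1,
  N-termini neutral) and the E/K/A/Y ratio excluding branching lysines;
- **structure** — full atom-level expansion to canonical isomeric SMILES
  with correct D/L stereocenters, used as an independent mass oracle and
  as fingerprint input;
- **library** — seeded rejection sampling of virtual G2 dendrimer
  libraries constrained to a GA-like composition (L1 distance on
  normalized A/K/E/Y fractions), with byte-identical manifest replay;
- **mapspace** — MinHashed atom-pair fingerprints (circular environments
  at radii 1–2, d = 1024 minima), exact kNN graph, Kruskal minimum
  spanning tree and a deterministic radial layout: a tree map of
  chemical space with virtual / active / inactive color coding.

## Worked example

```
$ dendrimap props "(KA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2"
name,notation,formula,mono_mass,avg_mass,net_charge,ratio_E,ratio_K,ratio_A,ratio_Y,ratio_display,n_residues,n_branchK,n_termini
,(KA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2,C210H387N67O51S,4695.947,4698.884,12,3.0,15.0,17.0,1.0,3/15/17/1,44,7,8
```

Reading the row: 44 residues, of which 7 are branching lysines carrying
no charge; 8 free N-termini; monoisotopic mass 4695.9470 Da
(formula C210H387N67O51S); net charge +12 = 15 free lysines − 3
glutamates − 0 (amide terminus); E/K/A/Y ratio 3/15/17/1 with branching
lysines excluded from the K count.

Other entry points:

```
dendrimap fixtures -o table1.csv          # bundled designed-compound table
dendrimap props --check table1.csv        # recompute vs printed values
dendrimap smiles -i table1.csv -o out.smi # canonical isomeric SMILES
dendrimap library --n 1000 --seed 7 -o run/   # virtual library + manifest
dendrimap map --n 1000 --seed 7 -o map/       # full library → tree map
```

The bundled table transcribes printed characterization data verbatim; an
audit recomputes every value from the notation and flags the rows whose
printed mass, charge or ratio is internally inconsistent with the table's
own conventions (they are reported as `discrepant`, never silently
corrected).

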