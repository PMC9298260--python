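# Methods

## Scope and model

`dendrimap` works with peptide dendrimers built from the Ala/Lys/Glu/Tyr
(+Cys/Gly) alphabet: tree-shaped peptides in which *branching lysines* are
acylated on both their alpha- and epsilon-amines so every generation
doubles the number of chains. A compound is represented as a
`DendrimerTopology` — an ordered list of segments, outermost first, with
strictly halving multiplicities — from which all downstream quantities are
derived deterministically. The package's reference point is glatiramer
acetate (GA), a random A/K/E/Y copolymer (composition 4.2/3.4/1.4/1.0,
5–9 kDa) used in multiple sclerosis; dendrimers are precisely defined
single compounds with a GA-like composition, and the library and map
modules explore that design space.

## Property calculus

**Monoisotopic mass.** Sum of condensed residue compositions, plus one
H2O per covalent chain, plus modification deltas: amide C-terminus
−O+NH (−0.98402 Da), acetyl +C2H2O (+42.0106), chloroacetyl +C2HClO
(+75.9716), monoethyl-fumarate +C6H6O3 (+126.0317) per capped N-terminus,
−2 H for the disulfide dimer. Atomic masses are the standard monoisotopic
values (H 1.00782503207, C 12, N 14.0030740048, O 15.9949146196,
S 31.972071, Cl 34.96885268), which reproduce the printed calculated
masses of the designed-compound table to ≤ 0.1 mDa; the comparison
tolerance used everywhere is 0.005 Da (printed precision 1e-4 plus
constant-set drift). Average masses use standard atomic weights and are
reported only as metadata.

The fluorescein-type core label has no modeled connectivity (the printed
reagent name is ambiguous); it is treated as a *mass-only* delta of
511.0903 Da, obtained as the difference of the two printed calculated
masses of the labelled and unlabelled parent compound. Labelled compounds
therefore have a mass and charge but no molecular formula or structure,
and are skipped by fingerprinting.

**Formal net charge at neutral pH.** +1 per lysine with a free
epsilon-amine (i.e. every non-branching lysine), −1 per glutamate, −1 per
free carboxyl C-terminus; all N-termini — free or capped — count 0. This
mirrors the charge convention of the source characterization table. No
pKa/pH curve is attempted (out of scope).

**E/K/A/Y ratio.** Residue counts excluding branching lysines, normalized
to Tyr = 1, or to the smallest nonzero component when no Tyr is present;
displayed at one decimal (integers bare), exact fractions retained.

**Three mass oracles.** Mass is computed independently from (1) residue
bookkeeping, (2) the elemental formula, and (3) atom counts of the
generated structure; the three agree to < 1e-6 Da on every structurally
defined designed compound. This is the package's main guard against
bookkeeping errors.

**Fixture audit.** The bundled designed-compound table transcribes the
printed values verbatim and never corrects them; an audit recomputes
mass/charge/ratio from the notation and flags fields where the print is
internally inconsistent with its own footnote rules (eight rows carry
flags: two charges, one ratio, and five masses including the dimer and
stereorandomized entries). Flagged fields are reported as "discrepant",
not as failures, and are excluded from reproduction checks.

## Structure generation

SMILES are emitted by a recursive writer that starts at the core
C-terminus and walks each chain N-ward, attaching the epsilon child chain
inside the branching lysine's side-chain parentheses and continuing the
alpha child on the backbone. L residues are written `[C@@H]` in this
emission order (verified against canonical L-alanine), D residues `[C@H]`;
glycine has no stereocenter. Dimers are emitted as two dot-separated
monomers sharing a ring-closure bond between the cysteine sulfurs.
Structures are neutral (no formal charges written); atom order — and hence
the per-atom residue provenance the builder records — is deterministic,
and RDKit canonicalization produces the final string. Stereorandomized
compounds have no single structure; callers must explicitly request the
all-L surrogate.

## Virtual library

The published virtual-library grammar is not printed anywhere, so the
generator is a parameterized *reconstruction*: G2 scaffold (multiplicities
4/2/1), outer segments 2–3 residues, middle 3–4, core 4–8 (branching
lysine included), free N-termini, amide C-terminus, all-L, alphabet
{A,K,E,Y}. These defaults put members at roughly 1.9–3.3 kDa, the lower
end of the GA mass window, consistent with how the synthesized G2
compounds are described. Every non-branching position is drawn uniformly
from the alphabet; a candidate is kept iff the L1 distance between its
normalized non-branching A/K/E/Y fractions and the normalized reference
(default 4.2/3.4/1.4/1.0) is ≤ 0.25 (a free parameter) and its notation is
new. Sampling is rejection-based on a PCG64 generator; the (config, seed)
pair fully determines the member list, and every run writes a manifest
(config echo, version, seed, PRNG identifier) from which it can be
replayed byte-identically. Roughly 2–3 % of uniform draws pass the default
composition filter, so a 1000-member library costs a few tens of thousands
of cheap draws (about a second).

What the generator does *not* emulate: the exact scaffold ranges, G3
members, capping variants and any hand-curation of the original virtual
library; the published 1000-member list itself is not printed and is not
claimed to be regenerated. Passing tests show the contract (validity,
constraint satisfaction, reproducibility) holds, not that the original
member list is recovered.

## Fingerprints and the chemical-space tree

Shingles are atom-pair strings
`min(env_i, env_j) | topological distance | max(env_i, env_j)` over all
heavy-atom pairs, where `env` is the canonical SMILES of the circular
environment of radius 1 and 2 rooted at the atom (pairs are skipped at a
radius where either atom has no exact-radius environment; sorting the two
substructures makes the shingle permutation-invariant). The shingle set is
MinHashed into d = 1024 minima: shingle strings are pre-hashed to 64 bits
(BLAKE2b, process-independent), then passed through d seeded affine
permutations `x -> a*x + b (mod 2^64)` (a odd). Jaccard similarity is
estimated as the fraction of equal minima; calibration against exact
set-intersection Jaccard on random set pairs shows |estimate − exact| ≤
3/√d in ≥ 99 % of trials and mean bias well below 0.02.

The map layout deliberately simplifies the published tree-map tool: at
n ≈ 10^3 an *exact* kNN graph (default k = 10) under estimated Jaccard
distance is cheap, so no LSH forest is used; the minimum spanning forest
is extracted with Kruskal's algorithm, ties broken lexicographically by
molecule id (required for byte-identical reruns); coordinates come from a
deterministic radial layout (root = highest-degree node, children ordered
by id, angular wedges proportional to subtree leaf counts, radius = tree
depth). The published force-based layout looks different cosmetically; the
tree topology, not the embedding, carries the neighborhood structure.
Color code on the rendered map: grey = virtual library, orange =
synthesized active, blue = synthesized inactive, green = activity unknown.

## Numerical and design choices

- Mass comparisons to printed values: |Δ| ≤ 0.005 Da; internal cross-path
  checks: < 1e-6 Da.
- Zero-distance edges (duplicate molecules, identical sketches) are valid;
  an all-identical input yields a zero-weight star tree.
- Degenerate inputs raise typed errors: empty shingle sets
  (single-atom molecules), all-zero compositions, stereorandomized
  structure requests, infeasible sampling constraints (with attempt
  counts).
- Deterministic tie-breaks everywhere randomness is absent by design:
  lexicographic molecule ids in kNN selection, Kruskal ordering, and
  child ordering in the layout.
- Problem sizes: the test suite and the acceptance script exercise the
  full 1000-member library → map chain (the published virtual-library
  size) and brute-force spanning-tree checks at n ≤ 7, where exhaustive
  enumeration is exact and fast.

## Known limitations

- The charge model is a formal neutral-pH convention, not a titration;
  tyrosine/cysteine deprotonation and N-terminal protonation are ignored
  by design.
- The fluorescein label is mass-only; labelled compounds cannot be
  fingerprinted or exported as structures.
- The library generator is a documented reconstruction (see above), and
  the map layout is not the published force-directed embedding.
- Biological read-outs (cytokine release, marker profiles, donor
  variability) are outside what can be computed from sequences and are
  not modeled; activity flags are carried as metadata only.
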