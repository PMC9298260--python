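"""Atom-level expansion of dendrimer topologies to molecular graphs / SMILES.

The notation <-> structure correspondence: backbone amides run along each
segment; a branching lysine is acylated on both its alpha- and
epsilon-amine by the C-termini of the two child chains of the next-outer
segment; caps acylate N-termini; the C-terminus is a free acid or a
carboxamide; lowercase residues carry the mirror (D) alpha-carbon
configuration. Structures are emitted neutral (no formal charges written) —
the formal-charge model is a separate annotation in the chemistry module.

SMILES strings are generated by a deterministic depth-first emission
starting at the core C-terminus, so atom order (and hence residue
provenance, recorded per atom) is reproducible run to run; RDKit then
canonicalizes the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from rdkit import Chem

from .errors import LabelledStructureError, MixtureError, StructureError
from .notation import ACID, DendrimerTopology

# side-chain fragments emitted inside the alpha-carbon parentheses,
# with their heavy-atom counts
_SIDE_CHAINS = {
    "A": ("C", 1),
    "C": ("CS", 2),
    "E": ("CCC(=O)O", 5),
    "K": ("CCCCN", 5),
    "Y": ("Cc1ccc(O)cc1", 8),
    "G": (None, 0),
}

_CAP_FRAGMENTS = {
    "Ac": ("C(C)=O", 3),
    "ClAc": ("C(CCl)=O", 4),
    "Fum": ("C(=O)/C=C/C(=O)OCC", 9),
}

# ring-closure label reserved for the disulfide bridge
_SS_BOND = "%99"


@dataclass(frozen=True)
class MolecularGraph:
    """An RDKit molecule with per-atom residue provenance.

    ``provenance[i]`` is the position id (see ``notation.enumerate_residues``)
    of the residue that contributed atom ``i``, or -1 for terminus/cap atoms.
    """

    mol: Chem.Mol
    provenance: tuple[int, ...]
    topology: DendrimerTopology

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    def element_counts(self, include_h: bool = True) -> dict[str, int]:
        counts: dict[str, int] = {}
        for atom in self.mol.GetAtoms():
            counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
            if include_h:
                counts["H"] = counts.get("H", 0) + atom.GetTotalNumHs()
        return {el: n for el, n in counts.items() if n}

    def monoisotopic_mass(self) -> float:
        """Mass from atom counts under the package's standard atomic masses."""
        from .chemistry import formula_mass

        return formula_mass(self.element_counts())


class _Emitter:
    """Accumulates SMILES fragments while recording atom provenance."""

    def __init__(self):
        self.parts: list[str] = []
        self.provenance: list[int] = []

    def add(self, fragment: str, n_atoms: int, position: int) -> None:
        self.parts.append(fragment)
        self.provenance.extend([position] * n_atoms)

    def smiles(self) -> str:
        return "".join(self.parts)


def _emit_chain(em: _Emitter, t: DendrimerTopology, seg_idx: int, copy_idx: int,
                positions: dict, bridge: bool) -> None:
    """Emit one segment copy from its C-terminal residue to its N-terminus,
    recursing into child chains at the branching lysine (which, when present,
    is the segment's N-terminal residue)."""
    seg = t.segments[seg_idx]
    label_map = {(si, ri): tag for si, ri, tag in t.segment_labels}
    for ri in range(len(seg.residues) - 1, -1, -1):
        code = seg.residues[ri]
        pos = positions[(seg_idx, copy_idx, ri)]
        upper = code.upper()
        chiral = "[C@@H]" if code.isupper() else "[C@H]"
        em.add("C(=O)", 2, pos)
        if upper == "G":
            em.add("C", 1, pos)
        else:
            if (seg_idx, ri) in label_map:
                raise LabelledStructureError(
                    f"residue at position {pos} carries the mass-only label "
                    f"{label_map[seg_idx, ri]!r}; no structure is defined"
                )
            side, n_side = _SIDE_CHAINS[upper]
            if t.is_branching(seg_idx, ri):
                # epsilon chain: child copy 2c+1 grafted on the side-chain amine
                em.add(chiral + "(" + "CCCC" + "N", 5 + 1, pos)
                _emit_chain(em, t, seg_idx - 1, 2 * copy_idx + 1, positions, bridge)
                em.add(")", 0, pos)
            elif upper == "C" and bridge:
                em.add(chiral + "(CS" + _SS_BOND + ")", 3, pos)
            else:
                em.add(chiral + "(" + side + ")", 1 + n_side, pos)
        em.add("N", 1, pos)
        if ri == 0:
            if t.is_branching(seg_idx, ri):
                # alpha chain: child copy 2c continues on the backbone amine
                _emit_chain(em, t, seg_idx - 1, 2 * copy_idx, positions, bridge)
            elif seg.cap is not None:
                frag, n = _CAP_FRAGMENTS[seg.cap]
                em.add(frag, n, -1)


def _positions_by_slot(t: DendrimerTopology, monomer: int) -> dict:
    """(segment_index, copy_index, residue_index_in_segment) -> position id."""
    from .notation import enumerate_residues

    out = {}
    counters: dict[tuple[int, int], int] = {}
    for p in enumerate_residues(t):
        if p.monomer != monomer:
            continue
        key = (p.segment_index, p.copy_index)
        ri = counters.get(key, 0)
        counters[key] = ri + 1
        out[(p.segment_index, p.copy_index, ri)] = p.position
    return out


def _emit_monomer(em: _Emitter, t: DendrimerTopology, monomer: int, bridge: bool) -> None:
    positions = _positions_by_slot(t, monomer)
    core_idx = len(t.segments) - 1
    # C-terminus prefix: the first emitted heavy atom bonds to the core
    # C-terminal carbonyl carbon
    if t.c_terminus == ACID:
        em.add("O", 1, -1)
    else:
        em.add("N", 1, -1)
    _emit_chain(em, t, core_idx, 0, positions, bridge)


def generate_smiles(t: DendrimerTopology, allow_stereorandom_surrogate: bool = False
                    ) -> tuple[str, tuple[int, ...]]:
    """Emit a (non-canonical) SMILES string plus per-atom residue provenance.

    Stereorandomized topologies have no single structure; pass
    ``allow_stereorandom_surrogate=True`` to emit the all-L surrogate.
    """
    if t.stereorandomized and not allow_stereorandom_surrogate:
        raise MixtureError(
            "stereorandomized compounds are diastereomer mixtures; "
            "pass allow_stereorandom_surrogate=True for the all-L surrogate"
        )
    em = _Emitter()
    _emit_monomer(em, t, 0, bridge=t.dimer)
    if t.dimer:
        em.add(".", 0, -1)
        _emit_monomer(em, t, 1, bridge=True)
    return em.smiles(), tuple(em.provenance)


def build_molecular_graph(t: DendrimerTopology,
                          allow_stereorandom_surrogate: bool = False) -> MolecularGraph:
    """Expand a topology into an atom-level molecular graph.

    The graph is connected (dimers through exactly one S-S bond) and its
    element counts equal ``chemistry.molecular_formula``.
    """
    smiles, provenance = generate_smiles(t, allow_stereorandom_surrogate)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - emission is by construction valid
        raise StructureError(f"internal SMILES emission failed for {t.name!r}")
    if mol.GetNumAtoms() != len(provenance):  # pragma: no cover
        raise StructureError("provenance bookkeeping out of sync with atom count")
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    return MolecularGraph(mol=mol, provenance=provenance, topology=t)


def to_smiles(t: DendrimerTopology, allow_stereorandom_surrogate: bool = False) -> str:
    """Canonical isomeric SMILES of the compound (RDKit canonicalization)."""
    return Chem.MolToSmiles(build_molecular_graph(t, allow_stereorandom_surrogate).mol)


# ---------------------------------------------------------------------------
# SMILES file interface ("smiles" or "name<TAB>smiles" per line)
# ---------------------------------------------------------------------------

def write_smiles_file(entries, path) -> None:
    """Write (name, smiles) pairs, one per line, tab-separated."""
    with open(path, "w") as fh:
        for name, smi in entries:
            fh.write(f"{name}\t{smi}\n" if name else f"{smi}\n")


def read_smiles_file(path) -> list[tuple[str, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if "\t" in line:
                name, smi = line.split("\t", 1)
            else:
                name, smi = "", line
            out.append((name, smi))
    return out
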