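"""Property calculus for parsed dendrimer topologies.

Computes, purely from residue bookkeeping, the molecular formula,
monoisotopic and average mass, formal net charge at neutral pH, composition
counts and the E/K/A/Y amino-acid ratio of a compound.

Model conventions:

* **Mass.** Each residue contributes its peptide-bond-condensed elemental
  composition; every covalent chain adds one H2O; an amide C-terminus swaps
  OH for NH2 (delta -O +NH); N-terminal caps add their acyl delta per
  capped terminus; the disulfide dimer loses two hydrogens. Monoisotopic
  masses are derived from standard atomic masses, so all mass paths
  (residue sum, elemental formula, atom counts of the built structure)
  agree to machine precision.
* **Charge.** Formal net charge at neutral pH counts +1 per lysine with a
  free epsilon-amine (i.e. every non-branching lysine), -1 per glutamate
  side chain and -1 per free carboxyl C-terminus; N-termini, free or
  capped, count 0.
* **Ratio.** E/K/A/Y counts exclude branching lysines and are normalized
  to Y = 1 (or to the smallest nonzero component when no tyrosine is
  present).

Stereochemistry (D-residues, stereorandomization) never changes any of
these quantities.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional

from .errors import DegenerateCompositionError, VocabularyError
from .notation import ACID, AMIDE, DendrimerTopology, enumerate_residues

# ---------------------------------------------------------------------------
# elemental constants
# ---------------------------------------------------------------------------

#: Monoisotopic atomic masses (Da), most abundant isotope.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "Cl": 34.96885268,
}

#: Standard average atomic weights (Da).
AVERAGE_MASS: Mapping[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "Cl": 35.45,
}

#: Residue elemental compositions in peptide-bond-condensed form
#: (free amino acid minus H2O).
RESIDUE_COMPOSITION: Mapping[str, Mapping[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
}

#: Side-chain formal charge at neutral pH (lysine counted only when its
#: epsilon-amine is free, i.e. for non-branching positions).
RESIDUE_CHARGE: Mapping[str, int] = {"G": 0, "A": 0, "C": 0, "E": -1, "K": 1, "Y": 0}

WATER = {"H": 2, "O": 1}

#: Elemental deltas of the modification vocabulary. Negative counts allowed.
MODIFICATION_DELTA: Mapping[str, Mapping[str, int]] = {
    "Ac": {"C": 2, "H": 2, "O": 1},
    "ClAc": {"C": 2, "H": 1, "Cl": 1, "O": 1},
    "Fum": {"C": 6, "H": 6, "O": 3},
    "amide": {"N": 1, "H": 1, "O": -1},
    "disulfide": {"H": -2},
}

#: Mass-only delta (Da) of the fluorescein-type core label, derived as the
#: difference of the two printed calculated masses of the labelled and
#: unlabelled parent compound (5207.0373 - 4695.9470); the label's exact
#: connectivity is not modeled, so it has no elemental composition.
FL_MASS_DELTA = 511.0903

LABEL_MASS_DELTA: Mapping[str, float] = {"Fl": FL_MASS_DELTA}
LABEL_CHARGE_DELTA: Mapping[str, int] = {"Fl": 0}


def formula_mass(formula: Mapping[str, int], masses: Mapping[str, float] = MONOISOTOPIC_MASS) -> float:
    """Mass of an elemental composition under a given atomic-mass table."""
    try:
        return sum(masses[el] * n for el, n in formula.items())
    except KeyError as exc:  # pragma: no cover - guarded by vocabulary
        raise VocabularyError(f"no atomic mass for element {exc}") from exc


def residue_monoisotopic_mass(code: str) -> float:
    """Monoisotopic mass (Da) of one condensed residue."""
    comp = RESIDUE_COMPOSITION.get(code.upper())
    if comp is None:
        raise VocabularyError(f"unknown residue {code!r}")
    return formula_mass(comp)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PropertyReport:
    """Computed chemical properties of one compound."""

    name: str
    notation: str
    formula: Optional[Mapping[str, int]]  # None when a mass-only label is present
    monoisotopic_mass: float
    average_mass: float
    net_charge: int
    counts: Mapping[str, int]            # per residue letter; branching K under "K*"
    ratio: tuple[float, float, float, float]   # E/K/A/Y, normalized
    n_residues: int
    n_branching: int
    n_termini: int
    c_terminus: str
    caps: Mapping[str, int]              # cap tag -> number of capped termini
    labels: Mapping[str, int]            # label tag -> count

    @property
    def ratio_display(self) -> str:
        return format_ratio(self.ratio)


def format_ratio(ratio: tuple[float, ...]) -> str:
    """Render a normalized ratio the way composition tables print it:
    integers bare, otherwise one decimal place (e.g. ``1.3/7.3/6/1``)."""
    parts = []
    for x in ratio:
        r = round(x, 1)
        parts.append(str(int(r)) if float(r).is_integer() else f"{r:.1f}")
    return "/".join(parts)


# ---------------------------------------------------------------------------
# composition bookkeeping
# ---------------------------------------------------------------------------

def composition_counts(t: DendrimerTopology) -> Counter:
    """Residue counts over the expanded tree; branching lysines are counted
    separately under ``"K*"`` (case-folded to uppercase)."""
    counts: Counter = Counter()
    for pos in enumerate_residues(t):
        key = pos.code.upper()
        counts[key + "*" if pos.is_branching else key] += 1
    return counts


def _cap_counts(t: DendrimerTopology) -> Counter:
    caps: Counter = Counter()
    outer = t.segments[0]
    if outer.cap is not None:
        caps[outer.cap] = outer.multiplicity * t.n_monomers
    return caps


def _label_counts(t: DendrimerTopology) -> Counter:
    labels: Counter = Counter()
    for _, _, tag in t.segment_labels:
        labels[tag] += t.n_monomers  # core labels double in a dimer
    return labels


def molecular_formula(t: DendrimerTopology) -> dict[str, int]:
    """Elemental composition: residue sum + one H2O per chain + cap and
    terminus deltas (disulfide dimer: -2 H).

    Raises :class:`VocabularyError` for labelled compounds, whose label is
    modeled mass-only and has no elemental composition.
    """
    if t.segment_labels:
        tags = sorted({tag for _, _, tag in t.segment_labels})
        raise VocabularyError(
            f"label(s) {tags} are mass-only and have no elemental composition"
        )
    formula: Counter = Counter()
    for pos in enumerate_residues(t):
        formula.update(RESIDUE_COMPOSITION[pos.code.upper()])
    for _ in range(t.n_monomers):
        formula.update(WATER)
        if t.c_terminus == AMIDE:
            formula.update(MODIFICATION_DELTA["amide"])
    for cap, n in _cap_counts(t).items():
        for _ in range(n):
            formula.update(MODIFICATION_DELTA[cap])
    if t.dimer:
        formula.update(MODIFICATION_DELTA["disulfide"])
    return {el: n for el, n in formula.items() if n}


def _mass(t: DendrimerTopology, masses: Mapping[str, float]) -> float:
    total = 0.0
    for pos in enumerate_residues(t):
        total += formula_mass(RESIDUE_COMPOSITION[pos.code.upper()], masses)
    total += t.n_monomers * formula_mass(WATER, masses)
    if t.c_terminus == AMIDE:
        total += t.n_monomers * formula_mass(MODIFICATION_DELTA["amide"], masses)
    for cap, n in _cap_counts(t).items():
        total += n * formula_mass(MODIFICATION_DELTA[cap], masses)
    if t.dimer:
        total += formula_mass(MODIFICATION_DELTA["disulfide"], masses)
    for tag, n in _label_counts(t).items():
        # mass-only labels: same delta applied on both mass scales
        total += n * LABEL_MASS_DELTA[tag]
    return total


def monoisotopic_mass(t: DendrimerTopology) -> float:
    """Calculated monoisotopic mass (Da) from residue bookkeeping."""
    return _mass(t, MONOISOTOPIC_MASS)


def average_mass(t: DendrimerTopology) -> float:
    """Average (isotope-weighted) mass in Da. For labelled compounds the
    mass-only label delta is monoisotopic by construction."""
    return _mass(t, AVERAGE_MASS)


def net_charge(t: DendrimerTopology) -> int:
    """Formal net charge at neutral pH.

    +1 per non-branching lysine (free epsilon-amine), -1 per glutamate,
    -1 per free carboxyl C-terminus; N-termini neutral; dimers sum both
    monomers.
    """
    charge = 0
    for pos in enumerate_residues(t):
        if pos.is_branching:
            continue  # both amines acylated; side chain carries no charge
        charge += RESIDUE_CHARGE[pos.code.upper()]
    if t.c_terminus == ACID:
        charge -= t.n_monomers
    return charge


def aa_ratio(t: DendrimerTopology) -> tuple[float, float, float, float]:
    """E/K/A/Y ratio excluding branching lysines, normalized to Y = 1
    (or to the smallest nonzero component when Y = 0)."""
    counts = composition_counts(t)
    e, k, a, y = counts["E"], counts["K"], counts["A"], counts["Y"]
    if e == k == a == y == 0:
        raise DegenerateCompositionError(
            "no E/K/A/Y residues outside branching positions"
        )
    denom = y if y > 0 else min(v for v in (e, k, a, y) if v > 0)
    return (e / denom, k / denom, a / denom, y / denom)


def property_report(t: DendrimerTopology) -> PropertyReport:
    """Full property report for one compound."""
    counts = composition_counts(t)
    try:
        formula = molecular_formula(t)
    except VocabularyError:
        formula = None  # mass-only label present
    return PropertyReport(
        name=t.name,
        notation=_notation_of(t),
        formula=formula,
        monoisotopic_mass=monoisotopic_mass(t),
        average_mass=average_mass(t),
        net_charge=net_charge(t),
        counts=dict(counts),
        ratio=aa_ratio(t),
        n_residues=t.n_residues,
        n_branching=t.n_branching,
        n_termini=t.n_termini,
        c_terminus=t.c_terminus,
        caps=dict(_cap_counts(t)),
        labels=dict(_label_counts(t)),
    )


def _notation_of(t: DendrimerTopology) -> str:
    from .notation import write_notation

    return write_notation(t)


def report_row(report: PropertyReport) -> dict:
    """Flatten a report into the CSV property-table row schema."""
    e, k, a, y = report.ratio
    return {
        "name": report.name,
        "notation": report.notation,
        "formula": format_formula(report.formula) if report.formula else "",
        "mono_mass": round(report.monoisotopic_mass, 4),
        "avg_mass": round(report.average_mass, 4),
        "net_charge": report.net_charge,
        "ratio_E": round(e, 4),
        "ratio_K": round(k, 4),
        "ratio_A": round(a, 4),
        "ratio_Y": round(y, 4),
        "ratio_display": report.ratio_display,
        "n_residues": report.n_residues,
        "n_branchK": report.n_branching,
        "n_termini": report.n_termini,
    }


_HILL_ORDER = ("C", "H", "Cl", "N", "O", "S")


def format_formula(formula: Mapping[str, int]) -> str:
    """Hill-system formula string (C, H, then alphabetical)."""
    parts = []
    for el in _HILL_ORDER:
        n = formula.get(el, 0)
        if n:
            parts.append(el + (str(n) if n != 1 else ""))
    for el in sorted(set(formula) - set(_HILL_ORDER)):
        parts.append(el + str(formula[el]))
    return "".join(parts)
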