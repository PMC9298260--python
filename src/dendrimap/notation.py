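"""Linear notation for branched peptide dendrimers.

A peptide dendrimer is a tree-shaped peptide in which *branching lysines*
are acylated on both their alpha- and epsilon-amines, so each branching
layer (generation) doubles the number of chains. The linear notation writes
the outermost segment first with a multiplicity subscript and the core
segment last, unparenthesized::

    (KA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2

reads as a G3 dendrimer: eight copies of the outer dipeptide KA, grafted
pairwise onto four copies of *K*AK, onto two copies of *K*EKA, onto the
single core *K*AKEAYCA with a carboxamide C-terminus. ``*K*`` marks a
branching lysine; the star is optional for the leading lysine of an inner
segment (branching is positional). Lowercase letters denote D-residues,
``Ac``/``ClAc``/``Fum`` at the start of the outermost segment cap every
N-terminus, ``C(Fl)`` is a labelled cysteine, ``-OH``/``-NH_2`` select the
C-terminus, a leading ``sr-`` marks a stereorandomized preparation, and a
whole-sequence wrapper ``((...)-NH_2)_2`` denotes the disulfide-bridged
homodimer. The full grammar is in ``docs/NOTATION.md``.

Position ids used throughout the package are 0-based, depth-first from the
core: each segment copy emits its residues in written (N-to-C) order, then
recurses into the two child copies of the next-outer segment in ascending
copy order; for dimers the second monomer follows the first.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from typing import NamedTuple, Optional

import pandas as pd

from .errors import (
    BranchingError,
    DimerError,
    NotationError,
    TopologyError,
    VocabularyError,
)

#: Residue vocabulary (uppercase = L). G is included for test fixtures only.
RESIDUE_LETTERS = frozenset("ACEKYG")

#: Recognized N-terminal cap tags.
CAP_TAGS = ("ClAc", "Fum", "Ac")  # longest-match order

#: Recognized residue label tags.
LABEL_TAGS = frozenset({"Fl"})

ACID = "acid"
AMIDE = "amide"

# every hyphen-like codepoint seen in print is normalized to ASCII "-"
_HYPHENS = dict.fromkeys(map(ord, "‐‑‒–—−"), "-")


class ResiduePosition(NamedTuple):
    """One residue of the expanded dendrimer tree."""

    position: int          # 0-based, depth-first from the core
    code: str              # one-letter code, case carries stereo
    is_branching: bool     # lysine acylated on alpha- and epsilon-amine
    segment_index: int     # index into topology.segments (0 = outermost)
    copy_index: int        # 0-based copy of that segment (within a monomer)
    monomer: int           # 0, or 1 for the second chain of a dimer
    label: Optional[str]   # label tag (e.g. "Fl") or None


@dataclass(frozen=True)
class Segment:
    """One notation segment: a residue run with a tree multiplicity."""

    residues: tuple[str, ...]
    multiplicity: int
    cap: Optional[str] = None
    is_core: bool = False

    def __post_init__(self):
        if not self.residues:
            raise TopologyError("empty segment")
        if self.multiplicity < 1:
            raise TopologyError("segment multiplicity must be positive")
        if self.is_core and self.multiplicity != 1:
            raise TopologyError("core segment must have multiplicity 1")
        for code in self.residues:
            if code.upper() not in RESIDUE_LETTERS:
                raise VocabularyError(f"unknown residue letter {code!r}")
        if self.cap is not None and self.cap not in CAP_TAGS:
            raise VocabularyError(f"unknown cap tag {self.cap!r}")


@dataclass(frozen=True)
class DendrimerTopology:
    """A validated branched-peptide topology (segments outermost first)."""

    segments: tuple[Segment, ...]
    c_terminus: str = AMIDE
    stereorandomized: bool = False
    dimer: bool = False
    #: labels as (segment_index, residue_index_in_segment, tag); a label on a
    #: segment with multiplicity > 1 applies to every copy.
    segment_labels: tuple[tuple[int, int, str], ...] = ()
    name: str = ""

    def __post_init__(self):
        if not self.segments:
            raise TopologyError("topology needs at least one segment")
        if self.c_terminus not in (ACID, AMIDE):
            raise TopologyError(f"unknown C-terminus {self.c_terminus!r}")
        mults = [s.multiplicity for s in self.segments]
        if mults[-1] != 1 or not self.segments[-1].is_core:
            raise TopologyError("last segment must be the core (multiplicity 1)")
        if any(s.is_core for s in self.segments[:-1]):
            raise TopologyError("only the last segment may be the core")
        for outer, inner in zip(mults, mults[1:]):
            if outer != 2 * inner:
                raise TopologyError(
                    f"multiplicities must strictly halve to 1, got {mults}"
                )
        # every inner segment starts with a (branching) lysine
        for i, seg in enumerate(self.segments):
            if i > 0 and seg.residues[0].upper() != "K":
                raise BranchingError(
                    f"inner segment {i} must start with a branching lysine, "
                    f"got {seg.residues[0]!r}"
                )
            if i > 0 and seg.cap is not None:
                raise TopologyError("caps apply to the outermost segment only")
        for si, ri, tag in self.segment_labels:
            if not (0 <= si < len(self.segments)):
                raise TopologyError(f"label on unknown segment {si}")
            if not (0 <= ri < len(self.segments[si].residues)):
                raise TopologyError(f"label on unknown residue {ri} of segment {si}")
            if tag not in LABEL_TAGS:
                raise VocabularyError(f"unknown label tag {tag!r}")
        if self.dimer:
            n_cys = sum(
                (seg.residues.count("C") + seg.residues.count("c"))
                * seg.multiplicity
                for seg in self.segments
            )
            if n_cys != 1:
                raise DimerError(
                    f"dimer requires exactly one cysteine per monomer, found {n_cys}"
                )

    # -- derived structure ------------------------------------------------

    @property
    def n_monomers(self) -> int:
        return 2 if self.dimer else 1

    @property
    def n_residues(self) -> int:
        per = sum(len(s.residues) * s.multiplicity for s in self.segments)
        return per * self.n_monomers

    @property
    def n_termini(self) -> int:
        """Number of N-termini (chain ends), equal to the outermost multiplicity."""
        return self.segments[0].multiplicity * self.n_monomers

    @property
    def n_branching(self) -> int:
        """Number of branching lysines (outermost multiplicity - 1 per monomer)."""
        return (self.segments[0].multiplicity - 1) * self.n_monomers

    @property
    def generations(self) -> int:
        return len(self.segments) - 1

    @property
    def stereo_mode(self) -> str:
        if self.stereorandomized:
            return "stereorandomized"
        letters = [c for s in self.segments for c in s.residues]
        if all(c.isupper() for c in letters):
            return "all-L"
        if all(c.islower() for c in letters):
            return "all-D"
        return "mixed"

    @property
    def labels(self) -> Mapping[int, str]:
        """Mapping position id -> label tag over the expanded tree."""
        return {p.position: p.label for p in enumerate_residues(self) if p.label}

    def is_branching(self, segment_index: int, residue_index: int) -> bool:
        return (
            len(self.segments) > 1
            and segment_index > 0
            and residue_index == 0
        )


# ---------------------------------------------------------------------------
# tree expansion
# ---------------------------------------------------------------------------

def enumerate_residues(t: DendrimerTopology) -> list[ResiduePosition]:
    """Flatten a topology into its residue positions, depth-first from the core.

    The order is deterministic: a segment copy emits its residues in written
    (N-to-C) order, then recurses into child copies ``2c`` and ``2c + 1`` of
    the next-outer segment; a dimer emits monomer 0 then monomer 1.
    """
    label_map = {(si, ri): tag for si, ri, tag in t.segment_labels}
    out: list[ResiduePosition] = []

    def walk(seg_idx: int, copy_idx: int, monomer: int) -> None:
        seg = t.segments[seg_idx]
        for ri, code in enumerate(seg.residues):
            out.append(
                ResiduePosition(
                    position=len(out),
                    code=code,
                    is_branching=t.is_branching(seg_idx, ri),
                    segment_index=seg_idx,
                    copy_index=copy_idx,
                    monomer=monomer,
                    label=label_map.get((seg_idx, ri)),
                )
            )
        if seg_idx > 0:
            walk(seg_idx - 1, 2 * copy_idx, monomer)
            walk(seg_idx - 1, 2 * copy_idx + 1, monomer)

    for mono in range(t.n_monomers):
        walk(len(t.segments) - 1, 0, mono)
    return out


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _find_matching_paren(s: str, start: int) -> int:
    depth = 0
    for i in range(start, len(s)):
        if s[i] == "(":
            depth += 1
        elif s[i] == ")":
            depth -= 1
            if depth == 0:
                return i
    raise TopologyError(f"unbalanced parentheses in {s!r}")


def _read_multiplicity(s: str, i: int) -> tuple[Optional[int], int]:
    """Read a subscript multiplicity ("_8" or bare "8") at position i."""
    if i < len(s) and s[i] == "_":
        i += 1
    j = i
    while j < len(s) and s[j].isdigit():
        j += 1
    if j == i:
        return None, i
    return int(s[i:j]), j


def _parse_segment_body(body: str) -> tuple[Optional[str], list[str], list[bool], dict]:
    """Parse one segment body into (cap, residues, star flags, labels)."""
    cap = None
    for tag in CAP_TAGS:
        if body.startswith(tag):
            cap = tag
            body = body[len(tag):]
            break
    residues: list[str] = []
    stars: list[bool] = []
    labels: dict[int, str] = {}
    i = 0
    while i < len(body):
        ch = body[i]
        if ch == "*":
            if i + 2 >= len(body) or body[i + 2] != "*" or not body[i + 1].isalpha():
                raise BranchingError(f"malformed branch marker in {body!r}")
            residues.append(body[i + 1])
            stars.append(True)
            i += 3
        elif ch == "(":
            j = _find_matching_paren(body, i)
            tag = body[i + 1 : j]
            if not residues:
                raise VocabularyError(f"label {tag!r} attached to no residue")
            if tag not in LABEL_TAGS:
                raise VocabularyError(f"unknown label tag {tag!r}")
            labels[len(residues) - 1] = tag
            i = j + 1
        elif ch.isalpha():
            if ch.upper() not in RESIDUE_LETTERS:
                raise VocabularyError(f"unknown residue letter {ch!r}")
            residues.append(ch)
            stars.append(False)
            i += 1
        else:
            raise VocabularyError(f"unexpected character {ch!r} in segment {body!r}")
    if not residues:
        raise TopologyError(f"empty segment body {body!r}")
    return cap, residues, stars, labels


def parse_notation(text: str, name: str = "") -> DendrimerTopology:
    """Parse a dendrimer linear-notation string into a validated topology.

    Accepts the printed dialect: Unicode or ASCII hyphens, ``_n`` or bare
    subscripts, optional ``*K*`` branch stars (branching is inferred from
    position), an optional ``sr-`` prefix and the ``((...)-NH_2)_2`` dimer
    wrapper.
    """
    if not text or not text.strip():
        raise TopologyError("empty notation string")
    s = text.translate(_HYPHENS)
    s = re.sub(r"\s+", "", s)

    stereorandomized = False
    if s.startswith("sr-"):
        stereorandomized = True
        s = s[3:]

    # dimer wrapper: "((...)-NH_2)_2" — the wrapped text carries the terminus
    dimer = False
    if s.startswith("("):
        close = _find_matching_paren(s, 0)
        mult, end = _read_multiplicity(s, close + 1)
        inner = s[1:close]
        if end == len(s) and mult is not None and re.search(r"-(OH|NH_?2)$", inner):
            if mult != 2:
                raise DimerError(f"dimer wrapper multiplicity must be 2, got {mult}")
            dimer = True
            s = inner

    if s.endswith("-NH_2") or s.endswith("-NH2"):
        c_terminus = AMIDE
        s = s[: s.rindex("-")]
    elif s.endswith("-OH"):
        c_terminus = ACID
        s = s[:-3]
    else:
        raise TopologyError("missing C-terminus (-OH or -NH_2)")

    # parenthesized segments, outermost first; remainder is the core
    raw: list[tuple[Optional[str], list[str], list[bool], dict, int]] = []
    while s.startswith("("):
        close = _find_matching_paren(s, 0)
        mult, end = _read_multiplicity(s, close + 1)
        if mult is None:
            raise TopologyError(f"segment {s[:close + 1]!r} lacks a multiplicity")
        cap, residues, stars, labels = _parse_segment_body(s[1:close])
        raw.append((cap, residues, stars, labels, mult))
        s = s[end:]
    if not s:
        raise TopologyError("missing core segment")
    cap, residues, stars, labels = _parse_segment_body(s)
    raw.append((cap, residues, stars, labels, 1))

    n_seg = len(raw)
    segments = []
    segment_labels: list[tuple[int, int, str]] = []
    for idx, (cap, residues, stars, labels, mult) in enumerate(raw):
        for ri, star in enumerate(stars):
            if star:
                if idx == 0 and n_seg > 1:
                    raise BranchingError(
                        "outermost segment cannot contain a branching lysine"
                    )
                if n_seg == 1:
                    raise BranchingError(
                        "a linear peptide cannot contain a branching lysine"
                    )
                if ri != 0:
                    raise BranchingError(
                        "branch marker allowed only on the first residue "
                        "of an inner segment"
                    )
                if residues[ri].upper() != "K":
                    raise BranchingError(
                        f"branching residue must be lysine, got {residues[ri]!r}"
                    )
        segments.append(
            Segment(
                residues=tuple(residues),
                multiplicity=mult,
                cap=cap,
                is_core=(idx == n_seg - 1),
            )
        )
        for ri, tag in labels.items():
            segment_labels.append((idx, ri, tag))

    return DendrimerTopology(
        segments=tuple(segments),
        c_terminus=c_terminus,
        stereorandomized=stereorandomized,
        dimer=dimer,
        segment_labels=tuple(sorted(segment_labels)),
        name=name,
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_notation(t: DendrimerTopology) -> str:
    """Serialize a topology to canonical notation.

    Canonical form: ASCII hyphens, ``_n`` subscripts, explicit ``*K*`` branch
    stars on every inner leading lysine, caps written inside the outermost
    parentheses, one space before the core. ``parse_notation`` of the result
    reproduces the topology exactly.
    """
    label_map = {(si, ri): tag for si, ri, tag in t.segment_labels}
    parts = []
    for si, seg in enumerate(t.segments):
        body = seg.cap or ""
        for ri, code in enumerate(seg.residues):
            if t.is_branching(si, ri):
                body += f"*{code}*"
            else:
                body += code
            if (si, ri) in label_map:
                body += f"({label_map[si, ri]})"
        if seg.is_core:
            parts.append(body)
        else:
            parts.append(f"({body})_{seg.multiplicity}")
    core = parts.pop()
    s = "".join(parts) + (" " if parts else "") + core
    s += "-NH_2" if t.c_terminus == AMIDE else "-OH"
    if t.dimer:
        s = f"({s})_2"
    if t.stereorandomized:
        s = "sr-" + s
    return s


# ---------------------------------------------------------------------------
# CSV interface (one compound per row)
# ---------------------------------------------------------------------------

CSV_COLUMNS = ("name", "notation", "activity", "notes")


def read_compound_csv(path) -> pd.DataFrame:
    """Read a compound table (columns name, notation, activity, notes)."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(CSV_COLUMNS))
    missing = {"name", "notation"} - set(df.columns)
    if missing:
        raise NotationError(f"compound CSV missing columns: {sorted(missing)}")
    for col in CSV_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    return df


def write_compound_csv(rows: Iterable[Mapping], path) -> None:
    df = pd.DataFrame(list(rows))
    for col in CSV_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df.to_csv(path, index=False)
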