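"""Seeded enumeration of virtual G2 dendrimer libraries with a
glatiramer-like composition constraint.

Glatiramer acetate (GA) is a random Ala/Lys/Glu/Tyr copolymer with an
A/K/E/Y composition of 4.2/3.4/1.4/1.0. The generator samples G2 dendrimer
topologies (multiplicities 4/2/1) over the same four-letter alphabet,
drawing each non-branching position uniformly, and keeps a candidate only
if the L1 distance between its normalized non-branching A/K/E/Y fractions
and the normalized reference is at most the configured tolerance, and its
notation has not been emitted before. Identical (config, seed) pairs
reproduce the member list exactly.

The published virtual-library grammar itself is not printed anywhere, so
the scaffold defaults here are a parameterized reconstruction, not a
reproduction: outer segments of 2-3 residues, middle of 3-4, core of 4-8
(branching lysine included), free N-termini, amide C-terminus, all-L.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chemistry import PropertyReport, property_report
from .errors import ConfigError, DegenerateCompositionError, NotationError, SamplingExhaustedError
from .notation import (
    AMIDE,
    DendrimerTopology,
    parse_notation,
    read_compound_csv,
    write_notation,
)

#: Sampling algorithm identifier recorded in manifests.
PRNG_ALGORITHM = "numpy.random.Generator(PCG64)"

#: GA reference composition, A/K/E/Y.
GA_RATIO = (4.2, 3.4, 1.4, 1.0)


@dataclass(frozen=True)
class CompositionTarget:
    """Reference A/K/E/Y composition and the admissible L1 distance."""

    ratio: tuple[float, float, float, float] = GA_RATIO
    tolerance: float = 0.25

    def __post_init__(self):
        if len(self.ratio) != 4 or any(r <= 0 for r in self.ratio):
            raise ConfigError("reference ratio must be four positive numbers")
        if self.tolerance < 0:
            raise ConfigError("tolerance must be nonnegative")

    @property
    def fractions(self) -> np.ndarray:
        """Reference normalized to sum 1 (A, K, E, Y)."""
        arr = np.asarray(self.ratio, dtype=float)
        return arr / arr.sum()


@dataclass(frozen=True)
class LibraryConfig:
    """Scaffold grammar and sampling parameters for a virtual G2 library."""

    #: inclusive residue-count ranges per segment, outermost -> core;
    #: inner segments include their leading branching lysine.
    segment_length_ranges: tuple[tuple[int, int], ...] = ((2, 3), (3, 4), (4, 8))
    alphabet: tuple[str, ...] = ("A", "K", "E", "Y")
    n_members: int = 1000
    seed: int = 0
    c_terminus: str = AMIDE
    cap: Optional[str] = None
    #: give up after this many rejection-sampling attempts
    max_attempts: int = 2_000_000

    def __post_init__(self):
        if self.n_members < 1:
            raise ConfigError("n_members must be >= 1")
        if not self.segment_length_ranges:
            raise ConfigError("scaffold needs at least one segment")
        for lo, hi in self.segment_length_ranges:
            if lo < 1 or hi < lo:
                raise ConfigError(
                    f"invalid segment length range ({lo}, {hi})"
                )
        for i, (lo, hi) in enumerate(self.segment_length_ranges[1:], start=1):
            if lo < 2:
                raise ConfigError(
                    "inner segments need >= 2 residues (branching K + payload)"
                )
        if not self.alphabet or any(
            a.upper() not in "ACEKYG" or len(a) != 1 for a in self.alphabet
        ):
            raise ConfigError(f"invalid alphabet {self.alphabet!r}")

    @property
    def multiplicities(self) -> tuple[int, ...]:
        n = len(self.segment_length_ranges)
        return tuple(2 ** (n - 1 - i) for i in range(n))

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["segment_length_ranges"] = [list(r) for r in self.segment_length_ranges]
        d["alphabet"] = list(self.alphabet)
        d["multiplicities"] = list(self.multiplicities)
        d["prng"] = PRNG_ALGORITHM
        return d

    @classmethod
    def from_manifest(cls, d: dict) -> "LibraryConfig":
        d = dict(d)
        d.pop("prng", None)
        d.pop("multiplicities", None)
        d["segment_length_ranges"] = tuple(
            tuple(r) for r in d["segment_length_ranges"]
        )
        d["alphabet"] = tuple(d["alphabet"])
        return cls(**d)


@dataclass(frozen=True)
class LibraryMember:
    """One enumerated (or designed) dendrimer with computed properties."""

    topology: DendrimerTopology
    notation: str
    properties: PropertyReport
    provenance: str = "virtual"   # "virtual" | "designed"
    activity: str = "NA"          # "+" | "-" | "NA"


# ---------------------------------------------------------------------------
# composition metric
# ---------------------------------------------------------------------------

def composition_fractions(t: DendrimerTopology) -> np.ndarray:
    """Normalized non-branching (A, K, E, Y) fractions of a topology."""
    from .chemistry import composition_counts

    counts = composition_counts(t)
    vec = np.array(
        [counts["A"], counts["K"], counts["E"], counts["Y"]], dtype=float
    )
    if vec.sum() == 0:
        raise DegenerateCompositionError("no non-branching A/K/E/Y residues")
    return vec / vec.sum()


def composition_distance(t: DendrimerTopology, target: CompositionTarget) -> float:
    """L1 distance between normalized A/K/E/Y fractions and the reference.

    Zero iff the proportions match exactly; invariant under scaling every
    count by the same factor.
    """
    return float(np.abs(composition_fractions(t) - target.fractions).sum())


def _counts_distance(counts: np.ndarray, ref_fractions: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return np.inf
    return float(np.abs(counts / total - ref_fractions).sum())


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def enumerate_library(
    config: LibraryConfig, target: CompositionTarget = CompositionTarget()
) -> list[LibraryMember]:
    """Rejection-sample ``config.n_members`` distinct valid dendrimers.

    Every emitted member re-parses through :func:`parse_notation` and
    satisfies ``composition_distance <= target.tolerance``. Raises
    :class:`SamplingExhaustedError` when the attempt budget runs out.
    """
    rng = np.random.default_rng(config.seed)
    alphabet = np.array([a.upper() for a in config.alphabet])
    aidx = {letter: i for i, letter in enumerate("AKEY")}
    alpha_to_akey = np.array([aidx.get(a, -1) for a in alphabet])
    ranges = config.segment_length_ranges
    n_seg = len(ranges)

    members: list[LibraryMember] = []
    seen: set[str] = set()
    attempts = 0
    while len(members) < config.n_members:
        if attempts >= config.max_attempts:
            raise SamplingExhaustedError(
                f"drew {attempts} candidates but only {len(members)} of "
                f"{config.n_members} members satisfied the constraints",
                attempts=attempts,
            )
        attempts += 1
        lengths = [int(rng.integers(lo, hi + 1)) for lo, hi in ranges]
        # non-branching draw counts: inner segments reserve position 0 for K
        seq_parts: list[str] = []
        counts = np.zeros(4)
        mults = config.multiplicities
        for si, L in enumerate(lengths):
            n_free = L if si == 0 else L - 1
            draw = rng.integers(0, len(alphabet), size=n_free)
            letters = alphabet[draw]
            for d in draw:
                j = alpha_to_akey[d]
                if j >= 0:
                    counts[j] += mults[si]
            seq_parts.append(("" if si == 0 else "K") + "".join(letters))
        if _counts_distance(counts, target.fractions) > target.tolerance:
            continue
        notation = _assemble_notation(seq_parts, config)
        if notation in seen:
            continue
        seen.add(notation)
        topo = parse_notation(notation, name=f"V{len(members):04d}")
        # independent re-check of the constraint on the parsed topology
        if composition_distance(topo, target) > target.tolerance:  # pragma: no cover
            continue
        members.append(
            LibraryMember(
                topology=topo,
                notation=write_notation(topo),
                properties=property_report(topo),
                provenance="virtual",
                activity="NA",
            )
        )
    return members


def _assemble_notation(seq_parts: Sequence[str], config: LibraryConfig) -> str:
    mults = config.multiplicities
    cap = config.cap or ""
    parts = []
    for si, seq in enumerate(seq_parts[:-1]):
        body = (cap if si == 0 else "") + seq
        parts.append(f"({body})_{mults[si]}")
    core = seq_parts[-1]
    if len(seq_parts) == 1:
        core = cap + core
    term = "-NH_2" if config.c_terminus == AMIDE else "-OH"
    return "".join(parts) + (" " if parts else "") + core + term


def members_table(members: Sequence[LibraryMember]) -> pd.DataFrame:
    """Member list as a property table (one compound per row)."""
    from .chemistry import report_row

    rows = []
    for m in members:
        row = report_row(m.properties)
        row["name"] = m.properties.name or m.topology.name
        row["provenance"] = m.provenance
        row["activity"] = m.activity
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# designed compounds
# ---------------------------------------------------------------------------

@dataclass
class LoadResult:
    """Outcome of loading a designed-compound CSV."""

    members: list[LibraryMember]
    errors: list[tuple[int, str, str]] = field(default_factory=list)  # (row, name, message)


def load_designed_set(path) -> LoadResult:
    """Load a designed-compound CSV (columns name, notation, activity).

    Rows that fail to parse are reported in ``errors`` with their row
    numbers; valid rows are still loaded.
    """
    df = read_compound_csv(path)
    result = LoadResult(members=[])
    for i, row in df.iterrows():
        name = str(row.get("name", "") or "")
        try:
            topo = parse_notation(str(row["notation"]), name=name)
            member = LibraryMember(
                topology=topo,
                notation=write_notation(topo),
                properties=property_report(topo),
                provenance="designed",
                activity=_norm_activity(row.get("activity", "")),
            )
        except NotationError as exc:
            result.errors.append((int(i) + 2, name, str(exc)))  # +2: header + 1-based
            continue
        result.members.append(member)
    return result


def _norm_activity(value) -> str:
    v = str(value or "").strip()
    if v in ("+", "-"):
        return v
    if v in ("−",):  # typographic minus
        return "-"
    return "NA"


def save_manifest(config: LibraryConfig, target: CompositionTarget, path) -> None:
    """Write the reproducibility manifest (config echo + seeds + algorithm)."""
    from . import __version__

    manifest = {
        "dendrimap_version": __version__,
        "config": config.to_manifest(),
        "target": {"ratio": list(target.ratio), "tolerance": target.tolerance},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_manifest(path) -> tuple[LibraryConfig, CompositionTarget]:
    with open(path) as fh:
        manifest = json.load(fh)
    config = LibraryConfig.from_manifest(manifest["config"])
    target = CompositionTarget(
        ratio=tuple(manifest["target"]["ratio"]),
        tolerance=manifest["target"]["tolerance"],
    )
    return config, target
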