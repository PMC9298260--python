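"""Bundled designed-compound table and its consistency audit.

The table transcribes the printed characterization of the designed
dendrimers verbatim: linear notation, calculated and observed monoisotopic
mass, formal net charge, E/K/A/Y ratio, IL-1Ra activity flag and isolated
yield. Printed values are never corrected; instead :func:`audit_record`
recomputes mass, charge and ratio from the notation alone and flags each
field where the print disagrees with the footnote rules (several printed
rows are internally inconsistent). The flags are machine-readable so
downstream checks can exclude discrepant fields rather than silently fail
on them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .chemistry import aa_ratio, format_ratio, monoisotopic_mass, net_charge
from .notation import parse_notation

#: |calculated - printed| tolerance in Da: printed precision is 1e-4 and the
#: atomic-mass constant set drifts by a few 1e-4 over ~6 kDa.
MASS_TOLERANCE = 0.005


@dataclass(frozen=True)
class FixtureRecord:
    """One printed table row (verbatim) plus its audit flags."""

    name: str
    notation: str
    calc_mass: float
    obs_mass: float
    charge: int
    ratio: str
    activity: str            # "+" | "-" | "NA"
    yield_pct: Optional[float] = None
    flags: tuple[str, ...] = ()   # subset of {"mass", "charge", "ratio"}

    @property
    def consistency(self) -> str:
        return "discrepant" if self.flags else "ok"


# (name, notation, calc mass, obs mass, charge, ratio, activity, yield %)
_RAW_TABLE = [
    ("1", "(KA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2",
     4695.9470, 4695.9625, 12, "3/15/17/1", "+", 61.9),
    ("Ac1", "(AcKA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2",
     5032.0315, 5032.0448, 12, "3/15/17/1", "-", 53.9),
    ("2", "(KAEKAYA)_4(*K*EKYAKA)_2 *K*EKYKA-NH_2",
     5447.0133, 5447.0332, 7, "1/1/2.4/1", "-", 221.0),
    ("3", "(AKA)_8(*K*YEK)_4(*K*EKA)_2 *K*AKY-OH",
     5775.3771, 5775.3854, 8, "1.2/3/3.8/1", "-", 23.7),
    ("4", "(KA)_8(KKAKE)_4(KYKAKA)_2KAYKKA-OH",
     6016.7929, 6016.7972, 17, "1.3/7.3/6/1", "+", 127.0),
    ("Ac4", "(AcKA)_8(*K*KAKE)_4(*K*YKAKA)_2 *K*AYKKA-OH",
     6352.8774, 6352.8918, 17, "1.3/7.3/6/1", "-", 52.8),
    ("5", "(AK)_8(*K*AKAKY)_4(*K*AKEYEY)_2 *K*AKEYEY-NH_2",
     6916.1419, 6916.1596, 13, "0.6/1.9/1.9/1", "-", 51.3),
    ("33", "(KAK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2",
     3102.8903, 3102.8874, 4, "3/11/9/1", "-", 21.9),
    ("34", "(AK)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2",
     4695.9470, 4695.9469, 12, "3/15/17/1", "+", 23.2),
    ("35", "(KK)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2",
     5152.4098, 5152.4134, 12, "3/23/9/1", "+", 18.9),
    ("36", "(KA)_8(*K*KKAK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2",
     5720.7067, 5720.7070, 20, "3/23/17/1", "+", 28.0),
    ("Ac36", "(AcKA)_8(*K*KKAK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2",
     6056.7912, 6056.7988, 20, "3/23/17/1", "+", 28.6),
    ("Fum36", "(FumKA)_8(*K*KKAK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2",
     6728.9602, 6728.9614, 20, "3/23/17/1", "+", 27.5),
    ("1-1", "((KA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2)_2",
     9247.8040, 9247.8422, 24, "3/15/17/1", "+", 7.9),
    ("D-1", "(ka)_8(*k*ak)_4(*k*eka)_2 *k*akeayca-NH_2",
     4695.9470, 4695.9606, 12, "3/15/17/1", "-", 56.8),
    ("sr-1", "sr-(KA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2",
     4624.9098, 4624.9212, 12, "3/15/17/1", "+", 32.9),
    ("D-4", "(ka)_8(*k*kake)_4(*k*ykaka)_2 *k*aykka-OH",
     6015.8089, 6015.8149, 8, "1.3/7.3/6/1", "-", 67.1),
    ("sr-4", "sr-(KA)_8(*K*KAKE)_4(*K*YKAKA)_2 *K*AYKKA-OH",
     6016.7929, 6016.8081, 8, "1.3/7.3/6/1", "+", 89.6),
    ("1Fl", "(KA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYC(Fl)A-NH_2",
     5207.0373, 5207.0391, 12, "3/15/17/1", "+", 6.5),
]


def audit_record(name, notation, calc_mass, obs_mass, charge, ratio,
                 activity, yield_pct) -> FixtureRecord:
    """Recompute mass/charge/ratio from the notation and flag each printed
    field that disagrees with the rule-based value."""
    t = parse_notation(notation, name=name)
    flags = []
    if abs(monoisotopic_mass(t) - calc_mass) > MASS_TOLERANCE:
        flags.append("mass")
    if net_charge(t) != charge:
        flags.append("charge")
    if format_ratio(aa_ratio(t)) != ratio:
        flags.append("ratio")
    return FixtureRecord(
        name=name, notation=notation, calc_mass=calc_mass, obs_mass=obs_mass,
        charge=charge, ratio=ratio, activity=activity, yield_pct=yield_pct,
        flags=tuple(flags),
    )


def table1_records() -> list[FixtureRecord]:
    """The bundled designed-compound rows, audited."""
    return [audit_record(*row) for row in _RAW_TABLE]


def table1_frame() -> pd.DataFrame:
    rows = []
    for r in table1_records():
        rows.append({
            "name": r.name,
            "notation": r.notation,
            "calc_mass": f"{r.calc_mass:.4f}",
            "obs_mass": f"{r.obs_mass:.4f}",
            "charge": r.charge,
            "ratio": r.ratio,
            "activity": r.activity,
            "yield_pct": r.yield_pct,
            "consistency": r.consistency,
            "flags": ";".join(r.flags),
            "notes": "",
        })
    return pd.DataFrame(rows)


def make_fixtures(path) -> pd.DataFrame:
    """Write the bundled table as CSV (round-trips through the designed-set
    loader) and return the frame."""
    df = table1_frame()
    df.to_csv(path, index=False)
    return df


def fixture_checksum() -> str:
    """SHA-256 over the verbatim printed values (guards against silent
    mutation of the transcription)."""
    payload = "\n".join(
        "|".join(str(v) for v in row) for row in _RAW_TABLE
    ).encode()
    return hashlib.sha256(payload).hexdigest()
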