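"""Grammar, tree expansion and round-trip behaviour of the linear notation."""

import pytest
from hypothesis import given, settings, strategies as st

from dendrimap.errors import (
    BranchingError,
    DimerError,
    TopologyError,
    VocabularyError,
)
from dendrimap.notation import (
    DendrimerTopology,
    Segment,
    enumerate_residues,
    parse_notation,
    write_notation,
)


class TestParsing:
    def test_g3_dendrimer_structure(self):
        t = parse_notation("(KA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2")
        assert len(t.segments) == 4
        assert [s.multiplicity for s in t.segments] == [8, 4, 2, 1]
        assert t.n_residues == 44
        assert t.n_branching == 7
        assert t.n_termini == 8
        assert t.c_terminus == "amide"
        assert t.stereo_mode == "all-L"

    def test_g3_residue_composition(self):
        t = parse_notation("(KA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2")
        counts = {}
        for p in enumerate_residues(t):
            counts[p.code] = counts.get(p.code, 0) + 1
        assert counts == {"K": 22, "A": 17, "E": 3, "Y": 1, "C": 1}

    def test_linear_core_only(self):
        t = parse_notation("AKY-OH")
        assert len(t.segments) == 1
        assert t.n_residues == 3
        assert t.n_branching == 0
        assert t.n_termini == 1
        assert t.c_terminus == "acid"

    def test_all_d_form_same_topology(self):
        L = parse_notation("(KA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2")
        D = parse_notation("(ka)_8(*k*ak)_4(*k*eka)_2 *k*akeayca-NH_2")
        assert D.stereo_mode == "all-D"
        assert D.n_residues == L.n_residues
        assert D.n_branching == L.n_branching
        assert [s.multiplicity for s in D.segments] == [
            s.multiplicity for s in L.segments
        ]

    def test_branching_inferred_without_stars(self):
        bare = parse_notation("(KA)_8(KKAKE)_4(KYKAKA)_2KAYKKA-OH")
        starred = parse_notation("(KA)_8(*K*KAKE)_4(*K*YKAKA)_2 *K*AYKKA-OH")
        assert bare.segments == starred.segments
        assert bare.n_branching == 7

    def test_printed_dialect_variants_parse_identically(self):
        canonical = parse_notation("(KA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2")
        unicode_hyphen = parse_notation(
            "(KA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA‐NH_2"
        )
        bare_subscripts = parse_notation("(KA)8(*K*AK)4(*K*EKA)2 *K*AKEAYCA-NH2")
        assert unicode_hyphen.segments == canonical.segments
        assert bare_subscripts.segments == canonical.segments
        assert bare_subscripts.c_terminus == "amide"

    def test_sr_prefix(self):
        t = parse_notation("sr-(KA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2")
        assert t.stereorandomized
        assert t.stereo_mode == "stereorandomized"
        plain = parse_notation("(KA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2")
        assert t.segments == plain.segments

    def test_dimer_wrapper(self):
        t = parse_notation("((KA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2)_2")
        assert t.dimer
        assert t.n_residues == 88
        assert t.n_termini == 16
        assert len(enumerate_residues(t)) == 88

    def test_label(self):
        t = parse_notation("(KA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYC(Fl)A-NH_2")
        assert t.segment_labels == ((3, 6, "Fl"),)
        labelled = [p for p in enumerate_residues(t) if p.label == "Fl"]
        assert len(labelled) == 1
        assert labelled[0].code == "C"

    def test_cap_parsing(self):
        t = parse_notation("(AcKA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2")
        assert t.segments[0].cap == "Ac"
        t2 = parse_notation("(ClAcKA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2")
        assert t2.segments[0].cap == "ClAc"


class TestErrors:
    @pytest.mark.parametrize(
        "text, exc",
        [
            ("(KA)_8(*A*AK)_4 *K*AK-NH_2", BranchingError),   # non-K branch
            ("(KA)_8(AAK)_4(*K*EKA)_2 *K*AK-NH_2", BranchingError),  # inner not K-led
            ("(K*A*K)_4 *K*EKA-NH_2", BranchingError),        # star off-lead
            ("(*K*A)_8 *K*AK-NH_2", BranchingError),          # star in outermost
            ("*K*AK-NH_2", BranchingError),                   # star in linear
            ("(KA)_8(*K*AK)_2 *K*AK-NH_2", TopologyError),    # 8/2/1 not halving
            ("(KA)_3 *K*AK-NH_2", TopologyError),             # 3 not a doubling
            ("(KA)_8 ", TopologyError),                       # no terminus
            ("AKYA", TopologyError),                          # no terminus
            ("", TopologyError),
            ("(KA)_8 *K*AXK-NH_2", VocabularyError),          # unknown letter
            ("AKC(Dan)A-NH_2", VocabularyError),              # unknown label
            ("((KA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYA-NH_2)_2", DimerError),  # no Cys
            ("((KA)_8(*K*CK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2)_2", DimerError),  # 5 Cys
        ],
    )
    def test_invalid_notation(self, text, exc):
        with pytest.raises(exc):
            parse_notation(text)

    def test_missing_multiplicity(self):
        with pytest.raises(TopologyError):
            parse_notation("(KA)(*K*AK)_4 *K*AK-NH_2")

    def test_cap_on_inner_segment_rejected(self):
        with pytest.raises(TopologyError):
            parse_notation("(KA)_8(AcKAK)_4 *K*AK-NH_2")


class TestEnumeration:
    def test_positions_are_stable_and_sequential(self, topologies):
        for t in topologies.values():
            positions = enumerate_residues(t)
            assert [p.position for p in positions] == list(range(t.n_residues))
            assert positions == enumerate_residues(t)

    def test_g2_example(self):
        t = parse_notation("(KAK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2")
        positions = enumerate_residues(t)
        assert len(positions) == 28
        assert sum(p.is_branching for p in positions) == 3

    def test_halving_law(self, topologies):
        for t in topologies.values():
            assert t.n_termini == t.segments[0].multiplicity * t.n_monomers
            assert t.n_branching == (t.segments[0].multiplicity - 1) * t.n_monomers


class TestRoundTrip:
    def test_canonical_form_of_designed_compound(self):
        t = parse_notation("(KA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2")
        assert write_notation(t) == "(KA)_8(*K*AK)_4(*K*EKA)_2 *K*AKEAYCA-NH_2"

    def test_write_normalizes_bare_branching(self):
        t = parse_notation("(KA)_8(KKAKE)_4(KYKAKA)_2KAYKKA-OH")
        out = write_notation(t)
        assert out == "(KA)_8(*K*KAKE)_4(*K*YKAKA)_2 *K*AYKKA-OH"
        assert parse_notation(out) == t

    def test_core_only_identity(self):
        assert write_notation(parse_notation("G-OH")) == "G-OH"

    def test_round_trip_all_fixture_rows(self, table1, topologies):
        for name, t in topologies.items():
            again = parse_notation(write_notation(t), name)
            assert again == t, name

    def test_write_is_idempotent(self, topologies):
        for t in topologies.values():
            once = write_notation(t)
            assert write_notation(parse_notation(once)) == once


# -- property-based round trip ---------------------------------------------

_letters = st.sampled_from("ACEKYGacekyg")


@st.composite
def random_topology(draw):
    generations = draw(st.integers(0, 3))
    segments = []
    for gi in range(generations + 1):
        is_core = gi == generations
        length = draw(st.integers(1 if gi == 0 else 2, 5))
        residues = [draw(_letters) for _ in range(length)]
        if gi > 0:
            residues[0] = draw(st.sampled_from("Kk"))
        cap = draw(st.sampled_from([None, "Ac", "ClAc", "Fum"])) if gi == 0 else None
        segments.append(
            Segment(
                residues=tuple(residues),
                multiplicity=2 ** (generations - gi),
                cap=cap,
                is_core=is_core,
            )
        )
    return DendrimerTopology(
        segments=tuple(segments),
        c_terminus=draw(st.sampled_from(["acid", "amide"])),
        stereorandomized=draw(st.booleans()),
    )


@settings(max_examples=120, deadline=None, derandomize=True)
@given(random_topology())
def test_parse_write_round_trip(t):
    """parse(write(t)) == t for arbitrary valid topologies."""
    assert parse_notation(write_notation(t)) == t


@settings(max_examples=120, deadline=None, derandomize=True)
@given(random_topology())
def test_case_change_only_affects_stereo(t):
    """Lowercasing every residue flips stereo_mode but no counts."""
    lowered = DendrimerTopology(
        segments=tuple(
            Segment(
                residues=tuple(c.lower() for c in s.residues),
                multiplicity=s.multiplicity,
                cap=s.cap,
                is_core=s.is_core,
            )
            for s in t.segments
        ),
        c_terminus=t.c_terminus,
        stereorandomized=t.stereorandomized,
    )
    assert lowered.n_residues == t.n_residues
    assert lowered.n_branching == t.n_branching
    assert lowered.n_termini == t.n_termini
    if not t.stereorandomized:
        assert lowered.stereo_mode == "all-D"
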