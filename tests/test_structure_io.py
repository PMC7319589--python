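"""Structure parsing, writing, mutation grammar and mutant modelling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abddg.structure_io import (
    AA1_TO_3,
    MultiMutation,
    MutationSpec,
    StructureError,
    build_mutant,
    distance_to_partner,
    format_mutation,
    interface_residues,
    min_heavy_distance,
    parse_mutation_list,
    read_pdb,
    write_pdb,
)

from conftest import single_atom_complex

ALTLOC_PDB = """\
ATOM      1  N   ALA H   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA H   1       1.458   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA H   1       1.500   0.100   0.000  0.40  0.00           C
ATOM      4  C   ALA H   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      5  O   ALA H   1       1.500   2.500   0.000  1.00  0.00           O
TER       6      ALA H   1
ATOM      7  N   GLY A   1       0.000   8.000   0.000  1.00  0.00           N
ATOM      8  CA  GLY A   1       1.458   8.000   0.000  1.00  0.00           C
ATOM      9  C   GLY A   1       2.000   9.400   0.000  1.00  0.00           C
ATOM     10  O   GLY A   1       1.500  10.500   0.000  1.00  0.00           O
TER      11      GLY A   1
END
"""


class TestPdbIO:
    def test_round_trip_preserves_identity_and_coordinates(self, toy_complex, tmp_path):
        """write ∘ read is lossless for keys, names and coords to format precision."""
        path = tmp_path / "toy.pdb"
        write_pdb(toy_complex, path)
        reparsed = read_pdb(path, toy_complex.antibody_chains, toy_complex.antigen_chains)
        assert len(reparsed.residues) == len(toy_complex.residues)
        for a, b in zip(toy_complex.residues, reparsed.residues):
            assert (a.key, a.name3) == (b.key, b.name3)
            assert [x.name for x in a.atoms] == [x.name for x in b.atoms]
            assert np.allclose(a.coords(), b.coords(), atol=1.5e-3)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        path.write_text(ALTLOC_PDB)
        cx = read_pdb(path, {"H"}, {"A"})
        ca = cx.residue(("H", 1, "")).atom("CA")
        assert np.allclose(ca.position, [1.458, 0.0, 0.0])  # occupancy 0.6 wins

    def test_read_rejects_empty_structure(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(StructureError, match="no (standard protein atoms|models)"):
            read_pdb(path, {"H"}, {"A"})


class TestMutationGrammar:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("H.Y33A;L.S52W", [("H", "Y", 33, "", "A"), ("L", "S", 52, "", "W")]),
            ("H.A100BY", [("H", "A", 100, "B", "Y")]),
        ],
    )
    def test_parses_fields(self, text, expected):
        (multi,) = parse_mutation_list(text)
        got = [(s.chain_id, s.wt_aa, s.number, s.icode, s.mt_aa) for s in multi]
        assert got == expected

    @pytest.mark.parametrize(
        "bad",
        ["H.Y33A;H.Y33F",  # duplicate site
         "H.Y33",          # no mutant letter
         "Y33A",           # missing chain
         "H.X33A",         # non-standard wild type
         "H.A33A"],        # wt == mt
    )
    def test_rejects_malformed_or_invalid(self, bad):
        with pytest.raises(StructureError):
            parse_mutation_list(bad)

    @settings(derandomize=True, max_examples=100)
    @given(
        chain=st.sampled_from("HLAB"),
        wt=st.sampled_from(sorted(AA1_TO_3)),
        number=st.integers(1, 9999),
        icode=st.sampled_from(["", "A", "B", "Z"]),
        mt=st.sampled_from(sorted(AA1_TO_3)),
    )
    def test_format_parse_round_trip(self, chain, wt, number, icode, mt):
        """The grammar and formatter are inverses over all valid specs."""
        if wt == mt:
            return
        spec = MutationSpec(chain, wt, number, icode, mt)
        (multi,) = parse_mutation_list(format_mutation(spec))
        assert multi.specs == (spec,)


class TestBuildMutant:
    def test_to_glycine_strips_side_chain(self, toy_complex):
        res = toy_complex.residues[2]
        if res.aa1 == "G":
            res = toy_complex.residues[3]
        mt = build_mutant(
            toy_complex,
            MultiMutation((MutationSpec(res.chain_id, res.aa1, res.number, res.icode, "G"),)),
        )
        names = [a.name for a in mt.residue(res.key).atoms]
        assert sorted(names) == ["C", "CA", "N", "O"]

    def test_backbone_never_moves(self, toy_complex):
        res = toy_complex.residues[1]
        mt_aa = "W" if res.aa1 != "W" else "F"
        mutant = build_mutant(
            toy_complex,
            MultiMutation((MutationSpec(res.chain_id, res.aa1, res.number, res.icode, mt_aa),)),
        )
        for r_wt, r_mt in zip(toy_complex.residues, mutant.residues):
            for name in ("N", "CA", "C", "O"):
                if r_wt.has_atom(name):
                    assert np.array_equal(
                        r_wt.atom(name).position, r_mt.atom(name).position
                    )

    def test_double_mutant_is_composition_of_singles(self, toy_complex):
        r1, r2 = toy_complex.residues[1], toy_complex.residues[4]
        s1 = MutationSpec(r1.chain_id, r1.aa1, r1.number, r1.icode,
                          "K" if r1.aa1 != "K" else "R")
        s2 = MutationSpec(r2.chain_id, r2.aa1, r2.number, r2.icode,
                          "D" if r2.aa1 != "D" else "E")
        both = build_mutant(toy_complex, MultiMutation((s1, s2)))
        seq = build_mutant(
            build_mutant(toy_complex, MultiMutation((s1,))), MultiMutation((s2,))
        )
        for a, b in zip(both.residues, seq.residues):
            assert a.name3 == b.name3
            assert [x.name for x in a.atoms] == [x.name for x in b.atoms]
            assert np.array_equal(a.coords(), b.coords())

    def test_wild_type_mismatch_reports_expected_and_found(self, toy_complex):
        res = toy_complex.residues[0]
        wrong = "W" if res.aa1 != "W" else "F"
        other = "K" if wrong != "K" else "R"
        with pytest.raises(StructureError, match=f"expected {wrong}, found {res.aa1}"):
            build_mutant(
                toy_complex,
                MultiMutation(
                    (MutationSpec(res.chain_id, wrong, res.number, res.icode, other),)
                ),
            )


class TestInterfaceGeometry:
    def test_close_pair_is_interfacial_far_pair_is_not(self):
        cx = single_atom_complex([[0, 0, 0], [4, 0, 0]])
        assert interface_residues(cx, 5.0) == {("H", 1, ""), ("A", 1, "")}
        cx_far = single_atom_complex([[0, 0, 0], [10, 0, 0]])
        assert interface_residues(cx_far, 5.0) == set()

    def test_matches_brute_force_all_pairs_scan(self, toy_complex):
        cutoff = 5.0
        expected = set()
        for ra in toy_complex.residues:
            for rb in toy_complex.residues:
                if toy_complex.side_of(ra.chain_id) == toy_complex.side_of(rb.chain_id):
                    continue
                d = min(
                    np.linalg.norm(p - q)
                    for p in ra.coords()
                    for q in rb.coords()
                )
                if d <= cutoff:
                    expected |= {ra.key, rb.key}
        assert interface_residues(toy_complex, cutoff) == expected

    def test_symmetric_under_partition_swap(self, toy_complex):
        from abddg.structure_io import Complex

        swapped = Complex(
            [r for r in toy_complex.copy().residues],
            set(toy_complex.antigen_chains),
            set(toy_complex.antibody_chains),
        )
        assert interface_residues(toy_complex, 5.0) == interface_residues(swapped, 5.0)

    def test_min_heavy_distance_triangle_case(self):
        cx = single_atom_complex([[0, 0, 0], [3, 4, 0]])
        assert min_heavy_distance(cx, ("H", 1, ""), ("A", 1, "")) == pytest.approx(5.0)
        assert min_heavy_distance(cx, ("H", 1, ""), ("H", 1, "")) == 0.0

    def test_min_heavy_distance_matches_exhaustive_oracle(self, toy_complex):
        ra, rb = toy_complex.residues[0], toy_complex.residues[-1]
        brute = min(
            np.linalg.norm(p - q) for p in ra.coords() for q in rb.coords()
        )
        assert min_heavy_distance(toy_complex, ra.key, rb.key) == pytest.approx(brute)
        assert min_heavy_distance(toy_complex, rb.key, ra.key) == pytest.approx(brute)

    def test_distance_to_partner_is_min_over_opposite_side(self, toy_complex):
        site = toy_complex.residues[0].key
        brute = min(
            min_heavy_distance(toy_complex, site, r.key)
            for r in toy_complex.residues
            if toy_complex.side_of(r.chain_id) != toy_complex.side_of(site[0])
        )
        assert distance_to_partner(toy_complex, site) == pytest.approx(brute)
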