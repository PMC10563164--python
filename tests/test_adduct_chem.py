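"""Unit tests for adduct enumeration, mass arithmetic and grouping."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clirms.adduct_chem import (
    DEFAULT_LOSSES,
    LABELING_SCHEMES,
    LOSS_BY_NAME,
    NUCLEOTIDE_MONOPHOSPHATE,
    ElementalFormula,
    NucleotideComposition,
    build_adduct_species,
    enumerate_adducts,
    enumerate_compositions,
    formula_mass,
    generate_covering_rna,
    group_by_delta,
    oligonucleotide_formula,
    read_adduct_table,
    write_adduct_table,
)

# independent atomic-mass oracle: values typed in separately from the
# module's table (NIST monoisotopic masses)
ORACLE_MASS = {
    "H": 1.0078250321,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "13C": 13.0033548378,
    "15N": 15.0001088984,
    "18O": 17.9991604,
}

D13C = ORACLE_MASS["13C"] - ORACLE_MASS["C"]
D15N = ORACLE_MASS["15N"] - ORACLE_MASS["N"]


def oracle_formula_mass(counts, heavy=None):
    total = sum(n * ORACLE_MASS[e] for e, n in counts.items())
    for iso, n in (heavy or {}).items():
        parent = {"13C": "C", "15N": "N", "18O": "O"}[iso]
        total += n * (ORACLE_MASS[iso] - ORACLE_MASS[parent])
    return total


def brute_force_compositions(seq, min_len, max_len):
    out = set()
    for k in range(min_len, max_len + 1):
        for i in range(len(seq) - k + 1):
            sub = seq[i : i + k]
            out.add(tuple(sorted(sub)))
    return out


class TestElementalFormula:
    def test_parse_and_str(self):
        f = ElementalFormula.parse("C9H13N2O9P")
        assert f.counts == {"C": 9, "H": 13, "N": 2, "O": 9, "P": 1}

    def test_arithmetic_closed(self):
        a = ElementalFormula.parse("H2O")
        b = ElementalFormula.parse("HPO3")
        assert (a + b - b).counts == a.counts

    def test_negative_subtraction_errors(self):
        with pytest.raises(ValueError):
            ElementalFormula.parse("H2O") - ElementalFormula.parse("H3PO4")

    def test_heavy_exceeding_parent_errors(self):
        with pytest.raises(ValueError):
            ElementalFormula({"C": 2}, {"13C": 3})

    def test_unknown_element_errors(self):
        with pytest.raises(ValueError):
            ElementalFormula({"Xx": 1})

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "P"]),
            st.integers(min_value=0, max_value=50),
            max_size=5,
        ),
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "P"]),
            st.integers(min_value=0, max_value=50),
            max_size=5,
        ),
    )
    @settings(max_examples=50, deadline=None)
    def test_addition_commutes(self, c1, c2):
        a, b = ElementalFormula(c1), ElementalFormula(c2)
        assert (a + b).counts == (b + a).counts


class TestFormulaMass:
    def test_water(self):
        assert formula_mass(ElementalFormula.parse("H2O")) == pytest.approx(
            18.01056, abs=1e-4
        )

    def test_ump(self):
        assert formula_mass(
            ElementalFormula.parse("C9H13N2O9P")
        ) == pytest.approx(324.03587, abs=1e-4)

    def test_empty_formula_is_zero(self):
        assert formula_mass(ElementalFormula()) == 0.0

    @pytest.mark.parametrize("base", ["A", "C", "G", "U"])
    def test_nucleotides_match_oracle(self, base):
        f = NUCLEOTIDE_MONOPHOSPHATE[base]
        assert formula_mass(f) == pytest.approx(
            oracle_formula_mass(f.counts), abs=1e-4
        )

    @pytest.mark.parametrize("loss", DEFAULT_LOSSES, ids=lambda l: l.name)
    def test_losses_match_oracle(self, loss):
        assert formula_mass(loss.formula_delta) == pytest.approx(
            oracle_formula_mass(loss.formula_delta.counts), abs=1e-4
        )


class TestEnumerateCompositions:
    def test_ucucu_worked_example(self):
        comps = enumerate_compositions("UCUCU", 1, 4)
        tags = {c.tag for c in comps}
        assert tags == {"U1", "C1", "C1U1", "C1U2", "C2U1", "C2U2"}
        assert len(comps) == 6

    def test_cgcuu_worked_example(self):
        comps = enumerate_compositions("CGCUU", 1, 4)
        tags = {c.tag for c in comps}
        assert tags == {
            "C1", "G1", "U1", "C1G1", "C1U1", "U2", "C2G1", "C1G1U1",
            "C1U2", "C2G1U1", "C1G1U2",
        }
        assert len(comps) == 11

    def test_single_base(self):
        comps = enumerate_compositions("A", 1, 1)
        assert {c.tag for c in comps} == {"A1"}

    def test_case_insensitive(self):
        assert enumerate_compositions("ucu", 1, 2) == enumerate_compositions(
            "UCU", 1, 2
        )

    def test_invalid_base_names_position(self):
        with pytest.raises(ValueError, match=r"'T'.*position 3"):
            enumerate_compositions("ACTG", 1, 2)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            enumerate_compositions("", 1, 1)

    def test_bad_bounds_error(self):
        with pytest.raises(ValueError):
            enumerate_compositions("ACGU", 3, 2)
        with pytest.raises(ValueError):
            enumerate_compositions("ACGU", 1, 5)

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 31))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            max_len = int(rng.integers(1, n + 1))
            min_len = int(rng.integers(1, max_len + 1))
            got = {
                tuple(sorted("A" * c.A + "C" * c.C + "G" * c.G + "U" * c.U))
                for c in enumerate_compositions(seq, min_len, max_len)
            }
            assert got == brute_force_compositions(seq, min_len, max_len)


class TestBuildAdductSpecies:
    def test_mono_u_metabolic(self):
        sp = build_adduct_species(
            NucleotideComposition.from_tag("U"),
            LOSS_BY_NAME["none"],
            "metabolic_13C15N",
        )
        assert sp.light_mass_da == pytest.approx(324.0359, abs=1e-4)
        # 9 carbons + 2 nitrogens, via the independent oracle deltas
        assert sp.delta_mass_da == pytest.approx(
            9 * D13C + 2 * D15N, abs=1e-4
        )
        assert sp.delta_mass_da == pytest.approx(11.0243, abs=1e-4)

    def test_mono_u_hpo3_loss_keeps_delta(self):
        sp = build_adduct_species(
            NucleotideComposition.from_tag("U"),
            LOSS_BY_NAME["-HPO3"],
            "metabolic_13C15N",
        )
        assert sp.light_mass_da == pytest.approx(244.0695, abs=1e-4)
        assert sp.delta_mass_da == pytest.approx(11.0243, abs=1e-4)

    def test_dinucleotide_cu(self):
        sp = build_adduct_species(
            NucleotideComposition.from_tag("C1U1"),
            LOSS_BY_NAME["none"],
            "metabolic_13C15N",
        )
        assert sp.light_mass_da == pytest.approx(
            324.03587 + 323.05185 - 18.01056, abs=1e-4
        )
        assert sp.delta_mass_da == pytest.approx(
            18 * D13C + 5 * D15N, abs=1e-4
        )
        assert sp.delta_mass_da == pytest.approx(23.0456, abs=1e-4)

    def test_delta_equals_heavy_minus_light(self):
        for comp_tag in ["A1", "C1G1", "A1C1G1U1"]:
            for loss in DEFAULT_LOSSES:
                sp = build_adduct_species(
                    NucleotideComposition.from_tag(comp_tag),
                    loss,
                    "metabolic_13C15N",
                )
                assert sp.delta_mass_da == pytest.approx(
                    sp.heavy_mass_da - sp.light_mass_da, abs=1e-9
                )
                assert sp.delta_mass_da >= 0

    def test_scheme_none_zero_delta(self):
        for comp_tag in ["U1", "C2U2"]:
            sp = build_adduct_species(
                NucleotideComposition.from_tag(comp_tag),
                LOSS_BY_NAME["none"],
                "none",
            )
            assert sp.delta_mass_da == 0.0

    def test_phosphate_18o_delta(self):
        sp = build_adduct_species(
            NucleotideComposition.from_tag("U"),
            LOSS_BY_NAME["none"],
            "phosphate_18O",
        )
        assert sp.delta_mass_da == pytest.approx(2.00425, abs=1e-4)

    def test_phosphate_loss_removes_18o_label(self):
        sp = build_adduct_species(
            NucleotideComposition.from_tag("U"),
            LOSS_BY_NAME["-H3PO4"],
            "phosphate_18O",
        )
        assert sp.delta_mass_da == 0.0

    def test_impossible_loss_errors(self):
        from clirms.adduct_chem import LossSpec

        big = LossSpec("-2P", ElementalFormula({"P": 2}))
        with pytest.raises(ValueError, match="not subtractable"):
            build_adduct_species(
                NucleotideComposition.from_tag("U"), big, "none"
            )

    def test_terminus_5p_oh(self):
        sp = build_adduct_species(
            NucleotideComposition.from_tag("U"),
            LOSS_BY_NAME["none"],
            "none",
            terminus="5p_oh",
        )
        hpo3 = formula_mass(ElementalFormula.parse("HPO3"))
        assert sp.light_mass_da == pytest.approx(324.03587 - hpo3, abs=1e-4)

    def test_determinism(self):
        a = build_adduct_species(
            NucleotideComposition.from_tag("C1U1"),
            LOSS_BY_NAME["-H2O"],
            "metabolic_13C15N",
        )
        b = build_adduct_species(
            NucleotideComposition.from_tag("C1U1"),
            LOSS_BY_NAME["-H2O"],
            "metabolic_13C15N",
        )
        assert a.light_mass_da == b.light_mass_da
        assert a.delta_mass_da == b.delta_mass_da


class TestGroupByDelta:
    def test_ucucu_six_groups(self):
        species = enumerate_adducts(
            "UCUCU", losses=[LOSS_BY_NAME["none"]], max_len=4
        )
        groups = group_by_delta(species)
        assert len(groups) == 6

    def test_scheme_none_collapses(self):
        species = enumerate_adducts(
            "UCUCU", scheme="none", losses=[LOSS_BY_NAME["none"]]
        )
        groups = group_by_delta(species)
        assert len(groups) == 1
        assert groups[0].delta_mass_da == 0.0

    def test_partition(self):
        species = enumerate_adducts("CGCUU")
        groups = group_by_delta(species)
        member_keys = [
            (sp.composition.tag, sp.loss.name)
            for g in groups
            for sp in g.members
        ]
        assert len(member_keys) == len(species)
        assert sorted(member_keys) == sorted(
            (sp.composition.tag, sp.loss.name) for sp in species
        )

    def test_within_tolerance_same_group(self):
        species = enumerate_adducts("UCUCU", losses=[LOSS_BY_NAME["none"]])
        # huge tolerance merges everything
        groups = group_by_delta(species, tol_da=1e6)
        assert len(groups) == 1

    def test_order_independent(self, rng):
        species = enumerate_adducts("CGCUU")
        shuffled = list(species)
        rng.shuffle(shuffled)
        g1 = group_by_delta(species)
        g2 = group_by_delta(shuffled)
        assert [
            [(s.composition.tag, s.loss.name) for s in g.members]
            for g in g1
        ] == [
            [(s.composition.tag, s.loss.name) for s in g.members]
            for g in g2
        ]

    def test_deltas_ascending(self):
        groups = group_by_delta(enumerate_adducts("UGCAUGU"))
        deltas = [g.delta_mass_da for g in groups]
        assert deltas == sorted(deltas)


class TestCoveringRna:
    def test_k1(self):
        seq = generate_covering_rna(1)
        assert len(enumerate_compositions(seq, 1, 1)) == 4

    def test_k2_two_bases(self):
        seq = generate_covering_rna(2, alphabet={"A", "C"})
        tags = {c.tag for c in enumerate_compositions(seq, 1, 2)}
        assert {"A1", "C1", "A2", "A1C1", "C2"} <= tags

    def test_k4_covers_69(self):
        seq = generate_covering_rna(4)
        assert len(enumerate_compositions(seq, 1, 4)) == 69

    def test_multiset_count_formula(self):
        # C(n+k-1, k) multisets per length
        from math import comb

        assert sum(comb(4 + k - 1, k) for k in range(1, 5)) == 69

    def test_deterministic(self):
        assert generate_covering_rna(4) == generate_covering_rna(4)
        assert generate_covering_rna(3, method="greedy") == (
            generate_covering_rna(3, method="greedy")
        )

    def test_greedy_also_covers(self):
        seq = generate_covering_rna(4, method="greedy")
        assert len(enumerate_compositions(seq, 1, 4)) == 69


class TestSerialization:
    def test_adduct_table_round_trip(self, tmp_path):
        groups = group_by_delta(enumerate_adducts("UCUCU"))
        path = tmp_path / "adducts.tsv"
        write_adduct_table(groups, path)
        df = read_adduct_table(path)
        assert len(df) == sum(len(g.members) for g in groups)
        assert set(df["group_id"]) == {g.group_id for g in groups}

    def test_read_missing_column_errors(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("composition\tloss\nU1\tnone\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_adduct_table(path)
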