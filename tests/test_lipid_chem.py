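"""Nomenclature parsing and monoisotopic mass arithmetic."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidmrm.lipid_chem import (
    AcylChain,
    CapabilityError,
    LipidSpecies,
    MONOISOTOPIC,
    ParseError,
    PROTON,
    SphingoidBase,
    acyl_mass,
    base_fragment_mz,
    format_shorthand,
    parse_shorthand,
    precursor_mz,
    species_formula,
    species_mass,
)

# independent oracle: literal atomic compositions (element counts drawn from
# the structures, not from the package's formula builder)
ATOM_COUNT_ORACLE = {
    "FFA(16:0)": {"C": 16, "H": 32, "O": 2},
    "FFA(16:0)OH": {"C": 16, "H": 32, "O": 3},
    "FFA(22:6)": {"C": 22, "H": 32, "O": 2},
    "FFA(26:0)": {"C": 26, "H": 52, "O": 2},
    "FFA(2:0)": {"C": 2, "H": 4, "O": 2},
    "CerNS(d18:1/16:0)": {"C": 34, "H": 67, "N": 1, "O": 3},
    "CerNS(d18:1/24:0)": {"C": 42, "H": 83, "N": 1, "O": 3},
    "CerAS(d18:1/16:0)2OH": {"C": 34, "H": 67, "N": 1, "O": 4},
    "CerAS(d18:1/24:0)2OH": {"C": 42, "H": 83, "N": 1, "O": 4},
    "CerNP(t18:0/16:0)": {"C": 34, "H": 69, "N": 1, "O": 4},
    "CerAP(t18:0/16:0)2OH": {"C": 34, "H": 69, "N": 1, "O": 5},
    "CerDS(d18:0/10:0)": {"C": 28, "H": 57, "N": 1, "O": 3},
    "SM(d18:1/16:0)": {"C": 39, "H": 79, "N": 2, "O": 6, "P": 1},
    "SM(34:1)": {"C": 39, "H": 79, "N": 2, "O": 6, "P": 1},
    "PC(34:1)": {"C": 42, "H": 82, "N": 1, "O": 8, "P": 1},
    "PC(32:0)": {"C": 40, "H": 80, "N": 1, "O": 8, "P": 1},
    "ePC(34:1)": {"C": 42, "H": 84, "N": 1, "O": 7, "P": 1},
    "pPC(34:0)": {"C": 42, "H": 84, "N": 1, "O": 7, "P": 1},
    "PE(34:1)": {"C": 39, "H": 76, "N": 1, "O": 8, "P": 1},
    "PS(36:2)": {"C": 42, "H": 78, "N": 1, "O": 10, "P": 1},
    "PI(38:4)": {"C": 47, "H": 83, "O": 13, "P": 1},
    "AC(16:0)": {"C": 23, "H": 45, "N": 1, "O": 4},
    "CE(18:1)": {"C": 45, "H": 78, "O": 2},
}


class TestParsing:
    @pytest.mark.parametrize("name", sorted(ATOM_COUNT_ORACLE))
    def test_round_trip_canonical(self, name):
        assert format_shorthand(parse_shorthand(name)) == name

    def test_reference_panel_names_round_trip(self, reference_panel):
        """Every canonical attribution in the packaged panel re-parses to itself."""
        names = [n for cell in reference_panel["canonical"] if cell for n in cell.split("|")]
        assert names
        for name in names:
            assert format_shorthand(parse_shorthand(name)) == name

    def test_normalizes_bare_sphinganine_base(self):
        # the literature sometimes omits the 'd' prefix for sphinganine
        assert parse_shorthand("CerDS(18:0/10:0)").name == "CerDS(d18:0/10:0)"

    def test_ceramide_subfields(self):
        sp = parse_shorthand("CerAS(d18:1/16:0)2OH")
        assert sp.lipid_class == "Cer"
        assert sp.base.kind == "sphingosine"
        assert sp.chains[0] == AcylChain(16, 0, 1)

    @pytest.mark.parametrize(
        "bad",
        ["XX(9:9)", "", "PC()", "CerNS(d18:1/16:0)2OH" , "CerQS(d18:1/16:0)", "Cer(16:0)"],
    )
    def test_unparseable_names_raise(self, bad):
        with pytest.raises(ParseError):
            parse_shorthand(bad)

    def test_base_letter_must_match_base_code(self):
        with pytest.raises(ParseError):
            parse_shorthand("CerAS(t18:0/16:0)2OH")


class TestMasses:
    @pytest.mark.parametrize(
        "chain, expected",
        [(AcylChain(16, 0, 0), 256.2402), (AcylChain(24, 0, 1), 384.3603), (AcylChain(2, 0, 0), 60.0211)],
    )
    def test_acyl_mass_examples(self, chain, expected):
        assert acyl_mass(chain) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize(
        "base, expected, printed",
        [
            (SphingoidBase.sphingosine(), 264.2686, 264.3),
            (SphingoidBase.sphinganine(), 266.2842, 266.4),
            (SphingoidBase.phytosphingosine(), 282.2791, 282.4),
        ],
    )
    def test_sphingoid_fragment_keys(self, base, expected, printed):
        mz = base_fragment_mz(base).mz
        assert mz == pytest.approx(expected, abs=5e-4)
        assert abs(mz - printed) <= 0.5

    @pytest.mark.parametrize(
        "name, adduct, expected",
        [
            ("CerNS(d18:1/16:0)", "[M+H]+", 538.519),
            ("FFA(26:0)", "[M-H]-", 395.389),
            ("FFA(22:6)", "[M-H]-", 327.233),
        ],
    )
    def test_precursor_examples(self, name, adduct, expected):
        assert precursor_mz(parse_shorthand(name), adduct).mz == pytest.approx(expected, abs=1e-3)

    def test_unsupported_adduct_combinations(self):
        with pytest.raises(CapabilityError):
            precursor_mz(parse_shorthand("PC(34:1)"), "[M-H]-")
        with pytest.raises(CapabilityError):
            precursor_mz(parse_shorthand("FFA(16:0)"), "[M+H-H2O]+")

    @pytest.mark.parametrize("name", sorted(ATOM_COUNT_ORACLE))
    def test_mass_additivity_against_atom_count_oracle(self, name):
        """Brute-force atom-count summation reproduces every species mass."""
        counts = ATOM_COUNT_ORACLE[name]
        expected = sum(MONOISOTOPIC[el] * n for el, n in counts.items())
        sp = parse_shorthand(name)
        assert dict(species_formula(sp)) == counts
        assert species_mass(sp) == pytest.approx(expected, abs=1e-9)

    def test_against_rdkit_exact_masses(self):
        """Independent cross-check: exact masses from chemical structures."""
        rdkit_chem = pytest.importorskip("rdkit.Chem")
        from rdkit.Chem.Descriptors import ExactMolWt

        from lipidmrm.lipid_chem import formula_mass

        cases = {
            # palmitic acid, DHA, sphingosine
            "CCCCCCCCCCCCCCCC(=O)O": acyl_mass(AcylChain(16, 0, 0)),
            "CC/C=C\\C/C=C\\C/C=C\\C/C=C\\C/C=C\\C/C=C\\CCC(=O)O": acyl_mass(AcylChain(22, 6, 0)),
            "CCCCCCCCCCCCC/C=C/C(O)C(N)CO": formula_mass(SphingoidBase.sphingosine().formula),
        }
        for smiles, ours in cases.items():
            mol = rdkit_chem.MolFromSmiles(smiles)
            assert mol is not None
            assert ours == pytest.approx(ExactMolWt(mol), abs=2e-3)


class TestMassProperties:
    @given(
        c=st.integers(10, 34),
        d=st.integers(0, 3),
        h=st.integers(0, 1),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotonic_in_composition(self, c, d, h):
        m = acyl_mass(AcylChain(c, d, h))
        assert acyl_mass(AcylChain(c + 2, d, h)) > m
        assert acyl_mass(AcylChain(c, d + 1, h)) < m
        # one extra hydroxyl adds exactly one oxygen mass
        if h == 0:
            assert acyl_mass(AcylChain(c, d, 1)) - m == pytest.approx(
                MONOISOTOPIC["O"], abs=1e-12
            )

    @given(c=st.integers(2, 30), d=st.integers(0, 1), h=st.integers(0, 1))
    @settings(max_examples=40, deadline=None)
    def test_ceramide_round_trip_property(self, c, d, h):
        sp = LipidSpecies("Cer", (AcylChain(c, d, h),), SphingoidBase.sphingosine())
        assert parse_shorthand(sp.name) == sp

    def test_proton_adducts_are_symmetric(self):
        sp = parse_shorthand("FFA(16:0)")
        neutral = species_mass(sp)
        assert precursor_mz(sp, "[M-H]-").mz == pytest.approx(neutral - PROTON)

    def test_invalid_chains_rejected(self):
        with pytest.raises(ValueError):
            AcylChain(1, 0, 0)
        with pytest.raises(ValueError):
            AcylChain(16, 16, 0)
        with pytest.raises(ValueError):
            SphingoidBase(18, 1, 3)
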