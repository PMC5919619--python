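"""Lipid shorthand nomenclature and monoisotopic mass arithmetic.

This module is the mass backbone of the MRM-profiling pipeline: it parses
and formats lipid shorthand names (``CerAS(d18:1/16:0)2OH``, ``PC(34:1)``,
``FFA(26:0)``, ...), builds elemental formulas for acyl chains, sphingoid
bases, and whole species, and converts them to precursor and diagnostic
fragment m/z values.

Conventions
-----------
* All masses are monoisotopic; low-resolution instrument set-points are
  reconciled with exact masses downstream via a matching tolerance, never by
  switching to average masses.
* Glycerophospholipids (PC, PE, PS, PI and the ether/plasmalogen PC
  variants) are represented at the sum-composition level (total acyl
  carbons : total double bonds) because precursor/neutral-loss scans cannot
  resolve sn-positions.  Sphingolipids (Cer, SM) may carry an explicit
  sphingoid base plus one N-acyl chain; SM is also accepted at sum level.
* Ceramide sub-class letters follow the skin-lipid literature:
  first letter N (non-hydroxy) or A (alpha-hydroxy fatty acid), second
  letter S (sphingosine, d18:1), DS (sphinganine, d18:0) or
  P (phytosphingosine, t18:0).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "MONOISOTOPIC",
    "PROTON",
    "WATER",
    "AcylChain",
    "SphingoidBase",
    "LipidSpecies",
    "MzValue",
    "ParseError",
    "CapabilityError",
    "acyl_mass",
    "base_fragment_mz",
    "precursor_mz",
    "parse_shorthand",
    "format_shorthand",
    "species_mass",
    "species_formula",
    "formula_mass",
    "FRAGMENT_KEYS",
]

#: Monoisotopic atomic masses (Da).
MONOISOTOPIC = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
}

#: Proton mass used for [M+H]+ / [M-H]- adducts (Da).
PROTON = 1.00727646

#: Mass of one neutral water loss (Da).
WATER = 2 * MONOISOTOPIC["H"] + MONOISOTOPIC["O"]

#: Mass difference of one 13C isotope substitution (Da); used to flag
#: possible +1-isotope interferences in attribution.
C13_SHIFT = 1.0033548

GLYCEROPHOSPHOLIPID_CLASSES = ("PC", "ePC", "pPC", "PE", "PS", "PI")
SINGLE_CHAIN_CLASSES = ("Cer", "FFA", "AC", "CE")
CLASSES = GLYCEROPHOSPHOLIPID_CLASSES + SINGLE_CHAIN_CLASSES + ("SM",)


class ParseError(ValueError):
    """A lipid shorthand name could not be parsed."""


class CapabilityError(ValueError):
    """A class/adduct combination is outside the supported mass model."""


def formula_mass(formula: Counter) -> float:
    """Monoisotopic mass of an elemental formula given as a Counter."""
    return sum(MONOISOTOPIC[el] * n for el, n in formula.items())


def formula_to_string(formula: Counter) -> str:
    """Hill-order text form of an elemental formula (C, H, then alphabetic)."""
    order = ["C", "H"] + sorted(el for el in formula if el not in ("C", "H"))
    return "".join(f"{el}{formula[el]}" if formula[el] != 1 else el for el in order if formula.get(el))


@dataclass(frozen=True, order=True)
class AcylChain:
    """A fatty acyl chain: carbon count, double bonds, hydroxyl count.

    ``hydroxyls`` counts hydroxyl substituents on the chain (0 for the
    "N" non-hydroxy series, 1 for the "A" alpha-hydroxy series).
    """

    carbons: int
    double_bonds: int = 0
    hydroxyls: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"acyl chain needs >= 2 carbons, got {self.carbons}")
        if self.double_bonds < 0 or 2 * self.double_bonds > 2 * self.carbons - 2:
            raise ValueError(
                f"invalid double bond count {self.double_bonds} for C{self.carbons}"
            )
        if self.hydroxyls not in (0, 1, 2):
            raise ValueError(f"hydroxyl count must be 0, 1 or 2, got {self.hydroxyls}")

    @property
    def formula(self) -> Counter:
        """Elemental formula of the free fatty acid CnH(2n-2d)O(2+h)."""
        return Counter(
            {
                "C": self.carbons,
                "H": 2 * self.carbons - 2 * self.double_bonds,
                "O": 2 + self.hydroxyls,
            }
        )

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}" + "OH" * self.hydroxyls


@dataclass(frozen=True)
class SphingoidBase:
    """A sphingoid long-chain base.

    The hydroxyl count fixes the family: 2 = dihydroxy ("d", sphingosine
    when one double bond, sphinganine when none), 3 = trihydroxy
    ("t", phytosphingosine).
    """

    carbons: int = 18
    double_bonds: int = 1
    hydroxyls: int = 2

    def __post_init__(self) -> None:
        if self.hydroxyls not in (2, 3):
            raise ValueError("sphingoid bases carry 2 ('d') or 3 ('t') hydroxyls")
        if self.double_bonds not in (0, 1):
            raise ValueError("only fully saturated or mono-unsaturated bases supported")
        if self.hydroxyls == 3 and self.double_bonds != 0:
            raise ValueError("phytosphingosine ('t') bases are saturated")

    @classmethod
    def sphingosine(cls, carbons: int = 18) -> "SphingoidBase":
        return cls(carbons, 1, 2)

    @classmethod
    def sphinganine(cls, carbons: int = 18) -> "SphingoidBase":
        return cls(carbons, 0, 2)

    @classmethod
    def phytosphingosine(cls, carbons: int = 18) -> "SphingoidBase":
        return cls(carbons, 0, 3)

    @property
    def kind(self) -> str:
        if self.hydroxyls == 3:
            return "phytosphingosine"
        return "sphingosine" if self.double_bonds == 1 else "sphinganine"

    @property
    def code(self) -> str:
        prefix = "d" if self.hydroxyls == 2 else "t"
        return f"{prefix}{self.carbons}:{self.double_bonds}"

    @property
    def formula(self) -> Counter:
        # amino alcohol C_n H_(2n+3-2d) N O_h
        return Counter(
            {
                "C": self.carbons,
                "H": 2 * self.carbons + 3 - 2 * self.double_bonds,
                "N": 1,
                "O": self.hydroxyls,
            }
        )


@dataclass(frozen=True)
class MzValue:
    """A mass-to-charge value with its ionization polarity."""

    mz: float
    polarity: str = "+"

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.polarity not in ("+", "-"):
            raise ValueError("polarity must be '+' or '-'")


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species with a computable monoisotopic neutral mass.

    ``chains`` holds one acyl chain for the single-chain classes
    (Cer/FFA/AC/CE and split-form SM) and one *summed* pseudo-chain for
    glycerophospholipids and sum-form SM.
    """

    lipid_class: str
    chains: tuple
    base: Optional[SphingoidBase] = None
    #: True when an SM (or PC-family) name was given at sum-composition level.
    sum_level: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.lipid_class not in CLASSES:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        if self.lipid_class == "Cer":
            if self.base is None or len(self.chains) != 1:
                raise ValueError("a ceramide has exactly one base and one chain")
        if self.lipid_class in GLYCEROPHOSPHOLIPID_CLASSES and self.base is not None:
            raise ValueError(f"{self.lipid_class} species carry no sphingoid base")

    @property
    def name(self) -> str:
        return format_shorthand(self)

    @property
    def sum_composition(self) -> tuple:
        """(total carbons, total double bonds) over base + chains."""
        c = sum(ch.carbons for ch in self.chains)
        d = sum(ch.double_bonds for ch in self.chains)
        if self.base is not None:
            c += self.base.carbons
            d += self.base.double_bonds
        return c, d

    def __str__(self) -> str:
        return self.name


# ---------------------------------------------------------------------------
# mass arithmetic


def acyl_mass(chain: AcylChain) -> float:
    """Monoisotopic neutral mass of the free fatty acid for ``chain`` (Da)."""
    return formula_mass(chain.formula)


def base_fragment_mz(base: SphingoidBase) -> MzValue:
    """Diagnostic [base + H - 2 H2O]+ fragment of a sphingoid base.

    These are the precursor-ion scan keys: nominal m/z 264 (sphingosine),
    266 (sphinganine) and 282 (phytosphingosine).
    """
    return MzValue(formula_mass(base.formula) + PROTON - 2 * WATER, "+")


#: Class-diagnostic fragment m/z keys (positive mode unless noted).
#: Values are computed where the fragment ion formula is unambiguous and the
#: instrument set-point otherwise (arachidonate precursor scan key).
FRAGMENT_KEYS = {
    "Cer[S]": base_fragment_mz(SphingoidBase.sphingosine()).mz,
    "Cer[DS]": base_fragment_mz(SphingoidBase.sphinganine()).mz,
    "Cer[P]": base_fragment_mz(SphingoidBase.phytosphingosine()).mz,
    # phosphocholine head group C5H15NO4P+
    "PC": formula_mass(Counter({"C": 5, "H": 15, "N": 1, "O": 4, "P": 1})),
    # acylcarnitine marker C4H5O2+
    "AC": formula_mass(Counter({"C": 4, "H": 5, "O": 2})),
    # cholestadienyl cation C27H45+
    "CE": formula_mass(Counter({"C": 27, "H": 45})),
    # arachidonate acyl-residue precursor-scan set-point
    "AA": 303.1,
}

#: Neutral-loss masses (Da) of the class-diagnostic neutral-loss scans.
NEUTRAL_LOSS_KEYS = {"PE": 141.0, "PS": 185.0, "PI": 277.0, "OA": 299.0, "AA-NL": 321.0}

_PHOSPHOCHOLINE = Counter({"C": 5, "H": 14, "N": 1, "O": 4, "P": 1})  # 183.066
_CARNITINE = Counter({"C": 7, "H": 15, "N": 1, "O": 3})
_CHOLESTEROL = Counter({"C": 27, "H": 46, "O": 1})
_H2O = Counter({"H": 2, "O": 1})


def _sub(a: Counter, b: Counter) -> Counter:
    out = Counter(a)
    out.subtract(b)
    if any(v < 0 for v in out.values()):
        raise ValueError("negative element count in formula arithmetic")
    return +out


def species_formula(species: LipidSpecies) -> Counter:
    """Elemental formula of the neutral species."""
    cls = species.lipid_class
    if cls == "FFA":
        return species.chains[0].formula
    if cls == "Cer" or (cls == "SM" and species.base is not None):
        # amide condensation of base + fatty acid
        cer = _sub(species.base.formula + species.chains[0].formula, _H2O)
        if cls == "Cer":
            return cer
        return _sub(cer + _PHOSPHOCHOLINE, _H2O)
    if cls == "SM":  # sum composition, dihydroxy backbone assumed
        t, d = species.chains[0].carbons, species.chains[0].double_bonds
        return Counter({"C": t + 5, "H": 2 * t - 2 * d + 13, "N": 2, "O": 6, "P": 1})
    if cls == "AC":
        return _sub(_CARNITINE + species.chains[0].formula, _H2O)
    if cls == "CE":
        return _sub(_CHOLESTEROL + species.chains[0].formula, _H2O)
    if cls in GLYCEROPHOSPHOLIPID_CLASSES:
        t, d = species.chains[0].carbons, species.chains[0].double_bonds
        if cls in ("PC", "ePC", "pPC"):
            f = Counter({"C": t + 8, "H": 2 * t - 2 * d + 16, "N": 1, "O": 8, "P": 1})
            if cls == "ePC":  # alkyl ether: -O +H2
                f = _sub(f + Counter({"H": 2}), Counter({"O": 1}))
            elif cls == "pPC":  # 1Z-alkenyl ether (plasmalogen): -O
                f = _sub(f, Counter({"O": 1}))
            return f
        if cls == "PE":
            return Counter({"C": t + 5, "H": 2 * t - 2 * d + 10, "N": 1, "O": 8, "P": 1})
        if cls == "PS":
            return Counter({"C": t + 6, "H": 2 * t - 2 * d + 10, "N": 1, "O": 10, "P": 1})
        if cls == "PI":
            return Counter({"C": t + 9, "H": 2 * t - 2 * d + 15, "O": 13, "P": 1})
    raise CapabilityError(f"no formula model for class {cls!r}")


def species_mass(species: LipidSpecies) -> float:
    """Monoisotopic neutral mass of the species (Da)."""
    return formula_mass(species_formula(species))


_ADDUCTS = {
    "[M+H]+": (PROTON, "+"),
    "[M-H]-": (-PROTON, "-"),
    "[M+H-H2O]+": (PROTON - WATER, "+"),
}


def precursor_mz(species: LipidSpecies, adduct: str = "[M+H]+") -> MzValue:
    """Expected precursor m/z of ``species`` under the given adduct.

    ``[M+H-H2O]+`` models in-source water loss, the dominant form for
    phytosphingosine ceramides (and seen for sphinganine ceramides).
    """
    if adduct not in _ADDUCTS:
        raise CapabilityError(f"unsupported adduct {adduct!r}")
    if adduct == "[M-H]-" and species.lipid_class != "FFA":
        raise CapabilityError(f"negative mode is modeled for FFA only, not {species.lipid_class}")
    if adduct == "[M+H-H2O]+" and species.lipid_class not in ("Cer", "SM"):
        raise CapabilityError(f"in-source water loss modeled for sphingolipids only")
    delta, pol = _ADDUCTS[adduct]
    return MzValue(species_mass(species) + delta, pol)


# ---------------------------------------------------------------------------
# shorthand parsing / formatting

_CHAIN_RE = re.compile(r"^(\d+):(\d+)(OH|\(2OH\))?$")
_CER_RE = re.compile(r"^Cer(A|N)?(S|DS|P)\(([dt]?\d+:\d+)/(\d+:\d+)\)(2OH|OH)?$")
_SM_SPLIT_RE = re.compile(r"^SM\(([dt]\d+:\d+)/(\d+:\d+)(OH)?\)$")
_SUM_RE = re.compile(r"^(e|p)?(PC|PE|PS|PI|SM|CE|AC|FFA)\((\d+:\d+)\)(OH|2OH)?$")


def _parse_chain(text: str, hydroxyls: int = 0) -> AcylChain:
    m = _CHAIN_RE.match(text)
    if not m:
        raise ParseError(f"cannot parse acyl chain token {text!r}")
    h = hydroxyls + (1 if m.group(3) else 0)
    try:
        return AcylChain(int(m.group(1)), int(m.group(2)), h)
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


def _parse_base(text: str) -> SphingoidBase:
    if text[0] in "dt":
        prefix, rest = text[0], text[1:]
    else:  # the literature sometimes writes CerDS(18:0/...) without the 'd'
        prefix, rest = "d", text
    c, _, d = rest.partition(":")
    try:
        return SphingoidBase(int(c), int(d), 2 if prefix == "d" else 3)
    except ValueError as exc:
        raise ParseError(f"invalid sphingoid base {text!r}: {exc}") from exc


def parse_shorthand(name: str) -> LipidSpecies:
    """Parse a lipid shorthand name into a :class:`LipidSpecies`.

    Accepts ceramide sub-class notation (``CerAS(d18:1/16:0)2OH``),
    split- and sum-level SM, sum-level glycerophospholipids including the
    ``e-``/``p-`` ether prefixes, and the single-chain classes
    (``FFA(26:0)``, ``AC(12:1)OH``, ``CE(18:1)``).
    """
    name = name.strip()
    if not name:
        raise ParseError("empty lipid name")

    m = _CER_RE.match(name)
    if m:
        fa_letter, base_letter, base_txt, chain_txt, oh = m.groups()
        base = _parse_base(base_txt)
        expect = {"S": ("sphingosine",), "DS": ("sphinganine",), "P": ("phytosphingosine",)}
        if base.kind not in expect[base_letter]:
            raise ParseError(
                f"base code {base_txt!r} inconsistent with sub-class letter {base_letter!r}"
            )
        h = 1 if (fa_letter == "A" or oh) else 0
        if fa_letter == "N" and oh:
            raise ParseError(f"contradictory hydroxylation in {name!r}")
        chain = _parse_chain(chain_txt, hydroxyls=h)
        return LipidSpecies("Cer", (chain,), base)

    m = _SM_SPLIT_RE.match(name)
    if m:
        base = _parse_base(m.group(1))
        chain = _parse_chain(m.group(2), hydroxyls=1 if m.group(3) else 0)
        return LipidSpecies("SM", (chain,), base)

    m = _SUM_RE.match(name)
    if m:
        ether, cls, chain_txt, oh = m.groups()
        if ether:
            if cls != "PC":
                raise ParseError(f"ether prefix only supported for PC, got {name!r}")
            cls = ("ePC" if ether == "e" else "pPC")
        chain = _parse_chain(chain_txt, hydroxyls=1 if oh else 0)
        if oh and cls not in ("FFA", "AC"):
            raise ParseError(f"hydroxyl suffix not supported for class {cls!r}")
        sum_level = cls in GLYCEROPHOSPHOLIPID_CLASSES or cls == "SM"
        return LipidSpecies(cls, (chain,), None, sum_level=sum_level)

    raise ParseError(f"unparseable lipid name {name!r}")


def format_shorthand(species: LipidSpecies) -> str:
    """Canonical shorthand for a species; inverse of :func:`parse_shorthand`."""
    cls = species.lipid_class
    if cls == "Cer":
        chain = species.chains[0]
        fa_letter = "A" if chain.hydroxyls else "N"
        base_letter = {"sphingosine": "S", "sphinganine": "DS", "phytosphingosine": "P"}[
            species.base.kind
        ]
        sub = fa_letter + base_letter
        if sub == "NDS":  # the literature writes CerDS, not CerNDS
            sub = "DS"
        suffix = "2OH" if chain.hydroxyls else ""
        return (
            f"Cer{sub}({species.base.code}/"
            f"{chain.carbons}:{chain.double_bonds}){suffix}"
        )
    if cls == "SM" and species.base is not None:
        chain = species.chains[0]
        oh = "OH" if chain.hydroxyls else ""
        return f"SM({species.base.code}/{chain.carbons}:{chain.double_bonds}{oh})"
    chain = species.chains[0]
    prefix = {"ePC": "ePC", "pPC": "pPC"}.get(cls, cls)
    oh = "OH" * chain.hydroxyls if cls in ("FFA", "AC") else ""
    return f"{prefix}({chain.carbons}:{chain.double_bonds}){oh}"
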