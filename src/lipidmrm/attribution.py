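"""Transition classification and species attribution by exact-mass arithmetic.

A transition's Q3 fragment (or its Q1-Q3 neutral loss) identifies the lipid
class; candidate species of that class are then enumerated over a bounded
chain grid and kept when their expected precursor m/z matches the observed
Q1 set-point within tolerance.

Matching details that follow how unit-resolution QqQ set-point tables are
written in practice:

* Mass errors are evaluated at 0.1-Da precision (set-points are printed to
  one decimal, so a strict window would reject matches by less than the
  print quantization).
* Ceramides are enumerated under both [M+H]+ and the in-source dehydrated
  [M+H-H2O]+ adduct.  Trihydroxy (phytosphingosine) bases lose water so
  readily that their dehydrated ion is the expected form and ranks first;
  dihydroxy bases rank the protonated form first.
* PC-family searches also enumerate +1 isotopologue interferences (+1.0034);
  these are only ever reported as co-candidates, never as the top call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .lipid_chem import (
    C13_SHIFT,
    FRAGMENT_KEYS,
    NEUTRAL_LOSS_KEYS,
    WATER,
    AcylChain,
    LipidSpecies,
    MzValue,
    SphingoidBase,
    acyl_mass,
    precursor_mz,
)
from .scan_library import ScreeningMethod, TransitionDefinition

__all__ = [
    "ChainGrid",
    "Candidate",
    "AttributionResult",
    "MsmsEvidence",
    "classify_transition",
    "attribute_species",
    "attribute_method",
    "interpret_msms",
    "DEFAULT_TOLERANCE",
]

#: Default m/z matching window (Da).
DEFAULT_TOLERANCE = 0.5

#: Candidates closer than this to the top call are reported as ambiguous (Da).
AMBIGUITY_WINDOW = 0.1


@dataclass(frozen=True)
class ChainGrid:
    """Bounds of the candidate acyl-chain enumeration.

    Even carbon counts by default: fatty-acid biosynthesis proceeds in C2
    units, so odd chains are rare in mammalian tissue; sum-composition
    classes (PC/SM) allow odd totals because two chains plus variable
    sphingoid bases produce them naturally.
    """

    min_carbons: int = 2
    max_carbons: int = 36
    max_double_bonds: int = 6
    #: hydroxy fatty acyls of the skin barrier (alpha-/omega-hydroxy) are
    #: saturated or monounsaturated; polyunsaturated hydroxy chains would
    #: otherwise create spurious isobaric matches
    max_double_bonds_hydroxylated: int = 1
    max_hydroxyls: int = 1
    even_only: bool = True

    def chains(self):
        step = 2 if self.even_only else 1
        start = self.min_carbons + (self.min_carbons % 2 if self.even_only else 0)
        for c in range(start, self.max_carbons + 1, step):
            for d in range(0, self.max_double_bonds + 1):
                if 2 * d > 2 * c - 2:
                    continue
                for h in range(0, self.max_hydroxyls + 1):
                    if h and d > self.max_double_bonds_hydroxylated:
                        continue
                    yield AcylChain(c, d, h)


DEFAULT_GRID = ChainGrid()

_BASES = {
    "Cer[S]": SphingoidBase.sphingosine(),
    "Cer[DS]": SphingoidBase.sphinganine(),
    "Cer[P]": SphingoidBase.phytosphingosine(),
}


@dataclass(frozen=True)
class Candidate:
    """One candidate species for a transition."""

    species: LipidSpecies
    adduct: str
    mz: float
    mass_error: float  # computed - observed, Da
    isotope: bool = False  # +1 isotopologue interference

    @property
    def name(self) -> str:
        return self.species.name + (" (+1 isotope)" if self.isotope else "")


@dataclass
class AttributionResult:
    """Ranked candidate species for one transition."""

    transition: TransitionDefinition
    class_call: str
    candidates: list
    tolerance: float = DEFAULT_TOLERANCE

    @property
    def status(self) -> str:
        if not self.candidates:
            return "not_attributed"
        top = self.candidates[0]
        for other in self.candidates[1:]:
            if abs(other.mz - top.mz) < AMBIGUITY_WINDOW:
                return "ambiguous"
        return "attributed"

    @property
    def top(self) -> Optional[Candidate]:
        return self.candidates[0] if self.candidates else None


@dataclass
class MsmsEvidence:
    """Interpretation of a ceramide product-ion (MS/MS) spectrum.

    A ceramide MS/MS typically shows the parent, a water loss (-18), and
    the sphingoid-base fragment; the difference between the water-loss peak
    and the base peak is the fatty-acyl residue mass, matched against the
    chain grid.
    """

    parent: MzValue
    fragments: list
    water_loss_peak: Optional[float] = None
    base_peak: Optional[float] = None
    base_kind: Optional[str] = None
    fa_residue_mass: Optional[float] = None
    matched_fa: Optional[AcylChain] = None

    @property
    def complete(self) -> bool:
        return self.matched_fa is not None


def classify_transition(t: TransitionDefinition) -> str:
    """Lipid-class call for a transition from its diagnostic fragment.

    Q3 within 0.5 of a class fragment key wins; otherwise negative-mode
    Q1 == Q3 is an FFA SIM; otherwise a Q1-Q3 difference of 299 or 321
    marks an oleate/arachidonate neutral-loss feature.  ``unknown`` is a
    value, not an error.
    """
    q1, q3 = t.q1.mz, t.q3.mz
    if t.polarity == "+":
        for cls in ("Cer[S]", "Cer[DS]", "Cer[P]", "PC", "AC", "CE", "AA"):
            if abs(q3 - FRAGMENT_KEYS[cls]) <= DEFAULT_TOLERANCE:
                return cls
        for cls, loss in (("OA", NEUTRAL_LOSS_KEYS["OA"]), ("AA-NL", NEUTRAL_LOSS_KEYS["AA-NL"])):
            if abs((q1 - q3) - loss) <= DEFAULT_TOLERANCE:
                return cls
        return "unknown"
    if abs(q1 - q3) <= 1e-6:
        return "FFA"
    return "unknown"


def _quantized_error(computed: float, observed: float) -> float:
    """|mass error| rounded to the 0.1-Da print precision of set-points."""
    return round(abs(computed - observed), 1)


def _enumerate(class_call: str, grid: ChainGrid):
    """Yield (species, adduct, preference, isotope) for a class call."""
    if class_call in _BASES:
        base = _BASES[class_call]
        preferred_dehydrated = base.hydroxyls == 3
        # amide-linked fatty acids of tissue ceramides are saturated or
        # monounsaturated; allowing polyunsaturation here would admit
        # isobaric nonsense (e.g. an 18:6 N-acyl)
        cer_grid = replace(grid, max_double_bonds=min(grid.max_double_bonds, 1))
        for chain in cer_grid.chains():
            sp = LipidSpecies("Cer", (chain,), base)
            yield sp, "[M+H]+", (1 if preferred_dehydrated else 0), False
            yield sp, "[M+H-H2O]+", (0 if preferred_dehydrated else 1), False
    elif class_call == "PC":
        # diacyl PC and sum-level SM over all integer totals; ether and
        # plasmalogen PC over even totals (even alkyl + even acyl)
        for t in range(20, 49):
            for d in range(0, 7):
                pc = LipidSpecies("PC", (AcylChain(t, d),), sum_level=True)
                yield pc, "[M+H]+", 0, False
                yield pc, "[M+H]+", 2, True
                if t % 2 == 0:
                    for cls in ("ePC", "pPC"):
                        sp = LipidSpecies(cls, (AcylChain(t, d),), sum_level=True)
                        yield sp, "[M+H]+", 0, False
                        yield sp, "[M+H]+", 2, True
        for t in range(26, 49):
            for d in range(0, 7):
                sm = LipidSpecies("SM", (AcylChain(t, d),), sum_level=True)
                yield sm, "[M+H]+", 0, False
                yield sm, "[M+H]+", 2, True
    elif class_call == "AC":
        for chain in grid.chains():
            yield LipidSpecies("AC", (chain,)), "[M+H]+", 0, False
    elif class_call == "CE":
        for chain in grid.chains():
            if chain.hydroxyls == 0:
                yield LipidSpecies("CE", (chain,)), "[M+H]+", 0, False
    elif class_call == "FFA":
        for chain in grid.chains():
            yield LipidSpecies("FFA", (chain,)), "[M-H]-", 0, False
    # OA / AA-NL / AA / unknown: acyl-residue scans name no enumerable
    # species class; they stay not_attributed


def attribute_species(
    t: TransitionDefinition,
    class_call: Optional[str] = None,
    tolerance: float = DEFAULT_TOLERANCE,
    grid: ChainGrid = DEFAULT_GRID,
) -> AttributionResult:
    """Rank candidate species for a transition by absolute mass error.

    Candidates with quantized |error| <= ``tolerance`` are kept and sorted
    by (isotope flag, quantized error, adduct preference, raw error, double
    bonds, hydroxyls, name); an empty set yields status ``not_attributed``.
    """
    if class_call is None:
        class_call = classify_transition(t)
    observed = t.q1.mz
    candidates = []
    for species, adduct, pref, isotope in _enumerate(class_call, grid):
        mz = precursor_mz(species, adduct).mz + (C13_SHIFT if isotope else 0.0)
        if _quantized_error(mz, observed) <= tolerance + 1e-9:
            candidates.append(
                (
                    (
                        isotope,
                        _quantized_error(mz, observed),
                        pref,
                        abs(mz - observed),
                        species.chains[0].double_bonds,
                        species.chains[0].hydroxyls,
                        species.name,
                    ),
                    Candidate(species, adduct, mz, mz - observed, isotope),
                )
            )
    candidates.sort(key=lambda pair: pair[0])
    return AttributionResult(t, class_call, [c for _, c in candidates], tolerance)


def attribute_method(
    method: ScreeningMethod,
    tolerance: float = DEFAULT_TOLERANCE,
    grid: ChainGrid = DEFAULT_GRID,
) -> dict:
    """Attribute every transition of a method; keys are transition ids."""
    return {
        t.transition: attribute_species(t, tolerance=tolerance, grid=grid)
        for t in method.transitions
    }


def species_table(grid: ChainGrid = DEFAULT_GRID) -> "pd.DataFrame":
    """The packaged candidate-species table used in place of database lookups.

    One row per enumerable species: canonical name, class, elemental
    formula, and neutral monoisotopic mass.  Regenerable from the CLI.
    """
    import pandas as pd

    from .lipid_chem import formula_to_string, species_formula, species_mass

    rows, seen = [], set()
    for cls in ("Cer[S]", "Cer[DS]", "Cer[P]", "PC", "AC", "CE", "FFA"):
        for species, _adduct, _pref, isotope in _enumerate(cls, grid):
            if isotope or species.name in seen:
                continue
            seen.add(species.name)
            rows.append(
                {
                    "name": species.name,
                    "class": species.lipid_class,
                    "formula": formula_to_string(species_formula(species)),
                    "monoisotopic_mass": round(species_mass(species), 4),
                }
            )
    return pd.DataFrame(rows).sort_values(["class", "monoisotopic_mass"]).reset_index(drop=True)


def interpret_msms(
    parent: MzValue,
    fragments: Sequence[float],
    tolerance: float = DEFAULT_TOLERANCE,
    grid: ChainGrid = DEFAULT_GRID,
) -> MsmsEvidence:
    """Read a ceramide product-ion spectrum the way an analyst does.

    Finds the water-loss peak (parent - 18.011), the sphingoid-base
    fragment, takes their difference as the fatty-acyl residue mass, and
    matches it against the chain grid.  Missing peaks leave the
    corresponding fields ``None`` rather than raising.
    """
    fragments = [f.mz if isinstance(f, MzValue) else float(f) for f in fragments]
    if not fragments:
        raise ValueError("empty fragment list")
    evidence = MsmsEvidence(parent, fragments)

    expected_loss = parent.mz - WATER
    losses = [f for f in fragments if abs(f - expected_loss) <= tolerance]
    if losses:
        evidence.water_loss_peak = min(losses, key=lambda f: abs(f - expected_loss))

    base_hits = []
    for cls, base in _BASES.items():
        key = FRAGMENT_KEYS[cls]
        for f in fragments:
            if abs(f - key) <= tolerance:
                base_hits.append((abs(f - key), f, base.kind))
    if base_hits:
        _, evidence.base_peak, evidence.base_kind = min(base_hits)

    if evidence.water_loss_peak is not None and evidence.base_peak is not None:
        evidence.fa_residue_mass = evidence.water_loss_peak - evidence.base_peak
        # ceramide N-acyl residues: saturated or monounsaturated only
        fa_grid = replace(grid, max_double_bonds=min(grid.max_double_bonds, 1))
        matches = [
            (abs(acyl_mass(ch) - evidence.fa_residue_mass), ch)
            for ch in fa_grid.chains()
            if abs(acyl_mass(ch) - evidence.fa_residue_mass) <= tolerance
        ]
        if matches:
            evidence.matched_fa = min(matches)[1]
    return evidence
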