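"""Discovery scans and targeted screening methods.

Discovery in MRM-profiling runs class-supervised scans on a triple
quadrupole: precursor-ion (Prec) scans with Q3 parked on a class-diagnostic
fragment, neutral-loss (NL) scans with a fixed Q1-Q3 offset, and single-ion
monitoring (SIM, Q1 == Q3) for ions such as deprotonated free fatty acids
that do not fragment informatively.  Features detected there are assembled
into two fast flow-injection screening methods, one per polarity, with a
class-specific collision-energy map.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .lipid_chem import FRAGMENT_KEYS, NEUTRAL_LOSS_KEYS, MzValue

__all__ = [
    "ScanDefinition",
    "TransitionDefinition",
    "ScreeningMethod",
    "build_discovery_scans",
    "detect_features",
    "collision_energy_for",
    "assemble_screening_methods",
    "read_method",
    "write_method",
    "synthetic_screening_methods",
    "FRAGMENTOR_V",
]

#: Fragmentor voltage shared by both screening methods (V).
FRAGMENTOR_V = 100.0

#: Collision energy (V) per lipid class in positive mode.
_CE_POSITIVE = {
    "Cer": 22.0,
    "Cer[S]": 22.0,
    "Cer[DS]": 22.0,
    "Cer[P]": 22.0,
    "PE": 22.0,
    "AA": 22.0,
    "AA-NL": 22.0,
    "OA": 22.0,
    "PC": 20.0,
    "SM": 20.0,
    "PS": 16.0,
    "PI": 16.0,
    "CE": 17.0,
    "AC": 30.0,
}

#: Collision energy (V) in negative mode (SIM of deprotonated FFAs).
_CE_NEGATIVE = 2.0


@dataclass(frozen=True)
class ScanDefinition:
    """One discovery scan: mode, diagnostic key, polarity and Q1 range."""

    mode: str  # precursor_ion | neutral_loss | single_ion | mrm
    key_mz: float  # fragment m/z (Prec), neutral-loss mass (NL); 0 for SIM
    polarity: str
    target_class: str
    q1_range: tuple = (200.0, 1000.0)

    def __post_init__(self) -> None:
        if self.mode not in ("precursor_ion", "neutral_loss", "single_ion", "mrm"):
            raise ValueError(f"unknown scan mode {self.mode!r}")
        if self.mode != "single_ion" and self.key_mz <= 0:
            raise ValueError("scan key must be positive")
        if not self.q1_range[0] < self.q1_range[1]:
            raise ValueError("q1_range must be (low, high) with low < high")


@dataclass(frozen=True)
class TransitionDefinition:
    """One Q1 -> Q3 ion pair with acquisition parameters."""

    q1: MzValue
    q3: MzValue
    collision_energy: float = 0.0
    fragmentor: float = FRAGMENTOR_V
    class_hint: str = "unknown"

    def __post_init__(self) -> None:
        if self.q1.polarity != self.q3.polarity:
            raise ValueError("Q1 and Q3 polarities differ")
        if self.collision_energy < 0:
            raise ValueError("collision energy must be >= 0")
        if self.polarity == "-" and abs(self.q1.mz - self.q3.mz) > 1e-6:
            raise ValueError("negative-mode FFA SIM requires q1 == q3")

    @property
    def polarity(self) -> str:
        return self.q1.polarity

    @property
    def transition(self) -> str:
        return f"{self.q1.mz:g}->{self.q3.mz:g}"


@dataclass(frozen=True)
class ScreeningMethod:
    """An ordered, polarity-pure set of transitions acquired per injection."""

    polarity: str
    transitions: tuple
    acquisition_time: float = 2.0  # minutes

    def __post_init__(self) -> None:
        pairs = set()
        for t in self.transitions:
            if t.polarity != self.polarity:
                raise ValueError("transition polarity differs from method polarity")
            key = (round(t.q1.mz, 1), round(t.q3.mz, 1))
            if key in pairs:
                raise ValueError(f"duplicate transition {key}")
            pairs.add(key)

    def __len__(self) -> int:
        return len(self.transitions)

    @property
    def transition_ids(self) -> tuple:
        return tuple(t.transition for t in self.transitions)

    @property
    def content_hash(self) -> str:
        text = self.polarity + ";".join(self.transition_ids)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def build_discovery_scans() -> list:
    """The full discovery panel used to profile epidermal lipid classes.

    Positive mode: Prec 184 (PC/SM head group), NL 141/185/277 (PE/PS/PI),
    Prec at the three sphingoid-base fragments (ceramides by base), Prec 85
    (acylcarnitines), Prec at the cholestadienyl cation (CE), NL 299/321 and
    Prec 303.1 (oleate/arachidonate acyl residues).  Negative mode: FFA SIM
    over m/z 199-600.
    """
    pos = (200.0, 1000.0)
    scans = [
        ScanDefinition("precursor_ion", FRAGMENT_KEYS["PC"], "+", "PC", pos),
        ScanDefinition("neutral_loss", NEUTRAL_LOSS_KEYS["PE"], "+", "PE", pos),
        ScanDefinition("neutral_loss", NEUTRAL_LOSS_KEYS["PS"], "+", "PS", pos),
        ScanDefinition("neutral_loss", NEUTRAL_LOSS_KEYS["PI"], "+", "PI", pos),
        ScanDefinition("precursor_ion", FRAGMENT_KEYS["Cer[S]"], "+", "Cer[S]", pos),
        ScanDefinition("precursor_ion", FRAGMENT_KEYS["Cer[DS]"], "+", "Cer[DS]", pos),
        ScanDefinition("precursor_ion", FRAGMENT_KEYS["Cer[P]"], "+", "Cer[P]", pos),
        ScanDefinition("precursor_ion", FRAGMENT_KEYS["AC"], "+", "AC", pos),
        ScanDefinition("precursor_ion", FRAGMENT_KEYS["CE"], "+", "CE", pos),
        ScanDefinition("neutral_loss", NEUTRAL_LOSS_KEYS["OA"], "+", "OA", pos),
        ScanDefinition("neutral_loss", NEUTRAL_LOSS_KEYS["AA-NL"], "+", "AA-NL", pos),
        ScanDefinition("precursor_ion", FRAGMENT_KEYS["AA"], "+", "AA", pos),
        ScanDefinition("single_ion", 0.0, "-", "FFA", (199.0, 600.0)),
    ]
    return scans


def detect_features(
    scan_profile,
    scan: ScanDefinition,
    min_rel_intensity: float = 0.01,
) -> list:
    """Pick local maxima of a discovery-scan Q1 profile as transitions.

    ``scan_profile`` is a (m/z, intensity) pair of 1-D arrays.  Peaks above
    ``min_rel_intensity`` x base peak become transitions whose Q3 follows the
    scan mode: the fragment key for Prec scans, Q1 minus the loss for NL
    scans, and Q1 itself for SIM.
    """
    mz, intensity = (np.asarray(a, dtype=float) for a in scan_profile)
    if mz.size == 0 or intensity.size == 0:
        raise ValueError("empty discovery spectrum")
    if not 0 < min_rel_intensity < 1:
        raise ValueError("min_rel_intensity must be in (0, 1)")
    base = intensity.max()
    if base <= 0:
        raise ValueError("discovery spectrum has no signal")
    order = np.argsort(mz)
    mz, intensity = mz[order], intensity[order]
    padded = np.concatenate([[-np.inf], intensity, [-np.inf]])
    is_peak = (padded[1:-1] >= padded[:-2]) & (padded[1:-1] > padded[2:])
    keep = is_peak & (intensity >= min_rel_intensity * base)
    keep &= (mz >= scan.q1_range[0]) & (mz <= scan.q1_range[1])

    out = []
    for q1 in mz[keep]:
        if scan.mode == "precursor_ion":
            q3 = scan.key_mz
        elif scan.mode == "neutral_loss":
            q3 = q1 - scan.key_mz
        else:
            q3 = q1
        out.append(
            TransitionDefinition(
                MzValue(q1, scan.polarity),
                MzValue(q3, scan.polarity),
                collision_energy=collision_energy_for(scan.target_class, scan.polarity),
                class_hint=scan.target_class,
            )
        )
    return out


def collision_energy_for(class_hint: str, polarity: str) -> float:
    """Collision energy (V) for a lipid class; 2 V for all of negative mode."""
    if polarity == "-":
        return _CE_NEGATIVE
    try:
        return _CE_POSITIVE[class_hint]
    except KeyError:
        raise KeyError(
            f"no collision energy mapped for class {class_hint!r} in positive mode"
        ) from None


def assemble_screening_methods(
    transitions: Iterable[TransitionDefinition],
    acquisition_time: float = 2.0,
) -> tuple:
    """Split transitions by polarity into the two screening methods.

    Duplicates (same Q1/Q3 to one decimal) are removed keeping the first
    occurrence; collision energies are filled from the class map where unset.
    Returns ``(positive_method, negative_method)``; an empty polarity yields
    a method with no transitions.
    """
    buckets = {"+": [], "-": []}
    seen = {"+": set(), "-": set()}
    for t in transitions:
        key = (round(t.q1.mz, 1), round(t.q3.mz, 1))
        if key in seen[t.polarity]:
            continue
        seen[t.polarity].add(key)
        if t.collision_energy == 0.0 and t.class_hint != "unknown":
            t = replace(t, collision_energy=collision_energy_for(t.class_hint, t.polarity))
        buckets[t.polarity].append(t)
    methods = []
    for pol in "+-":
        ordered = tuple(sorted(buckets[pol], key=lambda t: (t.q1.mz, t.q3.mz)))
        methods.append(ScreeningMethod(pol, ordered, acquisition_time))
    return tuple(methods)


# ---------------------------------------------------------------------------
# method TSV interface


def write_method(method: ScreeningMethod, path) -> None:
    """Write a screening method as TSV (q1, q3, polarity, CE, fragmentor, class)."""
    rows = [
        {
            "q1": t.q1.mz,
            "q3": t.q3.mz,
            "polarity": t.polarity,
            "collision_energy": t.collision_energy,
            "fragmentor": t.fragmentor,
            "class_hint": t.class_hint,
        }
        for t in method.transitions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_method(path) -> ScreeningMethod:
    """Read a screening-method TSV written by :func:`write_method`."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # propagate with context for pipeline staging
        raise ValueError(f"cannot read method file {path}: {exc}") from exc
    required = {"q1", "q3", "polarity"}
    if not required.issubset(df.columns):
        raise ValueError(f"method file {path} lacks columns {sorted(required - set(df.columns))}")
    transitions = []
    for row in df.itertuples(index=False):
        transitions.append(
            TransitionDefinition(
                MzValue(float(row.q1), row.polarity),
                MzValue(float(row.q3), row.polarity),
                collision_energy=float(getattr(row, "collision_energy", 0.0)),
                fragmentor=float(getattr(row, "fragmentor", FRAGMENTOR_V)),
                class_hint=str(getattr(row, "class_hint", "unknown")),
            )
        )
    polarities = {t.polarity for t in transitions}
    if len(polarities) != 1:
        raise ValueError("a method file must be polarity-pure")
    return ScreeningMethod(polarities.pop(), tuple(transitions))


# ---------------------------------------------------------------------------
# synthetic default methods


def _mrm(q1: float, q3: float, pol: str, hint: str) -> TransitionDefinition:
    return TransitionDefinition(
        MzValue(round(q1, 1), pol),
        MzValue(round(q3, 1), pol),
        collision_energy=collision_energy_for(hint, pol),
        class_hint=hint,
    )


def synthetic_screening_methods() -> tuple:
    """Synthetic reconstruction of the two published screening methods.

    The original transition lists live in supplementary tables that are not
    redistributed with this package.  This builds a stand-in panel from the
    discovery-scan design over realistic chain grids, sized to the published
    method lengths (217 transitions in positive mode, 83 in negative mode)
    and guaranteed to contain every transition of the packaged
    discriminative panel.  It exists so the pipeline can run end to end
    without instrument data; it is NOT the published method.
    """
    from .lipid_chem import (
        AcylChain,
        LipidSpecies,
        SphingoidBase,
        precursor_mz,
    )
    from .reference import discriminative_transitions

    pos, neg = [], []

    # negative mode: FFA SIM, even chains 12-36, 0-6 double bonds, +-OH
    for c in range(12, 37, 2):
        for d in range(0, 7):
            for h in (0, 1):
                if 2 * d > 2 * c - 2:
                    continue
                sp = LipidSpecies("FFA", (AcylChain(c, d, h),))
                mz = precursor_mz(sp, "[M-H]-").mz
                if 199 <= mz <= 600:
                    neg.append(_mrm(mz, mz, "-", "FFA"))

    # positive mode: ceramides by base over even N-acyl chains
    bases = {
        "Cer[S]": SphingoidBase.sphingosine(),
        "Cer[DS]": SphingoidBase.sphinganine(),
        "Cer[P]": SphingoidBase.phytosphingosine(),
    }
    from .lipid_chem import base_fragment_mz

    for hint, base in bases.items():
        q3 = base_fragment_mz(base).mz
        adduct = "[M+H-H2O]+" if base.hydroxyls == 3 else "[M+H]+"
        for c in range(14, 29, 2):
            for d in (0, 1):
                for h in (0, 1):
                    sp = LipidSpecies("Cer", (AcylChain(c, d, h),), base)
                    pos.append(_mrm(precursor_mz(sp, adduct).mz, q3, "+", hint))

    # PC / SM family via Prec 184
    for t in range(28, 43, 2):
        for d in (0, 1, 2):
            pc = LipidSpecies("PC", (AcylChain(t, d),), sum_level=True)
            pos.append(_mrm(precursor_mz(pc).mz, FRAGMENT_KEYS["PC"], "+", "PC"))
    for t in range(30, 43, 2):
        for d in (0, 1):
            sm = LipidSpecies("SM", (AcylChain(t, d),), sum_level=True)
            pos.append(_mrm(precursor_mz(sm).mz, FRAGMENT_KEYS["PC"], "+", "SM"))

    # acylcarnitines via Prec 85
    for c in range(10, 27, 2):
        for d in (0, 1):
            ac = LipidSpecies("AC", (AcylChain(c, d),))
            pos.append(_mrm(precursor_mz(ac).mz, FRAGMENT_KEYS["AC"], "+", "AC"))

    # cholesterol esters via Prec 369
    for c in range(14, 25, 2):
        for d in (0, 1, 2):
            ce = LipidSpecies("CE", (AcylChain(c, d),))
            pos.append(_mrm(precursor_mz(ce).mz, FRAGMENT_KEYS["CE"], "+", "CE"))

    # oleate / arachidonate acyl-residue NL features over a PL-like Q1 grid
    for q1 in np.arange(620.5, 790.0, 14.0):
        pos.append(_mrm(q1, q1 - NEUTRAL_LOSS_KEYS["OA"], "+", "OA"))
        pos.append(_mrm(q1 + 6.2, q1 + 6.2 - NEUTRAL_LOSS_KEYS["AA-NL"], "+", "AA-NL"))

    # the discriminative panel itself must be present, listed first so the
    # de-duplication pass keeps the printed set-points over grid values
    ref = discriminative_transitions()
    hint_by_scan = {"Ceramide": "Cer", "PC": "PC", "Acylcarnitine": "AC", "NL AA": "AA-NL", "FFA": "FFA"}
    ref_pos, ref_neg = [], []
    for row in ref.itertuples(index=False):
        t = TransitionDefinition(
            MzValue(float(row.q1), row.polarity),
            MzValue(float(row.q3), row.polarity),
            collision_energy=collision_energy_for(hint_by_scan[row.scan], row.polarity),
            class_hint=hint_by_scan[row.scan],
        )
        (ref_pos if row.polarity == "+" else ref_neg).append(t)

    method_pos, method_neg = assemble_screening_methods(ref_pos + pos + ref_neg + neg)

    def _trim(method: ScreeningMethod, reference, target: int) -> ScreeningMethod:
        ref_keys = {(round(t.q1.mz, 1), round(t.q3.mz, 1)) for t in reference}
        keep = [t for t in method.transitions if (round(t.q1.mz, 1), round(t.q3.mz, 1)) in ref_keys]
        rest = [t for t in method.transitions if t not in keep]
        if len(keep) + len(rest) < target:
            raise RuntimeError("synthetic grid smaller than published method size")
        keep += rest[: target - len(keep)]
        return ScreeningMethod(
            method.polarity, tuple(sorted(keep, key=lambda t: (t.q1.mz, t.q3.mz)))
        )

    return (_trim(method_pos, ref_pos, 217), _trim(method_neg, ref_neg, 83))
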