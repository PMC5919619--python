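"""Read acquisitions, integrate transitions, and build the feature matrix.

Per-transition intensity is the trapezoidal integral of the chronogram over
the whole acquisition window (flow injection gives one burst per transition;
the integral is robust to peak shape).  Each sample is then normalized by
the total ion intensity of all transitions in its method, yielding relative
amounts that sum to one — the scale on which all downstream statistics run.
Positive- and negative-mode methods are normalized separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .scan_library import ScreeningMethod

__all__ = [
    "SampleProfile",
    "FeatureMatrix",
    "read_acquisition",
    "tic_normalize",
    "assemble_matrix",
    "MZ_MATCH_TOLERANCE",
]

#: m/z window for matching file transitions to method transitions (Da),
#: mirroring the attribution tolerance.
MZ_MATCH_TOLERANCE = 0.5


@dataclass
class SampleProfile:
    """TIC-normalized per-transition relative intensities of one sample."""

    sample_id: str
    intensities: pd.Series  # index transition ids; sums to 1
    group: str = "unknown"  # WT | cpdm | unknown
    split: str = "unknown"  # testing | validation | unknown
    polarity: str = "+"
    method_hash: Optional[str] = None

    def __post_init__(self) -> None:
        total = float(self.intensities.sum())
        if (self.intensities < 0).any():
            raise ValueError(f"negative relative intensity in sample {self.sample_id}")
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(
                f"relative intensities of {self.sample_id} sum to {total}, expected 1"
            )


@dataclass
class FeatureMatrix:
    """Samples x transitions of relative intensities with labels."""

    X: pd.DataFrame  # index sample ids (sorted), columns transition ids
    groups: pd.Series
    splits: pd.Series
    polarity: str = "+"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing cells")

    def subset(self, split: str) -> "FeatureMatrix":
        mask = self.splits == split
        return FeatureMatrix(
            self.X.loc[mask], self.groups.loc[mask], self.splits.loc[mask],
            self.polarity, dict(self.provenance),
        )

    @property
    def transitions(self) -> list:
        return list(self.X.columns)


def _match_transition(q1: float, q3: float, method: ScreeningMethod) -> str:
    """Nearest method transition within the window on both quadrupoles."""
    best, best_dist = None, np.inf
    for t in method.transitions:
        d1, d3 = abs(t.q1.mz - q1), abs(t.q3.mz - q3)
        if d1 <= MZ_MATCH_TOLERANCE and d3 <= MZ_MATCH_TOLERANCE and d1 + d3 < best_dist:
            best, best_dist = t, d1 + d3
    if best is None:
        raise KeyError(
            f"transition {q1:g}->{q3:g} matches nothing in the {method.polarity} method "
            f"within {MZ_MATCH_TOLERANCE} m/z"
        )
    return best.transition


def _integrate_long(df: pd.DataFrame, method: ScreeningMethod) -> pd.DataFrame:
    """Integrate a long chronogram table to one row per (sample, transition)."""
    rows = []
    for (sample_id, q1, q3), chunk in df.groupby(["sample_id", "q1", "q3"], sort=True):
        chunk = chunk.sort_values("time_min")
        value = float(np.trapezoid(chunk["intensity"].to_numpy(), chunk["time_min"].to_numpy()))
        rows.append(
            {
                "sample_id": sample_id,
                "transition": _match_transition(float(q1), float(q3), method),
                "intensity": value,
                "group": chunk["group"].iloc[0] if "group" in chunk else "unknown",
                "split": chunk["split"].iloc[0] if "split" in chunk else "unknown",
            }
        )
    return pd.DataFrame(rows)


def _decode_binary_array(array_el, ns: str) -> np.ndarray:
    import base64
    import zlib

    accessions = {p.get("accession") for p in array_el.findall(f"{ns}cvParam")}
    binary = array_el.find(f"{ns}binary")
    raw = base64.b64decode((binary.text or "").encode("ascii"))
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f8" if "MS:1000523" in accessions else "<f4"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path, method: ScreeningMethod) -> pd.DataFrame:
    """Integrate the SRM chromatograms of one mzML file.

    Chromatogram-level mzML (time/intensity binary arrays with precursor
    and product isolation windows) is parsed directly with lxml.
    """
    from lxml import etree

    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"corrupt mzML file {path}: {exc}") from exc
    root = tree.getroot()
    ns = f"{{{root.nsmap.get(None, '')}}}" if root.nsmap.get(None) else ""

    def _target_mz(chrom, kind):
        window = chrom.find(f"{ns}{kind}/{ns}isolationWindow")
        if window is None:
            return None
        for p in window.findall(f"{ns}cvParam"):
            if p.get("accession") == "MS:1000827":  # isolation window target m/z
                return float(p.get("value"))
        return None

    rows = []
    for chrom in root.iter(f"{ns}chromatogram"):
        q1, q3 = _target_mz(chrom, "precursor"), _target_mz(chrom, "product")
        if q1 is None or q3 is None:
            continue  # e.g. a TIC chromatogram
        arrays = {}
        for array_el in chrom.findall(f"{ns}binaryDataArrayList/{ns}binaryDataArray"):
            accs = {p.get("accession") for p in array_el.findall(f"{ns}cvParam")}
            if "MS:1000595" in accs:
                arrays["time"] = _decode_binary_array(array_el, ns)
            elif "MS:1000515" in accs:
                arrays["intensity"] = _decode_binary_array(array_el, ns)
        if "time" not in arrays or "intensity" not in arrays:
            raise ValueError(f"chromatogram in {path} lacks time or intensity array")
        order = np.argsort(arrays["time"])
        value = float(np.trapezoid(arrays["intensity"][order], arrays["time"][order]))
        rows.append(
            {
                "sample_id": path.stem,
                "transition": _match_transition(q1, q3, method),
                "intensity": value,
                "group": "unknown",
                "split": "unknown",
            }
        )
    if not rows:
        raise ValueError(f"no SRM chromatograms found in {path}")
    return pd.DataFrame(rows)


def read_acquisition(path, method: ScreeningMethod, fmt: str = "csv") -> pd.DataFrame:
    """Read one acquisition into per-transition scalar intensities.

    Formats:

    ``csv``
        Either the scalar dialect (columns ``sample_id, q1, q3, intensity``
        and optionally ``group, split``) which passes through, or the long
        chronogram dialect (extra ``time_min`` column) which is integrated
        trapezoidally per transition.
    ``mzml``
        An SRM-chromatogram mzML file for a single sample (sample id =
        file stem); chromatograms are integrated over the whole window.

    Every (q1, q3) in the file must match a method transition within
    +-0.5 m/z on both quadrupoles; an orphan raises a KeyError naming it.
    Returns a long DataFrame with columns
    ``sample_id, transition, intensity, group, split``.
    """
    if fmt == "mzml":
        return _read_mzml(path, method)
    if fmt != "csv":
        raise ValueError(f"unknown acquisition format {fmt!r}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"cannot read acquisition file {path}: {exc}") from exc
    needed = {"sample_id", "q1", "q3", "intensity"}
    if not needed.issubset(df.columns):
        raise ValueError(f"acquisition CSV lacks columns {sorted(needed - set(df.columns))}")
    if "time_min" in df.columns:
        return _integrate_long(df, method)
    out = df.copy()
    out["transition"] = [
        _match_transition(float(a), float(b), method) for a, b in zip(df["q1"], df["q3"])
    ]
    for col in ("group", "split"):
        if col not in out.columns:
            out[col] = "unknown"
    return out[["sample_id", "transition", "intensity", "group", "split"]]


def tic_normalize(
    raw: Mapping[str, float] | pd.Series,
    sample_id: str = "sample",
    group: str = "unknown",
    split: str = "unknown",
    polarity: str = "+",
    method_hash: Optional[str] = None,
) -> SampleProfile:
    """Divide each transition by the sample's summed intensity over the method.

    Output is scale-invariant and sums to one; an all-zero sample is
    rejected (there is no meaningful relative profile for it).
    """
    series = pd.Series(raw, dtype=float)
    if (series < 0).any():
        raise ValueError(f"negative raw intensity in sample {sample_id}")
    total = float(series.sum())
    if total <= 0:
        raise ValueError(f"sample {sample_id} has zero total ion intensity")
    return SampleProfile(sample_id, series / total, group, split, polarity, method_hash)


def profiles_from_table(table, method: ScreeningMethod) -> list:
    """TIC-normalize every sample of a raw intensity table (generator output)."""
    out = []
    for sample_id, row in table.intensities.iterrows():
        meta = table.samples.loc[sample_id]
        out.append(
            tic_normalize(
                row,
                sample_id=sample_id,
                group=meta["group"],
                split=meta["split"],
                polarity=table.polarity,
                method_hash=method.content_hash,
            )
        )
    return out


def assemble_matrix(profiles: Sequence[SampleProfile]) -> FeatureMatrix:
    """Stack sample profiles into a dense labeled feature matrix.

    All profiles must come from the same method (identical transition sets
    and method hash); a transition missing from any profile is an error
    because targeted screening produces complete rows, not sparse ones.
    Rows are sorted by sample id for deterministic output.
    """
    if not profiles:
        raise ValueError("no profiles to assemble")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")
    hashes = {p.method_hash for p in profiles}
    if len(hashes) > 1:
        raise ValueError(f"profiles come from different methods: {sorted(map(str, hashes))}")
    columns = list(profiles[0].intensities.index)
    for p in profiles[1:]:
        missing = set(columns).symmetric_difference(p.intensities.index)
        if missing:
            raise ValueError(
                f"sample {p.sample_id} does not cover the method transitions: {sorted(missing)}"
            )
    X = pd.DataFrame(
        {p.sample_id: p.intensities.reindex(columns) for p in profiles}
    ).T.sort_index()
    X.index.name = "sample_id"
    groups = pd.Series({p.sample_id: p.group for p in profiles}, name="group").loc[X.index]
    splits = pd.Series({p.sample_id: p.split for p in profiles}, name="split").loc[X.index]
    polarity = profiles[0].polarity
    return FeatureMatrix(
        X, groups, splits, polarity,
        provenance={"method_hash": profiles[0].method_hash, "n_samples": len(profiles)},
    )
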