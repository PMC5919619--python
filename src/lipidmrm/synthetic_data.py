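"""Synthetic inputs for the MRM-profiling pipeline.

Real acquisitions from the mouse-epidermis study are not redistributed;
this module generates every input the pipeline needs instead:

* two-group (WT vs *cpdm*) per-transition intensity cohorts with known
  fold changes, log-normal within-group noise, and per-sample total-ion
  scale factors;
* flow-injection chronograms (tabular or minimal SRM-chromatogram mzML)
  whose integrals recover the generated intensities;
* a spiked calibration series;
* LC-MS quantification tables (peak areas, internal-standard areas, dry
  weights) and qPCR Ct tables.

Effects are specified on the *normalized* (relative-abundance) scale,
because published fold changes are computed after total-ion normalization;
raw intensities are obtained by multiplying back a random per-sample TIC
factor, which cancels exactly under TIC normalization downstream.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .reference import default_effects
from .scan_library import ScreeningMethod

__all__ = [
    "CohortConfig",
    "RawIntensityTable",
    "generate_cohort",
    "render_chronograms",
    "write_mzml",
    "generate_calibration",
    "generate_quant_and_qpcr",
    "QPCR_GENES",
]

#: Genes assayed by qPCR; Actb is the housekeeping reference.
QPCR_GENES = ("Gba", "Pde12", "Fasn", "Elovl1")


@dataclass
class CohortConfig:
    """Study design and noise model of a synthetic two-group cohort.

    Group sizes default to the study design: a testing set of 8 WT + 7
    *cpdm* and a validation set of 11 WT + 10 *cpdm* (36 mice).  ``effects``
    maps transition ids to true cpdm/WT fold changes on the normalized
    scale (default: the packaged discriminative-transition panel);
    transitions absent from the map have fold change 1.  ``cv`` is the
    within-group coefficient of variation of each transition's intensity
    and ``tic_scale_sd`` the log-scale SD of the per-sample total-intensity
    factor; neither was reported for the original data, so the defaults
    (0.2 and 0.3) are documented knobs, not claims.
    """

    n_wt_testing: int = 8
    n_cpdm_testing: int = 7
    n_wt_validation: int = 11
    n_cpdm_validation: int = 10
    effects: Optional[dict] = None
    baseline: Optional[dict] = None
    cv: float = 0.2
    tic_scale_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_wt_testing, self.n_cpdm_testing):
            if n < 2:
                raise ValueError("each testing group needs >= 2 samples")
        if self.n_wt_validation < 0 or self.n_cpdm_validation < 0:
            raise ValueError("validation group sizes must be >= 0")
        if self.cv < 0 or self.tic_scale_sd < 0:
            raise ValueError("cv and tic_scale_sd must be >= 0")
        if self.effects is not None and any(v <= 0 for v in self.effects.values()):
            raise ValueError("fold-change effects must be positive")
        if self.baseline is not None and any(v <= 0 for v in self.baseline.values()):
            raise ValueError("baselines must be positive")


@dataclass
class RawIntensityTable:
    """Raw (un-normalized) per-transition intensities with sample labels."""

    intensities: pd.DataFrame  # index sample_id, columns transition ids
    samples: pd.DataFrame  # index sample_id; columns group, split
    polarity: str

    def __post_init__(self) -> None:
        if (self.intensities.values < 0).any():
            raise ValueError("raw intensities must be >= 0")
        if not self.intensities.index.equals(self.samples.index):
            raise ValueError("intensity and sample tables disagree on sample ids")


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def generate_cohort(config: CohortConfig, method: ScreeningMethod) -> RawIntensityTable:
    """Simulate raw flow-injection intensities for one screening method.

    For sample *s* of group *g* and transition *t*::

        raw(s, t) = TIC_s * profile_g(t) * eps(s, t)

    with ``eps`` log-normal of mean 1 and CV ``config.cv`` and ``TIC_s``
    log-normal with log-scale SD ``config.tic_scale_sd``.  The WT mean
    profile is the baseline (summing to 1).  Because effects are defined on
    the TIC-normalized scale, the cpdm profile must also sum to 1 or the
    normalization itself would shrink every stated fold change by the
    closure factor; transitions carrying an effect are therefore set to
    ``baseline * FC`` and the *unmodeled* transitions absorb the
    compensation pro rata, making the stated fold changes recoverable by
    construction.  Runs with the same seed are bit-reproducible.
    """
    transitions = list(method.transition_ids)
    if config.effects is None:
        effects = {t: fc for t, fc in default_effects().items() if t in set(transitions)}
    else:
        unknown = set(config.effects) - set(transitions)
        if unknown:
            raise KeyError(f"effects reference transitions not in the method: {sorted(unknown)}")
        effects = dict(config.effects)

    if config.baseline is None:
        base = np.full(len(transitions), 1.0 / len(transitions))
    else:
        unknown = set(config.baseline) - set(transitions)
        if unknown:
            raise KeyError(f"baselines reference unknown transitions: {sorted(unknown)}")
        base = np.array([config.baseline.get(t, 1.0) for t in transitions])
        base = base / base.sum()

    # cpdm mean profile: stated fold changes on effect transitions, closure
    # compensation spread over the unmodeled ones so both profiles sum to 1
    has_effect = np.array([t in effects for t in transitions])
    fc = np.array([effects.get(t, 1.0) for t in transitions])
    cpdm_profile = base * fc
    effect_mass = cpdm_profile[has_effect].sum()
    free_mass = base[~has_effect].sum()
    if effect_mass >= 1.0 and free_mass > 0:
        raise ValueError(
            "effect transitions claim the whole normalized profile; "
            "lower their baselines or fold changes"
        )
    if free_mass > 0:
        cpdm_profile[~has_effect] *= (1.0 - effect_mass) / free_mass
    else:  # every transition carries an effect: closure is unavoidable
        cpdm_profile /= cpdm_profile.sum()

    groups = (
        ["WT"] * config.n_wt_testing
        + ["cpdm"] * config.n_cpdm_testing
        + ["WT"] * config.n_wt_validation
        + ["cpdm"] * config.n_cpdm_validation
    )
    splits = (
        ["testing"] * (config.n_wt_testing + config.n_cpdm_testing)
        + ["validation"] * (config.n_wt_validation + config.n_cpdm_validation)
    )
    sample_ids = [
        f"{sp[:4]}_{g}_{i:02d}"
        for i, (g, sp) in enumerate(zip(groups, splits), start=1)
    ]

    rng = np.random.default_rng(config.seed)
    n, m = len(sample_ids), len(transitions)
    tic = rng.lognormal(mean=0.0, sigma=config.tic_scale_sd, size=n) if config.tic_scale_sd else np.ones(n)
    eps = _lognormal_unit_mean(rng, config.cv, (n, m))
    is_cpdm = np.array([g == "cpdm" for g in groups], dtype=bool)
    profile = np.where(is_cpdm[:, None], cpdm_profile[None, :], base[None, :])
    raw = tic[:, None] * profile * eps
    # an overall counts scale so values resemble instrument intensities
    raw *= 1e6

    intensities = pd.DataFrame(raw, index=pd.Index(sample_ids, name="sample_id"), columns=transitions)
    samples = pd.DataFrame(
        {"group": groups, "split": splits}, index=pd.Index(sample_ids, name="sample_id")
    )
    return RawIntensityTable(intensities, samples, method.polarity)


def render_chronograms(
    table: RawIntensityTable,
    method: ScreeningMethod,
    n_points: int = 121,
    peak_center_min: float = 0.6,
    peak_sigma_min: float = 0.12,
) -> pd.DataFrame:
    """Render each raw intensity as one Gaussian flow-injection peak.

    Returns a long table (sample_id, group, split, q1, q3, polarity,
    time_min, intensity) over the method's acquisition window, scaled so the
    trapezoidal integral of every trace equals the raw intensity exactly.
    """
    missing = set(table.intensities.columns) - set(method.transition_ids)
    if missing:
        raise KeyError(f"method does not cover transitions {sorted(missing)}")
    time = np.linspace(0.0, method.acquisition_time, n_points)
    shape = np.exp(-0.5 * ((time - peak_center_min) / peak_sigma_min) ** 2)
    shape /= np.trapezoid(shape, time)

    by_id = {t.transition: t for t in method.transitions}
    frames = []
    for sample_id, row in table.intensities.iterrows():
        meta = table.samples.loc[sample_id]
        for trans_id, value in row.items():
            t = by_id[trans_id]
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sample_id,
                        "group": meta["group"],
                        "split": meta["split"],
                        "q1": t.q1.mz,
                        "q3": t.q3.mz,
                        "polarity": t.polarity,
                        "time_min": time,
                        "intensity": value * shape,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# minimal mzML writer (SRM chromatogram dialect)

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="{run_id}">
    <chromatogramList count="{count}" defaultDataProcessingRef="dp1">
"""

_MZML_FOOTER = """    </chromatogramList>
  </run>
</mzML>
"""


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=float))
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


def _binary_array_xml(values: np.ndarray, kind: str) -> str:
    accession, name, unit = {
        "time": ("MS:1000595", "time array", ' unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"'),
        "intensity": ("MS:1000515", "intensity array", ""),
    }[kind]
    encoded = _encode_array(values)
    return (
        f'        <binaryDataArray encodedLength="{len(encoded)}">\n'
        '          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        '          <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>\n'
        f'          <cvParam cvRef="MS" accession="{accession}" name="{name}" value=""{unit}/>\n'
        f"          <binary>{encoded}</binary>\n"
        "        </binaryDataArray>\n"
    )


def write_mzml(chronograms: pd.DataFrame, path) -> None:
    """Write one sample's chronograms as a minimal SRM-chromatogram mzML.

    ``chronograms`` is the long-format output of :func:`render_chronograms`
    restricted to a single sample.  Arrays are 64-bit floats with zlib
    compression, readable by any conforming mzML parser.
    """
    sample_ids = chronograms["sample_id"].unique()
    if len(sample_ids) != 1:
        raise ValueError("write_mzml expects chronograms of exactly one sample")
    groups = list(chronograms.groupby(["q1", "q3"], sort=True))
    parts = [_MZML_HEADER.format(run_id=sample_ids[0], count=len(groups))]
    for index, ((q1, q3), chunk) in enumerate(groups):
        chunk = chunk.sort_values("time_min")
        cid = f"SRM SIC Q1={q1:g} Q3={q3:g}"
        parts.append(
            f'      <chromatogram id="{cid}" index="{index}" defaultArrayLength="{len(chunk)}">\n'
            '        <cvParam cvRef="MS" accession="MS:1001473" name="selected reaction monitoring chromatogram" value=""/>\n'
            "        <precursor>\n"
            "          <isolationWindow>\n"
            f'            <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{q1:g}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
            "          </isolationWindow>\n"
            "        </precursor>\n"
            "        <product>\n"
            "          <isolationWindow>\n"
            f'            <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{q3:g}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
            "          </isolationWindow>\n"
            "        </product>\n"
            '        <binaryDataArrayList count="2">\n'
            + _binary_array_xml(chunk["time_min"].to_numpy(), "time")
            + _binary_array_xml(chunk["intensity"].to_numpy(), "intensity")
            + "        </binaryDataArrayList>\n"
            "      </chromatogram>\n"
        )
    parts.append(_MZML_FOOTER)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("".join(parts))


# ---------------------------------------------------------------------------
# calibration, quantification, qPCR


def generate_calibration(
    levels=(1.0, 10.0, 100.0, 1000.0, 10000.0),
    replicates: int = 3,
    response_slope: float = 100.0,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Spiked calibration series: ``intensity = slope * ppm * eps``.

    Defaults emulate the five-level, three-replicate single-standard series
    (1 to 10,000 ppm, fifteen points) used to establish assay linearity.
    """
    levels = np.asarray(levels, dtype=float)
    if (levels <= 0).any():
        raise ValueError("calibration levels must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for level in levels:
        eps = _lognormal_unit_mean(rng, noise_cv, replicates)
        for rep in range(replicates):
            rows.append(
                {
                    "level_ppm": level,
                    "replicate": rep + 1,
                    "intensity": response_slope * level * eps[rep],
                }
            )
    return pd.DataFrame(rows)


def generate_quant_and_qpcr(
    n_wt: int = 11,
    n_cpdm: int = 10,
    analyte_fold: Optional[dict] = None,
    gene_expression_ratio: Optional[dict] = None,
    is_nmol: float = 0.5,
    weight_mg: float = 10.0,
    cv: float = 0.2,
    ct_sd: float = 0.3,
    seed: int = 0,
) -> tuple:
    """Synthetic LC-MS quantification and qPCR Ct tables.

    Quantification: per sample and sphingolipid analyte, a peak area pair
    (analyte, internal standard spiked at ``is_nmol`` nmol) plus the dry
    tissue weight; true WT concentrations are fixed per analyte and *cpdm*
    concentrations scaled by ``analyte_fold`` (default: the published
    fold changes of the three-ceramide panel).

    qPCR: Ct values for the lipid-enzyme genes and the Actb housekeeping
    gene, with true cpdm/WT expression ratios (default: Fasn halved,
    the idea the expression data support; others unchanged).
    """
    if analyte_fold is None:
        analyte_fold = {
            "CerAS(d18:1/24:0)2OH": 18.73,
            "CerAS(d18:1/16:0)2OH": 5.23,
            "CerNS(d18:1/16:0)": 4.89,
        }
    wt_conc = {a: 0.05 * (i + 1) for i, a in enumerate(analyte_fold)}  # nmol/mg
    if gene_expression_ratio is None:
        gene_expression_ratio = {"Gba": 1.0, "Pde12": 1.0, "Fasn": 0.5, "Elovl1": 1.0}

    rng = np.random.default_rng(seed)
    samples = [(f"q_WT_{i+1:02d}", "WT") for i in range(n_wt)] + [
        (f"q_cpdm_{i+1:02d}", "cpdm") for i in range(n_cpdm)
    ]

    quant_rows = []
    for sample, group in samples:
        for analyte, fold in analyte_fold.items():
            conc = wt_conc[analyte] * (fold if group == "cpdm" else 1.0)
            conc *= _lognormal_unit_mean(rng, cv, 1)[0]
            is_area = rng.normal(5e5, 2e4)
            area = conc * weight_mg / is_nmol * is_area
            quant_rows.append(
                {
                    "sample": sample,
                    "group": group,
                    "analyte": analyte,
                    "area": area,
                    "is_area": is_area,
                    "is_nmol": is_nmol,
                    "weight_mg": weight_mg,
                    "true_nmol_per_mg": conc,
                }
            )
    quant = pd.DataFrame(quant_rows)

    base_ct = {"Gba": 24.0, "Pde12": 26.0, "Fasn": 22.0, "Elovl1": 25.0, "Actb": 17.0}
    qpcr_rows = []
    for sample, group in samples:
        loading = rng.normal(0.0, 0.2)  # per-sample cDNA input, cancels in dCt
        for gene in (*QPCR_GENES, "Actb"):
            ratio = gene_expression_ratio.get(gene, 1.0) if group == "cpdm" else 1.0
            ct = base_ct[gene] - np.log2(ratio) + loading + rng.normal(0.0, ct_sd)
            qpcr_rows.append({"sample": sample, "group": group, "gene": gene, "ct": ct})
    qpcr = pd.DataFrame(qpcr_rows)
    return quant, qpcr
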