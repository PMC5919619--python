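"""Absolute quantification and gene-expression fold changes.

LC-MS quantification converts analyte peak areas to nmol per mg of dry
tissue via a spiked internal standard (one per sphingolipid class, 0.5 nmol
by default)::

    concentration = (analyte_area / IS_area) * IS_nmol / dry_weight_mg

Calibration linearity is assessed by ordinary least squares over the
spiked-level series.  qPCR expression ratios use the comparative-Ct method:
Ct values are referenced to the housekeeping gene (dCt), contrasted
between groups (ddCt), and reported as 2**-ddCt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "QuantRecord",
    "CalibrationFit",
    "QpcrRecord",
    "quantify_sample",
    "quantify_table",
    "fit_calibration",
    "ddct_fold_change",
]


@dataclass(frozen=True)
class QuantRecord:
    """One sample/analyte quantification in nmol per mg dry tissue."""

    sample_id: str
    analyte: str
    area: float
    is_area: float
    is_nmol: float
    weight_mg: float
    nmol_per_mg: float


@dataclass(frozen=True)
class CalibrationFit:
    """OLS fit of intensity against spiked concentration (ppm)."""

    levels_ppm: tuple
    slope: float
    intercept: float
    r_squared: float
    linear: bool  # R^2 >= threshold across the full level span
    decades: float  # log10 span of the calibration levels


@dataclass(frozen=True)
class QpcrRecord:
    """Comparative-Ct result for one gene."""

    gene: str
    ddct: float
    fold_change: float  # 2 ** -ddct, cpdm relative to WT
    p_value: float  # unpaired t-test on per-sample dCt


def quantify_sample(
    area: float,
    is_area: float,
    weight_mg: float,
    is_nmol: float = 0.5,
    sample_id: str = "sample",
    analyte: str = "analyte",
) -> QuantRecord:
    """Internal-standard quantification of one analyte in one sample."""
    if area < 0 or is_area < 0:
        raise ValueError("peak areas must be >= 0")
    if is_area == 0:
        raise ValueError(f"internal standard signal failure in {sample_id}")
    if weight_mg <= 0:
        raise ValueError("dry tissue weight must be positive")
    conc = (area / is_area) * is_nmol / weight_mg
    return QuantRecord(sample_id, analyte, area, is_area, is_nmol, weight_mg, conc)


def quantify_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`quantify_sample` over a quantification input table.

    Expects columns ``sample, analyte, area, is_area, weight_mg`` and
    optionally ``is_nmol`` (default 0.5); adds ``nmol_per_mg``.
    """
    out = df.copy()
    is_nmol = out["is_nmol"] if "is_nmol" in out.columns else 0.5
    records = [
        quantify_sample(
            row.area,
            row.is_area,
            row.weight_mg,
            is_nmol if np.isscalar(is_nmol) else row.is_nmol,
            sample_id=str(row.sample),
            analyte=str(row.analyte),
        )
        for row in out.itertuples(index=False)
    ]
    out["nmol_per_mg"] = [r.nmol_per_mg for r in records]
    return out


def fit_calibration(series: pd.DataFrame, r2_threshold: float = 0.99) -> CalibrationFit:
    """Assess linearity of a spiked calibration series.

    ``series`` needs columns ``level_ppm`` and ``intensity`` with at least
    three distinct levels.  The verdict is linear when R^2 of the OLS fit
    over the full span reaches ``r2_threshold``.
    """
    levels = np.sort(series["level_ppm"].unique())
    if len(levels) < 3:
        raise ValueError(f"calibration needs >= 3 distinct levels, got {len(levels)}")
    fit = sps.linregress(series["level_ppm"], series["intensity"])
    r2 = float(fit.rvalue**2)
    return CalibrationFit(
        tuple(levels),
        float(fit.slope),
        float(fit.intercept),
        r2,
        bool(r2 >= r2_threshold),
        float(np.log10(levels[-1] / levels[0])),
    )


def ddct_fold_change(
    ct: pd.DataFrame, housekeeping: str = "Actb", genes: Optional[list] = None
) -> list:
    """Comparative-Ct (2**-ddCt) fold changes of cpdm relative to WT.

    ``ct`` is a long table with columns ``sample, group, gene, ct``.  Each
    sample's target Ct is referenced to its own housekeeping Ct (dCt); the
    group contrast ddCt = mean dCt(cpdm) - mean dCt(WT) gives the fold
    change 2**-ddCt, with an unpaired t-test on the per-sample dCt values.
    """
    wide = ct.pivot_table(index=["sample", "group"], columns="gene", values="ct")
    if housekeeping not in wide.columns or wide[housekeeping].isna().any():
        raise ValueError(f"housekeeping gene {housekeeping!r} missing for some samples")
    if genes is None:
        genes = [g for g in wide.columns if g != housekeeping]
    groups = wide.index.get_level_values("group")
    out = []
    for gene in genes:
        if gene not in wide.columns:
            raise KeyError(f"gene {gene!r} absent from Ct table")
        dct = wide[gene] - wide[housekeeping]
        dct_wt = dct[groups == "WT"].dropna()
        dct_cpdm = dct[groups == "cpdm"].dropna()
        ddct = float(dct_cpdm.mean() - dct_wt.mean())
        p = float(sps.ttest_ind(dct_cpdm, dct_wt, equal_var=True).pvalue)
        out.append(QpcrRecord(gene, ddct, float(2.0 ** (-ddct)), p))
    return out
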