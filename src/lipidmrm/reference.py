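"""Packaged reference panel of discriminative epidermal lipid transitions.

The TSV shipped under ``data/table1.tsv`` lists the MRM transitions found to
discriminate wild-type from SHARPIN-deficient (*cpdm*) mouse epidermis:
parent/fragment m/z, polarity, scan family, the published tentative
attribution (verbatim and in canonical shorthand), and the published
cpdm/WT fold change with its t-test p-value.  The fold-change column is the
default effect map of the synthetic cohort generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "discriminative_transitions",
    "default_effects",
    "transition_id",
    "CERAMIDE_PANEL",
    "FFA_PANEL",
]

#: Transition ids of the three-ceramide biomarker panel
#: (CerAS(d18:1/24:0)2OH, CerAS(d18:1/16:0)2OH, CerNS(d18:1/16:0)).
CERAMIDE_PANEL = ("666.35->264.1", "554.2->264.1", "538.3->264.1")

#: Transition ids of the three-FFA panel (16OH-16:0, cerotic acid, DHA).
#: DHA (22:6, m/z 327.2) was monitored but is not in the significant-feature
#: table; its id follows the SIM convention q1 == q3.
FFA_PANEL = ("271.3->271.3", "395.4->395.4", "327.2->327.2")


def transition_id(q1: float, q3: float) -> str:
    """Canonical string id of a transition, e.g. ``'666.35->264.1'``."""
    return f"{q1:g}->{q3:g}"


def discriminative_transitions() -> pd.DataFrame:
    """The packaged panel of discriminative transitions.

    Returns a DataFrame with columns ``q1, q3, polarity, scan,
    printed_attribution, canonical, fold_change, p_value`` plus a derived
    ``transition`` id column.  ``canonical`` holds ``|``-separated canonical
    shorthand for multi-candidate cells and is empty for transitions whose
    species could not be attributed.
    """
    ref = resources.files("lipidmrm").joinpath("data/table1.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
    df["transition"] = [transition_id(a, b) for a, b in zip(df["q1"], df["q3"])]
    return df


def default_effects() -> dict:
    """Published cpdm/WT fold changes keyed by transition id."""
    df = discriminative_transitions()
    return dict(zip(df["transition"], df["fold_change"]))
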