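"""Univariate and multivariate statistics on the relative-intensity matrix.

Group comparisons are unpaired two-sided t-tests per transition with
step-down Holm-Sidak control of the family-wise error rate at alpha = 5%.
Volcano selection uses the raw p-value together with a two-fold-change cut,
the convention under which the discriminative-feature table was built (the
adjusted significance flag is carried alongside).  Multivariate views
(PCA, hierarchical clustering) run on autoscaled data: each feature
mean-centered and scaled to unit variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .ingest import FeatureMatrix

__all__ = [
    "FeatureStat",
    "ProfileAggregate",
    "holm_sidak_ttests",
    "volcano_select",
    "pca_autoscaled",
    "cluster_heatmap",
    "aggregate_profiles",
    "autoscale",
]


@dataclass
class FeatureStat:
    """Univariate comparison of one transition between phenotypes."""

    transition: str
    mean_wt: float
    mean_cpdm: float
    fold_change: float  # cpdm / WT ratio of group means
    raw_p: float
    significant: bool  # Holm-Sidak at family alpha
    tested: bool = True


@dataclass
class ProfileAggregate:
    """Per-category, per-phenotype summary for one grouping scheme.

    ``table`` columns: category, group, mean, se, share — mean +- SE of the
    per-sample summed relative amounts, and the mean per-sample share of
    the scheme total (shares sum to 1 within a phenotype).
    """

    scheme: str
    table: pd.DataFrame


def holm_sidak_reject(pvals, alpha: float = 0.05) -> np.ndarray:
    """Step-down Holm-Sidak rejection flags for a vector of raw p-values."""
    return multipletests(np.asarray(pvals, dtype=float), alpha=alpha, method="holm-sidak")[0]


def _group_arrays(matrix: FeatureMatrix):
    wt = matrix.X.loc[matrix.groups == "WT"]
    cpdm = matrix.X.loc[matrix.groups == "cpdm"]
    if len(wt) < 2 or len(cpdm) < 2:
        raise ValueError("both groups need >= 2 samples")
    return wt, cpdm


def holm_sidak_ttests(
    matrix: FeatureMatrix, alpha: float = 0.05, equal_var: bool = True
) -> list:
    """Per-transition unpaired t-tests with Holm-Sidak correction.

    The equal-variance (pooled) t-test is the default; Welch is available
    with ``equal_var=False``.  A transition with zero variance in both
    groups and equal means cannot be tested and is flagged accordingly.
    """
    wt, cpdm = _group_arrays(matrix)
    stats_out = []
    pvals, testable_idx = [], []
    for j, transition in enumerate(matrix.X.columns):
        a, b = wt.iloc[:, j].to_numpy(), cpdm.iloc[:, j].to_numpy()
        mean_wt, mean_cpdm = float(a.mean()), float(b.mean())
        fc = mean_cpdm / mean_wt if mean_wt > 0 else np.inf
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            stat = FeatureStat(transition, mean_wt, mean_cpdm, fc, np.nan, False, tested=False)
        else:
            p = float(sps.ttest_ind(b, a, equal_var=equal_var).pvalue)
            stat = FeatureStat(transition, mean_wt, mean_cpdm, fc, p, False)
            pvals.append(p)
            testable_idx.append(len(stats_out))
        stats_out.append(stat)
    if pvals:
        reject = holm_sidak_reject(pvals, alpha=alpha)
        for idx, rej in zip(testable_idx, reject):
            stats_out[idx].significant = bool(rej)
    return stats_out


def volcano_select(
    stats_list: Sequence[FeatureStat], p_max: float = 0.05, min_fold: float = 2.0
) -> list:
    """Features with raw p <= ``p_max`` and at least ``min_fold`` change
    in either direction (cpdm/WT >= min_fold or <= 1/min_fold)."""
    if not stats_list:
        raise ValueError("no feature statistics supplied")
    return [
        s
        for s in stats_list
        if s.tested
        and s.raw_p <= p_max
        and (s.fold_change >= min_fold or s.fold_change <= 1.0 / min_fold)
    ]


def autoscale(X: pd.DataFrame, drop_constant: bool = True) -> pd.DataFrame:
    """Per-feature mean-center and scale to unit variance (ddof = 1)."""
    sd = X.std(ddof=1)
    constant = sd[sd == 0].index
    if len(constant):
        if not drop_constant:
            raise ValueError(f"constant features cannot be autoscaled: {list(constant)}")
        warnings.warn(f"dropping {len(constant)} constant feature(s) before scaling")
        X = X.drop(columns=constant)
        sd = sd.drop(constant)
    return (X - X.mean()) / sd


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray


def pca_autoscaled(matrix: FeatureMatrix, n_components: Optional[int] = None) -> PcaResult:
    """PCA of the autoscaled matrix with a fixed sign convention.

    Explained-variance fractions are non-negative, non-increasing and sum
    to one over the full decomposition.  Each component's sign is chosen so
    its largest-magnitude loading is positive, making score plots
    reproducible across linear-algebra backends.
    """
    if len(matrix.X) < 3:
        raise ValueError("PCA needs at least 3 samples")
    Z = autoscale(matrix.X)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z.to_numpy())
    loadings = pca.components_.T
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    comps = [f"PC{i+1}" for i in range(loadings.shape[1])]
    return PcaResult(
        pd.DataFrame(scores, index=Z.index, columns=comps),
        pd.DataFrame(loadings, index=Z.columns, columns=comps),
        pca.explained_variance_ratio_,
    )


@dataclass
class ClusterResult:
    sample_order: list
    feature_order: list
    scaled: pd.DataFrame
    sample_linkage: np.ndarray
    feature_linkage: np.ndarray


def cluster_heatmap(matrix: FeatureMatrix) -> ClusterResult:
    """Ward/Euclidean agglomerative clustering of samples and features.

    Works on autoscaled values; leaf order is deterministic (scipy's
    ordering with index tie-breaks on identical merge heights).
    """
    if len(matrix.X) < 2:
        raise ValueError("clustering needs at least 2 samples")
    Z = autoscale(matrix.X)
    sample_link = hierarchy.ward(Z.to_numpy())
    feature_link = hierarchy.ward(Z.to_numpy().T)
    sample_order = [Z.index[i] for i in hierarchy.leaves_list(sample_link)]
    feature_order = [Z.columns[i] for i in hierarchy.leaves_list(feature_link)]
    return ClusterResult(sample_order, feature_order, Z, sample_link, feature_link)


# ---------------------------------------------------------------------------
# ceramide / FFA aggregate profiles

_FFA_LENGTH_BINS = (("12-18", 12, 18), ("20-24", 20, 24), (">=26", 26, 10**6))


def _scheme_members(attributions) -> dict:
    """Category membership per scheme from per-transition attributions."""
    schemes = {
        "ceramide_base": {},
        "ceramide_hydroxylation": {},
        "ceramide_chain_length": {},
        "ffa_saturation": {},
        "ffa_chain_length": {},
    }
    for trans_id, result in attributions.items():
        cls = result.class_call
        if cls in ("Cer[S]", "Cer[DS]", "Cer[P]"):
            schemes["ceramide_base"].setdefault(cls, []).append(trans_id)
            if result.status in ("attributed", "ambiguous"):
                chain = result.top.species.chains[0]
                hydroxyl = "A" if chain.hydroxyls else "N"
                schemes["ceramide_hydroxylation"].setdefault(f"{cls}:{hydroxyl}", []).append(trans_id)
                schemes["ceramide_chain_length"].setdefault(f"C{chain.carbons}", []).append(trans_id)
        elif cls == "FFA" and result.status in ("attributed", "ambiguous"):
            chain = result.top.species.chains[0]
            sat = {0: "saturated", 1: "monounsaturated"}.get(chain.double_bonds, "polyunsaturated")
            schemes["ffa_saturation"].setdefault(sat, []).append(trans_id)
            for label, lo, hi in _FFA_LENGTH_BINS:
                if lo <= chain.carbons <= hi:
                    schemes["ffa_chain_length"].setdefault(label, []).append(trans_id)
    return schemes


def aggregate_profiles(matrix: FeatureMatrix, attributions: Mapping) -> list:
    """Ceramide and FFA composition profiles by phenotype.

    Ceramide schemes: by sphingoid base (all ceramide-scan transitions), by
    fatty-acid hydroxylation within base, and by fatty-acid chain length
    (attributed transitions).  FFA schemes: by saturation class and by
    chain-length bin.  Values are per-sample sums of relative intensities,
    summarized as mean +- SE per phenotype, plus phenotype-mean shares of
    the scheme total.  Schemes with no members are omitted with a warning.
    """
    out = []
    for scheme, members in _scheme_members(attributions).items():
        members = {c: [t for t in ts if t in matrix.X.columns] for c, ts in members.items()}
        members = {c: ts for c, ts in members.items() if ts}
        if not members:
            warnings.warn(f"no attributed transitions for scheme {scheme!r}; omitted")
            continue
        rows = []
        for group in ("WT", "cpdm"):
            sub = matrix.X.loc[matrix.groups == group]
            if sub.empty:
                continue
            per_sample = pd.DataFrame(
                {cat: sub[ts].sum(axis=1) for cat, ts in members.items()}
            )
            totals = per_sample.sum(axis=1)
            shares = per_sample.div(totals.where(totals > 0), axis=0)
            for cat in members:
                rows.append(
                    {
                        "category": cat,
                        "group": group,
                        "mean": float(per_sample[cat].mean()),
                        "se": float(per_sample[cat].std(ddof=1) / np.sqrt(len(per_sample))),
                        "share": float(shares[cat].mean()),
                    }
                )
        out.append(ProfileAggregate(scheme, pd.DataFrame(rows)))
    return out
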