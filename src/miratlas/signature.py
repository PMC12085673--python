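"""Region-distinct expression signatures.

Features are ranked by the coefficient of variation of their per-region
median expression; z-scores of the region medians are binarized at
|z| >= 0.5 ("different from the brain average"), regions are clustered on
the binary profiles (complete linkage, four clusters), and male/female
signatures can be linked feature-by-feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "SignatureResult", "top_variable_features", "region_medians",
    "region_zscores", "binarize_and_classify", "cluster_regions",
    "compute_signature", "link_sexes",
]


@dataclass
class SignatureResult:
    cv: pd.Series                   # selected features, CV value, descending
    medians: pd.DataFrame           # feature x region medians
    z: pd.DataFrame                 # feature x region z-scores
    binary: pd.DataFrame            # feature x region flags
    labels: pd.Series               # specificity label per feature
    region_clusters: pd.Series      # region -> cluster id (1..n)

    def flagged_regions(self, feature: str) -> frozenset:
        row = self.binary.loc[feature]
        return frozenset(row.index[row])


def region_medians(expr: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Median expression per (feature, region)."""
    groups = meta.loc[list(expr.columns)].groupby("region", observed=True)
    return pd.DataFrame({
        region: expr[list(sub.index)].median(axis=1)
        for region, sub in groups
    })


def top_variable_features(expr: pd.DataFrame, meta: pd.DataFrame,
                          k: int = 50) -> pd.Series:
    """Top-k features by CV of region medians (sample sd / mean).

    Features whose region-median mean is zero have no defined CV and are
    excluded from the ranking with a warning.
    """
    med = region_medians(expr, meta)
    if med.shape[1] < 2:
        raise ValueError("need at least 2 regions")
    mean = med.mean(axis=1)
    sd = med.std(axis=1, ddof=1)
    zero = mean == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} feature(s) with zero median mean "
                      "excluded from CV ranking")
    cv = (sd / mean)[~zero]
    return cv.sort_values(ascending=False, kind="mergesort").head(k)


def region_zscores(expr: pd.DataFrame, meta: pd.DataFrame,
                   features=None) -> pd.DataFrame:
    """Z-score of the per-region medians, per feature across regions
    (sample sd). Zero-sd features get an all-zero row with a warning."""
    med = region_medians(expr, meta)
    if features is not None:
        med = med.loc[list(features)]
    if med.shape[1] < 2:
        raise ValueError("need at least 2 regions")
    mean = med.mean(axis=1)
    sd = med.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant feature(s); z set to 0")
    sd = sd.replace(0, np.inf)
    return med.sub(mean, axis=0).div(sd, axis=0)


def binarize_and_classify(z: pd.DataFrame, threshold: float = 0.5,
                          inclusive: bool = True
                          ) -> tuple[pd.DataFrame, pd.Series]:
    """Flag |z| >= threshold (``inclusive=False`` for strict >) and label
    features: not-different / region-specific:<r> / multi-region:{...}."""
    a = z.abs()
    binary = (a >= threshold) if inclusive else (a > threshold)
    labels = {}
    for f, row in binary.iterrows():
        flagged = list(row.index[row])
        if not flagged:
            labels[f] = "not-different"
        elif len(flagged) == 1:
            labels[f] = f"region-specific:{flagged[0]}"
        else:
            labels[f] = "multi-region:" + "|".join(sorted(flagged))
    return binary, pd.Series(labels, name="label")


def cluster_regions(binary: pd.DataFrame, n_clusters: int = 4) -> pd.Series:
    """Complete-linkage hierarchical clustering of the region columns of
    the binary matrix (Euclidean distance on 0/1 profiles)."""
    regions = list(binary.columns)
    if len(regions) < n_clusters:
        raise ValueError(
            f"{len(regions)} regions < {n_clusters} requested clusters")
    # sort columns so the partition ignores input column order
    order = sorted(regions)
    M = binary[order].to_numpy(dtype=float).T
    Z = linkage(M, method="complete", metric="euclidean")
    ids = fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(ids, index=order).reindex(regions)


def compute_signature(expr: pd.DataFrame, meta: pd.DataFrame, k: int = 50,
                      threshold: float = 0.5, n_clusters: int = 4
                      ) -> SignatureResult:
    """Full signature analysis: CV ranking, z-scores, binarization,
    specificity labels, and region clustering."""
    cv = top_variable_features(expr, meta, k=k)
    z = region_zscores(expr, meta, features=cv.index)
    binary, labels = binarize_and_classify(z, threshold=threshold)
    med = region_medians(expr, meta).loc[cv.index]
    clusters = cluster_regions(binary, n_clusters=n_clusters)
    return SignatureResult(cv=cv, medians=med, z=z, binary=binary,
                           labels=labels, region_clusters=clusters)


def link_sexes(sig_male: SignatureResult, sig_female: SignatureResult
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-sex linkage of signature features.

    Categories per feature: same-single-region, same-multi-region-set,
    shared-feature (flagged in both sexes, differing region sets),
    sex-specific(male/female). Also returns per-region Venn counts
    (male-only / female-only / both).
    """
    fm = set(sig_male.binary.index)
    ff = set(sig_female.binary.index)
    if not fm & ff and (fm or ff):
        raise ValueError("disjoint feature universes between sexes")
    rows = []
    for f in sorted(fm | ff):
        rm = sig_male.flagged_regions(f) if f in fm else frozenset()
        rf = sig_female.flagged_regions(f) if f in ff else frozenset()
        if rm and rf:
            if rm == rf:
                cat = ("same-single-region" if len(rm) == 1
                       else "same-multi-region-set")
            else:
                cat = "shared-feature"
        elif rm:
            cat = "sex-specific(male)"
        elif rf:
            cat = "sex-specific(female)"
        else:
            continue
        rows.append({"feature": f, "category": cat,
                     "male_regions": "|".join(sorted(rm)),
                     "female_regions": "|".join(sorted(rf))})
    link = pd.DataFrame(rows)
    regions = sorted(set(sig_male.binary.columns)
                     | set(sig_female.binary.columns))
    venn = []
    for r in regions:
        m = (set(sig_male.binary.index[sig_male.binary[r]])
             if r in sig_male.binary.columns else set())
        f_ = (set(sig_female.binary.index[sig_female.binary[r]])
              if r in sig_female.binary.columns else set())
        venn.append({"region": r, "male_only": len(m - f_),
                     "female_only": len(f_ - m), "both": len(m & f_)})
    return link, pd.DataFrame(venn).set_index("region")
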