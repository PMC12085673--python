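"""isomiR-archetype analysis and miRNA-mRNA target anti-correlation.

isomiRs are length/sequence variants of a mature archetype miRNA; their
per-variant trajectories and canonical fraction are tracked per region
and age. Target integration screens a miRNA's target genes for
significant negative Spearman correlation with the miRNA across samples,
per brain region, with BH control over the (gene, region) family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .stats import bh_adjust, spearman_test

__all__ = [
    "isomir_trajectories", "top_isomirs", "cluster_isomir_regions",
    "target_anticorrelation", "validated_target_mode", "median_profiles",
]


def _variants_of(isomirs: pd.DataFrame, info: pd.DataFrame,
                 archetype: str) -> pd.DataFrame:
    vs = info.index[info["archetype"] == archetype]
    if not len(vs):
        raise ValueError(f"archetype absent from isomiR table: {archetype!r}")
    return isomirs.loc[list(vs)]


def isomir_trajectories(isomirs: pd.DataFrame, info: pd.DataFrame,
                        meta: pd.DataFrame, archetype: str
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median expression per (variant, region, age) and the canonical
    fraction per (region, age).

    Returns (trajectories long frame, canonical fraction region x age).
    """
    sub = _variants_of(isomirs, info, archetype)
    meta = meta.loc[list(sub.columns)]
    rows = []
    for (region, age), g in meta.groupby(["region", "age_months"],
                                         observed=True):
        med = sub[list(g.index)].median(axis=1)
        for v, m in med.items():
            rows.append({"variant": v, "region": region, "age_months": age,
                         "median": m})
    traj = pd.DataFrame(rows)
    canonical = info.index[(info["archetype"] == archetype)
                           & info["canonical"]]
    tot = traj.groupby(["region", "age_months"])["median"].sum()
    can = (traj[traj["variant"].isin(canonical)]
           .groupby(["region", "age_months"])["median"].sum())
    frac = (can / tot).rename("canonical_fraction")
    frac = frac.reset_index().pivot(index="region", columns="age_months",
                                    values="canonical_fraction")
    return traj, frac


def top_isomirs(isomirs: pd.DataFrame, k: int = 25) -> pd.Series:
    """Variants ranked by median expression over all samples, descending."""
    med = isomirs.median(axis=1)
    return med.sort_values(ascending=False, kind="mergesort").head(k)


def cluster_isomir_regions(isomirs: pd.DataFrame, meta: pd.DataFrame,
                           n_clusters: int = 3) -> pd.Series:
    """Complete-linkage clustering of regions on averaged standardized
    isomiR expression (z per variant across regions of the region means)."""
    meta = meta.loc[list(isomirs.columns)]
    regions = sorted(set(meta["region"]))
    if len(regions) < n_clusters:
        raise ValueError(f"{len(regions)} regions < {n_clusters} clusters")
    means = pd.DataFrame({
        r: isomirs[list(meta.index[meta["region"] == r])].mean(axis=1)
        for r in regions
    })
    sd = means.std(axis=1, ddof=1).replace(0, np.inf)
    z = means.sub(means.mean(axis=1), axis=0).div(sd, axis=0)
    Z = linkage(z.to_numpy().T, method="complete", metric="euclidean")
    ids = fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(ids, index=regions)


def target_anticorrelation(mirna: pd.Series, mrna: pd.DataFrame,
                           meta: pd.DataFrame, targets: list[str],
                           threshold: float = 0.3, alpha: float = 0.05,
                           strict: bool = False, by: str = "region"
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlation of a miRNA with each target gene per region.

    A (gene, region) pair is flagged significantly anti-correlated when
    R <= -threshold (strictly < with ``strict``) and the BH-adjusted p,
    over all computed (gene, region) pairs, is below alpha. Samples are
    the intersection of the miRNA and mRNA columns. Genes absent from
    the mRNA table are recorded as missing. Returns the per-pair table
    and a per-gene summary of flagged region sets.
    """
    if not targets:
        raise ValueError("empty target list")
    samples = [s for s in mirna.index if s in set(mrna.columns)]
    meta = meta.loc[samples]
    rows = []
    for gene in targets:
        if gene not in mrna.index:
            rows.append({"gene": gene, by: None, "R": np.nan,
                         "p_raw": np.nan, "n": 0, "missing": True})
            continue
        for region, sub in meta.groupby(by, observed=True):
            ids = list(sub.index)
            r, p = spearman_test(mirna[ids].to_numpy(),
                                 mrna.loc[gene, ids].to_numpy())
            rows.append({"gene": gene, by: region, "R": r, "p_raw": p,
                         "n": len(ids), "missing": False})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    meets = (out["R"] < -threshold) if strict else (out["R"] <= -threshold)
    out["significant"] = meets & (out["p_adj"] < alpha)
    flagged = out[out["significant"]]
    summary = (flagged.groupby("gene")[by]
               .agg(lambda s: "|".join(sorted(s)))
               .rename("regions").reset_index())
    summary["n_regions"] = summary["regions"].str.count(r"\|") + 1
    return out, summary


def validated_target_mode(mirna: pd.Series, mrna: pd.DataFrame,
                          meta: pd.DataFrame, validated_targets: list[str],
                          threshold: float = 0.5, alpha: float = 0.05
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stricter screen for functionally validated target panels:
    correlation strictly below -0.5 in at least one region."""
    return target_anticorrelation(mirna, mrna, meta, validated_targets,
                                  threshold=threshold, alpha=alpha,
                                  strict=True)


def median_profiles(mirna: pd.Series, gene: pd.Series, meta: pd.DataFrame
                    ) -> pd.DataFrame:
    """Paired (region, age) median series of a miRNA and a gene, for
    scatter export."""
    samples = [s for s in mirna.index if s in set(gene.index)]
    meta = meta.loc[samples]
    rows = []
    for (region, age), sub in meta.groupby(["region", "age_months"],
                                           observed=True):
        ids = list(sub.index)
        rows.append({"region": region, "age_months": age,
                     "mirna_median": float(mirna[ids].median()),
                     "gene_median": float(gene[ids].median())})
    return pd.DataFrame(rows)
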