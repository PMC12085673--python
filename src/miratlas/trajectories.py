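"""Aging-trajectory construction and fuzzy c-means clustering.

A trajectory is the per-age median expression of one feature in one brain
region, standardized across the age axis (population sd, the convention
of soft time-course clustering tools). Trajectories are clustered with
fuzzy c-means; each is assigned to its highest-membership cluster,
low-membership trajectories are discarded, and clusters are profiled for
region- and feature-specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrajectorySet", "ClusterModel", "ClusterProfile",
    "build_trajectories", "estimate_fuzzifier", "cmeans",
    "cmeans_fit", "select_k", "assign_and_filter", "characterize",
]


@dataclass
class TrajectorySet:
    """Standardized median-expression-vs-age vectors keyed by
    (region, feature)."""

    data: pd.DataFrame            # MultiIndex (region, feature) x age grid
    ages: tuple
    dropped: list = field(default_factory=list)   # (region, feature, reason)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ClusterModel:
    k: int
    m: float
    centers: np.ndarray           # k x n_ages
    membership: pd.DataFrame      # trajectory x k, rows sum to 1
    seed: int
    n_iter: int
    objective: float


@dataclass
class ClusterProfile:
    cluster: int
    size: int
    region_fractions: dict
    feature_counts: dict
    region_specific: bool
    feature_specific: bool
    center: np.ndarray


def build_trajectories(expr: pd.DataFrame, meta: pd.DataFrame,
                       ages=None, min_ages: int = 3) -> TrajectorySet:
    """Median rpmm per (region, feature, age), z-standardized over ages.

    ``ages``: the age grid; defaults to the ages available in every
    retained region (c-means needs equal-length vectors). Regions with
    fewer than ``min_ages`` ages are excluded with a warning;
    zero-variance trajectories are dropped with a record.
    """
    meta = meta.loc[list(expr.columns)]
    region_ages = {r: sorted(set(sub["age_months"]))
                   for r, sub in meta.groupby("region", observed=True)}
    usable = {r: a for r, a in region_ages.items() if len(a) >= min_ages}
    for r in set(region_ages) - set(usable):
        warnings.warn(f"region {r!r} has fewer than {min_ages} ages; "
                      "excluded from trajectories")
    if ages is None:
        common = set.intersection(*(set(a) for a in usable.values())) \
            if usable else set()
        ages = sorted(common)
    else:
        ages = sorted(ages)
    if len(ages) < min_ages:
        raise ValueError("common age grid has fewer than "
                         f"{min_ages} ages: {ages}")
    blocks, keys, dropped = [], [], []
    for region in sorted(usable):
        sub = meta[meta["region"] == region]
        med = np.column_stack([
            expr[list(sub.index[sub["age_months"] == a])].median(axis=1)
            for a in ages
        ])
        mean = med.mean(axis=1, keepdims=True)
        sd = med.std(axis=1, ddof=1)   # sample sd, as in R's sd()
        flat = sd == 0
        z = (med - mean) / np.where(flat, 1.0, sd)[:, None]
        for i, f in enumerate(expr.index):
            if flat[i]:
                dropped.append((region, f, "zero-variance"))
            else:
                keys.append((region, f))
                blocks.append(z[i])
    data = pd.DataFrame(
        np.asarray(blocks) if blocks else np.empty((0, len(ages))),
        index=pd.MultiIndex.from_tuples(keys, names=["region", "feature"]),
        columns=ages)
    return TrajectorySet(data=data, ages=tuple(ages), dropped=dropped)


def estimate_fuzzifier(n: int, d: int) -> float:
    """Fuzzifier heuristic of Schwaemmle & Jensen (2010) from the data
    size n and dimensionality d."""
    return float(1.0 + (1418.0 / n + 22.05) * d ** -2
                 + (12.33 / n + 0.243)
                 * d ** (-0.0406 * np.log(n) - 0.1134))


def cmeans(X: np.ndarray, k: int, m: float, seed: int,
           tol: float = 1e-6, max_iter: int = 1000
           ) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Standard fuzzy c-means (Bezdek) on Euclidean distance.

    Initial centers are ``k`` distinct rows drawn by seeded choice.
    Returns (centers k x d, membership n x k, n_iter, objective). The
    objective sum_ij u_ij^m d_ij^2 is checked to be non-increasing.
    """
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of trajectories ({n})")
    rng = np.random.default_rng(seed)
    # prefer distinct rows for initialization
    uniq = np.unique(X, axis=0)
    if len(uniq) >= k:
        centers = uniq[rng.choice(len(uniq), size=k, replace=False)].copy()
    else:
        centers = X[rng.choice(n, size=k, replace=False)].copy()
    prev_obj = np.inf
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        # u_ij = 1 / sum_l (d_ij/d_lj)^(2/(m-1)) = w_ij / sum_l w_lj
        with np.errstate(divide="ignore", invalid="ignore"):
            w = d2 ** (-1.0 / (m - 1.0))
            u = w / w.sum(axis=1, keepdims=True)
        hit = zero.any(axis=1)
        if hit.any():
            u[hit] = 0.0
            u[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
        um = u ** m
        obj = float((um * d2).sum())
        assert obj <= prev_obj + 1e-8 * max(prev_obj, 1.0), \
            "c-means objective increased"
        new_centers = (um.T @ X) / um.sum(axis=0)[:, None]
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        prev_obj = obj
        if shift < tol:
            break
    return centers, u, it, prev_obj


def cmeans_fit(trajectories: TrajectorySet, k: int, m: float | None = None,
               seed: int = 42, tol: float = 1e-6, max_iter: int = 1000,
               n_init: int = 3) -> ClusterModel:
    """Fit fuzzy c-means to a trajectory set.

    ``m`` defaults to the Schwaemmle-Jensen estimate from the set's size
    and age-grid length. ``n_init`` seeded restarts are run and the fit
    with the lowest objective kept (deterministic given ``seed``).
    """
    X = trajectories.data.to_numpy(dtype=float)
    if m is None:
        m = estimate_fuzzifier(max(len(X), 3), X.shape[1])
    best = None
    for r in range(max(n_init, 1)):
        fit = cmeans(X, k, m, seed + r, tol=tol, max_iter=max_iter)
        if best is None or fit[3] < best[3]:
            best = fit
    centers, u, n_iter, obj = best
    membership = pd.DataFrame(u, index=trajectories.data.index,
                              columns=range(k))
    return ClusterModel(k=k, m=float(m), centers=centers,
                        membership=membership, seed=seed, n_iter=n_iter,
                        objective=obj)


def select_k(trajectories: TrajectorySet, k_range=range(2, 201),
             m: float | None = None, seed: int = 42,
             tol: float = 1e-4, max_iter: int = 200) -> pd.DataFrame:
    """Minimum pairwise centroid distance per k (elbow diagnostic for
    choosing the cluster count; no automatic selection)."""
    rows = []
    for k in k_range:
        model = cmeans_fit(trajectories, k, m=m, seed=seed, tol=tol,
                           max_iter=max_iter)
        c = model.centers
        if k < 2:
            mind = np.nan
        else:
            d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(axis=2))
            mind = float(d[np.triu_indices(k, 1)].min())
        rows.append({"k": k, "min_centroid_distance": mind})
    return pd.DataFrame(rows)


def assign_and_filter(model: ClusterModel, min_membership: float = 0.15
                      ) -> pd.DataFrame:
    """Assign each trajectory to its argmax cluster; discard strictly
    below ``min_membership``. Returns a frame indexed like the
    trajectories with columns cluster / membership / assigned."""
    u = model.membership.to_numpy()
    best = u.argmax(axis=1)
    best_u = u[np.arange(len(u)), best]
    return pd.DataFrame({
        "cluster": best,
        "membership": best_u,
        "assigned": best_u >= min_membership,
    }, index=model.membership.index)


def characterize(model: ClusterModel, assignments: pd.DataFrame,
                 region_frac_threshold: float = 0.30,
                 feature_count_threshold: int = 4
                 ) -> list[ClusterProfile]:
    """Cluster profiles from assignments; singleton clusters excluded.

    A cluster is region-specific if one region holds >= 30% of its
    members and feature-specific if one feature occurs >= 4 times.
    """
    kept = assignments[assignments["assigned"]]
    profiles = []
    for c, sub in kept.groupby("cluster"):
        if len(sub) <= 1:
            continue      # singleton clusters carry no composition signal
        regions = sub.index.get_level_values("region")
        features = sub.index.get_level_values("feature")
        rfrac = regions.value_counts(normalize=True).to_dict()
        fcount = features.value_counts().to_dict()
        profiles.append(ClusterProfile(
            cluster=int(c), size=len(sub),
            region_fractions=rfrac, feature_counts=fcount,
            region_specific=max(rfrac.values()) >= region_frac_threshold,
            feature_specific=max(fcount.values()) >= feature_count_threshold,
            center=model.centers[c],
        ))
    return profiles
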