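"""Principal Variance Component Analysis.

PCA of the feature-standardized expression matrix followed, for each
retained principal component, by a random-effects variance decomposition
over the declared experimental factors and their two-way interactions.
The reported share per factor is the eigenvalue-fraction-weighted average
of the per-PC variance proportions, renormalized to sum to one.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PvcaResult", "pvca", "pvca_by_region"]


@dataclass
class PvcaResult:
    """Weighted variance proportions per factor label ('a:b' = interaction)."""

    proportions: pd.Series              # label -> share, sums to 1
    per_pc: pd.DataFrame                # PC x label proportion table
    eigenvalue_fractions: np.ndarray    # of the retained PCs
    n_pcs: int
    dropped_factors: list = field(default_factory=list)

    def summary(self, min_share: float = 1e-6) -> pd.Series:
        """Reported table: interaction terms with vanishing share omitted."""
        keep = [lab for lab, v in self.proportions.items()
                if ":" not in lab or v >= min_share]
        return self.proportions[keep]


def _design_matrix(levels: pd.Series) -> np.ndarray:
    """0/1 incidence matrix sample x level."""
    cats = pd.Categorical(levels)
    Z = np.zeros((len(levels), len(cats.categories)))
    Z[np.arange(len(levels)), cats.codes] = 1.0
    return Z


def _em_reml(y: np.ndarray, Zs: list[np.ndarray], tol: float = 1e-8,
             max_iter: int = 500) -> np.ndarray:
    """EM-REML for y = mu + sum_k Z_k u_k + e; returns variance components
    (sigma^2_1..K, sigma^2_e), each clipped at zero."""
    n = y.size
    y = y - y.mean()
    K = len(Zs)
    q = np.array([Z.shape[1] for Z in Zs], dtype=float)
    var0 = y.var(ddof=1) if n > 1 else 1.0
    sig = np.full(K + 1, var0 / (K + 1))
    ZZt = [Z @ Z.T for Z in Zs]
    X = np.ones((n, 1))
    for _ in range(max_iter):
        V = sig[-1] * np.eye(n)
        for k in range(K):
            V += sig[k] * ZZt[k]
        Vinv = np.linalg.inv(V)
        VX = Vinv @ X
        P = Vinv - VX @ np.linalg.solve(X.T @ VX, VX.T)
        Py = P @ y
        new = np.empty_like(sig)
        for k in range(K):
            # tr(P @ ZZt) via elementwise product (both symmetric)
            new[k] = sig[k] + (sig[k] ** 2 / q[k]) * (
                Py @ ZZt[k] @ Py - (P * ZZt[k]).sum())
        new[-1] = sig[-1] + (sig[-1] ** 2 / (n - 1)) * (
            Py @ Py - np.trace(P))
        new = np.clip(new, 0.0, None)
        if new.sum() == 0:
            new[-1] = var0
        delta = np.abs(new - sig).max()
        sig = new
        if delta < tol * max(var0, 1.0):
            break
    return sig


def pvca(expr: pd.DataFrame, meta: pd.DataFrame, factors: list[str],
         pc_var_threshold: float = 0.6, interactions: bool = True,
         tol: float = 1e-8, max_iter: int = 500) -> PvcaResult:
    """Attribute expression variance to metadata factors.

    Parameters
    ----------
    expr : features x samples expression matrix (rpmm); standardized
        per feature internally.
    factors : metadata columns treated as random effects. Factors with a
        single observed level are dropped with a warning.
    pc_var_threshold : retain the first K PCs whose cumulative explained
        variance first reaches this fraction.
    """
    samples = list(expr.columns)
    if len(samples) < 3:
        raise ValueError("PVCA needs at least 3 samples")
    sub = meta.loc[samples]
    used, dropped = [], []
    for f in factors:
        if sub[f].nunique() < 2:
            warnings.warn(f"factor {f!r} has a single level; dropped")
            dropped.append(f)
        else:
            used.append(f)
    if not used:
        raise ValueError("no usable factors (all single-level)")

    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    X = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    # PCs of the sample-sample covariance
    n = X.shape[1]
    C = (X.T @ X) / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    frac = evals / evals.sum()
    K = int(np.searchsorted(np.cumsum(frac), pc_var_threshold) + 1)
    K = min(K, n)
    scores = evecs[:, :K] * np.sqrt(np.clip(evals[:K], 0, None))

    labels = list(used)
    Zs = [_design_matrix(sub[f]) for f in used]
    if interactions:
        for a, b in itertools.combinations(used, 2):
            combo = sub[a].astype(str) + "␟" + sub[b].astype(str)
            if combo.nunique() > max(sub[a].nunique(), sub[b].nunique()):
                labels.append(f"{a}:{b}")
                Zs.append(_design_matrix(combo))
    labels.append("residual")

    per_pc = np.zeros((K, len(labels)))
    for i in range(K):
        sig = _em_reml(scores[:, i], Zs, tol=tol, max_iter=max_iter)
        per_pc[i] = sig / sig.sum()
    w = frac[:K] / frac[:K].sum()
    weighted = w @ per_pc
    weighted = weighted / weighted.sum()
    return PvcaResult(
        proportions=pd.Series(weighted, index=labels),
        per_pc=pd.DataFrame(per_pc, index=[f"PC{i+1}" for i in range(K)],
                            columns=labels),
        eigenvalue_fractions=frac[:K],
        n_pcs=K,
        dropped_factors=dropped,
    )


def pvca_by_region(expr: pd.DataFrame, meta: pd.DataFrame,
                   factors=("age_months", "sex"),
                   pc_var_threshold: float = 0.6) -> pd.DataFrame:
    """Per-region PVCA over the given factors (default age and sex),
    including their interaction share. Regions failing the preconditions
    are skipped with a warning."""
    rows = {}
    for region, sub in meta.groupby("region", observed=True):
        cols = [s for s in expr.columns if s in set(sub.index)]
        try:
            res = pvca(expr[cols], meta, list(factors),
                       pc_var_threshold=pc_var_threshold)
        except ValueError as e:
            warnings.warn(f"region {region!r} skipped: {e}")
            continue
        rows[region] = res.proportions
    return pd.DataFrame(rows).T
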