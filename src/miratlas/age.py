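"""Age- and sex-association screening.

Spearman age-correlation per (feature, region) with BH control and an
AS 89-style exact/Edgeworth p-value, Welch's-t differential expression of
older ages against the 3-month reference with fold-change thresholds,
the unique/multiple/candidate taxonomy, cross-sex aging features, Cohen's
d effect sizes, enrichment rank lists, and the human age-binning preset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, spearman_matrix


def _center_rows(X: np.ndarray, kind: str) -> np.ndarray:
    """Row-wise group center: median, geometric mean/median
    (zero-excluded, consistent with the scalar forms in .stats)."""
    if kind == "median":
        return np.median(X, axis=1)
    if kind in ("geometric_mean", "geometric_median"):
        agg = np.mean if kind == "geometric_mean" else np.median
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            pos = row[row > 0]
            out[i] = np.exp(agg(np.log(pos))) if pos.size else 0.0
        return out
    raise ValueError(f"unknown center statistic: {kind!r}")

__all__ = [
    "spearman_age", "classify_correlation", "differential_expression",
    "age_contrasts", "unique_multiple", "candidate_set",
    "rank_for_enrichment", "bin_human_ages", "effect_size_filter",
    "intersect_reference", "cross_sex_features",
]

HUMAN_AGE_BINS = ((71, 81), (81, 92), (92, 103))


def spearman_age(expr: pd.DataFrame, meta: pd.DataFrame,
                 stratify_by=("region",)) -> pd.DataFrame:
    """Spearman correlation of every feature with age, per stratum.

    BH adjustment is applied within each stratum's feature family.
    Strata with fewer than 3 samples are skipped; constant features are
    reported with missing R/p.
    """
    stratify_by = list(stratify_by)
    meta = meta.loc[list(expr.columns)]
    frames = []
    for key, sub in meta.groupby(stratify_by, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        if len(sub) < 3:
            continue
        X = expr[list(sub.index)].to_numpy(dtype=float)
        age = sub["age_months"].to_numpy(dtype=float)
        r, p = spearman_matrix(X, age)
        frame = pd.DataFrame({
            "feature": expr.index,
            "R": r, "p_raw": p, "p_adj": bh_adjust(p),
            "n": len(sub),
        })
        for col, val in zip(stratify_by, key):
            frame[col] = val
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=["feature", "R", "p_raw", "p_adj", "n",
                                     *stratify_by])
    return pd.concat(frames, ignore_index=True)


def classify_correlation(results: pd.DataFrame, r_threshold: float = 0.5,
                         alpha: float = 0.05,
                         inclusive: bool = False) -> pd.DataFrame:
    """Label each row sig-positive / sig-negative / sig-only / ns.

    sig-positive: p_adj < alpha and R > r_threshold (>= if ``inclusive``);
    sig-only: significant but |R| below the strength threshold.
    """
    out = results.copy()
    sig = out["p_adj"] < alpha
    if inclusive:
        pos, neg = out["R"] >= r_threshold, out["R"] <= -r_threshold
    else:
        pos, neg = out["R"] > r_threshold, out["R"] < -r_threshold
    label = np.where(~sig | out["R"].isna(), "ns",
                     np.where(pos, "sig-positive",
                              np.where(neg, "sig-negative", "sig-only")))
    out["label"] = label
    return out


def differential_expression(expr: pd.DataFrame, meta: pd.DataFrame,
                            group_col: str, value_a, value_b,
                            stratify_by=("region",),
                            center: str = "median", alpha: float = 0.05,
                            fc_threshold: float = 1.5) -> pd.DataFrame:
    """Welch's-t differential expression of group A vs group B per stratum.

    Fold change is the ratio of group centers (A over B). Features with
    fold change exactly 1 are removed before testing; features whose
    reference center is zero are excluded with an ``undefined_fc`` flag.
    The significance flag requires p_adj < alpha and fc >= fc_threshold
    or <= 1/fc_threshold. BH runs within each (stratum, contrast) family.
    """
    stratify_by = list(stratify_by)
    meta = meta.loc[list(expr.columns)]
    comparison = f"{value_a}-vs-{value_b}"
    frames = []
    groups = (meta.groupby(stratify_by, observed=True) if stratify_by
              else [((), meta)])
    for key, sub in groups:
        key = key if isinstance(key, tuple) else (key,)
        a_ids = sub.index[sub[group_col] == value_a]
        b_ids = sub.index[sub[group_col] == value_b]
        if len(a_ids) < 2 or len(b_ids) < 2:
            continue
        A = expr[list(a_ids)].to_numpy(dtype=float)
        B = expr[list(b_ids)].to_numpy(dtype=float)
        ca = _center_rows(A, center)
        cb = _center_rows(B, center)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = ca / cb
        undefined = (ca == 0) | (cb == 0)
        fc[undefined] = np.nan
        flat = fc == 1.0            # no deregulation: removed before testing
        with np.errstate(invalid="ignore"):
            log2fc = np.log2(fc)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_res = sps.ttest_ind(A, B, axis=1, equal_var=False)
            p = np.asarray(t_res.pvalue, dtype=float)
        p[undefined | flat] = np.nan
        # both groups constant -> test undefined
        both_flat = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
        p[both_flat] = np.nan
        na, nb = A.shape[1], B.shape[1]
        pooled = np.sqrt(((na - 1) * A.var(axis=1, ddof=1)
                          + (nb - 1) * B.var(axis=1, ddof=1))
                         / (na + nb - 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            d = (A.mean(axis=1) - B.mean(axis=1)) / pooled
        d[pooled == 0] = np.nan
        d[undefined] = np.nan
        frame = pd.DataFrame({
            "feature": expr.index, "fold_change": fc, "log2_fc": log2fc,
            "p_raw": p, "cohen_d": d, "undefined_fc": undefined,
        })
        frame["p_adj"] = bh_adjust(frame["p_raw"].to_numpy())
        frame["n_a"], frame["n_b"] = len(a_ids), len(b_ids)
        frame["comparison"] = comparison
        for col, val in zip(stratify_by, key):
            frame[col] = val
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=["feature", "fold_change", "log2_fc",
                                     "p_raw", "cohen_d", "undefined_fc",
                                     "p_adj", "n_a", "n_b", "comparison",
                                     *stratify_by])
    out = pd.concat(frames, ignore_index=True)
    up = out["fold_change"] >= fc_threshold
    down = out["fold_change"] <= 1.0 / fc_threshold
    out["significant"] = (out["p_adj"] < alpha) & (up | down)
    out["direction"] = np.where(out["fold_change"] > 1, "up",
                                np.where(out["fold_change"] < 1, "down",
                                         "none"))
    return out


def age_contrasts(expr: pd.DataFrame, meta: pd.DataFrame,
                  reference_age: float = 3, stratify_by=("region",),
                  center: str = "median", alpha: float = 0.05,
                  fc_threshold: float = 1.5) -> pd.DataFrame:
    """DE of every older age against the reference age, per stratum."""
    ages = sorted(a for a in set(meta["age_months"]) if a != reference_age)
    frames = [
        differential_expression(expr, meta, "age_months", a, reference_age,
                                stratify_by=stratify_by, center=center,
                                alpha=alpha, fc_threshold=fc_threshold)
        for a in ages
    ]
    frames = [f for f in frames if len(f)]
    return (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame())


def unique_multiple(sig: pd.DataFrame, direction_col: str,
                    region_col: str = "region") -> pd.DataFrame:
    """Scope annotation per (feature, direction) from per-region significant
    rows: unique (one region) or multiple (>1 region, same direction)."""
    rows = []
    for (f, d), sub in sig.groupby(["feature", direction_col],
                                   observed=True):
        regions = sorted(set(sub[region_col]))
        rows.append({"feature": f, "direction": d,
                     "scope": "unique" if len(regions) == 1 else "multiple",
                     "n_regions": len(regions),
                     "regions": "|".join(regions)})
    return pd.DataFrame(rows, columns=["feature", "direction", "scope",
                                       "n_regions", "regions"])


def candidate_set(corr_labeled: pd.DataFrame, de: pd.DataFrame,
                  region_col: str = "region") -> pd.DataFrame:
    """Aging candidates: features significantly age-correlated in >= 1
    region or significantly deregulated in >= 1 age comparison.

    A feature is one candidate even if its direction flips between
    regions; per-feature evidence, direction(s), scope, and cross-region
    counts are reported.
    """
    corr_sig = corr_labeled[
        corr_labeled["label"].isin(["sig-positive", "sig-negative"])]
    de_sig = de[de["significant"]] if len(de) else de
    per_feature: dict[str, dict] = {}
    for _, row in corr_sig.iterrows():
        d = "up" if row["label"] == "sig-positive" else "down"
        rec = per_feature.setdefault(row["feature"], {
            "corr_regions": {}, "de_regions": {}})
        rec["corr_regions"].setdefault(row[region_col], set()).add(d)
    if len(de_sig):
        for _, row in de_sig.iterrows():
            rec = per_feature.setdefault(row["feature"], {
                "corr_regions": {}, "de_regions": {}})
            rec["de_regions"].setdefault(row[region_col], set()).add(
                row["direction"])
    rows = []
    for f, rec in sorted(per_feature.items()):
        regions = set(rec["corr_regions"]) | set(rec["de_regions"])
        dirs = set().union(*rec["corr_regions"].values(), set()) | \
            set().union(*rec["de_regions"].values(), set())
        evidence = ("both" if rec["corr_regions"] and rec["de_regions"]
                    else "correlation" if rec["corr_regions"]
                    else "deregulation")
        rows.append({
            "feature": f, "evidence": evidence,
            "direction": "|".join(sorted(dirs)),
            "scope": "unique" if len(regions) == 1 else "multiple",
            "n_regions": len(regions),
            "regions": "|".join(sorted(regions)),
        })
    return pd.DataFrame(rows, columns=["feature", "evidence", "direction",
                                       "scope", "n_regions", "regions"])


def cross_sex_features(candidates_by_sex: dict[str, pd.DataFrame]
                       ) -> pd.DataFrame:
    """Candidates with same-direction evidence in both sex strata."""
    male = candidates_by_sex.get("male")
    female = candidates_by_sex.get("female")
    if male is None or female is None or not len(male) or not len(female):
        return pd.DataFrame(columns=["feature", "direction"])
    rows = []
    fm = male.set_index("feature")
    ff = female.set_index("feature")
    for f in sorted(set(fm.index) & set(ff.index)):
        dm = set(str(fm.loc[f, "direction"]).split("|"))
        df_ = set(str(ff.loc[f, "direction"]).split("|"))
        shared = (dm & df_) - {""}
        for d in sorted(shared):
            rows.append({"feature": f, "direction": d})
    return pd.DataFrame(rows, columns=["feature", "direction"])


def rank_for_enrichment(results: pd.DataFrame, effect_col: str = "log2_fc",
                        p_col: str = "p_raw") -> list[str]:
    """Single ranked feature list for GSEA submission.

    Positive-effect features sorted by ascending p (most significant
    first) head the list; negative-effect features sorted by descending p
    form the tail, so the most significant negatives end the list. Ties
    break by |effect| (larger first) then feature id.
    """
    res = results.dropna(subset=[effect_col, p_col])
    pos = res[res[effect_col] > 0].copy()
    neg = res[res[effect_col] < 0].copy()
    pos["_abs"] = pos[effect_col].abs()
    neg["_abs"] = neg[effect_col].abs()
    pos = pos.sort_values([p_col, "_abs", "feature"],
                          ascending=[True, False, True], kind="mergesort")
    neg = neg.sort_values([p_col, "_abs", "feature"],
                          ascending=[False, True, True], kind="mergesort")
    return list(pos["feature"]) + list(neg["feature"])


def bin_human_ages(meta: pd.DataFrame, age_col: str = "age_years",
                   bins=HUMAN_AGE_BINS) -> pd.Series:
    """Half-open age-of-death bins [71,81), [81,92), [92,103)."""
    ages = meta[age_col]
    lo, hi = bins[0][0], bins[-1][1]
    bad = ages[(ages < lo) | (ages >= hi)]
    if len(bad):
        raise ValueError(f"ages outside [{lo},{hi}): "
                         f"{sorted(bad.unique().tolist())}")
    labels = pd.Series(index=meta.index, dtype=object)
    for a, b in bins:
        labels[(ages >= a) & (ages < b)] = f"[{a},{b})"
    return labels


def effect_size_filter(de: pd.DataFrame,
                       d_threshold: float = 0.5) -> pd.DataFrame:
    """Deregulated features with |Cohen's d| >= threshold (age-related
    candidates in the human preset)."""
    sig = de[de["significant"]] if "significant" in de else de
    return sig[sig["cohen_d"].abs() >= d_threshold]


def intersect_reference(candidates: pd.DataFrame, reference: set[str],
                        region_col: str = "regions") -> pd.DataFrame:
    """Per-region overlap of the candidate features with a reference
    feature list (e.g. cholinergic-signaling miRNAs)."""
    counts: dict[str, list] = {}
    for _, row in candidates.iterrows():
        if row["feature"] not in reference:
            continue
        for r in str(row[region_col]).split("|"):
            counts.setdefault(r, []).append(row["feature"])
    rows = [{"region": r, "n_overlap": len(fs),
             "features": "|".join(sorted(fs))}
            for r, fs in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["region", "n_overlap", "features"])
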