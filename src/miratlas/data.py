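"""Data model, TSV I/O, rpmm normalization, and the QC/filtering rules.

Counts are held as an integer feature x sample DataFrame together with a
per-feature RNA-class Series; sample annotations live in a metadata
DataFrame keyed by sample id. All downstream statistics run on the
rpmm-normalized (reads per million mapped) expression matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

ATLAS_REGIONS = (
    "corpus callosum", "choroid plexus", "SVZ",
    "hippocampus anterior", "hippocampus posterior", "hypothalamus",
    "thalamus", "caudate putamen", "pons", "medulla", "cerebellum",
    "olfactory bulb", "motor cortex", "entorhinal cortex", "visual cortex",
)
ATLAS_AGES = (3, 12, 15, 18, 21, 26, 28)

RNA_CLASSES = ("miRNA", "lncRNA", "piRNA", "rRNA", "scaRNA",
               "snoRNA", "snRNA", "tRNA")

META_COLUMNS = ("sample_id", "region", "age_months", "sex", "cohort",
                "aligned_reads")

#: cohort presets: (min aligned reads, feature-filter min raw count)
COHORT_THRESHOLDS = {
    "aging": (2_000_000, 5),
    "aDR": (2_000_000, 5),
    "YMP": (2_000_000, 5),
    "microglia": (1_800_000, 5),
    "human": (10_000, 2),
}


class SchemaError(ValueError):
    """Input table violates the expected schema."""


@dataclass
class CountTable:
    """Integer feature x sample matrix with per-feature RNA class labels."""

    counts: pd.DataFrame            # features x samples, integer
    feature_class: pd.Series        # index = feature ids

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise SchemaError(f"duplicate feature id: {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise SchemaError(f"duplicate sample id: {dup!r}")
        if (self.counts.to_numpy() < 0).any():
            raise SchemaError("negative counts present")
        self.feature_class = self.feature_class.reindex(self.counts.index)

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset(self, features=None, samples=None) -> "CountTable":
        c = self.counts
        if features is not None:
            c = c.loc[list(features)]
        if samples is not None:
            c = c[list(samples)]
        return CountTable(c, self.feature_class.reindex(c.index))


@dataclass
class FilterReport:
    """Bookkeeping of a QC step: what went in, what was dropped, and why."""

    step: str
    samples_in: int
    samples_out: int
    features_in: int
    features_out: int
    dropped_sample_ids: list = field(default_factory=list)
    dropped_feature_ids: list = field(default_factory=list)
    dropped_regions: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.samples_in == self.samples_out + len(self.dropped_sample_ids)
        assert self.features_in == self.features_out + len(self.dropped_feature_ids)

    def to_dict(self) -> dict:
        return asdict(self)


def validate_metadata(meta: pd.DataFrame,
                      known_regions=None) -> pd.DataFrame:
    """Check metadata invariants; returns the frame indexed by sample_id."""
    for col in META_COLUMNS:
        if col not in meta.columns and meta.index.name != col:
            raise SchemaError(f"metadata missing required column: {col!r}")
    if meta.index.name != "sample_id":
        meta = meta.set_index("sample_id")
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise SchemaError(f"duplicate sample id: {dup!r}")
    if (meta["age_months"] <= 0).any():
        raise SchemaError("age_months must be positive")
    bad_sex = set(meta["sex"]) - {"male", "female"}
    if bad_sex:
        raise SchemaError(f"unknown sex labels: {sorted(bad_sex)}")
    if known_regions is not None:
        bad = set(meta["region"]) - set(known_regions)
        if bad:
            raise SchemaError(f"unknown region labels: {sorted(bad)}")
    return meta


def read_counts(counts_path, meta_path,
                known_regions=None) -> tuple[CountTable, pd.DataFrame]:
    """Read a counts TSV (feature_id, feature_class, <samples...>) + metadata TSV."""
    raw = pd.read_csv(counts_path, sep="\t", dtype={0: str, 1: str})
    for col in ("feature_id", "feature_class"):
        if col not in raw.columns:
            raise SchemaError(f"counts table missing column: {col!r}")
    raw = raw.set_index("feature_id")
    fclass = raw.pop("feature_class")
    for col in raw.columns:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            row = raw.index[bad.to_numpy()][0]
            raise SchemaError(
                f"non-integer count at feature {row!r}, sample {col!r}")
        raw[col] = vals.astype(np.int64)
    meta = validate_metadata(pd.read_csv(meta_path, sep="\t"), known_regions)
    table = CountTable(raw, fclass)
    missing = set(table.sample_ids) - set(meta.index)
    if missing:
        raise SchemaError(f"samples without metadata: {sorted(missing)[:5]}")
    meta = meta.loc[list(table.sample_ids)]
    return table, meta


def write_counts(table: CountTable, meta: pd.DataFrame,
                 counts_path, meta_path) -> None:
    out = table.counts.copy()
    out.insert(0, "feature_class", table.feature_class)
    out.index.name = "feature_id"
    out.to_csv(counts_path, sep="\t")
    meta.to_csv(meta_path, sep="\t")


def rpmm_normalize(table: CountTable,
                   denominator_class: str = "all") -> pd.DataFrame:
    """Reads-per-million-mapped: counts scaled so the denominator-class
    column total is 1e6 in every sample.

    ``denominator_class`` selects which feature class forms the per-sample
    denominator ("all" = every feature in the table).
    """
    counts = table.counts
    if denominator_class == "all":
        denom = counts.sum(axis=0)
    else:
        mask = table.feature_class == denominator_class
        denom = counts.loc[mask.to_numpy()].sum(axis=0)
    zero = denom[denom == 0]
    if len(zero):
        raise ValueError(
            f"zero normalization denominator for sample(s): "
            f"{list(zero.index[:5])}")
    return counts / denom * 1e6


def filter_samples(table: CountTable, meta: pd.DataFrame,
                   min_aligned: int = 2_000_000
                   ) -> tuple[CountTable, pd.DataFrame, FilterReport]:
    """Keep samples with strictly more than ``min_aligned`` aligned reads."""
    keep = meta["aligned_reads"] > min_aligned
    kept = meta.index[keep]
    report = FilterReport(
        step="filter_samples",
        samples_in=len(meta), samples_out=int(keep.sum()),
        features_in=len(table.feature_ids), features_out=len(table.feature_ids),
        dropped_sample_ids=list(meta.index[~keep]),
        thresholds={"min_aligned": min_aligned},
    )
    return table.subset(samples=kept), meta.loc[kept], report


def filter_features(table: CountTable, meta: pd.DataFrame,
                    group_by=("region", "age_months", "sex"),
                    min_count: int = 5, min_frac: float = 0.10
                    ) -> tuple[CountTable, FilterReport]:
    """Keep a feature iff in >=1 group, >= ``min_frac`` of its samples have
    raw count >= ``min_count`` (both bounds inclusive)."""
    group_by = list(group_by)
    if not group_by:
        raise ValueError("empty grouping")
    ge = table.counts.to_numpy() >= min_count
    keep = np.zeros(len(table.feature_ids), dtype=bool)
    cols = {s: i for i, s in enumerate(table.sample_ids)}
    for _, sub in meta.groupby(group_by, observed=True):
        idx = [cols[s] for s in sub.index]
        frac = ge[:, idx].mean(axis=1)
        keep |= frac >= min_frac
    kept = table.feature_ids[keep]
    report = FilterReport(
        step="filter_features",
        samples_in=len(meta), samples_out=len(meta),
        features_in=len(table.feature_ids), features_out=int(keep.sum()),
        dropped_feature_ids=list(table.feature_ids[~keep]),
        thresholds={"min_count": min_count, "min_frac": min_frac,
                    "group_by": group_by},
    )
    return table.subset(features=kept), report


def drop_sparse_regions(table: CountTable, meta: pd.DataFrame,
                        min_samples: int = 4
                        ) -> tuple[CountTable, pd.DataFrame, FilterReport]:
    """Drop every sample of a region left with fewer than ``min_samples``
    samples (the study removes regions with three or fewer)."""
    sizes = meta.groupby("region", observed=True).size()
    bad_regions = list(sizes.index[sizes < min_samples])
    keep = ~meta["region"].isin(bad_regions)
    kept = meta.index[keep]
    report = FilterReport(
        step="drop_sparse_regions",
        samples_in=len(meta), samples_out=int(keep.sum()),
        features_in=len(table.feature_ids), features_out=len(table.feature_ids),
        dropped_sample_ids=list(meta.index[~keep]),
        dropped_regions=bad_regions,
        thresholds={"min_samples": min_samples},
    )
    return table.subset(samples=kept), meta.loc[kept], report


def expressed_in_region(table: CountTable, meta: pd.DataFrame, region: str,
                        min_count: int = 5, min_frac: float = 0.10
                        ) -> set[str]:
    """Features with raw count >= ``min_count`` in >= ``min_frac`` of the
    region's samples."""
    samples = meta.index[meta["region"] == region]
    if len(samples) == 0:
        raise ValueError(f"unknown or empty region: {region!r}")
    sub = table.counts[list(samples)]
    frac = (sub >= min_count).mean(axis=1)
    return set(table.feature_ids[(frac >= min_frac).to_numpy()])


def composition_summary(table: CountTable, meta: pd.DataFrame,
                        by=("region",), min_count: int = 5,
                        min_frac: float = 0.10) -> pd.DataFrame:
    """Per-group relative raw-count share of each RNA class, computed over
    the features expressed (10%/>=5 rule) in the group's region."""
    by = list(by)
    rows = []
    for key, sub in meta.groupby(by, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        region = key[by.index("region")] if "region" in by else None
        if region is not None:
            expressed = expressed_in_region(table, meta, region,
                                            min_count, min_frac)
        else:
            frac = (table.counts[list(sub.index)] >= min_count).mean(axis=1)
            expressed = set(table.feature_ids[(frac >= min_frac).to_numpy()])
        sub_counts = table.counts.loc[
            table.feature_ids.isin(expressed), list(sub.index)]
        totals = sub_counts.groupby(
            table.feature_class.reindex(sub_counts.index), observed=True
        ).sum().sum(axis=1)
        total = totals.sum()
        for cls, t in totals.items():
            rows.append(dict(zip(by, key)) | {
                "feature_class": cls,
                "share": t / total if total > 0 else np.nan,
            })
    return pd.DataFrame(rows)
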