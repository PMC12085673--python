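"""Synthetic atlas generator with planted, recoverable structure.

Emulates the design of a spatio-temporal brain small-RNA profiling study:
a grid of brain regions x ages x sexes with a few replicates per cell,
negative-binomial counts with library-size variation, and planted
region-specific, sex-linked, and aging features whose ground truth is
returned alongside the data so every downstream stage can be scored.

Counts for feature f in sample s are drawn NB(mu, alpha) with
Var = mu + alpha*mu^2 and

    log2 mu_fs = baseline_f + region_f(r_s) + sex_f(x_s) + g_f(age_s)
                 + log2(library factor_s)

Age trajectories g_f are linear ramps, a step at 15 months, or a peak at
15 months, applied on the log scale (mirrors the abrupt mid-life switch
seen in ventricular tissue and the transient pons pattern).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ATLAS_AGES, ATLAS_REGIONS, CountTable

DEFAULT_REGIONS = ("choroid plexus", "SVZ", "pons", "medulla",
                   "olfactory bulb", "motor cortex")
DEFAULT_AGES = (3, 12, 15, 21)

TRAJECTORY_SHAPES = ("linear", "step@15", "peak@15", "constant")


@dataclass
class PlantedEffect:
    feature: str
    regions: tuple        # region labels the effect applies to
    log2_effect: float


@dataclass
class PlantedAging:
    feature: str
    regions: tuple
    shape: str            # one of TRAJECTORY_SHAPES
    direction: int        # +1 up with age, -1 down
    magnitude: float      # total log2 change across the age span

    def __post_init__(self) -> None:
        if self.shape not in TRAJECTORY_SHAPES:
            raise ValueError(f"unknown trajectory shape: {self.shape!r}")


@dataclass
class PlantedTarget:
    mirna: str
    gene: str
    rho: float            # target Spearman correlation, negative

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("|rho| must be < 1")


@dataclass
class SimConfig:
    """Study-design parameters of the simulated atlas.

    The default is a shrunk grid (6 regions x 4 ages x 2 sexes x 4
    replicates, 300 features) so a full analysis runs in seconds; the
    study-scale grid is available via :func:`full_atlas_config`.
    """

    seed: int
    regions: Sequence[str] = DEFAULT_REGIONS
    ages_months: Sequence[float] = DEFAULT_AGES
    sexes: Sequence[str] = ("male", "female")
    n_per_cell: int = 4
    n_features: int = 300
    library_size_mean: float = 3_000_000.0
    library_size_sigma: float = 0.25      # lognormal sigma of library factor
    nb_dispersion: float = 0.15           # alpha in Var = mu + alpha mu^2
    baseline_log2_mean: float = 9.0
    baseline_log2_sd: float = 2.5
    region_effect_sd: float = 0.0         # global region wobble for all features
    planted_region_specific: list = field(default_factory=list)
    planted_sex: list = field(default_factory=list)
    planted_aging: list = field(default_factory=list)
    planted_targets: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_per_cell <= 0:
            raise ValueError("n_per_cell must be positive")
        universe = set(self.feature_ids())
        for eff in (self.planted_region_specific + self.planted_sex
                    + self.planted_aging):
            if eff.feature not in universe:
                raise ValueError(f"planted feature outside universe: "
                                 f"{eff.feature!r}")

    def feature_ids(self) -> list[str]:
        return [f"mir-{i:04d}" for i in range(self.n_features)]


@dataclass
class PlantedTruth:
    """Realized ground truth: everything needed to score recovery."""

    region_specific: list
    sex: list
    aging: list
    targets: list
    ages: tuple
    regions: tuple

    def to_dict(self) -> dict:
        return {
            "region_specific": [asdict(e) for e in self.region_specific],
            "sex": [asdict(e) for e in self.sex],
            "aging": [asdict(e) for e in self.aging],
            "targets": [asdict(e) for e in self.targets],
            "ages": list(self.ages),
            "regions": list(self.regions),
        }


def default_config(seed: int, *, n_region_specific: int = 10,
                   n_sex: int = 6, n_aging: int = 12,
                   region_log2: float = 3.0, sex_log2: float = 1.5,
                   aging_log2: float = 2.0, **overrides) -> SimConfig:
    """Shrunk atlas with planted effects spread over features and regions."""
    cfg = SimConfig(seed=seed, **overrides)
    feats = cfg.feature_ids()
    regions = list(cfg.regions)
    rs, sx, ag = [], [], []
    j = 0
    for i in range(n_region_specific):
        rs.append(PlantedEffect(feats[j], (regions[i % len(regions)],),
                                region_log2))
        j += 1
    for i in range(n_sex):
        sx.append(PlantedEffect(feats[j], tuple(regions), sex_log2))
        j += 1
    shapes = ("linear", "linear", "step@15", "peak@15")
    for i in range(n_aging):
        shape = shapes[i % len(shapes)]
        direction = 1 if (i // len(shapes)) % 2 == 0 else -1
        # aging features span several regions -> cross-region candidates
        ag.append(PlantedAging(feats[j], tuple(regions[:4]), shape,
                               direction, aging_log2))
        j += 1
    cfg.planted_region_specific = rs
    cfg.planted_sex = sx
    cfg.planted_aging = ag
    cfg.planted_targets = [
        PlantedTarget(a.feature, f"Gene{i + 1:04d}", -0.8)
        for i, a in enumerate(ag[:2])
    ]
    return cfg


def full_atlas_config(seed: int, **overrides) -> SimConfig:
    """Study-scale grid: 15 regions x 7 ages x 2 sexes, 1174 features."""
    overrides.setdefault("regions", ATLAS_REGIONS)
    overrides.setdefault("ages_months", ATLAS_AGES)
    overrides.setdefault("n_per_cell", 5)
    overrides.setdefault("n_features", 1174)
    return SimConfig(seed=seed, **overrides)


def _age_profile(shape: str, direction: int, magnitude: float,
                 ages: np.ndarray) -> np.ndarray:
    """Log2 offset per age; changepoint for step/peak fixed at 15 months."""
    amin, amax = ages.min(), ages.max()
    span = max(amax - amin, 1e-12)
    if shape == "constant":
        g = np.zeros_like(ages, dtype=float)
    elif shape == "linear":
        g = (ages - amin) / span
    elif shape == "step@15":
        g = (ages >= 15).astype(float)
    elif shape == "peak@15":
        up = np.clip((ages - amin) / max(15 - amin, 1e-12), 0, 1)
        down = np.clip((amax - ages) / max(amax - 15, 1e-12), 0, 1)
        g = np.minimum(up, down)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return direction * magnitude * g


def expected_log2_mu(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noise-free log2 mean per (feature, sample-design-cell).

    Returns (log2mu, design) where design enumerates the sample grid and
    log2mu is features x design-cells, before library scaling.
    """
    rng = np.random.default_rng(config.seed)
    feats = config.feature_ids()
    baseline = rng.normal(config.baseline_log2_mean,
                          config.baseline_log2_sd, size=len(feats))
    cells = [(r, a, x)
             for r in config.regions
             for a in config.ages_months
             for x in config.sexes]
    design = pd.DataFrame(cells, columns=["region", "age_months", "sex"])
    L = np.tile(baseline[:, None], (1, len(cells)))
    fidx = {f: i for i, f in enumerate(feats)}
    ages_arr = design["age_months"].to_numpy(dtype=float)
    for eff in config.planted_region_specific:
        mask = design["region"].isin(eff.regions).to_numpy()
        L[fidx[eff.feature], mask] += eff.log2_effect
    for eff in config.planted_sex:
        mask = (design["region"].isin(eff.regions)
                & (design["sex"] == "male")).to_numpy()
        L[fidx[eff.feature], mask] += eff.log2_effect
    for eff in config.planted_aging:
        mask = design["region"].isin(eff.regions).to_numpy()
        g = _age_profile(eff.shape, eff.direction, eff.magnitude, ages_arr)
        L[fidx[eff.feature], mask] += g[mask]
    if config.region_effect_sd > 0:
        wobble = rng.normal(0, config.region_effect_sd,
                            size=(len(feats), len(config.regions)))
        rpos = {r: i for i, r in enumerate(config.regions)}
        cols = design["region"].map(rpos).to_numpy()
        L += wobble[:, cols]
    return pd.DataFrame(L, index=feats), design


def simulate_atlas(config: SimConfig
                   ) -> tuple[CountTable, pd.DataFrame, PlantedTruth]:
    """Draw the synthetic count table, metadata, and ground truth."""
    log2mu, design = expected_log2_mu(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows = []
    sample_cells = []
    for ci, cell in design.iterrows():
        for rep in range(config.n_per_cell):
            sample_cells.append((ci, cell, rep))
    n_samples = len(sample_cells)
    lib = config.library_size_mean * rng.lognormal(
        -config.library_size_sigma ** 2 / 2.0, config.library_size_sigma,
        size=n_samples)
    mu_rel = 2.0 ** log2mu.to_numpy()
    frac = mu_rel / mu_rel.sum(axis=0, keepdims=True)
    counts = np.empty((config.n_features, n_samples), dtype=np.int64)
    alpha = config.nb_dispersion
    for j, (ci, cell, rep) in enumerate(sample_cells):
        mu = frac[:, ci] * lib[j]
        if alpha > 0:
            r = 1.0 / alpha
            p = r / (r + mu)
            counts[:, j] = rng.negative_binomial(r, p)
        else:
            counts[:, j] = rng.poisson(mu)
        rows.append({
            "sample_id": f"S{j:04d}",
            "region": cell["region"],
            "age_months": cell["age_months"],
            "sex": cell["sex"],
            "cohort": "aging",
            "aligned_reads": int(counts[:, j].sum()),
        })
    meta = pd.DataFrame(rows).set_index("sample_id")
    table = CountTable(
        pd.DataFrame(counts, index=config.feature_ids(),
                     columns=meta.index),
        pd.Series("miRNA", index=config.feature_ids()),
    )
    truth = PlantedTruth(
        region_specific=list(config.planted_region_specific),
        sex=list(config.planted_sex),
        aging=list(config.planted_aging),
        targets=list(config.planted_targets),
        ages=tuple(config.ages_months),
        regions=tuple(config.regions),
    )
    return table, meta, truth


def simulate_annotation(config: SimConfig, n_clustered: int = 6,
                        cluster_span_bp: int = 8_000,
                        n_chromosomes: int = 4,
                        opposite_strand_frac: float = 0.3,
                        locus_len: tuple[int, int] = (60, 120)) -> str:
    """GFF3 text with one locus per feature; the first ``n_clustered``
    features are packed into one genomic cluster tighter than
    ``cluster_span_bp``. Deterministic given the config seed."""
    if cluster_span_bp <= 0:
        raise ValueError("cluster_span_bp must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    feats = config.feature_ids()
    chrom_len = 5_000_000
    lines = ["##gff-version 3"]
    for c in range(n_chromosomes):
        lines.append(f"##sequence-region chr{c + 1} 1 {chrom_len}")
    # clustered block on chr1
    base = int(rng.integers(100_000, 1_000_000))
    step = max(1, (cluster_span_bp - locus_len[1]) // max(n_clustered, 1))
    records = []
    for i, f in enumerate(feats):
        length = int(rng.integers(*locus_len))
        if i < n_clustered:
            chrom = "chr1"
            start = base + i * step
            strand = "+"
        else:
            chrom = f"chr{int(rng.integers(1, n_chromosomes + 1))}"
            start = int(rng.integers(1, chrom_len - length))
            strand = "-" if rng.random() < opposite_strand_frac else "+"
        records.append((chrom, start, start + length - 1, strand, f))
    for chrom, start, end, strand, f in records:
        lines.append("\t".join([
            chrom, "miratlas_sim", "miRNA", str(start), str(end), ".",
            strand, ".", f"ID={f};Name={f}",
        ]))
    return "\n".join(lines) + "\n"


def simulate_isomirs(config: SimConfig, table: CountTable,
                     meta: pd.DataFrame, archetypes: Sequence[str],
                     n_isomirs_per_archetype: int = 4,
                     canonical_start: float = 0.8,
                     drift: dict | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split each archetype's counts multinomially across isomiR variants.

    ``drift`` maps archetype -> total change of the canonical fraction
    across the age span (negative = canonical share falls with age). The
    remaining mass is spread evenly over the non-canonical variants.

    Returns (isomir_counts, variant_info) where variant_info holds
    (archetype, variant, canonical flag).
    """
    drift = drift or {}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    ages = np.asarray(sorted(set(meta["age_months"])), dtype=float)
    amin, amax = ages.min(), ages.max()
    span = max(amax - amin, 1e-12)
    var_rows, count_rows, index = [], [], []
    for arch in archetypes:
        if arch not in table.feature_ids:
            raise ValueError(f"archetype not in count table: {arch!r}")
        k = n_isomirs_per_archetype
        labels = [f"{arch}|canonical"] + [f"{arch}|iso{v}" for v in
                                          range(1, k)]
        for li, lab in enumerate(labels):
            var_rows.append({"archetype": arch, "variant": lab,
                             "canonical": li == 0})
        totals = table.counts.loc[arch]
        mat = np.zeros((k, len(totals)), dtype=np.int64)
        d = drift.get(arch, 0.0)
        for j, s in enumerate(totals.index):
            age = float(meta.loc[s, "age_months"])
            frac = canonical_start + d * (age - amin) / span
            if not 0.0 <= frac <= 1.0:
                raise ValueError(
                    f"canonical fraction outside [0,1] for {arch!r}: {frac}")
            probs = [frac] + [(1 - frac) / (k - 1)] * (k - 1) if k > 1 else [1.0]
            mat[:, j] = rng.multinomial(int(totals.iloc[j]), probs)
        count_rows.append(mat)
        index.extend(labels)
    counts = pd.DataFrame(np.vstack(count_rows), index=index,
                          columns=table.sample_ids)
    return counts, pd.DataFrame(var_rows).set_index("variant")


def simulate_mrna(config: SimConfig, expr: pd.DataFrame, meta: pd.DataFrame,
                  n_uncoupled_genes: int = 20
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """mRNA matrix with genes rank-coupled to planted miRNAs.

    A coupled gene attains (approximately) the configured negative Spearman
    correlation with its miRNA via a Gaussian copula on the miRNA's
    normal scores; uncoupled genes are independent lognormals.
    Returns (mrna_expr genes x samples, target mapping mirna_id/gene_id).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    samples = expr.columns
    n = len(samples)
    genes, rows, mapping = [], [], []
    from scipy import stats as sps
    for tgt in config.planted_targets:
        x = expr.loc[tgt.mirna].to_numpy(dtype=float)
        # normal scores of the miRNA ranks (copula margin)
        z = sps.norm.ppf((sps.rankdata(x) - 0.375) / (n + 0.25))
        rho_p = 2.0 * np.sin(np.pi * tgt.rho / 6.0)   # Spearman -> Pearson
        g = rho_p * z + np.sqrt(1 - rho_p ** 2) * rng.normal(size=n)
        genes.append(tgt.gene)
        rows.append(np.exp(2.0 + 0.5 * g))
        mapping.append({"mirna_id": tgt.mirna, "gene_id": tgt.gene,
                        "evidence": "planted"})
    for i in range(n_uncoupled_genes):
        gid = f"GeneNull{i:03d}"
        genes.append(gid)
        rows.append(np.exp(2.0 + 0.5 * rng.normal(size=n)))
        if config.planted_targets:
            mapping.append({"mirna_id": config.planted_targets[0].mirna,
                            "gene_id": gid, "evidence": "null"})
    mrna = pd.DataFrame(np.vstack(rows), index=genes, columns=samples)
    return mrna, pd.DataFrame(mapping)


def simulate_archetype_trajectories(seed: int, n_per_archetype: int = 40,
                                    noise_sd: float = 0.25,
                                    ages: Sequence[float] = ATLAS_AGES
                                    ) -> tuple[np.ndarray, np.ndarray]:
    """Standardized trajectories from three planted archetypes
    (steady increase, steady decrease, peak at 15 months) plus noise.

    Returns (matrix n_trajectories x n_ages, integer archetype labels).
    """
    rng = np.random.default_rng(seed)
    ages = np.asarray(ages, dtype=float)
    shapes = [
        _age_profile("linear", 1, 1.0, ages),
        _age_profile("linear", -1, 1.0, ages),
        _age_profile("peak@15", 1, 1.0, ages),
    ]
    rows, labels = [], []
    for k, shape in enumerate(shapes):
        for _ in range(n_per_archetype):
            v = shape + rng.normal(0, noise_sd, size=len(ages))
            v = (v - v.mean()) / v.std()
            rows.append(v)
            labels.append(k)
    return np.asarray(rows), np.asarray(labels)
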