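"""End-to-end orchestration: deterministic staged runs over a data
directory, with a manifest of output checksums.

The pipeline consumes the TSV/GFF3 inputs written by ``simulate`` (or
supplied by the user in the same layout) and materializes every stage's
result tables under an output directory:

    qc -> normalize -> [pvca | signature | age] -> trajectories
       -> neighborhood -> isomir -> targets -> report
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import age as age_mod
from . import data as data_mod
from . import genomic as genomic_mod
from . import integration as integ_mod
from . import signature as sig_mod
from . import trajectories as traj_mod
from .pvca import pvca, pvca_by_region
from .simulate import (default_config, simulate_annotation, simulate_atlas,
                       simulate_isomirs, simulate_mrna)

_FLOAT_FMT = "%.10g"

KNOWN_KEYS = {
    "seed", "cohort", "min_aligned", "min_count", "min_frac",
    "min_region_samples", "denominator_class", "signature_k",
    "z_threshold", "n_region_clusters", "r_threshold", "alpha",
    "fc_threshold", "center", "reference_age", "k_clusters",
    "min_membership", "fuzzifier", "window", "target_threshold",
    "pc_var_threshold",
}


@dataclass
class PipelineConfig:
    """All stage thresholds with the study's defaults."""

    seed: int = 1
    cohort: str = "aging"
    min_aligned: int = 2_000_000        # sample filter: strictly more reads
    min_count: int = 5                  # feature filter raw-count bound
    min_frac: float = 0.10
    min_region_samples: int = 4         # regions with <= 3 samples dropped
    denominator_class: str = "all"
    signature_k: int = 50
    z_threshold: float = 0.5
    n_region_clusters: int = 4
    r_threshold: float = 0.5
    alpha: float = 0.05
    fc_threshold: float = 1.5
    center: str = "median"
    reference_age: float = 3
    k_clusters: int = 8
    min_membership: float = 0.15
    fuzzifier: float | None = None
    window: int = 10_000
    target_threshold: float = 0.3
    pc_var_threshold: float = 0.6

    def __post_init__(self) -> None:
        if self.cohort in data_mod.COHORT_THRESHOLDS:
            ma, mc = data_mod.COHORT_THRESHOLDS[self.cohort]
            if self.min_aligned == 2_000_000 and self.min_count == 5:
                self.min_aligned, self.min_count = ma, mc

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class RunManifest:
    config: dict
    stages: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    wall_time_s: float = 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True,
                          default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def write_simulation(outdir, seed: int, **config_overrides) -> Path:
    """Generate the default synthetic atlas and write every input the
    pipeline reads (counts, metadata, annotation, isomiRs, mRNA,
    target mapping, planted truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = default_config(seed, **config_overrides)
    table, meta, truth = simulate_atlas(cfg)
    data_mod.write_counts(table, meta, outdir / "counts.tsv",
                          outdir / "metadata.tsv")
    (outdir / "annotation.gff3").write_text(simulate_annotation(cfg))
    arch = [t.mirna for t in cfg.planted_targets][:2]
    iso_counts, iso_info = simulate_isomirs(
        cfg, table, meta, archetypes=arch,
        drift={a: -0.2 for a in arch})
    iso_out = iso_counts.copy()
    iso_out.insert(0, "archetype", iso_info["archetype"])
    iso_out.insert(1, "canonical", iso_info["canonical"].astype(int))
    iso_out.index.name = "variant"
    _write(iso_out, outdir / "isomirs.tsv")
    expr = data_mod.rpmm_normalize(table)
    mrna, mapping = simulate_mrna(cfg, expr, meta)
    mrna.index.name = "gene_id"
    _write(mrna, outdir / "mrna.tsv")
    _write(mapping, outdir / "targets.tsv", index=False)
    (outdir / "truth.json").write_text(
        json.dumps(truth.to_dict(), indent=2))
    return outdir


def run_pipeline(datadir, outdir, config: PipelineConfig | None = None
                 ) -> RunManifest:
    """Execute all stages over a data directory; returns the manifest."""
    t0 = time.time()
    datadir, outdir = Path(datadir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config or PipelineConfig()
    manifest = RunManifest(config=asdict(cfg))
    caught: list[str] = []

    def stage(name):
        manifest.stages.append(name)

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        # ---- qc ----------------------------------------------------
        stage("qc")
        table, meta = data_mod.read_counts(datadir / "counts.tsv",
                                           datadir / "metadata.tsv")
        reports = []
        table, meta, rep = data_mod.filter_samples(
            table, meta, min_aligned=cfg.min_aligned)
        reports.append(rep.to_dict())
        table, meta, rep = data_mod.drop_sparse_regions(
            table, meta, min_samples=cfg.min_region_samples)
        reports.append(rep.to_dict())
        table, rep = data_mod.filter_features(
            table, meta, min_count=cfg.min_count, min_frac=cfg.min_frac)
        reports.append(rep.to_dict())
        (outdir / "filter_report.json").write_text(
            json.dumps(reports, indent=2, default=str))

        # ---- normalize ---------------------------------------------
        stage("normalize")
        expr = data_mod.rpmm_normalize(
            table, denominator_class=cfg.denominator_class)
        _write(expr, outdir / "expression_rpmm.tsv")

        # ---- pvca --------------------------------------------------
        stage("pvca")
        res = pvca(expr, meta, ["region", "age_months", "sex"],
                   pc_var_threshold=cfg.pc_var_threshold)
        _write(res.proportions.rename("share").to_frame(),
               outdir / "pvca.tsv")
        per_region = pvca_by_region(expr, meta,
                                    pc_var_threshold=cfg.pc_var_threshold)
        _write(per_region, outdir / "pvca_by_region.tsv")

        # ---- signature ---------------------------------------------
        stage("signature")
        sig = sig_mod.compute_signature(
            expr, meta, k=cfg.signature_k, threshold=cfg.z_threshold,
            n_clusters=cfg.n_region_clusters)
        _write(sig.z, outdir / "signature_z.tsv")
        _write(sig.binary.astype(int), outdir / "signature_binary.tsv")
        _write(sig.labels.to_frame(), outdir / "signature_labels.tsv")
        _write(sig.region_clusters.rename("cluster").to_frame(),
               outdir / "signature_region_clusters.tsv")

        # ---- age analysis ------------------------------------------
        stage("age")
        corr = age_mod.spearman_age(expr, meta)
        corr = age_mod.classify_correlation(
            corr, r_threshold=cfg.r_threshold, alpha=cfg.alpha)
        _write(corr, outdir / "age_correlation.tsv", index=False)
        de = age_mod.age_contrasts(
            expr, meta, reference_age=cfg.reference_age, center=cfg.center,
            alpha=cfg.alpha, fc_threshold=cfg.fc_threshold)
        _write(de, outdir / "age_de.tsv", index=False)
        candidates = age_mod.candidate_set(corr, de)
        _write(candidates, outdir / "candidates.tsv", index=False)

        # ---- trajectories ------------------------------------------
        stage("trajectories")
        ts = traj_mod.build_trajectories(expr, meta)
        model = traj_mod.cmeans_fit(ts, k=cfg.k_clusters, m=cfg.fuzzifier,
                                    seed=cfg.seed)
        assignments = traj_mod.assign_and_filter(
            model, min_membership=cfg.min_membership)
        _write(assignments, outdir / "trajectory_assignments.tsv")
        profiles = traj_mod.characterize(model, assignments)
        (outdir / "cluster_profiles.json").write_text(json.dumps(
            [{**asdict(p), "center": list(np.round(p.center, 10))}
             for p in profiles], indent=2, default=str))

        # ---- neighborhood ------------------------------------------
        stage("neighborhood")
        gff = datadir / "annotation.gff3"
        if gff.exists():
            loci = genomic_mod.load_annotation(
                str(gff), expressed=set(expr.index))
            sig_set = set(
                corr.loc[corr["label"].isin(["sig-positive",
                                             "sig-negative"]), "feature"])
            sig_set &= {l.feature_id for l in loci}
            per_anchor, tuples = genomic_mod.neighborhood_counts(
                loci, sig_set, window=cfg.window)
            ref = genomic_mod.reference_average(loci, window=cfg.window)
            _write(per_anchor, outdir / "neighborhood.tsv", index=False)
            _write(tuples, outdir / "neighborhood_tuples.tsv", index=False)
            (outdir / "neighborhood_reference.json").write_text(
                json.dumps({"mean_same_strand": ref[0],
                            "mean_opposite_strand": ref[1]}))

        # ---- isomir ------------------------------------------------
        stage("isomir")
        iso_path = datadir / "isomirs.tsv"
        if iso_path.exists():
            iso = pd.read_csv(iso_path, sep="\t", index_col=0)
            info = iso[["archetype", "canonical"]].copy()
            info["canonical"] = info["canonical"].astype(bool)
            iso_counts = iso.drop(columns=["archetype", "canonical"])
            iso_counts = iso_counts[[c for c in iso_counts.columns
                                     if c in set(meta.index)]]
            for arch in sorted(set(info["archetype"])):
                _, frac = integ_mod.isomir_trajectories(
                    iso_counts, info, meta, arch)
                _write(frac, outdir / f"isomir_fraction_{arch}.tsv")
            top = integ_mod.top_isomirs(iso_counts)
            _write(top.rename("median_expression").to_frame(),
                   outdir / "isomir_top.tsv")

        # ---- targets -----------------------------------------------
        stage("targets")
        mrna_path = datadir / "mrna.tsv"
        if mrna_path.exists():
            mrna = pd.read_csv(mrna_path, sep="\t", index_col=0)
            mrna = mrna[[c for c in mrna.columns if c in set(meta.index)]]
            mapping = pd.read_csv(datadir / "targets.tsv", sep="\t")
            for mirna_id in sorted(set(mapping["mirna_id"])):
                if mirna_id not in expr.index:
                    continue
                genes = list(mapping.loc[mapping["mirna_id"] == mirna_id,
                                         "gene_id"])
                tab, summary = integ_mod.target_anticorrelation(
                    expr.loc[mirna_id], mrna, meta, genes,
                    threshold=cfg.target_threshold, alpha=cfg.alpha)
                _write(tab, outdir / f"targets_{mirna_id}.tsv", index=False)
                _write(summary, outdir / f"targets_{mirna_id}_summary.tsv",
                       index=False)

        caught = [str(w.message) for w in wlist]

    # ---- report ----------------------------------------------------
    manifest.stages.append("report")
    report_text = build_report(outdir)
    (outdir / "report.md").write_text(report_text)

    manifest.warnings = caught
    for p in sorted(outdir.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest.checksums[p.name] = _sha256(p)
    manifest.wall_time_s = round(time.time() - t0, 3)
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def build_report(outdir) -> str:
    """Human-readable markdown summary of a finished run."""
    outdir = Path(outdir)
    lines = ["# Atlas analysis report", ""]
    cand_path = outdir / "candidates.tsv"
    if cand_path.exists():
        cand = pd.read_csv(cand_path, sep="\t")
        lines.append(f"## Aging candidates: {len(cand)}")
        if len(cand):
            per_region: dict[str, int] = {}
            for rs in cand["regions"]:
                for r in str(rs).split("|"):
                    per_region[r] = per_region.get(r, 0) + 1
            lines.append("")
            lines.append("| region | candidates |")
            lines.append("| --- | --- |")
            for r, n in sorted(per_region.items()):
                lines.append(f"| {r} | {n} |")
        else:
            lines.append("No candidates found.")
        lines.append("")
    prof_path = outdir / "cluster_profiles.json"
    if prof_path.exists():
        profiles = json.loads(prof_path.read_text())
        n_rs = sum(p["region_specific"] for p in profiles)
        n_fs = sum(p["feature_specific"] for p in profiles)
        lines += [f"## Trajectory clusters: {len(profiles)} profiled",
                  f"- region-specific: {n_rs}",
                  f"- feature-specific: {n_fs}", ""]
    tup_path = outdir / "neighborhood_tuples.tsv"
    if tup_path.exists():
        tup = pd.read_csv(tup_path, sep="\t")
        lines.append("## Genomic neighborhood tuples "
                     "(same, opposite) -> occurrences")
        for _, row in tup.iterrows():
            lines.append(f"- ({row['n_same_strand']}, "
                         f"{row['n_opposite_strand']}): "
                         f"{row['occurrences']}")
        lines.append("")
    pvca_path = outdir / "pvca.tsv"
    if pvca_path.exists():
        pv = pd.read_csv(pvca_path, sep="\t", index_col=0)
        lines.append("## PVCA variance shares")
        for lab, row in pv.iterrows():
            lines.append(f"- {lab}: {row['share']:.3f}")
        lines.append("")
    return "\n".join(lines) + "\n"
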