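"""End-to-end pipeline binding all stages together.

Stage order: simulate (or load inputs) -> differential expression ->
time-course clustering -> binding features + direction model ->
enrichment tests -> interaction-eQTL scan -> eQTL/binding overlap.
Each stage writes TSV tables stamped with the configuration hash; the
whole run is deterministic under a fixed configuration and seed.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, de, enrichment, eqtl, overlap, peaks as peak_ops, timecourse
from .io import (
    config_hash,
    read_bed,
    read_expression,
    read_genotypes,
    write_bed,
    write_dosage_tsv,
    write_table,
    write_vcf_lite,
)
from .simulate import (
    SimulationConfig,
    colocalize_peaks,
    contig_length,
    resample_tags,
    simulate_annotations,
    simulate_genotypes,
    simulate_paired_expression,
    simulate_peaks,
    simulate_timecourse,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Windows, thresholds and priors for a full pipeline run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    cis_window: int = 100_000
    primary_target_window: int = 100_000
    gr_window: int = 100
    nfkb_window: int = 1000
    fdr: float = 0.05
    k: int = 8
    priors: eqtl.ModelPriors = field(default_factory=eqtl.ModelPriors)
    n_resamples: int = 1000
    n_multinomial_sim: int = 10_000
    n_gr_peaks: int | None = None
    n_nfkb_peaks: int | None = None
    #: optional real-input paths; keys among {genotypes, expr_treated,
    #: expr_control, peaks_gr_dex, peaks_gr_ctrl, peaks_nfkb_dex,
    #: peaks_nfkb_ctrl}; anything not given is simulated
    inputs: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("cis_window", "primary_target_window", "gr_window", "nfkb_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0, 1)")
        if self.k <= 0:
            raise ValueError("k must be positive")
        missing = [p for p in self.inputs.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["eqtl_class_fractions"] = dict(d["sim"]["eqtl_class_fractions"])
        return d


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # halt with a stage-named error
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return out
        return wrapper
    return deco


@_stage("simulate")
def stage_simulate(config: PipelineConfig, outdir: Path, h: str) -> dict:
    sim = config.sim
    n_gr = config.n_gr_peaks or 2 * sim.n_genes
    n_nfkb = config.n_nfkb_peaks or sim.n_genes
    clen = contig_length(sim)

    if "genotypes" in config.inputs:
        genotypes = read_genotypes(config.inputs["genotypes"])
    else:
        genotypes = simulate_genotypes(sim)
    if "expr_treated" in config.inputs:
        expression = read_expression(
            config.inputs["expr_treated"], config.inputs["expr_control"]
        )
        truth = None
    else:
        expression, truth = simulate_paired_expression(genotypes, sim)
    panel, tc_truth = simulate_timecourse(sim)

    if "peaks_gr_dex" in config.inputs:
        gr_dex = read_bed(config.inputs["peaks_gr_dex"])
        gr_dex["tags"] = gr_dex.get("tags", 0)
    else:
        gr_dex = simulate_peaks(sim, n_gr, clen, factor="GR", condition="dex", stream=4)
        if truth is not None:
            # plant GC-only causal variants inside receptor binding regions
            gc_pos = genotypes.positions[
                truth.loc[truth["class"] == "gc_only", "snp"]
            ].to_numpy()
            gr_dex = colocalize_peaks(gr_dex, gc_pos, sim, stream=44)
    # control occupancy: a small subset of the treated regions re-sampled
    rng = np.random.default_rng([sim.seed, 40])
    keep = rng.random(len(gr_dex)) < 0.05
    gr_ctrl = resample_tags(
        gr_dex[keep].reset_index(drop=True), sim, sim.tag_mean * 0.5, stream=41,
        condition="ctrl",
    ) if keep.any() else gr_dex.iloc[:0].copy()

    # NF-kB occupancy colocalizes with a subset of receptor regions
    # (cross-talk sites); treatment multiplies the mean tag count by the
    # configured gain (default +16%)
    pick = rng.choice(len(gr_dex), size=min(n_nfkb, len(gr_dex)), replace=False)
    base = gr_dex.iloc[np.sort(pick)].reset_index(drop=True)
    if truth is not None:
        # control-only causal variants sit in NF-kB-bound regions
        ctrl_pos = genotypes.positions[
            truth.loc[truth["class"] == "control_only", "snp"]
        ].to_numpy()
        base = colocalize_peaks(base, ctrl_pos, sim, stream=45)
    base = base.assign(
        factor="NFKB",
        name=[f"NFKB_ctrl_{i:04d}" for i in range(len(base))],
        condition="ctrl",
    )
    nfkb_ctrl = resample_tags(base, sim, sim.tag_mean, stream=42, condition="ctrl")
    nfkb_dex = resample_tags(
        nfkb_ctrl, sim, sim.tag_mean * sim.nfkb_tag_gain, stream=43, condition="dex"
    )
    tracks = simulate_annotations(sim, peaks=gr_dex)

    write_dosage_tsv(genotypes, outdir / "genotypes.tsv")
    write_vcf_lite(genotypes, outdir / "genotypes.vcf")
    expression.treated.to_csv(outdir / "expression_treated.tsv", sep="\t")
    expression.control.to_csv(outdir / "expression_control.tsv", sep="\t")
    panel.to_csv(outdir / "timecourse_lfc.tsv", sep="\t")
    for nm, df in (
        ("peaks_gr_dex", gr_dex),
        ("peaks_gr_ctrl", gr_ctrl),
        ("peaks_nfkb_dex", nfkb_dex),
        ("peaks_nfkb_ctrl", nfkb_ctrl),
    ):
        write_bed(df, outdir / f"{nm}.bed")
    write_bed(tracks.ctcf, outdir / "ctcf.bed")
    write_bed(tracks.dnase, outdir / "dnase.bed")
    write_table(tracks.genes, outdir / "genes.tsv", h)
    if truth is not None:
        write_table(truth.reset_index(), outdir / "eqtl_truth.tsv", h)
    write_table(tc_truth.reset_index(), outdir / "timecourse_truth.tsv", h)
    logger.info(
        "simulated %d individuals, %d genes, %d SNPs, %d+%d GR and %d NF-kB peaks",
        sim.n_individuals, sim.n_genes, sim.n_snps, len(gr_dex), len(gr_ctrl), n_nfkb,
    )
    return {
        "genotypes": genotypes,
        "expression": expression,
        "truth": truth,
        "panel": panel,
        "tc_truth": tc_truth,
        "gr_dex": gr_dex,
        "gr_ctrl": gr_ctrl,
        "nfkb_dex": nfkb_dex,
        "nfkb_ctrl": nfkb_ctrl,
        "tracks": tracks,
    }


@_stage("de")
def stage_de(config: PipelineConfig, data: dict, outdir: Path, h: str) -> de.DeResult:
    result = de.de_from_panel(data["panel"], fdr=config.fdr)
    frames = []
    for tp, tab in result.tables.items():
        t = tab.reset_index()
        t.insert(0, "timepoint", tp)
        frames.append(t)
    write_table(pd.concat(frames, ignore_index=True), outdir / "de_tests.tsv", h)
    write_table(
        pd.DataFrame({"gene": result.de_genes}), outdir / "de_genes.tsv", h
    )
    logger.info("DE genes at FDR %.2f: %d", config.fdr, len(result.de_genes))
    return result


@_stage("cluster")
def stage_cluster(
    config: PipelineConfig, data: dict, de_result: de.DeResult, outdir: Path, h: str
) -> timecourse.ClusterResult:
    panel = data["panel"].loc[de_result.de_genes]
    f = timecourse.median_profile(panel)
    dfm = pd.DataFrame(
        timecourse.delta_transform(f.to_numpy()), index=f.index, columns=f.columns
    )
    k = min(config.k, np.unique(dfm.to_numpy(), axis=0).shape[0])
    result = timecourse.kmeans_cluster(dfm, k=k, seed=config.sim.seed)
    write_table(result.assignments.reset_index(), outdir / "cluster_assignments.tsv", h)
    write_table(result.centers, outdir / "cluster_centers.tsv", h)
    write_table(result.summary, outdir / "cluster_summary.tsv", h)
    logger.info("clustered %d DE genes into k=%d clusters", len(panel), k)
    return result


@_stage("features")
def stage_features(
    config: PipelineConfig, data: dict, outdir: Path, h: str
) -> dict:
    tracks = data["tracks"]
    pwm = annotation.default_gr_pwm()
    motif = annotation.scan_peaks(
        tracks.peak_sequences, pwm, tracks.background_sequence
    )
    primary = annotation.primary_targets(
        tracks.genes, data["gr_dex"], window=config.primary_target_window
    )
    lfc8 = timecourse.median_profile(data["panel"])[8]
    rows = annotation.nearest_peak_features(
        tracks.genes, data["gr_dex"], tracks.ctcf, tracks.dnase,
        motif, lfc8, window=config.primary_target_window,
    )
    fit = annotation.fit_logistic(rows)
    write_table(primary.reset_index(), outdir / "primary_targets.tsv", h)
    write_table(rows, outdir / "feature_rows.tsv", h)
    write_table(fit.summary.reset_index(), outdir / "logistic_fit.tsv", h)
    logger.info(
        "feature rows: %d; logistic converged=%s (%d iter)",
        len(rows), fit.converged, fit.n_iter,
    )
    return {"primary": primary, "rows": rows, "fit": fit, "motif": motif}


@_stage("enrich")
def stage_enrich(
    config: PipelineConfig,
    data: dict,
    de_result: de.DeResult,
    clusters: timecourse.ClusterResult,
    features: dict,
    outdir: Path,
    h: str,
) -> pd.DataFrame:
    primary = features["primary"].reindex(clusters.assignments.index).fillna(False)
    enrich = enrichment.cluster_enrichment(clusters.assignments, primary)
    p_multi = enrichment.multinomial_cluster_test(
        enrich["successes"].to_numpy(),
        enrich["size"].to_numpy(),
        n_sim=config.n_multinomial_sim,
        seed=config.sim.seed,
    )
    enrich["multinomial_p"] = p_multi

    # NF-kB tag shift at GR sites near DE genes
    de_tss = data["tracks"].genes.set_index("gene").loc[
        [g for g in de_result.de_genes if g in data["tracks"].genes["gene"].values],
        "tss",
    ].to_numpy(dtype=float)
    gr = data["gr_dex"]
    mids = (gr["start"].to_numpy() + gr["end"].to_numpy()) / 2.0
    near = np.zeros(len(gr), dtype=bool)
    if de_tss.size:
        near = (
            np.abs(mids[:, None] - de_tss[None, :]).min(axis=1)
            <= config.primary_target_window
        )
    sites = gr[near].reset_index(drop=True)
    tag_stats = pd.DataFrame()
    if len(sites):
        tags = peak_ops.tags_at_sites(
            sites, {"dex": data["nfkb_dex"], "ctrl": data["nfkb_ctrl"]}
        )
        u, p_mwu = enrichment.mann_whitney_u(tags["dex"], tags["ctrl"])
        inc = enrichment.percent_increase(
            float(tags["dex"].mean()), float(tags["ctrl"].mean())
        ) if tags["ctrl"].mean() > 0 else np.nan
        tag_stats = pd.DataFrame(
            [{"n_sites": len(sites), "U": u, "p": p_mwu, "percent_increase": inc}]
        )
    write_table(enrich, outdir / "cluster_enrichment.tsv", h)
    write_table(tag_stats, outdir / "nfkb_tag_shift.tsv", h)
    logger.info("multinomial p=%.4f over %d clusters", p_multi, len(enrich))
    return enrich


@_stage("eqtl")
def stage_eqtl(config: PipelineConfig, data: dict, outdir: Path, h: str) -> pd.DataFrame:
    scan = eqtl.cis_scan(
        data["expression"],
        data["genotypes"],
        data["tracks"].genes,
        window=config.cis_window,
        priors=config.priors,
    )
    write_table(scan, outdir / "eqtl_scan.tsv", h)
    counts = scan["class"].value_counts()
    logger.info("eQTL classes: %s", counts.to_dict())
    return scan


@_stage("overlap")
def stage_overlap(
    config: PipelineConfig, data: dict, scan: pd.DataFrame, outdir: Path, h: str
) -> pd.DataFrame:
    frames = []
    for factor, pk, window in (
        ("GR", data["gr_dex"], config.gr_window),
        ("NFKB", data["nfkb_dex"], config.nfkb_window),
    ):
        counts = overlap.class_overlap_counts(scan, pk, window)
        counts.insert(0, "factor", factor)
        a = scan[scan["class"] == "gc_only"]
        b = scan[scan["class"] == "control_only"]
        fold = p = np.nan
        if len(a) and len(b):
            p, na, nb = overlap.resampling_pvalue(
                a, b, pk, window, n_resamples=config.n_resamples, seed=config.sim.seed
            )
            fold = overlap.fold_enrichment(na, nb) if nb else np.nan
        counts["gc_vs_ctrl_fold"] = fold
        counts["gc_vs_ctrl_p"] = p
        frames.append(counts)
    out = pd.concat(frames, ignore_index=True)
    write_table(out, outdir / "class_overlap.tsv", h)
    return out


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run all stages into ``outdir``; returns the report directory."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config_hash(config.to_dict())

    handler = logging.FileHandler(outdir / "pipeline.log")
    stream = logging.StreamHandler(sys.stderr)
    root = logging.getLogger("gcresponse")
    root.addHandler(handler)
    root.addHandler(stream)
    try:
        logger.info("pipeline start: seed=%d config=%s", config.sim.seed, h)
        data = stage_simulate(config, outdir, h)
        de_result = stage_de(config, data, outdir, h)
        clusters = stage_cluster(config, data, de_result, outdir, h)
        features = stage_features(config, data, outdir, h)
        stage_enrich(config, data, de_result, clusters, features, outdir, h)
        scan = stage_eqtl(config, data, outdir, h)
        stage_overlap(config, data, scan, outdir, h)
        logger.info("pipeline complete: outputs in %s", outdir)
    finally:
        root.removeHandler(handler)
        root.removeHandler(stream)
        handler.close()
    return outdir
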