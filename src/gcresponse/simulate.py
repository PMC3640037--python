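"""Synthetic data generators for the glucocorticoid-response pipeline.

The generators emulate the statistical structure of the real study inputs:
Hardy-Weinberg genotypes for a cohort of individuals, paired
treatment/control expression with planted eQTL interaction classes,
time-course log2 fold-change profiles built from planted cluster shapes,
non-overlapping ChIP-seq-like binding regions with overdispersed tag
counts, and gene/CTCF/DNase/motif annotation tracks.  Everything is
deterministic under ``SimulationConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: eQTL interaction classes, in canonical order.
CLASSES = ("null", "no_interaction", "gc_only", "control_only", "general")

#: Treatment timepoints (hours after dexamethasone exposure).
DEFAULT_TIMEPOINTS = (2, 4, 8, 12, 16, 24)

_DEFAULT_FRACTIONS = {
    "null": 0.5,
    "no_interaction": 0.2,
    "gc_only": 0.1,
    "control_only": 0.1,
    "general": 0.1,
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design: 57 individuals in the eQTL cohort,
    8 time-course samples over 2-24 h of dexamethasone treatment, and a
    mean binding-region width of 157 bp.  ``effect_size`` and
    ``noise_sd`` (expression units, log2 scale) default to a
    signal-to-noise ratio of 5 per allele at planted eQTLs.
    """

    n_individuals: int = 57
    n_genes: int = 120
    n_snps: int = 120
    maf_range: tuple[float, float] = (0.05, 0.5)
    eqtl_class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FRACTIONS)
    )
    effect_size: float = 1.0
    noise_sd: float = 0.2
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS
    n_timecourse_samples: int = 8
    peak_mean_width: float = 157.0
    peak_width_shape: float = 8.0
    tag_mean: float = 50.0
    tag_dispersion: float = 5.0
    #: multiplicative NF-kB tag gain under treatment (1.16 = +16%)
    nfkb_tag_gain: float = 1.16
    #: fraction of condition-specific causal SNPs planted inside a binding
    #: region of the matching factor (GC-only in GR, control-only in NF-kB)
    frac_eqtl_snps_in_peaks: float = 0.6
    gene_spacing: int = 150_000
    cis_placement: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(
                f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}"
            )
        total = sum(self.eqtl_class_fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ConfigurationError(
                f"eqtl_class_fractions must sum to 1, got {total!r}"
            )
        unknown = set(self.eqtl_class_fractions) - set(CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown eQTL classes: {sorted(unknown)}")
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size == 0 or np.any(tp <= 0) or np.any(np.diff(tp) <= 0):
            raise ConfigurationError(
                "timepoints must be positive and strictly increasing"
            )
        if self.n_individuals < 2 or self.n_genes < 1 or self.n_snps < 1:
            raise ConfigurationError("cohort dimensions too small")
        if self.noise_sd < 0 or self.peak_mean_width <= 0:
            raise ConfigurationError("noise_sd and peak_mean_width must be positive")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Independent deterministic stream per generator."""
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with SNP coordinates.

    ``dosages`` has individuals as rows and SNP ids as columns; values are
    allele counts in {0, 1, 2} (NaN = missing).  ``positions`` maps SNP id
    to a 0-based coordinate on ``chrom``.
    """

    dosages: pd.DataFrame
    positions: pd.Series
    chrom: str = "chrS"

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index


def gene_tss_positions(config: SimulationConfig, n_genes: int | None = None) -> np.ndarray:
    """Deterministic TSS grid: gene *i* sits at ``(i + 1) * gene_spacing``."""
    n = config.n_genes if n_genes is None else n_genes
    return (np.arange(n, dtype=np.int64) + 1) * config.gene_spacing


def contig_length(config: SimulationConfig, n_genes: int | None = None) -> int:
    n = config.n_genes if n_genes is None else n_genes
    return int((n + 1) * config.gene_spacing)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw Hardy-Weinberg genotypes at SNPs placed inside gene cis windows.

    Each SNP's minor-allele frequency is uniform in ``maf_range`` and
    genotypes are Binomial(2, MAF).  SNP *j* is placed within
    ``cis_placement`` bp of the TSS of gene ``j % n_genes``, at distinct
    coordinates, so each gene owns at least one cis SNP when
    ``n_snps >= n_genes``.
    """
    rng = _rng(config, 1)
    n, m = config.n_individuals, config.n_snps
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=m)
    dosages = rng.binomial(2, mafs[None, :], size=(n, m)).astype(float)

    tss = gene_tss_positions(config)
    gene_of_snp = np.arange(m) % config.n_genes
    span = 2 * config.cis_placement + 1
    positions = np.empty(m, dtype=np.int64)
    for gi in np.unique(gene_of_snp):
        idx = np.flatnonzero(gene_of_snp == gi)
        offsets = rng.choice(span, size=idx.size, replace=False) - config.cis_placement
        positions[idx] = tss[gi] + offsets

    snp_ids = pd.Index([f"rs{j:05d}" for j in range(m)], name="snp")
    sample_ids = pd.Index([f"ind{i:03d}" for i in range(n)], name="sample")
    return GenotypeMatrix(
        dosages=pd.DataFrame(dosages, index=sample_ids, columns=snp_ids),
        positions=pd.Series(positions, index=snp_ids, name="pos"),
    )


# ---------------------------------------------------------------------------
# paired expression with planted eQTL classes
# ---------------------------------------------------------------------------

@dataclass
class PairedExpression:
    """Per-gene expression (log2 scale) under paired treatment/control.

    Both frames are genes x individuals with identical axes.
    """

    treated: pd.DataFrame
    control: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.treated.index.equals(self.control.index) or not (
            self.treated.columns.equals(self.control.columns)
        ):
            raise ValueError("treated and control must share gene and sample axes")


def _class_betas(cls: str, beta: float) -> tuple[float, float]:
    if cls in ("null",):
        return 0.0, 0.0
    if cls == "no_interaction":
        return beta, beta
    if cls == "gc_only":
        return beta, 0.0
    if cls == "control_only":
        return 0.0, beta
    if cls == "general":
        # distinguishable from both single-condition classes
        return beta, -beta / 2.0
    raise ValueError(f"unknown class {cls!r}")


def simulate_paired_expression(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[PairedExpression, pd.DataFrame]:
    """Plant one causal cis SNP and one interaction class per gene.

    For individual *i* and gene *g*::

        y_treat = mu_g + beta_t * dosage_i + eps
        y_ctrl  = mu_g + beta_c * dosage_i + eps'

    with independent Normal(0, noise_sd^2) errors and (beta_t, beta_c)
    determined by the planted class.  Returns the expression container and
    a truth table (gene, causal SNP, class, betas, TSS).
    """
    rng = _rng(config, 2)
    n_genes = config.n_genes
    if n_genes > config.n_snps:
        raise ConfigurationError(
            "one causal SNP per gene requires n_genes <= n_snps"
        )
    classes = list(config.eqtl_class_fractions)
    probs = np.array([config.eqtl_class_fractions[c] for c in classes])
    gene_class = rng.choice(len(classes), size=n_genes, p=probs)

    tss = gene_tss_positions(config)
    gene_ids = pd.Index([f"gene{g:04d}" for g in range(n_genes)], name="gene")
    snp_ids = genotypes.snp_ids

    dosage = genotypes.dosages.to_numpy()  # individuals x snps
    n_ind = dosage.shape[0]
    mu = rng.normal(8.0, 1.0, size=n_genes)

    treat = np.empty((n_genes, n_ind))
    ctrl = np.empty((n_genes, n_ind))
    truth_rows = []
    for g in range(n_genes):
        cls = classes[gene_class[g]]
        beta_t, beta_c = _class_betas(cls, config.effect_size)
        gvec = dosage[:, g]  # SNP g lies in gene g's cis window
        treat[g] = mu[g] + beta_t * gvec + rng.normal(0, config.noise_sd, n_ind)
        ctrl[g] = mu[g] + beta_c * gvec + rng.normal(0, config.noise_sd, n_ind)
        truth_rows.append(
            {
                "gene": gene_ids[g],
                "snp": snp_ids[g],
                "class": cls,
                "beta_treat": beta_t,
                "beta_control": beta_c,
                "tss": int(tss[g]),
            }
        )

    samples = genotypes.sample_ids
    expr = PairedExpression(
        treated=pd.DataFrame(treat, index=gene_ids, columns=samples),
        control=pd.DataFrame(ctrl, index=gene_ids, columns=samples),
    )
    truth = pd.DataFrame(truth_rows).set_index("gene")
    return expr, truth


# ---------------------------------------------------------------------------
# time course
# ---------------------------------------------------------------------------

#: Default planted response shapes (delta log2 fold change per interval):
#: strong early up, late up, late-peaking down, strong early down, and flat
#: (non-responsive) genes.  Cumulative sums give the f-profiles.
DEFAULT_CLUSTER_SHAPES = (
    (1.5, 0.3, -0.2, -0.3, -0.4, -0.5),   # up, peak 4 h, decays
    (0.2, 0.4, 0.8, 0.4, -0.2, -0.4),     # up, peak 12 h
    (-0.2, -0.4, -0.6, -0.2, 0.2, 0.4),   # down, trough 12 h
    (-1.6, -0.2, 0.3, 0.4, 0.4, 0.3),     # down, trough 4 h, recovers
    (0.0, 0.0, 0.0, 0.0, 0.0, 0.0),       # flat / non-responsive
)


def simulate_timecourse(
    config: SimulationConfig,
    cluster_shapes: Sequence[Sequence[float]] = DEFAULT_CLUSTER_SHAPES,
    n_genes: int | None = None,
    noise_sd: float | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample log2 fold-change panel built from planted delta shapes.

    Each gene is assigned one shape (balanced, then shuffled).  The gene's
    true f-profile is the cumulative sum of its shape; every sample
    observes ``f + Normal(0, noise_sd)`` at each timepoint.  Returns a
    genes x (timepoint, sample) frame and the truth labels (shape index).
    """
    rng = _rng(config, 3)
    n = config.n_genes if n_genes is None else n_genes
    sd = config.noise_sd if noise_sd is None else noise_sd
    tps = config.timepoints
    shapes = [np.asarray(s, dtype=float) for s in cluster_shapes]
    for s in shapes:
        if s.size != len(tps):
            raise ConfigurationError(
                f"cluster shape length {s.size} != number of timepoints {len(tps)}"
            )

    labels = np.arange(n) % len(shapes)
    rng.shuffle(labels)
    f_true = np.stack([np.cumsum(shapes[l]) for l in labels])  # genes x T

    n_samp = config.n_timecourse_samples
    noise = (
        rng.normal(0.0, sd, size=(n, len(tps), n_samp))
        if sd > 0
        else np.zeros((n, len(tps), n_samp))
    )
    values = f_true[:, :, None] + noise

    gene_ids = pd.Index([f"gene{g:04d}" for g in range(n)], name="gene")
    cols = pd.MultiIndex.from_product(
        [list(tps), [f"s{j + 1}" for j in range(n_samp)]],
        names=["timepoint", "sample"],
    )
    panel = pd.DataFrame(values.reshape(n, -1), index=gene_ids, columns=cols)
    truth = pd.Series(labels, index=gene_ids, name="shape")
    return panel, truth


# ---------------------------------------------------------------------------
# binding regions
# ---------------------------------------------------------------------------

def simulate_peaks(
    config: SimulationConfig,
    n_peaks: int,
    contig_len: int,
    factor: str = "GR",
    condition: str = "dex",
    stream: int = 4,
    min_gap: int = 10,
    min_width: int = 20,
) -> pd.DataFrame:
    """Non-overlapping binding regions with overdispersed tag counts.

    Widths are rounded Gamma draws with mean ``peak_mean_width``; tag
    counts are negative binomial with mean ``tag_mean`` and dispersion
    ``tag_dispersion``.  Intervals are 0-based half-open on ``chrS``.
    """
    rng = _rng(config, stream)
    if n_peaks == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "name", "tags", "factor", "condition"]
        ).astype({"start": np.int64, "end": np.int64, "tags": np.int64})
    shape = config.peak_width_shape
    widths = np.maximum(
        np.rint(rng.gamma(shape, config.peak_mean_width / shape, size=n_peaks)),
        min_width,
    ).astype(np.int64)
    needed = int(widths.sum() + n_peaks * min_gap)
    if needed > contig_len:
        raise ConfigurationError(
            f"cannot pack {n_peaks} peaks ({needed} bp incl. gaps) into {contig_len} bp"
        )
    slack = contig_len - needed
    extra = np.sort(rng.integers(0, slack + 1, size=n_peaks))
    starts = extra + np.concatenate([[0], np.cumsum(widths[:-1] + min_gap)])
    ends = starts + widths

    size = config.tag_dispersion
    p = size / (size + config.tag_mean)
    tags = rng.negative_binomial(size, p, size=n_peaks).astype(np.int64)

    return pd.DataFrame(
        {
            "chrom": "chrS",
            "start": starts,
            "end": ends,
            "name": [f"{factor}_{condition}_{i:04d}" for i in range(n_peaks)],
            "tags": tags,
            "factor": factor,
            "condition": condition,
        }
    )


def colocalize_peaks(
    peaks: pd.DataFrame,
    snp_positions: Sequence[int],
    config: SimulationConfig,
    stream: int,
    fraction: float | None = None,
) -> pd.DataFrame:
    """Relocate the nearest peak to cover each selected SNP position.

    Plants causal variants inside binding regions (the mechanism the
    overlap analysis is designed to detect).  A random ``fraction`` of the
    given SNPs is chosen; for each, the nearest peak is re-centered on the
    SNP.  Non-relocated peaks that end up overlapping a relocated one are
    dropped so the set stays non-overlapping.
    """
    rng = _rng(config, stream)
    frac = config.frac_eqtl_snps_in_peaks if fraction is None else fraction
    out = peaks.copy().reset_index(drop=True)
    if out.empty or len(snp_positions) == 0:
        return out
    chosen = [p for p in snp_positions if rng.random() < frac]
    mids = (out["start"].to_numpy() + out["end"].to_numpy()) // 2
    relocated = np.zeros(len(out), dtype=bool)
    for pos in chosen:
        candidates = np.where(relocated, np.iinfo(np.int64).max,
                              np.abs(mids - pos))
        j = int(np.argmin(candidates))
        width = int(out.at[j, "end"] - out.at[j, "start"])
        out.at[j, "start"] = int(pos) - width // 2
        out.at[j, "end"] = int(pos) - width // 2 + width
        relocated[j] = True
        mids[j] = pos
    out["_relocated"] = relocated
    out = out.sort_values(["start", "end"], kind="mergesort").reset_index(drop=True)
    keep = np.ones(len(out), dtype=bool)
    last_end = -1
    for i in range(len(out)):
        if out.at[i, "start"] < last_end and not out.at[i, "_relocated"]:
            keep[i] = False
            continue
        last_end = max(last_end, int(out.at[i, "end"]))
    return out[keep].drop(columns="_relocated").reset_index(drop=True)


def resample_tags(
    peaks: pd.DataFrame,
    config: SimulationConfig,
    mean: float,
    stream: int,
    condition: str | None = None,
) -> pd.DataFrame:
    """Same intervals, fresh negative-binomial tag counts with a new mean."""
    rng = _rng(config, stream)
    out = peaks.copy()
    size = config.tag_dispersion
    p = size / (size + mean)
    out["tags"] = rng.negative_binomial(size, p, size=len(peaks)).astype(np.int64)
    if condition is not None:
        out["condition"] = condition
        out["name"] = [n.replace(peaks["condition"].iloc[0], condition) if len(peaks) else n
                       for n in out["name"]]
    return out


# ---------------------------------------------------------------------------
# annotation tracks
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_sequence(rng: np.random.Generator, length: int, gc: float = 0.41) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


@dataclass
class AnnotationTracks:
    """Gene/CTCF/DNase tracks plus motif-planted peak sequences."""

    genes: pd.DataFrame           # gene, chrom, tss, strand, start, end
    ctcf: pd.DataFrame            # chrom, start, end
    dnase: pd.DataFrame           # chrom, start, end
    motif_truth: pd.Series        # peak name -> bool (motif planted)
    peak_sequences: dict          # peak name -> str
    background_sequence: str


def simulate_annotations(
    config: SimulationConfig,
    n_genes: int | None = None,
    peaks: pd.DataFrame | None = None,
    motif_fraction: float = 0.4,
    motif_consensus: str = "AGAACAGAATGTTCT",
    n_ctcf: int | None = None,
    n_dnase: int | None = None,
    background_length: int = 100_000,
) -> AnnotationTracks:
    """Gene TSS track (alternating strands), CTCF/DNase intervals and
    peak sequences with the canonical receptor motif planted in a random
    subset of peaks (recorded in the truth table)."""
    rng = _rng(config, 5)
    n = config.n_genes if n_genes is None else n_genes
    tss = gene_tss_positions(config, n)
    clen = contig_length(config, n)
    genes = pd.DataFrame(
        {
            "gene": [f"gene{g:04d}" for g in range(n)],
            "chrom": "chrS",
            "tss": tss,
            "strand": np.where(np.arange(n) % 2 == 0, "+", "-"),
        }
    )
    genes["start"] = genes["tss"]
    genes["end"] = genes["tss"] + 1

    def _track(count: int, width: int) -> pd.DataFrame:
        starts = np.sort(rng.integers(0, clen - width, size=count))
        return pd.DataFrame(
            {"chrom": "chrS", "start": starts, "end": starts + width}
        )

    ctcf = _track(n if n_ctcf is None else n_ctcf, 400)
    # DNase hypersensitive sites partially colocalize with binding regions,
    # as open chromatin does with TF occupancy
    n_dn = 2 * n if n_dnase is None else n_dnase
    dnase = _track(n_dn, 300)
    if peaks is not None and len(peaks):
        n_coloc = min(len(peaks), n_dn // 2)
        chosen = rng.choice(len(peaks), size=n_coloc, replace=False)
        mids = ((peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2)[chosen]
        coloc = pd.DataFrame(
            {"chrom": "chrS", "start": np.maximum(mids - 150, 0), "end": mids + 150}
        )
        dnase = (
            pd.concat([dnase.iloc[n_coloc:], coloc], ignore_index=True)
            .sort_values("start", kind="mergesort")
            .reset_index(drop=True)
        )

    motif_truth = pd.Series(dtype=bool)
    seqs: dict[str, str] = {}
    if peaks is not None and len(peaks):
        planted = rng.random(len(peaks)) < motif_fraction
        L = len(motif_consensus)
        names, flags = [], []
        for (_, row), has in zip(peaks.iterrows(), planted):
            width = int(row["end"] - row["start"])
            seq = _random_sequence(rng, max(width, L))
            if has:
                pos = int(rng.integers(0, len(seq) - L + 1))
                seq = seq[:pos] + motif_consensus + seq[pos + L:]
            seqs[row["name"]] = seq
            names.append(row["name"])
            flags.append(bool(has))
        motif_truth = pd.Series(flags, index=pd.Index(names, name="name"))
    background = _random_sequence(rng, background_length)
    return AnnotationTracks(genes, ctcf, dnase, motif_truth, seqs, background)
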