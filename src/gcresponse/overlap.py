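"""Overlap of classified eQTLs with binding regions.

SNPs are intersected with binding-region windows (100 bp for the receptor,
1 kb for NF-kB by default); class-level counts feed fold-enrichment ratios
and a label-permutation resampling p-value.  The permutation scheme holds
SNP positions and class sizes fixed and shuffles the class labels across
the pooled SNPs — the two compared classes are assumed exchangeable in
their ascertainment properties.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GR_WINDOW = 100
NFKB_WINDOW = 1000


def within_window(
    snp_pos, peaks: pd.DataFrame, window: int, chrom: str | None = None
) -> np.ndarray:
    """True where the distance from a SNP to the nearest peak interval is
    <= window bp (0 when the SNP lies inside a peak; boundary inclusive).
    """
    pos = np.atleast_1d(np.asarray(snp_pos, dtype=float))
    sub = peaks if chrom is None else peaks[peaks["chrom"] == chrom]
    if sub.empty:
        return np.zeros(pos.size, dtype=bool)
    starts = sub["start"].to_numpy(dtype=float)
    ends = sub["end"].to_numpy(dtype=float)
    # distance from position to half-open interval [start, end)
    d = np.maximum.reduce(
        [
            starts[None, :] - pos[:, None],
            pos[:, None] - (ends[None, :] - 1),
            np.zeros((pos.size, len(sub))),
        ]
    )
    return d.min(axis=1) <= window


def class_overlap_counts(
    eqtls: pd.DataFrame, peaks: pd.DataFrame, window: int
) -> pd.DataFrame:
    """Per-class counts of eQTL SNPs within the window of any peak.

    ``eqtls`` needs ``snp``, ``pos`` and ``class`` columns; each SNP is
    counted once even if it is paired with several genes.
    """
    uniq = eqtls.drop_duplicates(subset="snp")
    flags = within_window(uniq["pos"].to_numpy(), peaks, window)
    out = (
        pd.DataFrame({"class": uniq["class"].to_numpy(), "in_window": flags})
        .groupby("class")
        .agg(n_snps=("in_window", "size"), n_overlapping=("in_window", "sum"))
        .reset_index()
    )
    out["window"] = window
    return out


def fold_enrichment(count_a: int, count_b: int) -> float:
    """Ratio of overlap counts between two eQTL classes."""
    if count_b == 0:
        raise ZeroDivisionError("fold enrichment undefined for a zero baseline")
    return count_a / count_b


def resampling_pvalue(
    eqtls_a: pd.DataFrame,
    eqtls_b: pd.DataFrame,
    peaks: pd.DataFrame,
    window: int,
    n_resamples: int = 1000,
    seed: int = 0,
) -> tuple[float, int, int]:
    """Label-permutation p-value for the excess overlap of class A over B.

    Class labels are permuted across the pooled SNPs with class sizes held
    fixed; the statistic is (overlap count A) - (overlap count B) and
    ``p = (1 + #{permuted >= observed}) / (1 + n_resamples)``.  Returns
    (p, observed overlap A, observed overlap B).
    """
    if eqtls_a.empty or eqtls_b.empty:
        raise ValueError("both classes must be non-empty")
    pos_a = eqtls_a.drop_duplicates(subset="snp")["pos"].to_numpy()
    pos_b = eqtls_b.drop_duplicates(subset="snp")["pos"].to_numpy()
    pooled = np.concatenate([pos_a, pos_b])
    flags = within_window(pooled, peaks, window)
    n_a = pos_a.size
    obs_a = int(flags[:n_a].sum())
    obs_b = int(flags[n_a:].sum())
    observed = obs_a - obs_b

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_resamples):
        perm = rng.permutation(flags)
        stat = int(perm[:n_a].sum()) - int(perm[n_a:].sum())
        if stat >= observed:
            count += 1
    p = (1 + count) / (1 + n_resamples)
    return float(p), obs_a, obs_b
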