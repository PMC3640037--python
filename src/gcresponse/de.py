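"""Differential expression from paired treatment/control samples.

The response of each gene is summarized per individual as the log2 fold
change (treated minus control, both already log2 scale).  Evidence of
differential expression is assessed with a paired one-sample moderated
t-test: per-gene variances are shrunk toward a common prior estimated by
empirical Bayes (moment matching of log sample variances via
digamma/trigamma identities), and the t statistic gains the prior degrees
of freedom.  Multiplicity is handled with Storey-Tibshirani q-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats


def compute_lfc(expr_treat: pd.DataFrame, expr_ctrl: pd.DataFrame) -> pd.DataFrame:
    """Per-individual log2 fold change (treated - control).

    Inputs must be aligned genes x samples matrices on the log2 scale.
    """
    if expr_treat.shape != expr_ctrl.shape:
        raise ValueError(
            f"shape mismatch: {expr_treat.shape} vs {expr_ctrl.shape}"
        )
    if not expr_treat.index.equals(expr_ctrl.index) or not expr_treat.columns.equals(
        expr_ctrl.columns
    ):
        raise ValueError("treated and control matrices must share gene/sample axes")
    return expr_treat - expr_ctrl


def _invert_trigamma(target: float) -> float:
    """Solve trigamma(x) = target for x > 0 (target > 0)."""
    # trigamma is strictly decreasing from +inf to 0
    lo, hi = 1e-8, 1e8
    return float(optimize.brentq(lambda x: special.polygamma(1, x) - target, lo, hi))


def estimate_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) for gene variances.

    Moment-matches the log sample variances: with
    ``e = log(s2) - digamma(df/2) + log(df/2)``, the hierarchical model
    implies ``Var(e) = trigamma(df/2) + trigamma(d0/2)`` and
    ``E(e) = log(s0^2) - digamma(d0/2) + log(d0/2)``.  Under-dispersion
    (no excess variance to explain) yields ``d0 = inf``.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive gene variances to estimate the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _invert_trigamma(excess)
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


@dataclass
class ModeratedTResult:
    table: pd.DataFrame      # columns: mean, s2, s2_post, t, p, flagged
    prior_df: float
    prior_s2: float
    n: int


def moderated_t(
    lfc: pd.DataFrame, prior_df: float | None = None, prior_s2: float | None = None
) -> ModeratedTResult:
    """Paired one-sample moderated t-test on per-individual log2 fold changes.

    ``lfc`` is genes x individuals.  ``prior_df``/``prior_s2`` override the
    empirical-Bayes estimates (``prior_df=0`` recovers the ordinary t-test;
    ``prior_df=inf`` fixes every posterior variance at the prior).
    """
    values = np.asarray(lfc, dtype=float)
    n = values.shape[1]
    if n < 2:
        raise ValueError("need >= 2 samples per gene")
    if values.shape[0] < 2:
        raise ValueError("need >= 2 genes to estimate the variance prior")
    mean = values.mean(axis=1)
    s2 = values.var(axis=1, ddof=1)
    df = n - 1

    if prior_df is None:
        d0, s02 = estimate_variance_prior(s2, df)
    else:
        d0 = float(prior_df)
        s02 = prior_s2 if prior_s2 is not None else float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 1.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        total_df = np.inf
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        total_df = d0 + df

    flagged = s2_post <= 0  # zero-variance genes with no moderation
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(s2_post / n)
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=total_df)
    p = np.where(flagged, np.nan, p)

    table = pd.DataFrame(
        {"mean": mean, "s2": s2, "s2_post": s2_post, "t": t, "p": p, "flagged": flagged},
        index=lfc.index,
    )
    return ModeratedTResult(table=table, prior_df=d0, prior_s2=s02, n=n)


def storey_qvalue(pvalues, lambda_: float = 0.5) -> tuple[np.ndarray, float]:
    """Storey-Tibshirani q-values with pi0 estimated at a single lambda.

    ``pi0_hat = #{p > lambda} / (m * (1 - lambda))`` clipped to (0, 1];
    ``q_(i) = min_{j >= i} pi0 * m * p_(j) / j``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = np.mean(p > lambda_) / (1.0 - lambda_)
    pi0 = min(pi0, 1.0)
    if pi0 <= 0:
        pi0 = 1.0 / m
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, float(pi0)


@dataclass
class DeResult:
    """Per-timepoint moderated-t tables with q-values and the DE calls."""

    tables: dict            # timepoint -> DataFrame(mean, t, p, q)
    pi0: dict               # timepoint -> pi0 estimate
    fdr: float
    de_genes: pd.Index


def de_from_panel(panel: pd.DataFrame, fdr: float = 0.05) -> DeResult:
    """Run the moderated t-test per timepoint on a (timepoint, sample) panel
    of per-individual log2 fold changes and call DE genes at the FDR level
    (union over timepoints)."""
    timepoints = panel.columns.get_level_values("timepoint").unique()
    tables, pi0s = {}, {}
    for tp in timepoints:
        res = moderated_t(panel[tp])
        tab = res.table[["mean", "t", "p"]].copy()
        valid = tab["p"].notna()
        q = np.full(len(tab), np.nan)
        q[valid.to_numpy()], pi0 = storey_qvalue(tab.loc[valid, "p"].to_numpy())
        tab["q"] = q
        tables[tp] = tab
        pi0s[tp] = pi0
    de = call_de(tables, fdr)
    return DeResult(tables=tables, pi0=pi0s, fdr=fdr, de_genes=de)


def call_de(tables: dict, fdr: float = 0.05) -> pd.Index:
    """Genes with q <= fdr at one or more timepoints."""
    hits: pd.Index | None = None
    for tab in tables.values():
        sel = tab.index[tab["q"] <= fdr]
        hits = sel if hits is None else hits.union(sel)
    return hits if hits is not None else pd.Index([])
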