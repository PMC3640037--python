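"""Binding-region annotation and the logistic direction model.

Binding regions (peaks) are assigned to genes by distance from the peak
midpoint to the gene's transcription start site (TSS).  For each gene with
a peak within the cis window, seven covariates are derived: distance (D),
strand-aware direction (d, 1 = upstream), whether the nearest peak is
closer to another gene (C), tag count at the nearest peak (T), whether a
CTCF region lies between TSS and peak (c), DNase hypersensitivity overlap
(Dh), and presence of a significant canonical receptor motif (M).  A
logistic model regresses the probability that a gene is up-regulated
(log2 fold change > 0) on these covariates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FEATURES = ["D", "d", "C", "T", "c", "Dh", "M"]


def _midpoints(peaks: pd.DataFrame) -> np.ndarray:
    return (peaks["start"].to_numpy() + peaks["end"].to_numpy()) / 2.0


def primary_targets(
    genes: pd.DataFrame, peaks: pd.DataFrame, window: int = 100_000
) -> pd.Series:
    """Flag genes with any peak midpoint within ``window`` bp of the TSS
    (boundary inclusive).  Genes on chromosomes absent from the peak track
    are flagged False with a warning."""
    flags = pd.Series(False, index=genes["gene"], name="primary_target")
    peak_chroms = set(peaks["chrom"]) if len(peaks) else set()
    for chrom, sub in genes.groupby("chrom"):
        if chrom not in peak_chroms:
            logger.warning("no peaks on %s; %d genes skipped", chrom, len(sub))
            continue
        mids = _midpoints(peaks[peaks["chrom"] == chrom])
        tss = sub["tss"].to_numpy(dtype=float)
        dist = np.abs(tss[:, None] - mids[None, :])
        flags.loc[sub["gene"]] = (dist.min(axis=1) <= window)
    return flags


def nearest_peak_features(
    genes: pd.DataFrame,
    peaks: pd.DataFrame,
    ctcf: pd.DataFrame,
    dnase: pd.DataFrame,
    motif_hits: Mapping[str, bool] | pd.Series,
    lfc: pd.Series,
    window: int = 100_000,
) -> pd.DataFrame:
    """Covariate table for the logistic direction model.

    One row per gene with >= 1 peak midpoint within ``window`` bp of its
    TSS; genes without such a peak are omitted.  The nearest peak is
    chosen by |TSS - midpoint| with ties broken toward the smaller start
    coordinate.  On minus-strand genes larger coordinates are upstream.
    ``lfc`` supplies the response label (up-regulated iff lfc > 0).
    """
    rows = []
    for chrom, gsub in genes.groupby("chrom"):
        psub = peaks[peaks["chrom"] == chrom]
        if psub.empty:
            logger.warning("no peaks on %s; %d genes omitted", chrom, len(gsub))
            continue
        psub = psub.sort_values(["start", "end"], kind="mergesort").reset_index(drop=True)
        mids = _midpoints(psub)
        all_tss = gsub["tss"].to_numpy(dtype=float)
        csub = ctcf[ctcf["chrom"] == chrom]
        cmids = _midpoints(csub) if len(csub) else np.empty(0)
        dsub = dnase[dnase["chrom"] == chrom]

        for _, gene in gsub.iterrows():
            tss = float(gene["tss"])
            dist = np.abs(tss - mids)
            j = int(np.argmin(dist))  # start-sorted, so first minimum = smallest start
            D = dist[j]
            if D > window:
                continue
            peak = psub.iloc[j]
            mid = mids[j]
            if gene["strand"] == "+":
                upstream = mid < tss
            else:
                upstream = mid > tss
            other = np.abs(all_tss - mid)
            other_min = np.min(other[all_tss != tss]) if np.sum(all_tss != tss) else np.inf
            C = other_min < D
            lo, hi = min(tss, mid), max(tss, mid)
            c_flag = bool(np.any((cmids > lo) & (cmids < hi))) if cmids.size else False
            if len(dsub):
                dh = bool(
                    np.any(
                        (dsub["start"].to_numpy() < peak["end"])
                        & (dsub["end"].to_numpy() > peak["start"])
                    )
                )
            else:
                dh = False
            m_flag = bool(
                motif_hits.get(peak["name"], False)
                if hasattr(motif_hits, "get")
                else motif_hits[peak["name"]]
            )
            rows.append(
                {
                    "gene": gene["gene"],
                    "peak": peak["name"],
                    "D": float(D),
                    "d": int(upstream),
                    "C": int(C),
                    "T": float(peak.get("tags", 0.0)),
                    "c": int(c_flag),
                    "Dh": int(dh),
                    "M": int(m_flag),
                    "label": int(float(lfc.get(gene["gene"], np.nan)) > 0),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PWM scanning (replacement for randomization-based motif callers)
# ---------------------------------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class PwmModel:
    """Log-odds position weight matrix with background frequencies.

    ``log_odds`` is 4 x L with rows A, C, G, T.  ``p_threshold`` is the
    empirical p-value below which a window is a significant hit.
    """

    log_odds: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    p_threshold: float = 0.01

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.log_odds.shape[0] != 4 or self.log_odds.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    @classmethod
    def from_probabilities(
        cls, probs: np.ndarray, background: np.ndarray | None = None, **kw
    ) -> "PwmModel":
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        probs = np.asarray(probs, dtype=float)
        return cls(np.log2(probs / bg[:, None]), bg, **kw)

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]


def default_gr_pwm(p_threshold: float = 0.01) -> PwmModel:
    """Canonical receptor half-site palindrome AGAACAnnnTGTTCT.

    Consensus bases carry probability 0.85 (0.05 otherwise); the 3-bp
    spacer is uninformative.
    """
    consensus = "AGAACANNNTGTTCT"
    probs = np.full((4, len(consensus)), 0.05)
    for j, base in enumerate(consensus):
        if base == "N":
            probs[:, j] = 0.25
        else:
            probs[_CODE[base], j] = 0.85
    return PwmModel.from_probabilities(probs, p_threshold=p_threshold)


def _encode(sequence: str) -> np.ndarray:
    return np.fromiter((_CODE.get(b, 4) for b in sequence.upper()), dtype=np.int8)


def score_windows(sequence: str, pwm: PwmModel) -> pd.DataFrame:
    """Log-odds score of every window on both strands.

    Windows containing N are skipped.  Returns columns pos, strand, score.
    """
    codes = _encode(sequence)
    L = pwm.length
    n = codes.size - L + 1
    if n <= 0:
        return pd.DataFrame(columns=["pos", "strand", "score"])
    lo = pwm.log_odds
    # minus strand == reverse complement PWM on the forward sequence
    rc = lo[::-1, ::-1]
    fwd = np.zeros(n)
    rev = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(L):
        col = codes[j : j + n]
        bad = col == 4
        valid &= ~bad
        safe = np.where(bad, 0, col)
        fwd += lo[safe, j]
        rev += rc[safe, j]
    frames = []
    for strand, scores in (("+", fwd), ("-", rev)):
        frames.append(
            pd.DataFrame(
                {"pos": np.arange(n)[valid], "strand": strand, "score": scores[valid]}
            )
        )
    return pd.concat(frames, ignore_index=True)


def empirical_pvalues(scores: np.ndarray, null_scores: np.ndarray) -> np.ndarray:
    """Upper-tail empirical p of each score against a null score sample,
    with add-one correction: p = (1 + #{null >= s}) / (1 + #null)."""
    null_sorted = np.sort(np.asarray(null_scores, dtype=float))
    n = null_sorted.size
    ge = n - np.searchsorted(null_sorted, np.asarray(scores, float), side="left")
    return (1.0 + ge) / (1.0 + n)


def pwm_scan(
    sequence: str, pwm: PwmModel, background_sequence: str
) -> pd.DataFrame:
    """Scan a sequence for significant motif matches.

    Scores every window on both strands, derives empirical p-values from
    the null score distribution over all windows (both strands) of the
    background sequence, and flags hits at p < ``pwm.p_threshold``.
    """
    hits = score_windows(sequence, pwm)
    null = score_windows(background_sequence, pwm)
    if hits.empty:
        return hits.assign(p=pd.Series(dtype=float), hit=pd.Series(dtype=bool))
    hits = hits.copy()
    hits["p"] = empirical_pvalues(hits["score"].to_numpy(), null["score"].to_numpy())
    hits["hit"] = hits["p"] < pwm.p_threshold
    return hits


def scan_peaks(
    sequences: Mapping[str, str], pwm: PwmModel, background_sequence: str
) -> pd.Series:
    """Per-peak flag: does the peak sequence contain a significant motif?

    The best window's empirical p-value is Sidak-corrected for the number
    of windows scanned in the peak, so the flag keeps its nominal
    specificity regardless of peak width.
    """
    null = score_windows(background_sequence, pwm)["score"].to_numpy()
    flags = {}
    for name, seq in sequences.items():
        sc = score_windows(seq, pwm)
        if sc.empty:
            flags[name] = False
            continue
        p = empirical_pvalues(sc["score"].to_numpy(), null)
        p_peak = 1.0 - (1.0 - p.min()) ** len(p)
        flags[name] = bool(p_peak < pwm.p_threshold)
    return pd.Series(flags, name="motif")


# ---------------------------------------------------------------------------
# logistic direction model
# ---------------------------------------------------------------------------

class SeparationWarning(UserWarning):
    """Quasi-complete separation detected in the logistic fit."""


@dataclass
class LogisticFit:
    summary: pd.DataFrame     # coef, se, z, p per term
    converged: bool
    n_iter: int
    separation: bool
    loglik: float


def _log_likelihood(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    rows: pd.DataFrame,
    features: Sequence[str] = FEATURES,
    label: str = "label",
    tol: float = 1e-8,
    max_iter: int = 100,
    min_rows: int = 20,
) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS.

    Design = intercept + the seven binding covariates.  Wald two-sided
    p-values per coefficient.  Perfect separation is flagged with a
    warning (coefficients still reported); a rank-deficient design raises
    an error naming the collinear columns.
    """
    if len(rows) < min_rows:
        raise ValueError(f"need >= {min_rows} rows to fit the direction model")
    y = rows[label].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both up- and down-regulated genes required")
    X = np.column_stack([np.ones(len(rows))] + [rows[f].to_numpy(float) for f in features])
    names = ["intercept"] + list(features)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                collinear.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")

    beta = np.zeros(X.shape[1])
    ll_prev = _log_likelihood(X, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        ll = _log_likelihood(X, y, beta)
        if ll + 1e-10 < ll_prev:
            logger.debug("IRLS log-likelihood decreased at iter %d", it)
        ll_prev = ll
        if step < tol:
            converged = True
            break

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    separation = bool(np.any(np.abs(eta) > 30) or np.all(np.abs(y - mu) < 1e-8))
    if separation:
        warnings.warn(
            "quasi-complete separation: coefficients are unstable", SeparationWarning
        )
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.inv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))
    zstat = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    summary = pd.DataFrame(
        {"coef": beta, "se": se, "z": zstat, "p": pvals}, index=pd.Index(names, name="term")
    )
    return LogisticFit(
        summary=summary,
        converged=converged,
        n_iter=it,
        separation=separation,
        loglik=ll_prev,
    )
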