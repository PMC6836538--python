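"""Selective-expression measures.

Four per-feature, per-tissue scores of how selectively a gene (or transcript)
is expressed across a panel of N tissues, given per-tissue means ``y_1..y_N``
and standard errors ``s_1..s_N``:

* **REZ** (robust-regression z-score) — the rank-sorted means of a
  non-selective gene approximately form a line; a Huber robust regression of
  the sorted means on their ranks, weighted by the expression SEs, downweights
  tissues that deviate from that line. The converged weights yield a robust
  mean and SD, and each tissue's deviation is standardized into a z-score,
  calibrated by a constant ``lambda = sqrt(1.5)`` so null p-values are
  approximately uniform.
* **conventional z** — plain (y - mean) / SD over tissues.
* **MAD z** — |y - median| / (1.4826 * median absolute deviation), with exact
  zero deviations removed so the MAD cannot collapse to zero.
* **RVP** — ratio of vector-scalar projection, ``y_i^2 / sum_j y_j^2``.

REZ and the conventional z carry two-sided normal p-values; MAD z and RVP do
not (none is defined for them).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import TissueSummary

logger = logging.getLogger("dese")

__all__ = [
    "HuberFit",
    "SelectiveExpressionProfile",
    "fit_huber_line",
    "rez_scores",
    "conventional_z",
    "mad_z",
    "rvp",
    "collapse_to_gene",
    "declare_selective_genes",
    "DEFAULT_LAMBDA",
    "HUBER_K_FACTOR",
]

#: calibration constant for REZ p-values
DEFAULT_LAMBDA = math.sqrt(1.5)
#: Huber tuning multiple on the scale of the weighted residuals
HUBER_K_FACTOR = 1.345


@dataclass
class HuberFit:
    """Converged Huber IRLS fit of sorted means against their ranks."""

    beta0: float
    beta1: float
    residuals: np.ndarray  # per sorted position
    weights: np.ndarray  # converged w_(i), sorted order
    k: float
    n_iter: int
    converged: bool


@dataclass
class SelectiveExpressionProfile:
    """Feature x tissue selective-expression scores under one measure."""

    score: pd.DataFrame  # features x tissues
    pvalue: pd.DataFrame | None  # None for mad_z / rvp
    measure: str  # rez | conventional_z | mad_z | rvp
    level: str = "gene"
    robust_mean: pd.Series | None = None  # REZ only
    robust_sd: pd.Series | None = None  # REZ only
    lam: float | None = None  # REZ calibration constant
    sign: pd.DataFrame | None = None  # mad_z only: sign(y - M)
    representing: pd.DataFrame | None = None  # transcript ids after collapse
    transcript_counts: pd.Series | None = None  # per gene, after collapse
    flags: dict = field(default_factory=dict)

    @property
    def feature_ids(self) -> pd.Index:
        return self.score.index

    @property
    def tissues(self) -> pd.Index:
        return self.score.columns

    def to_long(self) -> pd.DataFrame:
        """Tidy (feature, tissue, score, p) table for TSV export."""
        long = self.score.stack().rename("score").reset_index()
        long.columns = ["feature", "tissue", "score"]
        if self.pvalue is not None:
            long["p"] = self.pvalue.stack().values
        long["measure"] = self.measure
        if self.representing is not None:
            long["representing_transcript"] = self.representing.stack().values
        return long


# ---------------------------------------------------------------------------
# Huber IRLS on sorted means
# ---------------------------------------------------------------------------

def _batch_irls(
    y: np.ndarray,
    s: np.ndarray,
    k_factor: float = HUBER_K_FACTOR,
    tol: float = 1e-6,
    max_iter: int = 100,
):
    """Vectorized IRLS over a (features, N) batch of *sorted* rows.

    Model: y_(i) = b0 + b1 * i + e_(i) on ranks i = 1..N, refit by weighted
    least squares each round with Huber weights on the SE-standardized
    ("weighted") residuals u_(i) = e_(i) / s_(i):
        w_(i) = 1/s_(i)                              if |u_(i)| <= k
        w_(i) = k / (s_(i) |u_(i)|)  ( = k/|e_(i)| ) otherwise,
    where k = 1.345 x SD of the current round's weighted residuals
    w_(i)*e_(i). Standardizing inside the cutoff makes the procedure
    invariant to the units of y and s and reduces to the classic
    homoscedastic Huber rule (cutoff on raw residuals) when all SEs are 1,
    e.g. under the single-subject convention. Iterates until the largest
    absolute weight change drops below ``tol``. Rows whose weighted residuals
    all coincide (k = 0, e.g. an exact linear fit) freeze at their current
    weights.

    Returns (beta0, beta1, residuals, weights, k, n_iter, converged), each an
    array over the batch.
    """
    F, N = y.shape
    x = np.arange(1, N + 1, dtype=float)
    w = 1.0 / s
    b0 = np.zeros(F)
    b1 = np.zeros(F)
    e = np.zeros_like(y)
    k = np.zeros(F)
    n_iter = np.zeros(F, dtype=int)
    converged = np.zeros(F, dtype=bool)
    active = np.ones(F, dtype=bool)

    for it in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        wa, ya = w[idx], y[idx]
        sw = wa.sum(axis=1)
        sx = wa @ x
        sy = (wa * ya).sum(axis=1)
        sxx = wa @ (x * x)
        sxy = (wa * ya) @ x
        denom = sw * sxx - sx * sx
        with np.errstate(divide="ignore", invalid="ignore"):
            b1a = (sw * sxy - sx * sy) / denom
            b0a = (sy - b1a * sx) / sw
        bad = ~np.isfinite(b1a)  # weights collapsed onto (nearly) one point
        b1a[bad] = 0.0
        b0a[bad] = (sy / sw)[bad]
        ea = ya - (b0a[:, None] + b1a[:, None] * x)
        ka = k_factor * np.std(wa * ea, axis=1)
        ka[bad] = 0.0  # freeze degenerate rows at their current weights
        # Huber weight update on standardized residuals; |u| <= k covers
        # u = 0, so the division by |e| in the discarded branch may hit 0
        sa = s[idx]
        ua = ea / sa
        with np.errstate(divide="ignore", invalid="ignore"):
            new_w = np.where(
                np.abs(ua) <= ka[:, None], 1.0 / sa, ka[:, None] / np.abs(ea)
            )
        frozen = ka == 0.0  # degenerate scale: keep current weights, stop
        new_w[frozen] = wa[frozen]
        # relative change keeps the stopping rule invariant to the units of s
        delta = np.abs(new_w - wa).max(axis=1) / wa.max(axis=1)
        b0[idx], b1[idx], e[idx], k[idx] = b0a, b1a, ea, ka
        w[idx] = new_w
        n_iter[idx] = it + 1
        done = (delta < tol) | frozen
        converged[idx[done]] = True
        active[idx[done]] = False
    return b0, b1, e, w, k, n_iter, converged


def fit_huber_line(
    sorted_means: np.ndarray,
    sorted_ses: np.ndarray,
    k_factor: float = HUBER_K_FACTOR,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> HuberFit:
    """Fit one feature's sorted tissue means by Huber robust regression."""
    y = np.asarray(sorted_means, dtype=float)
    s = np.asarray(sorted_ses, dtype=float)
    if y.ndim != 1 or y.shape != s.shape:
        raise ValueError("sorted_means and sorted_ses must be 1-D of equal length")
    if y.size < 3:
        raise ValueError("need at least 3 tissues")
    if not (np.isfinite(y).all() and np.isfinite(s).all()):
        raise ValueError("non-finite input")
    if (s <= 0).any():
        raise ValueError("standard errors must be > 0")
    b0, b1, e, w, k, n_iter, conv = _batch_irls(y[None, :], s[None, :], k_factor, tol, max_iter)
    return HuberFit(
        beta0=float(b0[0]), beta1=float(b1[0]), residuals=e[0], weights=w[0],
        k=float(k[0]), n_iter=int(n_iter[0]), converged=bool(conv[0]),
    )


# ---------------------------------------------------------------------------
# The four measures
# ---------------------------------------------------------------------------

def _two_sided_normal_p(z: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(z))


def _rez_batch(y: np.ndarray, s: np.ndarray, order: np.ndarray, lam: float, tol, max_iter):
    """REZ core for a complete (no-NaN) batch; ``order`` is the per-row sort."""
    F, N = y.shape
    rows = np.arange(F)[:, None]
    ys = y[rows, order]
    ss = s[rows, order]
    _, _, _, w_sorted, _, _, _ = _batch_irls(ys, ss, tol=tol, max_iter=max_iter)
    w = np.empty_like(w_sorted)
    w[rows, order] = w_sorted  # back to original tissue order
    wn = w / w.sum(axis=1, keepdims=True)
    mu = (wn * y).sum(axis=1)
    denom = 1.0 - (wn ** 2).sum(axis=1)
    var = (wn * (y - mu[:, None]) ** 2).sum(axis=1)
    degenerate = (denom <= 0) | np.isclose(var, 0.0)
    sigma = np.sqrt(np.where(degenerate, 1.0, var / np.where(denom <= 0, 1.0, denom)))
    z = (y - mu[:, None]) / (sigma[:, None] * lam)
    z[degenerate] = 0.0
    return z, mu, np.where(degenerate, 0.0, sigma), degenerate


def rez_scores(
    s: TissueSummary,
    lam: float = DEFAULT_LAMBDA,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> SelectiveExpressionProfile:
    """Robust-regression z-scores of selective expression, with p-values.

    Per feature the tissue means are sorted ascending (stable, tissue label
    breaking ties) carrying their SEs, fitted by Huber IRLS against the ranks,
    and the converged weights — mapped back to the original tissue order and
    normalised to sum to one — define the robust mean and SD that standardize
    each tissue's deviation. Degenerate features (robust SD ~ 0, or a single
    tissue holding all weight) get score 0 / p 1 and are listed in
    ``flags['degenerate']``.
    """
    if s.mean.shape[1] < 3:
        raise ValueError("REZ needs >= 3 tissues")
    # label-sorted columns + stable argsort on means == sort by (mean, label)
    label_order = np.argsort(s.tissues.astype(str))
    mean = s.mean.iloc[:, label_order]
    se = s.se.iloc[:, label_order]
    y = mean.values.astype(float)
    sv = se.values.astype(float)

    score = np.full_like(y, np.nan)
    mu_out = np.full(y.shape[0], np.nan)
    sd_out = np.full(y.shape[0], np.nan)
    degen = np.zeros(y.shape[0], dtype=bool)

    complete = np.isfinite(y).all(axis=1)
    if complete.any():
        idx = np.flatnonzero(complete)
        order = np.argsort(y[idx], axis=1, kind="stable")
        z, mu, sigma, dg = _rez_batch(y[idx], sv[idx], order, lam, tol, max_iter)
        score[idx], mu_out[idx], sd_out[idx], degen[idx] = z, mu, sigma, dg
    for i in np.flatnonzero(~complete):  # rows with missing tissues
        ok = np.isfinite(y[i])
        if ok.sum() < 3:
            degen[i] = True
            score[i, ok] = 0.0
            continue
        order = np.argsort(y[i, ok], kind="stable")[None, :]
        z, mu, sigma, dg = _rez_batch(y[i, ok][None, :], sv[i, ok][None, :], order, lam, tol, max_iter)
        score[i, ok] = z[0]
        mu_out[i], sd_out[i], degen[i] = mu[0], sigma[0], dg[0]

    pval = _two_sided_normal_p(np.nan_to_num(score, nan=0.0))
    pval[~np.isfinite(score)] = np.nan
    pval[degen] = np.where(np.isfinite(score[degen]), 1.0, np.nan)

    back = np.argsort(label_order)  # restore caller's tissue order
    score_df = pd.DataFrame(score, index=s.feature_ids, columns=mean.columns).iloc[:, back]
    p_df = pd.DataFrame(pval, index=s.feature_ids, columns=mean.columns).iloc[:, back]
    return SelectiveExpressionProfile(
        score=score_df, pvalue=p_df, measure="rez", level=s.level,
        robust_mean=pd.Series(mu_out, index=s.feature_ids),
        robust_sd=pd.Series(sd_out, index=s.feature_ids),
        lam=lam, flags={"degenerate": list(s.feature_ids[degen])},
    )


def conventional_z(s: TissueSummary) -> SelectiveExpressionProfile:
    """Plain z-score over tissues, (y_i - mean) / SD, with normal p-values."""
    if s.mean.shape[1] < 2:
        raise ValueError("conventional z needs >= 2 tissues")
    y = s.mean.values.astype(float)
    mu = np.nanmean(y, axis=1, keepdims=True)
    sd = np.nanstd(y, axis=1, ddof=1, keepdims=True)
    degen = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    sd = np.where(sd <= 0, 1.0, sd)
    z = (y - mu) / sd
    z[degen] = 0.0
    p = _two_sided_normal_p(np.nan_to_num(z, nan=0.0))
    p[~np.isfinite(z)] = np.nan
    p[degen] = 1.0
    return SelectiveExpressionProfile(
        score=pd.DataFrame(z, index=s.feature_ids, columns=s.tissues),
        pvalue=pd.DataFrame(p, index=s.feature_ids, columns=s.tissues),
        measure="conventional_z", level=s.level,
        flags={"degenerate": list(s.feature_ids[degen])},
    )


def mad_z(s: TissueSummary) -> SelectiveExpressionProfile:
    """Median-absolute-deviation robust z-score, |y_i - M| / MAD.

    Exact zero deviations are dropped before taking the median deviation so a
    feature expressed identically in most tissues still gets a positive MAD.
    The companion ``sign`` frame records sign(y_i - M) so direction is
    recoverable; no p-value is defined for this measure.
    """
    if s.mean.shape[1] < 3:
        raise ValueError("MAD z needs >= 3 tissues")
    y = s.mean.values.astype(float)
    M = np.nanmedian(y, axis=1, keepdims=True)
    dev = np.abs(y - M)
    z = np.zeros_like(y)
    degen = np.zeros(y.shape[0], dtype=bool)
    for i in range(y.shape[0]):
        nz = dev[i][np.isfinite(dev[i]) & (dev[i] > 0)]
        if nz.size == 0:
            degen[i] = True
            continue
        mad = 1.4826 * np.median(nz)
        z[i] = dev[i] / mad
    z[~np.isfinite(y)] = np.nan
    return SelectiveExpressionProfile(
        score=pd.DataFrame(z, index=s.feature_ids, columns=s.tissues),
        pvalue=None, measure="mad_z", level=s.level,
        sign=pd.DataFrame(np.sign(y - M), index=s.feature_ids, columns=s.tissues),
        flags={"degenerate": list(s.feature_ids[degen])},
    )


def rvp(s: TissueSummary) -> SelectiveExpressionProfile:
    """Ratio of vector-scalar projection, y_i^2 / sum_j y_j^2, in [0, 1]."""
    y = s.mean.values.astype(float)
    sq = np.square(y)
    total = np.nansum(sq, axis=1, keepdims=True)
    degen = total[:, 0] == 0
    out = np.where(total > 0, sq / np.where(total == 0, 1.0, total), np.nan)
    if degen.any():
        logger.warning("%d all-zero features have undefined RVP", int(degen.sum()))
    return SelectiveExpressionProfile(
        score=pd.DataFrame(out, index=s.feature_ids, columns=s.tissues),
        pvalue=None, measure="rvp", level=s.level,
        flags={"degenerate": list(s.feature_ids[degen])},
    )


MEASURES = {
    "rez": rez_scores,
    "conventional_z": conventional_z,
    "mad_z": mad_z,
    "rvp": rvp,
}


# ---------------------------------------------------------------------------
# Transcript -> gene collapse and selectivity calls
# ---------------------------------------------------------------------------

def collapse_to_gene(
    p: SelectiveExpressionProfile,
    transcript_gene_map: dict | pd.Series,
    mode: str = "max",
) -> SelectiveExpressionProfile:
    """Represent each gene, per tissue, by its highest-scoring transcript.

    The representing transcript id is recorded and its p-value carried over.
    Transcripts absent from the map are excluded with a warning.
    """
    if mode != "max":
        raise ValueError(f"unsupported collapse mode {mode!r}")
    tmap = pd.Series(transcript_gene_map)
    unmapped = p.feature_ids.difference(tmap.index)
    if len(unmapped):
        logger.warning("%d unmapped transcripts excluded from gene collapse", len(unmapped))
    keep = p.feature_ids.intersection(tmap.index)
    genes = tmap.loc[keep]
    score = p.score.loc[keep]
    grouped = score.groupby(genes.values)
    gene_score = grouped.max()
    rep_pos = grouped.idxmax()  # transcript id of the max, per tissue
    gene_p = None
    if p.pvalue is not None:
        pv = p.pvalue.loc[keep]
        gene_p = pd.DataFrame(
            {t: pv[t].reindex(rep_pos[t]).values for t in p.tissues},
            index=gene_score.index,
        )
    counts = genes.groupby(genes.values).size()
    return SelectiveExpressionProfile(
        score=gene_score, pvalue=gene_p, measure=p.measure, level="gene",
        lam=p.lam, representing=rep_pos,
        transcript_counts=pd.Series(counts, index=gene_score.index),
        flags=dict(p.flags),
    )


def declare_selective_genes(
    p: SelectiveExpressionProfile,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    transcript_gene_map: dict | pd.Series | None = None,
) -> dict[str, set]:
    """Per-tissue sets of genes with significant selective expression.

    At transcript level (a map is given, or the profile retains transcript
    counts from :func:`collapse_to_gene`), a gene is selective in a tissue if
    any of its transcripts passes ``alpha / (its transcript count)``. At gene
    level the threshold is ``alpha / (number of genes)``.
    """
    if p.pvalue is None:
        raise ValueError(f"measure {p.measure!r} emits no p-values")
    if correction != "bonferroni":
        raise ValueError(f"unsupported correction {correction!r}")
    out: dict[str, set] = {}
    if p.level == "transcript":
        if transcript_gene_map is None:
            raise ValueError("transcript-level profile needs a transcript->gene map")
        tmap = pd.Series(transcript_gene_map)
        keep = p.feature_ids.intersection(tmap.index)
        genes = tmap.loc[keep]
        counts = genes.groupby(genes.values).size()
        thr = (alpha / counts).reindex(genes.values).values  # per transcript
        pv = p.pvalue.loc[keep]
        for t in p.tissues:
            hit = pv[t].values < thr
            out[t] = set(genes.values[hit & np.isfinite(pv[t].values)])
    else:
        if p.transcript_counts is not None:
            thr = (alpha / p.transcript_counts).reindex(p.feature_ids).values
        else:
            thr = np.full(len(p.feature_ids), alpha / max(len(p.feature_ids), 1))
        for t in p.tissues:
            pv = p.pvalue[t].values
            out[t] = set(p.feature_ids[(pv < thr) & np.isfinite(pv)])
    return out
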