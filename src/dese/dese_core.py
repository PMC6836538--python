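"""The iterative driver-tissue estimation loop.

Given gene-level selective-expression scores and GWAS summary statistics, the
framework alternates three stages until the per-tissue enrichment p-values
stabilise:

1. conditional gene-based association (:func:`dese.assoc.conditional_ecs`),
   entered in ascending raw-p order on the first pass and by descending
   tissue-selectivity ranking score afterwards;
2. per-tissue one-sided Wilcoxon rank-sum tests of whether the conditionally
   associated genes have higher selective-expression scores than the other
   profiled genes;
3. the gene ranking score s_j = sum_i (k_ji / T_i) * (-log10 p_i), where
   k_ji is gene j's ascending score rank among the T_i scored genes of
   tissue i and p_i is that tissue's current enrichment p — genes selectively
   expressed in the putative driver tissues rise to the front of the next
   conditional pass.

The rationale: if truly causal genes (which tend to be selectively expressed
in driver tissues) enter the conditioning first, LD-shadow genes are
explained away, which in turn sharpens the tissue enrichment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb

from .assoc import (
    GwasSummary,
    GeneModel,
    LdReference,
    assign_variants_to_genes,
    conditional_ecs,
    ecs_gene_p,
    results_to_frame,
    significant_genes,
)
from .selexp import SelectiveExpressionProfile, collapse_to_gene, declare_selective_genes

logger = logging.getLogger("dese")

__all__ = [
    "TissueEnrichment",
    "RankingScores",
    "DeseConfig",
    "DeseResult",
    "tissue_enrichment",
    "ranking_scores",
    "run_dese",
    "prioritized_genes",
]

MIN_P = 1e-300
# full enumeration of label assignments is used when C(n, n1) stays below this
MAX_ENUMERATION = 200_000


@dataclass
class TissueEnrichment:
    tissue: str
    u_statistic: float
    pvalue: float
    n_assoc: int
    n_background: int
    iteration: int = 0
    method: str = "exact"


@dataclass
class RankingScores:
    """Tissue-selectivity ranking scores s_j with their per-tissue makeup."""

    score: pd.Series  # s_j per gene
    per_tissue_terms: pd.DataFrame  # (k_ji / T_i) * (-log10 p_i)
    ranks: pd.DataFrame  # k_ji (average ranks, ascending scores)
    totals: pd.Series  # T_i per tissue


@dataclass
class DeseConfig:
    flank: int = 5000
    alpha: float = 0.05
    correction: str = "bonferroni"
    tol: float = 0.01
    max_iter: int = 20
    screen_p: float | None = 0.01
    exact_limit: int = 25
    exact_total: int = 1000
    seed: int | None = None


@dataclass
class DeseResult:
    tissue_table: pd.DataFrame  # final enrichment per tissue, sorted by p
    gene_table: pd.DataFrame  # association results + ranking scores
    history: list[pd.Series]  # tissue p-values per iteration
    n_iterations: int
    converged: bool
    profile: SelectiveExpressionProfile | None = None
    config: DeseConfig = field(default_factory=DeseConfig)
    ranking: RankingScores | None = None
    significant: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# Wilcoxon tissue enrichment
# ---------------------------------------------------------------------------

def _rank_sum_enumeration(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact one-sided p by enumerating all foreground label assignments."""
    n = len(ranks)
    offset = n1 * (n1 + 1) / 2.0
    hits = 0
    total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if u >= u_obs - 1e-9:
            hits += 1
    return hits / total


def tissue_enrichment(
    assoc_genes,
    profile: SelectiveExpressionProfile,
    tissue: str,
    exact_limit: int = 25,
    exact_total: int = 1000,
    iteration: int = 0,
) -> TissueEnrichment:
    """One-sided Mann-Whitney U test: do the associated genes have higher
    selective-expression scores in this tissue than the other profiled genes?

    The exact null distribution is used for small groups (for tied scores, by
    full enumeration of label assignments while that remains feasible);
    otherwise the normal approximation with tie and continuity corrections.
    """
    scores = profile.score[tissue].dropna()
    assoc_genes = set(assoc_genes)
    fg = scores[scores.index.isin(assoc_genes)]
    bg = scores[~scores.index.isin(assoc_genes)]
    if len(fg) < 1:
        raise ValueError(f"no associated gene has a score in tissue {tissue!r}")
    if len(bg) < 1:
        raise ValueError(f"empty background in tissue {tissue!r} (all genes associated)")
    n1, n2 = len(fg), len(bg)
    pooled = np.concatenate([fg.values, bg.values])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(pooled)) < len(pooled)

    small = min(n1, n2) <= exact_limit and n1 + n2 <= exact_total
    if small and not has_ties:
        res = stats.mannwhitneyu(fg.values, bg.values, alternative="greater", method="exact")
        p, method = float(res.pvalue), "exact"
    elif small and comb(n1 + n2, n1) <= MAX_ENUMERATION:
        p, method = _rank_sum_enumeration(ranks, n1, u_obs), "exact"
    else:
        res = stats.mannwhitneyu(
            fg.values, bg.values, alternative="greater",
            method="asymptotic", use_continuity=True,
        )
        p, method = float(res.pvalue), "asymptotic"
    return TissueEnrichment(
        tissue=tissue, u_statistic=float(u_obs), pvalue=min(max(p, MIN_P), 1.0),
        n_assoc=n1, n_background=n2, iteration=iteration, method=method,
    )


# ---------------------------------------------------------------------------
# Ranking score s_j
# ---------------------------------------------------------------------------

def ranking_scores(
    profile: SelectiveExpressionProfile, tissue_ps: pd.Series
) -> RankingScores:
    """s_j = sum over tissues of (ascending score rank / T_i) * (-log10 p_i).

    Ties receive average ranks; a gene without a score in a tissue
    contributes 0 for that tissue. p-values of 0 are clamped to the smallest
    representable positive with a warning.
    """
    ps = tissue_ps.reindex(profile.tissues).astype(float)
    if (ps <= 0).any():
        logger.warning("tissue p-values <= 0 clamped to %g", MIN_P)
        ps = ps.clip(lower=MIN_P)
    neglogp = -np.log10(ps)
    ranks = pd.DataFrame(index=profile.feature_ids, columns=profile.tissues, dtype=float)
    totals = pd.Series(index=profile.tissues, dtype=float)
    terms = pd.DataFrame(0.0, index=profile.feature_ids, columns=profile.tissues)
    for t in profile.tissues:
        col = profile.score[t]
        ok = col.notna()
        T = int(ok.sum())
        totals[t] = T
        if T == 0:
            continue
        k = stats.rankdata(col[ok].values)  # ascending, average ranks
        ranks.loc[ok, t] = k
        terms.loc[ok, t] = (k / T) * neglogp[t]
    score = terms.sum(axis=1)
    return RankingScores(score=score, per_tissue_terms=terms, ranks=ranks, totals=totals)


# ---------------------------------------------------------------------------
# The iterative loop
# ---------------------------------------------------------------------------

def _enrich_all(sig_genes, profile, cfg, iteration) -> list[TissueEnrichment]:
    rows = []
    for t in profile.tissues:
        try:
            rows.append(
                tissue_enrichment(
                    sig_genes, profile, t,
                    exact_limit=cfg.exact_limit, exact_total=cfg.exact_total,
                    iteration=iteration,
                )
            )
        except ValueError:
            # no scored associated gene (or no background) in this tissue
            rows.append(TissueEnrichment(t, math.nan, 1.0, 0, 0, iteration, "undefined"))
    return rows


def _enrichment_frame(rows: list[TissueEnrichment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tissue": [r.tissue for r in rows],
            "U": [r.u_statistic for r in rows],
            "p": [r.pvalue for r in rows],
            "neg_log10_p": [-math.log10(r.pvalue) for r in rows],
            "n_assoc": [r.n_assoc for r in rows],
            "n_background": [r.n_background for r in rows],
            "iteration": [r.iteration for r in rows],
            "method": [r.method for r in rows],
        }
    )


def run_dese(
    gwas: GwasSummary,
    model: GeneModel,
    ld: LdReference,
    profile: SelectiveExpressionProfile,
    config: DeseConfig | None = None,
    transcript_gene_map=None,
) -> DeseResult:
    """Iterate conditional association, tissue enrichment and gene re-ranking
    until the tissue p-values converge.

    Iteration 0 orders genes by ascending unconditional gene p; every later
    iteration orders by descending ranking score s_j (ties: ascending
    conditional p, then gene id). Convergence is declared when the largest
    per-tissue change in -log10 p between two consecutive iterations drops
    below ``config.tol``. If no gene is significant at iteration 0 the run
    terminates with ``converged=False`` and an empty driver report.
    """
    cfg = config or DeseConfig()
    if profile.level == "transcript":
        if transcript_gene_map is None:
            raise ValueError("transcript-level profile needs transcript_gene_map")
        profile = collapse_to_gene(profile, transcript_gene_map)

    gene_variants = assign_variants_to_genes(gwas, model, flank=cfg.flank)
    if not gene_variants:
        raise ValueError("no gene received any variant")
    vp = gwas.variant_p

    # unconditional gene p-values define the first entry order
    raw = {}
    for g, variants in gene_variants.items():
        raw[g] = ecs_gene_p(vp.loc[variants].values, ld.corr(variants))
    order = sorted(gene_variants, key=lambda g: (raw[g], g))

    results = conditional_ecs(
        order, gene_variants, vp, ld,
        alpha=cfg.alpha, screen_p=cfg.screen_p,
    )
    sig = {r.gene_id for r in results if r.selected}
    history: list[pd.Series] = []
    converged = False
    ranking: RankingScores | None = None
    enrich_rows: list[TissueEnrichment] = []

    if not sig:
        logger.warning("no significant genes at iteration 0; empty driver report")
        tissue_table = _enrichment_frame(
            [TissueEnrichment(t, math.nan, 1.0, 0, 0, 0, "undefined") for t in profile.tissues]
        )
        return DeseResult(
            tissue_table=tissue_table, gene_table=results_to_frame(results),
            history=[], n_iterations=0, converged=False, profile=profile,
            config=cfg, significant=set(),
        )

    prev_logp: pd.Series | None = None
    iteration = 0
    for iteration in range(cfg.max_iter):
        enrich_rows = _enrich_all(sig, profile, cfg, iteration)
        tissue_ps = pd.Series({r.tissue: r.pvalue for r in enrich_rows})
        history.append(tissue_ps)
        logp = -np.log10(tissue_ps.clip(lower=MIN_P))
        logger.info(
            "iteration %d: %d significant genes, top tissue %s (p=%.3g)",
            iteration, len(sig), tissue_ps.idxmin(), tissue_ps.min(),
        )
        if prev_logp is not None and float((logp - prev_logp).abs().max()) < cfg.tol:
            converged = True
            break
        prev_logp = logp

        ranking = ranking_scores(profile, tissue_ps)
        cond_p = {r.gene_id: r.cond_p for r in results}
        order = sorted(
            gene_variants,
            key=lambda g: (
                -float(ranking.score.get(g, 0.0)),  # absent genes fall back
                cond_p.get(g, raw[g]),
                g,
            ),
        )
        results = conditional_ecs(
            order, gene_variants, vp, ld,
            alpha=cfg.alpha, screen_p=cfg.screen_p,
        )
        sig = {r.gene_id for r in results if r.selected}
        if not sig:
            logger.warning("significant gene set became empty at iteration %d", iteration + 1)
            break

    tissue_table = _enrichment_frame(enrich_rows).sort_values("p", kind="stable")
    gene_table = results_to_frame(results)
    if ranking is not None:
        gene_table["s_j"] = ranking.score.reindex(gene_table["gene"]).fillna(0.0).values
    else:
        gene_table["s_j"] = 0.0
    return DeseResult(
        tissue_table=tissue_table.reset_index(drop=True), gene_table=gene_table,
        history=history, n_iterations=len(history), converged=converged,
        profile=profile, config=cfg, ranking=ranking, significant=sig,
    )


def prioritized_genes(result: DeseResult, alpha: float = 0.05) -> pd.DataFrame:
    """Flag genes that are both conditionally significant and selectively
    expressed in at least one significant driver tissue.

    Driver tissues are those with enrichment p below ``alpha / N`` (Bonferroni
    over the N tested tissues). Selectivity per tissue follows
    :func:`dese.selexp.declare_selective_genes` at level ``alpha``.
    """
    profile = result.profile
    if profile is None:
        raise ValueError("result carries no expression profile")
    tt = result.tissue_table
    n_tissues = len(tt)
    driver_tissues = list(tt.loc[tt["p"] < alpha / max(n_tissues, 1), "tissue"])
    table = result.gene_table.copy()
    sig = result.significant
    supporting: list[str] = []
    flags: list[bool] = []
    if profile.pvalue is not None:
        selective = declare_selective_genes(profile, alpha=alpha)
    else:  # score-only measures: no selectivity call possible
        selective = {t: set() for t in profile.tissues}
    for gene in table["gene"]:
        tissues = [t for t in driver_tissues if gene in selective.get(t, set())]
        supporting.append(",".join(tissues))
        flags.append(gene in sig and len(tissues) > 0)
    table["supporting_tissues"] = supporting
    table["prioritized"] = flags
    return table
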