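"""Gene-based association from GWAS summary statistics.

Variants are assigned to genes within a flank (default 5 kb), each gene's
variant p-values are combined into a gene-level p-value by an
effective-chi-square (ECS) statistic that corrects for linkage
disequilibrium (LD), and a conditional entry procedure removes genes whose
association is explained by genes already selected.

The ECS statistic is the sum of 1-df chi-squares, T = sum_k q_k with q_k the
inverse upper-tail chi-square of variant k's p-value. For jointly normal
z-scores with correlation matrix R the null law of T is exactly the weighted
chi-square sum  sum_i lambda_i chi^2_1  with lambda_i the eigenvalues of R
(E[T] = m, Var[T] = 2 sum lambda_i^2 = 2m + 4 sum_{i<j} r_ij^2); the gene
p-value approximates its upper tail by moment matching to a (non-central)
chi-square on the first three/four cumulants (Liu-Tang-Zhang), which is
effectively a chi-square with LD-corrected degrees of freedom and is exact in
the limiting cases of one variant and of perfect LD. Conditioning projects a candidate
gene's |z|-scores onto the span of the already-selected genes' variants using
the LD correlation matrix and re-applies ECS to the variance-renormalised
residuals. Summary p-values carry no effect sign, so conditioning uses
unsigned z-scores; the removed association is therefore an upper bound on the
association actually explained by the selected genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("dese")

__all__ = [
    "GwasSummary",
    "GeneModel",
    "LdReference",
    "BlockLdReference",
    "VcfLdReference",
    "GeneAssocResult",
    "read_gwas_tsv",
    "read_gene_model_tsv",
    "read_gene_model_bed",
    "assign_variants_to_genes",
    "ecs_gene_p",
    "conditional_ecs",
    "significant_genes",
]

MIN_P = 1e-300


@dataclass
class GwasSummary:
    """Variant-level GWAS summary statistics (id, chrom, pos, p)."""

    table: pd.DataFrame  # columns: variant_id, chrom, pos, p

    def __post_init__(self) -> None:
        need = {"variant_id", "chrom", "pos", "p"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"GWAS table needs columns {sorted(need)}")
        if (self.table["p"] <= 0).any():
            n = int((self.table["p"] <= 0).sum())
            logger.warning("%d variant p-values <= 0 clamped to %g", n, MIN_P)
            self.table = self.table.copy()
            self.table.loc[self.table["p"] <= 0, "p"] = MIN_P

    @property
    def variant_p(self) -> pd.Series:
        return pd.Series(self.table["p"].values, index=self.table["variant_id"].values)


@dataclass
class GeneModel:
    """Gene coordinate table (gene_id, symbol, chrom, strand, start, end).

    Coordinates are 1-based inclusive. One genome build across GWAS, gene
    model and LD reference is the caller's responsibility.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"gene_id", "chrom", "start", "end"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"gene model needs columns {sorted(need)}")
        if (self.table["start"] > self.table["end"]).any():
            raise ValueError("gene model has start > end")

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.table["gene_id"])


def read_gwas_tsv(
    path,
    variant_col: str = "SNP",
    chrom_col: str = "CHR",
    pos_col: str = "BP",
    p_col: str = "P",
    sep: str = "\t",
) -> GwasSummary:
    t = pd.read_csv(path, sep=sep, comment="#", dtype={chrom_col: str})
    for col in (variant_col, chrom_col, pos_col, p_col):
        if col not in t.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out = pd.DataFrame(
        {
            "variant_id": t[variant_col].astype(str),
            "chrom": t[chrom_col].astype(str),
            "pos": t[pos_col].astype(int),
            "p": t[p_col].astype(float),
        }
    )
    return GwasSummary(out)


def read_gene_model_tsv(path) -> GeneModel:
    """RefSeq-style TSV with 1-based inclusive start/end."""
    t = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    return GeneModel(t)


def read_gene_model_bed(path) -> GeneModel:
    """BED (0-based half-open); converted to 1-based inclusive: start+1, end."""
    t = pd.read_csv(path, sep="\t", comment="#", header=None)
    out = pd.DataFrame(
        {
            "gene_id": t.iloc[:, 3].astype(str),
            "symbol": t.iloc[:, 3].astype(str),
            "chrom": t.iloc[:, 0].astype(str),
            "strand": t.iloc[:, 5] if t.shape[1] > 5 else "+",
            "start": t.iloc[:, 1].astype(int) + 1,
            "end": t.iloc[:, 2].astype(int),
        }
    )
    return GeneModel(out)


# ---------------------------------------------------------------------------
# LD references
# ---------------------------------------------------------------------------

class LdReference:
    """Provider of pairwise Pearson correlations between variants."""

    def corr(self, variant_ids: list[str]) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class BlockLdReference(LdReference):
    """LD as per-block correlation matrices; zero correlation across blocks.

    ``blocks`` maps a block id to (list of variant ids, correlation matrix).
    """

    def __init__(self, blocks: dict):
        self._loc: dict[str, tuple] = {}
        self._blocks = blocks
        for bid, (ids, R) in blocks.items():
            R = np.asarray(R, dtype=float)
            if R.shape != (len(ids), len(ids)):
                raise ValueError(f"block {bid}: matrix shape does not match variant count")
            for i, vid in enumerate(ids):
                self._loc[vid] = (bid, i)

    def corr(self, variant_ids: list[str]) -> np.ndarray:
        n = len(variant_ids)
        R = np.zeros((n, n))
        locs = [self._loc[v] for v in variant_ids]
        for a in range(n):
            ba, ia = locs[a]
            R[a, a] = 1.0
            for b in range(a + 1, n):
                bb, ib = locs[b]
                if ba == bb:
                    R[a, b] = R[b, a] = self._blocks[ba][1][ia, ib]
        return R

    def save_tsv(self, path) -> None:
        """One row per variant pair within a block: block, id_i, id_j, r."""
        with open(path, "w") as fh:
            fh.write("#block\tvariant_i\tvariant_j\tr\n")
            for bid, (ids, R) in self._blocks.items():
                for i in range(len(ids)):
                    for j in range(i, len(ids)):
                        fh.write(f"{bid}\t{ids[i]}\t{ids[j]}\t{R[i, j]:.10g}\n")

    @classmethod
    def load_tsv(cls, path) -> "BlockLdReference":
        t = pd.read_csv(path, sep="\t", header=None, comment="#",
                        names=["block", "variant_i", "variant_j", "r"])
        blocks = {}
        for bid, sub in t.groupby("block"):
            ids = list(pd.unique(pd.concat([sub["variant_i"], sub["variant_j"]])))
            pos = {v: i for i, v in enumerate(ids)}
            R = np.eye(len(ids))
            for _, row in sub.iterrows():
                i, j = pos[row["variant_i"]], pos[row["variant_j"]]
                R[i, j] = R[j, i] = row["r"]
            blocks[bid] = (ids, R)
        return cls(blocks)


class VcfLdReference(LdReference):
    """Pearson correlation of allele dosages from reference-panel genotypes.

    Loads biallelic variants from a VCF into memory; variants on different
    chromosomes get correlation 0.
    """

    def __init__(self, vcf_path):
        from cyvcf2 import VCF

        self._dosage: dict[str, np.ndarray] = {}
        self._chrom: dict[str, str] = {}
        for rec in VCF(str(vcf_path)):
            if len(rec.ALT) != 1:
                continue
            vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
            gt = np.asarray(rec.gt_types, dtype=float)  # 0,1,3->2 hom-alt, 2 unknown
            dos = np.where(gt == 3, 2.0, gt)
            dos[gt == 2] = np.nan
            self._dosage[vid] = dos
            self._chrom[vid] = rec.CHROM

    def corr(self, variant_ids: list[str]) -> np.ndarray:
        n = len(variant_ids)
        R = np.eye(n)
        for a in range(n):
            for b in range(a + 1, n):
                va, vb = variant_ids[a], variant_ids[b]
                if self._chrom[va] != self._chrom[vb]:
                    continue
                da, db = self._dosage[va], self._dosage[vb]
                ok = np.isfinite(da) & np.isfinite(db)
                if ok.sum() < 2 or da[ok].std() == 0 or db[ok].std() == 0:
                    continue
                R[a, b] = R[b, a] = np.corrcoef(da[ok], db[ok])[0, 1]
        return R


@dataclass
class GeneAssocResult:
    gene_id: str
    n_variants: int
    raw_p: float
    cond_p: float
    entry_rank: int
    selected: bool
    condition_number: float | None = None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def assign_variants_to_genes(
    gwas: GwasSummary, model: GeneModel, flank: int = 5000
) -> dict[str, list[str]]:
    """Assign each variant to every gene within ``flank`` bp of its body.

    A variant lands on gene g iff ``g.start - flank <= pos <= g.end + flank``
    on the same chromosome; shared variants go to every overlapping gene.
    Genes with no variants are omitted from the map.
    """
    out: dict[str, list[str]] = {}
    by_chrom = {}
    for chrom, sub in gwas.table.groupby("chrom"):
        sub = sub.sort_values("pos")
        by_chrom[chrom] = (sub["pos"].values, sub["variant_id"].values)
    for row in model.table.itertuples():
        if row.chrom not in by_chrom:
            continue
        pos, ids = by_chrom[row.chrom]
        lo = np.searchsorted(pos, row.start - flank, side="left")
        hi = np.searchsorted(pos, row.end + flank, side="right")
        if hi > lo:
            out[row.gene_id] = list(ids[lo:hi])
    return out


def _chi2_upper(p: np.ndarray) -> np.ndarray:
    return stats.chi2.isf(np.clip(p, MIN_P, 1.0), df=1)


def _weighted_chi2_sf(T: float, lam: np.ndarray) -> float:
    """Upper tail of sum_i lam_i chi^2_1 by 3-moment chi-square matching.

    Liu-Tang-Zhang approximation: match skewness (and kurtosis when
    attainable) of the weighted sum with a non-central chi-square. Exact when
    the weights are a single non-zero value (one variant, or perfect LD).
    """
    lam = lam[lam > 1e-12]
    c1 = lam.sum()
    c2 = float(lam @ lam)
    c3 = float((lam ** 3).sum())
    c4 = float((lam ** 4).sum())
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - math.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        df = a ** 2 - 2.0 * delta
    else:
        a = 1.0 / s1
        delta = 0.0
        df = c2 ** 3 / c3 ** 2
    t_star = (T - c1) / math.sqrt(2.0 * c2)
    x = t_star * math.sqrt(2.0) * a + df + delta
    if delta == 0.0:
        return float(stats.chi2.sf(max(x, 0.0), df=df))
    return float(stats.ncx2.sf(max(x, 0.0), df=df, nc=delta))


def ecs_gene_p(variant_ps, ld_corr) -> float:
    """Effective-chi-square gene p-value for one gene's variants.

    With a single variant this reduces to the variant p; with m identical
    variants in perfect LD it collapses back to the single-variant p. It is
    monotone: lowering any variant p never raises the gene p.
    """
    p = np.atleast_1d(np.asarray(variant_ps, dtype=float))
    if p.size == 0:
        raise ValueError("need at least one variant")
    if (p <= 0).any():
        logger.warning("p-values <= 0 clamped to %g", MIN_P)
    q = _chi2_upper(p)
    m = p.size
    if m == 1:
        return float(np.clip(p[0], MIN_P, 1.0))
    R = np.asarray(ld_corr, dtype=float)
    if R.shape != (m, m):
        raise ValueError("LD matrix shape does not match variant count")
    lam = np.linalg.eigvalsh(R)
    return _weighted_chi2_sf(float(q.sum()), np.clip(lam, 0.0, None))


def _decorrelate(
    z_c: np.ndarray, z_s: np.ndarray, R: np.ndarray, nc: int,
    ridge: float, var_floor: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Residualize candidate z-scores on selected variants' z-scores.

    R is the joint correlation matrix ordered [candidate, selected]. Returns
    standardized residual z, residual correlation, and the condition number
    of the selected-block matrix.
    """
    R_cc = R[:nc, :nc]
    R_cs = R[:nc, nc:]
    R_ss = R[nc:, nc:] + ridge * np.eye(R.shape[0] - nc)
    cond = float(np.linalg.cond(R_ss))
    if cond > 1e8:
        logger.warning("ill-conditioned selected-variant LD block (cond=%.3g)", cond)
    A = R_cs @ np.linalg.inv(R_ss)
    z_r = z_c - A @ z_s
    R_rr = R_cc - A @ R_cs.T
    d = np.clip(np.diag(R_rr).copy(), var_floor, None)
    scale = np.sqrt(d)
    z_std = z_r / scale
    corr = R_rr / np.outer(scale, scale)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return z_std, corr, cond


def conditional_ecs(
    ordered_genes: list[str],
    gene_variants: dict[str, list[str]],
    variant_p: pd.Series | dict,
    ld: LdReference,
    alpha: float = 0.05,
    screen_p: float | None = 0.01,
    ridge: float = 1e-6,
    var_floor: float = 1e-4,
) -> list[GeneAssocResult]:
    """Conditional gene-based association under a caller-supplied entry order.

    Genes enter one by one in the given order. Each candidate's unsigned
    z-scores (|z| = Phi^{-1}(1 - p/2)) are projected out of the span of all
    previously *selected* genes' variants; ECS on the variance-renormalised
    residuals gives the conditional p. A gene is selected when its
    conditional p passes the Bonferroni threshold ``alpha / n_genes``. Genes
    whose unconditional p exceeds ``screen_p`` skip the (quadratic-cost)
    conditioning and keep cond_p = raw_p; pass ``screen_p=None`` to condition
    every gene.
    """
    vp = pd.Series(variant_p)
    n_genes = len(ordered_genes)
    threshold = alpha / max(n_genes, 1)
    zscore = pd.Series(
        stats.norm.isf(np.clip(vp.values, MIN_P, 1.0) / 2.0), index=vp.index
    )

    results: list[GeneAssocResult] = []
    selected_variants: list[str] = []
    selected_set: set[str] = set()
    for rank, gene in enumerate(ordered_genes):
        variants = gene_variants.get(gene, [])
        if not variants:
            continue
        R_cc = ld.corr(variants)
        raw_p = ecs_gene_p(vp.loc[variants].values, R_cc)
        cond = None
        if screen_p is not None and raw_p > screen_p:
            cond_p = raw_p
        elif not selected_variants:
            cond_p = raw_p
        else:
            joint = list(variants) + selected_variants
            R = ld.corr(joint)
            z_c = zscore.loc[variants].values
            z_s = zscore.loc[selected_variants].values
            z_std, corr, cond = _decorrelate(
                z_c, z_s, R, len(variants), ridge, var_floor
            )
            p_resid = 2.0 * stats.norm.sf(np.abs(z_std))
            cond_p = ecs_gene_p(p_resid, corr)
        is_selected = cond_p < threshold
        if is_selected:
            for v in variants:
                if v not in selected_set:
                    selected_set.add(v)
                    selected_variants.append(v)
        results.append(
            GeneAssocResult(
                gene_id=gene, n_variants=len(variants), raw_p=raw_p,
                cond_p=cond_p, entry_rank=rank, selected=is_selected,
                condition_number=cond,
            )
        )
    return results


def significant_genes(
    results: list[GeneAssocResult], alpha: float = 0.05, correction: str = "bonferroni"
) -> set[str]:
    """Genes whose conditional p passes Bonferroni over the tested genes."""
    if correction != "bonferroni":
        raise ValueError(f"unsupported correction {correction!r}")
    n = len(results)
    if n == 0:
        return set()
    thr = alpha / n
    return {r.gene_id for r in results if r.cond_p < thr}


def results_to_frame(results: list[GeneAssocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene_id for r in results],
            "n_variants": [r.n_variants for r in results],
            "raw_p": [r.raw_p for r in results],
            "cond_p": [r.cond_p for r in results],
            "entry_rank": [r.entry_rank for r in results],
            "selected": [r.selected for r in results],
        }
    )
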