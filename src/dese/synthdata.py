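"""Synthetic multi-tissue expression, gene models and LD-blocked GWAS.

Generates the full input set of the driver-tissue pipeline with planted
ground truth: per-tissue selectively expressed gene sets, a designated driver
tissue, and causal genes concentrated in that tissue's selective set whose
variants carry non-centrality in the simulated GWAS z-scores.

Expression is simulated on the log scale (normal noise, exponentiated to
TPM-like positives, so positivity is automatic); a "uniform" option draws the
between-tissue noise from a variance-matched uniform instead. GWAS z-scores
are multivariate normal over exchangeable-correlation LD blocks; the marginal
mean is R @ ncp, so variants merely in LD with causal variants also show
inflated signal — the redundancy the conditional gene test must remove.

Everything is deterministic given the spec's seed; independent substreams are
derived per stage so regenerating one output never perturbs another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import BlockLdReference, GeneModel, GwasSummary
from .expression_io import ExpressionMatrix

logger = logging.getLogger("dese")

__all__ = [
    "PlantingSpec",
    "make_expression",
    "make_gene_model",
    "choose_causal_genes",
    "make_gwas",
    "simulate_all",
    "make_shadow_scenario",
]


@dataclass
class PlantingSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe a modest multi-tissue panel: 20 tissues x 10 samples,
    500 genes of which 2% per tissue are selectively expressed (disjoint sets),
    a 5-SD selective mean shift on the log scale, and 8 causal genes drawn
    entirely from the driver tissue's selective set. LD blocks of 20 variants
    with exchangeable within-block correlation 0.5 tile the variants (10 per
    gene), and causal variants carry non-centrality 6 on the z scale.
    """

    n_tissues: int = 20
    n_genes: int = 500
    transcripts_per_gene: int = 1
    n_samples_per_tissue: int = 10
    driver_tissue: str = "T01"
    selective_gene_fraction: float = 0.02
    selective_effect: float = 5.0  # mean shift in units of between-tissue SD
    n_causal_genes: int = 8
    causal_overlap: float = 1.0
    variants_per_gene: int = 10
    ld_block_size: int = 20
    ld_rho: float = 0.5
    noncentrality: float = 6.0
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.0
    tissue_sd: float = 0.3  # between-tissue SD of a gene's log mean
    sample_sd: float = 0.5  # within-tissue sample noise, log scale
    noise: str = "normal"  # between-tissue noise family: normal | uniform
    gene_length: int = 10_000
    gene_gap: int = 20_000
    genes_per_chrom: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("selective_gene_fraction", "causal_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.selective_effect < 0:
            raise ValueError("selective_effect must be >= 0")
        if self.n_tissues * self.selective_gene_fraction > 1.0 + 1e-9:
            raise ValueError("disjoint selective sets need n_tissues * fraction <= 1")
        if self.noise not in ("normal", "uniform"):
            raise ValueError("noise must be 'normal' or 'uniform'")

    @property
    def tissues(self) -> list[str]:
        return [f"T{i + 1:02d}" for i in range(self.n_tissues)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), stage])

    def to_dict(self) -> dict:
        return asdict(self)


def _tissue_noise(spec: PlantingSpec, rng, shape) -> np.ndarray:
    if spec.noise == "normal":
        return rng.normal(0.0, spec.tissue_sd, shape)
    half = spec.tissue_sd * np.sqrt(3.0)  # variance-matched uniform
    return rng.uniform(-half, half, shape)


def plant_selective_sets(spec: PlantingSpec) -> dict[str, set[str]]:
    """Disjoint per-tissue selective gene sets (deterministic in the seed)."""
    rng = spec.rng(1)
    per_tissue = int(round(spec.selective_gene_fraction * spec.n_genes))
    order = rng.permutation(spec.n_genes)
    truth: dict[str, set[str]] = {}
    genes = spec.gene_ids
    pos = 0
    for t in spec.tissues:
        truth[t] = {genes[i] for i in order[pos:pos + per_tissue]}
        pos += per_tissue
    return truth


def make_expression(spec: PlantingSpec) -> tuple[ExpressionMatrix, dict[str, set[str]]]:
    """Simulate a TPM-like expression matrix with planted selective genes.

    Every transcript of a selectively planted gene gets a
    ``selective_effect * tissue_sd`` upward mean shift (log scale) in its
    assigned tissue. Returns the matrix and the per-tissue truth sets.
    """
    if spec.selective_effect == 0 and spec.selective_gene_fraction > 0:
        logger.warning("selective_effect = 0 with planted genes: truth is unidentifiable")
    truth = plant_selective_sets(spec)
    rng = spec.rng(2)

    # features: one or more transcripts per gene
    if spec.transcripts_per_gene <= 1:
        n_tx = np.ones(spec.n_genes, dtype=int)
    else:
        n_tx = 1 + rng.poisson(spec.transcripts_per_gene - 1, spec.n_genes)
    feature_ids, feature_gene = [], []
    for g, k in zip(spec.gene_ids, n_tx):
        if k == 1:
            feature_ids.append(g)
            feature_gene.append(g)
        else:
            for j in range(k):
                feature_ids.append(f"{g}.t{j + 1}")
                feature_gene.append(g)
    F = len(feature_ids)
    T = spec.n_tissues

    base = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, F)
    tissue_mean = base[:, None] + _tissue_noise(spec, rng, (F, T))
    gene_of = np.asarray(feature_gene)
    for ti, t in enumerate(spec.tissues):
        hit = np.isin(gene_of, list(truth[t]))
        tissue_mean[hit, ti] += spec.selective_effect * spec.tissue_sd

    n = spec.n_samples_per_tissue
    samples, labels = [], []
    values = np.empty((F, T * n))
    for ti, t in enumerate(spec.tissues):
        noise = rng.normal(0.0, spec.sample_sd, (F, n))
        values[:, ti * n:(ti + 1) * n] = np.exp(tissue_mean[:, [ti]] + noise)
        for j in range(n):
            samples.append(f"{t}_s{j + 1}")
            labels.append(t)
    frame = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature"), columns=samples)
    sample_tissue = pd.Series(labels, index=samples, name="tissue")
    symbols = pd.Series(feature_gene, index=frame.index)
    level = "gene" if spec.transcripts_per_gene <= 1 else "transcript"
    return ExpressionMatrix(frame, symbols, sample_tissue, level=level), truth


def transcript_gene_map(m: ExpressionMatrix) -> pd.Series:
    """Transcript -> gene map for matrices produced by :func:`make_expression`."""
    return pd.Series(m.feature_symbols.values, index=m.feature_ids)


def make_gene_model(spec: PlantingSpec) -> GeneModel:
    """Tile non-overlapping genes along synthetic chromosomes.

    Genes are laid down sequentially with a fixed ``gene_gap`` between bodies
    (default 20 kb, i.e. larger than the 5 kb assignment flank, so adjacent
    genes share no variants; shrink the gap below twice the flank to exercise
    shared-boundary assignment). Deterministic: no randomness involved.
    """
    rows = []
    for i, g in enumerate(spec.gene_ids):
        chrom = f"chr{i // spec.genes_per_chrom + 1}"
        slot = i % spec.genes_per_chrom
        start = 1 + slot * (spec.gene_length + spec.gene_gap)
        rows.append(
            {
                "gene_id": g, "symbol": g, "chrom": chrom, "strand": "+",
                "start": start, "end": start + spec.gene_length - 1,
            }
        )
    return GeneModel(pd.DataFrame(rows))


def choose_causal_genes(spec: PlantingSpec, truth: dict[str, set[str]]) -> list[str]:
    """Pick causal genes: ``causal_overlap`` of them from the driver tissue's
    selective set, the rest from unplanted genes."""
    rng = spec.rng(3)
    driver_set = sorted(truth[spec.driver_tissue])
    n_from_driver = min(int(round(spec.causal_overlap * spec.n_causal_genes)), len(driver_set))
    causal = list(rng.choice(driver_set, size=n_from_driver, replace=False))
    planted_anywhere = set().union(*truth.values()) if truth else set()
    pool = sorted(set(spec.gene_ids) - planted_anywhere - set(causal))
    n_rest = spec.n_causal_genes - len(causal)
    if n_rest > 0:
        causal += list(rng.choice(pool, size=n_rest, replace=False))
    return sorted(causal)


def make_gwas(
    spec: PlantingSpec,
    model: GeneModel,
    causal_genes: list[str],
) -> tuple[GwasSummary, BlockLdReference]:
    """Simulate LD-blocked GWAS summary statistics with planted causal genes.

    ``variants_per_gene`` variants are spaced evenly through each gene body;
    consecutive variants on a chromosome form exchangeable-correlation LD
    blocks of ``ld_block_size``. z-scores are multivariate normal with
    covariance R (the block correlation) and mean R @ ncp, where ncp carries
    ``spec.noncentrality`` at causal genes' variants; p = 2 * (1 - Phi(|z|)).
    The returned LD reference exposes the true block correlations.
    """
    missing = set(causal_genes) - set(model.gene_ids)
    if missing:
        raise ValueError(f"causal genes absent from the model: {sorted(missing)}")
    rng = spec.rng(4)
    causal = set(causal_genes)

    rows = []  # variant records in genomic order
    ncp = []
    for rec in model.table.itertuples():
        step = max(spec.gene_length // (spec.variants_per_gene + 1), 1)
        for j in range(spec.variants_per_gene):
            rows.append(
                {
                    "variant_id": f"{rec.gene_id}_v{j + 1}",
                    "chrom": rec.chrom,
                    "pos": rec.start + (j + 1) * step,
                }
            )
            ncp.append(spec.noncentrality if rec.gene_id in causal else 0.0)
    table = pd.DataFrame(rows)
    ncp = np.asarray(ncp)

    z = np.empty(len(table))
    blocks: dict[str, tuple[list[str], np.ndarray]] = {}
    bid = 0
    for chrom, sub in table.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        for lo in range(0, len(idx), spec.ld_block_size):
            sel = idx[lo:lo + spec.ld_block_size]
            m = len(sel)
            R = np.full((m, m), spec.ld_rho)
            np.fill_diagonal(R, 1.0)
            L = np.linalg.cholesky(R)
            mean = R @ ncp[sel]
            z[sel] = mean + L @ rng.standard_normal(m)
            blocks[f"b{bid}"] = (list(table.loc[sel, "variant_id"]), R)
            bid += 1

    table["p"] = 2.0 * stats.norm.sf(np.abs(z))
    return GwasSummary(table), BlockLdReference(blocks)


def simulate_all(spec: PlantingSpec) -> dict:
    """Generate the complete input set plus truth for one seed."""
    matrix, truth = make_expression(spec)
    model = make_gene_model(spec)
    causal = choose_causal_genes(spec, truth)
    gwas, ld = make_gwas(spec, model, causal)
    return {
        "expression": matrix,
        "truth": truth,
        "model": model,
        "causal_genes": causal,
        "gwas": gwas,
        "ld": ld,
        "spec": spec,
    }


def make_shadow_scenario(
    seed: int,
    rho: float = 0.8,
    ncp: float = 6.0,
    variants_per_gene: int = 5,
):
    """Two-LD-block scenario with one causal gene and one LD-shadow gene.

    Block 1 holds the variants of the causal gene A and the non-causal gene B
    under exchangeable correlation ``rho``; only A's variants carry
    non-centrality, but B inherits a marginal mean of ``rho * ncp`` through
    LD. Block 2 holds an independent null gene C. Returns
    ``(gene_variants, variant_p, ld, "A", "B")`` ready for
    :func:`dese.assoc.conditional_ecs`.
    """
    rng = np.random.default_rng([int(seed) % (2**31), 99])
    genes = {"A": [], "B": [], "C": []}
    ids1, ids2 = [], []
    for g in ("A", "B"):
        for j in range(variants_per_gene):
            vid = f"{g}_v{j + 1}"
            genes[g].append(vid)
            ids1.append(vid)
    for j in range(variants_per_gene):
        vid = f"C_v{j + 1}"
        genes["C"].append(vid)
        ids2.append(vid)

    m1 = len(ids1)
    R1 = np.full((m1, m1), rho)
    np.fill_diagonal(R1, 1.0)
    ncp_vec = np.array([ncp] * variants_per_gene + [0.0] * variants_per_gene)
    z1 = R1 @ ncp_vec + np.linalg.cholesky(R1) @ rng.standard_normal(m1)

    m2 = len(ids2)
    R2 = np.eye(m2)
    z2 = rng.standard_normal(m2)

    p = pd.Series(
        2.0 * stats.norm.sf(np.abs(np.concatenate([z1, z2]))),
        index=ids1 + ids2,
    )
    ld = BlockLdReference({"b1": (ids1, R1), "b2": (ids2, R2)})
    return genes, p, ld, "A", "B"
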