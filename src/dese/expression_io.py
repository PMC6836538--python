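"""Expression matrix I/O, quality control and per-tissue summarization.

Reads GCT 1.2 / plain-TSV expression matrices (TPM units assumed), maps
samples to tissues, applies the standard QC filters used for multi-tissue
selective-expression analysis, and reduces the matrix to per-tissue means and
standard errors — the ``y_i`` / ``s_i`` consumed by the selective-expression
measures in :mod:`dese.selexp`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("dese")

__all__ = [
    "ExpressionMatrix",
    "TissueSummary",
    "read_gct",
    "write_gct",
    "read_expression_tsv",
    "read_sample_tissue_map",
    "summarize_by_tissue",
    "filter_low_expression",
    "tissue_correlation_qc",
    "rank_to_normal",
    "sample_correlation_filter",
    "drop_sparse_features",
    "filter_by_symbol_map",
]


class FormatError(ValueError):
    """Malformed input file (bad GCT dims, non-numeric cell, ...)."""


@dataclass
class ExpressionMatrix:
    """A feature x sample expression matrix with an optional tissue map.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample ids as columns. Entries
        are non-negative TPM (or rank-normalised units after
        :func:`rank_to_normal`); NaN marks a missing observation.
    feature_symbols
        Optional Series mapping feature id -> official gene symbol.
    sample_tissue
        Optional Series mapping sample id -> tissue label.
    level
        ``"gene"``, ``"transcript"`` or ``"exon"``.
    """

    values: pd.DataFrame
    feature_symbols: pd.Series | None = None
    sample_tissue: pd.Series | None = None
    level: str = "gene"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("feature ids must be unique")
        if self.level not in ("gene", "transcript", "exon"):
            raise ValueError(f"unknown feature level {self.level!r}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_features(self, keep: np.ndarray | pd.Index) -> "ExpressionMatrix":
        symbols = self.feature_symbols
        vals = self.values.loc[keep]
        if symbols is not None:
            symbols = symbols.loc[vals.index]
        return ExpressionMatrix(vals, symbols, self.sample_tissue, self.level)


@dataclass
class TissueSummary:
    """Per-feature, per-tissue expression means and standard errors."""

    mean: pd.DataFrame  # features x tissues
    se: pd.DataFrame  # features x tissues, > 0
    n_samples: pd.Series  # per tissue
    feature_symbols: pd.Series | None = None
    level: str = "gene"
    flags: dict = field(default_factory=dict)

    @property
    def feature_ids(self) -> pd.Index:
        return self.mean.index

    @property
    def tissues(self) -> pd.Index:
        return self.mean.columns

    def subset_features(self, keep) -> "TissueSummary":
        mean = self.mean.loc[keep]
        symbols = self.feature_symbols
        if symbols is not None:
            symbols = symbols.loc[mean.index]
        return TissueSummary(mean, self.se.loc[keep], self.n_samples, symbols, self.level, dict(self.flags))

    def subset_tissues(self, keep) -> "TissueSummary":
        return TissueSummary(
            self.mean.loc[:, keep], self.se.loc[:, keep], self.n_samples.loc[keep],
            self.feature_symbols, self.level, dict(self.flags),
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_gct(path, level: str = "gene") -> ExpressionMatrix:
    """Read a GCT 1.2 file (version line, dims line, Name/Description columns).

    Raises :class:`FormatError` when the declared dimensions disagree with the
    body or a cell is non-numeric.
    """
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise FormatError(f"{path}: malformed dimensions line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        table = pd.read_csv(fh, sep="\t", header=0, index_col=None, dtype=str)
    if table.columns[0] != "Name" or table.columns[1] != "Description":
        raise FormatError(f"{path}: header must start with Name<TAB>Description")
    if table.shape[0] != n_rows or table.shape[1] - 2 != n_cols:
        raise FormatError(
            f"{path}: dims line declares {n_rows} x {n_cols} but body is "
            f"{table.shape[0]} x {table.shape[1] - 2}"
        )
    names = pd.Index(table["Name"], name="feature")
    symbols = pd.Series(table["Description"].values, index=names)
    data = table.iloc[:, 2:]
    try:
        values = data.astype(float)
    except ValueError:
        # locate the offending cell for the error message
        for col in data.columns:
            bad = pd.to_numeric(data[col], errors="coerce").isna() & data[col].notna()
            if bad.any():
                row = names[np.flatnonzero(bad.values)[0]]
                raise FormatError(f"{path}: non-numeric cell at row {row!r}, column {col!r}") from None
        raise
    values.index = names
    return ExpressionMatrix(values, feature_symbols=symbols, level=level)


def write_gct(m: ExpressionMatrix, path) -> None:
    """Write an :class:`ExpressionMatrix` in GCT 1.2 format."""
    symbols = m.feature_symbols
    if symbols is None:
        symbols = pd.Series(m.feature_ids, index=m.feature_ids)
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{m.values.shape[0]}\t{m.values.shape[1]}\n")
        out = m.values.copy()
        out.insert(0, "Description", symbols.loc[m.feature_ids].values)
        out.insert(0, "Name", m.feature_ids)
        out.to_csv(fh, sep="\t", index=False)


def read_expression_tsv(path, level: str = "gene") -> ExpressionMatrix:
    """Read a plain TSV matrix: header = sample ids, first column = feature id.

    NA cells are accepted and kept as missing observations.
    """
    table = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    values = table.astype(float)
    values.index.name = "feature"
    return ExpressionMatrix(values, level=level)


def read_sample_tissue_map(path) -> pd.Series:
    """Read a two-column TSV sample -> tissue map."""
    table = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if table.shape[1] < 2:
        raise FormatError(f"{path}: sample map needs two columns (sample, tissue)")
    return pd.Series(table.iloc[:, 1].values, index=table.iloc[:, 0].values, name="tissue")


# ---------------------------------------------------------------------------
# Summaries and QC
# ---------------------------------------------------------------------------

def summarize_by_tissue(
    m: ExpressionMatrix,
    sample_tissue: pd.Series | dict | None = None,
    se_floor_scale: float = 1e-6,
) -> TissueSummary:
    """Reduce samples to per-tissue means and standard errors.

    For a tissue with n >= 2 samples the SE is the (n-1)-denominator sample
    standard deviation divided by sqrt(n); a single-subject tissue gets
    SE = 1 exactly. Zero SEs (identical replicates) are floored at
    ``se_floor_scale * (global mean expression + 1)`` so downstream z-scores
    stay finite; floored features are recorded in ``flags['se_floored']``.

    Missing values (NaN) are ignored pairwise; a tissue with zero samples
    raises ``ValueError``.
    """
    if sample_tissue is None:
        sample_tissue = m.sample_tissue
    if sample_tissue is None:
        raise ValueError("no sample->tissue map provided")
    sample_tissue = pd.Series(sample_tissue)
    missing = m.sample_ids.difference(sample_tissue.index)
    if len(missing):
        raise ValueError(f"samples without tissue label: {list(missing)[:5]} ...")
    tissues = sample_tissue.loc[m.sample_ids]
    groups = m.values.T.groupby(tissues.values)
    n_samples = groups.size()
    if (n_samples < 1).any():
        raise ValueError("tissue with zero samples")
    mean = groups.mean().T  # NaN-aware
    sd = groups.std(ddof=1).T
    counts = groups.count().T  # non-missing obs per feature per tissue
    se = sd / np.sqrt(counts)
    # single-subject tissues (or single non-missing obs): SE := 1
    se = se.where(counts >= 2, 1.0)
    floor = se_floor_scale * (float(np.nanmean(m.values.values)) + 1.0)
    floored = se <= 0
    if floored.any().any():
        feats = list(mean.index[floored.any(axis=1)])
        logger.info("SE floored at %.3g for %d features", floor, len(feats))
    se = se.mask(floored, floor)
    return TissueSummary(
        mean=mean, se=se, n_samples=n_samples,
        feature_symbols=m.feature_symbols, level=m.level,
        flags={"se_floored": list(mean.index[floored.any(axis=1)])},
    )


def filter_low_expression(
    m: ExpressionMatrix | TissueSummary,
    cutoff: float = 0.01,
    mode: str = "all_tissues",
    k: int | None = None,
):
    """Drop features with negligible expression.

    ``all_tissues`` drops a feature whose value is <= ``cutoff`` in *every*
    tissue (or sample, when given a raw matrix). ``k_or_more_tissues`` drops a
    feature whose value is < ``cutoff`` in at least ``k`` tissues. Survivor
    order is preserved; the operation is idempotent.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    values = m.mean if isinstance(m, TissueSummary) else m.values
    if mode == "all_tissues":
        keep = ~(values.fillna(-np.inf) <= cutoff).all(axis=1)
    elif mode == "k_or_more_tissues":
        if k is None or not (1 <= k <= values.shape[1]):
            raise ValueError("k_or_more_tissues mode needs 1 <= k <= n tissues")
        keep = (values < cutoff).sum(axis=1) < k
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return m.subset_features(values.index[keep])


def tissue_correlation_qc(
    s: TissueSummary, threshold: float = 0.3
) -> tuple[TissueSummary, list[str]]:
    """Exclude tissues that correlate poorly with the rest of the panel.

    Pairwise Pearson correlations of the per-tissue mean vectors (across
    features) are computed; a tissue is excluded when its *median* correlation
    with all other tissues falls below ``threshold``. A tissue with a constant
    mean vector has undefined correlations and is excluded with reason
    "degenerate".
    """
    if s.mean.shape[1] < 3:
        raise ValueError("tissue correlation QC needs >= 3 tissues")
    if s.mean.shape[0] < 2:
        raise ValueError("correlation undefined with a single feature")
    corr = s.mean.corr()  # tissue x tissue, pairwise-complete
    excluded: list[str] = []
    for t in s.tissues:
        others = corr.loc[t].drop(t)
        if others.isna().all():
            logger.warning("tissue %s has degenerate (constant) mean vector", t)
            excluded.append(t)
        elif others.median() < threshold:
            excluded.append(t)
    keep = [t for t in s.tissues if t not in excluded]
    return s.subset_tissues(keep), excluded


def rank_to_normal(m: ExpressionMatrix) -> ExpressionMatrix:
    """Map each sample's expression to standard-normal quantiles by rank.

    Within each sample, features are ranked (ties get the average rank) and
    transformed to ``Phi^{-1}((rank - 0.5) / G)`` where G is the feature
    count. The output per sample is a fixed normal-quantile grid, so any
    monotone transform of the input yields identical output.
    """
    G = m.values.shape[0]
    out = np.empty_like(m.values.values, dtype=float)
    for j in range(m.values.shape[1]):
        col = m.values.values[:, j]
        if np.nanmax(col) == np.nanmin(col):
            raise ValueError(f"constant sample {m.sample_ids[j]!r}")
        ranks = stats.rankdata(col, nan_policy="omit")
        out[:, j] = stats.norm.ppf((ranks - 0.5) / G)
    values = pd.DataFrame(out, index=m.feature_ids, columns=m.sample_ids)
    return ExpressionMatrix(values, m.feature_symbols, m.sample_tissue, m.level)


def sample_correlation_filter(
    m: ExpressionMatrix,
    low_q: float = 0.05,
    high_q: float = 0.95,
    groups: pd.Series | dict | None = None,
) -> tuple[ExpressionMatrix, list[str]]:
    """Remove outlier samples by their pairwise correlation with the group.

    Within each caller-defined group (default: all samples as one group, so
    the same code serves GSE-wise or tissue-wise use), all pairwise Pearson
    correlations are pooled; a sample is removed when its median pairwise
    correlation lies strictly below the ``low_q`` quantile or strictly above
    the ``high_q`` quantile of the pooled distribution. Groups with fewer
    than 4 samples are passed through with a warning.
    """
    if not (0 <= low_q < high_q <= 1):
        raise ValueError("need 0 <= low_q < high_q <= 1")
    if groups is None:
        groups = pd.Series("all", index=m.sample_ids)
    else:
        groups = pd.Series(groups).loc[m.sample_ids]
    removed: list[str] = []
    for _, members in groups.groupby(groups).groups.items():
        members = list(members)
        if len(members) < 4:
            warnings.warn(f"group with {len(members)} samples passed through unfiltered")
            continue
        corr = m.values[members].corr().values
        iu = np.triu_indices(len(members), k=1)
        pooled = corr[iu]
        lo, hi = np.quantile(pooled, [low_q, high_q])
        np.fill_diagonal(corr, np.nan)
        med = np.nanmedian(corr, axis=1)
        for i, sample in enumerate(members):
            if med[i] < lo or med[i] > hi:
                removed.append(sample)
    keep = [sid for sid in m.sample_ids if sid not in removed]
    vals = m.values[keep]
    return ExpressionMatrix(vals, m.feature_symbols, m.sample_tissue, m.level), removed


def drop_sparse_features(m: ExpressionMatrix, min_obs: int = 9) -> ExpressionMatrix:
    """Remove features observed (non-missing) in ``min_obs`` or fewer samples."""
    if min_obs < 0:
        raise ValueError("min_obs must be >= 0")
    n_obs = m.values.notna().sum(axis=1)
    return m.subset_features(m.feature_ids[n_obs > min_obs])


def filter_by_symbol_map(m: ExpressionMatrix, id_to_symbol: dict) -> ExpressionMatrix:
    """Keep only features present in an id -> official-symbol map.

    Stands in for 'exclude ids without an official HGNC symbol' without a
    live lookup; the retained features get their mapped symbols attached.
    """
    keep = [f for f in m.feature_ids if f in id_to_symbol]
    out = m.subset_features(pd.Index(keep))
    out.feature_symbols = pd.Series({f: id_to_symbol[f] for f in keep})
    return out
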