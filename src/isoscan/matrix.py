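"""Normalization, QC, HVG selection, differential expression and
complexity/down-sampling utilities shared by every downstream stage.

Expression level is TPM (reads per 1e6 mapped full-length reads per
feature), presented as log(TPM/10 + 1) with the natural logarithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import ExpressionMatrix, NormalizedMatrix

log = logging.getLogger("isoscan")


def normalize_expression(m: ExpressionMatrix, level: str = "isoform") -> NormalizedMatrix:
    """TPM per cell plus the log(TPM/10 + 1) transform.

    ``level='gene'`` sums isoform counts through the gene map first.
    All-zero cells keep all-zero columns and are flagged in
    ``zero_cells`` rather than producing NaNs.
    """
    if level not in {"isoform", "gene"}:
        raise ValueError("level must be 'isoform' or 'gene'")
    mm = m.to_gene_level() if level == "gene" else m
    dense = mm.dense().astype(float)
    totals = dense.sum(axis=0)
    zero = totals == 0
    safe = np.where(zero, 1.0, totals)
    tpm = dense / safe[None, :] * 1e6
    tpm[:, zero] = 0.0
    tpm = pd.DataFrame(tpm, index=mm.feature_ids, columns=mm.cell_ids)
    logexpr = np.log(tpm / 10.0 + 1.0)
    return NormalizedMatrix(
        tpm=tpm, logexpr=logexpr, level=level,
        zero_cells=[c for c, z in zip(mm.cell_ids, zero) if z],
    )


@dataclass
class FilterReport:
    n_cells_low_genes: int = 0
    n_cells_high_mito: int = 0
    n_isoforms_removed: int = 0
    notes: list = field(default_factory=list)


def qc_filters(
    m: ExpressionMatrix,
    mito_genes: set | None = None,
    min_genes: int = 500,
    max_mito_fraction: float = 0.60,
    min_cells_per_individual: int = 3,
    min_individuals: int = 3,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Cell and isoform quality filters.

    Cells with fewer than ``min_genes`` detected genes, or with a
    mitochondrial count fraction strictly greater than
    ``max_mito_fraction``, are discarded.  Isoforms are then kept only when
    at least ``min_individuals`` individuals each contribute at least
    ``min_cells_per_individual`` cells with a nonzero count ("detected"
    means count >= 1 throughout).
    """
    report = FilterReport()
    dense = m.dense()
    genes = m.feature_genes.values
    gene_detected = (
        pd.DataFrame(dense > 0).groupby(genes).any().sum(axis=0).values
    )
    keep_cells = gene_detected >= min_genes
    report.n_cells_low_genes = int((~keep_cells).sum())

    if mito_genes:
        mito_mask = np.isin(genes, list(mito_genes))
        totals = dense.sum(axis=0).astype(float)
        mito_frac = np.divide(
            dense[mito_mask].sum(axis=0), totals,
            out=np.zeros_like(totals), where=totals > 0,
        )
        high_mito = mito_frac > max_mito_fraction
        report.n_cells_high_mito = int((keep_cells & high_mito).sum())
        keep_cells &= ~high_mito
    else:
        report.notes.append("mito gene set empty: mitochondrial rule skipped")
        log.warning("qc_filters: empty mito gene set; skipping mito rule")

    kept_cell_ids = [c for c, k in zip(m.cell_ids, keep_cells) if k]
    sub = m.subset_cells(kept_cell_ids)

    patients = sub.metadata["patient"].values
    detected = sub.dense() > 0
    keep_iso = np.zeros(len(sub.feature_ids), dtype=bool)
    for i in range(len(sub.feature_ids)):
        per_ind = pd.Series(detected[i]).groupby(patients).sum()
        keep_iso[i] = (per_ind >= min_cells_per_individual).sum() >= min_individuals
    report.n_isoforms_removed = int((~keep_iso).sum())
    out = sub.subset_features([f for f, k in zip(sub.feature_ids, keep_iso) if k])
    return out, report


def select_hvg(
    nm: NormalizedMatrix,
    batch: pd.Series,
    n: int = 1000,
    n_bins: int = 20,
) -> list[str]:
    """Top highly-variable genes per batch; return the union across batches.

    Within each batch, genes are ranked by standardized dispersion: the
    variance of logexpr z-scored within bins of mean expression (removing
    the mean-variance trend).  Ties break on gene id for determinism.
    """
    union: set[str] = set()
    for b in sorted(batch.unique()):
        cells = batch.index[batch == b]
        sub = nm.logexpr[cells]
        mean = sub.mean(axis=1)
        var = sub.var(axis=1)
        order = mean.rank(method="first")
        bins = pd.cut(order, bins=min(n_bins, max(1, len(mean) // 2)), labels=False)
        disp = pd.Series(index=mean.index, dtype=float)
        for bi in np.unique(bins):
            sel = bins == bi
            v = var[sel]
            sd = v.std()
            disp[sel] = (v - v.mean()) / sd if sd > 0 else 0.0
        nonconstant = var > 0
        ranked = sorted(
            disp[nonconstant].items(), key=lambda kv: (-kv[1], kv[0])
        )
        k = n
        if n > len(ranked):
            log.warning("select_hvg: requested %d > %d genes; taking all", n, len(ranked))
            k = len(ranked)
        union.update(g for g, _ in ranked[:k])
    return sorted(union)


def wilcoxon_de(
    nm: NormalizedMatrix,
    group_a: list[str],
    group_b: list[str],
    min_fc: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression between two cell sets.

    Fold change is (mean TPM A + 1) / (mean TPM B + 1); a feature is
    significant when the BH-adjusted p-value is < ``alpha`` and the fold
    change is >= ``min_fc`` or <= 1/``min_fc``.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    a = nm.tpm[list(group_a)].values
    b = nm.tpm[list(group_b)].values
    ps = np.ones(a.shape[0])
    for i in range(a.shape[0]):
        pooled = np.concatenate([a[i], b[i]])
        if np.ptp(pooled) == 0:  # constant feature: no rank information
            ps[i] = 1.0
            continue
        ps[i] = stats.mannwhitneyu(a[i], b[i], alternative="two-sided").pvalue
    fc = (a.mean(axis=1) + 1.0) / (b.mean(axis=1) + 1.0)
    adj = multipletests(ps, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "feature": nm.feature_ids,
            "p": ps,
            "adj_p": adj,
            "fc": fc,
            "significant": (adj < alpha) & ((fc >= min_fc) | (fc <= 1.0 / min_fc)),
        }
    ).set_index("feature")
    return out


ISOFORM_BINS = [(1, 1, "1"), (2, 3, "2-3"), (4, 5, "4-5"), (6, np.inf, ">=6")]


def complexity_metrics(
    m: ExpressionMatrix, groups: pd.Series | None = None
) -> dict[str, pd.DataFrame]:
    """Per-cell detection counts, pooled isoform-count bins, top-2 shares.

    Pooled metrics are computed per group (all cells as one group when
    ``groups`` is None): the fraction of detected genes expressing 1, 2-3,
    4-5 or >=6 isoforms, and for each multi-isoform gene the share of its
    pooled counts carried by its two most abundant isoforms.
    """
    dense = m.dense()
    genes = m.feature_genes.values
    per_cell = pd.DataFrame(
        {
            "n_isoforms": (dense > 0).sum(axis=0),
            "n_genes": pd.DataFrame(dense > 0).groupby(genes).any().sum(axis=0).values,
        },
        index=m.cell_ids,
    )
    if groups is None:
        groups = pd.Series("all", index=m.cell_ids)
    bin_rows, top2_rows = [], []
    for g in sorted(groups.unique()):
        cols = [i for i, c in enumerate(m.cell_ids) if groups[c] == g]
        pooled = dense[:, cols].sum(axis=1)
        per_gene = pd.Series(pooled).groupby(genes)
        n_iso = per_gene.apply(lambda s: int((s > 0).sum()))
        n_iso = n_iso[n_iso > 0]
        total = len(n_iso)
        for lo, hi, label in ISOFORM_BINS:
            frac = ((n_iso >= lo) & (n_iso <= hi)).sum() / total if total else np.nan
            bin_rows.append({"group": g, "bin": label, "fraction": frac})
        for gene, s in per_gene:
            expressed = np.sort(s.values[s.values > 0])[::-1]
            if len(expressed) == 0:
                continue
            top2_rows.append(
                {
                    "group": g, "gene": gene, "n_isoforms": len(expressed),
                    "top2_share": expressed[:2].sum() / expressed.sum(),
                }
            )
    return {
        "per_cell": per_cell,
        "isoform_bins": pd.DataFrame(bin_rows),
        "top2_share": pd.DataFrame(top2_rows),
    }


def downsample(
    m: ExpressionMatrix,
    n_cells: int,
    depth_fraction: float,
    seed: int,
    group_col: str = "group",
) -> ExpressionMatrix:
    """Subsample ``n_cells`` per group without replacement and thin each
    retained cell's counts binomially at ``depth_fraction``."""
    if not 0 < depth_fraction <= 1:
        raise ValueError("depth_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    keep = []
    for g in sorted(m.metadata[group_col].unique()):
        cells = [c for c in m.cell_ids if m.metadata.loc[c, group_col] == g]
        if n_cells > len(cells):
            raise ValueError(f"group {g} has only {len(cells)} cells")
        keep.extend(sorted(rng.choice(cells, size=n_cells, replace=False)))
    sub = m.subset_cells(keep)
    if depth_fraction == 1.0:
        return sub
    dense = sub.dense()
    thinned = rng.binomial(dense, depth_fraction)
    return ExpressionMatrix(
        thinned, sub.feature_ids, sub.cell_ids, sub.feature_genes, sub.metadata
    )
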