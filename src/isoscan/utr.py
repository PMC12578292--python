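"""Expressed UTR length, gene UTR deviation, and the shortened/lengthened
gene classifier.

The expressed UTR length (EUL) of gene g in cell c is the expression-
weighted mean of its isoforms' UTR lengths,

    EUL[g,c] = sum_i M[g,i] C[i,c] l[i] / sum_i M[g,i] C[i,c],

with M the binary gene-isoform incidence, C the isoform TPM and l the
isoform UTR length at the chosen end (3' or 5').  Gene UTR deviation (GUD)
subtracts the gene's mean EUL over a normal-cell baseline, so negative
values mean shortening relative to normal epithelium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .models import NormalizedMatrix, TranscriptModelSet

log = logging.getLogger("isoscan")


def compute_eul(
    nm: NormalizedMatrix, annotation: TranscriptModelSet, end: str = "3p"
) -> pd.DataFrame:
    """Gene x cell expressed-UTR-length matrix (bases); NaN where the gene
    has no UTR-informative expression in the cell.

    Isoforms without a defined UTR (non-coding) are excluded from both the
    numerator and denominator; genes with no UTR-defined isoform are
    dropped with a log entry.
    """
    if nm.level != "isoform":
        raise ValueError("compute_eul needs an isoform-level matrix")
    lengths, rows, gene_of = [], [], []
    dropped = []
    for gid in annotation.gene_ids:
        any_defined = False
        for t in annotation.gene_transcripts(gid):
            L = t.utr_len(end)
            if L is None or t.transcript_id not in nm.tpm.index:
                continue
            lengths.append(float(L))
            rows.append(t.transcript_id)
            gene_of.append(gid)
            any_defined = True
        if not any_defined:
            dropped.append(gid)
    if dropped:
        log.info("compute_eul: %d genes without UTR-defined isoforms dropped",
                 len(dropped))
    if not rows:
        raise ValueError("no UTR-defined isoforms present in the matrix")
    W = nm.tpm.loc[rows]
    L = np.asarray(lengths)
    gene_of = np.asarray(gene_of)
    num = pd.DataFrame(W.values * L[:, None], columns=W.columns).groupby(gene_of).sum()
    den = pd.DataFrame(W.values, columns=W.columns).groupby(gene_of).sum()
    eul = num / den.where(den > 0)
    eul.index.name = "gene"
    return eul


@dataclass
class UTRDeviationResult:
    eul: pd.DataFrame  # gene x cell, NaN where undefined
    gud: pd.DataFrame  # eul minus per-gene normal baseline
    baseline: pd.Series  # per-gene mean EUL over normal cells
    per_cell_mean: pd.Series  # mean GUD across genes per cell
    end: str


def compute_gud(
    eul: pd.DataFrame, normal_cells: list[str], end: str = "3p"
) -> UTRDeviationResult:
    """Subtract the per-gene mean EUL over the normal-cell baseline.

    Genes never expressed in the baseline cells are dropped (logged).
    """
    normal_cells = [c for c in normal_cells if c in eul.columns]
    if not normal_cells:
        raise ValueError("empty normal cell set")
    baseline = eul[normal_cells].mean(axis=1)
    defined = baseline.notna()
    if (~defined).any():
        log.info("compute_gud: %d genes unexpressed in normal cells dropped",
                 int((~defined).sum()))
    eul = eul.loc[defined]
    baseline = baseline[defined]
    gud = eul.sub(baseline, axis=0)
    return UTRDeviationResult(
        eul=eul, gud=gud, baseline=baseline,
        per_cell_mean=gud.mean(axis=0), end=end,
    )


def classify_utr_genes(
    res: UTRDeviationResult,
    cell_type: pd.Series,
    batch: pd.Series,
    target: str,
    reference: str,
    min_cells: int = 10,
    alpha: float = 0.05,
    min_diff: float = 10.0,
) -> pd.DataFrame:
    """Shortened/lengthened/unchanged call per gene from a mixed model.

    Fits GUD ~ cell_type with a technological-batch term (random intercept
    when >= 3 batch levels, fixed covariate otherwise) over cells of the
    target and reference types.  A gene is called shortened when the
    cell-type estimate is negative with p < ``alpha`` and the mean GUD
    difference (target - reference) is <= -``min_diff`` bp; lengthened
    symmetrically; otherwise unchanged.  Singular fits are reported
    unchanged with a diagnostic flag.
    """
    cells = cell_type.index[cell_type.isin([target, reference])]
    rows = []
    for gene in res.gud.index:
        vals = res.gud.loc[gene, res.gud.columns.intersection(cells)].dropna()
        ct = cell_type.loc[vals.index]
        n_t = int((ct == target).sum())
        n_r = int((ct == reference).sum())
        if n_t < min_cells or n_r < min_cells:
            continue
        df = pd.DataFrame(
            {
                "gud": vals.values,
                "is_target": (ct == target).astype(float).values,
                "batch": batch.loc[vals.index].astype(str).values,
            }
        )
        mean_diff = df.loc[df.is_target == 1, "gud"].mean() - \
            df.loc[df.is_target == 0, "gud"].mean()
        est, p, flag = _fit_celltype_effect(df)
        cls = "unchanged"
        if flag is None and p < alpha:
            if est < 0 and mean_diff <= -min_diff:
                cls = "shortened"
            elif est > 0 and mean_diff >= min_diff:
                cls = "lengthened"
        rows.append(
            {
                "gene": gene, "estimate": est, "p_value": p,
                "mean_diff": mean_diff, "class": cls,
                "n_target": n_t, "n_reference": n_r,
                "flag": flag or "",
            }
        )
    return pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["estimate", "p_value", "mean_diff", "class",
                 "n_target", "n_reference", "flag"]
    )


def _fit_celltype_effect(df: pd.DataFrame):
    """(estimate, p, flag) for the cell-type coefficient; flag on failure."""
    n_batches = df["batch"].nunique()
    try:
        if df["gud"].std() == 0:
            return 0.0, 1.0, "constant"
        if n_batches >= 3:
            model = smf.mixedlm("gud ~ is_target", df, groups=df["batch"])
            fit = model.fit(reml=True, method="lbfgs")
            return float(fit.params["is_target"]), float(fit.pvalues["is_target"]), None
        if n_batches == 2:
            fit = smf.ols("gud ~ is_target + C(batch)", df).fit()
        else:
            fit = smf.ols("gud ~ is_target", df).fit()
        p = float(fit.pvalues["is_target"])
        if np.isnan(p):
            return float(fit.params["is_target"]), 1.0, "singular"
        return float(fit.params["is_target"]), p, None
    except (np.linalg.LinAlgError, ValueError) as exc:
        return 0.0, 1.0, f"fit_failed:{exc.__class__.__name__}"


def correlate_deviation(
    res: UTRDeviationResult,
    nm_gene: NormalizedMatrix,
    gene_subset: list[str],
    method: str = "spearman",
    regulators: list[str] | None = None,
    min_cells: int = 20,
) -> pd.DataFrame:
    """Correlate per-gene UTR deviation with gene expression.

    Self mode (``regulators`` None) pairs each gene's GUD with its own
    expression; cross mode pairs each gene's GUD with each regulator
    gene's expression.  Pairs with fewer than ``min_cells`` jointly
    defined cells, or a constant vector, get NaN with a reason.
    """
    if method not in {"spearman", "pearson"}:
        raise ValueError("method must be 'spearman' or 'pearson'")
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    shared = res.gud.columns.intersection(nm_gene.logexpr.columns)
    rows = []
    for gene in gene_subset:
        if gene not in res.gud.index:
            continue
        gud = res.gud.loc[gene, shared]
        partners = regulators if regulators is not None else [gene]
        for partner in partners:
            if partner not in nm_gene.logexpr.index:
                continue
            expr = nm_gene.logexpr.loc[partner, shared]
            ok = gud.notna() & expr.notna()
            reason = ""
            rho = p = np.nan
            if ok.sum() < min_cells:
                reason = "too_few_cells"
            elif gud[ok].nunique() <= 1 or expr[ok].nunique() <= 1:
                reason = "constant_vector"
            else:
                r = corr(gud[ok], expr[ok])
                rho, p = float(r.statistic), float(r.pvalue)
            rows.append(
                {"gene": gene, "partner": partner, "rho": rho, "p": p,
                 "n_cells": int(ok.sum()), "reason": reason}
            )
    out = pd.DataFrame(rows)
    if len(out):
        tested = out["p"].notna()
        out["fdr"] = np.nan
        if tested.any():
            out.loc[tested, "fdr"] = multipletests(
                out.loc[tested, "p"], method="fdr_bh"
            )[1]
    return out
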