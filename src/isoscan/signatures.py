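"""Gene-set module scores, intrinsic-subtype (iCMS2/iCMS3) assignment,
and subtype-consistent differential calls.

The module score of a gene set in a cell is the mean log-normalized
expression of the set minus the mean of expression-matched control
genes: genes are binned by average expression, and for every set gene a
fixed number of controls is sampled (seeded) from its bin.  The iCMS
score of a subtype is the module score of its up-regulated markers minus
that of its down-regulated markers; each patient is assigned to the
subtype with the higher mean score over its cancer cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import matrix as core
from . import splicing
from .models import NormalizedMatrix

log = logging.getLogger("isoscan")


def module_score(
    nm: NormalizedMatrix,
    gene_set: list[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell binned-control module score of a gene set."""
    expr = nm.logexpr
    present = [g for g in gene_set if g in expr.index]
    missing = sorted(set(gene_set) - set(present))
    if not present:
        raise ValueError(f"gene set has no overlap with matrix; missing: {missing[:10]}")
    if missing:
        log.info("module_score: %d set genes absent from matrix", len(missing))
    rng = np.random.default_rng(seed)
    avg = expr.mean(axis=1)
    n_bins = min(n_bins, max(1, len(avg) // 2))
    bins = pd.Series(
        pd.cut(avg.rank(method="first"), bins=n_bins, labels=False), index=avg.index
    )
    in_set = set(present)
    ctrl_genes: list[str] = []
    for g in present:
        bin_members = bins.index[bins == bins[g]]
        # controls must be expression-matched but outside the set, else a
        # coherently shifted set cancels against itself; degenerate bins
        # (all members in the set) fall back to the full bin
        pool = [x for x in bin_members if x not in in_set] or list(bin_members)
        take = min(n_ctrl, len(pool))
        ctrl_genes.extend(rng.choice(pool, size=take, replace=False))
    score = expr.loc[present].mean(axis=0) - expr.loc[ctrl_genes].mean(axis=0)
    score.name = "module_score"
    return score


@dataclass
class ModuleScoreResult:
    scores: pd.DataFrame  # per cell: icms2_score, icms3_score and components


def icms_scores(
    nm: NormalizedMatrix,
    markers: dict,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScoreResult:
    """iCMS2/iCMS3 scores from four marker sets (up/down per subtype).

    ``markers`` needs keys icms2_up, icms2_down, icms3_up, icms3_down.
    The subtype score is up-set score minus down-set score.
    """
    need = {"icms2_up", "icms2_down", "icms3_up", "icms3_down"}
    if not need <= set(markers):
        raise ValueError(f"markers must provide {sorted(need)}")
    cols = {}
    for i, key in enumerate(sorted(need)):
        cols[key] = module_score(nm, markers[key], n_bins, n_ctrl, seed + i)
    df = pd.DataFrame(cols)
    df["icms2_score"] = df["icms2_up"] - df["icms2_down"]
    df["icms3_score"] = df["icms3_up"] - df["icms3_down"]
    return ModuleScoreResult(scores=df)


def icms_assign(
    result: ModuleScoreResult,
    metadata: pd.DataFrame,
    cancer_mask: pd.Series,
    patient_col: str = "patient",
    tie_threshold: float = 0.0,
) -> pd.DataFrame:
    """Assign each patient the subtype with the higher mean cancer-cell
    score; margins <= ``tie_threshold`` give 'unassigned'."""
    rows = []
    scores = result.scores
    for patient in sorted(metadata[patient_col].unique()):
        cells = metadata.index[(metadata[patient_col] == patient)
                               & cancer_mask.reindex(metadata.index, fill_value=False)]
        cells = scores.index.intersection(cells)
        if not len(cells):
            continue
        s2 = scores.loc[cells, "icms2_score"].mean()
        s3 = scores.loc[cells, "icms3_score"].mean()
        margin = s2 - s3
        if abs(margin) <= tie_threshold:
            subtype = "unassigned"
        else:
            subtype = "iCMS2" if margin > 0 else "iCMS3"
        rows.append({"patient": patient, "icms2_score": s2, "icms3_score": s3,
                     "margin": margin, "subtype": subtype})
    return pd.DataFrame(rows).set_index("patient")


def subtype_consistent_changes(
    data,
    groups: dict,
    mode: str = "det",
    min_fc: float = 2.0,
    min_dpsi: float = 0.1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Features consistently changed in one subtype versus both the other
    subtype and normal epithelium.

    ``groups`` maps {'icms2', 'icms3', 'normal'} to cell-id lists.  In
    'det' mode ``data`` is a NormalizedMatrix and a feature is "Up" (or
    "Down") in subtype S when both pairwise rank-sum comparisons (S vs the
    other subtype, S vs normal) pass fold change >= ``min_fc`` (resp.
    <= 1/min_fc) with raw p < ``alpha``; in 'das' mode ``data`` is a PSI
    DataFrame and only upward consistency (dPSI >= ``min_dpsi``,
    p < ``alpha``) defines subtype specificity.  The table carries one
    column per subtype; a feature can never be Up in both subtypes.
    """
    for key in ("icms2", "icms3", "normal"):
        if not len(groups.get(key, [])):
            raise ValueError(f"group {key} empty")

    def compare(a, b):
        if mode == "det":
            t = core.wilcoxon_de(data, groups[a], groups[b], min_fc=min_fc,
                                 alpha=alpha)
            return t["fc"], t["p"]
        t = splicing.differential_splicing(data, groups[a], groups[b],
                                           alpha=alpha, min_dpsi=min_dpsi)
        return t["dpsi"], t["p"]

    out = None
    for s, other in (("icms2", "icms3"), ("icms3", "icms2")):
        eff1, p1 = compare(s, other)
        eff2, p2 = compare(s, "normal")
        if mode == "det":
            up = (eff1 >= min_fc) & (eff2 >= min_fc) & (p1 < alpha) & (p2 < alpha)
            dn = (eff1 <= 1 / min_fc) & (eff2 <= 1 / min_fc) & \
                (p1 < alpha) & (p2 < alpha)
        else:
            up = (eff1 >= min_dpsi) & (eff2 >= min_dpsi) & \
                (p1 < alpha) & (p2 < alpha)
            dn = pd.Series(False, index=up.index)
        if out is None:
            out = pd.DataFrame(index=eff1.index)
        col = np.where(up.fillna(False), "Up",
                       np.where(dn.fillna(False), "Down", "unclassified"))
        out[s] = col
    return out
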