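"""Allele-specific expression at somatic mutation sites.

Per (site, cell) the pileup gives read counts of the wild-type allele
(Cwt), the mutant allele (Cmut) and any other base (Cother).  The
per-observation sequencing error rate is estimated from the "other"
reads,

    epsilon = Cother / (Cwt + Cmut + Cother),

and the null hypothesis that mutant reads arise purely from sequencing
error is tested with a one-sided binomial tail P(X >= Cmut) for
X ~ Binomial(n = Cwt + Cmut + Cother, epsilon), BH-corrected across all
tested (site, cell) pairs.  A mutation is confirmed in a cell when
FDR < 0.05 and Cwt + Cmut >= 3 (cancer cells) or >= 10 (normal cells).

The default pools epsilon per site across cells (a per-cell epsilon
degenerates to zero whenever Cother = 0, making any single mutant read
"significant"); per-cell mode is retained.  Because misreads of the
wild-type base land on the specific mutant base only a third of the
time, epsilon over-estimates the mutant-specific error and the test is
conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .models import AllelicCounts, ExpressionMatrix, NormalizedMatrix

log = logging.getLogger("isoscan")

COVERAGE_MIN = {"cancer": 3, "normal": 10}


@dataclass
class AllelicMatrices:
    site_ids: list
    cell_ids: list
    e_wt: np.ndarray
    e_mut: np.ndarray
    e_tot: np.ndarray
    norm_wt: pd.DataFrame
    norm_mut: pd.DataFrame
    norm_tot: pd.DataFrame
    uncovered_sites: list = field(default_factory=list)


def build_allelic_matrices(ac: AllelicCounts, m: ExpressionMatrix) -> AllelicMatrices:
    """Assemble Ewt/Emut/Etot plus log(CPM/10+1) views normalized by each
    cell's total mapped read count from the expression matrix."""
    shared = [c for c in ac.cell_ids if c in set(m.cell_ids)]
    if not shared:
        raise ValueError("no shared cells between allelic counts and matrix")
    aj = np.array([ac.cell_ids.index(c) for c in shared])
    e_wt = ac.c_wt[:, aj]
    e_mut = ac.c_mut[:, aj]
    e_tot = e_wt + e_mut
    lib = np.asarray(
        m.counts[:, [m.cell_ids.index(c) for c in shared]].sum(axis=0)
    ).ravel().astype(float)
    lib = np.where(lib > 0, lib, 1.0)

    def norm(x):
        cpm = x / lib[None, :] * 1e6
        return pd.DataFrame(np.log(cpm / 10.0 + 1.0),
                            index=ac.site_ids, columns=shared)

    uncovered = [s for s, tot in zip(ac.site_ids, e_tot.sum(axis=1)) if tot == 0]
    if uncovered:
        log.info("build_allelic_matrices: %d sites uncovered in all cells",
                 len(uncovered))
    return AllelicMatrices(
        site_ids=ac.site_ids, cell_ids=shared,
        e_wt=e_wt, e_mut=e_mut, e_tot=e_tot,
        norm_wt=norm(e_wt), norm_mut=norm(e_mut), norm_tot=norm(e_tot),
        uncovered_sites=uncovered,
    )


def call_mutations(
    ac: AllelicCounts,
    cell_class: pd.Series,
    epsilon_mode: str = "per_site_pooled",
    epsilon_floor: float = 1e-3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided binomial mutant-allele test per (site, cell).

    ``cell_class`` maps cell id to 'cancer' or 'normal' and sets the
    coverage requirement for confirmation.  Cells with zero total reads
    at a site are untested.
    """
    unknown = set(cell_class.unique()) - set(COVERAGE_MIN)
    if unknown:
        raise ValueError(f"unknown cell classes: {sorted(unknown)}")
    missing = [c for c in ac.cell_ids if c not in cell_class.index]
    if missing:
        raise ValueError(f"cells without class label: {missing[:5]}")
    if epsilon_mode not in {"per_cell", "per_site_pooled"}:
        raise ValueError("epsilon_mode must be per_cell or per_site_pooled")

    n = ac.c_wt + ac.c_mut + ac.c_other
    if epsilon_mode == "per_cell":
        with np.errstate(invalid="ignore"):
            eps = np.where(n > 0, ac.c_other / np.maximum(n, 1), 0.0)
    else:
        site_tot = n.sum(axis=1, keepdims=True).astype(float)
        site_eps = np.divide(ac.c_other.sum(axis=1, keepdims=True), site_tot,
                             out=np.zeros_like(site_tot), where=site_tot > 0)
        eps = np.broadcast_to(site_eps, n.shape)
    eps = np.clip(eps, epsilon_floor, 1.0)

    classes = cell_class.loc[ac.cell_ids].values
    rows = []
    for i, sid in enumerate(ac.site_ids):
        tested = np.flatnonzero(n[i] > 0)
        for j in tested:
            p = float(stats.binom.sf(ac.c_mut[i, j] - 1, int(n[i, j]), eps[i, j]))
            rows.append({
                "site_id": sid, "cell_id": ac.cell_ids[j],
                "cell_class": classes[j],
                "epsilon": float(eps[i, j]),
                "c_wt": int(ac.c_wt[i, j]), "c_mut": int(ac.c_mut[i, j]),
                "c_other": int(ac.c_other[i, j]),
                "coverage": int(ac.c_wt[i, j] + ac.c_mut[i, j]),
                "p_value": p,
            })
    calls = pd.DataFrame(rows)
    if not len(calls):
        return pd.DataFrame(columns=[
            "site_id", "cell_id", "cell_class", "epsilon", "c_wt", "c_mut",
            "c_other", "coverage", "p_value", "fdr", "confirmed"])
    calls["fdr"] = multipletests(calls["p_value"], method="fdr_bh")[1]
    cov_min = calls["cell_class"].map(COVERAGE_MIN)
    calls["confirmed"] = (calls["fdr"] < alpha) & (calls["coverage"] >= cov_min)
    return calls


def mutant_dominance(ac: AllelicCounts, calls: pd.DataFrame) -> pd.DataFrame:
    """Pooled mutant-allele share and mut/wt ratio per site over confirmed
    cancer cells; NA rows for sites with no confirmed cell."""
    conf = calls[(calls["confirmed"]) & (calls["cell_class"] == "cancer")]
    rows = []
    for sid in ac.site_ids:
        sub = conf[conf["site_id"] == sid]
        if not len(sub):
            rows.append({"site_id": sid, "n_cells": 0, "mut_fraction": np.nan,
                         "mut_wt_ratio": np.nan, "ratio_infinite": False})
            continue
        mut, wt = sub["c_mut"].sum(), sub["c_wt"].sum()
        rows.append({
            "site_id": sid, "n_cells": len(sub),
            "mut_fraction": mut / (mut + wt) if mut + wt else np.nan,
            "mut_wt_ratio": mut / wt if wt > 0 else np.inf,
            "ratio_infinite": wt == 0 and mut > 0,
        })
    return pd.DataFrame(rows).set_index("site_id")


def correlation_shift(
    am: AllelicMatrices,
    hvg_expr: NormalizedMatrix,
    k: int = 2,
    min_cells: int = 15,
):
    """Correlate allelic expression with highly-variable-gene expression
    and cluster HVGs on the mutant-minus-wild-type shift.

    Per site, cells are restricted to those with any allelic coverage
    (e_tot > 0); Pearson r is computed between each normalized allelic
    vector and each HVG logexpr vector over those cells.  Returns a dict
    with r_tot/r_wt/r_mut/delta DataFrames (site x HVG) and the HVG
    cluster labels from average-linkage clustering of delta profiles.
    """
    shared = [c for c in am.cell_ids if c in set(hvg_expr.logexpr.columns)]
    hv = hvg_expr.logexpr[shared]
    col = {c: j for j, c in enumerate(am.cell_ids)}
    jj = np.array([col[c] for c in shared])

    mats = {"r_tot": am.norm_tot, "r_wt": am.norm_wt, "r_mut": am.norm_mut}
    out = {name: pd.DataFrame(np.nan, index=am.site_ids, columns=hv.index)
           for name in mats}
    for i, sid in enumerate(am.site_ids):
        covered = np.flatnonzero(am.e_tot[i, jj] > 0)
        if len(covered) < min_cells:
            continue
        cells = [shared[c] for c in covered]
        for name, mat in mats.items():
            vec = mat.loc[sid, cells].values
            if np.ptp(vec) == 0:
                continue  # zero-variance allelic vector: NA row
            expr = hv[cells].values
            sd = expr.std(axis=1)
            okg = sd > 0
            if okg.any():
                v = (vec - vec.mean()) / vec.std()
                E = (expr[okg] - expr[okg].mean(axis=1, keepdims=True)) / \
                    sd[okg][:, None]
                out[name].loc[sid, hv.index[okg]] = (E @ v) / len(v)

    delta = out["r_mut"] - out["r_wt"]
    valid = delta.dropna(axis=0, how="all").dropna(axis=1, how="any")
    if valid.shape[1] >= 2 and valid.shape[0] >= 1:
        Z = linkage(valid.T.values, method="average", metric="euclidean")
        labels = pd.Series(fcluster(Z, t=k, criterion="maxclust"),
                           index=valid.columns)
    else:
        labels = pd.Series(dtype=int)
    return {"r_tot": out["r_tot"], "r_wt": out["r_wt"], "r_mut": out["r_mut"],
            "delta": delta, "clusters": labels}
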