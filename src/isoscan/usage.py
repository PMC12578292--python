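"""Differential transcript usage and differential CDS usage.

Two-stage procedure: a per-gene screen of equal within-gene unit
proportions between conditions (per-unit rank-sum p-values on per-cell
proportions, combined per gene by Sidak), BH-corrected across genes to
give the screen-stage overall FDR (OFDR); then per-unit confirmation
within screened genes, Holm-adjusted within each gene.  A unit is called
significant when its gene passes the screen at OFDR < 0.05, its confirmed
p is < 0.05, and the pooled-count proportion difference exceeds 10% —
matching the stage-wise OFDR + proportion-difference criterion used for
isoform-switch calls in tumor-vs-normal contrasts.

Units are transcripts, or CDS groups: transcripts sharing a CCDS id (or,
lacking one, an identical CDS interval set) collapse into one unit, so
UTR-only switches cannot masquerade as coding-sequence switches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import ExpressionMatrix, TranscriptModel, TranscriptModelSet

log = logging.getLogger("isoscan")


def group_by_cds(annotation: TranscriptModelSet) -> pd.DataFrame:
    """Map each transcript to a CDS usage group within its gene.

    Coding transcripts sharing a ``ccds_id`` — or, when no id is
    annotated, an identical CDS genomic interval set — share a group;
    non-coding transcripts form singleton groups flagged non-coding.
    """
    rows = []
    for gid in annotation.gene_ids:
        seen: dict = {}
        for t in annotation.gene_transcripts(gid):
            if not t.is_coding:
                rows.append({"transcript_id": t.transcript_id, "gene_id": gid,
                             "cds_group": f"{gid}:nc:{t.transcript_id}",
                             "non_coding": True})
                continue
            key = t.ccds_id if t.ccds_id else ("cds", tuple(t.cds))
            if key not in seen:
                seen[key] = f"{gid}:cds{len(seen) + 1}"
            rows.append({"transcript_id": t.transcript_id, "gene_id": gid,
                         "cds_group": seen[key], "non_coding": False})
    return pd.DataFrame(rows).set_index("transcript_id")


@dataclass
class UsageResult:
    gene_table: pd.DataFrame  # screen_p, screen_ofdr per gene
    unit_table: pd.DataFrame  # confirm_p, proportions, delta, significant
    grouping: str


def usage_test(
    m: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    grouping: str = "transcript",
    annotation: TranscriptModelSet | None = None,
    min_cells: int = 10,
    ofdr: float = 0.05,
    min_delta: float = 0.10,
    alpha_confirm: float = 0.05,
) -> UsageResult:
    """Two-stage differential usage between two cell sets.

    ``grouping='cds'`` first collapses transcripts into CDS groups (needs
    ``annotation``); genes left with fewer than two units, or with fewer
    than ``min_cells`` gene-expressing cells in either group, are skipped.
    """
    if grouping == "cds":
        if annotation is None:
            raise ValueError("grouping='cds' requires the annotation")
        cds_map = group_by_cds(annotation)
        unit_of = cds_map["cds_group"].reindex(m.feature_ids)
        if unit_of.isna().any():
            raise ValueError("matrix features missing from annotation")
    elif grouping == "transcript":
        unit_of = pd.Series(m.feature_ids, index=m.feature_ids)
    else:
        raise ValueError("grouping must be 'transcript' or 'cds'")

    dense = m.dense().astype(float)
    cell_pos = {c: j for j, c in enumerate(m.cell_ids)}
    ja = np.array([cell_pos[c] for c in group_a])
    jb = np.array([cell_pos[c] for c in group_b])
    genes = m.feature_genes.values

    gene_rows, unit_rows = [], []
    for gid in pd.unique(genes):
        gmask = genes == gid
        sub = dense[gmask]
        units = unit_of[gmask].values
        uniq_units = sorted(set(units))
        if len(uniq_units) < 2:
            continue
        # collapse features into units
        ucounts = np.vstack([sub[units == u].sum(axis=0) for u in uniq_units])
        tot = ucounts.sum(axis=0)
        ca = ja[tot[ja] > 0]
        cb = jb[tot[jb] > 0]
        if len(ca) < min_cells or len(cb) < min_cells:
            continue
        prop_a = ucounts[:, ca] / tot[ca]
        prop_b = ucounts[:, cb] / tot[cb]
        unit_ps = []
        for u in range(len(uniq_units)):
            pooled = np.concatenate([prop_a[u], prop_b[u]])
            if np.ptp(pooled) == 0:
                unit_ps.append(1.0)
            else:
                unit_ps.append(
                    stats.mannwhitneyu(prop_a[u], prop_b[u],
                                       alternative="two-sided").pvalue
                )
        unit_ps = np.array(unit_ps)
        n_units = len(uniq_units)
        screen_p = float(1.0 - (1.0 - unit_ps.min()) ** n_units)  # Sidak
        pool_pa = ucounts[:, ca].sum(axis=1) / ucounts[:, ca].sum()
        pool_pb = ucounts[:, cb].sum(axis=1) / ucounts[:, cb].sum()
        gene_rows.append({"gene_id": gid, "screen_p": screen_p,
                          "n_units": n_units,
                          "n_cells_a": len(ca), "n_cells_b": len(cb)})
        for u, uid in enumerate(uniq_units):
            unit_rows.append({
                "gene_id": gid, "unit": uid, "confirm_raw_p": unit_ps[u],
                "prop_a": pool_pa[u], "prop_b": pool_pb[u],
                "delta_proportion": pool_pa[u] - pool_pb[u],
            })

    gene_table = pd.DataFrame(gene_rows)
    unit_table = pd.DataFrame(unit_rows)
    if len(gene_table):
        gene_table["screen_ofdr"] = multipletests(
            gene_table["screen_p"], method="fdr_bh")[1]
        gene_table = gene_table.set_index("gene_id")
        screened = set(gene_table.index[gene_table["screen_ofdr"] < ofdr])
        confirm = np.full(len(unit_table), np.nan)
        for gid in screened:
            sel = unit_table["gene_id"] == gid
            confirm[sel.values] = multipletests(
                unit_table.loc[sel, "confirm_raw_p"], method="holm")[1]
        unit_table["confirm_p"] = confirm
        unit_table["significant"] = (
            unit_table["gene_id"].isin(screened)
            & (unit_table["confirm_p"] < alpha_confirm)
            & (unit_table["delta_proportion"].abs() > min_delta)
        )
    else:
        gene_table = pd.DataFrame(
            columns=["screen_p", "n_units", "n_cells_a", "n_cells_b",
                     "screen_ofdr"])
        unit_table = pd.DataFrame(
            columns=["gene_id", "unit", "confirm_raw_p", "prop_a", "prop_b",
                     "delta_proportion", "confirm_p", "significant"])
    return UsageResult(gene_table, unit_table, grouping)


# --------------------------------------------------- CDS change annotation

def _cds_relative_to_genomic(t: TranscriptModel, start: int, end: int):
    """Map a 1-based CDS-relative interval to genomic intervals,
    walking the CDS in transcript orientation."""
    blocks = t.cds if t.strand == "+" else list(reversed(t.cds))
    out, offset = [], 0
    for (a, b) in blocks:
        blen = b - a + 1
        lo = max(start, offset + 1)
        hi = min(end, offset + blen)
        if lo <= hi:
            if t.strand == "+":
                out.append((a + (lo - offset - 1), a + (hi - offset - 1)))
            else:
                out.append((b - (hi - offset - 1), b - (lo - offset - 1)))
        offset += blen
    return out


def _subtract_intervals(avs, bvs):
    """Parts of intervals avs not covered by bvs."""
    out = []
    for (a, b) in avs:
        pieces = [(a, b)]
        for (c, d) in bvs:
            nxt = []
            for (x, y) in pieces:
                if d < x or c > y:
                    nxt.append((x, y))
                else:
                    if x < c:
                        nxt.append((x, c - 1))
                    if y > d:
                        nxt.append((d + 1, y))
            pieces = nxt
        out.extend(pieces)
    return out


def annotate_cds_change(
    usage: UsageResult,
    annotation: TranscriptModelSet,
    domains: pd.DataFrame | None = None,
    min_cds_change: float = 20.0,
) -> pd.DataFrame:
    """Describe the coding consequence of each significant usage switch.

    For every gene with a significant unit, the dominant up- and
    down-regulated units (largest |delta_proportion| in each direction)
    are compared: CDS length difference in bp (flagged as a CDS change
    when > ``min_cds_change``), number of differing exons (symmetric
    difference of exon interval sets), and — when a domain table with
    columns transcript_id/domain/cds_start/cds_end is given — domains
    lost in either isoform (a domain is lost in B when its genomic
    footprint overlaps CDS regions absent from B's CDS).
    """
    sig = usage.unit_table[usage.unit_table["significant"]]
    rows = []
    for gid in sorted(sig["gene_id"].unique()):
        units = usage.unit_table[usage.unit_table["gene_id"] == gid]
        up = units.loc[units["delta_proportion"].idxmax()]
        down = units.loc[units["delta_proportion"].idxmin()]
        if up["delta_proportion"] <= 0 or down["delta_proportion"] >= 0:
            continue
        t_up = _unit_representative(up["unit"], gid, annotation, usage.grouping)
        t_dn = _unit_representative(down["unit"], gid, annotation, usage.grouping)
        row = {"gene_id": gid, "up_unit": up["unit"], "down_unit": down["unit"],
               "up_delta": up["delta_proportion"],
               "down_delta": down["delta_proportion"]}
        if t_up is None or t_dn is None or not t_up.is_coding or not t_dn.is_coding:
            row.update({"cds_len_diff": np.nan, "cds_changed": False,
                        "n_exons_diff": np.nan, "flag": "untestable"})
            rows.append(row)
            continue
        diff = abs(t_up.cds_len - t_dn.cds_len)
        row.update({
            "cds_len_diff": diff,
            "cds_changed": diff > min_cds_change,
            "n_exons_diff": len(set(map(tuple, t_up.exons))
                                ^ set(map(tuple, t_dn.exons))),
            "flag": "",
        })
        if domains is not None:
            row["domains_lost_in_down"] = _lost_domains(t_up, t_dn, domains)
            row["domains_lost_in_up"] = _lost_domains(t_dn, t_up, domains)
        rows.append(row)
    return pd.DataFrame(rows)


def _unit_representative(unit, gid, annotation, grouping):
    if grouping == "transcript":
        return annotation[unit] if unit in annotation.transcripts else None
    key_map = group_by_cds(annotation)
    for t in annotation.gene_transcripts(gid):
        if key_map.loc[t.transcript_id, "cds_group"] == unit:
            return t
    return None


def _lost_domains(src: TranscriptModel, other: TranscriptModel,
                  domains: pd.DataFrame) -> list[str]:
    """Domains of ``src`` whose genomic footprint overlaps CDS regions
    missing from ``other``."""
    missing = _subtract_intervals(src.cds, other.cds)
    lost = []
    own = domains[domains["transcript_id"] == src.transcript_id]
    for rec in own.itertuples(index=False):
        footprint = _cds_relative_to_genomic(src, int(rec.cds_start),
                                             int(rec.cds_end))
        if any(a <= d and c <= b for (a, b) in footprint for (c, d) in missing):
            lost.append(rec.domain)
    return sorted(lost)
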