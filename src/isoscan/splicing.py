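"""Local alternative-splicing events, PSI, differential splicing, and
splicing-factor correlation structure.

Event types follow the standard local-event taxonomy: skipped exon (SE),
retained intron (RI), alternative 5'/3' splice site (A5/A3), alternative
first/last exon (AF/AL) and mutually exclusive exons (MX).  Events are
derived purely from exon coordinates of the isoforms of one gene; PSI of
an event in a cell is the TPM of its inclusion isoforms divided by the
TPM of all isoforms participating in the event.

Inclusion-form conventions (deterministic, documented in the methods
note): SE - exon-containing isoforms; RI - intron-retaining isoforms;
A5/A3 - isoforms using the shorter intron (more exonic sequence); AF/AL -
isoforms using the genomically left alternative terminal exon; MX -
isoforms containing the genomically left exon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .models import NormalizedMatrix, TranscriptModelSet

log = logging.getLogger("isoscan")

EVENT_TYPES = ("SE", "RI", "A5", "A3", "AF", "AL", "MX")


@dataclass(frozen=True)
class SplicingEvent:
    event_id: str
    type: str
    gene_id: str
    chrom: str
    strand: str
    inclusion_isoforms: frozenset
    total_isoforms: frozenset

    @property
    def exclusion_isoforms(self) -> frozenset:
        return self.total_isoforms - self.inclusion_isoforms


def _overlaps(a, b) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def extract_events(annotation: TranscriptModelSet) -> list[SplicingEvent]:
    """Enumerate local AS events per gene; deterministic and independent of
    transcript input order.  Single-isoform genes yield no events."""
    events: dict[str, SplicingEvent] = {}
    for gid in annotation.gene_ids:
        txs = annotation.gene_transcripts(gid)
        if len(txs) < 2:
            continue
        for ev in _gene_events(gid, txs):
            prev = events.get(ev.event_id)
            if prev is not None:
                ev = SplicingEvent(
                    ev.event_id, ev.type, ev.gene_id, ev.chrom, ev.strand,
                    prev.inclusion_isoforms | ev.inclusion_isoforms,
                    prev.total_isoforms | ev.total_isoforms,
                )
            events[ev.event_id] = ev
    return [events[k] for k in sorted(events)]


def _gene_events(gid: str, txs) -> list[SplicingEvent]:
    chrom, strand = txs[0].chrom, txs[0].strand
    exon_map: dict[tuple, set] = {}       # exact exon -> tids
    intron_map: dict[tuple, set] = {}     # intron -> tids
    triple_map: dict[tuple, set] = {}     # (prev_end, exon, next_start) -> tids
    intron_up: dict[tuple, set] = {}      # intron -> upstream exons used with it
    intron_dn: dict[tuple, set] = {}      # intron -> downstream exons
    first_forms: dict[tuple, dict] = {}   # shared next_start -> {first_exon: tids}
    last_forms: dict[tuple, dict] = {}    # shared prev_end -> {last_exon: tids}
    tx_exons = {t.transcript_id: set(map(tuple, t.exons)) for t in txs}

    for t in txs:
        tid = t.transcript_id
        ex = [tuple(e) for e in t.exons]
        for e in ex:
            exon_map.setdefault(e, set()).add(tid)
        for i, (a, b) in enumerate(zip(ex, ex[1:])):
            intr = (a[1] + 1, b[0] - 1)
            intron_map.setdefault(intr, set()).add(tid)
            intron_up.setdefault(intr, set()).add(a)
            intron_dn.setdefault(intr, set()).add(b)
        for i in range(1, len(ex) - 1):
            key = (ex[i - 1][1], ex[i], ex[i + 1][0])
            triple_map.setdefault(key, set()).add(tid)
        if len(ex) >= 2:
            first_forms.setdefault((ex[1][0],), {}).setdefault(ex[0], set()).add(tid)
            last_forms.setdefault((ex[-2][1],), {}).setdefault(ex[-1], set()).add(tid)

    out: list[SplicingEvent] = []

    # SE: internal exon with both flanks vs a spanning intron
    for (pe, exon, ns), inc in triple_map.items():
        span = (pe + 1, ns - 1)
        exc = intron_map.get(span)
        if exc:
            eid = f"SE:{chrom}:{pe}-{exon[0]}:{exon[1]}-{ns}:{strand}"
            out.append(SplicingEvent(eid, "SE", gid, chrom, strand,
                                     frozenset(inc), frozenset(inc | exc)))

    # RI: adjacent exon pair vs a single exon spanning both
    for intr, tids in intron_map.items():
        for up in intron_up[intr]:
            for dn in intron_dn[intr]:
                spliced = {
                    t for t in tids
                    if up in tx_exons[t] and dn in tx_exons[t]
                }
                retained = exon_map.get((up[0], dn[1]))
                if spliced and retained:
                    eid = (f"RI:{chrom}:{up[0]}:{up[1]}-{dn[0]}:{dn[1]}:{strand}")
                    out.append(SplicingEvent(
                        eid, "RI", gid, chrom, strand,
                        frozenset(retained), frozenset(retained | spliced)))

    # A5/A3: intron pairs sharing one boundary, overlapping variable exons
    introns = sorted(intron_map)
    for i, i1 in enumerate(introns):
        for i2 in introns[i + 1:]:
            if i1[1] == i2[1] and i1[0] != i2[0]:
                # variable donor side (genomic left); exons upstream must overlap
                if not _any_overlap(intron_up[i1], intron_up[i2]):
                    continue
                typ = "A5" if strand == "+" else "A3"
                short, longi = (i2, i1) if i2[0] > i1[0] else (i1, i2)
                eid = (f"{typ}:{chrom}:{longi[0]}-{longi[1]}:"
                       f"{short[0]}-{short[1]}:{strand}")
                inc = intron_map[short]
                out.append(SplicingEvent(
                    eid, typ, gid, chrom, strand,
                    frozenset(inc), frozenset(inc | intron_map[longi])))
            elif i1[0] == i2[0] and i1[1] != i2[1]:
                if not _any_overlap(intron_dn[i1], intron_dn[i2]):
                    continue
                typ = "A3" if strand == "+" else "A5"
                short, longi = (i1, i2) if i1[1] < i2[1] else (i2, i1)
                eid = (f"{typ}:{chrom}:{longi[0]}-{longi[1]}:"
                       f"{short[0]}-{short[1]}:{strand}")
                inc = intron_map[short]
                out.append(SplicingEvent(
                    eid, typ, gid, chrom, strand,
                    frozenset(inc), frozenset(inc | intron_map[longi])))

    # AF/AL: alternative non-overlapping terminal exons to a shared exon
    for shared, forms in first_forms.items():
        typ = "AF" if strand == "+" else "AL"
        out.extend(_terminal_events(forms, typ, gid, chrom, strand,
                                    shared[0], side="first"))
    for shared, forms in last_forms.items():
        typ = "AL" if strand == "+" else "AF"
        out.extend(_terminal_events(forms, typ, gid, chrom, strand,
                                    shared[0], side="last"))

    # MX: two non-overlapping internal exons with identical flanks,
    # never co-occurring in one transcript
    by_flanks: dict[tuple, dict] = {}
    for (pe, exon, ns), tids in triple_map.items():
        by_flanks.setdefault((pe, ns), {}).setdefault(exon, set()).update(tids)
    for (pe, ns), exons in by_flanks.items():
        exlist = sorted(exons)
        for i, e1 in enumerate(exlist):
            for e2 in exlist[i + 1:]:
                if _overlaps(e1, e2):
                    continue
                if any(e1 in tx_exons[t] and e2 in tx_exons[t] for t in tx_exons):
                    continue
                eid = (f"MX:{chrom}:{pe}:{e1[0]}-{e1[1]}:"
                       f"{e2[0]}-{e2[1]}:{ns}:{strand}")
                inc = exons[e1]
                out.append(SplicingEvent(
                    eid, "MX", gid, chrom, strand,
                    frozenset(inc), frozenset(inc | exons[e2])))
    return out


def _any_overlap(exons_a, exons_b) -> bool:
    return any(_overlaps(a, b) for a in exons_a for b in exons_b)


def _terminal_events(forms, typ, gid, chrom, strand, shared, side):
    out = []
    exlist = sorted(forms)
    for i, e1 in enumerate(exlist):
        for e2 in exlist[i + 1:]:
            if _overlaps(e1, e2):
                continue
            eid = (f"{typ}:{chrom}:{e1[0]}-{e1[1]}:{e2[0]}-{e2[1]}:"
                   f"{shared}:{strand}")
            inc = forms[e1]  # genomically left alternative exon
            out.append(SplicingEvent(
                eid, typ, gid, chrom, strand,
                frozenset(inc), frozenset(inc | forms[e2])))
    return out


# ----------------------------------------------------------------- PSI

def compute_psi(
    nm: NormalizedMatrix,
    events: list[SplicingEvent],
    min_total_tpm: float = 1.0,
) -> pd.DataFrame:
    """Event x cell PSI: TPM(inclusion) / TPM(total participating), NaN
    when the participating TPM falls below ``min_total_tpm``."""
    if nm.level != "isoform":
        raise ValueError("compute_psi needs an isoform-level matrix")
    rows = {}
    for ev in events:
        inc = [t for t in sorted(ev.inclusion_isoforms) if t in nm.tpm.index]
        tot = [t for t in sorted(ev.total_isoforms) if t in nm.tpm.index]
        if not inc or not tot:
            continue
        tot_tpm = nm.tpm.loc[tot].sum(axis=0)
        inc_tpm = nm.tpm.loc[inc].sum(axis=0)
        psi = inc_tpm / tot_tpm.where(tot_tpm >= min_total_tpm)
        rows[ev.event_id] = psi
    out = pd.DataFrame(rows).T
    out.index.name = "event_id"
    return out


def event_type(event_id: str) -> str:
    return event_id.split(":", 1)[0]


# --------------------------------------------------- differential splicing

def differential_splicing(
    psi: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    min_cells: int = 10,
    alpha: float = 0.05,
    min_dpsi: float = 0.1,
) -> pd.DataFrame:
    """Per-event rank-sum test on per-cell PSI between two cell sets.

    dPSI = mean(A) - mean(B); an event is significant when the raw p-value
    is < ``alpha`` and |dPSI| >= ``min_dpsi`` (the BH column is reported
    additionally, not used for the gate).  Events with fewer than
    ``min_cells`` defined-PSI cells in either group are skipped with a
    reason.
    """
    rows = []
    ga = [c for c in group_a if c in psi.columns]
    gb = [c for c in group_b if c in psi.columns]
    for eid in psi.index:
        a = psi.loc[eid, ga].dropna()
        b = psi.loc[eid, gb].dropna()
        if len(a) < min_cells or len(b) < min_cells:
            rows.append({"event_id": eid, "dpsi": np.nan, "p": np.nan,
                         "n_a": len(a), "n_b": len(b), "significant": False,
                         "skipped": "too_few_cells"})
            continue
        pooled = np.concatenate([a.values, b.values])
        if np.ptp(pooled) == 0:
            p = 1.0
        else:
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        dpsi = a.mean() - b.mean()
        rows.append({"event_id": eid, "dpsi": dpsi, "p": p,
                     "n_a": len(a), "n_b": len(b),
                     "significant": bool(p < alpha and abs(dpsi) >= min_dpsi),
                     "skipped": ""})
    out = pd.DataFrame(rows).set_index("event_id")
    tested = out["p"].notna()
    out["adj_p"] = np.nan
    if tested.any():
        out.loc[tested, "adj_p"] = multipletests(out.loc[tested, "p"],
                                                 method="fdr_bh")[1]
    return out


def per_patient_das(
    psi: pd.DataFrame,
    metadata: pd.DataFrame,
    target: str,
    reference: str,
    cell_type_col: str = "cell_type",
    patient_col: str = "patient",
    **kwargs,
) -> pd.DataFrame:
    """Run differential splicing per patient (patient's target cells vs all
    reference cells) and report the union with per-patient flags."""
    flags = {}
    for patient in sorted(metadata[patient_col].unique()):
        ga = metadata.index[(metadata[patient_col] == patient)
                            & (metadata[cell_type_col] == target)]
        gb = metadata.index[metadata[cell_type_col] == reference]
        if not len(ga):
            continue
        tab = differential_splicing(psi, list(ga), list(gb), **kwargs)
        flags[patient] = tab["significant"]
    out = pd.DataFrame(flags).fillna(False)
    out["n_patients"] = out.sum(axis=1)
    out["significant_any"] = out["n_patients"] > 0
    return out


# -------------------------------------------- SF-PSI correlation structure

def sf_psi_correlation(
    psi_das: pd.DataFrame,
    sf_expr: NormalizedMatrix,
    k: int = 2,
    min_cells: int = 10,
):
    """Pearson correlation between DAS-event PSI and splicing-factor
    expression, hierarchical clustering of events, and per-cluster Fisher
    tests of retained-intron enrichment.

    Returns (correlation DataFrame events x SFs, cluster label Series,
    enrichment DataFrame).
    """
    shared = psi_das.columns.intersection(sf_expr.logexpr.columns)
    sf = sf_expr.logexpr[shared]
    rows, kept = [], []
    for eid in psi_das.index:
        p = psi_das.loc[eid, shared]
        ok = p.notna()
        if ok.sum() < min_cells or p[ok].nunique() <= 1:
            continue
        rvec = []
        for sf_gene in sf.index:
            e = sf.loc[sf_gene, shared][ok]
            if e.nunique() <= 1:
                rvec.append(0.0)
            else:
                rvec.append(float(stats.pearsonr(p[ok], e).statistic))
        rows.append(rvec)
        kept.append(eid)
    corr = pd.DataFrame(rows, index=kept, columns=list(sf.index))
    if len(corr) < 2:
        labels = pd.Series(1, index=corr.index)
    else:
        Z = linkage(corr.values, method="average", metric="euclidean")
        labels = pd.Series(fcluster(Z, t=k, criterion="maxclust"), index=corr.index)
    enrich = []
    is_ri = corr.index.map(lambda e: event_type(e) == "RI")
    for cl in sorted(labels.unique()):
        in_cl = labels == cl
        a = int((in_cl & is_ri).sum())
        b = int((in_cl & ~is_ri).sum())
        c = int((~in_cl & is_ri).sum())
        d = int((~in_cl & ~is_ri).sum())
        odds, p = stats.fisher_exact([[a, b], [c, d]])
        enrich.append({"cluster": cl, "n_ri": a, "n_other": b,
                       "odds_ratio": odds, "fisher_p": p})
    return corr, labels, pd.DataFrame(enrich)


# ---------------------------------------------------------- event overlap

def event_overlap(
    das_a: pd.DataFrame,
    das_b: pd.DataFrame,
    universe: list[str],
    min_dpsi: float = 0.05,
    rescue: bool = False,
) -> tuple[list[str], float]:
    """Consistent events between two DAS tables plus a hypergeometric
    overlap p-value.

    An event is consistent when |dPSI| > ``min_dpsi`` in both tables with
    the same sign (opposite sign in ``rescue`` mode — e.g. a knockdown
    reverting an in-vivo change).  The upper-tail hypergeometric p uses
    (|universe|, |A|, |B|, |consistent|) where A and B are the events
    passing the dPSI filter in each table.
    """
    if not len(universe):
        raise ValueError("empty event universe")
    uni = set(universe)
    a_pass = {e for e in das_a.index
              if e in uni and abs(das_a.loc[e, "dpsi"]) > min_dpsi}
    b_pass = {e for e in das_b.index
              if e in uni and abs(das_b.loc[e, "dpsi"]) > min_dpsi}
    consistent = []
    for e in sorted(a_pass & b_pass):
        same = np.sign(das_a.loc[e, "dpsi"]) == np.sign(das_b.loc[e, "dpsi"])
        if (same and not rescue) or (rescue and not same):
            consistent.append(e)
    M, nA, nB, kk = len(uni), len(a_pass), len(b_pass), len(consistent)
    p = float(stats.hypergeom.sf(kk - 1, M, nA, nB))
    return consistent, p
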