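"""Event extraction (with exhaustive pairwise oracle), PSI, DAS, overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from isoscan import matrix, simulate, splicing
from isoscan.models import NormalizedMatrix, TranscriptModel, TranscriptModelSet


def tx(tid, exons, gid="G1", strand="+"):
    return TranscriptModel(transcript_id=tid, gene_id=gid, chrom="chr",
                           strand=strand, exons=exons)


def nm_from_tpm(tpm):
    return NormalizedMatrix(tpm=tpm, logexpr=np.log(tpm / 10 + 1),
                            level="isoform")


# ------------------------------------------------------------------ oracle

def pairwise_event_oracle(txs):
    """Brute-force event enumeration by pairwise isoform comparison.

    Independent of the production extractor: every transcript pair is
    compared directly; event ids found in any pair are collected, and
    membership is then derived from the defining intron/exon containment.
    """
    chrom, strand = txs[0].chrom, txs[0].strand
    by_tid = {t.transcript_id: t for t in txs}
    exset = {t.transcript_id: set(map(tuple, t.exons)) for t in txs}
    inset = {t.transcript_id: set(map(tuple, t.introns)) for t in txs}

    def triples(t):
        ex = [tuple(e) for e in t.exons]
        return [(ex[i - 1][1], ex[i], ex[i + 1][0])
                for i in range(1, len(ex) - 1)]

    found = {}

    def has_triple(tid, trip):
        return trip in triples(by_tid[tid])

    def add(eid, inc, tot):
        if eid in found:
            inc = inc | found[eid][0]
            tot = tot | found[eid][1]
        found[eid] = (inc, tot)

    tids = sorted(by_tid)
    for ta in tids:
        for tb in tids:
            if ta == tb:
                continue
            A, B = by_tid[ta], by_tid[tb]
            # SE: internal exon of A spanned by an intron of B
            for (pe, e, ns) in triples(A):
                if (pe + 1, ns - 1) in inset[tb]:
                    eid = f"SE:{chrom}:{pe}-{e[0]}:{e[1]}-{ns}:{strand}"
                    inc = {t for t in tids if has_triple(t, (pe, e, ns))}
                    exc = {t for t in tids if (pe + 1, ns - 1) in inset[t]}
                    add(eid, inc, inc | exc)
            # RI: intron of A fully exonic in B with matching outer bounds
            for (i0, i1) in inset[ta]:
                exA = [tuple(e) for e in A.exons]
                up = [e for e in exA if e[1] == i0 - 1]
                dn = [e for e in exA if e[0] == i1 + 1]
                if not up or not dn:
                    continue
                span = (up[0][0], dn[0][1])
                if span in exset[tb]:
                    eid = (f"RI:{chrom}:{span[0]}:{up[0][1]}-{dn[0][0]}:"
                           f"{span[1]}:{strand}")
                    inc = {t for t in tids if span in exset[t]}
                    exc = {t for t in tids
                           if up[0] in exset[t] and dn[0] in exset[t]
                           and (i0, i1) in inset[t]}
                    add(eid, inc, inc | exc)
            # A5/A3: introns sharing one boundary, variable exons overlap
            for ia in inset[ta]:
                for ib in inset[tb]:
                    if ia == ib:
                        continue
                    if ia[1] == ib[1] and ia[0] != ib[0]:
                        upA = [e for e in exset[ta] if e[1] == ia[0] - 1]
                        upB = [e for e in exset[tb] if e[1] == ib[0] - 1]
                        if not any(a[0] <= b[1] and b[0] <= a[1]
                                   for a in upA for b in upB):
                            continue
                        typ = "A5" if strand == "+" else "A3"
                        short, longi = (ia, ib) if ia[0] > ib[0] else (ib, ia)
                    elif ia[0] == ib[0] and ia[1] != ib[1]:
                        dnA = [e for e in exset[ta] if e[0] == ia[1] + 1]
                        dnB = [e for e in exset[tb] if e[0] == ib[1] + 1]
                        if not any(a[0] <= b[1] and b[0] <= a[1]
                                   for a in dnA for b in dnB):
                            continue
                        typ = "A3" if strand == "+" else "A5"
                        short, longi = (ia, ib) if ia[1] < ib[1] else (ib, ia)
                    else:
                        continue
                    eid = (f"{typ}:{chrom}:{longi[0]}-{longi[1]}:"
                           f"{short[0]}-{short[1]}:{strand}")
                    inc = {t for t in tids if short in inset[t]}
                    exc = {t for t in tids if longi in inset[t]}
                    add(eid, inc, inc | exc)
            # AF/AL: non-overlapping terminal exons to a shared splice site
            if len(A.exons) >= 2 and len(B.exons) >= 2:
                fA, fB = tuple(A.exons[0]), tuple(B.exons[0])
                if A.exons[1][0] == B.exons[1][0] and fA != fB \
                        and not (fA[0] <= fB[1] and fB[0] <= fA[1]):
                    typ = "AF" if strand == "+" else "AL"
                    e1, e2 = sorted([fA, fB])
                    eid = (f"{typ}:{chrom}:{e1[0]}-{e1[1]}:{e2[0]}-{e2[1]}:"
                           f"{A.exons[1][0]}:{strand}")
                    inc = {t for t in tids
                           if tuple(by_tid[t].exons[0]) == e1
                           and by_tid[t].exons[1][0] == A.exons[1][0]}
                    exc = {t for t in tids
                           if tuple(by_tid[t].exons[0]) == e2
                           and by_tid[t].exons[1][0] == A.exons[1][0]}
                    add(eid, inc, inc | exc)
                lA, lB = tuple(A.exons[-1]), tuple(B.exons[-1])
                if A.exons[-2][1] == B.exons[-2][1] and lA != lB \
                        and not (lA[0] <= lB[1] and lB[0] <= lA[1]):
                    typ = "AL" if strand == "+" else "AF"
                    e1, e2 = sorted([lA, lB])
                    eid = (f"{typ}:{chrom}:{e1[0]}-{e1[1]}:{e2[0]}-{e2[1]}:"
                           f"{A.exons[-2][1]}:{strand}")
                    inc = {t for t in tids
                           if tuple(by_tid[t].exons[-1]) == e1
                           and by_tid[t].exons[-2][1] == A.exons[-2][1]}
                    exc = {t for t in tids
                           if tuple(by_tid[t].exons[-1]) == e2
                           and by_tid[t].exons[-2][1] == A.exons[-2][1]}
                    add(eid, inc, inc | exc)
            # MX: same-flank internal exons, disjoint, never co-occurring
            for (pe, ea, ns) in triples(A):
                for (pe2, eb, ns2) in triples(B):
                    if (pe, ns) != (pe2, ns2) or ea == eb:
                        continue
                    if ea[0] <= eb[1] and eb[0] <= ea[1]:
                        continue
                    if any(ea in exset[t] and eb in exset[t] for t in tids):
                        continue
                    e1, e2 = sorted([ea, eb])
                    eid = (f"MX:{chrom}:{pe}:{e1[0]}-{e1[1]}:"
                           f"{e2[0]}-{e2[1]}:{ns}:{strand}")
                    inc = {t for t in tids if has_triple(t, (pe, e1, ns))}
                    exc = {t for t in tids if has_triple(t, (pe, e2, ns))}
                    add(eid, inc, inc | exc)
    return {
        eid: (frozenset(inc), frozenset(tot)) for eid, (inc, tot) in found.items()
    }


class TestExtractEvents:
    def test_se_hand_enumeration(self):
        ann = TranscriptModelSet([
            tx("T1", [(101, 200), (301, 400), (501, 600)]),
            tx("T2", [(101, 200), (501, 600)]),
        ])
        events = splicing.extract_events(ann)
        assert len(events) == 1
        ev = events[0]
        assert ev.event_id == "SE:chr:200-301:400-501:+"
        assert ev.inclusion_isoforms == {"T1"}
        assert ev.total_isoforms == {"T1", "T2"}

    def test_ri_hand_enumeration(self):
        ann = TranscriptModelSet([
            tx("T1", [(101, 200), (301, 400)]),
            tx("T2", [(101, 400)]),
        ])
        events = splicing.extract_events(ann)
        assert len(events) == 1
        ev = events[0]
        assert ev.type == "RI"
        assert ev.inclusion_isoforms == {"T2"}  # intron-retaining form

    def test_transcript_order_invariance(self, small_bundle):
        ann, *_ = small_bundle
        rev = TranscriptModelSet(list(ann)[::-1])
        ev1 = [(e.event_id, e.inclusion_isoforms) for e in splicing.extract_events(ann)]
        ev2 = [(e.event_id, e.inclusion_isoforms) for e in splicing.extract_events(rev)]
        assert ev1 == ev2

    def test_single_isoform_gene_yields_nothing(self):
        ann = TranscriptModelSet([tx("T1", [(101, 200), (301, 400)])])
        assert splicing.extract_events(ann) == []

    def test_matches_pairwise_oracle_on_simulated_genes(self):
        cfg = simulate.SimulationConfig(
            seed=17, n_genes=100,
            isoforms_per_gene={2: 0.4, 3: 0.35, 4: 0.25},
        )
        ann = simulate.simulate_annotation(cfg)
        events = splicing.extract_events(ann)
        by_gene = {}
        for ev in events:
            by_gene.setdefault(ev.gene_id, {})[ev.event_id] = (
                ev.inclusion_isoforms, ev.total_isoforms)
        for gid in ann.gene_ids:
            txs = ann.gene_transcripts(gid)
            oracle = pairwise_event_oracle(txs) if len(txs) > 1 else {}
            assert by_gene.get(gid, {}) == oracle, gid

    def test_all_event_types_instantiable(self):
        planted = [
            simulate.PlantedDAS(f"G{i + 1:04d}", typ, 0.2)
            for i, typ in enumerate(splicing.EVENT_TYPES)
        ]
        cfg = simulate.SimulationConfig(seed=3, n_genes=8, planted_das=planted)
        ann = simulate.simulate_annotation(cfg)
        events = splicing.extract_events(ann)
        types_by_gene = {}
        for ev in events:
            types_by_gene.setdefault(ev.gene_id, set()).add(ev.type)
        for p in planted:
            assert p.event_type in types_by_gene[p.gene], p.event_type


class TestPSI:
    def _one_event(self):
        ann = TranscriptModelSet([
            tx("T1", [(101, 200), (301, 400), (501, 600)]),
            tx("T2", [(101, 200), (501, 600)]),
        ])
        return splicing.extract_events(ann)

    def test_tpm_ratio(self):
        events = self._one_event()
        tpm = pd.DataFrame({"c1": [30.0, 10.0]}, index=["T1", "T2"])
        psi = splicing.compute_psi(nm_from_tpm(tpm), events)
        assert psi.iloc[0, 0] == pytest.approx(0.75)

    def test_only_inclusion_expressed_gives_one(self):
        events = self._one_event()
        tpm = pd.DataFrame({"c1": [20.0, 0.0]}, index=["T1", "T2"])
        psi = splicing.compute_psi(nm_from_tpm(tpm), events)
        assert psi.iloc[0, 0] == 1.0

    def test_below_threshold_missing(self):
        events = self._one_event()
        tpm = pd.DataFrame({"c1": [0.3, 0.3]}, index=["T1", "T2"])
        psi = splicing.compute_psi(nm_from_tpm(tpm), events, min_total_tpm=1.0)
        assert np.isnan(psi.iloc[0, 0])

    def test_complement_symmetry(self, small_bundle, small_nm):
        ann, *_ = small_bundle
        events = splicing.extract_events(ann)
        flipped = [
            splicing.SplicingEvent(
                e.event_id, e.type, e.gene_id, e.chrom, e.strand,
                e.total_isoforms - e.inclusion_isoforms, e.total_isoforms)
            for e in events
        ]
        psi = splicing.compute_psi(small_nm, events)
        psi_f = splicing.compute_psi(small_nm, flipped)
        both = psi.notna() & psi_f.notna()
        assert np.allclose((psi + psi_f).values[both.values], 1.0)


class TestDifferentialSplicing:
    def test_identical_groups_not_significant(self, small_bundle, small_nm):
        ann, em, _, _ = small_bundle
        events = splicing.extract_events(ann)
        psi = splicing.compute_psi(small_nm, events)
        cells = list(psi.columns)
        tab = splicing.differential_splicing(psi, cells[:60], cells[:60],
                                             min_cells=5)
        assert (tab["dpsi"].dropna().abs() < 1e-12).all()
        assert not tab["significant"].any()

    def test_planted_dpsi_detected(self):
        cfg = simulate.SimulationConfig(
            seed=23, n_genes=5, n_cells_per_group={"normal": 40, "cancer": 40},
            planted_das=[simulate.PlantedDAS("G0001", "SE", 0.3, "cancer")],
        )
        ann, em, _, truth = simulate.simulate_bundle(cfg)
        nm = matrix.normalize_expression(em)
        events = splicing.extract_events(ann)
        psi = splicing.compute_psi(nm, events)
        meta = em.metadata
        tab = splicing.differential_splicing(
            psi,
            list(meta.index[meta["group"] == "cancer"]),
            list(meta.index[meta["group"] == "normal"]),
        )
        planted_events = [e for e in tab.index if e.startswith("SE")
                          and "G0001.inc" in _inclusion_of(events, e)]
        assert planted_events
        assert tab.loc[planted_events[0], "significant"]
        assert tab.loc[planted_events[0], "dpsi"] == pytest.approx(0.3, abs=0.1)

    def test_small_dpsi_excluded_despite_significance(self):
        rng = np.random.default_rng(5)
        cells_a = [f"a{i}" for i in range(300)]
        cells_b = [f"b{i}" for i in range(300)]
        psi = pd.DataFrame(
            [np.concatenate([
                np.clip(rng.normal(0.58, 0.05, 300), 0, 1),
                np.clip(rng.normal(0.50, 0.05, 300), 0, 1),
            ])],
            index=["SE:1:1-2:3-4:+"], columns=cells_a + cells_b,
        )
        tab = splicing.differential_splicing(psi, cells_a, cells_b)
        assert tab.iloc[0]["p"] < 0.05
        assert abs(tab.iloc[0]["dpsi"]) < 0.1
        assert not tab.iloc[0]["significant"]

    def test_min_cell_rule_reports_reason(self):
        psi = pd.DataFrame([[0.5] * 6], index=["SE:1:1-2:3-4:+"],
                           columns=[f"c{i}" for i in range(6)])
        tab = splicing.differential_splicing(psi, ["c0", "c1", "c2"],
                                             ["c3", "c4", "c5"])
        assert tab.iloc[0]["skipped"] == "too_few_cells"


def _inclusion_of(events, event_id):
    return next(e.inclusion_isoforms for e in events if e.event_id == event_id)


class TestSFCorrelation:
    def test_identical_vectors_r_one(self):
        cells = [f"c{i}" for i in range(30)]
        vec = np.linspace(0, 1, 30)
        psi = pd.DataFrame([vec, 1 - vec],
                           index=["SE:1:1-2:3-4:+", "RI:1:5:6-7:8:+"],
                           columns=cells)
        sf = NormalizedMatrix(
            tpm=pd.DataFrame([vec], index=["SF1"], columns=cells),
            logexpr=pd.DataFrame([vec], index=["SF1"], columns=cells),
            level="gene",
        )
        corr, labels, enrich = splicing.sf_psi_correlation(psi, sf, k=2)
        assert corr.loc["SE:1:1-2:3-4:+", "SF1"] == pytest.approx(1.0)
        assert corr.loc["RI:1:5:6-7:8:+", "SF1"] == pytest.approx(-1.0)
        assert labels.nunique() == 2

    def test_sign_structure_recovered_from_simulator(self):
        das = [simulate.PlantedDAS(f"G{i + 1:04d}", "SE", 0.0, "cancer")
               for i in range(10)]
        coupling = [
            simulate.PlantedSFCoupling("G0011", f"G{i + 1:04d}",
                                       +1 if i < 5 else -1)
            for i in range(10)
        ]
        cfg = simulate.SimulationConfig(
            seed=29, n_genes=12,
            n_cells_per_group={"normal": 150, "cancer": 150},
            planted_das=das, planted_sf_coupling=coupling,
        )
        ann, em, _, _ = simulate.simulate_bundle(cfg)
        nm = matrix.normalize_expression(em)
        events = splicing.extract_events(ann)
        psi = splicing.compute_psi(nm, events)
        nm_gene = matrix.normalize_expression(em, level="gene")
        sf = NormalizedMatrix(
            tpm=nm_gene.tpm.loc[["G0011"]],
            logexpr=nm_gene.logexpr.loc[["G0011"]], level="gene",
        )
        se_events = [e.event_id for e in events
                     if e.type == "SE" and e.gene_id in
                     {f"G{i + 1:04d}" for i in range(10)}]
        corr, labels, _ = splicing.sf_psi_correlation(
            psi.loc[psi.index.intersection(se_events)], sf, k=2)
        pos_genes = {f"G{i + 1:04d}" for i in range(5)}
        for eid in corr.index:
            gene = eid_gene(events, eid)
            r = corr.loc[eid, "G0011"]
            assert (r > 0.2) if gene in pos_genes else (r < -0.2), (eid, r)
        # clusters separate the positive from the negative program
        cl_pos = {labels[e] for e in corr.index if eid_gene(events, e) in pos_genes}
        cl_neg = {labels[e] for e in corr.index
                  if eid_gene(events, e) not in pos_genes}
        assert cl_pos.isdisjoint(cl_neg)

    def test_fisher_p_matches_exact_enumeration(self):
        # cluster RI counts 10/20 vs 1/30: two-sided Fisher by direct
        # hypergeometric mass summation
        table = [[10, 20], [1, 30]]
        _, p = stats.fisher_exact(table)
        N, K, n = 61, 11, 30
        probs = [comb(K, k, exact=True) * comb(N - K, n - k, exact=True)
                 / comb(N, n, exact=True) for k in range(0, min(K, n) + 1)]
        p_obs = probs[10]
        p_manual = sum(pr for pr in probs if pr <= p_obs * (1 + 1e-12))
        assert p == pytest.approx(p_manual, rel=1e-10)


def eid_gene(events, eid):
    return next(e.gene_id for e in events if e.event_id == eid)


class TestEventOverlap:
    def _das(self, dpsi_map):
        return pd.DataFrame({"dpsi": pd.Series(dpsi_map)})

    def test_empty_overlap_p_is_one(self):
        a = self._das({"e1": 0.3})
        b = self._das({"e2": 0.3})
        consistent, p = splicing.event_overlap(a, b, ["e1", "e2", "e3"])
        assert consistent == []
        assert p == pytest.approx(1.0)

    def test_hypergeometric_matches_exact_sum(self):
        universe = [f"e{i}" for i in range(100)]
        a = self._das({f"e{i}": 0.2 for i in range(10)})
        b = self._das({f"e{i}": 0.2 for i in list(range(5)) + list(range(50, 55))})
        consistent, p = splicing.event_overlap(a, b, universe)
        assert len(consistent) == 5
        exact = sum(
            comb(10, k, exact=True) * comb(90, 10 - k, exact=True)
            / comb(100, 10, exact=True)
            for k in range(5, 11)
        )
        assert p == pytest.approx(exact, rel=1e-10)

    def test_five_percent_rule_excludes_small_changes(self):
        a = self._das({"e1": 0.04, "e2": 0.2})
        b = self._das({"e1": 0.3, "e2": 0.3})
        consistent, _ = splicing.event_overlap(a, b, ["e1", "e2"])
        assert consistent == ["e2"]

    def test_rescue_mode_requires_opposite_signs(self):
        a = self._das({"e1": 0.3, "e2": 0.3})
        b = self._das({"e1": -0.2, "e2": 0.25})
        consistent, _ = splicing.event_overlap(a, b, ["e1", "e2"], rescue=True)
        assert consistent == ["e1"]

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            splicing.event_overlap(self._das({}), self._das({}), [])
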