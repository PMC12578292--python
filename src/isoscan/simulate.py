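"""Synthetic data generator with known planted effects.

Emits a transcript annotation, an isoform x cell negative-binomial count
matrix, and per-cell allelic read counts, together with a truth table of
every planted effect, so each downstream statistic has a ground-truth
recovery surface.

Planted effects and their encodings:

* APA shift: a two-isoform gene whose isoforms share the CDS but differ in
  3'-UTR length by ``2*|delta_utr3|``; isoform proportions move from
  (0.25, 0.75) to (0.75, 0.25) short/long in the affected group, so the
  expected expression-weighted UTR-length difference equals ``delta_utr3``.
* Differential splicing: a gene instantiating the requested local event
  type; inclusion-isoform proportion is ``0.5 + dpsi/2`` in the affected
  group and ``0.5 - dpsi/2`` elsewhere.
* DTU switch: per-group isoform proportion vectors taken verbatim from the
  config.
* Splicing-factor coupling: a latent per-cell factor moves both the SF
  gene's expected expression and the coupled event's per-cell inclusion
  proportion, with the configured sign.
* Mutant subclone: a fraction of cancer cells carry each mutation site;
  reads are misread with probability ``error_rate``, split 1/3 to the
  mutant base and 2/3 to the two remaining bases.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .models import ExpressionMatrix, TranscriptModel, TranscriptModelSet, site_key
from . import readwrite

AS_TYPES = ("SE", "RI", "A5", "A3", "AF", "AL", "MX")

#: default isoform-count distribution: roughly half of genes multi-isoform
DEFAULT_ISOFORM_DIST = {1: 0.49, 2: 0.25, 3: 0.13, 4: 0.08, 5: 0.03, 6: 0.02}


@dataclass
class PlantedAPA:
    gene: str
    delta_utr3: float  # expected EUL change in the affected group, bp (signed)
    group: str = "cancer"


@dataclass
class PlantedDAS:
    gene: str
    event_type: str  # one of AS_TYPES
    delta_psi: float  # PSI(affected) - PSI(other groups), in [-1, 1]
    group: str = "cancer"


@dataclass
class PlantedDTU:
    gene: str
    proportions: dict[str, tuple]  # group -> isoform proportion vector


@dataclass
class PlantedSFCoupling:
    sf_gene: str
    das_gene: str  # must also appear in planted_das
    sign: int  # +1 or -1


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 50
    isoforms_per_gene: dict = field(default_factory=lambda: dict(DEFAULT_ISOFORM_DIST))
    n_cells_per_group: dict = field(
        default_factory=lambda: {"normal": 200, "cancer": 200}
    )
    n_patients: int = 4
    n_batches: int = 2
    library_size_meanlog: float = np.log(10_000.0)
    library_size_sdlog: float = 0.3
    nb_dispersion: float = 0.3  # variance = mu * (1 + dispersion * mu)
    batch_effect_sdlog: float = 0.1
    planted_apa: list = field(default_factory=list)
    planted_das: list = field(default_factory=list)
    planted_dtu: list = field(default_factory=list)
    planted_sf_coupling: list = field(default_factory=list)
    n_mutation_sites: int = 0
    error_rate: float = 0.02
    mutant_cell_fraction: float = 0.8
    mutant_allele_fraction: float = 0.5
    coverage_mean: float = 10.0
    coverage_dropout: float = 0.3

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_patients < 1 or self.n_batches < 1:
            raise ValueError("counts must be >= 1")
        if any(n < 1 for n in self.n_cells_per_group.values()):
            raise ValueError("each group needs >= 1 cell")
        total = sum(self.isoforms_per_gene.values())
        if not np.isclose(total, 1.0):
            raise ValueError("isoforms_per_gene must sum to 1")
        for frac in (self.mutant_cell_fraction, self.mutant_allele_fraction,
                     self.error_rate, self.coverage_dropout):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for p in self.planted_das:
            if not -1.0 <= p.delta_psi <= 1.0:
                raise ValueError("delta_psi must lie in [-1, 1]")
            if p.event_type not in AS_TYPES:
                raise ValueError(f"unknown event type {p.event_type}")
        for p in self.planted_dtu:
            for vec in p.proportions.values():
                if not np.isclose(sum(vec), 1.0):
                    raise ValueError(f"{p.gene}: proportions must sum to 1")

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass
class TruthTable:
    """Planted effects as emitted: what is true in this simulation."""

    apa: list = field(default_factory=list)
    das: list = field(default_factory=list)
    dtu: list = field(default_factory=list)
    sf_coupling: list = field(default_factory=list)
    mutations: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True) + "\n"
        )


# ------------------------------------------------------------- annotation

def _intersect_span(exons, lo, hi):
    """Genomic intersection of an interval span with an exon chain."""
    out = []
    for (a, b) in exons:
        s, e = max(a, lo), min(b, hi)
        if s <= e:
            out.append((s, e))
    return out


class _GeneBuilder:
    """Builds one gene's isoforms from a base exon chain plus variants."""

    def __init__(self, gene_id: str, start: int, rng: np.random.Generator,
                 n_exons: int = 6, strand: str = "+"):
        self.gene_id = gene_id
        self.rng = rng
        self.strand = strand
        lens = rng.integers(120, 280, size=n_exons)
        gaps = rng.integers(400, 1500, size=n_exons - 1)
        pos = start
        self.chain: list[tuple[int, int]] = []
        for i, L in enumerate(lens):
            self.chain.append((pos, pos + int(L) - 1))
            if i < n_exons - 1:
                pos += int(L) + int(gaps[i])
        # CDS spans from inside the first exon to inside the last exon,
        # leaving a 5'UTR and a generous 3'UTR for APA variants
        self.utr5 = int(rng.integers(40, 80))
        self.utr3 = int(rng.integers(200, 260))
        self.cds_lo = self.chain[0][0] + self.utr5
        self.cds_hi = self.chain[-1][1] - self.utr3
        self.end = self.chain[-1][1]

    def transcript(self, tid: str, exons, cds_lo=None, cds_hi=None) -> TranscriptModel:
        lo = self.cds_lo if cds_lo is None else cds_lo
        hi = self.cds_hi if cds_hi is None else cds_hi
        return TranscriptModel(
            transcript_id=tid, gene_id=self.gene_id, chrom="1",
            strand=self.strand, exons=list(exons),
            cds=_intersect_span(exons, lo, hi),
        )

    # each variant returns a distinct exon chain derived from the base
    def variant_exons(self, kind: str, alt: bool = False):
        ch = self.chain
        mid = len(ch) // 2
        if kind == "full":
            return list(ch)
        if kind == "SE":  # drop an internal exon
            return ch[:mid] + ch[mid + 1:]
        if kind == "SE2":  # drop a different internal exon
            return ch[:mid - 1] + ch[mid:]
        if kind == "RI":  # merge two exons, retaining the intron
            return ch[:mid] + [(ch[mid][0], ch[mid + 1][1])] + ch[mid + 2:]
        if kind == "A5":  # move an internal donor site (shorter exon end)
            d = 60
            e = ch[mid]
            return ch[:mid] + [(e[0], e[1] - d)] + ch[mid + 1:]
        if kind == "A3":  # move an internal acceptor site
            d = 60
            e = ch[mid]
            return ch[:mid] + [(e[0] + d, e[1])] + ch[mid + 1:]
        if kind == "AF":  # alternative first exon inside intron 1
            gap_lo, gap_hi = ch[0][1] + 1, ch[1][0] - 1
            alt_exon = (gap_lo + 80, min(gap_lo + 200, gap_hi - 80))
            return [alt_exon] + ch[1:]
        if kind == "AL":  # alternative last exon inside the final intron
            gap_lo, gap_hi = ch[-2][1] + 1, ch[-1][0] - 1
            alt_exon = (max(gap_lo + 80, gap_hi - 200), gap_hi - 80)
            return ch[:-1] + [alt_exon]
        if kind == "MX":  # alternative middle exon inside the next intron
            gap_lo, gap_hi = ch[mid][1] + 1, ch[mid + 1][0] - 1
            alt_exon = (gap_lo + 120, min(gap_lo + 240, gap_hi - 120))
            return ch[:mid] + [alt_exon] + ch[mid + 1:]
        raise ValueError(f"unknown variant kind {kind}")


_GENERIC_VARIANTS = ["SE", "RI", "A5", "A3", "AF", "AL", "SE2"]


def simulate_annotation(config: SimulationConfig) -> TranscriptModelSet:
    """Generate a deterministic annotation honouring every planted template.

    Genes named in planted effects receive the structure their effect
    requires (APA: shared-CDS isoform pair differing only in 3'-UTR; DAS:
    the requested event type; DTU: as many structurally distinct isoforms
    as the proportion vectors are long).  Remaining genes draw an isoform
    count from ``isoforms_per_gene`` and random structural variants.
    """
    rng = np.random.default_rng([config.seed, 1])
    gene_ids = config.gene_ids()
    known = set(gene_ids)
    roles: dict[str, tuple] = {}
    for p in config.planted_apa:
        _require_known(p.gene, known, "planted_apa")
        roles[p.gene] = ("apa", p)
    for p in config.planted_das:
        _require_known(p.gene, known, "planted_das")
        if p.gene in roles:
            raise ValueError(f"{p.gene} assigned two planted roles")
        roles[p.gene] = ("das", p)
    for p in config.planted_dtu:
        _require_known(p.gene, known, "planted_dtu")
        if p.gene in roles:
            raise ValueError(f"{p.gene} assigned two planted roles")
        roles[p.gene] = ("dtu", p)

    max_k = max(k for k, w in config.isoforms_per_gene.items() if w > 0)
    if max_k > 1 + len(_GENERIC_VARIANTS):
        raise ValueError(
            f"isoforms_per_gene requests {max_k} distinct structures; the "
            f"exon template supports at most {1 + len(_GENERIC_VARIANTS)}"
        )

    ks = list(config.isoforms_per_gene)
    ws = np.array([config.isoforms_per_gene[k] for k in ks], dtype=float)
    models: list[TranscriptModel] = []
    cursor = 10_000
    for gid in gene_ids:
        rng_g = np.random.default_rng([config.seed, 1, int(gid[1:])])
        builder = _GeneBuilder(gid, cursor, rng_g)
        role = roles.get(gid, (None,))[0]
        if role == "apa":
            p = roles[gid][1]
            d = int(round(2 * abs(p.delta_utr3)))
            if d >= builder.utr3 - 20:
                builder.utr3 = d + 60
                builder.cds_hi = builder.chain[-1][1] - builder.utr3
            long_ex = list(builder.chain)
            short_ex = builder.chain[:-1] + [
                (builder.chain[-1][0], builder.chain[-1][1] - d)
            ]
            models.append(builder.transcript(f"{gid}.long", long_ex))
            models.append(builder.transcript(f"{gid}.short", short_ex))
        elif role == "das":
            p = roles[gid][1]
            if p.event_type == "MX":
                ex_a = builder.variant_exons("full")
                ex_b = builder.variant_exons("MX")
            elif p.event_type in {"SE", "RI"}:
                # inclusion form carries the extra sequence
                ex_a = (builder.variant_exons("RI") if p.event_type == "RI"
                        else builder.variant_exons("full"))
                ex_b = (builder.variant_exons("full") if p.event_type == "RI"
                        else builder.variant_exons("SE"))
            else:
                ex_a = builder.variant_exons("full")
                ex_b = builder.variant_exons(p.event_type)
            models.append(builder.transcript(f"{gid}.inc", ex_a))
            models.append(builder.transcript(f"{gid}.exc", ex_b))
        elif role == "dtu":
            p = roles[gid][1]
            k = len(next(iter(p.proportions.values())))
            for vec in p.proportions.values():
                if len(vec) != k:
                    raise ValueError(f"{gid}: ragged proportion vectors")
            if k > 1 + len(_GENERIC_VARIANTS):
                raise ValueError(f"{gid}: too many isoforms requested")
            kinds = ["full"] + _GENERIC_VARIANTS[: k - 1]
            for j, kind in enumerate(kinds):
                models.append(
                    builder.transcript(f"{gid}.t{j + 1}", builder.variant_exons(kind))
                )
        else:
            k = int(rng.choice(ks, p=ws / ws.sum()))
            kinds = ["full"] + list(
                rng.choice(_GENERIC_VARIANTS, size=k - 1, replace=False)
            )
            for j, kind in enumerate(kinds):
                models.append(
                    builder.transcript(f"{gid}.t{j + 1}", builder.variant_exons(kind))
                )
        cursor = builder.end + int(rng_g.integers(5_000, 10_000))

    # transcripts of the same CDS share a CCDS id within each gene
    by_cds: dict[tuple, str] = {}
    for t in models:
        if t.cds:
            key = (t.gene_id, tuple(t.cds))
            if key not in by_cds:
                by_cds[key] = f"CCDS{len(by_cds) + 1:05d}"
            t.ccds_id = by_cds[key]
    return TranscriptModelSet(models)


def _require_known(gene: str, known: set, what: str) -> None:
    if gene not in known:
        raise ValueError(f"{what}: gene {gene} not in simulated gene set")


# ------------------------------------------------------------- expression

def make_cell_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Cell table: group-blocked ids, patients round-robin, batch by patient."""
    rows = []
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    batches = [f"batch{(i % config.n_batches) + 1}" for i in range(config.n_patients)]
    for group, n in config.n_cells_per_group.items():
        for i in range(n):
            pi = i % config.n_patients
            rows.append(
                {
                    "cell_id": f"{group}_{i:04d}",
                    "patient": patients[pi],
                    "batch": batches[pi],
                    "tissue": "tumor" if group != "normal" else "normal",
                    "group": group,
                    "cell_type": "stem_TA" if group == "normal" else "stem_TA_like",
                }
            )
    return pd.DataFrame(rows).set_index("cell_id")


def simulate_expression(
    config: SimulationConfig, annotation: TranscriptModelSet
) -> tuple[ExpressionMatrix, TruthTable]:
    """Negative-binomial isoform counts around group-wise expected proportions."""
    rng = np.random.default_rng([config.seed, 2])
    meta = make_cell_metadata(config)
    cells = list(meta.index)
    n_cells = len(cells)
    groups = meta["group"].values
    batch_names = sorted(meta["batch"].unique())

    iso_ids, iso_gene = [], []
    for gid in annotation.gene_ids:
        for t in annotation.gene_transcripts(gid):
            iso_ids.append(t.transcript_id)
            iso_gene.append(gid)
    iso_gene = np.array(iso_gene)
    gene_ids = annotation.gene_ids
    for p in list(config.planted_apa) + list(config.planted_das):
        if p.gene not in annotation.genes:
            raise ValueError(f"planted gene {p.gene} absent from annotation")
    for p in config.planted_dtu:
        if p.gene not in annotation.genes:
            raise ValueError(f"planted gene {p.gene} absent from annotation")

    truth = TruthTable()
    das_by_gene = {p.gene: p for p in config.planted_das}
    apa_by_gene = {p.gene: p for p in config.planted_apa}
    dtu_by_gene = {p.gene: p for p in config.planted_dtu}
    coupled = {c.das_gene: c for c in config.planted_sf_coupling}
    for c in config.planted_sf_coupling:
        if c.das_gene not in das_by_gene:
            raise ValueError(f"sf coupling references unplanted event gene {c.das_gene}")
        if c.sf_gene not in annotation.genes:
            raise ValueError(f"sf gene {c.sf_gene} absent from annotation")

    # latent per-cell factors for SF-coupled events
    latents = {
        c.sf_gene: rng.standard_normal(n_cells) for c in config.planted_sf_coupling
    }

    # per-gene baseline abundance and batch factors
    base_abund = pd.Series(
        np.exp(rng.normal(0.0, 0.8, size=len(gene_ids))), index=gene_ids
    )
    batch_fac = pd.DataFrame(
        np.exp(rng.normal(0.0, config.batch_effect_sdlog,
                          size=(len(gene_ids), len(batch_names)))),
        index=gene_ids, columns=batch_names,
    )

    # isoform proportion matrix (iso x cell); default: fixed per-gene vector
    prop = np.zeros((len(iso_ids), n_cells))
    pos = 0
    for gid in gene_ids:
        txs = annotation.gene_transcripts(gid)
        k = len(txs)
        sl = slice(pos, pos + k)
        if gid in dtu_by_gene:
            p = dtu_by_gene[gid]
            for g in np.unique(groups):
                vec = p.proportions.get(g)
                if vec is None:
                    vec = next(iter(p.proportions.values()))
                prop[sl, groups == g] = np.asarray(vec)[:, None]
            truth.dtu.append(
                {
                    "gene": gid,
                    "isoforms": [t.transcript_id for t in txs],
                    "proportions": {g: list(map(float, v))
                                    for g, v in p.proportions.items()},
                }
            )
        elif gid in apa_by_gene:
            p = apa_by_gene[gid]
            # row order follows transcript-id sort: .long before .short
            long_row, short_row = pos, pos + 1
            p_short = np.where(groups == p.group,
                               0.75 if p.delta_utr3 < 0 else 0.25,
                               0.25 if p.delta_utr3 < 0 else 0.75)
            prop[short_row] = p_short
            prop[long_row] = 1.0 - p_short
            utr_l = txs[0].utr3_len
            utr_s = txs[1].utr3_len
            truth.apa.append(
                {
                    "gene": gid, "group": p.group,
                    "delta_eul": float(p.delta_utr3),
                    "utr3_long": utr_l, "utr3_short": utr_s,
                }
            )
        elif gid in das_by_gene:
            p = das_by_gene[gid]
            exc_row, inc_row = pos, pos + 1  # ".exc" sorts before ".inc"
            p_inc = np.where(groups == p.group, 0.5 + p.delta_psi / 2,
                             0.5 - p.delta_psi / 2)
            if gid in coupled:
                c = coupled[gid]
                p_inc = np.clip(p_inc + 0.15 * c.sign * latents[c.sf_gene],
                                0.02, 0.98)
            prop[inc_row] = p_inc
            prop[exc_row] = 1.0 - p_inc
            truth.das.append(
                {
                    "gene": gid, "event_type": p.event_type, "group": p.group,
                    "delta_psi": float(p.delta_psi),
                    "inclusion_isoform": f"{gid}.inc",
                }
            )
        else:
            vec = rng.dirichlet(np.full(k, 5.0)) if k > 1 else np.ones(1)
            prop[sl] = vec[:, None]
        pos += k

    for c in config.planted_sf_coupling:
        truth.sf_coupling.append(
            {"sf_gene": c.sf_gene, "das_gene": c.das_gene, "sign": int(c.sign)}
        )

    # expected per-cell gene weights -> isoform means scaled to library size
    lib = np.exp(
        rng.normal(config.library_size_meanlog, config.library_size_sdlog, n_cells)
    )
    gene_w = np.empty((len(gene_ids), n_cells))
    for gi, gid in enumerate(gene_ids):
        w = base_abund[gid] * batch_fac.loc[gid, meta["batch"].values].values
        for c in config.planted_sf_coupling:
            if c.sf_gene == gid:
                w = w * np.exp(0.4 * latents[c.sf_gene])
        gene_w[gi] = w
    gene_w /= gene_w.sum(axis=0, keepdims=True)
    gene_row = {g: i for i, g in enumerate(gene_ids)}
    mu = prop * gene_w[[gene_row[g] for g in iso_gene], :] * lib[None, :]

    phi = config.nb_dispersion
    if phi > 0:
        size = 1.0 / phi
        counts = rng.negative_binomial(size, size / (size + np.maximum(mu, 1e-12)))
        counts[mu <= 0] = 0
    else:
        counts = rng.poisson(mu)

    em = ExpressionMatrix(
        counts, iso_ids, cells, pd.Series(iso_gene, index=iso_ids), meta
    )
    return em, truth


# ---------------------------------------------------------- allelic counts

def simulate_allelic_counts(
    config: SimulationConfig, cells: pd.DataFrame
) -> tuple["AllelicCounts", TruthTable]:
    """Per-site per-cell (wt, mut, other) read counts with a mutant subclone.

    Non-carrier cells produce mutant reads only through the misread
    process: each read is misread with probability ``error_rate``, landing
    on the mutant base with probability ``error_rate/3`` and on the two
    remaining bases with ``2*error_rate/3``.
    """
    from .models import AllelicCounts

    rng = np.random.default_rng([config.seed, 3])
    cancer_cells = cells.index[cells["group"] != "normal"]
    if config.n_mutation_sites > 0 and config.mutant_cell_fraction > 0 and not len(cancer_cells):
        raise ValueError("mutant_cell_fraction > 0 requires cancer cells")

    bases = np.array(list("ACGT"))
    gene_pool = config.gene_ids()
    recs, truth = [], TruthTable()
    n_cells = len(cells)
    shape = (config.n_mutation_sites, n_cells)
    c_wt = np.zeros(shape, dtype=np.int64)
    c_mut = np.zeros(shape, dtype=np.int64)
    c_other = np.zeros(shape, dtype=np.int64)

    eps, maf = config.error_rate, config.mutant_allele_fraction
    p_noncar = [1 - eps, eps / 3, 2 * eps / 3]
    p_car = [
        (1 - maf) * (1 - eps) + maf * eps / 3,
        maf * (1 - eps) + (1 - maf) * eps / 3,
        2 * eps / 3,
    ]
    cancer_mask = (cells["group"] != "normal").values

    for s in range(config.n_mutation_sites):
        gene = gene_pool[int(rng.integers(len(gene_pool)))]
        pos = int(rng.integers(10_000, 5_000_000))
        ref, alt = rng.choice(bases, size=2, replace=False)
        sid = site_key("1", pos, ref, alt)
        n_car = int(round(config.mutant_cell_fraction * len(cancer_cells)))
        car_idx = rng.choice(np.flatnonzero(cancer_mask), size=n_car, replace=False) \
            if n_car else np.array([], dtype=int)
        is_car = np.zeros(n_cells, dtype=bool)
        is_car[car_idx] = True
        covered = rng.random(n_cells) >= config.coverage_dropout
        depth = rng.poisson(config.coverage_mean, size=n_cells) * covered
        for j in range(n_cells):
            if depth[j] == 0:
                continue
            probs = p_car if is_car[j] else p_noncar
            w, m, o = rng.multinomial(depth[j], probs)
            c_wt[s, j], c_mut[s, j], c_other[s, j] = w, m, o
        recs.append({"site_id": sid, "chrom": "1", "pos": pos,
                     "ref": str(ref), "alt": str(alt), "gene_id": gene})
        truth.mutations.append(
            {
                "site_id": sid, "gene": gene,
                "carrier_cells": sorted(cells.index[car_idx].tolist()),
            }
        )

    sites = pd.DataFrame(recs).set_index("site_id") if recs else pd.DataFrame(
        columns=["chrom", "pos", "ref", "alt", "gene_id"]
    )
    ac = AllelicCounts(sites, list(cells.index), c_wt, c_mut, c_other)
    return ac, truth


# ------------------------------------------------------------------ bundle

def merge_truth(*tables: TruthTable) -> TruthTable:
    out = TruthTable()
    for t in tables:
        out.apa += t.apa
        out.das += t.das
        out.dtu += t.dtu
        out.sf_coupling += t.sf_coupling
        out.mutations += t.mutations
    return out


def simulate_bundle(config: SimulationConfig):
    """Run all three generators; returns (annotation, expr, allelic, truth)."""
    ann = simulate_annotation(config)
    em, t1 = simulate_expression(config, ann)
    ac, t2 = simulate_allelic_counts(config, em.metadata)
    return ann, em, ac, merge_truth(t1, t2)


def write_fixture_bundle(
    annotation: TranscriptModelSet,
    expr: ExpressionMatrix,
    allelic,
    truth: TruthTable,
    directory: str | Path,
) -> dict[str, Path]:
    """Emit GTF, MTX(+index TSVs), dense TSV, metadata, VCF, allele counts,
    truth JSON.  Round-trips losslessly through the readwrite readers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": directory / "annotation.gtf",
        "mtx": directory / "counts.mtx",
        "features": directory / "counts.features.tsv",
        "cells": directory / "counts.cells.tsv",
        "dense": directory / "counts.dense.tsv",
        "metadata": directory / "cell_metadata.tsv",
        "vcf": directory / "sites.vcf",
        "allele_counts": directory / "allele_counts.tsv",
        "truth": directory / "truth.json",
    }
    try:
        readwrite.write_gtf(annotation, paths["gtf"])
        readwrite.write_counts_mtx(expr, directory, prefix="counts")
        readwrite.write_counts_dense(expr, paths["dense"])
        readwrite.write_cell_metadata(expr, paths["metadata"])
        readwrite.write_vcf(allelic.sites, paths["vcf"])
        readwrite.write_allele_counts(allelic, paths["allele_counts"])
        truth.to_json(paths["truth"])
    except OSError as exc:
        raise OSError(f"writing fixture bundle under {directory}: {exc}") from exc
    return paths
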