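"""Readers and writers for the standard formats the pipeline touches.

GTF (Ensembl dialect) via gffutils; Matrix Market triplets via scipy.io;
minimal VCF v4 via cyvcf2 on the read side.  All coordinates are 1-based
inclusive after parsing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

import gffutils
from cyvcf2 import VCF

from .models import (
    AllelicCounts,
    ExpressionMatrix,
    TranscriptModel,
    TranscriptModelSet,
    site_key,
)

log = logging.getLogger("isoscan")


# ---------------------------------------------------------------- annotation

def read_annotation(path: str | Path) -> TranscriptModelSet:
    """Parse a GTF into transcript models with derived UTR lengths.

    Requires exon features (CDS optional) carrying gene_id/transcript_id
    attributes.  Transcripts without CDS get undefined UTR lengths and are
    excluded from UTR analyses downstream.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in {"exon", "CDS"}:
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise ValueError(
                f"{path}: {feat.featuretype} feature missing {exc} "
                f"attribute near {feat.seqid}:{feat.start}"
            ) from None
        rec = per_tx.setdefault(
            tid,
            {
                "gene_id": gid,
                "chrom": feat.seqid,
                "strand": feat.strand,
                "exons": [],
                "cds": [],
                "ccds_id": None,
            },
        )
        if feat.featuretype == "exon":
            rec["exons"].append((feat.start, feat.end))
        else:
            rec["cds"].append((feat.start, feat.end))
        if "ccds_id" in feat.attributes:
            rec["ccds_id"] = feat.attributes["ccds_id"][0]

    models = []
    for tid, rec in per_tx.items():
        if not rec["exons"]:
            raise ValueError(f"transcript {tid} has CDS but no exons")
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=rec["exons"],
                cds=rec["cds"],
                ccds_id=rec["ccds_id"],
            )
        )
    mset = TranscriptModelSet(models)
    n_noncoding = sum(1 for t in mset if not t.is_coding)
    if n_noncoding:
        log.info("read_annotation: %d transcripts without CDS (UTRs undefined)",
                 n_noncoding)
    return mset


def write_gtf(mset: TranscriptModelSet, path: str | Path) -> None:
    """Write transcript models as Ensembl-style GTF (exon + CDS features)."""
    with open(path, "w") as fh:
        fh.write("#!genome-version synthetic\n")
        for t in mset:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            if t.ccds_id:
                attrs += f' ccds_id "{t.ccds_id}";'
            fh.write(
                f"{t.chrom}\tisoscan\ttranscript\t{t.exons[0][0]}\t"
                f"{t.exons[-1][1]}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for (a, b) in t.exons:
                fh.write(
                    f"{t.chrom}\tisoscan\texon\t{a}\t{b}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            for (a, b) in t.cds:
                fh.write(
                    f"{t.chrom}\tisoscan\tCDS\t{a}\t{b}\t.\t{t.strand}\t0\t{attrs}\n"
                )


# ------------------------------------------------------------------- counts

def read_counts(
    matrix_path: str | Path,
    metadata_path: str | Path,
    features_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    gene_map_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Load an isoform x cell count matrix plus cell metadata.

    ``matrix_path`` is either a Matrix Market .mtx (then ``features_path``
    and ``cells_path`` TSVs are required) or a dense TSV with feature rows,
    cell columns, and a leading ``feature_id`` + ``gene_id`` column pair.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        counts = sp.csr_matrix(scipy.io.mmread(matrix_path))
        feats = pd.read_csv(features_path, sep="\t")
        cells = pd.read_csv(cells_path, sep="\t", header=None)[0].astype(str).tolist()
        feature_ids = feats["feature_id"].astype(str).tolist()
        gene_map = pd.Series(feats["gene_id"].values, index=feature_ids)
    else:
        dense = pd.read_csv(matrix_path, sep="\t")
        feature_ids = dense["feature_id"].astype(str).tolist()
        gene_map = pd.Series(dense["gene_id"].values, index=feature_ids)
        body = dense.drop(columns=["feature_id", "gene_id"])
        cells = list(body.columns)
        counts = sp.csr_matrix(body.values)
    if (counts.data < 0).any() or not np.allclose(counts.data, np.round(counts.data)):
        raise ValueError("count matrix must contain non-negative integers")
    meta = pd.read_csv(metadata_path, sep="\t", index_col="cell_id")
    meta.index = meta.index.astype(str)
    missing = [c for c in cells if c not in meta.index]
    if missing:
        raise ValueError(f"cells missing from metadata: {missing}")
    return ExpressionMatrix(counts, feature_ids, cells, gene_map, meta)


def write_counts_mtx(m: ExpressionMatrix, directory: str | Path, prefix: str = "counts") -> None:
    directory = Path(directory)
    scipy.io.mmwrite(str(directory / f"{prefix}.mtx"), sp.coo_matrix(m.counts))
    pd.DataFrame(
        {"feature_id": m.feature_ids, "gene_id": m.feature_genes.values}
    ).to_csv(directory / f"{prefix}.features.tsv", sep="\t", index=False)
    with open(directory / f"{prefix}.cells.tsv", "w") as fh:
        fh.write("\n".join(m.cell_ids) + "\n")


def write_counts_dense(m: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.dense(), index=m.feature_ids, columns=m.cell_ids)
    df.insert(0, "gene_id", m.feature_genes.values)
    df.insert(0, "feature_id", m.feature_ids)
    df.to_csv(path, sep="\t", index=False)


def write_cell_metadata(m: ExpressionMatrix, path: str | Path) -> None:
    meta = m.metadata.copy()
    meta.index.name = "cell_id"
    meta.to_csv(path, sep="\t")


# ---------------------------------------------------------------- mutations

def write_vcf(sites: pd.DataFrame, path: str | Path) -> None:
    """Write mutation sites as a minimal VCF v4.2 (CHROM/POS/ID/REF/ALT)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for sid, row in sites.iterrows():
            filt = row.get("filter", "PASS")
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{sid}\t{row['ref']}\t"
                f"{row['alt']}\t.\t{filt}\tGENE={row['gene_id']}\n"
            )


def write_allele_counts(ac: AllelicCounts, path: str | Path) -> None:
    rows = []
    for i, sid in enumerate(ac.site_ids):
        for j, cell in enumerate(ac.cell_ids):
            tot = ac.c_wt[i, j] + ac.c_mut[i, j] + ac.c_other[i, j]
            if tot == 0:
                continue
            rows.append((sid, cell, ac.c_wt[i, j], ac.c_mut[i, j], ac.c_other[i, j]))
    pd.DataFrame(rows, columns=["site_id", "cell_id", "c_wt", "c_mut", "c_other"]).to_csv(
        path, sep="\t", index=False
    )


def read_mutation_inputs(
    vcf_path: str | Path,
    counts_path: str | Path,
    cell_ids: list[str],
    pass_only: bool = False,
) -> AllelicCounts:
    """Assemble per-site per-cell allele counts from a VCF plus a count TSV.

    Sites present in the VCF but absent from the count table get all-zero
    rows (uncovered); count rows for unknown sites raise.  With
    ``pass_only`` non-PASS records are dropped and the number removed is
    logged.
    """
    recs = []
    n_dropped = 0
    for var in VCF(str(vcf_path)):
        # cyvcf2 reports FILTER None for PASS / '.'
        if pass_only and var.FILTER is not None:
            n_dropped += 1
            continue
        alt = var.ALT[0] if var.ALT else "."
        gene = var.INFO.get("GENE", "")
        recs.append(
            (site_key(var.CHROM, var.POS, var.REF, alt),
             var.CHROM, var.POS, var.REF, alt, gene)
        )
    if n_dropped:
        log.info("read_mutation_inputs: dropped %d non-PASS records", n_dropped)
    sites = pd.DataFrame(
        recs, columns=["site_id", "chrom", "pos", "ref", "alt", "gene_id"]
    ).set_index("site_id")
    if sites.index.duplicated().any():
        raise ValueError("duplicate sites in VCF")

    tab = pd.read_csv(counts_path, sep="\t", dtype={"cell_id": str})
    if tab.duplicated(subset=["site_id", "cell_id"]).any():
        dups = tab[tab.duplicated(subset=["site_id", "cell_id"])]
        raise ValueError(f"duplicate (site, cell) rows: {dups.iloc[0].tolist()}")
    unknown = set(tab["site_id"]) - set(sites.index)
    if unknown:
        raise ValueError(f"counts reference unknown sites: {sorted(unknown)[:5]}")

    site_pos = {s: i for i, s in enumerate(sites.index)}
    cell_pos = {c: j for j, c in enumerate(cell_ids)}
    unknown_cells = set(tab["cell_id"]) - set(cell_pos)
    if unknown_cells:
        raise ValueError(f"counts reference unknown cells: {sorted(unknown_cells)[:5]}")
    shape = (len(sites), len(cell_ids))
    c_wt = np.zeros(shape, dtype=np.int64)
    c_mut = np.zeros(shape, dtype=np.int64)
    c_other = np.zeros(shape, dtype=np.int64)
    for row in tab.itertuples(index=False):
        i, j = site_pos[row.site_id], cell_pos[row.cell_id]
        c_wt[i, j] = row.c_wt
        c_mut[i, j] = row.c_mut
        c_other[i, j] = row.c_other
    return AllelicCounts(sites, list(cell_ids), c_wt, c_mut, c_other)


def pileup_allelic_counts(
    bam_paths: dict[str, str | Path],
    sites: pd.DataFrame,
    min_base_quality: int = 13,
) -> AllelicCounts:
    """Optional adapter: build allelic counts by piling up one aligned BAM
    per cell at the given mutation sites.

    ``bam_paths`` maps cell id to a genome-aligned BAM (one file per cell,
    as in plate-based long-read protocols); ``sites`` is indexed by site id
    with columns chrom/pos/ref/alt.  For substitutions a read counts as
    mut only on an exact alt base match at POS; deletions or other
    non-matching bases count as other.  This adapter is convenience I/O
    around pysam and is not part of the statistically tested surface.
    """
    import pysam

    cell_ids = sorted(bam_paths)
    shape = (len(sites), len(cell_ids))
    c_wt = np.zeros(shape, dtype=np.int64)
    c_mut = np.zeros(shape, dtype=np.int64)
    c_other = np.zeros(shape, dtype=np.int64)
    for j, cell in enumerate(cell_ids):
        with pysam.AlignmentFile(str(bam_paths[cell]), "rb") as bam:
            for i, (sid, row) in enumerate(sites.iterrows()):
                for col in bam.pileup(row["chrom"], row["pos"] - 1, row["pos"],
                                      truncate=True,
                                      min_base_quality=min_base_quality):
                    for read in col.pileups:
                        if read.is_del or read.is_refskip or \
                                read.query_position is None:
                            c_other[i, j] += 1
                            continue
                        base = read.alignment.query_sequence[read.query_position]
                        if base == row["ref"]:
                            c_wt[i, j] += 1
                        elif base == row["alt"]:
                            c_mut[i, j] += 1
                        else:
                            c_other[i, j] += 1
    return AllelicCounts(sites, cell_ids, c_wt, c_mut, c_other)


# -------------------------------------------------------------- gene lists

def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and # comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
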