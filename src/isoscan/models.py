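"""Core in-memory containers shared across the pipeline.

Coordinates are 1-based inclusive genomic intervals everywhere (GTF
convention); transcript-relative coordinates, where used, are 1-based as
well.  Count matrices are feature x cell with non-negative integer entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

Interval = tuple[int, int]


def _interval_len(iv: Interval) -> int:
    return iv[1] - iv[0] + 1


@dataclass
class TranscriptModel:
    """Exon/CDS structure of a single transcript isoform.

    Exons are sorted by genomic start and non-overlapping.  UTR lengths are
    derived from the exonic bases outside the CDS, oriented by strand:
    the 5' UTR is upstream of the CDS in transcript orientation and the
    3' UTR downstream.  Transcripts without a CDS have undefined UTRs
    (``utr3_len``/``utr5_len`` are ``None``).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    ccds_id: str | None = None

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        self.cds = sorted((int(a), int(b)) for a, b in self.cds)
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        for (a, b) in self.exons:
            if a > b:
                raise ValueError(f"{self.transcript_id}: exon start > end")
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur[0] <= prev[1]:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.cds and not self._cds_within_exons():
            raise ValueError(f"{self.transcript_id}: CDS outside exons")

    def _cds_within_exons(self) -> bool:
        for (a, b) in self.cds:
            if not any(ea <= a and b <= eb for (ea, eb) in self.exons):
                return False
        return True

    @property
    def length(self) -> int:
        return sum(_interval_len(iv) for iv in self.exons)

    @property
    def cds_len(self) -> int:
        return sum(_interval_len(iv) for iv in self.cds)

    @property
    def introns(self) -> list[Interval]:
        return [
            (a[1] + 1, b[0] - 1) for a, b in zip(self.exons, self.exons[1:])
        ]

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def _utr_lengths(self) -> tuple[int, int] | None:
        """(left, right) exonic bases outside the CDS in genomic order."""
        if not self.cds:
            return None
        cds_start = self.cds[0][0]
        cds_end = self.cds[-1][1]
        left = sum(
            max(0, min(eb, cds_start - 1) - ea + 1) if ea < cds_start else 0
            for (ea, eb) in self.exons
        )
        right = sum(
            max(0, eb - max(ea, cds_end + 1) + 1) if eb > cds_end else 0
            for (ea, eb) in self.exons
        )
        return left, right

    @property
    def utr5_len(self) -> int | None:
        lr = self._utr_lengths()
        if lr is None:
            return None
        return lr[0] if self.strand == "+" else lr[1]

    @property
    def utr3_len(self) -> int | None:
        lr = self._utr_lengths()
        if lr is None:
            return None
        return lr[1] if self.strand == "+" else lr[0]

    def utr_len(self, end: str) -> int | None:
        if end == "3p":
            return self.utr3_len
        if end == "5p":
            return self.utr5_len
        raise ValueError("end must be '3p' or '5p'")


class TranscriptModelSet:
    """A collection of transcript models indexed by transcript and gene."""

    def __init__(self, transcripts: list[TranscriptModel]):
        ordered = sorted(transcripts, key=lambda t: (t.gene_id, t.transcript_id))
        self.transcripts: dict[str, TranscriptModel] = {}
        self.genes: dict[str, list[str]] = {}
        for t in ordered:
            if t.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript id {t.transcript_id}")
            self.transcripts[t.transcript_id] = t
            self.genes.setdefault(t.gene_id, []).append(t.transcript_id)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def gene_transcripts(self, gene_id: str) -> list[TranscriptModel]:
        return [self.transcripts[t] for t in self.genes[gene_id]]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes)


class ExpressionMatrix:
    """Isoform x cell count matrix with per-cell metadata.

    ``counts`` is stored CSR (features on rows).  ``feature_genes`` maps
    every feature to exactly one gene (the binary gene-isoform incidence).
    ``metadata`` is indexed by cell id and must cover every cell; expected
    columns: patient, batch, tissue, cell_type (extra columns pass through).
    """

    def __init__(
        self,
        counts,
        feature_ids: list[str],
        cell_ids: list[str],
        feature_genes: pd.Series | dict,
        metadata: pd.DataFrame,
    ):
        counts = sp.csr_matrix(counts)
        if counts.shape != (len(feature_ids), len(cell_ids)):
            raise ValueError("counts shape does not match index lengths")
        if (counts.data < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(counts.data, np.round(counts.data)):
            raise ValueError("non-integer counts")
        if len(set(feature_ids)) != len(feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(cell_ids)) != len(cell_ids):
            raise ValueError("duplicate cell ids")
        self.counts = counts
        self.feature_ids = list(feature_ids)
        self.cell_ids = list(cell_ids)
        fg = pd.Series(feature_genes)
        missing = [f for f in feature_ids if f not in fg.index]
        if missing:
            raise ValueError(f"features without gene mapping: {missing[:5]}")
        self.feature_genes = fg.loc[self.feature_ids]
        absent = [c for c in cell_ids if c not in metadata.index]
        if absent:
            raise ValueError(f"cells missing from metadata: {absent[:5]}")
        self.metadata = metadata.loc[self.cell_ids].copy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_features(self, keep: list[str]) -> "ExpressionMatrix":
        idx = [self.feature_ids.index(f) for f in keep] if len(keep) < 50 else \
            pd.Index(self.feature_ids).get_indexer(keep)
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.counts[idx], [self.feature_ids[i] for i in idx],
            self.cell_ids, self.feature_genes, self.metadata,
        )

    def subset_cells(self, keep: list[str]) -> "ExpressionMatrix":
        idx = pd.Index(self.cell_ids).get_indexer(keep)
        if (idx < 0).any():
            raise KeyError("unknown cell ids in subset")
        return ExpressionMatrix(
            self.counts[:, idx], self.feature_ids,
            [self.cell_ids[i] for i in idx], self.feature_genes, self.metadata,
        )

    def to_gene_level(self) -> "ExpressionMatrix":
        """Sum isoform counts into gene counts via the gene incidence map."""
        genes = sorted(set(self.feature_genes))
        gene_pos = {g: i for i, g in enumerate(genes)}
        rows = np.array([gene_pos[g] for g in self.feature_genes])
        agg = sp.csr_matrix(
            (np.ones(len(rows)), (rows, np.arange(len(rows)))),
            shape=(len(genes), len(self.feature_ids)),
        )
        gcounts = agg @ self.counts
        return ExpressionMatrix(
            gcounts, genes, self.cell_ids,
            pd.Series(genes, index=genes), self.metadata,
        )

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


@dataclass
class NormalizedMatrix:
    """TPM and log(TPM/10 + 1) views of an expression matrix.

    TPM here means reads per 1e6 mapped full-length reads per feature; the
    log transform is the natural logarithm.  Rows are features, columns
    cells; ``zero_cells`` flags cells whose total count was zero (their
    columns are all-zero rather than NaN).
    """

    tpm: pd.DataFrame
    logexpr: pd.DataFrame
    level: str
    zero_cells: list[str] = field(default_factory=list)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.tpm.columns)


class AllelicCounts:
    """Per mutation-site, per-cell wild-type / mutant / other read counts.

    ``sites`` is a DataFrame indexed by site id (``chrom:pos:ref>alt``) with
    columns chrom, pos, ref, alt, gene_id.  The three count matrices are
    dense int arrays of shape (n_sites, n_cells).
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        cell_ids: list[str],
        c_wt: np.ndarray,
        c_mut: np.ndarray,
        c_other: np.ndarray,
    ):
        n_sites = len(sites)
        for name, arr in (("c_wt", c_wt), ("c_mut", c_mut), ("c_other", c_other)):
            if arr.shape != (n_sites, len(cell_ids)):
                raise ValueError(f"{name} shape mismatch")
            if (arr < 0).any():
                raise ValueError(f"{name} has negative counts")
        if sites.index.duplicated().any():
            raise ValueError("duplicate site keys")
        self.sites = sites
        self.cell_ids = list(cell_ids)
        self.c_wt = np.asarray(c_wt, dtype=np.int64)
        self.c_mut = np.asarray(c_mut, dtype=np.int64)
        self.c_other = np.asarray(c_other, dtype=np.int64)

    @property
    def site_ids(self) -> list[str]:
        return list(self.sites.index)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def site_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"
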