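# isoscan

Isoform-level statistics for long-read single-cell RNA-seq of tumors, built
around the contrasts that matter in colorectal cancer: cancer cells versus
normal epithelium (stem/TA-like versus stem/TA cells), and iCMS2 versus
iCMS3 intrinsic subtypes. Starting from a quantified isoform × cell count
matrix, a transcript annotation (GTF) and per-cell allelic pileup counts at
somatic mutation sites, `isoscan` computes:

- **UTR deviation** — the expressed UTR length of gene *g* in cell *c* is
  the expression-weighted mean of its isoforms' UTR lengths,
  `EUL[g,c] = Σᵢ M[g,i]·C[i,c]·lᵢ / Σᵢ M[g,i]·C[i,c]`, and the gene UTR
  deviation `GUD[g,c] = EUL[g,c] − mean EUL over normal cells`. A linear
  mixed/fixed-effects model of GUD on cell type (with a technology-batch
  term) classifies genes as 3′-UTR **shortened** (estimate < 0, p < 0.05,
  mean difference ≤ −10 bp), **lengthened**, or unchanged.
- **Local splicing events and PSI** — SE, RI, A5, A3, AF, AL and MX events
  enumerated from exon structure; per-cell percent spliced in
  `PSI = TPM(inclusion) / TPM(all participating isoforms)`; differential
  splicing by rank-sum test gated at p < 0.05 and |ΔPSI| ≥ 0.1;
  splicing-factor–PSI Pearson correlation with hierarchical clustering and
  Fisher tests of retained-intron enrichment; hypergeometric overlap of
  event sets with a 5% ΔPSI consistency rule.
- **Differential transcript / CDS usage** — a two-stage screen/confirm
  procedure over within-gene isoform (or CCDS-group) proportions with
  overall FDR (OFDR) < 0.05 and a >10% proportion-difference requirement,
  plus annotation of coding consequences (>20 bp CDS change, exon
  differences, domain loss).
- **Allele-specific mutation calling** — per (site, cell) the sequencing
  error rate `ε = C_other / (C_wt + C_mut + C_other)` and a one-sided
  binomial test of the mutant read count against it, BH-corrected, with a
  mutation confirmed at FDR < 0.05 and coverage ≥ 3 (cancer) / ≥ 10
  (normal) — followed by mutant-allele dominance and mutant-vs-wild-type
  correlation-shift analysis against highly variable genes.
- **Signature scoring** — binned-control module scores, iCMS2/iCMS3
  patient assignment, and subtype-consistent differential transcripts and
  splicing events.

A synthetic-data generator (`isoscan.simulate`) produces GTF + counts +
allelic fixtures with planted APA shifts, ΔPSI effects, isoform switches,
splicing-factor couplings and mutant subclones, with the ground truth
emitted alongside, so every stage is testable without external data.

## Worked example

```python
from isoscan import simulate, matrix, utr

cfg = simulate.SimulationConfig(
    seed=1, n_genes=14,
    n_cells_per_group={"normal": 200, "cancer": 200},
    planted_apa=[simulate.PlantedAPA("G0001", -50.0, "cancer")],
)
ann, em, ac, truth = simulate.simulate_bundle(cfg)
nm = matrix.normalize_expression(em)             # TPM and log(TPM/10+1)
eul = utr.compute_eul(nm, ann, end="3p")
meta = em.metadata
res = utr.compute_gud(eul, list(meta.index[meta.group == "normal"]))
calls = utr.classify_utr_genes(res, meta.cell_type, meta.batch,
                               "stem_TA_like", "stem_TA")
print(calls.loc["G0001", ["estimate", "p_value", "mean_diff", "class"]])
```

```
estimate    -44.356733
p_value            0.0
mean_diff   -44.356733
class        shortened
Name: G0001, dtype: object
```

The planted −50 bp alternative-polyadenylation shift in cancer cells is
recovered: the cell-type coefficient is ≈ −50 bp, and the gene is called
shortened because the estimate is negative, significant, and the mean GUD
difference is below −10 bp.

The same bundle can be driven from a shell:

```bash
isoscan simulate --out data --seed 1
isoscan utr --bundle data --end 3p --target stem_TA_like \
        --reference stem_TA --out-prefix results/utr
isoscan splice --bundle data --target stem_TA_like \
        --reference stem_TA --out-prefix results/sp
```

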