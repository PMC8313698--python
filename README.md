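# loycite

Mosaic **loss of chromosome Y (LOY)** is the most common somatic mutation in
the blood of aging men: a fraction of a man's leukocytes simply lack the Y
chromosome. The *CD99* gene sits in pseudoautosomal region 1 (PAR1) of both
X and Y, so a LOY cell keeps one *CD99* copy instead of two — a dosage change
with consequences for transendothelial migration, adhesion and other
CD99-dependent immune functions.

`loycite` is a reusable pipeline for detecting LOY in single cells from
CITE-seq data (simultaneous mRNA + cell-surface protein readout via
antibody-derived tags, ADTs) and quantifying LOY-associated changes in CD99
mRNA and surface-protein abundance. It is aimed at analysts working with 10x
Genomics-style count matrices who want a tested, scriptable alternative to an
interactive notebook workflow. Because raw data of this kind is rarely
shareable, the package includes a first-class synthetic CITE-seq generator
with known ground truth, used by the test suite and usable for power
exploration.

## The inference chain

1. **QC** (per cell, RNA assay): keep cells with ≤ 2000 expressed genes
   (doublet guard), ≥ 2500 UMIs, and mitochondrial content in the closed
   interval [1.5 %, 5 %].
2. **Normalization**: RNA `x = ln(1 + count · 10⁴ / cell_total)`; ADT
   per-cell centered log-ratio over the 7-protein panel,
   `clrᵢ = ln(1+cᵢ) − (1/p)Σⱼ ln(1+cⱼ)`.
3. **LOY call**: a cell with autosomal expression but **zero** raw counts
   over the male-specific region of Y (MSY) is LOY; any MSY transcript means
   NORMAL. PAR genes (CD99!) are excluded from the MSY evidence because their
   X-linked copy is retained.
4. **Cell typing**: argmax over the six typing-marker CLR values
   (CD19 → B, CD14/CD16 → monocytes, CD56 → NK, CD8/CD4 → T), assigned only
   when the top marker is positive and ≥ 0.5 CLR above the runner-up,
   otherwise OTHER. CD99 is never a typing marker.
5. **Differential abundance**, per cell type, for CD99 and the type's own
   autosomal marker:
   * protein: 1-df likelihood-ratio test between logistic models of LOY
     membership with/without the CLR analyte,
   * RNA: two-part hurdle (logistic detection + Gaussian on positive
     log-normalized values), LRT with one df per estimable part,
   both adjusted for donor, library-prep batch, sequencing batch, UMI depth
   and mitochondrial %. All p-values across every cell type and assay are
   Benjamini–Hochberg adjusted as one family. Effects are average natural-log
   fold changes; `percent = 100·(e^logFC − 1)`.
6. **Pooled model**: logistic `LOY ~ CD99 + donor + batches + n_umi +
   pct_mito + cell_type` over all cells, reporting the Wald z of the CD99
   coefficient (one model per assay).

## Worked example

```bash
loy-cite simulate --out demo --seed 5 --cells-per-donor 250
loy-cite run --rna demo/rna --adt demo/adt --samples demo/samples.csv --out demo_results
loy-cite figures --results demo_results
```

The `run` step prints `results in demo_results`; the directory then holds
`qc_report.tsv`, `loy_calls.tsv`, `cell_types.tsv`, `loy_frequencies.tsv`,
`differential_results.tsv`, `pooled_overall.tsv` and `manifest.json`.
The same analysis from Python, at the default study scale (5,000 cells):

```python
>>> import loycite as lc
>>> sim = lc.simulate(lc.SimulationConfig(seed=1))
>>> out = lc.analyze(sim.rna, sim.adt, sim.sheet)
>>> out["loy_frequencies"][["cell_type", "n_cells", "n_loy", "pct_loy"]].head(3)
   cell_type  n_cells  n_loy    pct_loy
0          B      530     32   6.037736
1  CD14_MONO      863    132  15.295481
2  CD16_MONO      217     29  13.364055
```

Each row is one leukocyte type with its LOY percentage (a Wilson 95% CI is
attached in the full table). The differential table has one row per
(cell type × analyte × assay):

```python
>>> df = out["differential_results"]
>>> df[(df.cell_type == "B") & (df.analyte == "CD99") & (df.assay == "ADT")]
  cell_type analyte assay  avg_logfc  pct_change         p_raw         p_adj  n_loy  n_normal
1         B    CD99   ADT  -0.468167  -37.385077  2.192470e-13  5.261929e-12     32       498
```

Here the CD99 surface protein on B cells is estimated to be 37 % lower on
LOY cells in this particular draw (the generator injects a −0.31 log fold
change ≈ −27 %; single-seed estimates scatter around it), and the association
survives BH correction across all 24 tests. The autosomal-marker rows (CD19
in B cells, CD14 in classical monocytes, …) act as negative controls and
stay non-significant.

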