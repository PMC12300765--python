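# Methods

## Scope and model

`roifuse` covers the analysis path from per-ROI variant calls to an
annotated, heat-mapped slide. An ROI is a geometric selection (cell or
cell cluster) on a scanned H&E membrane slide, destined for laser
microdissection and single-cell whole-exome/genome sequencing. The
package assumes variant calling has already happened upstream; its job
is filtering, normalization, scoring, geometry and evaluation.

## Variant hard filters

Records are removed by fixed thresholds, each rule evaluated
independently so a record carries every reason it failed and the
outcome is order-free:

| rule | condition for removal | default |
|---|---|---|
| DRAGENSnpHardQUAL | SNP with QUAL < threshold | 10.41 |
| DRAGENIndelHardQUAL | INDEL with QUAL < threshold | 7.83 |
| LowDepth | DP ≤ threshold | 1 |
| PloidyConflict | genotype arity ≠ expected chromosome ploidy | map |
| base_quality | median base quality of alt reads < threshold | 20 Phred |
| lod_fstar | mitochondrial contig with LOD ≤ threshold | 6.3 |

QUAL is −10·log₁₀ P(GT = 0/0 | data). The QUAL cuts are exclusive below
(a record exactly at the threshold is retained); LowDepth and lod_fstar
are inclusive ("does not exceed"). The base-quality cut has no
published value; 20 Phred is a conventional default and the rule skips
records lacking the field. PloidyConflict is implemented as a genotype
arity check against a per-chromosome ploidy map (default male
karyotype: autosomes diploid, X/Y/MT haploid) — the most conservative
reading of "genotype inconsistent with chromosome ploidy" that needs no
caller internals.

VCFs are read with cyvcf2; because htslib stores QUAL and Float INFO
fields as 32-bit floats, parsed values are re-read at 6 significant
decimal digits so that thresholds expressed in decimal (10.41) compare
exactly.

## Per-chromosome burden and the relative score

Short-read sequencing reports which chromosome *type* carries a
mutation, not which homolog. Assuming both homologs are equally likely
to be hit, the distinct-gene count is doubled on diploid chromosomes:
for chromosome *i* with approximate gene count *Nᵢ* and copy number
*cᵢ*,

    pᵢ = (gᵢ·cᵢ) / (Nᵢ·cᵢ)        dᵢ = mᵢ / (gᵢ·cᵢ)

The copy-number factor cancels in *pᵢ* (kept in the two-factor form for
transparency) but not in *dᵢ*. Chromosomes without records carry zeros;
*dᵢ* is defined as 0 when *gᵢ* = 0. Records without a gene symbol count
toward *mᵢ* only, with a warning; *gᵢ* > *Nᵢ* (possible with an
inconsistent reference) warns rather than clamps, because surfacing a
reference mismatch beats silent truncation.

The default reference table is a male karyotype with gene counts
3000/2500/1900 (chr 1–3), 400 (chr 21), 1400 (X), 200 (Y); the
remaining chromosomes carry round approximate counts in the same
user-editable TSV (`data/chromosome_genes.tsv`). The burden reference
includes chromosome 22 by default; `load_reference(paper_compat=True)`
restricts to the index set 1–21, X, Y used by the original aggregation,
which omits it. MT is excluded from burden aggregation entirely (its
"gene count" is not comparable).

The relative mutation score C′ = (Σmᵢ − Σgᵢ)/Σmᵢ is 0 when all
mutations hit distinct genes and (m−1)/m when all m hit one gene — it
approaches, but never reaches, 1 for finite m; the implementation
follows the formula as printed. Σm = 0 (unsequenced ROI) maps to score
0 and a fully transparent heatmap state. Tumor-class aggregation uses
per-chromosome medians of *pᵢ* and *dᵢ* (even counts: mean of the two
middle order statistics) because class labels rest on pathologist
judgment and the median resists mislabeled cells.

## Annotation

Pathway/drug joins use a versioned local TSV snapshot rather than live
database queries, for reproducibility and offline testing. The bundled
snapshot covers ~23 colorectal-cancer genes; the colon panel is a plain
symbol list, both user-replaceable. Annotation is pure decoration —
counts and scores are never altered.

## Morphometry under anisotropic pixels

Each axis converts independently (w = w_px·res_x, h = h_px·res_y); a
circle of pixel radius r becomes a physical ellipse with semi-axes
r·res_x, r·res_y. The ellipse perimeter uses Ramanujan's second
approximation,

    h = ((a−b)/(a+b))²,   P = π(a+b)(1 + 3h/(10 + √(4−3h))),

chosen because it takes the two semi-axes separately (the anisotropy
requirement) and has known error bounds: exact at a = b, relative error
< 1e−4 up to aspect ratio 20, < 0.5% even in the flat limit b → 0
(checked against adaptive quadrature of the elliptic arc length in the
tests). The formula is isolated behind `ellipse_perimeter` so a
different approximation can be swapped in. Shapes are axis-aligned
only, with 0-based pixel coordinates; rotated shapes and freehand
polygons are out of scope.

## Registration and export

The pixel→stage transform is a full 6-parameter affine fitted by least
squares over ≥ 3 non-collinear reference pairs — a full affine, not a
similarity, because the stage's two axes have independent scales.
Collinearity is detected by the rank of the centered pixel coordinates.
The RMS stage-space residual is stored with the frame; with exact
correspondences parameters are recovered to < 1e−9, and with isotropic
Gaussian noise of σ per coordinate the 2-D RMS residual concentrates
near σ√2.

Stage units are μm internally and mm (4 decimals) in the export XML.
The microdissector vendor's XML schema is not public, so a documented
schema (`lmd_export` version 1) is written and validated here, isolated
behind one writer/reader pair; rectangles and lines export mapped
vertices, circles/ellipses a mapped center plus semi-axes scaled by the
per-axis magnification (axis-aligned approximation under shear).
Dissection parameters (cut velocity 30 μm/s, laser focus 533 μm, 80% of
10 mW, 2 cutting repeats, Z drill 0.1 μm, focus check 1 s) ride along
as metadata and are never acted upon. ROI archives are versioned JSON;
a version mismatch or truncated file is a hard error, never a partial
load.

## Nucleus segmentation

A deliberately compact intensity pipeline, configured by the
empirically optimized detector parameters: optional Gaussian smoothing;
exclusion of bright background above a global threshold (default 240 of
255); 2-cluster k-means on the remaining intensities with the darker
cluster taken as nuclear (deterministic under a fixed seed);
morphological closing (3 iterations, 3×3) then dilation (5×5, 1
iteration); connected-component labeling; and removal of components
under 250 px. The smoothing mask size is given in μm (5.76 per axis)
and converted via the pixel resolution to the nearest odd pixel extent,
with σ = extent/4 (the kernel/σ convention is not published; this one
keeps ~95% of the mass inside the stated extent). The Wallis filter of
the original configuration is disabled there and not implemented here.
Gland and surface-epithelium detection are separate algorithms outside
this package's scope.

Count-based DSC uses TP = manual − missed and FP = detected − TP
(FP < 0 is rejected as inconsistent); the published benchmark rows are
consistent with FP = 0. Two benchmark rows (H, I) and the published
0.891 average do not follow the count-based formula that reproduces the
other eight rows and are documented exclusions in the tests. Display
rounds to 3 decimals; full precision is kept internally.

## Synthetic data

Generators are seeded (`numpy.random.default_rng`) and deterministic.

- **Mutation tables**: a per-chromosome plan (n genes × mutations per
  gene) yields records whose (mᵢ, gᵢ) truth the aggregation must
  recover exactly; QUAL/DP are drawn above the hard-filter thresholds
  so filtering is a no-op unless a test configures otherwise. Synthetic
  symbols (`GENE_<chrom>_<k>`) avoid real HUGO names so nothing leans
  on external gene lists.
- **VCFs**: one record per (QUAL, DP, class) tuple with optional
  chromosome/gene/LOD/genotype vectors; parse∘generate is field-exact.
- **Tissue images**: dark discs (default intensity 60) on a bright
  background (250) with optional Gaussian noise, plus a ground-truth
  label mask. Defaults emulate well-separated hematoxylin-stained
  nuclei at a 0.24 μm/px scan: radii 15–21 px (nuclear diameters
  7–10 μm) and a minimum border gap of 8 px. The gap matters: the
  detector's 5×5 dilation plus smoothing merges objects closer than
  roughly twice the dilation radius plus the blur support, so images of
  countable nuclei need gaps of this order. What these images do *not*
  emulate: staining variability, overlapping/dividing nuclei, sectioning
  artifacts, stromal texture — so passing segmentation tests show the
  pipeline's mechanics are right, not that its accuracy transfers to
  real tissue, where the published benchmark reports DSC ≈ 0.82–0.99
  per sample.

## Numerical and design choices

- Aggregate exports write floats via `repr` (shortest round-trip
  decimal) and are read back with round-trip float parsing, so export →
  import is bit-identical.
- Colormap: the scale anchors are named colors; pure green/yellow/red
  with piecewise-linear channels (r = 255·min(2v,1),
  g = 255·min(2(1−v),1), b = 0) is the simplest mapping through all
  three anchors. Overlay opacity defaults to 0.4 (not specified
  upstream).
- Top-gene ranking breaks count ties by ascending symbol so reports are
  deterministic.
- Problem sizes in tests and the acceptance script (e.g. 512² synthetic
  images with 20 nuclei, 1000 random score draws, 100 burden plans,
  2000-point QUAL grids) are chosen to exercise every boundary while
  keeping the whole suite fast on one CPU.

## Known limitations

- The TSV mutation-table dialect maps only the fields this package
  consumes; the upstream exporter's full ~150-column schema is not
  modeled.
- The affine registration assumes a planar, rigid slide; membrane sag
  or stretch between scanning and cutting is not modeled beyond the
  residual diagnostic.
- The segmentation is an intensity method; it will undersegment
  touching nuclei and has no notion of texture or color deconvolution.
- The LMD XML schema is this package's own documented format, not the
  vendor's.
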