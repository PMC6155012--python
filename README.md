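# mzatlas

Analyses for separating human **marginal-zone (MZ) B cells** from memory
B cells across tissues, for immunologists working with mass cytometry,
imaging mass cytometry and IgH repertoire sequencing.  The package
implements the three bespoke computations this question needs, each
exercised end-to-end on synthetic data with known ground truth:

1. **Bootstrap distinctness test** — is a focal subpopulation (CD45RB+
   cells inside the naive bubble) phenotypically distinct from its parent
   population?  Resample `n_focal` cells with replacement from the parent
   B = 10,000 times, record per-marker resample medians as the null, and
   report `z = (median_focal − mean_null) / sd_null` per marker, with
   empirical p-values.

2. **Pixel-as-event imaging pipeline** — stitch tiles, threshold noise,
   treat each pixel as a cytometry event, classify pixels into B-cell
   subsets by sequential embedding/clustering plus rule-based bubbles,
   and quantify subset geography as Euclidean distances to reference
   structures (germinal centre, epithelium).

3. **Clonal grouping and clone sharing** — partition IgH rearrangements
   by V gene / J gene / junction length, link clones by single-linkage
   components under the 5-mer-context-weighted normalised junction
   distance `d = Σ w(context, substitution) / L < 0.2`, then compute
   clone × site-isotype matrices (Ward clustering on manhattan
   distances), directional sharing percentages, GC-membership rates,
   per-donor Fisher exact tests on IgA-containing clones combined by
   Fisher's method (`X² = −2 Σ ln pᵢ ~ χ²(2k)`), and the cross-donor
   public-sequence rate.

Supporting stages — arcsinh transform, threshold gating, seeded 2-D
embedding, node clustering, subset rules, median profiles, classical MDS
with Kruskal stress-1, amplicon read QC (length/quality filter, exact-MID
demultiplexing, primer masking/trimming, duplicate collapse), chimera
filters and lineage trees — are all part of the package; see
`docs/methods.md` for the full model description.

## Layout

```
src/mzatlas/      panels, synthetic, cytometry, distinctness, imc,
                  repqc, clonal, overlap, pipeline
analysis/         numbered drivers: 01_simulate ... 07_clone_overlap
tests/            unit + property + end-to-end suites
scripts/          acceptance.py (see below)
```

The `analysis/` scripts run in order and write their tables under
`results/`; each is a thin driver over the library.

## Worked example

```sh
python analysis/01_simulate.py
python analysis/03_distinctness_test.py
```

prints (abridged):

```
naive bubble: 1503 events; CD45RB+ focal: 244 events
12 of 18 markers flagged at |z| >= 2
 *  CD45RB  z =    +54.4  (over)
 *    CD24  z =    +27.8  (over)
 *     IgM  z =    +22.4  (over)
 ...
 *    BCMA  z =    -12.5  (under)
 *    CD38  z =    -14.2  (under)
 *  HLA-DR  z =    -16.8  (under)
 *     IgD  z =    -18.8  (under)
```

The focal CD45RB+ cells over-express CD24, IgM, CD45 and CD45RB and
under-express BCMA, HLA-DR, IgD and CD38 relative to random same-size
draws from the naive bubble — the signature of the MZ-precursor
phenotype, recovered here from data generated with exactly that shift.

Continuing with `analysis/06_clonal_grouping.py` and
`analysis/07_clone_overlap.py`:

```
1938 clones defined (largest 49, median 1); ARI vs generator truth = 1.000
distance-to-nearest: 4729 defined, suggested valley threshold 0.294
GC membership: 1 of 514 mz-containing GALT clones (0.2%)
IgA overlap: pooled table ((0, 514), (9, 488)), pooled p = 1.62e-03
public sequences across donors: 0.000%
```

Clone recovery is essentially perfect at the default mutation rate (the
adjusted Rand index compares defined clones with generator truth), the
distance-to-nearest valley sits between the within-clone and
between-clone regimes (the 0.2 default is retained), and MZ-containing
clones contain no IgA members while IgM-only clones do — the asymmetry
the clone-sharing statistics are built to detect.

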