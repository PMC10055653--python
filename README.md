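# pauseatlas

A tested pipeline for cross-species analysis of RNA polymerase II
promoter-proximal pausing from nascent-transcription (PRO-seq-style)
signal tracks, written for regulatory genomicists who want the full
chain — from per-base read-count tracks to comparative statistics —
reproducible on synthetic data with known ground truth.

The pipeline covers:

- **TSS reannotation** — each gene's start is re-called as the 10 bp
  sliding window with the maximal 5′-end read count inside a 1 kb
  region centred on the annotated start.
- **Pausing indexes** — for each gene, the ratio of Pol II density
  (3′-end reads per base, sense strand) in the pause region to the gene
  body,

  `PI = density([TSS−150, TSS+150)) / density([TSS+300, TES−300))`,

  with genes shorter than 300 bp removed and species summarised by the
  geometric mean (mean log₁₀ PI), since indexes span orders of
  magnitude across species.
- **Pause-site motifs** — the pause site is the base with the maximal
  3′-end count in [TSS, TSS+100); the quartile of genes with the most
  sharply positioned pause seeds a position weight matrix, scored as
  log₂ odds, and motif enrichment is the mean best-match score of the
  20 bp pause-centred sequence minus the mean over flanking DNA
  ([−500,−100) and [100,500) from the pause).
- **Ortholog presence/absence** — a two-pass reciprocal
  Smith–Waterman/E-value search (BLOSUM62, affine gaps 11/1,
  Karlin–Altschul E-values thresholded at 10⁻⁶) calls each query
  protein present or absent per species, in both a lenient
  (any reciprocal hit) and a strict (reciprocal best hit) mode.
- **Comparative statistics** — OLS regression of motif enrichment on
  mean log₁₀ pausing index, species grouped by detected NELF-like
  subunit count, and Mann–Whitney comparisons (exact by enumeration for
  small tie-free samples).
- **Perturbation response** — spike-in scaling, log₂ fold-change
  tracks (pseudocount 0.1), binned response matrices, k-means
  clustering of depletion time-course responses (k = 3), and
  heat-shock induction statistics over gene bodies excluding the first
  3 kb downstream of the TSS.

Every stage is exercised end-to-end by a synthetic-data module that
plants ground truth: per-gene pause offsets (30–60 bp downstream of the
TSS), pausing indexes, optional pause motifs, proteomes with known
ortholog/paralog/loss structure, and two-timepoint depletion courses
with three response archetypes.

## Worked example

The numbered drivers under `analysis/` run the study on simulated data
(outputs under `results/`):

```sh
python analysis/01_simulate_species_atlas.py   # writes 10 species datasets
python analysis/02_pausing_atlas.py            # per-species atlas + regression
python analysis/03_cross_species_statistics.py # orthology + subunit groups
python analysis/04_nelf_depletion_response.py  # depletion clustering + HS defect
```

`02_pausing_atlas.py` prints, for ten species simulated with a planted
positive relationship between pause-motif usage and pausing index:

```
   species  n_genes_ok  mean_log10_pi  geometric_mean_pi  motif_enrichment
species_00          80          0.298              1.985             1.064
...
species_09          80          1.809             64.366            14.976

enrichment vs mean log10 pausing index: R^2 = 0.830, p = 2.46e-04, slope = 0.093 (n = 10 species)
```

i.e. species whose pause sites carry the motif more often have
proportionally higher geometric-mean pausing indexes, and the
cross-species regression recovers the planted relationship.
`04_nelf_depletion_response.py` prints the depletion-course clustering
and induction-defect result:

```
3-archetype clustering: adjusted Rand index 1.000 over 300 genes
up-regulated genes: median defect 1.00 log2 units, Mann-Whitney p = 2.42e-15 (n = 50)
down-regulated genes: median difference 0.00, p = 1.00 -> defect is specific to induction
```

A `pauseatlas` CLI wraps the same pipeline for on-disk data
(`pauseatlas atlas run --config ...`, `pauseatlas perturb run
--config ...`, `pauseatlas simulate`, `pauseatlas validate-config`).

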