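# combisom

Integrative self-organizing-map (SOM) portrayal of patient-matched
multi-omics landscapes: gene expression (**Gex**), promoter DNA
methylation (**Dme**) and gene-centric copy-number variation (**CNV**).

Tumour cohorts — gliomas are the motivating case — are shaped by three
interacting regulatory layers: copy-number aberrations push expression
through a dose–response, promoter methylation represses it, and
transcription-factor programmes act on expression alone.  `combisom`
places all three layers into *one* shared coordinate system so they can
be compared gene by gene, sample by sample.

## Method

Each gene contributes three per-sample score profiles.  After
centralization (Δe, Δm, Δc: per-gene mean over all samples removed) and
harmonization (each modality divided by its global standard deviation),
the profiles are concatenated into one combined vector with modality
weights *w*<sub>e</sub> + *w*<sub>m</sub> + *w*<sub>c</sub> = 1; the
Euclidean distance between two genes is then
√(Σ<sub>b</sub> *w*<sub>b</sub>² d<sub>b</sub>²).  A batch-trained
Kohonen SOM (default 45 × 45 units) clusters the combined vectors into
"metagenes" arranged on a grid, and the trained unit vectors are
decomposed back into per-modality **portraits** — one image per sample
and modality, with every gene at the same grid position in all three.
The default weighting is balanced (1/3 each); dominant
(0.99/0.005/0.005) and bi-variant (0.5/0.5/0) presets flip the map into
single- or two-ome topologies.

Downstream maps all live on the same grid:

- **ScoV maps** — signed square-root covariance, sign(c)·√|c|, between
  two modalities' metagene profiles; methylation–expression repression
  shows up blue (negative), CNV dose–response red (positive).
- **Spot modules** — 8-connected regions above 90% of a portrait's
  extremum; overlapping detections across group portraits are merged and
  labelled A, B, … clockwise.  Spots collect co-expressed,
  co-methylated and/or co-aberrant genes.
- **GSZ scores** — per sample, a gene set's normalized set-mean score,
  (mean<sub>set</sub> − mean<sub>all</sub>)/(SD<sub>all</sub>/√n);
  ternary diagrams split the three modality GSZ into percentage shares.
- **Prognostic maps** — per metagene, samples above mean + 1 SD of the
  unit's profile form a "high" group and a univariate Cox fit of high
  vs rest gives a hazard ratio rendered on the grid.
- **Similarity networks** — Pearson correlation between sample
  portraits, top-k neighbour graphs and agreement with annotated groups.

A synthetic-cohort generator (`combisom.synthetic`) emulates the assumed
structure — trinary arm-level CNV segments with expression dose–response,
repressive methylation modules, a hypermethylator gradient, TF-driven
expression modules, low-purity samples and group-dependent survival —
with full ground truth, so the whole pipeline is testable without any
data download.

## Worked example

```python
import combisom as cs

ds, truth = cs.default_cohort(seed=7)            # 2000 genes x 120 samples
harm  = cs.harmonize(cs.centralize_dataset(ds))
prof  = cs.combine(harm, cs.weight_preset("balanced"))
model = cs.train_som(prof, grid_side=20, seed=11)
dec   = cs.decompose(model)

portraits = []
for m in cs.MODALITIES:
    portraits.extend(cs.group_portraits(model, dec, ds.groups(), m).values())
labels, spots = cs.spot_summary_map(portraits, model)
for s in spots:
    print(s.label, s.sign, s.n_units, len(s.member_genes), s.dominant_modality.value)

hr = cs.spot_hr(spots[1], dec, list(ds.sample_ids), ds.survival_frame())
```

prints

```
6 spots detected on the 20x20 map
A over  11  80 Gex
B mixed 12  80 Dme
C under 21 166 CNV
D mixed 19 172 CNV
E mixed 14 159 Dme
F mixed 22 174 CNV
spot B HR[Dme] = 2.76 (95% CI 1.81-4.22)
```

Spot B is the planted repressive methylation module: it is
hypermethylated in the high-hazard group, so high methylation at its
units predicts poor outcome (HR ≈ 2.8 against a planted group hazard of
3).  Spot D recovers the planted chromosome-7-like gain with
gene-membership Jaccard 0.96.  The CLI wraps the same workflow:
`combisom demo --out demo/` runs it end to end, and `combisom simulate`,
`train`, `portray`, `scov`, `spots`, `genesets`, `prognosis`, `cohort`
and `run` expose the individual stages.

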