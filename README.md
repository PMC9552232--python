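# prepmatrix

Comparative analysis of bottom-up proteomics sample-preparation methods
from label-free quantification (LFQ) tables.

Choosing a sample-preparation protocol — classical in-solution digests
(urea, guanidine hydrochloride or sodium-deoxycholate buffers, with or
without protein precipitation), SPEED, or device/kit-based cleanup
methods (FASP, iST, EasyPep, S-Trap, SP3) — shapes which parts of a
proteome an experiment can see. `prepmatrix` implements the
post-acquisition comparison of such protocols: it takes MaxQuant-style
`proteinGroups.txt` / `peptides.txt` tables, a PTM-Shepherd-style
open-search modification summary and a sample-design table, and
produces a descriptive **guide matrix** that tells you which protein
classes each method extracts well or poorly.

## What it computes

Given log2 LFQ intensities `x[i, s]` for protein group `i` in run `s`:

1. **Preprocessing** — remove reverse hits, contaminants, only-by-site
   identifications, iRT standards and groups with < 2 razor+unique
   peptides; keep only MS/MS-based identifications; require ≥ 3 valid
   values in at least one method group; impute remaining missing
   values with the constant `⌊min x⌋` (the detection-limit regime).
2. **Profiling** — average replicates per method, center each protein's
   profile (`x̃[i, m] = x̄[i, m] − mean_m x̄[i, m]`), and run k-means
   over k = 2…15 (25 restarts). k is chosen at the elbow of the
   within-cluster sum of squares (SSW) curve — the k maximizing the
   second forward difference — with an explicit override available.
3. **Enrichment** — for every binary protein feature f and cluster c,
   the enrichment factor `EF = observed / expected` with
   `expected = n_c · K_f / N`, and a one-sided Fisher exact p-value
   (upper hypergeometric tail). Cells with p < 0.05 are flagged
   significant, EF ≥ 2 strong; together they form the guide matrix.
4. **ID statistics** — per-run protein/peptide counts, missed-cleavage
   profiles, a median-based bridging correction that puts two
   measurement blocks on one scale via re-measured bridge samples,
   and an OLS model `IDs ~ batch + precipitation + buffer` with
   sequential F/ANOVA, 95% CIs on per-level predictions and partial
   residuals.
5. **Modification artifacts** — open-search PSM percentages per method
   and flags for method-specific modifications (known artifacts such
   as the +40.0313 Da acetone adduct are annotated by mass).

A fully deterministic synthetic-data generator
(`prepmatrix.synthetic_data`) emulates the study layout — 16 methods ×
3 replicates in 6 batches, planted abundance clusters,
intensity-dependent dropout, decoy rows, planted feature enrichment
and ID-count structure — so the entire pipeline is testable without
any raw data.

## Worked example

```python
from prepmatrix import synthetic_data, preprocess, clustering, enrichment

cfg = synthetic_data.SimulationConfig(seed=1)
table, design, truth = synthetic_data.simulate_protein_groups(cfg)
filtered = preprocess.filter_protein_groups(table, design)
matrix = preprocess.impute_constant(
    preprocess.valid_value_filter(
        preprocess.log2_transform(preprocess.mask_non_msms(filtered)), design
    )
)
print(f"{len(matrix.values)} proteins quantified; imputation constant "
      f"{matrix.imputation_constant}")

profiles = clustering.center_rows(clustering.average_replicates(matrix, design))
sweep = clustering.sweep_kmeans(profiles, seed=1)
k, info = sweep.select_k()
model = sweep.models[k]
print(f"selected k = {k} ({info['rule']}); cluster sizes:",
      model.sizes().to_dict())

annotation = synthetic_data.simulate_annotations(cfg, truth)
guide = enrichment.build_guide_matrix(model.assignments, annotation)
hits = guide.long.query("significant and strong")
print(hits[["feature", "cluster", "observed", "expected",
            "enrichment_factor", "p_value"]].round(3).to_string(index=False))
```

prints

```
1836 proteins quantified; imputation constant 22
selected k = 5 (max_second_difference); cluster sizes: {1: 279, 2: 456, 3: 317, 4: 646, 5: 138}
       feature  cluster  observed  expected  enrichment_factor  p_value
     cytosolic        2       207    83.451              2.480      0.0
iron_transport        5        67    16.912              3.962      0.0
      membrane        1       141    45.588              3.093      0.0
 mitochondrial        3       140    51.452              2.721      0.0
       nuclear        4       288   141.093              2.041      0.0
```

The filter kept 1836 of the 2241 simulated protein-group rows (decoys,
low-evidence groups and sparsely observed proteins removed); missing
cells were imputed at log2 = 22, the floor of the lowest observed
value. The SSW elbow recovered the five planted abundance clusters,
and each planted feature shows up in exactly one cluster as a
significant (p < 0.05), strong (EF ≥ 2) guide-matrix cell — e.g. the
`iron_transport` feature with 67 carriers observed in its 138-protein
cluster against 16.9 expected (EF ≈ 4.0).

The same flow is available from the shell:

```bash
prepmatrix simulate --out sim --seed 1
prepmatrix run --config pipeline.yaml          # full pipeline from YAML
prepmatrix cluster --matrix log2_matrix.tsv --design sim/design.tsv --out out
```

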