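# allotrack

Identify alloreactive T-cell clones from a mixed-lymphocyte reaction (MLR)
single-cell experiment and track them across bulk TCRβ repertoires from
blood and tissues over time.

When a transplant recipient receives immune-checkpoint inhibition for
cancer, pre-existing donor-reactive (alloreactive) T-cell clones can
expand and reject the graft. An MLR — co-culturing recipient lymphocytes
with irradiated donor cells — expands those clones in vitro; paired
single-cell RNA/TCR sequencing of the proliferated cells defines them as
clonotypes; and bulk TCRβ sequencing of longitudinal blood and biopsy
samples lets you ask where and when those exact clones appear. `allotrack`
is the analysis layer for that design, for immunologists working with
immunoSEQ-style bulk exports and 10x-style single-cell V(D)J output.

## What it computes

- **Clonotyping**: productive-contig filtering, multichain resolution
  (highest-UMI chain per cell), αβ clone grouping, and cross-platform
  clone matching on the beta chain (CDR3 nt or aa, optionally requiring
  V/J concordance; Adaptive `TCRBV05-01*01` and IMGT `TRBV5-1` spellings
  are unified).
- **Repertoire statistics**: inverse Simpson diversity D = 1/Σpᵢ²;
  Morisita-Horn overlap MH = 2Σxᵢyᵢ/((Σxᵢ²/X² + Σyᵢ²/Y²)·X·Y); fold
  expansion with a pseudocount for undetected clones; per-clone dynamics
  (emerged / expanded / contracted / stable / absent) via two-sided
  Fisher's exact tests with Benjamini-Hochberg correction.
- **Single-cell scoring**: QC on mitochondrial fraction and feature
  counts, log-normalization, gene-module scores (plain mean or
  bin-matched control subtraction), S/G2M cell-cycle phase calls, and
  one-vs-rest Wilcoxon cluster markers with log-FC and detection filters.
- **Integration**: a clone × sample tracking matrix across compartments
  and timepoints, cluster distributions of tracked clones in blood
  single-cell data, and enrichment of newly emerged clones' phenotype.
- **Simulation**: a fully ground-truthed synthetic study bundle
  (heavy-tailed repertoires, tunable compartment sharing, MLR fold
  expansion, paired expression/TCR single cells with cluster programs and
  multichain decoys) so every stage is testable without downloads.

## Worked example

Generate a synthetic study and run the full pipeline:

```sh
allotrack simulate --seed 1 --out simdir
allotrack run --manifest simdir/manifest.tsv --out results/
```

or in Python:

```python
from allotrack import PipelineConfig, run_pipeline
from allotrack.simulate import MlrStudySimulator, SimConfig

manifest = MlrStudySimulator(SimConfig(seed=1)).simulate_bundle("simdir")
cfg = PipelineConfig(seed=1, qc_features_min=50,
                     signatures_dir="simdir/signatures",
                     specificity_path="public_tcrs.tsv")
res = run_pipeline(manifest, cfg, "results")
print(res["diversity"][["sample_id", "inverse_simpson"]].to_string(index=False))
summary = res["tracking"].compartment_summary()
print(summary[summary.clone_set == "C1"].to_string(index=False))
```

prints

```
    sample_id  inverse_simpson
    blood_pre        66.337316
blood_pembro1        67.108459
blood_pembro2        66.667027
       kidney        60.099902
   lymph_node        39.110794
         skin        76.729496
          mlr        75.489348

clone_set     sample_id  n_clones  n_present  percent_present
       C1     blood_pre        20          0              0.0
       C1 blood_pembro1        20         20            100.0
       C1 blood_pembro2        20         20            100.0
       C1        kidney        20         20            100.0
       C1    lymph_node        20          0              0.0
       C1           mlr        20         20            100.0
       C1          skin        20          0              0.0
```

Diversity is the effective number of equally abundant clones per sample.
The second table is the study's central readout: the 20 clones defined by
the proliferating MLR cluster (C1) are absent from pre-treatment blood
and from both tumor-containing compartments, but present in
post-treatment blood and in the rejected kidney — exactly where the
generator seeded them. `results/` additionally contains the overlap
matrix, per-clone dynamics calls, cluster distributions of tracked clones
in the blood single-cell data, marker and score tables, and a run log;
reruns with the same seed are byte-identical.

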