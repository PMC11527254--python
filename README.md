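# lesionmap

Voxel-wise permutation mapping of catecholaminergic cell and fiber changes in
3D brain volumes, with cluster-constrained FDR correction, tissue-space
cluster validation, region-wise counting and optical-fractionator stereology.
A synthetic-data generator emulates a unilaterally lesioned bilateral brain
(dense somata in cell-group nuclei, curvilinear fibers in projection regions,
smooth background, additive noise) with full ground truth, so the entire
pipeline is testable without any real imaging data.

## Pipeline

1. **simulate** — build a mirror-symmetric toy atlas (NIfTI label volume +
   region table CSV) and a lesion/vehicle cohort with recorded ground truth
   (cell centers, fiber masks, applied effect factors).
2. **preprocess** — slice-wise rolling-ball background subtraction (grayscale
   opening with a flat disk), world-unit Gaussian smoothing (sigma in mm,
   fslmaths `-s` convention), hemisphere flipping, atlas-based exclusion
   masking.
3. **voxelwise** — 2×2 (side × treatment) permutation ANOVA F-maps with
   empirical p-values `(1+b)/(1+P)` (exact enumeration when feasible), then
   the four post hoc two-sample permutation t-contrasts gated by the union of
   ANOVA-significant voxels (uncorrected p < 0.05).
4. **fdr** — Benjamini–Hochberg step-up thresholding with the
   cluster-size-constrained q selection: the most stringent q on a grid that
   still admits a cluster of ≥ 100 significant voxels; 3D connected-component
   labelling (6/18/26 connectivity), direction splitting, regional
   composition tables.
5. **validate** — clusters are partitioned into cell-group and fiber parts,
   warped to tissue space, and measured per sample on a deterministic
   segmentation (quantile/Otsu threshold + minimum object size, or an
   external mask): 3D component counting with a centroid membership rule for
   cell density (cells/mm³) and the voxel-fraction fiber density (%), each
   validated by unpaired two-tailed t-tests.
6. **stereology** — shoelace polygon areas, count-weighted mean section
   thickness, systematic section sampling, the optical-fractionator total
   `N = ΣQ·(1/ssf)(1/asf)(1/tsf)`, and the ipsi/contra mean-fluorescence
   ratio.

## CLI

Every stage is a subcommand operating in a working directory; `run-all`
composes them. The bundled smoke configuration (32³ atlas, n = 3+3, 200
permutations) runs in seconds:

```bash
lesionmap run-all --smoke --workdir scratch/smoke
lesionmap simulate --smoke --workdir scratch/staged   # stage-wise
lesionmap preprocess --smoke --workdir scratch/staged
lesionmap voxelwise --smoke --workdir scratch/staged
lesionmap fdr --smoke --workdir scratch/staged
lesionmap validate --smoke --workdir scratch/staged
```

A YAML config may override any section of the defaults
(`lesionmap.pipeline.DEFAULT_CONFIG`): seed, atlas shape, cohort sizes,
densities/fills/effect factors, rolling-ball radius, smoothing sigma,
permutation count, alpha, q grid, minimum cluster size, connectivity and the
segmentation method. Outputs are plain NIfTI/CSV/JSON with a provenance hash;
reruns with the same config are byte-identical.

Stereology runs from trace CSVs:

```bash
lesionmap stereology --vertices traces.csv --sites sites.csv \
    --ssf 0.1667 --asf 0.2 --tsf 1.0 --out estimate.json
```

## Layout

```
src/lesionmap/
  volume_core.py        lattice types, affine warping, resampling, rescaling
  io.py                 NIfTI / TIFF / region-table CSV I/O
  synthetic_data.py     toy atlas + lesioned-cohort generator with ground truth
  preprocess.py         rolling ball, smoothing, flipping, exclusion mask
  voxelwise_stats.py    2x2 permutation ANOVA and post hoc t-contrasts
  fdr_clustering.py     BH FDR, q selection, clustering, direction splitting
  cluster_validation.py segmentation, counting, densities, validation tests
  stereology.py         optical fractionator and MFI ratio
  pipeline.py           stage orchestration, config, provenance
  cli.py                click-based command line
tests/                  unit, property and acceptance suites
scripts/acceptance.py   acceptance report
```
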