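# shellcount

Single-cell quantification of gene-delivery efficiency in dense 3D tissue
from two-channel confocal stacks: a nuclei channel that has been
instance-segmented (e.g. with Cellpose), and a cytoplasmic reporter channel
(e.g. AAV-delivered eGFP) whose expression varies strongly from cell to
cell.  The target users are organoid and gene-therapy labs that need
absolute, spatially resolved transduction efficiencies from live imaging —
for example to rank AAV serotypes by onset time and depth penetration in
retinal organoids.

## Method

Cytoplasm in packed neuro-epithelium cannot be segmented into cells, so the
pipeline never tries.  Instead:

1. **Transduced volume** — a seeded bagged-tree pixel classifier, trained on
   a sparse set of annotated voxels (dim *and* bright signal, at several
   depths), produces a per-voxel transduction probability; voxels with
   probability ≥ 0.5 are kept and objects ≤ 10 µm³ removed.
2. **Virtual shells** — every nucleus (volume > 100 µm³) is dilated by
   2 voxels and the union of all nuclei subtracted, leaving a thin
   (≈ 0.8 µm) perinuclear rind per cell; contested voxels go to the nearest
   nucleus, and shells < 50 µm³ (30 µm³ for mouse tissue) are discarded as
   artifacts.
3. **Classification** — a cell is transduced iff its shell overlap fraction
   |shell ∩ transduced| / |shell| is ≥ 0.4, a threshold calibrated against
   manual counting.  The transduction efficiency is

   E = N_Td / N_Tot

   computed per imaged area, then averaged areas → organoid → condition
   (unweighted at each step, never a pooled cell ratio), with SEM = σ/√N
   over organoids.  Depth profiles bin cells by nucleus-centroid depth into
   10 µm slices, excluding empty bins.

A seeded phantom generator (`shellcount.phantom`) produces synthetic
organoid stacks — packed ellipsoidal nuclei in two layers, bimodal-brightness
cytoplasmic rinds, depth gain, PSF blur and noise — with exact per-cell
ground truth, so every stage is testable without microscope data.

## Worked example

Classify every cell of a synthetic stack and compute its efficiency
(`examples/03_classify_cells.py`):

```python
from shellcount import PhantomConfig, RunConfig, generate_phantom, process_stack

res = generate_phantom(PhantomConfig(volume_shape=(100, 256, 256), n_nuclei=400,
                                     transduction_prob=0.7, seed=11))
out = process_stack(res.labels, res.transduced_mask, RunConfig())
```

prints

```
filter cascade: input_nuclei=400 -> band_filtered=400 -> volume_filtered=195 -> shell_filtered=195 -> transduced=145
N_Td = 145, N_Tot = 195
E = N_Td / N_Tot = 0.744
true fraction among surviving cells = 0.744
```

The cascade shows 400 placed nuclei, of which 195 pass the 100 µm³ nucleus
and 50 µm³ shell filters; 145 of those have shell overlap ≥ 0.4, giving
E = 74.4% — identical to the generator's true per-cell assignment among the
surviving cells, because the mask here is the ground-truth cytoplasm.  The
other examples cover phantom generation, classifier training (voxel F1 ≈ 0.93
against truth), depth profiles (recovering a 0.9 → 0.2 step across the 40 µm
layer boundary), and overlap-threshold calibration.

A thin CLI mirrors the stages:

```sh
shellcount phantom --seed 4 --out phantom/
shellcount segment --input reporter.ome.tif --annotations ann.csv --out mask.ome.tif
shellcount classify --nuclei labels.ome.tif --mask mask.ome.tif --out cells.csv
shellcount run --config run.yaml --manifest manifest.csv --input-dir stacks/ --out results/
```

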