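# lfseg — label-free cell segmentation of tissue microscopy

`lfseg` segments **every cell** in 2D confocal images and 3D z-stacks of
dense tissue **without segmentation stains**, using the back-scattered
excitation light (reflectance) that every laser-scanning confocal captures
for free.  It is aimed at microscopists and image analysts who want
flow-cytometry-style single-cell measurements from tissue sections while
keeping the whole fluorescence spectrum available for biologically
informative markers.

## How it works

A three-class U-Net is trained, with cross-entropy, to map the reflectance
image to per-pixel probabilities over {background, nuclei, cytoskeleton}.
Training labels come cheaply from one stained *training* section
(nuclear dye + F-actin or membrane counterstain, thresholded per channel);
after training, only reflectance is needed.  Individual cells are then cut
out by marker-controlled watershed: markers from the thresholded nuclei
probability, flooding over the elevation surface

    E = P(cytoskeleton) − P(nuclei)

restricted to the foreground `1 − P(background) ≥ 0.5`, followed by a
5th–95th percentile object-size filter.  Accuracy is scored against manual
annotations with the Jaccard index

    J(A, M) = |A ∩ M| / |A ∪ M|,

where `A` and `M` are the pixel sets of an automated object and a manual
annotation (J = 1: exact overlap; J = 0: missed cell; ~0.7 is a good
segmentation given hand-annotation ambiguity).  3D segmentations are
validated per plane on xy, zy and xz cross-sections.  Downstream, cells are
measured per channel (mean/integrated intensity, binarized fluorescence
area), gated sequentially (control-derived intensity cutoff, then
fluorescence-area fraction — the second gate removes bystander-positive
neighbors), binned into dim/low/intermediate/high expression levels, and
linked into nearest-neighbor graphs by 3-pixel boundary dilation.

Because no deep-learning framework is assumed, the networks run on a small,
fully deterministic numpy engine included in the package (`lfseg.nn`); the
published full-size training schedules are available as presets
(`published2d`, `published3d`) alongside reduced CPU-scale profiles
(`tiny`, `tiny3d`).

A synthetic tissue simulator (`lfseg.synthetic`) generates densely packed
contacting-cell scenes with paired fluorescence, reflectance-like, marker
and control channels plus exact instance ground truth, so the complete
pipeline runs and is validated at desk scale without any microscopy data.

## Worked example

Train the reduced 2D network on one simulated section, segment a held-out
section from reflectance alone, and score against the simulator's truth:

```python
import warnings; warnings.filterwarnings("ignore")
from lfseg.benchmarks import run_label_free_2d, run_bystander_gating

result = run_label_free_2d(seed=0)
print(f"held-out median IOU : {result['median_iou']:.3f}")
print(f"cells scored        : {result['n_scored']}")
print(f"final training loss : {result['loss_history'][-1]:.3f}")

gating = run_bystander_gating(seed=0)
print(f"gate sensitivity    : {gating['sensitivity']:.2f}")
print(f"gate precision      : {gating['precision']:.2f}")
print(f"bystanders removed  : {gating['false_positives_intensity_gate'] - gating['false_positives_sequential_gate']}")
```

prints (≈30 s on one CPU):

```
held-out median IOU : 0.812
cells scored        : 49
final training loss : 0.136
gate sensitivity    : 1.00
gate precision      : 1.00
bystanders removed  : 21
```

A median IOU of 0.81 against exact truth on a *held-out* scene means the
tiny network learned the reflectance→structure mapping and the watershed
recovered individual touching cells; the gating numbers show the
sequential fluorescence-area gate removing all 21 bystander-positive
neighbors created by marker spill-over while keeping every planted
positive cell.

The same pipeline is available from the shell:

```sh
lfseg simulate --out scenes/train --seed 1 --shape 256,256 --n-cells 60
lfseg simulate --out scenes/test  --seed 2 --shape 256,256 --n-cells 60
lfseg train    --scene scenes/train --preset tiny --out run/model.npz
lfseg predict  --model run/model.npz --scene scenes/test --tile 128,128 --out run/probs.tif
lfseg segment  --probmap run/probs.tif --out run/cells.tif
lfseg evaluate --auto run/cells.tif --manual scenes/test/truth.tif --out run/report
lfseg profile  --objects run/cells.tif --scene scenes/test --out run/profile
```

Every command writes a manifest (config + seed + input checksums) beside
its outputs; `evaluate` refuses to score a model on the scene seed it was
trained on unless `--allow-train-eval` is passed.

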