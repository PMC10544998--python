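# Methods

## The problem and the approach

`stagedistill` trains a compact convolutional **student** classifier for a
severely imbalanced multi-class image task (the reference task is 5-way
subtyping of lung-adenocarcinoma surgical-specimen photographs: Grade 1/2/3,
AIS, MIA, with class counts as skewed as 41 : 1317 : 196 : 121 : 546) by
distilling knowledge from a stronger, frozen **teacher** network. Both
networks are treated as four ordered stage blocks with the conventional
4×/8×/16×/32× downsampling schedule, plus a classification head.

Three signals are combined into one objective:

```
L = α · L_feat + (1 − α) · L_soft + β · L_focal
```

* **Feature matching** `L_feat`: for each stage k, a learnable 1×1
  convolution (the *adapter*) projects the student's stage-k feature map
  into the teacher's channel space; the loss is the mean squared difference
  against the teacher's stage-k map, averaged over the four stages. The
  teacher-side transform is the identity — only the student carries an
  adapter. If spatial sizes differ (they do not for backbones sharing the
  standard schedule), the adapted map is bilinearly resized to the
  teacher's.
* **Soft targets** `L_soft`: cross-entropy between the teacher's and the
  student's temperature-smoothed class distributions,
  `p_i(z; T) = exp(z_i/T) / Σ_j exp(z_j/T)`, averaged over the batch. A
  higher temperature T exposes more inter-class structure, which carries
  proportionally more signal for rare classes. The tempered cross-entropy
  is used literally, with no `T²` gradient rescaling (a `t_squared` flag
  restores the classic variant; default off).
* **Focal ground-truth loss** `L_focal`:
  `−α_t (1 − p_t)^γ log p_t` averaged over the batch, where `p_t` is the
  predicted probability of the true class and `α_t` a per-class weight.
  The focusing term down-weights easy (majority-class) examples; the
  weights up-weight rare classes.

No gradient ever reaches the teacher; the student and the four adapters are
optimized jointly with decoupled-weight-decay Adam.

### Reduction conventions

The stage reduction of `L_feat` (MSE per stage, then mean over the four
stages) keeps the loss magnitude independent of feature-map and channel
sizes, so the mixing coefficient α transfers across backbone pairs. The
batch reduction of `L_soft` and `L_focal` is the mean.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| α | 0.5 | feature-vs-soft mixing; reference protocol value |
| β | 1.0 | weight of the supervised focal term; reference protocol value |
| T | 4.0 | distillation temperature; conventional mid-range value (the reference protocol does not state one), exposed in config |
| γ | 2.0 | focal exponent; the standard choice (again unstated in the reference protocol), exposed in config |
| α_t | inverse class frequency, mean 1 | `w_c = (1/n_c) / mean_j(1/n_j)`; mean-1 normalization keeps the focal term on the cross-entropy scale and is invariant to dataset size |
| learning rate | 0.001 | AdamW, reference protocol |
| first-moment decay | 0.9 | the "momentum" of the reference protocol, read as Adam's β₁ since AdamW has no classical momentum |
| weight decay | 5e-4 | decoupled, applied to matrices only (biases exempt, the usual convention) |
| epochs / batch | 100 / 32 | reference protocol defaults |
| repeats | 5 | each repeat re-partitions the data and retrains from scratch, seeds `seed … seed+4` |

`p_t` is floored at 1e-12 before the log so a confident wrong prediction
yields a large finite loss rather than −∞.

## Staged backbones

Any network expressible as a named sequential composition can be cut into
4 stages + head with `partition_backbone`; the composed forward pass is
bitwise identical to the uncut network, and the per-stage channel counts /
downsampling factors are read off a probe forward pass, so adapters always
get the right shapes. Full-size backbones plug in through this contract.

The bundled miniature stand-ins keep the whole protocol runnable on one
CPU in minutes: a student with stage widths (8, 16, 32, 64) (~25k
parameters, one 3×3 stride-2 convolution + ReLU per stage, two in the
stem) and a wider, deeper teacher with widths (12, 24, 48, 96) and two
convolutions per stage (~100k parameters). Global average pooling feeds a
linear head. All arithmetic is float32 NumPy with deterministic seeding:
identical config + data ⇒ bitwise-identical training histories.

## Training protocol

The three loss components are optimized **jointly** (the combined `L` is
the objective), not as sequential phases: the staged description of the
procedure is read as three loss *components*. To accommodate the
sequential reading, a configurable feature-only warm-up precedes joint
optimization (`warmup_epochs`, engine default 0): during warm-up only
`α·L_feat` is optimized, letting the randomly initialized adapters align
with the teacher's feature basis before the label losses shape the
student.

Run modes ablate the objective: `plain` (focal only, no teacher), `logits`
((1−α)L_soft + βL_focal), `feature` (αL_feat + βL_focal), `full` (all
three). The best-on-validation-accuracy checkpoint is retained per run.
`freeze_all_but_head` reproduces a pure transfer-learning baseline; it is
off in distillation modes because feature matching is vacuous with a
frozen trunk.

### Desk-scale protocol

The reference task's data are private and full backbones are GPU-scale, so
the repository's experiments run the miniature pair on the synthetic
dataset (below): 300 images at 64×64, students trained 20 epochs, the
teacher 30 epochs (plain mode, best-on-validation), feature warm-up 2
epochs, five repeats with seeds `s … s+4`, each repeat re-partitioning the
data 8:1:1. The warm-up length and teacher budget were chosen by a pilot
across three disjoint seed bases: 2 warm-up epochs was the only setting
where full distillation matched or beat the plain student on every base —
without warm-up the randomly initialized adapters inject noisy feature
gradients exactly in the epochs that decide a 20-epoch run. Augmentation
is available throughout the pipeline but is disabled in the desk-scale
runs: at 64×64 with 20 epochs it mostly slows convergence, and its
correctness is tested separately.

At this scale the test split holds only ~31 images (singleton minority
classes), so macro-F1 has Monte-Carlo noise of roughly ±0.05 on the
5-seed mean; the full-vs-plain comparison is accordingly a coarse ordering
check, not an effect-size estimate.

## Data pipeline

Manifests (CSV: `path,label[,lesion_id,split]`) are the unit of exchange.
Splitting is stratified per class and deterministic given a seed: within
each class, `round(0.8·n)` samples go to training (this reproduces the
reference task's published per-class training counts and their total of
1778 exactly), `round(0.1·n)` of the remainder to the **test** split, and
the rest to validation. Test is allocated before validation so that a
class with only a handful of images is represented in the split where
per-class metrics are computed; validation only steers checkpoint
selection via overall accuracy. The published validation/test totals of
the reference task (234/209) are not reproducible by any per-class
arithmetic rule — the published row for the majority class puts 122 of
263 non-training images in test, far from any 1:1 or 10% rule — so this
package's rule yields 220/223 on those counts; the discrepancy is
documented rather than special-cased. An optional `lesion_id` column
groups all images of a lesion into one split to prevent leakage; a
non-stratified global split exists behind a flag.

Augmentation (training split only): independent horizontal/vertical
flips, random cropping removing at most 10% of image area (resized back),
and random translation up to 10% per axis with edge padding. Preprocessing
resizes to the target square (default 224, 64 in desk-scale runs), scales
to [0,1] and normalizes per channel. Input channels default to 3 (the
reference images are colour photographs); a grayscale mode exists.

## Synthetic dataset

The generator emulates exactly two properties of the clinical data:
severe class imbalance (default proportions 41 : 1317 : 196 : 121 : 546,
apportioned by largest remainder — 300 images give 6/178/26/16/74) and
class-discriminative colour/texture structure. Each class has a base hue,
an elliptical blob density and radius range, and a vein-line count; images
are rendered with per-image hue jitter (σ = 0.025) and Gaussian pixel
noise (σ = 0.06 of full scale). A `difficulty` knob in [0,1] linearly
interpolates all class parameters toward their common mean: at 0 the
classes are maximally separable for the palette, at 1 they are identically
distributed and only chance performance is possible.
`expected_separability` reports the mean pairwise distance between the
interpolated class parameter vectors, normalized to 1 at difficulty 0.

The palette was calibrated so difficulty is *meaningful* for the miniature
student — roughly: macro-F1 ≈ 0.9 at difficulty 0, ≈ 0.8 at the default
0.3, ≈ 0.5 at 0.6, chance at 1. What passing tests on this fixture shows
is that the losses, gradients, staging and protocol are implemented
correctly and that the pipeline orders ablation modes sensibly on an
imbalanced separable task. It shows nothing about histology: there is no
staining variation, no morphology, no inter-lesion correlation, and the
colour cue is far cleaner than any real tissue signal.

## Evaluation

Confusion matrices use rows = true, columns = predicted (a transposed
display is available for reports that print the other orientation).
Per-class precision/recall/F1 are one-vs-rest; macro values are unweighted
means. A class never predicted gets precision 0 and is counted in
`n_undefined` instead of producing NaN. Two macro-F1 variants are
reported, because they differ and published tables are only reproducible
under the second: `macro_f1` (mean of per-class F1) and `macro_f1_paper`
(harmonic mean of macro precision and macro recall).

## Known limitations

* The NumPy layer kit covers exactly what the miniature backbones need
  (strided 3×3 convolution, ReLU, global average pooling, linear); there
  is no batch norm, dropout, attention, or GPU path. Full-size backbones
  are supported by contract, not by bundled implementations.
* Checkpoints store raw parameter arrays plus factory metadata; only
  miniature-factory models can be rebuilt from a checkpoint alone.
* The desk-scale ablation's full-vs-plain margin is small relative to its
  seed noise (see above); increasing `total_images` sharpens it at the
  cost of runtime.
* The synthetic learnability floor (difficulty 0, macro-F1 ≥ 0.8 over
  3 seeds) is a mean over seeds; individual seeds can dip below when the
  single minority-class test image is missed.
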