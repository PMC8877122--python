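# Methods

## The featurization

Image-based QSAR replaces hand-picked molecular descriptors with photographs
of the molecule itself.  Each compound's SMILES string is converted to a
single low-energy 3D conformer (distance-geometry embedding followed by
MMFF94 minimisation, explicit hydrogens, fixed random seed) and depicted as
a ball-and-stick model.  The model is then "photographed" from a grid of
orientations: for an angle increment θ, the per-axis angle set is every
multiple of θ in [0°, 360°), and the snapshot set is the full Cartesian
product over rotations about the x-, y- and z-axes — m³ images per molecule
when θ has m multiples below 360°.  Multi-angle capture is the pipeline's
only data augmentation: at θ = 360° a molecule contributes exactly one
image, at θ = 120° it contributes 27.

The renderer is a self-contained numpy rasterizer rather than a wrapper
around an interactive viewer, because the images are the model's input
features and must be bit-reproducible.  Conventions: centre on the centroid;
rotate about the fixed lab x-, then y-, then z-axis; orthographic
projection scaled to fit the molecule's bounding sphere (atom radii
included) with a 10% margin, which guarantees background-coloured corners;
z-buffered sphere and cylinder impostors with Lambert shading under one
fixed directional light; CPK atom colours; bonds drawn as two half-cylinders
taking their atom's colour.  Default image size is 256×256 RGB PNG; the
background colour (default black) is a style parameter.

## Labels

Activity scores come from reporter-assay well values through

    % activity = (V_compound − V_dmso) / (V_pos − V_dmso) × 100,

and a compound is *active* when its 0–100 score is ≥ 40, *inactive*
otherwise.  Screens of this type are heavily imbalanced (roughly 1–5%
actives), which drives several choices below.

## Splitting

The split unit is the molecule, never the image: all rotated views of one
structure land in the same partition, so near-duplicate images cannot leak
between train and test.  Sizes follow the requested train:valid:test ratio
by largest-remainder apportionment (ties resolved train → valid → test), and
actives are apportioned separately so every partition's active fraction is
within one molecule of the global fraction.  Assignments are a function of
the molecule ids and the seed only — permuting the input rows changes
nothing.  A foldout test set can be pinned (`fixed_test_ids`) so that later
ratio changes re-split only train and valid.  Stratification can be
disabled, but with 1% actives an unstratified valid partition frequently
contains no active at all.

## Classifier and training

The classifier is a small convolutional network implemented directly on
numpy (im2col convolutions, batch normalisation, ReLU, max-pool, global
average pooling, softmax head).  The default `tinycnn` has three 3×3 conv
blocks (8/16/32 channels, each conv–batchnorm–ReLU, the first two followed
by 2× max-pool) and a 2-class linear head; `pixellr` (multinomial logistic
regression on raw pixels) is registered as the linear baseline.  Snapshots
are downsampled to 64×64 with a box (area-average) filter — an
interpolating filter point-samples on large reductions and can drop small
colour features entirely — and standardised per channel with training-set
statistics that are stored on the model.

Training is plain SGD with momentum 0.9 at a constant learning rate, for at
most 30 epochs (default).  After each epoch the unweighted mean
cross-entropy is recorded on both partitions; training halts early when the
validation loss has not improved for `patience` consecutive epochs
(default 5; patience 0 disables early stopping), and the returned model is
the checkpoint from the epoch with the lowest validation loss.  Class
imbalance is handled by inverse-frequency class weights in the training
loss (on by default); the recorded losses stay unweighted so histories are
comparable across weighting choices.  An early design iteration that also
early-stopped on the weighted loss was rejected: with a 20-molecule valid
partition containing a single active, the weighted loss is dominated by one
sample and the stopping time becomes noise.

Everything is deterministic given the seed on a fixed machine: weight
initialisation, batch order, and batch-norm statistics all flow from one
`numpy` generator.

## Evaluation

Per-image probabilities are aggregated to one score per molecule by the
median (mean of the middle two for even counts).  The decision cutoff θ is
the observed score value maximising Youden's J = sensitivity + specificity
− 1, ties broken toward the smallest cutoff; a molecule is called active
when its score is ≥ θ.  By default θ is fit on the partition being
reported; a cutoff fitted elsewhere (e.g. on the validation set) can be
passed in instead.  From the confusion matrix the report carries
sensitivity, specificity, BAC = (sensitivity + specificity)/2, accuracy,
precision, recall, F = 2·recall·precision/(recall + precision), and
Matthews' correlation (defined as 0 when its denominator vanishes), plus
the rank-based (Mann–Whitney, ties at ½) ROC AUC, the step-integrated
precision–recall AUC (average precision), and the mean cross-entropy of the
aggregated scores.  The BAC identity is asserted in-code on every report.

`paper_roc_auc` is a second, threshold-weighted AUC estimator kept separate
from the rank-based one.  It walks the sorted unique scores as thresholds
(descending, so the precision profile is non-increasing for well-ranked
data), gives each threshold the central-difference weight
W_t = (prec_{t−1} − prec_{t+1})/2 under the endpoint conventions
prec₀ = prec₁ and prec_T = 0, and averages, over the true points, the sum
of weights each point's score reaches.  The weighted sum telescopes to the
interpolated precision at the point's own threshold, so the estimate is
translation-invariant in the scores, lies in [0, 1] for monotone precision
profiles, and equals 1 on perfectly separated data — but it is a
precision-flavoured approximation and differs numerically from the
rank-based AUC on overlapping score distributions, which is why both are
exposed.  The multi-category generalisation of Youden's index is not
implemented; only the binary case is.

## Sweeps

A sweep axis is one of angle, split ratio, learning rate or batch size; a
condition is one value on that axis plus its replicate seeds (defaults: 3
replicates for angle and split, 2 for learning rate, matching common
screening practice).  Each condition × seed runs the full pipeline;
failures are recorded per condition without aborting the sweep, and
finished runs can be cached on disk keyed by a config hash, making sweeps
resumable.  Replicates are averaged within a condition first; the summary
then reports, per metric, the mean ± sample (n−1) SD across condition
means, the extremum (minimum for loss, maximum otherwise), and the
condition achieving it.

## The synthetic library

The fixture generator emulates a screening library at desk scale: two
parametric SMILES families with an image-learnable structure–activity rule.
Inactives are branched hydrocarbons (grey/white spheres only); actives are
nitro-substituted aromatics, whose red oxygens and blue nitrogen make the
label recoverable from gross colour statistics (the linear functional
mean(R − G) separates the classes perfectly on rendered snapshots).
Families are enumerated deterministically and deduplicated on canonical
SMILES, so generated libraries pass curation unchanged.  Scores are not
assigned directly: each molecule receives raw well values that map through
the %-activity equation to a nominal score (75 for actives, 10 for
inactives) plus truncated Gaussian noise (SD 5 by default), keeping labels
consistent with the ≥ 40 threshold by construction.  The default class
imbalance is 5% — the upper end of the 0.87–5.19% range typical of such
screens — because a 0.87% library needs thousands of molecules before a
7:1:2 split leaves any active in the valid partition; both extremes remain
reachable through `active_fraction`.

A generation-time probe fits a pixel-level logistic regression and requires
≥ 0.95 accuracy on the generated set.  This certifies that the label is
decodable from the images alone; it deliberately does not certify held-out
generalisation of a linear model, which fails here for an instructive
reason — the generalising colour direction has a tiny margin relative to
within-class shape variance, exactly the situation where a convolutional
network's shared filters and global pooling pay off.

What the fixture does *not* emulate: real chemistry-space diversity,
conformational ambiguity, activity cliffs, or label noise from assay
artefacts.  Passing the desk-scale suite therefore demonstrates that the
pipeline's machinery is correct and that an image-learnable signal is
recovered end-to-end; it says nothing about predictive performance on a
real screening library.

## Numerical choices and degenerate inputs

* Angle grids use exact floating multiples of θ; θ must be positive, and
  angles are validated to [0°, 360°).
* Metrics with zero denominators (precision, F, MCC, …) are defined as 0.
* Youden's cutoff requires both classes; single-class inputs raise a
  degenerate-labels error, as do both AUCs.
* `% activity` with coinciding control medians raises rather than dividing
  by zero.
* Median aggregation of an empty probability list is an error, not a NaN.
* Embedding retries distance-geometry up to 5 times with incremented seeds
  before failing with the molecule id; curation drops unparseable SMILES
  with a logged count instead of raising.
* SDF I/O uses the V2000 dialect; coordinates survive a round-trip to the
  format's 4-decimal precision.

## Problem sizes

The shipped test suite and the acceptance script run the end-to-end
experiment at 200 molecules / 5% actives / θ = 360° with the 64×64 input
CNN — sizes chosen so a complete run takes about a minute on one CPU core
while still exercising every stage on several hundred images.  Larger
angle grids (θ = 120° already gives 27 images per molecule) scale linearly
in rendering and training time.

## Known limitations

* The renderer is orthographic with sphere/cylinder impostors; it does not
  reproduce any particular viewer's pixel output (nor ray-traced shadows).
* Conformer generation returns a single minimised conformer; molecules
  whose activity depends on conformational ensembles are out of scope.
* The numpy network trains desk-scale problems; it is not a GPU framework,
  and architecture fidelity to any published large CNN is a non-goal.
* `paper_roc_auc` is an approximation by construction; the rank-based
  estimator is the primary ROC AUC everywhere.
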