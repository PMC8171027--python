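# Methods

## The prediction problem

A non-coding variant locus is "functional" if it measurably perturbs gene
regulation. `sslvar` casts this as binary classification of a genomic
position from two information sources observed in a 150-bp window centred on
the variant:

1. **Sequence context** — the window's nucleotides, one-hot encoded as a
   150 x 4 binary matrix (column order A, T, C, G; ambiguous bases get an
   all-zero row).
2. **Epigenetic state** — for each of ten histone marks (H3K4me1, H3K4me2,
   H3K4me3, H3K9ac, H3K9me3, H4K20me1, H3K27ac, H3K27me3, H3K36me3,
   H3K79me2) and DNase I sensitivity, three window summaries:
   *Peak* (1 iff the variant base lies inside a peak interval), *Max*
   (maximum per-base enrichment over the window) and *Sum* (total per-base
   enrichment). 33 values.
3. **Nucleotide composition** — mononucleotide counts of A/T/G/C; counts of
   the dinucleotides GC, GT and GA over overlapping adjacent pairs;
   AT skew = (A − T)/(A + T) and GC skew = (G − C)/(G + C) on
   mononucleotide totals; and their ratio GC_skew/AT_skew. 10 values.

Coordinates are 0-based half-open throughout (the native BED/bedGraph
convention); strand is ignored. An even window cannot centre exactly on one
base: we use `[pos − 75, pos + 75)` so the variant sits at row 75. Skews
with zero denominators return 0.0 to keep the feature vector finite. In the
skew denominators "GC count" means the mononucleotide total G + C, which is
distinct from the dinucleotide GC count feature; both are computed, named
`gc_mono`-style (`g_count + c_count`) versus `gc_dinuc_count`.

Overlapping intervals within one track are merged at load time by per-base
maximum — tracks are treated as a single enrichment profile, and maximum is
the conservative resolution when replicate peak calls disagree.

## Network

The sequence branch treats the one-hot map as a length-150 signal with 4
input channels: conv(kernel 4, stride 1) → 2 channels → ReLU → conv(kernel
4, stride 1) → 4 channels → ReLU → dropout(0.5) → max-pool(kernel 2, stride
2), yielding a 4 x 72 dense map whose 288 values are concatenated with the
43 tabular features. Three fully connected layers of sizes 40, 10, 2
follow; the first has batch-norm, ReLU and dropout(0.5), the second
batch-norm and ReLU, and the third is followed by a ReLU and a softmax over
the two class units. Every length obeys `floor((L − k)/s) + 1`, so the
chain is 150 → 147 → 144 → 72 and the first FC layer sees 288 + 43 = 331
inputs. An alternative preset (`ModelConfig.literal_text_geometry`) with
kernels 1 and 2 and stride 2 on the second convolution is provided for
comparison; its pooled map is 4 x 37 and it is not the reference geometry.

The implementation is a self-contained float64 numpy network with
hand-written backward passes, verified against central-difference gradients
in the test suite. This keeps training bit-reproducible under a single
seeded generator — a property the semi-supervised-versus-supervised
equivalence checks rely on — and the architecture is small enough that CPU
numpy is entirely adequate (a 30-epoch run on 2000 loci takes a few
seconds). Parameters are initialised uniform(−1/√fan_in, 1/√fan_in);
batch-norm uses batch statistics during training and running averages
(momentum 0.1, variance floor 1e-5) at evaluation; dropout is inverted
(masks scaled by 1/(1 − p)).

A note on the post-FC3 ReLU: clipping logits at zero before the softmax is
unusual (a sample whose both logits are negative receives no gradient), but
it is part of the layer narrative this architecture follows and trains
without trouble at this scale; it is kept deliberately.

## Semi-supervised training with pseudo labels

The loss is `L = L_label + alpha(t) · L_unlabel`: both terms are mean
cross-entropies, the unlabeled one against the model's own argmax
predictions (pseudo labels, ties broken toward class 0). The weight

```
alpha(t) = 0                    t ≤ T1
         = (t − T1)/(T2 − T1)   T1 < t < T2
         = 1                    t ≥ T2
```

ramps up the unlabeled term; `t` counts **global optimizer steps** (one per
labeled mini-batch), which is the only reading consistent with T1 = 100 and
T2 = 600 against epochs of tens of batches. The boundary points, excluded
by the strict inequalities of the piecewise definition, take their
continuous limits.

Each epoch iterates labeled mini-batches of 16; when `alpha > 0` each step
also draws an unlabeled mini-batch of 32 (without replacement within an
epoch, reshuffled when exhausted), computes pseudo labels from the same
training-mode forward pass whose gradient is taken — the classical
self-labelling step — and applies one SGD update (learning rate 0.03,
momentum 0) to `grad(L_label) + alpha · grad(L_unlabel)`. When `alpha = 0`
the unlabeled pass is skipped entirely; it would contribute nothing to the
gradient, and skipping it makes the supervised baseline (`mode="supervised"`,
which pins alpha at 0 and disables promotion) *bit-identical* to the
semi-supervised loop before the ramp starts, not merely statistically
equivalent.

At the end of every epoch the remaining pool is scored in evaluation mode
and every example with max predicted probability ≥ 0.95 is promoted
permanently into the labeled set, carrying its pseudo label. Promotion
cadence is once per epoch end (the natural reading of "used in the next
epoch"); promoted examples thereafter count toward `L_label`; their true
labels are retained only in the audit trail. Pseudo-label targets are
computed for **all** rows of each unlabeled batch, not only confident ones —
the classical pseudo-label formulation; the confidence threshold governs
promotion only.

Preprocessing (log1p on the Max/Sum columns, then per-column z-scoring) is
fitted on the labeled training part only and reapplied unchanged to the
unlabeled pool and validation set; zero-variance columns get scale 1 so
constant features become exactly zero.

## Dataset splits

`make_split` partitions a catalogue into a class-balanced labeled part, a
class-balanced validation part, and an unlabeled remainder that inherits
whatever imbalance the catalogue has (positives are typically a 10–20%
minority, matching real variant catalogues where balancing the labeled and
validation parts exhausts the positives). Splits are stratified, seeded and
disjoint by locus.

## Synthetic benchmark

The generator emulates the statistical structure the method assumes, so the
whole pipeline is exercisable with no external data:

- **Genome**: i.i.d. uniform A/C/G/T, default 2 chromosomes x 200 kb.
- **Tracks**: per-mark peaks from a renewal process (exponential gaps, mean
  4 kb; uniform lengths 400–1200 bp; DNase narrower and denser at 150–400 bp
  with mean gap 3 kb), log-normal enrichment (log-mean 1.0, log-sd 0.5).
  DNase peaks are re-seated inside H3K27ac peaks with probability 0.7,
  emulating the coupling of accessibility with active enhancers.
- **Loci**: candidate positions uniform over the genome;
  `P(functional) = logistic(intercept + Σ_m w_m z_m)` where `z_m` is the
  candidate-standardized window Max score of mark m and `w` is a cell-line
  effect vector. Effects act through the same window scores the pipeline
  extracts, so the planted signal is learnable by the feature set by
  construction. Labels are drawn from that probability and then flipped
  with probability 0.15 — chosen so attainable AUCs land in the 0.65–0.75
  band typical of this problem rather than saturating (the Bayes-optimal
  AUC computed from the latent probabilities is ≈ 0.69–0.70 under the
  defaults, and it upper-bounds any trained model).
- **Default benchmark**: two cell lines with orthogonal effect vectors —
  cell A driven by accessibility/enhancer marks (DNase 1.5, H3K27ac 1.0,
  H3K4me1 0.8), cell B by promoter marks (H3K4me3 1.2, H3K4me2 1.0,
  H3K9ac 0.8) — 2000 loci each at a 20% positive rate, split 320 labeled
  (160/160), 1520 unlabeled, 160 validation (80/80).

What the generator does **not** emulate: realistic nucleotide composition
(no isochores, CpG islands or motifs by default — an optional planted-motif
hook exists), mark-to-mark correlation structure beyond the DNase–H3K27ac
coupling, broad domains versus sharp peaks, or linkage between nearby loci.
Consequently a passing benchmark demonstrates that the pipeline recovers
planted epigenetic signal and that pseudo-labeling behaves as designed; it
does not certify performance on real epigenomes.

## Evaluation

AUC uses the rank (Mann-Whitney) statistic with averaged ties, equal to the
trapezoidal area under the ROC points. Cross-validation is stratified
k-fold (default 5), each fold trained from scratch, held-out folds balanced
by seeded subsampling; summaries report mean ± sd/√k. Cross-cell-line
transfer scores each fold's model on a fixed balanced validation split of
every other cell line and compares the five within-cell with the five
cross-cell AUCs by a Welch two-tailed t-test (equal variances not assumed —
the more conservative choice where the text of a comparison specifies only
"two-tailed t-test"). Feature-group ablations zero the excluded tabular
columns rather than shrinking the first FC layer, so AUC differences
reflect features, not architecture; the sequence branch is retained for
mark groups by default (`tabular_only` switches it off), kept alone for the
Seq-based group, and zeroed for the Nuc-based (composition-only) group.

## Problem sizes and numerical choices

Benchmark-level comparisons (semi-supervised vs supervised; within- vs
cross-cell transfer) run 30-epoch trainings: with 20 labeled batches per
epoch, the alpha ramp completes near epoch 18, and validation AUC plateaus
well before epoch 30 at this data size, so longer runs add cost without
changing the comparisons. The default `epochs` for general use remains 100.
Five training seeds per condition are used for seed-mean comparisons.
Cross-entropy probabilities are floored at 1e-12 inside logs; softmax
subtracts the row maximum; exact probability ties in `pseudo_label` break
toward class 0 deterministically.

## Known limitations

- The supervised baseline shares the promotion-free code path but still
  trains on the same balanced labeled set; no class-weighting is applied
  anywhere.
- Pseudo-label noise compounds: a wrong confident promotion is permanent by
  design, which is faithful to the method but means early-epoch calibration
  matters; the audit trail exists precisely to quantify this.
- The bigWig adapter loads entire chromosomes' intervals into memory;
  adequate for per-cell-line track sets, not for whole-genome multi-sample
  collections.
- `momentum` is accepted in the configuration for completeness but the
  reference setting is plain SGD (momentum 0).
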