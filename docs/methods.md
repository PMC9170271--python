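# Methods

## The model

`mccm` predicts per-residue protein secondary structure (eight DSSP states
C, B, E, G, I, H, S, T, coarsened to H/E/C for three-state scoring) with a
cascade of two classifiers over one shared feature trunk.

**Input encoding.** Each residue is a 50-vector: a 21-dim identity one-hot
(20 standard amino acids plus X), a 21-dim sequence profile
(logistic-rescaled substitution scores from an iterative homology search),
7 physicochemical parameters (steric parameter, polarizability, van der
Waals volume, hydrophobicity, isoelectric point, helix and sheet
propensity), and a 1-dim conservation score. The conservation score is
recovered from the profile: the logistic rescale is inverted to give
scores S_i, probabilities L_i = exp(S_i·λu)·P_i are formed against a
background distribution P (λu = 0.3176; Robinson–Robinson frequencies by
default), renormalised onto the 20-simplex, and scored as
R = log 20 + Σ L_i log L_i (natural log, so R ∈ [0, log 20]). The
renormalisation step and the background vector are choices of this
package: the score is only defined on a probability vector, and published
descriptions of the encoding do not pin the background source. Both are
configurable through `EncodingConfig`.

**Feature trunk.** Four per-block linear branches (hidden sizes 64, 128,
32, 16; dropout τ) are concatenated (width 240) and convolved with
same-length 1-D kernels of sizes 5, 9, 13 (64 channels each, ReLU),
giving the *easy feature* c (width 192). A bidirectional gated recurrent
pass (hidden 256 per direction) over c yields per-position global
contexts h (width 512); additive attention (hidden 256) with softmax
restricted to real residues pools h into a per-protein summary α_h, and
the *hard feature* is v = [c, h, α_h] with α_h tiled to every position
(width 1216). Convolutions are zero-padded and centred so every residue
keeps an output; a per-sequence α_h concatenated with per-position blocks
is only shape-consistent if tiled, which is what we do.

**Heads and evidential opinions.** The easy head is a single affine map
c → Z logits; the hard head is a multilayer perceptron (512, 1024, ReLU,
dropout) over v. Each head's logits are read twice: softmax for
cross-entropy, and rectified into evidence e = relu(logits) defining a
Dirichlet opinion α = e + 1 with strength S = Σα and expectation p = α/S.
Both losses attach to the same logits; no separate evidence head exists.
The evidential loss is the expected Brier score under Dir(α),

    L_dir = Σ_z (y_z − p_z)² + p_z(1 − p_z)/(S + 1),

i.e. squared error of the expectation plus the Dirichlet variance. The
printed form of this loss is typographically ambiguous between
multiplying and dividing the variance term by (S+1); we divide, the form
under which the loss is the expected Brier score — verified against a
Monte-Carlo Dirichlet oracle in the tests.

**Routing.** Difficulty is measured by the base-2 Shannon entropy H(p) of
the easy head's opinion. During training a residue is routed *easy* iff
the easy head already calls it correctly **and** H is below the per-th
percentile (per ∈ {15, 30, 35}) of the batch's entropies; otherwise
*hard*. At test time no labels are consulted: a residue is easy iff H is
below a frozen threshold, taken as the running average of the per-batch
training percentiles. Averaging over all batches (rather than keeping
only the final epoch's percentile) makes the frozen threshold an
intentionally conservative estimate; with it roughly the hardest quarter
of residues is routed to the hard head in our runs. Easy-routed residues
take the easy head's argmax-p call, hard-routed the hard head's; argmax
ties break toward the lowest class index.

**Objective.** ce_easy and the easy head's evidential loss average over
all real residues; ce_hard and the hard head's evidential loss average
over hard-routed residues only. The combined objective is

    L = ce_easy + β·dir_easy + ce_hard + β·dir_hard   (β = 1 default),

so hard residues accumulate both heads' penalties — the mechanism that
shifts capacity toward hard examples. Variants: `mccm` (label routing:
easy iff correct; diagnostic upper bound), `mccm_easy` (label routing,
hard terms recorded but not backpropagated), `mccm_dir` (evidential
routing; the deployable model), `mccm_conf` (early-exit baseline routing
on softmax confidence > 0.9; the confidence comparison is implemented in
the exit-when-confident direction of the early-exit literature), and `c1`
(conv features + easy head, plain cross-entropy; the easy-only ablation).

## Numerical machinery

No GPU tensor framework is used: the network runs on a compact in-package
reverse-mode autodiff engine over numpy (`mccm.nn`), with Adam
(lr 5e-4 default), uniform fan-in initialisation, and inverted dropout.
All randomness — initialisation, batch shuffling, dropout masks — flows
from a single seeded generator, so training histories are bit-reproducible
from the seed. Batches are whole proteins padded to the longest member;
padded positions carry zero features, receive zero attention mass, and are
excluded from every loss, routing decision and metric. A non-finite loss
aborts training with a diagnostic. Gradient correctness is checked against
central finite differences in the test suite.

## Synthetic data

The generator emulates the statistical situation the method assumes, not
protein physics. Labels follow a short-memory Markov chain (self-transition
0.9, mean run ≈ 10 residues) with stationary state frequencies matching a
realistic benchmark label distribution (30.9% H, 21.3% E, 21.1% C, …).
Class signal lives in the 20-dim profile-score space: one random
unit-direction centroid per class, isotropic unit noise, logistic squash.
Easy residues use centroids with pairwise separation ≈ 11 (score units,
chosen so that a linear classifier is essentially Bayes-separable —
certified at ≥ 99% in the tests); hard residues use the same directions
shrunk to pairwise separation `hard_overlap` (default 1), making them
ambiguous from their own features. Hardness arrives in segments (two-state
chain, mean hard segment 6 residues) rather than independently per
residue, mirroring how alignment quality degrades over whole stretches of
real profiles; this also means the information that rescues a hard
residue often sits beyond the convolutional kernels' reach, which is
exactly the regime where the recurrent/attention branch earns its keep.
Ground-truth easy/hard flags are stored on each record for test oracles.
What the generator does **not** model: amino-acid/structure dependence in
the identities, sheet-partner long-range correlations, class-dependent
physicochemical signal, or real profile noise statistics — so passing the
behavioural tests certifies the mechanism (routing, loss accumulation,
context use), not benchmark-level accuracy on real proteins.

## Desk-scale study conditions

The behavioural tests and `scripts/acceptance.py` train at desk scale on
1 CPU: ≈ 30–50 proteins of 60–120 residues, extractor widths 16/24/8/4,
conv 12 channels × kernels {3,5,7}, recurrent hidden 16, MLP 48/64,
learning rate 5e-3, dropout 0.2, up to 30 epochs. Learning rate and
dropout are scaled to these widths (0.5 dropout is calibrated to
512/1024-unit layers and cripples 48-unit ones); all full-scale defaults
remain the published values (64/128/32/16, 64 × {5,9,13}, 256, 512/1024,
lr 5e-4, τ 0.5). Comparisons between variants are made at convergence:
the easy-only ablation optimises much faster than the cascade, so
short-budget comparisons measure optimisation speed rather than model
capacity.

## Degenerate inputs and tie-breaks

All-padding proteins yield empty predictions; attention on a fully masked
sequence is an error. per = 0 routes every residue hard (the easy set
under a strict percentile inequality is empty). Probabilities entering
entropies use the 0·log 0 = 0 convention. Opinion expectations are always
strictly positive (α ≥ 1). `mccm_easy` reports cascade predictions by
default even though its hard head is untrained; the easy head's calls are
available from the same forward pass for users who prefer the
easy-readout.

## Known limitations

* Full-benchmark training (thousands of proteins, full widths) is
  supported but slow on the numpy engine; the package's verified claims
  are the desk-scale mechanism properties above.
* Profiles must be supplied in the packed benchmark layout; the package
  does not run homology searches to build profiles for new sequences.
* The frozen-threshold rule is one reasonable reading of "percentile
  threshold" at test time; alternatives (last-epoch percentile,
  validation-set percentile) would shift the easy/hard split by a few
  percent.
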