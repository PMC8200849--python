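# Methods

`pdvoice` classifies the dopaminergic motor state (ON = medicated, OFF =
unmedicated) of a person with Parkinson's disease from short speech
recordings. It implements two classifiers over a shared front end, a
personalization layer, feature-level statistics, and a leave-one-patient-out
(LOPO) evaluation harness, together with a synthetic cohort generator that
stands in for clinical data.

## Feature front end

Recordings (nominally 44.1 kHz float WAV) are downsampled to 16 kHz with an
anti-aliasing polyphase filter and round-tripped through 16-bit quantization.
Training audio of one motor state is concatenated in manifest order and cut
into non-overlapping 10-s segments; a trailing remainder under 10 s is
dropped. Each segment is represented by the magnitude of a short-time
Fourier transform with a 25 ms window and 7.5 ms overlap (hop 17.5 ms = 280
samples, 400-point transform, 201 one-sided bins), giving a 201 x 571 matrix
for a 10-s segment with the no-padding convention
`frames = floor((N - win)/hop) + 1`. Each frequency channel is z-scored with
mean and standard deviation estimated on the training fold only (standard
deviations are floored at 1e-8; floored channels are zeroed). The window
function is Hamming and the magnitude is linear; both are configurable, as
neither choice is forced by the analysis geometry.

Test recordings are never concatenated: each 10-s test segment is split into
a first 5-s validation half and a second 5-s test half, and each half is
extended back to 10 s by signal repetition before entering the network.

Phone-attribute posterior streams — per-frame posterior probabilities of 21
phonological classes (20 distinctive features plus silence) — are the input
representation of the codebook classifier. They are carried as
frames x 21 matrices (10 ms frame period) and serialized as headered CSV.
In a clinical deployment they would come from a phonological vocoder's
per-class DNNs; that analyzer is out of scope here, and the synthetic
generator produces streams with the same schema.

## Phone-Attribute Codebook (PAC) classifier

Instance-based, no trained weights. Posteriors are 1-bit quantized at 0.5
(a value exactly equal to 0.5 maps to 1; the case has probability zero
under the noise model, the convention just fixes determinism). Each frame
becomes a 21-bit code. Per speech protocol, all training codes of one class
form a codebook (a set of unique codes; frame-occurrence counts are kept).
Codes present in both the ON and OFF books are removed from both, so the
unique books are disjoint by construction — this is asserted on every run.
If both unique books come out empty the protocol is degenerate and cannot
decide.

A test sample is scored in two stages:

1. **Exact matching** — `on_score` counts test frames whose code is in the
   unique ON book (per-frame counting by default; per-unique-code counting
   is a config switch). The larger score wins.
2. **Jaccard fallback** — on an exact tie (including the common
   no-match 0 = 0 case), each test code is scored by its maximum Jaccard
   similarity `a/(a+b+c)` (joint absences ignored; two all-zero codes are
   defined as identical, similarity 1) to each book, summed over test
   codes. A persistent tie yields ABSTAIN.

The patient-level call is a majority vote over the non-abstaining
per-protocol decisions; a vote tie is broken by the summed (on - off) score
margin, with the margin-zero case going to ON. Codes are stored packed as
integers, so exact matching is a hash lookup and Jaccard a popcount; a
brute-force all-pairs oracle checks the fast path in the test suite.

## Convolutional-recurrent classifier

Input is the normalized spectrogram, time-major (571 x 201). The reference
design — a 1-D convolution with 196 filters, kernel 15 and strides
"(4, 4) for the time and frequency dimensions" — is internally inconsistent
for a purely temporal convolution; it is realized here as a 4x mean
decimation of the frequency axis followed by a temporal convolution
(stride 4, ReLU), which honors both stated stride factors. A pure-temporal
mode without the frequency decimation is a config switch. With kernel 15
and stride 4, 571 input steps map to m = 140 output steps.

Then: two stacked bidirectional recurrent layers (GRU by default, LSTM by
switch; 128 units each), each followed by dropout (rate 0.8, read as the
fraction of units dropped) and batch normalization (order
dropout -> batch-norm, fixed here since the source order is unstated), and
a time-distributed single-unit sigmoid head. Targets are the state label
(0 = OFF, 1 = ON) repeated over the m steps; the loss is per-timestep
binary cross-entropy; the optimizer is Adam (choices not stated at the
source; these are the standard ones for this head). The whole network —
forward pass, backpropagation through time for both cell types, batch-norm
backward, Adam — is implemented directly on numpy arrays and verified
against finite differences to ~1e-6 relative error.

A segment-level decision binarizes the m outputs at a threshold
(probability >= threshold counts as ON) and calls ON iff strictly more than
m/2 steps are ON (exactly m/2 is OFF: "more than" is strict). The
fixed reference threshold is 0.44; alternatively a per-fold grid
search (step 0.01, ties to the smallest value) maximizes validation
accuracy, and the across-fold mean is reported. Per-protocol calls are
majority votes over segments, patient calls majority votes over protocols,
with the same margin tie-break as PAC.

## Personalized evaluation (p-CRNN)

The network stays speaker-independent; only the protocol set used at test
time is personalized. For the held-out patient, each protocol's validation
halves are classified; a protocol is selected iff every validation segment
of **both** states is called correctly (strict rule; a majority variant is
available). Testing restricts the protocol vote to the selected set. If no
protocol passes, the full set is used and the selection is flagged as a
fallback — a patient must still receive a call. When selection returns the
full set, p-CRNN reduces exactly to the plain evaluation.

## Feature statistics

* Per-attribute paired t-test between states. The pairing unit is the mean
  posterior per patient x protocol by default (per segment or per frame by
  config). Sign convention: t > 0 iff mean(ON) > mean(OFF). Degenerate
  inputs use t = 0, p = 1 for identical samples and t = +/-inf, p = 0 for a
  constant nonzero difference. Bonferroni-adjusted p-values over the 21
  attributes are reported alongside raw ones.
* Pairwise attribute correlation: Pearson correlation of the two
  attributes' posterior time series concatenated over one state's
  recordings of one protocol; zero-variance series return a flagged
  undefined value.
* 2-D embedding: seeded t-SNE of per-segment mean posterior vectors, with a
  nearest-centroid accuracy in the embedded plane reported as a
  separability score per protocol.

## Evaluation harness

One LOPO fold per patient; the held-out patient's data never reaches
codebooks, normalization statistics, or network weights (guarded by
explicit leakage checks). Each fold contributes two patient-level calls
(the ON and the OFF recording sets). Metrics — accuracy, sensitivity,
specificity, precision, with ON the positive class — are computed from the
pooled confusion matrix and as macro-averages over folds; ratios with zero
denominators are reported as flagged missing values, not zeros.

The packaged per-patient UPDRS-III rating table (14 analyzed patients)
feeds a worked example: mean ON motor score 20.93 (rounds to 21), mean
per-patient OFF - ON difference 11.93 +/- 5.09 (rounds to 12 +/- 5). The
OFF mean of this 14-patient table is 32.86 (rounds to 33), slightly above
the 16-patient recruitment summary of 32 — the table is the ground truth
used here.

## Synthetic cohort generator

The generator emulates the statistical structure the classifiers assume,
not German phonetics. A fixed 21-attribute inventory (silence plus 20
Chomsky-Halle-style distinctive features) and a small phone inventory with
canonical binary attribute vectors define scripted phone templates for the
seven protocols (digits, months, vowels, pataka, twisters, read,
monologue). Design choices worth calling out:

* **Posterior noise is asymmetric.** Canonically active attributes are
  realized reliably (logit 3.0, spread 0.5 — essentially never quantized to
  0), while inactive attributes occasionally pop above threshold
  (logit -1.5, spread 1.2, ~10% of frames). Consequently OFF-state
  attribute dropout produces *subset* codes the ON state cannot generate,
  and each class owns genuinely unique codes — the premise of the codebook
  method. With symmetric noise every frequent code appears in both classes
  and the unique-codebook construction removes all signal; the asymmetric
  model is what makes the instance-based method meaningful at this cohort
  size. With the master `noise_sd` at 0 the canonical binary frames are
  returned exactly.
* **OFF-state degradations** (all scaled by a per-patient x per-protocol
  effect multiplier): per-phone-instance attribute dropout (default
  probability 0.35), inserted silence (0.12), per-attribute posterior
  offsets (defaults put fricative/continuant/tense higher in OFF and
  voice/vocalic higher in ON, keeping both signs represented), duration
  scaling 1.1, and — on the audio side — 6 dB gain reduction, added
  aspiration noise, and 4% pitch jitter.
* **Heterogeneity.** Effect multipliers are log-normal (sigma 0.5) times a
  per-protocol informativeness weight (pataka/vowels 1.0, twisters 0.85,
  digits/months 0.7, read 0.15, monologue 0.12), so articulation-stressing
  tasks separate the states while connected speech barely does, and some
  protocols are uninformative for some patients — the regime in which
  personalized protocol selection matters. An explicit multiplier matrix
  can be supplied; `single_informative_config` builds the extreme case of
  one informative protocol per patient.
* **Speaker idiosyncrasy.** A per-patient, per-attribute logit offset
  (sigma 0.4) is applied identically to both states. It widens the
  between-speaker spread without creating ON/OFF contrast, cancels in the
  paired t-test, and keeps weakly informative protocols from being
  trivially separable in the embedding.
* **Audio** is source-filter synthesis at 44.1 kHz: harmonic pulse source
  (f0 120 Hz) through two formant resonators for voiced phones,
  band-limited noise for fricatives, closure + burst for stops; every
  recording is at least 10 s by template repetition.
* The clinical-style score table assigns OFF - ON severity differences
  correlated with each patient's mean effect multiplier.

Generation is a pure function of (config, seed); per-recording streams are
seeded by (seed, patient, protocol, state), so cohorts are bit-reproducible.

What the generator does **not** emulate: real phonological-vocoder error
structure (correlated across attributes and time), intelligible speech,
session effects, recording-channel variation, or non-motor symptoms.
Passing the synthetic-recovery tests therefore shows the pipeline is
correct and that the classifiers recover the designed contrasts — it does
not certify clinical accuracy on real cohorts.

## Problem sizes and numerical choices in the shipped experiments

The test suite and acceptance script run the full-size architecture's
geometry checks, but train the network in a reduced configuration (12
conv filters, 6 recurrent units per direction, dropout 0.2, 3 epochs,
single precision) so that a full 14-patient, 7-protocol LOPO sweep runs in
CPU minutes; the reduced network is the package's chosen desk-scale
experiment size. Above-chance checks pool patient-level calls over 5
cohort seeds (binomial test, alpha 0.01); the personalization comparison
uses 20 replicates of 5-patient single-informative-protocol cohorts; null
controls pool >= 50 calls over cohorts with every effect zeroed.
Single-precision arithmetic is used for training (gradient checks run in
double precision); determinism is per-seed exact on a given platform.

## Known limitations

* Clinical-grade accuracy claims cannot be made from this repository: the
  clinical recordings this method family was developed on are not public,
  and the default synthetic cohort is easier than the clinic
  (near-perfect recovery).
* Dropout 0.8 with the full 196/128 architecture on minutes of audio is
  unusually aggressive and untested at scale in this repository.
* With the default patient x protocol pairing the t-tests are
  conservative; per-frame pairing (a config option) yields the very large
  |t| magnitudes typical of frame-level analyses; the choice of pairing
  unit materially changes the reported significance.
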