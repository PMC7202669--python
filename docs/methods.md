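# Methods

## The prediction problem

Given an amino-acid sequence, predict a per-residue secondary-structure
label. Ground truth comes from DSSP assignments over experimental
structures, distributed as per-chain triples (sequence, DSSP string,
disorder mask) in the PDB `ss_dis.txt` dialect. Spaces in the DSSP string
are resolved to coil `C` for ordered residues; residues without coordinates
are labeled `X` and are excluded from all training and evaluation counts,
while still contributing sequence and profile context to the windows of
their neighbours.

Six label alphabets are supported: the raw 8 DSSP states; the two 3-state
conventions from the literature (`rule1_3`: H,G,I→H, E,B→E, rest→C;
`rule2_3`: only pure H and E survive); and three reduced alphabets (5, 4 and
3 letters) that fold the low-signal bend (S) and bridge (B) states — and
progressively 3₁₀ helix (G) and turn (T) — into coil while sending the rare
π helix (I) to H. All reductions are total, length-preserving letter maps;
`X` is preserved verbatim.

## Features

Each prediction sample is a (29, 92) matrix: a window of ±14 positions
around the central residue with 92 features per position, in frozen block
order:

1. 22 one-hot indicators — the 20 standard amino acids alphabetically, `X`
   (non-standard residue inside the chain), `?` (position outside the
   chain). The `X`/`?` distinction is kept because an in-chain non-standard
   residue still has profile columns, while an out-of-chain position does
   not.
2. 20 PSI-BLAST log-odds scores from the round-1 profile (the "score"
   columns of the ASCII PSSM, never the weighted percentages; integers,
   possibly negative, no sigmoid squashing).
3. 20 log-odds scores from the round-2 profile. If only a round-1 file
   exists (profile search converged after one round), round-1 scores are
   duplicated so the feature width stays 92.
4. 30 HMM parameters (20 emissions, 7 transitions, 3 Neff diversity
   values), with `*` entries replaced by 99999.0 and all values divided
   by 99999.0 into [0, 1].

Positions outside the chain are padded with a fixed column: one-hot on `?`,
log-odds −19 in both PSSM blocks, 1.0 for the first 27 HMM parameters and
0.0 for the three Neff values. The flattened window has 2,668 values.

Profile generation itself (PSI-BLAST against Uniref90 with
`-inclusion_ethresh 0.001 -evalue 10 -num_iterations 2
-save_pssm_after_last_round -out_ascii_pssm`, and `hhblits` + `hhmake`
against uniprot20) is out of scope; the package parses and writes the file
formats and ships the command templates as documentation only.

## Network and training

The predictor is a deliberately traditional CNN implemented on numpy
kernels (`sscnn/nn.py`): four valid-border 1-D convolutions of width 7 with
128/256/384/512 filters and ReLU, 30% inverted dropout in front of every
convolutional layer and the final dense layer (train-time only), then a
dense softmax over the label alphabet. With a 29-position input the stack
leaves 29 − 4·6 = 5 positions, so the dense layer sees 2,560 features. The
trainable-parameter count is a closed form of the alphabet size: 2,397,960
for 8 labels, 2,385,155 for 3.

Training uses SGD with momentum 0.9 (no Nesterov), categorical
cross-entropy, batch size 256, learning rate 0.01, and a hyperbolic decay
`lr_t = lr / (1 + decay·t)` over update steps with decay = lr / n_epochs
(1.54e-5 at the reference 650 epochs; recomputed automatically when the
epoch count changes). Sample order is a uniform shuffle of all labeled
residues each epoch. At every epoch end the validation accuracy is
measured and the weights are checkpointed whenever it improves; the model
returned is the best-validation checkpoint, never the last epoch. The
per-epoch "train accuracy" in the history is the running mean over that
epoch's mini-batches, measured with dropout active — a one-pass estimate
that is slightly pessimistic relative to a dedicated evaluation pass.

Weight initialization is He-uniform, seeded; runs are bit-reproducible
given (architecture seed, training seed). The reference predictor is an
ensemble of 10 networks, one per fold of a chain-level 10-fold
cross-validation split (each split 9:1 by chain count, every chain in
exactly one validation fold). Prediction is a per-residue majority vote of
member argmax labels; ties are broken by the highest softmax probability
summed across all members over the tied labels — the vote statement alone
leaves ties undefined, and the summed probability uses information the
ensemble already has, deterministically.

## Evaluation

Accuracy = correctly predicted / all assigned labels = trace of the percent
confusion matrix. Column-normalizing the matrix gives per-label recalls
(TPR) on the diagonal and false-negative rates elsewhere; row-normalizing
gives precisions (PPV) and false-discovery rates. Because recalls differ by
label, overall accuracy depends on a test set's label composition:
`extrapolate_accuracy` computes Σ fraction·TPR for any composition, and
`adjust_to_reference` re-weights one set's accuracy to another set's
proportions. Re-weighting a matrix to its own fractions returns its own
accuracy exactly (algebraic identity, property-tested on random matrices).

Rates are computed from full-precision counts. When a one-decimal printed
matrix is entered directly, column sums of the supplied entries serve as
denominators, and recalls can disagree with separately printed recall
tables by ±0.4 points — the printed tables were produced from unrounded
counts. Labels with empty columns/rows get missing (None) rates, never
zero, so adjusted accuracies are not silently skewed.

## Data-set construction protocol

Benchmark sets are built from chain-metadata tables by a deterministic
filter pipeline: date split (test candidates released on/after the cutoff);
collapse of identical sequences keeping the best structure (resolution,
then effective free R, then most residues with coordinates, then chain key
for determinism); quality filters (resolution ≤ 2.2 Å inclusive, effective
R ≤ 0.25 where effective R is the free R or R-work + 0.05, length ≥ 40, no
Cα-only models, records without resolution rejected and logged); removal of
any candidate with identity strictly above 25% to *any* pre-cutoff chain
under *either* identity definition; and the same 25% cutoff enforced
greedily within the set, visiting chains best-quality first so the result
is order-independent. An optional final filter removes candidates sharing
an ECOD X.H homology group with any training chain, with a lookup cascade
(exact chain → same-sequence chain in the same entry → same-sequence chain
in another entry); chains that resolve nowhere are excluded and logged,
since their homology status is unknown. The HTTP search fallback of the
original cascade is out of scope.

Identity backends are pluggable. The built-in backend aligns globally with
BLOSUM62 and affine gaps (−11/−1) via Biopython and supports both
denominator conventions: identities / shortest sequence length (symmetric)
and identities / aligned non-gap columns. Protocol tests instead inject an
exact pairwise identity matrix, so the pipeline can be compared against a
brute-force reference filter with no alignment ambiguity.

## Synthetic data

The generator produces corpora in which every artifact cross-references
consistently and every parser round-trips exactly. Labels come from a
run-length process: run labels i.i.d. with weights w_l ∝ f_l/m_l and
geometric run lengths with mean m_l, so expected label fractions equal the
targets f_l (defaults: H 34.1, E 22.3, C 19.4, T 11.1, S 8.2, G 3.9, B 1.1
percent, the composition of a large nonredundant PDB snapshot). π-helix
labels are written only over the final turn of long helix runs, matching
where they occur in real structures, at a rate giving ~0.02% frequency.
Disorder (6.5% of residues by default) is placed at chain termini, where
missing density actually concentrates, and never interrupts a run
mid-segment.

Sequence signal is planted at the emission level: each label has a small
set of favoured residues whose probability is boosted by
exp(signal_strength) over a uniform background (signal_strength 2.0 by
default; 0 yields a null corpus whose sequences are independent of the
labels). PSSM fixtures carry the scaled log-odds of those emission
distributions plus Gaussian integer noise, with round 2 a
position-smoothed copy of round 1; HHM fixtures encode noisy versions of
the same distributions in the −1000·log₂(p) convention with `*` for
vanishing probabilities.

What this does *not* simulate: strand pairing, helical periodicity,
long-range structure, or real evolutionary profiles. Passing the
learning-sanity tests therefore demonstrates that featurization, training,
checkpointing and evaluation work end to end — not that the network
predicts real proteins at any particular accuracy.

## Problem sizes and numerical choices

Tests and the acceptance script train a scaled-down network (filters
16/32/48/64, 8 epochs, ~49k parameters) on corpora of 30–80 chains — sizes
chosen so the whole suite runs in about a minute while leaving wide margins
(the scaled-down model beats the majority-class baseline by 40–50 points
on held-out chains at default signal; a null-signal corpus trains to
exactly the baseline). Full-scale training at the reference configuration
(650 epochs, ~2M parameters, ~2M residues) is supported by the same code
path but is a multi-day computation and is not exercised by the tests.

Other numerical conventions: fractions and accuracies are kept at full
precision internally and rounded to one decimal only for reporting;
alphabet reduction and label statistics exclude `X` everywhere; dropout is
inactive at inference; softmax is computed with max-subtraction; float32
is used throughout the network for speed, float64 in analytics.

## Known limitations

* The built-in alignment identity is a stand-in for the two external
  aligners used to build the published sets; it implements their
  denominator definitions, not their exact scores.
* The e-value-based relatedness filter is exposed only as a generic
  predicate over an externally supplied pairwise table; computing profile
  e-values is out of scope.
* The ensemble vote tie-break is this package's own convention; published
  results do not specify one.
* History "train accuracy" is measured with dropout active (see above).
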