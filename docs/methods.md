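# Methods

## The model

`contactstack` refines residue–residue contact predictions with a
feed-forward stack of classifiers. For a protein of length L, every
unordered residue pair (i, j) with sequence separation |j−i| ≥ 5 is a
classification instance; pairs below that separation are trivially local
and are neither trained on nor scored (they are reported as 0).

Layer ℓ₀ sees only the *ordinary* feature vector x(i, j). Each later
layer ℓ_t sees x(i, j) concatenated with the receptive field
F_t(i, j) — the (2h+1)×(2h+1) window of layer ℓ_{t−1}'s predicted
contact-probability map centred on (i, j):

    P_0 = ℓ_0(x)
    P_t = ℓ_t(x ⊕ F_t),   F_t(i, j) = { P_{t−1}(i', j') :
                                         |i'−i| ≤ h, |j'−j| ≤ h }

Positions of the field outside the map are filled with 0, read as "no
predicted contact"; mirroring would invent structure at the termini.
The final layer's map is the method's output. The recurrence base case
is exact: with one layer the stack *is* a flat per-pair classifier, and
the test suite asserts bit-identical behaviour.

The rationale is that true contact maps are highly structured — paired
β-strands leave ladders in which a contact at (i, j) implies contacts at
(i±1, j∓1), helices leave |i−j| ∈ {3, 4} ladders and packing stripes —
while the errors of coevolution-based predictors are either sporadic
single pairs or compact clusters. A learner that sees the neighbourhood
of each pair can suppress the former and, given a partially detected
ladder, fill in the undetected rungs.

## Ordinary features

In frozen order (the order is part of the model archive contract):

| block | dims | content |
|---|---|---|
| base scores | k | the k base-predictor scores at (i, j) |
| separation | 1 | j − i (raw; a transform hook exists) |
| PSSM | 2·21 | log-ratio profile rows of i and of j |
| SS | 2·9·3 | helix/strand/coil probabilities, window i−4…i+4 |
| RSA | 2·9·5 | rsa, Z-fit reliability, 3 SS probabilities, same window |

With the default k = 4 this is 191 dimensions; the 11×11 receptive field
adds 121. Windows truncated by a sequence end are zero-padded. The PSSM
is the 21-state (20 amino acids + gap) log-ratio of observed column
frequency to a fixed background; the background table is Swiss-Prot-like
amino-acid frequencies renormalised around a 1 % gap state. The
pseudocount mixes the observed frequencies with the background at weight
1 by default, acting on frequencies rather than counts so the matrix is
invariant under duplicating alignment rows.

## The learner and the training protocol

Each layer is a scikit-learn `RandomForestClassifier` with 100 trees and
`min_samples_leaf=500`. The leaf floor is the only guard against
over-fitting the heavily unbalanced pair data (contact density falls off
as 1/L); class weighting and negative subsampling exist as options but
are off by default. Any object with `fit`/`predict_proba` can be plugged
in per layer.

Two protocol choices matter and were settled empirically on the
synthetic benchmark:

**Feedback maps (`oof_mode`).** The fields fed to layer t during
training come by default from the layer t−1 forest's own predictions on
the training families (`in_fold`). This is mildly optimistic in
principle, but the 500-sample leaf floor keeps the maps far from the
labels, and — decisively — they match the distribution of the fields the
stack produces at prediction time. Two guarded alternatives are kept for
comparison. `oob` scores each fitted pair only by the trees whose
bootstrap draw excluded it: honest feedback at zero extra fits, but
averaged over ~37 % of the trees and therefore noisier than the fields
seen at prediction time; on the synthetic benchmark it performs the same
as `in_fold` to within noise. `out_of_fold` is classical stacked
generalization with family-level folds; its fold models are trained on
fewer families and produce fields that mismatch the full model's, a
shift that compounds across layers and measurably degrades the deeper
layers.

**Training-vector subsampling (`max_train_samples`).** Pooled pair
vectors are capped at 60 000 per layer fit by a seeded subsample that
always keeps every positive pair and fills the remainder with random
negatives. The cap bounds the cost of a layer fit independently of the
number of training families; at 60 000 vectors the 500-sample leaf floor
allows forests of roughly 120 leaves. The cap is the main dial trading
accuracy against wall-clock time, and it bounds how much of a large
receptive field the forests can actually use (see Known limitations).

Per-layer mean training top-L PPV is logged and stored on the returned
`Stack`; a warning is emitted when a layer fails to improve on its
predecessor, the signature of an over-deep stack. There is no automatic
early stop.

Determinism: all randomness (fold shuffles, subsampling, forest seeds)
derives from `StackConfig.seed`; retraining with the same seed
reproduces bit-identical predictions, which the suite asserts.

## Evaluation conventions

*Top-αL PPV*: rank eligible pairs (separation ≥ 5, unmasked) by score,
take the ⌈α·L⌉ best, report the fraction that are true contacts. Score
ties are broken by separation (descending), then i, then j — determinism
is needed for exact oracle tests; the choice favours the harder
long-range prediction on a tie. Set-level numbers are means of
per-protein PPVs; pooled-pair PPV is available as an option.

*Separation ranges*: short 6–12, medium 12–24, long ≥ 24, with boundary
pairs (exactly 12 or 24) assigned to the lower-labelled range; L/10
predictions are ranked within each range. Ranges with no eligible pair
report as undefined rather than 0.

*SS categories*: the global top-αL predictions are assigned to the
unordered category of their residues' classes (helix/strand/loop);
per-category PPV and prediction fractions are reported, the fractions
summing to 1.

*Masking*: pairs where either residue lacks coordinates are excluded
from ranking, numerator and denominator alike. The contact definition is
Cβ–Cβ ≤ 8 Å, Cα for glycine and for residues whose Cβ is unresolved;
residues with neither atom are masked, not imputed.

*Isolated predictions*: a top-αL prediction with no other top prediction
in its 3×3 neighbourhood. The count per family, layer by layer, is the
direct measure of the stack's sporadic-error filtering.

## The synthetic generator

The generator emulates the *neighbourhood statistics* of real contact
maps and the *error structure* of coevolution predictors; it makes no
claim of 3D-geometric realism, and its surrogate sequence features carry
recoverable signal rather than biology.

Topology: H/E/C segments are laid down left to right (helix 6–14,
strand 5–9, coil 2–6 residues) to match requested composition
fractions. Helices contribute |i−j| ∈ {3, 4} ladders; consecutive
strands pair into 3-cell-wide ladders, antiparallel with probability
0.7, and sheets of ≥3 strands close first-to-last with probability 0.6;
sequence-adjacent helices pack through partially occupied anti-diagonal
stripes, less regular than the β-ladders as in real structures; distant segments occasionally pack. A chain with at
least two structured segments is guaranteed one interface. All-coil
compositions yield (near-)empty long-range maps, preserving the
degenerate case.

Base maps: score = max(0, signal·truth + N(0, 1)). Clustered 3×3
false-positive blobs (≈0.04·L per map, emulating e.g. oligomer-interface
couplings) and isolated single-pair peaks (≈0.8·L per map, the
"sporadic" errors) are sprinkled at contact-competitive amplitudes.
Gaussian noise with rectification at 0 was chosen for its analyzable
chance level: at zero signal the expected top-L PPV equals the
eligible-contact density, which the limit tests assert. An optional
*detection budget* (off by default) grants full signal to only a fixed
family-level subset of ≈budget·L contacts, emulating how coevolution
methods resolve a depth-limited number of couplings; it lowers the
flat layer's ceiling on contact-dense folds at the cost of overall
refinement, and is exposed for experimentation rather than used in the
default conditions.

Default study conditions: 4 base maps per family, signal drawn uniformly
from 0.9–1.9 per family, lengths 70–90, per-family random compositions.
The Meff surrogate is a monotone function of signal strength, standing
in for the alignment-depth/accuracy relation.

What passing tests on this generator do **not** show: performance on
real proteins, robustness to alignment artefacts beyond the modelled
blob/isolated errors, behaviour at L ≫ 100, or transfer across
predictors whose score scales differ from the training maps.

## Numerical and degenerate-input choices

- Receptive-field and window padding is 0 everywhere; no mirroring.
- Residue alternate locations: highest occupancy wins, ties to the first
  conformer; insertion codes order after their base residue number.
- RR scores serialise at 6 decimals; round-trips are exact to 5·10⁻⁷.
- APC: row and grand means exclude the diagonal; an all-zero matrix is
  returned unchanged with a warning.
- MI uses a 1/21² additive pseudocount by default; a single-row
  alignment yields an all-zero map with a warning.
- Meff reports single-linkage cluster counts; the DCA-style
  inverse-neighbourhood weight sum is the `weights` mode. The identity
  threshold is an explicit parameter (default 0.62) with a hook that
  accepts a callable of the alignment's mean pairwise identity, so a
  data-dependent threshold rule can be plugged in.
- Identity gap policy: columns gapped in both rows are skipped; gapped
  in one row counts as mismatch.
- A family whose truth has no eligible positive pair cannot be trained
  on alone (explicit error); families shorter than twice the field width
  train with a warning, covered by padding.

## Known limitations

- The stack's accuracy at desk scale is bounded by the training-vector
  cap; raising `max_train_samples` buys accuracy roughly linearly in
  fit time.
- With ~120-leaf forests, most of the receptive field's value is
  concentrated in its inner cells; very large fields mainly add unused
  dimensions at this capacity.
- The generator's surrogate PSSM/SS/RSA are class-conditional noise
  around the true secondary structure; they are deliberately informative
  and must not be mistaken for predictor outputs.
- Only intra-chain contacts are modelled; mmCIF input and inter-chain
  maps are out of scope.
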