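# Methods

## Relative compression and the NRS statistic

The core quantity is the *relative* code length C(x‖y): the ideal number of
bits needed to encode target *x* under probability models trained on
reference *y* and then frozen.  No arithmetic coder is run — downstream
consumers only ever use code lengths, so the package accumulates the exact
ideal length Σᵢ −log₂ P(xᵢ) instead of emitting a bitstream.  Freezing is
what makes the quantity a *similarity*: the encoder cannot exploit
redundancy within *x* itself, so any saving below the uniform 2 bits/base
must come from structure shared with *y*.  The Normalized Relative
Similarity is NRS(x‖y) = 1 − C(x‖y)/(2|x|), clamped to [0, 1] because a
smoothed model can in principle spend more than 2 bits/base on adversarial
input.  The identity RS = 2|x| − C holds exactly (both are plain float64
arithmetic on the same value).

## Models

**FCM.** An order-*k* finite-context model stores context → symbol counts
n(c, s) gathered in a single training pass and estimates

    P(s | c) = (n(c, s) + α) / (N(c) + 4α)

with additive smoothing α > 0.  Unseen contexts give the uniform 1/4, as
does the warm-up region (the first *k* symbols of every record).  Contexts
are packed 2 bits/symbol into a signed 64-bit integer, exactly (no lossy
fingerprinting); this caps the order at 31 so the key stays non-negative.
Counting is vectorised (sliding windows + `np.unique`); probability queries
never touch the tables, and tests assert byte-identical serialisation
before and after arbitrary encoding ("frozen contract").

**Inverted repeats.** A model may additionally count the
reverse-complement of every training event, which is algebraically the same
as also training on each record's reverse complement.  The per-model flag
defaults to off, but every built-in preset enables it: sequencers read
either strand, and without it a minus-strand read is invisible to a model
trained on the plus strand (read-level accuracy on simulated uniform-strand
data collapses from ~1.0 to ~0.8).

**STMM.** A substitution-tolerant Markov model shares the count table of an
FCM of equal order but keeps its own, possibly *edited*, context history:
when the observed symbol differs from the model's argmax prediction (ties
resolve to the lowest symbol index) and fewer than `max_substitutions`
edits are outstanding within a sliding window of `window` positions, the
prediction is recorded in place of the observation.  An isolated mismatch
— a deamination artefact or sequencing error — therefore corrupts only one
prediction rather than the next *k* contexts.  With budget 0 the STMM is
exactly its shared FCM (asserted in tests).

**Cooperative mixture.** Per position, model predictions combine as
P = Σᵢ wᵢpᵢ with weights updated multiplicatively, wᵢ ← wᵢ^γ·pᵢ, then
renormalised.  γ = 0.98 by default (γ = 0 forgets instantly; γ → 1
approaches Bayesian mixing); initial weights are uniform.  Uniform weights
are the fixed point under equal predictions; unequal weights contract
toward uniform — the update deliberately forgets so the mixture can switch
between shallow and deep models along the sequence.  Weights and STMM
states reset at every record boundary, making multi-record targets
record-order independent.

**Default ensemble** (compression level 3, also registered as the deepest
level 47; the table is user-extensible via a JSON file): FCMs of orders
3, 7, 11, 14 with α = 1, 1/16, 1/16, 1/64, plus one STMM of order 14
(α = 1/64, budget 8, window 64) sharing the order-14 table.  Low α sharpens
deep models on DNA; the shallow order-3 model keeps the mixture calibrated
where deep contexts are unseen.  Level 1 and 2 presets are truncations for
quick runs.

## Performance

The per-symbol loop is JIT-compiled (numba); count tables are packed once
per bundle into typed int64 dictionaries mapping context key → row of a
count matrix.  Because one kernel invocation has a fixed overhead, short
reads are encoded in batches (`relative_code_lengths`): one call encodes
thousands of reads, with identical per-record results to the single-record
path (asserted in tests).  Execution is single-threaded and
byte-deterministic; the `-n` flag is accepted for interface parity only.

## Classification, composition, pre-filter, profiles

*Classification* assigns each read to the bundle with maximum NRS; ties
break to the lexicographically smallest reference label and are flagged.
Reads below `--min-nrs` (default 0: everything is classified) are reported
`unclassified`.  *Composition* inverts the roles: one bundle is trained on
the read sample X (as a bag — contexts reset per read, so no artificial
cross-read contexts arise) and each reference y is encoded against it;
NRS(y‖X) ranks references by how well the sample explains them, with only
the top-K (default 20) reported.  *Pre-filtering* discards reads whose
maximum NRS against a contaminant library reaches τ (default 0.9;
0.6–0.7 recommended for damaged, heavily contaminated samples); τ = 1.0 is
provably the identity (NRS < 1 always, since smoothed probabilities are
< 1), which the test suite checks end-to-end as byte-identical
classification output.  *Local profiles* map per-position code lengths to
sᵢ = clamp(1 − bitsᵢ/2, 0, 1), smooth them with a centred moving average
(default window 21, edge-truncated — smoothed values stay within the raw
range), and segment maximal runs ≥ threshold (default 0.5) of at least
`min_length` (default 10) positions.  SVG output is deterministic text
(fixed canvas, 6-decimal coordinates) so renders can be compared
byte-for-byte, as can every TSV (fixed 6-decimal floats).

## Model persistence

`.fcm` files are a little-endian binary container: magic `FCM2`, format
version, a JSON header (tool version, labels, reference SHA-256 snapshot
hashes, SHA-256 parameter digest of the mixture configuration), then per
bundle the config JSON and each count table as sorted (key, 4×int64)
rows.  Sorted keys make save → load → save byte-identical.  Loading
rejects wrong magic, unknown versions, and — when the caller states the
expected configuration — digest mismatches, each with a specific error.
`-I` reads the header only.

## Synthetic benchmark design

The simulator emulates the standard ancient-DNA benchmark protocol at desk
scale:

- **genomes**: i.i.d.-uniform random sequences (default 5 × 20 kb);
- **fragments**: fixed length L ∈ {20, 40, 60, 80, 100} bp, uniform start
  and strand, count = round(depth·|genome|/L) with depth ∈ {1 … 60}×;
- **deamination**: C→T from the 5′ end and G→A from the 3′ end with
  per-site probability d·2^(−i/h), d ∈ [0, 0.3], half-life h = 3 positions
  by default — an exponential, terminal-biased damage profile;
- **sequencing error**: uniform per-base substitution (a hit base always
  changes), default 0.5% in the scaled benchmark;
- **contamination**: a configurable fraction of reads drawn from
  contaminant genomes, labelled in the ground truth;
- one FASTQ + ground-truth TSV per factorial grid cell, each cell seeded
  by a child of the base seed: fixed seed ⇒ byte-identical outputs.

This is a deliberate simplification of full damage/error simulators: no
indels, no fragment-length distribution, no quality-dependent errors, and
constant quality strings (qualities are not modelled downstream).  Random
genomes also lack the shared phylogenetic structure of real viral
databases, so passing benchmarks here demonstrates correct mechanics and
separation behaviour of the statistic — not field accuracy on RefSeq-scale
databases, which depends on reference relatedness the generator does not
emulate.

The scaled benchmark the acceptance script runs (5 genomes × 20 kb, depth
5, ~8 000–25 000 reads per condition) was chosen to finish in seconds on
one CPU while keeping every pipeline stage at realistic read counts.

## Evaluation conventions

Micro-averaging pools TP/FP/FN across labels and grid cells before forming
ratios.  A correct read is a TP; a wrong assignment charges an FP to the
predicted label and an FN to the true one; an *unclassified* read is an FN
only (no FP).  Zero denominators yield 0 by convention.  AUPRC uses the
step-wise precision-at-recall sum (no interpolation — conservative under
class imbalance, which is why it is preferred over AUC-ROC here); AUC-ROC
uses trapezoidal integration with tied scores grouped, equivalent to the
pairwise rank estimator with half credit for ties (asserted against an
O(n²) oracle in tests).  Both delegate to scikit-learn, which implements
exactly these estimators.

## Numerical and design choices

- Ideal code lengths, not bitstreams: exact, testable, and sufficient for
  every downstream use.
- Non-ACGT input characters are replaced by a seeded pseudo-random
  in-alphabet symbol (default), keeping |x| — and hence the NRS
  denominator — intact; `strict` and `skip` policies exist.  Replacement
  counts are recorded per record.
- Context order capped at 31 (62 bits) so packed keys remain non-negative
  int64 throughout.
- NRS clamped at 0; tie-breaks (classification labels, STMM argmax) are
  always toward the lexicographically/numerically smallest candidate, so
  no ordering ambiguity exists anywhere.
- All stochastic plumbing (simulator, non-ACGT replacement) flows from one
  integer seed; every command is byte-deterministic given inputs, flags and
  seed.

## Known limitations

Single-threaded; models live fully in memory (a 20 kb genome at order 14
yields ~20 k contexts per model, but gigabase references will not fit the
packed-dictionary design as-is); no taxonomy tree or LCA logic (only a
flat reference → taxon mapping); no interoperability with other tools'
model file formats; the simulator's damage model is an emulation, not a
re-implementation of published damage simulators.
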