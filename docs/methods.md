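# Methods

## Problem and model

`dsite` classifies 41-nt RNA windows with a center uridine as dihydrouridine
(D) sites or non-sites. The model is a heterogeneous-feature ensemble: three
RBF-SVM base predictors, one per encoding (NPCP, PseDNC, SSC), combined by
majority vote. The assumption behind the design is that sequence identity,
sequence-order/physicochemical context, and secondary structure each carry
partly independent information about D deposition, so a 2-of-3 vote is more
robust than any single view.

Windows are 1-based closed intervals; the candidate uridine is position 21.
Windows that would overlap a transcript boundary are skipped, never padded:
a padded window would fabricate composition and structure where there is no
sequence. DNA-style input (`T`) is converted to `U` by default; ambiguity
codes are rejected outright rather than being encoded as arbitrary features.

## Encodings

**NPCP.** Position-wise 3-bit codes (ring count, hydrogen-bond strength,
amino/keto class) giving a 123-dim binary vector. The entry sum is
3·#A + #C + #G + #U, a useful integrity check.

**PseDNC.** 16 dinucleotide frequencies plus λ correlation tiers, sharing
one denominator so the vector always sums to 1. The coupling factor compares
standardized dinucleotide thermodynamics (μ = 3: enthalpy, entropy, free
energy at 37 °C). The packaged property table uses the Freier et al. (1986)
RNA nearest-neighbor parameters; the three columns are internally consistent
(ΔG ≈ ΔH − 310.15·ΔS) and obey strand symmetry. Because each column is
standardized to mean 0/sd 1 over the 16 steps (sample sd, the convention of
the pseudo-composition literature; a `ddof` switch exposes the population
variant), all downstream features are invariant to affine rescaling of a
column, so unit conventions in user-supplied tables do not matter.

Dinucleotide counting defaults to overlapping windows. A nonoverlapping mode
is provided as a switch: some descriptions of the composition use
nonoverlapping counts, but the correlation tiers are defined over
dinucleotides at every position, and overlapping counting is the dominant
convention — the discrepancy is surfaced as an option rather than silently
resolved.

**SSC.** The window is folded in isolation (the encoder sees only the
window, so folding only the window keeps the feature faithful to its input),
brackets are collapsed to paired/unpaired, and the 39 overlapping
trinucleotides are tallied into 32 (nucleotide × structure-status) modes,
normalized by the window count so vectors are comparable across lengths.
Mode order is fixed (nucleotide-major; statuses from `(((` to `...`) so
models are portable.

Two folding engines sit behind one adapter. The external thermodynamic
engine is ViennaRNA's MFE fold at default parameters; the adapter records
the bindings' version and warns when it differs from the 2.1.9 reference,
rather than enforcing it. The builtin engine is a Nussinov maximum-pairing
dynamic program (Watson–Crick + GU wobble, minimum hairpin loop 3,
deterministic traceback that pairs the smallest 5' index with its smallest
admissible partner). It keeps the default pipeline and test suite free of
external dependencies and is verified against brute-force enumeration of all
nested pairings up to length 12. Its known bias: maximum-pairing structures
are denser than thermodynamic ones, so SSC features from the two engines are
not interchangeable — the engine is therefore part of model provenance.

## Classifier

Base SVMs are RBF-kernel with libsvm's pairwise-coupling probability
calibration (fixed internal seed); a window is called positive when the
probability exceeds 0.5 (an exact 0.5 is negative, per the strict
threshold). The final label is the class with the larger voting score, i.e.
at least 2 of 3 votes; a variant rule sometimes described — requiring all
three probabilities above 0.5 — is *not* implemented, as it contradicts the
voting-score definition.

Grid search maximizes internal stratified k-fold CV accuracy (default
k = 5) over C exponents −5..15 step 2 and γ exponents −15..−5 step 1 (11 ×
11; the grids are read as exponent steps and are overridable). Ties break
toward smaller C then smaller γ. Samples are canonically sorted (label,
then feature bytes) before the seeded shuffle-split, making the selection
invariant to training-row order.

Two jackknife protocols are offered. `paper-parity` selects (C, γ) once on
the full dataset and then jackknifes with them fixed — the conventional
protocol in this literature, but its selection step sees every
later-held-out window, which optimistically biases the estimate (on a pure
noise benchmark it yields ~0.68 accuracy where chance is 0.5). `nested`
re-runs the grid search inside every leave-one-out round, which is
leakage-free and is what the package's null-calibration test uses; on the
same noise benchmark it sits at chance. Users comparing against published
jackknife numbers should use `paper-parity`; users estimating real
generalization should use `nested`.

## Metrics

Sn, Sp, Acc and MCC are computed in the confusion-count formulation given in
the module docstring; the MCC variant is algebraically identical to the
textbook Matthews coefficient (property-tested on random tables to 1e-12)
and is reported as *undefined* — never coerced to 0 — when no window is
predicted positive or none negative. Reports show fractions and two-decimal
percentages.

## Synthetic benchmark generator

The generator emulates the shape of the curated benchmark this class of
predictor is trained on: a balanced set (default 68+68) of 41-nt center-U
windows. Positives carry a purine-enriched, position-specific bias in the
10 nt on either side of the center (A-leaning 5', G-leaning 3'); purines on
both sides cannot pair with each other and the enrichment depletes their
pairing partners, so positive folds are biased toward an unpaired center.
This injects signal visible to all three encoders — positional (NPCP),
compositional (PseDNC) and structural (SSC) — mirroring the
heterogeneous-feature premise. `separability` ∈ [0, 1] linearly mixes
background and signal distributions: 0 gives identical class distributions
(a null benchmark), 1 the full signal. The background is i.i.d. with a GC
fraction defaulting to 0.40 (transcriptome-like for budding yeast).

What the generator does **not** emulate: real tRNA cloverleaf architecture,
position-dependent background composition, homology between windows, or the
redundancy structure of curated datasets. Passing tests on synthetic data
therefore demonstrate that the pipeline recovers planted signal of the kinds
encoded — not field performance on real transcriptomes.

Default problem sizes in tests are 30+30 windows (the full 68+68 default is
used when generating benchmarks for users); the null- and power-calibration
runs use n = 60 with a fixed seed, where the 95% binomial band around
chance is 0.5 ± 0.127.

## Numerical and design notes

* PseDNC vectors sum to exactly 1 (shared denominator); verified to 1e-12
  across random windows, weights and tiers.
* The grid-search CV fold count is capped at the smaller class count;
  degenerate single-class inputs are errors, not silent successes.
* Model archives embed a format version, the property-table hash, the
  folding engine and all hyperparameters; prediction with a mismatched
  property table is refused.
* The positional encoder tends to dominate on strongly position-biased
  data; majority voting then tracks the second-best predictor (a 2-of-3
  vote errs only when two bases err) rather than the best. The regression
  suite asserts exactly that guarantee.
* Known limitation: leave-one-out on an artificially balanced dataset makes
  the held-out label weakly decodable from the training class counts
  (29+/30− vs 30+/29−); probability-calibrated SVMs can latch onto this
  under pure noise. The nested protocol with 5-fold internal selection
  keeps the null run at chance; single fixed-configuration SVMs evaluated
  by LOO on balanced noise may not.
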