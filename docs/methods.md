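# Methods

## Model and fitting procedure

A sample is a channel-count vector **v** ∈ ℕ^ξ under a fixed mutational
schema (SBS-96 by default; DBS-78, ID-83, CN-48 and custom schemas are
supported via pre-built matrices). A reference set is a column-stochastic
matrix **S** ∈ ℝ₊^(ξ×n). The fit minimizes ‖v − S·a‖₂ subject to a ≥ 0 with
the Lawson–Hanson active-set NNLS solver (scipy's implementation); quality
is reported as the relative reconstruction error

    ε = ‖v − S·a‖₂² / ‖v‖₂²,

defined as 0 for a zero-burden sample (the formula divides by ‖v‖²; a
sample with no mutations short-circuits to zero activities).

Model selection is forward-stagewise: starting from the full reference set,

* **removal** — while the cheapest single-signature removal raises ε by at
  most `removal_tolerance` (default 0.01, absolute difference of relative
  errors), drop that signature;
* **addition** — while the best single-signature addition from the full set
  lowers ε by at least `addition_gain` (default 0.05), add it;

the two passes alternate until the selected set is unchanged over a full
iteration, with a hard cap (`max_outer_iterations`, default 100) guarding
against cycling; hitting the cap logs a warning. The comparison baseline
ε_min is updated on every accepted step, so each accepted removal costs at
most 0.01 and each accepted addition gains at least 0.05 *relative to the
previously accepted state*; both passes return the last accepted (ε, S).
The asymmetric thresholds mean a signature must explain a substantially
larger share of the catalog to enter the model than to survive in it —
this is the sparsity mechanism, and it also sets a detection limit (see
Limitations).

Every considered step (the best candidate of each round, accepted or
rejected) is recorded in an audit trail `(step, signature, ε before,
ε candidate, accepted)` used by tests and debug logging.

### Numerical choices

* **NNLS contract.** The solver must satisfy the KKT conditions: a ≥ 0,
  gradient g = Sᵀ(S·a − v) ≥ −tol, and |aᵢ·gᵢ| ≤ tol with
  tol = 1e-8·max(1, ‖Sᵀv‖∞). Tests verify this directly and check the
  attained objective against exhaustive active-set enumeration on small
  instances.
* **Zero-activity removals.** Removing a column with zero fitted activity
  leaves the NNLS optimum unchanged, so its removal error equals the
  current ε exactly; no refit is needed. When such columns exist the
  lowest-index one is removed directly. Otherwise all single-removal refits
  are evaluated and the arg-min taken. Ties break to the lowest column
  index in both passes (the minimum alone does not determine the candidate;
  a deterministic rule is required for reproducibility). The shortcut can
  differ from evaluating every candidate only in the degenerate case where
  a lower-index nonzero-activity column ties at exactly ε — the returned ε
  is identical either way.
* **Integer activities.** The real-valued solution on the selected set is
  rescaled so activities sum to the sample's burden, then rounded by
  largest remainder (remaining units go to the largest fractional parts,
  ties to the lowest index). Conservation — integer activities summing
  exactly to the observed mutation count — is the most interpretable
  contract for "number of mutations imprinted by each signature"; it can
  be disabled (`rescale_to_burden=False`), which rounds entries half-up
  independently. The rescaling normalizes before multiplying
  (a/Σa · burden) so subnormal sums cannot overflow.
* **Signature normalization.** Reference files carry rounded probabilities;
  columns whose sum deviates from 1 by ≤ 1e-3 are renormalized exactly on
  load, larger deviations are errors (silent rescaling would mask malformed
  input).

## Per-mutation attribution

For a sample with fitted activities a, a mutation in channel k is
attributed to signature i with probability
S[k,i]·a[i] / Σⱼ S[k,j]·a[j] — the activity-weighted share of the channel.
Probabilities are computed from the *integer* activities so the published
probability tables are consistent with the published activity tables; the
difference from using the real-valued solution is far below the 6-decimal
output precision. Channels where no selected signature carries mass have an
undefined posterior: rows are emitted as zeros and flagged (and a warning
is logged when a mutation falls there) rather than NaN, keeping outputs
numeric. Classification of single base substitutions into SBS-96 channels
is pyrimidine-strand normalized (purine references are reverse-
complemented) with the canonical substitution-major, flank-minor ordering;
mutation positions are 1-based and carried through but never used for
classification — the context column is authoritative, so no reference
genome is required.

## Synthetic benchmark

`generate_reference_signatures(ξ, n_ref, sparsity, seed)` draws each
synthetic signature on ⌈sparsity·ξ⌉ channels chosen uniformly, with
Dirichlet-flat masses. The default sparsity 0.1 (≈10 of 96 channels)
reflects that curated reference signatures typically concentrate most of
their mass on a modest number of channels; pairwise cosine similarities of
the resulting sets are available as a diagnostic (`pairwise_cosine`).

`simulate_catalog` draws, per sample: an active set (uniformly 1–5
signatures from a fixed generating pool of 21 drawn out of the 79-signature
reference set), relative exposures from a flat Dirichlet, a burden
log-uniform in [10², 10⁴], integer true activities by largest-remainder to
hit the burden exactly, and channel counts as a single multinomial draw
from S·(a/burden). `inject_noise(q)` removes ⌈q·burden⌉ mutations uniformly
without replacement (multivariate hypergeometric) and re-adds the same
number to uniformly random channels — nonsystematic, burden-preserving
noise; q = 0 is the identity. The benchmark generates one base catalog,
applies each noise level (default 0, 0.05, 0.10) to it, refits every noisy
catalog against the *full* reference set, and scores presence calls
(activity > 0 on both truth and estimate; a minimum-activity threshold is
configurable, default 0, the strictest parameter-free choice) pooled over
all sample–signature pairs: precision, sensitivity, specificity, and F1 as
the harmonic mean of precision and sensitivity. Empty denominators yield
flagged `None` values, never division errors. All randomness flows from a
single seed through spawned child sequences, so the whole
simulate → noise → assign → score chain is bit-reproducible.

What the generator does *not* emulate: real signature profiles (synthetic
profiles are random-sparse, not COSMIC shapes), inter-sample correlation of
exposures within a cancer type, systematic noise (sequencing artifacts,
mapping bias), and burden distributions of real cohorts. Passing benchmarks
therefore demonstrate the selection engine's behavior under controlled,
well-separated conditions, not accuracy on any particular tumor cohort.

### Problem sizes

The default benchmark shapes were fixed as the package's own study
conditions: 200 samples for the 96-channel headline run at 10% noise, and
100 samples per condition for the reduced-dimension runs (channel
dimensions 78, 83, 48 with reference sizes scaled proportionally to 64, 68
and 40 signatures, generating pools of 17, 18 and 11), all three noise
levels each. The full-scale 2700-sample shape is reachable through
`SimulationConfig`.

The exact-recovery test uses a separate planted construction: reference
profiles built from integer channel masses (denominator 1000) so that
activities in multiples of 1000 produce samples lying *exactly* in the
planted signatures' cone; active sets of ≤ 3 signatures are re-drawn until
pairwise cosines are < 0.6 and every component carries ≥ 20% of the burden.
The exposure floor is deliberate: a component whose removal costs less than
the 0.01 tolerance is pruned by the algorithm's own design, so an
exact-recovery test only makes sense for individually detectable
components.

## Known limitations

* **Detection limit.** The removal rule prunes any signature whose
  contribution to the squared relative error is below ~0.01 — in practice
  exposures below roughly 5–10% of a sample's burden (depending on profile
  overlap and burden). Under flat-Dirichlet exposures with up to 5 active
  signatures and burdens down to 100, many planted exposures fall below
  this limit; pooled sensitivity saturates near 0.8 while precision stays
  near 1. This is a property of the selection thresholds, not of the
  optimizer.
* **No DBS/ID/CN classification from raw mutations.** Those schemas are
  supported only via pre-built matrices; per-mutation attribution is
  SBS-only.
* **Per-sample independence.** No cohort-level joint sparsity, confidence
  intervals, or bootstrap stability.
* **Minimal mutation-list dialect.** Biallelic SNVs with an explicit
  context column; full VCF/MAF parsing (multi-allelic records, symbolic
  alleles, genome-based context extraction) is out of scope and rejected
  with a clear error.
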