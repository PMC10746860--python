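# sigassign

Sparse assignment of known mutational signatures to individual cancer
samples and to individual somatic mutations.

## The problem

Somatic mutations in a cancer genome are the superposition of several
mutagenic processes, each leaving a characteristic distribution over
mutation channels — a *mutational signature* (e.g. the COSMIC reference
sets for single base substitutions under the SBS-96 schema, doublets
DBS-78, indels ID-83 and copy-number segments CN-48). *Refitting* asks:
given a sample's channel-count vector **v** ∈ ℕ^ξ and a matrix
**S** ∈ ℝ₊^(ξ×n) of n known signatures (column-stochastic), how many
mutations did each signature contribute?

A plain nonnegative least squares (NNLS) fit over the full reference set
overfits badly — dozens of signatures receive small spurious activities.
`sigassign` uses a forward-stagewise selection loop around NNLS:

1. fit all n signatures with NNLS (Lawson–Hanson) and compute the relative
   reconstruction error ε = ‖v − S·a‖² / ‖v‖²;
2. **remove** signatures one at a time while the cheapest single removal
   raises ε by at most 0.01;
3. **add** signatures back one at a time while the best single addition
   lowers ε by at least 0.05;
4. alternate 2–3 until the selected set is stable, then refit and rescale
   the real-valued activities to the sample's total mutation burden,
   rounding by largest remainder so integer activities sum exactly to the
   burden.

The asymmetric thresholds buy sparsity: a signature stays in the model only
if it explains a substantial share of the catalog.

Given the fitted activities, each individual mutation (from a mutation-list
input carrying trinucleotide contexts) is attributed probabilistically via
its channel k:

    P(signature i | channel k) = S[k,i]·a[i] / Σⱼ S[k,j]·a[j]

The package also ships a synthetic benchmark: catalogs simulated from a
subset of a larger synthetic reference set (multinomial draws with known
integer ground-truth activities), burden-preserving random noise
(relocating a fraction of mutations to uniform channels), and pooled
precision / sensitivity / specificity / F1 scoring of signature-presence
calls against the ground truth.

## Worked example

```python
import numpy as np
import sigassign as sg

S = np.array([[1.0, 0.0, 1/3],
              [0.0, 1.0, 1/3],
              [0.0, 0.0, 1/3]])
sigs = sg.SignatureSet(sg.custom_schema(["c1", "c2", "c3"]), ["s1", "s2", "s3"], S)
res = sg.assign_sample(np.array([50, 50, 0]), sigs, sample_id="toy")
print("activities:", dict(zip(sigs.signature_ids, res.activities)))
print("relative error:", res.final_relative_error)
for e in res.audit:
    print(f"  {e.step:6s} {e.signature}: eps {e.eps_before:.4f} -> {e.eps_candidate:.4f} "
          f"({'accepted' if e.accepted else 'rejected'})")
```

prints

```
activities: {'s1': 50, 's2': 50, 's3': 0}
relative error: 0.0
  remove s3: eps 0.0000 -> 0.0000 (accepted)
  remove s1: eps 0.0000 -> 0.5000 (rejected)
  add    s3: eps 0.0000 -> 0.0000 (rejected)
  remove s1: eps 0.0000 -> 0.5000 (rejected)
  add    s3: eps 0.0000 -> 0.0000 (rejected)
```

The flat decoy signature s3 carries zero activity in the full NNLS fit, so
its removal is free (ε stays 0) and accepted under the 0.01 rule; removing
either axis signature would cost ε = 0.5 and is rejected; re-adding s3
would gain nothing and is rejected — the loop stops with the true pair
{s1, s2} and activities (50, 50, 0) summing exactly to the 100 observed
mutations.

From the shell, the same workflows are:

```bash
sigassign assign -i catalog.tsv -s cosmic_sbs.tsv -o results/
sigassign assign -i mutations.tsv -s cosmic_sbs.tsv -o results/   # + per-mutation probabilities
sigassign simulate  --samples 90 --seed 7 -o sim/
sigassign benchmark --samples 30 --seed 3 -o bench/
```

The benchmark command writes `benchmark_summary.json`; at the settings
above it prints, per noise level:

```
noise 0:    F1 0.8795  (precision 0.961, sensitivity 0.811)
noise 0.05: F1 0.8970  (precision 0.987, sensitivity 0.822)
noise 0.1:  F1 0.8862  (precision 0.961, sensitivity 0.822)
```

Precision stays near 1 — the stagewise loop almost never hallucinates a
signature — while sensitivity is bounded by the planted exposures that fall
under the removal threshold's detection limit (see `docs/methods.md`).

## Input formats

* **Catalogs / signatures** — tab-separated, UTF-8, first column
  `MutationType` with channel labels (SBS-96 labels like `A[C>A]A`),
  one column per sample (integer counts) or signature (probabilities,
  columns summing to 1 within 1e-3). Rows may be in any order; output is
  always in canonical channel order.
* **Mutation lists** — tab-separated with header
  `sample chrom pos ref alt context`; `context` is the reference-strand
  trinucleotide centered on the mutated base (no reference genome needed).
* **Activities** — samples as rows, signatures as columns, integers.

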