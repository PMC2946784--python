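# Methods

## Problem and model

`taphunter` classifies peptides as TAP binders or non-binders. The working
hypothesis, supported by TAP binding-assay studies, is that binding is
dominated by a few anchor residues near the termini, so the feature space is
built from a *subset* of residue positions rather than the whole sequence.

Positions are named on a 9-slot template: slots 1–8 are anchored at the
N-terminus (slot *s* = residue *s*), slot 9 is always the C-terminal
residue. On nonamers — the dominant length in TAP data — the template is the
identity map, so subsets read directly as p1…p9. For longer peptides
(accepted up to 21 residues in peptide mode) slot 9 tracks the C-terminus
while slots 1–8 stay N-anchored; for peptides shorter than 9, slots 4–8 are
only valid when they do not collide with the C-terminal residue
(slot ≤ length − 1). This keeps the feature-vector length constant for a
given configuration across peptide lengths.

Each selected residue contributes a block of descriptors, in fixed order:

| descriptor | definition | range |
|---|---|---|
| onehot | 20-dim residue identity indicator | {0,1} |
| hydrophobicity | Kyte–Doolittle index / 4.5 | [−1, 1] |
| aromaticity | indicator on {F, W, Y} | {0, 1} |
| charge | +1 for K/R, −1 for D/E, 0 otherwise (H neutral) | {−1, 0, 1} |
| residue_weight | monoisotopic residue mass, min–max rescaled | [0, 1] |

The descriptor *names* are fixed by the problem; the per-residue scales are
package defaults kept in a replaceable registry (`encoding.SCALE_SETS`), so
alternative scale sets can be swapped in without touching the pipeline.
Treating histidine as neutral is a deliberate simplification (its pKa sits
near physiological pH).

## Classifier

A soft-margin kernel SVM with the dual decision function
f(x) = Σᵢ αᵢ yᵢ K(sᵢ, x) + b under the box constraint 0 ≤ αᵢ ≤ C. The
quadratic program is delegated to scikit-learn's `SVC`; the fitted estimator
exposes the support vectors, dual coefficients and bias, and the package
re-evaluates the decision function from those stored quantities itself, so
the contract is testable against a brute-force summation independent of the
solver. The sign rule is strict: f(x) > 0 ⇒ binder; an exact zero is called
non-binder.

Defaults: RBF kernel, C = 1, γ = 1/d (d = feature dimension). No tuning
information was available for these, so they are the standard baseline;
both are exposed everywhere. Linear and polynomial kernels are available,
the sigmoid kernel is deliberately not. Accuracy is always measured at the
SVM's natural threshold 0 — no threshold tuning.

## Evaluation

* **AROC** is computed as the Mann–Whitney statistic via midranks
  (ties counted ½), which equals the trapezoidal area under the empirical
  ROC curve; ROC points come from a full threshold sweep.
* **SE/SP/ACC** with NaN (an explicit "undefined" flag) on zero
  denominators rather than a silent 0.
* **Cross-validation** is stratified k-fold (default k = 5), shuffled
  deterministically by seed; every fold's class ratio is within one
  instance of the global 276:94 ratio at the study scale. CV accuracy is
  reported both pooled over all held-out predictions (the default) and as
  the per-fold mean, since either convention is found in practice; CV AROC
  is the per-fold mean.
* **Truncation analysis** evaluates every candidate subset on the *same*
  fold partition (same seed), so ranking differences are attributable to the
  encoding alone. Ties on CV AROC break toward higher CV ACC, then smaller
  subsets, then lexicographic order — a parsimony preference. Hyperparameters
  are held fixed across subsets. The `table1` candidate family is the 32
  published subsets of the original truncation study; `exhaustive-anchored`
  generalizes it to all subsets of {1..9} with at least one anchor on each
  side.
* **Bootstrap comparison** of two predictors resamples positives and
  negatives separately with replacement (both classes always survive), at
  full test-set size by default; `--subsample-fraction` reproduces the
  smaller-replicate reading. The two-sided p-value is sign-based: twice the
  fraction of replicates whose AROC difference falls on the opposite side of
  zero from the mean difference, floored at 1/B, capped at 1; a mean
  difference of exactly zero gives p = 1. This is an explicit design choice —
  percentile CIs are reported alongside so other inferential conventions can
  be applied to the replicate distribution directly. B defaults to 1000.

## Synthetic data generator

The generator emulates the *structure* of TAP binding-assay datasets, not
any particular dataset: nonamer-dominated peptides (length distribution is a
free parameter, default point mass at 9), with binder residues drawn
position-wise from background frequencies reweighted by
`exp(effect_size · w)` and renormalized, where w = +1 for preferred classes
(aromatic/acidic at p1, hydrophobic/basic at p2, aromatic at p3, p7 and the
C-terminus) and w = −1 for proline at p1/p2. Non-binders are pure
background. Overlapping classes keep the larger exponent rather than
stacking. At effect_size 0 the two classes are identically distributed; the
default study strength is 2.0, at which anchor-position models reach CV
AROC ≈ 0.88–0.91 — comparable to what terminal-anchor models achieve on real
assay data — while remaining imperfectly separable.

The background is uniform over the 20 residues by default, which isolates
motif signal for testing; a Swiss-Prot-like natural-abundance background is
available by name. The generator acts on residue *classes* while the encoder
acts on numeric *scales*, so generator and features are consistent but not
identical — this avoids circular, trivially perfect separability.

What the synthetic data does **not** model: binding-affinity values (labels
are binary), inter-position dependencies, length mixtures of real assay
collections, and experimental label noise. Passing pipeline tests on this
generator therefore demonstrates correctness and calibration of the
machinery, not predictive performance on real TAP data.

Proteins for scan-mode testing are background-sampled with non-overlapping
binder-motif k-mers implanted at recorded 1-based positions.

## Numerical and degenerate-input choices

* Peptide alphabet is the 20 canonical residues; `X` is accepted in
  protein FASTA but any scan window containing it is skipped with a warning,
  preserving the 1-based coordinate frame of later windows.
* Peptide-mode length limits 4–21; scan windows 4–12; a protein shorter
  than the window yields an empty result with a warning, not an error.
* Duplicate (sequence, label) records are rejected at parse; a sequence
  carrying both labels is rejected as conflicting.
* Models persist to a flat JSON file carrying kernel parameters, C, bias,
  dual coefficients, support vectors and a hash of the encoding
  configuration; loading refuses a mismatched hash so a model can never be
  applied to features from a different encoding.
* All stochastic operations (generation, fold shuffling, bootstrap) take
  mandatory integer seeds and are bit-reproducible.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the pipeline at the study
scale of 276 binders / 94 non-binders with 5-fold CV, 5 seeds for
seed-averaged quantities, an independent synthetic test set of 91/32 for
the retrained winner, 1000 bootstrap replicates, and the full 32-subset
truncation family. These sizes mirror the composition of the original
assay datasets and keep every check fast and deterministic.

## Known limitations

* The exact binary encoding and property scales of the original server are
  unpublished; the defaults here are explicit, documented stand-ins.
* Real TAP datasets are needed for any claim about real-data performance;
  the package only verifies the machinery and its calibration.
* No integrated proteasome–TAP–HLA pathway modelling, no affinity
  regression, no greedy feature selection beyond subset enumeration.
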