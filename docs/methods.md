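# Methods

## Model and procedure

`ismvar` treats a protein as a discrete signal: the EIIP value of each
residue (a per-amino-acid constant in Rydbergs approximating the energy
of its valence electrons) at unit spacing.  The informational spectrum
is the raw energy density S(n) = |X(n)|² of that series over the
one-sided frequency grid fₙ = n/N, n = 1…⌊N/2⌋.  Conventions, all
following the standard ISM formulation:

* The DC bin is excluded; consequently the spectrum is invariant to
  adding a constant to the series and mean-centering changes nothing.
* Odd N: the grid stops at ⌊N/2⌋, so the 0.5 bound is attained exactly
  when N is even.
* No windowing, zero-padding or normalisation.  The implementation uses
  a real FFT, but the contract is the direct O(N²) sum; the test suite
  carries an independent direct-sum oracle and checks agreement to 1e-9
  relative tolerance over random sequences of both parities.

Classification is per protein.  Variant i is scored at frequency j by
S(i,j) = A(fⱼ)ᵥₐᵣᵢ − A(fⱼ)wt (exact elementwise difference, no
normalisation).  The classifier frequency is found by a sequential
search: frequencies in descending order of wild-type amplitude, at each
a two-sided Mann–Whitney U test of mutation-row vs SNP-row scores, stop
at the first p < α.  The wild-type amplitude there is the cutoff; the
orientation sign is +1 when the mutation median is at least the SNP
median, −1 otherwise; a variant is called MUT iff
orientation·(A_var − cutoff) > 0.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| α | 0.05 | significance level of each sequential Mann–Whitney test |
| Mann–Whitney method | auto | exact null when both groups ≤ 12 and the pooled sample is tie-free, else normal approximation with tie and continuity corrections; verified against a full-permutation enumeration oracle |
| orientation tie | +1 | equal group medians default to "higher = mutation" |
| cutoff tie | SNP | a variant whose amplitude equals the cutoff exactly is called benign |
| amplitude tie in search order | ascending frequency | deterministic visiting order when wild-type amplitudes are equal |

Frequency selection always uses *all* labelled variants of a gene;
evaluation may then be restricted to the subset outside conserved
domains (`subset="nCFD"` in `run_study`), which is the regime the method
targets.  Both the all-variant and subset evaluations are supported; the
in-sample reading (models fitted on all variants, evaluated on a subset)
is the default.

## Statistical choices

* **No multiplicity correction** is applied across the sequential
  frequency tests — deliberately, since the procedure being implemented
  is defined that way.  The cost is quantified rather than hidden:
  `frequencies_tested` reports the search depth, and the null simulation
  (200 seeded datasets with no planted signal) measures the family-wise
  discovery rate, which comes out near 0.98 — far above α, exactly the
  inflation uncorrected stepwise testing produces over ~100 correlated
  frequency columns.  A selected frequency should therefore never be
  taken at face value without a stability check
  (`cross_validate_frequency`).
* Fisher's exact test is two-sided by hypergeometric enumeration (via
  scipy); a zero-margin table returns p = 1 with a warning.
* ROC/AUC uses the rank (Mann–Whitney) estimator with ties counted 1/2,
  identical to trapezoidal integration over all distinct thresholds;
  single-class inputs are rejected, undefined confusion metrics (zero
  denominators) are reported as missing, never as 0.
* Third-party score conventions: SIFT scores are reoriented as 1 − s so
  higher means damaging; binarisation uses SIFT original < 0.05 → MUT
  (strict: 0.05 itself is SNP) and PolyPhen-2 ≥ 0.5 → MUT (the boundary
  is classified as mutation; the published rule leaves equality open and
  the inclusive reading is fixed here for determinism).

## Synthetic data: what it emulates, what it does not

`generate_planted_dataset` builds the situation the method presumes:

* **Wild type** (default length 300): at a mixing fraction of 0.5 the
  residue whose EIIP best tracks a cosine at the planted bin n* is
  chosen, otherwise a uniform draw.  This plants a strong periodic
  component so that n* ranks at or near the top of the wild-type
  amplitudes — mirroring the premise that classifier frequencies are
  prominent spectrum peaks, and keeping the sequential search's early
  tests focused on the planted bin.
* **Mutations** (default 20): the candidates (position, alternate
  residue) with the largest positive amplitude shift at n*, evaluated in
  closed form (a single substitution changes X(n) by
  δ·e^(−i2πn(p−1)/N)).  Candidate evaluation is capped at 5,000 seeded
  draws per dataset for speed.
* **SNPs** (default 20): candidates from the smallest decile of
  |shift at n*| that are also quietest over the 3 bins either side of
  n*, preventing leakage of the planted signal into neighbouring bins
  from confounding recovery tests.
* The realised standardised separation (difference of group means over
  pooled SD of the shifts at n*) is recorded and must reach the
  requested effect size (default 3 SD); otherwise generation fails with
  a hint to increase the length.  `effect_size=0` switches to the
  exchangeable null (both classes uniform draws), as does
  `generate_null_dataset`.

Because the planted bin is deliberately a top wild-type peak, the
relevant "chance" level for selecting it under the null is α (it is
tested first), not 1/M; the seeded simulations in the test suite bear
this out (~3% hit rate at α = 0.05).

What the generator does **not** emulate: real mutational spectra, codon
or transition/transversion structure, disease prevalence, positional
clustering of somatic mutations, or isoform ambiguity.  Passing the
recovery tests therefore shows the algorithm is implemented correctly
and is sensitive when its assumptions hold; it does not certify
real-data performance, which in published use reaches accuracy ≈ 0.7 on
substitutions outside conserved domains, not the near-perfect separation
the planted construction produces.

## Numerical choices and degenerate inputs

* Sequences shorter than 2 residues, empty label classes, and
  non-canonical residues (X, B, Z, U, `*`, gaps) are errors; an optional
  sequence-mean imputation for non-canonical residues exists but is off
  by default.
* Model files store floats at full `repr` precision: the cutoff takes
  part in an exact tie rule, so round-tripping must not move it.
* Duplicate (gene, substitution) rows collapse with a warning; a
  substitution listed as both SNP and MUT is excluded (conservative) with
  a warning.
* Cross-validation folds that lose a class report "degenerate split"
  rather than failing the whole run.
* Domain intervals are 1-based and inclusive on both ends and may not
  overlap within a gene.

## Problem sizes

The default simulations — 100 planted datasets (length 300, 20+20
variants) for recovery, 200 null datasets (length 200, 15+15) for the
discovery-rate estimate, 5-fold cross-validation on one strong dataset —
were chosen to give stable rate estimates (±0.03 at n = 200) while a full
run of the acceptance script stays in the seconds range on one CPU.

## Known limitations

* Single-residue substitutions only — no indels, no multi-site variants,
  no nucleotide-level input.
* One classifier frequency per protein; multi-frequency criteria are out
  of scope.
* The sequential selection is anti-conservative by construction (see
  above); p-values attached to the selected frequency are not corrected
  for the search.
* Positions are literature coordinates; mismatches against the supplied
  wild-type sequence (e.g. isoform differences) surface as explicit
  consistency errors rather than being silently remapped.
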