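# Methods

## Model

The pipeline compares mapped-read depth between a female DNA pool and a
male DNA pool over a softmasked male reference. Per diploid genome a male
carries 2 copies of each autosome, 1 X and 1 Y; a female carries 2
autosomal copies, 2 X and 0 Y. If both pools were sequenced to the same
effective depth, the expected female:male count ratio per fragment is
therefore 1 (autosome), 2 (X) and 0 (Y). Real libraries differ in size,
so the raw ratio R_i = F_i/M_i is multiplied by norm = M_total/F_total,
giving R_i-norm with those same expectations.

Fragments — maximal runs of unmasked, non-gap sequence — are the unit of
analysis rather than whole scaffolds because repeats attract multi-source
mappings and would blur the ratio; restricting to unique-looking sequence
between repeat runs keeps each depth measurement interpretable.

Scaffold calls aggregate fragments: with N fragments genome-wide, n of
them below the ratio threshold, a scaffold with M fragments and k
below-threshold fragments is scored by the hypergeometric upper tail
P(X ≥ k). Fragments are treated as exchangeable draws; no positional
clustering within scaffolds is modelled.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_len` | 200 bp | minimum retained fragment length |
| `y_max` | 0.3 | R-norm threshold for Y candidates (strict `<`) |
| `stringent_max` | 0.15 | stricter threshold feeding the marker stage |
| `min_male_reads` | 15 | male-pool depth filter; below it a fragment is `low_coverage` |
| `alpha` | 1e-5 | scaffold enrichment p-value cutoff (strict `<`, no multiplicity correction) |
| `evalue_max` | 1e-5 | female-assembly hit e-value that discards a marker candidate |
| `totals_mode` | `mapped_reads` | denominator convention for `norm` |

These defaults are the method's published operating point, so a bare
invocation reproduces its decision rules. The X/autosome diagnostic bands
(≥ 1.5 X-like; 0.6–1.4 autosome-like) only label output rows; no
inference uses them.

**Totals convention.** `norm` may be computed from mapped-read totals or
from sequenced-library sizes. Mapped totals are the default: they are
internally consistent with the counts in the numerator and denominator of
R_i, and make R_i-norm invariant to a global rescaling of one library.
Sequenced totals can be supplied via `totals_mode="total_reads"` with
`external_totals`. The two conventions differ by ~5% on the motivating
data; published per-fragment example ratios are not exactly reproducible
under either single convention, so they are treated as illustrative and
only their qualitative content (F_i = 0 ⇒ R_i-norm = 0) is asserted.

**Tail direction.** The enrichment formula is sometimes written as the
lower-tail sum over i = 0..k−1, which would approach 1 for enriched
scaffolds. The implementation computes the upper tail P(X ≥ k), which
reproduces all published per-scaffold p-values exactly; the lower-tail
form is its complement.

## Numerical choices

- The hypergeometric tail is summed in log space: each term's log comes
  from log-gamma binomial coefficients and terms combine via logsumexp.
  `log10_p` therefore stays accurate (tested to 1e-9 against exact
  integer arithmetic over all instances with N ≤ 60) even where the
  p-value itself underflows double precision. The relative-error check is
  floored at magnitude 1 because log10 p → 0 as p → 1 makes a pure
  relative criterion ill-conditioned precisely where the probability is
  trivially accurate.
- M_i = 0 leaves R_i undefined (reported `NA`) rather than infinite; such
  fragments are `low_coverage` regardless, since 0 < 15.
- Threshold comparisons are strict everywhere (`< y_max`, `< alpha`,
  `< evalue_max`); boundary values are excluded.
- Ties in enrichment output are broken by scaffold id after p-value, so
  reports are byte-stable.
- Fragment ordinals are assigned 1-based over *retained* fragments (after
  the length filter) in scaffold order. This is a convention: the naming
  scheme does not itself determine whether dropped runs consume an
  ordinal.
- Any run of ≥ 1 masked or N base splits fragments; there is no merging
  across short masked runs. N runs act as separators by default
  (`split_on_n=True`) because assembly gaps are not sequence; setting it
  false treats N as fragment interior (the masked-base invariant then no
  longer guarantees N-free fragments).
- `masked_fraction` reports lowercase bases over non-N bases, the usual
  convention for repeat content over resolved sequence.

## Synthetic data: what it emulates, and what it does not

`simulate_genome` draws scaffolds (default 50 autosomal, 5 X, 5 Y of
8–16 kb — a deliberately small genome that keeps a full pipeline run
under a second) as alternating unmasked runs (mean 750 bp, so most clear
the 200-bp filter) and lowercase repeat runs sized to hit a target masked
density: 17.53% genome-wide and 30.71% on Y scaffolds, mirroring the
repeat accumulation observed on real Y-linked sequence.
`simulate_pool_counts` draws per-fragment counts as
Poisson(depth × copies/2 × L/read_len) per pool at 25× pooled depth and
150-bp reads, with two knobs: `leakage` adds female reads on Y fragments
in proportion to female depth, emulating residual X–Y homology (the main
real-world reason Y fragments sit above 0); `overdispersion` switches to
a gamma-mixed (negative-binomial) draw. All randomness flows through one
seeded generator, so a config is exactly reproducible.

The simulator does not model sequencing error, GC or mappability bias,
multi-mapping between homologous X and Y copies, library-specific mapping
rates, or read placement (counts are drawn directly, though a BAM-backed
path is exercised with synthetic alignments in the tests). Passing
recovery tests therefore demonstrate the statistical machinery —
thresholds, enrichment, calibration — under the copy-number model, not
robustness to alignment artefacts in real data.

Default-regime expectations used by the tests: autosomal mean R-norm in
[0.95, 1.05], X mean in [1.85, 2.15], Y mean ≤ 0.05 (exactly 0 at
leakage 0); all 5 Y scaffolds enriched at p < 1e-5 with no autosomal
false calls; and under a randomized-null candidate assignment over
10,000 scaffolds the enriched fraction at level α stays within binomial
sampling error of α.

## Known limitations

- Sensitivity at a fixed 0.3 threshold degrades as X–Y homology
  (leakage) grows; the package reports this through
  `evaluate_recovery` but does not adapt the threshold (no mixture
  modelling of the genome-wide ratio distribution).
- The homology discard uses e-value only; no coverage or identity floor
  is applied, so a short strong hit discards a candidate even if most of
  the fragment is male-specific.
- Scaffolds whose fragments all fail the male-depth filter never reach
  the enrichment stage in candidate-bearing reports.
- The enrichment test assumes fragments are exchangeable across the
  genome; long repeat-dense scaffolds with few retained fragments have
  little power regardless of their true origin.
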