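# Methods

## The spectral-counting model

Spectral counting treats the number of MS/MS spectra assigned to a protein
in one LC-MS/MS run as a proxy for its abundance. For a two-condition
comparison with one pooled sample per condition, the package computes, per
protein, the corrected log2 count ratio

    Rsc = log2[(n_s + f)/(n_n + f)] + log2[(t_n − n_n + f)/(t_s − n_s + f)]

where n_n, n_s are the protein's counts in the reference and case run,
t_n, t_s the run totals over all proteins, and f a pseudo-count. The first
term is the fold change proper; the pseudo-count regularizes it when one
count is zero (a protein detected only in the case still gets a finite,
depth-dependent Rsc rather than ±∞). The second term corrects for unequal
total sampling depth: if one run simply acquired more spectra overall,
every raw ratio would be biased, and the complement term removes that bias
exactly in the large-count limit. When counts are small relative to the
totals and the depths are equal, Rsc → log2(n_s/n_n), which is why the
selection thresholds ±1 are read as 2-fold and 0.5-fold changes.

Within-run relative abundance uses the normalized spectral abundance
factor, NSAF_i = (SpC_i/L_i) / Σ_j (SpC_j/L_j): dividing by the protein
length L_i (residues) removes the trivial advantage long proteins have in
generating peptides, and the normalization makes the values a composition
summing to 1. The denominator runs over every protein in the count matrix,
including zero-count ones (which contribute 0), so the two conditions share
one protein universe and their NSAF columns are directly comparable.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| f | 1.25 | spectra | pseudo-count in both Rsc terms |
| up/down thresholds | +1 / −1 | log2 | strict DE cutoffs (boundary = unchanged) |
| min_count | 1 | spectra | identification criterion for the Venn sets |
| min_k | 2 | proteins | smallest DE-category overlap reported by enrichment |

Rsc classification uses strict inequalities; a protein sitting exactly on a
threshold is "unchanged". Proteins absent from one condition are not
special-cased anywhere — handling them is precisely what the pseudo-count
is for.

## Counting conventions

A PSM row counts once toward exactly the accession it carries; there is no
shared-peptide or razor-protein apportionment, because the pipeline's input
is a flat per-PSM report in which protein inference has already happened
upstream. Counts are per PSM row, not per distinct spectrum id; with
typical exports these coincide, and a deduplicated input realizes the other
convention. Multiple sample ids may be pooled into one condition by
summation (`condition_of` mapping), reflecting designs that pool biological
replicates into one run per condition. "Identified" for set comparison
means spectral count ≥ min_count (default 1).

Percentages in the Venn summary are rounded half-up to one decimal, the
convention of printed identification tables (Python's built-in bankers'
rounding would disagree on exact .05 boundaries).

## Enrichment

Category over-representation among DE proteins is tested with the one-sided
hypergeometric tail P(X ≥ k) for a category with K background members, a DE
set of size n, and a background of size N. The default background is all
identified proteins, not a whole-proteome list: the question answered is
"among the proteins this experiment could see, are DE calls concentrated in
this category?". Web annotation tools often use a modified Fisher score
that tests k−1 successes; that conservative variant is available behind the
`ease` flag for comparability, but the plain tail is the default because it
is the exactly defined statistic. Benjamini–Hochberg adjustment is applied
across the reported categories; both raw and adjusted p-values are emitted
since threshold conventions differ between studies.

## Wound healing

Corneal wound healing at time t is (area_0 − area_t)/area_0 × 100. Only the
ratio of areas enters, so units (mm², pixels) are the caller's choice and
the statistic is scale-invariant; negative values (wound growth) are
reported, not clipped. Group summaries are mean ± SEM with the sample
standard deviation (n−1); a group needs at least two subjects. The
evaluation time is a parameter rather than a constant because monitoring
schedules vary (6 h and 25 h are typical for rodent corneal abrasion).

## The synthetic generator

`simulate` emulates the statistical skeleton of a pooled two-condition
spectral-counting experiment: per condition, a total spectrum count drawn
Poisson around the target depth, distributed over proteins multinomially
according to the condition's true relative abundances. The
multinomial-conditional-on-Poisson construction keeps the true abundances
an exact composition (summing to 1) while making per-protein counts
marginally independent Poissons; a pure independent-Poisson switch is
provided. Baseline abundances are log-uniform over two orders of magnitude
— spectral-count data are strongly right-skewed, with a handful of
proteins carrying a large share of spectra. A planted fraction of proteins
(default 10%) carries a multiplicative fold change (default 4), up or down
with equal probability, in the second condition before renormalization.
Defaults of 500 proteins and ~5,000 spectra per condition approximate a
small-animal tissue run yielding a few hundred identifications.

What the generator deliberately does not model: peptide-level
detectability and length-dependent peptide yield (lengths are drawn
independently of abundance), run-to-run technical variation beyond
sampling noise, shared peptides, and post-translational heterogeneity.
Passing recovery tests therefore demonstrate that the statistic recovers
planted abundance shifts under sampling noise — not that it is robust to
every systematic effect in real LC-MS/MS data.

`evaluate_recovery` scores a quantitation table against the planted truth:
sensitivity (planted proteins called with the correct sign / planted),
false-positive rate (null proteins called DE / null), and sign accuracy
among recovered. An expected-count filter (depth × true abundance) is
available because count-based calls are meaningless for proteins expected
to yield a couple of spectra.

### False-positive behaviour of the ±1 rule

The threshold rule has no significance calibration, and its null
false-positive rate depends strongly on a protein's sampling depth. With
both counts Poisson with mean λ and run totals near 5,000, the exact
probability that |Rsc| exceeds 1 under the null is ≈ 17.8% at λ = 5, 9.1%
at λ = 10, 4.7% at λ = 15, and 0.7% at λ = 30 (computed by direct
truncated double summation over the Poisson joint law; the package's
Monte-Carlo tallies reproduce these figures). Aggregated over the
generator's defaults, the null FPR among proteins with expected count ≥ 5
is ≈ 6%, dropping below 5% only around expected count 15. This is a
property of the rule itself, not of the implementation: users wanting
calibrated error rates at low counts should pair the threshold with a
count-based test, which is outside this package's scope.

## Numerical choices

- Rsc is evaluated with one log2 per term (scalar: `math.log2`; matrix:
  `numpy.log2`); the scalar and vectorized paths agree to < 1e−12 and are
  cross-checked in the tests against an independent natural-log oracle.
- Float comparisons in the suite use an absolute tolerance of 1e−12 for
  algebraic identities (NSAF sums, antisymmetry).
- Preconditions (negative counts, count exceeding its total, non-positive
  f, zero initial wound area) raise typed errors; nothing is clamped
  silently.
- Quantitation tables sort by Rsc descending with lexicographic accession
  tie-breaks (stable mergesort), so reruns are byte-identical.
- All simulation randomness flows through `numpy.random.default_rng`
  seeded explicitly; there is no global random state.

## Test problem sizes

Property suites run on the order of 10³–10⁴ random tuples/matrices, and
the Monte-Carlo recovery study uses 100 simulated experiments of 500
proteins at depth 5,000 per arm — enough for the tallied rates to have
standard errors well under a percentage point while the whole suite stays
in the seconds range.

## Known limitations

- No peptide-level quantitation, protein grouping, or FDR filtering of
  PSMs; the input is assumed to be a final, filtered identification report.
- The enrichment stage does no ontology-graph propagation; categories are
  taken as flat labels from the annotation table.
- The ±1 rule's uncalibrated false-positive behaviour at low counts,
  quantified above.
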