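# Methods

## The SNMM model

The single-nucleotide mutation matrix is an additive mononucleotide model of
NF-κB p50 binding to 10-bp sites. Its training data are microarray signal
intensities for one wild-type site (GGGACTTTCC) and all 30 single-base
mutants, spotted in replicate. Construction subtracts the reference probe's
aggregated intensity from each mutant probe's, giving a 4 × 10 grid of
affinity deltas ΔS(b, n) with the reference base pinned at 0 in every
column. The bundled published matrix has column maxima of 0 everywhere
except positions 5 (T, +5.74) and 8 (C, +8.13) — two mutations that bind
*better* than wild type — giving S_max = 13.87 and S_min = −301.50.

A 10-mer is scored by summing its per-position deltas and min–max
normalizing: score = (ΣΔS − S_min)/(S_max − S_min). The additivity
assumption — each position contributes independently — is shared with all
PWM-style models; it ignores inter-position dependence, which is why a
dependence-aware model restricted to the GGRRNNYYCC consensus can correlate
better on consensus sequences while the SNMM generalizes to arbitrary
10-mers.

Replicates are aggregated with the arithmetic mean (median available via
`aggregator="median"`). Recovered cells are rounded at 1e-6 — far below the
instrument's ~0.01 resolution — so subtracting the large common baseline
does not leave binary-representation dust in the cells; with zero simulated
noise, construction then inverts the simulator bit-exactly.

Incomplete mutant panels are an error by default (every scoring column
needs all four cells); `missing="impute_min"` fills gaps with the column
minimum (conservative: an unobserved mutant is presumed deleterious) and
`missing="nan"` leaves sentinels that scoring rejects.

## Comparator scorers

* **PWMSA** (log-odds): raw = Σᵢ ln(f(bᵢ, i)/bg(bᵢ)), min–max normalized by
  the per-column extreme log-odds sums. Requires strictly positive
  frequencies, hence a positive pseudocount.
* **Match** (matrix similarity score): raw = Σᵢ I(i)·f(bᵢ, i) with
  per-column information I(i) = Σ_b f·ln(4f) (0·ln 0 = 0), normalized the
  same way. Information is kept in nats; the normalized score is invariant
  to the log base. The published Match algorithm's 5-bp core pre-filter is
  omitted: for width-10 sites the core only gates candidates and the full
  MSS is the reported quantity.

PWM frequencies use Laplace smoothing spread by the background:
f = (count + p·bg)/(N + p) with pseudocount p = 1 by default — a named
parameter, never hard-coded, because comparator scores are sensitive to it.

The default NF-κB PWM (`nfkb_pwm()`) is constructed by the package from the
30 highest-EMSA sites of the bundled affinity table; the original
SELEX-derived TRANSFAC count matrix is not redistributed. This stand-in
captures the canonical GGGRNNYYCC motif (the consensus scores > 0.9, random
10-mers average far below) and is used only to *reject* random sequences
when assembling the negative set, a role insensitive to its exact counts.
Users with the original TRANSFAC file can pass it via `read_transfac` /
`--pwm`; comparator scores against published PWMSA/Match columns are
therefore secondary validation, not a primary claim.

## Evaluation

Model scores are compared with measured affinities by Pearson product-moment
correlation over pairwise-complete rows (rows missing either value are
dropped per comparison — this is what makes n = 52 for EMSA but 41 for the
z-scored subset). Two-sided p values come from t = r·√((n−2)/(1−r²)) on
n−2 degrees of freedom; |r| = 1 maps to p = 0. The verbal scale for |r| uses
left-closed intervals [0, 0.2), [0.2, 0.4), [0.4, 0.6), [0.6, 0.8),
[0.8, 1]: 0.8 itself is "very strong", consistent with calling 0.884 very
strong. Whether correlations are computed from full-precision or 3-dp
rounded scores does not change any reported value at its printed precision;
the package uses full precision.

## Threshold optimization

S1 holds scores of known sites (by default the 30 highest-EMSA sequences,
ties at the cut broken lexicographically); S2 holds scores of 30 random
10-mers rejected by the Match model. "Rejected" is interpreted as MSS below
a configurable cutoff (default 0.5) rather than literally zero, which only
the per-column-minimum sequence attains. Every threshold on the grid 0,
0.001, …, 1 is evaluated; a score counts as a predicted site iff
round(score, 3) ≥ threshold — rounding at the grid resolution guarantees a
site whose printed score equals the chosen threshold is classified positive,
and a half-grid-step epsilon keeps binary float noise from flipping the
equality. rFN = misses/N and rFP = accepts/M. The optimum minimizes
rFN + rFP, ties broken by smaller rFN and then by the largest threshold
(the most stringent among equally good predictors); on separable inputs this
provably returns the smallest rounded S1 score with zero losses, which for
the bundled data is 0.747 for every seed tried.

## Synthetic data

`simulate_microarray` emulates only the *structure* of the mutation-panel
experiment: 31 probes in R replicates, reference intensity B (default 1000,
matching the scale at which a ~32-unit mutation deficit is a plausible
signal drop), i.i.d. Gaussian noise with sd σ (default 2, giving a
triplicate-mean cell error comfortably under the matrix's smallest
informative contrast), negative draws truncated at zero with a warning.
Real scanner data have spatially correlated noise, intensity-dependent
variance and saturation, none of which are modeled — passing recovery tests
demonstrates the estimator inverts its own generative assumptions, not that
it is robust to real microarray artifacts. `random_10mers` draws i.i.d.
uniform (optionally weighted) bases.

## Numerical choices

* Scores are computed in full double precision; 3-dp rounding happens only
  when comparing to printed tables or applying the decision predicate.
* Per-column argmax/argmin ties (for the 0/1-attaining sequences and PWM
  normalization) break toward the first base in A<C<G<T order; this picks
  which sequence attains the extreme, never the value of any score.
* Inputs are uppercased and U→T; IUPAC ambiguity codes are rejected.
* A degenerate matrix with S_max = S_min cannot be wrapped in a scorer; a
  flat PWM column set scores every site 1 under min–max normalization.
* Sequences shorter than the site width scan to an empty hit list with a
  warning rather than an error.

## Problem sizes

Tests and the acceptance script run the published-scale problems directly:
52 sites, 30+30 threshold sets, a 1001-point grid, 100-seed threshold
stability, 200-seed recovery at triplicate depth. The whole suite completes
in a few seconds.

## Known limitations

* Mononucleotide additivity; no dinucleotide or higher-order terms.
* The model is specific to the 10-bp NF-κB p50 site geometry; `SITE_WIDTH`
  is fixed at 10 for the mutation matrix (PWMs may have any width).
* The SELEX-Seq enrichment table is not bundled; `load_selex_table` accepts
  a user-supplied TSV for large-scale re-scoring, and no numeric claims are
  made about it.
* The scan deliberately reports quasi-palindromic partners on both strands
  (the consensus site's reverse complement scores 0.907); deduplication is
  left to the caller, since which strand is "the" site is biology, not
  arithmetic.
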