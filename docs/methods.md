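# Methods

## Scope and model

plexquant implements relative protein quantitation from 4-plex isobaric
reporter ions. The statistical object is simple: each protein's abundance
ratio between a stress channel and the control channel is estimated by the
median of its per-spectrum normalized reporter-ion ratios, and a protein is
"accurately quantified" when at least 3 spectra contribute and a one-sample
location test of the log₂ ratios rejects "no information" at p ≤ 0.01.
Differential expression is then a fixed fold-change rule (≥ 1.2 up, ≤ 0.83
down, both boundaries inclusive — roughly symmetric on the log scale). The
pipeline deliberately contains no shrinkage, no variance modelling across
proteins and no multiple-testing correction at the DE step; it reproduces the
classic recipe faithfully so that its operating characteristics can be
measured, not improved silently.

## Isotope cross-over correction

Reporter reagents are isotopically impure: a channel's signal partly appears
one mass unit up or down. With purity matrix P (column c = the distribution
of channel c's true signal over observed channels), observed intensities are
I = P·T. We recover T by non-negative least squares rather than plain
inversion: on consistent data the two coincide (the NNLS solution is interior
and equals P⁻¹I), while on noisy spectra plain inversion can produce negative
intensities, which are physically meaningless and break the downstream ratio
algebra. Correction is vectorized as a single linear solve with an NNLS
fallback only for rows whose unconstrained solution dips below zero (beyond a
1e-9 relative tolerance), then clipped at zero.

The default purity matrix (93% on-channel, 6% at +1 Da, 1% at −1 Da, per
column) is typical of 4-plex reagent certificates. Lot certificates vary, so
the matrix is always user-overridable (`--purity purity.tsv`); the algorithm,
not the constants, is the contract. A condition number above 1e12 is rejected
as a configuration error.

## Normalization and what "recovering a ratio" means

The summed-intensity normalization divides each spectrum ratio by
ν = ΣI_num/ΣI_den over qualifying spectra. Algebraically this rescales every
protein's ratio by the intensity-weighted mean ratio R̄ of the whole
population: the pipeline estimates abundance *relative to the population
average*, which is exactly the equal-loading premise of the design. Two
consequences matter for testing:

- Ratios are invariant under any global scaling of a channel (the factor is
  absorbed by ν) — this is a tested invariant.
- A planted fold change is recovered on the normalized scale, i.e. as
  ratio/R̄, not as the raw design value. The synthetic generator therefore
  records both: `GroundTruth.ratios` (design values) and
  `GroundTruth.expected_ratios` (design values divided by the normalization
  factor the pipeline will compute, using identical arithmetic). Exactness
  tests compare against the latter; DE truth labels use the former, with
  planted effect sizes (|FC| = 1.6) chosen far enough from the call
  thresholds (1.2/0.83) that the ≈2% population-average shift of a typical
  20%-DE design cannot flip a label.

## Sentinel and degenerate spectra

A spectrum with a positive numerator and a zero denominator ("Divide 0") is
kept, with its ratio replaced by the fixed placeholder 10. The placeholder is
final: it is not divided by ν. Sentinel spectra count toward a protein's
spectrum tally (if they pass the intensity filter) and enter the median, but
are excluded from the location test — they are imputations, not measurements.
A spectrum with zero numerator carries no finite positive ratio and has no
published placeholder; it is excluded from ratio emission entirely, as is a
0/0 spectrum. This preserves the pipeline invariant that every emitted ratio
is finite and strictly positive.

The per-spectrum intensity filter (numerator + denominator, after correction,
strictly > 20,000) is applied at the median stage only; normalization sums run
over all qualifying spectra.

## The location test

The test behind the p ≤ 0.01 gate is not fixed by the original description;
the default here is a two-sided one-sample Wilcoxon signed-rank test of the
log₂ normalized ratios against 0, chosen for robustness against the heavy
tails of ratio noise. Its null is computed exactly where feasible:

- n ≤ 14: full enumeration of all 2ⁿ sign assignments with average ranks,
  which stays exact under tied |log₂ ratios| (ubiquitous in idealized data);
- 15 ≤ n ≤ 25, no ties/zeros: the classical exact signed-rank distribution;
- otherwise: normal approximation with continuity correction.

Exact zeros are dropped (classical treatment); an all-zero sample is perfectly
consistent with no change and returns p = 1 by convention. A one-sample
t-test is selectable (`quant.test: ttest`) for users who prefer it.

## Synthetic data generator

The generator emulates a 4-plex experiment over 0/50/100/200 mM exogenous
ethanol. Per spectrum: a log-normal base intensity for channel 114
(median 2×10⁵, SD 1.0 log₂ units — a typical reporter-ion dynamic range),
stress-channel intensities = base × planted ratio × 2^N(0, σ²) with
σ = 0.25 log₂ units of multiplicative noise, then defects applied to the true
signal (a randomly chosen zero channel with probability 0.02; a rescaling to
a 10,000-count total with probability 0.05, putting every channel pair under
the 20,000 filter), and finally channel leakage through the purity matrix —
leakage happens in the instrument, after the sample state is fixed.
Qualification defects are independent: 5% low-confidence identifications
(log e > −2), 3% unlabeled peptides, 5% off-database peptides. The default
design is 500 proteins × 20 spectra with 20% of proteins planted at
|FC| = 1.6 (half up, half down, same sign across the three stress channels)
and no leakage; these are the benchmark conditions under which the pipeline's
recall and false-positive rate are measured (mean recall ≥ 0.9 and FPR ≤ 0.05
over ten seeds, verified in the acceptance tests — in practice recall is ≈1.0
and FPR ≈ 10⁻³ at these settings).

What the generator does *not* emulate: peptide detectability and shared
peptides (each spectrum carries one accession), chromatographic effects,
missed cleavages, co-isolation interference beyond the purity matrix,
condition-dependent fold-change profiles, or correlated noise between
channels of a spectrum. Passing the recovery benchmark therefore shows the
pipeline's algebra and thresholds behave as specified under the stated noise
model; it does not certify performance on real spectra, where interference
and protein-inference ambiguity dominate.

## Profiles, clustering, enrichment

The profile matrix holds log₂ median ratios per condition with the control
column identically 0; a protein not quantified in some comparison is imputed
as 0 (no change) and flagged. Rows are standardized with the sample SD
(n−1 denominator); constant rows map to all-zero by convention. Clustering is
agglomerative with Euclidean distance and average linkage, cut to exactly k
clusters (default 6); distance, linkage and k are exposed because the choice
of 6 "major clusters" is descriptive, not derived. Cluster ids are relabeled
by first appearance in row order, making assignments deterministic and
invariant to library-internal numbering.

Enrichment uses the hypergeometric upper tail with the background defaulting
to all accurately quantified proteins — the population the DE set was drawn
from. Raw p ≤ 0.05 defines "significant", matching the published convention;
Benjamini–Hochberg adjusted values are always reported alongside so the
rigorous criterion is visible in the same row. Pathways with no background
member are skipped.

## Fermentation stoichiometry

Endogenous ethanol = measured total − exogenous addition, converting mM to
mg L⁻¹ with M(EtOH) = 46.07 g mol⁻¹; acetate uses M(HAc) = 60.05 g mol⁻¹.
Slightly negative differences (within 5% of the exogenous mass, a
measurement-error allowance) clamp to zero; grossly negative differences
raise. The reference yield table encodes the published end-point
measurements of the ethanol-stress series; the control endogenous yield is
recovered from the 100 mM yield (4030.4 mg L⁻¹) and its reported relative
increase (30.1%), because the control value itself was reported only as a
relative change. Acetate at 50/100 mM was reported graphically only and is
stored as NA, so molar ratios are derived only where both inputs were printed
numerically (0 and 200 mM). Reproduction of the printed ratios is asserted at
1% relative tolerance — the inputs are printed to one decimal, the ratios to
two.

## Numerical conventions

- Medians over an even number of spectra take the midpoint of the two central
  values.
- All thresholds are strict or inclusive exactly as documented: log e ≤ −2.0
  inclusive, intensity sum > 20,000 strict, n ≥ 3 and p ≤ 0.01 inclusive,
  fold-change boundaries inclusive.
- TSV float fields are written with `repr`, so write→read round-trips are
  exact; missing optional values are `NA`.
- All randomness flows from a single `numpy.random.default_rng(seed)` per
  generated dataset; identical config + seed ⇒ byte-identical tables.

## Problem sizes

The test suite exercises the exactness limit at 50 proteins × 10 spectra
(noise-free) and the stochastic recovery benchmark at the full default design
(500 × 20, ten seeds); hypergeometric p-values are verified against exhaustive
subset enumeration for populations up to N = 12. These sizes were chosen so
the entire suite documents the method's behaviour in minutes on a laptop
while still covering every code path at realistic scale.
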