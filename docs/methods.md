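# Methods

`cidval` implements a validation scheme for ¹³C metabolite tracer studies
run on high-resolution (orbitrap-class) mass spectrometers. The scheme has
three legs: (1) benchmark the instrument's spectral accuracy on a standard
with a rich non-carbon isotope pattern (selenomethionine), (2) validate
metabolite- and isotopologue-specific accuracy against a labeled reference
material whose carbon isotopologue distributions (CIDs) are exactly
predictable, and (3) screen procedural blanks, an unlabeled sample, and the
target list itself for contamination and isobaric interference.

## The binomial CID model

A metabolite biosynthesized on a substrate whose carbon pool contains a
fraction *p* of ¹³C incorporates each of its *n* carbons independently, so
the fraction of molecules carrying *k* heavy carbons is

    M_k = C(n, k) p^k (1 − p)^(n−k),   k = 0 … n.

The package's reference conditions are *p* = 0.49755 with standard
uncertainty σ_p = 0.00009 (an NMR determination of a ¹²C/¹³C methanol feed
used to grow yeast biomass). Binomial coefficients are computed in exact
integer arithmetic; *n* = 21 (NAD⁺) is routine.

**Uncertainty propagation.** σ_p is propagated to each M_k by Monte Carlo:
1000 draws of *p\** ~ Normal(*p*, σ_p), truncated to [0, 1] by rejection
(the truncation is unreachable at realistic σ_p but keeps the contract
total). The per-channel uncertainty is the sample standard deviation (n−1)
of M_k(*p\**) across draws. The Normal shape is a modeling choice — the
quoted "± 0.009 %" is read as one standard deviation on the percent scale —
and it is cross-checked in the tests against the delta-method value
|dM_k/dp|·σ_p. Reported central values are the analytic binomial, not the
MC mean, which differs from it only by simulation noise. All draws are
seeded and the seed is recorded in report provenance.

## Isotope patterns at finite resolving power

Fine structure is built by iterative convolution of per-element multinomial
expansions (binary exponentiation per element), never by Cartesian
enumeration; an exhaustive enumeration oracle exists in the test suite for
formulas of ≤ 8 atoms. Pruning shares one probability budget across all
convolution steps so the retained pattern always carries at least
1 − `prune_threshold` of total probability (default 10⁻¹⁰, which keeps a
21-carbon nucleotide pattern exact to well past the third decimal in
percent).

**Instrument model.** Resolving power R is quoted at a reference m/z
(200 by convention) and scales as R(m) = R_ref·√(m_ref/m) for orbitrap-type
analyzers; a flat law is available. FWHM(m) = m/R(m).

**Centroiding.** Left-to-right single-linkage clustering on the sorted mass
axis: the next species joins the current cluster when its gap to the
cluster's last member is below the FWHM at the abundance-weighted mean mass
of the two. This rule is deterministic, order-independent, conserves total
abundance, and is monotone: lowering R never increases the centroid count.

**Channel grouping.** Channels are anchored at theoretical masses — M0 plus
k·(¹³C−¹²C) for a carbon tracer, or the all-light molecule shifted by each
isotope offset for a marker element such as selenium. A centroid is
assigned to its nearest anchor only if the instrument cannot resolve it
from that anchor; resolved centroids fall outside every channel and are
excluded before the retained groups are renormalized to 100 %. This is the
"main isotopologues, sum set to 100 %" reporting convention, and it is what
makes the selenomethionine pattern resolution-dependent: at R = 30 000 the
(⁷⁶Se + ¹³C) species (≈2.7 mDa from the ⁷⁷Se monoisotopic species at
m/z ≈ 197) merges into the ⁷⁷Se channel; at 120 000 it is resolved away.

The exact theoretical digits of a marker pattern depend on which isotopic
abundance compilation is used. The package ships one pinned table
(`data/isotopes.tsv`, normalized NIST abundances, version-tagged) and
stamps the tag into every report rather than claiming digit-exact agreement
with values computed from other compilations.

## Natural-abundance correction

The correction matrix entry (j, k) is the probability that a molecule
carrying k tracer ¹³C atoms is *measured* in channel j. Per column k, the k
labeled carbons are fixed as ¹³C, the remaining carbons are either pure ¹²C
(default) or natural (see below), the non-tracer elements keep their
natural distributions, and the resulting fine species are binned to the
nearest channel anchor using the same FWHM criterion as centroiding, so
correction and theoretical patterns are mutually consistent.

Two refinements matter at high resolving power:

* **Resolved isotopes are excluded, not lost.** A heavy isotope whose mass
  offset is resolved from every multiple of the ¹³C−¹²C spacing (e.g. ²H at
  R = 120 000) produces its own peak outside all channels. Because the
  non-tracer composition is identical in every column, that loss scales all
  channels equally and cancels on normalization; the element's abundances
  are therefore renormalized with the resolved isotope removed. This makes
  the matrix exactly the identity for a C/H-only formula at high R with
  carbon correction off. Residual multi-substitution species that are still
  resolved from every anchor are dropped at binning, which is why column
  sums may be slightly below 1.
* **Carbon correction is off by default.** For a reference material grown
  on a defined ¹²C/¹³C substrate the binomial CID *is* the quantity of
  interest — every carbon already carries enrichment *p* — so correcting
  for natural ¹³C would corrupt it. Carbon is treated as 100 % ¹²C unless
  `carbon_correction=True`, which is the right mode for ordinary tracer
  samples where unlabeled positions carry natural ¹³C.

Unmixing solves matrix·x = areas by non-negative least squares
(`scipy.optimize.nnls`), never by inversion, so corrected CIDs are
non-negative on noisy data; the relative residual norm is reported and a
warning is raised above 0.5. A tracer-purity option (impure ¹³C source) is
implemented but off by default: the reference material is defined by *p*
alone.

## Validation metrics

Measured CIDs: per replicate, channel area divided by the replicate's total
area, × 100; all-zero replicates are excluded with a warning. Trueness bias
is measured minus predicted fraction per channel (the biases of one
metabolite sum to zero by construction); precision is the sample standard
deviation (n−1) across technical replicates — with the conventional N = 4
technical replicates that is the natural reading of "standard deviation of
replicates".

**Contamination flag.** An unlabeled contaminant mixes its
natural-abundance envelope (nearly all M0) into the measurement, inflating
M0 and deflating every heavier channel proportionally. The flag fires when
the M0 bias exceeds both 3× the predicted M0 error and a 1-point absolute
floor while the heavier channels are on balance biased downward. The floor
separates the sub-1 % biases typical of clean measurements from the
~20-point excursions of genuinely contaminated organic acids (succinate
being the classic case).

## Screening

**Interference.** Every unordered pair of same-polarity targets eluting
within the RT window (default ± 0.5 min, inclusive) is compared channel
against channel; a pair of channel m/z values within the ppm tolerance
(default 5 ppm, inclusive) is one hit. Channel m/z values are built from
the formula, the polarity's default adduct ([M+H]⁺ / [M−H]⁻ unless
specified), and k·(¹³C−¹²C)/|z|. Each overlap is reported once, in the
canonical direction where the *affected* target is the one with the higher
channel index — its enriched isotopologue is the signal being sat upon —
with the ppm difference computed relative to the affected channel's m/z.
Shrinking either tolerance can only remove hits.

**Blanks.** Blank-to-sample area ratio in percent, banded as negligible
(< 0.1 %), minor (0.1–5 %) and major (> 5 %); bands are configurable. A
compound found only in the blank is classified `blank-only`.

## Synthetic data generator

The generator emulates the measured columns of a labeled reference-material
campaign so the whole pipeline is testable without an instrument:

    area(rep, k) = I · [(1−f)·CID_pred_k + f·natural_k]/100 · ε,

with I the per-metabolite total intensity (default 10⁸ area units), f the
unlabeled-contaminant fraction (default 0), natural_k the natural channel
envelope at the configured resolving power, and ε lognormal with mean 1 and
CV 1 % by default — peak areas are positive and heteroscedastic, and ~1 %
relative spread matches well-behaved replicate precision for abundant
compounds. Defaults of 4 replicates and R = 120 000 at m/z 200 mirror the
standard acquisition conditions. Areas below a hard detection limit are
zeroed (channel missing), reproducing the missing-M0/M6 failure mode of
low-abundance isotopologues. Blank injections reuse the same noise model on
the natural envelope scaled by a per-target blank fraction.

What the generator does **not** emulate: chromatographic peak shape,
retention-time drift, detector saturation or dynamic-range compression,
spectral-accuracy bias of the analyzer (the documented M0 overestimation of
high-mass natural-abundance nucleotides at high resolution is deliberately
not modeled — its mechanism is not established), or isomer co-elution.
Passing the end-to-end tests on synthetic data therefore demonstrates the
correctness of the arithmetic and the statistical machinery, not the
spectral accuracy of any particular instrument.

## Numerical choices and conventions

* Channel indexing is 0-based (M0 = unlabeled). Percent in user-facing
  tables, fractions internally; CSV reports round to 3 decimals, JSON keeps
  full precision.
* Monoisotopic m/z uses the lightest isotope per element; the electron mass
  is neglected by default (a switch includes it; the effect is < 3 ppm
  below m/z 200, far inside a 5-ppm screen).
* Printed three-decimal predicted-CID values in the tables this package is
  checked against appear truncated rather than rounded in some cells; test
  comparisons use a 0.002-point tolerance.
* Species closer than 1 nDa are treated as one isotopologue during
  convolution (floating-point dedup, far below any resolvable difference).
* Degenerate inputs: empty formulas, zero-charge adducts, all-zero area
  vectors and single-replicate precision requests raise; all-zero
  replicates are dropped with a warning.

## Problem sizes

Test-suite and acceptance computations use the study-scale inputs directly:
metabolites up to 21 carbons, fine patterns of a few hundred retained
species, 1000 Monte Carlo draws, 4–8 replicates, and panels of a handful of
targets. These sizes are the package's intended operating regime, not
reductions of it.

## Known limitations

* Measured isotopologue tables, the exact theoretical digits of the
  selenomethionine benchmark, the reported M0 overestimation percentages of
  natural-abundance NAD⁺/ATP, and interference contributions in real cell
  extracts all require the instrument or the extracts; the package
  establishes correctness through oracle-based and synthetic-data property
  tests instead, and its reports are only as good as the peak areas fed in.
* Single-tracer (carbon) correction only; no ¹⁵N/²H dual-tracer support.
  Non-carbon elements enter only as natural-abundance contaminants of the
  channels.
* No positional isotopomer (MS²) analysis; isotopologue totals only.
* No raw-spectrum ingestion: the pipeline starts from integrated peak
  areas, and peak integration quality is outside its control.
* The formula grammar is flat (no parentheses, hydrates, or charge-carrier
  syntax beyond the adduct table).
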