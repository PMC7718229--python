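# Methods

## Signal model and the matrix-pencil decomposition

Every analysis in this package assumes a uniformly sampled series
`y_n = y(t_0 + nΔ)`, `n = 0..N−1`, modelled as a DC level plus up to M
exponentially damped sinusoids:

    y_n = c0 + Σ_i A_i e^{b_i t_n} cos(2π t_n / T_i + θ_i) + ε_n.

Each damped cosine is a conjugate pair of complex exponentials
`r z^n + r̄ z̄^n` with pole `z = e^{(b + iω)Δ}` and residue `r`. The
decomposition proceeds in the standard matrix-pencil (Hua–Sarkar) form:

1. Build the Hankel matrix `H[i, j] = y_{i+j}` of shape
   `(N−P) × (P+1)`, with pencil parameter `P` (default `⌊N/3⌋`, the
   conventional noise-robust choice in the `N/3..N/2` range).
2. Truncate to the signal subspace by SVD. The model order is
   `K = 2M + 1` (M conjugate pairs plus DC); when trailing singular
   values fall below `rank_tolerance · s_1` (default 1e-10) the rank is
   reduced and *fewer* components are returned — degenerate signals
   never produce fabricated components.
3. Form the sub-pencil from the truncated right singular vectors with
   first/last rows dropped; its eigenvalues are the poles.
4. Solve the Vandermonde system `Z r = y` by least squares for the
   residues.
5. Merge conjugate pairs into components with `T = 2πΔ/|arg z|`,
   `A = 2|r|`, `b = ln|z|/Δ`, and phase reported as the peak time of the
   undamped cosine after `t_0`, folded to `[0, T)`. The decay-induced
   peak shift is deliberately *not* folded into the phase; it is
   recoverable from `b`.

Real poles are not oscillations. Their content — a constant for
`z = 1`, a drifting exponential otherwise — is summarised into the DC
level as its time-mean over the grid; whatever time variation that
summary misses appears in the residual, which is always the literal RMS
difference between the input and the reconstruction.

For noiseless sums of up to M well-separated damped cosines the recovery
is exact to numerical precision (the test suite verifies ≤1e-6 relative
error over 1000 random draws with periods in 6–30 h, amplitudes 0.1–10,
|b| ≤ 0.05/h, and cross-checks the poles against a classical Prony
solve to 1e-8). "Well-separated" means component frequencies differing
by more than about 1/150 h⁻¹; coincident poles are a genuinely
unidentifiable corner that no spectral method resolves from 24 points.

The default M = 3 reflects how many superimposed oscillations a 48-h,
2-h-resolution liver time course supports: circadian, 12-h, and one
shorter/weaker term.

## Which components count as oscillations

The data give no principled amplitude or damping cutoff for calling a
gene "cycling", so the filter is configuration with conservative
defaults: period between the Nyquist limit (2Δ) and the grid span,
|b| ≤ 0.2 /h, and relative amplitude ≥ 0.1 of the DC level.

Amplitude is judged, by default, at mid-series: `A_eff = A e^{b·span/2}`.
The raw coefficient `A` is the amplitude at `t_0`, which systematically
overstates components that decay quickly — with the permissive default
damping bound (|b| = 0.2/h decays by e^{-9.2} over 46 h), noise fitted
by strongly damped poles can carry a large `t_0` coefficient while
contributing almost nothing over the record. On synthetic cohorts at the
package's default conditions the raw measure lets ~7.5% of flat genes
acquire a spurious passing 12-h-band component; the mid-series measure
reduces that to ~0.2% without losing genuine (weakly damped) rhythms.
`amplitude_measure="raw"` restores the raw convention.

Classification then reads the dominant (largest effective amplitude)
passing component: period in [10, 14] h → `twelve_h`, [20, 28] h →
`twentyfour_h`, any other passing period → `other`, no passing
component → `arrhythmic`.

## The umbrella rhythm test

An independent check on pencil calls that assumes nothing about
waveform: under a rhythm of period `mΔ`, observations folded to the m
phase groups rise to some peak position and fall after it. For each
peak position `p ∈ {1..m−1}` the Mack–Wolfe statistic sums Mann–Whitney
counts over rising ordered group pairs up to p and falling pairs after
p, with mid-ranks for ties. Folding pools cycles and replicates as
independent observations — appropriate for designs like 2 replicates ×
4 cycles where consecutive cycles come from different animals.

Per position, the p-value uses the normal approximation with the exact
null mean and variance of the statistic (the continuous-case variance
scaled by the standard rank tie-correction factor). Across positions,
the default correction is the **single-step min-p adjustment under the
exact joint null covariance** of the peak statistics: the positions are
strongly positively correlated (adjacent-position correlation ≈ 0.6),
so a plain Bonferroni multiplier measurably deflates the null rejection
rate (≈0.0415 instead of 0.05 at α = 0.05 for the 24×2 design). The
joint covariance follows in closed form from U-statistic identities
(P(x<y, x<z) = 1/3, P(x<y, y<z) = 1/6) and is validated against both the
Mack–Wolfe variance formula and simulation; the joint Gaussian tail is
evaluated through a fixed-stream 200 000-draw Cholesky lookup, cached
per folding design, which is bit-deterministic and adds negligible
error relative to the normal approximation itself.
`correction="bonferroni"` is available for the conventional form.

For pooled samples of at most 8 observations an exact mode enumerates
all permutations (vectorised); it reports the Bonferroni form so that
its output matches hand enumeration. `method="auto"` (the default)
switches to exact in that regime. Degenerate inputs are handled
explicitly: all-tied data carry no ordering evidence and return p = 1.

Gene-level multiplicity uses Benjamini–Hochberg; the conventional
screening thresholds p < 0.005 (strict) and p < 0.05 are carried as
defaults in the run configuration.

## Preprocessing

Genes with a zero in any replicate or timepoint are removed before
anything else; this both mirrors standard practice for rhythm detection
(a dropout breaks the damped-cosine model) and keeps all geometric means
finite. Size factors are median-of-ratios: per sample, the median over
all-positive genes of the ratio to the gene's geometric mean. Factors
are rescaled to geometric mean 1 — relative normalisation is unchanged
and the estimator becomes exactly idempotent (the factors of a
normalised matrix are all 1), a property the raw convention lacks (it
returns the constant geomean of the original factors). Replicates are
then averaged per timepoint and the mean series is decomposed.
Filtering-before-normalisation order is logged; only size-factor
scaling feeds the oscillation analysis, so dispersion modelling is out
of scope.

## Differential rhythmicity

For genes classified `twelve_h` in the control genotype, the knockout
decomposition is searched for any passing component with period in
[10, 14] h. Absence → `abolished`; presence → `sustained`, with the
phase difference (knockout − control, circular on the control period,
in (−T/2, T/2]) and the knockout/control amplitude ratio taken from the
largest in-band knockout component. Band *presence* rather than strict
dominance is the default criterion, because a gene whose 12-h component
merely slips below its 24-h component still has a 12-h rhythm — genes
with disrupted amplitude or phase belong with "sustained", not
"abolished". `require_dominant=True` gives the stricter reading. The
control period anchors the circular modulus because the control defines
the reference rhythm.

## Calorimetry (RER)

RER = VCO2/VO2 per timepoint. Traces are linearly interpolated onto a
uniform grid (default Δ = 0.5 h over 96 h, matching sub-hourly metabolic
cage cadence over several days), averaged across the animals of a
group, and pencil-decomposed; the group mean is decomposed rather than
per-animal decompositions averaged, because band parameters are not
linear in the data (a per-animal mode can be built from the same
primitives when dispersion is wanted). Each band (12-h, 24-h) is
summarised by its largest passing component. The oscillation filter
defaults to a 0.5% relative-amplitude floor here: RER is confined to a
narrow physiological range (~0.7 on fat to ~1.0 on carbohydrate
oxidation), so meaningful oscillations are a few percent of the mean
and the 10% expression default would discard them. "Relative" RER
divides a trace by its own full-record mean (dimensionless, mean 1),
the convention that preserves oscillation shape.

## Synthetic data: what it emulates and what it does not

Cohorts emulate the canonical design: 24 timepoints at 2-h spacing over
48 h (end-exclusive, so folding keeps cycles balanced), 2 replicates per
timepoint sharing the truth and differing only in noise. Baselines are
log-normal (median 100, log-sd 0.5). Rhythmic genes carry a dominant
component (period uniform within its class band, phase uniform,
relative amplitude 0.5 of baseline by default) plus a weaker component
in the sibling band at 0.3 of the dominant amplitude, as real rhythmic
genes superimpose circadian and ultradian content. Noise is
multiplicative Gaussian, `max(0, clean·(1+ε))` with ε ~ N(0, cv²) and
cv = 0.1 by default — the analysis operates on normalised continuous
abundances, and the pencil assumes additive-ish perturbation of a
smooth signal; the measured-count distribution of any particular
normalised dataset is unknowable from first principles, so the noise
model is exposed in configuration and a Poisson count mode is provided.
Paired cohorts delete all 10–14 h-band components from a seeded
fraction of 12-h genes (default 0.8855, the regime where nearly all
12-h rhythms collapse) in the knockout.

Passing tests on these cohorts therefore demonstrates correct recovery
under multiplicative noise with balanced replication — not robustness
to library-size confounding, batch effects, read-level sampling,
missing timepoints, or non-stationary baselines, none of which the
generator produces.

RER traces are baseline + components + i.i.d. Gaussian noise
(sd 0.005–0.01 in RER units) per animal; generator defaults (baseline
0.85, 24-h amplitude 0.05 peaking at hour 18, 12-h amplitude 0.02
peaking at hour 2, 4 animals) emulate ad-libitum-fed mice whose RER
swings between fat- and carbohydrate-burning across the dark/light
cycle.

## Problem sizes and numerical choices

Default analysis sizes — 1000-signal exactness sweeps, 2000-gene
classification cohorts, 5000-gene null calibration, 800-gene paired
cohorts, 4-animal calorimetry groups — are chosen so a full validation
pass completes in well under a minute on one core while leaving
binomial sampling error small against every margin tested.

Ties in rank tests use mid-ranks with a multiplicative variance
correction; an all-tied series returns p = 1. Even-count medians are
the mean of the central pair. Conjugate pole pairing is greedy from the
largest residue with a 1e-6 relative matching tolerance, and pair
members are averaged for symmetry; tie-breaks in dominance go to the
shorter period. Seeds derive from one master seed through
`SeedSequence([seed, stage])`, so stages re-run in isolation reproduce
the full pipeline's draws.

## Known limitations

- The pencil method requires uniform sampling; missing timepoints must
  be imputed or the series re-gridded upstream.
- Nearly coincident component frequencies are unidentifiable on short
  grids; the decomposition returns a merged component and a larger
  residual rather than failing.
- The joint min-p correction assumes the normal approximation of the
  peak statistics, which is excellent at ≥4 observations per phase
  group but untested below that (use exact mode there).
- The umbrella test's independent folding treats within-animal cycles
  as independent; longitudinal weighting for designs with few animals
  and many cycles is not implemented.
- Band summaries report the single largest in-band component; multiple
  distinct components inside one band (possible at high M) are not
  aggregated.
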