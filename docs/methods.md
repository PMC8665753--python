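# Methods

This note documents the models, conventions and numerical choices behind
`nativems`, and what its synthetic tests do and do not establish about real
data.

## The electrospray relation and its conventions

All mass↔m/z conversions use `m/z = (M + z·m_a)/z` with adduct mass
`m_a = 1.007276` Da (proton, positive ion mode) by default. The adduct mass
is a parameter on every operation for negative mode or alternative charge
carriers (e.g. Na⁺, 22.989218 Da). The electron mass is not subtracted; at
the mass accuracy relevant for intact complexes (≫ 0.01 Da) this is
negligible. All masses are average (not monoisotopic) masses, the
convention for native MS of large complexes.

## MacSED charge-series assignment

**Model.** k peaks picked from one species are assumed to carry consecutive
positive charges with no missing states. For every admissible base charge
z₀ ∈ {1, …, z_max − k + 1} the peak m/z values are deconvolved to neutral
masses `M_i = mz_i·(z₀+i) − (z₀+i)·m_a`; the z₀ with minimal sample
variance of {M_i} is selected. Mass = mean, uncertainty = sample (k−1)
standard deviation of the winning mass vector.

**Numerical choices.**
- Variance is computed on the mass vector in Da² (absolute, not relative),
  with the k−1 denominator. The argmin is invariant to the denominator;
  the reported uncertainty is not, and the sample convention was chosen as
  the standard small-k estimator.
- Ties in the variance scan break to the smallest z₀ — deterministic, and
  favouring the lower-charge (wider-spacing) interpretation. Ties are
  essentially measure-zero for real inputs.
- `z_max` defaults to 500, covering MDa-scale assemblies. The variance
  grows without bound at implausibly high z₀, so the cap bounds runtime,
  not correctness.
- The scan is fully vectorized (one (n_candidates × k) matrix); an
  independent pure-Python exhaustive scan is kept in the test suite as an
  oracle and the two are asserted equal on every tested input.
- Masses are unweighted: peak intensity does not enter the statistic.
  An intensity-weighted variant would down-weight envelope-edge peaks but
  introduces a second convention; unweighted matches the simple
  mean/standard-deviation reporting.

**Peak picking.** A peak is the apex *sample* (grid point of maximum
intensity, ties → lowest m/z) inside a user-given closed m/z window —
grid-exact and reproducible. An intensity-weighted centroid would
interpolate below grid resolution but is sensitive to window placement and
baseline; it is deliberately not used. Windows containing only zero
intensity yield no peak; windows containing no samples at all are an error.

**Behaviour with few peaks.** With k = 2 the variance has many
near-degenerate minima and assignment is correspondingly fragile; the
implementation still returns the global argmin (verified against the
exhaustive oracle), but ≥ 3 peaks are recommended in practice.

## Preprocessing

All operations preserve the m/z grid and length, and subtraction modes
clamp at zero (no negative intensities).

- **Gaussian smoothing** convolves intensities with a unit-area Gaussian of
  standard deviation `sigma`, truncated at 4σ, with nearest-value edge
  extension, applied `repeats` times. Units are **data points**, not
  Thomson, because exported CSVs need not be uniformly gridded. The 4σ
  truncation discards erfc(4/√2) ≈ 6·10⁻⁵ of the kernel mass; repeated
  smoothing therefore matches a single √n-wider pass only to ≈ 10⁻⁵ of
  peak height, which is the accuracy limit of the semigroup property under
  this contract.
- **Constant subtraction**: `max(I − value, 0)`.
- **Linear subtraction**: subtracts the straight line through the first and
  last (m/z, intensity) points; the endpoints are pinned to exactly zero.
- **Curved subtraction**: baseline = Gaussian smooth (σ = window/2, same
  kernel contract) of the rolling minimum over a centred window of `window`
  data points. This is a concrete, testable realization of the
  rolling-minimum family of curved baselines used by standard deconvolution
  software; `window` is the single tuning parameter and should exceed the
  widest genuine peak (features ≪ window survive within ~1 % of apex,
  structure ≫ window is removed).
- **Minimum intensity** zeroes points strictly below the threshold
  (boundary points are kept) rather than deleting them, so array alignment
  and session replay are preserved.

Every operation has a named `ProcessingStep` record; replaying a recorded
log on the same raw spectrum is bitwise deterministic (pure floating-point
pipeline, no randomness, no environment dependence).

## Stoichiometry matching

Bounded integer enumeration: all count vectors `c` with
`|Σ cᵢ·massᵢ − target| ≤ tolerance`, `0 ≤ cᵢ ≤ max_copiesᵢ`, `Σ cᵢ ≥ 1`.
Explicit per-subunit copy bounds are required because unbounded subset-sum
over real masses explodes; a guard refuses search spaces above 10⁸ nodes.
Depth-first enumeration with two prunes (partial sum above target +
tolerance; partial sum plus the maximal remaining mass below target −
tolerance) provably returns the same set as full enumeration, which the
tests verify against an itertools-product oracle on random instances.
Solutions are sorted by |deviation|, ties by lexicographic counts in table
order. Tolerance is absolute (Da); `ppm_to_da` converts a relative
tolerance. When matching an assigned series, the effective tolerance is
`max(tolerance, 3·uncertainty)` so a poorly determined mass is not
over-matched.

## Session format

A session JSON (format_version 1.0, UTF-8) holds `raw_spectrum`
(m/z + intensity arrays as loaded, after normalization), `processing`
(ordered step log), `series` (assigned charge series with their peaks,
charges, mass, uncertainty and adduct mass), and `annotations`
(free-text map). Unknown top-level keys are preserved on re-save. Floats
are serialized at full `repr` precision, so arrays round-trip bit-equal.
A major-version mismatch on load is an error. The schema is this package's
own versioned definition; byte-level compatibility with other tools'
session files is not claimed.

CSV input: two columns (m/z, intensity), comma-delimited, decimal point
only, one optional header row (skipped iff a cell fails numeric parsing).
Rows are sorted; duplicate m/z bins are collapsed by summing (centroided
exports can repeat bins). Intensities are normalized once on load to
percent of base peak (max = 100) and not re-normalized after background
subtraction.

## The simulator

`simulate_spectrum` emulates the first-order structure of a native ESI
spectrum: per species a Gaussian charge envelope
`w(z) = exp(−(z − charge_center)²/(2·charge_spread²))` (truncated at
w > 10⁻⁴), Gaussian peaks of the stated FWHM at the exact electrospray
positions, heights `abundance · w(z)`, on a uniform m/z grid. The clean
signal is scaled to base peak = 100 **before** baseline and noise are
added, so `noise_sigma` and baseline parameters are in percent-of-base-peak
units (`noise_sigma = 0.5` ⇒ 0.5 % of base peak). The "curved" baseline is
a broad Gaussian hump centred mid-range with width = range/4. Noise is
`numpy.random.default_rng(seed)` Gaussian, so identical seeds give bitwise
identical spectra. The exact truth (per-species (charge, m/z, height)
table, baseline parameters, noise level, seed) is returned alongside.

Not modelled: physical ESI charging statistics, isotope structure, adduct
heterogeneity, detector saturation, non-uniform grids, chemical baselines
with sharp structure. Passing the synthetic end-to-end tests therefore
shows the *algorithms* are correct under the stated peak model; it does not
certify performance on spectra whose peak shapes or baselines depart
strongly from it.

## Study sizes used in tests and the acceptance script

Chosen as the package's standard verification conditions: 200 random
noiseless (mass, charge-set) inversions with masses 5 kDa–5 MDa and 2–40
consecutive charges within 1–500; 40 jittered series for oracle agreement;
100 random bounded stoichiometry instances (≤ 4 subunits, ≤ 8 copies)
against full enumeration; 20 simulated single-species pipelines
(20 kDa–1 MDa, 0.25 Th grid, 0.5 % noise) with success defined as relative
mass error < 10⁻³; a tetradecamer fixture (800 758 Da, charges ≈ 60–75)
with a 0.02 % recovery requirement; 200 replicates per jitter level
σ ∈ {0.01, 0.1, 0.5} Th for noise robustness of a 100 kDa, charges 40–50
series (≥ 95 % correct at 0.1 Th, median error monotone in σ); and one full
session round trip verified bitwise.

## Known limitations

- Assignment assumes gap-free consecutive charges; a missing charge state
  in the picked set silently yields a wrong (higher-variance) answer —
  inspect `ChargeSeriesResults.variance_profile` when in doubt.
- Apex-sample centroids quantize m/z to the grid; on coarse grids this is
  the dominant mass-error term (error per peak ≈ z · grid spacing / 2).
- The curved-baseline construction and the zero-vs-delete behaviour of the
  minimum-intensity filter are this package's documented interpretations
  of conventions that differ between tools.
- Stoichiometry enumeration is exact but exponential in the number of
  subunits; the 10⁸-node guard refuses pathological tables rather than
  approximating.
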