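# Methods

This note documents the measurement conventions, the statistical
procedures, the synthetic-population model and the numerical choices made
where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Contour morphometry

Objects are represented as per-section traces (closed polygons and open
polylines) with a single section thickness *t* per stack; coordinates are
in μm, the z position of section *i* is *i·t*.

* **Volume** is a Cavalieri sum: Σ over sections of (total closed-contour
  area on the section) × *t*. No interpolation between sections is
  performed — this matches the behaviour of serial-reconstruction software,
  where the operator outlines each section and volumes are section-wise
  area×thickness sums. Multiple contours on a section are summed, so
  splitting a profile into adjacent polygons leaves the volume unchanged.
* **PSD surface area** combines two trace conventions, reflecting how a
  thin sheet-like PSD intersects the cutting plane: a PSD roughly
  perpendicular to the plane is drawn as an open line along the active
  zone and contributes *length × t*; a PSD lying parallel to the plane is
  outlined as a closed contour and contributes its planar area. Both kinds
  may coexist in one stack and are summed. The package does not classify
  orientation itself — the trace kind is an input attribute.
* **Section thickness** is estimated by the cylindrical-diameters method:
  a roughly cylindrical organelle lying in the section plane with in-plane
  diameter *d* crossing *s* consecutive sections gives a per-object
  estimate *d/s*; estimates are averaged arithmetically and returned
  per-object for quality control. The adopted span convention (tested by
  forward simulation) counts the sections whose mid-plane falls within the
  organelle's extent.
* Polygon areas are computed on the raw traced vertices (no smoothing);
  self-intersecting outlines are rejected rather than silently repaired.
* The spine–dendrite cut-off is assumed already applied in the input
  traces; the package does not re-cut necks.

Multisynaptic spines are merged by summing PSD areas and PSD-core volumes
across the spine's synapses, OR-combining annotation flags and recording
the synapse count; conflicting spine volumes across the per-synapse rows
are an input error.

## Unbiased-brick census

Each synapse-bearing spine is reduced to one reference point (its PSD
centroid). The counting brick is an axis-aligned box with half-open
membership: points on the three origin-side (inclusion) faces count,
points on the three opposite (exclusion) faces do not. For point
references this implements the inclusion/exclusion-plane rule exactly —
abutting bricks tile space with every point counted once — and the
extended exclusion planes of the original rule are unnecessary. The
default brick is 10 × 10 × 1.5 μm (150 μm³); densities are per tissue
volume (μm⁻³), averaged over bricks within a sample, and the sample (not
the brick or the spine) is the statistical unit for density comparisons.

## Local Spearman correlation profiling

Given per-spine pairs (V, Y) with Y the PSD area, the PSD-core volume, or
— for the internal-control pair — (A, V_P), the data are sorted by the
index variable and both variables converted to global average ranks. For
each spine, one window of every size in {14…24} is centred on the spine's
rank; windows are shifted inward at the edges (truncated centring) so
every spine receives all sizes. Each window is resampled `n_boot = 2500`
times without replacement into subsets 4 pairs smaller than the window
(sizes 10–20); per subset, Spearman ρ is computed on within-subset ranks
and its two-sided p from the t approximation
t = ρ·√((m−2)/(1−ρ²)) with m−2 df, adequate for the default subset sizes
(≥ 10; the approximation is also used if a caller configures smaller
subsets). ρ and p are averaged arithmetically over all subsets and window
sizes; a spine is *significant* when its mean p < α (strict inequality,
α = 0.05). Design notes:

* Averaging p values (not Fisher combination, not rho-to-p conversion)
  defines the curve; the per-spine mean ρ is computed and exported
  alongside, since either may be the quantity a reader wants plotted.
* Subsets in which either variable is constant have no defined ρ and
  contribute ρ = 0, p = 1 (logged via the `n_constant` counter); a `skip`
  policy is available. With continuous data such subsets are rare.
* Ties in the index variable are broken by stable input order when
  forming windows.
* Decoupled bands are maximal contiguous runs (in index-variable order)
  of non-significant spines; band bounds are the values of the run's first
  and last spines. Decoupled counts between two populations are compared
  with a Pearson χ² (2×2, no continuity correction).
* Because significance is declared on a mean of thousands of p values,
  the procedure is conservative under the null: with the paired variable
  globally permuted, the mean p per spine concentrates near 0.5 and the
  significant fraction falls far *below* α rather than matching it. The
  null-calibration test therefore checks the one-sided bound
  (fraction ≤ α + tolerance).

The implementation uses a vectorised fast path when the window is
tie-free: subset x-ranks are implicit in sorted subset order and y-ranks
follow from a single argsort per resample; windows with ties fall back to
general average-rank computation.

## Group statistics

* Mann–Whitney U: exact null when the smaller sample has ≤ 8 observations
  and the data are tie-free; tie-corrected normal approximation otherwise.
  Both U and n₁n₂ − U are reported, since printing conventions differ.
* Unpaired t test: pooled variance, df = n₁ + n₂ − 2.
* Regression and ANCOVA are performed on log₁₀-transformed values: the
  size relations are allometric (power-law), and slope comparison on raw
  scale would be dominated by the scale of the largest spines. A raw-scale
  option remains behind a flag. Slope homogeneity: F = ΔRSS/(RSS_sep/(n₁+n₂−4))
  with df (1, n₁+n₂−4); elevation under the common slope with df
  (1, n₁+n₂−3), flagged as not meaningful when slopes differ.
* Spearman correlation: exact permutation p for tie-free n ≤ 8, t
  approximation otherwise.
* Kruskal–Wallis with tie correction; Dunn's post-hoc z on pooled ranks
  with the standard tie term, Bonferroni-adjusted over the pairwise
  comparisons (no correction is named in typical reports; Bonferroni is
  the common plotting-software default).
* Relative change under potentiation: the populations are
  cross-sectional, so no per-spine baseline exists; each potentiated
  spine's value is divided by the *median* of control spines in its SER
  stratum, and the SER / no-SER strata of relative values are compared
  with Mann–Whitney. This is a population-level contrast, not a
  longitudinal measurement.
* Normality is assessed by Shapiro–Wilk at α = 0.05; summaries always
  carry both mean ± SEM and median ± IQR so the display can follow the
  normality rule.
* Volume histograms use left-closed right-open 0.05 μm³ bins from zero;
  frequencies are percentages summing to 100.

## Synthetic populations

No public dataset accompanies this kind of 3D-EM spine census, so the
package generates populations with the statistical structure the analysis
assumes. Defaults (all log-scale parameters in log₁₀ units):

| parameter | default | rationale |
|---|---|---|
| n_control / n_cltp | 119 / 138 | group sizes of the emulated study design |
| logV_mean / logV_sd | −1.1 / 0.45 | volumes centred near 0.08 μm³, ~3 decades of range |
| slope_a / intercept_b | 1.0 / −0.15 | A ≈ 0.07 μm² at V = 0.1 μm³, near-isometric coupling |
| noise_sd_base / noise_sd_band | 0.015 / 0.25 | see below |
| band_lo / band_hi | 0.04 / 0.10 μm³ | control decoupling band |
| cltp_band_lo / cltp_band_hi | 0.048 / 0.073 μm³ | narrower band after potentiation |
| core_area_ratio / core_noise_sd | 0.03 μm / 0.01 | V_P ≈ A × 30 nm effective PSD thickness, tight coupling |
| ser_logit_b0 / ser_logit_b1 | 3.0 / 3.2 | P(SER) rises with volume; ~40% overall |
| cltp_psd_factor | 2.2 | PSD growth under cLTP, all spines |
| cltp_spine_factor_ser | 1.8 | spine growth under cLTP, SER spines only |
| perf_prob_ser / perf_prob_noser | 0.15 / 0.01 | perforation essentially confined to SER spines |

Generation order: volumes are drawn log-normal; SER is drawn from the
logistic model on the baseline volume (SER gates growth); potentiated
SER spines are scaled by `cltp_spine_factor_ser` *before* the coupling is
evaluated, so the decoupling band is defined on the measured volume; PSD
area follows the power law with residual sd inflated inside the band;
PSD-core volume follows the area; potentiated spines' A and V_P are then
scaled by `cltp_psd_factor`. Spines are assigned uniformly to 4 samples
per condition.

Decoupling is injected as residual-variance inflation inside the band —
the simplest mechanism that breaks local rank correlation while
preserving the global correlation. Consequently `noise_sd_base` is kept
small (0.015): sliding windows of 14–24 adjacent spines span only a few
hundredths of a log₁₀ decade in the bulk of the distribution, and the
outside-band windows must be clearly significant for the band to be
recoverable. The generator's job is to inject a *known* band, not to
mimic the full biological scatter of real populations; with realistic
uniform scatter (~0.15 log₁₀), mid-range windows would fail significance
everywhere and no sharp band would exist to recover.

The cLTP effect sizes were set by a power check at the study's group
sizes: with ~55 SER spines per condition and logV sd 0.45, a SER-stratum
volume shift below ~0.23 log₁₀ (factor ≲ 1.7) cannot reach significance
in the stratified comparisons, i.e. the generated conditions would not
exhibit the SER-restricted growth the analysis is designed to detect;
1.8× spine growth with 2.2× PSD growth keeps PSD growth ahead of spine
growth at magnitudes in line with reported potentiation-induced
enlargement. The narrowed cLTP band encodes the tightened coupling after
potentiation; multiplicative growth factors alone cannot produce it.

What the generator deliberately does **not** emulate: EM images or
segmentation noise, dendrite/neck geometry, temporal dynamics of
potentiation, per-sample (slice-level) heterogeneity, measurement error
on volumes, or an increase of SER frequency after cLTP. Passing tests
therefore validate the *analysis machinery* under known structure, not
the biology of any particular dataset.

Contour-stack fixtures model the spine body as a sphere sliced into
64-gon cross-sections at the section spacing, with radii normalised so
the Cavalieri sum reproduces the record's volume exactly (polygonisation
would otherwise bias it by ~0.2%); the PSD is laid down as open line
traces on the top third of the sections with summed length × t equal to
the record's PSD area. Sub-slice volumes produce a single-contour stack.
Brick scenes are homogeneous Poisson point processes.

## Problem sizes and tolerances in the test suite

Stochastic checks fix their seeds. Band recovery runs at 250 spines per
condition with band-edge tolerance of one maximum-window span (24 spines)
at the injected edge; the shrinking-band check steps the in-band residual
sd through 0.25 / 0.04 / 0.015 (strong inflation → none). Null
calibration uses 20 permutation replicates for the local profile and 1000
simulations for the type-I error of the two-group, k-group and slope
tests (nominal 5% ± 2%). The potentiation-pattern checks run five
replicate populations at the default group sizes and assert each
comparison by majority at thresholds set from its measured single-draw
power (e.g. ≥ 3/5 for the relative-change Mann–Whitney at ~85% power).
Oracle-equivalence checks compare the Cavalieri volume against 1-nm
pixel-counting voxelisation (0.5%), Mann–Whitney and Spearman p values
against exhaustive enumeration at n = 6+6 and n = 5, and brick counts
against brute-force tiling membership.

## Known limitations

* The t approximation for subset Spearman p values is used for all subset
  sizes; exact small-sample Spearman tables are not consulted below 10.
* Dunn's post-hoc on pooled ranks loses power when a stratum occupies one
  tail of the pooled distribution (rank compression); the relative-change
  comparison is the more sensitive test of stratum-restricted growth.
* Edge spines receive inward-shifted windows, so their local statistics
  share data with neighbours more strongly than interior spines'.
* `read_records` validates invariants but does not deduplicate spine ids;
  multisynaptic merging is explicit, not automatic.
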