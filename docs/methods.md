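# Methods

## Image pipeline

A degradation series is an ordered set of grey-level frames of one well,
with strictly increasing acquisition times; the first frame is the
reference t0. RGB input collapses to grey with the 0.299/0.587/0.114 luma
weights; integer images are normalized by their dtype's full range.

**Binarization.** One closed interval `[low, high]` of grey levels is
applied to *every* frame of a series — comparability over time is the
point, so the threshold is a series-level, logged input rather than a
per-frame optimization. A pixel is white iff `low ≤ g ≤ high`; both ends
inclusive so boundary grey levels behave predictably. When a circular well
mask is present, out-of-well pixels are never counted. The remaining
percentage is `100·WP_t/WP_t0`, exactly 100 at t0; values above 100
(specular highlights, condensation) are kept, not clipped, because they
flag acquisition faults.

**Threshold suggestion.** The automated default splits the t0 histogram
(well-restricted) with Otsu's criterion and then places `low` a quarter of
the class separation below the bright-class mean:
`low = μ_fg − 0.25·(μ_fg − μ_bg)`. The raw Otsu cut on an agar-dominated
t0 frame falls near the agar mode, which would later admit mycelium —
filamentous growth is brighter than agar but darker than polymer grains.
Anchoring near the grain intensity leaves that headroom while keeping
essentially all grain pixels (the 0.25 margin is ≳ 3 noise standard
deviations below the dimmest grains under the default illumination model).
The result is a suggestion; users can and should override it after
inspecting the masks, and the value used is recorded in the run outputs.

## Kinetics and t50

Each replicate curve (remaining-% vs hours) is fitted by OLS polynomial
regression. Fitting uses a centred/scaled time axis internally for
conditioning; coefficients are reported in original hours, ascending
order. For degree *d* on *n* points, `R² = 1 − SSres/SStot`,
`adj-R² = 1 − (1−R²)(n−1)/(n−d−1)`, and the overall F statistic
`[R²/d]/[(1−R²)/(n−d−1)]` is referred to the F(d, n−d−1) distribution.

**Degree selection.** Candidate degrees are `1..min(max_degree, n−2)`
(default `max_degree = 6`, leaving at least one residual degree of
freedom). The selection is:

1. *Screen*: the degree-1 regression must be significant at `alpha`
   (default 0.05). If not, the curve is declared to have no significant
   model. Screening on one pre-specified test keeps the false-model rate
   on trendless data at exactly `alpha`; accepting *any* significant
   degree among six candidates would inflate it roughly three-fold
   (≈13% measured by simulation at n = 20), and a Bonferroni filter
   overshoots in the other direction (≈2.5%). Degradation curves are
   monotone in expectation, so requiring a linear trend costs nothing in
   practice; a pathological exactly-trend-free polynomial signal would be
   missed, which we accept.
2. All candidate degrees are fitted; models with overall F-test
   `p < alpha` are kept.
3. Among the kept models the one maximizing adj-R² wins, ties (e.g.
   several perfect fits) broken toward the lowest degree. adj-R² rather
   than R² because only the adjusted form can prefer parsimony.

**t50 extraction.** The fitted polynomial is scanned on a 2000-point grid
over the *observed* time window and the first sign change of `f(t) − 50`
is refined by root bracketing to < 1e−6 h. The first crossing is used
because polynomial fits can wiggle. No extrapolation: a fit that stays
above 50% is censored `> t_max` (too slow to half-degrade inside the
observation window), one starting below it `< t_min`. Censoring is a
value, not an error. t50 is computed per replicate (not on the mean
curve) so the downstream ANOVA has within-group variance to work with.

## NMR quantification

Spectra are (ppm, intensity) arrays, either axis direction. Peaks are
integrated by the trapezoidal rule over `centre ± 0.15 ppm` windows
(defaults 4.20 and 5.20 ppm, both configurable) after subtracting the
straight line through the window's endpoint intensities. This endpoint
baseline removes flat offsets and linear drifts exactly; it also shaves a
chord off the true Lorentzian area (for a window of ±10 half-widths the
captured fraction is `2/π·arctan(10) − 20/(101π) ≈ 0.874`). Both peaks
lose the same fraction, so the ratio-based degradation degree
`100·I_m/(I_m+I_p)` is unaffected — which is why the round trip on
noiseless synthetic spectra is accurate to ≪ 0.5 percentage points across
the whole range. Negative integrals (noise) are floored at zero; a
spectrum with no signal in either window yields NaN in a kinetic series
rather than being dropped, so gaps stay visible.

## Group statistics

One-way fixed-effects ANOVA on (k−1, N−k) degrees of freedom, then Tukey
HSD on all pairs: `q = |mean_i − mean_j| / sqrt(MSW/2·(1/n_i + 1/n_j))`
referred to the studentized range distribution at (k, N−k). Equal group
sizes give the exact Tukey test; unequal sizes the Tukey-Kramer variant.
Censored t50 replicates (NaN) are excluded with a logged warning — a
censored value carries no location information for a mean comparison; a
survival-style treatment is noted as future work.

The compact letter display uses insert-and-absorb: start with one letter
containing all groups; for each rejected pair, every letter containing
both groups is split into two (each missing one member); letters whose
group set is contained in another's are absorbed. Groups are processed in
order of decreasing mean so the leading letter follows the magnitude
ranking. By construction two groups share a letter iff their pair was not
rejected, and the tests re-derive the rejections from the letters to hold
the algorithm to that contract.

## Synthetic data model

**Scene.** A circular well (radius 0.45·image size, default 512×512) on a
dark background. Non-overlapping circular grains (default 40, radii 5–9
px) are placed uniformly in the well; grey levels default to agar 0.2,
mycelium 0.55, grains 0.9, so a separating interval exists by
construction. Grain consumption is radial: each grain's pixels are
ordered centre-outwards once, and at remaining fraction *f* the closest
`round(n₀·f)` pixels survive — total area therefore tracks the prescribed
trajectory to within half a pixel per grain, and a grain whose target
drops below one pixel disappears. Mycelium is drawn as correlated random
walks (Gaussian turning angles) from random starting points; the pixel
*visit order* is fixed once per series, and the colony at time t is the
first `min(1, rate·t)·well_area` pixels of that order, so growth is
cumulative and monotone. Its intensity lies strictly between agar and
grains: a threshold excluding it exists, but a naive low threshold fails,
which is exactly the interference the threshold-suggestion logic must
survive. Illumination is a smooth multiplicative low-order polynomial
field with a configurable maximum relative deviation (default 10%), and
i.i.d. Gaussian pixel noise (default sd 0.02) is added last before
clipping to [0, 1]. All randomness flows from one explicit seed per call.

**Trajectories.** The reference consumption curve is a falling logistic
renormalized to start at exactly 1, with the midpoint solved so the curve
crosses 0.5 exactly at the requested t50; the default steepness 0.03/h
spreads the 10–90% transition over roughly 150 h, matching a two-week
incubation. The default study design is four blends at 0/5/20/40 w%
plasticizer with true t50 300/220/150/100 h — slowest for the pure
polymer, fastest at high plasticizer content — in triplicate, observed at
13 time points over 336 h. Replicate trajectories jitter the blend t50
with a lognormal factor of 5% coefficient of variation, standing in for
biological replicate variability. Curve-level simulation
(`simulate_kinetic_curves`) adds Gaussian noise of 5 percentage points to
the remaining-% values with t0 pinned at 100, for studies where rendering
images would add nothing.

**Spectra.** Two unit-integral Lorentzians (half-width at half-maximum
0.015 ppm — a ±0.15 ppm window is then 10 half-widths) at 4.20 and
5.20 ppm scaled by *d* and *1−d*, on a flat baseline (default 0.02) with
Gaussian noise (default 0.001), sampled on a 0.0005-ppm grid over
3.0–6.5 ppm.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: grain shapes are circular rather than
irregular powder particles; mycelium has no branching morphology, radial
front or optical translucency; illumination drift over time, focus
changes, condensation and specular reflections are absent; NMR spectra
have no multiplet structure, phasing errors, solvent peaks or shoulder
overlap. Results on real imagery will degrade in proportion to how far
these assumptions are violated, the shared-threshold assumption being the
most sensitive.

## Numerical and design choices

* Polynomial fits use an orthogonal-basis domain mapping internally;
  reported coefficients are converted back and can lose precision for
  high degrees, so evaluation (including root finding) uses the fitted
  object directly.
* A perfect fit (SSres = 0) reports R² = adj-R² = 1 and p = 0 rather than
  an infinite F.
* Degenerate inputs are rejected with named errors: flat curves ("no
  variance"), constant reference frames ("degenerate histogram"), empty
  reference masks ("empty reference frame"), zero spectra ("no signal").
* Problem sizes in the test suite and acceptance script are chosen to
  keep statistical power high while the whole suite stays fast: 2000
  repetitions for the null-calibration check, 200 (tests) / 100 (script)
  repetitions for t50 recovery, 10⁴ permutations for the max-t oracle,
  and 20 fixtures for Tukey agreement.
* Sample processing is sequential and order-independent: per-sample seeds
  are spawned from the master seed up front, and one failing sample is
  logged and skipped rather than aborting a batch.

## Known limitations

* t50 depends on the polynomial family fitting the sigmoidal shape well
  inside the window; mechanistic kinetic models (first-order decay,
  Gompertz) are deliberately out of scope.
* Censored t50 values are excluded from the comparison instead of being
  modelled; with many censored replicates the ANOVA loses balance and
  power.
* The threshold suggestion assumes the t0 frame is mycelium-free and
  bimodal; wells already colonized at t0 need a manual range.
* JCAMP-DX and vendor NMR formats are not read; spectra arrive as
  two-column CSV.
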