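# Methods

This note records the models behind each module, the conventions chosen
where several are in circulation, and what the synthetic study design does
and does not establish about real registry data.

## Synthetic study design

The generator emulates a ten-district, ten-year urban panel. Per district
*i* and year *t* (t = 0..9):

- population `N_{i,t} = N_i (1+g)^t` with base populations 1.2e5–9.5e5 and
  growth g = 0.05/yr — the order of magnitude and secular growth of a
  fast-growing city's administrative districts;
- admissions `Q_{i,t} ~ Poisson(N_{i,t} · r_i · τ^t)` with baseline rates
  r_i spanning 0.3–2.4 per 1,000 person-years and trend τ = 1.08/yr, so
  rates roughly double over the decade — the "gradual increase in all
  districts" regime this kind of surveillance is designed for;
- district centroids scatter over a ~40×20 km strip and translate 200 m/yr
  northward; each admission becomes one case point, isotropic bivariate
  normal (σ = 2,500 m) around the district's year-t centroid. The
  within-district spatial law of real cases is unknown; the isotropic normal
  is an explicit assumption of this generator, not an estimate.

Poisson counts on a log-linear rate surface are the minimal generative model
consistent with the discrete-Poisson scan: when rates are homogeneous the
scan's null holds *exactly*, which is what makes the calibration test sharp.
Two named designs are exposed: `default_config()` (heterogeneous rates +
trend, used everywhere a realistic panel is wanted) and `null_config()` (one
common rate, no trend). Scan calibration and power studies use the null
design, because the default design's rate heterogeneity and secular trend
are themselves true departures from the scan's null hypothesis —
expectations proportional to population — and would be (correctly) flagged
as clusters.

Seeding: every operation draws from its own stream derived from the master
seed via `numpy.random.SeedSequence(seed, spawn_key=(k,))` with a fixed
per-operation `k`, so adding an operation never perturbs another's draws,
and a fixed seed reproduces panels byte-for-byte.

What passing tests on this design do **not** show: robustness to
overdispersion (real admissions are typically extra-Poisson variable),
migration-driven population error, age/sex structure, district boundary
changes, or non-Gaussian case geography. All are out of scope.

## Rates and rank grading

`G` is computed per year for the SR tables (annual SR maps), and once over
the whole study period for scan expectations (see below). Σ_i E_i = Σ_i Q_i
per year to round-off, and the pooled SR is identically 1 — both are
asserted, not assumed.

IR ranks: z-scores of district *average* IRs with the population
(divide-by-n) standard deviation; cut points at z = −0.29, 0.61, 1.5;
intervals left-open/right-closed, so a value exactly at a cut stays in the
lower rank. The printed-interval convention of published four-rank maps
leaves gaps at the third decimal; treating the cuts as points on the
continuous line removes unassignable values. Zero cross-district variance
puts everyone in the z = 0 interval (rank 2) with a warning. SR ranks use
fixed default breakpoints (0.580, 0.890, 1.270, 1.840, 2.500); `kmeans_1d`
(Lloyd's iteration from quantile-seeded centers, deterministic, boundaries
at midpoints between adjacent sorted cluster extremes) can regenerate
data-driven breakpoints, but the fixed defaults are the default because
reproducibility of a published grading takes precedence over re-deriving it
from each dataset. Values above the top breakpoint grade into the top rank
with a warning rather than failing.

## Mean center and standard deviational ellipse

Deviations are taken from the weighted mean center; the SDE is the
eigendecomposition of the weighted second-moment matrix — algebraically the
classical closed-form tan θ solution, but robust at the Σx̃ỹ = 0 branch
point. Conventions, each chosen once and exposed:

- axis lengths are RMS deviations with denominator m (`ddof=0`); no √2
  inflation (`inflation=1.0`) — some GIS products apply both, so both are
  parameters;
- θ is the **major-axis** angle, counterclockwise from the positive x-axis,
  reduced mod 180°; `theta_to_gis` converts to the clockwise-from-north
  convention desktop GIS reports. The mathematical convention makes
  rotation-equivariance tests one-liners;
- exact isotropy (equal moments, zero cross-moment) has no orientation;
  θ = 0 is returned with a `degenerate` flag;
- ellipse overlap is seeded Monte-Carlo intersection-over-union on the joint
  bounding box. With 1e5 samples the standard error is ~0.002 for
  unit-order fractions; the exact conic intersection buys nothing for a
  statistic used qualitatively, and a polygonal cross-check (shapely, 256-gon)
  is kept in the tests.

## Space-time scan

Windows are cylinders: for each center district the radius sweeps the sorted
centroid distances (radius 0 = the single-district base); membership is
centroid-in-circle with inclusive boundary; a base survives if its share of
the *study-average* population (populations vary by year) is ≤ 50% by
default; duplicate member-sets keep the smallest radius. Year intervals are
contiguous with length ≤ floor(0.5 × study length), clamped to ≥ 1 — for a
10-year panel that is the conventional 5-year cap.

Expected counts use the whole-study general rate applied to district-year
populations, making E purely population-proportional across space-time. The
LLR is the one-sided (high-rate) discrete-Poisson statistic with the
0·ln 0 ≡ 0 convention; relative risk is (O/E)/((C−O)/(C−E)). Inference
conditions on the observed total C: replicates redistribute C multinomially
with probabilities ∝ E, and p = (1 + #{replicate max ≥ LLR})/(1 + R) with
R = 999 by default, so the smallest attainable p is 0.001. Reporting is
greedy: LLR-maximal window first (ties → fewer districts, then
lexicographic ids, then earlier/shorter interval), then significant windows
sharing no district with anything already reported.

Calibration: under the null design the observed panel is, conditional on C,
exchangeable with the replicates, so the most-likely-cluster p-value is
uniform on its grid — verified over 200 seeded panels with a
Kolmogorov–Smirnov test at α = 0.01 (199 replicates per panel keep the p
grid at 1/200 without affecting exchangeability). Power: a multiplier-3
cluster spanning 3 districts × 5 years is recovered exactly, at p = 0.001
with 999 replicates, in ≥ 90% / ≥ 95% of 50 seeds respectively (observed:
50/50 for both). The brute-force oracle used in tests re-derives the whole
statistic with plain loops and `math.log` — independent code path, same
window-family definition.

## GM(1,1)

Fitting solves the least-squares system x_t + α z_t = μ (t = 1..n, n ≥ 3)
via `numpy.linalg.lstsq`; the reconstruction and forecasts come from the
continuous solution ŷ_t = (x_0 − μ/α)e^{−αt} + μ/α by first differences,
with x̂_0 = x_0. Note the inherent discrete/continuous gap: a geometric
series x_t = a·q^t solves the difference system exactly (α = −2(q−1)/(q+1),
μ = 2a/(q+1) — asserted to 1e-10), yet its reconstruction uses e^{−α} ≠ q,
so fitted values track but do not equal the input. This is the standard
formulation, not a defect; the posterior-deviation validation exists
precisely to grade that gap.

Conventions: |α| < 1e-10 switches to the exact linear limit ŷ_t = x_0 + μt
(constant series would otherwise divide by zero); s1, s2 are population
standard deviations of the series and of the residuals δ_t = x_t − x̂_t over
t = 0..n (δ_0 = 0 by construction); c = s2/s1; p counts residuals within
0.6745·s1 of the mean residual; degree thresholds are
excellent (p > 0.95, c < 0.35), good (p > 0.80, c < 0.50), marginal
(p > 0.70, c < 0.65), else unreliable. The c = s2/s1 arithmetic and the
degree grading are pinned against twenty worked-example validation rows
(ten incidence-rate fits, ten admission-count fits) at two very different
scales. A zero-variance series makes c undefined; it is reported degenerate
with a warning rather than graded.

The pipeline fits each district's IR series (per 1,000) and admission series
separately, forecasts a default horizon of 3 years, and divides admission
forecasts by hospital counts for the burden projection. Series containing
non-positive values cannot enter a grey fit and are skipped with a recorded
reason (under the default design, minimum cell means are ~30, so this is a
guard, not a path the defaults exercise).

## Pipeline and reproducibility

`load_and_validate` reports *every* violation found (duplicates,
non-positive populations, negative counts, orphan case points) in one error;
missing cells of a non-rectangular panel are logged, never silently dropped.
Reports carry no timestamps and use fixed float formatting, so identical
configurations and seeds yield byte-identical report trees (sha256 manifest
asserted in tests). Coordinates are assumed planar/projected (meters);
no geodetic computation is performed, appropriate for intra-city distances.

Problem sizes used by the shipped checks — 200 seeds × 199 replicates for
calibration, 50 seeds × 999 replicates for power, 1e5 samples for overlap
fractions — were chosen as the smallest sizes at which the respective
binomial/KS error bands are decisively narrower than the tolerances being
asserted.

## Known limitations

- The scan considers circular bases only; elongated or non-convex true
  clusters are approximated by the best circular cover.
- Monte-Carlo p-values are granular at 1/(R+1); secondary-cluster reporting
  inherits the greedy non-overlap rule and can mask nested structure.
- GM(1,1) extrapolates a single exponential; it is a short-horizon tool and
  the degree grading should gate any use of its forecasts.
- Indirect standardization uses total population only; no age/sex
  adjustment.
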