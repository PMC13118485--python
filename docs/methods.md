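# Methods

## The estimation problem

A three-outlet microfluidic sorter (the motivating device is a
deterministic-lateral-displacement post array, but nothing below is specific
to it) splits an unsorted inlet suspension into Small, Medium and Large
outlet reservoirs.  The property that characterises the device is the
routing probability `P(k | d)` — the chance that a particle of size `d` is
directed to outlet `k ∈ {S, M, L}` — but no experiment observes it
directly.  What is measurable is

- the size distribution of each outlet, `P(d_i | k)`, from imaging the
  collected reservoirs and recording each segmented object's major-axis
  length (for a sphere, its diameter), and
- the fraction of all sorted particles found in each outlet, `P(k)`, from
  per-outlet counts or concentrations.

Under the assumption that every particle entering the device reaches some
outlet (no loss), the conditional-probability identity gives, per size bin
`d_i`,

    P(k | d_i) = P(k) · P(d_i | k) / Σ_j P(j) · P(d_i | j).

The unknown total particle number cancels, which is why outlet fractions
suffice.  When a complete per-bin count table `n_{d_i,k}` is available the
same quantity is the plain count ratio `n_{d_i,k} / Σ_j n_{d_i,j}`; the two
pathways agree bin-by-bin as an algebraic identity, and the test suite
asserts that equality to 1e-12 on random tables — the count route is the
internal oracle for the distribution route.

Bins in which no outlet has any mass are *undefined*, not zero.  They carry
an explicit mask; zero-filling would fabricate certainty about size ranges
the experiment never observed.

## Binning

All reservoirs share a single grid of equal-width, half-open bins
`[lo, hi)` (the last bin also includes its upper edge).  The width is the
Freedman–Diaconis choice `2·IQR·n^(−1/3)` evaluated on the inlet sample,
with linear-interpolation quantiles; the grid is anchored at the pooled
minimum so outlet sizes outside the inlet range stay representable.
Degenerate data fall back to `(max−min)/⌈√n⌉` when the IQR is zero, and to
a fixed 1 μm width when all values coincide.  The quantile estimator, bin
anchoring and the degenerate fallbacks are this package's conventions,
fixed so results are deterministic; no smoothing or adaptive binning is
applied anywhere.

## Critical diameter

The probabilistic critical diameter `DC` is the size at which routing to
Small and Large is equally likely, `P(L | DC) = P(S | DC)`.  It is located
by scanning `f(d_i) = P(L | d_i) − P(S | d_i)` over the defined bins in
increasing size and linearly interpolating each sign change.  Two numerical
choices matter:

- **Abscissa.**  Each bin's probabilities are placed at the bin's
  density-weighted mean size (computed from the per-bin size sums of the
  outlet histograms, mixed with weights `P(k)/n_k`) rather than at the
  geometric bin center.  With a sloping size density across a bin, the
  bin-aggregated ratio effectively "lives" at the within-bin center of
  mass; using the geometric center instead shifts the interpolated
  crossover by a systematic fraction of a bin width (about +0.04 μm at the
  default simulation conditions, comparable to the estimator's standard
  error), which is enough to degrade bootstrap coverage.  When only counts
  are available (no raw sizes), the abscissa falls back to the bin center
  and the estimator reduces to plain center interpolation.
- **Multiple crossings.**  Sampling noise can produce spurious sign
  changes far from the true transition, backed by a handful of particles.
  The crossing whose two flanking bins carry the largest total particle
  mass wins; exact ties break toward the smaller diameter.  A routing
  table whose curves never cross raises a dedicated error rather than
  returning a fabricated value.

`DC` is reported as found by interpolation; it is related to, but distinct
from, the geometric critical diameter of the array (below).

## Purity, yield, capture rate

- `Purity(S) = P(d < DC | S)` and `Purity(L) = P(d > DC | L)`: sums of the
  outlet's size pmf on one side of `DC`.
- `Yield(S) = P(S | d < DC)` and `Yield(L) = P(L | d > DC)`: the
  inlet-mass-weighted conditional probabilities
  `Σ_i P(target | d_i) w_i / Σ_i w_i` over the bins on the requested side,
  where `w_i = Σ_k P(k) P(d_i | k)` is the inlet mixture reconstructed from
  the outlets.  This weighting is the only reading that both stays in
  [0, 1] and coincides with the direct count ratio "particles of that size
  range routed to the target outlet / all particles of that size range"
  under the no-loss assumption; an unweighted sum of conditionals is not a
  probability and is not offered.  Weighting by a separately measured inlet
  histogram is available (`yield_weighting="measured"`), but the
  reconstructed mixture is the default for self-consistency with the
  *nominal* (no-loss) yield convention.
- **Fractional-bin rule.**  The bin containing `DC` contributes to each
  side in proportion to the sub-bin interval on that side.  This removes
  any dependence of purity/yield on where `DC` happens to fall inside a
  bin and makes `purity(below) + purity(above) = 1` exact.  A `strict`
  mode (whole bins only; the straddled bin counts for neither side) is
  exposed for comparison; both modes agree whenever `DC` lies on a bin
  edge, and at a bin edge both reduce exactly to per-particle count
  ratios, which the tests verify.
- **Capture rate** = summed outlet concentrations divided by
  `dilution_fraction ×` inlet concentration (default dilution 0.3,
  i.e. 3 sample channels merging with 7 buffer channels).  Counting noise
  can push it above 1; values above 1.2 warn but are reported unclamped.

## Uncertainty

Percentile bootstrap (2.5/97.5) over `B ≥ 100` replicates.  Records are
resampled with replacement *within each reservoir* and the pipeline re-run
on the original grid.  Because the pipeline sees the data only through
per-bin counts on that fixed grid, the resampling is realised as a
multinomial redraw of each reservoir's bin counts — distributionally
identical and far cheaper.  Per-bin mean abscissas and the outlet
fractions are held at their observed values (the fractions are an external
measurement, not part of the size tables).  Replicates with no crossover
are recorded as failures and excluded; their count is reported.  The
whole procedure is deterministic given a seed.

## Device-design arithmetic

For a post array with gap `G`, post diameter `D` and periodicity `N`
(tilt `tan θ = 1/N`, pitch `λ = D + G`), the nominal geometric critical
diameter is estimated by Davis' empirical correlation
`DC = 1.4 G N^(−0.48)` (default) or the square-root approximation
`DC = G (2/N)^(1/2)`.  Both are singlet-sphere rules of thumb; at
`G = 45 μm`, `N = 60` they give 8.8 and 8.2 μm respectively.
`geometry_consistency` cross-checks a stated pitch and tilt angle against
`D + G` and `atan(1/N)` and reports discrepancies without judging them.

## The simulator

The generator emulates a microsphere sorting experiment with known ground
truth:

- **Populations**: a mixture of nominal diameters with Gaussian size noise
  truncated at 0.1× nominal.  Defaults: 7, 10, 16 μm at equal weights with
  CVs 13%, 12%, 12% — the certificate values of typical polystyrene size
  standards.
- **Clusters**: with probability `cluster_prob` (default 0.05) a particle
  is a chain of `c` spheres, `c` uniform on {2, …, max_cluster_size}
  (default 3).  Its *observed* major axis is the chain length `c·d0`; the
  size that drives routing is a damped effective diameter
  `d_eff = d0 (1 + β (c − 1))` with `β = 0.6` by default.  This reproduces
  the qualitative behaviour of sphere pairs reaching the intermediate and
  displacement outlets while their constituent spheres would not; no claim
  of hydrodynamic accuracy is made.
- **Routing law**: a Gaussian intermediate-outlet bump of amplitude `A`
  (default 0.2) and width `s` (default 1 μm) centred on the true critical
  diameter `dc_true` (default 11 μm), and a logistic Small/Large switch of
  width `w` (default 0.5 μm).  At `d_eff = dc_true` the Small and Large
  probabilities are equal by construction, so the pipeline's crossover
  estimate is directly comparable with the configured truth.  Outlet
  assignment is an independent categorical draw per particle; all
  randomness flows from one seeded generator.

What the simulator does *not* model: hydrodynamics, diffusion physics,
particle–particle interactions, losses inside the device, segmentation
error in the size measurement.  Passing the recovery and coverage tests
therefore shows that the statistical pipeline is correct and calibrated
under its own assumptions (no loss, independent routing, exact sizes); it
does not validate those assumptions for any physical device.

## Validation study sizes

The test suite recovers the 11 μm true critical diameter within
max(0.5 μm, one bin width) in at least 18 of 20 simulated experiments at
n = 10,000 particles, and checks 95% bootstrap coverage of the truth over
50 independent experiments (band 88–100%) with B = 200 replicates at the
default n.  These problem sizes are the package's validation conventions.

## Known limitations

- The crossover estimator assumes a single genuine transition; devices
  with multiple cutoffs are out of scope.
- Undefined bins inside the transition region (possible at very small n)
  simply drop out of the scan; no imputation is attempted.
- Yields are nominal: selective particle loss between inlet and outlets
  would bias them without being detectable from the size tables alone —
  the capture rate is the coarse guard against that.
- The printed tilt angle of a fabricated array may disagree with
  `atan(1/N)`; the geometry checker surfaces such inconsistencies but has
  no basis to resolve them.
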