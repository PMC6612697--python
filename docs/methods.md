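# Methods

## The comparison model

Two absorbed-dose fields on regular 2D grids are compared: a reference
distribution (planning-system calculation, treated as ground truth) and
an evaluated distribution (measurement).  Grid positions are element
*centres*; all distances are 2D Euclidean in mm.  Doses are unit-agnostic:
only ratios to the normalization dose enter the computation.

**Gamma index.**  For reference point r_r,
γ(r_r) = min_{r_e} sqrt(δ²/ΔD_abs² + r²/Δd²), with δ the evaluated-minus-
reference dose difference, r the distance, ΔD_abs the absolute dose
tolerance and Δd the distance tolerance.  Global normalization is used:
ΔD_abs = (ΔD% / 100) · max(reference dose).  The normalization dose is
taken from the *reference* grid (it is the planned, ground-truth
distribution); an override parameter exists for protocols that normalize
differently.  A point passes when γ ≤ 1.0, inclusive — a uniform +3%
dose offset at ΔD = 3% passes exactly at γ = 1.

**Lower dose threshold.**  Points with reference dose < LDT% of the
normalization dose are excluded from analysis.  The comparison is
inclusive (≥), computed from the reference only: the reference defines
the clinically intended dose region, and inclusivity keeps uniform fields
fully analysed.  Default LDT 5%.

**GAI.**  The gamma agreement index is 100 · n_passed / n_included.

## Inverse search

Given a target GAI and one held-fixed quantity, the free criterion starts
at 0 and advances on a fixed lattice (0.1 mm for Δd searches, 0.1% for ΔD
searches; both configurable), running a full global gamma evaluation at
each value and stopping at the first value that meets the target.  The
target comparison is count-based — met when n_passed ≥
ceil(target/100 · n_included) — so percentage round-off can never decide
convergence ("95% of 53 points" is unambiguous).  A small epsilon
(1e−9) inside the ceiling guards against targets whose product with
n_included is representable only approximately.

Caps default to 20 mm / 20%; if reached first, the result carries status
`cap_reached` and the cap's GAI.  Targets of exactly 100% are allowed but
fragile — one corrupted pixel with no in-tolerance dose anywhere runs the
search to the cap — so the CLI recommends 99–99.5% when 100% is requested.

Internally the iteration only re-evaluates undecided points: passed
points stay passed (γ is non-increasing in both criteria), and points
that fail a gamma test at the cap can never pass and are set aside after
that single test.  Results, traces and statuses are identical to
re-evaluating every point at every step.

**Per-point requirement maps.**  The passing condition inverts in closed
form per point:

* min Δd at fixed ΔD: min over in-tolerance candidates (|δ| ≤ ΔD_abs) of
  r / sqrt(1 − δ²/ΔD_abs²); +inf (unreachable) when no in-tolerance
  candidate exists inside the cap disc — no distance criterion rescues a
  point whose dose matches nothing nearby.
* min ΔD at fixed Δd: min over candidates with r < Δd of
  100·|δ| / (norm · sqrt(1 − r²/Δd²)); a candidate exactly at r = Δd
  passes only with δ = 0 (the distance term alone saturates Γ there).
* min Δd at fixed ratio k = ΔD/Δd: min over candidates of
  sqrt((100·δ/(k·norm))² + r²).

The m-th smallest requirement (m the count threshold above), rounded up
to the search lattice, equals the iterative result exactly; this
"quantile fast path" is the primary correctness oracle in the tests and
an optional accelerator (`use_fast_path=True`).  The maps themselves show
*where* agreement is demanding, and their cumulative histogram reads off
the criterion needed for any pass rate.

## Numerical choices

* **Resampling.**  The evaluated grid is bilinearly refined to a pitch of
  at most `interp_step_mm` (default 0.2 mm, twice as fine as the 0.1 mm
  search step) before the candidate search; otherwise the distance term
  is quantized to the detector pitch.  The grid is never coarsened, and
  the extent is preserved.
* **Candidate discs.**  For pass/fail and the GAI a disc of radius Δd is
  exact (any farther candidate has Γ > 1).  When full γ values are
  reported the disc is 3·Δd: values up to 3 are exact, beyond that the
  stored value is the guaranteed lower bound radius/Δd, flagged
  *censored*; censored points never count as passing.  A `radius_mm=None`
  option removes the cap for exact maps.
* **Boundary consistency.**  Squared distances within 1e−18 mm² snap to
  exactly 0, and r² is clamped to radius² inside the disc (relative
  1e−12), so boundary candidates (r = Δd, δ = 0) behave identically in
  the iterative gamma route and the closed-form requirement route — the
  exact search/quantile equivalence depends on this.
* **Degenerate criteria.**  Δd = 0 restricts the test to co-located
  candidates (pure dose difference) — this is the first iterate of every
  Δd search.  ΔD = 0 (first iterate of the ΔD search) requires an exact
  dose match within the distance tolerance.  The lattice round-up in the
  fast path compares against the exact float lattice k·step the
  iteration visits, not against an algebraic multiple.
* **Sentinels.**  Excluded points carry NaN, unreachable points +inf;
  the two are never conflated with numeric values.

## Synthetic data

The generator emulates the features of planar PSQA fields that drive
gamma behaviour: separable square fields D(x,y) = D_max·P(x)·P(y) with an
erf penumbra (top-hat convolved with a Gaussian of scale σ; 50% dose at
the field edge), rigid shifts, uniform dose scalings, Gaussian dose noise
(amplitude in percent of the maximum, matching the globally-normalized
dose criterion; doses floored at 0) and single-pixel corruption.  Shifts
are applied through the analytic form, never by interpolating the
discrete grid, so a shifted pair is exact ground truth for
distance-to-agreement recovery.

Defaults — 90 mm grid at 1 mm pitch, 60 mm field, σ = 3 mm, 2 Gy plateau
— represent a typical per-fraction field on a planning-system export
grid.  The cohort in `scripts/acceptance.py` draws field widths of
40–70 mm, penumbra σ of 2.5–4 mm, setup shifts up to ±1.2 mm per axis,
output errors of ±1.5% and 0.75% dose noise across 12 pairs; single-pair
demonstrations use a 2 mm shift and a 4.05% scaling.

What the generator does **not** model: realistic VMAT fluence modulation,
detector spatial response and cylindrical-array geometry, setup rotations,
or spatially correlated measurement noise.  Passing tests therefore
demonstrate the correctness of the gamma/inverse-gamma computation on
fields with clinical geometry and noise scales, not equivalence with any
commercial system on clinical measurements.

## Design notes and limitations

* The iterative search, not the quantile fast path, is the default: the
  iteration is the defining procedure and its trace is part of the
  result; the fast path is flagged in explicitly.
* Only global normalization is implemented; local (point-by-point)
  normalization and 3D gamma are out of scope.
* The per-point map for the fixed-ΔD mode can be read two ways ("minimum
  Δd per point" vs "γ recomputed at the converged Δd"); the former is the
  primary product, and the latter is available by running `gamma_map` at
  the found criterion.
* Requirement values above the cap are kept finite in the maps (they are
  informative); the search and fast path respect the cap when deciding
  convergence.
* Grid pairs must overlap: every analysed reference point must lie inside
  the evaluated extent (configurable margin).  Points near the evaluated
  boundary see a clipped candidate disc, which can only raise their γ.
* Problem sizes in the tests (grids ≤ 30×30 for oracle comparisons,
  12×12 for the search-equivalence sweeps, 91×91 for shift recovery) keep
  the exhaustive brute-force oracles and repeated searches cheap while
  covering the full code paths; they are the package's own choice of
  verification scale.
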