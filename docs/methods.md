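# Methods

## Scope and model assumptions

`memkit` analyzes *planar* bilayers: the bilayer normal is fixed to the
global z axis and no local-normal estimation is attempted, so curved or
strongly undulating membranes are outside the model.  A system is a static
topology (species, per-site roles, leaflet counts) plus one or more frames
(periodic box, site coordinates in nm) and optional scalar channels
(projected area in nm², surface tension in mN/m, temperature in K).
Internally everything is nm / J / mN/m; unit conversion happens only at
I/O boundaries (PDB Å → nm on read).  Physical constants: Boltzmann
constant 1.380649e−23 J/K; the default temperature is 310.15 K (37 °C),
but every routine that needs a temperature takes it explicitly or from the
ensemble's channel.

## Leaflet assignment

The midplane is the mean z of the interface-anchor sites of all lipids
(phosphate where the species has one, headgroup otherwise, the OH-bearing
carbon for cholesterol).  A lipid is *upper* iff its anchor sits above the
midplane; an anchor exactly on the midplane falls back to the mean z of
the tail carbons (tails point toward the midplane), and a molecule with
neither resolvable is a degenerate-input error rather than a silent guess.
Across frames, labels are set by majority vote and any per-frame flip
(e.g. cholesterol moving between leaflets) is logged, then reassigned —
there is no accepted convention for flip handling, so the simplest
deterministic rule was chosen.

## Structural observables

**Area per lipid.**  Box route: `Lx·Ly / n_per_leaflet`.  Voronoi route:
a periodic 2D tessellation of the headgroup (x, y) projections, computed
by tiling the box 3×3, tessellating the nine copies with `scipy.spatial`,
and reading off the central cells.  This makes the partition property
(`Σ cell areas = Lx·Ly`) exact to rounding, which the tests assert at
1e−9 relative.  Coincident seeds are jittered by 1e−6 nm with a warning.

**Density profiles and thickness.**  Profiles are z-histograms about the
per-frame midplane (minimum-image in z), weighted by per-site mass or by
per-site electron counts declared in the topology YAML; mass weighting is
the default, since simplified/coarse-grained sites have no canonical
electron assignment.  The profile integral equals the selected weight per
unit in-plane area (conservation is tested at 1e−6 relative).  Thickness
is the distance between the two phosphate peaks, one per side of the
midplane, each refined by 3-point parabolic interpolation around the
maximal bin; equal-height ties go to the outermost pair.  A single-peak
profile (collapsed or fully interdigitated bilayer) returns a flagged
result with no number.

**Order parameters.**  `S_C = ½⟨3cos²θᵢ − 1⟩` with θᵢ measured between
the C(i−1)→C(i+1) axis and the global z axis.  Only interior carbons are
scored — the axis is undefined at chain ends — and the global axis (not an
instantaneous local normal) is used even under tension, consistent with
the planar-system assumption.  Coincident axis carbons are skipped with a
warning.

**Cholesterol tilt.**  The angle of the OH-carbon → tail-carbon axis
against the leaflet *outward* normal (+z upper, −z lower), so both
leaflets histogram onto one axis.  This is a pure convention; the
synthetic generator draws cholesterol axes about the same reference, so
generator and analyzer are consistent by construction.

**Interdigitation.**  `λ = ∫4ρ_u ρ_l dz / ∫(ρ_u+ρ_l)² dz` over the
tail-site mass-density profiles of the two leaflets (100 bins by
default); λ is 0 for disjoint profiles, 1 for identical ones, and the
tests pin the analytic value 2/3 for half-overlapping rectangles.  The
interdigitated-state flag fires at λ ≥ 0.9 (inclusive, configurable).

**Neighbors and packing distances.**  First-shell neighbors default to
periodic Voronoi adjacency (parameter-free); an in-plane cutoff mode
exists for lattice-style analyses.  Sugar–sugar (or any site-group)
packing is reported as nearest-neighbor center-of-mass distances with the
minimum-image convention.

## Interactions

**Hydrogen bonds.**  A bond requires D–A distance ≤ 0.35 nm and D–H–A
angle ≥ 135°, both inclusive.  The angle is the donor-hydrogen-acceptor
angle itself (near-linear bonds score ≈180°), which differs from the
deviation-angle convention of some MD toolchains — stated here because it
changes which geometries pass.  The search uses uniform cell lists with
minimum image and is contractually identical to an all-pairs scan; the
test suite enforces equality against an independent O(n²) oracle on 100
random fixtures.

**Water penetration.**  The hydrophobic-center slab is one bin high
(half-width `bin_size/2`) centered on the instantaneous midplane.  The
default bin, 0.31 nm, is `(1/33.36 nm⁻³)^(1/3)` — the cube that holds one
water at bulk density — rounded to 2 decimals for reporting (the exact
value is available).  Each bin's value is the fraction of frames with at
least one water site in the sub-volume; `fraction_nonzero` summarizes how
much of the plane ever sees a water.

## Mechanics

**Block statistics.**  Production series are split into 4 contiguous
equal blocks (any remainder dropped from the *front*, where equilibration
artifacts would live); the standard error is SD(block means)/√4.  Blocks
are treated as independent; the generator's optional AR(1) area mode
exists precisely to quantify the bias of that assumption on correlated
data.

**K_A, regression route.**  Per tension, per block: mean area → strain
`ε = A/A₀ − 1`; unweighted OLS of γ on ε over all block points gives K_A
and its SE.  A₀ defaults to the zero-tension ensemble mean, and the γ = 0
point is *excluded* from the fit by default (it only defines A₀),
mirroring the experimental practice of fitting a small-tension regime;
`include_zero_tension=True` adds it.  Fits with r² < 0.9 are flagged, not
rejected.  `ka_from_tension_strain` applies the same block-mean + OLS
procedure to direct (strain, tension) samples.

**K_A, fluctuation route.**  `k_B·T·⟨A⟩/var(A)` with the *population*
variance of the full series (at n ≥ 100 the ddof choice is negligible);
zero variance raises rather than returning infinity.  The SE is a
delete-one-block jackknife over the 4 blocks.

**K_c.**  `K_A·(h−h₀)²/24` with `h₀ = 1 nm`; callers should note the
relation is established for PC-type bilayers in the liquid phase.  The
exact quadratic scaling in (h−h₀) is a test invariant.

**Regime classification.**  The γ–ε curve is split into a *linear*
maximal prefix (through-origin fit, every relative residual < 5%, at
least 3 points), a *plateau* maximal suffix (every local slope < 10% of
the linear slope), and a *logarithmic-like* middle.  The 5%/10%
thresholds are package choices exposed as parameters — the underlying
regimes are qualitative — and classification is stable under factor-2
subsampling (boundaries move at most one grid point, tested).

**Pore detection.**  A pore is a (x, y) bin column whose water sites span
the slab between the two phosphate planes with every vertical gap
(including the gaps to the planes) smaller than the bin size; when the
planes cannot be resolved the check falls back to a fixed ±1 nm central
slab with a warning.

## The synthetic generator

The generator emulates the *statistical* structure the estimators assume,
with every parameter recorded as ground truth:

- two leaflets of simplified multi-site lipids (headgroup, phosphate or
  sugar ring, backbone, 2×6 tail carbons; cholesterol as a two-site axis;
  one-site waters) on a jittered square lattice with box area
  `n_lipids_per_leaflet · target_apl` and phosphate planes at
  ±thickness/2.  Defaults describe a cholesterol-containing reference
  membrane at 37 °C: 100 lipids per leaflet (≈200 molecules, a 7×7 nm
  box at 0.49 nm² per lipid), thickness 4 nm, 35/35/30 POPC/POPE/CHOL;
- mole fractions → integer counts by largest-remainder rounding, ties to
  the earlier species in the canonical order (POPC, POPE, CHOL, SM,
  GalCer); the documented molar-mass table uses formula masses (POPC
  C42H82NO8P = 760.08 g/mol, POPE 718.00, CHOL 386.65, palmitoyl-SM
  703.03, GalCer d18:1/16:0 700.05).  Weight-fraction accounting is exact
  for this table; other mass conventions (e.g. coarse-grained tails of
  different length) shift the weights at the second decimal;
- tail segments drawn from a tilt model (fixed angle → straight rods with
  exactly the closed-form S_C; Gaussian per-segment tilt, default
  25° ± 10°, a realistic fluid-phase spread; isotropic for the S_C → 0
  limit), cholesterol axes at Gaussian tilt (default 20° ± 10°, clipped
  to [0°, 89°]) about the leaflet outward normal;
- equilibrium area series: i.i.d. Gaussian with mean ⟨A⟩ and variance
  `k_B·T·⟨A⟩/K_A` (an optional AR(1) mode matches the stationary
  moments); tension–strain data: `γ = K_A·ε + N(0, σ)`;
- water-penetration events planted per 0.31 nm bin with a Bernoulli
  probability per frame (a fixed-size water pool keeps the site count
  constant across frames); `interdigitation_depth` pushes tail ends past
  the midplane to create leaflet overlap;
- planted donor–H–acceptor triplets with exact distance and angle, the
  hydrogen 0.1 nm from the donor.

Everything is driven by one mandatory seed through `numpy`'s PCG64
generator and is bit-reproducible.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: no physical dynamics or forces (no correlations
between frames, no realistic chain conformational statistics beyond the
prescribed tilt model), no membrane undulations or curvature, no
electrostatics or chemistry behind hydrogen bonds (geometry only), no
asymmetric leaflets, no proteins.  Parameter recovery demonstrates that
the estimators measure what they claim on data satisfying their own
assumptions; it does not validate any force field or predict moduli of
real mixtures.

## Problem sizes and defaults used for validation

The acceptance computations use ensembles of 100,000 area samples (means
49 and 1764 nm², matching 7×7 and 42×42 nm boxes; generative moduli 457
and 360 mN/m at 310 K) and tension–strain sets of 40 strains in
[0.005, 0.05] × 40 samples with σ = 2 mN/m noise at a generative slope of
188 mN/m — sizes at which both estimator routes sit well inside 5% of
truth while the whole validation runs in seconds.  Configuration-level
tests use 9–400 lipids per leaflet depending on the observable.

## I/O choices

GRO is the canonical format (single- and multi-frame; 3-decimal nm
coordinates, round-trip tested at that precision); PDB (CRYST1 + ATOM,
Å) is read-only.  Binary trajectory formats are deliberately out of
scope: multi-frame GRO plus scalar CSV
(`time_ns,area_nm2,tension_mN_m,temperature_K`) cover desk-scale
analysis.  Topologies are YAML (species with per-site roles and optional
per-site masses/electron counts, ordered per-leaflet molecule lists,
water count).  Parsers report the offending line number; site-count
mismatches against the topology are topology errors, and coordinates are
only wrapped into the primary box on request, never silently.

## Known limitations

- Planar systems only; no local-normal or undulation corrections.
- H-bond detection needs explicit donor/hydrogen/acceptor site indices;
  the simplified synthetic species carry no hydrogens, so the pipeline's
  interaction stage reports water penetration, and H-bond analysis is
  exercised through the library on planted geometries.
- The 4-block error model understates errors on strongly autocorrelated
  series (use the AR(1) generator mode to calibrate).
- Regime boundaries depend on the configured thresholds for curves
  without sharp transitions.
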