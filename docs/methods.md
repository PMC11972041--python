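# Methods

`fragmon` implements fragmentation-vertex imaging for treatment monitoring in
scanned carbon-ion therapy: charged nuclear fragments leaving the patient are
tracked with a small two-layer pixel telescope ("mini-tracker"), each track is
projected back onto the pencil beam that was being delivered at its timestamp,
and the voxelised collection of these reconstructed fragmentation vertices
(FVs) is compared between treatment fractions to detect internal density
changes.

## Coordinate conventions and geometry

The room frame is right-handed: the isocenter at the origin, the beam along
`+z`, `+y` vertically up.  The tracker's *focus line* (through both layer
centers) passes through the isocenter at 30° to the beam axis, in the y–z
plane by default (configurable azimuth), front layer 167 mm from the
isocenter, layers 20.3 mm apart and perpendicular to the focus line.  Each
layer is a 28 mm × 14 mm sensor of 509 × 254 pixels at 55 µm pitch (two
read-out chips share one sensor; columns are continuous across the chip
boundary).  A known 1.6° mounting tilt is applied as a rotation of the
in-plane sensor basis about the focus line; the tilt axis is not otherwise
constrained, and rotating about the focus line is the choice that leaves the
layer planes invariant.

The Monte-Carlo solid-angle estimator samples directions uniformly in a
spherical cap guaranteed to cover the layers; from the isocenter the front
layer subtends ≈ 1.40 × 10⁻² sr and the two-layer coincidence ≈ 1.11 × 10⁻²
sr — the detector sees of order one fragment in a thousand.

## Reconstruction chain

1. **Clustering.** Charge sharing spreads one particle over neighbouring
   pixels.  Hits are partitioned so that two hits share a cluster iff they
   are linked by a chain of (adjacent AND |Δt| ≤ window) pairs.  Cluster
   timestamp = earliest constituent ToA; energy = sum; 2D position =
   energy-weighted centroid.  Defaults: 8-connected adjacency (diagonal
   charge sharing is common) and a 100 ns intra-cluster window (well above
   per-pixel time walk, well below typical inter-particle spacing); both are
   config keys since neither is pinned by hardware.  Connectivity is solved
   with hash-joined neighbour pairs and sparse connected components, after
   splitting the stream at time gaps larger than the window (no cluster can
   span such a gap: any chain link across it would itself violate the
   window).
2. **Coincidence matching.**  A track requires one cluster in each layer
   within |Δt| ≤ 75 ns.  The merged time-sorted stream is cut into groups at
   gaps > window; within a group, pairs are matched greedily by smallest
   |Δt|, ties broken by earlier front then back timestamp (the greedy rule is
   the standard procedure; an assignment-problem oracle in the tests bounds
   how often it is also optimal — ≥ 95 % even at cluster densities far above
   physical rates).
3. **Tracks and vertices.**  Matched centroids are mapped to the room frame;
   the track is the line through the two points, directed away from the
   phantom.  Each track is associated to the spot whose delivery interval
   (closed, `[t_start, t_end]`) contains its timestamp; tracks in inter-spot
   gaps are excluded and reported rather than snapped to a neighbouring
   spot.  The reconstructed FV is the midpoint of the shortest segment
   between the track line and the *nominal* beam line (through the logged
   spot position, along `+z`); using the nominal rather than the true
   primary trajectory is deliberate — it is what the real monitoring system
   can know, and it contributes to the 3–5 mm projection uncertainty along
   z.  Parallel track/beam geometry (cross-product norm < 1e−9) is skipped
   with a reason count.  No miss-distance cut is applied by default; one is
   available in the config.

## Significance analysis

Two FV distributions are voxelised on an 8 mm × 8 mm × 10 mm grid
(half-open voxels; default grid centred laterally on the beam axis, which
keeps the beam-core statistics in single voxel columns) and subtracted.  A
voxel difference is *significant* when

    |N₂ − N₁| ≥ k·√(N₁ + N₂),   k = 2  (95.4 % confidence),

restricted to voxels with more than 100 counts.  The count eligibility is
applied to both distributions by default ("either"/"first" modes are
provided; the choice only matters for voxels near the threshold).  No
multiple-testing correction is applied; instead the analysis is calibrated
by the number of voxels expected to pass by chance, estimated per voxel by
Monte Carlo with the observed reference count as plug-in Poisson mean.  For
200 voxels at mean 400 this expectation is 9.1 — the large-mean limit is
2·(1−Φ(2)) ≈ 4.55 % per voxel.

Depth profiles integrate the FVs transversely into 5 mm z bins; region
deltas integrate profile differences over configured z intervals (phantom,
PTV, nasopharynx), apportioning partial edge bins by overlap fraction.  The
model-shortfall helper turns measured and simulated region reductions into
the relative fraction of the measured change a model fails to reproduce.

## Synthetic delivery generator

The generator is phenomenological — a single effective fragment species,
exponential attenuation, one net Gaussian scattering kick — not a transport
code.  It reproduces the statistical structure the analysis relies on; it
does not model fragment spectra, nuclear cross sections, dose, or CT-based
heterogeneity beyond a piecewise density profile.

* **Plan.**  Energies linearly spaced over 153–250 MeV/u; spots on a
  centred raster grid (default desk-scale plan: 5 layers × 40 spots ×
  2000 primaries, 2 mm spacing; a `full_plan` flag switches to 25 layers ×
  238 spots × 5.18e4 primaries ≈ 3.1e8 total).  Spot intervals are
  non-overlapping (5 ms delivery, 1 ms gap).
* **Ranges.**  Bragg–Kleeman `R = αE^p` with α = 0.00733 mm, p = 1.77: the
  proton water-range coefficient scaled by A/Z² for carbon, ≈ 128 mm at
  250 MeV/u and ≈ 54 mm at 153 MeV/u, so the field's Bragg peaks lie inside
  the default 160 mm phantom.
* **Vertex production.**  Depth density ∝ ρ(z)·S(z), with primary survival
  S(z) = exp(−∫ρ dz′/λ_p), λ_p = 250 mm, truncated at the range.  Lateral
  position = nominal spot + N(0, σ = 2 mm), the beam-spot width.
* **Insert.**  The nasopharynx filling is modelled as *added* density
  (+0.98, the silicone at HU −20) over a 10 mm × 25 mm × 25 mm box (≈ 6 mL):
  it doubles local production, shortens primary ranges beyond it (the
  dominant downstream loss is Bragg-peak pull-back, not just the ~4 %
  survival change), and absorbs fragments whose exit path toward the
  tracker crosses it (≈ e^(−0.98·11.5/400) ≈ 2.8 % loss for upstream
  emissions at 30°).
* **Emission and transport.**  Polar angle density ∝ exp(−θ/θ₀) on
  [0, π/2], θ₀ = 0.35 rad, azimuth uniform; fragment survival
  exp(−∫ρ ds/λ_f), λ_f = 400 mm, along the exit path through a slab-plus-
  lateral-box phantom (default half-width 75 mm); surviving directions get
  Gaussian kicks of σ = 8 mrad per transverse component.
* **Detector.**  Rays are intersected with both layer planes; the per-layer
  deposit (lognormal, median 40 keV, σ_log 0.5) is split bilinearly over
  the 2 × 2 nearest pixels, pixels below 3 keV are dropped, and a fragment
  is detected iff it leaves at least one recorded pixel in each layer.
  ToA = spot-uniform delivery time + 3 ns Gaussian jitter, quantised to the
  1.5625 ns grid.

**Importance sampling.**  Since the emission direction is independent of
the vertex position, produced vertices are thinned by the exact emission
probability mass of a conservative (θ, φ) envelope that contains every
direction able to reach the tracker (corner-to-corner construction over the
vertex bounding box and both layers, padded by 5 σ of the scattering kick
plus 0.05 rad), and directions are sampled conditionally inside the
envelope.  The detected-event distribution is exactly preserved up to the
< 1e−6 truncated scattering tail; a full-sphere mode
(`importance_sampling=False`) exists and the equivalence is tested.  All
randomness flows from one master seed through named per-(repetition, spot,
stage) substreams, so insert-on/off runs share draws where their physics
coincides.

What the generator does *not* emulate: real cluster morphology (δ-rays,
skewed charge clouds), energy-dependent scattering and absorption, fragment
multiplicity per interaction, beam-intensity structure within a spot, the
anthropomorphic phantom's heterogeneous anatomy, detector dead time.
Passing tests therefore demonstrate correctness of the *analysis* under the
stated statistical structure, not fidelity to any specific measurement.

## Problem sizes in the test suite

The default desk-scale delivery (5 × 40 × 2000 primaries, 7 repetitions)
yields ≈ 1.3e3 detected fragments and runs in ~1 s; it is used for the
projection-uncertainty check (z-residual RMS ≈ 4.2 mm at defaults, inside
the 3–5 mm band; the two comparable contributions are the 2 mm spot width
entering through the nominal-beam projection, ≈ σ·cot 30° = 3.5 mm, and the
8 mrad scattering over the ≈ 180 mm lever arm, ≈ 2.5 mm).  Null-calibration
runs use 2e5 primaries/spot (≈ 1.9e4 vertices, ≈ 50 eligible voxels).  The
signature-recovery study uses 2e6 primaries/spot: a per-voxel deficit of
ε ≈ 2.5 % passes the k = 2 threshold only for N ≳ 8/ε² ≈ 1.3e4 counts, and
a robust margin needs N of a few 1e4, i.e. ≈ 1.3e6 detected fragments per
distribution — the same order as a real monitored fraction.  These sizes
are derived from that threshold arithmetic, not tuned.

## Numerical choices

* Parallel-line tolerance 1e−9 on the cross-product norm (double precision
  at mm scale); closest-approach via the 2 × 2 normal equations.
* Times are multiples of the 1.5625 ns quantum (exact in binary floating
  point; TSV writes use `repr` so round trips are bit-exact).
* Voxels and depth bins are half-open `[edge, edge + size)`; a vertex on an
  interior edge goes to the higher bin.  Depth-bin edges anchor at z = 0.
* Cluster ordering is canonicalised by (timestamp, centroid), making the
  partition and all downstream tables independent of input row order.
* Degenerate inputs: empty hit lists propagate to empty outputs without
  error; identical front/back points reject the pair with a reason count;
  beam-gap tracks are excluded and counted.

## Known limitations

* The greedy coincidence rule is not globally optimal under heavy pile-up
  (tested bound: ≥ 95 % agreement with the assignment oracle at several
  times physical density).
* The plug-in chance calibration ignores the sampling noise of using
  observed counts as means; at ≥ 100 counts the bias is negligible
  compared with the Monte-Carlo error reported alongside.
* Truth-to-reconstruction pairing uses the front-cluster timestamp as the
  track identity; simultaneous (same-tick) fragments are dropped from
  residual summaries (≲ 0.1 % at the largest sizes used).
* The insert's production-side effect uses the spot centre to decide
  footprint membership; fragments' transport-side absorption uses exact
  per-ray geometry.
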