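# Methods

## Model

The nerve is a homogeneous cylinder (axis = z) of white-matter-like
tissue in air. Each light source is a lens of numerical aperture NA whose
convergence cone — apex at the focal point, half-angle
`asin(NA / n_coupling)`, axis toward the source azimuth — is intersected
with the cylinder wall to produce a mesh of surface contact points; each
point launches photon packets aimed exactly at the focal point
(refraction at the entry interface is deliberately ignored, matching the
convention that the lens is designed to place its focus at the target).
Packets then undergo:

1. **Free paths** drawn from an exponential distribution (see
   *Free-path conventions* below).
2. **Henyey–Greenstein scattering**: deflection θ sampled from
   `p(θ) ∝ (1−g²)/(1+g²−2g cosθ)^{3/2}` over solid angle, azimuth uniform,
   `dot(prev, new) = cosθ` exactly. A `weighted-list` sampling mode
   reproduces a discrete-table construction of the same distribution at
   configurable resolution, and a `paper-literal` direction convention
   reproduces a historical orthogonal-vector construction whose realised
   deflection is `π/2 − θ` with non-uniform azimuth (kept for comparison
   only; the pure-Python engine implements it, the compiled kernel does
   not).
3. **Intensity decay** `I = I₀ exp(−μ_eff t)` with
   `μ_eff = √(3 μₐ (μₐ + μ_s(1−g)))` and `t` the cumulative path. The
   decay-law exponent is printed in some sources with the minus sign
   inside the square root (imaginary as written); the standard
   diffusion-theory decaying exponential is the only physical reading and
   is what we implement. Likewise μₐ is sometimes printed with units
   "mm"; dimensional consistency of μ_eff requires mm⁻¹.
4. **Deposition**: at fixed steps (default 1 µm) along every travelled
   segment, the packet's *remaining intensity* is added to the containing
   voxel (default 10 µm, half-open bins). This is a fluence proxy, not
   absorbed energy per voxel (the convention of absorbed-fraction codes
   such as mcxyz); an absorbed-energy mode is out of scope.
5. **Boundary**: the first crossing of the side wall is found in closed
   form (quadratic); incidence at or above the critical angle
   `asin(n_out/n_in)` (49.25° for 1.32 → 1.0) reflects specularly, the
   packet continues with a fresh free path, and the reflection replaces
   the next scatter; below the critical angle the packet transmits and
   terminates (no Fresnel partial reflection — sub-critical packets leave
   with probability 1). End-cap exits terminate. One description of this
   loop states reflection happens *below* the critical angle; that
   contradicts both the accompanying methods text and total-internal-
   reflection physics, so above-critical reflection is implemented.
6. Transport is time-independent (ChR2 latency ~10 ms dwarfs photon
   transit), so voxels accumulate without time bins.

## Free-path conventions

The phrase defining the step length — "the average scatter distance in
tissue is the light scattering coefficient (μ_s = 43 mm⁻¹)" — is
dimensionally broken (a distance set equal to a rate), so the engine
exposes three readings via `RunConfig.free_path_mean`:

- **`inverse-mu-s`** (default): mean free path `1/μ_s` = 23 µm — standard
  Monte Carlo transport. Under this reading a 0.5 mm radius is ~4
  transport mean free paths (`1/(μ_s(1−g))` = 0.116 mm): the light field
  is fully diffusive, the fluence near a surface source exceeds the
  centre by a factor 40–100 (point-source diffusion with μ_eff·R ≈ 1.5),
  and **no** source count k ≤ 8 produces a positive focal gain. A
  collimated beam is destroyed within ~0.1 mm and its deposited intensity
  decays at the diffusive asymptote (~10 mm⁻¹), not at μ_eff.
- **`mu-s-literal`**: mean free path = 43 mm, the sentence at face value.
  Sub-millimetre tissue is then essentially transparent; a focused source
  produces a sharp ballistic focus and the focal gain is already +170% at
  a single source. This is the regime in which a collimated beam's
  fitted attenuation equals μ_eff to ~0.1% from above, which is what the
  attenuation validation is *for*, so
  `collimated_attenuation_check` defaults to it.
- **`mu-s-per-cm`**: sampling rate `μ_s/10` per mm (mean free path
  0.233 mm), i.e. the coefficient's numeric value read per centimetre —
  the unit convention of the white-matter optical literature (reduced
  scattering ~40–45 cm⁻¹) and of the standard tissue codes. This is the
  only reading that lands in the partially collimated regime where the
  published-style focal-gain behaviour exists: gains rise monotonically
  with source count, cross zero within k = 1..5 on a 1 mm nerve, and
  show diminishing returns beyond. The decay law keeps
  μ_eff = 3.0655 mm⁻¹ (per-mm, as printed) in all three modes; the
  per-cm mode is therefore an *empirical reconstruction* of the regime
  the original results inhabit, not a self-consistent unit system.

The focal-gain sweeps in `scripts/acceptance.py` use `mu-s-per-cm`; all
other defaults, tests and examples use standard transport unless stated.
Under the reconstruction the minimum source count for positive gain on
the canonical 1 mm / NA 0.68 case is **3** (10/10 seeds at the desk-scale
budget), one below the published 4, and the 1.2 mm NA sweep peaks at
NA 0.68 rather than requiring NA ≥ 1: with a fixed per-point ray budget a
wider cone lengthens the slant attenuation path faster than it dilutes
the surface spot. We deliberately did not adjust the free-path rate or
any analysis parameter to force agreement.

## Emission geometry

Surface meshes are built from a symmetric polar grid of cone directions:
`≈√N` concentric rings with populations ∝ sin(polar angle), each ring
offset by half its azimuthal spacing. The set is exactly mirror-symmetric
about the meridional plane (like a real lens spot) while no two rings
share an azimuth — without the offset, every ring's meridional point
projects into the same (x, y) column after the axial summation and
creates an artificial surface hot spot. The default mesh density is 119
contact points per source. NA values at or above 0.95·n_ext are realised
by an immersion droplet at the lens (coupling index `NA/0.95`, capping
the cone half-angle at asin 0.95 ≈ 71.8°); the droplet shapes the entry
cone only — the reflection boundary keeps the true external medium, since
oil at the lens does not bathe the rest of the nerve.

## Analysis

Cross-sections are summed over a 0.6 mm axial window centred on the focal
plane (the internodal spacing of mouse motor axons — ChR2 responds at
nodes of Ranvier, so nodal-scale totals are what matter). The summed
matrix is reduced to per-annulus maxima (default ring width 5 voxels =
50 µm); the "surface" reference is the outermost annulus lying completely
inside the nerve radius, avoiding edge voxels that straddle the boundary.
Focal gain = 100·(innermost − surface)/surface; it is invariant under
uniform grid scaling. Sweeps share one seed across sweep points (common
random numbers) so that monotonicity in k or NA is not swamped by Monte
Carlo noise, and the minimum-source verdict is replicated over 10 seeds.

The collimated validation sends a pencil beam down the axis of a 2 mm
diameter, 1.2 mm long phantom of the same tissue and log-linearly fits
each transverse slice's total deposited intensity over 1 mm of depth
(≥5 non-empty bins required). With scattering negligible over the
phantom, the fit returns μ_eff exactly (the per-slab sample sums form an
exact geometric progression); with the literal free paths it returns
μ_eff within ~0.2% from above, because the rare scattered packets arrive
with t > z.

The energy-scale utility converts packet counts to an estimated per-voxel
initialised power: total power = per-photon power × photons per packet ×
packets, spread over the illuminated surface area and multiplied by the
voxel footprint. Its defaults reproduce a published worked example
(3.3617×10⁻²² mW/photon, 10⁶ photons/packet, 0.6249 mm², 10⁻¹⁰ mm²
voxels → 6.916×10⁻²⁰ mW per illuminated voxel) whose printed constant
chain does not self-check (3.3617e−22 × 1.19e12 = 4.000e−10, not the
printed 4.3217e−10; 2.2667e−3 meV is not the photon energy at 465 nm), so
the printed intermediate total power is accepted as an explicit override
rather than re-derived.

## Numerical choices

- Desk-scale defaults: 10 µm voxels, 1 µm deposition steps, 169 rays per
  mesh point (≈2×10⁴ per source). The historical 10 nm voxels/steps are
  ~10¹⁵ voxels/mm³ and days of CPU; the figures of merit are ratios of
  ring maxima and are insensitive to resolution above the ring width.
- The compiled kernel and the pure-Python reference engine consume the
  identical MT19937 stream (numba's `np.random.seed` reproduces numpy's
  legacy `RandomState`), so they agree event-for-event; the kernel
  attenuates per segment by a multiplicative per-step factor (one `exp`
  per segment), so voxel values agree to round-off rather than bitwise.
  Runs are bit-reproducible per engine for a fixed seed.
- Voxels are half-open (`floor((x − origin)/voxel)`); samples on the
  grid's upper faces are counted as skipped, not deposited.
- After a wall reflection the packet is pulled inward by a relative
  10⁻¹² to keep the next boundary solve well-posed.
- Packets are force-terminated after 10⁶ events (never reached in
  practice; there is no roulette and no intensity cutoff).
- Sampling points along a segment use `ceil(length/step − 10⁻⁹)` samples
  at `k·step` from the segment start, i.e. the half-open interval
  [start, end).
- The cylinder-crossing quadratic takes the larger root; launches exactly
  on the wall (c ≈ 0) are therefore handled without special-casing.

## What the simulations do and do not show

All inputs are synthetic: the generator *is* the study design (cylinder,
homogeneous constants, cardinal source placement, axis-centred focus).
Real nerves are heterogeneous (perineurium, fascicle structure),
wavelength-dispersive and not perfectly cylindrical; the model ignores
Fresnel partial reflection, entry refraction, polarisation and
time-of-flight, and packet intensity is a deterministic function of path
length rather than per-photon energy tracking. Passing tests therefore
validate the transport/analysis machinery and the internal consistency
of the design conclusions, not their in vivo accuracy. The minimum-source
and NA-threshold numbers in particular are regime-dependent (see
*Free-path conventions*): under fully standard transport with the stated
constants, no circumferential arrangement of sub-threshold focused
sources concentrates light at a 0.5 mm deep target — a conclusion that
itself matters for instrument design at these optical constants.
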