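# Methods

## Geometry and optical properties

The head is modeled as laterally infinite plane-parallel layers with z = 0
at the scalp surface and z increasing downward, all lengths in cm (the
config I/O also accepts mm with an explicit `units` key — the internal cm
convention matches the cm⁻¹ coefficients and avoids silent 10× errors).
Two preset stacks encode the tissue optical parameters at the excitation
(785 nm) and emission (1100 nm) wavelengths; they are bundled as YAML
(`mousehead_785`, `mousehead_1100`) and reproduced bit-exactly by
`default_stack`. Notes on individual entries:

* CSF is a clear fluid: µs = 0 and g = 1 by definition. g is inert when
  nothing scatters; we keep it as a no-op marker. With µs = 0 an
  interaction, when one occurs at all (mean free path 10 cm at 785 nm),
  deposits the full packet weight — which is the correct limit of the
  µa/µt rule.
* The cortex is effectively semi-infinite. We give it a 1 cm substrate;
  packets crossing its bottom are terminated and booked as transmitted.
  Quantum-dot planes at 0.4/0.8/1.4/2.0 mm below the scalp correspond to
  0/0.4/1.0/1.6 mm of cortex path below the cortical surface at 0.4 mm.
* The 1100 nm stack has a 0.1 mm air layer (n = 1, µs = 0) above the skin
  at z ∈ [−0.1, 0] mm; emission exit records are taken at its top. The
  785 nm stack has no air row; the ambient above the skin is air with
  n = 1 and the entry loss is the normal-incidence specular reflectance
  ((1−1.37)/(1+1.37))² = 2.44%.
* A depth exactly on a boundary belongs to the layer below (deterministic
  tie-break, consistent with z increasing downward).

## Transport

Weighted photon packets follow the standard multi-layer hop/drop/spin
cycle:

* **hop** — dimensionless step `-ln(ξ)` converted by the local µt; the
  unused residual carries across boundaries scaled by the next layer's µt.
  Layers with µt = 0 are traversed ballistically.
* **drop** — fraction µa/µt of the weight deposited at the interaction
  site into the (r, z) grid (default dr = dz = 0.05 mm, 100 radial bins,
  grid spanning the stack; off-grid absorption goes to a scalar overflow).
* **spin** — azimuth uniform on [0, 2π), polar deflection from the
  Henyey–Greenstein inverse CDF with the layer's g; |g| = 1 is handled as
  deterministic forward/backward. Direction cosines are renormalised
  whenever drift exceeds 1e-12.
* **boundary** — default `fresnel_full`: the unpolarized Fresnel
  reflectance at the actual incidence angle decides
  reflect-versus-transmit probabilistically, with Snell refraction on
  transmission and total internal reflection beyond the critical angle.
  The alternative `specular_split` applies the boundary rules literally as
  printed: total internal reflection above the critical angle, otherwise
  deterministic transmission with the weight multiplied by (1 − R) at the
  normal-incidence reflectance. The reflected fraction R·W has nowhere to
  go in that scheme, so it is booked to a dedicated `boundary_lost`
  ledger slot. The two modes agree in expectation at normal incidence.
  In both modes we read the transmitted intensity as I₀·(1 − R): the
  literal transmitted-equals-I₀·R reading does not conserve energy.
* **termination** — Russian roulette below weight 1e-4 with survival
  probability 1/10 and weight ×10 (standard multi-layer-code defaults;
  the source publication is silent on termination, and the small printed
  acceptance counts at depth are sensitive to this knob — treat absolute
  counts as termination-rule dependent).

Every run closes a weight ledger: specular + absorbed (grid + overflow) +
escaped(top) + transmitted(bottom) + roulette-net + boundary-lost =
launched weight, to ≤1e-6 relative — exactly, not just in expectation,
because roulette is booked as the *net* weight it removed (kills minus
survival boosts). Identical stack + source + seed + mode reproduce
bit-identical grids, ledgers and exit records; one integer seed expands to
per-stage child seeds through `numpy.random.SeedSequence`, so the
excitation and each emission stage are independently reproducible.

Exit records keep the exit radius, the polar angle *in the ambient medium
after the final refraction* (that is what an objective above the animal
sees) and the residual weight, for both surfaces, plus the scattering
count, so detector filters can be applied after the fact.

## Excitation efficiency

The dose at a quantum-dot plane is the summed weight of downward plane
crossings within a 0.05 mm-radius on-axis disc (every crossing by
default; a first-crossing-only flag exists and differs by under 3% here),
per launched photon and per disc area. Efficiencies are quoted relative
to the *incident* post-specular beam concentrated in the same disc. This
is the published normalisation: the printed reference intensity at the
cortical surface, ≈3100 cm⁻², equals (1 − R_sp)/(π·(0.1 mm)²) — the
undiminished incident beam — and the quantum dot there inherits weight 1
by definition. A measured crossing score at 0.4 mm is several-fold lower
than that reference (the skin and skull scatter most of the beam off
axis), so the two relative columns in the efficiency table differ:
`relative_to_incident` matches the published convention;
`relative_to_shallowest` is the self-referenced measured ratio.

## Emission sources

Physically, quantum dots re-emit isotropically, and
`IsotropicPointSource` (the package default) samples the unit sphere
uniformly — its 15° acceptance statistics match the spherical-cap solid
angle analytically in a transparent stack, which the tests assert.

The published depth-study figures, however, are quantitatively
inconsistent with an isotropic source: the reported 15°-cone acceptance
of 3.1×10⁵ per 10⁶ photons at 0.4 mm exceeds the isotropic cap fraction
(1.7%) by an order of magnitude even before attenuation, and the reported
radial section weights *fall* with radius, which no smooth isotropic
field can do against linearly growing annulus area. Both observations are
reproduced by a zenith angle drawn from the Henyey–Greenstein
distribution (g of the source layer) about the upward normal with a
uniform azimuth — i.e. the scattering sampler reused as the source
sampler. `ForwardPointSource` implements that variant; the published-protocol
presets (`FocusStudyConfig`, the acceptance script) use it so the figures
are comparable, and the methods-level caveat is that *absolute* emission
numbers should be read under that convention, not as isotropic physics.

Detected profiles bin the accepted exit radii in 0.05 mm sections and
report per-section counts, weight sums, per-annulus-area intensity, and
fractions of the first section computed on the weight sums (the
convention the published section ratios use).

Even under the forward source, a faithful weighted transport retains a
multiply-scattered pedestal that the published profiles lack: our 0.8 mm
section ratios are ≈220% (second/first) against the printed 55%. The
printed values coincide with the *unscattered* transport of the forward
source; no physically defensible termination or filtering rule we tested
(boundary modes, scatter-count cutoffs, per-area versus per-bin
normalisation, exit radius at the skin versus above the air layer)
removes the diffuse component while keeping the 2.0 mm profile non-empty.
The radial *trends* — profiles broadening monotonically with depth, the
accepted yield collapsing by orders of magnitude — are robust to all of
these conventions and carry the focus conclusion.

## Detection optics and the focus study

The acceptance cone is arcsin(NA/n) (14.48° for NA 0.25 in air); the
published preset pins it to the stated 15°, and both are available.
`collect` is idempotent and order-independent, and the accepted yield is
monotone in the half-angle. The Berek depth of field uses
DOF = n·λ/(2·NA²) + n·e/(M·NA); the magnification M and the camera-side
resolvable distance e are instrument parameters with no published values,
so defaults (M = 1, e = 20 µm) make no claim to reproduce the printed
0.3 mm figure — the formula is tested term by term instead.

`simulate_focus_study` shares one excitation run across depths, runs one
emission stage per depth, and recommends the depth maximizing the
accepted weight. Under every convention we tested this is the cortical
surface at 0.4 mm, with the accepted yield strictly decreasing in depth.

## Problem sizes and numerics

The published protocol is 10⁶ photons per stage; the acceptance script
uses exactly that (about two minutes on one core). The test suite runs
the same pipelines at 1.5×10⁵–5×10⁵ photons with correspondingly wider
Monte Carlo bands, sizes chosen so the whole suite finishes in a few
minutes. Statistical assertions use 3σ bands computed from the binomial
or empirical variance. Degenerate inputs are defined, not errors: an
empty fluence grid normalises to zeros, an empty exit set collects to an
all-zero profile, and a single-depth focus study recommends its only
candidate.

## Known limitations

* Flat layers only: the real mouse head is curved, and the published
  workflow explicitly flags the non-flat surface as an imaging caveat.
* No polarization, no time-resolved transport, no wavelength
  interpolation between the two tabulated windows, no quantum-dot
  photophysics (quantum yield, spectra, saturation) — inherited weights
  carry all depth dependence.
* Absolute detector counts depend on the termination rule and on the
  forward-source convention above; ratios and trends are the reliable
  outputs.
* The (r, z) grid truncates at r = 5 mm; wide-angle absorption lands in
  the overflow scalar, so radial tails of the fluence map beyond the grid
  are not resolved.
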