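# Methods

## Scope and model

`icescreen` characterizes single-particle cryoEM grid holes from
tomographic volumes.  The physical picture is a thin film of vitreous ice
spanning a grid hole, bounded by two air-water interfaces (AWIs).  During
the seconds between sample application and plunge-freezing, most particles
diffuse to an AWI and adsorb, forming one or two particle layers a few
nanometres inside each interface; the film is rarely flat (it is usually
thinner at the hole centre) and rarely normal to the beam (layer tilts of
a few degrees are the norm).  Each of these facts has measurable
consequences for collection: layer counts and saturation set the number of
non-overlapping particles per micrograph, ice thickness sets signal,
adsorption can restrict orientations, and tilts plus double layers
dephase whole-image CTF correction.

Each interface is modelled as

    z(x, y) = a x + b y + c + q [(x-x0)^2 + (y-y0)^2],

a tilted plane with an optional radially quadratic bowl about the hole
centre.  The beam axis is z, the *bottom* interface has the lower z, all
analysis quantities are nanometres (the voxel size, in ångströms, enters
only at the MRC boundary), and voxel centres sit at `(index + 0.5) ×
voxel size`.  Interface tilt is the angle between the plane normal (the
quadratic term excluded) and the beam axis, reported in `[0°, 90°)`.

Curvature is classified per interface by comparing its mean de-tilted
height over a centre disc (radius 20% of the hole radius) with an edge
annulus nominally 100 nm inside the hole rim (clipped to 60% of the hole
radius for scaled-down holes): within ±5 nm — the nominal thickness
measurement error — the interface is flat (C2); bulging away from the ice
is C1; recessed is C3, demoted to C4 when the minimum centre thickness is
below the particle minor axis (whole particles no longer fit there).  The
"centre" delimitation is this package's convention; the survey the
taxonomy comes from delimits it visually.

## Interface location

Three locators mirror how interfaces are found in practice:

* **gradient** — the density step between air and ice.  The field of view
  is tiled into 16×16-column patches; each patch's median column profile
  is thresholded halfway between its air and ice levels, the densest
  contiguous below-half run is taken as the local slab, and the two
  crossings are interpolated to sub-voxel z.  The patch points are fitted
  with the surface model above (least squares, one trimmed refit pass at
  2.5×RMS to reject patches corrupted by particles or contamination).
  Median profiles matter: particle layers covering ~50% of the area would
  bias mean profiles by several nanometres.
* **contamination** — surface ice contamination always sits on the air
  side of an interface, so each blob's face nearest the vitreous ice marks
  the interface.  Blobs are found by multi-scale blob detection; each
  anchor is refined by walking the blob's column profile toward the ice
  until it recovers halfway from the blob level to the ice level.  At
  least 3 blobs per surface are required for the plane fit.
* **particle_layer** — a sequestered particle layer always corresponds to
  an AWI.  Detected centroids are refined in z against the nearby density
  step (parabolic interpolation at the column minimum), tested for
  one-versus-two layers by the residual of a single plane fit (threshold:
  half the particle diameter), fitted per layer, and the interface placed
  one layer-offset outside the layer plane.  Sides without a layer fall
  back to the gradient surface.

When more than two boundary candidates appear in the global z profile,
the outermost pair enclosing the densest slab is kept and the full scored
candidate list is attached to the returned surfaces; fewer than two
boundaries raises an error carrying the candidates.

## Particle detection and layer statistics

Particles are detected as maxima of a scale-normalized
Laplacian-of-Gaussian score over 3 scales spanning the requested diameter
range, thresholded adaptively at median + 10 MAD-sigmas of the response
(absolute floor 0.02).  Two additions matter in this geometry: (i) the
air–ice step also excites the LoG, but its response is antisymmetric
along z, so candidates whose two z-probes at one radius out do not sum to
a clear darkness excess are rejected; (ii) for elongated particles the
response forms a ridge along the long axis whose maxima wander, so each
detection is re-centred twice on the local response centre of mass.
Detections closer than 0.7× the (mean) diameter are suppressed,
strongest first.

Distances from particle centre to each surface are measured along z (the
slice-based convention; surface-normal distance is available).  A
particle within the adsorption cutoff — default 10 nm, reflecting the
observed 5–10 nm layer offsets — joins that side's layer.  Layer
saturation is `100 × count × footprint / (area × 0.9069)`, i.e. relative
to hexagonal close packing, capped at 100%.  Layer tilt is the fitted
layer-plane angle with one trimmed refit pass.  Projection overlap marks
a particle overlapped when any other centre lies within one diameter in
(x, y); the complement is the uniquely identifiable count.

Behavior codes: B1 non-adsorbed; B2 adsorbed without preferred
orientation; B3 adsorbed with preferred orientation — assigned when the
on-sphere mode clustering (average linkage on angular distance, cut at
2×15° bandwidth, modes must be compact within the bandwidth and jointly
hold ≥80% of the mass) finds concentrated modes, or when the resultant
length exceeds 0.6.  B4/B5 (denaturation) are only assignable from
ground-truth or manual fragment annotation; automated detection is out of
scope because fragments, surfactant films and clean interfaces are not
reliably distinguishable in this kind of data.

Orientation dispersion classes map the resultant length R (axial
concentration `(3λmax−1)/2` for sign-ambiguous axes) to none (<0.2), some
(0.2–0.6), strong (>0.6); the thresholds are this package's quantitative
stand-in for a visual yes/some/no judgement and are configurable.

`tilt_expanded_coverage` quantifies why tilted interfaces help
preferentially oriented samples: each preferred direction, replicated
under the particle's cyclic symmetry about z, sweeps an annulus of
angular radius equal to each tilt (in-plane rotation marginalized), and
the covered fraction of the projection hemisphere is integrated on an
equal-area Fibonacci grid (default 8000 points; agrees with closed-form
cap/band areas to well under 2%).  Coverage is monotone in bandwidth and
in the tilt set; in the symmetry order it is monotone along nested
subgroup chains (C1 ⊂ C2 ⊂ C4 …) but not between incommensurate orders,
which is a property of the geometry, not of the implementation.

## CTF defocus-error budgets

The usable resolution under a defocus error dz is taken at the spatial
frequency where two CTFs differing by dz are 90° out of phase:
`π λ dz s² = π/2`, so `d = 1/s = √(2 λ dz)` — independent of spherical
aberration and of the common defocus, which cancel in the phase
difference (verified numerically over a frequency grid).  Wavelength
follows the relativistic relation `λ = 12.2639/√(V(1+0.97845e−6 V))`.
The worked example — a field 4096 px wide at 1 Å/px tilted 10°, so the
worst particle sits 2048·tan 10° = 361 Å off the estimated defocus —
gives 3.77 Å at 300 kV, i.e. a limit of about 4 Å.  Two companion
figures sometimes quoted for bilayer offsets (about 2.5 Å for a 10 nm
offset and about 6 Å for 50 nm) are mutually inconsistent under any
single voltage-plus-criterion pair (at 300 kV the criterion gives 1.98 Å
and 4.4 Å); the calculators report the closed form and do not tune
constants to force agreement.  `dz = 0` is reported as the explicit
sentinel "no limit", never as infinity.  The cosine dose scheme
`dose(θ) = dose₀/cos θ` totals 70.2 e⁻/Å² for 2.0 e⁻/Å² at −45°…45° in
3° steps.

## Survey aggregation

The packaged CSV transcribes the screening survey's two summary tables
(46 samples; one sample appears only in the behavior table and carries no
thickness data).  Aggregation conventions: thickness uses the minimum of
a printed range (tilt uses the midpoint); the SD is population (N) by
default with a sample (N−1) flag — the two round identically for the
quantities checked; every mean carries a propagated measurement error
`δq = √(Σδx²)/N` (5 nm per thickness measurement, 1° per tilt) combined
with the SD in quadrature, so the combined dispersion always dominates
the SD.  Preparation families are string predicates over the grid type
(Spotiton + gold/carbon; otherwise conventional carbon/gold); affinity
overlays are flagged separately but aggregate with their substrate
family.  Intentionally-thick preparations are excluded from centre
statistics (they were deliberately made unrepresentative of centre
thickness) and retained at edges.  Under these rules the fixture
reproduces, to the printed precision: gold-Spotiton centre 30 ± 13 nm
(N=11) and edge 61 nm (N=4), carbon-Spotiton edge 107 nm,
carbon-conventional edge 99 nm, and layer tilts 4.8 ± 3.1° (N=89 centre)
and 6.9 ± 3.5° (N=61 edge).  Group means whose printed inclusion sets
cannot be reconstructed from the tables (e.g. carbon-Spotiton centre) are
treated as consistency bands only.

Classification: a sample is *near-ideal* at a location when the minimum
ice thickness is under 100 nm, the layer token admits a single
non-overlapping layer (tokens 1, 1–2, 0–1, 0–2), and preferred
orientation is absent or mild; *ideal* additionally requires evidence of
no particle–interface interaction (a transcription flag — this fact is
not derivable from the numeric columns).  Missing fields give
*indeterminate*, never a guess.

## Collection advisor

The recommendation cascade, in order: (1) if the radial mean thickness
profile has a band at or below the particle minor axis plus 20 nm of
clearance (and at least one particle diameter), recommend collecting a
distance d in from the hole edge where that band begins — on real holes
typically 100–500 nm; (2) otherwise a single layer with strong preferred
orientation calls for tilted collection, with tilts chosen greedily to
maximize tilt-expanded coverage; (3) otherwise collection proceeds with
caveats carrying the bilayer midway-defocus resolution limit, or the hole
is rejected when the ice exceeds 100 nm everywhere and no layer reaches
30% saturation.  The 20 nm clearance and 100 nm ceiling are exposed as
parameters.  Every recommendation lists the rules that fired.

## Synthetic phantoms

The phantom generator is the package's test bed: it renders a hole
volume from the same surface model the analysis fits, so every
downstream quantity has exact ground truth.  It emulates: two bounding
interfaces with per-surface curvature class and centre/edge offsets
(quadratic in radius, clamped at the rim), a rigid tilt applied to both
surfaces (0–16° is the observed range); particle layers at a configurable
offset (0–10 nm) placed by dart throwing with minimum spacing equal to
the particle footprint; non-adsorbed particles uniform in the mid-ice
with half-diameter clearance; orientation models (uniform or von
Mises–Fisher mixtures) encoded in the long axis of soft-edged ellipsoids;
surface contamination spheres tangent to the air side; small fragment
debris at the interfaces; Gaussian noise; and an optional missing wedge
(Fourier coefficients zeroed outside the retained tilt range about the
x tilt axis).  Densities are additive constants — air 0, ice −0.3,
particles −0.7 further, contamination −0.9 — dark-is-dense, as in
tomographic reconstructions; absolute contrast is a free choice since
only ratios matter, and "SNR" below means particle contrast over noise
sigma.  Requests that exceed the saturation cap or the packing bound
raise an explicit infeasibility error rather than silently truncating.
All randomness flows from one integer seed; identical configurations are
bit-identical.

Default conditions follow the survey's typical observations: a 256³
volume at 8 Å voxels (a tomogram binned by four from ~2 Å pixels),
hole radius 90 nm scaled to fit the field of view, C3/C3 profiles with
30 nm centre and 70 nm edge thickness, 5° tilt, 12 nm particles with 90%
adsorbed at 5 nm offset split evenly between the interfaces, and noise
at particle SNR 3.  Unit tests use 160×192² volumes for speed; the
recovery suite runs the full 256³ size.

What the phantoms do **not** emulate — hence what passing tests do not
show about real tomograms: reconstruction artefacts beyond the missing
wedge (ray artefacts, CTF modulation, dose-dependent blurring),
structured particle densities and true SO(3) orientations (an ellipsoid
axis only), denatured protein films, substrate layers (affinity samples
exist in the survey fixture only), and hole-rim/carbon signal.  The
measured recovery error bands (thickness within 5 nm, tilts within 1°,
adsorbed fraction within ±0.05 at SNR 3) therefore bound the method's
geometric error, not its robustness to every real-world artefact.  With
a full ±45° missing wedge the gradient locator degrades by construction
(a horizontal interface's spectral energy lies inside the wedge); on such
data the contamination or particle-layer locators are the appropriate
choice, which is also how the original screening was done.

## Numerical choices and degenerate inputs

Sub-voxel boundary crossings by linear interpolation of the thresholded
profile; trimmed refits at 2.5×RMS wherever outliers are structural
(patch points, layer planes); crossing surfaces reported as C4-degenerate
with zeroed thickness rather than raised; empty detection results are
valid; adsorbed fraction is an exact rational; "no limit" is a sentinel.
Poisson-disc placement rejects after 40×n failed darts and names the
violated bound.  The hexagonal packing constant 0.9069 defines 100%
saturation.

## Problem sizes

Unit tests run on 160×192×192 phantoms (~10 s each to generate and
analyse); the recovery suite runs 20 phantoms at the default 256³ in
under 5 minutes; the acceptance script runs 5 recovery seeds plus the
survey and CTF calculations in about a minute.  These sizes were chosen
so the full suite exercises the pipeline at realistic binned-tomogram
dimensions while staying convenient to run locally.
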