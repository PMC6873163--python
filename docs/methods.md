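# Methods

`synquant` quantifies putative synapses on individual neurons from
multi-channel 3D fluorescence stacks. The intended experiment is a
sparsely labelled neocortical pyramidal neuron imaged by confocal
microscopy in four channels: a cytosolic cell fill delineating the
target cell, a postsynaptically targeted punctate label marking
candidate synapses, a saturated presynaptic label of one interneuron
class (PV, SST or VIP) per specimen, and optionally an active-zone
marker (bassoon-style immunolabel) used to validate puncta as synaptic.
All geometry is computed in physical micrometres on the anisotropic
voxel grid (default 0.32 x 0.13 x 0.13 um in z, y, x; axis order
(z, y, x) everywhere).

## Detection and segmentation

**Puncta.** The puncta (or marker) channel is background-subtracted with
a Gaussian background whose sigma is 3x the expected object diameter,
then thresholded automatically: Otsu's threshold on the residual, but
never below five robust noise sigmas (1.4826 x MAD of the signed
residual). The noise floor matters because Otsu alone splits the noise
distribution when foreground occupies a tiny volume fraction.
26-connected components strictly larger than 3 voxels are retained —
"larger than three voxels" is read as >= 4 — and passed through
split-touching.

**Split-touching.** Merged blobs are divided by marker-controlled
watershed on the inverted smoothed intensity. Markers are intensity
maxima with (i) relative prominence of at least 10% of the component
peak (h-maxima; shallow partial-volume ripple cannot seed a split),
(ii) connected maximum plateaus collapsed to a single candidate, and
(iii) pairwise physical separation of at least the split diameter
(0.5 um for puncta, 1 um for neurites); closer maxima merge into the
brighter one. The separation test uses sub-voxel maximum positions
(intensity-weighted centroid of the peak neighbourhood): with a
0.32 um axial step, voxel-quantized positions can shrink a genuinely
resolvable pair below the split diameter. Splitting partitions the voxel set exactly. The
commercial algorithm this emulates is proprietary; equivalence is
functional, not bit-level.

**Cell surface.** The cell-fill channel is Otsu-thresholded, reduced to
its largest 26-connected component and lightly closed. The signed
distance field combines two anisotropic Euclidean distance transforms
(positive outside, zero on the one-voxel surface shell, negative
inside). The soma submask is the largest inscribed sphere grown from a
soma hint (or the deepest interior voxel), extended by one voxel
diagonal — half for shell quantization, half for the sub-voxel offset
of the depth-map centre — so the submask reaches its own surface
voxels on every side; dendrites are the remainder of the mask. Soma surface area is measured on an
isosurface mesh (marching cubes at the 0.5 level with physical
spacing); voxel-face counting, which overestimates curved surfaces by
tens of percent, is used only for masks too small to mesh.

**Presynaptic neurites.** Per z-block (two blocks handle axial signal
drop-off by thresholding superficial and deep sections separately), the
presynaptic channel is background-subtracted, thresholded, reduced to
26-connected components of at least 6 voxels and split at 1 um with
prominence 0.3 — thin axons sampled at sub-voxel thickness carry strong
intensity ripple along their length that must not fragment them.
Surface voxels are component voxels with a 6-neighbour outside the
component.

## Distance rules

All decisions are Euclidean in physical um. Comparison conventions
follow the wording they implement: "within 0.5 um" and the 0.15 um
input rule are inclusive; "<1 um" (dendritic association) and
"<0.25 um" (marker alignment) are strict.

* **Membrane association** uses the punctum *edge*: the minimum over
  its voxels of the distance-transform distance to the soma or dendrite
  submask. A punctum is cytosolic (excluded) when its entire voxel set
  lies more than 0.5 um below the cell surface; somatic when its edge
  is within 0.5 um of the soma submask; else dendritic when strictly
  closer than 1 um to a dendrite, attributed to the nearest skeleton
  segment; else unassociated. Somatic wins at the perisomatic junction,
  where the two compartments are pooled downstream anyway.
* **Input assignment** uses the spot *centroid* against the
  reconstructed neurite *edge*: the distance to the nearest point of a
  surface voxel's physical extent (an axis-aligned box). Measuring to
  voxel centres instead would add up to half the 0.32 um axial voxel to
  every distance — larger than the 0.15 um rule itself. A spot takes
  the type of the globally nearest neurite within 0.15 um; exact
  cross-type ties are flagged ambiguous and resolved deterministically
  by (distance, type name). The edge-vs-centroid asymmetry between the
  two rules is deliberate and preserved from the workflow being
  reproduced.
* **Soma appositions** (the two-feature proxy count): per neurite
  object, its surface voxels within the apposition threshold of the
  soma are grouped into 26-connected patches after one dilation that
  bridges single-voxel gaps; each patch is one putative contact. The
  apposition threshold is not independently specified by the source
  workflow; the default 0.15 um mirrors the input rule and is exposed
  in the config.
* **Marker alignment** is directional: a query punctum aligns when its
  centroid lies strictly within 0.25 um of any voxel of a reference
  punctum (or reference point).

A brute-force all-pairs oracle over voxel centres/extents defines
correctness for every one of these decisions; the KD-tree and
distance-transform implementations are tested against it on randomized
small scenes.

## Quantification

Per-segment dendritic density is count / arc length (puncta/um) over
the centrifugally branch-ordered segments of the supplied SWC skeleton
(stems leaving the soma are 1st order; the order increments at every
branch point). The cell-level dendritic summary is the mean of
per-segment densities excluding the soma and the 1st-order apical
segment — a distinct, unusually synapse-dense perisomatic compartment —
with the median substituted when the per-segment densities fail
Shapiro-Wilk normality at p < 0.05. Somatic density is the somatic
spot count divided by the mesh surface area of the soma submask.
Input proportions are percentages of total puncta per compartment bin:
perisomatic (soma + 1st-order apical), higher-order apical (3rd + 4th)
and higher-order basal (3rd + 4th), plus a full per-order table.
Contact overestimation is reported per cell and input type as
(surface - puncta contacts) and as a percent error rate with the
puncta-contact count as denominator (undefined and flagged when it is
zero); group statistics are means +/- SEM of per-cell values, never
ratios of group means. Detection against ground truth uses greedy
one-to-one matching by increasing centroid distance at 0.3 um
tolerance; greedy matching is a 2-approximation in adversarial
geometry but is exact at the hard-core synapse spacings the simulator
produces, which the tests verify against exhaustive matching.

## The synthetic-scene simulator

Because no raw image data are available for the source experiments, the
package bundles a simulator that generates scenes with the statistical
structure the analysis assumes, plus the rendered noisy stacks.

**Geometry.** A deterministic branched pyramidal-like skeleton: a soma
sphere (default radius 4 um), one apical stem toward the pia that
bifurcates into 2nd-4th order branches, and three basal stems of which
one branches to 4th order (~100 um of dendrite in a 33 x 33 x 20 um
stack). Dendritic stems attach to anchor nodes 0.8 um beyond the soma
sphere, so the perisomatic collar — where membrane association is
ambiguous by construction — carries no dendritic arc length.

**Truth sampling.** Dendritic synapse counts per segment are
Poisson(density x arc length) and somatic counts
Poisson(density x 4 pi r^2). Somatic synapses sit on the soma sphere;
dendritic synapses occupy a spine-length band 0.05-0.6 um beyond the
local shaft radius — spines are not modelled as explicit necks and
heads, but the radial spread they produce is what lets several puncta
per micron coexist, and it keeps every synapse inside the 1 um capture
radius used for membrane association. All positions obey a hard-core
minimum separation of 0.7 um (distinct ~0.5 um puncta cannot overlap;
the hard core also makes the 0.5 um split-touching diameter a
meaningful resolvability scale). Because plain dart throwing jams well
below the nominal density on short thin branches, each point searches
stratified ring angles at its sampled arc position and falls back to a
fine (arc, angle, reach) grid scan, so the realized density stays
within about a percent of the Poisson target. Each synapse
draws an input type from the configured fractions; each typed synapse
gets a presynaptic tube of its type routed tangentially through a
contact point 0.03 um from it, and distractor tubes graze the soma at
0.05 um without any synapse. Markers are jittered copies of synapse
positions (Gaussian sigma, truncated at 3 sigma) except a missed
fraction.

**Rendering.** Cell and tubes are rasterized as capsule unions; puncta
and markers as isotropic Gaussian blobs (sigma 0.15 um) with log-normal
amplitude spread. Channels are blurred with a separable anisotropic
Gaussian PSF, then Poisson shot noise at a photon scale and additive
Gaussian read noise are applied over a uniform background. One master
seed drives per-stage sub-streams, so scenes and stacks are bitwise
reproducible.

**Defaults and rationale.**

| parameter | default | why |
|---|---|---|
| dendritic density | 2.3 puncta/um | observed mean for L2/3 pyramidal dendrites |
| somatic density | 0.35 puncta/um^2 | ~260 somatic puncta on a ~750 um^2 soma |
| input fractions | PV 0.25, SST 0.05, VIP 0.02 | observed somatic assignment proportions |
| min separation | 0.7 um | non-overlapping ~0.5 um puncta + cleft margin |
| neurite radius | 0.25 um | thin cortical axon |
| marker jitter / miss | 0.05 um / 0.15 | sub-voxel apposition; ~85% alignment rates |
| emission sigma | 0.15 um | diffraction-limited punctum (~0.5 um object) |
| PSF sigma (z, y, x) | 0.4, 0.1, 0.1 um | confocal at NA ~1.4, no vendor model |
| photon scale / read noise | 300 / 0.01 | peak SNR ~15 for a median punctum |
| amplitude spread | log-normal sigma 0.25 | expression heterogeneity |
| distractors | 4 | non-synaptic passers-by near the soma |

**What the simulator does not emulate:** dendritic spines as explicit
necks and heads (puncta are placed within the capture band instead),
axonal morphology beyond near-straight perturbed tubes, cytosolic label
pools, tissue autofluorescence, bleaching, chromatic aberration, or
depth-dependent attenuation beyond a linear z-gain option used to
exercise the two-block neurite path. Passing round-trip tests therefore
demonstrates the correctness of the measurement logic under the stated
noise model, not performance on real tissue.

## Validation scenes and a known optical limitation

The bundled validation runs use two regimes. The *ideal-optics* scene
(no PSF, no noise, uniform amplitudes, ~200 synapses on a 64 x 256 x
256 stack) isolates the detection, splitting, assignment and counting
logic, where the pipeline is expected to be exact. The
*moderate-SNR* scenes keep shot noise (photon scale 300), read noise
and amplitude heterogeneity, and are used for density-recovery runs
(five seeds) and the contact-counting comparisons; problem sizes
(48-64 z-planes, 160-256 lateral pixels, one simulated cell per seed)
were chosen so a full validation pass completes on a single CPU core in
a few minutes.

Under the full default PSF the simulator exposes a genuine physical
limitation rather than a software one: two synapses separated mostly
along z by less than roughly 2x the axial blur merge into a single
intensity maximum that split-touching cannot divide, so detection
undercounts at high densities. Real diffraction-limited confocal data
share exactly this ambiguity — apparent and true contacts cannot be
perfectly differentiated — which is why validation of the measurement
logic uses ideal optics and why axial resolution, not the algorithm, is
the binding constraint at 2+ puncta/um.

## Degenerate inputs and tie-breaks

Empty channels yield empty object lists (not errors); an all-background
cell-fill channel is an error. Zero-area soma and zero-length segments
are errors. Rates with empty denominators (alignment of an empty query
set, error rate at zero puncta contacts, proportions of an empty bin)
are flagged undefined (None/NaN) rather than coerced to zero.
Cross-type distance ties are resolved by type name after the distance;
equal-intensity maximum plateaus take the voxel nearest the plateau
centroid. Matching ties in detection scoring follow ascending distance
with a stable sort.
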