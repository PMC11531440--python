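# Methods

This note documents the models, parameter choices and numerical decisions
behind `lcn`, in the package's own terms. All defaults live in
`lcn.synth.GeneratorParams` and `lcn.extract.ExtractionConfig` and are fully
configurable; what follows explains why the defaults are what they are.

## Synthetic phantom model

The generator draws a ground-truthed spatial network and voxelizes it into
a confocal-like image stack. It is designed so that the *statistical*
targets of the analysis are realized and known exactly, not to be a
biophysical simulation of osteocyte biology.

**Lacunae.** Ellipsoids with fixed axis ratios 1 : 0.54 : 0.34 (rod-like:
stretch 1 − c/a ≈ 0.66, oblateness 2(b−c)/(a−c) − 1 ≈ −0.40, matching the
measured rod-like character of osteocyte lacunae) and mean volume 350 µm³,
linear size jittered uniformly ±20 %. Placement is a hard-core point
process (minimum separation twice the mean long semi-axis) at density
3·10⁻⁵ µm⁻³, within the measured range for murine cortical bone; the hard
core prevents merged lacunae that would make morphometry ill-defined. In
the ordered region the long axis is drawn within ±20° of the alignment
axis, elsewhere isotropically.

**Junctions and degrees.** Junction counts are Poisson with density
0.05 µm⁻³ (the measured node density scale). Positions are dart-thrown
with a hard-core minimum separation of 1.8 µm: branch points closer than
the resolvable branch-segment scale do not occur as distinct nodes in
skeleton-based analyses, and a pure Poisson process (mean nearest-neighbor
distance ≈ 1.5 µm, four voxels) is unresolvable by construction. Each
junction draws a degree from the discrete law P(K ≥ k) = e^(−β(k−3)),
k ≥ 3, whose survival function is exactly the exponential tail the
cumulative-degree analysis fits. The default β = 2.0 gives mean degree
3.16; this matches the measured mean node degree of cortical LCNs and the
arithmetic linking Can.Dn, Nd.Nr and mean degree (implied mean edge length
≈ 2.66 µm). Published tail fits on real data report β closer to 1 *on the
extracted network*; the package reproduces that discrepancy rather than
hiding it — junction merging at imaging resolution fattens the extracted
tail, so the fitted β of an extracted phantom is systematically smaller
than the generator's β (see Limitations).

Drawn degrees are assigned to junctions by local crowding: the
highest-degree draws go to the junctions with the most neighbors within
3 µm. The marginal degree law is unchanged, every extra branch can find a
nearby partner, and the assignment reproduces the positive spatial
correlation between node density and node degree observed in real
subvolume maps.

**Edges.** Every junction degree contributes one "end"; every lacuna
contributes one end per primary canaliculus, with count = surface area
(Thomsen approximation) / 5 µm² — the constant area-per-canaliculus rule,
under which lacunar volume scales as degree^{3/2}. Ends are paired
greedily, shortest chord first (within 2× the implied mean edge length,
chords below ~1.7 µm excluded as unresolvable), with three refinements:
lacuna–junction pairs are prioritized so primary canaliculi join the
network; in the ordered region off-axis chords are penalized so edges lean
toward the alignment axis; and pairs crossing a configured mineral
interface plane are forbidden. Leftover ends become endpoint-terminated
terminal branches whose length is set from the remaining region length
budget (floor 1.4 µm; lacunar terminal branches 3 µm so they reach past
the lacuna's halo). Edge paths get a random perpendicular half-sine bump
scaled by bisection to the target tortuosity (arc/chord, default 1.03 —
essentially straight at the 2–3 µm segment scale, and consistent with
treating canalicular tortuosity as a minor factor; larger values push the
realized canalicular density above its ±10 % target envelope because chord
lengths are bounded below by the resolvable-node separation).

With these rules the realized Can.Dn lands within ~10 % of target (slightly
above, because the minimum resolvable chord bounds edge lengths from
below), Nd.Nr within Poisson fluctuation of target, and the realized degree
distribution is the drawn one exactly.

**Regions.** The "unordered" region is a central slab along x occupying a
fraction f (default 0.28, the measured area share) of the domain, with node
and length densities scaled by 0.7 relative to the ordered remainder; the
global targets are preserved by renormalization. This emulates the sparser,
isotropic woven-bone band; its geometry (a slab rather than a horse-shoe)
is deliberately simple.

**Rasterization.** Canaliculi (radius 0.15 µm, well below the
0.379 × 0.379 × 0.340 µm voxel) deposit their exact line integral: a voxel
crossed by tube length dL receives intensity πr²·dL / voxel volume, the
partial-volume fraction of a thin tube. Lacunae are filled by 3×-per-axis
supersampled ellipsoid membership. Voxel values are capped at 1.

**Degradation.** Anisotropic Gaussian blur with σ = (0.12, 0.12, 0.35) µm —
the diffraction-limited PSF of a 40×/NA 1.3 oil objective at 514 nm with a
1-Airy pinhole — plus a linear background gradient (default
5·10⁻⁴ intensity/µm) and additive Gaussian noise (default SD 0.01,
i.e. SNR ≈ 20 at the blurred canalicular peak, representative of
well-stained, well-exposed stacks). All randomness flows from named
substreams spawned from one seed (`lacunae`, `junctions`, `degrees`,
`matching`, `geometry`, `noise`), so identical parameters give bit-identical
output and adding draws to one stage never perturbs another.

**Cohorts.** `generate_cohort` draws one multiplicative jitter per animal
(CV 3 %) applied to the density targets; both limbs share the animal-level
targets but use different realization seeds. The between-animal spread of
means is therefore much smaller than the within-stack spread — the
inter- vs intra-individual variability structure of paired-limb designs.
Strain presets: `balbc_like` (Can.Dn 0.21 µm/µm³, Nd.Nr 0.050 µm⁻³,
β 2.0, Lc.V 350 µm³, unordered 28 %) and `c57_like` (0.23, 0.059, 1.8,
380 µm³, 30 %), the second strictly denser.

**qBEI companion.** A 2D calcium map constant on each side of the truth's
interface plane, with gray levels computed by inverting the package's
two-reference calibration, so the network disruption and the mineral
interface are co-located by construction and a calibration round trip is
exact to the gray-level quantum.

## Extraction

1. **Binarization** — difference of Gaussians, σ_small = 0.15 µm,
   σ_large = 1.2 µm (converted per-axis to voxels), thresholded at
   mean + k·SD of the positive DoG response with k = 0. The statistics are
   estimated on the interior (a 3σ_large margin is excluded) because
   boundary padding turns smooth backgrounds into spurious band-pass
   response. These defaults were calibrated on phantoms: the positive-DoG
   population is dominated by structure halos, so thresholds like
   mean + 2 SD sit far above the thin-tube ridge response and fragment the
   network. Raising k can only shrink the mask (monotone).
2. **Lacuna/canaliculus separation** — enclosed cavities are filled (a
   bright solid body seen through a band-pass binarization is a closed
   shell), then voxels with distance-transform radius ≥ 1 µm seed lacuna
   bodies, seeds grow back over foreground within that radius, and grown
   components ≥ 50 µm³ become lacunae; everything else is canaliculus.
3. **Skeletonization** — topology-preserving 3D thinning (Lee) of the
   canalicular phase only; 26-connectivity throughout.
4. **Branch smoothing** — each simple skeleton path (between junction
   clusters, endpoints and lacuna attachments) is replaced by a cubic
   smoothing spline through its voxel centers with endpoints pinned;
   smoothing backs off until the maximum displacement is below one voxel
   diagonal; arc length is integrated on a ≤ 0.1 µm polyline. Paths of
   fewer than 4 points stay polylines.
5. **Graph building** — junction clusters within 0.5 µm merge at their
   centroid; free branch ends within 2.5 µm of a lacuna surface are
   rewired onto the lacuna (the bright lacuna suppresses the local
   band-pass response and severs the first ~2 µm of its canaliculi);
   endpoint spurs shorter than 1 µm are pruned, degree-2 junctions
   dissolved, so junction nodes keep degree ≥ 3. Edge paths are extended
   to the collapsed cluster centroid so summed edge lengths meet the
   nodes. Lc.Dg is the number of edges incident to a lacuna node.

On the default 50³ µm³ noisy phantom the pipeline recovers total
canalicular length within 15 %, junction count within 20 %, mean junction
degree within 0.3, lacuna count exactly, Lc.V within 10 % and Lc.Dg within
20 % per lacuna on average — these are the tolerances asserted in the test
suite, which runs exactly this comparison.

## Metrics

* Subvolume maps use cubic cells of exactly 400^{1/3} µm edge, half-open
  per axis; edge paths are clipped to cells *exactly* (segments are split
  at cell boundaries), so summed per-cell length conserves total length to
  machine precision. Nd.Nr counts junction and lacuna nodes (free
  endpoints are not branching points); Nd.Dg averages only genuine
  (degree ≥ 3, non-lacuna) nodes and is undefined (NaN) in cells without
  one. Cells not entirely inside the domain/ROI are invalid — partial
  cells would bias densities downward.
* Lacunar semi-axes come from second central moments of the voxel cloud
  (semi-axis = √(5λ)); stretch = 1 − c/a; oblateness = 2(b−c)/(a−c) − 1
  with the degenerate value 0 when a − c < 10⁻⁶ µm; lacunae under 10
  voxels are flagged invalid.
* The degree-tail exponent is an unweighted least-squares fit of −ln C(x)
  against x − 3 through the origin (C(3) = 1 is exact by construction),
  over observed degrees with C(x) > 0; all-degree-3 graphs report NaN with
  a reason.
* Power-law fits are ordinary least squares on log-log axes; R is the
  Pearson coefficient on the fitted axes. SDs use n − 1 throughout;
  inter-individual variability = SD of per-sample means, intra-individual
  = mean of per-sample SDs. Group tests are Student's t (paired or
  pooled-variance independent), two-sided; degenerate zero-variance inputs
  with equal means report t = 0, p = 1.

## Regions

Region masks are 2D (drawn on a z-projection of the skeleton) and extruded
along z; each valid subvolume cell takes the majority label of its xy
footprint, ties resolved toward "unordered" (conservative for the sparser
class). Area fractions are shares of in-ROI pixels and sum to 100 %. An
optional structure-tensor coherence map of the projection is provided as a
drafting aid for masks; it is not a substitute for manual segmentation.

## qBEI calibration

Gray → backscatter coefficient η is linear through the measured gray
levels of pure carbon and aluminum references, with η(Z) from Reuter's
polynomial (η_C ≈ 0.0641, η_Al ≈ 0.1529); η → wt% Ca is affine through two
configurable anchors, default (carbon, 0 wt%) and (aluminum, 39.86 wt%,
the calcium fraction of hydroxyapatite). These defaults are conventions of
this package — real instruments are calibrated against published standard
procedures whose constants are instrument-specific. Higher gray level
always means higher wt% Ca.

## Problem sizes in the tests

The test suite exercises a 50³ µm³ default phantom (one full
generate → rasterize → degrade → extract chain, shared across tests), a
30³ µm³ phantom for graph-level properties, 20–24 µm³-scale domains for
cohort and interface tests, and 10⁴–10⁵ sampled degrees for distribution
recovery. The whole suite runs in about a minute on one CPU.

## Limitations

* The phantom is statistically faithful, not biologically mechanistic: no
  vascular porosity, no drifting-vessel fan, no staining chemistry, no
  stitching artifacts, and the unordered region is a slab rather than a
  horse-shoe band. Passing recovery tests says the *pipeline* is correct
  at realistic densities and imaging conditions; it does not validate
  biological conclusions drawn from any particular real dataset.
* The generator's network is largely a union of short paths rather than a
  single spanning tree; global connectivity statistics (component sizes,
  path lengths) are not calibrated and should not be read off phantoms.
* Extracted degree tails are biased: junction merging at imaging
  resolution inflates high degrees, so β fitted on an extracted network
  is smaller than the generating β. Comparisons of β between groups
  extracted identically remain meaningful; absolute values are
  resolution-dependent.
* Skeleton thinning assumes near-isotropic voxels; at the default spacing
  (0.379/0.340 µm) the anisotropy is 11 % and ignored during thinning,
  while all lengths and radii are computed in physical units.
* The qBEI module models the calibration mapping only; detector physics,
  probe-current drift and mineral heterogeneity below pixel scale are out
  of scope.
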