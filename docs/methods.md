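# Methods

## Coordinate conventions and units

All in-memory positions are nanometres in dataset coordinates: x is the
mediolateral slicing axis (0 at the lateral face, increasing medially), y
dorsoventral, z anteroposterior.  The convention is configurable where it
matters (`merge_parts(axis=...)`, `sagittal_clip(axis=...)`,
`voxelize(axis=...)`).  NML files carry voxel units with a per-file scale
(default 11 × 11 × 25 nm: 11 nm pixels, 25 nm cutting thickness); radii in
NML are converted with the x scale.  SWC uses micrometres, per the common
convention.  Slice indices convert to depth as index × 25 nm; note that
some depths quoted for this kind of data are rounded to the micrometre.

## Skeletons

A skeleton is an undirected node/edge graph with a per-node radius (half
the annotated process diameter).  Cycles are tolerated in the containers —
merged annotations can contain them — and only rooted-tree exports
(SWC, hoc) reject them.  Soma nodes are identified by a comment containing
"soma" (case-insensitive); there is no stronger convention in the source
formats.  Nodes without a radius annotation read as radius 0 and are
flagged in the annotation metadata; volume and contact operations refuse
radius-0 input rather than guessing.

**Merging dataset parts.**  Reconstructions split across a lateral and a
medial sub-dataset are joined by matching tree endpoints (degree ≤ 1)
within a tolerance of the seam plane; a unique mutual match within the
tolerance gets a bridging edge, a multi-way match raises an error listing
the candidates (the original data was resolved by human annotators, and
silently picking one would hide exactly the cases that need eyes).  The
tolerance is exposed because no canonical value exists.  Medial node ids
are renumbered with an offset; an id map and per-node provenance are
returned, and no node is ever dropped.

**Resampling.**  Each edge of length L becomes ceil(L / 400 nm) equal
colinear sub-edges with linearly interpolated radii.  Original nodes stay
fixed (no smoothing), cable length is conserved exactly, and a 1e-9
relative slack in the ceil keeps the operation idempotent under
floating-point noise.  Resampling makes node counts a cable-length proxy,
which is what the layer histograms weight by.

**Volume.**  Sum over edges of the truncated-cone volume
π L (r₁² + r₁r₂ + r₂²)/3, reported in μm³.  Branch-point overlap is *not*
corrected — the estimate is an additive assembly of per-edge frusta — and
the test-suite oracle counts fine voxels per flat-ended cone and sums,
matching that definition (agreement ≤ 0.03% at 20 nm voxels).  For thin,
gently turning neurites the union and the sum differ by ~1%; for
self-crossing or densely branched geometry the sum overestimates, which is
a known model limitation.  "Largest component" is decided by cable length,
not node count, so annotation density cannot flip the choice.

## Layer model

The plate outline cloud is split into anterior/posterior either by
explicit labels or by the sign of the residual against a least-squares
quadratic mid-surface z = g(x, y); a cloud whose residuals never exceed
1 nm is one surface, not a slab, and is rejected.  Each side is
interpolated piecewise-linearly over the Delaunay triangulation of its
(x, y) support (linear precision: planes are reproduced exactly); the
footprint is the intersection of the two triangulations' hulls, and
thickness is verified positive on the support points plus a 25 × 25 probe
grid at construction time.

Depth is evaluated along z at the node's (x, y) — a vertical projection,
chosen as the simplest reading of projecting nodes "into" a two-surface
model; closest-point projection would differ on strongly curved plates.
Layer bins are half-open, [0,¼), [¼,½), [½,¾), [¾,1], with d = 1 assigned
to layer 4; tie handling has no canonical choice and is documented rather
than hidden.  Histograms are node-count fractions over in-footprint nodes
(six bins: four layers plus anterior-of-plate d < 0 and posterior-of-plate
d > 1) and sum to 1.  Boxplot statistics first drop nodes more than 50%
anterior or posterior of the plate (d outside [−0.5, 1.5]), then use Tukey
midpoint quartiles and 1.5 × IQR whiskers; other quartile rules differ by
O(1/n) and the difference is below every tolerance used here.

## Contact analysis

Skeleton edges are rasterized as capsule/cone sweeps onto a (140 nm)³
grid restricted to the configured depth window (default 86–203 μm from the
lateral face; cross axes get a 10-voxel margin so later dilations have
room).  A voxel claimed by two processes becomes *contested* background,
permanently — processes are disjoint by construction at every stage.

All morphology uses the cubic 3×3×3 element (26-connectivity), implemented
as separable maximum/minimum filters (r rounds of a cube compose into one
size-2r+1 filter).  Closing is per label, padded so the grid boundary does
not clip it, with disjointness re-enforced afterwards.  Constrained
dilation is synchronous: per sweep every label dilates into free
background, a voxel reached by ≥ 2 labels in the same sweep is contested
forever.  Synchronous-with-ties is order-independent; sequential growth
would make results depend on label numbering.  The final measurement
dilates one label once against the frozen rest and divides the overlap
voxel count by 51 (the study's literal divisor; `divisor=None` uses the
exact reciprocal face area 51.02).  Directed areas are symmetrized by the
mean; zero pairs are flagged for manual review.

**Resolution stability.**  For perfectly coherent geometry (two
mathematically parallel cylinders) the tie rule makes the measured area
grid-phase dependent: whether colliding growth fronts end adjacent or
separated by a one-voxel contested seam is a parity effect, coherent along
a flat interface.  Real neurites are not flat; accordingly the
oracle-equivalence test gives its tubes 100 nm sub-voxel axis roughness
(`make_parallel_bundle(axis_jitter_nm=100)`), which decoheres the parity
and makes the estimate stable (production at 140 nm agrees with an
independent shifted-slice implementation at 70 nm — closing/growth rounds
doubled to preserve physical reach, the single kernel-defined measuring
dilation kept at one round — to within ~15%).  Absolute areas from this
estimator should be read as method-defined quantities at the stated voxel
size, not as geometric surface areas.

## Tile alignment

Shifts between adjacent tiles are the argmax of the normalized
cross-correlation (zero-mean, unit-variance — robust to brightness drift)
of the overlap strips, searched within a configurable radius of the
nominal offset.  Peak quality is the peak value over the mean absolute
correlation in a 3–8 px ring around it, with the denominator floored at
0.1 so an uncorrelated pair (tiny peak *and* tiny ring) scores low;
simulated noise pairs score < 1.2 while genuine pairs score > 3, and the
default floor is 2.  Reweighting multiplies the weight by
min(1, tol/‖shift − expected‖) and zeroes blurry peaks; the Huber-style
form is convex and has a single tolerance parameter.  How many
reweight/re-solve iterations the original outlier compensation used is not
knowable; one pass is the default and passes compound, which the outlier
test exploits (two passes suppress a 20 px outlier below 1 px recovered
error).  Global positions minimize the weighted quadratic residual per
axis over the measurement graph (connected, positive weights required),
anchored at one tile; the solve is a sparse Laplacian system and is exact
on consistent measurements.  Translation-only by design: rotation and
scale are out of model.

## Synthetic data

The generators define the conditions every recovery test runs at; all are
deterministic given a seed and return machine-readable ground truth.

* **Plate**: two parallel analytic surfaces, anterior
  z₀ + A sin(2πx/Lx) sin(2πy/Ly), defaults A = 5 μm, thickness 20 μm,
  extent 120 × 150 μm, z₀ = 40 μm — a curved slab at the scale of the real
  neuropil.  Outline points sit on a regular grid spanning the extent so
  the model footprint is the full rectangle.
* **Cells**: per-layer cable budgets are spent by branching random walks
  confined to each layer's depth band (2 μm steps, ±0.05 depth wiggle,
  headings reflected at the field boundary, branch probability 0.25),
  hanging off a trunk that crosses the slab; an axon leaves the plate
  medially at a layer-4 depth, its in-plate stretch charged against the
  layer-4 budget, ending in a soma blob flagged by comment.  Default 5 mm
  cable per cell (≈ 12,500 resampled nodes in-plate) puts target-recovery
  noise well under the ±0.02 test band.  Dendrite radii 150–500 nm, axon
  700 nm — large-tangential-cell calibers.  What the generator does *not*
  emulate: realistic branching statistics, tapering, or tortuosity at the
  sub-segment scale; passing recovery tests show the measurement chain is
  unbiased, not that it handles every real morphology.
* **Bundles**: tubes are polylines with constant radius; pairwise minimal
  wall-to-wall gaps inside the roi are computed exactly over all segment
  pairs.  The 9-tube braid rests the tubes on a 9 μm ring and brings every
  pair except one to the ring center for a 1 μm wall-contact interval
  (walls overlapping 0.15 μm), one pair at a time; ring geometry keeps
  every bystander ≥ 5.7 μm (centers) from a traveling tube, beyond the
  pipeline's total dilation reach 2·(7+1)·0.14·√3 ≈ 3.9 μm, so the skipped
  pair is the unique non-touching pair by construction (verified
  analytically by the generator's gap table).
* **Tiles**: one band-limited Gaussian-noise mother image (σ = 2 px
  smoothing) cropped into overlapping tiles at nominal grid positions plus
  integer Gaussian jitter, with additive intensity noise.  Integer jitter
  keeps the NCC peak on-lattice, so alignment recovery can be tested
  against exact truth; sub-pixel registration is out of scope.

## Problem sizes

The default test and acceptance runs use: 20 random trees at 20 nm oracle
voxels for the volume check; 5 mm cells (≈ 14,000 nodes) for layer
recovery; a 4 × 4 tile grid (128² tiles, 32 px overlap) for alignment; and
the 9-tube braid over a ~180 μm tract (≈ 22 M voxels at 140 nm) for the
contact pipeline.  These sizes were chosen so the full suite exercises
every stage at study-like dimensions while remaining quick to run on a
laptop.

## Known limitations

* Consensus building across redundant tracings of the same cell is not
  implemented; the pipeline accepts one designated skeleton per cell.
* Contact areas are parity-limited under the synchronous tie rule (see
  above); comparisons between runs are only meaningful at a fixed voxel
  size.
* The layer model is vertical-projection based; a strongly folded plate
  would need geodesic depth, which is out of scope.
* The volume threshold classification uses an inclusive ≥ 500 μm³ rule to
  avoid float-equality pathologies at the boundary.
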