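# Methods

## The stage-series model

A developmental stage series is an ordered list of surface meshes with an
identical face list and vertex count; vertex *i* denotes the same material
point at every stage. The continuous stage parameter *s* spans
`[0, n_stages − 1]` and blends the two bracketing stages' vertex arrays
piecewise-linearly ("shape keys"). Two consequences matter downstream:

* at integer *s* the stored stage is returned bit-exactly, so repeated
  round trips cannot drift;
* *s* is **ordinal**. The real stages it mirrors (HH10, HH11, HH14, HH20 in
  the default labels) are not equally spaced in developmental time, and the
  package never converts *s* to hours.

Quads are accepted in face lists and triangulated internally by the fixed
(0,1,2)/(0,2,3) split, applied identically at every stage so the
correspondence key (vertex index) survives all geometric queries.

## Digital dye and the no-mixing property

A dye patch is face-granular: a face is dyed or it is not, mirroring a
painted-face workflow; sub-face dye gradients are out of scope. A patch
carries a fixed number of seeded barycentric sample points per face
(default 10) used for metric estimation, decoupling metric precision from
mesh resolution. Transport to another stage re-evaluates the same face set
and samples on the interpolated vertex array. Labels therefore never
transfer between faces: disjoint patches stay disjoint and connected
patches stay connected at every *s*. This also means digital growth lines
are slightly conservative in extent compared with real dye, which spreads
into neighbouring cells; the injection radius is the only size control and
no compensation is applied.

`inject` dyes every face all of whose vertices lie within a geodesic radius
of the seed (plus the seed face, so a patch is never empty). This rule
under-covers the true geodesic disc by up to one boundary-edge band — an
inherent inward bias of order (edge length) / radius that shows up in the
spherical-cap checks below.

## Geodesic distances

Two solvers are exposed, with different contracts:

* `geodesic_distance` — Dijkstra shortest paths on the triangulated edge
  graph, with the source point attached through its triangle's three
  vertices. This is exactly symmetric and satisfies the triangle
  inequality, so it is the reference for metric-style uses. Its accuracy is
  limited by a direction-dependent stretch of the edge graph (up to ~15% on
  a regular triangulation) that does **not** vanish with refinement.
* `eikonal_distance` — a first-order surface-eikonal solution: the graph
  distances initialise a Tsitsiklis/fast-marching local update applied in
  ascending causal order, after replacing near-source values (where the
  linear-wavefront model is worst) with distances measured in an isometric
  unfolding of the surrounding triangle fan. The unfolding is intrinsic, so
  it cannot shortcut through ambient space on folded surfaces, and it is
  exact on developable patches such as tubes. Accuracy is O(edge length)
  with a small constant (≤1.5% relative error on an icosphere at
  subdivision 5–6). `inject` uses this solver by default.

Measured on a subdivision-6 unit icosphere, a radius-1.2 dye disc covers
98.2% of the analytic spherical-cap area 2π(1 − cos r); the deficit is the
sum of the face-granularity rim bias (~1.2%) and the residual distance
error (~0.5%), both shrinking with mesh resolution.

## Growth-line metrics

All in-plane quantities are computed after projecting the stage-t1 sample
points onto their total-least-squares plane (the SVD of the centred
points): patches are thin shells, and 3D principal components would
conflate surface curvature with elongation.

* **area ratio** — summed dyed-face area at t1 over t0 (exact, so a uniform
  scale k gives k² to machine precision).
* **elongation** — ratio of the in-plane principal standard deviations
  (≥ 1). Patches below 1.05 are treated as isotropic: a perfectly circular
  sampled disc already reads a few parts in 10³ above 1, so orientation and
  convergence are undefined below that.
* **orientation** — the major axis against the A-P polyline tangent nearest
  the patch centroid, projected into the patch plane; reported as an
  undirected axis in [0, 180). The sense of the angle depends on the fitted
  plane normal's sign, which is arbitrary; comparisons should be made mod
  180°.
* **convergence** — in-plane perpendicular distance from the named target
  (the "eye") to the major-axis line; an error (not NaN) for isotropic
  patches, directing the caller to check elongation.
* **shape class** — spot / line / V. The V test runs first: the apex is the
  projected sample farthest from the chord between the two extreme points
  along the first principal direction, and the patch is a V when the arms
  meet below 150°, each arm carries ≥ 25% of the two-arm length, and each
  arm's own point subset is elongated (≥ the line threshold). The per-arm
  thinness condition exists because a bent shape can have modest *overall*
  elongation — two equal arms at 90° have elongation exactly 2 — while a
  disc's extreme points also form two wide "arms"; testing arm thinness
  separates the two. Failing the V test, the patch is a spot below
  elongation 2.5 and a line otherwise. The thresholds (2.5, 150°, 25%, and
  the conformity grey band [2, 3]) are a reproducible surrogate for expert
  visual scoring; they live in the config and are echoed with every output.
  A "tricorn"-like three-armed patch is reported as V or line by these
  rules; no fourth class is introduced.

## Outcome scoring

The seventeen-area vocabulary (T1–T2, D1–D7, H1–H5, Hm1–Hm3) is fixed; the
face-set geometry behind each label is an annotation input. The synthetic
default layout cuts the final-stage mesh into four angular sectors split
axially into 2/7/5/3 bands — test geometry only, not an anatomical claim.
Assignment includes every area covering ≥ `min_overlap` (default 5%) of the
patch's area; when nothing passes, the single best-overlap area is returned
flagged, so every sample gets a label as in manual scoring. Conformity
compares the measured shape class with a per-area expectation; elongations
inside the grey band are indeterminate, and summaries pool indeterminate
with non-conforming. Zone intersections are encoded as sorted label pairs
("4+5"). Multi-injection samples contribute one record carrying all zones
by default (a flag on the record structure allows splitting). Frequency
thumbnails colour each face by the highest-frequency area containing it on
a monotone white-to-red ramp with exact white at zero.

## Landmark morphometry and statistics

* **B:A ratio** — line A joins landmarks X and Y; the optic-margin polyline
  fixes a perpendicular foot on A (at the margin's crossing of line A, or
  at its closest point when it does not cross); B is the distance from Y to
  that foot, required to fall within segment XY. The construction is
  invariant under rigid motions of all landmarks.
* **log trend** — ordinary least squares of ratio on ln(stage); stages are
  ordinal stage numbers (HH10 → 10), not hours.
* **ZLI angles** — angle in [0, 180] between the ZLI chord (first-to-last
  point of the annotation; a total-least-squares fit is available for
  curved annotations) and the base-to-star segments.
* **expression area** — fixed order: bright-outlier despeckle (each pixel
  exceeding its radius-r disk median by more than a threshold is replaced
  by that median — an emulation of the common "remove outliers" tool's
  documented semantics, not a bit-compatible port), then a strict
  greater-than intensity threshold, then a count inside the rasterised ROI
  polygon. The despeckle radius and both thresholds have **no defaults**:
  they must be stated explicitly in the config, because any silent default
  would masquerade as a calibrated value.
* **t tests** — Student (pooled variance, df = nA+nB−2) and Welch
  (Welch–Satterthwaite df) from the closed forms, p two-sided from the t
  distribution. Two zero-variance groups with equal means give t = 0,
  p = 1; with unequal means the statistic is undefined and an error says
  so. Note Welch's p is *not* always ≥ Student's; the only inequality
  asserted is df_Welch ≤ nA+nB−2.

## Gene-set stage

The expression container is an `AnnData` (cells × genes, sparse integer
counts). Filtering retains cells with Otp and/or Sim1 counts > 0 or an
explicit per-cell NPC flag (the NPC definition is an input, not inferred),
then removes any cell with a positive count for an exclusion gene
(Foxa1/Foxa2/Pitx2/Shh, and Nr5a1/Foxb1/Tbr1/Agrp/Pomc — "expressing" is
interpreted as count > 0 for both lists, as no alternative cutoff is
defined). Retention and exclusion combine as a conjunction, so their order
cannot change the result; the report nevertheless counts removals per rule
in a fixed order for bookkeeping.

Scores are computed on log1p counts-per-10k (stated in outputs; the
normalisation is a package choice). Genes are ranked by dataset-mean
expression into `n_bins` equal-frequency bins (default 24); each set gene
draws `n_ctrl` (default 100) control genes from its bin, seeded, without
replacement, excluding the set itself — so a set shifted uniformly by +c on
the log scale scores ≈ c, and adding any constant to all genes leaves
scores unchanged. Bins smaller than `n_ctrl` reduce the draw with a
warning. Cluster summaries report per-cluster means and the argmax cluster
per score, with ties listed rather than broken. Reclustering and embedding
are out of scope: cluster labels are inputs.

The preset gene lists ship under names `retain`, `exclude_ventral`,
`exclude_markers`, `terminal` (Fgf15, Six3, Zic1, Zic5), `peduncular`
(Mfap4, Lmo4, Rgs4), `progenitor` (Mki67, Top2a, Pcna) and `neuronal`
(Neurod1, Dcx, Tubb3); gene matching is case-sensitive with missing names
reported as hard errors for filter/score genes.

## The synthetic-embryo generator

The generator defines the study conditions for every test. Its deformation
fields are the three growth modes the model describes, applied cumulatively
over a default of four stages:

* **directional growth**: displacement `g · f_k · w(v) · (a − v)/|a − v|`
  toward an attractor point, with `w` decaying linearly in geodesic
  distance from a marked origin vertex set — the simplest field that makes
  labels converge toward an "eye";
* **isotropic zone expansion**: `(scale_k − 1) (v − c)` about the zone
  centroid;
* **midline-band translation**: a per-stage shift along the anterior axis.

Zero strength, unit scales and zero shifts give an exactly identity series.
The magnitudes in `default_deformation` (strength 1.0, dorsal zone scaling
to 1.8, midline shift to 0.9 over a 4-unit tube) are free parameters chosen
to produce clearly elongated, clearly V-bent and clearly isometric regions
at the default mesh resolution; they are not calibrated growth rates and
make no claim about real embryos.

Injection zones partition the stage-0 faces into 12 areas (4 axial × 3
angular quantile bins); outcome regions partition the final stage into the
17-label layout described above. Ground-truth outcome areas are computed by
a per-face brute-force forward map, independent of the scoring path, and
the closing-the-loop test demands ≥ 95% exact agreement at zero jitter.
Synthetic images are two-level 16-bit frames with a polygonal signal and
isolated salt pixels (pairwise Chebyshev distance ≥ 3, kept 2 px off the
signal boundary) so that a radius-2 bright-outlier despeckle removes the
salt exactly without touching the signal. Synthetic count matrices plant
retention markers in a chosen fraction of cells, positive exclusion-gene
counts in chosen cells, and multiplicative rate effects for a gene set in
one cluster; the truth retained-mask is evaluated by a plain per-cell loop.

What the generator does **not** emulate: imaging noise beyond salt,
mesh-extraction artefacts, doublets/ambient RNA in counts, spatially
correlated biological variability, or realistic growth magnitudes. Passing
tests therefore demonstrate correctness of the algorithms under known
ground truth, not performance on real micrographs or sequencing data.

## Problem sizes and numerical choices

Tests and the acceptance script run on deliberately small problems: tubes
of a few hundred vertices, a subdivision-6 icosphere (~82k faces) for the
one high-resolution cap check, 36 injections in the demo, 50×20 to 300×150
count matrices, 100-seed property sweeps. Everything completes in well
under a minute per module on one CPU. Closest-point ties break toward the
lowest face index; degenerate inputs (empty patches, zero-variance groups,
empty zones, all-cells-filtered matrices) raise informative errors rather
than returning silent defaults. All randomness flows through
`numpy.random.default_rng` seeded per call, and every run's effective
configuration (with hash) is serialised next to its outputs.

## Known limitations

* Geodesics are first-order accurate; highly obtuse or strongly anisotropic
  triangulations degrade both solvers (the tube's coarse circumferential
  resolution shows ~5% local error).
* Orientation requires an oriented tangent plane; only comparisons mod 180°
  are meaningful.
* Correspondence between stages is assumed given (as in a hand-built
  model); no automatic correspondence estimation, remeshing or subdivision
  is provided.
* The 17-area default geometry and the 12-zone layout are synthetic stand-ins
  for annotation inputs.
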