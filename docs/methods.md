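# Methods

This note documents the models and procedures implemented in `rhizotrack`,
the assumptions they rest on, the parameters that matter, and what the
synthetic benchmark does and does not demonstrate.

## Problem setting and assumptions

The input is a time-ordered series of grayscale images of one vertical
agar plate holding `N_p` seedlings, backlit so roots are darker than the
background (≈100 gray levels of contrast at the root centerline), observed
at a fixed cadence (defaults: 21 observations, 8 h apart). The framework
rests on three assumptions:

* **Monotone growth ("Russian dolls").** Roots neither die nor regress
  during the experiment: the set of root-covered pixels at observation
  `t` is contained in the set at `t+1`. This is what allows collapsing the
  whole series into a single apparition-time image.
* **One primary per plant, second-order laterals only.** Each seedling has
  exactly one first-order root, laterals insert on it and do not branch
  further. Third-order laterals, seminal or adventitious roots are out of
  scope.
* **Temporal offset at crossings.** When one root crosses another's path
  in the 2D projection, it does so at least one observation interval
  later — otherwise the two trajectories are indistinguishable in this
  representation.

## Registration

Each frame is registered to the next (the moving image is the earlier
frame, whose structures all exist in the later one) and the chain is
composed onto the last frame. The rigid stage matches square blocks
(half-size 8 px, grid stride 10 px) by normalized cross-correlation with
parabolic sub-pixel peak refinement, keeps only blocks whose intensity
variance clears both a percentile threshold and an absolute floor of
30 gray² (well above the sensor noise of a few gray levels — on sparse
early frames most of the image is featureless background, and blocks of
pure noise would otherwise flood the fit), and estimates rotation +
translation by least squares with iterative residual trimming, repeated
estimate/warp/re-estimate rounds with a shrinking search radius. Because
daisy-chain composition accumulates small pairwise errors, each composed
transform is finally refined directly against the reference frame. An
optional dense stage spreads residual block displacements onto a coarse
grid by Gaussian-weighted normalized convolution (σ = 24 px, capped at
8 px of displacement); it is off by default — plate motion is rigid to a
very good approximation, and the synthetic benchmark validates the rigid
path. Every frame is resampled exactly once (bilinear), out-of-field
pixels filled with the frame's median.

On synthetic plates with injected jitter up to ±20 px and ±2°, the
recovered per-frame transforms are accurate to well under 0.5 px and
0.1°; the acceptance script re-measures this.

## Temporal segmentation

Each pixel's intensity series is classified independently. A root arrival
produces a step down: the detector computes the maximum mean shift
(mean of the head minus mean of the tail over all split points) and
requires it to reach `s1 = 25` gray levels, then requires the maximum
successive drop to reach `s2 = 10`; the label is the observation
following the maximal drop, earliest index on ties. Both thresholds are
expressed in 8-bit gray levels; 16-bit input is rescaled first. Pixels
already dark at the first observation (seeds, pre-germinated roots) show
no drop, so a virtual background observation — the median intensity of
the first frame — is prepended to every series; a drop at the virtual
position labels the pixel 1. An optional transient suppressor resets
pixels whose intensity later recovers toward background (roots only
darken; recovery indicates a moving artefact), and a user exclusion mask
can force regions (fallen leaves, plate frame) to background.

Finally, 4-connected components of the nonzero label mask smaller than
`min_component_px` are removed (default 2000 px; at 19 µm/px this is
equivalent to rejecting candidate root systems whose cumulative organ
length at the last observation is below 38 mm — the equivalence is
recomputed for whatever pixel size is configured).

## Topological tracking

Vertices of the region adjacency graph (RAG) are 8-connected components
of same-label pixels; a directed edge joins 4-adjacent components forward
in time, weighted by surface dissimilarity + temporal gap + vertical
orientation (straight-down edges get −1). The graph is acyclic by
construction.

**Primaries.** Sources are the label-1 vertices inside the `N_p` largest
whole-plant components of the segmentation (ranked by vertex area); each
primary is the maximal greedy walk along minimum-weight outgoing edges.
Two refinements make the walk robust: candidate edges are penalized by
their angular deviation from the recent trajectory (where a lateral's
fresh growth is adjacent to the primary's path, the raw weight alone
cannot tell the primary's own continuation apart), and the walk stops at
any temporal gap of two or more intervals — a primary grows continuously,
so such a gap means the path is interrupted (crossing, artefact) and the
continuation is better recovered by the global matching below. Lateral
arcs pointing into primary vertices are removed, and connected components
(undirected, computed on the full adjacency before that removal) that
contain no primary vertex are dropped as outliers.

**Spanning forest.** Every remaining vertex keeps exactly one incoming
arc. On a DAG any per-vertex choice of parent is acyclic, so the general
minimum-arborescence algorithm's cycle-contraction phase never triggers
and the optimum is the independent minimum-weight incoming arc (the
implementation is certified against exhaustive enumeration on random
DAGs). The arc choice used by the pipeline additionally carries the same
angular-continuity penalty, evaluated in time order so each candidate
parent's chain is already resolved. Lateral branching is then suppressed:
each lateral vertex keeps only its cheapest outgoing arc (again with the
angular penalty); orphaned subchains become "root starts".

**Crossing resolution.** Root stops are vertices without a continuation
arc (for a primary-path end, emergence arcs hanging from it do not
count); root starts are lateral vertices without an incoming arc, plus
*suspicious chain heads* — vertices whose single incoming arc spans a
temporal gap implausible for what it claims to be (≥ 3 intervals for an
emergence from a primary; ≥ 1 for a continuation after a lateral vertex,
since genuine continuations are gap-free). Suspicious heads are only
candidates: they lose their arc solely if the matching finds a cheaper
continuation. The connection cost of an ordered (stop, start) pair is the
mean of five features, each in [0, 1] and replaced by the majoring value
1 when the chains are too short to support the estimate:

1. the virtual RAG edge weight, rescaled from [−1, 4] to [0, 1];
2. the angle between the stop's terminal and the start's initial
   directions, θ/π;
3. the relative speed difference, max-ed with the speed implied by the
   hidden stretch (nearest-pixel gap over temporal gap) when that exceeds
   the organs' own speed — a long jump in little time is no continuation;
4. a topological score on the original RAG: wrong-direction edges plus
   temporal gap along the min-hop undirected path, normalized by 6,
   capped at 1 (1 if no path within 8 hops);
5. gross misalignment of the stop→start jump with the stop's heading,
   with a dead zone below 60° (centroid jumps are noisy at small gaps, but
   a connection that requires the root to double back is no continuation).

Pairs are inadmissible if temporally backward (one interval of overlap is
tolerated when the stop is a primary: merged growth at a primary crossing
can locally invert apparition labels), farther than 60 px of pixel gap, or
cycle-creating. Resolution runs in two phases. Interrupted primaries are
reconnected first, cheapest admissible pair at a time: a primary's
continuation is distinctive (large, fast, collinear), and committing
those connections before the ambiguous lateral matching injects certain
knowledge into the system. (The primary walk itself stops at any temporal
gap of two or more intervals or on growth-area collapse below 25% of its
recent median — slivers along a blocking root would otherwise let it
overrun in time; a premature stop is recoverable here, an overrun is
not.) The second phase iterates the optimal assignment (Hungarian,
certified against brute-force permutation search), applies only the
matched pair of minimal cost if it is below `max_connection_cost = 0.6`,
and recomputes — each new connection informs the next, which is what
chains a root hidden below a primary out of its surfaced fragments. Both
loops terminate because every splice consumes a start.

**Artefact rejection.** For every lateral, cumulative length, step speed
and component surface are binned by age (timesteps since emergence);
within each bin the population median and MADe (1.483×MAD, floored at
1e-6) are computed, and any root with a value outside median ± 25×MADe in
any bin is removed. Rejection is skipped below 5 laterals.

## Geometric reconstruction

A forest edge corresponds to the tip crossing the frontier between two
consecutive growth regions, which happens exactly at the observation
preceding the newer region's label: the dual vertex is placed at the
midpoint of the median element of the shared pixel-edge chain (ordered by
a nearest-neighbour walk from the lexicographically smallest element;
even chains resolve to the lower median). Spliced chains whose regions
are not adjacent use the midpoint of the closest pixel pair. The organ
base is the topmost pixel of the first component for a primary (time 1),
the frontier with the parent's component for a lateral (time = first
label − 1), and the tip is the pixel of the last component geodesically
farthest (8-connected, Euclidean steps) from the previous vertex.

Within each component the centerline is the Dijkstra shortest path with
step cost = Euclidean step × 1/(1 + min(D(a), D(b))), `D` being the
distance transform to the component contour; any weight decreasing in
depth pulls the path onto the medial axis, and this form is bounded and
parameter-free. Paths are decimated by Douglas–Peucker (tolerance 1.5 px,
endpoints kept, error bounded by the tolerance) and interior node times
are interpolated linearly in arc length between the bounding vertices.

Post-processing: when a seed row is configured, primaries are extended
upstream by a minimum-cost pixel path (step length × mean intensity) from
the first node to the seed line — over a uniform background the distance
term alone makes the path vertical. Organs ending before the last
observation are suspect: if not incident to any other root in the RAG
(the organ's own parent near the attachment does not count), they are
kept only when they grew over at least 3 observation times; if incident
to an earlier root, their growth is assumed hidden below it and the path
is continued along the host's centerline at the stopped organ's mean
observed speed until the last observation or the host's end, all added
nodes flagged `extrapolated`. Extrapolated segments are excluded from
length and growth statistics by default (flag to include); they do count
in topology.

## RSML

Models serialize to RSML 1.0: one scene per plate, plants ordered by seed
position left to right, laterals nested under their primary and ordered
by attachment position, coordinates in raw pixels with the µm/px
resolution, the timestep (hours) and observation count in the metadata.
Two polyline-domain functions carry the dynamics: `time` (continuous
observation index per node) and `extrapolated` (0/1). Fixed float
formatting makes writes byte-deterministic. The reader also accepts
time-free RSML, assigning all nodes the last observation index with a
warning.

## Phenes

Organ length at time `t` sums the centerline segments whose apparition
time (the later node's) is ≤ `t`, converted by the pixel size; growth
between observations is the difference of such lengths, hence
non-negative and telescoping. Insertion depth of a lateral is measured
from the plate's seed line along y. The elongation heatmap assigns
laterals to insertion-depth bins and averages per-interval growth across
the population (empty cells are NaN, distinct from observed zeros), with
primary tip depth mean ± sd per time alongside. Two-group per-timestep
comparisons use the two-sided Mann–Whitney U test — exact null for small
tie-free samples, tie-corrected normal approximation otherwise (without
continuity correction, so identical groups give p = 1 exactly).

## Time-lapse rendering

The reconstructed architecture is rasterized back into pixel space:
centerline pixels take their interpolated node time and every other
segmented pixel the time of the nearest centerline pixel. Thresholding
this time function gives a nested family of masks; a frame at time `t`
between keyframes composites the next keyframe inside the mask and the
previous outside, with a linear crossfade in a ±30 min window around each
keyframe, and root tips overlaid as markers colored by elongation rate.
With the study cadence (21 keyframes every 8 h) and the default 15-min
step this yields 641 frames.

## The synthetic generator and what the benchmark shows

`rhizotrack.simulate` draws per-plant primaries as mean-reverting
directed random walks (rate ~ N(0.42, 0.05) mm/h truncated at ±2σ,
heading noise 0.06 rad per 2-px step), laterals as a homogeneous Poisson
process along the primary (0.18 emergences/mm, refractory zones near tip
and seed) with an emergence delay of N(20, 6) h after the primary tip
passes, sideways-then-down trajectories, and rates ~ N(0.12, 0.05) mm/h.
With probability 0.4 a lateral is steered to cross an already-grown organ
transversally (35–145° to the local tangent) with an enforced temporal
offset ≥ 1 interval; the actual crossing events are detected geometrically
afterwards and recorded in a ledger. Rasterization draws tubes with a
transverse Gaussian profile (3 px wide, centerline at background − 100),
snapshots at integer observation indices (coverage exactly nested before
jitter), then applies per-frame rigid jitter, Gaussian sensor noise
(sd 3), and persistent dark blobs from the second frame on (60–250 px,
below the component filter at any supported scale). The default sampling
is 100 µm/px on a 960×960 frame — coarser than the reference instrument's
19 µm/px but the finest scale that keeps the 20-plate benchmark fast;
physical quantities (rates, cadence, contrast, plant count) are kept at
study scale.

The default benchmark (20 plates × 5 plants × 21 observations, fixed
seed) regresses reconstructed phenes onto ground truth. Representative
values at seed 0: final primary length R² ≈ 0.9999 (slope 1.003), final
cumulated lateral length R² ≈ 0.987 (slope 1.00), per-interval cumulated
lateral growth R² ≈ 0.97, lateral count R² ≈ 0.94, and 93% of crossing
events resolved with correct organ identity (one reconstructed organ
passing time-consistently through probes 2 mm before and after each
ground-truth crossing).

What passing this benchmark does **not** show: the generator draws smooth
tubes of constant width on a clean background — it does not emulate root
hairs, intensity texture inside the medium, condensation films, fallen
leaves, bacterial growth, or plants touching the plate frame, all of
which degrade real-world segmentation in ways no synthetic test exercises
here. Conversely, the generator is deliberately adversarial about
crossings (steered, clustered), and the residual crossing failures
concentrate where sibling laterals emerge adjacently and grow entangled,
so that their same-interval growth regions merge into single graph
vertices — a genuine limit of the one-region-one-root representation at
this sampling, which finer imaging pushes back but does not remove.

## Numerical choices and degeneracies

Ties in the maximal intensity drop resolve to the earliest observation;
ties in arc choices resolve by weight, then earlier target time, then
larger target area, then vertex ids — all walks are deterministic, and
fixed seeds make entire pipeline runs byte-reproducible. Zero-length
centroid vectors contribute no orientation term. The MADe floor (1e-6)
prevents zero-spread bins from rejecting identical roots. Single-pixel
components are their own tip; frontier chains of one element are their
own median. Empty graphs, all-background stacks and single-organ plates
are handled without special casing.

## Known limitations

* One primary per plant; no third-order laterals; no root regression.
* Crossings with a temporal offset below one observation interval are
  indistinguishable by design.
* Organs whose growth regions merge with a sibling's (adjacent emergence,
  prolonged parallel contact) can swap or absorb identity through the
  entangled stretch.
* The leaf-fall recipe of the reference setup is replaced by a
  configurable exclusion mask plus the optional transient suppressor.
* The seed-line row for upstream extrapolation is a configuration
  parameter with no default; insertion depths are measured from the
  plant's seed position.
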