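# Methods

This note records the models, conventions and parameter choices behind
`dendroquant`, and what the synthetic generators do and do not emulate.

## Reconstructions and compartments

An arbor is a single-rooted tree of SWC points (structure codes 1 = soma,
2 = axon, 3 = dendrite; radii > 0; the root at the soma). Channel signals
ride in a sidecar TSV (`node_id`, `channel`, `intensity_I`, `fraction_F`)
so the SWC file itself stays compatible with standard morphology tools and
repositories. Validation enforces unique ids, a single root, acyclicity,
connectivity, code and range checks, and rejects channel rows referencing
unknown nodes; zero-length (coincident-endpoint) edges are a hard error at
compartmentalization.

Every non-root node defines one **compartment** — the edge to its parent —
with:

- length `L`: the Euclidean endpoint distance (µm);
- diameter `D`: the *sum* of the two endpoint radii, i.e. the mean of the
  endpoint diameters. No consensus definition exists for an edge diameter
  from point radii; the mean-endpoint form is symmetric and robust to
  digitization jitter, which is why it is the default here;
- midpoint path distance: cable distance from the root to the edge's
  parent plus `L/2`;
- structure class: taken from the *child* node, the convention most SWC
  consumers use.

Node-level channel signals are averaged onto edges (mean of the endpoints
carrying the channel; an edge with no signal at either endpoint is excluded
and counted in the log). Whether signals are stored per node or per edge
midpoint is immaterial for smooth profiles; the endpoint-mean makes the two
readings agree to first order.

## Morphometry

**Branches.** A branch is a maximal unbranched path delimited by the root,
branch points (≥ 2 dendritic children) and terminals; a k-furcation ends
the parent branch and starts k daughters. This makes the branch count equal
to `terminals + non-root branch points`, the degree census that the test
suite uses as an independent oracle. Branch density is branches per µm of
dendritic cable. Whether a soma-adjacent stem counts as a branch differs
between tools; here it does (it is a maximal unbranched path).

**Strahler order.** Terminal branches are order 1. A parent whose children
attain maximal order k is k+1 when at least two children attain k, else k
(the classical generalization at multifurcations). Orders are assigned
iteratively (explicit stack) so deep arbors cannot overflow the recursion
limit; the brute-force recursive definition serves as the test oracle.
"Reverse" order displays are a plotting direction, not a second ordering.

**Sholl.** Intersections at radius r count the dendritic compartments
whose endpoint radial distances straddle r (`min < r ≤ max`): exactly the
crossing parity of the segment with the sphere. Radii are multiples of the
step (default 10 µm — the source imaging plugin's step is rarely reported,
so it is configurable) up to the maximal radial extent. Radial distance is
3-D by default; a projected (x–y) mode matches analyses performed on
maximum-intensity projections. Peak intersections and peak radius use a
proximal tie-break.

**Internal coverage.** The x–y bounding rectangle of the dendritic nodes is
partitioned into `box × box` squares (partial far-edge boxes included); a
box is occupied when any projected dendritic segment intersects it (exact
segment–rectangle test via `shapely`; the tests cross-check against an
independent Liang–Barsky clipping oracle). The default box is 10 µm. The
original measurements used a 20 × 20 *pixel* grid with unstated pixel size,
so the physical box size is the largest fidelity gap in this module; all
comparisons within a study should therefore fix one box size.

**Organelles.** Densities are `100 × count / total dendritic length`;
positions beyond the arbor's path extent are rejected with a warning.
Branch-point occupancy attributes a flagged organelle to the branch point
at the distal end of its branch and reports the percentage of branch points
occupied.

## Compartment quantities

For a channel with edge intensity `I` and volume fraction `F`:

- `Q_c = I·F·D·L` for distributed cytoskeletal channels (MT, F-actin) and
  for the dendritic marker DenMark (`DEN_c`, same formula, no class
  restriction — axonal DenMark is exactly what a polarity-defect analysis
  needs to see);
- `SYN_i = I·F·D` for punctate channels, deliberately length-independent.

**Binning.** Each compartment's quantity is assigned wholly to the
half-open bin `[k·w, (k+1)·w)` containing its midpoint path distance
(default w = 40 µm); bins run through the last non-empty one. Assigning by
midpoint rather than splitting straddling compartments keeps the three
summations (binned, Strahler-stratified, total) exactly equal, which the
suite asserts at 1e-9 relative tolerance. The area-under-curve total is the
plain sum of bin values (bin width is constant, so this is proportional to
any quadrature rule).

**Cohort normalization.** The factor is `1 / mean(control per-neuron
totals)`; every profile in the cohort is scaled by it, making the control
mean total exactly 1. Normalizing before or after binning is equivalent by
conservation. Re-normalizing an already-normalized cohort is refused,
because silently compounding factors is a classic pipeline bug.

**Strahler stratification** reports, per order, the summed quantity, the
order's cable length, and quantity per length — either per that order's
length or per the arbor total. Empty orders report 0 rather than erroring.

**SYN classification.** SYN_i values are pooled per cell class across
neurons (pooling per neuron would let a dim neuron mint positives), ranked
descending, and the top `⌈0.10·N⌉` flagged. "Top 10 %" is made exact by
rank with deterministic tie-breaks (larger D, then lower compartment id).
`p_dendrite` / `p_axon` are positives over compartments within each class.
A punctum is a single compartment; connected runs of supra-threshold
compartments are not merged.

**Peak location** is the midpoint of the maximal bin, ties resolved toward
the soma.

## Dynamics

**Photoconversion.** The remaining fraction subtracts the neighboring
region at every timepoint and normalizes by the t = 0 difference, making it
invariant under affine detector rescaling (the suite asserts this).
Fractions outside [0, 1] are reported as-is with warnings — clipping would
hide background or drift problems. A one-parameter exponential
`f(t) = e^(−λt)` summarizes each series by least squares of `log f` against
t through the origin; non-positive fractions are excluded (log-undefined),
fewer than two usable points is a fit error, and a negative slope estimate
is clipped to λ = 0. The fit is exact (1e-10) on noiseless exponentials.

**Comets.** Summaries are per neurite class (primary dendrite, higher-order
dendrite, axon): comet count, percent anterograde/retrograde (anterograde =
away from the cell body in both dendrites and axons), and mean ± SEM of
speed and track length (SEM uses the n−1 standard deviation; a single track
reports NaN SEM). Group comparisons are left to downstream statistics by
design. Kymograph/movie processing is upstream of this package; input is
the track table.

## Phenotype embedding

Feature vectors use the morphometrics the rest of the package computes
(total length, branch count, branch density, coverage, maximal order,
per-order branch counts, Sholl peak and peak radius). Columns are z-scored;
constant columns are dropped with a warning. t-SNE (scikit-learn, PCA
initialization, auto learning rate) runs under a mandatory seed, making
coordinates reproducible bit-for-bit for a fixed library version;
perplexity must be below `(n−1)/3` and defaults to 5, appropriate for
cohorts of 10–30 neurons. The silhouette score over group labels is the
quantitative stand-in for visual "co-clustering" claims. The original
embedding hyperparameters and feature list for such plots are generally
unstated; both are surfaced as configuration rather than guessed.

## Synthetic generators

The generators exist so that every analysis can be tested against
programmed ground truth; they emulate the *contrast* between neuron
classes, not the biophysics of dendrite growth.

**Arbors.** Topology and geometry are decoupled. The terminal budget is
split recursively with Beta(a, a)-distributed fractions — `a` directly
controls balance and hence Strahler depth — and the resulting branch tree
is laid out in the plane by stochastic elongation: jittered headings,
normal step lengths, radius taper with branch depth, mirror reflection at
the domain boundary. Space-filling classes add occupancy-grid steering
(choose the least-crowded of five candidate headings, with a small
straightness bonus), a cheap surrogate for dendritic self-avoidance.
Presets:

- `ci-control`: 30 terminals, 2 stems, 12 µm segments, a = 2, 240 µm
  domain → sparse arbors of 3–5 Strahler orders;
- `civ-control`: 400 terminals, 2 stems, 6 µm segments, ~4 segments per
  branch, a = 5, 225 µm domain with avoidance → 6–7 orders and ≥ 0.9 grid
  coverage at the 10 µm box.

These presets were calibrated once against the qualitative CI/CIV contrast
(branch count, order depth, coverage) and are fixed. Arbors are quasi-planar
(z = 0 by default, optional jitter), carry one soma node, one two-node axon
stub, and pass full validation. What they do *not* reproduce: realistic
branch-angle statistics, diameter scaling laws, tortuosity, or
activity-dependent growth — so passing tests demonstrate correctness of the
measurement code under known truth, not biological realism of the inputs.

**Channels.** Per-node intensity profiles over path distance (uniform,
linear decay, Gaussian bump) with additive Gaussian noise clipped to valid
ranges; volume fractions constant per spec. Cohort effects are programmed
as an MT baseline ratio and an F-actin bump center per group.

**Photoconversion series** are `B + A·e^(−λt) + ε` against a constant-`B`
neighboring region, with ε ~ N(0, noise·A) and a noise-free t = 0 so the
normalization denominator is exact. **Comet tables** draw directions
Bernoulli(p_retrograde) with truncated-normal speeds and lengths.
**Feature cohorts** for embedding tests are i.i.d. N(shift, 1) per group,
so "shift" is separation in within-group standard deviations.

Determinism: every generator is a pure function of (spec, seed); per-neuron
seeds derive from the master seed via `numpy` seed sequences with the
neuron index as spawn key. Ground truth is written beside generated data
and tests never re-derive truth through the code paths under test.

## Pipeline

`run_cohort` reads a manifest (neuron id, SWC path, channel path, group,
cell class), computes per-neuron morphometry, normalized per-channel
profiles, Strahler tables, pooled SYN classification and the embedding, and
writes TSVs with unit-declaring header comments and a run log listing every
warning and exclusion. Outputs carry no timestamps, so identical inputs and
configuration reproduce identical bytes. A failing neuron is skipped,
logged, and flags the run as failed while the remaining neurons still
produce output. Group statistics stop at mean ± SEM; inferential tests are
out of scope and can be applied to the emitted tables by any statistics
package.

## Problem sizes in the test and acceptance runs

The suite exercises oracle equivalences on hundreds of random trees of up
to ~80 nodes, recovery studies on CI-preset cohorts (3–4 neurons per group,
20 master seeds), 50-seed peak-recovery and comet-coverage studies, and a
handful of full CIV-preset arbors (~2 600 nodes each) for coverage and
round-trip checks; these sizes give stable statistics while keeping the
default run fast.

## Known limitations

- Coverage depends on the physical box size, which the original pixel-grid
  definition leaves open; only within-study comparisons at a fixed box are
  meaningful.
- Sholl profiles from projected images differ from 3-D profiles on
  non-planar arbors; both modes are provided but the default is 3-D.
- The exponential turnover model is a summary, not a mechanistic claim;
  two-component decays will show a systematic residual.
- t-SNE coordinates are only reproducible for a fixed scikit-learn
  version; the silhouette, not the coordinates, is the quantitative output.
- The growth model is phenomenological; generator calibration targets the
  class contrast, not any specific neuron's geometry.
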