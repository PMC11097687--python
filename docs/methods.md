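# Methods

This note documents the models, conventions, and numerical choices behind
vilinet, and what its synthetic data can and cannot tell you about real
histology.

## Model

Injury sizes are assumed power-law distributed, P(m) ∝ m⁻ᵅ, with α fit by
maximum likelihood per lobe. The expected number of injuries within Δm of
size m inside a region of radius r over time τ is n̄ = C·τ·r^d_f·Δm·m⁻ᵅ,
where d_f is the box-counting fractal dimension of the injured set — the
spatial scaling is r^d_f rather than r² because injuries do not fill the
plane uniformly. Histology is terminal, so the time factor is dropped for
measured data, giving the pairwise correlation weight

    n*_ij = C · l_ij^d_f · Δm · m_i^(−α)

with l_ij the Euclidean distance between region centroids and m_i the
candidate parent's area. This is the expected number of injuries of
comparable size in the space between i and j: when it is small, finding
those two injuries together is unlikely under independence, so they are
treated as correlated. Each region j links to the single parent i′
minimizing n*_ij (nearest-neighbor style, as in earthquake
mainshock–aftershock declustering); all other candidate links are
discarded. The in-degree of a node is the number of regions that select it
as parent; on both real and synthetic lobes the in-degree distribution is
power-law (scale-free), with a few hub regions receiving many
correlations.

With simulated event times the weight becomes
n_ij = C·l^d_f·t_ij·Δm·m_i^(−α), t_ij = t_j − t_i, with candidate parents
restricted to strictly earlier events; the earliest event is the lone
root, so a timed network over N nodes always has N − 1 edges.

Design choices within this model:

- **m in the weight is the candidate parent's area m_i.** This is what
  produces the rich-get-richer hub effect: large regions are cheap parents
  for everyone.
- **Edges are stored child → parent** so that "in-degree of i = number of
  regions correlating to i" holds literally. PageRank is run on that
  orientation (mass flows into hubs); a `reverse_edges` flag scores the
  opposite convention, since the directionality phrasing is genuinely
  ambiguous in the source description.
- **C = 1 and Δm = 1.** Both are positive scale factors that cancel in
  every argmin and in percentile thresholds; tests verify this invariance.
- **Ties** (exactly equal weights) break toward the larger parent area,
  then the smaller node id, making construction order-independent. Timed
  ties break by event order. Coincident centroids (l = 0) are an error —
  distinct nodes cannot share a centroid after component extraction.
- **Thresholding** keeps edges with weight ≤ n_c, where n_c is the linear
  interpolated percentile of edge weights (numpy convention). Percentile 0
  keeps the minimum-weight edge(s); 100 keeps all.
- PageRank uses damping 0.85, dangling mass redistributed uniformly,
  iterated to an L1 change below 1e-12; scores sum to 1 per lobe, with an
  optional per-lobe max-1 rescaling for display.

## Segmentation post-processing

Inputs are label images with codes {0 background, 1 injury, 2 air,
3 other}. The processing order is fixed: (1) the island filter reassigns
8-connected injured components of **fewer than 100 px** (strict
inequality) to `other`; (2) merging applies **five successive dilations
then five successive erosions** with a diameter-5 (radius-2) disk — read
as one large closing, which bridges gaps up to ~20 px; the alternative
reading (five dilate–erode closings, bridging ≤ 4 px) is available as
`mode="repeated_closing"`; (3) nodes are the 8-connected injured
components, with unweighted pixel-mean centroids ((row, col), 0-based) and
pixel-count areas. The closing operates on a zero-padded copy so the image
border never leaves erosion residue. 8-connectivity is used for the island
filter as well, for consistency with node extraction.

Lobe masks grow from connected `other` regions: regions whose
boundary-to-boundary distance is within 100 px are grouped (implemented by
growing every region by 50 px via a distance transform and unioning
regions that touch), interior holes (airways, enclosed airspaces) are
filled, and masks below 100,000 px are dropped as artifact. The optional
k-means background-exclusion step (brightest intensity cluster = bare
slide) is bypassed whenever a mask is supplied, as with synthetic data.

## Power-law fitting and plausibility

The continuous variant (injury areas) uses the exact MLE
α̂ = 1 + n/Σ ln(xᵢ/x_min); the discrete variant (in-degrees) maximizes the
Hurwitz-zeta-normalized likelihood numerically, started from
α̂ ≈ 1 + n/Σ ln(xᵢ/(x_min − ½)). When x_min is not fixed it is scanned
over the distinct sample values (thinned to ≤ 100 candidates) and chosen
to minimize the KS distance between the tail and the fitted model,
following the standard MLE+KS procedure. The scan requires at least 10
tail samples; a user-fixed x_min permits smaller samples with an
instability warning.

Plausibility is a semiparametric bootstrap: each replicate draws a
same-size dataset from the fitted tail model (exact inverse-CDF sampling
in both variants; the discrete inverse is solved by bisection on the zeta
survival function), resampling the observed below-x_min body when x_min
was scanned, refits under the same protocol, and records its KS distance.
p is the fraction of replicate distances ≥ the observed one, floored at
the resolution 1/n_boot; p ≥ 0.1 deems the power law plausible. Under the
null this p is approximately uniform: the rejection rate at 0.1 measures
0.10–0.11 over 200 runs (n = 500, 200 bootstrap replicates).

**In-degree fits use x_min = 1 (the full positive support).** The degree
law P(k) = k^(−γ) is a statement about the whole distribution, and a
500-node lobe typically has only ~25–30 nodes with positive in-degree, too
few for a meaningful cutoff scan. Size fits, with hundreds of
order-of-magnitude-spanning areas, use the scan (or a fixed floor at the
100-px filter, via config).

Box counting lays a grid anchored at the top-left of the lobe bounding
box, counts boxes containing ≥ 1 injured pixel for box sizes descending by
powers of two (base configurable; base 3 reproduces the Sierpinski carpet
dimension exactly), and takes d_f as the least-squares slope of
log N(s) vs log(1/s). No grid-offset averaging is performed. A single
injured pixel yields d_f = 0 with a degeneracy warning.

A log-log histogram-regression slope is provided alongside the MLE
(`histogram_slope`) because published "slopes of the frequency of injury
sizes" can mean either; the MLE is primary.

## Temporal simulation

Sizes and times are modeled as independent: a uniformly random injury
order receives cumulative exponential intervals (mean 2 s — a Poisson
process chosen for illustration, not mechanism). Each assignment yields a
timed network; 100 replicates (default) form the ensemble. Replicate
generators are spawned deterministically from the master seed, so
ensembles are exactly reproducible.

Secondary-injury rates: every edge is one secondary event at elapsed time
t_child − t_parent, pooled per replicate and per integer magnitude class
⌊log₁₀ m_parent⌋ (reference size 1 px). Counts fall into exponentially
growing time bins (growth factor 2 by default, configurable — no factor is
canonical) starting at the smallest observed elapsed time so that counts
are conserved; count/width gives the rate per second. Ensemble means carry
percentile-bootstrap 95% bands (10,000 resamples). Rates are pooled per
magnitude class by default; per-primary normalization (dividing by the
number of distinct parents) is an option, as the published curves do not
state which was used.

Centrality overlap: the top 0.5% (or 1%) of time-free PageRank scores is
intersected with the top-f timed scores for a grid of f, ensemble-averaged
with bootstrap bands; the chance line is f itself. Overlap is
non-decreasing in f and reaches 1 at f = 1.

Slope comparison (γ vs α): the ensemble of per-replicate in-degree slopes
is summarized by its median, with a percentile-bootstrap 95% CI for the
difference from the time-free slope and a two-sided bootstrap p;
single-replicate ensembles are flagged degenerate.

## Resampling inference

The group-difference test (medians or means) uses a **centered
within-group bootstrap null** by default: both groups are resampled from
themselves, and the bootstrap differences are centered at zero to form the
null. This gives p = 1 for identical constant groups, the 1/n_boot floor
for perfectly separated groups, and a measured type-I error of 0.03–0.05
at nominal 0.05 (500 null simulations, n = 30 per group). A pooled-null
variant (both groups resampled from the pooled data) is available;
pooled resampling of medians misbehaves on small strongly-bimodal groups,
which is why it is not the default. Sidedness is two-sided on
|difference| by default with a one-sided option. CIs are percentile
bootstrap; multiple comparisons use Benjamini–Hochberg step-up (via
statsmodels).

## Synthetic data

The generator emulates the *statistical* structure the analysis assumes,
not histology. A lobe is an inscribed ellipse; injuries are rasterized
disks with continuous power-law areas rounded to pixels, placed by
rejection sampling (10,000 attempts per blob, then an explicit failure
naming the blob) either uniformly or biased toward existing blobs
("clustered" — both are provided because the true spatial point process of
injuries is unknown); remaining lobe pixels are split into an air speckle
and `other`; outside is background. Ground truth (id, centroid, area,
optional time) is recorded for every blob.

Defaults, chosen once as the study-like regime: 768×768 px lobes, 150
injuries, α = 2.5, minimum area 100 px (the island-filter floor — the
smallest injury the pipeline would retain), minimum edge-to-edge gap 25 px
(just above the 21-px bridging reach of the default closing, so generated
blobs correspond 1:1 to extracted nodes), air fraction 0.3. A deterministic
200×200 toy fixture with a documented island manifest (99/100/150-px
islands, a 4-px-gap pair, an isolated control) supports exact tests of the
filter and merge rules.

What synthetic tests do **not** show: realistic injury shapes (disks have
no texture or anisotropy), staining or classifier noise (labels are
exact), the true spatial clustering of lung injury, or physical pixel
scale. Passing them demonstrates the pipeline's correctness and the
statistical behavior of the method under its own assumptions — not
biological validity on any particular dataset.

## Verification problem sizes

The acceptance checks run at sizes chosen to finish in about a minute:
simulator calibration over 10,000 intervals; MLE recovery over 100 runs of
n = 10⁴ per exponent; KS-null calibration over 200 runs (n = 500, 200
bootstrap replicates); brute-force network equivalence on 100 instances of
≤ 50 nodes; scale-free emergence on 20 synthetic 500-node lobes with a
10-replicate timed ensemble each (100 bootstrap replicates per fit);
overlap chance line over 20 configurations × 100 permutations; test
calibration over 500 null simulations with n_boot = 2000. The full-study
settings (100 replicates, 10,000 bootstrap samples) remain the library
defaults.

## Known limitations

- The correlation network is a modeling construct: links are statistical
  ("unlikely to co-occur by chance"), not mechanistic stress pathways.
- Injury growth and merging over time are not simulated; regions appear
  instantaneously with fixed sizes, and the timed analysis randomizes
  order rather than modeling propagation.
- Discrete power-law fits on very hub-dominated networks can rest on few
  distinct degree values; their p-values are then coarse.
- Box counting without offset averaging is grid-anchored; dimensions of
  sparse sets carry a small anchoring bias (an offset-averaging option
  exists).
- Percentile conventions, tie-breaks, and bin growth factors are stated
  choices; alternatives move only borderline cases.
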