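# Methods

This note records the models and procedures the package implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical conventions chosen where the design was open.

## Data model and preprocessing

Event data live in an `EventMatrix`: an events × channels matrix tagged
`raw` (ion counts, non-negative) or `arcsinh` (dimensionless). All analysis
operates on `asinh(x / c)`-transformed intensities with cofactor c = 5, the
mass-cytometry convention; the transform is applied uniformly to every
channel, and downstream operations select channels explicitly. Files are
read and written as FCS (3.0/3.1 read; 3.1 written: list mode, 32-bit
little-endian float, single dataset, fixed keyword order so identical inputs
produce byte-identical files). Per-event acquisition time is carried as a
`Time` channel on disk and as a separate non-decreasing vector in memory.

Single-channel spillover compensation subtracts a fixed fraction of a source
channel from a target channel (the oxide-spillover case, e.g. 1.9% of CD8
from gdTCR). Negative compensated values are retained: clamping at zero
would bias the medians used throughout the screen statistics. Compensation
is defined on the raw scale, before transformation.

## Barcode schemes and the experiment manifest

A k-of-n scheme enumerates the C(n, k) k-subsets of its channels in
lexicographic order; code ids are positions in that enumeration. The
manifest fixes all assignment conventions deterministically: wells are
batched in input order into ⌈n_wells / batch_size⌉ batches; each (donor,
treatment) pair takes the inner code of its lexicographic position; each
well takes the outer code of its position within its batch. Excluded wells
remain in the manifest with a flag — exclusion is an analysis decision, not
a design change — and are dropped from analysis after debarcoding.

## Debarcoding

Top-k route: each barcode channel is rescaled to [0, 1] over its 1st–99th
percentile window (robust to outliers; both percentiles configurable). An
event's candidate code is the set of its k brightest rescaled channels; its
separation is the difference between the k-th and (k+1)-th rescaled values
(for k = n, the k-th value itself). The event is assigned iff the candidate
is a valid scheme code and separation ≥ `min_separation` (default 0.3).
Invalid patterns and low-separation events are `Unassigned` by design: in
combinatorial barcoding such events are predominantly doublets or
acquisition artifacts, and forcing them to a nearest code would contaminate
downstream per-sample statistics. Raising `min_separation` can only shrink
the assigned set (monotone rejection).

Cluster route: the scheme is rewritten as a one-level gating hierarchy
(each code = conjunction of k positive and n−k negative barcode channels)
and passed through the subset labeler on the barcode channels only. On
well-separated data the two routes agree; the top-k route is the default
for speed.

Two-tier resolution solves the outer (well-within-batch) tier first, then
the inner (donor × treatment) tier, and accepts an event only when the
(inner, outer) pair appears in the batch's expected code table; pairs
outside the table (e.g. outer codes beyond a partial final batch's well
count) are `Unassigned`, not errors.

## SOM clustering

The FlowSOM-style backend is a rectangular-grid batch SOM: codebook
initialized by seeded sampling of events, then `n_epochs` (default 10–15)
rounds of assign-all-events / neighborhood-weighted-mean updates under a
Gaussian neighborhood whose width decays geometrically from half the grid
dimension to 0.5. Batch updates make training order-independent within an
epoch; rows are additionally canonicalized lexicographically before
training, so the fitted model is invariant to input event order and fully
determined by (data, parameters, seed). Metaclustering is average-linkage
agglomerative clustering on Euclidean codebook distances with ids
renumbered by first node occurrence; assignment is nearest-codebook-node
with ties to the lowest node index. Default grid 8×8 for labeling (10×10
available), metacluster count set by the caller.

## Subset labeling

The labeler walks the hierarchy level by level. Per parent subset it
clusters that parent's events on the union of the level's rule markers,
with k = min(2 × n_rules, 20, n_nodes, n_events) metaclusters — enough
granularity that clusters are pure in their sign vectors without
fragmenting small subsets.

Per marker, the binarization cutoff t* is searched over midpoints of
consecutive distinct cluster medians; t* maximizes the event-level MCC
between (x > t) and (event's cluster median > t), ties broken toward the
lowest t. A single cluster, or all medians equal, makes the marker
uninformative (score 0).

Cluster signing has one guard beyond the raw search. Quantizing a unimodal
marker into SOM clusters produces nonzero MCC (measured 0.45–0.84 on flat
markers), so median-side signing alone would invent positive clusters where
the parent has no modality structure on that marker. A marker's optimal
split therefore only signs clusters when the median intensity of events in
its positive clusters exceeds that of its negative clusters by at least
`min_marker_gap` (default 0.8 arcsinh units — above quantization gaps on
realistic within-modality spreads, below genuine staining separations).
Below the gap, clusters are signed against an absolute positivity anchor
(default 1.0 arcsinh units, the boundary between background and stained
signal at cofactor 5): a parent uniformly negative for a rule marker then
matches no spurious rule, and a parent uniformly positive (e.g. a batch
containing a single barcode code) still matches the right one.

A cluster satisfying exactly one rule takes that rule's child label;
satisfying none makes it `Unassigned` (conservative: hierarchy gaps should
surface, not be papered over); satisfying several is a configuration error —
rules within a level must be mutually exclusive. Every event ends at a
terminal label or `Unassigned`, and label counts always partition the
events. Each sample unit is labeled independently, as an automated platform
does per sample.

## Profiling

Each terminal subset is clustered separately, so profiling clusters never
straddle subsets. A probe partition (the subset's SOM metaclustered to 8)
measures each marker's achievable binarization MCC; the same quantization
guard applies, with a larger gap (`het_min_gap` = 1.2 arcsinh units) since
profiling should only split on unambiguous bimodality. The cluster count is
then k = 1 + (number of markers with achievable MCC ≥ 0.7), capped at
min(8, ⌊n_events / 200⌋), and k = 1 for subsets under 200 cells or with no
heterogeneous marker. Clusters are named by the top marker(s) — all within
0.05 of the best MCC, at most two — with `hi`/`lo` suffixes per cluster
sign; collisions append the next-best marker, and if no marker reaches MCC
0.5 the clusters fall back to `C1..Ck`. Profiling pools each subset across
sample units so profiling-subset names are comparable between donors and
treatments.

## AOF family

AOF fits a normal to each modality and measures cross-tails: the fraction
of negative events above the positive fit's 5th percentile, averaged with
the fraction of positive events below the negative fit's 95th percentile.
Complete separation gives 0; identical normal modalities give Φ(1.645) ≈
0.95, the formula's intrinsic ceiling. A zero-variance modality is treated
as a point mass (tail percentile = its mean). Modalities come from an exact
1-d two-means split (boundary at the midpoint of the cluster means), a
fixed threshold, or caller-supplied labels. The labeled split is preferred
for drift QC: when a drifting background merges into the positive
population, an unsupervised split under-reports the overlap by
construction, while expected-positive subset membership does not.

Scaled²AOF z-scores each marker's AOF across samples (sd with ddof 1;
negative z floored at 0, then squared; zero-sd rows scale to 0) and
Quality²AOF sums over markers per sample, making quality additive over
disjoint marker sets. Drift detection splits each batch into four
equal-count time quartiles and flags when last-quartile AOF exceeds
first-quartile AOF by more than 0.1 (conservative; configurable). The
first quartile of a flagged batch retains pre-drift quality.

## Screen statistics

One blank threshold — the 99th percentile (linear interpolation) of the
blank well's readout — is computed per (donor, treatment): blank background
may shift with fixation, and the blank well itself then scores ≈1% positive
by construction. Percent positive is the strict fraction above threshold.
Every (subset, antibody) combination present in a condition is emitted,
with null statistics at zero events.

Fixation analysis converts arcsinh medians back to the raw scale
(sinh(m)·c) before taking fold changes, because fixation acts
multiplicatively on raw intensity and medians commute with the monotone
transform; log10 ratios of transformed medians would understate every fold
change. An antibody is "expressed" when its percent positive reaches 5% in
at least one subset in either condition (the floor is configurable; a
literal above-blank criterion is vacuous at the ~1% base rate). The
antibody-level ratio is the median log10(fixed/fresh) over expressing
subsets — robust to subset-specific exceptions, which remain visible in the
per-subset table — and the class is gain/loss at ±log10(2) (the 2-fold
convention; the alternative log10 > 0.5 convention is a parameter).

The differential-marker test fits, per donor, OLS of percent positive in
the target profiling subset on the reference subset across antibodies
(intercept included, so a constant shift in both subsets cancels).
Standardized residuals are residual / sd(residuals) (simple, not
studentized); an antibody is flagged when |standardized residual| > 2 in
every donor with one consistent sign, and sign-inconsistent candidates are
dropped with a warning. At least two donors and ten antibodies are required
for the consensus and the residual scale to be meaningful.

## Synthetic experiments

The generator emulates the screen design end to end: per-donor subset
mixtures with Gaussian marker modalities on the arcsinh scale (optionally
bimodal with a high-expressing fraction), two-tier barcode channels
(positive/negative levels 2.5/0.3 with noise sd 0.15 by default), a
per-antibody readout channel with per-subset (or per-profiling-component)
positive fractions, uniformly-spread sorted acquisition times, optional
linear background drift on one marker's negative modality, and
multiplicative fixation factors on the raw readout. Values map to raw
counts via sinh(x)·c clipped at zero; ground truth (subset, bimodal
component, readout positivity, sample unit) is returned as a sidecar.

Random streams are keyed by (seed, donor, well): the fresh and fixed
aliquots of a well share draws, so a planted fixation factor produces an
exactly known fold change, which is what the fixation statistics are tested
against. The bundled reference configuration uses 3 donors × 2 treatments ×
20 wells (blank + 19 antibodies, two batches of ten) at 400 events per
sample unit — 48,000 events per run, sized so the full pipeline and its
recovery checks complete in seconds while every per-cell statistic retains
a few hundred events.

What the generator does not emulate — and what passing tests therefore do
not establish about real data: doublets and debris, bead events, spillover
between barcode channels, heavy-tailed or zero-inflated count noise,
donor-specific staining shifts, and instrument sensitivity changes beyond
the linear drift term. Recovery rates on generator output are upper bounds;
the design-arithmetic and formula checks are exact regardless.

## Numerical conventions

Percentiles use linear interpolation throughout. Precision/recall with an
empty denominator return 0 with a warning; MCC with an empty marginal
returns 0. Sample standard deviations use ddof 1. The MCC threshold search
breaks ties toward the lowest cutoff; metacluster ids renumber by first
node occurrence; nearest-node ties go to the lowest index. All stochastic
steps derive from a single integer seed via independent spawned streams,
and every artifact (FCS, CSV, JSON) is byte-stable under a fixed seed.
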