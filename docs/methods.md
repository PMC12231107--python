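# Methods

This note documents the models, estimators and numerical choices behind
`chemnet`, what its synthetic data does and does not emulate, and the
known limitations of each stage.

## Growth and phenotype statistics

**Mid-log selection.** Residual growth is evaluated at the earliest
control time point with OD600 inside [0.3, 0.5] (inclusive, no
interpolation). A curve that skips the window between hourly readings
raises an explicit error rather than silently using a neighbouring
point; the window is configurable.

**Percent residual growth** is (treated OD / control OD) × 100. When
replicate vectors have equal length they are paired by index (replicates
of a screen are usually processed in parallel and share batch effects);
unequal counts fall back to the mean over all pairs. The statistic is
invariant to a common gain on both channels.

**Dose-response (IC50).** The 4-parameter log-logistic
`r(d) = bottom + (top − bottom)/(1 + (d/IC50)^h)` is fitted by bounded
least squares on log10 dose (trust-region reflective, xtol = ftol =
1e-14). On the percent-growth scale `bottom` is constrained to ≥ 0 and
`top` to ≤ 120 to stabilise small-n fits; an IC50 outside the tested
dose range is flagged `extrapolated`. Fits require ≥ 4 distinct doses
and ≥ 10 percentage points of response span — flatter data carry no
dose information and are rejected rather than fitted.

**Synergy.** The combination index
((combo/drug A)/(drug B/vehicle)) × 100 equals 100 under Bliss-style
multiplicative non-interaction; values below 100 indicate synergy. The
pairing of numerators and denominators follows the convention that drug
A is the reference backbone treatment; because the published shorthand
for this ratio is notationally ambiguous, the function takes all four
growth values explicitly and documents the order.

**t-test.** Classical equal-variance Student's t (two-tailed) by
default, Welch by flag. Degenerate inputs (n < 2, zero pooled variance
with unequal means) raise instead of returning p = 0.

## Screen scoring

**Plate normalization.** Colony sizes are divided by the plate median;
multiplicative row and column effects are then estimated *from interior
(non-border) positions only* by alternating median division to a fixed
point (tolerance 1e-13, ≤ 200 sweeps), and divided out of full rows and
columns. Border positions never enter a median estimate; they receive a
single border/interior median-ratio rescale, which corrects the mean
nutrient-surplus edge effect of pinned arrays but — a deliberate
limitation — not per-row/column trends along the border itself.
Rankings of candidate hits should therefore be read within the interior.
Missing colonies are NaN throughout and are never imputed to zero. The
transform is idempotent and leaves the interior median at exactly 1.

**Epistasis score.** ((double/query)/(array/wild-type)) × 100, i.e. the
double mutant's growth relative to the multiplicative expectation of
the two single mutants. Scores are rescaled so a phenotypically neutral
reference double (the query crossed with a filler deletion) scores
exactly 100; the rescaling is per-plate, since plate effects dominate
pinned screens.

**Hit calling** is two-stage. Screen stage: a strain is a putative hit
if its per-screen mean crosses the effect threshold *and* a one-sample
t-test against 100 gives p < α, in at least 2 of 3 independent screens,
all in one direction. Validation stage: replicates are pooled and the
call made once at tighter thresholds (defaults 75/130 on the percent
scale). No multiple-testing correction is applied by default — the
screen design relies on effect-size plus replication filtering — but BH
is available by flag. A strain whose vehicle growth is below 10% of the
plate median is reported `inviable` and excluded from calls. With
effect thresholds disabled, the validation-stage caller's false-positive
rate under a null screen is the nominal α (checked at 5% ± 2% over 200
simulated screens); the 2-of-3 replication rule is far stricter than α
by construction, so calibration is a property of the single-screen test.

## Microscopy scoring

Abundance is the median per-cell GFP/RFP ratio per condition; the
percent change of the treated median versus control is flagged above a
20% cutoff. The median is used because high-content imaging produces
heavy-tailed bright-aggregate outliers that would dominate a mean; the
test suite demonstrates that a 5% contamination of 10× outliers flips a
mean-based call but not the median-based one. Calls require ≥ 50 cells
per condition (a floor well under the ~200 cells per replicate of a
typical imaging run). Localization uses the modal-compartment rule: a
shift is called when the modal compartment changes and the new mode
gains ≥ 20 percentage points of cells. This is a codified proxy for
what is, in practice, visual inspection; it deliberately ignores
secondary-compartment growth that leaves the mode unchanged.

## Network analysis

**Filtering.** Edges are kept at combined score ≥ 900 (0–1000 scale)
with a non-zero experimental-evidence channel, the conventional
high-confidence setting for STRING-style interactomes. Duplicate
orientations collapse to one undirected edge (max scores kept);
identifiers are opaque case-normalized strings — ortholog/alias mapping
is the caller's responsibility.

**Minimum network.** The smallest connector-augmented subnetwork
joining the seeds is a node-weighted Steiner problem; `chemnet` uses
the Takahashi–Matsuyama incremental heuristic with unit edge lengths:
grow a tree from the lexicographically smallest seed, repeatedly
attaching the nearest unconnected seed via its shortest path. Parent
selection in the multi-source BFS is lexicographic, so results are
fully deterministic. The heuristic carries the classical 2-approximation
guarantee on tree cost; on trees it is exact, and the test suite checks
a ≤ 2× connector-count ratio against exhaustive enumeration on small
instances. Seeds in different components get one tree each and are
reported, never dropped.

**Betweenness** is Brandes on the unweighted undirected subnetwork,
unnormalized, endpoints excluded, with fractional credit across
equal-length shortest paths — the raw-scale values practitioners rank
hub genes by. Confidence scores are not used as distances.

**Communities.** The two-level map equation
`L(M) = q H(Q) + Σ_i p_i H(P_i)` scores a partition by the description
length of a degree-proportional random walk with one index codebook and
one codebook per module (no teleportation). It is minimised
Louvain-style: greedy node moving to the neighbouring module with the
largest codelength decrease (strict descent, 1e-12 threshold), module
aggregation, and repetition until no merge occurs; the result is a flat
partition. Node visit order is the only randomised choice and is drawn
from a seeded substream, so runs are deterministic, and the codelength
trace is non-increasing by construction. On planted partitions with 4
blocks of 25 nodes (within-block edge probability 0.3, between 0.02)
the optimiser recovers the blocks at NMI ≥ 0.9 in ≥ 18/20 seeds.

**Community significance.** For each community, p = (1 + #{null ≥
observed internal edges})/(n_null + 1) under a degree-preserving
double-edge-swap null of the whole graph (10 × |E| swap attempts per
sample, fresh RNG substream per sample index, so samples are
reproducible independently of each other). The estimator is exact-level
for continuous statistics but conservative under ties: on small sparse
graphs the internal-edge count takes few values and the achievable
significance level drops below nominal. Calibration checks therefore
use graphs dense enough (100 nodes, edge density 0.1) for the count to
be nearly continuous; on very small subnetworks p-values should be read
as conservative. A community spanning the whole graph has an invariant
statistic and p = 1 by construction.

## Enrichment

The exact hypergeometric upper tail P(X ≥ k) is computed for each set
(sets intersected with the universe first), BH-adjusted across the
collection. Two effect descriptions are reported side by side: the
literal observed/expected ratio (fold enrichment, (k/n)/(K/N)) and the
standardized deviation z = (k − nK/N)/sd, whose product with −ln p
gives the Enrichr-style combined ranking score (unadjusted p by
default, adjusted by flag). The default universe is the screened
library, not the genome — enrichment is universe-sensitive by design
and the universe is always an explicit argument. Per-community
enrichment skips communities of fewer than 3 mapped genes (a
hypergeometric test on 1–2 genes is vacuous) and reports them as
`too_small`.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their parameters and a master
seed; per-entity substreams (keyed by stage name and entity id) keep
existing draws stable when entities are added. Noise is multiplicative
log-normal on OD and fluorescence intensities — biological measurements
are positive with roughly constant CV; the relative s.d. defaults to
0.05 for growth and 0.10 for intensities, calibration choices in the
range typical of replicate yeast screens rather than measured values.

Growth curves follow the logistic closed form
OD(t) = K·od0·e^{rt}/(K + od0(e^{rt} − 1)) (defaults r = 0.5 h⁻¹,
K = 2.0, od0 = 0.05, hourly readings); a planted strain's effect
multiplier scales its growth rate under treatment. A separate
score-level generator draws percent-growth observations directly around
a planted true score (100 × multiplier), which is the right level for
exercising the hit caller. Interactomes come as Erdős–Rényi,
preferential-attachment, or planted-partition graphs with integer
confidence scores (a configurable fraction ≥ 900) and an
experimental-evidence channel; beyond degree heterogeneity no attempt
is made to mimic real interactome topology. Gene-set collections
default to a universe of 2000, query of 20 and sets of 10, with planted
sets drawing 80% of their members from the query — sizes at which a
decoy set needs an overlap of ≥ 3 (probability ≈ 1.5 × 10⁻⁴) to reach
BH significance, so exact-recovery tests are meaningful. Microscopy
tables draw per-cell intensities log-normally with 90% of cells in the
condition's dominant compartment.

Passing tests on these inputs demonstrate the estimators' correctness
and calibration under the stated noise model; they do not demonstrate
robustness to batch effects, spatial autocorrelation within plates,
cell-cycle heterogeneity, or annotation errors, none of which are
simulated.

## Pipeline

The default pipeline config defines a coherent simulated study over one
gene namespace: 100 genes in 4 planted blocks (within-block edge
probability 0.5, 70% of edges high-confidence, 90% with experimental
evidence — a curated high-confidence interactome retains most true
edges), 8 sensitive and 2 resistant strains plus 4 abundance-shifted
proteins all inside the first block, and a gene-set collection whose
first set is that block. Outputs are plain TSV/JSON; `manifest.json`
records the config echo, seed, package version and SHA-256 checksums of
every output, and contains no timestamps, so identical configs produce
byte-identical runs. Stages abort with the stage name on error rather
than cascading.

## Problem sizes in the test suite

Oracle comparisons run on exhaustively enumerable instances (graphs of
≤ 10 nodes, hypergeometric grids to N = 30, all bipartitions of 12
nodes); recovery and calibration studies use 20–200 simulated
repetitions with seeds fixed in the test code. These sizes were chosen
so each property is measured with useful statistical resolution while
the whole suite stays quick to run end to end.
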