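# Methods

This note documents the models implemented in `glandphylo`, the
assumptions behind them, the defaults of the synthetic-data generator,
and the numerical choices that are not obvious from the API.

## The observable and its reading

The central observable is a matrix of alt/total read counts per
(mutation, microdissection). A microdissection is a patch of ~200–500
contiguous epithelial cells sequenced as one ~25–35× whole genome; it
is generally a polyclonal mixture, so a mutation carried by a fraction
*cc* of its cells appears at VAF *cc*/2 under diploidy. Diploidy is
assumed genome-wide: copy-number events are rare in normal epithelium
and are out of scope, as is any sequence context (mutations are opaque
integer ids; signature analysis is not attempted).

A mutation is *reported* in a sample when it reaches 4 alt reads
there; a locus enters the matrix when it is reported in at least one
sample, and its counts are then taken from every sample.

## Burden clock

**Clonality.** *c* = median VAF of a sample's reported calls. It
proxies half the cellular fraction of the dominant clone; in this
tissue it typically falls in 0.15–0.3 (30–60 % of cells clonally
related).

**Inclusion filter.** Because a call needs 4 alt reads, clonality *c*
is only measurable where depth *d* ≥ 4/*c* (8× suffices for a clonal
diploid sample at *c* = 0.5; *c* = 0.1 needs 40×). A sample is kept
when that depth is available over at least 75 % of its genome. Depth
profiles are summarised as empirical fraction-at-depth (or a Poisson
model around the sample mean when only the mean is known); per-site
genome depth is not modelled. The float quotient 4/*c* is computed
with a 1e−9 guard before the ceiling so that, e.g., *c* = 0.1 maps to
40 and not 41.

**Sensitivity and correction.** Default sensitivity is the exact
binomial tail s(d, v) = P(X ≥ 4), X ~ Binomial(d, v), evaluated at the
sample's clonality and averaged over its depth distribution; corrected
burden is *b*<sub>c</sub> = *b*<sub>r</sub>/*s*. A logistic GLM
(features 1, d, v, d·v) trained on simulated adjacent-section-style
detection data is available as `fitted_glm`; the binomial tail is the
default because it is analytically exact under the calling rule and
requires no external calibration data. VAFs above the diploid bound
0.5 are clamped with a warning. Corrections at *s* ≤ 0.05 are refused
(the estimate would be explosive) and the sample excluded with a
reason. Sensitivity is applied per sample, at the sample's overall
clonality; a per-clone correction would be the natural refinement but
requires the clustering step to precede burden estimation.

**Clock.** *b*<sub>c</sub> ~ age with a donor random intercept,
fitted by REML (statsmodels `MixedLM`) with Wald 95 % CIs. Two
degenerate cases are handled explicitly: a single donor falls back to
OLS with a warning (the random intercept is unidentifiable), and
exactly collinear data (zero residual variance, as in a noise-free
round-trip test) returns the OLS interpolating line, since REML
variance components are unidentifiable at zero residual. Inverting
the clock maps burdens to ages ((b − intercept)/rate, clamped at 0);
integer brackets use floor for the lower bound and ceiling for the
upper, which is how a 300–400-mutation range reads as "ages 10–17" at
intercept 130 and rate 16.4.

## VAF clustering

Mutations on the same ancestral branch share a VAF vector across
samples. The model is a Dirichlet-process mixture: cluster *k* has an
independent latent VAF θ<sub>k,s</sub> per sample with a Beta(1, 5)
prior (favouring low VAFs, the polyclonal regime), alt counts are
Binomial(depth, θ), and the partition follows a CRP with α = 1. The
Betas are integrated out and the partition sampled by collapsed Gibbs.
This is a deliberate simplification of a full hierarchical DP: the
hierarchical sharing of atoms across samples is not needed to obtain
concentrated clusters of mutations with similar VAF vectors, which is
the object the downstream tree requires.

Single-site Gibbs mixes poorly across partition modes: it drains
clusters one mutation at a time, so it can neither merge a redundantly
split cluster nor nucleate a small cluster whose first member loses
probability on its own. The sampler therefore (i) starts from a
deliberately over-fragmented k-means partition of the VAF vectors
(k ≈ n/150, clipped to [15, 120]), and (ii) follows every sweep with
whole-cluster merge proposals and 2-means split proposals, accepted
when they raise the collapsed posterior. These moves make the chain a
MAP-seeking search; the reported hard assignment is the best sweep by
joint posterior (ties keep the earliest), and the co-clustering
frequencies retained over a ≤ 1500-mutation diagnostic subset are
approximate posterior summaries rather than exact MCMC averages — a
trade documented here because the downstream pipeline only consumes
the MAP partition. Defaults are 60 sweeps with 30 burn-in; the scan
runs in canonical (sorted id) order with all randomness from one
seeded generator, so results are independent of input row order and
reproducible across processes. Above 40 000 mutations a random subset
is sampled and the remainder assigned to the MAP clusters by
posterior-mean likelihood. When Beta hyperparameters are integers the
Beta-function ratios are evaluated through a precomputed log-gamma
table on integer counts.

Missing observations (depth 0) contribute likelihood 1. Clusters below
10 mutations are dropped before tree building. `artifact_screen` is a
reporting hook flagging clusters whose members are systematically
marked by a caller-quality predicate; it replaces manual per-cluster
inspection and removes nothing by itself.

Cellular contribution per sample is *cc* = min(2 *m*, 1) with *m* the
cluster's per-sample median VAF; *m* = 0.5 means every cell of the
microdissection descends from the cluster's ancestral cell. The cap
handles sampling noise above 0.5.

## Pigeonhole phylogeny

Contributions of disjoint clones cannot sum above 100 % in any
microdissection. Three rules generate nesting evidence for a cluster
pair, strongest first:

* `certain_95` — both clusters above 95 % cc in the same sample;
* `strong_75` — same relative contribution pattern across samples
  (operationalised as cosine similarity ≥ 0.95 between cc vectors; the
  pattern-match metric is this package's choice) with joint cc ≥ 75 %
  in at least one sample;
* `pigeonhole_sum` — joint cc above 1 + tolerance somewhere.

The cc tolerance defaults to 0.1 to absorb binomial noise in median
VAFs. Direction: a direction is admissible only if the descendant
never exceeds the ancestor by more than the tolerance in any sample;
among admissible directions the cluster with the larger cc in the
witnessing sample is the ancestor (total cc breaks exact ties). Pairs
with no admissible direction, or with witnessing samples disagreeing,
are reported as conflicts and excluded rather than silently resolved.

Each cluster's parent is its most recent proven ancestor: among the
transitively closed ancestor set, the candidate nested below the most
other candidates, with total cc slack (Σ<sub>s</sub> max(cc<sub>anc</sub> −
cc<sub>child</sub>, 0)) breaking ties. Ancestor sets that are not
totally ordered are recorded as ambiguous on the tree. Cyclic evidence
raises an error naming the cycle. Unnested clusters attach to a
synthetic zero-length root; branch lengths are cluster mutation
counts, so molecular time (root-to-node mutation sum) dates nodes to
epochs: < 20 embryonic, 20–300 childhood (a quiescent interval in
which essentially no coalescences occur), 300–500 pubertal, > 500
adult. Trees round-trip through Newick with internal labels and exact
branch lengths.

## Spatial cartography

Distances are duct-path distances from the urethral origin (sums of
segment lengths), not Euclidean distances — clones spread along ducts,
and the contiguity claims are ductal. Classical (Torgerson) MDS
flattens 3D sample positions: double-centred −D²/2, top-2
eigenvectors scaled by √eigenvalues, each axis oriented so its
largest-magnitude loading is positive (projections are otherwise
orientation-arbitrary); a warning fires when more than half the
positive eigenvalue mass is matched by negative mass (grossly
non-Euclidean input). Gradient fits (burden ~ distance, telomere ~
distance, telomere ~ burden) are plain OLS with Wald CIs; excluding
outlying samples (e.g. burdens above 2 000) is a re-fit option, not a
default. Clone territories take a cluster's positive samples
(cc ≥ 0.10, boundary inclusive) and join two samples when the duct
path between them crosses no negative sample's node (unsampled nodes
do not interrupt). A microdissection is multiclonal when more than
one embryonic cluster exceeds 10 % contribution. Adult clones whose
territory exceeds 5 microdissections are flagged as candidate driver
expansions. Whether multiclonality correlates with distance is
assessed by a logistic regression of the multiclonal flag on distance
(the model choice is ours; no particular test is canonical here).
Static clone-map plotting is deliberately not included; territories
and projections are emitted as tables.

## Synthetic gland

The generator encodes the tissue's developmental narrative; its
defaults are the study conditions the recovery modules are tested
against.

* **Topology** — a short trunk from the urethral origin, then
  recursive binary splitting down to `n_terminal_acini` (default 14)
  acinus leaves, segment lengths log-normal (median 150 μm, σ = 0.4),
  positions from a persistent 3D random walk. The paper-scale object
  is one ductal subunit; the default tree has ~35 nodes.
* **Embryonic founders** — 5–10 founders colonise the tree by
  competitive boundary spreading from farthest-point-separated seeds
  (contiguous territories), and a repair pass guarantees each founder
  at least ~3 duct segments: each founder built a rudimentary duct,
  not a single segment, and a one-segment founder would leave an
  embryonic cluster witnessed by a single microdissection, which no
  VAF clustering can place. 27 % of nodes receive a minor second founder at a
  10.5–15 % cell share, which is what makes microdissections
  multiclonal; founder-split times are drawn at 16–19.5 mutations so
  embryonic clusters carry ~16–20 mutations — below the 20-mutation
  embryonic boundary but robustly above the 10-mutation cluster
  filter.
* **Pubertal subclones** — up to 2 per founder, founded at 300–500
  mutations of molecular time, each owning a contiguous side-branch
  subtree within founder-pure territory and claiming 90–98 % of local
  cells (these branches grew from the clone during puberty).
* **Adult lineages** — per duct node, one dominant lineage claiming
  52–60 % of its parent clone's cells (dominant-clone cellular
  fractions around 0.45–0.6, i.e. the upper half of the observed
  30–60 % clonal-relatedness range, and median VAFs in 0.15–0.3) and
  two minor lineages at 12–19 % shares. The minors sit below the 0.2
  cc detectability bar by design: they exist to supply the low-VAF
  call mass that makes samples polyclonal, not to be recovered. The
  dominant lineage's MRCA sits at 70–90 % of total molecular time;
  later mutations form a subclonal tail at Beta(1, 5)-scaled fractions
  of the dominant cc.
* **Clock and gradient** — total molecular time is intercept +
  rate × age (defaults 133 and 16.4; age 59), and the 0.06
  mutations/μm proximal-to-distal gradient plus a 100-mutation
  Gaussian dispersion are realised on the terminal branch of each
  node's dominant lineage. Attributing the gradient to terminal
  branches (rather than a per-branch rate multiplier) keeps shared
  branch lengths consistent across nodes while preserving the
  defining property — expected terminal burden = intercept +
  rate × age + gradient × distance.
* **Telomeres** — baseline 5 000 bp − 0.32 bp/mutation × true burden
  + N(0, 70 bp) noise; the noise level puts the telomere~burden R²
  near the observed ~0.2.
* **Reads** — microdissections sample every non-root node by default
  (48 requested against ~35 available — the study design microdissects
  whole ductal units nearly exhaustively, and sparse sampling leaves
  clones witnessed by a single sample, which no VAF clustering can
  place reliably). Depth is Poisson per mutation around a per-sample
  mean drawn N(30, 2.5); alt counts Binomial(depth, cc/2); reporting
  requires 4 alt reads somewhere. Truth retains censored mutations,
  per-clone cc per sample, realised branch lengths, and per-sample
  true burden (the dominant lineage's realised mutation count).
* **Driver runs** — with `driver_expansion_flag` one adult clone
  (founded at 550–700 mutations) takes a 75–90 % share across a whole
  reserved subtree with ≥ 4 terminal branches and ≥ 13 nodes,
  emulating a driver-mutant intraepithelial expansion; its per-node
  adult subclones make it the only adult coalescence in the tree.

The separate clock-cohort simulator draws corrected burdens for eight
donors (ages 22–78) as intercept + slope × age + donor intercept
(sd 150) + within-donor noise (sd 550). Burdens are not truncated at
zero, so the Gaussian mixed model analysing them is correctly
specified; at the youngest ages this admits (biologically impossible)
negative burdens — it is a calibration construct for the regression,
not a tissue model.

**What the generator does not emulate.** Real data have mapping and
calling artifacts, copy-number aberrations, index swaps, and clones
whose cc hovers at the detection boundary; the generator's clones are
cleanly separated in VAF space and its noise is exactly binomial.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to caller artifacts.
The artifact screen and the conflict reporting are the hooks where
real-data messiness would surface.

## Validation harness

`evaluate.clustering_ari` scores the partition on the stem mutations
of *detectable* clones (≥ 10 realised stem mutations and cc ≥ 0.2 in
at least one sample — clones below either bar are not recoverable from
read counts even in principle). `evaluate.tree_recovery_rf` maps
inferred clusters to clones by majority vote, restricts both trees to
the matched detectable set, and reports the Robinson–Foulds distance
as the symmetric difference of clade label-sets (trees here are
fully labelled, so RF 0 is identical parent structure). Problem sizes
used by the test suite — a ~35-node gland with ~30 000 detected
mutations for the recovery checks, fifty 10-acinus glands and fifty
8-donor cohorts for the coverage checks — were chosen as the smallest
instances that still exercise every regime of the model.
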