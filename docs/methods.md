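# Methods

This note documents the models implemented in `tipdating`, the
numerical and design choices behind them, what the synthetic-data
generators do and do not emulate, and the package's known limitations.

## Data model

A `CombinedDataset` joins a discrete morphological matrix, a
partitioned molecular supermatrix and per-taxon metadata (extant flag,
stratigraphic age window in Ma, one of six biogeographic areas) onto a
single taxon namespace. Taxa present in only one source receive
all-missing rows in the other. Missing (`?`) and inapplicable (`-`)
observations are preserved verbatim on round-trip but are treated
identically in the likelihood (all states allowed), since the Mk model
makes no distinction. Taxon-name matching is exact after
whitespace/underscore normalization.

Ordering flags and per-character state counts live in a JSON sidecar
rather than being guessed from NEXUS dialects; the sidecar is
authoritative.

### Ordered-polymorphism recoding

Ordered transformation series that contain polymorphic cells are
recoded by inserting an intermediate state between every adjacent pair
of original states that co-occurs in a polymorphism, relabeling once at
the end so the scale stays contiguous; a polymorphic pair `{a, a+1}`
becomes the single inserted intermediate. A character whose expanded
scale would exceed six states (the common tool limit for ordered
series) keeps standard polymorphic scoring and is flagged. Polymorphic
cells spanning more than two states map to the contiguous block of new
labels between their endpoints; cells spanning non-adjacent ordered
states follow a configurable policy (reject, or leave the character
with polymorphic scoring — the default, since no convention is
universal). The operation is idempotent: recoded characters carry an
internal processed flag and are skipped on re-application.

## Likelihoods

Morphological partitions use the Mk model: a symmetric k-state CTMC
with uniform stationary frequencies, either unordered (all exchanges
allowed) or ordered (only |i−j| = 1 exchanges). Molecular partitions
use GTR, optionally +I. Both support discrete-gamma rate heterogeneity
with four categories by default, using **category means** (the
convention of the inference tool the pipeline mirrors; medians are
available via a flag). Rate matrices are normalized to one expected
event per unit branch length at stationarity, so branch lengths read as
expected substitutions per site/character.

Likelihoods are computed by Felsenstein pruning, vectorized over site
patterns, with per-node rescaling by the pattern-wise maximum and
accumulated log factors to prevent underflow; transition matrices come
from a cached symmetric eigendecomposition (all implemented models are
reversible). DNA columns are compressed to unique patterns with
weights. Polymorphic observations enter as partial-ambiguity
indicators (sum over member states); a fully missing character
contributes exactly zero log-likelihood and no ascertainment term.

**Variable coding (ascertainment correction).** Each character's
log-likelihood is corrected to condition on the character being
variable: `lnL_corrected = lnL − log(1 − Σ_s P(constant pattern s))`,
with the constant-pattern probabilities computed by a pruning pass over
the k constant patterns under the same gamma mixture. When the
correction argument is numerically non-positive (e.g. tree length → 0,
where all patterns are constant) the operation raises with diagnostics
rather than silently returning −inf.

`p_invariant` is implemented as a two-component mixture with the gamma
mixture nested inside the variable component.

## Tree priors

**FBD.** The fossilized-birth-death prior is parameterized as
(speciation λ, turnover μ/λ, sampling proportion ψ/(μ+ψ), fixed extant
sampling probability ρ), so the two bounded quantities take flat
Beta(1,1) priors and λ takes an exponential(rate 10) prior — the
defaults of the mirrored tool. The density is the standard q/p0
product form for trees whose fossils are terminal sampled tips:
conditioning on the origin (origin defaulting to the root age, i.e. a
zero-length stem), with a condition-on-root alternative and optional
survival conditioning. It reduces exactly to the pure-birth closed
form at μ = ψ = 0, ρ = 1, and is cross-checked against an
independently coded edge-wise evaluation.

A **sampling-with-removal** variant (`removal=True`) is also provided,
in which a lineage terminates at fossil sampling. The p0 and q
functions satisfy the same ODEs in both variants; the only difference
is that the per-fossil no-sampled-descendants factor p0(y) is dropped.
This variant exactly matches the forward simulator (below) and is used
in the self-consistency recovery experiments; the no-removal form
remains the default because it is the convention of the tool the
pipeline mirrors.

**Relaxed clock (IGR).** Each branch of duration d carries an
independent multiplier m ~ Gamma(shape d/v, rate d/v) — mean 1,
variance v/d — so the variance of the branch-length deviation is
proportional to v, and v takes an exponential(10) prior. The effective
branch length is duration × multiplier × base clock rate. The exact
variance convention of the original tool version is not documented;
this contract is stated explicitly so the density oracle is
unambiguous.

**Clock-rate prior derivation.** From a non-clock tree, per-tip rates
are computed as (root-to-tip path length in substitutions) / (root age −
tip age), with tip ages 0 for extant taxa and age-window midpoints for
fossils. Normal, lognormal and gamma families are fit by maximum
likelihood and ranked by BIC = k·ln(n) − 2·lnL; the winner becomes the
base clock-rate prior.

**Calibrations.** Truncated-normal node-age calibrations (zero below
the minimum, renormalized above). The study-style configuration sets
minimum = mean at the oldest contained fossil's earliest bound
(Primates 55.8 Ma, Euarchonta 65.2 Ma) with a 1 Ma standard deviation.

**Fossil tip ages** are uniform over their stratigraphic windows and
are proposed by independent uniform redraws (symmetric, Hastings
ratio 1).

## MCMC

One chain state holds topology, node ages, fossil tip ages, FBD
parameters, clock base rate, IGR variance and branch multipliers, and
per-partition gamma shapes. The proposal mix: node-age slides (uniform
between bounding ages), a root-span scaler, whole-tree age scaling, a
joint age×(1/rate) "ridge" scaler (the critical move for traversing the
time–rate ridge of dating posteriors), fossil-tip-age redraws,
multiplicative scalers for scalar parameters, reflected random walks
for bounded FBD parameters, and dated narrow/wide exchange moves for
topology. Hard clade constraints are enforced by rejection.

Metropolis coupling follows the incremental heating ladder
β_i = 1/(1 + i·T) with default T = 0.02, 2 runs × 4 chains, sampling
every 1000 generations; a random chain pair attempts a swap each
generation. Desk-scale defaults (thousands of generations, reduced
chain counts) are deliberately far below the tens of millions of
generations appropriate for real datasets; full-scale settings are
plain configuration.

Under prior-only sampling the marginals of the clock rate, IGR
variance and gamma shapes reproduce their priors exactly (verified by
test). The FBD parameters do **not**: with the taxon set fixed, the
joint prior's λ-marginal is tilted by the tree-space normalizer
P(n, m | λ), a property of all fixed-n tree samplers, so the tests
check the exactly-recoverable marginals.

### Diagnostics and summarization

ASDSF: splits are pooled across two independent runs; for every split
whose pooled frequency reaches 0.10 (configurable) the across-run
population standard deviation of its frequency is averaged. ESS: the
Geyer initial-positive-sequence autocorrelation sum via FFT, capped at
n. The burn-in grid rule collects (ASDSF, minESS) at candidate
burn-ins, keeps candidates with ASDSF ≤ 0.01, and picks the one whose
least-sampled parameter most exceeds the minESS ≥ 100 target; if none
qualifies an explicit extend-run signal is raised rather than choosing
silently.

The allcompat summary adds all clades with frequency > 0.5 (mutually
compatible by construction), then lower-frequency clades in decreasing
order when compatible, until resolved. Node ages are means over the
samples containing the clade (medians available); tip ages are means
over samples. Rare age conflicts among low-support nested clades are
resolved by nudging parents above children.

## Hypothesis testing

The four placement hypotheses are expressed as constraint sets on a
backbone tree (the dated summary tree with the focal fossils pruned):
H1 backbone only; H2 additionally forbids the exact (focal₂, reference)
pair clade; H3 forbids any clade holding a focal with the reference
taxon but no other crown member (a stem placement); H4 adds the
requirement that the crown clade's spanning node contain both focals.
"Soft backbone" means: relationships among backbone taxa fixed (the
pruned tree's clades must all appear in the restriction of the sampled
tree), focals free to attach anywhere not excluded.

Marginal likelihoods use stepping-stone sampling: powers descend from
1 to 0 at quantiles of Beta(0.4, 1) (50 steps by default), each step's
chain initialized from the previous, the first 25% of each step's
samples discarded, and the estimator sums log mean importance ratios
between adjacent powers. The estimator is calibrated against the
closed-form beta-binomial marginal likelihood. Bayes factors are
exp(ΔlnML) with the conventional strict thresholds: >10 strong, >100
decisive.

## Ancestral reconstruction and biogeography

Marginal ASR combines downward conditional likelihoods with upward
outside arrays per gamma category, normalized per node; it matches
brute-force enumeration on small trees. Conditioning on variable
coding does not alter node marginals given an observed (hence
variable) character, so no ascertainment term appears in ASR.

The best-state calling rule is the absolute-difference reading of the
>10% separation criterion: a single call when top − runner-up > 0.10,
otherwise the inclusive set of states within 0.10 of the top. (The
rule as usually stated is ambiguous between absolute and ratio
readings; a ratio mode is provided and logged.) Branch change counting
treats a character as one change event when the endpoint call sets are
disjoint — a multi-step ordered jump is one event; a step-count mode is
provided because published change counts rarely state their units.

Biogeography treats the six land masses as one unordered 6-state Mk
character on the dated tree, with the dispersal rate ML-optimized
(bounded 1-D search) when not supplied; reconstruction can be averaged
over a posterior tree sample, weighting each clade by the trees that
contain it.

## Morphometrics

Pseudolandmarks are spread by greedy farthest-point sampling over an
area-uniform surface sample (plus mesh vertices). Pairwise alignment:
shapes are normalized to unit centroid size; ICP alternates
nearest-neighbor correspondence and orthogonal Procrustes fits from
principal-axis initializations with all sign combinations (reflections
included when allowed), then refines under the bijective
optimal-assignment objective, which makes the alignment distance
exactly symmetric. Correspondences are propagated along the minimum
spanning tree of pairwise alignment distances (an explicit Prim
implementation, robust to exact-zero distances between congruent
specimens). Generalized Procrustes superimposition then iterates
rotations onto the evolving unit-size mean; PCA is an SVD of the
tangent-space deviations, unweighted. The two-resolution protocol
(coarse set for alignment/MST, fine set for the final correspondence
and PCA) defaults to 300/1100 points with 3000 ICP iterations and
reflections allowed.

Outliers are flagged — never silently removed — when a specimen's
distance to its class centroid exceeds 3× the class median distance;
this is an explicit stand-in for ad hoc removals whose criteria are
typically unpublished.

## Synthetic data

The generators produce data with the statistical structure the
inference assumes, not realistic anatomy or genomes:

- **Trees**: forward birth-death simulation from an origin age;
  fossil sampling is Poisson along lineages and *terminates* the
  sampled lineage (sampling-with-removal), so every fossil is a
  terminal tip, matching the fossil-tip data shape; extant survivors
  are Bernoulli(ρ)-thinned. Replicates outside a tip-count window are
  rejected and redrawn.
- **Characters**: CTMC evolution with branch multipliers × gamma site
  rates; constant characters are rejected and redrawn when
  variable-only coding is simulated. Default 2-state characters.
- **DNA**: per-subset GTR+G(+I) with discrete-gamma site rates
  (matching the inference discretization exactly).
- **Age windows**: fixed width (default 1.5 Ma, an early-Miocene-style
  bracket) with uniform random offset, so the true age is uniformly
  positioned within the window; extant tips get [0, 0].
- **Biogeography**: symmetric 6-state dispersal CTMC with node states
  recorded as truth.
- **Tooth meshes**: a parametric cusp-bearing crown made deliberately
  asymmetric (distinct cusp heights, mesial tilt) so rigid alignment
  has no spurious near-symmetries; class-specific smooth low-frequency
  deformation fields (RMS-normalized magnitude), per-vertex Gaussian
  jitter, random rigid motion and optional mirroring.

Consequently, passing tests demonstrate internal correctness and
self-consistent recovery, not robustness to the things real data add:
model misspecification, correlated characters, alignment error,
heterogeneous fossilization, wear/breakage on surfaces.

## Validation experiments and problem sizes

The desk-scale experiment suite (`tipdating.validation`, reported by
`scripts/acceptance.py`) uses: 4-taxon enumeration oracles; 20 random
trees for the Yule check; a beta-binomial stepping-stone calibration at
50 steps × 1000 samples; 125 tips for clock-prior recovery; an AR(1)
series of 10⁵ for ESS; 10 specimens × 100 pseudolandmarks for
morphometrics; and 20 tip-dating replicates (10–18 tips, 100
characters + 500 bp, 8000 generations each) for root-age coverage.
and 20 tip-dating replicates for root-age coverage.

Each coverage replicate simulates a 10–18-tip tree from a 15 Ma
origin (speciation 0.22, extinction 0.05, fossilization 0.05,
ρ = 0.7), evolves 100 variable-coded binary characters and 500 bp of
equal-exchangeability GTR+G sequence at 0.02 substitutions/site/Ma,
brackets each fossil in a 1.5 Ma window, and re-infers with the
matched model: the removal-variant FBD conditioned on the known
origin age, the same ρ, and a lognormal clock prior centered on the
generating rate, using two Metropolis-coupled chains (heated chains
demonstrably rescue cold-chain mode-sticking here; the time×rate
posterior can be bimodal when old fossils sit near the root).
Matching the inference prior to the generator is what makes interval
coverage the right diagnostic: it measures sampler and model
self-consistency, not robustness to misspecification. The residual
mismatch — the generator conditions on a 10–18-tip outcome while the
density does not — is irreducible in a fixed-size design and is the
main reason coverage can fall slightly below nominal. These sizes
were chosen as the smallest at which each check is decisive.

## Known limitations

- No sampled-ancestor FBD, skyline rates, or autocorrelated clocks.
- GTR exchangeabilities and base frequencies are fixed at their
  configured values during MCMC (only gamma shapes are sampled);
  partitioned analyses remain unlinked across all other parameters.
- The stepping-stone tree sampler is single-chain and desk-scale; real
  hypothesis tests need longer ladders and chains.
- Biogeography is a single discrete character (no
  dispersal-extinction-cladogenesis model), as in the mirrored design.
- The non-clock stage approximates unconstrained branch lengths as
  dated branches × free rates under a flat age prior; it exists to
  feed the clock-rate-prior derivation, not as a general non-clock
  inference engine.
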