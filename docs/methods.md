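# Methods

This note documents the models, estimators and numerical choices behind
`methkin`, in the order the pipeline applies them, together with the design
decisions that were genuinely open and the limitations a user should know
about.

## Kinetic model and likelihood

Post-replication maintenance methylation at CpG *i* is modelled as a
unidirectional Poisson process: with probability `f_i` the parental cytosine
is methylated (the site is a maintenance target), and a targeted nascent
cytosine becomes methylated after an exponential waiting time with rate
`k_i` (h⁻¹). A binary read of post-replication age τ is then methylated with
probability `p = f_i (1 − e^{−k_i τ})`.

Reads do not come with exact ages. The labelling pulse lasts one hour, so a
read at chase time *t* ∈ {0, 1, 4, 16} h has age uniform on [t, t+1]. The
likelihood marginalizes this jitter in closed form:

    p(k, f, t) = f · [1 − e^{−k t} (1 − e^{−k}) / k],

with the k → 0 limit handled by series expansion (p → 0). `window_prob` is
monotone in k, f and t, which the property tests assert.

**Fitting.** Per site, the Bernoulli log-likelihood over per-timepoint
methylated/unmethylated counts is maximized on a 60 × 41 grid — log-spaced k
from 10⁻³ to `k_max` (plus k = 0) by linear f in [0, 1] — followed by
Nelder–Mead refinement in (log k, logit f). The refined optimum is accepted
only if it improves the grid optimum, so the returned likelihood dominates
every coarse-grid point by construction and the whole fit is deterministic
given the data.

**Statuses.** `unidentifiable` when no methylated read exists (the rate is
undefined without observed methylation; f̂ = 0), `insufficient_data` below
10 total reads or fewer than 2 distinct timepoints, `at_upper_bound` when
k̂ reaches `k_max` (default 10 h⁻¹ — kinetics faster than the 1-h schedule
resolves are flagged rather than reported as point estimates). Downstream
correlation uses `ok` and `at_upper_bound` sites; this site-matched universe
is also the one on which state correlation is recomputed when comparing the
two modalities. Uncertainty is available as profile-likelihood intervals
(Δ log L = 1.92, ≈95%).

At the experiment-like depth of ~30 reads/site the median relative error of
k̂ is about 30% (`analysis/03_inference_accuracy.py` tabulates the depth
sweep; the bias vanishes by depth 1000).

## Distance-resolved correlation

For values v on sorted positions x, the correlation function at integer
distance d collects every unordered pair with `x_j − x_i = d` and computes
Pearson r with both orientations (i,j) and (j,i) included, which symmetrizes
the estimator (r is then invariant to which member is called X). Distances
start at d = 2 because CpG dinucleotides cannot overlap. r is masked where
fewer than `min_pairs` (default 50) pairs exist or the pair lists are
degenerate (variance guard scaled to the data magnitude). Pairing is
per-chromosome on plus-strand cytosine coordinates; sites carrying several
region labels enter every matching regional analysis. Within/across scoping
classifies pairs by membership in the same merged annotation interval;
pairs with a member outside every interval are dropped.

Smoothing uses LOESS (tricube weights, locally linear, statsmodels
`lowess`) with a fixed 100-bp bandwidth evaluated at every integer d;
masked distances are excluded from the fit. The summary magnitude of a
curve is the arithmetic mean of the raw (unsmoothed) r over d ∈ [2, 1000].
Regional feature associations are plain Pearson correlations (two-sided
t-approximation p-values) of regional magnitude against regional feature
means.

## Mechanism simulators

Both mechanisms act on a strand of N CpGs whose parental states are
Bernoulli(f_i), resampled per replicate; nascent methylation is 0 → 1 only,
with no de novo methylation or demethylation, so the landscape is
recapitulated in the long-time limit by construction.

* **Distributive** (Gillespie-equivalent): each target methylates at an
  independent Exponential(k_f) time, truncated at `t_end`. Catalysis and
  unbinding are merged into one reaction (k_off ≫ k_cat).
* **Processive**: every remaining target keeps an Exponential(k_f) binding
  clock. When a clock fires, the site methylates and a chain iterates: the
  nearest remaining targets left (d_L) and right (d_R) compete with
  unbinding according to the splitting probabilities of 1D diffusion with
  killing (solution of D u″ = k_off u with absorbing targets),

      P_right = sinh(d_L/λ) / sinh((d_L+d_R)/λ),   λ = sqrt(D/k_off),

  one-sided `e^{−d/λ}` past the outermost target, unbinding beyond strand
  ends. A reached target methylates at the same clock time, leaves the
  pending set, and the chain continues from it. The implementation keeps a
  doubly linked list of remaining targets and processes clocks in time
  order, which is exact Gillespie for this system. The sinh ratios are
  evaluated in exponential form to stay stable for d ≫ λ.

**Instantaneous sliding.** With plausible 1D diffusion coefficients
(10⁵–10⁷ bp² s⁻¹), traversing tens of bp takes ≪ 1 s against hour-scale
kinetics, so chains execute atomically at the firing time. This is the
dominant approximation; it removes the finite first-passage time but leaves
the splitting structure exact. A validation test checks that the simulated
same-chain co-methylation probability of an isolated pair equals `e^{−d/λ}`.

**Enzyme pool.** Binding is pseudo-first-order: no explicit enzyme copy
number, propensity k_f per remaining target.

**Readouts.** WGBS-like: each replicate observed once at U[0, 24] h (the
unsynchronized cell population), per-site fractions averaged over
replicates (10 by default); requires `t_end ≥ 24`. Repli-BS-like: per site
and chase timepoint, Poisson(depth/4) reads, each picking a replicate
uniformly and reporting the nascent state at `t_chase + U[0,1]` h.

Defaults: `k_f = 0.7 h⁻¹` (roughly half the targets methylated within the
first hour, consistent with fast bulk remethylation), `λ = 36 bp`,
`t_end = 17 h` for pulse-chase runs (covers the last read window), strands
of 25,000–75,000 CpGs. All overridable via `SimulationParams` or the CLI.

## Decomposition into θ and φ

Total rate correlation is modelled as `Total(d) = θ(d) + (1−θ(d))·φ(d)`:
with probability θ a neighbour is reached by diffusion (perfectly
correlated times), otherwise any residual correlation φ comes from shared
regional features. No mechanistic model is imposed on φ.

φ is estimated by a cluster-shuffle null: z-score the per-site features
(q, r, s), k-means with K = 8 (sensitivity over K ∈ {4, 8, 16} is cheap to
run; K is a genuinely open choice), then permute positions uniformly within
each cluster and recompute the distance correlation, averaging over 10
permutations of one clustering to reduce permutation noise. The shuffled
lists preserve the feature–position relationship while destroying genuine
distance structure. θ follows algebraically,
`θ = (Total − φ) / (1 − φ)`, masked where |1 − φ| < 10⁻³, and satisfies
the reconstruction identity to 10⁻¹² wherever defined.

The θ track is summarized by nonlinear least squares of `A·e^{−a·d}` over
d ∈ [2, 100] (300 bp window available), without an additive offset —
residual long-range correlation is reported, not modelled. **The raw track
is fitted directly by default.** Pre-smoothing with a bandwidth comparable
to or wider than the decay length provably flattens an exponential and
inflates the recovered decay length; the direct fit recovers an exact
exponential to optimizer precision and, in calibration runs on simulated
ground truth at the default conditions, recovers the simulated sliding
length to within a few percent where the smoothed fit overshot by ~15–20%.
LOESS pre-smoothing remains available (`span=...`) and is still used for
display tracks. Reported constants: a (bp⁻¹), decay length 1/a (bp),
`D/k_off = (1/a)²` (bp², reported to two significant figures).

**Estimator limitations.** The exponential-fit summary is well calibrated
when the sliding length is comparable to a few times the inter-CpG spacing
(the regime of the default conditions, where it is also insensitive to
spacing: CGI-like 10 bp and intergenic-like 161 bp maps give matching decay
lengths). Outside that regime it is biased: for an isolated pair the exact
rate-time correlation is `q(2−q)/(4−2q−q²)` with `q = e^{−d/λ}`, whose
log-slope is ≈ 4/λ near saturation (short d) versus 1/λ in the dilute tail,
so a single exponential fitted across both regimes underestimates λ when
λ greatly exceeds the spacing (the saturated head dominates the window) and
overestimates it when λ falls below the resolvable pair distances (the
noise floor dominates). The same-chain probability itself follows
`e^{−d/λ}` exactly at all λ — the bias lives in the scalar summary, not in
the simulated physics. The cluster-shuffle φ is exact for region-level
(piecewise-constant) feature effects, but quantizes smooth per-site
feature–rate maps, leaving a residual in θ that shrinks slowly with K.
Joint (k, f) estimation can also leak a small amount of landscape structure
into rate correlation on strongly bimodal landscapes (visible as a
sub-0.03 short-range magnitude under the distributive mechanism in
`analysis/02_mechanism_fingerprint.py`), which is an order of magnitude
below the processive fingerprint there.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the genome itself:

* **Positions**: inter-CpG gaps are shifted-geometric (minimum 2 bp,
  memoryless) with the parameter set so the distribution's median equals
  the target (10 bp CGI-like, 161 bp intergenic-like); the half-unit offset
  in the parameterization keeps the sample median off a probability-½
  boundary.
* **Landscape**: a latent Gaussian AR(1) field in genomic distance with
  exponential autocorrelation (default length 500 bp) pushed through a
  steep logistic (slope 4) whose centre is calibrated by quadrature so the
  mean equals the target (default 0.8); this yields the bimodal
  methylated/unmethylated mosaic of real methylomes.
* **Features**: q equals the landscape; r is the exact neighbour count in
  a centred 500-bp window; s is a smoothed positive score anticorrelated
  with methylation plus noise, mimicking accessibility.
* **Reads**: Bernoulli draws from the kinetic model at Poisson per-site
  depths (default 30 total across the four timepoints); an optional
  fragment mode groups consecutive CpGs onto reads sharing one sampled age,
  reproducing the read-length artefact of fragment sequencing.

What it deliberately does not emulate: bisulfite conversion errors, mapping
artefacts, strand-specific calls, real annotation geometry, replication
timing, or the empirical read-depth distribution (only its mean is
matched). Tests passing on this generator therefore demonstrate estimator
correctness and pipeline self-consistency under the modelled structure, not
robustness to those real-data complications.

## Reproducibility and problem sizes

Every stochastic stage draws from a generator derived from a single global
seed plus the stage name (`SeedSequence([seed, crc32(stage)])`), so stages
rerun independently yet reproducibly and identical configurations produce
byte-identical outputs. Headline runs use 25,000 CpGs with 10 simulation
replicates and ~30 reads/site (the sparse-spacing comparison uses 75,000
sites to keep per-distance pair counts adequate); these sizes give
per-distance pair counts in the thousands at CGI-like spacing while keeping
a full pipeline run around half a minute on one core. The acceptance script
averages five independently seeded pipeline runs because the single-run
fitted decay length has a seed-to-seed spread of several bp.

## File formats

All coordinates are 0-based half-open. Regions: BED (merged per chromosome
on read; promoters constructed as TSS−2000/+200 from stranded gene
records). Landscapes and WGBS-like fractions: bedGraph with the cytosine at
the interval start. Reads, rates, features, correlation and decomposition
tables: TSV with headers, schemas shared between the synthetic generator
and the simulators so every stage consumes the previous stage's output.
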