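# Methods

This note documents the models implemented in `geoshift`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Age convention

All modules share one time axis: ages in Ma before present, present = 0 at
the tips, root = maximum age. Branch lengths are in Myr. Trees must be
ultrametric (tolerance 1e-6 Myr for analysis inputs; the simulator
produces trees ultrametric to better than 1e-9).

## Occurrence cleaning and region coding

Cleaning applies rules in a fixed order so that removal counts are
reproducible and each row is removed at most once, by the first matching
rule: truthy source flag, missing/blank species name, non-numeric or
missing coordinates, out-of-range coordinates, latitude == longitude,
zero latitude or longitude, and finally deduplication to one record per
species per location. Locations are compared after rounding coordinates
to 4 decimal places (~11 m at the equator); aggregated occurrence data
mix precisions, and a coarser grid would merge genuinely distinct
localities. Cleaning is idempotent.

Region polygons are treated as closed sets (boundary points count as
inside) and must be pairwise interior-disjoint, so each point gets at
most one label; points covered by no polygon are labelled `unassigned`
and excluded from counts.

Presence filters (inclusive thresholds):

| level | min records | min % of records | multiple regions |
|-------|-------------|------------------|------------------|
| 0     | 1           | —                | allowed          |
| 1     | 3           | —                | allowed          |
| 2     | 3           | 10               | allowed          |
| 3     | 3           | 10               | top-count region only |

The percentage base for level 2 is the species' records assigned to any
named region (unassigned excluded). Level-3 ties on the maximum count are
broken deterministically by the region precedence order and are visible
in the outputs. Range-shift analyses default to the filter-2 coding
reduced to a single state per species by the same top-count rule (a
configuration switch drops widespread species instead); diversification
analyses use the filter-3 coding. Name matching canonicalizes to the
binomial (underscores to spaces, case-fold, first two tokens) and refuses
to merge canonical collisions, reporting them instead.

Sampling fractions are reported as raw ratios and rounded to 2 decimals:
fraction = (species present in the region that matched a tree tip) /
(species present in the region), overall and per clade when a
species-to-clade table is supplied.

## Mk model and stochastic mapping

Region evolution along the tree is a continuous-time Markov chain with
rate matrix Q. The likelihood is computed by Felsenstein pruning with
per-branch transition matrices exp(Qt) (eigendecomposition, with an
`expm` fallback when the eigenvector matrix is ill-conditioned).
Model classes: equal-rates, symmetric, and all-rates-different. The
default is all-rates-different, because directional immigration versus
emigration is the object of study and an equal-rates model would erase
it. The default root prior for mapping is the stationary distribution of
the fitted Q (uniform and likelihood-weighted priors are selectable);
the choice is recorded in output metadata. ML fitting runs L-BFGS-B on
log rates within [1e-8, 100]/Myr from several deterministic starts.

Stochastic maps are drawn exactly: (i) conditional node-state
distributions from the pruning pass, (ii) node states sampled root to
tips from their joint conditional, (iii) branch paths sampled conditional
on endpoint states by uniformization with dominating rate
Λ = max<sub>i</sub> |Q<sub>ii</sub>|. Uniformization was preferred over
rejection sampling because its runtime is bounded even when endpoint
states differ across a short branch. Calibration is verified two ways in
the tests: sampled node-state frequencies converge to the analytically
computed marginals, and mean per-branch event counts match an independent
quadrature oracle (endpoint posterior × Markov-bridge expectation).

The shift-rate statistic divides mapped transition counts per age bin
(default width 5 Myr, bins anchored at the present; the oldest, partial
bin's true width is recorded in metadata) by the number of lineages
available in the bin. Two denominator definitions are provided: branches
whose age span intersects the bin (default — it cannot be zero wherever
the tree exists) and branching events inside the bin. The definition in
use is recorded in the output. Note that the branch-intersection count is
*not* monotone through time in general: a deep bin rich in branching
events can contain more branch segments than a younger bin; only the
count of lineages crossing a fixed age is monotone. Event times are taken
at their sampled ages, and bins with zero denominator are reported as
missing rather than zero. The 95% interval is the empirical 2.5–97.5
percentile band across replicate maps (default 100).

## MuSSE likelihood

Along each branch the coupled equations

    dE_i/dt = mu_i − (lam_i + mu_i + q_i·)E_i + lam_i E_i² + Σ_{j≠i} q_ij E_j
    dD_i/dt = −(lam_i + mu_i + q_i·)D_i + Σ_{j≠i} q_ij D_j + 2 lam_i E_i D_i

are integrated from the branch's young end toward the root (tip
conditions D_i = ρ_i·1[state = i], E_i = 1 − ρ_i), sister D vectors are
multiplied together with λ_i at each node, and the root combines states
by FitzJohn likelihood weighting (w_i ∝ D_root,i) by default, without
survival conditioning; equilibrium and uniform weightings and
condition-on-survival are selectable and always recorded. D is
renormalized at every node and branch end with the log of the scaling
factors accumulated, so large trees do not underflow.

The integrator is an adaptive Cash–Karp Runge–Kutta 4(5) written in
numba, tolerances rtol 1e-10 / atol 1e-12. These are tighter than a
generic default because the package promises closed-form agreement at the
1e-8 level on small trees (at rtol 1e-8 the accumulated error is ~3e-8);
the extra steps are immaterial at the tree sizes involved. E is clamped
to [0, 1] against round-off and integration aborts (with the offending
branch identified) if it leaves that interval materially.

Correctness anchors used in the tests, rather than an external MuSSE
implementation: (i) with one state, no extinction and complete sampling,
the log-likelihood equals the pure-birth closed form
(n−1)·log λ − λ·(total branch length) under this density convention;
(ii) with rates equal across states the likelihood factorizes exactly
into the single-state likelihood plus the Mk likelihood of the character
(FitzJohn weighting on both) — note the character term does not vanish,
so a two-state fit with equal rates is *not* numerically equal to the
one-state fit alone; (iii) with q = 0 and both states observed the data
are impossible and the log-likelihood is −∞.

Fitting maximizes over log rates (L-BFGS-B, bounds [1e-6, 10]/Myr) from
three deterministic starts seeded by birth–death moment estimates
(net rate ≈ ln(n/2)/root age); equality constraints (e.g. all μ equal, a
single symmetric q) reduce the parameter count. The reported
log-likelihood is reproducible by re-evaluating the likelihood at the
reported parameters.

Per-clade analysis extracts each clade's crown subtree (stem edge off),
fits independently with clade-specific per-state ρ, and pools the
estimates. Rates are normalized within clade — each region's rate divided
by the clade's across-region sum, separately for speciation and
extinction — to remove intrinsic between-clade rate differences before
regions are compared with one-way ANOVA (clades as observations) and
Tukey's HSD, both on the normalized values, with means as point
summaries. Tukey's adjusted p-values are guaranteed to be at least the
pairwise t-test p computed from the same pooled within-group variance;
they can fall below a per-pair-variance t-test when a pair happens to be
less variable than the pooled estimate, which is expected behaviour.
Significance is annotated at 0.05 and 0.001; raw p-values are always
emitted.

## Clustering statistics

PS is the small-parsimony minimum computed with Hartigan's algorithm,
exact on multifurcating trees and identical to the Fitch count on binary
trees. AI sums (1 − f)/2^(n−1) over internal nodes (n = descendant tips,
f = majority-state frequency). MC is, per state, the largest clade whose
tips all carry the state (single tips count). The null permutes tip
states uniformly (≥ 19 replicates required); p-values use the add-one
estimator (1 + #{null at least as clustered})/(1 + n_reps), with "at
least as clustered" meaning ≤ for PS and AI and ≥ for MC. The default
reporting mode codes each region one-vs-rest; joint multi-state coding is
also available. Because PS and MC are integers with small support, their
permutation p-values are conservative (super-uniform) rather than exactly
uniform; only the continuous AI statistic is uniformly calibrated, which
is what the calibration test checks. The test operates on a single fixed
tree; it does not integrate over phylogenetic uncertainty.

## Synthetic data

The generator is the study's forward model, not a fixture: a Gillespie
simulation of the multi-state birth–death process from a single root
lineage (root state drawn from the stationary distribution of q unless
fixed), stopped at a time horizon or a taxon count, with extinct lineages
pruned, unifurcations suppressed (branch lengths added, event lists
concatenated) and the stem above the crown discarded. Every transition on
a surviving branch is recorded with its age, giving ground truth for the
mapping calibration. Replicates that die before leaving two survivors
raise an explicit signal so callers can retry.

Tip subsampling retains each tip independently with state-specific
probability ρ and reports realized per-state fractions, emulating
incomplete, state-biased taxonomic sampling.

Toy geography is four disjoint lon/lat rectangles named after the study
regions. Occurrences are uniform points inside a species' home rectangle
plus controlled pathologies: appended exact duplicates, zero
coordinates, latitude == longitude rows, missing names, non-numeric
coordinate strings, flagged rows, and "stray" points relocated to a wrong
region at a stated rate. Ground-truth labels are kept per row, and the
cleaner provably removes exactly the pathological rows on such tables.
What the generator does not emulate: real ecoregion geometry, spatial
autocorrelation or sampling-effort gradients within ranges, taxonomic
synonymy, and gradated coordinate error — so passing tests demonstrate
the pipeline's logic and calibration under its stated model, not
robustness to every bias of real aggregated occurrence data.

Default problem sizes in the tests and the acceptance script (250-tip
trees and 50 replicates for rate recovery; 150-tip trees, 30 replicates
and 40 maps for mapping calibration; 200 experiments of 99 permutations
for null calibration; a ~200-tip, 4-region synthetic demo) were chosen as
the smallest designs whose Monte-Carlo error leaves the checked effects
clearly resolvable on a single CPU.

## Reproducibility

One master seed drives every stage; per-operation substreams are derived
deterministically (seed XOR CRC32 of the stage name), so stages can be
re-run independently. Pipeline runs write a manifest with config hash,
per-stage seeds and SHA-256 of all inputs and outputs; re-running an
identical config reproduces all result tables byte for byte.

## Limitations

* Single fixed tree throughout: no integration over topology or dating
  uncertainty.
* One state per tip for mapping and MuSSE: widespread species are reduced
  to their top-count region (or dropped); range-evolution models with
  polymorphic states (DEC-type) and cladogenetic change (GeoSSE/ClaSSE)
  are out of scope, as are hidden-state extensions and time-varying
  rates.
* State-dependent diversification estimates from sparsely sampled
  phylogenies (sampling fractions around 10%) are point estimates under
  a uniform-sampling assumption; the methods are known to be strained in
  that regime, and the package does not attempt to correct for
  non-uniform sampling schemes.
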