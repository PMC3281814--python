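# Methods notes

This note records the models behind each analysis, the numerical choices
made where conventions diverge, and what the synthetic-data generator does
and does not emulate.  Units follow the single-locus mtDNA convention
throughout: θ = 2N_f·u with N_f the female effective size and u the
mutation rate per *sequence* (per year for natural-unit conversions, per
generation inside the coalescent samplers); τ is time since expansion in
mutational units (pairwise divergence accumulates one expected difference
per unit); M = 2N_f·m is a scaled migration rate.

## Alignment handling

Alignments are rectangular over A/C/G/T/N/`-`; unrecognised IUPAC symbols
are read as N.  Ingroup alignments are assumed essentially gap-free (the
motivating data carry gaps only against outgroups): a gap is treated as
missing for site statistics and pairwise distances (pairwise deletion) and
as a genuine mismatch for haplotype collapsing.  Sequences differing only
at N positions are merged into the earlier haplotype; this greedy
first-appearance rule is not transitive in pathological cases, but
matches common practice and is exact for data without ingroup ambiguity.
Haplotypes are labelled H1..Hk in file order for reproducible reports.

The base-composition homogeneity test is a plain contingency χ² on the
taxa × 4 count table (gaps/N excluded) with df = (n_taxa − 1) × 3.  With
near-identical sequences the test is grossly conservative (rows are almost
copies); that mirrors how the classical programs report it.

Variable and parsimony-informative sites are counted per partition; codon
sub-partitions of a protein-coding fragment require an explicit reading
frame (a config input — the fragment's frame is not derivable from the
alignment itself).

## Diversity

Unbiased estimators are used for both reported statistics:
h = n(1 − Σp_i²)/(n − 1) and π = Σ_{i<j} d_ij / C(n,2) over individuals
(equivalently the haplotype-frequency form with the n/(n−1) correction).
π_n = π/L is reported in percent with two decimals.  Printed reference
values for h in the motivating study truncate rather than round at three
decimals (0.7778 prints as 0.777, 0.7308 as 0.730, 0.3526 as 0.352); the
tests therefore allow one unit in the last printed place and nothing is
force-matched.  Similarly π_n for the CP-like deme computes to 0.0976% →
0.10% although the source prints 0.09.

## Φ_ST and AMOVA

The number of differing sites is used directly as the squared Euclidean
distance between sequences — the Excoffier–Quattro–Smouse convention for
haplotype data — and variance components come from the nested sums of
squares with unequal-sample-size coefficients (n', n'', n''') solved from
the expected mean squares.  Negative components are retained, not
truncated: a balanced panmictic design legitimately estimates small
negative Φ_ST.  The two-level identity (1 − F_CT)(1 − F_SC) = 1 − F_ST
holds algebraically and is asserted to 1e-12.

Permutation schemes follow the standard AMOVA testing logic: individuals
among demes for F_ST (and for each pairwise Φ_ST, restricted to the two
demes); individuals among demes within groups for F_SC; whole demes among
groups for F_CT.  p = (#{Φ* ≥ Φ} + 1)/(B + 1).  Pairwise significance is
Holm step-down ("sequential Bonferroni") at family α = 0.05; for seven
demes the entry threshold is 0.05/21 ≈ 0.0024.  With strongly discrete
data (few haplotypes) the permutation distribution has atoms and p-values
are conservative; the calibration tests therefore run at high diversity
where the statistic is effectively continuous.

"Φ_ST" (distance-based) rather than frequency-only F_ST is deliberate:
it is the default for sequence data in the program lineage this package
replaces, and the motivating study's table is consistent with it.

## Statistical-parsimony network

The connection limit is the largest number of steps j whose cumulative
parsimony probability reaches the confidence level (default 95%).  The
exact probability computation inside the historical TCS implementation is
under-documented, and published descriptions admit several formalizations.
Two were implemented and compared during development:

* a coalescent-integral computation (pair divergence time exponential,
  per-site Poisson mutation, Jukes–Cantor visibility, parsimony = every
  differing site struck exactly once), which yields limits of 10–12 steps
  at L ≈ 1000 depending on how hidden back-mutations at identical sites
  are treated;
* a cumulative per-step homoplasy-avoidance product
  P_j = Π_{i=1..j} (1 − i/(2L)): the i-th connecting mutation must avoid
  the i sites already involved in the path, each counted with probability
  1/2 of striking the same lineage of the two-lineage path.

The product form reproduces the published limits of the original program
(13 steps at L = 1025, 14 at L ≈ 1100) and is adopted as the default;
`parsimony_probability` exposes it directly.  At L = 1025 it gives
P₁₃ = 0.9565 and P₁₄ = 0.94997 — the published 13-step limit sits on a
knife edge, which is consistent with how sensitive reported limits are to
the program version.

Networks are built agglomeratively: components are joined at increasing
step distance d ≤ limit, inserting d − 1 anonymous intermediates ("missing
haplotypes"); among equal-length candidates the connection through the
higher-frequency haplotype wins, then label order.  The default output is
the frequency-resolved tree (edge count = node count − components);
alternative equal-length connections can be retained as reticulations up
to a configurable cap.

## Spatial analyses

Great-circle distances use the haversine formula with R = 6371 km.
Individuals inherit their deme's coordinates, and the individual-level
genetic distance is the same site-difference count used everywhere else
(treated as a squared distance).  The autocorrelation coefficient per
half-open distance class (lower, upper] is the Smouse–Peakall construction:
Gower-centre the squared-distance matrix into C, then
r = 2 Σ c_ij / Σ (c_ii + c_jj) over pairs in the class — bounded by
[−1, 1] and invariant to rescaling all genetic distances.  Permutation
p-values shuffle individual locations; bootstrap intervals resample pairs
within the class; the x-intercept is found by linear interpolation of r
across class midpoints (the interpolation method is a choice; the sources
do not state one).  Class sizes are analysis inputs (the motivating design
used 10/50/100 km depending on the deme grouping).

The Mantel statistic is the Pearson correlation of off-diagonal entries
under simultaneous row/column permutation of the second matrix, one-sided.

## Mismatch distributions

Expected curves are exact mixtures, not approximations.  Sudden
demographic expansion (hazard 1/θ₁ on (0, τ), 1/θ₀ beyond; differences
Poisson given coalescence time):

F_j = (θ₁^j/(1+θ₁)^{j+1}) · P(Γ(j+1) ≤ τ(1+θ₁)/θ₁)
      + e^{−τ/θ₁} · Σ_k Pois(k; τ) Geom(j−k; θ₀).

Spatial (infinite-island) expansion: within the recent phase a pair in the
focal deme coalesces (rate 1/θ) or separates forever (rate M/θ; with
infinitely many demes, separated lineages never rejoin before the
ancestral phase), so the event split is 1/(1+M) vs M/(1+M); the ancestral
single deme has the same θ.  The per-pair separation rate M/θ follows from
m = M/2N per generation per lineage; this convention also reproduces the
immigration-rate conversion m = M/(2N) used in the reference tables.  As
M → ∞ the spatial curve converges to the demographic curve with
θ₀ = θ, θ₁ = ∞, the expected limiting behaviour.

Fitting minimises the sum of squared deviations (SSD) between the observed
histogram (0..j_max) and the model curve by Nelder–Mead on square-root
transformed parameters, with a coarse multi-start grid seeded from the
observed mean (ftol 1e-10; θ capped at 9999, the conventional solver
ceiling — capped values are flagged and their natural-unit conversions
should not be over-read).  P_SSD is a parametric bootstrap: simulate
samples of the observed size under the fitted model with the internal
coalescent simulator (infinite sites), refit each (warm-started at the
fitted parameters), and report the fraction with SSD at least the observed
value.  Stationary data (θ₀ ≈ θ₁) make τ unidentifiable; the fit is
flagged rather than rejected.

Natural units use u_seq = 2×10⁻⁵ mutations per sequence per year by
default (T = τ/2u, N = θ/2u, m = M/2N).  The nominal basis — 2% pairwise
sequence divergence per Myr — is only consistent with the reference
tables when 2u = 4×10⁻⁵/yr, i.e. an effective length of ≈1000 sites with
the divergence rate read as a per-lineage rate; u_seq is therefore a
pinned, configurable constant rather than a derived one.  Two reference
rows are internally inconsistent with their own printed parameters (a
capped θ = 9999 printed with N = 2.5×10⁵, and one immigration-rate cell);
the package reports the computed value and flags the cap rather than
reproducing inconsistent cells.

## Fu's F_S

S′ = Pr(K ≥ k_obs | θ = π̂, n) from the Ewens sampling distribution,
computed with an unsigned-Stirling-number recursion in log space;
F_S = ln(S′/(1 − S′)).  The p-value compares F_S against samples simulated
under neutrality (constant size, θ = π̂): p = Pr(F_S,sim ≤ F_S,obs).  As in
the classical implementation, these plug-in p-values are anticonservative:
the conventional 0.02 cutoff corresponds to a ≈5% level test, which the
calibration test verifies.  Monomorphic samples leave F_S undefined and
raise an error.

## Isolation with migration

Two demes of equal θ split T·N_f generations ago from an ancestral deme of
the same size, exchanging migrants symmetrically at rate M/2 per lineage
(directionality is deliberately not estimated).  The sampler is
Metropolis–Hastings over the augmented state (topology, node ages,
per-branch two-state migration paths, θ, M, T) with independent uniform
priors on [0, bound]; prior upper bounds are required configuration — they
materially shape the posterior modes and should be chosen per dataset.
The likelihood is HKY (κ estimated once from the empirical
transition/transversion ratio unless supplied; JC optional) by Felsenstein
pruning over compressed site patterns, with branch lengths
Δage · θ/(2L) per site.

Moves: reflected sliding windows for θ, M, T; node-age slides inside
migration-event-free windows (multiplicative for the root); subtree
pruning-regrafting with the migration path on the moved branch resimulated
as a prior bridge (rejection sampling corrected by the analytic two-state
transition probability, so the Hastings ratio is exact); and single-branch
path refreshes.  Internal-node deme labels are always derived by
propagation from leaves and migration events, never cached, so split-time
and node-age moves cannot leave stale labels.  With no data the sampler
reproduces its uniform priors (tested by coarse KS); with M = 0 every
accepted genealogy keeps cross-deme coalescences above T (tested).

Posterior summaries report marginal modes from Freedman–Diaconis-binned
histograms (the classical convention of "highest posterior probability"
estimates); recovery tests use posterior medians, which are markedly more
stable at the small per-replicate sample sizes used.  A Gelman–Rubin
dispersion diagnostic across chains flags poor mixing (threshold 1.2)
instead of silently returning.  Desk-scale defaults are thousands of
sweeps with 2–3 chains; production-scale runs (millions of states) are
config-reachable but not the default.  Natural-unit summaries convert with
N_ef = θ/(2·u·g) over a generation-time range g (1–10 years by default),
T to generations as T·N_ef and TMRCA as TMRCA/(u·g), reported as
(long-generation, short-generation) ranges; the TMRCA/T ratio is reported
as a qualitative isolation-versus-migration diagnostic.

## Synthetic data

The internal simulator covers every statistical structure the analyses
assume: panmixia, finite island and 1-D stepping-stone migration, the
two-deme IM history, sudden demographic expansion (piecewise-constant
size) and spatial expansion (emigrants to private demes until the
collecting phase), with infinite-sites or HKY mutation over partitions
(A+T-rich base frequencies by default, matching the motivating
composition).  Under infinite sites, pairwise differences equal path
mutation counts exactly, which the diversity/mismatch oracles rely on.

The study-design fixture is deterministic given its seed: 93 individuals
in 7 demes (sizes 10–20) with real-world coordinates, three planted
haplogroups whose ancestors sit 30 mutational steps apart (far beyond the
13-step connection limit), 27 haplotypes whose per-deme frequency spectra
match the published design exactly (so the printed h values recompute
automatically), a CP-like deme with two haplotypes exactly 5 sites apart
(π = 1.000), and two far outliers 16–17 steps from their own group that
the network must leave unplaced.  The fixture emulates the *design*
(sample sizes, frequency spectra, divergence structure, composition), not
the actual sequences: per-deme π values other than the pinned CP case,
pairwise Φ_ST magnitudes and all time estimates differ from the real
data.  Tests passing on the fixture therefore validate the machinery and
the design-level structure, not any biological conclusion about real
populations.

## Reproducibility and problem sizes

The pipeline expands one global seed into per-stage seeds with fixed
SeedSequence spawn keys, so toggling a stage never shifts another stage's
random stream, and rerunning with the same seed reproduces every report
byte for byte.  The statistical acceptance checks use deliberately
desk-scale designs chosen to give clear signal: 50 coalescent replicates
at n = 20 for mismatch recovery; 150 neutral datasets × 120 null
simulations for the F_S calibration; 200 replicates × 200 permutations for
the uniformity checks; and 20 IM replicates (n = 9+9, θ = 6, T = 2,
M = 0, 3000 sweeps) for posterior recovery, with success defined as
medians within a factor two of truth and the migration posterior
concentrated near zero.

## Known limitations

* Single-locus, strictly neutral, non-recombining inference throughout —
  by construction of the underlying models.
* The statistical-parsimony probability is a reconstruction of an
  under-documented historical computation; limits for lengths far outside
  the few-hundred-to-kilobase range should be interpreted cautiously.
* The IM sampler assumes equal and constant deme sizes, symmetric
  migration and a single locus; divergence-time posteriors from one locus
  are intrinsically wide, and prior bounds matter.
* AMOVA p-values with very few distinct haplotypes are conservative
  (permutation ties), as in the classical implementations.
* The χ² homogeneity test ignores phylogenetic non-independence of taxa.
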