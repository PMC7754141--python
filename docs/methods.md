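# Methods

## The modelling framework

A metabolic network is represented by its stoichiometric matrix S
(metabolites × reactions), flux bounds lb ≤ v ≤ ub in mmol·gDW⁻¹·h⁻¹, and
gene–protein–reaction (GPR) rules. All analyses operate on the
steady-state polytope {v : S·v = 0, lb ≤ v ≤ ub}. Flux balance analysis
(FBA) maximises or minimises one reaction flux over this polytope; the
package solves every LP with HiGHS through `scipy.optimize.linprog`.
Exchange reactions follow the global sign convention flux < 0 = uptake,
flux > 0 = secretion; this is what makes the downstream
concentration-level interpretation of flux shifts well defined.

Thermodynamic (loopless) constraints and elemental/charge balancing are
deliberately out of scope: internal thermodynamically infeasible cycles
are left in the solution space, and the model linter warns rather than
fails on unbalanced toy reactions.

## Gene activity and context extraction

A gene is called active when its raw counts, **summed across all
samples**, reach the threshold (default 10), OR a curated binary evidence
table reports the gene present in fibroblasts. The summed interpretation
was chosen because the per-sample alternative is ambiguous at this
sequencing depth and the related filtering step for differential
expression in this field also sums across samples; the threshold is a
parameter. Proteomics and database knowledge enter only through the
evidence table — there is no separate protein-abundance channel.

Extraction then proceeds: reactions whose (non-empty) GPR evaluates false
under the active gene set are removed; the remaining network is pruned to
its flux-consistent part with fastcc; the core set is every reaction whose
GPR is satisfied (empty-GPR reactions are neither core nor removed); and
FASTCORE returns a near-minimal flux-consistent subnetwork containing the
core. Biomass, the ATP demand and the exchange reactions surviving the
consistency prune are appended to the core — whether the original study
protected these is unstated, but without them the extraction would be free
to drop the model's boundary and maintenance functions, leaving a model
that cannot perform the analyses that follow. Tie-breaking inside the LPs
is delegated to the deterministic solver, and candidate sets are processed
in lexicographic reaction order, so extraction is fully deterministic.

### fastcc and FASTCORE

Both follow the published LP schemes. Consistency testing uses LP7
(maximise the number of candidate reactions carrying flux ≥ ε), flipping
reversible candidates before declaring them blocked; the result is
validated in the test suite against a naive two-LP-per-reaction oracle.
FASTCORE alternates LP7 on the remaining core with a sparsity step that
minimises Σ|v| over the penalty set while pinning the found core reactions
at ≥ ε; an inconsistent core member raises an error naming the offenders
before iteration. ε defaults to 1e-4 (the convention of the FASTCORE
literature; the value used in the original study is unreported) and is
configurable everywhere. FASTCORE guarantees near-minimality, not global
minimality; the tests check exact minimality only on small enumerable
fixtures where the brute-force subset search is tractable.

## ATP-yield screen

For each carbon source: close every exchange uptake, open the minimal
medium at ±1000 mmol·gDW⁻¹·h⁻¹, force oxygen uptake open, fix the carbon
uptake at exactly −1 mmol·gDW⁻¹·h⁻¹, and maximise the ATP demand flux
(`DM_atp_c`, with the genome-scale spelling `DM_atp_c_` accepted). Because
the demand hydrolyses ATP, its optimum is the net yield after internal ATP
costs. Infeasibility is reported as such — it is the screen's signal that
the source cannot be catabolised (the "crossed-out" outcome), distinct
from a feasible yield of zero. Two pragmatic choices: a biomass minimum,
if set, is relaxed to zero inside the screen (minimal media carry no
biomass precursors, so the screen would otherwise be uniformly
infeasible), and medium components absent from a context-extracted model
are skipped rather than raising (they are simply unavailable to that
model). The garbled ammonium/sulfate token in the published minimal-medium
recipe is interpreted as two separate species; this only affects
genome-scale media files, which the user supplies as TSV.

## Disease simulation

The disease condition is a single-gene deletion evaluated through the
GPRs: reactions whose rule becomes false get bounds (0, 0), everything
else is untouched. On top of the deletion, the α- and ω-oxidation pathway
reactions are capped at literature-derived maxima (48.7656 and 20.2176
mmol·gDW⁻¹·h⁻¹ for the hydroxylase and CYP steps respectively, applied to
both conditions before warmup), and the phytanate exchange upper bound is
set to −0.1 mmol·gDW⁻¹·h⁻¹, making an uptake of at least 0.1 mandatory —
the in-silico analogue of phytol loading.

## ACHR sampling

Warmup points are the FVA extrema (two LP optima per reaction) plus
random-objective optima up to the requested count. The chain then
iterates: direction = (random warmup point − running centre), step uniform
on the feasible chord, centre updated as the running mean. One point is
recorded every `thinning` iterations until `n_total` are stored, and a
uniformly random `n_kept`-subset is returned — the most literal consistent
reading of the published "10 000 kept of 50 000 recorded with step 500";
the alternative reading (50 000 iterations total) is obtainable by setting
the parameters accordingly. Numerical drift off the null space is
corrected by re-projection onto a precomputed orthonormal null-space basis
every 1 000 iterations. Every kept point is hard-checked: ‖S·v‖∞ ≤ 1e-6
and bounds within 1e-8; violations raise rather than warn. A
zero-dimensional polytope (all bounds fixed) short-circuits to the unique
feasible point.

The sampler's defaults keep the published chain parameters
(n_total = 50 000, thinning = 500, n_kept = 10 000). The test suite and the
acceptance script run desk-scale chains (n_total = 10 000, thinning = 20,
n_kept = 10 000) — at toy-network size these chains are well mixed, as the
centroid-calibration checks on the unit box and the solid simplex verify
(sample means within 3 standard errors of the analytic centroids).
Hit-and-run with artificial centering is only asymptotically uniform; the
calibration tests are exactly the guard against centering bias at the
problem sizes used.

## Differential statistics

Each exchange reaction's sampled flux distributions are compared between
conditions. Normality is probed per group with a one-sample
Kolmogorov–Smirnov test against a normal with the sample's own mean and
standard deviation — the procedure as published names no parameters, so
this Lilliefors-style usage (anti-conservative as a pure KS test) is
applied and documented. If both groups pass, a two-sample F-test picks the
equal- or unequal-variance t-test; otherwise the Wilcoxon rank-sum test is
used (constant vectors fall through to Wilcoxon, identical constants give
p = 1). P-values are adjusted with the Bonferroni–Holm step-down
procedure; the adjusted values are reported in a column named `fdr` for
fidelity with the field's reporting convention, although Holm controls the
family-wise error rate, not the FDR. The fold change is
log₂(|mean_disease| / |mean_ctrl|) on the group means; when the means have
opposite signs a ratio is undefined and the reaction passes the
fold-change gate as a directionality change instead. The |log₂FC| > 1.3
gate is applied two-sided, since both increases and decreases are
findings. Significance requires both the adjusted p below 0.05 and the
fold-change/sign-flip gate.

Significant shifts are interpreted on the concentration level: a mean
shift towards secretion or away from uptake predicts a higher
extracellular concentration, the opposite a lower one.

Directionality accuracy against measured rates is the fraction of shared
exchanges whose predicted mean flux sign matches the measured net rate
sign; a measured zero counts as agreement iff the predicted mean is within
1e-3 of zero (unstated in the source; fixed here and configurable).

## The synthetic study conditions

The toy network emulates the pathway structure of the fibroblast study
with exact, designed ground truth:

* lumped aerobic glucose oxidation, net **32 ATP** per glucose;
* α route: ATP-costing peroxisomal import, gene-gated α-oxidation,
  β-oxidation repaying 60 — net **59 ATP** per phytanate, plus a secreted
  carnitine-ester by-product whose efflux collapses to zero under the
  deletion;
* ω route: CYP-style microsomal oxidation consuming glutathione (flag,
  default on), ATP-costing import, β-oxidation to secreted 3-MAA — net
  **39 ATP**;
* a sarcosine → glycine oxidation that disposes of a carbon source at
  zero ATP yield (the screen's "feasible but unproductive" control);
* five amino-acid exchanges, a biomass maintenance reaction, and two
  decoy pathways gated by silenced genes.

The designed yields (59/39, α > ω) reproduce the qualitative ordering and
glutathione dependence of the genome-scale screens at desk scale; the
genome-scale values themselves are properties of the full reconstruction
and are not targeted by the toy. Expression counts are negative-binomial
(mean 500, dispersion 0.5 — realistic RNAseq overdispersion, values not
stated in the source) for active genes over 6 CTRL + 5 disease samples
(the study's design), with decoy genes near zero (summed counts enforced
< 10) and one designated low-count gene carrying database evidence 1 to
exercise the manual-override path. Measured rates have designed signs,
with sign flips (citrulline/sarcosine-style) and attenuation (phytanate)
distinguishing the disease group.

What the toy does **not** emulate: elemental balance, cofactor detail
beyond ATP/ADP and glutathione, realistic human gene identifiers,
transcript-length or library-size effects in the counts, and measurement
noise in the rates. Passing tests therefore demonstrate the correctness of
the algorithms and the pipeline's logic under known truth, not the
numerical behaviour of a genome-scale reconstruction. Two structural
consequences are intentional: the phosphate exchange is moiety-blocked
(the adenylate pool is closed, so net phosphate exchange is always zero —
a natural blocked-reaction example), and a forced water "carbon source" is
infeasible rather than zero-yield, because a fully mass-balanced network
without sink reactions has no disposal route for net water uptake; the
zero-yield control is sarcosine instead.

## Numerical choices

* solver feasibility/optimality tolerances 1e-9; assertion tolerance on
  S·v residuals 1e-6; consistency threshold ε = 1e-4 with the 0.99·ε
  support cut-off of the FASTCORE literature;
* fluxes below 1e-9 in magnitude are treated as zero in fold-change and
  sign logic;
* degenerate inputs raise informative errors: infeasible models in
  warmup, inconsistent core members, unknown genes/reactions/exchanges,
  mismatched reaction universes in the differential step (listing the
  symmetric difference).

## Known limitations

FVA, fastcc, FASTCORE and warmup solve LPs one at a time through scipy's
interface, which is fine at toy scale but would benefit from a persistent
solver for genome-scale work. The ACHR chain is a single chain without
formal convergence diagnostics beyond the centroid calibration suite.
The statistical stage inherits the published design's caveat that with
10 000 sampled points per group nearly any distributional difference is
"significant" — the fold-change gate is what carries the practical
filtering burden.
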