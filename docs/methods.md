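# Methods

## Problem setting

CT-derived airway counts in COPD confound two pathologies: loss of airways
through narrowing/obliteration, and apparent loss through wall thinning
(thin-walled small airways fall below CT detectability). The package
estimates both pathways from a per-participant metrics table by (i) learning
a causal graph over the measured variables under biologically motivated
constraints, and (ii) decomposing the severity effect on the log airway
count into a direct coefficient and a wall-thickness-mediated product, per
COPD severity group.

## Structure learning

Conditional independence is tested with the Fisher z statistic
√(n−|Z|−3)·atanh(r_xy·Z), two-sided at α = 0.05; the partial correlation
r_xy·Z is computed by inverting the correlation submatrix (cross-checked in
the tests against residual regression). Markov blankets come from the
Grow–Shrink algorithm with a fixed variable ordering: greedy addition sweeps
until a full pass adds nothing, then conditional removal. The skeleton
symmetrises blankets with the AND rule; each candidate pair is probed for a
separating subset inside the smaller blanket, smallest subsets first with
lexicographic tie-break, recording the first separator found. Orientation
applies, in order: whitelist edges; the unshielded-collider rule (skipping
arms that are blacklisted or already directed — finite samples can propose
conflicting colliders, and a deterministic first-come skip keeps small-n
runs total); blacklist forcing (an adjacency with one forbidden direction
takes the other); and Meek rules 1–4 to closure. The rules were validated
against exhaustive enumeration of consistent DAG extensions on random
graphs. Constraint semantics follow the study design: severity → count and
wall thickness → count are whitelisted, and age and sex accept no incoming
edges, which in particular forces age—severity to orient as age → severity
whenever that adjacency is found. Remaining edges are reported undirected.

The default node set for learning is {age, sex, BMI, log lung size,
severity (ordinal 0–3), scanner, log WT, log count}, one run per count
outcome. Spirometry is excluded because it is definitional of the severity
grade; pack-years is excluded because the reference graph carries no
pack-years edges (it still drives severity inside the generator and simply
acts as extra latent noise from the learner's viewpoint). Both exclusions
are toggleable by passing a different `nodes` list.

## Effect identification and estimation

d-separation queries run on the directed part of the learned PDAG (networkx;
tested against brute-force path enumeration). The single-door set for the
direct effect is the minimum-cardinality, lexicographically first set of
non-descendants of the outcome that d-separates severity from the outcome in
the graph with the direct edge removed, found by exhaustive subset search
(node sets are ≤ 10, so the search is exact and deterministic); the
back-door set is the analogous minimal blocker of paths entering severity.
On the reference graph these are {log WT, scanner} and ∅: conditioning on
the mediator WT opens the collider path severity → WT ← scanner → count, so
scanner must join WT in the single-door set, while severity has no back-door
path at all. Undirected PDAG edges are tolerated only when irrelevant — any
undirected edge touching the severity→outcome machinery raises an
orientation error, and adjustment sets are re-verified under every
orientation of the tolerated edges.

All regressions are OLS computed from first and second moments, so the same
code path serves finite cohorts and the generator's exact population
moments; on samples this is algebraically identical to row-level OLS
(cross-checked against statsmodels). Severity enters every effect regression
as three dummies against the preserved-lung-function reference (matching the
per-group reporting convention), although structure learning uses the
ordinal code — that asymmetry is inherited from the analysis design and is
the reason the population oracle needs a small independence threshold (see
below). The indirect effect is primarily the product of path coefficients
along every directed mediated path (exactly one, severity → log WT → count,
in the reference graph); the difference method total − direct is reported as
a cross-check, and total − direct − indirect is exposed as a consistency
delta (zero to numerical precision at the population moments). Percentage
declines use (1 − e^α)·100. Both the minimal single-door adjustment and the
all-parents-of-outcome adjustment are computed; they coincide on the
reference graph.

## Synthetic cohort generator

The generator is a linear-Gaussian SEM over the reference DAG, ancestrally
sampled with per-node noise substreams (re-seeding one node perturbs only
that node and its descendants — the mechanism behind the locality tests).
Sex, scanner, age and pack-years are exogenous; BMI and log lung size load
on sex; severity is an ordered-threshold discretisation of a unit-variance
latent with standardised loadings 0.31 (age) and 0.37 (pack-years) and
thresholds set so the population group proportions are exactly
362/122/116/49 out of 649; log WT and the two log counts follow the
structural equations above; spirometry is emitted per group; counts are
exponentiated back to the natural scale (left continuous by default, with a
rounding flag) and TACp is clipped to TAC in the rare (~0.4%) crossing, with
a counter in the cohort metadata.

Calibration. The direct effects a_g are the published per-group
coefficients for both outcomes. The published indirect effects are products
b_g·d, so a decomposition is needed: the WT slope is fixed at d = 4.6 and
b_g = bd_g/d. The value 4.6 is the only region consistent with the published
per-group WT means — the per-group implied slopes bd_g / ln(WT_g/WT_0) are
5.2/4.6/4.4, and any d outside (4.19, 4.79) pushes at least one implied
group WT mean more than half a printed digit from its published value. For
the peripheral count the published indirect effects stand in a nearly
constant ratio 1.58 to the TAC ones, so d′ = 7.27 (the least-squares fit
given b_g); the implied TACp products then match the published values within
0.005, which is as close as any single shared WT path allows. Equation
intercepts are solved in closed form (log-normal/Bernoulli moment-generating
functions) so the preserved-group natural-scale means equal the published
1.23 mm, 417.94 and 294.82 exactly. Residual SDs (0.0386, 0.147, 0.128 on
the log scale) reproduce the preserved-group coefficients of variation; the
log-scale residuals are homoscedastic across groups, so the generator does
not reproduce the rising natural-scale SDs of the more severe groups. The
TAC and TACp residuals share a correlation of 0.9 — the peripheral count is
a sub-count of the total, and without this term the implied r(logTAC,
logTACp) would be ~0.88 instead of the ~0.96 the generator produces
(real-cohort reports put it near 0.99). Scanner effects are not published;
they are set to −0.02 (WT) and +0.05 (both counts), values chosen — by
exhaustive audit of the implied covariance — to keep the model faithful to
its graph: every true edge retains |partial correlation| ≥ 0.05 under all
conditioning sets and every non-adjacent pair separates below 0.0035.
Same-signed scanner effects of similar magnitude sit near a cancellation
surface (conditioning on the count almost exactly cancels the scanner→WT
association) and would make the graph unrecoverable in principle, not just
at finite n.

Exact implied moments. `implied_moments` returns the population mean vector
and covariance of all model variables including the severity dummies,
computed in closed form (truncated-normal moments handle the discretised
severity). It backs the population oracle for structure learning and the
exact effect-decomposition identities. Because severity's per-group effect
shifts are not linear in its 0–3 code, d-separated pairs routed through
severity keep partial correlations of order 10⁻³; the covariance oracle
therefore uses |pcor| < 0.01 as its independence decision, ~5× above the
leakage and ~5× below the weakest true edge.

Repeat scans add Gaussian measurement error to the observed metric with
variance Var_between·(1 − ICC)/ICC, so the population intraclass correlation
of the pair equals the requested target; a target of 1 duplicates exactly.

## Descriptive layer

Group tables report mean/SD/n per severity group (SD of a single-participant
group is NaN, not 0), counts and percentages for binary variables. Group
comparisons use Welch's unequal-variance t-test (scipy), two-sided at 0.05,
unadjusted for multiplicity, and are also computable directly from printed
summary statistics. Group sizes and SDs in this design are markedly unequal,
which is why the unpooled form is the default. The correlation matrix is
plain Pearson with binary and ordinal variables entered as numeric codes
(point-biserial correlations are the same quantity); zero-variance columns
yield flagged NaN entries. ICC defaults to ICC(2,1) — two-way random
effects, absolute agreement, single measurement — with a one-way ICC(1,1)
variant selectable, since repeatability reports rarely state the form used.

## Problem sizes and numerics

The recovery protocol used by the tests and the acceptance script is 10
cohorts of n = 20,000 (about 3 s end-to-end): at this size the severe-group
coefficient SE is ~0.004 per cohort, so 10-cohort means pin the truths to
~±0.001 while still exercising genuine sampling noise. Calibration checks of
group marginals use one cohort of n = 50,000. Degenerate inputs surface as
typed errors (schema violations name row and column; singular conditioning
sets name the collinear variables; missing adjustment sets raise
identifiability errors mapped to distinct CLI exit codes). All determinism
flows from explicit seeds; identical configs give byte-identical artifacts.

## Limitations

The generator emulates the study's variable structure and printed marginals,
not the original cohort: no missing data, Gaussian within-group spirometry,
homoscedastic log-scale airway residuals, and an exactly linear SEM. Tests
passing on it show the machinery is correct under the stated model, not that
the model captures every feature of real CT cohorts. Real-cohort quantities
that depend on unreleased participant data (the full correlation matrix, the
exact p-values, repeat-scan ICCs of 0.99/0.99/0.95) are covered only by the
property-based surrogates described above. Nonlinear or interaction effects,
latent confounding, and selection effects are out of scope.
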