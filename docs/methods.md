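# Methods

## Data model

A cohort is a table of subjects × biomarkers. Subjects carry a group
label (HD = healthy donors, SCA = sickle cell anemia patients at steady
state), optional demographics, and three optional clinical covariates:
reticulocyte count (×10⁶/mm³), platelet count (×10⁶/mm³), and a
death-risk severity score in [0, 1] produced by an external calculator
and treated purely as an input. Biomarkers belong to one of three unit
classes — cell-phenotype frequency (percent, bounded in [0, 100]),
receptor expression (MFI, positive and unbounded), and serum analyte
concentration (pg/mL, positive with a per-analyte limit of detection).
The built-in registry holds the 23-analyte serum panel with each analyte's
assay LOD plus the cell-phenotype, Toll-like-receptor and adhesion-molecule
markers of the flow panel. Canonical names are ASCII ("IL-1b",
"MIP-1a", "IFN-g"); Greek-letter spellings are accepted on input via an
alias map so files are encoding-proof.

Missing measurements are allowed (empty CSV cells) and are excluded
pairwise from every downstream statistic. Real multiplex panels are rarely complete per subject; pairwise
deletion is this package's policy, and every correlation edge
records the number of complete pairs it used.

## Quantification (5PL) and censoring

Concentration readout from a bead assay follows the five-parameter
logistic curve f(x) = d + (a − d)/(1 + (x/c)^b)^g with a the blank
response, d the saturated response, c (> 0) the scale concentration,
b (≠ 0) the slope and g (> 0) the asymmetry. Inversion is closed-form
and is defined on the open response interval between the asymptotes;
responses at or beyond an asymptote are blank/saturated wells and raise
rather than return a number. At x = 0 the forward model returns a by
the parameter's definition (the blank well), which for b < 0 differs
from the pointwise limit; this keeps the parameterization's semantics
independent of the sign convention chosen for b. Curve *fitting* is out
of scope — vendor software fits the calibrators; the pipeline consumes
fitted curves and concentrations.

Values below the LOD are censored. Sub-LOD handling varies across labs
and is rarely reported, so the policy here is explicit and
configurable: substitute LOD/2 (default, the conventional single
imputation), substitute LOD, or keep the raw value; the flag is carried
either way, and reading a cohort file re-derives flags as value ≤ LOD.

## Stratification

Patients are split at the median of each covariate: value > cut ⇒ high,
value ≤ cut ⇒ low. Ties at the cut go to "low" because "high" is
defined as *above* the median. The median is the midpoint of the two
central order statistics for even n, so 30 distinct severity scores
split exactly 15/15. Cuts default to the in-data medians and can be
overridden with the published split points (reticulocytes 400,
platelets 450, severity 0.670); both modes exist because published
round cut-points and exact in-data medians can differ, and which one a
study applied is often ambiguous. Only
the patient group is stratified; HD is a single reference group.

## Group comparisons

All tests are rank-based; nothing assumes a distributional form.

* Mann–Whitney U (two-tailed): U counts (x, y) pairs with x > y plus
  half the ties. The p-value is exact — full enumeration over all
  C(N, n₁) assignments of the pooled ranks — for tie-free samples with
  N ≤ 12, otherwise the normal approximation with tie and continuity
  corrections. The switch point is where enumeration is both cheap and
  testable against a brute-force oracle.
* Kruskal–Wallis on midranks with tie correction, χ² with k − 1 df;
  all-constant input returns H = 0, p = 1 rather than an error. The
  omnibus test is followed by Dunn's pairwise z statistic with the
  pooled tie-corrected variance, Bonferroni-adjusted over the pairs of
  one family (the mainstream software convention for "Dunn's multiple
  comparison test"). The omnibus rank test stands in for the
  parametric ANOVA sometimes reported alongside it in this literature,
  which is not interpretable next to rank-based post-hoc tests.
* Significance is α = 0.05 per biomarker with no correction across
  biomarkers, matching the reporting convention of this literature; a
  Benjamini–Hochberg option exists but is off by default.
* HD reference intervals are the 25th–75th percentiles with linear
  interpolation between order statistics (plotting position
  (k − 1)/(n − 1)); patient medians are called above/below/within.

## Ascendant signatures and Venn partition

For each biomarker the cut-off is the median over the *whole universe*
of subjects (all groups pooled, non-missing values only). A subject is
"high" iff strictly above the cut-off — the strict rule keeps the
pooled frequency at exactly 50% for tie-free even-n data, which is the
mechanism that makes group-level departures from 50% interpretable. A
group's signature lists biomarkers by the percentage of its subjects
high, ascending (ties broken by name); the selected set is freq > 50%
(strictly, so the boundary case is deterministic). Selected sets across
groups/subgroups are partitioned by exact membership-pattern set
algebra: common-to-all, selective-to-one, and every other intersection
cell; regions are disjoint and cover the union by construction, and a
brute-force oracle asserts this for randomized systems of up to 6 sets.
Pooling over HD + SCA is the default universe; a restricted universe is
available for sensitivity analysis.

## Correlation networks

Spearman's ρ is the Pearson correlation of midranks, computed per
biomarker pair after pairwise deletion (n ≥ 3 required; zero-variance
vectors raise an undefined-correlation error and the pair is skipped
with a warning). The p-value is exact — the full n! rank-permutation
null, cached per n — for tie-free samples with n ≤ 8, else the
t-approximation with n − 2 df. Edges are retained at raw p < 0.05,
exactly as the networks in this literature are drawn; no correction
across pairs (an FDR mode exists but is off by default).

Edge strength uses the Taylor categories on |r|: weak below 0.36,
moderate in the closed band [0.36, 0.68], strong strictly above 0.68;
the sign is negative iff r < 0. The open boundary at 0.68 (strong is
strictly above) is this package's documented convention; boundary cases
have measure zero in practice. The three-class scheme (including "weak") is
applied symmetrically to both signs. Triads are 3-cliques of the
retained graph, found by clique enumeration; exports are SIF, TSV
(round-trippable) and GraphML for downstream viewers — layout fidelity
is explicitly not a goal.

## Synthetic cohorts

The generator exists because raw cohort data for this
study design are not publicly deposited: it
reproduces the *structure* the analysis assumes, with known ground
truth, so every stage can be verified by recovery rather than by value
replication.

Within each group, biomarkers are drawn from a Gaussian copula: latent
standard normals with correlation ρ_lat = 2·sin(π·ρ_s/6) for each
requested Spearman ρ_s (the exact rank-correlation map for bivariate
normals; requested values are recovered within ±0.05 at n ≥ 5000).
Infeasible (non-positive-definite) combinations raise an error naming
the offending pairs. Marginals are log-normal for pg/mL and MFI
(location = median, CV on the natural scale, default 0.5 — plausible
for serum multiplex panels) and logit-normal for percentages (latent
sigma ≈ CV/(1 − p) by the delta method, capped at 2.5). Effects
multiply the location by a fold change within a selector (a group, or a
group restricted to the low/high side of a covariate's in-group
median). Serum values then pass through the same LOD-censoring policy
the analysis uses.

The default configuration encodes the study conditions: n_HD = 70,
n_SCA = 30; upward effects (fold 2.0 serum, 1.5 cellular) for the
markers reported elevated in patients (IL-1b, IL-6, IL-12, IFN-g, IL-4,
IL-17, IL-10, IL-8, IP-10, MIP-1a, MIP-1b, RANTES, VEGF, FGF-basic,
GM-CSF; activated monocytes, B/B1 cells, CD69+ T cells, TLR9);
downward effects (fold 0.5 / 0.6) for IL-2, IL-13, CD4+/CD8+ T cells,
neutrophils, NK, NKT and dendritic cells; ρ = 0.7 patient correlations
for the recurrent pairs IL-17~MIP-1b, IL-12~VEGF, IL-10~IP-10; and
covariate medians at the split points 400, 450 and 0.670 (the platelet
split applied in the study, 450, is used rather than the tabulated
median 421). Healthy-donor serum medians are set at 3× each analyte's
LOD — high enough that censoring touches only the lower tail, low
enough that the censoring path is exercised. The fold magnitudes and
CV are this package's choices; the directions and sizes above are the
study's.

What the generator does **not** emulate: heavy-tailed assay noise and
plate effects, correlated effect sizes across biomarkers, structured
missingness, demographic confounding, or the full empirical correlation
fabric of a real immune panel (only the injected pairs are correlated).
Passing recovery tests therefore demonstrates correctness of the
machinery under the stated model, not performance guarantees on real
cohorts.

## Verification problem sizes

The acceptance checks run at: all C(N, n₁) tie-free rank inputs with
N ≤ 10 for the Mann–Whitney oracle and all n! permutations with n ≤ 7
for the Spearman oracle (exact agreement); 1000 null biomarkers at
70 vs 30 and 1000 null pairs at n = 30 for type-I calibration (expected
fraction 0.05, accepted band [0.035, 0.065]); 200 seeded replicates for
signature recovery (10 markers at fold 3.0, CV 0.5, 30 vs 70; all 10
selected in ≥ 95% of replicates) and for network recovery (injected
ρ = 0.85 at n = 30; positive edge in ≥ 90%, mostly strong); 100 random
curve/concentration draws for the 5PL round trip (relative error
≤ 1e-9; draws sit in the quantifiable mid-band of each curve, since at
the asymptotes the response is float-indistinguishable from saturation);
and 50 randomized set systems for the Venn partition.

## Known limitations

* No curve fitting, no raw flow-cytometry (FCS) parsing, no gating —
  the pipeline starts from gated frequencies/MFI and fitted curves.
* Exact tests switch to approximations beyond small n; at the study's
  sizes (70/30) all p-values are asymptotic, which is standard but
  means borderline p ≈ 0.05 calls inherit approximation error.
* Half-LOD substitution biases low-concentration analytes' medians when
  the censored fraction is large; the policy is configurable but no
  maximum-likelihood censored estimator is provided.
* The severity score itself is an input; its external calculator is not
  reimplemented.
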