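# Methods

This note records the models, conventions, numerical choices and known
limitations behind `mixtoxsys`, in the package's own words. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Dose–response layer

Endpoints are modelled with a log-logistic curve on the raw response scale,
with additive Gaussian error, so least squares is the maximum-likelihood fit
and the nested likelihood-ratio machinery downstream is coherent with the
fitting criterion. The decreasing form anchors the control response at
`θmax`; the increasing form (used for endpoints such as lipid accumulation or
lysosome/cytoplasm ratio) anchors it at `θmin`. Both share the effect-fraction
scale `x(c) = (c/EC50)^β / (1+(c/EC50)^β)`, hence one ECx inversion formula.

`θmin` is fixed at 0 by default — biomarkers expressed as percent of control
have a natural floor — and can be freed, which then requires at least four
distinct concentrations for identifiability. The optimizer is bounded
nonlinear least squares over `(θmax, ln EC50, ln β)` with an 8-point
multi-start grid (two log-spaced EC50 seeds across the tested range crossed
with β ∈ {0.5, 1, 2, 4}); a flat response raises an identifiability error
rather than returning an arbitrary curve.

**Toxic-unit convention.** `TU = c/EC50`, and the equitoxic design maps a
nominal mixture level of `T` TU to each of `n` components dosed at its
`EC(50·T/n)`. This is the labelling convention of the underlying study design
(1.0 TU mixture = EC25 + EC25; 0.5 TU = EC12.5 + EC12.5; a single chemical at
1.0 TU = its EC50). It is a design label, not isobole algebra: the surface
models below use the linear `c/EC50` scale internally. An explicit ECx lookup
table, when supplied, takes precedence over model inversion, because
published effect-concentration triplets are not always jointly consistent
with a single two-parameter curve and should then be treated as inputs.

## Mixture response surfaces and deviation testing

The two non-interaction references are Concentration Addition (components are
dilutions of one another; the toxic-unit sum at the predicted effect level
is 1) and Independent Action (unaffected fractions multiply). Deviations
enter through a single scalar `G` built from EC50-based toxic-unit shares:

- SA: `G = a·z1·z2` — overall antagonism (`a > 0`, surface above the
  reference: higher response = less toxic) or synergism (`a < 0`);
- DR: `G = (a + b·z1)·z1·z2` — dose-ratio dependence (implemented, not part
  of the default ladder);
- DL: `G = a·z1·z2·(1 − b·TU_total)` — dose-level dependence, deviation sign
  flipping at `TU_total = 1/b`.

CA applies `G` as `Σ c_i/ECy,i = exp(G)`; IA as the power transform
`y = θmax·(Πq_i)^{exp(−G)}`. Both leave the single-chemical margins exactly
intact (`z1·z2 = 0` on the axes). The published description of this family of
deviation models does not print the functional forms; the forms above were
chosen to satisfy every property the framework is described as having
(overall synergy/antagonism, dose-level dependence with a sign change,
reference recovery at `a = 0`) while staying closed-form and testable.
Bit-level parity with the original spreadsheet implementation is not claimed.

**Numerics.** The CA prediction solves a strictly monotone scalar equation by
vectorized bisection on `y ∈ (ε, θmax − ε)` with `ε = 1e-9·θmax` and 90
halvings (interval ~`θmax·2^-90`, far below the 1e-8·θmax contract). For
extreme trial parameters during optimization (near-step marginals) the root
can fall outside the clamped bracket; predictions are then clipped to the
asymptote instead of failing, which keeps the least-squares objective finite
and continuous. An independent grid-refinement oracle checks the root to
1e-6·θmax on random instances in the test suite.

**Fitting and the ladder.** All surface parameters (shared plateau, two
marginal EC50/β pairs, deviation terms) are fitted jointly on pooled axis and
mixture data, as in a fixed-ray design. The SA fit is warm-started at the
reference optimum with `a = 0`, so its SS can only improve on the parent;
the reference is then re-polished from the SA marginals and, if it improves,
the SA fit is refreshed — this enforces the nesting
`SS(ref) ≥ SS(SA) ≥ SS(DL)` up to optimizer tolerance and stabilizes the
test's null behaviour. Nested fits are compared with
`χ² = n·ln(SS_reduced/SS_full)` (Gaussian ML with profiled variance) on
`Δk` degrees of freedom; the reference fit itself is screened with an F-test
against the grand mean, which is the interpretation adopted for the
"fit of CA/IA" significance row of interaction tables (the original null is
not specified there). The default ladder is reference → SA → DL, matching how
such tables are reported; DR is available but not run by default.
α = 0.05 throughout, configurable. Increasing endpoints are flipped to the
decreasing effect scale (`θref − y`) before surface fitting so one code path
serves both directions.

## Toxicokinetics

Single-compartment first-order depuration, `C_t = C_0·e^{−kt}`, anchored at
transfer to clean water; uptake kinetics are out of scope. The default fit is
OLS of `ln C` on `t` (closed form; exact ML under multiplicative lognormal
error, which is also the generator's noise model); a raw-scale nonlinear fit
seeded by the log-linear solution is available since the fitting scale of the
original analysis is not stated. `k ≤ 0` is returned but flagged as "no
elimination"; a constant series returns `k = 0` with `R² = 0`. Half-life is
`ln 2/k`, defined only for `k > 0`.

## Biomarker testing and the health status index

Two-sided Mann–Whitney U per biomarker; the exact permutation distribution is
used for tie-free samples up to total size 16, otherwise the tie-corrected
normal approximation with continuity correction. Significant changes
(`p < α`) become alteration levels: AL2 when the fractional median change is
in the harmful direction and at least the biomarker's severity threshold,
AL1 otherwise (including significant changes in the non-harmful direction —
AL0 is reserved for non-significant outcomes by definition). Default severity
thresholds: 50% labilization-time reduction for the guide biomarker LMS,
100% change otherwise; all per-biomarker configurable. A zero control median
is a normalization error, not a silent NaN.

The A–E grade comes from a first-match rule table whose conditions are
monotone in the alteration levels, so raising any alteration can never
improve the grade (property-tested over random panels):

| grade | default condition |
|---|---|
| E | guide biomarker AL2 and ≥ 2 further biomarkers AL2 |
| D | ≥ 2 biomarkers AL2 spanning ≥ 2 organization levels |
| C | any AL2, or ≥ 2 altered biomarkers with ≥ 1 above cell level |
| B | any (remaining, i.e. mild cell-level) alteration |
| A | no alteration |

The exact thresholds and rules of the original expert system are not
published; this table encodes its two stated drivers — how many biomarkers
are altered and at which biological organization level — in an auditable,
overridable form (YAML). The C row is deliberately broader than "AL2 at cell
level only": any severe alteration rates at least C, which makes the table
total (every panel matches some rule) and preserves monotonicity. Custom
tables must end in an unconditional rule and are validated at load.

Because each biomarker is tested at α = 0.05, a fully healthy four-biomarker
panel grades A only when *all four* tests are non-significant; the expected
grade-A rate under the null is therefore `(1−q)^4` with `q` the per-test
rejection probability (slightly below α for a discrete rank test), i.e.
around 0.84 rather than 0.95. The test suite derives `q` analytically from
the exact U null distribution and checks the simulated rate against it — a
useful reminder that the index has a non-trivial family-wise false-alarm
rate.

## Transcriptomic comparison layer

DEG calling: log-odds `B > 0` (threshold configurable), trend = sign of `M`;
a called gene with `M = 0` has no trend and is an error by default (or
dropped with a warning). Overlap accounting over three named lists treats
pairwise counts as **exclusive** of the triple intersection — the only
convention under which the published mixture-unique count follows from the
published list sizes and overlaps (103 − 15 − 19 − 8 = 61) — and reports
same/opposite trend splits per pair plus "unique including opposite-trend
shared genes". Percentages are relative to the focal (mixture) list for rows
involving it and to the union otherwise. The published union count itself is
not reproducible from the published row entries under either convention
(probe/gene redundancy is the likely cause), so it is not a package output of
record.

Concordance rule (reconstructed; the original paper states "consistent
outcomes" without a formula): a comparison matches iff the array calls the
gene (`B > 0`), the qPCR change is flagged significant and the platforms
agree in sign — or the array does not call it and the qPCR change is not
significant. This rule reproduces all four published match statistics
(8, 10, 9; 27/33) on the bundled 12-gene panel, with the gene lacking array
data excluded. qPCR significance is consumed as a boolean flag when only
summary values are available and computed by the randomization test when raw
Ct data are present.

Relative expression is the efficiency-corrected ratio
`E_t^{ΔCt_t} / geomean_r(E_r^{ΔCt_r})`, `ΔCt = mean Ct(control) − mean
Ct(exposed)`, geometrically normalized over the reference genes; with all
efficiencies at 2 it reduces exactly to the `2^{−ΔΔCt}` method. The
randomization test reallocates sample group labels (keeping group sizes),
recomputes the normalized |log ratio|, and enumerates all splits when there
are at most 10,000, sampling with a seeded RNG otherwise (observed allocation
included in the count).

## GO enrichment

One-sided hypergeometric over-representation of each term in the study list
against the array universe, after closing annotations over is_a ancestors
(on by default; the original tool's behaviour is unstated, and propagation is
what makes parent counts dominate child counts). `part_of` edges are ignored;
the OBO reader keeps only id/name/namespace/is_a. No multiple-testing
correction by default, matching the conventional raw `p < 0.05` reporting in
this literature; Benjamini–Hochberg is available and recommended for new
analyses. Lowest-node summarization returns the significant terms with no
significant descendant — an antichain whose ancestor closure covers the whole
significant set.

## Synthetic data: what it emulates, and what it does not

Each generator draws from its own seeded RNG stream and records its
generating parameters (provenance) for closed-loop recovery tests; identical
seeds give bit-identical output. Defaults mirror the study conditions:

- dose–response: responses on the curve plus additive Gaussian noise,
  controls always included;
- mixture ray: 3 single-chemical levels per chemical (EC12.5/EC25/EC50
  placement), two equitoxic mixtures (0.5 and 1.0 TU), 5 replicates per
  treated condition and 9 controls → n = 49, the sample size of the
  guide-biomarker analysis; noise sd 5% of the plateau in the simulation
  studies;
- elimination: multiplicative lognormal noise
  (`ε ~ N(0, ln(1+CV))`) on a 3 h–6 d sampling grid with triplicate
  measurements per time, as chemical analyses were run in triplicate; note
  that slow rates (k ≈ 0.008/d) decay only ~4% over the 6-day window and are
  barely identifiable at 10% CV — recovery studies therefore use the faster
  pesticide-like rate;
- DEG study: the requested overlap/trend structure is realized *exactly* as
  set identities (members get `B` above threshold, non-members below), which
  is what makes the accounting layer testable against printed counts;
- annotation: a random layered is_a DAG with one term spiked in the study
  list at a chosen odds ratio, all other terms independent of the study list;
- biomarker panels: Normal replicates (CV 10%) around shifted means for the
  four-biomarker battery.

What passing these tests shows is that the *analysis machinery* is correct
and calibrated under its stated error models. It does not validate the error
models against real mussel data: real biomarker distributions are skewed,
array probes cross-hybridize within gene families (the published concordance
mismatches cluster in chitinase/GM2-activator paralogues), annotation is
incomplete and biased, and real surfaces need not follow any log-logistic
margin. Those caveats transfer to any application to real data.

## Problem sizes used in the shipped checks

The simulation studies shipped with the package use the study-scale designs:
200 null replicates for the type-I calibration of the CA-vs-SA test and 100
replicates for power/recovery studies at n = 49, 100 seeds for the
enrichment and panel calibration checks, and exhaustive enumeration oracles
at small n (Mann–Whitney up to total size 10, hypergeometric up to N = 60,
randomization splits up to 10,000). These sizes make the full suite run in a
few minutes on one core while keeping the binomial uncertainty of each
simulated rate well inside the asserted bands.

## Known limitations

- Two-component mixtures only; no Hewlett/Plackett isoboles, no Bayesian
  fitting, no hormesis/biphasic curves.
- The deviation functional forms are a faithful-by-properties reconstruction,
  not a line-by-line port of the original spreadsheet.
- Dose-ratio (DR) deviations are identifiable only with several mixture rays:
  along a single fixed ray the toxic-unit share `z1` is constant at every
  interior point, so `a` and `b` enter only through `a + b·z1` and cannot be
  separated. The default single-ray design therefore supports SA/DL testing
  only, which is also why the default ladder stops at DL.
- The HSI rule table is a documented default, not the (unpublished) original;
  grade outputs on real panels should be read together with the per-biomarker
  alteration levels it reports.
- LIMMA-style preprocessing, array normalization and annotation generation
  are out of scope: `M`/`B` tables and GO annotation tables are consumed as
  inputs.
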