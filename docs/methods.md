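# Methods

This note documents the models, conventions and numerical choices behind
`sibmort`, and what the synthetic experiments do and do not establish about
real survey data.

## Dates, ages and windows

All dates are century-month codes (CMC): months since January 1900, with
January 1900 = 1, the convention of the major household-survey programmes.
Ages are completed years, computed from exact CMCs as
`floor((date − birth)/12)`, never from the age reported at interview.
Observation windows and age intervals are half-open: a "last 3 years"
window is the 36 months `[interview − 36, interview)`; a death exactly at
the window start is counted, one at the end is not; age groups are
`[x, x+5)`. When a year-valued age or duration is converted to a CMC, the
missing within-year month offset is either the deterministic mid-year value
(6, the default for derived birth dates) or drawn uniform on 0..11 from the
run RNG (the default inside imputation); both leave the completed-years age
consistent with the derived date.

## Direct estimation

Deaths and person-years are accumulated at month resolution per sibling and
5-year age group over ages 15-49; each month a sibling is alive inside the
window contributes `weight/12` person-years to the age group it occupies
that month, and a death inside the window contributes the weight to its
age-at-death group. Rates `m_a = D_a/PY_a` are converted with the
mid-interval actuarial form `q_a = 5m_a/(1 + 2.5m_a)` (deaths assumed to
occur halfway through the 5-year interval; this is the form implied by that
assumption, not the exponential `1 − exp(−5m_a)`, though the two agree to
~1e-6 at the rates involved) and chained to `35q15 = 1 − ∏(1 − q_a)`.
`q_a` is clipped at 1, which only matters for pathological rates above 0.4.

Respondents are alive by selection and contribute no exposure or deaths of
their own; no survivor-bias reweighting is applied — the estimator is the
plain direct method. Weights are respondent-level; every sibling inherits
its respondent's weight, and all outputs are invariant to a uniform
rescaling of the weights.

The jackknife deletes one respondent at a time, so a respondent's siblings
leave together (the natural clustering in a random-digit-dial phone sample,
which has no PSU structure). The variance is `((n−1)/n)·Σ(θ_(i) − θ̄)²`,
the CI is normal-approximation on the untransformed probability, truncated
to [0, 1]. Replicates in which an age group loses all person-years are
skipped with a warning and n adjusted. Inside `estimate_35q15` the
leave-one-out estimates are computed vectorised from per-respondent
death/exposure sums; a generic (estimator-agnostic) `jackknife_ci` is also
provided. In 200 simulated surveys of 2,000 respondents the 95% intervals
covered the true value in well over 90% of replicates (see the test suite,
which recomputes this).

A small helper scales a national rate schedule to a province by the ratio
of province to national under-five mortality (applied on the rate scale,
then re-chained), the standard rough subnational adjustment when no
province-level adult schedule exists.

## Raking

Weights are fitted by iterative proportional fitting over the weighting
variables, cycling until the largest absolute deviation of a weighted
category share from its target is below `tol` (default 1e-6, at most 100
cycles). The cap (default 2, on the mean-1 scale) is applied after each
full cycle and iteration continues — rake-trim-rerake — which keeps margins
as close as the cap allows; the alternatives (capping only once after
convergence, or not renormalising) are not used because they either leave
weights above the cap or leave the scale arbitrary. With a binding cap some
margins cannot be hit; the solution reports the residual deviation and the
capped count rather than failing. The final normalisation solves (by
bisection) for the scale at which the capped weights average exactly 1, so
"max weight ≤ cap" and "mean weight = 1" hold simultaneously; because
weighted shares are invariant to a uniform scale, this step does not move
the margins except through re-clipping. Per-stratum weight sets are
combined by rescaling each stratum's total weight to its population share.

## Imputation

Reference tables are weighted empirical histograms keyed by (respondent
5-year age group, sibling sex): age differences (respondent − sibling,
clipped to ±40 years) among surviving siblings, and the joint (age at
death 0-94, time since death 0-49 years) distribution among deceased
siblings. Pooled margins over sex and over age groups are always built, and
sparse cells resolve through a fixed fallback chain: exact key → collapsed
sex → nearest adjacent respondent age group → global pool (with a warning).

Sampling is proportional: a categorical draw on the table masses, via
inverse-CDF on the cumulative weights. Each respondent gets an RNG
sub-stream seeded from (run seed, CRC32 of respondent id), so imputed
values do not depend on the order of rows in the summary file.

Partial mode: survivors draw an age difference (redrawn up to 10 times if
the implied age falls outside [0, 95], then clamped — rare, and it keeps
counts conserved); recent deaths keep every reported field, and only
genuinely missing fields are filled — a missing month uniformly among the
months of the reported year compatible with the recency cutoff, a missing
age at death (the country variant that does not ask it) conditionally on
the reported time since death. The deaths *not* detailed — asserted by the
respondent to predate the cutoff — draw from the schedule truncated to
times since death beyond the cutoff. Whether to truncate or draw
unconditionally is a genuinely open choice; truncation is used because the
respondent's statement is information, and the choice is logged. Complete
mode redraws every death jointly from the untruncated schedule and flags
all death fields imputed.

The combined-sexes country variant flows through as sibling sex `u`
(unknown), kept unknown rather than imputed, with estimation run on both
sexes combined.

## The synthetic regime

The generator emulates a high-mortality stationary population. Mortality is
piecewise-constant by single year of age and sex: substantial
infant/child mortality (q0 ≈ 0.06-level hazard, declining through
childhood) and a Gompertz adult rise (slope 0.075/year, female level 0.85
of male). Adult hazards (15-49) are rescaled in closed form so the regime's
35q15 equals the target exactly: under piecewise-constant hazards
`35q15 = 1 − exp(−Σ h_a)`, so the scale factor is
`−log(1−target)/Σ h_a`. Defaults used in the validation experiments are
0.15 for both sexes — the mid range of the levels reported for the Sahelian
and central-African populations this instrument targets (WPP-type levels of
0.138-0.178 around 2019).

Sibship size is negative-binomial with mean 6 (high-fertility setting;
reported mean sibship sizes in such surveys run about 5-7) and dispersion
parameter 8 (variance ≈ 10.5 — moderate overdispersion; there is no strong
external anchor for the dispersion, so it is a fixed, configurable
default). Respondent-sibling age gaps are a discretised normal with sd 5
years plus uniform month noise, redrawn if they would place a sibling's
birth after the interview. Respondents are 18-64 with a gently declining
age distribution, assigned urban/rural residence, a three-level education
class and a two-level household-size class; respondents are alive by
construction and their own mortality is not simulated. Sibling lifetimes
are simulated year by year from the hazards, with an optional period shock
(hazard multiplier from a given calendar month onward) used to create the
recent-crisis scenarios; deaths after the interview are censored to alive.

Reporting-error injectors operate on the recorded data the way the
corresponding errors operate in interviews: heaping rounds the reported age
to the nearest multiple of 5 and rederives the birth date (preserving the
within-year offset); displacement slides a deceased sibling's whole
lifespan backward by a geometric number of months, so the recorded age at
death is untouched but the death can leave the reference period; omission
deletes the sibling row entirely. The error rates are free parameters — the
survey reports motivating them do not quantify them — so the validation
experiments run with all rates at zero and the injectors are exercised by
directional tests (heaping raises the Myers index; displacement lowers the
recent-death proportion; omission raises apparent survival).

What the generator does **not** emulate: mortality trends or crises unless
a shock is configured (real populations with irregular trends violate the
imputation's stationarity assumption more than these tests show),
correlation of mortality with the weighting covariates (so weighting
changes estimates only through composition, not bias), HIV-type age
patterns, multiple-birth structure, or recall decay with time depth.
Passing the validation experiment therefore shows the imputation machinery
is faithful under its own assumptions, not that those assumptions hold in
any particular country.

## Validation experiment

Each replicate simulates an independent reference and target survey from
the same regime, builds tables from the reference, collapses the target to
the summary instrument, imputes both ways, and compares each imputed 35q15
with the direct estimate from the target's own full history on the
0-3-year window (the window on which the survey estimates themselves are
reported). Aggregates are the mean absolute percentage deviation and the
median imputed/direct ratio, per method and sex. The default scale — 20
replicates of 4,000 respondents — was chosen as a desk-scale analogue of a
multi-country survey-pair comparison: 4,000 respondents is a typical
single-survey sibling-module size, and 20 replicates stabilise the MAPE to
a few tenths of a percentage point. At this scale partial imputation
deviates from direct estimation by about 1% per sex with median ratios
within 1.03 of unity, and complete imputation by an order of magnitude
more; under a recent mortality shock absent from the reference survey,
complete imputation systematically understates the shocked level while
partial imputation tracks it.

## Diagnostics

Myers' blended index is computed on the 0-90 scale over a decade-aligned
age range, default [10, 89]: for each terminal digit the age counts are
summed over all decades from two successive origins and blended with
weights (d+1) and (9−d); the index is half the sum of absolute deviations
of the blended percentages from 10. The age universe is selectable —
current ages of surviving siblings, or ages at death when diagnosing death
reports — because digit preference can differ between the two; results
carry the range used. Two anchor cases are exact: a digit-uniform
population scores 0, all ages on one digit scores 90, and ages heaped to
multiples of 5 (two digits) score exactly 80. The quality table reports,
per respondent age group, mean siblings ever born, the proportion
surviving, and the share of deceased siblings whose death is recent,
weighted and unweighted; it accepts either the full or the summary form and
gives identical results on a collapsed copy of the same data when the
recency window matches the collapse cutoff.

## Problem sizes and determinism

Default experiment sizes (4,000-50,000 respondents, 20-200 replicates
depending on the check) are chosen so each check's Monte-Carlo error is
comfortably below the tolerance it asserts. Every stochastic component
takes an explicit seed; simulator output is byte-identical under a fixed
seed, the pipeline writes its seed and a config hash into every output
bundle, and per-respondent RNG sub-streams make imputation invariant to row
order.

## Known limitations

Imputation is empirical hot-deck only (no model-based smoothing), so sparse
reference cells fall back to pooled distributions rather than borrowing
strength smoothly. The jackknife is respondent-level; if a design had
cluster structure above the respondent, variances would be understated. The
estimator includes no adjustment for survivor bias in sibling reporting
(siblings of dead respondents are unobserved). The Myers index is the only
digit-preference diagnostic provided.
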