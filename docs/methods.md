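# Methods

This note documents the statistical model behind each pipeline stage, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Report model and deduplication

A report is one individual case safety report: demographics, an ordered
drug list with FAERS role codes (PS/SS/C/I), therapy date ranges, a set of
MedDRA preferred terms (PTs, matched case-insensitively after whitespace
normalisation), outcome codes and reporter occupation. Only the post-2012
FAERS column layout is read. Unit handling: ages arrive under FAERS unit
codes (DEC ×10, YR, MON /12, WK, DY, HR → years; unknown codes leave age
missing), weights under KG/LBS/GMS. Dates missing a day or month are
completed to the 1st and flagged; this makes time-to-onset arithmetic
deterministic at the cost of up to one month of resolution for partially
dated reports.

Duplicate removal is two-staged:

1. **Case versions** — FAERS re-publishes updated cases; for each `caseid`
   the record with the greatest `primaryid` (the latest version) is kept.
2. **Redundancy** — records identical on the six-field key (event date, age,
   sex, reaction set, drug-name set, country) are collapsed to the latest
   receipt date, ties broken by greatest `primaryid`.

Two interpretations were open. The "drug group administered" element of the
key is read as the *set of normalised drug names* on the report — the only
definition that is computable from the tables alone. Missing values enter
the key as an explicit sentinel, so two resubmissions both missing, say, the
event date can still be recognised as duplicates; the alternative (missing
never matches) would leave most genuine resubmissions in place, defeating
the rule's purpose. Drug names are matched exactly after
uppercase/whitespace normalisation; no ingredient/brand mapping is
attempted, so analyses are per reported name.

## PT groups and counting conventions

A group of PTs representing one condition (an SMQ-style query) is counted
two ways. The default **PT-row sum** treats the group row as the column sum
of its member-PT rows: a report carrying k member PTs contributes k. This is
the convention under which a published group-level N equals the sum of its
printed PT-level Ns, and it is what the bundled osteoporosis group uses.
The MedDRA-standard **unique-case** count (a report contributes once) is
available via `aggregate_smq(..., unique_reports=True)`. The group-level
background count is summed with the same convention so the 2×2 margins stay
internally consistent.

## Disproportionality statistics

For a drug–event pair, a = reports with the drug as primary suspect and the
event, b = that drug's other reports, c = other drugs with the event,
d = the remainder; N = a+b+c+d and E = (a+b)(a+c)/N is the expected count
under independence (the unstratified row×column convention).

* **ROR** = ad/bc with the Wald interval exp(ln ROR ± z√(1/a+1/b+1/c+1/d)).
  The point is therefore the geometric mean of the CI bounds — a property
  used as a consistency check against published (point, CI) triples.
* **PRR** = (a/(a+b))/(c/(c+d)) with SE² = 1/a − 1/(a+b) + 1/c − 1/(c+d),
  accompanied by the Pearson χ² of the table, uncorrected by default since
  the conventional χ² ≥ 4 criterion is stated for the uncorrected statistic
  (Yates' correction is a flag).
* **IC** (BCPNN information component) = log₂((a+0.5)/(E+0.5)) with the
  Norén closed-form credibility bounds
  IC025 = IC − 3.3(a+0.5)^−1/2 − 2.0(a+0.5)^−3/2 and the symmetric-form
  upper bound with coefficients (+2.4, +0.5). Defined at a = 0.
* **EBGM** (gamma–Poisson shrinker): a_i ~ Poisson(λ_i E_i) with a
  two-component gamma mixture prior on λ_i whose five parameters
  (α₁, β₁, α₂, β₂, w) are fitted by maximum marginal likelihood over all
  (PS drug, PT) pairs in the dataset — the marginal is a negative-binomial
  mixture, maximised by L-BFGS-B on log/logit-transformed parameters from
  five fixed starts (canonical DuMouchel start first), ftol 1e−8, hence
  deterministic. The posterior is again a two-component gamma mixture;
  EBGM = exp(E[ln λ]) via digamma, EB05/EB95 by bisection on the mixture CDF
  to 1e−8. A `single_component` fit is provided for data where the mixture
  is weakly identified (e.g. simulation studies with one generating gamma).

Zero cells make ROR/PRR undefined; estimates then carry a machine-readable
reason and never silently apply a continuity correction (Haldane–Anscombe
+0.5 is an explicit opt-in). Signal criteria (ROR CI low > 1 & a ≥ 3;
PRR ≥ 2 & χ² ≥ 4 & a ≥ 3; IC025 > 0; EB05 > 2) follow pharmacovigilance
convention and are configuration-exposed; the consensus flag is the OR of
the per-method flags, with a = 0 never signalling.

The association p-value uses Pearson χ² (df 1, uncorrected) when all four
expected cells are ≥ 5 and the two-sided Fisher exact test otherwise.
Bonferroni correction multiplies by m (default: the number of pairs tested
in the run, since no external m is canonical) and caps at 1.

## Subgroups

Signal subgroups split by sex (unknown dropped from strata, retained
overall) and by age at 60 years, cutoff inclusive on the high side
(age 60.0 is "older"). Both the numerator and the background of a subgroup
2×2 are restricted to the stratum — a whole-database background would mix
strata-specific reporting propensities into c and d; the choice is recorded
in the run log. The descriptive table instead uses finer age bands
(<18, 18–64.9, 65–85, >85) and weight bands, with explicit Missing/unknown
rows and percentages of the column total including missing. For outcome
percentages each report contributes its single most serious outcome
(DE > LT > HO > DS > CA > RI > OT) so the block sums to 100%.

## Time to onset

TTO = whole days from the earliest primary-suspect therapy start to the
event date; reports missing either date are excluded and counted, as are
durations ≤ 0 (the Weibull support is positive — same-day onsets are not
representable and are reported in the exclusion tally). The Weibull MLE
solves the one-dimensional profile score equation for the shape by
bracketed Brent root finding; the scale follows in closed form. 95% CIs are
Wald on (ln α, ln β) using the observed information (central-difference
Hessian, step 1e−5). The failure classes are: CI entirely below 1 → early
(decreasing hazard), CI containing 1 → random (constant hazard), CI
entirely above 1 → wear-out (increasing hazard); a CI touching 1 is
classified random. Onset distributions of two drugs are compared with a
two-sided Mann–Whitney U test — chosen because onset distributions are
right-skewed; this is an interpretation, not a convention fixed by the
workflow — exact by full enumeration of group assignments when both n ≤ 8,
otherwise the normal approximation with tie correction. Degenerate samples
(all equal) are a hard error, not a silent fit.

## Synthetic data generator

The generator emulates the study conditions the pipeline is meant to face:
one primary-suspect drug per report drawn by marginal share; each reaction
PT drawn independently given the drug with probability
(background rate × planted rate ratio ρ), capped at 0.99; therapy starts
uniform over 2004–2024 with Weibull onset delays per drug rounded to days;
sex/age/weight/country/outcome/occupation drawn with explicit missingness
rates; receipt dates shortly after events. Reports that would carry no
reaction get one background PT so every report is analysable. The default
scenario holds two study drugs at a 1:5 share imbalance inside a
comparator-dominated stream (so the background is not polluted by either),
ten osteoporosis PTs at background rates of 4×10⁻⁴–4×10⁻³ plus fifty
background PTs at 4×10⁻², planted ρ of published magnitude (6–38) and
Weibull onset parameters of published magnitude (shape ≈ 1.1–1.3, scale
≈ 1,300–2,300 days).

Duplicates are injected at configurable rates: version duplicates (same
case, higher `primaryid`, receipt +30 d) and redundancy duplicates (new
case, identical six-field key, receipt +45 d). The manifest records every
(source, duplicate) pair, plus the count of *chance* six-field collisions
among independent base reports — those are genuine duplicates under the
rule, so exact accounting is: removed = injected + baseline collisions.
Each duplicate entry is flagged with whether its source's key was unique;
only for those clean pairs is the identity of the survivor predictable.

Deliberate simplifications, and hence what passing tests do not show about
real data: events are independent given the drug (no syndrome co-reporting
beyond the planted pairs), one suspect drug per report (no polypharmacy or
role-code noise), calendar structure is uniform (no reporting waves or
quarterly seasonality), drug names are clean (no misspellings needing
mapping), and missingness is completely at random. The planted ρ is a
*rate* ratio; the ROR estimates an *odds* ratio, so recovery checks use
rare events (≤ 5×10⁻⁴ background) where the two coincide to well under the
CI width.

## Problem sizes and numerical checks

The validation suite uses: 1,000 random tables against direct formula
evaluation (agreement to 1e−10); quadrature of the Poisson–gamma mixture on
five hand-built tables (1e−6); the digamma closed form for a single-gamma
prior (1e−8); hypergeometric enumeration for small-table Fisher p-values;
null calibration on a 200,000-report stream with all ρ = 1 (~480 drug–event
pairs: ROR CI coverage of 1 near 95%, Bonferroni-corrected consensus false
signals below 5%); ρ = 15 recovery within the ROR CI in ≥ 90 of 100 runs at
n = 200,000; Weibull shape-CI coverage over 500 fits of n = 254 (a
published-magnitude sample size) near its nominal 95% — the log-scale Wald
interval's true coverage at that n is ≈ 94%; and exact duplicate accounting
on a 10,000-report stream with 10% version and 5% redundancy duplicates.
These sizes keep the full suite under a minute while leaving Monte-Carlo
error well inside the asserted bands.

## Known limitations

No MedDRA hierarchy (PT lists are explicit; no narrow/broad query scopes or
SOC rollups), no ingredient-level drug normalisation, no covariate
stratification of E in the shrinker, no censoring model for time to onset
(spontaneous reports carry none), and no pre-2012 LAERS schema support.
One published-table quirk is intentionally not reproduced: a group-level
count quoted in prose differs by 7 from the column sum of its PT rows; the
column-sum convention is implemented because it is the one the printed
tables themselves satisfy.
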