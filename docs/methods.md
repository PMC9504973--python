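# Methods

## Counting unit and contingency tables

All disproportionality statistics count *case–PT pairs*: one unit per
distinct (case id, drug name, preferred term) triple, restricted by default
to drugs coded as suspect. The choice matters because a case can report
several events and a drug can be re-administered within a case; under this
unit a drug's "cases + non-cases" equals its total adverse-event reports,
which is how published JADER report counts behave (e.g. every olaparib row
of the transcribed signal table sums to 1,552 reports). The 2×2 table for
(D, E) is

|              | event E | other events |
|--------------|---------|--------------|
| drug D pairs | a       | b            |
| other pairs  | c       | d            |

and a + b + c + d is always the pair-table size. When several REAC rows of
one case share a PT, the retained pair carries the worst outcome (severity
order death > with sequelae > not recovered > remission > recovered >
unclear; missing lowest) and the best-precision, earliest onset date.

## ROR and the signal rule

ROR = (a·d)/(b·c) with the Woolf (log-normal) 95% interval
exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)), z = 1.959964. The CI method is a
package choice: the source study names none, and Woolf is the standard
textbook interval for SRS disproportionality. When any cell is zero the
Haldane–Anscombe correction adds 0.5 to *all four* cells before both the
point estimate and the interval; with every cell zero the estimate is
undefined and raises. A signal requires the CI lower limit > 1 *and* at
least `min_cases` (default 10) reports; screened-out pairs keep their
estimates but can never be signals. Display rounding is two decimals;
internal values stay full precision.

## Time to onset

days = (onset date − chosen start date) + 0.5, so a same-day onset counts
half a day. Both dates must have day precision; among a case's
day-precision start dates for the drug on or before the onset, the
*earliest* is chosen by default. The alternative reading of
"first start date prior to onset" — the most recent one — is available as
`start_rule="latest"`, since the phrase is genuinely ambiguous;
earliest-start is the default because re-administrations of the same drug
are one continuing exposure in this reading. Onsets more than `cap_days`
(default 730 d) after the chosen start are excluded. Every examined pair
produces either an observation or a machine-readable exclusion reason
(`onset_not_day_precision`, `no_day_precision_start`,
`no_start_on_or_before_onset`, `exceeds_cap`), and observations plus
exclusions always sum to pairs examined.

## Weibull fitting

Only observed onsets enter the fit (no censoring — the analysis models
occurrence times of reported events, not time-to-event among all exposed
patients). The log-likelihood

ℓ(α, β) = Σ [ln β − β ln α + (β − 1) ln tᵢ − (tᵢ/α)^β]

is maximized by profiling: α(β) = (mean tᵢ^β)^{1/β} in closed form, and the
one-dimensional score in β is solved by Brent's method on [0.05, 50]. The
bounds make degenerate samples (all values equal) deterministic: the fit
lands on the upper bound with a collapsed CI instead of diverging.
Observations are rescaled by their maximum inside the solver so t^β cannot
overflow. CIs are Wald intervals on (ln α, ln β) from the observed
information (central finite differences, step 10⁻⁴ on the log scale),
exponentiated — guaranteeing positive bounds. Failure type: early failure
iff the β CI upper limit < 1, wear-out iff the lower limit > 1, otherwise
"random". Raw medians/IQRs use type-7 (linear-interpolation) quantiles.

Simulation behaviour (measured by the test-bench): at n = 500 the shape
estimate is within 10% of truth; over 500 simulated samples (n = 200,
α = 50, β = 1.3) the 95% CI for β covers the truth at 94–96%; the MLE
matches an independent grid search to 10⁻⁶ log-likelihood and scipy's
Weibull MLE to 10⁻⁴ relative.

## Outcome tabulation

Outcomes attach to pairs (worst-outcome rule above). Reports with missing
outcome leave the denominator — the convention behind published outcome
tables whose n is smaller than the signal table's case count. Percentages
are computed in exact rational arithmetic and rounded half-up to one
decimal; a documented minority of the published cells were truncated
instead (and one row is internally inconsistent), which the regression
tests whitelist cell by cell.

## Synthetic databases

The generator emulates the *structure* the pipeline must survive — four
linked tables, suspect/concomitant codes, repeated courses
(`multi_dose_rate`, default 0.10), partial and missing dates
(`missing_date_rate`, default 0.10: half degrade day→month, half go
missing), multinomial outcomes including a missing share — with exposures
and events drawn independently per case except for planted associations.
It does not attempt realistic marginal AE frequencies, reporting-period
dynamics, or Japanese text fields; passing tests demonstrate statistical
correctness of the machinery, not fidelity to real JADER margins.

For a planted (drug, pt) with suspect-exposure probability s and
background event probability q, the event probability among suspect-exposed
cases is tilted to

p₁ = R·q·(1 − s) / (1 − R·s)

which makes the *expected pair-unit ROR* equal the target R: the comparator
cells contain a fraction s of tilted cases, so the expected ROR is
p₁ / (q + s·(p₁ − q)), and the formula inverts that. The tilt is infeasible
(config error) when R·s ≥ 1 or p₁ ∉ (0, 1). Planted onset dates are the
drug's start plus a Weibull(α, β) delay rounded to whole days before the
downstream +0.5 convention; the rounding adds a ≈ +0.5 d location shift
that biases fitted β upward by about 1–2% at α = 50 — visible in recovery
runs and accepted as the price of realistic day-resolution dates.
Background onsets follow an exponential delay (mean 60 d) from the case's
earliest suspect start. The ledger records the realized a/b/c/d cells for
every planted pair under exactly the pipeline's suspect-only pair unit
(verified cell-for-cell in tests), plus all pair counts and totals.
Identical seed and config give byte-identical CSVs.

**Reference conditions** (`default_config`): 20,000 cases; target drug
olaparib at 2% exposure; one planted association (olaparib, anaemia) with
target ROR 5 against a 2% background PT, α = 50 d, β = 1.5; six common
co-medication drugs (12–25%) supplying comparator mass; fourteen
background PTs at 0.3–0.8%. The background PT probabilities are kept below
the level where a 2%-exposure drug could reach the 10-case screen by
chance (expected ≤ 3 cases per null pair), which is what makes "the
planted pair is the drug's only signal" hold in ≥ 95% of databases as a
design property. Where high-precision recovery of the planted parameters
is wanted (fixed-seed ledger checks, the acceptance script's α/β/ROR
recovery), a denser design is used instead — target drug at 10% exposure
and thirty background PTs — because at the reference sparsity the sample
OR of a single database has a log-scale standard error near 0.3 and any
fixed seed would be a coin flip; the dense design shrinks it to ≈ 0.1.

## Pipeline determinism

`run_pipeline` restricts TTO and outcome analyses to the PTs flagged by
the signal screen, logs every TTO exclusion once with its reason, and
writes fixed-column-order UTF-8 TSVs plus a `run.json` carrying the config
echo, SHA-256 input hashes and per-stage counts — no timestamps or locale
state, so re-runs on identical inputs are byte-identical.

## Known limitations

- No censoring or competing risks in the Weibull stage; no stratified or
  adjusted disproportionality; ROR only (no PRR/IC/EBGM).
- MedDRA terms are opaque strings: no hierarchy expansion or dictionary
  lookup.
- Duplicate/revised-report semantics beyond case-id uniqueness are out of
  scope.
- Wald CIs on the log parameters are asymptotic; for very small n (< ~10)
  their coverage degrades, as with any quadratic-approximation interval.
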