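# Methods

## Data model and deduplication

A FAERS-style quarter is five `$`-delimited ASCII tables — DEMO, DRUG, REAC,
THER, OUTC — keyed by PRIMARYID (one report version) and CASEID (one
clinical case, shared across versions). The reader keeps every cell as a
string and rejects (with per-reason counts, never silently) rows with the
wrong field count or an empty PRIMARYID; unknown columns round-trip
opaquely. Only one post-2012 column dialect is supported.

Deduplication follows the FDA rule for versioned reports: group by CASEID,
keep the version with the latest FDA_DT, break FDA_DT ties by the higher
PRIMARYID (numeric comparison when all ids parse as integers, lexicographic
otherwise), and let undated versions lose to any dated one. The operation is
idempotent and never increases the case count. Deduplication runs before
role filtering and target selection; the order is observable only in edge
cases and is fixed here.

## Drug and event identification

Adverse events are matched at the MedDRA preferred-term level by exact PT
code (default target: 10012599, diabetes insipidus); no SMQ or hierarchy
expansion. Drug attribution uses primary-suspect (PS) records only — the
role the reporter considered chiefly responsible. Verbatim drug names are
standardized by exact dictionary lookup after case-folding, whitespace
collapsing and edge-punctuation stripping; there is deliberately no fuzzy
matching (deterministic, auditable), so unmapped verbatims are counted and
excluded from per-drug statistics. Salt/hydrate forms and combination
products are handled entirely inside the bundled synonym map; combination
products map to a single combined ingredient. The bundled synonym and
ATC-level-1 tables are small hand-curated stand-ins for DrugBank/MeSH and
the WHO ATC index, scoped to the catalog drugs.

Ages are harmonized to years (YR ×1, DEC ×10, MON ÷12, WK ÷52.18,
DY ÷365.25, HR ÷8766; a missing unit is read as years) with a 0–120-year
plausibility window: values outside it are set to unknown and counted,
which keeps unit-entry errors out of the age bands.

## Disproportionality

Per-ingredient 2×2 tables count deduplicated cases (a drug counts once per
case regardless of record multiplicity). ROR uses the Woolf log-scale 95%
interval with the z-value fixed at 1.96; any zero cell marks the ROR
undefined rather than applying a Haldane correction — the a ≥ 3 positivity
floor makes a correction irrelevant for reported signals. The BCPNN
information component uses the classical hyperparameters α = β = 2,
αᵢ = βⱼ = γᵢⱼ = 1, which center the prior IC at 0 under independence; they
are exposed in `BcpnnHyperparameters`. The lower credibility bound is
E(IC) − 2·√V(IC) (a two-standard-deviation bound); a raw E(IC) − 2·V(IC)
variant is available behind `ic025_rule="minus_2v"` for sensitivity
checks only. Positivity requires all of: ROR CI lower bound > 1, a ≥ 3,
IC₀₂₅ > 0. Strength strata are half-open on the right — weak (0, 1.5],
medium (1.5, 3], strong (3, ∞) — so a bound of exactly 1.5 is weak. No
multiplicity adjustment is applied beyond the dual criterion; no stratified
(age/sex) analyses are performed.

## Time-to-onset

TTO = EVENT_DT − START_DT in whole calendar days (0 allowed). Date policy is
strict: only 8-digit values encoding a real calendar date qualify; partial
(4/6-digit), empty, non-numeric and impossible dates are excluded with
reason codes, as are negative intervals (event before exposure — excluded as
data errors but separately coded so a sensitivity analysis can re-admit
them). Start dates prefer THER records joined via `dsg_drug_seq`, falling
back to the DRUG record's start date when no THER date parses; with several
valid dates, the earliest (first exposure) is used. Summaries are median and
quartiles with linear interpolation between order statistics (quantile
position 1 + p·(n − 1), numpy's default), which reproduces half-integer
medians at even n. Summary rows are reported for signal-positive drugs with
at least one usable record; drugs with none are omitted.

## Descriptive reporting

Target-case demographics: sex, age bands (<18, 18–64, ≥65, unknown), weight
bands (<80 kg, ≥80 kg, unknown), outcome codes, reporter occupations, top-5
countries, and per-year counts keyed on the FDA receipt date. Every
categorical block except outcomes sums to the case total; a case counts once
per distinct outcome code, so the outcome block may sum past the total and
the denominator (case total) is stated in the output rather than guessed
differently. Percentages print to one decimal, half-up. Rankings (by case
count and by ROR) break ties on ingredient name ascending so the order is
total. Figures are emitted as tidy CSVs; rendered plots are out of scope.

## Synthetic data generator

The generator's job is structural realism with analytic tractability, not
epidemiologic realism. Per report, one suspect-drug slot is drawn from the
catalog's baseline probabilities (which may sum below 1; the remainder
becomes an unmappable "UNSPECIFIED PRODUCT", exercising the unmapped-name
path), coded PS with probability `ps_fraction` (default 0.95). Given the
suspect drug d, each catalog event e occurs independently with probability
clip(q_e · rr(d,e), 0.95). Because the tilt acts on the conditional event
probability, the 2×2 expectations are exact closed forms
(`expected_counts`), which the tests use as the oracle; a side effect is
that a minority of synthetic cases carry no reaction row, unlike real
FAERS. Concomitant SS/C/I drug records, demographics (roughly matched to
published DI-case descriptives: sex ≈ 44/47/9% F/M/unknown, age ≈ N(47, 22)
years with 21% missing and occasional MON/DY unit coding, weight 76%
missing, US/JP/FR-dominated countries), outcome codes and reporter
occupations are decorated around that core and never perturb the 2×2.

Dates: FDA_DT is uniform in a 90-day quarter; EVENT_DT lags it by a
log-normal reporting delay (median 30 d); START_DT precedes EVENT_DT by a
log-normal onset lag — median 30 d by default, or the planted signal's
(median, σ) law for cases carrying that drug–event pair. Event and start
dates are then corrupted to empty / 6-digit partial / non-numeric forms at
configured rates (defaults 8% / 4% / 1%). Duplicated cases (default 5%)
are emitted as 2–3 versions: the true version keeps the latest FDA_DT;
earlier versions get cumulatively decremented dates (1–90 days per step),
permuted PRIMARYID suffixes (so id order disagrees with date order and
deduplication must consult FDA_DT), and degraded content. FDA_DT ties
between versions are not generated; the tie-break rule is covered by
crafted fixtures in the unit tests.

Default study-scale conditions (`paper_scale_config`): 200,000 reports, a
50-drug catalog of real ingredient names with a gently decaying baseline
(total 0.9), the target event at its database-wide marginal of
2,189/18,627,667 ≈ 1.18 × 10⁻⁴, and seven planted drug–DI associations
whose relative reporting ratios (5–850) and onset medians (0.7–226 days)
echo the published signal range. At desk scale the planted signals dominate
the simulated DI case pool far more than in the real database — a known
consequence of shrinking N by two orders of magnitude — so passing tests
demonstrate correct mechanics and calibration, not real-world effect sizes.
What the generator does not model: reporting dynamics over calendar time,
drug–drug interactions, MedDRA hierarchy structure, correlated
missingness, or reporting biases; conclusions about those cannot be drawn
from synthetic runs.

The statistical batteries in the test suite run at reduced but adequate
problem sizes chosen for statistical power: null calibration and
planted-signal recovery use 100 quarters of 50,000 reports with a 50-drug
catalog and a DI marginal of 2 × 10⁻³ (so per-drug null counts are ~5 and a
20-fold planted signal expects ~21 cases); onset recovery uses ≥ 200 usable
cases per seed, with tolerance set from the asymptotic standard error of a
log-normal sample median.

## Numerical and degenerate-input choices

* ROR/IC arithmetic is double-precision scalar math; the formula pair is
  verified against an independent literal transcription to 12 significant
  digits over all 2×2 tables with cells in {0..6}, and the ROR point
  estimate against statsmodels' `Table2x2`.
* An all-zero table has E(IC) = 0 exactly under the default priors (the
  prior is centered on independence); IC is defined for every table.
* `stratify` refuses IC₀₂₅ ≤ 0 — strata are only defined for positive
  signals.
* Empty inputs: an empty record list writes a header-only file; an empty
  case set yields zero-total demographics; a drug with no usable onset
  record is omitted from the onset table.
* Pipeline outputs are staged in a temporary directory and moved into place
  only on success, so failed runs leave no partial artifact bundle.

## Known limitations

* Exact-match drug standardization bounds recall by the synonym map; real
  FAERS verbatims (dose decorations, typos) would need a richer map.
* One table dialect only; pre-2012 ISR-era naming and E2B XML are out of
  scope, as is downloading real quarters.
* Disproportionality is hypothesis-generating: the statistics quantify
  reporting disproportion, not incidence or causality, and the package
  deliberately implements no causal adjustment.
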