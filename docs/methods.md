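# Methods

This note documents the modelling and numerical choices behind `biobank_dq`:
what the rule catalog encodes, how the engine counts, what the synthetic
generator emulates (and deliberately does not), and where the design was
genuinely open.

## Data model

The default schema describes one institution's yearly submission as five
tables keyed by the donor identifier `KBN_Donor`: basic information
(demographics, diagnosis, receipt date), physical measurements, disease
history, laboratory values, and lifestyle items — 54 fields in total. All
values are **raw strings** until a rule interprets them; empty CSV cells are
nulls. This is deliberate: the defects the pipeline exists to find (a
six-digit birthdate, a weight of `65000.0`, a code `?C21.49`) must survive
I/O verbatim rather than be destroyed or rejected by eager typing. Reading
only ever fails on *structure* (missing table file, header mismatch), never
on content.

Dates are 8-character `YYYYMMDD` strings; calendar validity is a rule, not a
parser property. Numeric fields accept the plain-decimal grammar
`[+-]?digits[.digits]` — scientific notation counts as malformed, matching
clinical capture systems. Disease-history *detail* fields use sentinel codes
(`0` = no disease / not applicable, `9` = not investigated) rather than
nulls, so that an unconditional not-null rule and a "type without history"
business rule can coexist in one catalog without contradicting each other on
clean data.

## The rule catalog

The pre-review catalog is constructed mechanically over the schema and
contains exactly 128 rules: one not-null rule per field (54), plausibility
ranges for height/weight/SBP/DBP (4) plus two cross-field comparisons
(height > weight, SBP > DBP), one format rule per checkable field — calendar
dates, code sets, numeric parsing — (42), two temporal orderings, 23
disease-history business rules (10 forward "flag ⇒ type", 10 reverse "type ⇒
flag", an other-cancer text requirement and two second-cancer-type
implications), and one donor-key uniqueness rule. Rules whose intent is
taken verbatim from the published rule examples are tagged
`provenance="paper-exampled"`; the rest are reconstructed filler and tagged
accordingly, so tests can separate anchored behaviour from scaffolding.

The expert review is shipped as a *data file* (`data/review_decisions.yaml`)
rather than code: 24 rules are dropped (detail-field not-null rules that are
unenforceable when the parent flag is absent or the item was not
investigated, narrative notes, one range and one comparison rule, and nine
business rules confounded by "not investigated" answers), most completeness
errors are reclassified to warnings, five format rules become warnings, and
the uniqueness rule is promoted from warning to error. The surviving catalog
has exactly 104 rules. Only the *marginal* before/after counts of such a
review are ever published; the shipped list is one consistent realization of
those marginals, and the catalog summary tests pin the marginals, not the
identities of the filler rules.

## Engine semantics

- **Null precedence.** A null can only trip a completeness rule (or a
  conditional-presence rule whose consequent it is). Format, range, parse,
  code and ordering predicates skip nulls; comparison and ordering
  predicates additionally skip values that do not parse, leaving the parse
  failure to the format rule. One defective cell therefore yields exactly
  one violation per applicable rule, and a record yields at most one
  violation per rule.
- **Double counting across rules is intentional.** A cell failing both a
  format rule and a range rule counts twice — they are distinct rules, and
  the per-rule tallies must add up. The report header records this
  convention.
- **Conditional rules** fire only when the antecedent is non-null and
  satisfied. The reverse business rules ("a concrete type requires the flag
  to record the disease") treat flag = 9 (not investigated) as acceptable
  and report the violation on the type field, whose value exists — so the
  invariant that only completeness-family violations carry a null observed
  value holds.
- **Applicability conditions** (e.g. the other-cancer rule applies only when
  the cancer flag is 1) *skip* evaluation; they never convert a failure into
  a pass.
- **Uniqueness** uses the all-but-first convention: in a group of k records
  sharing a non-null key, k − 1 violations. Null keys never form groups.
- **Determinism.** Output is sorted by (institution, rule, record key), so
  evaluation is invariant to input record order up to the row-index labels
  of records whose own key is null.
- **SQL export** emits one SELECT per rule that retrieves exactly the
  records the engine flags (tested by executing the emitted SQL on SQLite
  against the engine's output, including the correlated-minimum-rowid form
  of the uniqueness query). Execution against a production RDBMS is out of
  scope.

## Reporting

The error rate is `violations / (records × rules)`, with records counted
from the basic-information table and rules from the catalog actually run;
the percent string is rendered to two decimals with round-half-up in exact
decimal arithmetic. With the published 16-site counts this gives
42,829 / (55,316 × 104) = 0.7445 % → "0.74%", which is the convention's
cross-check. Institutions with zero violations keep a row of zeros in every
table.

Institution profiling compares completeness and validity counts: a site is
mapping-dominant when validity errors exceed `ratio_threshold ×`
completeness errors, omission-dominant in the converse case, balanced
otherwise (including 0/0). The threshold is a free parameter — published
analyses say only "significantly higher" — defaulting to 2 and reported
alongside the labels.

## Statistics

Chi-square independence uses the Pearson statistic Σ(O−E)²/E with margins
for expectations, dof = (rows−1)(cols−1), no continuity correction, p from
the chi-square survival function (delegated to
`scipy.stats.chi2_contingency(correction=False)`; the test suite checks it
against a hand-written Σ-formula implementation to 1e−9 on random tables up
to 16×4). Degenerate tables — under 2×2, negative cells, an all-zero margin
— are errors, not NaNs. No significance threshold is interpreted anywhere:
the tool reports statistic/dof/p and stops. On a worked 2×2 example
[[20, 5], [5, 20]] all margins are 25, every expected cell is 12.5, and the
statistic is 4 × 7.5²/12.5 = 18, matching the closed form
n(ad−bc)²/(r₁r₂c₁c₂).

Correlations are Pearson product-moment by default (Spearman by flag), with
pairwise deletion for missing factor values — sixteen institutions leave no
room for listwise deletion — and a hard minimum of 3 pairs. A constant
vector raises an undefined-correlation error; it is never silently reported
as r = 0. The nine default factor names (biospecimen count, hospital level,
staffing, IT infrastructure, …) are placeholders for a site survey and fully
config-driven; any numeric columns are correlated against the total and the
four per-dimension counts.

## Synthetic data

`generate_clean` emulates the study conditions of a 16-site network in one
collection year: labels A–P, 1000 donors per site by default (the full
~55k-donor network scale is reachable by config), adult anthropometrics
drawn from normal distributions clipped inside the schema's plausibility
ranges (height 163 ± 9 cm, weight 63 ± 11 kg, SBP 125 ± 15 mmHg with a
positive pulse-pressure gap, so height > weight and SBP > DBP hold
record-wise), birth years 1930–2002, receipt dates uniform over 2020,
diagnosis dates between birth and receipt, ~15 % prevalence per
disease-history item with 5 % "not investigated", and fully populated
free-text and sentinel fields. Clean output yields **zero** violations under
both the 128- and 104-rule catalogs — that is its definition, and a test.

`inject_errors` corrupts clean data with the four observed defect families:
essential-field nulls; date truncation to 6-digit `YYMMDD` or a 7-digit form
(equal probability); code corruption by `?`-prefix or `-1`-suffix (equal
probability); weight ×1000 unit errors; concrete cancer types set on
no-history records; and duplicated donor IDs copied between disjoint record
pairs. Injection counts are deterministic (`round(rate × n)` per type and
site); sites are drawn without replacement and **no record is corrupted
twice**, so the ground-truth ledger equals the engine's per-rule
per-institution detections exactly — the module's central acceptance
property, checked at full default scale over five seeds. Two deliberate
conventions keep that equality exact: a unit error is entered in the ledger
under *both* rules it must trip (weight range and height > weight), and the
logical corruption keeps the history flag at "no history" rather than
nulling it (nulling would additionally fire the flag's completeness rule).

What the generator does **not** emulate: disease-specific clinical
distributions for the 26 disease groups, correlated defects (a sloppy site
is sloppy independently per error type here), multi-field corruption of a
single record, free-text noise, or encoding problems. Passing the recovery
tests therefore shows the engine counts what was planted — it does not show
that real submissions contain only these defect shapes.

`generate_factors` ties `biospecimen_count` to each site's record count and
draws the remaining survey slots from plausible distributions. For the
correlation-recovery study, per-site error burdens are constructed as
`intercept + slope × biospecimen_count + N(0, σ)`; for a fixed design of
site sizes the construction's population correlation is
`slope·sd(n) / √(slope²·var(n) + σ²)`. The study (16 sites sized 100–850,
50 replicates, defaults chosen to keep a full replicate under ~2 s) checks
that the end-to-end pipeline — generate, inject, evaluate, report,
correlate — recovers that value to ±0.1, and recovers ≈ 0 when the slope is
zero. The published factor correlations themselves (e.g. r = 0.81 between
total errors and biospecimen count) depend on an unavailable site survey
and are reproduced only qualitatively, by construction, on synthetic data.

## Known limitations

- The consistency dimension (cross-system referential checks) is out of
  scope; the emulated registry exports no foreign keys.
- The schema's 54 fields cover every field the rule examples name plus
  reconstructed filler; real network dictionaries are far wider. The schema
  is config-extensible, but the shipped 128/104 catalogs are tied to the
  default schema's field census.
- The expert-review decision list realizes published marginal counts; the
  identity of individual reclassified/dropped rules is a modelling choice.
- SQL export targets a portable dialect verified on SQLite; vendor dialects
  may need adjustment.
- Severity tables feed the chi-square test as given; with tens of thousands
  of counts the test is effectively a certainty to reject exact
  independence, so its output is descriptive, not confirmatory.
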