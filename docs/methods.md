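# Methods

## The index and its derivation model

The Complexity Index is a deficit-accumulation-style count: 26 binary
variables, each mirroring one item of a 30-item nursing checklist of
multidimensional care complexity, summed without weights to a 0–26
total. Each variable is defined by a predicate over one or more
assessment items (no item feeds two variables), ranging from a single
item ("any pain", J6a > 0) to compound conditions (social isolation:
living alone AND (no visits and no other interactions in the last 3
days, OR a decline in social activities)). Four checklist items
describing the care system itself (partnership between actors,
therapeutic incoherence, insurance problems, burden on the secondary
network) are not represented in the assessment and are never derived;
the checklist total restricted to the other 26 items (COMID-26) is the
comparison score.

Predicates are shipped as data (`data/ci_rules.yaml`), not code: each
rule lists its items and a small expression tree (`item` / `any` /
`all` / `count_ge` / `quantity` nodes). This keeps every threshold
auditable and lets a deployment adapt the catalogue to its instrument
edition without touching the engine.

## Item coding and positivity

The source instrument's per-item code scales are edition-specific and
not public in full, so the package ships a coding dictionary
(`data/coding_dictionary.yaml`) declaring, per item: the legal range,
the direction that counts as "problem present", an explicit
"uncertain" code where the instrument has one, and free-text flags for
fields like "other diagnoses" and the medication slots. Two
conventions matter:

* **Reverse-coded support items.** For the caregiving and
  social-contact items (helpers present, supportive family
  relationship, visits/interactions in the last 3 days) the problematic
  direction is the *absence* of support, so positivity is declared as
  code 0. With that convention every rule predicate is monotone in item
  positivity — flipping any single item from its negative to its
  positive code can never lower the total — which the test suite
  asserts item by item.
* **Uncertainty.** Three rules (inadequate housing 2e, ADL change 5b,
  cognitive change 5d) count an explicitly recorded "uncertain" code as
  positive, following their "problem with (or uncertainty about)"
  wording. Everywhere else an uncertain code is treated as
  undecidable. `UNCERTAIN` is a sentinel distinct from `MISSING`, and
  only items whose dictionary entry declares an uncertain code may
  carry it.

## Derived quantities

* **Chronic-condition count (rule 1a, "more than 2").** Thirteen
  disease sources (12 diagnosis/symptom slots plus a body-mass-index
  band) plus one for any response in the free-text "other diagnoses"
  field. The BMI band counts under-nutrition or obesity (BMI < 18.5 or
  ≥ 30, configurable) as one condition; height is stored in cm, weight
  in kg. An empty "other diagnoses" field counts as zero rather than
  missing — no response means nothing to count.
* **Medication count (rule 1d, "five or more").** Taken from a
  precomputed `medication_count` column when the file provides one
  (authoritative, empty → missing); otherwise counted from populated
  medication-slot items M1f…M9f.
* **Provider count (rule 6a, "at least three").** Positive sources
  among eight formal-care slots plus the legal-oversight item, which is
  counted as a provider source.

## Missing-data semantics

Predicates are evaluated in Kleene three-valued logic: a disjunction is
1 as soon as one branch is 1 even if others are missing, 0 only when
all branches are decidably 0, and missing otherwise; conjunctions and
counting thresholds are dual (a count decides early once the known
positives reach the threshold, or once the unknowns can no longer reach
it). The default scoring policy is *strict* — the total is missing
whenever any of the 26 variables is — mirroring the list-wise deletion
used by the validation battery; a *per-rule* policy that sums the
decided variables and reports the number missing is available for
descriptive use.

## Validation battery

Per variable, the derived value is crossed with its checklist
counterpart; phi = (ad − bc)/√((a+b)(c+d)(a+c)(b+d)), with the p-value
from the 1-df chi-square at nφ² (no continuity correction — the
canonical companion of phi; Yates-corrected and Fisher-exact variants
sit behind a flag since the choice is not standardised). A table with a
zero marginal (a constant variable) yields NOT_CALCULABLE rather than
an error. Significance uses strict inequality against the
Bonferroni-adjusted threshold α/m with α = 0.05, m = 26 (.0019).
Cronbach's alpha uses the classical k/(k−1)·(1 − Σs²ᵢ/s²ₜ) with sample
(n−1) variances by default; the population convention is available and
the two differ only in the third decimal at a couple hundred subjects.
Spearman's rho is the Pearson correlation of mid-ranks. List-wise
deletion drops any record with a hole on any of the 26 derived or 30
checklist variables and reports the excluded count and fraction;
pairwise deletion subsets per analysis. An empty analysis set raises,
never passes silently.

## Synthetic data: what it emulates, what it does not

No clinical dataset ships with the package, so all statistics are
exercised on generated records. Per subject and rule the generator
draws a latent binary truth with the configured prevalence, realises it
in raw item codes via the rule's deterministic witness settings (item
disjointness makes the union well-defined), and emits the paired
checklist answer as a noisy copy (equal to the truth with the
configured agreement probability, flipped otherwise). The four
non-derivable checklist items are drawn independently. Missingness is
injected per stored value, independently, at a single rate.

Defaults are the derivation-study conditions: 216 subjects, the
published per-variable prevalences (derived-yes fractions), and
agreement probabilities read off the published 2×2 marginals by brute
force over the joint table's one free cell (`interrai_ci.reference`).
Variable 4e keeps its observed prevalence of 0, so default datasets
reproduce the "not calculated" degenerate phi.

Deliberate simplifications: truths are independent across rules unless
the optional one-factor Gaussian severity dependence
(`latent_correlation`) is enabled, so default datasets exhibit
near-zero internal consistency, unlike real complexity data whose
items correlate positively; disagreement between index and checklist
is a symmetric flip, whereas in the field the index tends to be the
more sensitive instrument; item realisations use canonical codes only,
so marginal code distributions within an item are degenerate; and no
longitudinal structure is modelled. Passing tests therefore demonstrate
algorithmic correctness and statistical calibration of the machinery,
not distributional realism of any clinical population.

## Numerical and design choices

* Sentinels (`MISSING`, `UNCERTAIN`, `NOT_CALCULABLE`) are identity
  singletons, never equal to a legal code and with no truth value, so
  silent coercions cannot occur.
* Phi/alpha/rho are implemented directly from their defining formulas
  (scipy supplies only the chi-square tail and rank utilities); the
  test suite cross-checks them against independent brute-force oracles
  and, for alpha, against an external reliability implementation.
* Problem sizes in the test and acceptance suites — up to 5,000
  subjects for exact scorer recovery, 10,000 for closed-form phi
  calibration (3-standard-error bands), 40 replicates of 216 for the
  independence/false-positive check — were chosen to make the binomial
  error bands decisive while keeping the default run in tens of
  seconds.
* Report display rounds phi to 2 decimals and alpha/rho to 3, matching
  field convention.

## Known limitations

* The shipped coding dictionary encodes plausible, conventional scales;
  a deployment must align it with its own instrument edition (the
  config formats exist for exactly that purpose).
* The reference statistics module transcribes published per-variable
  marginals and coefficients for consistency checking and generator
  defaults; one published coefficient (variable 1b, 0.84) is not
  reachable from its own printed marginals by any integer 2×2 table
  (the achievable values jump from 0.83 to 0.86), which the suite
  asserts as a documented discrepancy rather than hiding.
* Empirical statistics of the original clinical sample (e.g. its alpha
  and rho) are properties of undeposited data and are not reproduction
  targets; the package validates machinery, calibration and structure.
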