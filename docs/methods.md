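# Methods

## Scope and model

`pedpip` operationalizes an explicit criteria list for potentially
inappropriate prescribing (PIP) in patients under 18 years.  The list
distinguishes potentially inappropriate medications (PIM) — wrong drug
selection, dose, duration, route, drug–drug interaction, or drug–disease
combination — from potential prescribing omissions (PPO) — a clearly
beneficial drug or safeguard (skin test, therapeutic drug monitoring, a
controller inhaler alongside a LABA) missing from the record.  The 136
criteria are split into 71 rules for children with non-specific
diseases/conditions and 65 rules tied to a specific disease context, and
each is encoded as one machine-readable entry: a trigger predicate, an
optional exception predicate, and either severity clauses (PIM) or a
required-action predicate (PPO).

A criterion is a declarative program over a small typed predicate language
(age ranges, gestational age, birth/current weight, sex, drug or drug-class
presence with optional route, six dose metrics, duration, daily frequency,
temporal co-prescription windows, diagnosis and procedure tags, Boolean
combinators).  The packaged drug lexicon (~170 drugs, ~40 closed-member
classes) and condition vocabulary (~100 tags) give every reference a
resolvable identity; a knowledge base fails validation if any reference
dangles.

## Encoding conventions

The printed rules are prose; turning them into predicates required a fixed
set of conventions, applied uniformly and testable at boundaries:

* **Ages.** "<N years" is the half-open day interval [0, ⌊N·365.25⌋).
  Day-denominated bounds ("≤14 days", "≤28 days") are inclusive as printed,
  as are "≤2 years"/"≤16 years" (the interval extends through the
  birthday).  Neonate = postnatal age ≤28 days; premature = gestational age
  at birth <37 weeks; very low birth weight <1500 g; "children" with no
  qualifier = under 18 years.
* **Comparators.** Strictness follows the printed text: ">10 mg/kg/d"
  excludes 10.0; "≥200 mg/kg" includes 200; "<6 years" excludes the sixth
  birthday.  Every numeric atom carries an `inclusive` bit.
* **Dose metrics.** Doses normalize to mg.  mg/day = per-dose amount ×
  daily frequency; per-kg metrics divide by current weight and are
  *unavailable* (not zero) when the weight is missing.  Rate metrics
  (mg/kg/h) treat the prescribed daily amount as spread over 24 h.
  Cumulative exposure uses the explicit cumulative-dose field when present,
  else dose × frequency × duration, flagged as derived.  1 week = 7 days,
  1 month = 30.44 days.
* **Severities.** A row bundling several tiers ("Avoid in <2 years;
  Caution in children") is ONE criterion with multiple severity clauses;
  the reported severity of a flag is the maximum (avoid > caution) over
  satisfied clauses.  Rows in the disease-specific table that print no
  Avoid/Caution keyword are encoded with a single clause: "avoid" where the
  text proscribes ("do not", "avoid"), otherwise "caution".
* **"First-line" rules.**  Rules of the form "X other than A or B as
  first-line" flag when a drug of class X is present and no first-line
  agent (A, B) appears anywhere on the record.  Treatment ordering is not
  recorded in prescriptions, so presence of the first-line agent is taken
  as compliance.
* **Interaction windows.**  "Within 48 h" is inclusive of the 48th hour.
  Separation rules ("at least 2 h before or 6 h after") are violated when
  neither gap is respected; a gap of exactly the stated hours is
  compliant.  "Simultaneous use" means identical start times; two orders
  with no recorded times on one record are treated as simultaneous.
* **Unquantifiable clauses.**  A CENTOR score ≥3, a "significantly"
  elevated CRP/neutrophil fraction, severe disease qualifiers, and
  administration technique (intravenous bolus) are not computable from a
  prescription record.  They enter as user-supplied vocabulary tags (the
  bolus as a procedure tag linked to the drug); the engine consumes but
  never infers them.  One indication row prints no risk text; its flag
  carries an empty rationale.
* **Ambiguous typesetting.**  One hyperbilirubinemia line sits between two
  antiretroviral rows in the source table; it is stored with the indinavir
  row and the ambiguity is recorded in that criterion's provenance note.

## Three-valued screening

Real prescriptions are incomplete, so predicates evaluate under strong
Kleene logic: satisfied / not-satisfied / indeterminate.  Atoms that need a
missing input (weight for per-kg doses, a timestamp for a window,
unrecorded sex) are indeterminate and name the missing field; conjunction
and disjunction propagate indeterminacy only when it is decisive, and
negation preserves it.  Order-scoped atoms are existential over matching
orders: one satisfying order suffices, and indeterminacy surfaces only when
no order satisfies but some cannot be decided.

A PIM flags when trigger ∧ ¬exception holds and at least one severity
clause holds; a PPO flags when trigger ∧ ¬exception holds and the required
action is absent.  An indeterminate exception or required action makes the
whole criterion indeterminate — the engine never flags through an
unverifiable exception — and each record's output partitions the criteria
into flagged, clean, and unscreenable (with the missing fields listed).
This gives the monotonicity property checked in the test suite: supplying a
missing value can only resolve indeterminate outcomes, never flip definite
ones.  Drugs that fail lexicon lookup never match any atom, so an unknown
drug can produce an ingestion warning but not a flag.

## Delphi consensus calculator

Each proposition × panelist rating is an integer on a 5-point Likert
scale.  Per proposition and round the calculator reports mean, standard
deviation, CV = sd/mean, median, quartiles, IQR, and the full-score rate
(share of 5s).  Classification uses the predefined thresholds: accept when
Q1 ≥ 4, mean > 4, CV < 0.20; reject when Q3 ≤ 2, mean < 2, CV < 0.20;
otherwise no consensus.  The CV bound is strict in both directions.  Two
conventions the protocol leaves open are defaulted to common spreadsheet
behavior and are switchable arguments recorded in the output: sample
standard deviation (n−1) and linearly interpolated quartiles.  The round
ledger enforces conservation (entered = accepted + rejected + carried;
next round enters carried + new) and leaves final-round non-consensus
retention to human adjudication, supplied as a count.

## Synthetic cohorts

The generator exists to give the engine ground truth, not to emulate
epidemiology.  For each criterion it derives a *planted positive* directly
from the predicate tree — first satisfiable branch of each disjunction,
first non-forbidden member of each drug class, dose at 1.25× a threshold,
the interacting order inside its window — with every exception context
absent and, for PPOs, the required action omitted.  A *boundary negative*
repeats the construction with the first numeric threshold placed exactly on
the clean side (dose at the printed value for a strict comparator, age on
the excluded birthday, the second order one hour outside the window), with
sibling disjuncts suppressed so the trigger genuinely fails; criteria whose
trigger has no numeric threshold raise a not-applicable error.  Planted
patients are fully specified so their evaluations are determinate, and
every plant is re-verified at generation time.

Background records draw from five age strata (premature neonate 5%, term
neonate 10%, infant <2 y 25%, child 2–11 y 40%, adolescent 12–17 y 20%)
and a short list of drug/dose combinations verified non-triggering at
generation time; some omit weights or timestamps to exercise indeterminate
paths, and one background drug is deliberately absent from the lexicon to
exercise the unknown-drug path.  Cohorts are byte-reproducible per seed.
What passing tests therefore show is that the engine implements the
criteria faithfully at and around every encoded threshold — not that it
performs at any particular sensitivity on real prescriptions, whose drug
name variants, free-text doses, and coding noise the generator does not
model.

## Verification set-up and problem sizes

The test suite checks the engine against an independently written
brute-force interpreter (flag sets and indeterminacy sets must match
exactly) on 1000 randomly generated messy records, runs the full
136-criterion plant sweep (recall 1.0 required; 54 criteria admit boundary
negatives, all must stay clean), and property-tests the consensus
classifier (accept/reject mutual exclusivity, permutation invariance) with
derandomized Hypothesis.  The acceptance script repeats the sweep and a
400-record oracle comparison from scratch at a caller-supplied seed.  The
whole suite runs in well under a minute on one CPU.

## Known limitations

* Diagnoses must arrive as vocabulary tags; there is no ICD-10 or free-text
  mapping (a user-supplied mapping file can bridge).
* Drug name resolution is exact case-insensitive synonym matching; no fuzzy
  matching, and "etc." class expansions beyond the printed members are
  lexicon additions versioned separately from the criteria.
* Screening considers prescribed amounts only, not administered ones.
* The tool screens; it does not judge. A flag is a prompt for clinical
  review, not a contraindication.
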