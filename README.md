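# pedpip

Rule-based screening of **potentially inappropriate prescribing (PIP) in
children** — for pharmacists, pediatric clinicians, and
pharmacoepidemiologists who want to audit structured prescription data
against an explicit criteria list, rather than review chart by chart.

The package ships three things:

1. **A machine-readable knowledge base of 136 explicit criteria** for
   patients under 18 years — 71 for children with non-specific
   diseases/conditions (68 PIM, 3 PPO) and 65 tied to specific disease
   contexts (55 PIM, 10 PPO).  A *PIM* (potentially inappropriate
   medication) is a drug order whose risks outweigh its benefits in a given
   pediatric context — wrong age band, dose, duration, route, interaction,
   or indication.  A *PPO* (potential prescribing omission) is a clearly
   beneficial drug or safeguard that is absent: a penicillin without a skin
   test, vancomycin without therapeutic drug monitoring (TDM), a long-acting
   beta2 agonist without an inhaled corticosteroid.
2. **A three-valued screening engine.**  Each criterion is a predicate tree
   (ages, weights, mg/kg/day doses, durations, co-prescription time windows,
   diagnosis and procedure tags).  Records with missing inputs don't produce
   silent misses: the affected criteria are reported as *indeterminate* with
   the missing fields named, alongside the flagged and clean sets.
3. **A modified-Delphi consensus calculator and a synthetic cohort
   generator.**  The calculator classifies Likert rating rounds with the
   predefined thresholds (accept: Q1 ≥ 4, mean > 4, CV < 0.20; reject:
   Q3 ≤ 2, mean < 2, CV < 0.20) and tallies multi-round proposition
   bookkeeping.  The generator plants per-criterion positive records and
   boundary negatives (dose exactly at the printed cutoff, age on the
   excluded birthday) with ground-truth labels for end-to-end testing.

See `docs/methods.md` for the encoding conventions (age arithmetic,
comparator strictness, window semantics) and the generator's design.

## Worked example

Generate a small labeled cohort — one aminophylline overdose, one
boundary-negative at exactly 10 mg/kg/day, one penicillin order without a
skin test — and screen it:

```bash
pedpip simulate --n 6 --seed 42 --out-dir cohort \
    --plant rs_aminophylline:1:1 --plant ai_penicillin_skin_test:1
pedpip screen --patients cohort/patients.csv --orders cohort/orders.csv \
    --procedures cohort/procedures.csv --out-dir screened
```

```
INFO pedpip: wrote 6 records (3 planted labels) to cohort
INFO pedpip: screened 6 records: 2 flagged (1 PIM, 1 PPO), 0 indeterminate evaluations
```

`screened/flags.csv` then contains:

```
record_id,criterion_id,category,severity,matched_orders,rationale
P-rs_aminophylline-0,rs_aminophylline,PIM,avoid,P-rs_aminophylline-0-o0,"Higher risks of convulsions, arrhythmia, severe hypotension, cardiac arrest with doses >10 mg/kg/d or in neonates. 5-6 mg/kg/d recommended for children."
P-ai_penicillin_skin_test-0,ai_penicillin_skin_test,PPO,omission,P-ai_penicillin_skin_test-0-o2,Risk of severe allergic reactions such as anaphylactic shock. A skin test must be performed before use.
```

Reading the output: the aminophylline order was planted above the
10 mg/kg/day threshold, so it flags as a PIM with severity *avoid*; the
boundary-negative sibling record (exactly 10.0 mg/kg/day, a strict ">"
comparator) stays clean.  The penicillin record flags as a PPO because no
skin-test procedure accompanies the order.  `screened/summary.json` reports
the cohort roll-up: 2 of 6 records flagged (prevalence 0.33), one flag per
criterion, no indeterminate evaluations.

The same workflow is available as a library:

```python
from pedpip import packaged_kb
from pedpip.engine import screen_record

kb = packaged_kb()
result = screen_record(my_record, kb)   # .flags / .indeterminate_criteria
```

Other subcommands: `pedpip kb-stats` prints criterion counts by part,
category, and group (total 136); `pedpip delphi --ratings ratings.csv --out
stats.csv` classifies consensus per proposition and round.

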