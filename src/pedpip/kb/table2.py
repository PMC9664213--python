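"""Criteria for children with specific diseases/conditions (65 rules).

Rows are organized by disease problem (the bold table heading becomes the
criterion group; the italic sub-heading becomes the subgroup).  "First-line"
rules flag when a drug of the offending class is present and no first-line
agent appears anywhere on the record.
"""

from __future__ import annotations

from typing import Optional

from .dsl import (
    age_ge, age_lt, all_of, any_of, avoid, caution, child, dose_gt, drug,
    duration_gt, dx, freq_above, n_of_class, not_, pair, premature, proc,
    simultaneous, years_to_days,
)
from .model import AgeInRange, Criterion, Predicate, Provenance, SeverityClause

_TABLE = "Table 2"


def _age_le_years(years: float) -> AgeInRange:
    """Inclusive upper bound: '<=2 years' includes the 2nd birthday."""
    return AgeInRange(min_days=0, max_days=years_to_days(years) + 1)


def _pim(cid: str, group: str, sub: str, row: str, trigger: Predicate,
         clauses: list[SeverityClause], risk: str,
         exception: Optional[Predicate] = None) -> Criterion:
    return Criterion(
        criterion_id=cid, part="specific", category="PIM", group=group,
        subgroup=sub, trigger=trigger, exception=exception,
        severity_clauses=clauses, risk_text=risk,
        provenance=Provenance(table=_TABLE, row_label=row),
    )


def _ppo(cid: str, group: str, sub: str, row: str, trigger: Predicate,
         required: Predicate, risk: str,
         exception: Optional[Predicate] = None) -> Criterion:
    return Criterion(
        criterion_id=cid, part="specific", category="PPO", group=group,
        subgroup=sub, trigger=trigger, exception=exception,
        required_action=required, risk_text=risk,
        provenance=Provenance(table=_TABLE, row_label=row),
    )


def build_table2() -> list[Criterion]:
    c: list[Criterion] = []
    g = "Respiratory problems"
    s = "Respiratory infections"
    c += [
        _pim("sr_antibiotic_short_uri", g, s,
             "Antibiotic for <4 days symptoms of acute URI",
             all_of(dx("acute_uri"), dx("uri_symptoms_lt_4_days"),
                    drug("antibiotics")),
             [avoid(child())],
             "Acute URI is usually viral and self-limited; antibiotic abuse "
             "induces resistance.",
             exception=any_of(
                 all_of(dx("bilateral_acute_otitis_media"), age_lt(2)),
                 all_of(dx("acute_otitis_media"), dx("otorrhoea")),
                 all_of(any_of(dx("acute_sore_throat"),
                               dx("streptococcal_pharyngitis"),
                               dx("acute_tonsillitis")),
                        dx("centor_ge_3")),
                 dx("elevated_crp_or_neutrophils"),
                 dx("bacterial_respiratory_secretions"))),
        _pim("sr_non_first_line_antibiotic", g, s,
             "Antibiotics other than amoxicillin or penicillin V as first-line",
             all_of(any_of(dx("acute_otitis_media"),
                           dx("streptococcal_pharyngitis"),
                           dx("acute_tonsillitis"), dx("acute_sinusitis")),
                    drug("antibiotics"),
                    not_(any_of(drug("amoxicillin"), drug("penicillin_v")))),
             [caution(child())],
             "Other antibiotics have more adverse reactions and no better "
             "efficacy than amoxicillin and penicillin V.",
             exception=dx("penicillin_allergy")),
        _pim("sr_salicylates_viral", g, s,
             "Salicylates for suspected viral infection",
             all_of(drug("salicylates"), dx("suspected_viral_infection")),
             [avoid(child())],
             "Risk of Reye's syndrome. Avoid with suspected viral infection "
             "(flu and chickenpox)."),
        _pim("sr_corticosteroids_otitis_pharyngitis", g, s,
             "Corticosteroids for suppurative otitis media/nasopharyngitis/pharyngitis",
             all_of(drug("systemic_corticosteroids"),
                    any_of(dx("acute_suppurative_otitis_media"),
                           dx("nasopharyngitis"),
                           dx("streptococcal_pharyngitis"))),
             [caution(child())],
             "No evidence of effectiveness and risks of adverse reactions."),
        _pim("sr_ics_respiratory_infection", g, s,
             "ICS for respiratory infections without chronic respiratory disease",
             all_of(drug("inhaled_corticosteroids"),
                    dx("respiratory_infection"),
                    not_(dx("chronic_respiratory_disease"))),
             [caution(child())],
             "No evidence that ICS are effective and there are risks of "
             "adverse reactions."),
        _pim("sr_decongestants_over_7d", g, s,
             "Decongestants >7 days for acute URI",
             all_of(dx("acute_uri"), duration_gt("decongestants", 7, "days")),
             [avoid(child())],
             "No definite evidence of effectiveness for URI complications. "
             "Avoid >7 days for symptom relief."),
        _pim("sr_sedating_antihistamines_uri", g, s,
             "Sedating antihistamines in <2 years (respiratory infections)",
             all_of(drug("sedating_antihistamines"), age_lt(2),
                    dx("respiratory_infection")),
             [avoid(age_lt(2))],
             "Risk of sedation. Avoid in <2 years, except for anaphylaxis.",
             exception=dx("anaphylaxis")),
        _ppo("sr_analgesia_with_ear_infection", g, s,
             "Acetaminophen combined with antibiotics for ear infections",
             all_of(dx("acute_otitis_media"), drug("antibiotics")),
             drug("acetaminophen"),
             "Acetaminophen reduces 48-h pain of acute otitis media with "
             "placebo-level adverse events."),
    ]
    s = "Asthma"
    c += [
        _pim("sr_antihistamines_asthma", g, s,
             "Ketotifen (or other antihistamines) for asthma",
             all_of(dx("asthma"), drug("antihistamines")),
             [caution(child())],
             "No definite curative effect."),
        _ppo("sr_ics_with_laba", g, s,
             "ICS for children 5-15 years taking LABA",
             all_of(drug("laba"),
                    AgeInRange(min_days=years_to_days(5),
                               max_days=years_to_days(16))),
             drug("inhaled_corticosteroids"),
             "Maintenance treatment regimens for children are all based on "
             "ICS; LABA should not be used without it."),
        _ppo("sr_ics_asthma_ge6", g, s,
             "ICS for children >=6 years with asthma",
             all_of(dx("asthma"), age_ge(6)),
             drug("inhaled_corticosteroids"),
             "Relief and maintenance regimens from age 6 are built on "
             "low-dose ICS (with SABA or formoterol as indicated)."),
    ]
    s = "Infantile bronchiolitis"
    c += [
        _pim("sr_bronchiolitis_antibiotics_steroids", g, s,
             "Antibiotics or corticosteroids for bronchiolitis",
             all_of(dx("bronchiolitis"),
                    any_of(drug("antibiotics"),
                           drug("systemic_corticosteroids"))),
             [caution(child())],
             "No definite curative effect and risk of adverse reactions."),
        _pim("sr_bronchiolitis_symptomatics", g, s,
             "H1-antagonist, antitussive, mucolytics or ribavirin for bronchiolitis",
             all_of(dx("bronchiolitis"),
                    any_of(drug("antihistamines"), drug("antitussives"),
                           drug("mucolytics"), drug("ribavirin"))),
             [caution(child())],
             "No definite curative effect and risk of adverse reactions."),
    ]
    s = "Cough"
    c += [
        _pim("sr_mucolytics_young_cough", g, s,
             "Mucolytics for <2 years with acute cough (URI/acute bronchitis)",
             all_of(any_of(drug("acetylcysteine"), drug("carbocysteine")),
                    age_lt(2), dx("acute_cough"),
                    any_of(dx("acute_uri"), dx("acute_bronchitis"))),
             [caution(age_lt(2))],
             "No definite curative effect and safety in <2 years unknown."),
        _pim("sr_antibiotics_acute_cough", g, s,
             "Antibiotics for acute cough",
             all_of(dx("acute_cough"), drug("antibiotics")),
             [avoid(child())],
             "Acute cough is generally self-limiting (3-4 weeks) without "
             "antibiotics; abuse induces resistance.",
             exception=any_of(dx("bacterial_infection_signs"),
                              dx("general_discomfort"),
                              dx("high_risk_condition"),
                              dx("immunocompromised"),
                              dx("cystic_fibrosis"),
                              premature())),
    ]
    c += [
        _pim("sr_iv_streptomycin_tb", g, "Tuberculosis",
             "Intravenous instead of intramuscular streptomycin",
             all_of(dx("tuberculosis"), drug("streptomycin", "intravenous")),
             [avoid(child())],
             "Higher risk of respiratory muscle paralysis. Avoid intravenous "
             "streptomycin."),
        _pim("sr_codeine_post_tonsillectomy", g,
             "Tonsillectomy and adenoidectomy",
             "Codeine after tonsillectomy and adenoidectomy",
             all_of(dx("post_tonsillectomy_adenoidectomy"), drug("codeine")),
             [avoid(child())],
             "Risk of worsening dyspnea. Avoid without CYP2D6 gene "
             "polymorphism testing after tonsillectomy and adenoidectomy.",
             exception=proc("cyp2d6_test")),
    ]

    g = "Urinary problems"
    s = "Urinary infections"
    c += [
        _pim("su_asymptomatic_bacteriuria", g, s,
             "Antibiotics for asymptomatic bacterial urinary tract infection",
             all_of(dx("asymptomatic_bacteriuria"), drug("antibiotics")),
             [caution(child())],
             "Can induce antibiotic resistance.",
             exception=dx("uropathy")),
        _pim("su_prophylaxis_uncomplicated", g, s,
             "Antibiotic prophylaxis after initial uncomplicated infection",
             all_of(dx("uti_prophylaxis_after_uncomplicated_infection"),
                    drug("antibiotics")),
             [caution(child())],
             "Can induce antibiotic resistance.",
             exception=dx("uropathy")),
    ]

    g = "Dermatological problems"
    s = "Atopic eczema"
    c += [
        _pim("sd_topical_cs_over_14d", g, s,
             "Topical corticosteroids (medium/high titers) >14 days",
             all_of(dx("atopic_eczema"),
                    duration_gt("topical_corticosteroids", 14, "days")),
             [caution(child())],
             "Children absorb topical corticosteroids faster than adults; "
             ">14 days increases HPA-axis inhibition risk."),
        _pim("sd_high_titer_cs_face", g, s,
             "High-titer corticosteroids on face/armpits/groin of infants",
             all_of(dx("atopic_eczema"),
                    drug("high_potency_topical_corticosteroids"),
                    age_lt(1), dx("applied_to_face_axillae_groin")),
             [caution(age_lt(1))],
             "Thin infant skin at these sites absorbs more; high-titer "
             "preparations are more likely to inhibit the HPA axis."),
        _pim("sd_oral_cs_eczema", g, s,
             "Oral corticosteroids for atopic eczema",
             all_of(dx("atopic_eczema"),
                    drug("systemic_corticosteroids", "oral")),
             [caution(child())],
             "Unknown effect and many adverse reactions."),
        _pim("sd_topical_cs_twice_daily", g, s,
             "Topical corticosteroids >= twice a day",
             all_of(dx("atopic_eczema"),
                    freq_above("topical_corticosteroids", 1)),
             [caution(child())],
             "No added effect at >= twice a day; adverse reaction risk "
             "increases.",
             exception=dx("severe_lichenification")),
        _pim("sd_tacrolimus_003", g, s,
             "0.03% tacrolimus ointment in <=2 years",
             all_of(drug("tacrolimus_0_03_ointment"), _age_le_years(2)),
             [avoid(_age_le_years(2))],
             "Risk of skin burns; not approved in <=2 years and not as mild "
             "as corticosteroids."),
        _pim("sd_tacrolimus_01", g, s,
             "0.1% tacrolimus ointment in <=16 years",
             all_of(drug("tacrolimus_0_1_ointment"), _age_le_years(16)),
             [avoid(_age_le_years(16))],
             "Risk of skin burns; not approved in <=16 years and not as "
             "mild as corticosteroids."),
    ]
    s = "Acne vulgaris"
    c += [
        _pim("sd_minocycline_acne", g, s,
             "Minocycline for <8 years with acne",
             all_of(dx("acne"), drug("minocycline"), age_lt(8)),
             [avoid(age_lt(8))],
             "Risk of tooth discoloration, DHS, Stevens-Johnson syndrome, "
             "lupus-like syndrome. Avoid in <8 years with acne."),
        _pim("sd_hormonal_acne", g, s,
             "Hormonal contraceptives to treat acne",
             all_of(dx("acne"), drug("acne_hormonal_contraceptives")),
             [caution(child())],
             "Adverse effects on growth, bone density, and thrombotic "
             "events."),
        _ppo("sd_antibiotic_acne_combination", g, s,
             "Antibiotics for acne combined with benzoyl peroxide/tretinoin",
             all_of(dx("acne"), drug("antibiotics")),
             any_of(drug("benzoyl_peroxide"), drug("tretinoin_topical")),
             "Benzoyl peroxide alongside topical or systemic antibiotics "
             "reduces resistance in propionibacterium acnes and improves "
             "effect."),
    ]
    s = "Scabies"
    c += [
        _pim("sd_benzyl_benzoate", g, s,
             "Benzyl benzoate for scabies",
             all_of(dx("scabies"), drug("benzyl_benzoate")),
             [caution(child())],
             "More irritating than permethrin or malathion, with no better "
             "effect."),
        _ppo("sd_ivermectin_second_dose", g, s,
             "Second ivermectin dose one week after the first",
             all_of(dx("scabies"), drug("ivermectin")),
             proc("repeat_dose", "ivermectin"),
             "A second dose a week later kills scabies eggs and increases "
             "the effect."),
    ]
    s = "Impetigo"
    c += [
        _pim("sd_non_fusidic_impetigo", g, s,
             "Antibiotic other than fusidic acid as first-line for impetigo",
             all_of(dx("impetigo"), drug("antibiotics"),
                    not_(drug("fusidic_acid"))),
             [caution(child())],
             "Other topical antibiotics have no better effect and are less "
             "safe than fusidic acid.",
             exception=dx("fusidic_acid_allergy")),
        _pim("sd_topical_oral_antibiotics", g, s,
             "Combined topical and oral antibiotics",
             all_of(dx("impetigo"), drug("antibiotics", "topical"),
                    drug("antibiotics", "oral")),
             [caution(child())],
             "No evidence that the combination is better."),
    ]
    c += [
        _pim("sd_topical_cs_herpes", g, "Herpes simplex",
             "Topical corticosteroids for herpes simplex",
             all_of(dx("herpes_simplex"), drug("topical_corticosteroids")),
             [avoid(child())],
             "May worsen the condition and prolong hospitalization."),
        _ppo("sd_ringworm_systemic", g, "Ringworm",
             "Combination of topical and oral antifungal treatment",
             all_of(dx("ringworm"), drug("antifungals", "topical")),
             drug("antifungals", "oral"),
             "Ringworm requires systemic treatment; topical antifungals do "
             "not penetrate hair follicles."),
    ]

    g = "Digestive problems"
    s = "Nausea, vomiting, or gastroesophageal reflux"
    c += [
        _pim("sg_acid_suppressants", g, s,
             "Acid inhibitors without feeding difficulties/pain/growth retardation",
             all_of(drug("acid_suppressants"),
                    any_of(dx("gastroesophageal_reflux"), dx("indigestion"),
                           dx("unexplained_crying"), dx("syncope"))),
             [caution(child())],
             "No definite curative effect and risk of adverse reactions.",
             exception=any_of(dx("feeding_difficulties"), dx("pain"),
                              dx("growth_retardation"))),
        _pim("sg_metoclopramide_gerd", g, s,
             "Metoclopramide for nausea/vomiting/gastroesophageal reflux",
             all_of(drug("metoclopramide"),
                    any_of(dx("nausea_or_vomiting"),
                           dx("gastroesophageal_reflux"))),
             [avoid(child())],
             "Extrapyramidal reaction risks (dystonia, tardive dyskinesia) "
             "outweigh the benefits."),
        _pim("sg_erythromycin_gerd", g, s,
             "Erythromycin for nausea/vomiting/gastroesophageal reflux",
             all_of(drug("erythromycin"),
                    any_of(dx("nausea_or_vomiting"),
                           dx("gastroesophageal_reflux"))),
             [caution(child())],
             "No effectiveness evidence in reflux; potential hepatic, "
             "allergic, arrhythmic reactions and pyloric stenosis."),
        _pim("sg_domperidone_gerd", g, s,
             "Domperidone for nausea/vomiting/gastroesophageal reflux",
             all_of(drug("domperidone"),
                    any_of(dx("nausea_or_vomiting"),
                           dx("gastroesophageal_reflux"))),
             [caution(child())],
             "No effect in GORD; potential serious cardiac and CNS adverse "
             "reactions, higher in <1 year."),
        _ppo("sg_ors_dehydration_vomiting", g, s,
             "ORS for dehydrated children (vomiting context)",
             all_of(dx("nausea_or_vomiting"), dx("dehydration")),
             drug("oral_rehydration_solution"),
             "Children benefit significantly and risk is low, unless "
             "intravenous fluid therapy is indicated.",
             exception=any_of(dx("shock"), dx("red_flag_symptoms"),
                              dx("persistent_vomiting_of_ors"))),
    ]
    s = "Diarrhea"
    c += [
        _pim("sg_loperamide", g, s,
             "Loperamide for <4 years or acute infectious diarrhea",
             all_of(drug("loperamide"),
                    any_of(age_lt(4), dx("acute_infectious_diarrhea"))),
             [avoid(child())],
             "More risk than other diarrhea treatments; no recommended dose "
             "for <4 years."),
        _pim("sg_antibiotics_diarrhea", g, s,
             "Antibiotics for diarrhea",
             all_of(dx("diarrhea"), drug("antibiotics")),
             [avoid(child())],
             "Diarrhea is mostly viral/cryptosporidial; antibiotic misuse "
             "harms patients and induces resistance.",
             exception=any_of(
                 dx("suspected_septicemia"),
                 dx("extraintestinal_bacterial_infection"),
                 all_of(dx("salmonella_gastroenteritis"),
                        any_of(age_lt(0.5), dx("malnourished"),
                               dx("immunocompromised"))),
                 dx("clostridium_difficile_colitis"), dx("giardiasis"),
                 dx("shigella_dysentery"), dx("amoebic_dysentery"),
                 dx("cholera"))),
        _ppo("sg_ors_dehydration_diarrhea", g, s,
             "ORS for dehydrated children (diarrhea context)",
             all_of(dx("diarrhea"), dx("dehydration")),
             drug("oral_rehydration_solution"),
             "Children benefit significantly and risk is low, unless "
             "intravenous fluid therapy is indicated.",
             exception=any_of(dx("shock"), dx("red_flag_symptoms"),
                              dx("persistent_vomiting_of_ors"))),
        _ppo("sg_probiotics_diarrhea", g, s,
             "Microecological preparations for acute/antibiotic-related diarrhea",
             any_of(dx("acute_diarrhea"), dx("antibiotic_associated_diarrhea")),
             drug("probiotics"),
             "Maintains the intestinal microbial balance; children benefit "
             "significantly and risk is low.",
             exception=dx("immunocompromised")),
    ]

    g = "Neuropsychiatric Disorders"
    s = "Nocturnal enuresis"
    c += [
        _pim("sn_tca_enuresis", g, s,
             "Tricyclic antidepressants as first-line for enuresis",
             all_of(dx("nocturnal_enuresis"),
                    drug("tricyclic_antidepressants")),
             [avoid(child())],
             "Risk of sudden cardiac death outweighs the benefits in "
             "enuresis."),
        _pim("sn_tca_anticholinergic", g, s,
             "Combined tricyclic antidepressants and anticholinergics",
             all_of(dx("nocturnal_enuresis"),
                    pair("tricyclic_antidepressants", "anticholinergics",
                         simultaneous())),
             [caution(child())],
             "Combination only increases the risk of adverse reactions, not "
             "the effect."),
        _pim("sn_desmopressin_daytime", g, s,
             "Desmopressin for children with only daytime symptoms",
             all_of(drug("desmopressin"), dx("daytime_symptoms_only")),
             [caution(child())],
             ""),
        _pim("sn_anticholinergic_monotherapy", g, s,
             "Anticholinergic monotherapy without daytime symptoms",
             all_of(dx("nocturnal_enuresis"), drug("anticholinergics"),
                    not_(dx("daytime_symptoms")), not_(drug("desmopressin"))),
             [caution(child())],
             "Anticholinergics are an addition for children poorly "
             "controlled by desmopressin alone."),
    ]
    s = "Attention deficit disorder with or without hyperactivity"
    c += [
        _pim("sn_adhd_meds_young", g, s,
             "Medications as first-line in <=6 years or any use in <=3 years",
             all_of(dx("adhd"), drug("adhd_medications"), _age_le_years(6)),
             [caution(_age_le_years(6))],
             "Behavioral interventions by parents or teachers are "
             "non-inferior to drug therapy without adverse drug reactions.",
             exception=all_of(dx("severe_adhd"), not_(_age_le_years(3)))),
        _pim("sn_methylphenidate_sr_twice", g, s,
             "Two daily doses of sustained-release methylphenidate",
             freq_above("methylphenidate_sr", 1),
             [caution(child())],
             "Special pharmacokinetics require only once-daily dosing; "
             "twice a day increases cost and risk."),
        _pim("sn_antipsychotics_adhd", g, s,
             "Antipsychotics for attention deficit hyperactivity disorder",
             all_of(dx("adhd"), drug("antipsychotics")),
             [caution(child())],
             "No significant benefit and risk of suicide."),
    ]
    c += [
        _pim("sn_multiple_antipsychotics", g, "Psychosis and schizophrenia",
             ">=2 antipsychotics routinely prescribed for initial treatment",
             all_of(dx("psychosis_or_schizophrenia"),
                    n_of_class("antipsychotics", 2)),
             [caution(child())],
             ""),
    ]
    s = "Epilepsy"
    c += [
        _pim("sn_absence_seizure_aeds", g, s,
             "Contraindicated antiepileptics for absence seizures",
             all_of(dx("absence_seizures"),
                    drug("absence_contraindicated_antiepileptics")),
             [avoid(child())],
             "Carbamazepine, gabapentin, oxcarbazepine, phenytoin, "
             "pregabalin, tiagabine exacerbate absence seizures, even "
             "inducing generalized seizures."),
        _pim("sn_myoclonic_aeds", g, s,
             "Contraindicated antiepileptics for myoclonic epilepsy",
             all_of(dx("myoclonic_epilepsy"),
                    drug("absence_contraindicated_antiepileptics")),
             [avoid(child())],
             "The same antiepileptics exacerbate myoclonic epilepsy, even "
             "inducing generalized seizures."),
        _ppo("sn_epilepsy_tdm", g, s,
             "TDM for problematic antiepileptic treatment",
             all_of(dx("epilepsy"), drug("antiepileptics"),
                    any_of(dx("uncontrolled_seizures"),
                           dx("aed_adverse_reactions"),
                           n_of_class("antiepileptics", 2),
                           dx("unidentified_self_medication"))),
             proc("tdm", "antiepileptics"),
             "TDM clarifies absorption and distribution and lets doses be "
             "individualized to improve effect and reduce adverse "
             "reactions."),
    ]
    s = "Depression"
    c += [
        _pim("sn_non_fluoxetine_ssri", g, s,
             "SSRIs other than fluoxetine as first-line for depression",
             all_of(dx("depression"), drug("ssris"),
                    not_(drug("fluoxetine"))),
             [caution(child())],
             "Fluoxetine is the only antidepressant with trial evidence "
             "that benefits outweigh risks in children with depression."),
        _pim("sn_tca_depression", g, s,
             "Tricyclic antidepressants for depression",
             all_of(dx("depression"), drug("tricyclic_antidepressants")),
             [avoid(child())],
             "Risk of sudden cardiac death outweighs the benefits."),
    ]
    c += [
        _pim("sn_anorexia_medication", g, "Anorexia nervosa",
             "Medication as the sole or primary treatment",
             all_of(dx("anorexia_nervosa"), drug("psychotropic_medications"),
                    not_(proc("psychotherapy"))),
             [caution(child())],
             "Cognitive behavioral therapy has a significant effect and no "
             "adverse drug reaction risk."),
        _pim("sn_antipsychotics_behavior", g,
             "Destructive or aggressive behaviors",
             "Antipsychotics for behaviors without autism/bipolar disorder",
             all_of(drug("antipsychotics"),
                    any_of(all_of(dx("destructive_aggressive_behavior"),
                                  not_(dx("autism"))),
                           all_of(dx("emotional_problems"),
                                  not_(dx("bipolar_disorder"))))),
             [caution(child())],
             "Psychosocial interventions are effective and non-inferior, "
             "without drowsiness, sedation, weight gain."),
    ]

    g = "Other Conditions"
    s = "Fever"
    c += [
        _pim("so_two_antipyretics", g, s,
             "Alternate or combined use of two antipyretics as first-line",
             all_of(dx("fever"), drug("acetaminophen"), drug("ibuprofen")),
             [caution(child())],
             "Not more effective than monotherapy; long-term safety "
             "unknown."),
        _pim("so_antipyretics_low_fever", g, s,
             "Antipyretics in <2 months, <38.2 C, or without discomfort",
             all_of(drug("antipyretics"), dx("fever"),
                    any_of(AgeInRange(min_days=0, max_days=60),
                           dx("temp_below_38_2"),
                           dx("no_obvious_discomfort"))),
             [caution(child())],
             "Physical cooling is recommended for children <2 months, "
             "<38.2 C axillary, or without obvious discomfort."),
        _pim("so_antipyretic_overdose", g, s,
             "More than four daily doses, ibuprofen >40 mg/kg/d or acetaminophen >4 g/d",
             any_of(freq_above("ibuprofen", 4),
                    freq_above("acetaminophen", 4),
                    dose_gt("ibuprofen", "per_kg_per_day", 40),
                    dose_gt("acetaminophen", "per_day", 4, "g")),
             [caution(child())],
             ""),
        _pim("so_corticosteroid_antipyretic", g, s,
             "Corticosteroids as antipyretics",
             all_of(dx("fever"), drug("systemic_corticosteroids")),
             [caution(child())],
             ""),
        _pim("so_rectal_acetaminophen", g, s,
             "Rectal rather than oral acetaminophen as first-line",
             all_of(dx("fever"), drug("acetaminophen", "rectal"),
                    not_(drug("acetaminophen", "oral"))),
             [caution(child())],
             ""),
    ]
    s = "Pain"
    c += [
        _pim("so_non_first_line_analgesics", g, s,
             "Drugs other than acetaminophen and ibuprofen as first-line pain relievers",
             all_of(dx("pain"), drug("analgesics"),
                    not_(any_of(drug("acetaminophen"), drug("ibuprofen")))),
             [caution(child())],
             "Acetaminophen and ibuprofen are effective and safer for "
             "children than other painkillers.",
             exception=dx("migraine")),
        _pim("so_opioids_migraine", g, s,
             "Opioids for migraine attacks",
             all_of(dx("migraine"), drug("opioids")),
             [avoid(child())],
             "Risk of serious adverse reactions such as respiratory "
             "depression outweighs the benefits."),
    ]
    return c
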