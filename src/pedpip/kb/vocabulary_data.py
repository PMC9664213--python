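"""Packaged condition vocabulary: diagnosis contexts, clinical flags, and
procedure tags referenced by the criteria.

Tags that the source rules leave unquantified (CENTOR score >= 3, a
"significant" CRP/neutrophil rise) are deliberately modeled as user-supplied
tags: the screening engine consumes them but never computes them.
"""

from __future__ import annotations

from .model import ConditionTag, ConditionVocabulary

_TAGS: list[tuple[str, str]] = [
    # clinical flags
    ("opioid_physical_dependence", "Known or suspected opioid physical dependence"),
    ("metabolic_or_mitochondrial_disease", "Metabolic or mitochondrial disease"),
    ("immunocompromised", "Immunocompromised"),
    ("malnourished", "Malnourished"),
    ("skin_test_waived_by_insert", "Package insert states skin test unnecessary"),
    ("penicillin_allergy", "Allergy to amoxicillin/penicillin V"),
    ("fusidic_acid_allergy", "Allergy to fusidic acid"),
    ("allergy_prone", "Allergy-prone constitution"),
    # infections and indications
    ("drug_resistant_tuberculosis", "Drug-resistant tuberculosis"),
    ("tuberculosis", "Tuberculosis"),
    ("bordetella_pertussis", "Bordetella pertussis infection"),
    ("chlamydia_trachomatis_pneumonia", "Chlamydia trachomatis pneumonia"),
    ("congenital_toxoplasmosis", "Congenital toxoplasmosis"),
    ("cystic_fibrosis", "Cystic fibrosis"),
    ("organ_transplantation", "Organ transplantation recipient"),
    ("nephrotic_syndrome", "Nephrotic syndrome"),
    # respiratory
    ("acute_uri", "Acute upper respiratory tract infection"),
    ("uri_symptoms_lt_4_days", "URI symptoms present for fewer than 4 days"),
    ("respiratory_infection", "Respiratory infection"),
    ("chronic_respiratory_disease", "Chronic respiratory disease"),
    ("bilateral_acute_otitis_media", "Bilateral acute otitis media"),
    ("acute_otitis_media", "Acute otitis media"),
    ("acute_suppurative_otitis_media", "Acute suppurative otitis media"),
    ("otorrhoea", "Otorrhoea"),
    ("acute_sore_throat", "Acute sore throat"),
    ("streptococcal_pharyngitis", "Streptococcal pharyngitis"),
    ("acute_tonsillitis", "Acute tonsillitis"),
    ("acute_sinusitis", "Acute sinusitis"),
    ("nasopharyngitis", "Nasopharyngitis"),
    ("centor_ge_3", "Three or more CENTOR criteria present (user-assessed)"),
    ("elevated_crp_or_neutrophils",
     "Significantly increased CRP or neutrophil proportion (user-assessed)"),
    ("bacterial_respiratory_secretions",
     "Respiratory secretion examination suggesting bacterial infection"),
    ("suspected_viral_infection", "Suspected viral infection (flu, chickenpox)"),
    ("anaphylaxis", "Anaphylaxis"),
    ("asthma", "Asthma"),
    ("bronchiolitis", "Infantile bronchiolitis"),
    ("acute_cough", "Acute cough"),
    ("acute_bronchitis", "Acute bronchitis"),
    ("bacterial_infection_signs", "Significant signs of bacterial infection"),
    ("general_discomfort", "General discomfort / systemically unwell"),
    ("high_risk_condition", "High-risk condition (severe comorbidity)"),
    ("post_tonsillectomy_adenoidectomy", "After tonsillectomy and adenoidectomy"),
    # urinary
    ("asymptomatic_bacteriuria", "Asymptomatic bacterial urinary tract infection"),
    ("uropathy", "Uropathy"),
    ("uti_prophylaxis_after_uncomplicated_infection",
     "Antibiotic prophylaxis after an initial uncomplicated urinary infection"),
    # dermatological
    ("atopic_eczema", "Atopic eczema"),
    ("severe_lichenification", "Severe lichenification"),
    ("applied_to_face_axillae_groin", "Preparation applied to face, axillae, groin or back"),
    ("acne", "Acne vulgaris"),
    ("scabies", "Scabies"),
    ("impetigo", "Impetigo"),
    ("herpes_simplex", "Herpes simplex"),
    ("ringworm", "Ringworm (tinea)"),
    # digestive
    ("gastroesophageal_reflux", "Gastroesophageal reflux"),
    ("indigestion", "Indigestion"),
    ("unexplained_crying", "Crying without other signs or symptoms"),
    ("syncope", "Syncope"),
    ("feeding_difficulties", "Feeding difficulties"),
    ("growth_retardation", "Growth retardation"),
    ("nausea_or_vomiting", "Nausea or vomiting"),
    ("dehydration", "Dehydration"),
    ("shock", "Shock"),
    ("red_flag_symptoms", "Red flag symptoms despite ORS"),
    ("persistent_vomiting_of_ors", "Persistent vomiting of ORS"),
    ("diarrhea", "Diarrhea"),
    ("acute_diarrhea", "Acute diarrhea"),
    ("acute_infectious_diarrhea", "Acute infectious diarrhea"),
    ("antibiotic_associated_diarrhea", "Antibiotic-associated diarrhea"),
    ("suspected_septicemia", "Suspected or confirmed septicemia"),
    ("extraintestinal_bacterial_infection", "Extra-intestinal spread of bacterial infection"),
    ("salmonella_gastroenteritis", "Salmonella gastroenteritis"),
    ("clostridium_difficile_colitis", "Clostridium difficile pseudomembranous enterocolitis"),
    ("giardiasis", "Giardiasis"),
    ("shigella_dysentery", "Shigella dysentery"),
    ("amoebic_dysentery", "Amoebic dysentery"),
    ("cholera", "Cholera"),
    # neuropsychiatric
    ("nocturnal_enuresis", "Nocturnal enuresis"),
    ("daytime_symptoms", "Daytime urinary symptoms"),
    ("daytime_symptoms_only", "Daytime urinary symptoms only"),
    ("adhd", "Attention deficit disorder with or without hyperactivity"),
    ("severe_adhd", "Severe ADHD"),
    ("psychosis_or_schizophrenia", "Psychosis or schizophrenia, initial treatment"),
    ("epilepsy", "Epilepsy"),
    ("absence_seizures", "Epileptic absence seizures"),
    ("myoclonic_epilepsy", "Myoclonic epilepsy"),
    ("uncontrolled_seizures", "Uncontrolled seizures during treatment"),
    ("aed_adverse_reactions", "Obvious adverse reactions during antiepileptic treatment"),
    ("unidentified_self_medication", "Self-administered unidentified medicines"),
    ("depression", "Depression"),
    ("anorexia_nervosa", "Anorexia nervosa"),
    ("autism", "Autism"),
    ("bipolar_disorder", "Bipolar disorder"),
    ("destructive_aggressive_behavior", "Destructive or aggressive behaviors"),
    ("emotional_problems", "Emotional problems"),
    # other conditions
    ("fever", "Fever"),
    ("temp_below_38_2", "Axillary temperature below 38.2 degrees C"),
    ("no_obvious_discomfort", "No obvious discomfort"),
    ("pain", "Pain"),
    ("migraine", "Migraine"),
    # procedures
    ("skin_test", "Skin test"),
    ("tdm", "Therapeutic drug monitoring (TDM)"),
    ("cyp2d6_test", "CYP2D6 gene polymorphism test"),
    ("pharmacogenetic_test", "Pharmacogenetic test"),
    ("iv_bolus", "Intravenous bolus administration"),
    ("repeat_dose", "Scheduled repeat dose"),
    ("psychotherapy", "Psychotherapy / behavioral intervention"),
]


def build_vocabulary() -> ConditionVocabulary:
    return ConditionVocabulary(
        tags=[ConditionTag(tag_id=i, label=l) for i, l in _TAGS]
    )
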