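"""Criteria for children with non-specific diseases/conditions (71 rules).

Each function-call below encodes exactly one printed row: trigger predicate,
optional exception, severity clauses (PIM) or required action (PPO), and the
risk/recommendation text condensed to its operative sentences.
"""

from __future__ import annotations

from typing import Optional

from .dsl import (
    age_days_le, age_lt, all_of, any_of, avoid, caution, child, dose_gt,
    drug, duration_gt, dx, freq_below, ga_below, infant_lt2y, neonate, not_,
    pair, proc, required_gap, sex, simultaneous, vlbw, weight_below,
    within_after,
)
from .model import Criterion, Predicate, Provenance, SeverityClause

_TABLE = "Table 1"


def _pim(cid: str, group: str, row: str, trigger: Predicate,
         clauses: list[SeverityClause], risk: str,
         exception: Optional[Predicate] = None,
         note: Optional[str] = None) -> Criterion:
    return Criterion(
        criterion_id=cid, part="non_specific", category="PIM", group=group,
        trigger=trigger, exception=exception, severity_clauses=clauses,
        risk_text=risk,
        provenance=Provenance(table=_TABLE, row_label=row, note=note),
    )


def _ppo(cid: str, group: str, row: str, trigger: Predicate,
         required: Predicate, risk: str,
         exception: Optional[Predicate] = None) -> Criterion:
    return Criterion(
        criterion_id=cid, part="non_specific", category="PPO", group=group,
        trigger=trigger, exception=exception, required_action=required,
        risk_text=risk,
        provenance=Provenance(table=_TABLE, row_label=row),
    )


def build_table1() -> list[Criterion]:
    c: list[Criterion] = []
    g = "Nervous system"
    c += [
        _pim("ns_propofol_infusion", g, "Propofol",
             all_of(drug("propofol"),
                    dose_gt("propofol", "per_kg_per_hour", 4),
                    duration_gt("propofol", 48, "hours")),
             [avoid(child())],
             "Risk of propofol-related infusion syndrome. Avoid doses "
             ">4 mg/kg/h over 48 h in children."),
        _pim("ns_dopamine_antagonists", g, "Dopamine antagonists",
             drug("dopamine_antagonists"),
             [avoid(infant_lt2y()), caution(child())],
             "Risk of acute dystonia; intravenous use increases risk of "
             "respiratory depression and death. Avoid in <2 years; caution "
             "in children."),
        _pim("ns_opioids", g, "Opioids",
             drug("opioids"),
             [avoid(infant_lt2y()), caution(child())],
             "Risk of respiratory depression. Avoid in <2 years (neonates, "
             "especially premature neonates, at highest risk); caution in "
             "children."),
        _pim("ns_naloxone", g, "Naloxone",
             all_of(drug("naloxone"),
                    any_of(neonate(), dx("opioid_physical_dependence"))),
             [avoid(neonate()), caution(dx("opioid_physical_dependence"))],
             "Risk of seizures. Avoid in neonates; caution with known or "
             "suspected opioid physical dependence."),
        _pim("ns_benzocaine", g, "Benzocaine",
             all_of(drug("benzocaine"), infant_lt2y()),
             [avoid(infant_lt2y())],
             "Risk of methemoglobinemia. Avoid in <2 years for teething or "
             "pharyngitis."),
        _pim("ns_lidocaine", g, "Lidocaine",
             all_of(drug("lidocaine"), age_lt(6)),
             [avoid(infant_lt2y()), caution(age_lt(6))],
             "Risk of seizures, arrhythmia, and death. Avoid in <2 years for "
             "teething pain; caution in local anesthesia in <6 years."),
        _pim("ns_atypical_antipsychotics", g,
             "Atypical/second-generation antipsychotics",
             drug("atypical_antipsychotics"),
             [avoid(duration_gt("atypical_antipsychotics", 24, "weeks")),
              caution(child())],
             "Risk of agranulocytosis and abnormal glucose/lipid metabolism. "
             "Caution in children; avoid long-term use (>24 weeks)."),
        _pim("ns_diazepam", g, "Diazepam",
             all_of(drug("diazepam"), infant_lt2y()),
             [avoid(neonate()), caution(infant_lt2y())],
             "Risk of sedation. Avoid in neonates; caution in <2 years."),
        _pim("ns_midazolam_vlbw", g, "Midazolam",
             all_of(drug("midazolam"), neonate(), vlbw()),
             [avoid(all_of(neonate(), vlbw()))],
             "Risk of severe intraventricular hemorrhage, periventricular "
             "leukomalacia, and death. Avoid in neonates with very low birth "
             "weight (<1500 g)."),
        _pim("ns_phenytoin", g, "Phenytoin",
             all_of(drug("phenytoin"),
                    any_of(age_lt(1), not_(proc("tdm", "phenytoin")))),
             [avoid(age_lt(1)), caution(not_(proc("tdm", "phenytoin")))],
             "Neurotoxicity; poisoning is difficult to identify. Avoid in "
             "<1 year; caution in children not undergoing TDM."),
        _pim("ns_tricyclics", g, "Tricyclic antidepressants",
             any_of(drug("desipramine"), drug("imipramine")),
             [avoid(drug("desipramine")), caution(drug("imipramine"))],
             "Risk of sudden cardiac death. Avoid desipramine; caution with "
             "imipramine in children."),
        _pim("ns_ssri_snri", g, "SSRIs and SNRIs",
             drug("ssris_and_snris"),
             [avoid(any_of(drug("paroxetine"), drug("venlafaxine"))),
              caution(child())],
             "Increased suicide risk. Avoid paroxetine and venlafaxine; "
             "caution with other SSRIs/SNRIs; close monitoring recommended."),
        _pim("ns_valproate", g, "Valproic acid and its derivatives",
             all_of(drug("valproic_acid"),
                    any_of(infant_lt2y(),
                           dx("metabolic_or_mitochondrial_disease"),
                           drug("non_valproate_antiepileptics"))),
             [avoid(infant_lt2y()),
              avoid(dx("metabolic_or_mitochondrial_disease")),
              avoid(drug("non_valproate_antiepileptics"))],
             "Risk of pancreatitis and fatal hepatotoxicity. Avoid in "
             "<2 years, especially with metabolic or mitochondrial diseases "
             "or other antiepileptic drugs such as phenytoin."),
        _pim("ns_lamotrigine", g, "Lamotrigine",
             all_of(drug("lamotrigine"), infant_lt2y()),
             [caution(child())],
             "Risk of serious skin rash. Caution in children; TDM is "
             "recommended during medication."),
        _pim("ns_antiepileptics", g, "Antiepileptic drugs (AEDs)",
             drug("antiepileptics"),
             [caution(child())],
             "Risk of osteoporosis with long-term use; risk of severe rash "
             "(carbamazepine). Caution in children."),
    ]

    g = "Antiinfectives For Systemic Use"
    c += [
        _pim("ai_indinavir", g, "Indinavir",
             all_of(drug("indinavir"), child()),
             [avoid(child())],
             "Risk of nephrolithiasis. Avoid in children. Risk of "
             "hyperbilirubinemia; avoid in neonates.",
             note="The 'Risk of hyperbilirubinemia. Avoid in neonates' line "
                  "sits between the indinavir and atazanavir rows in the "
                  "typeset table; assigned here with the ambiguity recorded."),
        _pim("ai_atazanavir", g, "Atazanavir",
             all_of(drug("atazanavir"), neonate()),
             [caution(neonate())],
             "Risk of kernicterus. Caution in neonates, unless "
             "pharmacogenetic testing is implemented.",
             exception=proc("pharmacogenetic_test", "atazanavir")),
        _pim("ai_darunavir", g, "Darunavir",
             all_of(drug("darunavir"), any_of(age_lt(3), weight_below(10))),
             [avoid(any_of(age_lt(3), weight_below(10)))],
             "Risk of seizures and death. Avoid in <3 years or <10 kg."),
        _pim("ai_chloramphenicol", g, "Chloramphenicol",
             all_of(drug("chloramphenicol"), neonate()),
             [avoid(neonate())],
             "Risk of gray baby syndrome, irreversible bone marrow "
             "suppression, aplastic anemia. Avoid in neonates unless the "
             "blood concentration is monitored.",
             exception=proc("tdm", "chloramphenicol")),
        _pim("ai_cefathiamidine_once_daily", g, "Cefathiamidine",
             all_of(drug("cefathiamidine"), freq_below("cefathiamidine", 2)),
             [avoid(child())],
             "Once-daily injection instead of the specified 2-4 times fails "
             "to maintain effective concentrations and raises the risk of "
             "severe allergic reactions. Avoid once a day."),
        _pim("ai_ceftriaxone_neonate", g, "Ceftriaxone - neonates",
             all_of(drug("ceftriaxone"), neonate()),
             [caution(neonate())],
             "Risk of hyperbilirubinemia; neonates (especially premature) "
             "may develop kernicterus. Caution in neonates."),
        _pim("ai_macrolide_pyloric_stenosis", g,
             "Azithromycin and erythromycin (oral or intravenous)",
             all_of(any_of(drug("azithromycin", "oral"),
                           drug("azithromycin", "intravenous"),
                           drug("erythromycin", "oral"),
                           drug("erythromycin", "intravenous")),
                    age_days_le(14)),
             [avoid(age_days_le(14))],
             "Risk of hypertrophic pyloric stenosis. Avoid in neonates "
             "<=14 days, unless treating Bordetella pertussis (azithromycin) "
             "or Chlamydia trachomatis pneumonia.",
             exception=any_of(all_of(dx("bordetella_pertussis"),
                                     drug("azithromycin")),
                              dx("chlamydia_trachomatis_pneumonia"))),
        _pim("ai_lincomycin", g, "Lincomycin",
             all_of(drug("lincomycin"), child()),
             [caution(child())],
             "Risk of neuromuscular blockade, shock-like reaction, "
             "epidermolysis bullosa, and hearing loss. Caution in children."),
        _pim("ai_aminoglycosides_under6", g, "Aminoglycoside antibiotics",
             all_of(drug("aminoglycosides"), age_lt(6)),
             [avoid(age_lt(6))],
             "Risk of ototoxicity and nephrotoxicity. Avoid in <6 years, "
             "except for drug-resistant tuberculosis or children undergoing "
             "TDM.",
             exception=any_of(dx("drug_resistant_tuberculosis"),
                              proc("tdm", "aminoglycosides"))),
        _pim("ai_voriconazole", g, "Voriconazole",
             all_of(drug("voriconazole"), child()),
             [caution(child())],
             "Risk of hepatotoxicity, pancreatitis, and skeletal fluorosis. "
             "Caution in children."),
        _pim("ai_cefradine", g, "Cefradine",
             all_of(drug("cefradine"), child()),
             [caution(child())],
             "Risk of nephrotoxicity. Caution in children."),
        _pim("ai_nitrofurans", g, "Nitrofuran antibiotics",
             all_of(drug("nitrofuran_antibiotics"), child()),
             [avoid(neonate()), caution(child())],
             "Risk of nephrotoxicity, peripheral neurotoxicity, interstitial "
             "pneumonia. Avoid in neonates; caution in children."),
        _pim("ai_tetracycline", g, "Tetracycline",
             all_of(drug("tetracycline"), age_lt(8)),
             [caution(age_lt(8))],
             "Risk of tooth discoloration, enamel hypoplasia, and "
             "retardation of skeletal development. Caution in <8 years."),
        _pim("ai_sulfonamides_neonate", g, "Sulfonamides",
             all_of(drug("sulfonamides"), neonate()),
             [avoid(neonate())],
             "Risk of kernicterus and hemolytic anemia. Avoid in neonates, "
             "especially premature, except sulfadiazine as adjuvant "
             "treatment for congenital toxoplasmosis.",
             exception=all_of(dx("congenital_toxoplasmosis"),
                              drug("sulfadiazine"))),
        _pim("ai_quinolones", g, "Quinolones",
             all_of(drug("fluoroquinolones"), child()),
             [caution(child())],
             "Bone and cartilage toxicity. Caution in children."),
        _pim("ai_ceftriaxone_calcium", g,
             "Ceftriaxone - calcium-containing preparations",
             pair("ceftriaxone", "calcium_iv_preparations",
                  within_after(48), route_b="intravenous"),
             [avoid(child())],
             "Risk of ceftriaxone-calcium salt deposits. Do not inject "
             "calcium-containing medicines within 48 h of using ceftriaxone."),
        _pim("ai_fluoroquinolone_dtcc", g, "Fluoroquinolones - DTCC",
             any_of(pair("levofloxacin", "dtcc", required_gap(2, 2)),
                    pair("ciprofloxacin", "dtcc", required_gap(2, 6)),
                    pair("fluoroquinolones", "dtcc", simultaneous())),
             [avoid(child())],
             "DTCC chelate intestinal fluoroquinolones and reduce their "
             "bioavailability. Take levofloxacin at least 2 h before or "
             "after DTCC and ciprofloxacin at least 2 h before or 6 h after "
             "DTCC; avoid simultaneous use."),
        _pim("ai_aminoglycoside_cephalosporin", g,
             "Aminoglycosides and first-generation cephalosporins",
             pair("aminoglycosides", "first_generation_cephalosporins",
                  simultaneous()),
             [avoid(child())],
             "Combined use increases risk of nephrotoxicity and hematuria. "
             "Avoid simultaneous use in children."),
        _pim("ai_vancomycin_bolus", g, "Vancomycin",
             all_of(drug("vancomycin", "intravenous"),
                    proc("iv_bolus", "vancomycin")),
             [avoid(child())],
             "Risk of severe hypotension, upper body flushing, cardiac "
             "arrest. Avoid intravenous bolus; slow infusion (>1 h) with "
             "appropriate dilution is recommended."),
        _ppo("ai_penicillin_skin_test", g, "Penicillin antibiotics",
             all_of(drug("penicillins"), child()),
             proc("skin_test"),
             "Risk of severe allergic reactions such as anaphylactic shock. "
             "A skin test must be performed before use.",
             exception=dx("skin_test_waived_by_insert")),
        _ppo("ai_vancomycin_tdm", g, "Vancomycin - TDM",
             all_of(drug("vancomycin"), child()),
             proc("tdm", "vancomycin"),
             "TDM in children using vancomycin improves efficacy and avoids "
             "adverse reactions (peak >80 ug/ml or trough >20 ug/ml risky; "
             "trough >10 ug/ml in neonates)."),
        _ppo("ai_aminoglycoside_tdm", g, "Aminoglycosides - TDM",
             all_of(drug("aminoglycosides"),
                    any_of(ga_below(32), vlbw(), dx("cystic_fibrosis"))),
             proc("tdm", "aminoglycosides"),
             "Neonates with gestational age <32 weeks or very low birth "
             "weight (<1500 g) and children with cystic fibrosis should "
             "routinely undergo TDM when using aminoglycosides."),
    ]

    g = "Respiratory System"
    c += [
        _pim("rs_carbocysteine", g, "Carbocysteine",
             all_of(drug("carbocysteine"), child()),
             [avoid(child())],
             "No evidence of effectiveness in children; safety in <2 years "
             "unknown. Avoid in children, especially in <2 years."),
        _pim("rs_sedative_antihistamines", g, "Sedative antihistamines",
             all_of(drug("sedating_antihistamines"), infant_lt2y()),
             [avoid(infant_lt2y())],
             "Potential life-threatening side effects such as respiratory "
             "depression. Avoid in <2 years."),
        _pim("rs_aminophylline", g, "Aminophylline",
             any_of(dose_gt("aminophylline", "per_kg_per_day", 10),
                    all_of(drug("aminophylline"), neonate())),
             [avoid(child())],
             "Higher risks of convulsions, arrhythmia, severe hypotension, "
             "cardiac arrest with doses >10 mg/kg/d or in neonates. "
             "5-6 mg/kg/d recommended for children."),
        _pim("rs_fluticasone_high_dose", g, "Fluticasone propionate",
             all_of(dose_gt("fluticasone_propionate", "per_day", 500, "ug"),
                    age_lt(16)),
             [avoid(age_lt(16))],
             "Risk of growth delay and slow weight gain. Avoid long-term "
             "high-dose (>500 ug/d) use in <16 years; <=200 ug/d "
             "recommended."),
        _pim("rs_beclomethasone_nasal", g, "Beclomethasone (nasal use)",
             all_of(drug("beclomethasone", "nasal"), age_lt(6)),
             [avoid(age_lt(6))],
             "Risk of growth suppression and HPA-axis suppression; higher "
             "absorption than other intranasal corticosteroids. Avoid in "
             "<6 years."),
        _pim("rs_naphazoline", g, "Naphazoline hydrochloride",
             all_of(drug("naphazoline"), infant_lt2y()),
             [caution(infant_lt2y())],
             "High risk of poisoning. Caution in <2 years."),
    ]

    g = "Alimentary Tract And Metabolism"
    c += [
        _pim("at_polystyrene_sulfonate", g, "Sodium/calcium polystyrene sulfonate",
             all_of(drug("polystyrene_sulfonates"), vlbw()),
             [avoid(vlbw())],
             "Risk of colon perforation. Avoid in children with very low "
             "birth weight (<1500 g)."),
        _pim("at_metoclopramide", g, "Metoclopramide",
             drug("metoclopramide"),
             [avoid(infant_lt2y()), caution(child())],
             "Risk of acute dystonia/dyskinesia; intravenous use increases "
             "risk of respiratory depression and death. Avoid in <2 years; "
             "caution in children."),
        _pim("at_diphenoxylate", g, "Compound diphenoxylate",
             all_of(drug("diphenoxylate_atropine"), infant_lt2y()),
             [avoid(infant_lt2y())],
             "Risk of respiratory depression and death. Avoid in <2 years."),
        _pim("at_sodium_phosphate_enema", g, "Sodium phosphate solution (rectal enema)",
             all_of(drug("sodium_phosphate_enema", "rectal"), infant_lt2y()),
             [avoid(infant_lt2y())],
             "Risk of electrolyte abnormalities, acute kidney injury, "
             "arrhythmia, and death. Avoid in <2 years."),
        _pim("at_lipoic_acid", g, "Lipoic acid",
             any_of(all_of(drug("lipoic_acid"), infant_lt2y()),
                    dose_gt("lipoic_acid", "per_kg_per_day", 30)),
             [caution(child())],
             "Risk of refractory convulsions. Caution with doses >30 mg/kg "
             "and in <2 years."),
        _pim("at_domperidone_erythromycin", g, "Domperidone and erythromycin",
             pair("domperidone", "erythromycin", simultaneous()),
             [avoid(child())],
             "Erythromycin inhibits domperidone metabolism (up to 3x blood "
             "concentration), raising the risk of QT prolongation. Avoid "
             "simultaneous use."),
    ]

    g = "Cardiovascular System"
    c += [
        _pim("cv_verapamil", g, "Verapamil",
             all_of(drug("verapamil"), age_lt(1)),
             [avoid(age_lt(1))],
             "Risk of cardiac arrest. Avoid in <1 year."),
        _pim("cv_camphor", g, "Camphor",
             all_of(drug("camphor"), child()),
             [caution(child())],
             "Risk of seizures. Caution in children."),
    ]

    g = "Musculo-skeletal System"
    c += [
        _pim("ms_zoledronic_acid", g, "Zoledronic acid",
             all_of(drug("zoledronic_acid"), child()),
             [caution(child())],
             "Risk of flu-like symptoms, hypocalcemia, hypophosphatemia. "
             "Caution in children."),
    ]

    g = "Dermatologicals"
    c += [
        _pim("dm_topical_corticosteroids", g, "Topical corticosteroids",
             any_of(all_of(drug("topical_corticosteroids"), age_lt(1)),
                    duration_gt("topical_corticosteroids", 2, "months")),
             [avoid(child())],
             "Higher risk of HPA-axis inhibition (absorption higher than in "
             "adults). Avoid in <1 year and avoid use for more than "
             "2 months."),
        _pim("dm_isotretinoin", g, "Isotretinoin",
             all_of(drug("isotretinoin", "oral"), age_lt(12)),
             [caution(age_lt(12))],
             "Risk of precocious epiphyseal closure, severe skin damage, "
             "mental disorders, dyslipidemia, benign intracranial "
             "hypertension. Caution in <12 years."),
        _pim("dm_tretinoin_oral", g, "Tretinoin",
             all_of(drug("tretinoin", "oral"), child()),
             [caution(child())],
             "Risk of leukocytosis, pseudo-brain tumor, retinoic acid "
             "syndrome. Caution in children."),
        _pim("dm_chlorhexidine_vlbw", g, "Chlorhexidine",
             all_of(drug("chlorhexidine"), neonate(), vlbw()),
             [caution(all_of(neonate(), vlbw()))],
             "Risk of chemical burns. Caution in neonates with very low "
             "birth weight (<1500 g)."),
    ]

    g = "Antineoplastic And Immunomodulating Agents"
    c += [
        _pim("ao_l_asparaginase", g, "L-Asparaginase",
             all_of(drug("l_asparaginase"), child()),
             [caution(child())],
             "Risk of RPLS, seizures, pancreatitis, coagulopathy, abnormal "
             "blood glucose (more likely in >=10 years). Caution in "
             "children."),
        _pim("ao_thalidomide", g, "Thalidomide",
             any_of(dose_gt("thalidomide", "cumulative_total", 20, "g"),
                    duration_gt("thalidomide", 10, "months")),
             [caution(child())],
             "Risk of peripheral neuropathy; cumulative doses >20 g or "
             "duration >10 months increase it. Caution in children; "
             "follow-up every 3 months recommended."),
        _pim("ao_cyclosporine", g, "Cyclosporine",
             all_of(drug("cyclosporine"), age_lt(16)),
             [avoid(age_lt(16))],
             "Risk of hirsutism, gingival hyperplasia, nervous system "
             "damage. Avoid in <16 years, except organ transplantation or "
             "nephrotic syndrome.",
             exception=any_of(dx("organ_transplantation"),
                              dx("nephrotic_syndrome"))),
    ]

    g = "Sensory Organs"
    c += [
        _pim("so_dexamethasone_ophthalmic", g, "Dexamethasone (ophthalmic)",
             all_of(drug("dexamethasone", "ophthalmic"), child()),
             [caution(child())],
             "Risk of high intraocular pressure and glaucoma. Caution in "
             "children (especially <10 years)."),
        _pim("so_indomethacin", g, "Indomethacin",
             all_of(drug("indomethacin"), age_lt(14)),
             [caution(age_lt(14))],
             "Nephrotoxicity risk higher than ibuprofen and acetaminophen. "
             "Caution in <14 years; monitor renal function."),
    ]

    g = "Antiparasitic Products, Insecticides And Repellents"
    c += [
        _pim("ap_lindane", g, "Lindane",
             all_of(drug("lindane"), any_of(age_lt(10), weight_below(50))),
             [avoid(any_of(age_lt(10), weight_below(50)))],
             "Risk of seizures and convulsions. Avoid in <10 years or "
             "<50 kg."),
    ]

    g = "Chinese Patent Medicine"
    c += [
        _pim("cp_reduning", g, "Reduning injection",
             drug("reduning_injection"),
             [avoid(infant_lt2y()), caution(child())],
             "Risk of severe allergic reactions such as anaphylactic shock "
             "and dyspnea. Avoid in <2 years; caution in children. "
             "Indications: URI and acute bronchitis."),
        _pim("cp_chuanhuning", g, "Chuanhuning injection",
             all_of(drug("chuanhuning_injection"), child()),
             [caution(child())],
             "Risk of severe allergic reactions such as anaphylactic shock "
             "and dyspnea. Caution in children. Indications: viral pneumonia "
             "and viral URI."),
        _pim("cp_zedoary", g, "Zedoray turmric oil injection",
             all_of(drug("zedoary_turmeric_oil_injection"), child()),
             [caution(child())],
             "Risk of severe allergic reactions, rash, dyspnea. Caution in "
             "children (especially <10 years); special monitoring required."),
        _pim("cp_qingkailing", g, "Qingkailing injection",
             drug("qingkailing_injection"),
             [avoid(age_lt(3)), caution(child())],
             "Risk of severe allergic reactions such as anaphylactic shock. "
             "Avoid in <3 years; caution in children; special monitoring "
             "required."),
        _pim("cp_xiyanping", g, "Xiyanping injection",
             drug("xiyanping_injection"),
             [avoid(age_lt(1)), caution(child())],
             "Risk of severe allergic reactions such as anaphylactic shock. "
             "Avoid in <1 year; caution in children (especially <2 years)."),
        _pim("cp_asarone", g, "Asarone injection",
             all_of(drug("asarone_injection"), child()),
             [caution(child())],
             "Risk of severe allergic reactions such as anaphylactic shock. "
             "Caution in children (especially <6 years or allergy-prone)."),
        _pim("cp_yanhuning", g, "Yanhuning injection",
             all_of(drug("yanhuning_injection"), child()),
             [caution(child())],
             "Risk of severe allergic reactions such as anaphylactic shock. "
             "Caution in children; special monitoring required."),
        _pim("cp_houttuynia", g, "Houttuynia cordata injection",
             all_of(drug("houttuynia_cordata_injection"), child()),
             [avoid(child())],
             "Risk of severe allergic reactions such as anaphylactic shock. "
             "Avoid in children."),
        _pim("cp_tripterygium", g, "Tripterygium glycosides",
             all_of(drug("tripterygium_glycosides"), child()),
             [avoid(sex("male")), caution(sex("female"))],
             "Reproductive toxicity (persisting >=6 months after stopping in "
             "boys). Avoid in boys; caution in girls. Risk may increase with "
             "cumulative doses >=200 mg/kg."),
    ]
    return c
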