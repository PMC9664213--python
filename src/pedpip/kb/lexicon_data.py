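"""Packaged drug lexicon: canonical drugs and closed-member classes.

Class member lists are seeded from the parenthetical enumerations printed in
the criteria tables; additions beyond the printed members (needed so that
broad references such as "antibiotics" are screenable) are ordinary lexicon
entries and are versioned with the lexicon, not with the criteria.
"""

from __future__ import annotations

from .model import DrugClass, DrugEntry, DrugLexicon

# (canonical_id, label, synonyms)
_DRUGS: list[tuple[str, str, list[str]]] = [
    # anesthetics / sedatives / analgesics
    ("propofol", "Propofol", []),
    ("benzocaine", "Benzocaine", []),
    ("lidocaine", "Lidocaine", ["lignocaine"]),
    ("diazepam", "Diazepam", []),
    ("midazolam", "Midazolam", []),
    ("naloxone", "Naloxone", []),
    ("morphine", "Morphine", []),
    ("tramadol", "Tramadol", []),
    ("pethidine", "Pethidine", ["meperidine"]),
    ("codeine", "Codeine", []),
    ("dihydrocodeine", "Dihydrocodeine", []),
    ("sufentanil", "Sufentanil", []),
    # antipsychotics
    ("chlorpromazine", "Chlorpromazine", []),
    ("fluphenazine", "Fluphenazine", []),
    ("haloperidol", "Haloperidol", []),
    ("droperidol", "Droperidol", []),
    ("perphenazine", "Perphenazine", []),
    ("trifluoperazine", "Trifluoperazine", []),
    ("clozapine", "Clozapine", []),
    ("risperidone", "Risperidone", []),
    ("olanzapine", "Olanzapine", []),
    ("quetiapine", "Quetiapine", []),
    ("ziprasidone", "Ziprasidone", []),
    ("aripiprazole", "Aripiprazole", []),
    ("perospirone", "Perospirone", []),
    ("paliperidone", "Paliperidone", []),
    ("amisulpride", "Amisulpride", []),
    # antidepressants
    ("desipramine", "Desipramine", []),
    ("imipramine", "Imipramine", []),
    ("amitriptyline", "Amitriptyline", []),
    ("clomipramine", "Clomipramine", []),
    ("doxepin", "Doxepin", []),
    ("paroxetine", "Paroxetine", []),
    ("fluoxetine", "Fluoxetine", []),
    ("sertraline", "Sertraline", []),
    ("fluvoxamine", "Fluvoxamine", []),
    ("citalopram", "Citalopram", []),
    ("escitalopram", "Escitalopram", []),
    ("venlafaxine", "Venlafaxine", []),
    ("duloxetine", "Duloxetine", []),
    # antiepileptics
    ("phenytoin", "Phenytoin", []),
    ("valproic_acid", "Valproic acid", ["sodium valproate", "valproate"]),
    ("lamotrigine", "Lamotrigine", []),
    ("carbamazepine", "Carbamazepine", []),
    ("oxcarbazepine", "Oxcarbazepine", []),
    ("phenobarbital", "Phenobarbital", ["phenobarbitone"]),
    ("levetiracetam", "Levetiracetam", []),
    ("topiramate", "Topiramate", []),
    ("gabapentin", "Gabapentin", []),
    ("pregabalin", "Pregabalin", []),
    ("tiagabine", "Tiagabine", []),
    # anti-infectives
    ("indinavir", "Indinavir", []),
    ("atazanavir", "Atazanavir", []),
    ("darunavir", "Darunavir", []),
    ("chloramphenicol", "Chloramphenicol", []),
    ("cefathiamidine", "Cefathiamidine", []),
    ("ceftriaxone", "Ceftriaxone", []),
    ("azithromycin", "Azithromycin", []),
    ("erythromycin", "Erythromycin", []),
    ("lincomycin", "Lincomycin", []),
    ("amikacin", "Amikacin", []),
    ("streptomycin", "Streptomycin", []),
    ("gentamicin", "Gentamicin", []),
    ("etimicin", "Etimicin", []),
    ("voriconazole", "Voriconazole", []),
    ("cefradine", "Cefradine", ["cephradine"]),
    ("cefazolin", "Cefazolin", []),
    ("cefalexin", "Cefalexin", ["cephalexin"]),
    ("nitrofurantoin", "Nitrofurantoin", []),
    ("furazolidone", "Furazolidone", []),
    ("tetracycline", "Tetracycline", []),
    ("minocycline", "Minocycline", []),
    ("silver_sulfadiazine", "Silver sulfadiazine", []),
    ("sulfadiazine", "Sulfadiazine", []),
    ("sulfamethoxazole", "Sulfamethoxazole", ["co-trimoxazole"]),
    ("levofloxacin", "Levofloxacin", []),
    ("ciprofloxacin", "Ciprofloxacin", []),
    ("ofloxacin", "Ofloxacin", []),
    ("vancomycin", "Vancomycin", []),
    ("penicillin_g", "Penicillin G", ["benzylpenicillin"]),
    ("penicillin_v", "Penicillin V", ["phenoxymethylpenicillin"]),
    ("amoxicillin", "Amoxicillin", []),
    ("ampicillin", "Ampicillin", []),
    ("piperacillin", "Piperacillin", []),
    ("fusidic_acid", "Fusidic acid", []),
    ("mupirocin", "Mupirocin", []),
    ("ribavirin", "Ribavirin", []),
    ("terbinafine", "Terbinafine", []),
    ("griseofulvin", "Griseofulvin", []),
    ("itraconazole", "Itraconazole", []),
    ("clotrimazole", "Clotrimazole", []),
    ("miconazole", "Miconazole", []),
    # cation preparations
    ("calcium_gluconate", "Calcium gluconate", []),
    ("calcium_chloride", "Calcium chloride", []),
    ("parenteral_nutrition_with_calcium", "Calcium-containing TPN", ["TPN with calcium"]),
    ("calcium_carbonate", "Calcium carbonate", []),
    ("aluminum_hydroxide", "Aluminum hydroxide", ["aluminium hydroxide"]),
    ("magnesium_hydroxide", "Magnesium hydroxide", []),
    ("ferrous_sulfate", "Ferrous sulfate", ["iron sulfate"]),
    ("zinc_sulfate", "Zinc sulfate", []),
    # respiratory
    ("carbocysteine", "Carbocysteine", ["carbocisteine"]),
    ("acetylcysteine", "Acetylcysteine", ["N-acetylcysteine"]),
    ("ambroxol", "Ambroxol", []),
    ("diphenhydramine", "Diphenhydramine", []),
    ("promethazine", "Promethazine", []),
    ("chlorpheniramine", "Chlorpheniramine", ["chlorphenamine"]),
    ("loratadine", "Loratadine", []),
    ("cetirizine", "Cetirizine", []),
    ("ketotifen", "Ketotifen", []),
    ("aminophylline", "Aminophylline", []),
    ("fluticasone_propionate", "Fluticasone propionate", ["fluticasone"]),
    ("budesonide", "Budesonide", []),
    ("beclomethasone", "Beclomethasone", ["beclometasone"]),
    ("ciclesonide", "Ciclesonide", []),
    ("salmeterol", "Salmeterol", []),
    ("formoterol", "Formoterol", []),
    ("naphazoline", "Naphazoline", ["naphazoline hydrochloride"]),
    ("oxymetazoline", "Oxymetazoline", []),
    ("pseudoephedrine", "Pseudoephedrine", []),
    ("ephedrine", "Ephedrine", []),
    ("phenylephrine", "Phenylephrine", []),
    ("dextromethorphan", "Dextromethorphan", []),
    ("pholcodine", "Pholcodine", []),
    # alimentary
    ("sodium_polystyrene_sulfonate", "Sodium polystyrene sulfonate", []),
    ("calcium_polystyrene_sulfonate", "Calcium polystyrene sulfonate", []),
    ("metoclopramide", "Metoclopramide", []),
    ("diphenoxylate_atropine", "Compound diphenoxylate", ["lomotil", "diphenoxylate-atropine"]),
    ("sodium_phosphate_enema", "Sodium phosphate solution (rectal enema)", []),
    ("lipoic_acid", "Lipoic acid", ["alpha-lipoic acid"]),
    ("domperidone", "Domperidone", []),
    ("omeprazole", "Omeprazole", []),
    ("esomeprazole", "Esomeprazole", []),
    ("lansoprazole", "Lansoprazole", []),
    ("ranitidine", "Ranitidine", []),
    ("famotidine", "Famotidine", []),
    ("cimetidine", "Cimetidine", []),
    ("oral_rehydration_solution", "Oral rehydration solution", ["ORS"]),
    ("loperamide", "Loperamide", []),
    ("bifidobacterium_preparation", "Bifidobacterium preparation", []),
    ("lactobacillus_preparation", "Lactobacillus preparation", []),
    ("saccharomyces_boulardii", "Saccharomyces boulardii", []),
    # cardiovascular / musculoskeletal
    ("verapamil", "Verapamil", []),
    ("camphor", "Camphor", []),
    ("zoledronic_acid", "Zoledronic acid", []),
    # dermatologicals
    ("clobetasol_propionate", "Clobetasol propionate", ["0.05% clobetasol propionate"]),
    ("betamethasone_dipropionate", "Betamethasone dipropionate", []),
    ("mometasone_furoate", "Mometasone furoate", []),
    ("hydrocortisone_butyrate", "Hydrocortisone butyrate", []),
    ("isotretinoin", "Isotretinoin", []),
    ("tretinoin", "Tretinoin (oral)", []),
    ("tretinoin_topical", "Tretinoin (topical)", []),
    ("chlorhexidine", "Chlorhexidine", []),
    ("tacrolimus_0_03_ointment", "0.03% tacrolimus ointment", []),
    ("tacrolimus_0_1_ointment", "0.1% tacrolimus ointment", []),
    ("benzoyl_peroxide", "Benzoyl peroxide", ["BP"]),
    ("benzyl_benzoate", "Benzyl benzoate", []),
    ("permethrin", "Permethrin", []),
    ("malathion", "Malathion", []),
    ("ivermectin", "Ivermectin", []),
    ("levonorgestrel", "Levonorgestrel", []),
    ("norgestrel", "Norgestrel", []),
    ("norethisterone", "Norethisterone", ["norethindrone"]),
    ("estradiol", "Estradiol", []),
    ("dienogest", "Dienogest", []),
    ("contraceptive_implant", "Contraceptive implant", []),
    ("contraceptive_vaginal_ring", "Contraceptive vaginal ring", []),
    # antineoplastic / immunomodulating
    ("l_asparaginase", "L-Asparaginase", ["asparaginase"]),
    ("thalidomide", "Thalidomide", []),
    ("cyclosporine", "Cyclosporine", ["ciclosporin"]),
    # corticosteroids (systemic) and sensory
    ("prednisone", "Prednisone", []),
    ("prednisolone", "Prednisolone", []),
    ("methylprednisolone", "Methylprednisolone", []),
    ("hydrocortisone", "Hydrocortisone", []),
    ("dexamethasone", "Dexamethasone", []),
    ("indomethacin", "Indomethacin", ["indometacin"]),
    # antiparasitic
    ("lindane", "Lindane", []),
    # salicylates / antipyretics
    ("aspirin", "Aspirin", ["acetylsalicylic acid"]),
    ("methyl_salicylate", "Methyl salicylate", []),
    ("magnesium_salicylate", "Magnesium salicylate", []),
    ("bismuth_salicylate", "Bismuth salicylate", ["bismuth subsalicylate"]),
    ("choline_magnesium_trisalicylate", "Choline magnesium trisalicylate", []),
    ("acetaminophen", "Acetaminophen", ["paracetamol"]),
    ("ibuprofen", "Ibuprofen", []),
    # urological / neuropsychiatric
    ("oxybutynin", "Oxybutynin", []),
    ("tolterodine", "Tolterodine", []),
    ("propiverine", "Propiverine", []),
    ("desmopressin", "Desmopressin", []),
    ("amphetamine", "Amphetamine", []),
    ("methylphenidate", "Methylphenidate", []),
    ("methylphenidate_sr", "Sustained-release methylphenidate", ["methylphenidate SR"]),
    # Chinese patent medicines
    ("reduning_injection", "Reduning injection", []),
    ("chuanhuning_injection", "Chuanhuning injection", []),
    ("zedoary_turmeric_oil_injection", "Zedoary turmeric oil injection", []),
    ("qingkailing_injection", "Qingkailing injection", []),
    ("xiyanping_injection", "Xiyanping injection", []),
    ("asarone_injection", "Asarone injection", []),
    ("yanhuning_injection", "Yanhuning injection", []),
    ("houttuynia_cordata_injection", "Houttuynia cordata injection", []),
    ("tripterygium_glycosides", "Tripterygium glycosides", []),
]

_CLASSES: list[tuple[str, str, list[str]]] = [
    ("dopamine_antagonists", "Dopamine antagonists",
     ["chlorpromazine", "fluphenazine", "haloperidol", "droperidol",
      "perphenazine", "trifluoperazine"]),
    ("opioids", "Opioids",
     ["morphine", "tramadol", "pethidine", "codeine", "dihydrocodeine",
      "sufentanil"]),
    ("atypical_antipsychotics", "Atypical/second-generation antipsychotics",
     ["clozapine", "risperidone", "olanzapine", "quetiapine", "ziprasidone",
      "aripiprazole", "perospirone", "paliperidone", "amisulpride"]),
    ("antipsychotics", "Antipsychotics",
     ["chlorpromazine", "fluphenazine", "haloperidol", "droperidol",
      "perphenazine", "trifluoperazine", "clozapine", "risperidone",
      "olanzapine", "quetiapine", "ziprasidone", "aripiprazole",
      "perospirone", "paliperidone", "amisulpride"]),
    ("tricyclic_antidepressants", "Tricyclic antidepressants",
     ["desipramine", "imipramine", "amitriptyline", "clomipramine", "doxepin"]),
    ("ssris", "Selective serotonin reuptake inhibitors",
     ["paroxetine", "fluoxetine", "sertraline", "fluvoxamine", "citalopram",
      "escitalopram"]),
    ("ssris_and_snris", "SSRIs and SNRIs",
     ["paroxetine", "fluoxetine", "sertraline", "fluvoxamine", "citalopram",
      "escitalopram", "venlafaxine", "duloxetine"]),
    ("antiepileptics", "Antiepileptic drugs",
     ["phenytoin", "valproic_acid", "lamotrigine", "carbamazepine",
      "oxcarbazepine", "phenobarbital", "levetiracetam", "topiramate",
      "gabapentin", "pregabalin", "tiagabine"]),
    ("non_valproate_antiepileptics", "Antiepileptics other than valproate",
     ["phenytoin", "lamotrigine", "carbamazepine", "oxcarbazepine",
      "phenobarbital", "levetiracetam", "topiramate", "gabapentin",
      "pregabalin", "tiagabine"]),
    ("absence_contraindicated_antiepileptics",
     "Antiepileptics contraindicated in absence/myoclonic seizures",
     ["carbamazepine", "gabapentin", "oxcarbazepine", "phenytoin",
      "pregabalin", "tiagabine"]),
    ("aminoglycosides", "Aminoglycoside antibiotics",
     ["amikacin", "streptomycin", "gentamicin", "etimicin"]),
    ("nitrofuran_antibiotics", "Nitrofuran antibiotics",
     ["nitrofurantoin", "furazolidone"]),
    ("sulfonamides", "Sulfonamides",
     ["silver_sulfadiazine", "sulfadiazine", "sulfamethoxazole"]),
    ("fluoroquinolones", "Quinolones/fluoroquinolones",
     ["levofloxacin", "ciprofloxacin", "ofloxacin"]),
    ("first_generation_cephalosporins", "First-generation cephalosporins",
     ["cefradine", "cefazolin", "cefalexin"]),
    ("penicillins", "Penicillin antibiotics",
     ["penicillin_g", "penicillin_v", "amoxicillin", "ampicillin",
      "piperacillin"]),
    ("antibiotics", "Antibacterial drugs",
     ["penicillin_g", "penicillin_v", "amoxicillin", "ampicillin",
      "piperacillin", "cefazolin", "cefalexin", "cefradine", "cefathiamidine",
      "ceftriaxone", "azithromycin", "erythromycin", "lincomycin", "amikacin",
      "streptomycin", "gentamicin", "etimicin", "chloramphenicol",
      "nitrofurantoin", "furazolidone", "tetracycline", "minocycline",
      "sulfadiazine", "sulfamethoxazole", "levofloxacin", "ciprofloxacin",
      "ofloxacin", "vancomycin", "fusidic_acid", "mupirocin"]),
    ("calcium_iv_preparations", "Intravenous calcium-containing preparations",
     ["calcium_gluconate", "calcium_chloride",
      "parenteral_nutrition_with_calcium"]),
    ("dtcc", "Compounds containing divalent or trivalent cations",
     ["calcium_carbonate", "aluminum_hydroxide", "magnesium_hydroxide",
      "ferrous_sulfate", "zinc_sulfate", "calcium_gluconate"]),
    ("mucolytics", "Mucolytics",
     ["acetylcysteine", "carbocysteine", "ambroxol"]),
    ("sedating_antihistamines", "Sedative antihistamines",
     ["diphenhydramine", "promethazine", "chlorpheniramine"]),
    ("antihistamines", "Antihistamines (H1 antagonists)",
     ["diphenhydramine", "promethazine", "chlorpheniramine", "loratadine",
      "cetirizine", "ketotifen"]),
    ("inhaled_corticosteroids", "Inhaled corticosteroids (ICS)",
     ["fluticasone_propionate", "budesonide", "beclomethasone", "ciclesonide"]),
    ("laba", "Long-acting beta2 agonists (LABA)",
     ["salmeterol", "formoterol"]),
    ("decongestants", "Nasal or oral decongestants",
     ["oxymetazoline", "pseudoephedrine", "naphazoline", "ephedrine",
      "phenylephrine"]),
    ("antitussives", "Antitussives",
     ["dextromethorphan", "pholcodine", "codeine"]),
    ("polystyrene_sulfonates", "Sodium/calcium polystyrene sulfonate",
     ["sodium_polystyrene_sulfonate", "calcium_polystyrene_sulfonate"]),
    ("topical_corticosteroids", "Topical corticosteroids (medium/high potency)",
     ["clobetasol_propionate", "betamethasone_dipropionate",
      "mometasone_furoate", "hydrocortisone_butyrate"]),
    ("high_potency_topical_corticosteroids", "High-potency topical corticosteroids",
     ["clobetasol_propionate", "betamethasone_dipropionate"]),
    ("systemic_corticosteroids", "Systemic corticosteroids",
     ["prednisone", "prednisolone", "methylprednisolone", "hydrocortisone",
      "dexamethasone"]),
    ("salicylates", "Salicylates",
     ["aspirin", "methyl_salicylate", "magnesium_salicylate",
      "bismuth_salicylate", "choline_magnesium_trisalicylate"]),
    ("antipyretics", "Antipyretics",
     ["acetaminophen", "ibuprofen"]),
    ("acne_hormonal_contraceptives", "Hormonal contraceptives used for acne",
     ["levonorgestrel", "norgestrel", "norethisterone", "estradiol",
      "dienogest", "contraceptive_implant", "contraceptive_vaginal_ring"]),
    ("antifungals", "Antifungal agents",
     ["terbinafine", "griseofulvin", "itraconazole", "clotrimazole",
      "miconazole"]),
    ("acid_suppressants", "Acid inhibitors (PPIs and H2-receptor antagonists)",
     ["omeprazole", "esomeprazole", "lansoprazole", "ranitidine",
      "famotidine", "cimetidine"]),
    ("probiotics", "Intestinal microecological preparations",
     ["bifidobacterium_preparation", "lactobacillus_preparation",
      "saccharomyces_boulardii"]),
    ("anticholinergics", "Anticholinergic agents (urological)",
     ["oxybutynin", "tolterodine", "propiverine"]),
    ("adhd_medications", "ADHD medications",
     ["amphetamine", "methylphenidate", "methylphenidate_sr"]),
    ("psychotropic_medications", "Psychotropic medications",
     ["chlorpromazine", "haloperidol", "risperidone", "olanzapine",
      "quetiapine", "aripiprazole", "paroxetine", "fluoxetine", "sertraline",
      "fluvoxamine", "citalopram", "escitalopram", "venlafaxine",
      "duloxetine", "desipramine", "imipramine", "amitriptyline",
      "clomipramine", "doxepin"]),
    ("analgesics", "Analgesics",
     ["acetaminophen", "ibuprofen", "aspirin", "indomethacin", "morphine",
      "tramadol", "pethidine", "codeine", "dihydrocodeine", "sufentanil"]),
]


def build_lexicon() -> DrugLexicon:
    return DrugLexicon(
        drugs=[DrugEntry(canonical_id=i, label=l, synonyms=s) for i, l, s in _DRUGS],
        classes=[DrugClass(class_id=i, label=l, member_ids=m) for i, l, m in _CLASSES],
    )
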