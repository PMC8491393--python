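{
  "version": "seed-1.0",
  "drugs": [
    {"name": "dabrafenib", "drug_class": "small_molecule",
     "targets": ["BRAF"],
     "notes": "BRAF inhibitor; FDA-approved with trametinib for BRAF V600 tumors"},
    {"name": "trametinib", "drug_class": "small_molecule",
     "targets": ["MAP2K1", "MAP2K2", "BRAF", "KRAS", "NRAS"],
     "notes": "MEK1/2 inhibitor; BRAF/KRAS/NRAS listed as the immediate upstream aberrations whose downstream effector (MEK) it blocks"},
    {"name": "trastuzumab", "drug_class": "antibody",
     "targets": ["ERBB2"],
     "notes": "anti-HER2 antibody"},
    {"name": "pertuzumab", "drug_class": "antibody",
     "targets": ["ERBB2"],
     "notes": "anti-HER2 dimerization-domain antibody; synergistic with trastuzumab"},
    {"name": "letrozole", "drug_class": "hormone_modulator",
     "targets": [],
     "notes": "aromatase inhibitor; matches ER-positive IHC via the hormone rule"},
    {"name": "tamoxifen", "drug_class": "hormone_modulator",
     "targets": [],
     "notes": "selective estrogen receptor modulator"},
    {"name": "enzalutamide", "drug_class": "hormone_modulator",
     "targets": [],
     "notes": "androgen receptor antagonist; matches AR-positive IHC"},
    {"name": "erdafitinib", "drug_class": "small_molecule",
     "targets": ["FGFR1", "FGFR2", "FGFR3", "FGFR4"],
     "notes": "pan-FGFR inhibitor"},
    {"name": "carboplatin", "drug_class": "platinum_chemo",
     "targets": [],
     "notes": "platinum agent; matches BRCA-pathway alterations via the special rule"},
    {"name": "olaparib", "drug_class": "parp_inhibitor",
     "targets": ["PARP1", "PARP2"],
     "notes": "PARP inhibitor; matches BRCA-pathway alterations via the special rule"},
    {"name": "bevacizumab", "drug_class": "antibody",
     "targets": ["VEGFA"],
     "notes": "anti-VEGF-A antibody; satisfies the TP53->VEGF rule"},
    {"name": "pazopanib", "drug_class": "small_molecule",
     "targets": ["KDR", "FLT1", "FLT4", "KIT", "PDGFRA", "PDGFRB"],
     "notes": "multikinase VEGFR1-3/KIT/PDGFR inhibitor; satisfies the TP53->VEGF rule"},
    {"name": "pembrolizumab", "drug_class": "checkpoint_inhibitor",
     "targets": ["PDCD1", "CD274"],
     "notes": "anti-PD-1 antibody; CD274 listed so PD-L1 amplification counts as a direct genomic match"},
    {"name": "nivolumab", "drug_class": "checkpoint_inhibitor",
     "targets": ["PDCD1", "CD274"],
     "notes": "anti-PD-1 antibody"},
    {"name": "everolimus", "drug_class": "small_molecule",
     "targets": ["MTOR", "PIK3CA", "AKT1", "PTEN", "TSC1", "TSC2", "STK11"],
     "notes": "mTOR inhibitor; PI3K-pathway aberrations listed as upstream of its effector"},
    {"name": "alpelisib", "drug_class": "small_molecule",
     "targets": ["PIK3CA"],
     "notes": "PI3K-alpha inhibitor"},
    {"name": "palbociclib", "drug_class": "small_molecule",
     "targets": ["CDK4", "CDK6", "CCND1", "CDKN2A", "CDKN2B"],
     "notes": "CDK4/6 inhibitor; cell-cycle aberrations signalling through CDK4/6"},
    {"name": "erlotinib", "drug_class": "small_molecule",
     "targets": ["EGFR"],
     "notes": "EGFR tyrosine-kinase inhibitor"},
    {"name": "cetuximab", "drug_class": "antibody",
     "targets": ["EGFR"],
     "notes": "anti-EGFR antibody"},
    {"name": "crizotinib", "drug_class": "small_molecule",
     "targets": ["ALK", "MET", "ROS1"],
     "notes": "ALK/MET/ROS1 inhibitor"},
    {"name": "gemcitabine", "drug_class": "cytotoxic_other",
     "targets": [],
     "notes": "nucleoside analogue; never molecularly matched"}
  ],
  "synergy_pairs": [
    {"drug_a": "dabrafenib", "drug_b": "trametinib", "shared_target": "BRAF"},
    {"drug_a": "trastuzumab", "drug_b": "pertuzumab", "shared_target": "ERBB2"}
  ],
  "special_rules": [
    {"rule_id": "brca_platinum_parp",
     "trigger_genes": ["BRCA1", "BRCA2", "PALB2", "ATM", "BARD1", "CHEK2", "RAD51C", "RAD51D"],
     "satisfying_drug_classes": ["platinum_chemo", "parp_inhibitor"],
     "satisfying_targets": [],
     "enabled": true},
    {"rule_id": "tp53_vegf",
     "trigger_genes": ["TP53"],
     "satisfying_drug_classes": [],
     "satisfying_targets": ["VEGFA", "KDR", "FLT1", "FLT4"],
     "enabled": true}
  ]
}
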