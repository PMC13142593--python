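{
  "description": "Registry of the discovered 11-protein panel (PPAV11) and the thirteen published CSF proteomic signatures it is benchmarked against.",
  "signatures": [
    {"name": "PPAV11", "source": "this framework", "objective": "AD diagnosis",
     "discovery_method": "Cross-study vote counting of DAPs (p < 0.05, |log2 FC| >= 0.6) shared in >= 2 of 8 discovery studies with concordant direction, coverage-filtered in 3 validation cohorts, down-selected by model performance",
     "genes": ["CHI3L1", "CYCS", "DDAH1", "GDA", "LRRC4B", "NPTX2", "PKM", "SMOC1", "SPON1", "YWHAG", "YWHAZ"],
     "notes": "The PPMI coverage table lists the missing protein as 'DDHA1', a typo for DDAH1."},
    {"name": "Ali", "source": "Ali et al.", "objective": "AD diagnosis",
     "discovery_method": "DAP identification (FDR < 0.05), replication filtering, meta-analysis; ranking over Lasso 50-fold CV iterations",
     "genes": ["CD248", "HHIP", "LRRN1", "MIF", "PPP1R1A", "PPP3R1", "SMOC1", "TMED2", "TMOD2", "YWHAG"],
     "reported_auc": "0.98-1.00"},
    {"name": "Bader", "source": "Bader et al.", "objective": "AD diagnosis",
     "discovery_method": "DAP identification with replication filtering; decision-tree importance under k=6 cross-validation",
     "genes": ["ALDOC", "IMPA1", "MAPT", "PKM", "YWHAZ"],
     "reported_auc": "0.87-0.98"},
    {"name": "Del Campo", "source": "Del Campo et al.", "objective": "AD diagnosis and staging",
     "discovery_method": "DAP identification; generalized linear model with elastic-net penalty",
     "genes": ["ABL1", "CLEC5A", "ITGB2", "MMP10", "SDC4", "SPON2", "THBD", "TREM1"],
     "reported_auc": "0.85-0.99"},
    {"name": "Guo-1", "source": "Guo et al. (signature 1)", "objective": "AD diagnosis",
     "discovery_method": "DAP identification; best-AUC selection in validation",
     "genes": ["ACHE", "IRF1", "MMP10", "PCSK1", "YWHAG"],
     "reported_auc": "0.987"},
    {"name": "Guo-2", "source": "Guo et al. (signature 2)", "objective": "AD diagnosis",
     "discovery_method": "DAP identification; best-AUC selection in validation",
     "genes": ["PIGR", "SMOC1", "TMOD2", "YWHAG"],
     "reported_auc": "0.975"},
    {"name": "Hou", "source": "Hou et al.", "objective": "AD diagnosis",
     "discovery_method": "DAP identification in two cohorts (p < 0.05); recursive elimination of lowest-ranking protein, maximal AUC in cohort 1",
     "genes": ["BASP1", "CHI3L1", "ENO2", "F2", "FN1", "LDHA", "PKM", "PRDX1", "SMOC1", "SOD1", "VSTM2A", "YWHAZ"],
     "reported_auc": "0.80-0.97"},
    {"name": "Liu", "source": "Liu et al.", "objective": "AD diagnosis",
     "discovery_method": "DAP identification; best-AUC protein combination",
     "genes": ["AT1B1", "SRGN", "PRDX3"],
     "reported_auc": "0.933",
     "notes": "Gene symbol 'AT1B1' transcribed as printed (likely ATP1B1)."},
    {"name": "Sathe", "source": "Sathe et al.", "objective": "AD diagnosis",
     "discovery_method": "DAP identification with targeted validation; best-AUC combination in logistic regression ROC analysis",
     "genes": ["NPTX2", "PKM", "YWHAG"],
     "reported_auc": null},
    {"name": "Shen", "source": "Shen et al.", "objective": "ADAD mutation carriers",
     "discovery_method": "DAP identification; highly informative proteins by 60/40-split cross-validation, 50 iterations",
     "genes": ["GFAP", "NPTX2", "PEA15", "SMOC1", "SMOC2", "TNFRSF1B"],
     "reported_auc": "0.91"},
    {"name": "Sung", "source": "Sung et al.", "objective": "Distinguish sporadic and genetic AD",
     "discovery_method": "DAP identification with replication filtering (p < 0.05, same direction); stepwise model down-selection",
     "genes": ["CABIN1", "CNTN5", "EPHA5", "GFAP", "MINDY2", "POMC", "PPIA", "PRDX6", "RSPO1", "SST", "TPT1", "YWHAZ"],
     "reported_auc": "0.88-0.90"},
    {"name": "Tao", "source": "Tao et al.", "objective": "Early diagnosis (MCI)",
     "discovery_method": "DAP identification (p < 0.05, |log2 FC| >= 0.25) with replication filtering; random-forest down-selection",
     "genes": ["ART3", "B3GALNT1", "C16orf89", "CHRD", "COL18A1", "CXCL16", "FRZB", "GALNT7", "GM2A", "IGHM", "MAN1C1", "MAN2A2", "MGAT2", "MGP", "PCDHGC5", "PCSK1N", "PLTP", "SCRG1", "SHBG"],
     "reported_auc": "0.984"},
    {"name": "van Zalm", "source": "van Zalm et al.", "objective": "AD diagnosis",
     "discovery_method": "Meta-analytic DAP identification (p < 0.05) with replication filtering; best-AUC combination",
     "genes": ["ALDOA", "PKM", "LDHB"],
     "reported_auc": "0.83-0.87"},
    {"name": "Wang", "source": "Wang et al.", "objective": "AD diagnosis",
     "discovery_method": "DAP identification (p < 0.01) with filtering in two replication cohorts",
     "genes": ["GFAP", "MAPT", "NTN1", "PRDX3", "SMOC1", "SUCLG2"],
     "reported_auc": null}
  ]
}
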