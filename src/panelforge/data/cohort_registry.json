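{
  "description": "Demographic registry of the discovery, training, validation and differential-diagnosis cohorts.",
  "strata": ["n_aneg_tneg", "n_apos_tpos", "n_aneg_tneg_cu", "n_apos_tpos_ci", "n_apos_tpos_mci", "n_apos_tpos_dementia"],
  "entries": [
    {"study": "Bader et al. (Sweden)", "role": "discovery", "platform": "mass_spec", "n_total": 60,
     "n_aneg_tneg": 31, "n_apos_tpos": 29, "n_aneg_tneg_cu": null, "n_apos_tpos_ci": null,
     "n_apos_tpos_mci": null, "n_apos_tpos_dementia": null, "n_female": 24, "n_male": 36,
     "at_rule": "CSF t-Tau > 400 ng/l and Abeta42 < 550 ng/l or Abeta42/Abeta40 < 0.065"},
    {"study": "Bader et al. (Maldenburg)", "role": "discovery", "platform": "mass_spec", "n_total": 38,
     "n_aneg_tneg": 12, "n_apos_tpos": 26, "n_aneg_tneg_cu": 13, "n_apos_tpos_ci": 25,
     "n_apos_tpos_mci": null, "n_apos_tpos_dementia": null, "n_female": 24, "n_male": 14,
     "at_rule": "CSF t-Tau > 400 ng/l and Abeta42 < 550 ng/l or Abeta42/Abeta40 < 0.065"},
    {"study": "Bai et al.", "role": "discovery", "platform": "mass_spec", "n_total": 13,
     "n_aneg_tneg": 5, "n_apos_tpos": 8, "n_aneg_tneg_cu": 5, "n_apos_tpos_ci": 6,
     "n_apos_tpos_mci": 1, "n_apos_tpos_dementia": 5, "n_female": 7, "n_male": 6,
     "at_rule": "CERAD > 2.05 and Braak V or VI"},
    {"study": "Higginbotham et al. (Discovery)", "role": "discovery", "platform": "mass_spec", "n_total": 40,
     "n_aneg_tneg": 20, "n_apos_tpos": 20, "n_aneg_tneg_cu": 20, "n_apos_tpos_ci": 20,
     "n_apos_tpos_mci": null, "n_apos_tpos_dementia": null, "n_female": 17, "n_male": 23,
     "at_rule": "CSF t-Tau/Abeta42 ratio of 0.182"},
    {"study": "Higginbotham et al. (Replication 4)", "role": "discovery", "platform": "mass_spec", "n_total": 35,
     "n_aneg_tneg": 18, "n_apos_tpos": 17, "n_aneg_tneg_cu": 17, "n_apos_tpos_ci": 18,
     "n_apos_tpos_mci": null, "n_apos_tpos_dementia": null, "n_female": 14, "n_male": 21,
     "at_rule": "CSF t-Tau/Abeta42 ratio of 0.182"},
    {"study": "Liu et al.", "role": "discovery", "platform": "mass_spec", "n_total": 60,
     "n_aneg_tneg": 30, "n_apos_tpos": 30, "n_aneg_tneg_cu": 30, "n_apos_tpos_ci": 30,
     "n_apos_tpos_mci": 30, "n_apos_tpos_dementia": 0, "n_female": 27, "n_male": 33,
     "at_rule": "CSF Abeta42 or 18F-AV-45 PET positive (IWG)"},
    {"study": "Sathe et al.", "role": "discovery", "platform": "mass_spec", "n_total": 10,
     "n_aneg_tneg": 5, "n_apos_tpos": 5, "n_aneg_tneg_cu": 5, "n_apos_tpos_ci": 5,
     "n_apos_tpos_mci": 5, "n_apos_tpos_dementia": 0, "n_female": null, "n_male": null,
     "at_rule": "CSF Abeta42 402.11 +/- 189.62 pg/ml"},
    {"study": "Tao et al.", "role": "discovery", "platform": "mass_spec", "n_total": 58,
     "n_aneg_tneg": 20, "n_apos_tpos": 38, "n_aneg_tneg_cu": 20, "n_apos_tpos_ci": 38,
     "n_apos_tpos_mci": 7, "n_apos_tpos_dementia": 31, "n_female": 30, "n_male": 28,
     "at_rule": "CSF Abeta42, t-Tau and p-Tau181 positivity"},
    {"study": "van der Ende et al.", "role": "discovery", "platform": "pea", "n_total": 425,
     "n_aneg_tneg": 195, "n_apos_tpos": 230, "n_aneg_tneg_cu": null, "n_apos_tpos_ci": null,
     "n_apos_tpos_mci": null, "n_apos_tpos_dementia": null, "n_female": 174, "n_male": 251,
     "at_rule": "CSF t-Tau/Abeta42 > 0.46 (ADC, Erasmus) or > 0.30 (UPenn)"},
    {"study": "Wang et al.", "role": "discovery", "platform": "mass_spec", "n_total": 20,
     "n_aneg_tneg": 9, "n_apos_tpos": 11, "n_aneg_tneg_cu": 9, "n_apos_tpos_ci": 11,
     "n_apos_tpos_mci": null, "n_apos_tpos_dementia": null, "n_female": null, "n_male": null,
     "at_rule": "CERAD > 2.05 and Braak V or VI"},
    {"study": "Bader et al. (Sweden, training)", "role": "training", "platform": "mass_spec", "n_total": 60,
     "n_aneg_tneg": 31, "n_apos_tpos": 29, "n_aneg_tneg_cu": null, "n_apos_tpos_ci": null,
     "n_apos_tpos_mci": null, "n_apos_tpos_dementia": null, "n_female": 24, "n_male": 36,
     "at_rule": "CSF t-Tau > 400 ng/l and Abeta42 < 550 ng/l or Abeta42/Abeta40 < 0.065"},
    {"study": "Tao et al. (training)", "role": "training", "platform": "mass_spec", "n_total": 58,
     "n_aneg_tneg": 20, "n_apos_tpos": 38, "n_aneg_tneg_cu": 20, "n_apos_tpos_ci": 38,
     "n_apos_tpos_mci": 7, "n_apos_tpos_dementia": 31, "n_female": 28, "n_male": 30,
     "at_rule": "CSF Abeta42, t-Tau and p-Tau181 positivity"},
    {"study": "ADNI", "role": "validation", "platform": "aptamer", "n_total": 702,
     "n_aneg_tneg": 289, "n_apos_tpos": 413, "n_aneg_tneg_cu": 123, "n_apos_tpos_ci": 368,
     "n_apos_tpos_mci": 226, "n_apos_tpos_dementia": 142, "n_female": 299, "n_male": 398,
     "at_rule": "p-Tau181/Abeta42 ratio > 0.023"},
    {"study": "Bangs et al.", "role": "validation", "platform": "mass_spec", "n_total": 431,
     "n_aneg_tneg": 213, "n_apos_tpos": 218, "n_aneg_tneg_cu": 150, "n_apos_tpos_ci": 214,
     "n_apos_tpos_mci": 92, "n_apos_tpos_dementia": 122, "n_female": 267, "n_male": 164,
     "at_rule": "CSF t-Tau/Abeta42 ratio of 0.226"},
    {"study": "Johnson et al.", "role": "validation", "platform": "mass_spec", "n_total": 65,
     "n_aneg_tneg": 32, "n_apos_tpos": 33, "n_aneg_tneg_cu": 32, "n_apos_tpos_ci": 33,
     "n_apos_tpos_mci": null, "n_apos_tpos_dementia": 33, "n_female": 32, "n_male": 26,
     "at_rule": "CSF Abeta42 < 500 pg/mL, t-Tau > 350 pg/mL"},
    {"study": "PPMI", "role": "differential", "platform": "aptamer", "n_total": 798,
     "n_aneg_tneg": 184, "n_apos_tpos": 614, "n_aneg_tneg_cu": null, "n_apos_tpos_ci": null,
     "n_apos_tpos_mci": null, "n_apos_tpos_dementia": null, "n_female": 312, "n_male": 486,
     "at_rule": "Dopamine transporter imaging (PD, not A/T)",
     "notes": "Parkinson's disease cohort for differential diagnosis; the 614 count is PD cases, stored under the case stratum."}
  ]
}
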