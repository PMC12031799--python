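{
  "description": "Reference cross-tabulations for the severe-VUR prediction model: per-variable exposure counts by outcome group (with the reduced DMSA denominators), the per-score outcome distribution, the three risk bands, and the no-DMSA subgroup counts. 'no_mild'/'severe' entries are [exposed, group denominator]; 'p' and 'or' are the reference display strings carried as metadata only.",
  "table1": {
    "age_lt2": {"no_mild": [610, 958], "severe": [65, 86], "p": "0.027", "or": "1.8 (1.1-2.9)", "score": 1},
    "male": {"no_mild": [416, 958], "severe": [54, 86], "p": "<0.001", "or": "2.2 (1.4-3.5)", "score": 1},
    "uti": {"no_mild": [559, 958], "severe": [58, 86], "p": "0.100", "or": null, "score": null},
    "recurrent_uti": {"no_mild": [354, 958], "severe": [35, 86], "p": "0.117", "or": null, "score": null},
    "non_ecoli": {"no_mild": [206, 958], "severe": [32, 86], "p": "0.006", "or": "2.6 (1.7-4.1)", "score": 1},
    "usg_abnormal": {"no_mild": [650, 958], "severe": [73, 86], "p": "0.001", "or": "2.7 (1.5-4.9)", "score": null},
    "hydronephrosis": {"no_mild": [439, 958], "severe": [68, 86], "p": "<0.001", "or": "4.5 (2.6-7.6)", "score": null},
    "utd_p3": {"no_mild": [138, 958], "severe": [43, 86], "p": "<0.001", "or": "5.9 (3.8-9.4)", "score": 2},
    "any_scar": {"no_mild": [242, 439], "severe": [56, 68], "p": "<0.001", "or": "3.8 (2.0-7.3)", "score": null},
    "multiple_scars": {"no_mild": [147, 439], "severe": [50, 68], "p": "<0.001", "or": "5.5 (3.1-9.8)", "score": 2}
  },
  "table2": {
    "0": [140, 0],
    "1": [228, 0],
    "2": [329, 9],
    "3": [153, 14],
    "4": [83, 25],
    "5": [25, 24],
    "6": [0, 13],
    "7": [0, 1]
  },
  "table3": [
    {"label": "low", "range": [0, 2], "absent": 697, "present": 9},
    {"label": "moderate", "range": [3, 4], "absent": 236, "present": 39},
    {"label": "high", "range": [5, 7], "absent": 25, "present": 38}
  ],
  "nodmsa": {
    "score5": {"severe": 9, "no_mild": 15},
    "score_le4": {"severe": 9, "no_mild": 504}
  }
}
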