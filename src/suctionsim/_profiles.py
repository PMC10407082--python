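"""Built-in heart-failure profiles and calibrated device defaults.

The two phenotypes span the heart-failure spectrum: a dilated cardiomyopathy
(DCM; large compliant ventricle, Ees = 0.4 mmHg/mL, V30 = 210 mL) and a
restrictive cardiomyopathy (RCM; small stiff ventricle, Ees = 3.3 mmHg/mL,
V30 = 95 mL).  Published values cover heart rate, LV elastance, V30 and the
baseline target hemodynamics; every other entry (vascular resistances and
compliances, right-heart and atrial elastances, unstressed volumes) is a free
parameter calibrated so the closed loop supported at 2,800 rpm reproduces the
target hemodynamics.  Do not edit the calibrated entries casually: they were
fit jointly.
"""

DCM = {
    "name": "DCM",
    "hr": 78.0,
    "ees_lv": 0.4,
    "v0_lv": 30.0,
    "v30": 210.0,
    "passive_scale_lv": 0.04,
    "rv_params": {
        "e_max": 0.45, "passive_scale": 0.05, "v0": 10.0, "v30": 160.0,
    },
    "atrial_params": {
        "la": {"e_max": 0.35, "e_min": 0.25, "v0": 10.0},
        "ra": {"e_max": 0.30, "e_min": 0.20, "v0": 10.0},
    },
    "systemic": {
        "resistance": 0.885,         # [mmHg s/mL]
        "compliance": 2.2,           # arterial [mL/mmHg]
        "inertance": 0.0,
        "venous_resistance": 0.05,
        "venous_compliance": 60.0,
        "arterial_unstressed": 450.0,
        "venous_unstressed": 2900.0,
    },
    "pulmonary": {
        "resistance": 0.15,
        "compliance": 2.8,
        "inertance": 0.0,
        "venous_resistance": 0.035,
        "venous_compliance": 12.0,
        "arterial_unstressed": 120.0,
        "venous_unstressed": 280.0,
    },
    "valves": {"r_mv": 0.03, "r_av": 0.008, "r_tv": 0.0045, "r_pv": 0.006},
    "total_blood_volume": 5720.0,
    "activation": {"tau2_frac": 0.37},
    "target_hemodynamics": {
        "co": 4.7,
        "sap_sys": 87.0, "sap_dia": 81.0, "sap_mean": 84.0,
        "pap_sys": 37.0, "pap_dia": 16.0, "pap_mean": 24.0,
        "pcwp": 12.0, "edv": 183.0, "esv": 154.0,
    },
}

RCM = {
    "name": "RCM",
    "hr": 78.0,
    "ees_lv": 3.3,
    "v0_lv": -10.0,          # ESPVR intercept (linear fit over the operating range)
    "v0_ed_lv": 3.0,         # EDPVR zero-pressure volume
    "v30": 95.0,
    "passive_scale_lv": 0.8,
    "rv_params": {
        "e_max": 0.75, "passive_scale": 0.08, "v0": 10.0, "v30": 140.0,
    },
    "atrial_params": {
        "la": {"e_max": 0.35, "e_min": 0.22, "v0": 10.0},
        "ra": {"e_max": 0.30, "e_min": 0.20, "v0": 10.0},
    },
    "systemic": {
        "resistance": 0.98,
        "compliance": 2.1,
        "inertance": 0.0,
        "venous_resistance": 0.05,
        "venous_compliance": 60.0,
        "arterial_unstressed": 450.0,
        "venous_unstressed": 2900.0,
    },
    "pulmonary": {
        "resistance": 0.156,
        "compliance": 2.2,
        "inertance": 0.0,
        "venous_resistance": 0.035,
        "venous_compliance": 12.0,
        "arterial_unstressed": 120.0,
        "venous_unstressed": 300.0,
    },
    "valves": {"r_mv": 0.03, "r_av": 0.008, "r_tv": 0.0045, "r_pv": 0.006},
    "total_blood_volume": 5270.0,
    "target_hemodynamics": {
        "co": 5.0,
        "sap_sys": 102.0, "sap_dia": 83.0, "sap_mean": 92.0,
        "pap_sys": 37.0, "pap_dia": 10.0, "pap_mean": 20.0,
        "pcwp": 7.0, "edv": 67.0, "esv": 13.0,
    },
}

BUILTIN_PROFILES = {"DCM": DCM, "RCM": RCM}
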