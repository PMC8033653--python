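"""Registries shared across the pipeline.

The 34 candidate physiological variables (with cohort mean and standard
deviation in natural units), their measurable ranges used for outlier removal,
the 30 Elixhauser comorbidity categories, and the van Walraven weights used to
collapse the flags into a single comorbidity index.
"""

from __future__ import annotations

from types import MappingProxyType

# variable -> (mean, sd) in natural units
VARIABLE_STATS: MappingProxyType[str, tuple[float, float]] = MappingProxyType({
    "heart_rate": (88.4, 19.0),                 # bpm
    "respiratory_rate": (20.4, 6.2),            # insp/min
    "gcs_motor": (5.1, 1.5),
    "mean_arterial_pressure": (79.2, 18.2),     # mmHg
    "diastolic_bp": (61.7, 14.7),               # mmHg
    "systolic_bp": (121.6, 23.7),               # mmHg
    "urine_output": (120.7, 114.6),             # mL
    "temperature": (37.1, 0.9),                 # Celsius
    "spo2": (97.0, 3.2),                        # %
    "fio2": (47.5, 14.8),                       # %
    "pao2": (99.4, 34.0),                       # mmHg
    "pao2_fio2_ratio": (208.2, 110.5),
    "wbc": (12.1, 6.9),                         # K/uL
    "hemoglobin": (10.0, 1.8),                  # g/dL
    "hematocrit": (29.6, 5.2),                  # %
    "ph": (7.4, 0.1),
    "magnesium": (2.1, 0.4),                    # mg/dL
    "platelet_count": (215.3, 147.6),           # K/uL
    "ptt": (40.4, 17.1),                        # sec
    "inr": (1.5, 0.6),
    "bun": (32.8, 25.8),                        # mg/dL
    "creatinine": (1.5, 1.3),                   # mg/dL
    "total_bilirubin": (3.0, 4.3),              # mg/dL
    "direct_bilirubin": (4.4, 5.4),             # mg/dL
    "ast": (61.7, 43.1),                        # IU/L
    "base_excess": (-0.1, 5.6),                 # mEq/L
    "glucose": (136.7, 51.2),                   # mg/dL
    "chloride": (105.2, 6.9),                   # mEq/L
    "bicarbonate": (24.7, 5.4),                 # mEq/L
    "lactate": (2.3, 1.6),                      # mmol/L
    "albumin": (2.8, 0.6),                      # g/dL
    "co2": (26.0, 6.3),                         # mEq/L
    "potassium": (4.1, 0.7),                    # mEq/L
    "sodium": (139.3, 5.8),                     # mEq/L
})

VARIABLES: tuple[str, ...] = tuple(VARIABLE_STATS)

# Plausibility bounds in natural units; records outside are treated as
# measurement artifacts (e.g. a respiratory rate of 2,355,555 breaths/min)
# and removed before interpolation.
MEASURABLE_RANGES: MappingProxyType[str, tuple[float, float]] = MappingProxyType({
    "heart_rate": (0.0, 300.0),
    "respiratory_rate": (0.0, 120.0),
    "gcs_motor": (1.0, 6.0),
    "mean_arterial_pressure": (0.0, 300.0),
    "diastolic_bp": (0.0, 300.0),
    "systolic_bp": (0.0, 400.0),
    "urine_output": (0.0, 5000.0),
    "temperature": (25.0, 45.0),
    "spo2": (0.0, 100.0),
    "fio2": (21.0, 100.0),
    "pao2": (0.0, 700.0),
    "pao2_fio2_ratio": (0.0, 2000.0),
    "wbc": (0.0, 300.0),
    "hemoglobin": (0.0, 25.0),
    "hematocrit": (0.0, 75.0),
    "ph": (6.5, 8.0),
    "magnesium": (0.0, 10.0),
    "platelet_count": (0.0, 2000.0),
    "ptt": (0.0, 200.0),
    "inr": (0.0, 20.0),
    "bun": (0.0, 300.0),
    "creatinine": (0.0, 40.0),
    "total_bilirubin": (0.0, 60.0),
    "direct_bilirubin": (0.0, 60.0),
    "ast": (0.0, 10000.0),
    "base_excess": (-40.0, 40.0),
    "glucose": (0.0, 2000.0),
    "chloride": (60.0, 160.0),
    "bicarbonate": (0.0, 60.0),
    "lactate": (0.0, 40.0),
    "albumin": (0.0, 10.0),
    "co2": (0.0, 80.0),
    "potassium": (0.0, 15.0),
    "sodium": (80.0, 200.0),
})

# 30 Elixhauser comorbidity categories, fixed registry order.
ELIXHAUSER_CATEGORIES: tuple[str, ...] = (
    "congestive_heart_failure",
    "cardiac_arrhythmias",
    "valvular_disease",
    "pulmonary_circulation",
    "peripheral_vascular",
    "hypertension",
    "paralysis",
    "other_neurological",
    "chronic_pulmonary",
    "diabetes_uncomplicated",
    "diabetes_complicated",
    "hypothyroidism",
    "renal_failure",
    "liver_disease",
    "peptic_ulcer",
    "aids",
    "lymphoma",
    "metastatic_cancer",
    "solid_tumor",
    "rheumatoid_arthritis",
    "coagulopathy",
    "obesity",
    "weight_loss",
    "fluid_electrolyte",
    "blood_loss_anemia",
    "deficiency_anemias",
    "alcohol_abuse",
    "drug_abuse",
    "psychoses",
    "depression",
)

# van Walraven point weights for the Elixhauser index.
VAN_WALRAVEN_WEIGHTS: MappingProxyType[str, int] = MappingProxyType({
    "congestive_heart_failure": 7,
    "cardiac_arrhythmias": 5,
    "valvular_disease": -1,
    "pulmonary_circulation": 4,
    "peripheral_vascular": 2,
    "hypertension": 0,
    "paralysis": 7,
    "other_neurological": 6,
    "chronic_pulmonary": 3,
    "diabetes_uncomplicated": 0,
    "diabetes_complicated": 0,
    "hypothyroidism": 0,
    "renal_failure": 5,
    "liver_disease": 11,
    "peptic_ulcer": 0,
    "aids": 0,
    "lymphoma": 9,
    "metastatic_cancer": 12,
    "solid_tumor": 4,
    "rheumatoid_arthritis": 0,
    "coagulopathy": 3,
    "obesity": -4,
    "weight_loss": 6,
    "fluid_electrolyte": 5,
    "blood_loss_anemia": -2,
    "deficiency_anemias": -2,
    "alcohol_abuse": 0,
    "drug_abuse": -7,
    "psychoses": 0,
    "depression": -3,
})

SOFA_SUBSCORES: tuple[str, ...] = (
    "respiration",
    "coagulation",
    "liver",
    "cardiovascular",
    "cns",
    "renal",
)

ETHNICITIES: tuple[str, ...] = ("asian", "black", "white", "hispanic", "other")
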