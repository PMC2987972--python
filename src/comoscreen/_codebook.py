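"""Embedded ICD-9 code-description subset and the default simulation code book.

The full ICD-9-CM dictionary is not distributed; this module ships only the
small subset of level-5 codes needed to label the default synthetic scenario
and the worked examples (common chronic conditions plus conditions strongly
associated with rheumatoid arthritis, and a few locomotor-chapter codes used to
exercise the exclusion filter).
"""

from __future__ import annotations

CODE_DESCRIPTIONS: dict[str, str] = {
    # common chronic / ambulatory-care codes
    "4019": "Hypertension NOS",
    "4011": "Benign hypertension",
    "78650": "Chest pain NOS",
    "2724": "Hyperlipidemia NEC/NOS",
    "25000": "Diabetes mellitus II without complication",
    "78079": "Malaise & fatigue NEC",
    "5990": "Urinary tract infection NOS",
    "78900": "Abdominal pain unspecified site",
    "7862": "Cough",
    "2449": "Hypothyroidism NOS",
    "78605": "Shortness of breath",
    "4660": "Acute bronchitis",
    "2720": "Pure hypercholesterolemia",
    "4619": "Acute sinusitis NOS",
    "2859": "Anemia NOS",
    "73300": "Osteoporosis NOS",
    "41401": "Coronary atherosclerosis native vessel",
    "53081": "Esophageal reflux",
    "7020": "Actinic keratosis",
    "73390": "Bone & cartilage disease NOS",
    "4659": "Acute upper respiratory infection NOS",
    "496": "Chronic airway obstruction NEC",
    "36616": "Senile nuclear cataract",
    "78609": "Respiratory abnormality NEC",
    "7840": "Headache",
    "41400": "Coronary atherosclerosis unspecified vessel",
    # codes strongly associated with the case condition
    "6960": "Psoriatic arthropathy",
    "99529": "Adverse effect medicinal and biologic substance NEC/NOS",
    "99666": "Reaction - internal joint prosthesis",
    "9952": "Unspecified adverse effect drug properly administered",
    "73309": "Osteoporosis NEC",
    "5163": "Idiopathic fibrosing alveolitis",
    "73027": "Osteomyelitis NOS - ankle",
    "2793": "Immunity deficiency NOS",
    "7901": "Elevated sedimentation rate",
    "7955": "Tuberculin test reaction abnormal or positive",
    "99520": "Adverse effect medicinal and biologic substance NOS",
    "73020": "Osteomyelitis NOS - unspecified site",
    "28529": "Anemia of other chronic illness",
    "2550": "Cushing's syndrome",
    "515": "Postinflammatory pulmonary fibrosis",
    "2841": "Pancytopenia",
    "4920": "Emphysematous bleb",
    "79579": "Other and unspecified nonspecific immunologic findings",
    "2794": "Autoimmune disease NEC",
    "5369": "Stomach function disorder NOS",
    "4430": "Raynaud's syndrome",
    "53130": "Acute stomach ulcer NOS",
    "70709": "Decubitus ulcer, site NEC",
    "8082": "Fracture of pubis - closed",
    "27549": "Disorders of calcium metabolism NEC",
    "73340": "Aseptic necrosis bone NOS",
    "8088": "Pelvic fracture NOS - closed",
    "73007": "Acute osteomyelitis - ankle",
    "4476": "Arteritis NOS",
    "73302": "Idiopathic osteoporosis",
    # control-condition-associated and excluded-chapter codes
    "6989": "Pruritic disorder NOS",
    "7242": "Lumbago",
    "71590": "Osteoarthrosis NOS",
    "7140": "Rheumatoid arthritis",
    "6920": "Contact dermatitis due to detergents",
}

# Default planted comorbidity scenario: (icd9, control prevalence p0, relative
# risk). High-RR entries use observed case prevalences of the conditions most
# over-represented in rheumatoid arthritis with their reported prevalence
# ratios (p0 = p_case / RR); common chronic codes get modest RRs; one skin
# code is control-associated (RR < 1); two locomotor-chapter codes exist only
# to exercise the stem-range exclusion filter.
DEFAULT_CODEBOOK: list[tuple[str, float, float]] = [
    ("6960", 0.00203, 12.3),
    ("9952", 0.00308, 3.9),
    ("73309", 0.00205, 3.9),
    ("5163", 0.00077, 3.9),
    ("7955", 0.00121, 3.3),
    ("7901", 0.00091, 3.3),
    ("28529", 0.00226, 3.1),
    ("515", 0.00667, 3.0),
    ("4430", 0.00143, 2.8),
    ("4476", 0.00160, 2.5),
    ("99529", 0.00078, 7.7),   # rare: filtered out at small control-group sizes
    ("4019", 0.170, 1.2),
    ("4011", 0.166, 1.2),
    ("2724", 0.126, 1.1),
    ("25000", 0.109, 1.1),
    ("2449", 0.063, 1.4),
    ("2859", 0.041, 1.8),
    ("5990", 0.073, 1.3),
    ("7862", 0.069, 1.3),
    ("73300", 0.036, 2.0),
    ("6989", 0.050, 0.4),
    ("7242", 0.080, 1.6),      # dorsopathy chapter: excluded by the screen
    ("71590", 0.050, 2.5),     # arthropathy chapter: excluded by the screen
]
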