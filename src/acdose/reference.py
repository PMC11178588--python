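"""Reference five-patient cohort measurements.

Desk-scale inputs for examples and validation: per-patient urine activity
concentrations (Bq/ml, 1-ml aliquots) of ²²⁵Ac and ²¹³Bi at the two
collection epochs, the injected activities, and the calibration-phantom
fill.  These are measured quantities typical of an ≈ 7.7 MBq
[²²⁵Ac]Ac-PSMA-I&T therapy cycle, usable without any imaging data.
"""

from __future__ import annotations

#: patient -> {collection time h p.i.: (A_Ac0 Bq/ml, A_Bi0 Bq/ml)}
REFERENCE_URINE: dict[str, dict[float, tuple[float, float]]] = {
    "patient_1": {17.0: (242.6, 218.9), 42.5: (38.7, 41.7)},
    "patient_2": {18.0: (232.9, 248.3), 41.3: (38.8, 40.3)},
    "patient_3": {22.0: (61.1, 76.0), 39.0: (44.1, 55.7)},
    "patient_4": {17.0: (303.9, 250.6), 40.6: (42.9, 43.3)},
    "patient_5": {18.6: (128.6, 113.3), 42.0: (113.2, 115.6)},
}

#: injected activities per patient, MBq
REFERENCE_INJECTED_MBQ = (7.9, 8.0, 7.8, 7.6, 7.4)

#: calibration phantom: uniform fill concentration (Bq/ml) and volume (l)
PHANTOM_CONCENTRATION_BQML = 524.0
PHANTOM_VOLUME_L = 8.7
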