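{
  "name": "helsinki_ct_score",
  "version": "1.0",
  "source": "Raj R, Siironen J, Skrifvars MB, Hernesniemi J, Kivisaari R. Predicting outcome in traumatic brain injury: development of a novel computerized tomography classification system (Helsinki computerized tomography score). Neurosurgery 2014;75(6):632-646.",
  "note": "Weights as originally published; update this table (and bump version) if an erratum to the source changes any component weight.",
  "weights": {
    "subdural_hematoma": 2,
    "epidural_hematoma": -3,
    "intracerebral_hematoma": 2,
    "mass_lesion_gt_25cm3": 2,
    "intraventricular_hemorrhage": 3
  },
  "suprasellar_cisterns": {
    "normal": 0,
    "compressed": 1,
    "obliterated": 5
  }
}
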