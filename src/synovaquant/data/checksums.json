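{
  "study_patients.csv": "e42b8ff6f035f4362d155286be611a1458e813d227fbbfed0e33786022a51e0f",
  "study_agreement.csv": "57668acecd5c82b08fc41766deab98d81fa6287f7897b22c27ac5f65ff49858e"
}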