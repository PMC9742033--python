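[
  "LIVER INJURY",
  "LIVER DAMAGE",
  "HEPATIC DAMAGE",
  "HEPATOTOXICITY",
  "HEPATITIS",
  "NONALCOHOLIC FATTY LIVER DISEASE",
  "LIVER FATTY INFILTRATION",
  "CHOLESTASIS",
  "BILIARY CHOLANGITIS",
  "HEPATIC ENCEPHALOPATHY",
  "HEPATIC FAILURE",
  "PORTAL HYPERTENSION",
  "HEPATIC NECROSIS",
  "DILI",
  "HEPATOCELLULAR INJURY",
  "HEPATIC ENZYME ABNORMAL",
  "BLOOD BILIRUBIN ABNORMAL"
]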