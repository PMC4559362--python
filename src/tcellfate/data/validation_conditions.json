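{
  "version": 1,
  "notes": [
    "Five published in vitro CD4+ T cell stimulation experiments used for directional (up/down) checks of trained surrogates.",
    "Raw cytokine concentrations are normalized by the maximum concentration used for that cytokine across conditions: IL-6 100 ng/ml -> 1.0, 20 -> 0.2; TGF-beta 10 ng/ml -> 1.0, 3 -> 0.3; IL-12 saturating stimulation -> 1.0.",
    "Conditions 3 and 4 probe the effect of adding IL-6 to TGF-beta-induced FOXP3, so their controls are TGF-beta-only milieus; conditions 1, 2 and 5 compare against the unstimulated (zero-cytokine) baseline.",
    "Condition 5 is IL-12 stimulation with a T-bet readout.",
    "The two FOXP3 conditions report contradictory experimental directions (slight increase vs complete abrogation); both are kept as published."
  ],
  "conditions": [
    {
      "label": "study1-il17",
      "citation": "TGF-beta + IL-6 drive IL-17 production (IL-17 4875 vs baseline 188)",
      "stimulus": {"ifng": 0.0, "il12": 0.0, "il6": 1.0, "tgfb": 1.0},
      "control": {"ifng": 0.0, "il12": 0.0, "il6": 0.0, "tgfb": 0.0},
      "readout": "IL17",
      "experimental_direction": "up"
    },
    {
      "label": "study1-rorgt",
      "citation": "TGF-beta + IL-6 induce RORgt in committed Th17 cells",
      "stimulus": {"ifng": 0.0, "il12": 0.0, "il6": 1.0, "tgfb": 1.0},
      "control": {"ifng": 0.0, "il12": 0.0, "il6": 0.0, "tgfb": 0.0},
      "readout": "RORgt",
      "experimental_direction": "up"
    },
    {
      "label": "study1-foxp3",
      "citation": "FOXP3 reported to change little (slight increase) when IL-6 is added to TGF-beta",
      "stimulus": {"ifng": 0.0, "il12": 0.0, "il6": 1.0, "tgfb": 1.0},
      "control": {"ifng": 0.0, "il12": 0.0, "il6": 0.0, "tgfb": 1.0},
      "readout": "FOXP3",
      "experimental_direction": "up"
    },
    {
      "label": "study2-foxp3",
      "citation": "IL-6 abrogates TGF-beta-induced FOXP3+ Treg generation",
      "stimulus": {"ifng": 0.0, "il12": 0.0, "il6": 0.2, "tgfb": 0.3},
      "control": {"ifng": 0.0, "il12": 0.0, "il6": 0.0, "tgfb": 0.3},
      "readout": "FOXP3",
      "experimental_direction": "down"
    },
    {
      "label": "study3-tbet",
      "citation": "IL-12 stimulation upregulates T-bet in Th1 induction",
      "stimulus": {"ifng": 0.0, "il12": 1.0, "il6": 0.0, "tgfb": 0.0},
      "control": {"ifng": 0.0, "il12": 0.0, "il6": 0.0, "tgfb": 0.0},
      "readout": "Tbet",
      "experimental_direction": "up"
    }
  ]
}
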