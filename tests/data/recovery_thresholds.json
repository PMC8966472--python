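{
  "comment": "Class-recovery floors fixed by a pre-build calibration run (3 seeds x 3 pollutants, 20k CpGs, 300 planted sites/class, 25x coverage, 6-vs-3 design); observed minima were direct 0.61/0.74, persistent 0.61/0.93, legacy 0.95/0.76 (sensitivity/precision) with persistent leakage into single-contrast classes at most 0.15.",
  "direct": {"sensitivity": 0.55, "precision": 0.65},
  "persistent": {"sensitivity": 0.55, "precision": 0.85},
  "legacy": {"sensitivity": 0.85, "precision": 0.7},
  "persistent_leak_max": 0.25
}
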