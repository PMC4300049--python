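{
  "name": "dna-unified-nn-1.0",
  "comment": "Unified DNA nearest-neighbor stack set (dH kcal/mol, dS cal/(mol*K)); representative DNA loop dG37 tables (kcal/mol, treated as entropic); linear multibranch penalty. Stack keys are the 5'->3' top-strand dinucleotide of a Watson-Crick stack; the bottom strand is implied by complementarity.",
  "stacks": {
    "AA": [-7.9, -22.2],
    "AT": [-7.2, -20.4],
    "TA": [-7.2, -21.3],
    "CA": [-8.5, -22.7],
    "GT": [-8.4, -22.4],
    "CT": [-7.8, -21.0],
    "GA": [-8.2, -22.2],
    "CG": [-10.6, -27.2],
    "GC": [-9.8, -24.4],
    "GG": [-8.0, -19.9],
    "TT": [-7.9, -22.2],
    "TG": [-8.5, -22.7],
    "AC": [-8.4, -22.4],
    "AG": [-7.8, -21.0],
    "TC": [-8.2, -22.2],
    "CC": [-8.0, -19.9]
  },
  "initiation": {
    "duplex": [0.2, -5.7],
    "terminal_AT": [2.2, 6.9],
    "terminal_GC": [0.0, 0.0],
    "symmetry_dS": -1.4
  },
  "hairpin_dG37": {
    "3": 3.5, "4": 3.5, "5": 3.3, "6": 4.0, "7": 4.2, "8": 4.3,
    "9": 4.5, "10": 4.6, "12": 5.0, "14": 5.1, "16": 5.3, "18": 5.5,
    "20": 5.7, "25": 6.1, "30": 6.3
  },
  "bulge_dG37": {
    "1": 4.0, "2": 2.9, "3": 3.1, "4": 3.2, "5": 3.3, "6": 3.5,
    "7": 3.7, "8": 3.9, "9": 4.1, "10": 4.3, "12": 4.5, "14": 4.8,
    "16": 5.0, "18": 5.2, "20": 5.3, "25": 5.6, "30": 5.9
  },
  "internal_dG37": {
    "2": 3.2, "3": 3.2, "4": 3.6, "5": 4.0, "6": 4.4, "7": 4.6,
    "8": 4.8, "9": 4.9, "10": 4.9, "12": 5.2, "14": 5.4, "16": 5.6,
    "18": 5.8, "20": 5.9, "25": 6.3, "30": 6.6
  },
  "multiloop": {"a": 3.4, "b": 0.4, "c": 0.0},
  "loop_cap": 30
}
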