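{
  "comment": "Ordered adhesion-regime rules mapping (J_BB, J_OO, J_BO) to a phase label; first matching rule wins. Variables: J_BB, J_OO, J_BO, diff = J_BB - J_OO, absdiff = |J_BB - J_OO|, max_homo, min_homo. An expression operand may be a number, a variable name, or {var, scale, offset}. Edit freely: this table is data, the surrogate for manual annotation of steady-state snapshots.",
  "labels": {
    "i": "both types individually dispersed",
    "ii": "blue clusters, orange dispersed",
    "iii": "orange clusters, blue dispersed",
    "iv": "separately sorted blue and orange clusters",
    "v": "intermixed clusters",
    "vi": "alternating stripes 1-2 cells thick",
    "vii": "dispersed orange spots in hexagonal arrangement inside blue",
    "viii": "dispersed blue spots in hexagonal arrangement inside orange",
    "ix": "core-shell: orange core, blue periphery",
    "x": "packed orange spots in hexagonal arrangement inside packed blue",
    "xi": "orange spots in tightly packed blue",
    "xii": "labyrinth / finger-like domains",
    "xiii": "mixed stripes and spots",
    "xiv": "partially sorted, blue-rich clusters",
    "xv": "partially sorted, orange-rich clusters"
  },
  "constant": [
    {"label": "i",    "all": [["J_BO", "<", 0.03], ["J_BB", "<", 0.03], ["J_OO", "<", 0.03]]},
    {"label": "ii",   "all": [["J_BO", "<", 0.03], ["J_OO", "<", 0.03]]},
    {"label": "iii",  "all": [["J_BO", "<", 0.03], ["J_BB", "<", 0.03]]},
    {"label": "iv",   "all": [["J_BO", "<", 0.03]]},
    {"label": "vi",   "all": [["J_BB", "<", 0.03], ["J_OO", "<", 0.03]]},
    {"label": "viii", "all": [["J_BB", "<", 0.03]]},
    {"label": "vii",  "all": [["J_OO", "<", 0.03], ["J_BO", "<", 0.10]]},
    {"label": "vii",  "all": [["J_OO", "<", 0.03], ["J_BB", ">=", 0.19]]},
    {"label": "xi",   "all": [["J_OO", "<", 0.03]]},
    {"label": "v",    "all": [["J_BB", ">=", "J_BO"], ["J_OO", ">=", "J_BO"]]},
    {"label": "ix",   "all": [["J_OO", ">=", {"var": "J_BO", "offset": 0.04}], ["J_BB", "<", "J_BO"]]},
    {"label": "xii",  "all": [["J_OO", ">=", {"var": "J_BB", "offset": 0.04}]]},
    {"label": "x",    "all": [["J_BB", ">=", {"var": "J_OO", "offset": 0.04}]]},
    {"label": "vi",   "all": [["max_homo", "<=", 0.05]]},
    {"label": "vi",   "all": [["max_homo", "<=", {"var": "J_BO", "scale": 0.5}]]},
    {"label": "x",    "all": []}
  ],
  "proliferation": [
    {"label": "xiv",  "all": [["J_BO", "<=", 0.07], ["J_BB", "<=", 0.05], ["J_OO", ">=", 0.07]]},
    {"label": "xv",   "all": [["J_BO", "<=", 0.07], ["J_OO", "<=", 0.05], ["J_BB", ">=", 0.07]]},
    {"label": "vii",  "all": [["J_BO", "<=", 0.11], ["J_OO", "<=", 0.05], ["J_BB", ">=", {"var": "J_BO", "offset": 0.08}]]},
    {"label": "ix",   "all": [["J_OO", ">=", {"var": "J_BO", "offset": 0.08}], ["J_BB", "<=", "J_BO"]]},
    {"label": "xi",   "all": [["J_BO", ">=", 0.21], ["J_OO", "<=", 0.05], ["J_BB", ">=", 0.07], ["J_BB", "<=", 0.11]]},
    {"label": "xiii", "all": [["J_BO", ">=", 0.21], ["J_BB", "<=", 0.05], ["J_OO", ">=", 0.07]]},
    {"label": "v",    "all": [["J_BB", ">=", "J_BO"], ["J_OO", ">=", "J_BO"]]},
    {"label": "vi",   "all": [["absdiff", "<=", 0.04], ["J_BB", "<", "J_BO"], ["J_OO", "<", "J_BO"]]},
    {"label": "vi",   "all": [["J_BO", "<=", 0.13], ["J_OO", ">=", {"var": "J_BO", "offset": -0.02}], ["J_OO", "<=", {"var": "J_BO", "offset": 0.02}], ["J_BB", "<", "J_OO"]]},
    {"label": "xii",  "all": [["J_BO", "<=", 0.13], ["max_homo", "<=", {"var": "J_BO", "offset": 0.04}], ["min_homo", ">=", {"var": "J_BO", "offset": -0.04}]]},
    {"label": "x",    "all": [["J_BB", ">", "J_OO"]]},
    {"label": "xii",  "all": []}
  ]
}
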