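{
  "gender": {
    "levels": ["F", "M"],
    "subtype_counts": [[4, 3, 4, 3], [14, 8, 10, 9]],
    "cluster_counts": [[9, 5], [30, 11]]
  },
  "location": {
    "levels": ["floor of the mouth", "hypopharynx", "larynx", "oral cavity", "oropharynx", "tongue"],
    "subtype_counts": [[0, 1, 1, 1], [1, 0, 3, 2], [0, 5, 9, 2], [0, 1, 0, 0], [17, 2, 1, 4], [0, 2, 0, 3]],
    "cluster_counts": [[2, 1], [4, 2], [12, 4], [0, 1], [19, 5], [2, 3]]
  },
  "p16": {
    "levels": ["p16 neg.", "p16 pos."],
    "subtype_counts": [[0, 10, 14, 11], [18, 1, 0, 1]],
    "cluster_counts": [[23, 12], [16, 4]]
  },
  "pN": {
    "levels": ["<2", ">2"],
    "subtype_counts": [[12, 9, 12, 4], [6, 2, 2, 8]],
    "cluster_counts": [[26, 11], [13, 5]]
  },
  "stage": {
    "levels": ["I-II", "III-IV"],
    "subtype_counts": [[16, 5, 3, 4], [2, 6, 11, 8]],
    "cluster_counts": [[20, 8], [19, 8]]
  },
  "smoking": {
    "levels": ["0", "1"],
    "subtype_counts": [[14, 0, 0, 4], [4, 11, 14, 8]],
    "cluster_counts": [[14, 4], [25, 12]]
  }
}
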