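[
  {
    "name": "T_NK",
    "genes": ["CD3D", "CD3E", "CD3G", "NKG7", "GNLY"],
    "note": "coarse T/NK lymphocyte lineage markers"
  },
  {
    "name": "B",
    "genes": ["MS4A1", "CD79A", "CD79B"],
    "note": "coarse B lineage markers"
  },
  {
    "name": "Myeloid",
    "genes": ["LYZ", "VCAN", "CD68"],
    "note": "coarse monocyte/macrophage lineage markers"
  },
  {
    "name": "Erythroid",
    "genes": ["HBB", "HBA1", "ALAS2"],
    "note": "erythrocyte guard module"
  },
  {
    "name": "Platelet",
    "genes": ["PPBP", "PF4", "ITGA2B"],
    "note": "platelet guard module"
  },
  {
    "name": "S100A_memory",
    "genes": ["S100A4", "S100A6", "S100A10", "S100A11"],
    "note": "S100A calcium-binding program; rises with T cell memory differentiation"
  },
  {
    "name": "Granzyme_KM",
    "genes": ["GZMK", "GZMM"],
    "note": "granzyme K/M program: naive and central-memory-like cytotoxic cells"
  },
  {
    "name": "Granzyme_ABH",
    "genes": ["GZMA", "GZMB", "GZMH"],
    "note": "granzyme A/B/H program: effector-differentiated T and CD16+ NK cells"
  },
  {
    "name": "B_innate_like",
    "genes": ["AHNAK", "CD1C", "SOX5"],
    "note": "innate-like mature B cells"
  },
  {
    "name": "B_memory",
    "genes": ["PLAC8", "CR2", "LY86", "CD44"],
    "note": "memory-like mature B cells"
  },
  {
    "name": "B_naive",
    "genes": ["TCL1A", "FCER2", "CXCR4"],
    "note": "naive-like mature B cells"
  }
]
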