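{
  "species": "human",
  "modules": {
    "Surveillance": ["OLFML3", "P2RY12", "TGFBR1", "TMEM119"],
    "Neuroprotection": ["BDNF", "GDNF", "IGF1", "LIF", "TGFB1"],
    "Phagocytosis": ["APOE", "AXL", "C3AR1", "CD63", "CD68", "CD9", "CLEC7A", "LGALS3", "MYO1E", "SPP1", "TREM2", "TYROBP"],
    "Inflammation": ["AOAH", "APOD", "C5AR1", "CCL8", "FGR", "MSR1", "RNF169"],
    "Cytokine production": ["CCL2", "CXCL10", "IL10", "IL1B", "NFKBIA", "TNF"],
    "Antigen presentation": ["B2M", "HLA-A", "HLA-DMA", "HLA-DQA1", "HLA-DQB1", "HLA-DRB5", "NLRC5"],
    "IFN signature": ["CD69", "CXCL10", "IFI16", "IFIT2", "IFIT3", "IFITM3", "IRF7", "ISG15", "MNDA", "MX1", "USP18"],
    "Proliferation": ["BRIP1", "RAD51B", "TOP2A"]
  }
}
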