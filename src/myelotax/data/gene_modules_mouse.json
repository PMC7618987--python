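{
  "species": "mouse",
  "modules": {
    "Surveillance": ["Hexb", "Olfml3", "P2ry12", "Siglech", "Sparc", "Tgfbr1", "Tmem119"],
    "Neuroprotection": ["Bdnf", "Gdnf", "Igf1", "Lif", "Tgfb1"],
    "Phagocytosis": ["Apoe", "Axl", "C3ar1", "Cd9", "Cd63", "Cd68", "Clec7a", "Lgals3", "Myo1e", "Spp1", "Trem2", "Tyrobp"],
    "Inflammation": ["Apod", "Aoah", "C5ar1", "Ccl12", "Fgr", "Msr1", "Rnf169"],
    "Cytokine production": ["Ccl2", "Cxcl10", "Il10", "Il1b", "Nfkbia", "Tnf"],
    "Antigen presentation": ["B2m", "H2-D1", "H2-Aa", "H2-Ab1", "H2-DMa", "H2-Eb1", "H2-K1", "Nlrc5"],
    "IFN signature": ["Cd69", "Cxcl10", "Ifi204", "Ifi213", "Ifit2", "Ifit3", "Ifitm3", "Irf7", "Isg15", "Mx1", "Oasl2", "Usp18"],
    "Proliferation": ["Birc5", "Brip1", "Mcm5", "Mki67", "Rad51b", "Top2a"]
  }
}
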