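{
 "genes": [
  {
   "gene": "ITGA1",
   "chain": "alpha",
   "display": "α1"
  },
  {
   "gene": "ITGA2",
   "chain": "alpha",
   "display": "α2"
  },
  {
   "gene": "ITGA2B",
   "chain": "alpha",
   "display": "αIIb"
  },
  {
   "gene": "ITGA3",
   "chain": "alpha",
   "display": "α3"
  },
  {
   "gene": "ITGA4",
   "chain": "alpha",
   "display": "α4"
  },
  {
   "gene": "ITGA5",
   "chain": "alpha",
   "display": "α5"
  },
  {
   "gene": "ITGA6",
   "chain": "alpha",
   "display": "α6"
  },
  {
   "gene": "ITGA7",
   "chain": "alpha",
   "display": "α7"
  },
  {
   "gene": "ITGA8",
   "chain": "alpha",
   "display": "α8"
  },
  {
   "gene": "ITGA9",
   "chain": "alpha",
   "display": "α9"
  },
  {
   "gene": "ITGA10",
   "chain": "alpha",
   "display": "α10"
  },
  {
   "gene": "ITGA11",
   "chain": "alpha",
   "display": "α11"
  },
  {
   "gene": "ITGAD",
   "chain": "alpha",
   "display": "αD"
  },
  {
   "gene": "ITGAE",
   "chain": "alpha",
   "display": "αE"
  },
  {
   "gene": "ITGAL",
   "chain": "alpha",
   "display": "αL"
  },
  {
   "gene": "ITGAM",
   "chain": "alpha",
   "display": "αM"
  },
  {
   "gene": "ITGAV",
   "chain": "alpha",
   "display": "αv"
  },
  {
   "gene": "ITGAX",
   "chain": "alpha",
   "display": "αX"
  },
  {
   "gene": "ITGB1",
   "chain": "beta",
   "display": "β1"
  },
  {
   "gene": "ITGB2",
   "chain": "beta",
   "display": "β2"
  },
  {
   "gene": "ITGB3",
   "chain": "beta",
   "display": "β3"
  },
  {
   "gene": "ITGB4",
   "chain": "beta",
   "display": "β4"
  },
  {
   "gene": "ITGB5",
   "chain": "beta",
   "display": "β5"
  },
  {
   "gene": "ITGB6",
   "chain": "beta",
   "display": "β6"
  },
  {
   "gene": "ITGB7",
   "chain": "beta",
   "display": "β7"
  },
  {
   "gene": "ITGB8",
   "chain": "beta",
   "display": "β8"
  },
  {
   "gene": "ITGBL1",
   "chain": "beta",
   "display": "βL1"
  }
 ],
 "pairs": [
  [
   "ITGA1",
   "ITGB1"
  ],
  [
   "ITGA2",
   "ITGB1"
  ],
  [
   "ITGA3",
   "ITGB1"
  ],
  [
   "ITGA4",
   "ITGB1"
  ],
  [
   "ITGA5",
   "ITGB1"
  ],
  [
   "ITGA6",
   "ITGB1"
  ],
  [
   "ITGA7",
   "ITGB1"
  ],
  [
   "ITGA8",
   "ITGB1"
  ],
  [
   "ITGA9",
   "ITGB1"
  ],
  [
   "ITGA10",
   "ITGB1"
  ],
  [
   "ITGA11",
   "ITGB1"
  ],
  [
   "ITGAV",
   "ITGB1"
  ],
  [
   "ITGAL",
   "ITGB2"
  ],
  [
   "ITGAM",
   "ITGB2"
  ],
  [
   "ITGAX",
   "ITGB2"
  ],
  [
   "ITGAD",
   "ITGB2"
  ],
  [
   "ITGA2B",
   "ITGB3"
  ],
  [
   "ITGAV",
   "ITGB3"
  ],
  [
   "ITGA6",
   "ITGB4"
  ],
  [
   "ITGAV",
   "ITGB5"
  ],
  [
   "ITGAV",
   "ITGB6"
  ],
  [
   "ITGA4",
   "ITGB7"
  ],
  [
   "ITGAE",
   "ITGB7"
  ],
  [
   "ITGAV",
   "ITGB8"
  ]
 ]
}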