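{
 "name": "TGx-HDACi-19",
 "classes": [
  "HDACi",
  "non-HDACi"
 ],
 "genes": [
  "BMF",
  "ID1",
  "MYBL1",
  "DYRK3",
  "IFI6",
  "POTEM",
  "ATP1B1",
  "ST3GAL5",
  "TUBB2A",
  "TMEM2",
  "FAS",
  "E2F8",
  "CDK5R1",
  "RIPK1",
  "PPIL1",
  "AKAP8",
  "COIL",
  "SUV39H1",
  "GPR183"
 ],
 "centroids": {
  "HDACi": [
   3.564,
   2.287,
   2.279,
   1.769,
   1.506,
   1.274,
   1.268,
   1.257,
   1.243,
   1.237,
   -1.317,
   -1.497,
   -1.542,
   -1.615,
   -1.709,
   -1.758,
   -1.794,
   -1.867,
   -2.712
  ],
  "non-HDACi": [
   0.135,
   -2.029,
   0.344,
   -0.031,
   0.044,
   -0.22,
   -0.645,
   -0.414,
   -0.358,
   -0.465,
   0.353,
   0.226,
   0.043,
   0.346,
   0.078,
   -0.086,
   0.191,
   -0.003,
   -0.279
  ]
 },
 "sd": [
  1.171,
  2.607,
  1.122,
  0.86,
  0.896,
  0.92,
  0.898,
  0.906,
  1.017,
  1.031,
  1.007,
  0.985,
  0.954,
  1.227,
  0.978,
  0.93,
  1.073,
  1.102,
  1.273
 ],
 "priors": [
  0.5,
  0.5
 ],
 "cutoff": 0.9,
 "provenance": "TGx-HDACi transcriptomic biomarker, 19-gene S1500+ subset: shrunken class centroids and per-gene standard deviations from the TK6 HDACi reference-compound study (expression data: GEO GSE164478).",
 "sha256": "ee16457d5105687c917dad0545df5a870a0d41ec2041cadb9654c715e676d8e8"
}
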