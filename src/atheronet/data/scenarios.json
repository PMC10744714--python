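[
 {
  "name": "PKC (beta,gamma) pathway inhibition",
  "knocked": [
   "t55",
   "t58"
  ],
  "target": "t43",
  "expected_disabled": [
   "m1",
   "m2",
   "m7",
   "m9",
   "t15",
   "t17",
   "t38",
   "t45",
   "t55",
   "t57",
   "t62"
  ],
  "expected_remaining": 14,
  "expected_remaining_with_target": 0
 },
 {
  "name": "Polyol pathway inhibition (aldose reductase)",
  "knocked": [
   "t32"
  ],
  "target": "t43",
  "expected_disabled": [
   "m1",
   "m2",
   "m9",
   "t15",
   "t17",
   "t38",
   "t45"
  ],
  "expected_remaining": 27,
  "expected_remaining_with_target": 0
 },
 {
  "name": "AGE inhibition (MGO formation)",
  "knocked": [
   "t63"
  ],
  "target": "t43",
  "expected_disabled": [
   "m1",
   "m2",
   "m9",
   "t15",
   "t17",
   "t38",
   "t45"
  ],
  "expected_remaining": 27,
  "expected_remaining_with_target": 0
 },
 {
  "name": "NADPH oxidase inhibition",
  "knocked": [
   "t34",
   "t62"
  ],
  "target": "t43",
  "expected_disabled": [
   "m3"
  ],
  "expected_remaining": 71,
  "expected_remaining_with_target": 42
 },
 {
  "name": "NADPH oxidase + oxidized-LDL formation inhibition",
  "knocked": [
   "t0",
   "t34",
   "t62"
  ],
  "target": "t43",
  "expected_disabled": [
   "m2",
   "m3"
  ],
  "expected_remaining": 47,
  "expected_remaining_with_target": 18
 },
 {
  "name": "NADPH oxidase + peroxynitrite formation inhibition",
  "knocked": [
   "t7",
   "t34",
   "t62"
  ],
  "target": "t43",
  "expected_disabled": [
   "m2",
   "m3",
   "m4",
   "m8",
   "m9",
   "t8",
   "t14",
   "t15",
   "t17",
   "t18",
   "t20",
   "t57"
  ],
  "expected_remaining": 6,
  "expected_remaining_with_target": 0
 },
 {
  "name": "NADPH oxidase + AGE formation inhibition",
  "knocked": [
   "t34",
   "t36",
   "t62"
  ],
  "target": "t43",
  "expected_disabled": [
   "m1",
   "m2",
   "m3",
   "m5",
   "m9",
   "m10",
   "t15",
   "t17",
   "t38",
   "t45",
   "t62",
   "t75",
   "t76"
  ],
  "expected_remaining": 11,
  "expected_remaining_with_target": 0
 }
]
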