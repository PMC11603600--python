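{
 "description": "Ayala-Schlegel rational correction to the Pitzer-Gwinn hindered-rotor partition function: q_AS = q_PG * (1 + P2(x,y)e^{-y/2}) / (1 + P1(x,y)e^{-y/2}); coefficients fitted to the exact periodic torsional eigenvalue sum (plane-wave eigensolve) over the stated domain.",
 "version": 1,
 "fit_conditions": {
  "T_K": 298.15,
  "M_sigma": [
   2,
   3
  ],
  "basis": "x^i y^j, 1<=i+j<=5"
 },
 "domain": {
  "x": [
   0.0,
   0.7
  ],
  "y": [
   0.0,
   14.0
  ]
 },
 "P1": {
  "exponents": [
   [
    0,
    1
   ],
   [
    0,
    2
   ],
   [
    0,
    3
   ],
   [
    0,
    4
   ],
   [
    0,
    5
   ],
   [
    1,
    0
   ],
   [
    1,
    1
   ],
   [
    1,
    2
   ],
   [
    1,
    3
   ],
   [
    1,
    4
   ],
   [
    2,
    0
   ],
   [
    2,
    1
   ],
   [
    2,
    2
   ],
   [
    2,
    3
   ],
   [
    3,
    0
   ],
   [
    3,
    1
   ],
   [
    3,
    2
   ],
   [
    4,
    0
   ],
   [
    4,
    1
   ],
   [
    5,
    0
   ]
  ],
  "coeffs": [
   -0.033790469276238966,
   0.22654451378603258,
   0.2114308320846381,
   0.12999329328571196,
   -0.006709258858246747,
   -0.007952775372810972,
   -0.01303714680490381,
   0.14142661407413712,
   0.018816189008533716,
   -0.028583267538519752,
   -0.0061125514539222825,
   -0.003162711829316822,
   0.0873077792889797,
   -0.07991403599017569,
   -0.004457693735909839,
   0.0007141430124580316,
   0.05300493877150106,
   -0.00318017374616085,
   0.0018634743448345849,
   -0.002253372725486459
  ]
 },
 "P2": {
  "exponents": [
   [
    0,
    1
   ],
   [
    0,
    2
   ],
   [
    0,
    3
   ],
   [
    0,
    4
   ],
   [
    0,
    5
   ],
   [
    1,
    0
   ],
   [
    1,
    1
   ],
   [
    1,
    2
   ],
   [
    1,
    3
   ],
   [
    1,
    4
   ],
   [
    2,
    0
   ],
   [
    2,
    1
   ],
   [
    2,
    2
   ],
   [
    2,
    3
   ],
   [
    3,
    0
   ],
   [
    3,
    1
   ],
   [
    3,
    2
   ],
   [
    4,
    0
   ],
   [
    4,
    1
   ],
   [
    5,
    0
   ]
  ],
  "coeffs": [
   -0.028520525646879288,
   0.22107393764744487,
   0.2130146459646532,
   0.12981965825453595,
   -0.0067026615110393015,
   -0.01089806421034715,
   -0.1025933280608202,
   0.21136751243087532,
   0.0062504728023707445,
   -0.027946735800028755,
   0.06101196225220912,
   0.5410807138934306,
   -0.2540480106782815,
   0.08356732330775377,
   -0.3577892152638448,
   -0.4204885144745403,
   0.2585568809868895,
   0.5856845078486161,
   0.1331958132586416,
   -0.3233226835109112
  ]
 }
}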