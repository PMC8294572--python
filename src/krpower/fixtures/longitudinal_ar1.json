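{
 "schema_version": 1,
 "label": "longitudinal AR(1) trial with monotone dropout",
 "description": "Two arms, 50 participants each, 5 planned repeated measures with AR(1) errors (sigma2 1, rho 0.4); 10 participants per arm drop out after the 3rd occasion. Cell-means coding by arm-by-time; the hypothesis is the time-by-treatment interaction; effect 0.5 on arm 1 at time 1.",
 "covariance": {
  "family": "ar1",
  "dimension": 5,
  "variance": 1.0,
  "rho": 0.4
 },
 "patterns": [
  {
   "id": 1,
   "indices": "1:5"
  },
  {
   "id": 2,
   "indices": [
    1,
    2,
    3
   ]
  }
 ],
 "groups": [
  {
   "pattern": 1,
   "count": 40,
   "design": [
    [
     1.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0
    ],
    [
     0.0,
     1.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0
    ],
    [
     0.0,
     0.0,
     1.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0
    ],
    [
     0.0,
     0.0,
     0.0,
     1.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0
    ],
    [
     0.0,
     0.0,
     0.0,
     0.0,
     1.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0
    ]
   ]
  },
  {
   "pattern": 1,
   "count": 40,
   "design": [
    [
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     1.0,
     0.0,
     0.0,
     0.0,
     0.0
    ],
    [
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     1.0,
     0.0,
     0.0,
     0.0
    ],
    [
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     1.0,
     0.0,
     0.0
    ],
    [
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     1.0,
     0.0
    ],
    [
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     1.0
    ]
   ]
  },
  {
   "pattern": 2,
   "count": 10,
   "design": [
    [
     1.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0
    ],
    [
     0.0,
     1.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0
    ],
    [
     0.0,
     0.0,
     1.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0
    ]
   ]
  },
  {
   "pattern": 2,
   "count": 10,
   "design": [
    [
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     1.0,
     0.0,
     0.0,
     0.0,
     0.0
    ],
    [
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     1.0,
     0.0,
     0.0,
     0.0
    ],
    [
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     0.0,
     1.0,
     0.0,
     0.0
    ]
   ]
  }
 ],
 "beta": [
  0.5,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0
 ],
 "C": [
  [
   1.0,
   0.0,
   0.0,
   0.0,
   -1.0,
   -1.0,
   -0.0,
   -0.0,
   -0.0,
   1.0
  ],
  [
   0.0,
   1.0,
   0.0,
   0.0,
   -1.0,
   -0.0,
   -1.0,
   -0.0,
   -0.0,
   1.0
  ],
  [
   0.0,
   0.0,
   1.0,
   0.0,
   -1.0,
   -0.0,
   -0.0,
   -1.0,
   -0.0,
   1.0
  ],
  [
   0.0,
   0.0,
   0.0,
   1.0,
   -1.0,
   -0.0,
   -0.0,
   -0.0,
   -1.0,
   1.0
  ]
 ],
 "theta0": [
  0.0,
  0.0,
  0.0,
  0.0
 ],
 "alpha": 0.05,
 "q": 2
}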