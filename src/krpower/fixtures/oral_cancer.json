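{
 "schema_version": 1,
 "label": "oral-cancer worksite smoking-cessation trial",
 "description": "80 worksites randomized to 2 cessation programs, 40 per arm: 25 clusters of 30 members and 15 of 20 per arm. Urinary cotinine outcome, sd 125 ng/ml, ICC 0.04; detect a 25 ng/ml program difference at alpha 0.05. Cell-means coding: arm means (beta1, beta2), contrast beta1 - beta2.",
 "covariance": {
  "family": "cs",
  "dimension": 30,
  "variance": 15625.0,
  "icc": 0.04
 },
 "patterns": [
  {
   "id": 1,
   "indices": "1:30"
  },
  {
   "id": 2,
   "indices": "1:20"
  }
 ],
 "groups": [
  {
   "pattern": 1,
   "count": 25,
   "design": {
    "kron_ones": [
     1,
     0
    ]
   }
  },
  {
   "pattern": 2,
   "count": 15,
   "design": {
    "kron_ones": [
     1,
     0
    ]
   }
  },
  {
   "pattern": 1,
   "count": 25,
   "design": {
    "kron_ones": [
     0,
     1
    ]
   }
  },
  {
   "pattern": 2,
   "count": 15,
   "design": {
    "kron_ones": [
     0,
     1
    ]
   }
  }
 ],
 "beta": [
  25.0,
  0.0
 ],
 "C": [
  [
   1.0,
   -1.0
  ]
 ],
 "theta0": [
  0.0
 ],
 "alpha": 0.05,
 "q": 2,
 "analysis": {
  "cluster_mean_recast": true
 }
}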