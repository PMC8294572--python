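# Design configuration schema (JSON, `schema_version: 1`)

A study-design config is a single JSON object. Files with a different
`schema_version` are refused (no silent migration).

| field | required | meaning |
| --- | --- | --- |
| `schema_version` | yes | must be `1` |
| `label` | no | free-text design name |
| `description` | no | free-text documentation |
| `covariance` | yes | maximal covariance `Sigma_max` (see below) |
| `patterns` | yes | list of observation patterns |
| `groups` | yes | list of unit groups referencing patterns |
| `beta` | yes | regression coefficients (length `r`) |
| `C` | yes | contrast matrix, `a x r`, full row rank |
| `theta0` | yes | null values (length `a`) |
| `alpha` | no | Type I error rate, default `0.05` |
| `q` | no | rank of the between-unit design in the multivariate recast, default `2` |
| `analysis.cluster_mean_recast` | no | if `true`, the analytic pipeline collapses each cluster to its mean |

## `covariance`

One of:

```json
{"family": "cs",  "dimension": 30, "variance": 15625.0, "icc": 0.04}
{"family": "ar1", "dimension": 5,  "variance": 1.0,     "rho": 0.4}
{"family": "explicit", "matrix": [[...], ...]}
```

`cs` is compound symmetry `variance * (J*icc + I*(1-icc))`; `ar1` has
elements `variance * rho^|i-j|`.

## `patterns`

```json
{"id": 1, "indices": "1:30"}     // span shorthand, 1-based inclusive
{"id": 2, "indices": [1, 3, 5]}  // explicit, strictly increasing
```

`indices` are the observed row positions out of `1..p` where `p` is the
covariance dimension. Every row of `Sigma_max` must be observed under at
least one pattern.

## `groups`

```json
{"pattern": 1, "count": 25, "design": {"kron_ones": [1, 0]}}
{"pattern": 2, "count": 10, "design": [[1,0,0],[0,1,0],[0,0,1]]}
```

`design` is the per-unit fixed-effects matrix `X_i` with one row per
observed occasion (`p_d` rows, `r` columns). The shorthand
`{"kron_ones": row}` expands to `ones(p_d) ⊗ row` — every occasion carries
the same covariate row (the no-repeated-covariates assumption).

## Validation

Loading a config checks the schema, expands shorthands, and then enforces
design admissibility, in particular `N_d > q + p_d + 1` for every pattern
and `rank(C) = a`. Errors name the offending field or pattern.

Packaged examples: `krpower fixtures` lists them;
`krpower power --config oral_cancer` runs one.
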