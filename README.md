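# soilniche

Modelling the relative abundances of soil bacterial taxa from climate,
vegetation and soil drivers.

Soil bacteria drive biogeochemical cycling, yet predicting how their
relative abundances respond to environmental change is hard: community
summaries (alpha/beta diversity) discard most taxon-level information,
while unstructured machine learning cannot test causal hypotheses.
`soilniche` implements a pipeline built around **observed-variable
structural equation models (SEM, path analysis)**: a postulated causal
network links climate (temperature, humidity, precipitation), vegetation
(C3/C4 coverages) and soil (pH, conductivity, organic carbon) drivers to
each taxon's relative abundance. The fitted standardized path
coefficients act as indicators of the taxon's *response traits*, and
three layers of interpretation follow:

* **Niche space** — Huisman–Olff–Fresco (HOF) response curves I–VII
  along single gradients, AICc + bootstrap model selection, and machine
  rules for niche optima and inflection-point niche edges.
* **Phylogenetic signal** — Abouheif's Cmean (topological Moran's I)
  and per-tip LIPA (local Moran's I) of the SEM-derived trait
  indicators across a taxon phylogeny.
* **Projection** — predicted abundances under future driver scenarios,
  ln-fold changes with zero replacement, Bray–Curtis PCoA displacement
  of each site between periods, community-weighted functional (gene)
  profiles and inverse-distance maps.

It is written for microbial ecologists working with taxon/OTU tables,
sample environment tables, taxonomy maps and rooted phylogenies.

## The model

For exogenous drivers `x` (freely correlated, covariance Φ) and
endogenous variables `y = B y + Γ x + ζ` (diagonal residual covariance
Ψ), the implied covariance with `A = (I − B)⁻¹` is

    Σ̂ = [ Φ            Φ Γ' A'                 ]
         [ A Γ Φ        A (Γ Φ Γ' + Ψ) A'      ]

Each structural equation is estimated by least squares (the ML solution
for recursive systems with uncorrelated residuals); fit is judged by the
ML discrepancy `F_ML = ln|Σ̂| − ln|S| + tr(S Σ̂⁻¹) − p`, with
`χ² = (n−1)·F_ML`, CFI against the independence baseline, RMSEA and
SRMR. A standardized path of −0.46 for humidity means a one-standard-
deviation humidity increase moves the taxon's predicted relative
abundance by 0.46 of its own standard deviations. See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

```python
from soilniche.sem import StructuralEquationModel, default_spec, fit_many, holdout_validate
from soilniche.synthetic import default_config, generate_dataset
from soilniche.traits import coefficient_matrix, ternary_coordinates

# a synthetic world with the default causal topology, 1,381 samples
config, spec = default_config(n_samples=1381, n_taxa=1, seed=7)
dataset = generate_dataset(config, spec)

model = StructuralEquationModel(spec=spec).fit(dataset.data)
print(model.fit_indices_)
# {'F_ML': 0.011, 'chi2': 14.751, 'df': 12, 'p': 0.255,
#  'CFI': 1.0, 'RMSEA': 0.013, 'SRMR': 0.008}
```

The χ² p-value of 0.26 (> 0.05) means the implied and observed
covariance matrices are statistically congruent — the causal network is
consistent with the data; CFI ≈ 1 and small RMSEA/SRMR agree. The
taxon's standardized paths recover the generating trait profile
(humidity −0.40, precipitation −0.25, MAT −0.21, C4 megathermal
+0.21 ...):

```python
out = holdout_validate(spec, dataset.data, n_train=1000, seed=0)
print(out["pearson_r"], out["r2"], out["n_test"])
# 0.654 0.424 381
```

A network calibrated on 1,000 samples predicts the held-out 381
samples' abundances with r = 0.65 (R² = 0.42, close to the generating
conditional R²). Assembling per-taxon coefficient vectors into trait
space:

```python
collection = fit_many(default_spec("taxon"), dataset.abundances, dataset.env)
coeffs = coefficient_matrix(collection.fits)
print(ternary_coordinates(coeffs).round(1))
#          soil  vegetation  climate
# taxon_1  20.1        20.2     59.7
```

i.e. 59.7% of this taxon's absolute standardized-path mass lies on
climate drivers — a climate-responsive taxon. The three coordinates sum
to 100 by construction.

A `soilniche` CLI wraps the same library:

```sh
soilniche simulate --n 1000 --n-taxa 5 --seed 7 --out sim/
soilniche niche --abundance sim/abundances.tsv --env sim/env.csv --gradient pH --out niche.csv
soilniche project --abundance sim/abundances.tsv --current sim/env.csv \
    --scenario env2030.csv --out proj/
```

## Layout

| module | contents |
| --- | --- |
| `soilniche.io` | AbundanceTable/EnvTable/TaxonomyMap, TSV/CSV/newick IO, rarefaction, copy-number correction, rank aggregation, log10 transforms |
| `soilniche.sem` | SemSpec, `StructuralEquationModel`, fit indices, hold-out validation, per-taxon batch fitting |
| `soilniche.hof` | HOF curves I–VII, `NicheResponseCurve`, model selection, niche optima/edges |
| `soilniche.phylo` | Abouheif proximity, Cmean permutation test, LIPA, occupancy filter |
| `soilniche.traits` | coefficient matrix, ternary coordinates, `WardResponseGroups` |
| `soilniche.projection` | scenario projection, ln-fold change, Bray–Curtis, `PCoA`, displacement, functional projection, gridding |
| `soilniche.synthetic` | seeded generators for the SEM, HOF and phylogeny worlds |

Estimator classes follow scikit-learn conventions (`fit`/`predict`/
`fit_transform`, trailing-underscore fitted attributes) and compose with
sklearn tooling.
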