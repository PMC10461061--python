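# Methods

`soilniche` models the relative abundances of soil bacterial taxa as the
outcome of a postulated causal network of climate, vegetation and soil
drivers, and builds three layers of interpretation on top of the fitted
network: niche response curves along single gradients, phylogenetic
signal of the fitted driver associations, and projection of abundances
under changed drivers. This note records the models, their assumptions,
the defaults and the numerical choices, and what the synthetic test
worlds do and do not establish.

## Structural equation model (path analysis)

The causal network is an observed-variable, recursive SEM. A
`SemSpec` declares the DAG; the shipped default topology is:

* exogenous and freely correlated: MAT (maximum annual temperature),
  humidity, precipitation, pH, conductivity;
* each vegetation coverage (C3 macrothermal, C3 mesothermal,
  C4 megathermal) depends on the three climate drivers;
* organic carbon (OC) depends on conductivity, pH, humidity,
  precipitation and C3 macrothermal coverage;
* the taxon node depends on all nine drivers and is terminal.

The published account pins only OC's parents and the taxon's nine direct
links; the remaining edges of the default DAG are a documented choice
and the spec is data (YAML/JSON), not code, so any recursive topology
can be supplied.

Writing the endogenous block as `y = B y + Γ x + ζ` with `A = (I − B)⁻¹`,
the model-implied covariance is

    Cov(y) = A (Γ Φ Γ' + Ψ) A',   Cov(y, x) = A Γ Φ,

with Φ the free exogenous covariance and Ψ diagonal. For recursive
systems with uncorrelated residuals, maximum-likelihood estimation
decouples into equation-wise least squares; we verified numerically that
the equation-wise estimates minimise the ML discrepancy

    F_ML = ln|Σ̂| − ln|S| + tr(S Σ̂⁻¹) − p

to machine precision (this identity is also an acceptance test, checked
against a derivative-free numerical minimiser). All covariances use the
unbiased (n−1) denominator consistently; `chi2 = (n−1)·F_ML` with
`df = p(p+1)/2 − t` where `t` counts one parameter per edge, one
residual variance per endogenous variable and q(q+1)/2 exogenous
(co)variances (means are saturated and cancel). CFI is computed against
the independence baseline (variances free, covariances zero); RMSEA is
`sqrt(max(chi2−df,0)/(df·(n−1)))`; SRMR is the root mean square of
correlation-scale covariance residuals over the lower triangle including
the diagonal (the common convention; no formula is pinned by the source
description). Standardized coefficients are `unstandardized ×
sd(parent)/sd(child)` with sample standard deviations, so one parent
standard deviation moves the child by that many child standard
deviations.

Degenerate inputs: rows with missing values are listwise-deleted and
counted; a zero-variance variable or singular design raises; an exactly
noise-free equation makes Σ̂ singular, in which case coefficients and
predictions remain valid and the fit indices are reported as NaN with a
`degenerate` flag.

Hold-out validation uses a seeded random split (default 1,000 training
samples, remainder for validation — the 1,000/381 design at the source
dataset's size) and reports Pearson r and R² of observed versus
conditionally predicted abundances. Conditional prediction uses only the
taxon equation's parents, never the taxon column itself.

Calibration note: under the true default topology at n = 500 the
`chi2` test's empirical type-I rate is ≈ 0.06 (1,000 replicates during
development), the usual mild finite-sample inflation of the likelihood-
ratio statistic; it converges to the nominal 0.05 as n grows.

## HOF niche response curves

The seven Huisman–Olff–Fresco types are implemented with the logistic
building block `s(t) = 1/(1+e^t)` (see `soilniche.hof` for the exact
forms). The bimodal types VI/VII are parameterised as a type-IV peak
plus a second peak shifted by `d2 ∈ (0,1)` with height fraction
`h ∈ (0,1]`; VII gives the second peak its own width `b2`. This follows
the "extended" bimodal semantics; since no closed formula is pinned by
the source description, the parameterisation is documented here as a
deviation risk.

Fitting is Gaussian nonlinear least squares on max-scaled abundances
over a gradient internally rescaled to [0, 1] (the error model suits
relative abundances; binomial/Poisson families target presence or count
data). Each type gets heuristic starts (empirical argmax placement for
peaked types, slope-signed sigmoids for monotone ones) plus five seeded
random restarts, with box bounds that keep `M > 0`, `d2` interior and
`h ≤ 1`. Taxa with fewer than 10 positive observations are skipped with
a "minimum occurrence" reason ("occurrence" is read as occupied
samples, not reads). AICc (small-sample AIC, `k` counting the residual
variance) scores each type.

Model selection needed two rules beyond AICc-argmin, both fixed during
development against simulated unimodal/monotone data:

1. **Parsimony margin.** Types within 2 AICc units of the minimum are
   treated as equally supported and the least complex wins (the
   standard Burnham–Anderson convention for nested candidates). Without
   it, VI/VII beat IV on pure type-IV data by fractions of an AICc unit.
2. **Bimodality eligibility.** VI/VII compete only when their fitted
   curve is genuinely bimodal: the lesser peak must rise above the
   saddle between the peaks by at least 10% of the fitted response
   range. This is the machine equivalent of visually rejecting a
   "second peak" that is a noise spike (with free widths, a near-zero-
   width spike can otherwise buy more residual reduction than the AICc
   penalty charges).

The AICc choice is then re-selected on 5 bootstrap resamples
(warm-started from the full-data parameters); if the modal bootstrap
choice differs, it wins, with ties broken toward lower complexity.

Niche interpretation on a 2,001-point grid: the optimum is the interior
argmax of the fitted curve; the flat type I and the monotone types
II/III carry no optimum; VI/VII whose interior maxima all sit within 5%
(configurable) of the gradient ends are read as having no optimum.
Niche edges are the inflection points (sign changes of the numerical
second derivative) flanking the optimum; a side without an interior
inflection falls back to the range end and is flagged. Local-maximum
detection ignores float-level wiggles in saturated curve regions
(relative tolerance 1e-9 of the curve range).

## Phylogenetic signal

Abouheif's proximity is purely topological: `a_ij` is the product over
the internal nodes on the tip-to-tip path of 1/(number of direct
descendants), with zero diagonal. Branch lengths are deliberately not
used (this differs from branch-length-aware alternatives such as
Pagel's λ, which are out of scope). The global statistic is Moran's I
under this proximity,

    Cmean = (n/S0) · Σ_{i≠j} a_ij z_i z_j / Σ z_i²,

tested one-sided ("greater", i.e. trait conservation) by tip
permutation with `p = (hits+1)/(n_perm+1)` and 999 permutations by
default. On a star tree Cmean equals −1/(n−1) exactly for any trait, a
closed form used as a test anchor.

LIPA (local indicators of phylogenetic association) are per-tip local
Moran's I values on the row-normalised proximity matrix; their mean
equals the global Moran statistic under the same weights (asserted
numerically). Per-tip permutation p-values hold the focal tip's value
fixed, permute the rest, and are two-sided on |I|; significance is
reported at p < 0.05 without multiplicity correction by default, with a
Benjamini–Hochberg option.

The occupancy filter retains taxa present in strictly more than 200
samples by default before signal testing.

## Trait space

The taxon-equation standardized coefficients form a taxa × 9 matrix with
fixed column order (MAT, humidity, precipitation, C3 macrothermal, C3
mesothermal, C4 megathermal, OC, conductivity, pH). Ternary coordinates
take the absolute coefficients of each driver family (soil = OC,
conductivity, pH; vegetation = the three coverages; climate = the three
climate drivers) as a percentage of the absolute total, so the three
axes sum to 100 and the transform is invariant to positive rescaling of
a row. Response groups come from Ward's minimum-variance clustering on
Euclidean distances, k = 10 by default; an auto mode scans k ∈ [2, 15]
and keeps the average-silhouette maximiser ("misclassification", named
alongside silhouette in the source description, is not operationalisable
from the text and is not used).

## Projection under changed drivers

A scenario table supplies future values for at least the exogenous
drivers; unsupplied endogenous drivers (e.g. future OC) are propagated
through the fitted structural equations in topological order, then every
taxon equation predicts its abundance. Negative linear predictions are
truncated to zero and counted. Change summaries:

* **ln-fold change** with the zero-replacement rule: zeros in either
  matrix are replaced by half the lowest positive *current* value over
  the taxon set named in the call (per-call, not global — the published
  worked example 0.5 × 0.066 = 0.033 is an acceptance anchor).
* **Bray–Curtis PCoA displacement**: BC = Σ|u−v| / Σ(u+v) on the
  stacked current+future matrix, Gower double-centering of −D²/2,
  eigendecomposition, axes ordered by eigenvalue with negative-
  eigenvalue axes dropped but reported; per-site displacement is the
  Euclidean distance between a site's (axis1, axis2) positions in the
  two periods.
* **Functional projection**: gene profiles = trait-tableᵀ × abundance
  columns, renormalised, with the unmatched-taxon fraction reported.
  This is the community-weighting step only; hidden-state/ancestral
  reconstruction of gene content is out of scope and the trait table is
  a user input.
* **Gridding** for maps uses inverse-distance weighting (power 2,
  cutoff radius 2°, default resolution 0.2°) on a bounding-box grid;
  grid nodes coincident with a data point take its value exactly. The
  original spline-based interpolator is proprietary and maps are
  illustrative only.

## Synthetic worlds

The generator produces the three structures the analysis assumes, with
seeded determinism throughout:

* **SEM world**: exogenous drivers are multivariate normal (driver
  distributions are not published; normality matches the linear-normal
  SEM assumptions and makes parameter recovery well-posed, and the
  drivers are generated on the post-log10 analysis scale with unit
  variances and moderate correlations). Endogenous variables are exact
  linear combinations of parents plus independent normal residuals,
  evaluated in topological order. The default taxon coefficients are
  standardized-path magnitudes in the tenths (the published range), the
  residual sd 0.8 gives a conditional R² near 0.3–0.4, and the
  intercept of 10 keeps abundances far from the zero-truncation
  boundary so the linear world stays exact in practice.
* **HOF world**: abundances on-curve plus normal noise truncated at 0,
  over an evenly spaced gradient on [0, 1].
* **Phylogeny world**: unit-depth Yule trees with Brownian traits
  (tip variance = σ² × depth, the identity used in tests).
* **Sequencing**: one multinomial draw per sample turns relative
  abundances into counts so rarefaction (multivariate hypergeometric)
  and copy-number correction are exercisable.

What the synthetic worlds do *not* emulate: spatial autocorrelation
between samples (the analysis assumes limited geospatial dependency),
amplicon sequencing error, compositional closure of real relative-
abundance data, non-normal driver distributions and nonlinear
driver–abundance relationships outside the HOF world. Passing tests
therefore establish correctness of the machinery and calibration under
the model's own assumptions, not robustness to their violation on real
soils.

## Preprocessing defaults

Rarefaction subsamples each sample without replacement to 22,500 reads
by default; samples below depth are dropped (not up-sampled) and
logged. Copy-number correction follows rarefaction, divides each taxon
by its 16S copy number (missing → 1, logged) and renormalises to
relative abundances. Rank aggregation sums rows over shared lineage
prefixes and pools rows unassigned at the target rank into
`Unclassified_<deepest assigned parent>`. The environment transform
takes log10 of conductivity, OC, humidity, precipitation and both C3
coverage columns, refuses nonpositive values (no silent pseudo-counts)
and refuses double application.

## Problem sizes used in the test suite

Simulation-based checks use: 500 replicates at n = 500 for χ²
calibration; 200 replicates at n = 5,000 for standardized-path
recovery; 200 type-IV gradients (n = 300, noise sd 0.02) for HOF
type/optimum recovery; 500 permuted-trait replicates and 200 Brownian
replicates on 64-tip trees (199 permutations each) for the signal
tests; n = 10,000 with a 1,000-sample training split for hold-out R²
recovery. These sizes give Monte-Carlo error comfortably inside each
asserted band.

## Known limitations

* Latent variables, robust/weighted estimators and spatial error
  structures are not supported (observed-variable ML only).
* Whether taxon abundances should be transformed before SEM fitting is
  left to the caller (a config hook; the default fits them as given).
* The VI/VII parameterisation is one of several consistent with the
  "extended" bimodal description; niche records from bimodal fits
  should be read together with their flags.
* The eHOF R package's exact error family and bootstrap acceptance rule
  are not published in the source description; the rules above are
  documented substitutes.
* PCoA drops negative-eigenvalue axes rather than applying a
  correction; for strongly non-Euclidean dissimilarities consider a
  Cailliez/Lingoes correction upstream.
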