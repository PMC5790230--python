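# cropsuit

Ensemble niche-model suitability, climate-novelty detection and
geographically weighted variation partitioning for crop productivity.

## The problem

How much of the spatial variation in a crop's productivity is explained by
climate, how much by agricultural technology, and how much by the two
together — and does the answer itself vary over space? This package
implements the full analysis chain used to ask that question for a crop
observed at the municipality level:

1. **Ensemble niche modelling.** Occurrence records on a 0.5° grid are
   combined with bioclimatic layers (plus soil pH). For each of many
   randomizations, pseudo-absences are drawn from the background at
   prevalence 0.5, records are split 75/25 into calibration and evaluation,
   each niche model is fitted and binarized at the ROC threshold that
   maximizes sensitivity + specificity, and its skill is scored with the
   True Skill Statistic, TSS = sensitivity + specificity − 1. Binary
   predictions are stacked into per-(method × climate model) frequency maps
   and averaged, weighted by mean TSS, into a consensus environmental
   suitability surface in [0, 1]. Projections onto future climate layers
   reuse the fitted replicates and yield suitability-change (delta) maps.
2. **Extrapolation detection (ExDet).** Future climates are screened for
   novelty relative to the model training domain: NT1 ≤ 0 measures
   univariate range exceedance (type-1 novelty) and NT2 = D²/D²_max, a
   scaled Mahalanobis distance, flags novel variable *combinations* inside
   the univariate ranges (type-2 novelty when NT2 > 1).
3. **Geographically weighted regression (GWR) and variation partitioning.**
   Z-transformed productivity is regressed on consensus suitability and on
   forward-selected technology covariates with a bisquare kernel
   w = (1 − (d/b)²)² of fixed bandwidth b = 5°, giving one local
   coefficient vector per municipality. Three fits — all predictors,
   suitability only, technology only — partition the adjusted R² into pure
   climate (R²_all − R²_tec), pure technology (R²_all − R²_suit) and shared
   (R²_suit + R²_tec − R²_all) components, globally and per location. The
   improvement of GWR over a global OLS fit is tested with an ANOVA-style F
   statistic using the smoother's effective degrees of freedom, and model
   comparison uses the small-sample AICc with the hat-matrix trace as the
   effective parameter count.

Because the real census and climate services are not bundled, the package
ships a first-class synthetic-landscape generator with a known Gaussian
niche, a latent technology gradient and spatially varying regression
coefficients, so every stage can be validated against ground truth.

## Worked example

```python
import numpy as np
from scipy import stats
from cropsuit import (EnsembleSuitabilityModel, GWRegressor,
                      generate_landscape, variation_partition)
from cropsuit.gwr import fit_ols, gwr_vs_ols_ftest

land = generate_landscape(seed=1)          # 20x20 cells, known truth
enm = EnsembleSuitabilityModel(
    methods=("bioclim", "euclidean", "gower", "mahalanobis", "glm"),
    n_replicates=10, random_state=1,
).fit(land.presence_cells, land.current_env, {"future": land.future_env})

lon, lat = land.grid.cell_centers()
coords = np.column_stack([lon.ravel(), lat.ravel()])
y = land.productivity.ravel()
s = land.suitability.ravel()[:, None]
T = np.column_stack([land.technology[k].ravel()
                     for k in ("workers", "machinery_family", "agrochemicals")])
g_all = GWRegressor(bandwidth=5.0).fit(np.hstack([s, T]), y, coords)
g_s   = GWRegressor(bandwidth=5.0).fit(s, y, coords)
g_t   = GWRegressor(bandwidth=5.0).fit(T, y, coords)
part = variation_partition(g_all.adj_r2_, g_s.adj_r2_, g_t.adj_r2_)
F, p = gwr_vs_ols_ftest(g_all, fit_ols(np.hstack([s, T]), y))
```

Printed output of this run:

```
presences: 96 of 400 cells
consensus vs true suitability: Spearman rho = 0.912
adjusted R2: all=0.981 suit=0.129 tec=0.960
partition: pure climate=0.021 pure technology=0.852 shared=0.108
GWR vs OLS: F=9.02, p=7.75e-28
```

The consensus suitability ranks cells almost exactly as the generating
niche does (ρ = 0.91). On this landscape most productivity signal rides on
the technology covariates (pure technology 0.85), climate contributes a
small pure component plus a shared part, the three components sum to the
full model's adjusted R² = 0.981 by construction, and the strongly
significant F confirms the spatially varying coefficients the generator
built in.

The same chain runs from the shell, handing plain CSV/ESRI-ASCII files
between stages:

```bash
cropsuit run --outdir runs/demo --seed 1      # synth -> enm -> exdet -> gwr -> report
cropsuit synth --outdir runs/demo2 --seed 2   # or stage by stage
```

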