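# mycogrowth

Mature-tree growth as a function of the soil mycorrhizal fungal community
along a nitrogen-mineralization gradient.

Whether mycorrhizal fungi help or hurt an adult tree depends on which taxa
colonize its soil and how much mineral nitrogen that soil supplies: extra
N uptake matters most where N is scarce, while the photosynthate the fungi
charge for it matters everywhere. `mycogrowth` implements a complete,
testable pipeline for quantifying that relationship from field data —
increment cores, per-tree soil assays, and amplicon-based fungal abundance
tables — together with a ground-truth simulator that makes every stage
verifiable without any download.

## The model

Yearly growth is expressed as basal area increment,
BAI_y = π(dbh_y/2)² − π(dbh_{y−1}/2)² (cm²), with historical dbh
reconstructed backwards from the measured diameter and the ring widths.
For each tree *i* and year *y*, for one species at a time:

    BAI_{i,y} ~ LogNormal(D_{i,y}, σ²_{i,y})

    D_{i,y} = α₀ + α₁·ln(dbh) + α₂·Nmin + α₃·BAIS_{i,y−1} + α₄·age
              + α₅·minMayT + Σⱼ βⱼ·Mycoⱼ + Σⱼ γⱼ·Mycoⱼ² + Σⱼ μⱼ·Nmin·Mycoⱼ

    σ²_{i,y} = a + b·ln(dbh)

where Myco₁…₇ are standardized Hellinger abundances of the seven dominant
fungal taxa (selected by PCA on the Hellinger-transformed community
matrix), Nmin is net N mineralization, and BAIS is the per-tree
standardized growth of the previous year. Quadratic terms capture optimum-
type (humped) responses; the Nmin·Myco interactions let each taxon's
association shift along the fertility gradient. Priors are diffuse —
Normal(0, 1000) for α, μ and b, logNormal(1, 1000) for a — and the linear
and quadratic fungal blocks share a Wishart-distributed precision matrix
Ω, so codependence among taxa effects is estimated rather than assumed.
Sampling is adaptive Metropolis-within-Gibbs with a conjugate Wishart step
for Ω; model variants are compared by DIC, and fitted models feed four
posterior simulation sets (per-taxon response curves, high-vs-low
community contrasts, contrasts along the N gradient, and local-vs-average
community comparisons).

## Worked example

```python
from mycogrowth.synthetic import TruthConfig, generate_study
from mycogrowth.pipeline import fit_growth_model
from mycogrowth.model import summarize, dic
from mycogrowth.scenarios import community_contrast

study = generate_study(TruthConfig(n_locations=6, trees_per_location=5,
                                   years=(2002, 2021), seed=7))
data, selection, posterior = fit_growth_model(
    study.growth_table, study.community,
    chains=3, iterations=5000, burn_in=2000, thin=5, seed=7,
)
fit = summarize(posterior, data)
print("selected taxa:", ", ".join(selection.selected))
print(fit.table.loc[["alpha1_ln_dbh", "alpha2_nmin", "beta_" + selection.selected[0]]].round(3))
print(f"R2 = {fit.r2:.2f}   DIC = {dic(posterior, data).dic:.1f}")
contrast = community_contrast(posterior, data, taxon_index=1, seed=7)
print(f"high vs low {contrast.taxon}: {contrast.high[0]:.2f} vs {contrast.low[0]:.2f} cm2/yr,"
      f" significant: {contrast.significant}")
```

prints

```
selected taxa: VTX02, VTX04, VTX01, VTX05, VTX03, VTX06, VTX07
                mean     sd  ci_2.5  ci_97.5  significant
alpha1_ln_dbh  0.514  0.021   0.474    0.557         True
alpha2_nmin    0.124  0.055   0.016    0.234         True
beta_VTX02    -0.090  0.036  -0.160   -0.020         True
R2 = 0.90   DIC = 1817.7
high vs low VTX02: 3.57 vs 7.99 cm2/yr, significant: True
```

Tree size is the strongest growth predictor (α₁ ≈ 0.51 per SD of ln dbh),
growth rises along the N gradient (α₂ > 0, its 95% credible interval
excludes zero), and the first selected taxon is negatively associated with
growth — trees whose soils resemble the five highest-abundance communities
for that taxon are predicted to grow less than half as fast as those
resembling the five lowest, a significant paired contrast. The simulated
study here was generated with known coefficients, so every one of these
numbers can be (and in the test suite is) checked against its truth.

A command-line interface mirrors the library:
`mycogrowth generate | dendro | community | fit | simulate` (see
`mycogrowth --help`); tables are plain TSV and ring series travel as
Tucson `.rwl` files.

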