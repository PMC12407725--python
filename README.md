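# combatpredict

Empirical-Bayes harmonization of multi-site measurement matrices
(location-scale "ComBat" model), with **out-of-sample prediction of site
effects for sites the fit has never seen** — plus the evaluation harnesses
that show the out-of-sample path approximates pooled harmonization, and a
normative-modelling workflow (centile scoring of a new cohort against a
harmonized reference).

It is written for biostatisticians and neuroimaging researchers who need
to remove scanner/site effects from feature tables (e.g. regional cortical
thickness for 62 brain regions across dozens of small acquisition sites)
while preserving biological covariate effects, and in particular for the
common deployment problem: a harmonization model was fitted on data you no
longer have access to, and a *new* site's data must be mapped into the same
harmonized space using only the stored fit.

## The model

For subject *j* at site *i*, feature *g*:

```
Y_ijg = α_g + X_ij β_g + γ_ig + δ_ig ε_ijg ,   ε_ijg ~ N(0, σ_g²) ,   Σ_i n_i γ̂_ig = 0
```

Fitting standardizes the data with least-squares (α̂, β̂, σ̂), estimates
per-site additive/multiplicative effects on the standardized residuals,
shrinks them with parametric empirical Bayes (normal prior on γ,
inverse-gamma on δ², hyperpriors estimated across features within each
site by the method of moments), and removes them:

```
Y*_ijg = (σ̂_g / δ̂*_ig)(Z_ijg − γ̂*_ig) + α̂_g + X_ij β̂_g
```

For a **new** site the same machinery runs from the stored (α̂, β̂, σ̂)
alone: standardize, estimate the new site's effects and its own
across-feature hyperpriors, shrink, adjust. No pooling with the original
data; predicting one of the fit's own sites reproduces the pooled result
exactly. See `docs/methods.md` for the full account.

## Worked example

```python
import combatpredict as cp
from combatpredict.evaluation import loso_rmse

spec = cp.SimulationSpec(n_sites=12, n_features=8, site_sizes=(5, 15), seed=0)
inp, truth = cp.generate_combat_data(spec)

res = cp.CombatModel(inp).fit()          # pooled fit + harmonized data
print(res.summary())

rep = loso_rmse(inp)                     # leave-one-site-out experiment
print(rep[["site", "n", "rmse"]].head(5).to_string(index=False))
print(f"median LOSO RMSE: {rep.rmse.median():.5f}  "
      f"(raw site-effect SD: {truth.site_effect_sd():.4f})")
```

prints

```
ComBat harmonization fit (combatpredict 0.1.0)
  features: 8   subjects: 107   sites: 12
  empirical Bayes: True   reference site: None

        site    n  gamma_bar      tau2   lambda    theta  mean|g*|  mean d*  iters
     site001    5    -0.9375    0.9029     4.34     3.55    0.9401   0.9841      6
     site002    5     0.4825    0.6486     3.55     2.64    0.5962   0.9635      7
     ...
     site012    5    -0.3824    0.3281     2.83     2.04    0.4435   0.9779      7

   site  n     rmse
site001  5 0.007189
site002  5 0.014173
site003  9 0.007139
site004 14 0.014662
site005  9 0.016767
median LOSO RMSE: 0.01052  (raw site-effect SD: 0.0923)
```

Per site, the summary shows the across-feature hyperpriors (γ̄, τ², λ, θ),
the mean magnitude of the shrunken additive effects, the mean
multiplicative scale, and the EB iterations to convergence. The LOSO table
says: harmonizing each held-out site from the stored fit alone lands
within ~0.01 (in feature units) of what the site would have received from
a pooled fit — an order of magnitude below the raw site-effect SD of
0.09, even for sites with only 5 subjects.

Harmonizing a genuinely new site from a saved fit:

```python
res.save("fit.json")
fit = cp.load_fit("fit.json")
effects, Y_new_harmonized = fit.predict_new_site(Y_new, X_new, site_label="siteX")
```

The same workflow is available from the shell:

```
combat-predict simulate --n-sites 12 --n-features 8 --seed 0 --out data.csv
combat-predict fit --data data.csv --covars age,sex,dx_LMCI,dx_AD \
    --out fit.json --harmonized harmonized.csv
combat-predict predict --fit fit.json --data newsite.csv --out new_harmonized.csv
combat-predict evaluate loso --data data.csv --covars age,sex,dx_LMCI,dx_AD \
    --report loso.csv
combat-predict centiles fit-ref|score|compare ...
```

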