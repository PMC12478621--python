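# cmpirt

Multidimensional item response models for **count data** with flexible
dispersion, estimated by marginal maximum likelihood. `cmpirt` implements a
multidimensional two-parameter Conway–Maxwell–Poisson (CMP) response model:
person *i*'s count on item *j* follows a mean-parameterized CMP distribution
whose conditional mean is a log-linear factor model in *L* latent traits,

```
log mu_ij = delta_j + a_j' theta_i,      y_ij | theta_i ~ CMP(mu_ij, nu_j),
theta_i ~ MVN(0, Sigma),   diag(Sigma) = 1.
```

The discrimination vector `a_j` plays the role of factor loadings, `delta_j`
is the item intercept, and the item-specific dispersion `nu_j` lets each item
be conditionally over- (`nu < 1`), under- (`nu > 1`) or equidispersed
(`nu = 1`, the Poisson special case). Typical applications are psychometric
count tests — verbal fluency and divergent-thinking tasks, processing-speed
scores, symptom frequencies — where multidimensionality is realistic and the
Poisson equidispersion assumption is routinely violated.

Exploratory fits are identified by an echelon (upper-triangle) zero
constraint on the discrimination matrix and are otherwise rotationally
indeterminate. The package offers both classical routes to an interpretable
simple structure:

* **rotation** of the estimated discrimination matrix (varimax / oblimin via
  a gradient-projection engine), and
* **lasso regularization** inside the EM algorithm — item-blockwise
  coordinate descent with soft-thresholding yields exact zeros; the penalty
  weight is tuned by BIC over a log-equidistant grid with warm starts, with
  an optional plug-in of the latent trait correlations obtained from the
  oblique rotation ("oblique lasso").

A simulation module generates data under the validation study design
(L ∈ {3,4} traits, m ∈ {3,5} items per trait, slopes equidistant in
[0.2, 0.3], intercepts in [1.5, 3.5], log-dispersions in [−0.8, 0.8],
orthogonal or correlated traits, simple or slightly complex structure) and a
study runner scores all four methods with correct estimation rates (CER),
zero counts, bias/RMSE of intercepts and log-dispersions, and the
rotation-invariant item-association matrix Λ Φ Λ'.

## Worked example

```python
import numpy as np
from cmpirt import FitConfig, SimCondition, generate_dataset, fit
from cmpirt.lasso import sigma_plugin, tune_path
from cmpirt.em import apply_constraints
from cmpirt.metrics import cer

cond = SimCondition(L=3, m=5, N=1000, rho=0.5, structure="simple", seed=7)
Y, truth = generate_dataset(cond)          # 1000 x 15 count matrix

cfg = FitConfig(nodes_per_dim=5, tol=1e-4)
mask = apply_constraints(3, 15)
unp = fit(Y, 3, config=cfg, mask=mask)     # unpenalized exploratory fit
sigma = sigma_plugin(unp.params.slopes)    # trait correlations from oblimin
path = tune_path(Y, 3, sigma=sigma, config=cfg, n_grid=12)
best = path.selected_fit

print(f"loglik {unp.marginal_loglik:.1f}, selected eta {path.etas[path.selected]:.1f}")
print("CER:", cer(best.params.slopes, truth.params.slopes, mask))
print(path.summary()[["eta", "bic", "df", "n_zero_slopes"]].tail(4))
```

Output from this exact run:

```
loglik -42297.7, selected eta 59.7
CER: 0.6904761904761905
            eta           bic  df  n_zero_slopes
9    735.732947  85983.677659  45             27
10  1378.629214  88945.617565  33             39
11  2583.299441  89461.971288  30             42
12  4840.631502  89461.971288  30             42
```

The BIC-selected penalty zeroes 14 of the 42 free discrimination entries;
CER = 0.69 means 69% of the free entries have the correct zero/nonzero
status (a varimax rotation of the same fit, which cannot produce exact
zeros, scores 0.33 here). At the oracle penalty the path reaches CER = 1.0.

The same pipeline is available from the shell:

```bash
cmpirt simulate -L 3 -m 5 -N 1000 --rho 0.5 --seed 7 --out-prefix demo
cmpirt fit demo_counts.csv -L 3 --penalty lasso --sigma-mode oblique_plugin
cmpirt tune demo_counts.csv -L 3 --sigma-mode oblique_plugin --out-prefix demo
cmpirt study study.yaml --out results.tsv
```

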