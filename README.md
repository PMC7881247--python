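# pklreg

Shrinkage estimation for Poisson regression under multicollinearity.

## The problem

Count outcomes — damage locations on aircraft, software defects, disease
occurrences — are modelled by the Poisson regression model (PRM):
y_i ~ Poisson(μ_i) with log link μ_i = exp(x_i′β). The maximum-likelihood
estimator (PMLE) is found by Fisher scoring and has asymptotic covariance
(X′ŴX)⁻¹ with Ŵ = diag(μ̂_i). When regressors are nearly collinear the
smallest eigenvalues λ_i of X′ŴX collapse and the MLE risk

    MSE(β̂ᴾᴹᴸᴱ) = Σᵢ 1/λᵢ

explodes. Writing α̂ = Q′β̂ in the eigenbasis Q of X′ŴX, biased estimators
trade a little bias for a large variance reduction by shrinking each
canonical coordinate:

| estimator | canonical factor | biasing-parameter rule |
|---|---|---|
| ridge (PRRE) | λᵢ/(λᵢ+k) | k = 1/max α̂ᵢ² |
| Liu (PLE) | (λᵢ+d)/(λᵢ+1) | d = max(0, min (α̂ᵢ²−1)/(1/λᵢ+α̂ᵢ²)) |
| Kibria–Lukman (PKLE) | (λᵢ−k)/(λᵢ+k) | kᵢ = λᵢ/(1+2λᵢα̂ᵢ²); k₁ = min kᵢ, k₂ = √k₁ |

The Kibria–Lukman factor shrinks strictly more than ridge at the same k; its
per-coordinate k minimizes the closed-form risk

    MSE(α̂ᴾᴷᴸᴱ) = Σᵢ (λᵢ−k)²/(λᵢ(λᵢ+k)²) + 4k² Σᵢ α̂ᵢ²/(λᵢ+k)².

The package provides the four estimators (PKLE with both the k₁ and √k₁
rules), their scalar and matrix risks with dominance-condition reports, a
Monte Carlo framework that generates designs with controlled pairwise
correlation ρ² via x_ij = √(1−ρ²) w_ij + ρ w_{i,p+1}, and a CSV-driven
comparison workflow for real datasets.

## Worked example

```python
from pklreg import make_fixture, fit_report

data, beta = make_fixture("collinear", seed=1)   # n=100, 3 regressors, rho=0.99
print(fit_report(data).to_text())
```

```
        param   const      x1      x2      x3     mse
PMLE      NaN  0.4196  0.2112  0.7962  0.7359  0.1846
PRRE   0.8645  0.4199  0.2408  0.7867  0.7159  0.1585
PLE    0.0000  0.4199  0.2449  0.7853  0.7131  0.1553
PKLE1  0.4323  0.4199  0.2421  0.7864  0.7147  0.1575
PKLE2  0.6575  0.4200  0.2571  0.7815  0.7046  0.1464

eigenvalues of X'WX: 18278.9604, 161.0998, 17.8625, 8.1753
condition number: 47.2851
```

The condition number √(λ_max/λ_min) ≈ 47 flags harmful collinearity. Each
row shows an estimator's selected biasing parameter, its coefficients, and
its plug-in risk (the closed-form MSE evaluated at the fitted spectrum):
the MLE has the largest risk (0.1846) and the Kibria–Lukman estimator with
the square-root rule (PKLE2) the smallest (0.1464), while all coefficient
signs agree. The true generating coefficients here were
(0.5, 0.577, 0.577, 0.577).

The same report is available from the shell for any CSV with a count
response column:

```sh
pklreg fit mydata.csv --response y --format json
pklreg simulate --n 100 --p 4 --rho 0.99 --intercept 0 --reps 1000 --seed 7 --out sim.csv
pklreg risk --lambdas 1,2,4 --alpha 0.5,0.2,0.1 --k 0.3
pklreg check --versus prre --lambdas 1,2 --alpha 0.1,0.1 --k 0.5
```

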