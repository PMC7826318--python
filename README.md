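# ldefit

Latent differential equation (LDE) modeling of multivariate, multi-person
time series — for researchers studying self-regulating processes (daily
stress, affect, physiological cycles) as damped linear oscillators from
intensive longitudinal data such as daily diaries.

## The model

A damped linear oscillator relates a latent process *f* to its time
derivatives:

    f''(t) = η f(t) + ζ f'(t) + e(t),    e ~ N(0, V_e)

η < 0 is the *frequency* parameter and ζ the *damping* parameter; together
they imply the oscillation wavelength λ = 2π / √(−η − ζ²/4).

Estimation works on a **time-delay-embedded** (TDE) data matrix: each
person's series is cut into overlapping length-*D* windows which are
row-bound, and the per-series matrices are column-bound (window lag τ = 1,
so a window spans (D−1)·Δt time units — which must stay below λ for the
dynamics to be identifiable). The latent derivatives load on the embedded
columns through a *fixed* centered Taylor basis: for lag offset *o* and
derivative *k*, the loading is oᵏ/k! (scaled by a free series loading
l_s for indicators beyond the first). Two structural variants are
provided:

* **SOLDE** (second order): latents (f, f', f''), with f'' regressed on
  (f, f') with coefficients (η, ζ);
* **FOLDE** (constrained fourth order): adds f''' and f'''', each higher
  derivative regressed on the two below it with the *same* (η, ζ) —
  three structurally tied copies of the oscillator equation, at the cost
  of exactly two extra free parameters (two added residual variances), so
  SOLDE-vs-FOLDE likelihood-ratio tests have 2 degrees of freedom.

Person-specific equilibria enter as fixed-effect latent intercept means
m_j; estimation is full-information maximum likelihood (each embedded row
contributes the normal density of its observed cells only, so missing data
are handled under the missing-at-random assumption), with
uniformly-perturbed restarts until the optimum is confirmed. Because the
frequency estimate η̂ is typically unstable at small embedding dimensions,
the package scans a range of *D* and selects the dimension at which η̂
stabilizes (the "reversed elbow"); it also computes regression and
Bartlett factor scores for the latent derivatives and renders phase-plane
vector fields of the estimated dynamics.

A built-in simulator generates panels from the exact closed-form
oscillator solution with person-varying equilibria and measurement noise,
emulating a 41-person, 56-day, 3-indicator daily-diary design, so every
stage is testable end to end.

## Worked example

```python
import ldefit as lf

panel = lf.simulate_panel(lf.SimConfig(seed=20))   # 41 persons x 56 days x 3 series
tde = lf.embed_panel(panel, D=6)                   # 2091 rows x 18 columns
solde = lf.LDEModel(tde, order=2).fit(lf.FitOptions(seed=1))
folde = lf.LDEModel(tde, order=4).fit(lf.FitOptions(seed=1))
print(folde.summary())
lrt = lf.likelihood_ratio_test(solde, folde)
print(f"LRT: chi2 = {lrt.statistic:.4f}, df = {lrt.df}, p = {lrt.pvalue:.4g}")
```

prints

```
FOLDE latent differential equation model (order 4, D=6, P=3)
====================================================================
persons:    41    embedded rows:   2091    free parameters: 54
log-likelihood: -56379.7949    -2lnL: 112759.5898
converged: True    attempts: 2    |grad|: 2.03e-05
--------------------------------------------------------------------
parameter         estimate       std err
eta             -0.0104104    0.00234171
zeta            -0.0375215     0.0282365
l_2               0.901962   0.000749537
l_3                1.10275   0.000827188
V_f                4.02081      0.129001
V_df             0.0388038    0.00183657
C_f_df          -0.0916534     0.0114148
V_e_d2         9.35762e-14            --
V_e_d3         2.42817e-08            --
V_e_d4           0.0132986    0.00387032
u_series_1         1.00595     0.0143506
u_series_2        0.988095     0.0139544
u_series_3         0.98022     0.0145407
--------------------------------------------------------------------
wavelength: 62.649 time units (2*pi / sqrt(-eta - zeta^2/4))
person equilibria: 41 fixed-effect means (range 3.56 .. 26.2)
note: SEs are naive — embedded rows treated as independent despite window overlap.
LRT: chi2 = 4.6593, df = 2, p = 0.09733
```

The generating oscillator had η = −0.00997, ζ = −0.05 (wavelength 65.0
days): the fourth-order fit recovers the frequency within ~4%, the
wavelength within ~4%, and the two series loadings (0.9, 1.1) almost
exactly. The structural residual variances of f'' and f''' sit on the
zero boundary — the simulated latent dynamics are an exact oscillator —
so their standard errors are reported as unavailable. The 2-df
likelihood-ratio test does not prefer the fourth-order model here, as
expected when the second-order model is true.

The same pipeline is scriptable from a shell:

```sh
lde --seed 1 --out run1 simulate
lde --seed 1 --out run1 scan  --input run1/panel.csv --order 4 --d-min 5 --d-max 9
lde --seed 1 --out run1 fit   --input run1/panel.csv -D 6
lde --seed 1 --out run1 field --input run1/panel.csv -D 6
```

`scan` writes a per-dimension CSV of (η, ζ, wavelength, fit) with the
selected elbow dimension and a three-panel plot; `fit` writes both model
fits, the likelihood-ratio test and a text report; `field` writes the
binned phase-plane vector field and its quiver plot.

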