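# saltol — quantile analysis of plant salinity tolerance

`saltol` is a Python library for analysing two-condition (saline /
non-saline) field-trial trait tables with quantile methods, built for
plant scientists and biostatisticians who care about the *tails* of the
yield distribution — the high-yielding, highly salt-tolerant accessions —
rather than only its mean.

It implements four connected analyses:

1. **Univariate quantile regression of yield on plant traits.**
   The conditional quantile model is Q_y(p | x) = xᵀβ(p); coefficients
   minimise the pinball (check) loss ρ_p(u) = u(p − 𝟙[u < 0]), solved
   exactly as a linear program.  Both irrigation conditions enter one
   model through a dummy D (1 = non-saline) and its interactions with
   every trait, so main effects are saline-condition effects and
   interactions are the between-condition differences.  Confidence bands
   come from rank-score test inversion (iid and non-iid score variants),
   which avoids estimating the error density and behaves well for
   n < 1000.

2. **The stress-weighted performance index** SWP = y_s / √y_c (saline
   yield over the square root of control yield, g^{1/2}/m), regressed on
   saline-condition traits over a grid of quantile levels.

3. **Conditional + marginal quantile selection**: accessions strictly
   above the fitted no-intercept conditional quantile line of y_s on y_c
   at level p₁ *and* above the marginal empirical quantile of y_s at
   level p₂ (defaults 0.85 and 0.90) form the "top" set.

4. **Bivariate quantile regression via directional quantile envelopes.**
   For directions s on the unit circle, D(p) = ⋂_s H(s, Q(p, s)) with
   H(s, q) = {y : sᵀy ≥ q} is a discretised Tukey-depth contour.  Each
   projected response sᵀy is modelled as a truncated-power cubic spline
   in a single trait, giving covariate-conditional envelopes D̂(p | x),
   the bivariate median (vertex average of the median envelope at p*,
   the largest non-empty level in (1/3, 1/2]), and from it the predicted
   index curve ŜWP(x) = ŷ_s / √ŷ_c with bands from the inner (p = 0.25)
   and outer (p = 0.1) envelopes.

A synthetic-data generator produces barley-like two-condition tables from
a heteroscedastic location-scale model whose conditional-quantile
coefficients are known analytically, so every stage can be validated
against ground truth.

## Worked example

```python
from saltol import (
    SyntheticConfig, generate_trait_table, build_condition_design,
    rankscore_ci, compute_swp, select_top_accessions, swp_curve,
)

table = generate_trait_table(SyntheticConfig(seed=3))   # 404 accessions x 2 conditions
X, y = build_condition_design(table)                    # 808 x 12 interaction design

for p in (0.5, 0.9):
    fit = rankscore_ci(X, y, p, coef_indices=[5])       # grain-number slope
    lo, hi = fit.ci_lower[5], fit.ci_upper[5]
    print(f"grain number per ear, p={p}: "
          f"{fit.coefficients[5]:.3f} g/m2 per grain  (95% CI {lo:.3f} to {hi:.3f})")

swp = compute_swp(table)
sel = select_top_accessions(swp, p1=0.85, p2=0.9)
print("selection:", sel["category"].value_counts().to_dict())

saline = table[table.condition == "saline"].set_index("accession_id").loc[swp.accession_id]
curve = swp_curve(swp[["y_s", "y_c"]].to_numpy(),
                  saline["grain_number"].to_numpy(), x_grid=[7.0, 11.0, 15.0])
print(curve[["x", "swp_hat", "band_lower", "band_upper", "p_star"]].round(2).to_string(index=False))
```

prints

```
grain number per ear, p=0.5: 7.044 g/m2 per grain  (95% CI 6.036 to 8.066)
grain number per ear, p=0.9: 9.034 g/m2 per grain  (95% CI 5.260 to 11.814)
selection: {'other': 325, 'tolerant_only': 56, 'top': 23}
   x  swp_hat  band_lower  band_upper  p_star
 7.0     6.66        4.88        9.99    0.46
11.0     9.66        7.90       14.01    0.45
15.0    11.40        9.61       15.18    0.45
```

Reading this: each additional grain per ear raises *median* saline-condition
yield by ≈ 7.0 g/m², but raises the 90th percentile by ≈ 9.0 g/m² — the
trait matters more for high-yielding accessions, which a mean regression
would average away (the generator plants exactly this heteroscedastic
effect).  Twenty accessions clear both the 85th conditional and 90th
marginal quantile and are flagged "top".  The bivariate prediction says an
accession with 15 grains per ear has a predicted SWP of ≈ 11.4 g^{1/2}/m
versus ≈ 6.7 at 7 grains per ear, with envelope bands quantifying the
spread of the joint (y_s, y_c) distribution at each trait value; p* near
0.45–0.46 is the depth of the fitted median envelope.

## Command line

Every stage is also a subcommand (`saltol simulate|uqr|swp|select|envelope|bivreg|all`):

```bash
saltol all --seed 1 --outdir results/run1            # synthetic end-to-end run
saltol select --input mytrial.csv --p1 0.85 --p2 0.9 --outdir results/sel
```

Outputs are tidy CSVs (coefficient profiles, selection categories,
envelope vertices, SWP curves) plus optional PNG plots (`--plots`).

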