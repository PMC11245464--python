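# cfn3 — analytic maximum likelihood for 3-leaf CFN trees

`cfn3` solves the maximum-likelihood branch-length estimation problem for an
unrooted 3-leaf phylogenetic tree under the Cavender–Farris–Neyman (CFN)
model — the two-state symmetric substitution model with states −1 (purine)
and +1 (pyrimidine) and a uniform root — **in closed form**, including every
boundary case. It is aimed at people studying the geometry of maximum
likelihood in phylogenetics (boundary estimates, long-branch pathologies,
semi-algebraic model constraints) and at anyone who needs an exact,
instantaneous 3-taxon CFN estimator to validate numerical pipelines against.

## The model and the estimator

Each branch `e` carries a length `d_e ∈ [0, ∞]` (expected substitutions per
site), reparameterized by the Hadamard parameter `θ_e = exp(−2 d_e) ∈ [0, 1]`,
which equals the correlation of the states at the branch endpoints. Data are
`N` aligned iid sites summarized by the 8-pattern site-frequency vector `s`,
or equivalently the 4 split-class counts `s̄`. The sufficient statistics are
the per-pair agreement counts `M⁺_ij, M⁻_ij` and correlations

    B_ij = (M⁺_ij − M⁻_ij) / N,

which consistently estimate the Fourier coordinates `θ_i θ_j` of the model.
Let `D = {x ∈ (0,1)³ : x_i x_j < x_k for all distinct i, j, k}` — the set cut
out by the model's semi-algebraic constraints (positivity plus the triangle
inequality on distances, in disguise). For generic data (every split class
observed; the `B_ij` nonzero and distinct) the set of global maximizers of
the log-likelihood over `[0,1]³` is exactly one of:

| condition on `B` | maximizer set |
| --- | --- |
| `B ∈ D` | the single interior tree `θ* = (√(B₁₂B₁₃/B₂₃), √(B₁₂B₂₃/B₁₃), √(B₁₃B₂₃/B₁₂))` |
| all `B > 0`, one product constraint fails | a single boundary point with one `θ = 1` (zero-length branch) |
| exactly one `B > 0` | the curve `{θ_k = 0, θ_i θ_j = B_ij}` (one infinite branch) |
| all `B < 0` | the independence sets (≥ 2 coordinates zero); likelihood flat at `−N log 8` |

So the MLE is a biologically plausible tree *iff* the empirical correlations
satisfy the model's semi-algebraic constraints — and which constraint fails
determines exactly how estimation degenerates.

## Worked example

```sh
cfn3 estimate --counts 17,5,27,5,16,5,19,6
```

prints (abridged; the counts are in binary pattern order `(−,−,−) … (+,+,+)`):

```json
{
  "regime": "CURVE_THETA_ZERO",
  "theta": [0.31622776601683794, 0.0, 0.31622776601683794],
  "branch_lengths": [0.5756462732485114, "inf", 0.5756462732485114],
  "constraints": [{"fix": 2, "value": 0.0}, {"product": [1, 3], "value": 0.1}],
  "loglik": -207.4433174833479,
  "B": {"B12": -0.06, "B13": 0.1, "B23": -0.12}
}
```

Two of the three pair correlations are negative (`B12 = −0.06`,
`B23 = −0.12`), so no tree with finite branches can fit: the likelihood is
maximized on the whole curve `θ₂ = 0, θ₁θ₃ = 0.1` — leaf 2 sits at infinite
distance and only the product of the other two parameters is identifiable.
The reported `theta` is the balanced representative `(√0.1, 0, √0.1)`.

From Python the same computation is:

```python
from cfn3 import read_counts, solve_mle
sol = solve_mle(read_counts("17,5,27,5,16,5,19,6"))
sol.regime.value      # 'CURVE_THETA_ZERO'
sol.constraints       # ({'fix': 2, 'value': 0.0}, {'product': [1, 3], 'value': 0.1})
sol.max_loglik        # -207.4433174833479
```

The `examples/` directory holds short narrative scripts: the two published
worked data points (`01`), simulation + parameter recovery (`02`), and the
closed-form vs numerical-oracle cross-check (`03`). The CLI also provides
`simulate`, `loglik`, `oracle` and `distances` subcommands; every estimate
can be cross-checked against an independent grid-plus-quasi-Newton maximizer
(`cfn3 oracle`).

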