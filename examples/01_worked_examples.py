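"""The two published 100-site data points, solved in closed form.

Both examples show maximum likelihood failing to return a tree with
biologically plausible branch lengths -- for two different geometric reasons:
a negative pair correlation (an apparently infinite branch) and a violated
triangle-type product constraint (a zero-length branch).
"""

from cfn3 import cfn_distances, compute_B, in_region_D, read_counts, solve_mle, to_newick

for label, counts in (
    ("one positive correlation -> theta2 pinned to 0 (infinite branch)",
     "17,5,27,5,16,5,19,6"),
    ("all correlations positive but B12*B13 > B23 -> theta1 pinned to 1 (zero branch)",
     "21,12,9,8,7,11,17,15"),
):
    s = read_counts(counts)
    b = compute_B(s)
    sol = solve_mle(s)
    print(f"--- {label}")
    print(f"counts          : {s.s}  (N = {s.N})")
    print(f"B (correlations): B12={b.b[0]:+.2f}  B13={b.b[1]:+.2f}  B23={b.b[2]:+.2f}")
    print(f"in interior D?  : {in_region_D(b).in_D}  "
          f"(failed: {', '.join(in_region_D(b).failed_inequalities) or 'none'})")
    print(f"regime          : {sol.regime.value}  singleton={sol.is_singleton}")
    print(f"maximizer set   : {sol.constraints}")
    print(f"representative  : theta = {sol.theta.round(6)}")
    print(f"tree            : {to_newick(sol)}")
    print(f"CFN distances   : {cfn_distances(b).round(6)}  (inf = B <= 0)")
    print(f"max log-lik     : {sol.max_loglik:.4f}")
    print()

print("The B statistics estimate the pairwise state correlations theta_i*theta_j;")
print("whether they satisfy the model's semi-algebraic constraints decides whether")
print("the MLE is a tree with positive finite branch lengths or a boundary case.")
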