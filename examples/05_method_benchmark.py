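"""Small-scale benchmark of the four estimation methods.

Replicates simulate -> fit -> score a handful of times (the shipped
acceptance run uses 100 replicates) and prints the bias/MSE quantile
table for the group means and their variance.
"""

import qpcrmiss as q

res = q.run_benchmark(
    methods=("mean", "si", "direst", "mi"),
    n_reps=10,  # increase to 100 for publication-grade quantiles
    seed=0,
    links=("logit",),
)
print(res.markdown())
print(
    f"\n{res.n_reps} replicates, {res.n_failed} failed fits, "
    f"{res.n_gene_exclusions} per-replicate gene exclusions "
    "(genes with an all-non-detect sample type are dropped from that replicate)"
)
# Expect: mean imputation biased low on theta and sigma2_theta; SI
# unbiased on theta but low on sigma2_theta; DirEst and MI accurate on
# both, with theta-MSE tracking sigma2/m.
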