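"""Shared-label vs per-pair permutation schemes.

The legacy scheme reshuffles cell labels independently for every ordered
(sender, receiver) cell-type pair: N^2 x P shuffle evaluations. The shared
scheme draws P shuffles once and reuses them for all pairs: P evaluations,
an N^2-fold reduction (900-fold at N = 30 cell types, P = 1000). Both are
run here on one dataset and their significance calls compared.
"""

from lrcomm import (
    CCCConfig,
    benchmark_spec,
    load_toy_knowledgebase,
    run_ccc,
    simulate_expression,
)

kb = load_toy_knowledgebase()
ds = simulate_expression(benchmark_spec(kb, seed=0, n_cells_per_type=167))
n = len(ds.cell_types)

shared = run_ccc(ds, kb, CCCConfig(n_permutations=1000, seed=1))
per_pair = run_ccc(ds, kb, CCCConfig(n_permutations=1000, seed=2,
                                     permutation_scheme="per_pair"))

print(f"{ds.n_cells} cells, {n} cell types, P = 1000 permutations")
print(f"shared scheme:   {shared.n_shuffle_evaluations:>9,d} shuffle evaluations")
print(f"per-pair scheme: {per_pair.n_shuffle_evaluations:>9,d} shuffle evaluations"
      f"  (ratio = N^2 = {per_pair.n_shuffle_evaluations // shared.n_shuffle_evaluations})")

key = ["sender", "receiver", "ligand", "receptor"]
s = shared.table.set_index(key)["significant"]
p = per_pair.table.set_index(key)["significant"]
sig = s[s]
agreement = 100 * p.loc[sig.index].mean()
print(f"\nshared-scheme significant events: {len(sig)}")
print(f"also significant under per-pair:  {agreement:.1f}%")
print("\nThe schemes test the same null; residual disagreement comes from "
      "events sitting on the p = 0.05 boundary under two independent "
      "Monte-Carlo null samples.")
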