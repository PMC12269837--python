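# lrcomm

Cell-cell communication (CCC) analysis for single-cell expression data,
with differential signaling between samples, pathway-activity summaries
via reporter genes, and interface metrics for AlphaFold-Multimer
predictions of candidate ligand-receptor complexes.

## Who this is for

Given a cells × genes log-normalized expression matrix, per-cell cell-type
labels, and a knowledgebase of ligand-receptor (L-R) pairs grouped into
signaling pathways, `lrcomm` answers: *which cell types are talking to
which, through which ligand-receptor pairs, and how does that change
between conditions?* A companion module scores whether a candidate L-R
pair is likely to interact physically, from the predicted-aligned-error
(PAE) matrices and coordinates produced by AlphaFold-Multimer.

## The model

For sender type *s*, receiver type *r*, and an L-R pair, the interaction
score is

```
score = ln(1 + mean_ligand(s) · mean_receptor(r))
```

on log-normalized expression (means over all cells of a type, zeros
included). Significance comes from a permutation test: the cell-type label
vector is shuffled P times (default 1000), null scores are recomputed per
shuffle, and

```
p = (1 + #{null ≥ observed}) / (1 + P)
```

Shuffles are drawn **once and shared across all N² sender-receiver pairs**
— P shuffle evaluations instead of the legacy N²×P (a 900-fold reduction
at N = 30, P = 1000); the legacy per-pair scheme is kept for validation
and both expose evaluation counters. Events whose ligand (receptor) is
detected in fewer than 10 % of sender (receiver) cells are filtered as
noise; exactly 10 % passes.

Between two samples, events are compared by `log2fc =
log2(score_exp/score_ctrl)` and `abs_diff = score_exp − score_ctrl`;
dysregulated events are those significant in the experimental sample but
not the control with `abs_diff > 2` (`> 1` when the event is on in exactly
one sample). For predicted complexes, five metrics — LIS (mean inverted
PAE, `(12 − PAE)/12`, over inter-chain residue pairs with PAE ≤ 12 Å),
contact-restricted cLIS (Cβ–Cβ ≤ 8 Å), LIS×cLIS, ipTM and Model
Confidence — are calibrated against negative controls at 10 % FPR; a pair
is positive when ≥ 2 of 5 metrics pass. See `docs/methods.md` for the full
account.

## Worked example

A packaged 50-pair toy knowledgebase and a seeded simulator make the whole
pipeline runnable out of the box (`examples/01_run_ccc.py`):

```python
from lrcomm import (CCCConfig, benchmark_spec, load_toy_knowledgebase,
                    run_ccc, simulate_expression, summarize_celltypes)

kb = load_toy_knowledgebase()
ds = simulate_expression(benchmark_spec(kb, seed=1, n_cells_per_type=200))
result = run_ccc(ds, kb, CCCConfig(n_permutations=1000, seed=1))
sig = result.table[result.table["significant"]]
print(sig.nlargest(5, "score")[["sender", "receiver", "ligand", "receptor",
                                "pathway", "score", "p_value"]])
```

prints

```
sender receiver ligand receptor   pathway    score  p_value
 type1    type2   Pvf1      Pvr       PVR 2.402682 0.000999
 type0    type1    sli    robo2 Slit-Robo 2.303433 0.000999
 type5    type0   Wnt6      fz4       Wnt 2.236596 0.000999
 type3    type1    sli    robo2 Slit-Robo 2.186895 0.000999
 type0    type4    sli    robo1 Slit-Robo 2.177470 0.000999
```

Each row is one significant communication event: e.g. cell type 1 signals
to cell type 2 through the Pvf1 ligand and Pvr receptor with interaction
score 2.40; `p = 0.000999 = 1/1001` means the observed score exceeded all
1000 permutation nulls. `summarize_celltypes(result.table)` then totals
incoming/outgoing scores per cell type (the scatter-plot table).

The other examples cover two-sample comparison (`02`), reporter-gene
pathway activity (`03`), interface metrics with FPR calibration (`04`),
and the permutation-scheme comparison (`05`): run any of them as
`python examples/<name>.py`.

A thin CLI wraps the same library for shell use:

```
lrcomm simulate --seed 1 --out sim
lrcomm run --matrix sim/matrix.mtx --genes sim/genes.txt \
           --cells sim/cells.txt --metadata sim/metadata.tsv --out results
lrcomm compare --matrix ... --exp tumor --ctrl wildtype --out results
lrcomm lis --pae model0.json --structure model0.cif --out results
lrcomm render --results results/ccc_results.tsv --kind chord --out figures
```

Every run writes TSV tables plus a `manifest.json` echoing inputs,
configuration and outputs; figures always come with their underlying data
table.

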