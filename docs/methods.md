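# Methods

## Cell-cell communication model

The unit of inference is a *communication event*: an ordered pair of cell
types (sender, receiver) together with one ligand-receptor (L-R) pair from
a curated knowledgebase. On log-normalized expression (natural `log1p` of
library-size-scaled counts), the event's interaction score is

    score(s, r, L-R) = ln(1 + m_L(s) * m_R(r))

where `m_L(s)` is the arithmetic mean of the ligand's expression over all
cells of the sender type (zeros included) and `m_R(r)` the receptor mean
over receiver cells. The score is zero exactly when either side is silent,
strictly increasing in both means, and compresses large products the same
way the input normalization does. Means-then-log1p is the implemented
order of operations.

The model assumes cell types are given (no clustering or annotation is
performed), that a single ligand gene and single receptor gene represent
the interaction (no multi-subunit complexes), and that autocrine signaling
(sender = receiver) and homophilic pairs (ligand gene = receptor gene, as
for adhesion molecules) are meaningful and included.

### Permutation significance

A high score can reflect broadly expressed genes rather than cell-type-
specific signaling. Specificity is tested against a null obtained by
shuffling the cell-type label vector: each shuffle preserves group sizes,
group means are recomputed under the shuffled labels, and the null score
is the same log1p-product. With P shuffles the p-value is

    p = (1 + #{null >= observed}) / (1 + P)

one-sided (enrichment), with the add-one convention so p is never zero
and ties count toward the null (conservative). Defaults: P = 1000,
significance at p < 0.05 (exclusive).

Two schemes generate the shuffles:

* **shared** (default): P label shuffles are drawn once and reused for
  every ordered (sender, receiver) pair — P shuffle evaluations in total.
  This mirrors the fixed permutation sets used by gene-set enrichment
  methods: the null for each pair is marginally identical to independent
  shuffling; only the (irrelevant) dependence *across* pairs changes.
* **per_pair** (legacy): P fresh shuffles for each of the N² ordered
  cell-type pairs, N² × P evaluations. Kept for validation and
  benchmarking; both implementations expose an evaluation counter, whose
  ratio is exactly N² (900 at N = 30, P = 1000).

Group means under a batch of shuffles are computed as one indicator-matrix
product per cell type per batch (a (P × cells) mask times the cells × genes
panel), so an entire null distribution is a handful of BLAS calls. A test
hook accepts explicit label assignments (identity shuffles must reproduce
the observed scores, giving p = 1 everywhere), and an exhaustive mode
enumerates all distinct label assignments for tiny instances, where the
null can be checked against brute-force enumeration.

### Detection filter

Events whose ligand is detected (expression strictly > 0) in fewer than
10 % of sender cells, or whose receptor is detected in fewer than 10 % of
receiver cells, are flagged as filtered and excluded from significance.
The boundary is exclusive: exactly 10 % is retained. The filter is
evaluated on the observed labels only — recomputing it inside permutations
would change the meaning of the null. The threshold is configurable
(`min_detection_fraction`, default 0.10).

## Differential communication

Per-sample CCC runs are combined over the union of their events; an event
missing on one side (genes undetected there, or filtered) enters with
score 0 and p-value 1, which makes on/off events visible rather than
silently dropped. Two statistics are reported: `log2fc = log2(score_exp /
score_ctrl)` (NaN when either score is zero — never ±inf) and `abs_diff =
score_exp − score_ctrl` (always defined; the primary selection statistic).
An event is *on/off* when exactly one score is zero.

Default selection rule for dysregulated events: significant in the
experimental sample (p < 0.05) but not in the control (p ≥ 0.05), and
`abs_diff > 2`, or `> 1` for on/off events. The rule is direction-aware
(`direction="up"` selects experimental-above-control; `"down"` mirrors
it; `"both"` uses |abs_diff|). Optional conjunctive filters restrict
senders to a set of cell types or require the ligand to be in a
user-supplied DEG list. DEG lists are taken as-is; no internal
differential-expression testing is performed.

## Pathway activity summaries

Reporter genes — downstream transcriptional targets — indicate pathway
activity in the receiving cell independently of L-R co-expression. The
package exposes per-role (ligand / receptor / core / reporter) cell-type ×
gene mean-expression matrices and a dot-plot table giving, per (pathway,
cell type), the highest-expressed annotated receptor and reporter. "Highest
expressed" is the maximum over the pathway's annotated genes of the
per-cell-type *mean* (not a per-cell maximum), consistent with every other
summary operating on type-level means. Argmax ties break lexicographically
by gene symbol for determinism.

## Interface metrics for predicted complexes

For a two-chain AlphaFold-Multimer prediction with PAE matrix (Å) over the
concatenated residues:

* inverted PAE is linear and clamped: `(12 − PAE)/12` for PAE ≤ 12, else 0;
* **LIS** is the mean inverted PAE over all inter-chain residue pairs with
  PAE ≤ 12 Å. Both off-diagonal blocks enter (PAE is asymmetric). Zero
  when no pair qualifies;
* **cLIS** restricts the mean to pairs in physical contact, Cβ–Cβ ≤ 8 Å
  (Cα for glycine), and by default also requires PAE ≤ 12 (a
  `require_pae=False` flag gives the distance-only variant);
* **LIS × cLIS**, **ipTM** (reported by the predictor) and **Model
  Confidence** (`0.8·ipTM + 0.2·pTM`) complete the five metrics. Metrics
  are averaged over a prediction's models; the product metric averages the
  per-model products.

Residues lacking a Cβ (other than glycine) raise an error rather than
silently falling back to Cα, to surface malformed inputs. PAE is read from
the JSON layout of common AlphaFold-Multimer runners, coordinates from
mmCIF or PDB via gemmi.

Classification calibrates, per metric, the smallest cutoff t with
`#{negatives > t} ≤ fpr·n` (the empirical (1−fpr) quantile, ties resolved
upward; default fpr = 0.10, at least 10 negatives required), guaranteeing
the strict-exceedance false-positive rate on the calibration set. A pair
is positive when at least 2 of 5 metrics meet their cutoff (boundary
inclusive). Caveat: if a metric's negative distribution has a point mass
at the selected cutoff (e.g. cLIS exactly 0 for contact-free negatives),
boundary-inclusive passing is non-conservative for that metric —
calibration sets should contain realistically noisy negatives. Note also
that LIS is not monotone under arbitrary element-wise PAE increases: an
entry crossing the 12 Å cutoff leaves the local set and can raise the mean
of the survivors; monotonicity holds while the local set is unchanged.

A simpler screening rule for large scans calls a pair a putative
interaction when mean ipTM ≥ 0.4551 or mean LIS ≥ 0.2471 (boundaries
inclusive; thresholds configurable).

## Synthetic data

The expression simulator emits log-normalized values directly: background
is zero-inflated lognormal noise — Bernoulli(1 − dropout) detection times a
lognormal draw with mean `background_mean` (default 0.5 log-units, sigma
0.5) — and each planted event adds a constant effect (log-units) to the
ligand in all sender cells and the receptor in all receiver cells.
Defaults mirror a typical benchmarking dataset: 6 cell types × 1167 cells
(~7,000 cells), 70 % dropout (≈30 % background detection, comfortably
above the 10 % filter), and 20 planted events with effect sizes spanning
0.5–3.0 drawn on knowledgebase pairs. Everything is bit-for-bit
reproducible under a seed.

What the simulator does *not* model: count-level noise (no
negative-binomial sampling, no library-size variation), gene-gene
correlation, or realistic mean-variance relationships. Passing tests
therefore demonstrate the correctness of the scoring, permutation,
filtering and selection machinery under controlled signal — not
performance on real single-nuclei data, where detection fractions,
cluster imbalance and ambient contamination are harsher.

The structure simulator builds idealized point clouds: interface residue k
of each chain sits 4 Å from its partner, consecutive positions 30 Å apart,
non-interface residues of chain 2 displaced 1000 Å — so the contact set is
exactly the interface diagonal and expected LIS/cLIS have closed forms
((12 − interface PAE)/12 at full coverage). No realistic protein geometry
is attempted; the point is to exercise the distance- and PAE-cutoff logic
exactly.

## Numerical and design choices

* Matrices are handled densely (float64): the pipeline needs only group
  means and detection fractions over a gene panel, which at tool scale
  fits comfortably; MatrixMarket input is densified on load.
* The normalization scale factor defaults to counts-per-10k before log1p,
  the common single-cell convention; pre-normalized matrices are accepted
  verbatim (`normalize=False`, the default of the loader).
* Cell and gene identifiers match as exact, case-sensitive strings; no
  ortholog or identifier mapping is performed.
* Knowledgebase serialization is tab-delimited text with `|`-joined list
  fields; (ligand, receptor) pairs must be unique; ranks are restricted to
  {high, moderate, low} and component roles to {ligand, receptor, core,
  reporter}.
* The packaged 50-pair, 12-pathway knowledgebase is a synthetic toy (gene
  symbols follow *Drosophila* naming for familiarity); a real curated
  table loads through the same reader and schema.
* Problem sizes in the test suite: the scheme-agreement check runs at
  ~7,000 cells / 6 types / P = 1000 (plus a 1,000-cell variant), sizes at
  which a full dual-scheme run takes seconds to tens of seconds on one
  core; everything else runs on hundreds of cells or closed-form fixtures.

## Known limitations

* Single-gene ligand and receptor representation; no receptor complexes
  or co-receptors.
* The permutation null fixes group sizes; datasets with extremely small
  cell types yield coarse, heavily tied null distributions.
* Multi-sample designs are handled as repeated pairwise comparisons
  against a control, not jointly.
* Figures are deliberately simple renderings of their companion tables;
  the tables are the supported, tested surface.
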