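"""Cell-cell communication scoring and permutation significance testing.

For every ordered (sender, receiver) cell-type pair and every ligand-receptor
pair, the interaction score is

    score = ln(1 + mean_ligand(sender) x mean_receptor(receiver))

on log-normalized expression, with means taken over all cells of the type
(zeros included). Specificity is assessed against a null distribution
obtained by shuffling the cell-type label vector: the observed score is
compared with the scores recomputed under each of P shuffled label
assignments, and the p-value uses the add-one convention
(1 + #{null >= observed}) / (1 + P).

Two permutation schemes are provided:

``shared``
    Draw P label shuffles once and reuse them for every sender-receiver
    pair — P shuffle evaluations in total. This is the default and is
    analogous to the fixed label-permutation sets used by GSEA.
``per_pair``
    The legacy scheme: P independent shuffles for each of the N^2
    sender-receiver pairs (N^2 x P shuffle evaluations). Kept for
    validation and benchmarking; both schemes expose a shuffle counter,
    whose ratio is exactly N^2.

Events whose ligand is detected in fewer than 10 % of sender cells, or
whose receptor is detected in fewer than 10 % of receiver cells, are
flagged as filtered (the boundary is exclusive: exactly 10 % is retained).
Detection is evaluated on the observed labels only, never inside
permutations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionDataset
from .knowledgebase import Knowledgebase, LRPair

RESULT_COLUMNS = [
    "sender", "receiver", "ligand", "receptor", "pathway", "rank",
    "mean_ligand", "mean_receptor", "score",
    "ligand_detect_frac", "receptor_detect_frac",
    "p_value", "significant", "filtered", "filter_reason",
]


@dataclass
class CCCConfig:
    """Configuration of a communication analysis.

    Parameters
    ----------
    n_permutations
        Number of label shuffles P for the null distribution (default 1000).
    p_threshold
        Significance cutoff on the permutation p-value (default 0.05,
        exclusive: significant means p < threshold).
    min_detection_fraction
        Minimum fraction of sender cells expressing the ligand (and receiver
        cells expressing the receptor) for an event to pass the noise
        filter; strictly-below is filtered (default 0.10).
    seed
        RNG seed; fixed seeds make the whole analysis reproducible.
    permutation_scheme
        ``"shared"`` (default) or ``"per_pair"`` (legacy).
    """

    n_permutations: int = 1000
    p_threshold: float = 0.05
    min_detection_fraction: float = 0.10
    seed: int | None = 0
    permutation_scheme: str = "shared"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if not 0 <= self.min_detection_fraction < 1:
            raise ValueError("min_detection_fraction must lie in [0, 1)")
        if self.permutation_scheme not in ("shared", "per_pair"):
            raise ValueError(
                f"unknown permutation_scheme {self.permutation_scheme!r}"
            )


@dataclass
class NullDistribution:
    """Permutation null scores for every (sender, receiver, pair) triple.

    ``scores`` has shape ``(P, n_types, n_types, n_pairs)`` indexed by
    (permutation, sender, receiver, pair). ``n_shuffle_evaluations`` counts
    how many label shuffles were drawn and evaluated.
    """

    scores: np.ndarray
    cell_types: list[str]
    pairs: list[LRPair]
    n_shuffle_evaluations: int


@dataclass
class CCCRun:
    """Result of :func:`run_ccc`: one row per (sender, receiver, L-R pair)."""

    table: pd.DataFrame
    skipped_pairs: list[tuple[LRPair, str]]
    n_shuffle_evaluations: int
    config: CCCConfig = field(default_factory=CCCConfig)


def interaction_score(mean_ligand, mean_receptor):
    """``ln(1 + mean_ligand * mean_receptor)``; zero when either mean is zero.

    Accepts scalars or arrays (broadcast). Negative inputs are rejected.
    """
    ml = np.asarray(mean_ligand, dtype=float)
    mr = np.asarray(mean_receptor, dtype=float)
    if (ml < 0).any() or (mr < 0).any():
        raise ValueError("mean expression must be non-negative")
    out = np.log1p(ml * mr)
    return float(out) if out.ndim == 0 else out


def mean_expression_by_celltype(ds: ExpressionDataset, genes) -> pd.DataFrame:
    """Per-cell-type arithmetic means (zeros included) for ``genes``.

    Returns a cell types x genes DataFrame.
    """
    cols = [ds.gene_index(g) for g in genes]
    types = ds.cell_types
    out = np.empty((len(types), len(cols)))
    for i, t in enumerate(types):
        mask = ds.cell_type == t
        if not mask.any():
            raise ValueError(f"cell type {t!r} has no cells")
        out[i] = ds.matrix[np.ix_(mask, cols)].mean(axis=0)
    return pd.DataFrame(out, index=types, columns=list(genes))


def detection_fraction(ds: ExpressionDataset, gene: str, cell_type: str) -> float:
    """Fraction of cells of ``cell_type`` with expression strictly > 0."""
    col = ds.gene_index(gene)
    mask = ds.cell_type == cell_type
    if not mask.any():
        raise ValueError(f"unknown cell type {cell_type!r}")
    return float((ds.matrix[mask, col] > 0).mean())


def permutation_pvalue(observed: float, null_scores) -> float:
    """Add-one permutation p-value: ``(1 + #{null >= observed}) / (1 + P)``.

    One-sided (enrichment); ties count toward the null (conservative).
    """
    null_scores = np.asarray(null_scores, dtype=float)
    if null_scores.size == 0:
        raise ValueError("null_scores must be non-empty")
    return float((1 + (null_scores >= observed).sum()) / (1 + null_scores.size))


# ---------------------------------------------------------------------------
# permutation machinery


def _prepare(ds: ExpressionDataset, kb: Knowledgebase):
    """Resolve kb pairs against the dataset; build the compact gene panel."""
    types = ds.cell_types
    usable: list[LRPair] = []
    skipped: list[tuple[LRPair, str]] = []
    gene_pos = {g: i for i, g in enumerate(ds.gene_ids)}
    for p in kb.pairs:
        if p.ligand not in gene_pos:
            skipped.append((p, f"ligand {p.ligand!r} absent from gene list"))
        elif p.receptor not in gene_pos:
            skipped.append((p, f"receptor {p.receptor!r} absent from gene list"))
        else:
            usable.append(p)
    panel: list[str] = []
    for p in usable:
        for g in (p.ligand, p.receptor):
            if g not in panel:
                panel.append(g)
    X = ds.matrix[:, [gene_pos[g] for g in panel]]
    panel_pos = {g: i for i, g in enumerate(panel)}
    lig_cols = np.array([panel_pos[p.ligand] for p in usable], dtype=int)
    rec_cols = np.array([panel_pos[p.receptor] for p in usable], dtype=int)
    codes = np.array([types.index(t) for t in ds.cell_type], dtype=np.int16)
    counts = np.bincount(codes, minlength=len(types)).astype(float)
    return types, usable, skipped, X, lig_cols, rec_cols, codes, counts


def _group_means(X: np.ndarray, code_matrix: np.ndarray, n_types: int,
                 counts: np.ndarray) -> np.ndarray:
    """Group means for a batch of label assignments.

    ``code_matrix`` is (P, n_cells) integer type codes; returns
    (P, n_types, n_genes). Realized as one matrix product per cell type so
    a whole permutation batch costs a few BLAS calls.
    """
    P = code_matrix.shape[0]
    means = np.empty((P, n_types, X.shape[1]))
    for t in range(n_types):
        mask = (code_matrix == t).astype(X.dtype)
        means[:, t, :] = (mask @ X) / counts[t]
    return means


def _null_from_means(means: np.ndarray, lig_cols, rec_cols) -> np.ndarray:
    """(P, N, genes) group means -> (P, N, N, K) null interaction scores."""
    L = means[:, :, lig_cols]   # (P, N, K) ligand mean in sender
    R = means[:, :, rec_cols]   # (P, N, K) receptor mean in receiver
    return np.log1p(L[:, :, None, :] * R[:, None, :, :])


def _enumerate_assignments(codes: np.ndarray) -> np.ndarray:
    """All distinct permutations of a small label-code vector (test mode)."""
    seen = set()
    rows = []
    for perm in itertools.permutations(codes.tolist()):
        if perm not in seen:
            seen.add(perm)
            rows.append(perm)
    return np.array(rows, dtype=codes.dtype)


def shared_permutation_null(
    ds: ExpressionDataset,
    kb: Knowledgebase,
    cfg: CCCConfig,
    *,
    permutations: np.ndarray | None = None,
    exhaustive: bool = False,
) -> NullDistribution:
    """Null scores under the shared-label scheme.

    Draws ``cfg.n_permutations`` shuffles of the cell-type label vector
    (group sizes preserved) and reuses the same shuffles for every
    (sender, receiver) pair, so the number of shuffle evaluations is P
    rather than N^2 x P.

    ``permutations`` injects explicit label assignments (a (P, n_cells)
    array of cell-type labels) — a test hook; ``exhaustive=True`` replaces
    random shuffles with every distinct assignment of the observed labels
    (only feasible for a handful of cells).
    """
    if cfg.permutation_scheme != "shared":
        raise ValueError("cfg.permutation_scheme must be 'shared'")
    types, usable, _, X, lig_cols, rec_cols, codes, counts = _prepare(ds, kb)
    if permutations is not None:
        code_matrix = np.array(
            [[types.index(t) for t in row] for row in np.asarray(permutations)],
            dtype=np.int16,
        )
    elif exhaustive:
        code_matrix = _enumerate_assignments(codes)
    else:
        rng = np.random.default_rng(cfg.seed)
        code_matrix = rng.permuted(
            np.tile(codes, (cfg.n_permutations, 1)), axis=1
        )
    means = _group_means(X, code_matrix, len(types), counts)
    return NullDistribution(
        scores=_null_from_means(means, lig_cols, rec_cols),
        cell_types=types,
        pairs=usable,
        n_shuffle_evaluations=code_matrix.shape[0],
    )


def per_pair_permutation_null(
    ds: ExpressionDataset, kb: Knowledgebase, cfg: CCCConfig
) -> NullDistribution:
    """Null scores under the legacy scheme: fresh shuffles per (i, j) pair.

    Each of the N^2 ordered sender-receiver pairs gets its own P label
    shuffles (N^2 x P shuffle evaluations, counted); for pair (i, j) only
    the shuffled group-i ligand means and group-j receptor means are used.
    """
    if cfg.permutation_scheme != "per_pair":
        raise ValueError("cfg.permutation_scheme must be 'per_pair'")
    types, usable, _, X, lig_cols, rec_cols, codes, counts = _prepare(ds, kb)
    n_types = len(types)
    P = cfg.n_permutations
    rng = np.random.default_rng(cfg.seed)
    Xl = X[:, lig_cols]
    Xr = X[:, rec_cols]
    null = np.empty((P, n_types, n_types, len(usable)))
    n_evals = 0
    for i in range(n_types):
        for j in range(n_types):
            code_matrix = rng.permuted(np.tile(codes, (P, 1)), axis=1)
            n_evals += P
            mask_i = (code_matrix == i).astype(X.dtype)
            mL = (mask_i @ Xl) / counts[i]          # (P, K)
            if j == i:
                mR = (mask_i @ Xr) / counts[i]
            else:
                mask_j = (code_matrix == j).astype(X.dtype)
                mR = (mask_j @ Xr) / counts[j]
            null[:, i, j, :] = np.log1p(mL * mR)
    return NullDistribution(
        scores=null, cell_types=types, pairs=usable, n_shuffle_evaluations=n_evals
    )


def run_ccc(
    ds: ExpressionDataset,
    kb: Knowledgebase,
    cfg: CCCConfig | None = None,
    *,
    null: NullDistribution | None = None,
) -> CCCRun:
    """Score every (sender, receiver, L-R pair) event and test significance.

    Pairs whose ligand or receptor gene is absent from the dataset are
    skipped and reported in ``CCCRun.skipped_pairs``. The detection filter
    is computed on the observed labels only. A precomputed ``null`` (e.g.
    from a test hook) bypasses shuffle generation.
    """
    cfg = cfg or CCCConfig()
    types, usable, skipped, X, lig_cols, rec_cols, codes, counts = _prepare(ds, kb)
    if len(types) < 2:
        raise ValueError("CCC analysis needs at least 2 cell types")
    if not usable:
        raise ValueError("no knowledgebase pair maps to the dataset's genes")

    # observed group means and detection fractions on true labels
    obs_means = _group_means(X, codes[None, :], len(types), counts)[0]  # (N, G)
    detect = np.empty_like(obs_means)
    for t in range(len(types)):
        detect[t] = (X[codes == t] > 0).mean(axis=0)

    mean_l = obs_means[:, lig_cols]      # (N, K)
    mean_r = obs_means[:, rec_cols]
    observed = np.log1p(mean_l[:, None, :] * mean_r[None, :, :])  # (N, N, K)

    if null is None:
        if cfg.permutation_scheme == "shared":
            null = shared_permutation_null(ds, kb, cfg)
        else:
            null = per_pair_permutation_null(ds, kb, cfg)
    P = null.scores.shape[0]
    pvals = (1 + (null.scores >= observed[None]).sum(axis=0)) / (1 + P)

    det_l = detect[:, lig_cols]          # (N, K) ligand detection in sender
    det_r = detect[:, rec_cols]
    thr = cfg.min_detection_fraction
    filt_l = det_l[:, None, :] < thr     # broadcast over receiver
    filt_r = det_r[None, :, :] < thr     # broadcast over sender
    filtered = filt_l | filt_r

    n, k = len(types), len(usable)
    s_idx, r_idx, k_idx = np.meshgrid(
        np.arange(n), np.arange(n), np.arange(k), indexing="ij"
    )
    s_idx, r_idx, k_idx = s_idx.ravel(), r_idx.ravel(), k_idx.ravel()
    # filter reasons built only for flagged rows (usually few)
    reason_col = np.full(s_idx.shape, "", dtype=object)
    flagged = np.flatnonzero(filtered.ravel())
    filt_l_full = np.broadcast_to(filt_l, filtered.shape).ravel()
    filt_r_full = np.broadcast_to(filt_r, filtered.shape).ravel()
    for idx in flagged:
        parts = []
        if filt_l_full[idx]:
            parts.append(
                f"ligand detected in {det_l[s_idx[idx], k_idx[idx]]:.3f} of sender cells"
            )
        if filt_r_full[idx]:
            parts.append(
                f"receptor detected in {det_r[r_idx[idx], k_idx[idx]]:.3f} of receiver cells"
            )
        reason_col[idx] = "; ".join(parts)

    pv = pvals.ravel()
    filt = filtered.ravel()
    table = pd.DataFrame(
        {
            "sender": [types[i] for i in s_idx],
            "receiver": [types[i] for i in r_idx],
            "ligand": [usable[i].ligand for i in k_idx],
            "receptor": [usable[i].receptor for i in k_idx],
            "pathway": [usable[i].pathway for i in k_idx],
            "rank": [usable[i].rank for i in k_idx],
            "mean_ligand": mean_l[s_idx, k_idx],
            "mean_receptor": mean_r[r_idx, k_idx],
            "score": observed.ravel(),
            "ligand_detect_frac": det_l[s_idx, k_idx],
            "receptor_detect_frac": det_r[r_idx, k_idx],
            "p_value": pv,
            "significant": (pv < cfg.p_threshold) & ~filt,
            "filtered": filt,
            "filter_reason": reason_col,
        },
        columns=RESULT_COLUMNS,
    )
    return CCCRun(
        table=table,
        skipped_pairs=skipped,
        n_shuffle_evaluations=null.n_shuffle_evaluations,
        config=cfg,
    )


def summarize_celltypes(results: pd.DataFrame) -> pd.DataFrame:
    """Total incoming/outgoing signaling per cell type.

    Sums interaction scores of significant, unfiltered events; ``incoming``
    sums events where the type is receiver, ``outgoing`` where it is sender.
    Total incoming equals total outgoing (each event contributes to one of
    each).
    """
    sig = results[results["significant"]]
    types = sorted(set(results["sender"]) | set(results["receiver"]))
    out = pd.DataFrame(
        {
            "cell_type": types,
            "incoming_sum": [sig.loc[sig["receiver"] == t, "score"].sum() for t in types],
            "outgoing_sum": [sig.loc[sig["sender"] == t, "score"].sum() for t in types],
        }
    )
    return out


def summarize_pathways(results: pd.DataFrame) -> pd.DataFrame:
    """Significant-event scores summed by pathway and directed cell-type pair."""
    sig = results[results["significant"]]
    if sig.empty:
        return pd.DataFrame(columns=["pathway", "sender", "receiver", "score_sum"])
    grouped = (
        sig.groupby(["pathway", "sender", "receiver"], as_index=False)["score"]
        .sum()
        .rename(columns={"score": "score_sum"})
    )
    return grouped


def write_ccc_table(run: CCCRun, path) -> None:
    """Write the per-event results table as TSV."""
    run.table.to_csv(path, sep="\t", index=False)


__all__ = [
    "CCCConfig",
    "CCCRun",
    "NullDistribution",
    "RESULT_COLUMNS",
    "interaction_score",
    "mean_expression_by_celltype",
    "detection_fraction",
    "permutation_pvalue",
    "shared_permutation_null",
    "per_pair_permutation_null",
    "run_ccc",
    "summarize_celltypes",
    "summarize_pathways",
    "write_ccc_table",
]
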