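"""Interface metrics for AlphaFold-Multimer predictions of candidate
ligand-receptor complexes.

A predicted complex of two chains (lengths L1, L2) comes with a square
predicted-aligned-error (PAE) matrix over the concatenated residues, per-
residue coordinates, and the model's ipTM and Model Confidence scores.
Five interface metrics are computed per model:

LIS
    Local Interaction Score: the mean inverted PAE over all inter-chain
    residue pairs with PAE <= 12 Å (the "local interaction area"); 0 when
    no inter-chain pair qualifies. Inverted PAE is linear:
    ``(12 - PAE) / 12``, clamped to [0, 1].
cLIS
    contact LIS: the same mean restricted to residue pairs in physical
    contact, i.e. Cβ-Cβ distance (Cα for glycine) <= 8 Å (and, by default,
    also PAE <= 12 Å).
LIS x cLIS
    their product, capturing interface confidence and contact specificity.
ipTM
    the inter-chain TM-score reported by AlphaFold-Multimer.
Model Confidence
    the combined score ``0.8 * ipTM + 0.2 * pTM``.

Classification calibrates a per-metric cutoff on a negative (non-
interacting) reference set so that 10 % of negatives exceed it, and calls
a pair positive when at least two of the five metrics meet their cutoff.
A simpler screening rule (mean ipTM >= 0.4551 or mean LIS >= 0.2471,
thresholds calibrated on literature-curated positive-control pairs) flags
putative interactions in large scans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

METRIC_NAMES = ("lis", "clis", "lis_x_clis", "iptm", "model_confidence")

PAE_CUTOFF = 12.0          # Å, local interaction area
CONTACT_CUTOFF = 8.0       # Å, Cβ-Cβ physical contact
SCREEN_IPTM_THRESHOLD = 0.4551
SCREEN_LIS_THRESHOLD = 0.2471


@dataclass
class ModelPrediction:
    """One AlphaFold-Multimer model of a two-chain complex.

    ``pae`` is the (L1+L2) x (L1+L2) predicted-aligned-error matrix in Å;
    ``coords`` holds one interaction-site coordinate per residue (Cβ, or
    Cα for glycine), chain 1 first.
    """

    pae: np.ndarray
    chain_lengths: tuple[int, int]
    coords: np.ndarray
    iptm: float
    model_confidence: float

    def __post_init__(self) -> None:
        self.pae = np.asarray(self.pae, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        l1, l2 = self.chain_lengths
        if l1 < 1 or l2 < 1:
            raise ValueError("chain lengths must be >= 1")
        n = l1 + l2
        if self.pae.shape != (n, n):
            raise ValueError(
                f"PAE matrix shape {self.pae.shape} != ({n}, {n}) for chains {l1}+{l2}"
            )
        if (self.pae < 0).any():
            raise ValueError("PAE values must be non-negative")
        if self.coords.shape != (n, 3):
            raise ValueError(f"expected {n} residue coordinates, got {self.coords.shape}")
        for name in ("iptm", "model_confidence"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class PairPrediction:
    """A candidate protein pair with one or more predicted models."""

    pair_id: str
    models: list[ModelPrediction] = field(default_factory=list)


@dataclass
class InterfaceMetrics:
    """The five interface metrics (all in [0, 1]) plus pair counts.

    ``n_local_pairs`` counts inter-chain residue pairs with PAE <= 12 Å;
    ``n_contact_pairs`` counts inter-chain residue pairs within the contact
    distance that also satisfy the PAE bound (the cLIS support). The two
    sets are defined by different criteria, so neither contains the other
    in general.
    """

    lis: float
    clis: float
    lis_x_clis: float
    iptm: float
    model_confidence: float
    n_local_pairs: int = 0
    n_contact_pairs: int = 0

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class ClassifierThresholds:
    """Per-metric cutoffs calibrated to a target false-positive rate."""

    cutoffs: dict[str, float]
    fpr: float = 0.10
    min_metrics_passing: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.fpr < 1:
            raise ValueError("fpr must lie in (0, 1)")
        if not 1 <= self.min_metrics_passing <= len(METRIC_NAMES):
            raise ValueError(
                f"min_metrics_passing must lie in [1, {len(METRIC_NAMES)}]"
            )


def inverted_pae(pae, cap: float = PAE_CUTOFF):
    """Linear inverted PAE: ``(cap - pae) / cap`` for ``pae <= cap``, else 0."""
    pae = np.asarray(pae, dtype=float)
    if (pae < 0).any():
        raise ValueError("PAE must be non-negative")
    out = np.clip((cap - pae) / cap, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _interchain_blocks(model: ModelPrediction):
    """The two off-diagonal PAE blocks (PAE is asymmetric; both enter)."""
    l1, _ = model.chain_lengths
    return model.pae[:l1, l1:], model.pae[l1:, :l1]


def compute_lis(model: ModelPrediction, pae_cutoff: float = PAE_CUTOFF) -> float:
    """Mean inverted PAE over inter-chain residue pairs with PAE <= cutoff.

    Both off-diagonal blocks of the (asymmetric) PAE matrix contribute;
    returns 0 when no inter-chain entry is within the cutoff.
    """
    a, b = _interchain_blocks(model)
    vals = np.concatenate([a.ravel(), b.ravel()])
    local = vals[vals <= pae_cutoff]
    if local.size == 0:
        return 0.0
    return float(inverted_pae(local, cap=pae_cutoff).mean())


def _contact_mask(model: ModelPrediction, contact_cutoff: float) -> np.ndarray:
    """Boolean (L1, L2) matrix of inter-chain residue pairs within contact."""
    l1, _ = model.chain_lengths
    c1 = model.coords[:l1]
    c2 = model.coords[l1:]
    d = np.linalg.norm(c1[:, None, :] - c2[None, :, :], axis=-1)
    return d <= contact_cutoff


def compute_clis(
    model: ModelPrediction,
    contact_cutoff: float = CONTACT_CUTOFF,
    pae_cutoff: float = PAE_CUTOFF,
    require_pae: bool = True,
) -> float:
    """Mean inverted PAE over inter-chain residue pairs in physical contact.

    Contact means Cβ-Cβ (Cα for glycine) distance <= ``contact_cutoff``;
    with ``require_pae`` (default) the pair must additionally satisfy
    PAE <= ``pae_cutoff``. Returns 0 when no pair qualifies.
    """
    contact = _contact_mask(model, contact_cutoff)
    a, b = _interchain_blocks(model)
    vals = np.concatenate([a[contact].ravel(), b.T[contact].ravel()])
    if require_pae:
        vals = vals[vals <= pae_cutoff]
    if vals.size == 0:
        return 0.0
    return float(inverted_pae(vals, cap=pae_cutoff).mean())


def compute_metrics(
    model: ModelPrediction,
    contact_cutoff: float = CONTACT_CUTOFF,
    pae_cutoff: float = PAE_CUTOFF,
    require_pae: bool = True,
) -> InterfaceMetrics:
    """All five interface metrics for one model."""
    lis = compute_lis(model, pae_cutoff=pae_cutoff)
    clis = compute_clis(
        model, contact_cutoff=contact_cutoff, pae_cutoff=pae_cutoff,
        require_pae=require_pae,
    )
    a, b = _interchain_blocks(model)
    n_local = int((a <= pae_cutoff).sum() + (b <= pae_cutoff).sum())
    contact = _contact_mask(model, contact_cutoff)
    if require_pae:
        n_contact = int(
            (a[contact] <= pae_cutoff).sum() + (b.T[contact] <= pae_cutoff).sum()
        )
    else:
        n_contact = int(2 * contact.sum())
    return InterfaceMetrics(
        lis=lis,
        clis=clis,
        lis_x_clis=lis * clis,
        iptm=model.iptm,
        model_confidence=model.model_confidence,
        n_local_pairs=n_local,
        n_contact_pairs=n_contact,
    )


def aggregate_models(per_model: list[InterfaceMetrics]) -> InterfaceMetrics:
    """Arithmetic mean of each metric over a prediction's models.

    ``lis_x_clis`` is the mean of the per-model products (not the product
    of means). Pair counts are averaged and rounded.
    """
    if not per_model:
        raise ValueError("need at least one model")
    return InterfaceMetrics(
        lis=float(np.mean([m.lis for m in per_model])),
        clis=float(np.mean([m.clis for m in per_model])),
        lis_x_clis=float(np.mean([m.lis * m.clis for m in per_model])),
        iptm=float(np.mean([m.iptm for m in per_model])),
        model_confidence=float(np.mean([m.model_confidence for m in per_model])),
        n_local_pairs=int(round(np.mean([m.n_local_pairs for m in per_model]))),
        n_contact_pairs=int(round(np.mean([m.n_contact_pairs for m in per_model]))),
    )


def calibrate_thresholds(
    negative_scores: dict[str, np.ndarray],
    fpr: float = 0.10,
    min_metrics_passing: int = 2,
    min_negatives: int = 10,
) -> ClassifierThresholds:
    """Per-metric cutoff such that at most ``fpr`` of negatives exceed it.

    For each metric the cutoff is the smallest observed value t with
    ``#{negatives > t} <= fpr * n`` — the empirical (1 - fpr) quantile with
    ties resolved upward — so the empirical false-positive rate on the
    calibration set is guaranteed <= ``fpr``.
    """
    cutoffs: dict[str, float] = {}
    for metric, scores in negative_scores.items():
        scores = np.sort(np.asarray(scores, dtype=float))
        n = scores.size
        if n < min_negatives:
            raise ValueError(
                f"metric {metric!r}: {n} negatives < required {min_negatives}"
            )
        k = int(np.floor(fpr * n))          # allowed exceedances
        cutoffs[metric] = float(scores[n - k - 1])
    return ClassifierThresholds(
        cutoffs=cutoffs, fpr=fpr, min_metrics_passing=min_metrics_passing
    )


def classify_ppi(
    metrics: InterfaceMetrics, thresholds: ClassifierThresholds
) -> tuple[str, dict[str, bool]]:
    """Call a pair positive when enough metrics meet their FPR cutoff.

    Returns ``("positive" | "negative", per-metric pass vector)``; a metric
    passes when its value is >= the calibrated cutoff.
    """
    missing = [m for m in METRIC_NAMES if m not in thresholds.cutoffs]
    if missing:
        raise ValueError(f"thresholds missing metrics: {missing}")
    values = metrics.as_dict()
    passes = {m: values[m] >= thresholds.cutoffs[m] for m in METRIC_NAMES}
    label = (
        "positive"
        if sum(passes.values()) >= thresholds.min_metrics_passing
        else "negative"
    )
    return label, passes


def screen_classify(
    mean_iptm: float,
    mean_lis: float,
    iptm_threshold: float = SCREEN_IPTM_THRESHOLD,
    lis_threshold: float = SCREEN_LIS_THRESHOLD,
) -> str:
    """Large-scan screening rule: putative interaction when either the mean
    ipTM or the mean LIS reaches its threshold (boundaries inclusive)."""
    for name, v in (("mean_iptm", mean_iptm), ("mean_lis", mean_lis)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if mean_iptm >= iptm_threshold or mean_lis >= lis_threshold:
        return "putative_interaction"
    return "no_call"


# ---------------------------------------------------------------------------
# I/O: PAE JSON and mmCIF/PDB coordinates


def load_pae_json(path) -> dict:
    """Read a PAE JSON as produced by common AlphaFold-Multimer runners.

    Accepts either a top-level object or a one-element list wrapping it;
    the PAE lives under ``predicted_aligned_error`` (or ``pae``), with
    optional ``ptm`` / ``iptm`` fields.
    """
    with open(path) as fh:
        obj = json.load(fh)
    if isinstance(obj, list):
        obj = obj[0]
    key = "predicted_aligned_error" if "predicted_aligned_error" in obj else "pae"
    if key not in obj:
        raise ValueError(f"{path}: no predicted_aligned_error/pae field")
    pae = np.asarray(obj[key], dtype=float)
    if pae.ndim != 2 or pae.shape[0] != pae.shape[1]:
        raise ValueError(f"{path}: PAE is not a square matrix (shape {pae.shape})")
    return {
        "pae": pae,
        "ptm": float(obj["ptm"]) if "ptm" in obj else None,
        "iptm": float(obj["iptm"]) if "iptm" in obj else None,
    }


def _residue_site(residue: "gemmi.Residue") -> np.ndarray:
    """Cβ coordinate, Cα for glycine; error when neither is present."""
    name = "CA" if residue.name == "GLY" else "CB"
    atom = residue.find_atom(name, "*")
    if atom is None:
        raise ValueError(
            f"residue {residue.name} {residue.seqid.num} lacks a {name} atom"
        )
    return np.array([atom.pos.x, atom.pos.y, atom.pos.z])


def load_structure_sites(path) -> tuple[np.ndarray, tuple[int, int]]:
    """Per-residue interaction-site coordinates and chain lengths.

    Reads mmCIF or PDB via gemmi; expects exactly two chains; returns
    coordinates in file order (chain 1 then chain 2).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chains = list(model)
    if len(chains) != 2:
        raise ValueError(f"{path}: expected 2 chains, found {len(chains)}")
    coords = []
    lengths = []
    for chain in chains:
        n = 0
        for residue in chain:
            coords.append(_residue_site(residue))
            n += 1
        lengths.append(n)
    return np.array(coords), (lengths[0], lengths[1])


def load_model(
    pae_path, structure_path, iptm: float | None = None,
    model_confidence: float | None = None,
) -> ModelPrediction:
    """Assemble a :class:`ModelPrediction` from a PAE JSON and a structure.

    ipTM is taken from the JSON unless given explicitly; Model Confidence
    defaults to ``0.8 * ipTM + 0.2 * pTM`` when the JSON carries both.
    """
    pae = load_pae_json(pae_path)
    coords, lengths = load_structure_sites(structure_path)
    if iptm is None:
        iptm = pae["iptm"]
    if iptm is None:
        raise ValueError("ipTM neither in the PAE JSON nor given explicitly")
    if model_confidence is None:
        if pae["ptm"] is not None:
            model_confidence = 0.8 * iptm + 0.2 * pae["ptm"]
        else:
            model_confidence = iptm
    return ModelPrediction(
        pae=pae["pae"], chain_lengths=lengths, coords=coords,
        iptm=iptm, model_confidence=model_confidence,
    )


def write_pae_json(model: ModelPrediction, path, ptm: float | None = None) -> None:
    """Write a model's PAE (and scores) in the runner JSON layout."""
    obj = {
        "predicted_aligned_error": model.pae.tolist(),
        "iptm": model.iptm,
    }
    if ptm is not None:
        obj["ptm"] = ptm
    with open(path, "w") as fh:
        json.dump(obj, fh)


def write_structure(model: ModelPrediction, path) -> None:
    """Write per-residue sites as a minimal two-chain mmCIF/PDB structure.

    Every residue is emitted as an alanine with a single Cβ atom at the
    interaction-site coordinate — enough to round-trip the contact logic.
    """
    st = gemmi.Structure()
    st.name = "pair"
    md = gemmi.Model("1")
    l1, _ = model.chain_lengths
    for chain_name, idx in (("A", range(l1)), ("B", range(l1, len(model.coords)))):
        chain = gemmi.Chain(chain_name)
        for seq, i in enumerate(idx, start=1):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(seq, " ")
            atom = gemmi.Atom()
            atom.name = "CB"
            atom.element = gemmi.Element("C")
            x, y, z = model.coords[i]
            atom.pos = gemmi.Position(x, y, z)
            res.add_atom(atom)
            chain.add_residue(res)
        md.add_chain(chain)
    st.add_model(md)
    path = str(path)
    if path.endswith(".pdb"):
        st.write_pdb(path)
    else:
        st.make_mmcif_document().write_file(path)


def metrics_table(pair_metrics: dict[str, InterfaceMetrics],
                  classifications: dict[str, str] | None = None) -> pd.DataFrame:
    """Tabulate per-pair aggregated metrics (one row per pair id)."""
    rows = []
    for pair_id, m in pair_metrics.items():
        row = {"pair_id": pair_id, **m.as_dict(),
               "n_local_pairs": m.n_local_pairs,
               "n_contact_pairs": m.n_contact_pairs}
        if classifications is not None:
            row["classification"] = classifications.get(pair_id, "")
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "METRIC_NAMES",
    "PAE_CUTOFF",
    "CONTACT_CUTOFF",
    "SCREEN_IPTM_THRESHOLD",
    "SCREEN_LIS_THRESHOLD",
    "ModelPrediction",
    "PairPrediction",
    "InterfaceMetrics",
    "ClassifierThresholds",
    "inverted_pae",
    "compute_lis",
    "compute_clis",
    "compute_metrics",
    "aggregate_models",
    "calibrate_thresholds",
    "classify_ppi",
    "screen_classify",
    "load_pae_json",
    "load_structure_sites",
    "load_model",
    "write_pae_json",
    "write_structure",
    "metrics_table",
]
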