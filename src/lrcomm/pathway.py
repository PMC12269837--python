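"""Pathway-level expression summaries: role heatmaps and the
receptor-reporter dot plot.

Co-expression of a ligand and its receptor does not guarantee that the
downstream pathway is active; receptor desensitization or inhibitory
regulators can keep signaling off. Reporter genes — downstream
transcriptional targets of a pathway — give an independent readout of
activity in the receiving cell. These summaries expose, per pathway and
cell type, the mean expression of annotated ligands, receptors, core
components and reporters, and in the dot-plot table the highest-expressed
receptor and reporter (the argmax over the pathway's annotated genes of
the per-cell-type mean).
"""

from __future__ import annotations

import logging

import pandas as pd

from .ccc import mean_expression_by_celltype
from .expression import ExpressionDataset
from .knowledgebase import Knowledgebase, VALID_ROLES

logger = logging.getLogger(__name__)

DOTPLOT_COLUMNS = [
    "pathway", "cell_type",
    "max_receptor_gene", "max_receptor_value",
    "max_reporter_gene", "max_reporter_value",
]


def role_expression_heatmap(
    ds: ExpressionDataset, kb: Knowledgebase, role: str
) -> pd.DataFrame:
    """Cell types x genes mean-expression matrix for one annotation role.

    Genes annotated with ``role`` in the knowledgebase but absent from the
    dataset are omitted with a warning; an empty matrix (with a warning)
    results when no annotated gene is present.
    """
    if role not in VALID_ROLES:
        raise ValueError(f"role must be one of {sorted(VALID_ROLES)}, got {role!r}")
    genes = kb.genes_by_role(role)
    present = [g for g in genes if g in ds.gene_ids]
    absent = [g for g in genes if g not in ds.gene_ids]
    if absent:
        logger.warning("%d %s genes absent from dataset: %s", len(absent), role, absent)
    if not present:
        logger.warning("no %s-annotated genes present in the dataset", role)
        return pd.DataFrame(index=ds.cell_types)
    return mean_expression_by_celltype(ds, present)


def receptor_reporter_dotplot(
    ds: ExpressionDataset, kb: Knowledgebase
) -> pd.DataFrame:
    """Per (pathway, cell type): highest-expressed receptor and reporter.

    The maximum is over the pathway's annotated genes of the per-cell-type
    mean expression; ties break lexicographically by gene symbol. Pathways
    with no annotated receptor or reporter gene present in the dataset get
    gene ``""`` and value 0 for that slot.
    """
    rows = []
    for pathway in sorted({c.pathway for c in kb.components}):
        maxima = {}
        for role in ("receptor", "reporter"):
            genes = sorted(
                g for g in kb.genes_by_role(role, pathway) if g in ds.gene_ids
            )
            if genes:
                means = mean_expression_by_celltype(ds, genes)
                # idxmax on lexicographically sorted columns -> deterministic ties
                maxima[role] = (means.idxmax(axis=1), means.max(axis=1))
            else:
                maxima[role] = None
        if maxima["receptor"] is None and maxima["reporter"] is None:
            continue
        for ct in ds.cell_types:
            row = {"pathway": pathway, "cell_type": ct}
            for role in ("receptor", "reporter"):
                if maxima[role] is None:
                    row[f"max_{role}_gene"] = ""
                    row[f"max_{role}_value"] = 0.0
                else:
                    row[f"max_{role}_gene"] = maxima[role][0][ct]
                    row[f"max_{role}_value"] = float(maxima[role][1][ct])
            rows.append(row)
    return pd.DataFrame(rows, columns=DOTPLOT_COLUMNS)


__all__ = ["role_expression_heatmap", "receptor_reporter_dotplot", "DOTPLOT_COLUMNS"]
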