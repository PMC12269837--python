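"""Figure generation from result tables.

Every figure is an artifact of a tabular summary: the function first
builds (and writes) the underlying data table, then renders an image from
it. The tables are the tested surface; images regenerate deterministically
from them. Supported kinds:

``scatter``
    Total incoming vs outgoing interaction score per cell type.
``chord``
    Sender -> receiver matrix of summed significant scores, drawn as a
    circular layout with band width proportional to outgoing strength.
``circle_single_source``
    Significant outgoing edges from one chosen source cell type.
``dotplot``
    Per (pathway, cell type): dot size = highest receptor mean, dot color
    = highest reporter mean.
``heatmap``
    Cell type x gene mean-expression heatmap for one annotation role.
``diff_circle``
    Differential events aggregated per directed cell-type pair; edge color
    encodes direction (up/down), width the magnitude.
``diff_heatmap``
    Experimental-minus-control mean expression of a role's genes.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .ccc import summarize_celltypes
from .pathway import receptor_reporter_dotplot, role_expression_heatmap

FIGURE_KINDS = (
    "scatter", "chord", "circle_single_source", "dotplot",
    "heatmap", "diff_circle", "diff_heatmap",
)


def scatter_data(results: pd.DataFrame) -> pd.DataFrame:
    return summarize_celltypes(results)


def chord_data(results: pd.DataFrame) -> pd.DataFrame:
    """Sender -> receiver total significant score, long form."""
    sig = results[results["significant"]]
    if sig.empty:
        return pd.DataFrame(columns=["sender", "receiver", "score_sum"])
    return (
        sig.groupby(["sender", "receiver"], as_index=False)["score"]
        .sum()
        .rename(columns={"score": "score_sum"})
    )


def circle_single_source_data(results: pd.DataFrame, source: str) -> pd.DataFrame:
    data = chord_data(results)
    return data[data["sender"] == source].reset_index(drop=True)


def diff_circle_data(diff: pd.DataFrame) -> pd.DataFrame:
    """Aggregate differential score changes per directed cell-type pair."""
    agg = (
        diff.groupby(["sender", "receiver"], as_index=False)["abs_diff"]
        .sum()
    )
    agg = agg[agg["abs_diff"] != 0].reset_index(drop=True)
    agg["direction"] = np.where(agg["abs_diff"] > 0, "up", "down")
    return agg


def diff_heatmap_data(ds_exp, ds_ctrl, kb, role: str = "core") -> pd.DataFrame:
    """Experimental minus control per-cell-type means for a role's genes."""
    exp = role_expression_heatmap(ds_exp, kb, role)
    ctrl = role_expression_heatmap(ds_ctrl, kb, role)
    common_genes = [g for g in exp.columns if g in ctrl.columns]
    common_types = [t for t in exp.index if t in ctrl.index]
    return exp.loc[common_types, common_genes] - ctrl.loc[common_types, common_genes]


def _circular_positions(names):
    angles = np.linspace(0, 2 * np.pi, len(names), endpoint=False)
    return {n: (np.cos(a), np.sin(a)) for n, a in zip(names, angles)}


def _draw_edges(ax, data, value_col, color=None):
    names = sorted(set(data["sender"]) | set(data["receiver"]))
    pos = _circular_positions(names)
    vmax = data[value_col].abs().max() or 1.0
    for _, row in data.iterrows():
        x0, y0 = pos[row["sender"]]
        x1, y1 = pos[row["receiver"]]
        w = 0.5 + 4 * abs(row[value_col]) / vmax
        c = color
        if c is None:
            c = "tab:red" if row[value_col] > 0 else "tab:blue"
        ax.annotate(
            "", xy=(x1, y1), xytext=(x0, y0),
            arrowprops=dict(arrowstyle="-|>", lw=w, color=c,
                            connectionstyle="arc3,rad=0.15"),
        )
    for n, (x, y) in pos.items():
        ax.plot(x, y, "o", ms=10, color="0.3")
        ax.annotate(n, (x * 1.15, y * 1.15), ha="center", va="center")
    ax.set_xlim(-1.4, 1.4)
    ax.set_ylim(-1.4, 1.4)
    ax.set_aspect("equal")
    ax.axis("off")


def render_figures(
    kind: str,
    outdir,
    *,
    results: pd.DataFrame | None = None,
    diff: pd.DataFrame | None = None,
    ds=None,
    ds_ctrl=None,
    kb=None,
    source: str | None = None,
    role: str = "core",
    prefix: str = "",
) -> dict:
    """Write the data table and image for one figure kind.

    Returns ``{"data": DataFrame, "table": path, "figure": path}``.
    Inputs depend on the kind: CCC result tables for scatter/chord/circle,
    a differential table for diff_circle, datasets + knowledgebase for
    dotplot/heatmap/diff_heatmap.
    """
    if kind not in FIGURE_KINDS:
        raise ValueError(f"unknown figure kind {kind!r}; valid: {FIGURE_KINDS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = f"{prefix}{kind}"
    fig, ax = plt.subplots(figsize=(6, 6))

    if kind == "scatter":
        data = scatter_data(_req(results, "results"))
        ax.scatter(data["incoming_sum"], data["outgoing_sum"])
        for _, r in data.iterrows():
            ax.annotate(r["cell_type"], (r["incoming_sum"], r["outgoing_sum"]))
        ax.set_xlabel("total incoming interaction score")
        ax.set_ylabel("total outgoing interaction score")
    elif kind == "chord":
        data = chord_data(_req(results, "results"))
        if len(data):
            _draw_edges(ax, data, "score_sum", color="tab:purple")
    elif kind == "circle_single_source":
        if source is None:
            raise ValueError("circle_single_source needs a source cell type")
        data = circle_single_source_data(_req(results, "results"), source)
        if len(data):
            _draw_edges(ax, data, "score_sum", color="tab:green")
        ax.set_title(f"outgoing signaling from {source}")
    elif kind == "dotplot":
        data = receptor_reporter_dotplot(_req(ds, "ds"), _req(kb, "kb"))
        if len(data):
            pw = {p: i for i, p in enumerate(sorted(set(data["pathway"])))}
            ct = {t: i for i, t in enumerate(sorted(set(data["cell_type"])))}
            sizes = 20 + 180 * data["max_receptor_value"] / (
                data["max_receptor_value"].max() or 1.0
            )
            sc = ax.scatter(
                [ct[t] for t in data["cell_type"]],
                [pw[p] for p in data["pathway"]],
                s=sizes, c=data["max_reporter_value"], cmap="viridis",
            )
            fig.colorbar(sc, ax=ax, label="max reporter mean expression")
            ax.set_xticks(range(len(ct)), list(ct), rotation=45, ha="right")
            ax.set_yticks(range(len(pw)), list(pw))
    elif kind == "heatmap":
        data = role_expression_heatmap(_req(ds, "ds"), _req(kb, "kb"), role)
        if data.shape[1]:
            im = ax.imshow(data.values, aspect="auto", cmap="magma")
            fig.colorbar(im, ax=ax, label="mean expression")
            ax.set_xticks(range(data.shape[1]), data.columns, rotation=90)
            ax.set_yticks(range(data.shape[0]), data.index)
    elif kind == "diff_circle":
        data = diff_circle_data(_req(diff, "diff"))
        if len(data):
            _draw_edges(ax, data, "abs_diff")
        ax.set_title("differential signaling (red: up, blue: down)")
    elif kind == "diff_heatmap":
        data = diff_heatmap_data(_req(ds, "ds"), _req(ds_ctrl, "ds_ctrl"),
                                 _req(kb, "kb"), role)
        if data.shape[1]:
            lim = np.abs(data.values).max() or 1.0
            im = ax.imshow(data.values, aspect="auto", cmap="coolwarm",
                           vmin=-lim, vmax=lim)
            fig.colorbar(im, ax=ax, label="mean expression change")
            ax.set_xticks(range(data.shape[1]), data.columns, rotation=90)
            ax.set_yticks(range(data.shape[0]), data.index)

    table_path = outdir / f"{stem}.tsv"
    fig_path = outdir / f"{stem}.png"
    keep_index = kind in ("heatmap", "diff_heatmap")
    data.to_csv(table_path, sep="\t", index=keep_index)
    fig.tight_layout()
    fig.savefig(fig_path, dpi=100)
    plt.close(fig)
    return {"data": data, "table": str(table_path), "figure": str(fig_path)}


def _req(value, name):
    if value is None:
        raise ValueError(f"figure kind requires {name}=")
    return value


__all__ = [
    "FIGURE_KINDS",
    "render_figures",
    "scatter_data",
    "chord_data",
    "circle_single_source_data",
    "diff_circle_data",
    "diff_heatmap_data",
]
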