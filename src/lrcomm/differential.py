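"""Differential cell-cell communication between an experimental and a
control sample.

Per-sample CCC runs are combined over the union of their events. Two
differential statistics are computed per event: the log2 fold-change
(log2 of the experimental score divided by the control score, undefined —
reported as NaN — when either score is zero) and the absolute difference
(experimental minus control score, always defined). An event is "on/off"
when exactly one of the two scores is zero.

Dysregulated-event selection follows the rule: significant in the
experimental sample but not in the control (p_exp < 0.05, p_ctrl >= 0.05),
with interaction-score difference > 2, or > 1 for on/off events.
Optionally, user-supplied differentially-expressed-gene (DEG) lists flag
events whose ligand and/or receptor is a DEG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ccc import CCCRun

EVENT_KEY = ["sender", "receiver", "ligand", "receptor"]
CARRIED = ["pathway", "rank"]


@dataclass
class SelectionCriteria:
    """Thresholds for picking dysregulated events.

    ``min_abs_diff`` applies to ordinary events (score difference must be
    strictly greater); ``min_abs_diff_on_off`` applies when one score is
    exactly zero. ``direction`` selects up-regulated events (``"up"``,
    default: experimental above control), down-regulated (``"down"``) or
    both (``"both"``, on |abs_diff|).
    """

    p_threshold: float = 0.05
    min_abs_diff: float = 2.0
    min_abs_diff_on_off: float = 1.0
    require_exp_significant_only: bool = True
    restrict_senders: set | None = None
    require_ligand_deg: bool = False
    direction: str = "up"

    def __post_init__(self) -> None:
        if self.min_abs_diff < 0 or self.min_abs_diff_on_off < 0:
            raise ValueError("difference thresholds must be >= 0")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.direction not in ("up", "down", "both"):
            raise ValueError("direction must be 'up', 'down' or 'both'")


def _as_table(results) -> pd.DataFrame:
    return results.table if isinstance(results, CCCRun) else results


def combine_samples(results_by_sample: dict, exp_label: str, ctrl_label: str) -> pd.DataFrame:
    """Merge per-sample CCC tables into one differential table.

    The union of events across the two samples is taken; an event missing
    from one side (e.g. filtered there, or its genes undetected) enters
    with score 0 and p-value 1, which makes on/off events visible rather
    than silently dropped.
    """
    for label in (exp_label, ctrl_label):
        if label not in results_by_sample:
            raise ValueError(
                f"sample {label!r} not among {sorted(results_by_sample)}"
            )
    exp = _as_table(results_by_sample[exp_label]).copy()
    ctrl = _as_table(results_by_sample[ctrl_label]).copy()
    # filtered events carry no usable score: treat as absent (score 0, p 1)
    for df in (exp, ctrl):
        df.loc[df["filtered"], "score"] = 0.0
        df.loc[df["filtered"], "p_value"] = 1.0
    annot = pd.concat(
        [exp[EVENT_KEY + CARRIED], ctrl[EVENT_KEY + CARRIED]]
    ).drop_duplicates(EVENT_KEY)
    merged = exp[EVENT_KEY + ["score", "p_value"]].merge(
        ctrl[EVENT_KEY + ["score", "p_value"]],
        on=EVENT_KEY,
        how="outer",
        suffixes=("_exp", "_ctrl"),
    )
    merged = annot.merge(merged, on=EVENT_KEY, how="right")
    merged["score_exp"] = merged.pop("score_exp").fillna(0.0)
    merged["score_ctrl"] = merged.pop("score_ctrl").fillna(0.0)
    merged["p_exp"] = merged.pop("p_value_exp").fillna(1.0)
    merged["p_ctrl"] = merged.pop("p_value_ctrl").fillna(1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = merged["score_exp"] / merged["score_ctrl"]
    both_pos = (merged["score_exp"] > 0) & (merged["score_ctrl"] > 0)
    merged["log2fc"] = np.where(both_pos, np.log2(ratio.where(both_pos, 1.0)), np.nan)
    merged["abs_diff"] = merged["score_exp"] - merged["score_ctrl"]
    merged["on_off"] = (merged["score_exp"] == 0) ^ (merged["score_ctrl"] == 0)
    merged["ligand_deg"] = False
    merged["receptor_deg"] = False
    merged["dysregulated"] = False
    return merged


def flag_degs(
    records: pd.DataFrame,
    deg_lists: dict,
    criteria: SelectionCriteria | None = None,
) -> pd.DataFrame:
    """Mark events whose ligand/receptor appears in any supplied DEG list.

    ``deg_lists`` maps sample label to a set of gene symbols. An event is
    dysregulated when its ligand and/or receptor is a DEG and the event
    meets the significance part of ``criteria`` (experimental p below
    threshold and, by default, control p at or above it).
    """
    criteria = criteria or SelectionCriteria()
    degs: set[str] = set()
    for genes in deg_lists.values():
        degs |= set(genes)
    out = records.copy()
    out["ligand_deg"] = out["ligand"].isin(degs)
    out["receptor_deg"] = out["receptor"].isin(degs)
    sig = out["p_exp"] < criteria.p_threshold
    if criteria.require_exp_significant_only:
        sig &= out["p_ctrl"] >= criteria.p_threshold
    out["dysregulated"] = (out["ligand_deg"] | out["receptor_deg"]) & sig
    return out


def select_events(records: pd.DataFrame, criteria: SelectionCriteria | None = None) -> pd.DataFrame:
    """Apply the dysregulated-event selection rule.

    Keeps events significant in the experimental sample (and, by default,
    not in the control), whose score difference exceeds ``min_abs_diff``
    (``min_abs_diff_on_off`` for on/off events) in the requested direction.
    Optional conjunctive filters: restrict senders to a set of cell types,
    require the ligand to be a DEG.
    """
    criteria = criteria or SelectionCriteria()
    keep = records["p_exp"] < criteria.p_threshold
    if criteria.require_exp_significant_only:
        keep &= records["p_ctrl"] >= criteria.p_threshold
    diff = records["abs_diff"]
    if criteria.direction == "up":
        signed = diff
    elif criteria.direction == "down":
        signed = -diff
    else:
        signed = diff.abs()
    magnitude = np.where(
        records["on_off"],
        signed > criteria.min_abs_diff_on_off,
        signed > criteria.min_abs_diff,
    )
    keep &= magnitude
    if criteria.restrict_senders is not None:
        keep &= records["sender"].isin(criteria.restrict_senders)
    if criteria.require_ligand_deg:
        keep &= records["ligand_deg"]
    return records[keep].reset_index(drop=True)


def read_deg_list(path) -> set[str]:
    """Read a one-gene-symbol-per-line DEG file."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_combined_table(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


__all__ = [
    "SelectionCriteria",
    "combine_samples",
    "flag_degs",
    "select_events",
    "read_deg_list",
    "write_combined_table",
]
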