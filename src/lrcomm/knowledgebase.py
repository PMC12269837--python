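"""Ligand-receptor knowledgebase: curated pairs plus pathway annotations.

A knowledgebase couples ligand genes to receptor genes, assigns each pair
to a signaling pathway, and grades it with a confidence rank (``high`` for
literature-curated pairs, ``moderate`` for structure-predicted pairs with
orthology/paralogy support, ``low`` for the remaining predictions). Pathway
component tables annotate genes with a role: ligand, receptor, core
component, or downstream transcriptional reporter.

Serialization is tab-delimited text (one file for pairs, one for
components); list-valued fields are joined with ``|`` so the files stay
diff-able and spreadsheet-openable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

VALID_RANKS = frozenset({"high", "moderate", "low"})
VALID_ROLES = frozenset({"ligand", "receptor", "core", "reporter"})

PAIR_REQUIRED_COLUMNS = ("ligand", "receptor", "pathway", "rank")
PAIR_OPTIONAL_COLUMNS = (
    "source",
    "mammalian_orthologs",
    "ligand_annotation",
    "receptor_annotation",
)
COMPONENT_COLUMNS = ("pathway", "gene", "role")


class KnowledgebaseFormatError(ValueError):
    """A knowledgebase file does not conform to the expected schema."""


class KnowledgebaseValidationError(ValueError):
    """Knowledgebase content violates an invariant (rank, duplicates, ...)."""


@dataclass(frozen=True)
class LRPair:
    """One ligand gene / receptor gene couple with pathway and provenance.

    Gene symbols are case-sensitive opaque strings; no identifier mapping
    is performed. Homophilic pairs (ligand == receptor, e.g. cell-adhesion
    molecules) are allowed.
    """

    ligand: str
    receptor: str
    pathway: str
    rank: str
    source: str = ""
    mammalian_orthologs: tuple[str, ...] = ()
    ligand_annotation: str = ""
    receptor_annotation: str = ""

    def __post_init__(self) -> None:
        if not self.ligand or not self.receptor:
            raise KnowledgebaseValidationError(
                f"ligand and receptor must be non-empty (got ligand={self.ligand!r}, "
                f"receptor={self.receptor!r})"
            )
        if self.rank not in VALID_RANKS:
            raise KnowledgebaseValidationError(
                f"rank must be one of {sorted(VALID_RANKS)}, got {self.rank!r}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.ligand, self.receptor)


@dataclass(frozen=True)
class PathwayComponent:
    """A gene annotated with a role inside one signaling pathway."""

    pathway: str
    gene: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise KnowledgebaseValidationError(
                f"role must be one of {sorted(VALID_ROLES)}, got {self.role!r}"
            )


@dataclass
class Knowledgebase:
    """A collection of L-R pairs plus pathway component annotations."""

    pairs: list[LRPair] = field(default_factory=list)
    components: list[PathwayComponent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.pairs:
            raise KnowledgebaseValidationError("knowledgebase has no L-R pairs")
        seen: set[tuple[str, str]] = set()
        for pair in self.pairs:
            if pair.key in seen:
                raise KnowledgebaseValidationError(
                    f"duplicate (ligand, receptor) pair {pair.key}"
                )
            seen.add(pair.key)
        seen_comp: set[tuple[str, str, str]] = set()
        for comp in self.components:
            k = (comp.pathway, comp.gene, comp.role)
            if k in seen_comp:
                raise KnowledgebaseValidationError(
                    f"duplicate pathway component {k}"
                )
            seen_comp.add(k)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def pathways(self) -> list[str]:
        """Pathway names, in order of first appearance across pairs."""
        out: list[str] = []
        for p in self.pairs:
            if p.pathway not in out:
                out.append(p.pathway)
        return out

    def genes_by_role(self, role: str, pathway: str | None = None) -> list[str]:
        """Annotated genes with ``role``, optionally restricted to one pathway."""
        if role not in VALID_ROLES:
            raise KnowledgebaseValidationError(
                f"role must be one of {sorted(VALID_ROLES)}, got {role!r}"
            )
        out: list[str] = []
        for c in self.components:
            if c.role == role and (pathway is None or c.pathway == pathway):
                if c.gene not in out:
                    out.append(c.gene)
        return out

    def pairs_frame(self) -> pd.DataFrame:
        """Pairs as a DataFrame (list fields ``|``-joined)."""
        rows = [
            {
                "ligand": p.ligand,
                "receptor": p.receptor,
                "pathway": p.pathway,
                "rank": p.rank,
                "source": p.source,
                "mammalian_orthologs": "|".join(p.mammalian_orthologs),
                "ligand_annotation": p.ligand_annotation,
                "receptor_annotation": p.receptor_annotation,
            }
            for p in self.pairs
        ]
        return pd.DataFrame(rows, columns=PAIR_REQUIRED_COLUMNS + PAIR_OPTIONAL_COLUMNS)


def read_knowledgebase(pairs_path, components_path=None) -> Knowledgebase:
    """Read a knowledgebase from tab-delimited files.

    Parameters
    ----------
    pairs_path
        Tab-delimited table with header naming at least ``ligand``,
        ``receptor``, ``pathway`` and ``rank``. Optional columns: ``source``,
        ``mammalian_orthologs`` (``|``-joined list), ``ligand_annotation``,
        ``receptor_annotation``.
    components_path
        Optional companion table with columns ``pathway``, ``gene``, ``role``.

    Raises
    ------
    KnowledgebaseFormatError
        If a required column is missing.
    KnowledgebaseValidationError
        On unknown rank values (reported with row number) or duplicated
        (ligand, receptor) pairs.
    """
    df = pd.read_csv(pairs_path, sep="\t", dtype=str).fillna("")
    for col in PAIR_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise KnowledgebaseFormatError(
                f"pair table {pairs_path} is missing required column {col!r}"
            )
    pairs: list[LRPair] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        rank = getattr(row, "rank")
        if rank not in VALID_RANKS:
            raise KnowledgebaseValidationError(
                f"row {i} of {pairs_path}: rank {rank!r} is not one of "
                f"{sorted(VALID_RANKS)}"
            )
        orthologs = getattr(row, "mammalian_orthologs", "")
        pairs.append(
            LRPair(
                ligand=row.ligand,
                receptor=row.receptor,
                pathway=row.pathway,
                rank=rank,
                source=getattr(row, "source", ""),
                mammalian_orthologs=tuple(x for x in orthologs.split("|") if x),
                ligand_annotation=getattr(row, "ligand_annotation", ""),
                receptor_annotation=getattr(row, "receptor_annotation", ""),
            )
        )
    components: list[PathwayComponent] = []
    if components_path is not None:
        cdf = pd.read_csv(components_path, sep="\t", dtype=str).fillna("")
        for col in COMPONENT_COLUMNS:
            if col not in cdf.columns:
                raise KnowledgebaseFormatError(
                    f"component table {components_path} is missing column {col!r}"
                )
        components = [
            PathwayComponent(pathway=r.pathway, gene=r.gene, role=r.role)
            for r in cdf.itertuples(index=False)
        ]
    return Knowledgebase(pairs=pairs, components=components)


def write_knowledgebase(kb: Knowledgebase, pairs_path, components_path=None) -> None:
    """Write a knowledgebase to tab-delimited files (inverse of the reader)."""
    kb.validate()
    kb.pairs_frame().to_csv(pairs_path, sep="\t", index=False)
    if components_path is not None:
        cdf = pd.DataFrame(
            [(c.pathway, c.gene, c.role) for c in kb.components],
            columns=list(COMPONENT_COLUMNS),
        )
        cdf.to_csv(components_path, sep="\t", index=False)


def filter_by_rank(kb: Knowledgebase, ranks) -> Knowledgebase:
    """Keep only pairs whose confidence rank is in ``ranks``.

    Pathway component annotations are passed through unchanged.
    """
    ranks = set(ranks)
    if not ranks:
        raise ValueError("ranks must be a non-empty set")
    unknown = ranks - VALID_RANKS
    if unknown:
        raise ValueError(f"unknown ranks {sorted(unknown)}; valid: {sorted(VALID_RANKS)}")
    kept = [p for p in kb.pairs if p.rank in ranks]
    if not kept:
        raise KnowledgebaseValidationError(
            f"no pairs left after filtering to ranks {sorted(ranks)}"
        )
    return Knowledgebase(pairs=kept, components=list(kb.components))


def load_toy_knowledgebase() -> Knowledgebase:
    """Load the small packaged knowledgebase (10 pathways, 50 pairs).

    A synthetic stand-in for a full curated database, shipped so the whole
    pipeline runs out of the box; a user-supplied table loads through
    :func:`read_knowledgebase` with the same schema.
    """
    from importlib.resources import files

    data = files("lrcomm.data")
    return read_knowledgebase(
        str(data / "toy_pairs.tsv"), str(data / "toy_components.tsv")
    )


__all__ = [
    "LRPair",
    "PathwayComponent",
    "Knowledgebase",
    "KnowledgebaseFormatError",
    "KnowledgebaseValidationError",
    "read_knowledgebase",
    "write_knowledgebase",
    "filter_by_rank",
    "load_toy_knowledgebase",
    "VALID_RANKS",
    "VALID_ROLES",
]
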