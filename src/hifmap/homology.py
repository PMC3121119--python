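"""Pathway homology statistics: OrthNum/ParaNum and OrthRate/ParaRate.

A pathway is a set of nodes (ortholog groups, e.g. KEGG Orthology ids)
carrying the reference species' genes.  A homology table lists, per
reference gene and query species, the orthologous and paralogous query
genes.  Two indices quantify cross-species conservation of the pathway:

* OrthRate = OrthNum(query) / OrthNum(reference), where OrthNum counts
  pathway *nodes* with at least one ortholog in the query species — a
  conservation index in [0, 1];
* ParaRate = ParaNum(query) / ParaNum(reference), where ParaNum counts the
  distinct paralogous query genes summed over nodes — a flexibility index
  that may exceed 1 when the query species carries more duplicates than
  the reference.

``map_pathway`` annotates each node with the three-way shading used to
render a mapped pathway: white (no ortholog in the query), grey (ortholog
present, paralog count not above the reference's), black (ortholog present
and more query paralogs than reference paralogs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

from hifmap.errors import ValidationError

RELATIONS = ("ortholog", "paralog")
SHADING_LEVELS = ("absent", "equal_or_lower", "higher")


@dataclass(frozen=True)
class PathwayNode:
    node_id: str
    label: str
    reference_genes: tuple[str, ...] = ()

    def __init__(self, node_id, label, reference_genes=()):
        object.__setattr__(self, "node_id", node_id)
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "reference_genes", tuple(reference_genes))


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    reference_species: str
    nodes: tuple[PathwayNode, ...]
    edges: tuple[tuple[str, str, str], ...] = ()

    def __init__(self, pathway_id, reference_species, nodes, edges=()):
        nodes = tuple(nodes)
        ids = [n.node_id for n in nodes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate node_id in pathway")
        known = set(ids)
        edges = tuple(tuple(e) for e in edges)
        for e in edges:
            if e[0] not in known or e[1] not in known:
                raise ValidationError(f"edge {e!r} references an unknown node")
        object.__setattr__(self, "pathway_id", pathway_id)
        object.__setattr__(self, "reference_species", reference_species)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", edges)

    def node(self, node_id: str) -> PathwayNode:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)


class HomologyTable:
    """Records of (reference_gene, query_species, query_gene, relation)."""

    COLUMNS = ("reference_gene", "query_species", "query_gene", "relation")

    def __init__(self, records):
        df = pd.DataFrame(list(records), columns=self.COLUMNS)
        bad = set(df["relation"]) - set(RELATIONS)
        if bad:
            raise ValidationError(f"unknown relation values: {sorted(bad)}")
        if df.duplicated().any():
            dup = df[df.duplicated()].iloc[0]
            raise ValidationError(f"duplicate homology record: {tuple(dup)}")
        self.df = df

    @classmethod
    def from_tsv(cls, path) -> "HomologyTable":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        missing = set(cls.COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(
                f"homology table missing columns: {sorted(missing)}"
            )
        return cls(df[list(cls.COLUMNS)].itertuples(index=False, name=None))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def species(self) -> set[str]:
        return set(self.df["query_species"])

    def __len__(self) -> int:
        return len(self.df)


def _check_species(homology: HomologyTable, species: str) -> None:
    if species not in homology.species:
        raise ValidationError(
            f"unknown species code {species!r}; known: "
            f"{sorted(homology.species)}"
        )


def _node_relation_genes(
    node: PathwayNode, homology: HomologyTable, query_species: str, relation: str
) -> set[str]:
    df = homology.df
    sel = df[
        (df["query_species"] == query_species)
        & (df["relation"] == relation)
        & (df["reference_gene"].isin(node.reference_genes))
    ]
    return set(sel["query_gene"])


def orth_num(pathway: Pathway, homology: HomologyTable, query_species: str) -> int:
    """Number of pathway nodes with >= 1 ortholog in the query species.

    A node contributes at most 1 regardless of how many orthologous genes
    it has.  When the query is the reference species itself, any node with
    an assigned reference gene counts (self-orthology by convention).
    """
    if query_species not in homology.species:
        if query_species != pathway.reference_species:
            return 0
    total = 0
    for node in pathway.nodes:
        if query_species == pathway.reference_species:
            if node.reference_genes or _node_relation_genes(
                node, homology, query_species, "ortholog"
            ):
                total += 1
        elif _node_relation_genes(node, homology, query_species, "ortholog"):
            total += 1
    return total


def para_num(pathway: Pathway, homology: HomologyTable, query_species: str) -> int:
    """Total distinct paralogous query genes over all pathway nodes."""
    total = 0
    for node in pathway.nodes:
        total += len(_node_relation_genes(node, homology, query_species, "paralog"))
    return total


@dataclass(frozen=True)
class Rate:
    """A homology rate as numerator/denominator with percent renderings."""

    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator

    def percent(self, style: str = "percent_1dp") -> str:
        """Render as a percent string.

        ``percent_1dp``: one decimal place, trailing ".0" dropped
        ("92.9%", "100%").  ``whole_percent``: rounded to a whole percent
        ("33%").
        """
        pct = self.fraction * 100
        if style == "percent_1dp":
            s = f"{pct:.1f}".rstrip("0").rstrip(".")
            return f"{s}%"
        if style == "whole_percent":
            return f"{round(pct)}%"
        raise ValidationError(f"unknown percent style {style!r}")

    def ratio(self) -> str:
        return f"{self.numerator}/{self.denominator}"


def orth_rate(
    pathway: Pathway,
    homology: HomologyTable,
    query_species: str,
    reference_species: str | None = None,
) -> Rate:
    """OrthNum(query) / OrthNum(reference)."""
    reference_species = reference_species or pathway.reference_species
    den = orth_num(pathway, homology, reference_species)
    if den == 0:
        raise ValidationError(
            f"OrthRate undefined: reference {reference_species!r} has no "
            "orthologous nodes"
        )
    return Rate(orth_num(pathway, homology, query_species), den)


def para_rate(
    pathway: Pathway,
    homology: HomologyTable,
    query_species: str,
    reference_species: str | None = None,
) -> Rate:
    """ParaNum(query) / ParaNum(reference); may exceed 1."""
    reference_species = reference_species or pathway.reference_species
    den = para_num(pathway, homology, reference_species)
    if den == 0:
        raise ValidationError(
            f"ParaRate undefined: reference {reference_species!r} has no "
            "paralogous genes"
        )
    return Rate(para_num(pathway, homology, query_species), den)


@dataclass(frozen=True)
class MappedNode:
    node_id: str
    label: str
    ortholog_present: bool
    query_paralog_count: int
    reference_paralog_count: int
    shading: str


@dataclass(frozen=True)
class MappedPathway:
    pathway_id: str
    query_species: str
    reference_species: str
    nodes: tuple[MappedNode, ...]
    orth_num: int
    para_num: int
    orth_rate: Rate
    para_rate: Rate


def map_pathway(
    pathway: Pathway,
    homology: HomologyTable,
    query_species: str,
    reference_species: str | None = None,
) -> MappedPathway:
    """Project the pathway onto a query species with per-node shading."""
    reference_species = reference_species or pathway.reference_species
    for sp in (query_species, reference_species):
        if sp != pathway.reference_species:
            _check_species(homology, sp)
    mapped = []
    for node in pathway.nodes:
        if query_species == pathway.reference_species:
            present = bool(node.reference_genes)
        else:
            present = bool(
                _node_relation_genes(node, homology, query_species, "ortholog")
            )
        q_para = len(_node_relation_genes(node, homology, query_species, "paralog"))
        r_para = len(
            _node_relation_genes(node, homology, reference_species, "paralog")
        )
        if not present:
            shading = "absent"
        elif q_para > r_para:
            shading = "higher"
        else:
            shading = "equal_or_lower"
        mapped.append(
            MappedNode(
                node_id=node.node_id,
                label=node.label,
                ortholog_present=present,
                query_paralog_count=q_para,
                reference_paralog_count=r_para,
                shading=shading,
            )
        )
    return MappedPathway(
        pathway_id=pathway.pathway_id,
        query_species=query_species,
        reference_species=reference_species,
        nodes=tuple(mapped),
        orth_num=sum(n.ortholog_present for n in mapped),
        para_num=sum(n.query_paralog_count for n in mapped),
        orth_rate=orth_rate(pathway, homology, query_species, reference_species),
        para_rate=para_rate(pathway, homology, query_species, reference_species),
    )


# ---------------------------------------------------------------------------
# File I/O and rendering
# ---------------------------------------------------------------------------

def read_pathway_tsv(path, pathway_id=None, reference_species="HSA",
                     edges_path=None) -> Pathway:
    """Read a pathway node table: node_id, label, reference_genes
    (semicolon-joined, may be empty)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    nodes = [
        PathwayNode(
            node_id=row["node_id"],
            label=row["label"],
            reference_genes=tuple(
                g for g in row["reference_genes"].split(";") if g
            ),
        )
        for _, row in df.iterrows()
    ]
    edges = ()
    if edges_path is not None:
        edf = pd.read_csv(edges_path, sep="\t", comment="#", dtype=str)
        edges = tuple(
            (r["source"], r["target"], r.get("relation", ""))
            for _, r in edf.iterrows()
        )
    return Pathway(
        pathway_id=pathway_id or str(path),
        reference_species=reference_species,
        nodes=nodes,
        edges=edges,
    )


def write_pathway_tsv(pathway: Pathway, path) -> None:
    rows = [
        {
            "node_id": n.node_id,
            "label": n.label,
            "reference_genes": ";".join(n.reference_genes),
        }
        for n in pathway.nodes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def render_rate_cell(rate: Rate, style: str = "percent_1dp") -> str:
    """The published-style rate cell rendering, e.g. "12/14 (85.7%)"."""
    return f"{rate.ratio()} ({rate.percent(style)})"


def homology_report(
    pathway: Pathway,
    homology: HomologyTable,
    query_species_list: list[str],
    reference_species: str,
    style: str = "percent_1dp",
    phylogeny: dict[str, int] | None = None,
    header_lines: list[str] | None = None,
) -> str:
    """Render the per-species OrthNum/OrthRate/ParaNum/ParaRate summary
    table; rate cells for the reference species itself read "N/A"."""
    lines = list(header_lines or [])
    cols = ["species", "OrthNum", "OrthRate", "ParaNum", "ParaRate"]
    if phylogeny:
        cols.insert(1, "Phylogeny")
    lines.append("\t".join(cols))
    for sp in query_species_list:
        on = orth_num(pathway, homology, sp)
        pn = para_num(pathway, homology, sp)
        if sp == reference_species:
            orate, prate = "N/A", "N/A"
        else:
            orate = render_rate_cell(
                orth_rate(pathway, homology, sp, reference_species), style
            )
            prate = render_rate_cell(
                para_rate(pathway, homology, sp, reference_species), style
            )
        row = [sp, str(on), orate, str(pn), prate]
        if phylogeny:
            row.insert(1, str(phylogeny.get(sp, "")))
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


_DOT_FILL = {"absent": "white", "equal_or_lower": "grey75", "higher": "grey25"}
_DOT_FONT = {"absent": "black", "equal_or_lower": "black", "higher": "white"}


def mapped_pathway_to_dot(
    mapped: MappedPathway, pathway: Pathway | None = None,
    header_lines: list[str] | None = None,
) -> str:
    """Graphviz DOT rendering with fill colours keyed to shading (white =
    no ortholog, grey = equal or fewer paralogs, dark = more paralogs)."""
    lines = [f"// {h.lstrip('# ')}" for h in (header_lines or [])]
    lines.append(f'digraph "{mapped.pathway_id}" {{')
    lines.append("  node [shape=box style=filled];")
    for n in mapped.nodes:
        lines.append(
            f'  "{n.node_id}" [label="{n.label}" fillcolor={_DOT_FILL[n.shading]}'
            f" fontcolor={_DOT_FONT[n.shading]}"
            f' tooltip="paralogs {mapped.query_species}:{n.query_paralog_count}'
            f' {mapped.reference_species}:{n.reference_paralog_count}"];'
        )
    if pathway is not None:
        for src, dst, rel in pathway.edges:
            attr = f' [label="{rel}"]' if rel else ""
            lines.append(f'  "{src}" -> "{dst}"{attr};')
    lines.append("}")
    return "\n".join(lines) + "\n"


def mapped_pathway_to_json(mapped: MappedPathway, meta: dict | None = None) -> str:
    payload = {
        "meta": meta or {},
        "pathway_id": mapped.pathway_id,
        "query_species": mapped.query_species,
        "reference_species": mapped.reference_species,
        "orth_num": mapped.orth_num,
        "para_num": mapped.para_num,
        "orth_rate": {
            "numerator": mapped.orth_rate.numerator,
            "denominator": mapped.orth_rate.denominator,
            "fraction": mapped.orth_rate.fraction,
            "percent": mapped.orth_rate.percent(),
        },
        "para_rate": {
            "numerator": mapped.para_rate.numerator,
            "denominator": mapped.para_rate.denominator,
            "fraction": mapped.para_rate.fraction,
            "percent": mapped.para_rate.percent(),
        },
        "nodes": [
            {
                "node_id": n.node_id,
                "label": n.label,
                "ortholog_present": n.ortholog_present,
                "query_paralog_count": n.query_paralog_count,
                "reference_paralog_count": n.reference_paralog_count,
                "shading": n.shading,
            }
            for n in mapped.nodes
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"
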