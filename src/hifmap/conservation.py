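"""Multi-cutoff TFBS conservation statistics over gene sets.

For a gene set (one gene per species for an orthologous set; several genes
of one species for a paralogous set; or a seeded random baseline) and a
panel of score matrices, each cell of the conservation table counts the
matrix's hits in one member's promoter at each similarity cut-off of a
strictly decreasing profile (default 0.85 / 0.80 / 0.75).  Two summaries
mirror the standard report layout:

* pervasiveness — per matrix and cut-off, the number of members with at
  least one hit ("# of species/genes possessing the identical TFBS");
* totals — per member and cut-off, the hit count summed over matrices
  ("Total identified motifs").

Matrices are ranked by pervasiveness at the strictest cut-off, then by
total hit count, then lexicographically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from hifmap.errors import ValidationError
from hifmap.matrices import MotifMatrix
from hifmap.scanning import PromoterSequence, scan

DEFAULT_CUTOFFS = (0.85, 0.80, 0.75)

SET_KINDS = ("orthologous", "paralogous", "random")


@dataclass(frozen=True)
class CutoffProfile:
    """A strictly decreasing tuple of normalised-score cut-offs in (0, 1]."""

    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS

    def __post_init__(self):
        cs = tuple(float(c) for c in self.cutoffs)
        if not cs:
            raise ValidationError("cutoff profile is empty")
        if any(not (0 < c <= 1) for c in cs):
            raise ValidationError("cutoffs must lie in (0, 1]")
        if any(a <= b for a, b in zip(cs, cs[1:])):
            raise ValidationError("cutoffs must be strictly decreasing")
        object.__setattr__(self, "cutoffs", cs)

    @property
    def strictest(self) -> float:
        return self.cutoffs[0]

    def __iter__(self):
        return iter(self.cutoffs)

    def __len__(self):
        return len(self.cutoffs)


@dataclass(frozen=True)
class GeneSet:
    """Members of a conservation comparison, each with a promoter."""

    set_kind: str
    members: tuple[tuple[str, str, PromoterSequence | None], ...]
    provenance: str = ""

    def __init__(self, set_kind, members, provenance=""):
        if set_kind not in SET_KINDS:
            raise ValidationError(f"unknown gene-set kind {set_kind!r}")
        members = tuple(tuple(m) for m in members)
        species = [m[1] for m in members]
        if set_kind == "orthologous" and len(set(species)) != len(species):
            raise ValidationError(
                "orthologous gene sets allow at most one member per species"
            )
        if set_kind == "paralogous" and len(set(species)) > 1:
            raise ValidationError("paralogous gene sets span exactly one species")
        object.__setattr__(self, "set_kind", set_kind)
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "provenance", provenance)

    @property
    def labels(self) -> tuple[str, ...]:
        """Display label per member: species for orthologous sets (one gene
        per species), gene id otherwise."""
        if self.set_kind == "orthologous":
            return tuple(m[1] for m in self.members)
        return tuple(m[0] for m in self.members)


@dataclass
class ConservationTable:
    """Hit counts per (matrix, member, cutoff) with summary operations."""

    cutoffs: CutoffProfile
    members: tuple[str, ...]
    counts: dict[str, tuple[tuple[int, ...], ...]]  # matrix_id -> per member
    set_kind: str = "orthologous"
    provenance: str = ""

    def __post_init__(self):
        self.members = tuple(self.members)
        nc = len(self.cutoffs)
        for mid, per_member in self.counts.items():
            per_member = tuple(tuple(int(c) for c in v) for v in per_member)
            if len(per_member) != len(self.members):
                raise ValidationError(
                    f"matrix {mid!r}: {len(per_member)} count vectors for "
                    f"{len(self.members)} members"
                )
            for vec in per_member:
                if len(vec) != nc:
                    raise ValidationError(
                        f"matrix {mid!r}: count vector length {len(vec)} != "
                        f"{nc} cutoffs"
                    )
                if any(a > b for a, b in zip(vec, vec[1:])):
                    raise ValidationError(
                        f"matrix {mid!r}: counts must be non-decreasing as "
                        "the cutoff relaxes"
                    )
            self.counts[mid] = per_member

    @property
    def matrix_ids(self) -> tuple[str, ...]:
        return tuple(self.counts)

    def cell(self, matrix_id: str, member: str) -> tuple[int, ...]:
        return self.counts[matrix_id][self.members.index(member)]


def count_hits(
    geneset: GeneSet,
    matrices: list[MotifMatrix],
    cutoffs: CutoffProfile | None = None,
    strand_mode: str = "forward",
) -> ConservationTable:
    """Scan every member's promoter with every matrix and tabulate hit
    counts at each cut-off of the profile.

    Hit sets are nested across cut-offs by construction (a single scan at
    the loosest cut-off is thresholded at each stricter one), so each cell
    vector is non-decreasing as the cut-off relaxes.
    """
    cutoffs = cutoffs or CutoffProfile()
    if not matrices:
        raise ValidationError("no matrices supplied")
    for gene_id, species, promoter in geneset.members:
        if promoter is None:
            raise ValidationError(f"gene {gene_id!r} has no promoter sequence")
    counts: dict[str, tuple[tuple[int, ...], ...]] = {}
    loosest = min(cutoffs)
    for matrix in matrices:
        per_member = []
        for gene_id, species, promoter in geneset.members:
            hits = scan(promoter, matrix, cutoff=loosest, strand_mode=strand_mode)
            scores = np.array([h.norm_score for h in hits])
            per_member.append(
                tuple(int((scores >= c).sum()) for c in cutoffs)
            )
        counts[matrix.matrix_id] = tuple(per_member)
    return ConservationTable(
        cutoffs=cutoffs,
        members=geneset.labels,
        counts=counts,
        set_kind=geneset.set_kind,
        provenance=geneset.provenance,
    )


def pervasiveness(table: ConservationTable, matrix_id: str, cutoff: float) -> int:
    """Number of members with >= 1 hit of the matrix at the cut-off."""
    if matrix_id not in table.counts:
        raise KeyError(matrix_id)
    ci = table.cutoffs.cutoffs.index(cutoff)
    return sum(vec[ci] >= 1 for vec in table.counts[matrix_id])


def totals(table: ConservationTable, member: str, cutoff: float) -> int:
    """Hit count summed over matrices for one member at the cut-off."""
    mi = table.members.index(member)
    ci = table.cutoffs.cutoffs.index(cutoff)
    return sum(per_member[mi][ci] for per_member in table.counts.values())


def rank_tfs(table: ConservationTable) -> list[str]:
    """Matrices in priority order: pervasiveness at the strictest cut-off
    descending, then total hits at that cut-off descending, then id."""
    if not table.counts:
        raise ValidationError("cannot rank an empty conservation table")
    strictest = table.cutoffs.strictest
    ci = table.cutoffs.cutoffs.index(strictest)

    def key(mid: str):
        perv = pervasiveness(table, mid, strictest)
        total = sum(vec[ci] for vec in table.counts[mid])
        return (-perv, -total, mid)

    return sorted(table.counts, key=key)


def random_gene_set(
    pool: list[tuple[str, str, PromoterSequence]],
    size: int,
    seed: int,
    constraint: str = "one_per_species",
    exclude: set[str] | None = None,
) -> GeneSet:
    """Draw a seeded random baseline gene set from a candidate pool.

    ``one_per_species`` draws ``size`` distinct species, one gene each;
    ``within_species`` draws ``size`` genes from a single-species pool.
    Genes in ``exclude`` (e.g. homologs of the comparison set) are never
    selected.
    """
    if constraint not in ("one_per_species", "within_species"):
        raise ValidationError(f"unknown constraint {constraint!r}")
    exclude = exclude or set()
    candidates = [m for m in pool if m[0] not in exclude]
    rng = np.random.default_rng(seed)
    if constraint == "one_per_species":
        by_species: dict[str, list] = {}
        for m in candidates:
            by_species.setdefault(m[1], []).append(m)
        species = sorted(by_species)
        if len(species) < size:
            raise ValidationError(
                f"pool has {len(species)} species, {size} required"
            )
        chosen_species = [
            species[i]
            for i in sorted(rng.choice(len(species), size=size, replace=False))
        ]
        members = [
            by_species[sp][int(rng.integers(len(by_species[sp])))]
            for sp in chosen_species
        ]
        kind_note = "one_per_species"
    else:
        species = {m[1] for m in candidates}
        if len(species) > 1:
            raise ValidationError(
                "within_species constraint requires a single-species pool; "
                f"got {sorted(species)}"
            )
        if len(candidates) < size:
            raise ValidationError(
                f"pool has {len(candidates)} candidates, {size} required"
            )
        idx = sorted(rng.choice(len(candidates), size=size, replace=False))
        members = [candidates[int(i)] for i in idx]
        kind_note = "within_species"
    return GeneSet(
        set_kind="random",
        members=members,
        provenance=f"seed={seed} constraint={kind_note} pool={len(pool)}",
    )


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def _cell_str(vec: tuple[int, ...]) -> str:
    return "/".join(str(v) for v in vec)


def table_to_tsv(
    table: ConservationTable, header_lines: list[str] | None = None
) -> str:
    """Render with one "a/b/c" cell per cut-off profile, a pervasiveness
    column, and a totals row, mirroring the standard report layout."""
    lines = list(header_lines or [])
    lines.append(f"# cutoffs\t{_cell_str(table.cutoffs.cutoffs)}")
    if table.provenance:
        lines.append(f"# provenance\t{table.provenance}")
    perv_header = (
        "# of species possessing the identical TFBS"
        if table.set_kind == "orthologous"
        else "# of genes possessing the identical TFBS"
    )
    lines.append("\t".join(["TF ID", *table.members, perv_header]))
    for mid in rank_tfs(table):
        per_member = table.counts[mid]
        perv = tuple(
            pervasiveness(table, mid, c) for c in table.cutoffs
        )
        lines.append(
            "\t".join([mid, *(_cell_str(v) for v in per_member), _cell_str(perv)])
        )
    total_cells = [
        _cell_str(tuple(totals(table, member, c) for c in table.cutoffs))
        for member in table.members
    ]
    lines.append("\t".join(["Total identified motifs", *total_cells, "-"]))
    return "\n".join(lines) + "\n"


def table_to_json(table: ConservationTable, meta: dict | None = None) -> str:
    payload = {
        "meta": meta or {},
        "set_kind": table.set_kind,
        "provenance": table.provenance,
        "cutoffs": list(table.cutoffs.cutoffs),
        "members": list(table.members),
        "counts": {mid: [list(v) for v in vecs] for mid, vecs in table.counts.items()},
        "pervasiveness": {
            mid: [pervasiveness(table, mid, c) for c in table.cutoffs]
            for mid in table.counts
        },
        "totals": {
            member: [totals(table, member, c) for c in table.cutoffs]
            for member in table.members
        },
        "ranking": rank_tfs(table),
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"
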