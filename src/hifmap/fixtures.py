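"""Bundled reference data and synthetic promoter generation.

Two kinds of test-ready input live here:

* a fixture bundle transcribing the published HIF study inputs — the
  14-node HIF subpathway of the renal cell carcinoma pathway (hsa05211),
  per-species ortholog/paralog tables whose OrthNum/ParaNum totals match
  the published statistics, the aligned 18-bp HRE windows found in VEGF
  ortholog promoters with their TSS-relative coordinates, and the
  multi-cutoff hit-count grids of the orthologous/paralogous vs random
  comparisons.  Gene identities for unnamed homologs are synthetic
  placeholders ("MMU_VEGF_para1"): the published counts, not identities,
  are the reproducible surface.

* a seeded synthetic promoter generator: i.i.d. background sequence of a
  stated base composition with motif windows implanted at known
  TSS-relative coordinates, plus the implant truth table.  It emulates
  upstream regions only — no chromatin, no CpG islands, no positional
  bias of real promoters.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from hifmap.conservation import ConservationTable, CutoffProfile
from hifmap.errors import ValidationError
from hifmap.homology import HomologyTable, Pathway, orth_num, para_num, read_pathway_tsv
from hifmap.matrices import ALPHABET, AlignedSiteSet
from hifmap.scanning import PromoterSequence

#: Published per-species pathway homology statistics (OrthNum, ParaNum)
#: against the human reference, used to re-validate the bundle on load.
PUBLISHED_PATHWAY_STATS = {
    "HSA": (14, 24),
    "MMU": (14, 26),
    "GGA": (13, 20),
    "XTR": (9, 8),
    "DRE": (12, 23),
    "CIN": (9, 9),
}

#: Phylogenetic rank metadata (1 = reference), treated as given.
PHYLOGENY = {"HSA": 1, "MMU": 2, "GGA": 3, "XTR": 4, "DRE": 5, "CIN": 6}

SPECIES_ORDER = ("HSA", "MMU", "GGA", "XTR", "DRE", "CIN")

#: The one transcribed HRE row whose printed coordinate span (12
#: positions) contradicts its 18-bp window; excluded from coordinate
#: checks.
INCONSISTENT_HRE_ROWS = (("XTR", "ENSXETG00000016375", "TAATCGCGTGCTGATAAC"),)


def data_path(name: str):
    """Path-like handle to a bundled data file."""
    return resources.files("hifmap.data") / name


@dataclass(frozen=True)
class HreSiteRecord:
    species: str
    gene_id: str
    window: str
    start: int
    end: int


@dataclass(frozen=True)
class FixtureBundle:
    hif_pathway: Pathway
    homology: HomologyTable
    hre_sites: tuple[HreSiteRecord, ...]
    table3_orthologous: ConservationTable
    table3_random: ConservationTable
    table4_paralogous: ConservationTable
    table4_random: ConservationTable
    phylogeny: dict[str, int]

    def hre_site_set(
        self, species: str | None = None, gene_id: str | None = None
    ) -> AlignedSiteSet:
        """The aligned HRE windows, optionally restricted to one species
        and/or gene."""
        rows = [
            r
            for r in self.hre_sites
            if (species is None or r.species == species)
            and (gene_id is None or r.gene_id == gene_id)
        ]
        if not rows:
            raise ValidationError("no HRE sites match the requested filter")
        return AlignedSiteSet(
            site_ids=[f"{r.species}:{r.gene_id}:{r.start}" for r in rows],
            sequences=[r.window for r in rows],
        )


def _load_grid(name: str, block: str, set_kind: str) -> ConservationTable:
    df = pd.read_csv(data_path(name), sep="\t", dtype=str)
    df = df[df["block"] == block]
    members = list(dict.fromkeys(df["member"]))
    counts = {}
    for mid, sub in df.groupby("matrix_id", sort=False):
        sub = sub.set_index("member").loc[members]
        counts[mid] = tuple(
            (int(r["c085"]), int(r["c080"]), int(r["c075"]))
            for _, r in sub.iterrows()
        )
    return ConservationTable(
        cutoffs=CutoffProfile((0.85, 0.80, 0.75)),
        members=members,
        counts=counts,
        set_kind=set_kind,
        provenance=f"transcribed:{name}:{block}",
    )


def load_fixture_bundle() -> FixtureBundle:
    """Load and re-validate the bundled study fixtures.

    Validation recomputes every per-species OrthNum/ParaNum from the
    homology table and checks the HRE windows' geometry (18 bp, CGTG core
    at columns 7-10); any mismatch raises a corrupted-fixture error.
    """
    pathway = read_pathway_tsv(
        data_path("hif_pathway.tsv"),
        pathway_id="hsa05211/HIF-subpathway",
        reference_species="HSA",
        edges_path=data_path("hif_pathway_edges.tsv"),
    )
    homology = HomologyTable.from_tsv(data_path("homology.tsv"))
    sites_df = pd.read_csv(data_path("hre_sites.tsv"), sep="\t", dtype=str)
    hre_sites = tuple(
        HreSiteRecord(
            species=r["species"],
            gene_id=r["gene_id"],
            window=r["window"],
            start=int(r["start"]),
            end=int(r["end"]),
        )
        for _, r in sites_df.iterrows()
    )
    bundle = FixtureBundle(
        hif_pathway=pathway,
        homology=homology,
        hre_sites=hre_sites,
        table3_orthologous=_load_grid("table3_counts.tsv", "orthologous",
                                      "orthologous"),
        table3_random=_load_grid("table3_counts.tsv", "random", "random"),
        table4_paralogous=_load_grid("table4_counts.tsv", "paralogous",
                                     "paralogous"),
        table4_random=_load_grid("table4_counts.tsv", "random", "random"),
        phylogeny=dict(PHYLOGENY),
    )
    _validate_bundle(bundle)
    return bundle


def _validate_bundle(bundle: FixtureBundle) -> None:
    if len(bundle.hif_pathway.nodes) != 14:
        raise ValidationError("corrupted fixture: HIF pathway must have 14 nodes")
    for sp, (expected_on, expected_pn) in PUBLISHED_PATHWAY_STATS.items():
        on = orth_num(bundle.hif_pathway, bundle.homology, sp)
        pn = para_num(bundle.hif_pathway, bundle.homology, sp)
        if (on, pn) != (expected_on, expected_pn):
            raise ValidationError(
                f"corrupted fixture: {sp} OrthNum/ParaNum = {on}/{pn}, "
                f"expected {expected_on}/{expected_pn}"
            )
    inconsistent = {(s, g, w) for s, g, w in INCONSISTENT_HRE_ROWS}
    for r in bundle.hre_sites:
        if len(r.window) != 18 or r.window[6:10] != "CGTG":
            raise ValidationError(
                f"corrupted fixture: HRE window {r.window!r} lacks the "
                "18-bp geometry with CGTG at columns 7-10"
            )
        if (r.species, r.gene_id, r.window) in inconsistent:
            continue
        if r.end - r.start + 1 != 18:
            raise ValidationError(
                f"corrupted fixture: HRE window {r.window!r} coordinate "
                f"span {r.end - r.start + 1} != 18"
            )


# ---------------------------------------------------------------------------
# Synthetic promoters with implanted motifs
# ---------------------------------------------------------------------------

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class ImplantSpec:
    """A motif window to overwrite into one promoter at a known place."""

    gene_id: str
    window: str
    start: int  # TSS-relative coordinate of the most-upstream base
    strand: str = "+"

    @property
    def end(self) -> int:
        return self.start + len(self.window) - 1


def generate_promoters(
    n: int,
    extent: int = 2000,
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND,
    implants: list[ImplantSpec] | None = None,
    seed: int = 0,
    species: str = "SYN",
    gene_prefix: str = "synth",
) -> tuple[list[PromoterSequence], list[ImplantSpec]]:
    """Draw ``n`` i.i.d.-background promoters and implant motif windows.

    Promoter ids are ``{gene_prefix}{k}`` for k = 1..n; implants address
    promoters by gene id and are overwritten at their TSS-relative
    coordinates (a '-' strand implant inserts the reverse complement of
    its window).  Returns the promoters and the implant truth table.
    Fully reproducible for a fixed seed.
    """
    from hifmap.scanning import reverse_complement

    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or (background < 0).any() or not np.isclose(
        background.sum(), 1.0
    ):
        raise ValidationError("background must be 4 probabilities summing to 1")
    implants = list(implants or [])
    by_gene: dict[str, list[ImplantSpec]] = {}
    for imp in implants:
        if imp.start < -extent or imp.end > -1:
            raise ValidationError(
                f"implant {imp.window!r} at {imp.start} does not fit in a "
                f"{extent}-bp upstream region"
            )
        if imp.strand not in ("+", "-"):
            raise ValidationError(f"implant strand must be + or -, got {imp.strand!r}")
        by_gene.setdefault(imp.gene_id, []).append(imp)
    for gene_id, specs in by_gene.items():
        specs.sort(key=lambda s: s.start)
        for a, b in zip(specs, specs[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"overlapping implants in {gene_id!r}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )
    rng = np.random.default_rng(seed)
    promoters = []
    for k in range(1, n + 1):
        gene_id = f"{gene_prefix}{k}"
        draws = rng.choice(4, size=extent, p=background)
        chars = list("".join(ALPHABET[i] for i in draws))
        for imp in by_gene.get(gene_id, ()):
            window = imp.window if imp.strand == "+" else reverse_complement(
                imp.window
            )
            idx = imp.start + extent
            chars[idx : idx + len(window)] = window
        promoters.append(
            PromoterSequence(
                gene_id=gene_id,
                species=species,
                sequence="".join(chars),
                upstream_extent=extent,
            )
        )
    return promoters, implants


def implants_to_tsv(implants: list[ImplantSpec], matrix_id: str = "") -> str:
    lines = ["gene_id\tmatrix_id\tstart\tend\tstrand\twindow"]
    for imp in implants:
        lines.append(
            f"{imp.gene_id}\t{matrix_id}\t{imp.start}\t{imp.end}"
            f"\t{imp.strand}\t{imp.window}"
        )
    return "\n".join(lines) + "\n"
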