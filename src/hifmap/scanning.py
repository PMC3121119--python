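"""PSSM scanning of promoter sequences in TSS-relative coordinates.

A promoter is the upstream region of a gene read 5'->3' on the annotated
strand; positions are negative integers counting upstream from the
transcription start site (TSS), with -1 immediately adjacent to it.  A
window's raw score is the sum of the matrix entries matched by its bases;
the normalised score rescales it to [0, 1] between the matrix's achievable
minimum and maximum, so fixed similarity cut-offs (0.85 by default, with
0.80 and 0.75 as relaxed profiles) are comparable across matrices.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from hifmap.errors import ValidationError
from hifmap.matrices import MotifMatrix, encode, expand_core

logger = logging.getLogger(__name__)

DEFAULT_UPSTREAM_EXTENT = 2000
DEFAULT_CUTOFF = 0.85

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PromoterSequence:
    """An upstream region with a TSS-relative coordinate convention.

    ``upstream_extent`` is the distance upstream of the TSS of the first
    base, so base ``j`` (1-based string index) sits at coordinate
    ``-upstream_extent + (j - 1)`` and the whole sequence lies strictly
    upstream of the TSS.
    """

    gene_id: str
    species: str
    sequence: str
    upstream_extent: int = 0

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        extent = self.upstream_extent or len(self.sequence)
        object.__setattr__(self, "upstream_extent", extent)
        if extent <= 0:
            raise ValidationError("upstream_extent must be positive")
        if len(self.sequence) > extent:
            raise ValidationError(
                f"promoter {self.gene_id!r}: sequence length "
                f"{len(self.sequence)} exceeds upstream extent {extent}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def coordinate(self, index: int) -> int:
        """TSS-relative coordinate of the 0-based string ``index``."""
        return -self.upstream_extent + index

    def index(self, coordinate: int) -> int:
        """0-based string index of a TSS-relative ``coordinate``."""
        return coordinate + self.upstream_extent


@dataclass(frozen=True)
class MotifHit:
    """One scored window of a matrix on a promoter."""

    gene_id: str
    species: str
    matrix_id: str
    strand: str
    start: int  # TSS-relative, inclusive, most-upstream end
    end: int
    window: str
    raw_score: float
    norm_score: float
    core_exact: bool


def score_window(matrix: MotifMatrix, window: str) -> float:
    """Raw score of one window: the sum of matched matrix entries."""
    if matrix.form != "score":
        raise ValidationError("score_window expects a score-form matrix")
    if len(window) != matrix.width:
        raise ValidationError(
            f"window length {len(window)} != matrix width {matrix.width}"
        )
    idx = encode(window)
    return float(matrix.values[idx, np.arange(matrix.width)].sum())


def normalize_score(matrix: MotifMatrix, raw: float) -> float:
    """Min-max rescale a raw score to [0, 1] using the matrix bounds."""
    if matrix.form != "score":
        raise ValidationError("normalize_score expects a score-form matrix")
    span = matrix.max_score - matrix.min_score
    if span == 0:
        if raw == matrix.max_score:
            return 1.0
        raise ValidationError(
            "degenerate matrix (min_score == max_score) cannot normalise "
            f"raw score {raw}"
        )
    return (raw - matrix.min_score) / span


def window_has_core(matrix: MotifMatrix, window: str) -> bool:
    """True iff the window carries the matrix core exactly at the core
    columns (ambiguity codes in the core match any allowed base)."""
    if matrix.core is None:
        return False
    core_string, core_start = matrix.core
    allowed = expand_core(core_string)
    return all(
        window[core_start - 1 + j] in bases for j, bases in enumerate(allowed)
    )


def scan(
    seq: PromoterSequence,
    matrix: MotifMatrix,
    cutoff: float = DEFAULT_CUTOFF,
    strand_mode: str = "forward",
) -> list[MotifHit]:
    """Slide the matrix over the promoter and report windows above cutoff.

    One hit is emitted per window position (and per strand in ``both``
    mode, scoring the reverse complement of the window) whose normalised
    score reaches ``cutoff``.  Hits are ordered by start coordinate, then
    strand (+ before -).  Overlapping hits are all reported.
    """
    if strand_mode not in ("forward", "both"):
        raise ValidationError(f"unknown strand_mode {strand_mode!r}")
    w = matrix.width
    L = len(seq.sequence)
    if L < w:
        logger.warning(
            "promoter %s (%d bp) shorter than matrix %s width %d; no hits",
            seq.gene_id, L, matrix.matrix_id, w,
        )
        return []
    enc = encode(seq.sequence)
    n = L - w + 1
    span = matrix.max_score - matrix.min_score
    hits: list[MotifHit] = []

    def collect(raw: np.ndarray, strand: str, windows) -> None:
        if span == 0:
            norm = np.where(raw == matrix.max_score, 1.0, np.nan)
            if np.isnan(norm).any():
                raise ValidationError("degenerate matrix cannot be normalised")
        else:
            norm = np.clip((raw - matrix.min_score) / span, 0.0, 1.0)
        for j in np.flatnonzero(norm >= cutoff):
            start = seq.coordinate(int(j))
            window = windows(int(j))
            hits.append(
                MotifHit(
                    gene_id=seq.gene_id,
                    species=seq.species,
                    matrix_id=matrix.matrix_id,
                    strand=strand,
                    start=start,
                    end=start + w - 1,
                    window=window,
                    raw_score=float(raw[j]),
                    norm_score=float(norm[j]),
                    core_exact=window_has_core(matrix, window),
                )
            )

    raw_fwd = np.zeros(n)
    for i in range(w):
        raw_fwd += matrix.values[enc[i : i + n], i]
    collect(raw_fwd, "+", lambda j: seq.sequence[j : j + w])

    if strand_mode == "both":
        raw_rev = np.zeros(n)
        for i in range(w):
            # column i of the matrix reads the complement of forward
            # position j + w - 1 - i
            raw_rev += matrix.values[3 - enc[w - 1 - i : w - 1 - i + n], i]
        collect(
            raw_rev, "-", lambda j: reverse_complement(seq.sequence[j : j + w])
        )

    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def top_core_hits(hits: list[MotifHit], k: int = 3) -> list[MotifHit]:
    """The k best core-exact hits of one (gene, matrix) pair.

    Sorted by normalised score descending; ties go to the hit closer to
    the TSS (larger start coordinate), then to the + strand.
    """
    core = [h for h in hits if h.core_exact]
    core.sort(key=lambda h: (-h.norm_score, -h.start, h.strand))
    return core[:k]


# ---------------------------------------------------------------------------
# FASTA and hit-table I/O
# ---------------------------------------------------------------------------

def read_promoters_fasta(path) -> list[PromoterSequence]:
    """Read promoters from FASTA with ``gene_id|species|upstream_extent``
    headers; a missing extent defaults to the sequence length."""
    promoters = []
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.id.split("|")
        gene_id = parts[0]
        species = parts[1] if len(parts) > 1 else "NA"
        extent = int(parts[2]) if len(parts) > 2 else len(record.seq)
        promoters.append(
            PromoterSequence(
                gene_id=gene_id,
                species=species,
                sequence=str(record.seq),
                upstream_extent=extent,
            )
        )
    return promoters


def write_promoters_fasta(promoters: list[PromoterSequence], path) -> None:
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(f">{p.gene_id}|{p.species}|{p.upstream_extent}\n")
            for i in range(0, len(p.sequence), 70):
                fh.write(p.sequence[i : i + 70] + "\n")


HIT_FIELDS = (
    "gene_id", "species", "matrix_id", "strand", "start", "end",
    "window", "raw_score", "norm_score", "core_exact",
)


def hits_to_tsv(hits: list[MotifHit], header_lines: list[str] | None = None) -> str:
    lines = list(header_lines or [])
    lines.append("\t".join(HIT_FIELDS))
    for h in hits:
        lines.append(
            "\t".join(
                [h.gene_id, h.species, h.matrix_id, h.strand, str(h.start),
                 str(h.end), h.window, f"{h.raw_score:.6f}",
                 f"{h.norm_score:.6f}", str(h.core_exact).lower()]
            )
        )
    return "\n".join(lines) + "\n"


def hits_to_json(hits: list[MotifHit], meta: dict | None = None) -> str:
    payload = {
        "meta": meta or {},
        "hits": [
            {f: getattr(h, f) for f in HIT_FIELDS} for h in hits
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"
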