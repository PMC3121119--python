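"""Construction, transformation, and file I/O of TF-binding matrices.

A matrix is a 4 x width grid over the fixed alphabet A, C, G, T, in one of
three forms:

``count``
    integer observation counts per column (column sums equal the number of
    aligned sites);
``frequency``
    column-stochastic base probabilities;
``score``
    the grid actually used for scanning, together with the achievable
    ``min_score`` / ``max_score`` raw-score bounds that anchor the
    normalised [0, 1] matrix-similarity score.

The default score form keeps the frequencies verbatim, so a window's raw
score is the sum of matched-base frequencies and the familiar 0.85 / 0.80 /
0.75 similarity cut-offs apply; a log-odds score form is available as an
alternative.

The module also builds the custom hypoxia-response-element (HRE) matrix:
an 18-bp profile with the mandatory CGTG core fixed at columns 7-10 and
tolerant flanks estimated from aligned binding sites.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass

import numpy as np
from Bio import motifs as bio_motifs

from hifmap.errors import ParseError, ValidationError

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: IUPAC ambiguity codes, used in core-string specifications only.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

DEFAULT_PSEUDOCOUNT = 0.01
HRE_MATRIX_ID = "V$HIF_STKE_2005"
HRE_CORE = "CGTG"
HRE_CORE_START = 7
HRE_WIDTH = 18


def expand_core(core_string: str) -> list[str]:
    """Expand an IUPAC-coded core into the allowed base set per position."""
    try:
        return [IUPAC[c] for c in core_string.upper()]
    except KeyError as exc:
        raise ValidationError(f"unknown IUPAC code in core string: {exc.args[0]!r}")


def encode(sequence: str) -> np.ndarray:
    """Encode an A/C/G/T string as an int8 array of row indices."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    if (out < 0).any():
        bad = sequence[int(np.argmin(out >= 0))]
        raise ValidationError(f"non-ACGT symbol {bad!r} in sequence")
    return out


@dataclass(frozen=True)
class AlignedSiteSet:
    """A gapless alignment of equal-length binding sites."""

    site_ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __init__(self, site_ids, sequences):
        object.__setattr__(self, "site_ids", tuple(site_ids))
        object.__setattr__(self, "sequences", tuple(s.upper() for s in sequences))
        self._validate()

    def _validate(self) -> None:
        if not self.sequences:
            raise ValidationError("aligned site set is empty")
        if len(self.site_ids) != len(self.sequences):
            raise ValidationError("site_ids and sequences differ in length")
        width = len(self.sequences[0])
        if width < 1:
            raise ValidationError("site width must be >= 1")
        for sid, seq in zip(self.site_ids, self.sequences):
            if len(seq) != width:
                raise ValidationError(
                    f"site {sid!r} has length {len(seq)}, expected {width}"
                )
            if any(c not in _BASE_INDEX for c in seq):
                raise ValidationError(f"site {sid!r} contains a non-ACGT symbol")

    @property
    def width(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class MotifMatrix:
    """A 4 x width matrix over A, C, G, T in count, frequency, or score form.

    ``values[k, i]`` is the entry for base ``ALPHABET[k]`` at column ``i``
    (0-based internally; file dialects and error messages use 1-based
    columns).  ``core`` optionally pins a mandatory core sub-motif:
    ``(core_string, core_start)`` with a 1-based start column; the core
    string may use IUPAC ambiguity codes.
    """

    matrix_id: str
    form: str  # count | frequency | score
    values: np.ndarray
    core: tuple[str, int] | None = None
    min_score: float | None = None
    max_score: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 4:
            raise ValidationError("matrix values must be a 4 x width grid")
        if self.form not in ("count", "frequency", "score"):
            raise ValidationError(f"unknown matrix form {self.form!r}")
        if self.form == "count":
            if (self.values < 0).any() or not np.allclose(
                self.values, np.round(self.values)
            ):
                raise ValidationError("count matrices require non-negative integers")
        elif self.form == "frequency":
            if (self.values < 0).any():
                raise ValidationError("frequency entries must be non-negative")
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValidationError("frequency matrix columns must each sum to 1")
        else:  # score
            if self.min_score is None:
                self.min_score = float(self.values.min(axis=0).sum())
            if self.max_score is None:
                self.max_score = float(self.values.max(axis=0).sum())
            if self.min_score > self.max_score:
                raise ValidationError("min_score exceeds max_score")
        if self.core is not None:
            core_string, core_start = self.core
            expand_core(core_string)
            if core_start < 1 or core_start + len(core_string) - 1 > self.width:
                raise ValidationError(
                    f"core {core_string!r} at column {core_start} does not fit "
                    f"in a width-{self.width} matrix"
                )

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def consensus(self) -> str:
        """Column-wise argmax sequence; ties broken alphabetically."""
        return "".join(ALPHABET[k] for k in self.values.argmax(axis=0))


def build_count_matrix(sites: AlignedSiteSet, matrix_id: str = "counts") -> MotifMatrix:
    """Tally per-column base counts from a gapless site alignment."""
    values = np.zeros((4, sites.width))
    for seq in sites.sequences:
        values[encode(seq), np.arange(sites.width)] += 1
    return MotifMatrix(matrix_id=matrix_id, form="count", values=values)


def to_frequency(
    counts: MotifMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> MotifMatrix:
    """Convert counts to column-stochastic frequencies.

    Each cell receives ``pseudocount`` observations before normalising, so
    the column denominator is ``N + 4 * pseudocount``.
    """
    if counts.form != "count":
        raise ValidationError("to_frequency expects a count-form matrix")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    n = counts.values.sum(axis=0)
    if (n == 0).any():
        raise ValidationError("cannot normalise an empty count matrix")
    values = (counts.values + pseudocount) / (n + 4 * pseudocount)
    return MotifMatrix(
        matrix_id=counts.matrix_id, form="frequency", values=values, core=counts.core
    )


def to_score(
    freq: MotifMatrix,
    mode: str = "frequency",
    background: np.ndarray | None = None,
) -> MotifMatrix:
    """Turn a frequency matrix into a score matrix.

    mode="frequency" keeps the probabilities verbatim (a window's raw score
    is the sum of matched-base frequencies); mode="log_odds" uses
    log2(freq / background) and therefore requires strictly positive
    frequencies (build the frequency matrix with a pseudocount).
    """
    if freq.form != "frequency":
        raise ValidationError("to_score expects a frequency-form matrix")
    if mode == "frequency":
        values = freq.values.copy()
    elif mode == "log_odds":
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        if background.shape != (4,) or (background <= 0).any() or not math.isclose(
            background.sum(), 1.0, abs_tol=1e-9
        ):
            raise ValidationError(
                "background must be 4 strictly positive probabilities summing to 1"
            )
        if (freq.values == 0).any():
            raise ValidationError(
                "log-odds scoring requires strictly positive frequencies; "
                "rebuild the frequency matrix with a pseudocount > 0"
            )
        values = np.log2(freq.values / background[:, None])
    else:
        raise ValidationError(f"unknown score mode {mode!r}")
    return MotifMatrix(
        matrix_id=freq.matrix_id, form="score", values=values, core=freq.core
    )


def build_hre_matrix(
    sites: AlignedSiteSet,
    core_string: str = HRE_CORE,
    core_start: int = HRE_CORE_START,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    matrix_id: str = HRE_MATRIX_ID,
) -> MotifMatrix:
    """Build the HRE score matrix from aligned 18-mers with a fixed core.

    Every input site must carry the core (default CGTG, 1-based start
    column 7) exactly; a site violating the core is rejected by name.  Core
    columns put all probability on the observed core base (no pseudocount),
    so any core mismatch forfeits the full column score; flank columns use
    observed frequencies smoothed by ``pseudocount``.
    """
    allowed = expand_core(core_string)
    core_cols = range(core_start - 1, core_start - 1 + len(core_string))
    if core_start < 1 or core_start + len(core_string) - 1 > sites.width:
        raise ValidationError(
            f"core {core_string!r} at column {core_start} does not fit in "
            f"width-{sites.width} sites"
        )
    for sid, seq in zip(sites.site_ids, sites.sequences):
        for j, col in enumerate(core_cols):
            if seq[col] not in allowed[j]:
                raise ValidationError(
                    f"site {sid!r} lacks core {core_string!r} at column "
                    f"{core_start}: found {seq[col]!r} at column {col + 1}"
                )
    counts = build_count_matrix(sites, matrix_id=matrix_id)
    n = len(sites)
    values = np.empty((4, sites.width))
    for i in range(sites.width):
        col = counts.values[:, i]
        if i in core_cols:
            values[:, i] = col / n  # exact core: no smoothing
        else:
            values[:, i] = (col + pseudocount) / (n + 4 * pseudocount)
    return MotifMatrix(
        matrix_id=matrix_id,
        form="score",
        values=values,
        core=(core_string, core_start),
    )


# ---------------------------------------------------------------------------
# File dialects
# ---------------------------------------------------------------------------

DIALECTS = ("transfac_flat", "jaspar_pfm", "native_tsv")


def write_matrix(matrix: MotifMatrix, path, dialect: str = "native_tsv") -> None:
    with open(path, "w") as fh:
        fh.write(format_matrix(matrix, dialect))


def format_matrix(matrix: MotifMatrix, dialect: str = "native_tsv") -> str:
    if dialect == "native_tsv":
        lines = [f"# id\t{matrix.matrix_id}", f"# form\t{matrix.form}"]
        if matrix.core is not None:
            lines.append(f"# core\t{matrix.core[0]}\t{matrix.core[1]}")
        lines.append("pos\tA\tC\tG\tT")
        for i in range(matrix.width):
            row = "\t".join(repr(float(v)) for v in matrix.values[:, i])
            lines.append(f"{i + 1}\t{row}")
        return "\n".join(lines) + "\n"
    if dialect == "transfac_flat":
        lines = [f"AC  {matrix.matrix_id}", "XX", f"ID  {matrix.matrix_id}", "XX",
                 "P0      A      C      G      T"]
        for i in range(matrix.width):
            row = "  ".join(repr(float(v)) for v in matrix.values[:, i])
            lines.append(f"{i + 1:02d}  {row}")
        lines += ["XX", "//"]
        return "\n".join(lines) + "\n"
    if dialect == "jaspar_pfm":
        lines = [f">{matrix.matrix_id}"]
        for k, base in enumerate(ALPHABET):
            row = " ".join(repr(float(v)) for v in matrix.values[k])
            lines.append(f"{base} [ {row} ]")
        return "\n".join(lines) + "\n"
    raise ValidationError(f"unknown matrix dialect {dialect!r}")


def _infer_form(values: np.ndarray) -> str:
    if np.allclose(values, np.round(values)) and (values >= 0).all():
        return "count"
    if (values >= 0).all() and np.allclose(values.sum(axis=0), 1.0, atol=1e-9):
        return "frequency"
    return "score"


def read_matrix(path, dialect: str = "native_tsv") -> MotifMatrix:
    with open(path) as fh:
        text = fh.read()
    if dialect == "native_tsv":
        return _parse_native_tsv(text)
    if dialect == "transfac_flat":
        return _parse_transfac(text)
    if dialect == "jaspar_pfm":
        return _parse_jaspar(text, fallback_id=_stem(path))
    raise ValidationError(f"unknown matrix dialect {dialect!r}")


def _stem(path) -> str:
    name = str(path).rsplit("/", 1)[-1]
    return name.rsplit(".", 1)[0]


def _parse_native_tsv(text: str) -> MotifMatrix:
    matrix_id, form, core = "matrix", None, None
    cols: list[list[float]] = []
    expected_pos = 1
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if parts[0] == "id" and len(parts) > 1:
                matrix_id = parts[1]
            elif parts[0] == "form" and len(parts) > 1:
                form = parts[1]
            elif parts[0] == "core" and len(parts) > 2:
                core = (parts[1], int(parts[2]))
            continue
        if line.startswith("pos"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ParseError(
                f"expected 5 tab-separated fields, got {len(parts)}", line=lineno
            )
        try:
            pos = int(parts[0])
            vals = [float(v) for v in parts[1:]]
        except ValueError:
            raise ParseError(f"malformed matrix row {line!r}", line=lineno)
        if pos != expected_pos:
            raise ParseError(
                f"row out of order: position {pos}, expected {expected_pos}",
                line=lineno,
            )
        expected_pos += 1
        cols.append(vals)
    if not cols:
        raise ParseError("no matrix rows found")
    values = np.array(cols).T
    return MotifMatrix(
        matrix_id=matrix_id,
        form=form or _infer_form(values),
        values=values,
        core=core,
    )


def _parse_transfac(text: str) -> MotifMatrix:
    # Locate the first malformed line for diagnostics before handing the
    # block to Biopython's TRANSFAC parser.
    row_re = re.compile(r"^\d\d\s")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if row_re.match(raw):
            fields = raw.split()
            if len(fields) < 5:
                raise ParseError(
                    f"TRANSFAC matrix row has {len(fields) - 1} columns, "
                    "expected at least 4",
                    line=lineno,
                )
    try:
        records = bio_motifs.parse(io.StringIO(text), "TRANSFAC")
    except Exception as exc:
        raise ParseError(f"malformed TRANSFAC flat file: {exc}")
    if not records:
        raise ParseError("no matrix block found in TRANSFAC flat file")
    record = records[0]
    values = np.array([list(record.counts[b]) for b in ALPHABET])
    matrix_id = record.get("ID") or record.get("AC") or "matrix"
    return MotifMatrix(matrix_id=matrix_id, form=_infer_form(values), values=values)


def _parse_jaspar(text: str, fallback_id: str = "matrix") -> MotifMatrix:
    fmt = "jaspar" if text.lstrip().startswith(">") else "pfm"
    try:
        record = bio_motifs.read(io.StringIO(text), fmt)
    except Exception as exc:
        raise ParseError(f"malformed JASPAR/PFM file: {exc}")
    values = np.array([list(record.counts[b]) for b in ALPHABET])
    matrix_id = getattr(record, "matrix_id", None) or record.name or fallback_id
    return MotifMatrix(matrix_id=matrix_id, form=_infer_form(values), values=values)
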