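# Methods

## Pathway homology model

A pathway is a set of nodes, each an ortholog group (KEGG-Orthology-style
id) holding the reference species' gene(s). Homology is an input table of
(reference gene, query species, query gene, relation ∈ {ortholog,
paralog}) records — the package never infers homology from sequence.

OrthNum counts *nodes* with at least one ortholog in the query species: a
node with several orthologous query genes still contributes 1, which is
what bounds OrthNum by the node count and keeps OrthRate in [0, 1].
ParaNum counts distinct paralogous query genes summed over nodes, so
ParaRate = ParaNum(query)/ParaNum(reference) is unbounded above and reads
as a redundancy/flexibility index. The ParaRate denominator is the
reference's own ParaNum, not the pathway node count — the two readings
disagree in prose formulations of such rates, and the worked per-species
values only reproduce under the ParaNum denominator, so that is the
definition implemented. Self-comparison is defined as 1.0 by convention;
the tabular report renders the reference row's rate cells as "N/A".

Percent rendering supports two styles because published tables of this
kind mix them: `percent_1dp` (one decimal, trailing ".0" dropped:
"92.9%", "100%", "108.3%") and `whole_percent` ("33%", "83%"). The
default is `percent_1dp`.

Mapped-pathway shading is three-valued and purely per node: `absent`
(no ortholog in the query) ⇔ white; `higher` (ortholog present and
strictly more query paralogs than reference paralogs) ⇔ dark;
`equal_or_lower` otherwise ⇔ grey. The DOT export uses
white/grey75/grey25 fills.

## Motif model

Matrices are 4×width grids over the fixed alphabet A, C, G, T, in count,
frequency, or score form. The score form used throughout is the
*frequency-sum* convention: score entries are the column-stochastic
frequencies themselves, a window's raw score is the sum of matched-base
frequencies, and the normalised score is

    norm = (raw − min_score) / (max_score − min_score)

with `max_score`/`min_score` the column-wise max/min sums — so the
consensus scores exactly 1 and fixed cut-offs (0.85/0.80/0.75) act as
matrix-similarity thresholds comparable across matrices of different
widths and information content. This convention was chosen because such
normalised cut-offs are only meaningful on bounded similarity scores; a
log-odds score form (`to_score(mode="log_odds")`, log2 freq/background,
requiring a pseudocount upstream) is provided for users who want
likelihood-ratio scoring, but it is not the default and the fixed
cut-offs are not calibrated for it.

The HRE matrix builder takes aligned 18-mers that all carry the
mandatory core (default CGTG at 1-based columns 7–10; geometry
overridable) and produces a score matrix whose core columns put all
probability on the observed core base with **no** pseudocount — a core
mismatch therefore forfeits that column's entire contribution, which is
the operational meaning of a "mandatory" core. Flank columns get
observed frequencies smoothed by a per-cell pseudocount (default 0.01;
0 allowed explicitly). Core strings may use IUPAC codes (e.g. RCGTG);
an ambiguous core position accepts any allowed base both at build time
and in hit `core_exact` flags. Whether real HRE flanks should be
frequency-weighted or uniformly tolerant is not settled; this package
weights them by the observed site frequencies, which is what makes the
pooled 29-site matrix discriminative (input sites score 0.70–0.90,
median 0.82 — consistent with per-gene hit counts of 0–3 at cut-off
0.85) while a per-gene 3-site matrix scores its own sites ≥ 0.92.

Consensus extraction breaks column ties alphabetically (A < C < G < T)
for determinism.

## Scanning and coordinates

Promoters are upstream regions read 5′→3′ on the annotated strand;
`upstream_extent` is the distance upstream of the TSS of the first base,
so string index *j* (1-based) has TSS-relative coordinate
−extent + (*j* − 1), −1 abuts the TSS, and a width-18 hit is reported
inclusively as e.g. −963~−946. The default extent is 2000 bp.

Scanning is vectorised (one NumPy gather per matrix column) and scores
every window; default strand handling is forward-only, since reported
HRE windows are forward-strand substrings; `both` scores each window's
reverse complement as well and reports it on the − strand at the same
coordinates. All hits above cut-off are reported — no greedy masking of
overlaps. A sequence shorter than the matrix width yields an empty
result with a logged warning rather than an error. `top_core_hits`
filters to core-exact hits and returns the best *k* (default 3, the
number conventionally displayed per gene), tie-breaking by TSS proximity
(larger start) and then + strand.

Degenerate matrices (min_score = max_score) normalise only their own
max; any other raw value is an error rather than a silent 0/0.

## Conservation tables

`count_hits` scans once per (member, matrix) at the loosest cut-off and
thresholds the hit list at each stricter one, so cell count vectors are
nested by construction and validated as non-decreasing toward looser
cut-offs. Pervasiveness and totals are pure summaries of the stored
grid; `rank_tfs` orders by pervasiveness at the strictest cut-off, then
total hits at that cut-off, then id — the two tie-breaks are this
package's determinism choice on top of the "pervasiveness and
frequency" priority rule. "Possessing the identical TFBS" is
operationalised as ≥ 1 hit of the same matrix at the cut-off; every
bundled summary cell reproduces under this rule except one grand-total
cell whose printed source value contradicts its own column cells (the
self-consistent column sum is used; see the count-grid fixture notes).

Random baselines require an explicit candidate pool and seed
(`numpy.random.default_rng`); `one_per_species` draws distinct species
then one gene each, `within_species` samples without replacement from a
single-species pool, and an exclusion list (e.g. homologs of the signal
set) is never selected. The baseline generator does not match promoter
length or GC by default; pools should be constructed accordingly when
that matters.

## Synthetic promoters

`generate_promoters` draws i.i.d. bases from a stated composition
(uniform by default) and overwrites implant windows at given
TSS-relative coordinates (− strand implants insert the reverse
complement); overlapping implants within one promoter are rejected.
This emulates exactly what the scanner needs — known ground truth at
known coordinates over a known background — and none of what real
promoters add: CpG islands, repeats, positional bias of functional
sites, phylogenetic correlation between orthologous promoters. Passing
implant-recovery and signal-vs-baseline tests therefore demonstrates
correctness of scoring, normalisation and coordinates, not performance
on genomic sequence.

Test and acceptance problem sizes are desk-scale by design: 100
promoters × 2000 bp for implant recovery, 100 replicates of 6-member
signal vs 6-member baseline sets (three implanted consensus HREs per
signal promoter, mirroring the three sites displayed per gene in the
bundled site table), 500 random (sequence ≤ 200 bp, width ≤ 8) pairs
for the brute-force scanner oracle.

## Bundled fixtures

The bundle transcribes the published HIF study inputs: the 14-node HIF
subpathway of the renal cell carcinoma pathway (VHL E3 complex — VHL,
CUL2, ELOB, ELOC, RBX1; HIF1A, ARNT, EP300, EGLN; and the targets GLUT1,
VEGF, TGFB1, PDGFB, TGFA), per-species homology tables, the 29 aligned
18-bp HRE windows with coordinates, and the multi-cutoff count grids of
the orthologous/paralogous vs random comparisons. Only the per-species
*counts* are published for most homologs, so fixture gene ids are
synthetic placeholders ("MMU_VEGF_para1"), except the three zebrafish
VEGF-node paralogs, which carry their published ids. Loading re-derives
every per-species OrthNum/ParaNum from the homology table and re-checks
the HRE window geometry; a mismatch raises a corrupted-fixture error.
One transcribed HRE row has an 18-bp window but a printed 12-position
coordinate span; it is kept verbatim, flagged in
`INCONSISTENT_HRE_ROWS`, and excluded from span checks.

## File formats

TRANSFAC-flat and JASPAR/PFM matrix files are parsed with Biopython's
`Bio.motifs`; writers are formatted by this package so that round trips
preserve values to 1e-9 (stock writers round to two decimals). These two
dialects carry values and matrix id only; the native TSV dialect
additionally records form, core string, and core column. Promoter FASTA
headers are `gene_id|species|upstream_extent` (extent defaults to the
sequence length). Reports are TSV with `#` comment headers carrying the
tool version, a configuration hash, and the seed; graphs are DOT.

## Known limitations

- No statistical calibration of motif scores (no p-values) and no
  significance testing of conservation counts; the tables report raw
  counts, as in the source analyses.
- Orthology/paralogy are inputs, never inferred; no KGML/KEGG retrieval.
- The proprietary TRANSFAC matrix library is not shipped; its ids
  (V$HIF1_Q5 etc.) appear only as labels on transcribed count grids,
  and tests use stand-in matrices.
- Forward-strand scanning by default; reported scores in the source
  tables cannot be regenerated without the proprietary matrices and the
  original promoter retrievals, which is why the grids are transcribed
  rather than recomputed.
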