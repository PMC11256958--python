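# Methods

## The POCP computation

Two proteomes A and B (T1 and T2 proteins) are compared in both
directions. A protein of the query proteome is *conserved* in the subject
proteome when at least one of its local alignment hits passes all three
filters with strict inequalities:

- e-value < 1e-5,
- percent identity > 40,
- alignable query region > 50% of the query length.

The strictness follows the original criteria verbatim ("<" and ">"), so a
hit sitting exactly on a boundary is rejected; `FilterCriteria(strict=False)`
switches to closed comparisons if a user needs to mimic a tool with the
other convention. Conservation is existential — *any* passing hit
qualifies a protein, not only its best hit — which also makes the result
independent of hit-table row order; a protein with several passing HSPs
counts once. With directed conserved counts C1 (A→B) and C2 (B→A),

    POCP = 100 · (C1 + C2) / (T1 + T2).

The value is stored at full precision and rounded to two decimals only in
output files. The diagonal of a POCP matrix is set to 100.00 by convention
without computation: self-comparison is uninformative, and the internal
e-value approximation could make very short self-hits fail the e-value
filter, which would only confuse. In one-vs-all mode uncomputed cells are
written as `NA`, never zero-filled. The summary's genus count uses strict
`pocp > 50` (configurable threshold); the 50% limit was proposed without
boundary semantics, so the filter convention is reused.

Known caveat, reported but not corrected: unequal proteome sizes bias
POCP — a small proteome against a large one caps the achievable value at
(T1 + min(T1,T2) · c)/(T1+T2)-style ceilings regardless of biology.

## Percent identity and coverage conventions

Identity follows the BLAST `pident` convention: identical columns divided
by *all* alignment columns, including gap columns. Coverage is defined on
the query as 100 · (qend − qstart + 1) / qlen, i.e. the aligned query
*span*: query-internal gaps cannot inflate it, and with 12-column tabular
input the span is the only query-side measure available anyway.
Subject-side coverage is not computed. Tabular input is the standard
12-column `outfmt 6` (qseqid sseqid pident length mismatch gapopen qstart
qend sstart send evalue bitscore), optionally with a 13th `qlen` column;
without it, query lengths are looked up in the query FASTA, which is why
FASTA ids are the first whitespace-delimited header token — the token
aligners echo back.

## The built-in aligner

Exact Smith–Waterman with affine gaps (Gotoh three-state DP): a gap of
length g costs gap_open + g·gap_extend, default BLOSUM62 with 11/1 — the
BLASTP protein defaults the published filter thresholds were calibrated
against. The kernel is numba-compiled (nogil), with a score-only
rolling-row pass used to screen proteome cross-products and a full
pointer/traceback pass run only when a hit's score can matter. Traceback
tie-breaking on equal cell scores prefers diagonal, then gap-in-subject,
then gap-in-query; only the score is guaranteed unique, so co-optimal
alignments may differ in identity/coverage between implementations (the
oracle tests compare scores only). One optimal alignment is reported per
(query, subject) pair — no sub-optimal HSPs; since conservation is
existential over hits and the optimal alignment dominates, extra HSPs
could only matter for borderline pairs.

E-values use the Karlin–Altschul form E = K·m·n·e^(−λS) with the
published gapped BLOSUM62/11/1 parameters λ = 0.267, K = 0.041, and the
*pairwise* search space m·n (individual query × subject lengths). There is
no database-wide length, edge-effect, or composition correction, and no
low-complexity masking (DIAMOND masks by default). Consequences worth
knowing: internal e-values are systematically *smaller* than
database-wide BLAST/DIAMOND e-values, and borderline hits can differ from
external aligners; the identity and coverage filters dominate the
conservation decision in practice. For a protein aligned to an identical
copy, E < 1e-5 requires S > ln(K·m·n/1e-5)/λ ≈ 73 at m = n = 250 — any
self-alignment of ≳20 residues clears it, so the 100-residue minimum used
in the synthetic fixtures leaves enormous margin.

`align_proteomes(..., max_evalue=...)` drops pairs whose optimal score
already implies an e-value above the cutoff before traceback; passing
hit sets are unchanged (such hits could never be conserved), and the
default `None` emits every non-empty alignment.

## Synthetic proteomes

The generator emulates the one-FASTA-per-strain input of a taxonomic
study: n proteins per proteome (default lengths 100–400 residues,
i.i.d. residues from the BLOSUM62 background frequencies), of which
round(n·f) are copied between the two proteomes, under fresh ids, for a
constructed shared fraction f; expected POCP is 100·f. Optional point
mutations substitute each shared-copy site with probability r to a
uniformly random different residue (no indels), pushing expected identity
to 100·(1−r)% — r = 0.7 drops shared proteins below the 40% identity
filter, which is how tests exercise the filter's bite. Everything is
deterministic under the seed, to the byte in written FASTA.

What this does *not* emulate: paralogy and gene families, domain
shuffling, length/composition heterogeneity of real proteomes, indels,
and annotation noise. Passing the recovery tests shows the pipeline
measures what it is fed exactly; it does not validate the biological
interpretation of POCP on real genomes, where annotation choices alone
shift values by percents.

Background-frequency sequences keep chance similarity negligible: at the
study sizes used here, unrelated protein pairs essentially never pass all
three filters at once (the f = 0 recovery runs measure POCP 0.0), so the
±2-point recovery tolerance is in practice slack.

## Problem sizes and numerical choices

The acceptance checks use 100-protein proteomes for the self-identity
run, 20 random 30-protein pairs for symmetry/bounds, and 200-protein
pairs for the shared-fraction grid {0, 0.25, 0.5, 0.75, 1} — together a
few minutes on one CPU, dominated by the ~4×10⁵ Smith–Waterman problems
of the recovery grid. Scores are integer arithmetic throughout, so oracle
comparisons are exact, not tolerance-based. Degenerate inputs are errors,
not silent results: empty FASTA files, duplicate record ids or proteome
labels, internal stop codons, unmappable residues, malformed tabular rows
(with line numbers), unknown one-vs-all targets, and missing directed hit
tables (named by expected filename). Sequences are sanitized on input —
trailing `*` stripped, lowercase uppercased, U/O/J mapped to X — so the
aligner never sees a residue outside the 24-letter matrix alphabet.

## Design choices where the design was open

- Proteome labels derive from the file basename with one extension
  stripped; stable matrix headers under the one-file-per-strain input
  convention.
- Hit-table files are one per *directed* pair, named
  `<query>__vs__<subject>.tsv`; both directions are required, mirroring
  the bidirectional definition of the metric.
- Pairs may be computed on several threads (the alignment kernels release
  the GIL); results are assembled in deterministic label order regardless
  of completion order, so outputs are byte-identical across thread
  counts.
- Nonstandard criteria warn — prominently, with the changed values and
  the tool version — but never error, and the warning is copied into the
  run log.

## Limitations

- The built-in aligner is exact but quadratic per pair with no heuristic
  seeding; for many large proteomes, align externally (DIAMOND/BLASTP)
  and ingest the tabular output instead.
- E-values are approximate in the ways described above; do not compare
  them numerically against BLAST/DIAMOND e-values near the cutoff.
- Genome (nucleotide) input and gene prediction are out of scope; inputs
  are protein FASTA files.
- No clustering, dendrogram, or heatmap rendering of the matrix.
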