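# pocp

Percentage of conserved proteins (POCP) between prokaryotic proteomes — a
genome-based similarity index used to assess genus boundaries in bacterial
taxonomy.

## The metric

For two annotated proteomes with T1 and T2 proteins, count the proteins of
each that have at least one alignment hit in the other satisfying,
simultaneously and strictly,

    e-value < 1e-5,    identity > 40%,    alignable query region > 50%.

With C1 and C2 the two directed conserved counts,

    POCP = 100 · (C1 + C2) / (T1 + T2)

symmetric by construction and bounded in [0, 100]. A POCP above 50% was
originally proposed as a signal that two strains belong to the same genus;
it is one metric among several (alongside ANI, dDDH, and 16S similarity)
and unequal proteome sizes bias it, so interpret it in context.

`pocp` is aimed at microbial taxonomists who have protein FASTA files (one
per genome/strain, e.g. from Prokka) and want reproducible pairwise POCP
matrices. Alignments come from either

- the **built-in aligner**: exact Smith–Waterman, BLOSUM62 with affine
  gaps 11/1, and Karlin–Altschul e-values E = K·m·n·e^(−λS) over the
  pairwise search space — no external binaries needed; or
- **precomputed hit tables** in standard 12/13-column BLAST/DIAMOND
  tabular format (`outfmt 6`), one file per directed proteome pair, for
  large datasets aligned elsewhere.

## Worked example

```bash
pocp synth -n 8 -f 0.5 --seed 3 -o demo        # proteome pair sharing 50% of proteins
pocp run -p demo/synthA.faa -p demo/synthB.faa -o demo/out
cat demo/out/pocp_matrix.tsv
```

prints

```
computed 1 pairwise POCP value(s) -> demo/out
min 50.00  mean 50.00  max 50.00  pairs above 50% genus threshold: 0

	synthA	synthB
synthA	100.00	50.00
synthB	50.00	100.00
```

The two proteomes were constructed to share exactly half of their
proteins, and the full pipeline (alignment → filters → counting) recovers
POCP = 50.00; the diagonal is 100.00 by convention. At 50.00 the pair is
*not* above the strict >50% genus threshold. `pocp run` writes four files
into `--outdir`: the square matrix (`pocp_matrix.tsv`), a long table with
the per-pair counts C1/C2/T1/T2 (`pocp_pairs.tsv`), summary statistics
(`pocp_summary.tsv`), and a `run.log` recording the version, criteria, and
input manifest so any shared result is traceable to its configuration.
Changing any conservation threshold away from the original definition
prints a prominent warning (results are then not comparable with published
POCP values).

Other entry points: `pocp run --target LABEL` switches to one-vs-all
comparisons, `pocp run --hits-dir DIR` consumes external
`<query>__vs__<subject>.tsv` hit tables, `pocp filter` counts conserved
proteins in a single directed table, and `pocp summarize` recomputes
summary statistics from a long table. The same functionality is available
from Python (`pocp.compute_matrix`, `pocp.compare_pair`, ...); the
`examples/` directory holds short narrative scripts for each capability.

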