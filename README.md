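# rasodesign

Tools for finding nonsense mutations amenable to **readthrough-inducing
antisense oligonucleotides (R-ASOs)** and for designing those oligos.

Nonsense mutations convert a sense codon into a premature stop (UAA, UAG or
UGA), truncating the protein; they underlie a large fraction of severe
genetic disorders (cystic fibrosis, Duchenne muscular dystrophy, Alagille
syndrome, Rett syndrome, hereditary cancers). An antisense oligonucleotide
annealing just downstream of the premature stop — with its target window
starting at position **+8**, where +1 is the first stop nucleotide — can
sterically inhibit translation termination at the ribosomal mRNA entry
channel and so induce readthrough of that specific stop codon, without
touching normal stop codons elsewhere. Whether this works depends on the
local mRNA context: the stop codon itself (UGA > UAG > UAA), the +4 base
(a purine makes a "strong" termination site, a pyrimidine a "weak" one),
and above all the bases the ASO pairs — a **+8 G**, a G-run at +8..+11 and
higher downstream GC content all favour readthrough.

The package implements the computational side of this strategy, for
researchers triaging variant databases or designing reporter/oligo panels:

- `variant_context` — FASTA/variant-CSV ingestion, stop-codon validation,
  extraction of the +1..+27 context windows, strong/weak classification.
- `susceptibility` — IUPAC consensus matching over +8..+27, a transparent
  weighted amenability score, position-frequency matrices (WebLogo-style
  information content), and degenerate RY-template expansion.
- `aso_designer` — reverse-complement design at any register (+4..+12),
  length scans, nearest-neighbor duplex Tm (DNA:RNA hybrid by default),
  double-oligo conjugates (+8 plus +34), mismatch controls, and validation
  of sugar/backbone chemistry (D/M/F/L per base, O/S per linkage) against
  the empirical modification-tolerance rules.
- `cohort_pipeline` — build a premature-stop context database from a
  cohort, query it with a consensus, and summarize (matches, unique genes,
  pathogenic subset, +4 C subset, fraction of the database).
- `kinetics` — maximal translation rate (RLU/s) from real-time
  luminescence, termination rate constants `k_obs` from exponential-plateau
  fits `Y(t) = YM − (YM − Y0)·e^(−k·t)`, and 4-parameter-logistic EC50
  fits for dose–response curves.
- `synthetic_data` — seeded generators for all of the above inputs with
  recorded ground truth.

## Worked example

Simulate a cohort, build and query the context database, and summarize:

```sh
raso simulate cohort --out-dir demo --seed 1
raso build-db --fasta demo/transcripts.fasta --variants demo/variants.csv \
      --out demo/db.csv
raso query --db demo/db.csv --out demo/matched.csv
raso summarize --db demo/db.csv --matched demo/matched.csv --out demo/summary.json
```

which prints

```
wrote 500 variant rows (35 consensus matches) to demo
wrote 470 context rows (30 excluded) to demo/db.csv
35 of 470 rows match
{
  "n_matches": 35,
  "n_unique_genes": 32,
  "n_pathogenic": 24,
  "n_plus4C": 8,
  "fraction_of_db": 0.07446808510638298,
  "per_stop_codon": { "TGA": 15, "TAA": 12, "TAG": 8 },
  "n_unique_contexts": 35
}
```

Of 500 simulated variant rows, the 20 frameshift-derived stops and the 10
contexts truncated at the 3′ end are routed to the exclusion log
(`demo/db.log.csv`), leaving 470 context rows; 35 match the configured +8
consensus, in 32 distinct genes, 24 of them labelled (likely) pathogenic
and 8 with the favourable weak +4 C — exactly the counts the generator
planted.

Designing a register series against a stop-anchored segment from Python:

```python
>>> from rasodesign import design_aso
>>> seg = "TGACAATGGCACGTTGCAACGGATTCCGGAATTCCGGATC"  # +1 = first stop base
>>> aso = design_aso(seg, target_start=8, length=20)
>>> aso.sequence, round(aso.tm_c, 1)
('GGAATCCGTTGCAACGTGCC', 62.5)
```

The 20-mer pairs mRNA +8..+27; its 3′-terminal base pairs position +8,
next to the ribosomal mRNA entrance. `raso design --mode register` emits
the full +4..+12 panel with Tm-matched lengths, and
`raso fit-kinetics --mode plateau` fits release kinetics from trace CSVs.

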