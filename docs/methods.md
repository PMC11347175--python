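# Methods

This note documents the models, conventions and numerical choices behind
`rasodesign`, and what the synthetic-data generator does and does not
emulate.

## Coordinates and alphabets

All positions are stop-anchored: **+1 is the first nucleotide of the
premature stop codon**, so +4 is the first downstream base, the immediate
context is +4..+7, and the R-ASO target window is +8..+27. The external
interface is 1-based inclusive; internal slicing is 0-based half-open,
which removes off-by-one ambiguity at window boundaries. Sequences are
held as DNA (`ACGT`); `U` is accepted on input and converted, and stop
codons are rendered in the RNA alphabet (UGA/UAG/UAA) only in
classification output. IUPAC ambiguity codes are rejected in transcript
sequences — the pipeline assumes resolved coding sequences — but are the
vocabulary of consensus patterns and templates.

Contexts whose transcript ends before +27 are **rejected, never padded**;
the exclusion log records the transcript and the available length. Frame
validation against position 1 is available but off by default, because
reporter constructs need not start with the CDS.

## Consensus matching and the amenability score

A consensus is an IUPAC string anchored at a stop-relative position
(default +8) with a mismatch budget (default 0, i.e. grep-like degenerate
matching). A position mismatches when the context base falls outside the
IUPAC character's allowed set. The shipped default pattern
`GRRRNNYNNNNNNNNNNNNN` is **illustrative**: it encodes only the
established qualitative determinants (+8 G required, purines tolerated at
+9..+11, a pyrimidine at +14, no constraint elsewhere); any real analysis
should supply its own pattern via the run config. Near-consensus contexts
(e.g. a single +14 deviation) can be admitted by raising `max_mismatch`.

The susceptibility score is a transparent weighted sum,

    score = w_stop[codon] + w4[+4] + w8[+8]
          + w_grun · #G(+8..+11) + w_gc · GC(+8..+27),

with defaults `w_stop = {UGA: 2, UAG: 1, UAA: 0}`, `w4 = {C: 2, U: 1,
A: 0, G: 0}`, `w8 = {G: 3, A: 1, C: 0, U: 0}`, `w_grun = 0.5`,
`w_gc = 2`. The weights are deliberate inventions that encode only the
*ordinal* experimental findings (UGA > UAG > UAA; weak +4 pyrimidine
favoured; +8 G ≫ A > pyrimidines; G-run and GC content help); their
absolute values carry no meaning and are config-overridable, and every
report embeds its component values. Tier assignment is categorical and
independent of the weights: *amenable* requires +8 G **and** a consensus
match, *conditional* +8 G alone, *unlikely* anything else — so no weight
setting can promote a +8 non-G context.

Position-frequency matrices over aligned +8..+27 windows report
per-column information as `2 − H` bits (Shannon entropy of the column
frequencies), the WebLogo convention, without small-sample correction —
the caller controls n, and the uncorrected form keeps the quantity
interpretable as a plain entropy deficit.

## ASO design and Tm

"An ASO at +X" means: the mRNA window begins at +X. Because the duplex is
antiparallel, the oligo's **3′-terminal base pairs +X**; for the +8
R-ASO this places the 3′ end at the ribosomal mRNA entrance, which is why
3′ chemistry is the sensitive end (below). The designed sequence is the
exact reverse complement of the window.

Melting temperatures use the two-state nearest-neighbor model,
`Tm = ΔH° / (ΔS° + R·ln(C_T/x))`, with the Sugimoto 1995 RNA/DNA-hybrid
parameter set (Biochemistry 34:11211) for the default DNA:RNA duplex and
the SantaLucia DNA:DNA set as an option, both via Biopython's
`MeltingTemp`; monovalent salt enters through the SantaLucia 1998 entropy
correction. Defaults: 1 µM oligo (treated as in excess over target),
0.1 M monovalent salt. Two monotonicity facts matter for testing:
raising a window's GC content or lowering oligo concentration moves Tm
strictly in the expected direction, but **Tm is not monotone in length
for arbitrary extensions** — appending weak A/U stacks to an already
stable duplex can lower the two-state Tm (observed for ~17% of random
single-base extensions under the hybrid table). Length monotonicity holds
strictly for composition-preserving (repeat-unit) extensions, and that is
the form the test batteries assert.

The register scan (+4..+12) picks, per register, the length in [16, 24]
minimizing |Tm − target| with ties to the shorter oligo — emulating a
"similar predicted Tm" series; the window and tie-break are package
choices. The length scan defaults to 14..26 in steps of 2 at register +8.
The double-oligo constructor conjugates a +8 20-mer to a second oligo at
+34 (6 unpaired bases, +28..+33, in the default geometry); the linker is
an opaque label, as no linker chemistry is modelled. Mismatch controls
substitute seeded positions with a non-complementary base, preferring
transversions of the original base with alphabetical tie-break, so a
control with n planted mismatches can never match its target at fewer
than n mispairs. Mismatched-duplex Tm is out of scope and reported as
NaN.

### Chemistry rules

Per-nucleotide sugar codes D (DNA), M (2′-OMe), F (2′-F), L (LNA) and
per-linkage backbone codes O (phosphodiester), S (phosphorothioate),
both 5′→3′. The validator encodes the empirical tolerance pattern:
3′-terminal 2′-OMe reduces activity (R1, warn); 3′-terminal LNA or 2′-F
is well tolerated (R2, info); ≥ 4 fluoro among the 3′-terminal 6
positions reduces activity (R3, warn; both thresholds configurable); a
fully PS backbone inhibits translation outright (R4, error); a PS count
above half the length warns (R5) unless R4 already fired — R4 supersedes
R5 so each failure mode maps to one flag; modifications confined to the
5′ half trigger nothing. The R3 and R5 thresholds are package defaults
encoding qualitative findings, not measured breakpoints.

## Kinetics

*Maximal translation rate.* An ordinary least-squares slope in every
sliding window of 5 points (configurable, ≥ 3) over the luminescence
trace; the maximum and its window center are reported. The statistic is
invariant to signal offset and equivariant to scale. 5 points balances
noise suppression against resolution of rate transitions at typical
plate-reader sampling.

*Termination kinetics.* Release traces are fit to the exponential
plateau `Y(t) = YM − (YM − Y0)·e^(−k_obs·t)` by bounded nonlinear least
squares (`k_obs > 0`, tolerances 1e-10, ≤ 10,000 evaluations).
Initialization: Y0 from the first point, YM from the last, k from a
log-linear regression of the remaining fraction. Flat traces (dynamic
range below 1e-9 of the signal scale) return a degenerate flag with
`k_obs = NaN` rather than an arbitrary rate; non-convergence is reported
as such, never silently. An optional pre-fit baseline subtraction
(mean of an initial window) mirrors the usual 2-minute baseline reading.

*Dose–response.* A four-parameter logistic on log10 dose,
`y = bottom + (top − bottom) / (1 + 10^((logEC50 − logd)·hill))`, with
hill bounded positive and top/bottom free (so descending curves fit with
top < bottom). EC50 is reported in input dose units and is exactly
scale-equivariant. Constant responses are flagged degenerate.

## The synthetic cohort generator

The generator emulates the *statistical shape* of a curated
nonsense-variant extraction: per-row gene symbol, transcript, 1-based
stop position, consequence class and free-text pathogenicity label. Each
row sits on its own transcript built from uniform random non-stop codons
at a target GC content (achieved approximately, within a couple of
percent, by GC-weighted base sampling with stop-codon resampling). At
the planted site the stop codon is drawn from a configured distribution
(default 0.5/0.3/0.2 for UGA/UAG/UAA, reflecting UGA-biased cohorts),
+4..+7 is random, and +8..+27 is drawn from the consensus template (for
matching rows) or rejection-sampled to violate it (capped at 1,000
attempts, then one constrained position of a matching window is flipped,
guaranteeing termination); match status is asserted against the real
matcher at construction time. Frameshift rows point anywhere (they are
excluded before codon validation); truncated rows plant a genuine stop
with fewer than 27 nt remaining. Gene names are drawn from a pool of
0.6× the row count so unique-gene counts are non-trivial; pathogenicity
labels from {pathogenic, likely pathogenic, uncertain significance,
blank} at 0.55/0.2/0.15/0.1.

Default study conditions: 500 rows = 470 valid nonsense contexts (35
consensus matches) + 20 frameshift + 10 truncated, CDS lengths
300–1500 nt, GC 0.5. All outputs are byte-reproducible under a seed; the
degenerate-template expander consumes its PRNG stream sequence-major,
left-to-right.

What the generator does **not** emulate: human codon usage, real
mutational spectra, transcript-level duplicates of one genomic variant,
LOVD-style label vocabulary beyond the two pathogenic strings, or mRNA
secondary structure. Passing planted-recovery tests therefore
demonstrates the pipeline's bookkeeping and matching are exact — not
that the consensus would achieve any particular yield on a real variant
database, whose counts depend on the database snapshot and on the
consensus string used.

## Numerical and testing notes

- Planted-cohort recovery, matcher-vs-enumeration equivalence and
  template-draw statistics are exact or CI-bounded checks; the
  template-balance test uses the exact binomial acceptance region at a
  Bonferroni-adjusted family-wise 99% level across the 21 positions
  tested jointly (an unadjusted per-position region would falsely fail
  roughly one seed in five by construction).
- Kinetic recovery is tested noiseless (≤ 1e-6 relative) and at σ = 2%
  of plateau (median k̂ within 5%, 100 seeded traces); max-rate under
  noise within 10% median over 50 traces. Problem sizes (10,000 template
  draws, 1,000-duplex Tm batteries, 500-row cohorts) keep the whole
  suite and the acceptance script in the tens of seconds on one CPU
  while leaving the binomial and median checks well-powered.
- Duplicate (transcript, position) database rows are kept by default
  (variant rows are counted as given); `--dedupe` collapses exact
  duplicates and logs the count. The summary's denominator is the
  post-exclusion database, and both per-row and per-unique-context match
  counts are emitted, since either convention is defensible.

## Known limitations

- The default consensus is illustrative; results on real cohorts hinge
  on the pattern supplied.
- Tm for chemically modified oligos is computed as if unmodified
  (modification-specific nearest-neighbor sets are not included); the
  chemistry validator, not the Tm, carries the modification logic.
- No mRNA secondary-structure term, no off-target search, no
  genome-to-transcript mapping or HGVS parsing.
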