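"""Transcript sequences, nonsense-variant tables and stop-codon context windows.

Coordinates follow the stop-anchored convention used throughout the package:
position +1 is the first nucleotide of the (premature) stop codon, +4 the
first downstream base, and the readthrough-relevant downstream window spans
+8..+27.  The external interface is 1-based inclusive; all internal slicing
is 0-based half-open.

Sequences are held as DNA (``ACGT``) internally; ``U`` is accepted on input
and converted.  IUPAC ambiguity codes are rejected in transcript sequences —
the pipeline operates on resolved coding sequences.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP_CODONS = ("TGA", "TAG", "TAA")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_VALID_BASES = frozenset("ACGT")

#: readthrough propensity order of the three stop codons (1 = most prone)
READTHROUGH_RANK = {"TGA": 1, "TAG": 2, "TAA": 3}


class FastaError(ValueError):
    """Malformed or non-conforming FASTA input."""


class VariantTableError(ValueError):
    """Malformed variant CSV input."""


class NotAStopError(ValueError):
    """The sequence at the annotated position is not a stop codon."""


class TruncatedContextError(ValueError):
    """The transcript ends before position +27 of the annotated stop."""


class Consequence(enum.Enum):
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    OTHER = "other"


@dataclass(frozen=True)
class TranscriptSeq:
    """A coding or reporter transcript, normalized to uppercase DNA."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("transcript id must be non-empty")
        if not self.sequence:
            raise FastaError(f"transcript {self.id!r}: empty sequence")
        bad = next((i for i, b in enumerate(self.sequence) if b not in _VALID_BASES), None)
        if bad is not None:
            raise FastaError(
                f"transcript {self.id!r}: non-nucleotide character "
                f"{self.sequence[bad]!r} at offset {bad + 1}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantRecord:
    """One row of a nonsense-variant table (LOVD3-style).

    ``stop_start`` is the 1-based position of the premature stop codon's
    first nucleotide (+1) within the transcript sequence.
    """

    gene: str
    transcript_id: str
    stop_start: int
    consequence: Consequence
    pathogenicity: str = ""

    def __post_init__(self) -> None:
        if self.stop_start < 1:
            raise VariantTableError(
                f"{self.transcript_id}: stop_start must be >= 1, got {self.stop_start}"
            )


@dataclass(frozen=True)
class NonsenseContext:
    """A premature stop codon with its downstream context windows.

    ``nt4`` is the single base at +4, ``w47`` spans +4..+7, ``w827`` spans
    +8..+27 (the R-ASO target window) and ``full_window`` spans +1..+27.
    ``truncated`` marks contexts whose transcript ends before +27; their
    windows are correspondingly short.
    """

    gene: str
    transcript_id: str
    stop_start: int
    stop_codon: str
    nt4: str
    w47: str
    w827: str
    full_window: str
    truncated: bool
    pathogenicity: str = ""

    def __post_init__(self) -> None:
        if self.stop_codon not in STOP_CODONS:
            raise NotAStopError(f"{self.stop_codon!r} is not a stop codon")
        if not self.truncated and len(self.full_window) != 27:
            raise ValueError("full context must span +1..+27 (27 nt)")

    def base_at(self, plus_pos: int) -> str:
        """Base at stop-anchored position ``+plus_pos`` (1-based, +1..+27)."""
        if not 1 <= plus_pos <= len(self.full_window):
            raise IndexError(
                f"position +{plus_pos} outside available window "
                f"(+1..+{len(self.full_window)})"
            )
        return self.full_window[plus_pos - 1]


class Strength(enum.Enum):
    STRONG = "strong"
    WEAK = "weak"


@dataclass(frozen=True)
class StopClass:
    """Termination-site classification of a nonsense context.

    A +4 purine makes a 'strong' termination site (the +4 purine stacks with
    18S rRNA in release-factor-bound ribosomes); a +4 pyrimidine makes a
    'weak' one.  ``readthrough_rank`` orders the codons by intrinsic
    readthrough propensity, UGA > UAG > UAA.
    """

    codon: str  # RNA alphabet: UGA/UAG/UAA
    strength: Strength
    readthrough_rank: int


def normalize_sequence(raw: str, record_id: str) -> str:
    """Uppercase and convert RNA ``U`` to DNA ``T``; reject anything else."""
    seq = raw.upper().replace("U", "T")
    bad = next((i for i, b in enumerate(seq) if b not in _VALID_BASES), None)
    if bad is not None:
        raise FastaError(
            f"record {record_id!r}: non-nucleotide character {seq[bad]!r} "
            f"at offset {bad + 1}"
        )
    return seq


def read_fasta(path: str | Path) -> list[TranscriptSeq]:
    """Read a multi-record FASTA into normalized transcripts, order preserved.

    Raises :class:`FastaError` on duplicate ids or non-ACGTU characters.
    """
    seqs: list[TranscriptSeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seqs.append(TranscriptSeq(rec.id, normalize_sequence(str(rec.seq), rec.id)))
    return seqs


def write_fasta(seqs: Iterable[TranscriptSeq], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.sequence), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


_REQUIRED_COLUMNS = ("gene", "transcript_id", "stop_start", "consequence", "pathogenicity")


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Parse a variant CSV; rows are NOT filtered here (see filter_nonsense).

    Required header columns: gene, transcript_id, stop_start, consequence,
    pathogenicity.  ``consequence`` values other than ``nonsense`` /
    ``frameshift`` parse as OTHER.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise VariantTableError(f"missing required column {col!r}")
    records: list[VariantRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            stop_start = int(getattr(row, "stop_start"))
        except ValueError as exc:
            raise VariantTableError(
                f"row {idx + 1}: non-integer stop_start {getattr(row, 'stop_start')!r}"
            ) from exc
        cons_raw = getattr(row, "consequence").strip().lower()
        try:
            consequence = Consequence(cons_raw)
        except ValueError:
            consequence = Consequence.OTHER
        records.append(
            VariantRecord(
                gene=getattr(row, "gene"),
                transcript_id=getattr(row, "transcript_id"),
                stop_start=stop_start,
                consequence=consequence,
                pathogenicity=getattr(row, "pathogenicity"),
            )
        )
    return records


def filter_nonsense(
    records: Sequence[VariantRecord],
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Keep nonsense rows; exclude frameshift-derived (and other) stops.

    Returns ``(kept, excluded)`` where ``excluded`` pairs each dropped record
    with a reason tag; the two lists partition the input.
    """
    kept: list[VariantRecord] = []
    excluded: list[tuple[VariantRecord, str]] = []
    for rec in records:
        if rec.consequence is Consequence.NONSENSE:
            kept.append(rec)
        else:
            excluded.append((rec, rec.consequence.value))
    return kept, excluded


def extract_context(
    tseq: TranscriptSeq,
    rec: VariantRecord,
    require_full_window: bool = True,
    validate_frame: bool = False,
) -> NonsenseContext:
    """Extract the stop codon and +4..+27 windows at ``rec.stop_start``.

    Raises :class:`NotAStopError` if the annotated codon is not TGA/TAG/TAA,
    and :class:`TruncatedContextError` if the transcript ends before +27 and
    ``require_full_window`` is set (truncated windows are never padded).
    With ``validate_frame`` the stop must be in frame with position 1
    ((stop_start - 1) % 3 == 0); off by default because reporter constructs
    need not be full CDSs.
    """
    seq, pos = tseq.sequence, rec.stop_start
    if not 1 <= pos <= len(seq) - 2:
        raise NotAStopError(
            f"{tseq.id}: stop_start {pos} leaves no full codon "
            f"(sequence length {len(seq)})"
        )
    if validate_frame and (pos - 1) % 3 != 0:
        raise VariantTableError(f"{tseq.id}: stop_start {pos} is out of frame")
    codon = seq[pos - 1 : pos + 2]
    if codon not in STOP_CODONS:
        raise NotAStopError(f"{tseq.id}: codon at position {pos} is {codon!r}, not a stop")
    available = len(seq) - (pos - 1)  # bases from +1 to transcript end
    truncated = available < 27
    if truncated and require_full_window:
        raise TruncatedContextError(
            f"{tseq.id}: only {available} nt available from +1, need 27"
        )
    full = seq[pos - 1 : pos + 26]
    return NonsenseContext(
        gene=rec.gene,
        transcript_id=rec.transcript_id,
        stop_start=pos,
        stop_codon=codon,
        nt4=full[3:4],
        w47=full[3:7],
        w827=full[7:27],
        full_window=full,
        truncated=truncated,
        pathogenicity=rec.pathogenicity,
    )


def classify_stop(ctx: NonsenseContext) -> StopClass:
    """Classify a context by +4 strength and stop-codon readthrough rank."""
    if not ctx.nt4:
        raise TruncatedContextError(f"{ctx.transcript_id}: no +4 base available")
    strength = Strength.STRONG if ctx.nt4 in PURINES else Strength.WEAK
    return StopClass(
        codon=ctx.stop_codon.replace("T", "U"),
        strength=strength,
        readthrough_rank=READTHROUGH_RANK[ctx.stop_codon],
    )
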