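"""Design of readthrough-inducing antisense oligonucleotides (R-ASOs).

An R-ASO is written 5'->3' as the reverse complement of the mRNA window it
targets.  Because the duplex is antiparallel, the ASO's 3'-terminal base
pairs the 5'-most base of the mRNA window: a "+8 ASO" has its target window
starting at mRNA position +8 and its own 3' end annealing there, next to the
ribosomal mRNA entry channel.

Duplex melting temperatures come from two-state nearest-neighbor
thermodynamics (Tm = dH / (dS + R ln(C_T / x)) with a monovalent-salt
correction): the Sugimoto 1995 parameter set for DNA:RNA hybrids (the
physiologically relevant duplex) or the SantaLucia DNA:DNA set, both via
Biopython's ``MeltingTemp``.

Chemistry is encoded per nucleotide (D = DNA, M = 2'-O-methyl, F = 2'-fluoro,
L = locked nucleic acid) and per internucleotide linkage (O = phosphodiester,
S = phosphorothioate), 5'->3'.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as mt

SUGAR_CODES = frozenset("DMFL")
BACKBONE_CODES = frozenset("OS")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_TRANSVERSIONS = {  # purine <-> pyrimidine substitutions, preferred for controls
    "A": "CT", "G": "CT", "C": "AG", "T": "AG",
}


class DesignError(ValueError):
    """Invalid design request (window out of bounds, bad chemistry, ...)."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class AsoDesign:
    """One antisense oligo: sequence, target register, chemistry, Tm.

    ``target_start`` is the stop-anchored mRNA position (+N) of the 5'-most
    paired mRNA base; the ASO's 3'-terminal base pairs there.
    """

    name: str
    target_start: int
    length: int
    sequence: str  # DNA, 5'->3'
    chemistry: str  # per-nucleotide sugar codes, 5'->3'
    backbone: str  # per-linkage codes, 5'->3'
    tm_c: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise DesignError("sequence length disagrees with length field")
        if len(self.chemistry) != self.length:
            raise DesignError("chemistry string must match sequence length")
        if len(self.backbone) != self.length - 1:
            raise DesignError("backbone string must have length - 1 linkages")
        bad = set(self.chemistry) - SUGAR_CODES
        if bad:
            raise DesignError(f"unknown sugar code(s) {sorted(bad)}")
        bad = set(self.backbone) - BACKBONE_CODES
        if bad:
            raise DesignError(f"unknown backbone code(s) {sorted(bad)}")

    @property
    def target_window(self) -> str:
        """The mRNA window (DNA alphabet, 5'->3') this ASO pairs."""
        return reverse_complement(self.sequence)


@dataclass(frozen=True)
class DoubleOligo:
    """A primary R-ASO conjugated to a second, downstream-annealing oligo."""

    primary: AsoDesign
    secondary: AsoDesign
    linker: str = "conjugate"
    gap: int = 0

    def __post_init__(self) -> None:
        if self.secondary.target_start <= self.primary.target_start + self.primary.length - 1:
            raise DesignError("secondary window must lie fully downstream of primary")


def _window_slice(segment: str, segment_start: int, target_start: int, length: int) -> str:
    lo = target_start - segment_start
    hi = lo + length
    if lo < 0 or hi > len(segment):
        raise DesignError(
            f"window +{target_start}..+{target_start + length - 1} outside segment "
            f"(+{segment_start}..+{segment_start + len(segment) - 1})"
        )
    return segment[lo:hi]


def predict_tm(
    aso_sequence: str,
    target_rna_window: str,
    oligo_conc_molar: float = 1e-6,
    salt_molar: float = 0.1,
    duplex: str = "dna:rna",
) -> float:
    """Two-state nearest-neighbor Tm (deg C) of a fully complementary duplex.

    ``aso_sequence`` is the DNA oligo 5'->3'; ``target_rna_window`` the mRNA
    window 5'->3' (U or T accepted).  Hybrid duplexes use the Sugimoto 1995
    RNA/DNA table, ``duplex="dna:dna"`` the SantaLucia DNA table.  The oligo
    is assumed in excess over the target at ``oligo_conc_molar``; monovalent
    salt enters via the SantaLucia 1998 entropy correction.
    """
    target_dna = target_rna_window.upper().replace("U", "T")
    aso = aso_sequence.upper()
    if len(aso) != len(target_dna):
        raise DesignError(
            f"ASO length {len(aso)} != target length {len(target_dna)}"
        )
    for i, (a, t) in enumerate(zip(aso, reversed(target_dna))):
        if _COMPLEMENT.get(t) != a:
            raise DesignError(
                f"non-complementary pair at ASO position {i + 1}: "
                f"{a} vs target {t}"
            )
    conc_nm = oligo_conc_molar * 1e9
    na_mm = salt_molar * 1e3
    if duplex == "dna:rna":
        # the hybrid table indexes by the RNA strand
        seq = target_dna.replace("T", "U")
        table = mt.R_DNA_NN1
    elif duplex == "dna:dna":
        seq = aso
        table = mt.DNA_NN3
    else:
        raise DesignError(f"unknown duplex type {duplex!r}")
    return float(
        mt.Tm_NN(seq, nn_table=table, dnac1=conc_nm, dnac2=0, Na=na_mm, saltcorr=5)
    )


def design_aso(
    mrna_segment: str,
    target_start: int,
    length: int,
    segment_start: int = 1,
    name: str | None = None,
    oligo_conc_molar: float = 1e-6,
    salt_molar: float = 0.1,
    duplex: str = "dna:rna",
) -> AsoDesign:
    """Design an unmodified DNA ASO against mRNA positions
    ``target_start..target_start+length-1``.

    ``mrna_segment`` is given in the DNA alphabet with its first base at
    stop-anchored position ``segment_start`` (default +1).
    """
    if length < 8:
        raise DesignError(f"minimum ASO length is 8, got {length}")
    window = _window_slice(mrna_segment.upper().replace("U", "T"),
                           segment_start, target_start, length)
    sequence = reverse_complement(window)
    tm = predict_tm(sequence, window, oligo_conc_molar, salt_molar, duplex)
    return AsoDesign(
        name=name or f"+{target_start}",
        target_start=target_start,
        length=length,
        sequence=sequence,
        chemistry="D" * length,
        backbone="O" * (length - 1),
        tm_c=tm,
    )


def register_scan(
    mrna_segment: str,
    starts: Sequence[int] = tuple(range(4, 13)),
    target_tm: float = 60.0,
    length_range: tuple[int, int] = (16, 24),
    segment_start: int = 1,
    **tm_kwargs,
) -> list[AsoDesign]:
    """One ASO per register +4..+12, lengths tuned toward a common Tm.

    For each start the length in ``length_range`` minimizing |Tm - target_tm|
    is chosen (ties go to the shorter oligo), emulating a same-Tm register
    series.  Designs are labelled "+4".."+12".
    """
    lo, hi = length_range
    designs = []
    for start in starts:
        best = None
        for length in range(lo, hi + 1):
            d = design_aso(mrna_segment, start, length,
                           segment_start=segment_start, **tm_kwargs)
            dev = abs(d.tm_c - target_tm)
            if best is None or dev < best[0] - 1e-12:
                best = (dev, d)
        designs.append(best[1])
    return designs


def length_scan(
    mrna_segment: str,
    start: int = 8,
    lengths: Sequence[int] = tuple(range(14, 27, 2)),
    segment_start: int = 1,
    **tm_kwargs,
) -> list[AsoDesign]:
    """Fixed register (+8 by default), varying length (default 14..26 by 2)."""
    return [
        design_aso(mrna_segment, start, n, segment_start=segment_start,
                   name=f"+{start}x{n}", **tm_kwargs)
        for n in lengths
    ]


def design_double_oligo(
    mrna_segment: str,
    primary_start: int = 8,
    primary_len: int = 20,
    secondary_start: int = 34,
    secondary_len: int = 16,
    segment_start: int = 1,
    linker: str = "conjugate",
    **tm_kwargs,
) -> DoubleOligo:
    """A +8 R-ASO conjugated to an oligo annealing further downstream (+34).

    The gap counts unpaired mRNA bases between the two windows; the default
    (+8, 20-mer, +34) geometry leaves 6 (+28..+33).
    """
    if secondary_start < primary_start + primary_len:
        raise DesignError(
            f"secondary window at +{secondary_start} overlaps primary "
            f"+{primary_start}..+{primary_start + primary_len - 1}"
        )
    primary = design_aso(mrna_segment, primary_start, primary_len,
                         segment_start=segment_start, **tm_kwargs)
    secondary = design_aso(mrna_segment, secondary_start, secondary_len,
                           segment_start=segment_start, **tm_kwargs)
    gap = secondary_start - (primary_start + primary_len)
    return DoubleOligo(primary=primary, secondary=secondary, linker=linker, gap=gap)


def make_mismatch_control(aso: AsoDesign, n_mismatches: int, seed: int) -> AsoDesign:
    """A sequence-mismatched control oligo for target-specificity experiments.

    ``n_mismatches`` positions are chosen without replacement (seeded) and
    substituted with a base non-complementary to the target; transversions
    of the original base are preferred, ties broken alphabetically.  The
    result cannot match the original target at fewer than ``n_mismatches``
    mispairs.
    """
    if not 1 <= n_mismatches <= aso.length:
        raise DesignError(
            f"n_mismatches must be in 1..{aso.length}, got {n_mismatches}"
        )
    rng = np.random.default_rng(seed)
    positions = sorted(rng.choice(aso.length, size=n_mismatches, replace=False))
    bases = list(aso.sequence)
    for i in positions:
        original = bases[i]
        candidates = [b for b in "ACGT" if b != original]
        preferred = [b for b in candidates if b in _TRANSVERSIONS[original]]
        bases[i] = (preferred or candidates)[0]
    return replace(
        aso,
        name=f"{aso.name}_mm{n_mismatches}",
        sequence="".join(bases),
        tm_c=float("nan"),  # mismatch-duplex Tm is out of scope
        flags=aso.flags + ("control",),
    )


@dataclass(frozen=True)
class ChemFlag:
    rule: str
    level: str  # "info" | "warn" | "error"
    message: str


@dataclass(frozen=True)
class ChemistryThresholds:
    """Tunable cutoffs for the modification-tolerance rules."""

    fluoro_3prime_window: int = 6
    fluoro_3prime_max: int = 4  # >= this many F in the window triggers R3
    ps_warn_fraction: float = 0.5  # > length * fraction S linkages triggers R5


def validate_chemistry(
    aso: AsoDesign, thresholds: ChemistryThresholds | None = None
) -> list[ChemFlag]:
    """Evaluate an ASO's modification pattern against the tolerance rules.

    The 3' end of an R-ASO sits at the ribosomal mRNA entrance and is
    sensitive to modification; the 5' end is tolerant.  Rules:

    - R1: 3'-terminal 2'-OMe (M) -> warn (reduces readthrough activity).
    - R2: 3'-terminal LNA (L) or 2'-F (F) -> info (well tolerated).
    - R3: heavy 2'-F near the 3' end (>= ``fluoro_3prime_max`` F among the
      3'-terminal ``fluoro_3prime_window`` positions) -> warn.
    - R4: fully phosphorothioate backbone -> error (inhibits translation
      non-specifically).
    - R5: phosphorothioate count above ``length * ps_warn_fraction`` (but
      not fully PS; R4 supersedes) -> warn.
    - 5'-confined modifications trigger no rule: activity is retained.

    Flags depend only on the chemistry/backbone strings.
    """
    th = thresholds or ChemistryThresholds()
    flags: list[ChemFlag] = []
    if aso.chemistry[-1] == "M":
        flags.append(ChemFlag(
            "R1", "warn",
            "3'-terminal 2'-OMe reduces readthrough activity"))
    if aso.chemistry[-1] in "LF":
        flags.append(ChemFlag(
            "R2", "info",
            "3'-terminal LNA/2'-F is well tolerated"))
    tail = aso.chemistry[-th.fluoro_3prime_window:]
    if tail.count("F") >= th.fluoro_3prime_max:
        flags.append(ChemFlag(
            "R3", "warn",
            f"{tail.count('F')} 2'-F among the 3'-terminal "
            f"{th.fluoro_3prime_window} positions reduces readthrough"))
    s_count = aso.backbone.count("S")
    if aso.backbone and s_count == len(aso.backbone):
        flags.append(ChemFlag(
            "R4", "error",
            "fully phosphorothioate backbone inhibits translation"))
    elif s_count > aso.length * th.ps_warn_fraction:
        flags.append(ChemFlag(
            "R5", "warn",
            f"{s_count} phosphorothioate linkages may reduce readthrough"))
    return flags


def designs_to_records(designs: Iterable[AsoDesign]) -> "list[dict]":
    """Rows for the sidecar CSV (name, register, chemistry, Tm, flags)."""
    return [
        {
            "name": d.name,
            "target_start": d.target_start,
            "length": d.length,
            "sequence": d.sequence,
            "chemistry": d.chemistry,
            "backbone": d.backbone,
            "tm_c": round(d.tm_c, 2),
            "flags": ";".join(d.flags),
        }
        for d in designs
    ]
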