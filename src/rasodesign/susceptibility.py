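"""Consensus matching and rule-based scoring of R-ASO amenability.

The central question: given a premature stop codon and its downstream
sequence, how likely is an antisense oligonucleotide annealing from +8 to
induce readthrough?  The module provides (i) grep-style IUPAC consensus
matching over the +8..+27 window, (ii) a transparent weighted score built
from the known ordinal determinants (stop-codon identity, +4 base, +8 base,
G-run at +8..+11, downstream GC content), (iii) position-frequency-matrix
construction for logo-style summaries, and (iv) degenerate-template
expansion (the RY-template trick used to build semi-random reporter
contexts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .variant_context import NonsenseContext, TruncatedContextError

#: IUPAC nucleotide codes -> allowed DNA bases
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_BASES = "ACGT"

#: Illustrative default consensus: +8 G required, purines tolerated at
#: +9..+11, pyrimidine at +14, unconstrained elsewhere.  This encodes the
#: published qualitative determinants only; it is not a published consensus
#: string.
DEFAULT_CONSENSUS = "GRRRNNYNNNNNNNNNNNNN"

#: The 21-character RY template used to generate semi-random +8.. contexts.
RY_TEMPLATE = "RYRRRRYYRYRYYRRRYRRRR"


class PatternError(ValueError):
    """Invalid IUPAC pattern."""


@dataclass(frozen=True)
class ConsensusPattern:
    """An IUPAC degenerate pattern anchored at a stop-relative position.

    ``anchor`` is the mRNA position (+N, default +8) of the pattern's first
    character; ``max_mismatch`` is the number of tolerated out-of-set
    positions (0 = grep-like exact degenerate match).
    """

    pattern: str
    anchor: int = 8
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        if not self.pattern:
            raise PatternError("pattern must be non-empty")
        if self.anchor < 4:
            raise PatternError(f"anchor must be >= +4, got +{self.anchor}")
        if self.max_mismatch < 0:
            raise PatternError("max_mismatch must be non-negative")
        for i, ch in enumerate(self.pattern):
            if ch not in IUPAC_SETS:
                raise PatternError(f"invalid IUPAC character {ch!r} at offset {i + 1}")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def allowed_sets(self) -> tuple[frozenset[str], ...]:
        return tuple(IUPAC_SETS[ch] for ch in self.pattern)

    def cardinality(self) -> int:
        """Number of distinct sequences matching the pattern exactly."""
        n = 1
        for s in self.allowed_sets:
            n *= len(s)
        return n


def parse_iupac(pattern_string: str, anchor: int = 8, max_mismatch: int = 0) -> ConsensusPattern:
    """Validate an IUPAC pattern string into a :class:`ConsensusPattern`."""
    return ConsensusPattern(pattern_string.upper(), anchor, max_mismatch)


def _window_for(ctx: NonsenseContext, pat: ConsensusPattern) -> str:
    """Bases at pattern positions anchor..anchor+len-1, from the context."""
    start, stop = pat.anchor, pat.anchor + len(pat) - 1
    if stop > len(ctx.full_window):
        raise TruncatedContextError(
            f"{ctx.transcript_id}: window covers +1..+{len(ctx.full_window)}, "
            f"pattern needs +{start}..+{stop}"
        )
    return ctx.full_window[start - 1 : stop]


def match_window(window: str, pat: ConsensusPattern) -> tuple[bool, list[int]]:
    """Match a raw window (first base at pattern anchor) against a pattern.

    Returns ``(match, mismatch_positions)`` with mismatches in stop-anchored
    +N coordinates.
    """
    if len(window) < len(pat):
        raise PatternError(
            f"window of length {len(window)} shorter than pattern ({len(pat)})"
        )
    mism = [
        pat.anchor + i
        for i, (base, allowed) in enumerate(zip(window, pat.allowed_sets))
        if base not in allowed
    ]
    return len(mism) <= pat.max_mismatch, mism


def match_consensus(ctx: NonsenseContext, pat: ConsensusPattern) -> tuple[bool, list[int]]:
    """Degenerate consensus match of a context's downstream window.

    A position mismatches when the context base lies outside the IUPAC
    character's allowed set; the match succeeds when the mismatch count is
    at most ``pat.max_mismatch``.
    """
    return match_window(_window_for(ctx, pat), pat)


def plus8_filter(ctx: NonsenseContext) -> bool:
    """True iff the base at +8 is G (the single strongest determinant)."""
    return ctx.base_at(8) == "G"


@dataclass(frozen=True)
class ScoreWeights:
    """Config-overridable weights for the amenability score.

    Defaults encode only the ordinal findings: UGA > UAG > UAA; +4 C best
    (weak termination site), then U; +8 G >> A > pyrimidines; longer G-run
    at +8..+11 and higher GC over +8..+27 both help.  Keys use the DNA
    alphabet.
    """

    w_stop: dict = field(default_factory=lambda: {"TGA": 2.0, "TAG": 1.0, "TAA": 0.0})
    w4: dict = field(default_factory=lambda: {"C": 2.0, "T": 1.0, "A": 0.0, "G": 0.0})
    w8: dict = field(default_factory=lambda: {"G": 3.0, "A": 1.0, "C": 0.0, "T": 0.0})
    w_grun: float = 0.5
    w_gc: float = 2.0


@dataclass(frozen=True)
class SusceptibilityReport:
    consensus_match: bool
    mismatch_positions: tuple[int, ...]
    score: float
    components: dict
    tier: str  # amenable | conditional | unlikely


def score_context(
    ctx: NonsenseContext,
    weights: ScoreWeights | None = None,
    pattern: ConsensusPattern | None = None,
) -> SusceptibilityReport:
    """Score a context and assign an amenability tier.

    score = w_stop[codon] + w4[nt4] + w8[nt8] + w_grun * (#G in +8..+11)
            + w_gc * GC_fraction(+8..+27)

    Tier: *amenable* iff nt8 == G and the consensus matches; *conditional*
    iff nt8 == G only; *unlikely* otherwise.  Without a pattern the
    consensus is treated as non-matching (tier is at most conditional).
    """
    if ctx.truncated or len(ctx.full_window) != 27:
        raise TruncatedContextError(
            f"{ctx.transcript_id}: scoring requires the full +1..+27 window"
        )
    w = weights or ScoreWeights()
    nt8 = ctx.base_at(8)
    g_run = sum(1 for b in ctx.full_window[7:11] if b == "G")
    gc = sum(1 for b in ctx.w827 if b in "GC") / len(ctx.w827)
    score = (
        w.w_stop[ctx.stop_codon]
        + w.w4[ctx.nt4]
        + w.w8[nt8]
        + w.w_grun * g_run
        + w.w_gc * gc
    )
    if pattern is not None:
        matched, mism = match_consensus(ctx, pattern)
    else:
        matched, mism = False, []
    if nt8 == "G" and matched:
        tier = "amenable"
    elif nt8 == "G":
        tier = "conditional"
    else:
        tier = "unlikely"
    return SusceptibilityReport(
        consensus_match=matched,
        mismatch_positions=tuple(mism),
        score=score,
        components={
            "stop_weight": w.w_stop[ctx.stop_codon],
            "plus4_weight": w.w4[ctx.nt4],
            "plus8_weight": w.w8[nt8],
            "g_run_count": g_run,
            "gc_fraction": gc,
        },
        tier=tier,
    )


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Base counts over aligned +8..+27 windows with per-column information.

    ``counts`` is 4 x 20 (rows A, C, G, T); ``information_bits`` follows the
    WebLogo convention 2 - H (Shannon entropy in bits), without small-sample
    correction.
    """

    positions: tuple[int, ...]
    counts: np.ndarray
    information_bits: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts[:, 0].sum())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts.T,
            index=[f"+{p}" for p in self.positions],
            columns=list(_BASES),
        )
        df["information_bits"] = self.information_bits
        return df

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="position")


def build_pfm(windows: Iterable[NonsenseContext | str]) -> PositionFrequencyMatrix:
    """Count bases per position over aligned +8..+27 windows.

    Accepts contexts (their ``w827`` is used) or raw 20-nt strings; all
    inputs must be full-length.
    """
    mats = []
    for w in windows:
        s = w.w827 if isinstance(w, NonsenseContext) else w
        if len(s) != 20:
            raise ValueError(f"window {s!r} is not 20 nt")
        mats.append([_BASES.index(b) for b in s])
    if not mats:
        raise ValueError("cannot build a PFM from zero contexts")
    idx = np.asarray(mats)  # n x 20
    counts = np.zeros((4, 20), dtype=np.int64)
    for col in range(20):
        counts[:, col] = np.bincount(idx[:, col], minlength=4)
    freqs = counts / counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = 2.0 + plogp.sum(axis=0)
    return PositionFrequencyMatrix(
        positions=tuple(range(8, 28)),
        counts=counts,
        information_bits=info,
    )


def expand_template_random(
    template: ConsensusPattern | str,
    n: int,
    seed: int | np.random.Generator,
) -> list[str]:
    """Draw ``n`` sequences from a degenerate template, uniform per position.

    This is the RY-template trick: each position is drawn uniformly from the
    IUPAC character's allowed set (R -> A or G, Y -> C or T, ...).  Draws
    consume the PRNG stream left-to-right, sequence-major, so outputs are
    bit-reproducible under a fixed seed.
    """
    pat = template if isinstance(template, ConsensusPattern) else parse_iupac(template)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    allowed = [sorted(s) for s in pat.allowed_sets]
    sizes = np.array([len(a) for a in allowed])
    u = rng.random((n, len(pat)))  # C-order fill = sequence-major
    idx = (u * sizes).astype(np.int64)
    return ["".join(allowed[j][idx[i, j]] for j in range(len(pat))) for i in range(n)]


class CardinalityError(ValueError):
    """Template expansion would exceed the enumeration cap."""


@dataclass
class TemplateEnumeration:
    """Exhaustive expansion of a degenerate template (brute-force oracle)."""

    pattern: ConsensusPattern
    cardinality: int

    def __iter__(self) -> Iterator[str]:
        allowed = [sorted(s) for s in self.pattern.allowed_sets]

        def rec(prefix: str, rest: list) -> Iterator[str]:
            if not rest:
                yield prefix
                return
            for b in rest[0]:
                yield from rec(prefix + b, rest[1:])

        return rec("", allowed)


def enumerate_template(
    template: ConsensusPattern | str, cap: int = 2**22
) -> TemplateEnumeration:
    """Enumerate every sequence matching a template exactly once.

    Raises :class:`CardinalityError` when the expansion exceeds ``cap``.
    """
    pat = template if isinstance(template, ConsensusPattern) else parse_iupac(template)
    card = pat.cardinality()
    if card > cap:
        raise CardinalityError(
            f"template expands to {card} sequences, above the cap of {cap}"
        )
    return TemplateEnumeration(pattern=pat, cardinality=card)
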