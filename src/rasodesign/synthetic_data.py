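"""Synthetic cohorts and kinetic traces with recorded ground truth.

Everything the pipeline reads can be generated here: CDS FASTA files with
planted premature stops, LOVD3-like variant CSVs (including frameshift rows
that must be excluded and 3'-truncated contexts), and luminescence traces
drawn from the exponential-plateau or piecewise-linear models.  Every
generated object carries its ground truth, so planted-recovery tests are
exact, and all outputs are byte-reproducible under a fixed seed.

The generator emulates the statistical shape of a curated variant database
(per-row gene, transcript, stop position, consequence class, pathogenicity
label), not human codon usage or real mutational spectra.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import KineticTrace
from .susceptibility import (
    DEFAULT_CONSENSUS,
    ConsensusPattern,
    expand_template_random,
    match_window,
    parse_iupac,
)
from .variant_context import STOP_CODONS, TranscriptSeq, write_fasta

_BASES = "ACGT"


class InfeasibleSpecError(ValueError):
    """The spec cannot be satisfied (e.g. no sequence can violate an all-N pattern)."""


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults give 500 variant rows: 470 nonsense (of which 35 match the
    consensus), 20 frameshift rows (to be excluded) and 10 contexts
    truncated at the 3' end.
    """

    n_nonsense: int = 470
    n_frameshift: int = 20
    n_truncated: int = 10
    fraction_consensus_match: float = 35 / 470
    cds_length_range: tuple[int, int] = (300, 1500)
    gc_content: float = 0.5
    pattern: str = DEFAULT_CONSENSUS
    gene_pool_factor: float = 0.6  # gene-name pool size relative to row count
    stop_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)  # TGA, TAG, TAA
    pathogenicity_labels: tuple[str, ...] = (
        "pathogenic", "likely pathogenic", "uncertain significance", "")
    pathogenicity_probs: tuple[float, ...] = (0.55, 0.2, 0.15, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_nonsense, self.n_frameshift, self.n_truncated) < 0:
            raise InfeasibleSpecError("counts must be non-negative")
        if not 0 <= self.fraction_consensus_match <= 1:
            raise InfeasibleSpecError("fraction_consensus_match must be in [0, 1]")
        if not 0 < self.gc_content < 1:
            raise InfeasibleSpecError("gc_content must be in (0, 1)")

    @property
    def n_rows(self) -> int:
        return self.n_nonsense + self.n_frameshift + self.n_truncated

    @property
    def n_matches(self) -> int:
        return round(self.fraction_consensus_match * self.n_nonsense)


@dataclass
class GroundTruth:
    """Planted per-variant facts plus the summary counts a pipeline must recover."""

    per_variant: list[dict] = field(default_factory=list)
    n_matches: int = 0
    n_unique_genes: int = 0
    n_pathogenic: int = 0
    n_plus4C: int = 0
    n_valid_contexts: int = 0
    n_excluded: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_matches": self.n_matches,
            "n_unique_genes": self.n_unique_genes,
            "n_pathogenic": self.n_pathogenic,
            "n_plus4C": self.n_plus4C,
            "n_valid_contexts": self.n_valid_contexts,
            "n_excluded": self.n_excluded,
            "per_variant": self.per_variant,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return "".join(np.array(list(_BASES))[rng.choice(4, size=n, p=p)])


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """In-frame codon string without stop codons (resampled away)."""
    codons = []
    while len(codons) < n_codons:
        c = _random_bases(rng, 3, gc)
        if c not in STOP_CODONS:
            codons.append(c)
    return "".join(codons)


def _violating_window(
    rng: np.random.Generator,
    pat: ConsensusPattern,
    length: int,
    gc: float,
    max_attempts: int = 1000,
) -> str:
    """A window of ``length`` nt failing the pattern (rejection, then perturbation)."""
    constrained = [i for i, s in enumerate(pat.allowed_sets) if len(s) < 4]
    if len(constrained) <= pat.max_mismatch:
        raise InfeasibleSpecError(
            "pattern matches every sequence; cannot sample a violating window"
        )
    for _ in range(max_attempts):
        w = _random_bases(rng, length, gc)
        if not match_window(w, pat)[0]:
            return w
    # fall back: take a matching prefix and flip constrained positions
    w = list(expand_template_random(pat, 1, rng)[0]
             + _random_bases(rng, length - len(pat), gc))
    flip = rng.choice(constrained, size=min(pat.max_mismatch + 1, len(constrained)),
                      replace=False)
    for i in flip:
        disallowed = sorted(set(_BASES) - pat.allowed_sets[i])
        w[i] = disallowed[int(rng.integers(len(disallowed)))]
    return "".join(w)


def generate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> tuple[list[TranscriptSeq], pd.DataFrame, GroundTruth]:
    """Generate (FASTA transcripts, variant table, ground truth) per spec.

    Each variant row sits on its own transcript.  Nonsense rows get a
    planted stop codon (drawn from ``stop_probs``), a random +4..+7, and a
    +8..+27 window drawn from the consensus pattern (matching rows) or
    rejection-sampled to violate it; exactly ``spec.n_matches`` rows match.
    Frameshift rows point at non-stop codons; truncated rows plant a real
    stop too close to the 3' end for a full +27 window.  With ``out_dir``
    the FASTA, variant CSV and truth JSON are written.
    """
    rng = np.random.default_rng(spec.seed)
    pat = parse_iupac(spec.pattern)
    lo, hi = spec.cds_length_range
    n_rows = spec.n_rows
    gene_pool = [f"GENE{i:04d}" for i in range(max(1, round(spec.gene_pool_factor * n_rows)))]
    match_flags = np.zeros(spec.n_nonsense, dtype=bool)
    match_flags[rng.choice(spec.n_nonsense, size=spec.n_matches, replace=False)] = True

    transcripts: list[TranscriptSeq] = []
    rows: list[dict] = []
    truth = GroundTruth()

    def new_meta(i: int) -> tuple[str, str, str]:
        gene = gene_pool[int(rng.integers(len(gene_pool)))]
        label = str(rng.choice(spec.pathogenicity_labels,
                               p=spec.pathogenicity_probs))
        return gene, f"T{i:06d}", label

    stop_arr = np.array(STOP_CODONS)
    for i in range(spec.n_nonsense):
        gene, tid, label = new_meta(i)
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        seq = list(_random_cds(rng, n_codons, spec.gc_content))
        # plant so that a full +1..+27 window exists
        c_max = (len(seq) - 27) // 3
        c = int(rng.integers(3, c_max + 1))
        pos = 3 * c  # 0-based; stop_start = pos + 1
        stop = str(rng.choice(stop_arr, p=spec.stop_probs))
        seq[pos : pos + 3] = stop
        w47 = _random_bases(rng, 4, spec.gc_content)
        seq[pos + 3 : pos + 7] = w47
        if match_flags[i]:
            w827 = expand_template_random(pat, 1, rng)[0]
            w827 += _random_bases(rng, 20 - len(w827), spec.gc_content)
        else:
            w827 = _violating_window(rng, pat, 20, spec.gc_content)
        seq[pos + 7 : pos + 27] = w827
        assert match_window(w827, pat)[0] == bool(match_flags[i])
        transcripts.append(TranscriptSeq(tid, "".join(seq)))
        rows.append({"gene": gene, "transcript_id": tid, "stop_start": pos + 1,
                     "consequence": "nonsense", "pathogenicity": label})
        truth.per_variant.append({
            "transcript_id": tid, "gene": gene, "kind": "nonsense",
            "is_match": bool(match_flags[i]), "stop_codon": stop,
            "nt4": w47[0], "nt8": w827[0], "window": w827,
            "pathogenicity": label,
        })

    for i in range(spec.n_frameshift):
        gene, tid, label = new_meta(spec.n_nonsense + i)
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        seq = _random_cds(rng, n_codons, spec.gc_content)
        pos = int(rng.integers(1, len(seq) - 30))
        transcripts.append(TranscriptSeq(tid, seq))
        rows.append({"gene": gene, "transcript_id": tid, "stop_start": pos,
                     "consequence": "frameshift", "pathogenicity": label})
        truth.per_variant.append({"transcript_id": tid, "gene": gene,
                                  "kind": "frameshift", "is_match": False})

    for i in range(spec.n_truncated):
        gene, tid, label = new_meta(spec.n_nonsense + spec.n_frameshift + i)
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        seq = list(_random_cds(rng, n_codons, spec.gc_content))
        # stop codon complete but fewer than 27 nt remain from +1
        # (after in-frame rounding, available = short + pos % 3 <= 26)
        short = int(rng.integers(3, 25))  # bases available from +1
        pos = len(seq) - short  # 0-based
        pos -= pos % 3  # keep in frame
        stop = str(rng.choice(stop_arr, p=spec.stop_probs))
        seq[pos : pos + 3] = stop
        transcripts.append(TranscriptSeq(tid, "".join(seq)))
        rows.append({"gene": gene, "transcript_id": tid, "stop_start": pos + 1,
                     "consequence": "nonsense", "pathogenicity": label})
        truth.per_variant.append({"transcript_id": tid, "gene": gene,
                                  "kind": "truncated", "is_match": False})

    variants = pd.DataFrame(rows, columns=["gene", "transcript_id", "stop_start",
                                           "consequence", "pathogenicity"])
    matched = [v for v in truth.per_variant if v.get("is_match")]
    truth.n_matches = len(matched)
    truth.n_unique_genes = len({v["gene"] for v in matched})
    truth.n_pathogenic = sum(
        1 for v in matched
        if v["pathogenicity"].lower() in ("pathogenic", "likely pathogenic"))
    truth.n_plus4C = sum(1 for v in matched if v["nt4"] == "C")
    truth.n_valid_contexts = spec.n_nonsense
    truth.n_excluded = spec.n_frameshift + spec.n_truncated

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(transcripts, out / "transcripts.fasta")
        variants.to_csv(out / "variants.csv", index=False)
        truth.to_json(out / "truth.json")
    return transcripts, variants, truth


def generate_plateau_trace(
    y0: float,
    ym: float,
    k_obs: float,
    times,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    label: str = "",
) -> KineticTrace:
    """Sample Y(t) = YM - (YM - Y0) exp(-k t) plus Gaussian noise (seeded)."""
    if k_obs <= 0:
        raise ValueError("k_obs must be > 0")
    if ym < y0:
        raise ValueError("ym must be >= y0 for a releasing reaction")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    y = ym - (ym - y0) * np.exp(-k_obs * t)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.size)
    return KineticTrace(times=t, signal=y, label=label)


def generate_translation_trace(
    segment_slopes,
    breakpoints,
    times,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    label: str = "",
) -> tuple[KineticTrace, float]:
    """Continuous piecewise-linear trace; returns (trace, true max slope).

    ``breakpoints`` are the interior segment boundaries (len(slopes) - 1 of
    them, strictly increasing).
    """
    slopes = [float(s) for s in segment_slopes]
    bps = [float(b) for b in breakpoints]
    if len(bps) != len(slopes) - 1:
        raise ValueError("need len(slopes) - 1 breakpoints")
    if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
        raise ValueError("breakpoints must be strictly increasing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    y = np.zeros_like(t)
    edges = [t[0]] + bps + [t[-1]]
    level = 0.0
    for slope, lo, hi in zip(slopes, edges, edges[1:]):
        mask = (t >= lo) & (t <= hi)
        y[mask] = level + slope * (t[mask] - lo)
        level += slope * (hi - lo)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.size)
    return KineticTrace(times=t, signal=y, label=label), max(slopes)
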