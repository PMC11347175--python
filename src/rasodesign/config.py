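"""Run configuration: consensus pattern, score weights, Tm and chemistry knobs.

A run config is a flat YAML mapping; every key has a library default, so an
empty (or absent) file is a valid config.  Example::

    pattern: GRRRNNYNNNNNNNNNNNNN
    anchor: 8
    max_mismatch: 0
    weights:
      w_stop: {TGA: 2, TAG: 1, TAA: 0}
      w4: {C: 2, T: 1, A: 0, G: 0}
      w8: {G: 3, A: 1, C: 0, T: 0}
      w_grun: 0.5
      w_gc: 2.0
    tm:
      oligo_conc_molar: 1.0e-6
      salt_molar: 0.1
      duplex: dna:rna
    chemistry:
      fluoro_3prime_window: 6
      fluoro_3prime_max: 4
      ps_warn_fraction: 0.5
    seed: 0
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .aso_designer import ChemistryThresholds
from .susceptibility import DEFAULT_CONSENSUS, ConsensusPattern, ScoreWeights, parse_iupac


@dataclass(frozen=True)
class TmConfig:
    oligo_conc_molar: float = 1e-6
    salt_molar: float = 0.1
    duplex: str = "dna:rna"


@dataclass(frozen=True)
class RunConfig:
    pattern: ConsensusPattern = field(
        default_factory=lambda: parse_iupac(DEFAULT_CONSENSUS))
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    tm: TmConfig = field(default_factory=TmConfig)
    chemistry: ChemistryThresholds = field(default_factory=ChemistryThresholds)
    seed: int = 0


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run config; missing keys fall back to library defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    pattern = parse_iupac(
        data.get("pattern", DEFAULT_CONSENSUS),
        anchor=int(data.get("anchor", 8)),
        max_mismatch=int(data.get("max_mismatch", 0)),
    )
    w = data.get("weights", {})
    weights = ScoreWeights(
        w_stop={k: float(v) for k, v in w.get("w_stop", ScoreWeights().w_stop).items()},
        w4={k: float(v) for k, v in w.get("w4", ScoreWeights().w4).items()},
        w8={k: float(v) for k, v in w.get("w8", ScoreWeights().w8).items()},
        w_grun=float(w.get("w_grun", ScoreWeights().w_grun)),
        w_gc=float(w.get("w_gc", ScoreWeights().w_gc)),
    )
    t = data.get("tm", {})
    tm = TmConfig(
        oligo_conc_molar=float(t.get("oligo_conc_molar", TmConfig().oligo_conc_molar)),
        salt_molar=float(t.get("salt_molar", TmConfig().salt_molar)),
        duplex=str(t.get("duplex", TmConfig().duplex)),
    )
    c = data.get("chemistry", {})
    chemistry = ChemistryThresholds(
        fluoro_3prime_window=int(c.get("fluoro_3prime_window",
                                       ChemistryThresholds().fluoro_3prime_window)),
        fluoro_3prime_max=int(c.get("fluoro_3prime_max",
                                    ChemistryThresholds().fluoro_3prime_max)),
        ps_warn_fraction=float(c.get("ps_warn_fraction",
                                     ChemistryThresholds().ps_warn_fraction)),
    )
    return RunConfig(pattern=pattern, weights=weights, tm=tm,
                     chemistry=chemistry, seed=int(data.get("seed", 0)))
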