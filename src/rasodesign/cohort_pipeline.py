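"""End-to-end cohort stage: context database, consensus query, summary.

Mirrors the LOVD3-style workflow: resolve each nonsense variant against its
transcript, extract the +1..+27 context, drop frameshift/truncated/
non-stop rows into an exclusion log, store the retained contexts as a fixed-
column CSV, query it with an IUPAC consensus and optional extra filters, and
summarize match counts (matches, unique genes, pathogenic subset, +4 C
subset, fraction of the database).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .susceptibility import ConsensusPattern, match_window
from .variant_context import (
    NotAStopError,
    TruncatedContextError,
    extract_context,
    filter_nonsense,
    read_fasta,
    read_variant_table,
)

DB_COLUMNS = (
    "gene", "transcript_id", "stop_start", "stop_codon",
    "nt4", "w47", "w827", "pathogenicity",
)
PATHOGENIC_LABELS = frozenset({"pathogenic", "likely pathogenic"})


@dataclass
class ContextDB:
    """The premature-stop context database plus exclusion log and provenance."""

    df: pd.DataFrame
    exclusions: pd.DataFrame  # columns: transcript_id, reason
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def write(self, out_path: str | Path, log_path: str | Path | None = None) -> None:
        self.df.to_csv(out_path, index=False)
        if log_path is not None:
            self.exclusions.to_csv(log_path, index=False)


def load_context_db(path: str | Path) -> ContextDB:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(DB_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"context DB missing column(s) {sorted(missing)}")
    df["stop_start"] = df["stop_start"].astype(int)
    return ContextDB(df=df[list(DB_COLUMNS)],
                     exclusions=pd.DataFrame(columns=["transcript_id", "reason"]),
                     provenance={"source": str(path)})


def _config_hash(**params) -> str:
    blob = json.dumps(params, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def build_context_db(
    fasta_path: str | Path,
    variants_path: str | Path,
    out_path: str | Path | None = None,
    log_path: str | Path | None = None,
    require_full_window: bool = True,
    dedupe: bool = False,
) -> ContextDB:
    """read -> filter frameshifts -> extract contexts -> rows + exclusion log.

    Row order follows input order.  Unresolvable transcript ids, non-stop
    codons and truncated windows are logged, not fatal.  With ``dedupe``,
    exact duplicate (transcript_id, stop_start) rows are collapsed and the
    dropped count recorded in provenance.
    """
    transcripts = {t.id: t for t in read_fasta(fasta_path)}
    records = read_variant_table(variants_path)
    kept, excluded = filter_nonsense(records)
    rows: list[dict] = []
    log: list[dict] = [
        {"transcript_id": rec.transcript_id, "reason": reason}
        for rec, reason in excluded
    ]
    for rec in kept:
        tseq = transcripts.get(rec.transcript_id)
        if tseq is None:
            log.append({"transcript_id": rec.transcript_id,
                        "reason": "missing-transcript"})
            continue
        try:
            ctx = extract_context(tseq, rec, require_full_window=require_full_window)
        except TruncatedContextError:
            available = len(tseq) - (rec.stop_start - 1)
            log.append({"transcript_id": rec.transcript_id,
                        "reason": f"truncated(available={available})"})
            continue
        except NotAStopError as exc:
            log.append({"transcript_id": rec.transcript_id,
                        "reason": f"not-a-stop({exc})"})
            continue
        rows.append({
            "gene": ctx.gene, "transcript_id": ctx.transcript_id,
            "stop_start": ctx.stop_start, "stop_codon": ctx.stop_codon,
            "nt4": ctx.nt4, "w47": ctx.w47, "w827": ctx.w827,
            "pathogenicity": ctx.pathogenicity,
        })
    df = pd.DataFrame(rows, columns=list(DB_COLUMNS))
    n_dup = 0
    if dedupe and len(df):
        before = len(df)
        df = df.drop_duplicates(subset=["transcript_id", "stop_start"],
                                keep="first").reset_index(drop=True)
        n_dup = before - len(df)
    provenance = {
        "fasta": str(fasta_path),
        "variants": str(variants_path),
        "config_hash": _config_hash(require_full_window=require_full_window,
                                    dedupe=dedupe),
        "tool_version": __version__,
        "n_deduplicated": n_dup,
    }
    db = ContextDB(df=df,
                   exclusions=pd.DataFrame(log, columns=["transcript_id", "reason"]),
                   provenance=provenance)
    if out_path is not None:
        db.write(out_path, log_path)
    return db


def query_db(
    db: ContextDB,
    pattern: ConsensusPattern,
    plus4: set[str] | None = None,
    stop_codon: set[str] | None = None,
) -> pd.DataFrame:
    """Rows whose context matches the consensus and all extra filters.

    The pattern is matched against the window starting at its anchor
    (+4..+27 are available per row); default anchor +8 uses the w827 column.
    Row order is stable (input order).
    """
    if pattern.anchor + len(pattern) - 1 > 27:
        raise ValueError(
            f"pattern spans +{pattern.anchor}..+{pattern.anchor + len(pattern) - 1}, "
            "beyond the stored +27 window"
        )
    offset = pattern.anchor - 4  # window w47+w827 starts at +4
    def row_matches(row) -> bool:
        window = (row.w47 + row.w827)[offset:]
        return match_window(window, pattern)[0]

    mask = [row_matches(r) for r in db.df.itertuples(index=False)]
    out = db.df[mask]
    if plus4 is not None:
        out = out[out["nt4"].isin(plus4)]
    if stop_codon is not None:
        out = out[out["stop_codon"].isin(stop_codon)]
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class CohortSummary:
    """Headline counts for a consensus query against the context database."""

    n_matches: int
    n_unique_genes: int
    n_pathogenic: int
    n_plus4C: int
    fraction_of_db: float
    per_stop_codon: dict
    n_unique_contexts: int  # distinct (stop_codon, w47, w827) among matches

    def to_dict(self) -> dict:
        return {
            "n_matches": self.n_matches,
            "n_unique_genes": self.n_unique_genes,
            "n_pathogenic": self.n_pathogenic,
            "n_plus4C": self.n_plus4C,
            "fraction_of_db": self.fraction_of_db,
            "per_stop_codon": dict(self.per_stop_codon),
            "n_unique_contexts": self.n_unique_contexts,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def summarize(matched: pd.DataFrame, db: ContextDB) -> CohortSummary:
    """Counts over a query result: matches, unique genes, pathogenic, +4 C.

    Pathogenicity counts labels equal (case-insensitively) to "pathogenic"
    or "likely pathogenic"; anything else is non-pathogenic here.  Both
    per-row and per-unique-context counts are reported.
    """
    if len(db) == 0:
        raise ValueError("cannot summarize against an empty database")
    n_matches = len(matched)
    labels = matched["pathogenicity"].str.strip().str.lower()
    return CohortSummary(
        n_matches=n_matches,
        n_unique_genes=matched["gene"].nunique(),
        n_pathogenic=int(labels.isin(PATHOGENIC_LABELS).sum()),
        n_plus4C=int((matched["nt4"] == "C").sum()),
        fraction_of_db=n_matches / len(db),
        per_stop_codon=matched["stop_codon"].value_counts().to_dict(),
        n_unique_contexts=len(
            matched[["stop_codon", "w47", "w827"]].drop_duplicates()
        ),
    )
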