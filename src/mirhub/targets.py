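"""Integration of miRNA-target interaction sources.

Three kinds of evidence table are merged into one deduplicated
interaction set, restricted to significantly differentially expressed
miRNAs:

* a predicted-score table (scores 0-100, kept when score > 80.0),
* a regression-score table (mirSVR-style scores <= 0, kept when
  score < -1.2; more negative means stronger predicted repression),
* a curated table of experimentally validated interactions, kept
  unconditionally.

Both score cutoffs are strict inequalities and configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from mirhub.de import DEResult

logger = logging.getLogger(__name__)

PREDICTED_SCORE_A = "predicted_score_a"  # miRDB-like, score > cutoff passes
PREDICTED_SCORE_B = "predicted_score_b"  # mirSVR-like, score < cutoff passes
CURATED = "curated"

SOURCES = (PREDICTED_SCORE_A, PREDICTED_SCORE_B, CURATED)

DEFAULT_SCORE_CUTOFF = 80.0
DEFAULT_MIRSVR_CUTOFF = -1.2

__all__ = [
    "InteractionRecord",
    "normalize_mirna_name",
    "normalize_gene_name",
    "passes_filter",
    "integrate",
    "read_interaction_table",
    "write_interactions",
]


def normalize_mirna_name(raw: str) -> str:
    """Canonical mature-miRNA name: lower-case species prefix and id,
    with the stem rendered ``miR``; the -3p/-5p arm suffix is preserved.

    >>> normalize_mirna_name("RNO-MIR-141-3P")
    'rno-miR-141-3p'
    """
    if not raw or not raw.strip():
        raise ValueError("empty miRNA name")
    parts = raw.strip().split("-")
    out = []
    for part in parts:
        low = part.lower()
        out.append("miR" if low == "mir" else low)
    return "-".join(out)


def normalize_gene_name(raw: str) -> str:
    """Gene symbols are opaque; matching is case-insensitive and the
    stored form is upper-case."""
    if not raw or not raw.strip():
        raise ValueError("empty gene name")
    return raw.strip().upper()


@dataclass(frozen=True)
class InteractionRecord:
    """One deduplicated miRNA->gene interaction with provenance."""

    mirna: str
    gene: str
    sources: tuple[str, ...]
    best_score: float | None = None

    def __post_init__(self) -> None:
        bad = set(self.sources) - set(SOURCES)
        if bad:
            raise ValueError(f"unknown sources {bad}")


def passes_filter(
    source: str,
    score: float | None,
    score_cutoff: float = DEFAULT_SCORE_CUTOFF,
    mirsvr_cutoff: float = DEFAULT_MIRSVR_CUTOFF,
) -> bool:
    """Whether one evidence row survives its source's cutoff.

    Strict inequalities: a predicted score exactly at the cutoff fails,
    as does a regression score exactly at its cutoff.  Curated evidence
    always passes.
    """
    if source == PREDICTED_SCORE_A:
        return score is not None and score > score_cutoff
    if source == PREDICTED_SCORE_B:
        return score is not None and score < mirsvr_cutoff
    if source == CURATED:
        return True
    raise ValueError(f"unknown source {source!r}")


def read_interaction_table(path: str | Path, source: str) -> pd.DataFrame:
    """Read one interaction TSV (columns: mirna, gene, score or evidence)."""
    if source not in SOURCES:
        raise ValueError(f"unknown source {source!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.attrs["source"] = source
    return df


def _iter_rows(table: pd.DataFrame, source: str):
    """Yield (mirna, gene, score) from a raw table, skipping malformed rows."""
    skipped = 0
    score_col = None
    for cand in ("score", "mirsvr_score", "evidence"):
        if cand in table.columns:
            score_col = cand
            break
    for row in table.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(table.columns, row))
        mirna = d.get("mirna")
        gene = d.get("gene")
        if not isinstance(mirna, str) or not isinstance(gene, str) or not mirna.strip() or not gene.strip():
            skipped += 1
            continue
        score: float | None = None
        if source in (PREDICTED_SCORE_A, PREDICTED_SCORE_B):
            raw = d.get(score_col) if score_col else None
            try:
                score = float(raw)
            except (TypeError, ValueError):
                skipped += 1
                continue
            if math.isnan(score):
                skipped += 1
                continue
        yield mirna, gene, score
    if skipped:
        logger.warning("skipped %d malformed rows in %s table", skipped, source)


def integrate(
    predicted_a: pd.DataFrame,
    predicted_b: pd.DataFrame,
    curated: pd.DataFrame,
    de: Sequence[DEResult],
    score_cutoff: float = DEFAULT_SCORE_CUTOFF,
    mirsvr_cutoff: float = DEFAULT_MIRSVR_CUTOFF,
) -> list[InteractionRecord]:
    """Union of the three filtered sources, restricted to significant miRNAs.

    Duplicated (mirna, gene) pairs collapse into one record carrying all
    contributing sources and the best predicted score seen (the maximum
    for 0-100 scores; for regression scores "best" is the most negative,
    and the 0-100 score is preferred for reporting when both exist).
    Output is sorted by (gene, mirna).
    """
    significant = {
        normalize_mirna_name(r.mirna)
        for r in de
        if r.direction in ("up", "down")
    }
    if not significant:
        raise ValueError("no significantly DE miRNAs to integrate against")

    merged: dict[tuple[str, str], dict] = {}
    for table, source in ((predicted_a, PREDICTED_SCORE_A), (predicted_b, PREDICTED_SCORE_B), (curated, CURATED)):
        for mirna_raw, gene_raw, score in _iter_rows(table, source):
            mirna = normalize_mirna_name(mirna_raw)
            if mirna not in significant:
                continue
            if not passes_filter(source, score, score_cutoff, mirsvr_cutoff):
                continue
            gene = normalize_gene_name(gene_raw)
            slot = merged.setdefault((mirna, gene), {"sources": set(), "score_a": None, "score_b": None})
            slot["sources"].add(source)
            if source == PREDICTED_SCORE_A:
                slot["score_a"] = score if slot["score_a"] is None else max(slot["score_a"], score)
            elif source == PREDICTED_SCORE_B:
                slot["score_b"] = score if slot["score_b"] is None else min(slot["score_b"], score)

    records = []
    for (mirna, gene), slot in merged.items():
        best = slot["score_a"] if slot["score_a"] is not None else slot["score_b"]
        records.append(
            InteractionRecord(
                mirna=mirna,
                gene=gene,
                sources=tuple(sorted(slot["sources"])),
                best_score=best,
            )
        )
    records.sort(key=lambda r: (r.gene, r.mirna))
    return records


def write_interactions(records: Iterable[InteractionRecord], path: str | Path) -> None:
    rows = [
        {
            "mirna": r.mirna,
            "gene": r.gene,
            "sources": ",".join(r.sources),
            "best_score": "" if r.best_score is None else r.best_score,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["mirna", "gene", "sources", "best_score"]).to_csv(path, sep="\t", index=False)
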