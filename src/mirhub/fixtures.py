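"""Packaged worked-example fixtures.

Three small tables from the motivating cardiac study ship with the
package: the differentially expressed miRNA table (five miRNAs, two up
and three down), the selected-target interaction marks (five genes x
four miRNAs, fourteen marks), and the qRT-PCR primer table (six primer
pairs).  They are the canonical desk-scale inputs for the signed
network arithmetic and the amplicon checks.

Censored significance entries printed as upper bounds (``<0.001``) are
parsed as the bound itself; every downstream use only needs the value
to clear a much larger threshold.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from mirhub.de import DEResult
from mirhub.qpcr import PrimerPair
from mirhub.targets import CURATED, InteractionRecord

__all__ = [
    "load_de_table",
    "load_target_marks",
    "load_primers",
    "target_interactions",
    "fixture_path",
]


def fixture_path(name: str) -> Path:
    return Path(resources.files("mirhub") / "data" / name)


def _parse_bounded(value: str) -> float:
    value = str(value).strip()
    if value.startswith("<"):
        return float(value[1:])
    return float(value)


def load_de_table() -> list[DEResult]:
    """The study's differentially expressed miRNAs as DEResult rows."""
    df = pd.read_csv(fixture_path("table1_de_mirnas.tsv"), sep="\t", dtype=str)
    return [
        DEResult(
            mirna=row["mirna"],
            log_fc=float(row["logFC"]),
            p_value=_parse_bounded(row["p_value"]),
            fdr=_parse_bounded(row["fdr"]),
            direction=row["direction"],
        )
        for _, row in df.iterrows()
    ]


def load_target_marks() -> pd.DataFrame:
    """Selected target genes with one 0/1 mark column per DE miRNA."""
    return pd.read_csv(fixture_path("table2_target_marks.tsv"), sep="\t")


def target_interactions() -> list[InteractionRecord]:
    """The marked miRNA->gene pairs as interaction records."""
    marks = load_target_marks()
    mirna_cols = [c for c in marks.columns if c.startswith("rno-")]
    records = []
    for _, row in marks.iterrows():
        for m in mirna_cols:
            if int(row[m]) == 1:
                records.append(
                    InteractionRecord(mirna=m, gene=str(row["gene"]).upper(), sources=(CURATED,))
                )
    records.sort(key=lambda r: (r.gene, r.mirna))
    return records


def load_primers() -> list[PrimerPair]:
    """The study's qRT-PCR primer pairs."""
    df = pd.read_csv(fixture_path("table3_primers.tsv"), sep="\t")
    return [
        PrimerPair(
            gene=row["gene"],
            accession=row["accession"],
            forward=row["forward"],
            reverse=row["reverse"],
            expected_size=int(row["product_size"]),
        )
        for _, row in df.iterrows()
    ]
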