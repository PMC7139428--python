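"""GO over-representation analysis with fold enrichment.

For a target gene list of size n drawn from a universe of N genes, a
term annotating K universe genes and overlapping the list in k genes
has fold enrichment (k/n)/(K/N) and an upper-tail hypergeometric
p-value P(X >= k).  Either Benjamini-Hochberg or Bonferroni correction
is applied across all tested terms (only terms with k >= 1 are tested).
No term-hierarchy propagation is performed: the annotation is taken
flat, as in a GMT file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from mirhub.de import bh_adjust

__all__ = ["EnrichmentResult", "enrich", "top_terms", "read_gmt", "write_gmt", "write_enrichment"]


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # targets annotated to term
    n: int  # target-list size
    K: int  # universe genes annotated to term
    N: int  # universe size
    fold_enrichment: float
    p_value: float
    p_adjusted: float
    method: str

    @property
    def genes_hit(self) -> frozenset[str]:
        return getattr(self, "_genes_hit", frozenset())


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Parse a GMT file into term id -> (description, gene set)."""
    out: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term, desc, genes = parts[0], parts[1], parts[2:]
            out[term] = (desc, frozenset(g.strip().upper() for g in genes if g.strip()))
    return out


def write_gmt(annotation: Mapping[str, tuple[str, frozenset[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotation):
            desc, genes = annotation[term]
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def enrich(
    targets: Iterable[str],
    annotation: Mapping[str, tuple[str, frozenset[str]]],
    universe: Iterable[str] | None = None,
    method: str = "BH",
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``targets`` against ``annotation``.

    ``universe`` defaults to the union of all annotated genes.  Targets
    must be a subset of the universe.  Results are sorted by fold
    enrichment descending (ties: smaller p first, then term id).
    """
    if method not in ("BH", "Bonferroni"):
        raise ValueError("method must be 'BH' or 'Bonferroni'")
    target_set = {g.strip().upper() for g in targets}
    if not target_set:
        raise ValueError("empty target list")
    if universe is None:
        uni = set()
        for _, genes in annotation.values():
            uni |= genes
    else:
        uni = {g.strip().upper() for g in universe}
    if not uni:
        raise ValueError("empty universe")
    stray = target_set - uni
    if stray:
        raise ValueError(f"targets outside universe: {sorted(stray)[:5]} ...")

    N = len(uni)
    n = len(target_set)
    rows = []
    for term, (desc, genes) in annotation.items():
        term_genes = genes & uni
        hit = term_genes & target_set
        k, K = len(hit), len(term_genes)
        if k < 1:
            continue
        fold = (k / n) / (K / N)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, desc, k, K, fold, min(p, 1.0), frozenset(hit)))

    m = len(rows)
    if method == "BH":
        adj = bh_adjust([r[5] for r in rows])
    else:
        adj = [min(1.0, r[5] * m) for r in rows]

    results = []
    for (term, desc, k, K, fold, p, hit), pa in zip(rows, adj):
        res = EnrichmentResult(
            term_id=term,
            term_name=desc,
            k=k,
            n=n,
            K=K,
            N=N,
            fold_enrichment=fold,
            p_value=p,
            p_adjusted=float(pa),
            method=method,
        )
        res._genes_hit = hit
        results.append(res)
    results.sort(key=lambda r: (-r.fold_enrichment, r.p_value, r.term_id))
    return results


def top_terms(results: Sequence[EnrichmentResult], m: int, alpha: float = 0.05) -> list[EnrichmentResult]:
    """The ``m`` significant terms with the highest fold enrichment.

    Ties are broken by smaller p-value, then term id.  Fewer than ``m``
    significant terms returns them all.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    sig = [r for r in results if r.p_adjusted < alpha]
    sig.sort(key=lambda r: (-r.fold_enrichment, r.p_value, r.term_id))
    return sig[:m]


def write_enrichment(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "term": r.term_id,
                "name": r.term_name,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "fold_enrichment": r.fold_enrichment,
                "p": r.p_value,
                "p_adjusted": r.p_adjusted,
                "genes": ",".join(sorted(r.genes_hit)),
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)
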