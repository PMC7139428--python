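"""Integrate the three target-interaction sources at their cutoffs.

Keeps predicted interactions with score > 80.0 or mirSVR score < -1.2
and all curated interactions, restricted to the significantly DE
miRNAs from the previous step; writes results/interactions.tsv.
"""

from pathlib import Path

from mirhub.cli import _read_de_table
from mirhub.targets import (
    CURATED,
    PREDICTED_SCORE_A,
    PREDICTED_SCORE_B,
    integrate,
    read_interaction_table,
    write_interactions,
)

IN = Path("results/synthetic")
OUT = Path("results")


def main() -> None:
    de = _read_de_table(OUT / "de_table.tsv")
    records = integrate(
        read_interaction_table(IN / "predicted_a.tsv", PREDICTED_SCORE_A),
        read_interaction_table(IN / "predicted_b.tsv", PREDICTED_SCORE_B),
        read_interaction_table(IN / "curated.tsv", CURATED),
        de,
    )
    write_interactions(records, OUT / "interactions.tsv")
    genes = {r.gene for r in records}
    by_source: dict[str, int] = {}
    for r in records:
        for s in r.sources:
            by_source[s] = by_source.get(s, 0) + 1
    print(f"{len(records)} interactions over {len(genes)} predicted target genes")
    print("evidence:", ", ".join(f"{k}={v}" for k, v in sorted(by_source.items())))

if __name__ == "__main__":
    main()
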