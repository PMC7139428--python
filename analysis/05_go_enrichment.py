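"""GO over-representation of the predicted target set.

Hypergeometric upper-tail test with fold enrichment (k/n)/(K/N) and
BH correction over all tested terms; writes results/enrichment.tsv
and prints the top terms by fold enrichment.
"""

from pathlib import Path

import pandas as pd

from mirhub.enrichment import enrich, read_gmt, top_terms, write_enrichment

IN = Path("results/synthetic")
OUT = Path("results")


def main() -> None:
    targets = sorted(set(pd.read_csv(OUT / "interactions.tsv", sep="\t")["gene"]))
    annotation = read_gmt(IN / "annotation.gmt")
    results = enrich(targets, annotation, method="BH")
    write_enrichment(results, OUT / "enrichment.tsv")

    sig = [r for r in results if r.p_adjusted < 0.05]
    print(f"{len(results)} terms tested over {len(targets)} targets; {len(sig)} significant (BH < 0.05)")
    for r in top_terms(results, m=5, alpha=0.05):
        print(f"  {r.term_id:12s} fold {r.fold_enrichment:6.1f}  k/K = {r.k}/{r.K}  "
              f"p_adj {r.p_adjusted:.2e}  {r.term_name}")


if __name__ == "__main__":
    main()
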