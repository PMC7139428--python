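"""Generate the synthetic study inputs with planted ground truth.

Writes a full input bundle under results/synthetic/: a two-group NB
miRNA count matrix (500 miRNAs, 6 samples/group, 5 planted DE miRNAs
at |log2FC| = 2), three target-interaction tables hiding 11 planted
3-regulator hubs among decoy edges, a GO annotation with enriched
blocks, and a duplicate-well qPCR Cp table (n = 7/group) with planted
fold changes.
"""

from pathlib import Path

import pandas as pd

from mirhub.enrichment import write_gmt
from mirhub.simulate import (
    default_study_config,
    simulate_counts,
    simulate_go_annotation,
    simulate_qpcr,
    simulate_target_databases,
    write_cp_table,
)

SEED = 0
OUT = Path("results/synthetic")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = default_study_config(SEED)
    counts, truth = simulate_counts(cfg)
    counts.to_tsv(OUT / "counts.tsv")
    pd.DataFrame(
        {"sample": counts.samples, "group": [counts.groups[s] for s in counts.samples]}
    ).to_csv(OUT / "groups.tsv", sep="\t", index=False)
    a, b, c = simulate_target_databases(cfg)
    a.to_csv(OUT / "predicted_a.tsv", sep="\t", index=False)
    b.to_csv(OUT / "predicted_b.tsv", sep="\t", index=False)
    c.to_csv(OUT / "curated.tsv", sep="\t", index=False)
    write_gmt(simulate_go_annotation(cfg), OUT / "annotation.gmt")
    write_cp_table(simulate_qpcr(cfg), OUT / "cp_table.tsv")
    truth.to_json(OUT / "ground_truth.json")

    n_up = sum(1 for v in truth.de_mirnas.values() if v > 0)
    print(f"wrote synthetic inputs to {OUT} (seed {SEED})")
    print(f"planted: {len(truth.de_mirnas)} DE miRNAs ({n_up} up), "
          f"{len(truth.hub_genes)} target hubs, "
          f"{len(truth.qpcr_fold_changes)} qPCR effects")


if __name__ == "__main__":
    main()
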