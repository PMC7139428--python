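"""Select validation candidates from the hub set.

Negative-strength hubs are taken unconditionally; positive-strength
hubs are ranked by the best fold enrichment among significant GO terms
annotating them and the top three are added.  Writes
results/selection.json.
"""

import json
from pathlib import Path

from mirhub.cli import _read_de_table, _read_enrichment, _read_interactions
from mirhub.network import build_network, find_hubs
from mirhub.prioritize import select_candidates

OUT = Path("results")


def main() -> None:
    de = _read_de_table(OUT / "de_table.tsv")
    net = build_network(_read_interactions(OUT / "interactions.tsv"), de)
    hubs = find_hubs(net)
    enrichment = _read_enrichment(OUT / "enrichment.tsv")
    report = select_candidates(hubs, net, enrichment, n_positive=3)

    (OUT / "selection.json").write_text(
        json.dumps(
            {
                "selected": report.selected,
                "selected_negative": report.selected_negative,
                "selected_positive": report.selected_positive,
                "rationale": report.rationale,
            },
            indent=2,
        )
    )
    print(f"{len(report.hubs_considered)} hubs considered -> {len(report.selected)} candidates")
    print(f"  strength < 0 (unconditional): {', '.join(report.selected_negative)}")
    print(f"  strength > 0 (top GO fold):   {', '.join(report.selected_positive)}")

if __name__ == "__main__":
    main()
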