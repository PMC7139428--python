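"""qRT-PCR validation of the selected targets by 2^-ddCp.

Duplicate wells are averaged on the Cp scale, expression is referenced
to the housekeeping gene and calibrated to the control group, and
groups are compared with an unpaired Student's t-test.  Writes
results/qpcr_results.tsv and compares against the planted folds.
"""

import json
from pathlib import Path

from mirhub.qpcr import ddcp, read_cp_table, write_qpcr_results
from mirhub.simulate import GroundTruth, default_study_config

IN = Path("results/synthetic")
OUT = Path("results")


def main() -> None:
    cp = read_cp_table(IN / "cp_table.tsv")
    truth = GroundTruth.from_json(IN / "ground_truth.json")
    selected = json.loads((OUT / "selection.json").read_text())["selected"]
    reference = default_study_config(0).reference_gene

    measured = set(cp["gene"])
    results = [ddcp(cp, reference, g) for g in selected if g in measured]
    write_qpcr_results(results, OUT / "qpcr_results.tsv")

    print(f"reference gene {reference}; {len(results)} targets quantified (n = 7/group, duplicate wells)")
    for r in results:
        planted = truth.qpcr_fold_changes.get(r.gene)
        star = "*" if r.significant else " "
        print(f" {star} {r.gene}: {r.treated_mean:.2f} +/- {r.sem_treated:.2f} vs "
              f"{r.control_mean:.2f} +/- {r.sem_control:.2f} (planted {planted}), p = {r.p_value:.3g}")


if __name__ == "__main__":
    main()
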