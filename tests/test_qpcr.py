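"""2^-ddCp quantification chain and in-silico amplicons."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from mirhub.fixtures import load_primers
from mirhub.qpcr import PrimerPair, ddcp, verify_amplicon


def _cp(rows):
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "cp"])


def _build_table(ref_cp, target_cp):
    """ref_cp/target_cp: {sample: (group, cp)} with duplicate wells."""
    rows = []
    for s, (g, cp) in ref_cp.items():
        for rep in (1, 2):
            rows.append((s, g, "REF", rep, cp))
    for s, (g, cp) in target_cp.items():
        for rep in (1, 2):
            rows.append((s, g, "TGT", rep, cp))
    return _cp(rows)


def test_hand_computed_single_sample_chain():
    """Target 24 vs 25 cycles (treated vs control), reference 20
    everywhere: treated expression is 2^-((24-20)-(25-20)) = 2."""
    table = _build_table(
        ref_cp={"c1": ("control", 20.0), "t1": ("treated", 20.0)},
        target_cp={"c1": ("control", 25.0), "t1": ("treated", 24.0)},
    )
    with pytest.warns(UserWarning):  # <2 samples per group: no test
        res = ddcp(table, "REF", "TGT")
    assert res.expression["t1"] == pytest.approx(2.0)
    assert res.expression["c1"] == pytest.approx(1.0)
    assert res.p_value is None


def test_all_identical_cp_gives_unit_expression_and_p_one():
    table = _build_table(
        ref_cp={s: (g, 20.0) for s, g in [("c1", "control"), ("c2", "control"), ("t1", "treated"), ("t2", "treated")]},
        target_cp={s: (g, 23.0) for s, g in [("c1", "control"), ("c2", "control"), ("t1", "treated"), ("t2", "treated")]},
    )
    with pytest.warns(UserWarning):
        res = ddcp(table, "REF", "TGT")
    assert all(v == pytest.approx(1.0) for v in res.expression.values())
    assert res.p_value == 1.0
    assert not res.significant


def test_control_group_geometric_mean_is_one_by_construction():
    """Anchoring ddCp to the control-group mean dCp makes the geometric
    mean of control expressions exactly 1 (the arithmetic mean is 1
    only on noiseless data)."""
    rng = np.random.default_rng(0)
    ref = {f"c{i}": ("control", 20 + rng.normal(0, 0.3)) for i in range(4)}
    ref.update({f"t{i}": ("treated", 20 + rng.normal(0, 0.3)) for i in range(4)})
    tgt = {s: (g, cp + 4 + rng.normal(0, 0.3)) for s, (g, cp) in ref.items()}
    res = ddcp(_build_table(ref, tgt), "REF", "TGT")
    ctrl = [v for s, v in res.expression.items() if s.startswith("c")]
    assert np.exp(np.mean(np.log(ctrl))) == pytest.approx(1.0, abs=1e-12)
    assert all(v > 0 for v in res.expression.values())


def test_cp_shift_invariance():
    """Adding a constant to every Cp cancels in the ddCp chain."""
    rng = np.random.default_rng(1)
    ref = {f"c{i}": ("control", 20 + rng.normal()) for i in range(4)}
    ref.update({f"t{i}": ("treated", 20 + rng.normal()) for i in range(4)})
    tgt = {s: (g, cp + 3 + rng.normal()) for s, (g, cp) in ref.items()}
    t1 = _build_table(ref, tgt)
    t2 = t1.copy()
    t2["cp"] = t2["cp"] + 5.0
    r1 = ddcp(t1, "REF", "TGT")
    r2 = ddcp(t2, "REF", "TGT")
    for s in r1.expression:
        assert r1.expression[s] == pytest.approx(r2.expression[s], abs=1e-12)


def test_group_label_swap_inverts_fold_change():
    """Relabelling the groups re-calibrates to the other group's mean,
    inverting the fold change on noiseless data."""
    ref = {f"c{i}": ("control", 20.0) for i in range(3)}
    ref.update({f"t{i}": ("treated", 20.0) for i in range(3)})
    tgt = {s: (g, 25.0 if g == "control" else 24.0) for s, (g, _) in ref.items()}
    res = ddcp(_build_table(ref, tgt), "REF", "TGT")
    swapped = _build_table(
        {s: ({"control": "treated", "treated": "control"}[g], cp) for s, (g, cp) in ref.items()},
        {s: ({"control": "treated", "treated": "control"}[g], cp) for s, (g, cp) in tgt.items()},
    )
    res_sw = ddcp(swapped, "REF", "TGT")
    assert res.treated_mean == pytest.approx(2.0)
    assert res_sw.treated_mean == pytest.approx(0.5)


def test_t_statistic_matches_closed_form():
    xc = np.array([1.0, 1.2, 0.9, 1.1])
    xt = np.array([0.5, 0.65, 0.4, 0.55])
    # construct Cp values giving exactly these expressions: dCp = -log2(x)
    ref = {}
    tgt = {}
    for i, v in enumerate(xc):
        ref[f"c{i}"] = ("control", 20.0)
        tgt[f"c{i}"] = ("control", 20.0 - np.log2(v))
    for i, v in enumerate(xt):
        ref[f"t{i}"] = ("treated", 20.0)
        tgt[f"t{i}"] = ("treated", 20.0 - np.log2(v))
    res = ddcp(_build_table(ref, tgt), "REF", "TGT")
    # renormalise to the control mean as ddcp does
    cal = 2.0 ** -(np.mean([-np.log2(v) for v in xc]))
    a, b = xt / cal, xc / cal
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t_expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    assert res.t_statistic == pytest.approx(t_expected, abs=1e-12)


def test_missing_reference_sample_excluded_with_warning():
    table = _build_table(
        ref_cp={"c1": ("control", 20.0), "c2": ("control", 20.0), "t1": ("treated", 20.0), "t2": ("treated", 20.0)},
        target_cp={"c1": ("control", 25.0), "c2": ("control", 25.0), "t1": ("treated", 24.0), "t2": ("treated", 24.0)},
    )
    table = table[~((table["sample"] == "t2") & (table["gene"] == "REF"))]
    with pytest.warns(UserWarning, match="lacks reference"):
        res = ddcp(table, "REF", "TGT")
    assert "t2" not in res.expression


def test_nonpositive_cp_rejected():
    table = _build_table(ref_cp={"c1": ("control", 0.0)}, target_cp={"c1": ("control", 25.0)})
    with pytest.raises(ValueError):
        ddcp(table, "REF", "TGT")


# ---------------------------------------------------------------------------
# amplicons

def _template_with_sites(fwd, rev, gap, rng):
    """fwd + gap random bases + reverse-complement(rev), padded."""
    bases = "ACGT"
    middle = "".join(rng.choice(list(bases)) for _ in range(gap))
    site = str(Seq(rev).reverse_complement())
    pad = "".join(rng.choice(list(bases)) for _ in range(50))
    return pad + fwd + middle + site + pad


def test_constructed_amplicon_size():
    import random

    rng = random.Random(0)
    fwd, rev = "AGGCGATACCAGGCTTCAGA", "TCAGGAGCAAAGCAGAGCAG"
    primers = PrimerPair("X", "ACC.1", fwd, rev, 144)
    template = _template_with_sites(fwd, rev, gap=144 - len(fwd) - len(rev), rng=rng)
    assert verify_amplicon(primers, template) == 144


def test_forward_at_position_one():
    import random

    rng = random.Random(1)
    fwd, rev = "ATGCATGCAT", "GGGTTTCCCA"
    site = str(Seq(rev).reverse_complement())
    template = fwd + "A" * (144 - len(fwd) - len(site)) + site + "".join(rng.choice("ACGT") for _ in range(300))
    assert verify_amplicon(PrimerPair("Y", "ACC.2", fwd, rev, 144), template) == 144


def test_forward_primer_only_errors():
    primers = PrimerPair("Z", "ACC.3", "ATGCATGCAT", "GGGTTTCCCA", 0)
    with pytest.raises(ValueError):
        verify_amplicon(primers, "CCCC" + "ATGCATGCAT" + "CCCC")


def test_reverse_site_upstream_errors():
    fwd, rev = "ATGCATGCAT", "GGGTTTCCCA"
    site = str(Seq(rev).reverse_complement())
    template = site + "AAAA" + fwd
    with pytest.raises(ValueError):
        verify_amplicon(PrimerPair("Z", "ACC.4", fwd, rev, 0), template)


def test_multiple_sites_report_smallest():
    fwd, rev = "ATGCATGCAT", "GGGTTTCCCA"
    site = str(Seq(rev).reverse_complement())
    template = fwd + "A" * 30 + site + "C" * 30 + site
    with pytest.warns(UserWarning):
        size = verify_amplicon(PrimerPair("W", "ACC.5", fwd, rev, 0), template)
    assert size == len(fwd) + 30 + len(site)


def test_reverse_complemented_template_with_swapped_primers():
    import random

    rng = random.Random(2)
    fwd, rev = "AGGCGATACCAGGCTTCAGA", "TCAGGAGCAAAGCAGAGCAG"
    template = _template_with_sites(fwd, rev, gap=60, rng=rng)
    size = verify_amplicon(PrimerPair("A", "x", fwd, rev, 0), template)
    flipped = str(Seq(template).reverse_complement())
    size_flipped = verify_amplicon(PrimerPair("A", "x", rev, fwd, 0), flipped)
    assert size == size_flipped


def test_packaged_primers_amplify_synthetic_transcripts():
    """Each packaged primer pair recovers its printed product size on a
    synthetic transcript built to contain its two sites at the printed
    spacing."""
    import random

    rng = random.Random(3)
    for p in load_primers():
        gap = p.expected_size - len(p.forward) - len(p.reverse)
        template = _template_with_sites(p.forward, p.reverse, gap=gap, rng=rng)
        assert verify_amplicon(p, template) == p.expected_size


def test_primer_validation():
    with pytest.raises(ValueError):
        PrimerPair("B", "x", "ACGTN", "ACGT", 10)
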