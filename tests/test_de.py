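"""Differential expression: filtering, TMM, BH, and the NB LRT."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from mirhub.de import (
    CountMatrix,
    bh_adjust,
    filter_detectable,
    normalize_tmm,
    test_de as de_test,
)
from mirhub.simulate import SimulationConfig, simulate_counts


# ---------------------------------------------------------------------------
# detectability filter

def test_filter_removes_all_zero_rows(random_count_matrix):
    cm = random_count_matrix(seed=1)
    cm.counts.iloc[3] = 0
    out = filter_detectable(cm, min_total=1)
    assert cm.mirnas[3] not in out.mirnas
    assert len(out.mirnas) == len(cm.mirnas) - 1


def test_filter_zero_threshold_is_identity(random_count_matrix):
    cm = random_count_matrix(seed=2)
    out = filter_detectable(cm, min_total=0)
    assert out.mirnas == cm.mirnas


def test_filter_matches_brute_force_row_sums(random_count_matrix):
    cm = random_count_matrix(seed=3, n_mirnas=20, n_per_group=4)
    min_total = 900
    out = filter_detectable(cm, min_total=min_total)
    expected = [m for m in cm.mirnas if cm.counts.loc[m].sum() >= min_total]
    assert out.mirnas == expected


def test_filter_warns_when_everything_removed(random_count_matrix):
    cm = random_count_matrix(seed=4)
    with pytest.warns(UserWarning):
        out = filter_detectable(cm, min_total=10**9)
    assert out.mirnas == []


# ---------------------------------------------------------------------------
# TMM

def _tmm_oracle(cm: CountMatrix) -> np.ndarray:
    """Plain-loop reimplementation of doubly trimmed weighted TMM
    (30% M-trim, 5% A-trim, inverse-variance weights)."""
    y = cm.counts.to_numpy().astype(float)
    lib = y.sum(axis=0)
    uq = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = []
    for j in range(y.shape[1]):
        if j == ref:
            factors.append(1.0)
            continue
        ms, as_, vs = [], [], []
        for g in range(y.shape[0]):
            if y[g, j] > 0 and y[g, ref] > 0:
                o, r = y[g, j] / lib[j], y[g, ref] / lib[ref]
                ms.append(np.log2(o / r))
                as_.append(0.5 * np.log2(o * r))
                vs.append((lib[j] - y[g, j]) / (lib[j] * y[g, j]) + (lib[ref] - y[g, ref]) / (lib[ref] * y[g, ref]))
        ms, as_, vs = map(np.array, (ms, as_, vs))
        if ms.size == 0 or np.max(np.abs(ms)) < 1e-6:
            factors.append(1.0)
            continue
        n = ms.size
        lo_m, hi_m = int(np.floor(n * 0.3)) + 1, n - int(np.floor(n * 0.3))
        lo_a, hi_a = int(np.floor(n * 0.05)) + 1, n - int(np.floor(n * 0.05))
        rm, ra = rankdata(ms), rankdata(as_)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        w = 1.0 / vs[keep]
        factors.append(2.0 ** (np.sum(w * ms[keep]) / np.sum(w)))
    f = np.array(factors)
    return f / np.exp(np.mean(np.log(f)))


def test_tmm_identical_samples_give_unit_factors():
    df = pd.DataFrame({"a": [10, 20, 30, 5], "b": [10, 20, 30, 5]}, index=list("wxyz"))
    cm = CountMatrix(df, {"a": "control", "b": "treated"})
    assert np.allclose(normalize_tmm(cm), [1.0, 1.0])


def test_tmm_scale_invariance_on_doubled_sample():
    rng = np.random.default_rng(0)
    base = rng.integers(1, 200, size=50)
    df = pd.DataFrame({"a": base, "b": 2 * base}, index=[f"m{i}" for i in range(50)])
    cm = CountMatrix(df, {"a": "control", "b": "treated"})
    assert np.allclose(normalize_tmm(cm), [1.0, 1.0])


@pytest.mark.parametrize("seed", range(5))
def test_tmm_matches_independent_reference(seed, random_count_matrix):
    cm = random_count_matrix(seed=seed, n_mirnas=80, n_per_group=4)
    cm.counts += 1  # avoid empty overlap corner
    assert np.allclose(normalize_tmm(cm), _tmm_oracle(cm), atol=1e-10)


def test_tmm_zero_library_errors():
    df = pd.DataFrame({"a": [0, 0], "b": [1, 2]}, index=["m1", "m2"])
    cm = CountMatrix(df, {"a": "control", "b": "treated"})
    with pytest.raises(ValueError):
        normalize_tmm(cm)


# ---------------------------------------------------------------------------
# BH

def _bh_oracle(p):
    """Direct definition: adj_i = min(1, min over j >= rank(i) of m*p_(j)/j)."""
    m = len(p)
    sp = sorted(p)
    out = []
    for pi in p:
        rank_i = sp.index(pi) + 1
        out.append(min(min(m * sp[j] / (j + 1) for j in range(rank_i - 1, m)), 1.0))
    return out


def test_bh_single_value_unchanged():
    assert bh_adjust([0.123]) == [0.123]


def test_bh_hand_computed_step_up():
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])


@pytest.mark.parametrize("seed", range(8))
def test_bh_matches_brute_force_definition(seed):
    rng = np.random.default_rng(seed)
    p = list(np.round(rng.uniform(0, 1, size=rng.integers(1, 30)), 6))
    assert bh_adjust(p) == pytest.approx(_bh_oracle(p), abs=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=40))
def test_bh_bounds_and_monotonicity(p):
    adj = bh_adjust(p)
    assert all(a >= raw - 1e-12 for a, raw in zip(adj, p))
    assert all(0 <= a <= 1 for a in adj)
    order = np.argsort(p, kind="mergesort")
    sorted_adj = np.array(adj)[order]
    assert np.all(np.diff(sorted_adj) >= -1e-12)


# ---------------------------------------------------------------------------
# NB LRT

def test_identical_group_means_are_not_significant():
    rng = np.random.default_rng(1)
    base = rng.integers(50, 500, size=30)
    cols = {}
    for j in range(8):
        cols[f"s{j}"] = rng.poisson(base)
    df = pd.DataFrame(cols, index=[f"m{i}" for i in range(30)])
    groups = {f"s{j}": ("control" if j < 4 else "treated") for j in range(8)}
    results = de_test(CountMatrix(df, groups), dispersion=2.0)
    assert all(r.direction == "ns" for r in results)
    assert np.mean([r.p_value for r in results]) > 0.5


def test_de_needs_two_samples_per_group():
    df = pd.DataFrame({"a": [5, 5], "b": [5, 5], "c": [5, 5]}, index=["m1", "m2"])
    cm = CountMatrix(df, {"a": "control", "b": "treated", "c": "treated"})
    with pytest.raises(ValueError):
        de_test(cm)


def test_de_scale_handled_by_normalization_on_doubled_sample():
    """Doubling every count of one sample doubles its library size; the
    M-values against the reference are unchanged so the TMM factors are
    stable (to the small change in the inverse-variance weights), logFC
    barely moves, and the planted calls are unchanged."""
    cfg = SimulationConfig(rng_seed=9, n_mirnas=60, n_de_mirnas=3, dispersion=0.05)
    cm, truth = simulate_counts(cfg)
    base = {r.mirna: r for r in de_test(cm)}
    doubled = cm.counts.copy()
    doubled["ctrl_1"] = 2 * doubled["ctrl_1"]
    cm2 = CountMatrix(doubled, cm.groups)
    assert np.allclose(normalize_tmm(cm), normalize_tmm(cm2), atol=0.01)
    res2 = {r.mirna: r for r in de_test(cm2)}
    for name in base:
        assert res2[name].log_fc == pytest.approx(base[name].log_fc, abs=0.02)
    for name in truth.de_mirnas:
        assert res2[name].direction == base[name].direction


def test_planted_signs_and_logfc_recovered():
    """Planted |log2FC| = 2 at phi = 0.1, n = 6/group: every planted
    miRNA is called significant with the right sign, and the average
    logFC error is inside +/-0.3."""
    errors = []
    recovered = total = 0
    for seed in range(5):
        cfg = SimulationConfig(rng_seed=seed, n_mirnas=300, n_de_mirnas=10, dispersion=0.1)
        cm, truth = simulate_counts(cfg)
        results = {r.mirna: r for r in de_test(cm)}
        for name, lfc in truth.de_mirnas.items():
            r = results[name]
            total += 1
            if r.direction != "ns":
                recovered += 1
                assert r.direction == ("up" if lfc > 0 else "down"), (seed, name)
            errors.append(r.log_fc - lfc)
    assert recovered >= 0.95 * total  # power floor at the weakest abundances
    assert abs(np.mean(errors)) < 0.3


def test_null_type_one_error_near_nominal():
    fracs = []
    for seed in range(10):
        cfg = SimulationConfig(rng_seed=100 + seed, n_mirnas=200, n_de_mirnas=0)
        cm, _ = simulate_counts(cfg)
        p = np.array([r.p_value for r in de_test(cm)])
        fracs.append((p < 0.05).mean())
    assert 0.03 <= np.mean(fracs) <= 0.07


def test_result_invariants():
    cfg = SimulationConfig(rng_seed=12, n_mirnas=100, n_de_mirnas=5)
    cm, _ = simulate_counts(cfg)
    for r in de_test(cm, alpha=0.05):
        assert r.fdr >= r.p_value - 1e-12
        if r.direction == "up":
            assert r.fdr < 0.05 and r.log_fc > 0
        elif r.direction == "down":
            assert r.fdr < 0.05 and r.log_fc < 0
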