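"""Two-group differential expression of miRNA counts.

The model is the standard one for small-RNA count libraries: per miRNA,
counts are negative binomial with a sample-specific offset
``log(library size x TMM factor)`` and a group effect on the log scale.
A single common dispersion is estimated for the whole matrix by
maximising the Cox-Reid adjusted profile likelihood, each miRNA is then
tested with a likelihood-ratio test of the group coefficient against
chi-square(1), and p-values are Benjamini-Hochberg adjusted.

This is a deliberately transparent re-implementation of the classic
count-based DE workflow (TMM normalisation + NB GLM + LRT); it uses a
common dispersion rather than tagwise empirical-Bayes shrinkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, xlogy
from scipy.stats import chi2

CONTROL = "control"
TREATED = "treated"

__all__ = [
    "CountMatrix",
    "DEResult",
    "filter_detectable",
    "normalize_tmm",
    "test_de",
    "bh_adjust",
]


@dataclass
class CountMatrix:
    """Integer read counts for mature miRNAs across labelled samples.

    Parameters
    ----------
    counts
        DataFrame with miRNA ids as the index and sample ids as columns.
    groups
        Mapping from sample id to ``"control"`` or ``"treated"``.
    """

    counts: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.groups = dict(self.groups)
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate miRNA ids in count matrix")
        lowered = self.counts.index.str.lower()
        if lowered.has_duplicates:
            raise ValueError("miRNA ids duplicated after case normalization")
        missing = [s for s in self.counts.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        labels = {self.groups[s] for s in self.counts.columns}
        if not labels <= {CONTROL, TREATED}:
            raise ValueError(f"group labels must be {{control, treated}}, got {labels}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def mirnas(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([self.groups[s] == group for s in self.counts.columns])

    def library_sizes(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=0).astype(float)

    # --- I/O (TSV dialect: first column "mirna", then one column per sample)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "mirna"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, groups: Mapping[str, str]) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="mirna")
        return cls(df, groups)


@dataclass
class DEResult:
    """Per-miRNA differential expression call (treated vs control)."""

    mirna: str
    log_fc: float  # base-2 log fold change
    p_value: float
    fdr: float
    direction: str  # "up", "down" or "ns"
    flagged: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.direction not in {"up", "down", "ns"}:
            raise ValueError(f"bad direction {self.direction!r}")


def results_to_frame(results: Iterable[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"mirna": r.mirna, "logFC": r.log_fc, "p_value": r.p_value, "fdr": r.fdr, "direction": r.direction}
            for r in results
        ]
    )


def write_de_table(results: Iterable[DEResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def filter_detectable(counts: CountMatrix, min_total: int = 1) -> CountMatrix:
    """Keep miRNAs whose total count across all samples is >= ``min_total``.

    Row order is preserved.  Removing every row emits a warning rather
    than raising, so an over-aggressive threshold is visible but not fatal.
    """
    if min_total < 0:
        raise ValueError("min_total must be non-negative")
    totals = counts.counts.sum(axis=1)
    kept = counts.counts.loc[totals >= min_total]
    if kept.shape[0] == 0:
        warnings.warn("detectability filter removed every miRNA", UserWarning, stacklevel=2)
    return CountMatrix(kept, counts.groups)


# ---------------------------------------------------------------------------
# TMM normalization

def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    log_ratio_trim: float,
    abs_expr_trim: float,
) -> float:
    """Trimmed mean of M-values for one sample against the reference."""
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        return 1.0
    o = obs[ok] / lib_obs
    r = ref[ok] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # asymptotic (delta-method) variance of M; weights are its inverse
    v = (lib_obs - obs[ok]) / (lib_obs * obs[ok]) + (lib_ref - ref[ok]) / (lib_ref * ref[ok])
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = int(np.floor(n * log_ratio_trim)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * abs_expr_trim)) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or not np.isfinite(v[keep]).all():
        return 1.0
    w = 1.0 / v[keep]
    f = np.sum(w * m[keep]) / np.sum(w)
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def normalize_tmm(
    counts: CountMatrix,
    log_ratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, one per sample.

    Doubly trimmed weighted mean of per-miRNA log2 ratios against a
    reference sample (the sample whose counts-per-total upper quartile
    is closest to the across-sample mean), with inverse asymptotic
    variance weights.  Factors are rescaled so their geometric mean is
    1; multiplying library sizes by these factors gives effective
    library sizes.
    """
    y = counts.counts.to_numpy().astype(float)
    if y.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = y.sum(axis=0)
    if (lib == 0).any():
        bad = [s for s, l in zip(counts.samples, lib) if l == 0]
        raise ValueError(f"samples with zero library size: {bad}")
    uq = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array(
        [
            1.0
            if j == ref_idx
            else _tmm_pair_factor(y[:, j], y[:, ref_idx], lib[j], lib[ref_idx], log_ratio_trim, abs_expr_trim)
            for j in range(y.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# NB GLM with common dispersion + LRT

def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Row-wise NB log-likelihood (Poisson when phi == 0)."""
    if phi == 0.0:
        return (xlogy(y, mu) - mu - gammaln(y + 1.0)).sum(axis=-1)
    r = 1.0 / phi
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + xlogy(y, mu / (mu + r))
        + r * np.log(r / (r + mu))
    )
    # xlogy handles y=0, mu=0; the r*log term is finite for mu >= 0
    return ll.sum(axis=-1)


def _fit_means(y: np.ndarray, offset: np.ndarray, phi: float, n_iter: int = 50) -> np.ndarray:
    """MLE fitted means for a one-parameter (intercept-only) NB model.

    ``y`` is genes x samples, ``offset`` the per-sample log exposure.
    Returns the fitted mean matrix ``exp(beta_g + offset_j)``.  The score
    equation sum_j (y - mu)/(1 + phi mu) = 0 is solved per gene by
    damped Newton steps, started from the closed-form Poisson solution.
    """
    e = np.exp(offset)[None, :]
    tot = y.sum(axis=1)
    zero = tot == 0
    with np.errstate(divide="ignore"):
        beta = np.log(tot / e.sum())  # Poisson MLE; exact when phi == 0
    if phi == 0.0 or not np.any(~zero):
        mu = np.exp(beta)[:, None] * e
        mu[zero] = 0.0
        return mu
    beta = np.where(zero, -np.inf, beta)
    active = ~zero
    b = beta[active]
    ya = y[active]
    for _ in range(n_iter):
        mu = np.exp(b)[:, None] * e
        denom = 1.0 + phi * mu
        score = ((ya - mu) / denom).sum(axis=1)
        info = (mu * (1.0 + phi * ya) / denom**2).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-10:
            break
    beta[active] = b
    mu = np.exp(beta)[:, None] * e
    mu[zero] = 0.0
    return mu


def _profile_loglik(y: np.ndarray, offset: np.ndarray, masks: Sequence[np.ndarray], phi: float, adjusted: bool = True) -> float:
    """Sum over genes of the (Cox-Reid adjusted) profile log-likelihood
    of the cell-means model at dispersion ``phi``."""
    total = 0.0
    mu = np.zeros_like(y, dtype=float)
    for mask in masks:
        mu[:, mask] = _fit_means(y[:, mask], offset[mask], phi)
    total = _nb_loglik(y, mu, phi).sum()
    if adjusted:
        # cell-means coding -> X'WX is diagonal with per-group sums of
        # the working weights mu/(1+phi mu)
        for mask in masks:
            w = mu[:, mask] / (1.0 + phi * mu[:, mask])
            sw = w.sum(axis=1)
            pos = sw > 0
            total -= 0.5 * np.log(sw[pos]).sum()
    return float(total)


def estimate_common_dispersion(
    y: np.ndarray,
    offset: np.ndarray,
    masks: Sequence[np.ndarray],
    grid: np.ndarray | None = None,
) -> float:
    """Common NB dispersion maximising the Cox-Reid adjusted profile
    likelihood, by grid search followed by bounded refinement."""
    if grid is None:
        grid = np.concatenate([[0.0], np.logspace(-4, 1, 21)])
    vals = np.array([_profile_loglik(y, offset, masks, float(p)) for p in grid])
    i = int(np.argmax(vals))
    if i == 0:
        lo, hi = 0.0, float(grid[1])
    else:
        lo = float(grid[max(i - 1, 0)])
        hi = float(grid[min(i + 1, len(grid) - 1)])
    if hi <= lo:
        return float(grid[i])
    res = minimize_scalar(
        lambda p: -_profile_loglik(y, offset, masks, float(p)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    best = float(res.x)
    if -res.fun < vals[i]:
        best = float(grid[i])
    return best


def test_de(
    counts: CountMatrix,
    alpha: float = 0.05,
    tmm_factors: np.ndarray | None = None,
    dispersion: float | None = None,
    pseudo_cpm: float = 0.5,
) -> list[DEResult]:
    """Per-miRNA NB likelihood-ratio test of the group effect.

    The full model has one mean per group; the null model a single mean,
    both with offset ``log(library size x TMM factor)``.  Twice the
    log-likelihood difference is referred to chi-square(1).  logFC is
    ``log2((cpm_treated + pseudo)/(cpm_control + pseudo))`` on
    group-mean CPM.  Benjamini-Hochberg adjustment is applied over all
    tested miRNAs and the direction is called at ``fdr < alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    ctrl = counts.group_mask(CONTROL)
    trt = counts.group_mask(TREATED)
    if ctrl.sum() < 2 or trt.sum() < 2:
        raise ValueError("need at least two samples per group")
    y = counts.counts.to_numpy().astype(float)
    lib = counts.library_sizes()
    if tmm_factors is None:
        tmm_factors = normalize_tmm(counts)
    eff_lib = lib * tmm_factors
    offset = np.log(eff_lib)

    if dispersion is None:
        dispersion = estimate_common_dispersion(y, offset, [ctrl, trt])
    phi = float(dispersion)

    mu_full = np.zeros_like(y)
    mu_full[:, ctrl] = _fit_means(y[:, ctrl], offset[ctrl], phi)
    mu_full[:, trt] = _fit_means(y[:, trt], offset[trt], phi)
    mu_null = _fit_means(y, offset, phi)
    ll_full = _nb_loglik(y, mu_full, phi)
    ll_null = _nb_loglik(y, mu_null, phi)
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = chi2.sf(lrt, df=1)

    cpm = y / eff_lib[None, :] * 1e6
    mean_c = cpm[:, ctrl].mean(axis=1)
    mean_t = cpm[:, trt].mean(axis=1)
    log_fc = np.log2((mean_t + pseudo_cpm) / (mean_c + pseudo_cpm))

    bad = ~(np.isfinite(p) & np.isfinite(log_fc))
    p = np.where(bad, 1.0, p)
    log_fc = np.where(bad, 0.0, log_fc)
    fdr = np.asarray(bh_adjust(list(p)))

    results = []
    for i, name in enumerate(counts.mirnas):
        if fdr[i] < alpha and log_fc[i] > 0:
            direction = "up"
        elif fdr[i] < alpha and log_fc[i] < 0:
            direction = "down"
        else:
            direction = "ns"
        results.append(
            DEResult(
                mirna=name,
                log_fc=float(log_fc[i]),
                p_value=float(p[i]),
                fdr=float(fdr[i]),
                direction=direction,
                flagged=bool(bad[i]),
            )
        )
    return results


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return [float(v) for v in out]
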