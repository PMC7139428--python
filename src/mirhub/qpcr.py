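"""qRT-PCR relative quantification (2^-ddCp) and in-silico amplicons.

Quantification follows the classic comparative-Cp chain: duplicate
wells are averaged on the Cp scale, each sample's target Cp is
referenced to the housekeeping gene (dCp), dCp is calibrated to the
control-group mean (ddCp), and expression is reported as 2^-ddCp in
arbitrary units, so the control group averages 1 by construction.
Group differences are tested with an unpaired Student's t-test
(equal-variance by default, Welch optional) and summarised as
mean +/- SEM.

Amplicon verification is exact-string in-silico PCR: the forward primer
and the reverse complement of the reverse primer are located on the
spliced transcript sense strand and the product size is the 1-based
inclusive span from the start of the forward site to the end of the
reverse site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

CP_COLUMNS = ["sample", "group", "gene", "replicate", "cp"]

__all__ = [
    "PrimerPair",
    "RelativeExpressionResult",
    "ddcp",
    "verify_amplicon",
    "read_cp_table",
    "read_primers",
    "write_qpcr_results",
]


@dataclass(frozen=True)
class PrimerPair:
    gene: str
    accession: str
    forward: str  # 5'->3'
    reverse: str  # 5'->3'
    expected_size: int

    def __post_init__(self) -> None:
        for seq in (self.forward, self.reverse):
            if not seq or set(seq.upper()) - set("ACGT"):
                raise ValueError(f"primer must be non-empty over ACGT: {seq!r}")


@dataclass
class RelativeExpressionResult:
    gene: str
    expression: dict[str, float]  # sample -> 2^-ddCp (arbitrary units)
    control_mean: float
    treated_mean: float
    sem_control: float
    sem_treated: float
    t_statistic: float | None
    p_value: float | None
    significant: bool


def read_cp_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Cp table missing columns {missing}")
    return df


def read_primers(path: str | Path) -> list[PrimerPair]:
    df = pd.read_csv(path, sep="\t")
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


def _sem(x: np.ndarray) -> float:
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def ddcp(
    cp: pd.DataFrame,
    reference_gene: str,
    target_gene: str,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> RelativeExpressionResult:
    """Relative expression of ``target_gene`` by the 2^-ddCp method.

    ``cp`` has columns sample, group, gene, replicate, cp.  Samples
    missing the reference gene are dropped with a warning.  With fewer
    than two samples in either group, or zero variance in both groups,
    no test is performed (zero variance with equal means reports p = 1).
    """
    if (cp["cp"] <= 0).any():
        raise ValueError("Cp values must be positive cycles")
    means = cp.groupby(["sample", "gene"])["cp"].mean()
    groups = cp.drop_duplicates("sample").set_index("sample")["group"]

    samples = []
    for s in groups.index:
        if (s, reference_gene) not in means.index:
            warnings.warn(f"sample {s!r} lacks reference gene {reference_gene!r}; excluded", UserWarning, stacklevel=2)
            continue
        if (s, target_gene) not in means.index:
            continue
        samples.append(s)
    if not samples:
        raise ValueError(f"no sample measures both {target_gene!r} and {reference_gene!r}")

    dcp = pd.Series(
        {s: means[(s, target_gene)] - means[(s, reference_gene)] for s in samples}
    )
    ctrl = [s for s in samples if groups[s] == "control"]
    trt = [s for s in samples if groups[s] == "treated"]
    if not ctrl:
        raise ValueError("no control samples: ddCp needs a control calibrator")
    ddcp_vals = dcp - dcp[ctrl].mean()
    expr = np.power(2.0, -ddcp_vals)

    xc = expr[ctrl].to_numpy(dtype=float)
    xt = expr[trt].to_numpy(dtype=float) if trt else np.array([])

    t_stat: float | None = None
    p: float | None = None
    if len(xc) >= 2 and len(xt) >= 2:
        if np.var(xc) == 0 and np.var(xt) == 0:
            warnings.warn("zero variance in both groups; no t-test performed", UserWarning, stacklevel=2)
            if np.isclose(xc.mean(), xt.mean()):
                t_stat, p = 0.0, 1.0
        else:
            res = stats.ttest_ind(xt, xc, equal_var=equal_var)
            t_stat, p = float(res.statistic), float(res.pvalue)
    else:
        warnings.warn("fewer than two samples in a group; no t-test performed", UserWarning, stacklevel=2)

    return RelativeExpressionResult(
        gene=target_gene,
        expression={s: float(expr[s]) for s in samples},
        control_mean=float(xc.mean()),
        treated_mean=float(xt.mean()) if xt.size else float("nan"),
        sem_control=_sem(xc),
        sem_treated=_sem(xt),
        t_statistic=t_stat,
        p_value=p,
        significant=bool(p is not None and p < alpha),
    )


def verify_amplicon(primers: PrimerPair, transcript: str) -> int:
    """Exact-match in-silico PCR product size on a spliced transcript.

    Locates the forward primer and the reverse complement of the reverse
    primer on the sense strand; the product spans from the forward
    site's first base to the reverse site's last base (1-based
    inclusive).  Multiple possible products report the smallest with a
    warning; no valid orientation raises.
    """
    seq = str(transcript).upper().replace("U", "T")
    fwd = primers.forward.upper()
    rev_site = str(Seq(primers.reverse.upper()).reverse_complement())

    def find_all(hay: str, needle: str) -> list[int]:
        out, i = [], hay.find(needle)
        while i != -1:
            out.append(i)
            i = hay.find(needle, i + 1)
        return out

    fwd_starts = find_all(seq, fwd)
    rev_starts = find_all(seq, rev_site)
    if not fwd_starts or not rev_starts:
        raise ValueError(f"no amplicon: primer site(s) absent for {primers.gene}")

    sizes = []
    for f0 in fwd_starts:
        for r0 in rev_starts:
            end = r0 + len(rev_site) - 1
            if r0 >= f0 and end >= f0 + len(fwd) - 1:
                sizes.append(end - f0 + 1)
    if not sizes:
        raise ValueError(f"no amplicon: reverse site upstream of forward site for {primers.gene}")
    if len(sizes) > 1:
        warnings.warn(f"{len(sizes)} candidate products for {primers.gene}; reporting smallest", UserWarning, stacklevel=2)
    return min(sizes)


def write_qpcr_results(results: Iterable[RelativeExpressionResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene": r.gene,
                "control_mean": r.control_mean,
                "treated_mean": r.treated_mean,
                "sem_control": r.sem_control,
                "sem_treated": r.sem_treated,
                "t": "" if r.t_statistic is None else r.t_statistic,
                "p": "" if r.p_value is None else r.p_value,
                "significant": r.significant,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)
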