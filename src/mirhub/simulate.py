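"""Synthetic inputs with planted ground truth.

Every input the pipeline consumes can be generated here: a two-group
negative-binomial miRNA count matrix with planted differentially
expressed miRNAs, three target-interaction tables with plantable hub
structure, a GO annotation with enriched gene blocks, and a qPCR Cp
table with planted fold changes.  The planted truth is returned as a
:class:`GroundTruth` object so recovery can be asserted end to end.

All generators are deterministic functions of ``rng_seed``; each draws
from its own stream derived from the seed so the generators can be run
independently or together with identical results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mirhub.de import CountMatrix
from mirhub.targets import normalize_mirna_name

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_counts",
    "simulate_target_databases",
    "simulate_go_annotation",
    "simulate_qpcr",
    "default_study_config",
    "write_cp_table",
]

_EVIDENCE_TAGS = ("luciferase", "western_blot", "qRT-PCR")

# sub-stream indices derived from rng_seed, one per generator
_STREAM_SIGNS = 0
_STREAM_COUNTS = 1
_STREAM_TARGETS = 2
_STREAM_QPCR = 3
_STREAM_GO = 4


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror a small-animal two-group cardiac small-RNA study:
    6 sequenced samples per group, a few hundred detectable mature
    miRNAs of which a handful are differentially expressed with
    |log2FC| around 2, NB dispersion 0.1, and library sizes of one to
    two million mapped reads.
    """

    n_samples_per_group: int = 6
    n_mirnas: int = 500
    n_de_mirnas: int = 5
    de_log2fc_magnitude: float = 2.0
    dispersion: float = 0.1
    mean_log_expression_range: tuple[float, float] = (0.0, 12.0)
    library_size_range: tuple[int, int] = (1_000_000, 2_000_000)
    n_genes: int = 2000
    planted_hub_spec: list[tuple[str, frozenset]] = field(default_factory=list)
    go_term_blocks: list[tuple[str, frozenset]] = field(default_factory=list)
    qpcr_effects: dict[str, float] = field(default_factory=dict)
    rng_seed: int = 0
    # fixed DE signs (+1/-1 per planted miRNA); drawn from the seed when None
    de_signs: tuple[int, ...] | None = None
    reference_gene: str = "HPRT"
    qpcr_noise_sd: float = 0.1
    qpcr_samples_per_group: int = 7
    n_decoy_edges: int = 200
    n_background_terms: int = 30

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 1 or self.n_mirnas < 1 or self.n_genes < 1:
            raise ValueError("sizes must be positive")
        if not 0 <= self.n_de_mirnas <= self.n_mirnas:
            raise ValueError("n_de_mirnas must be between 0 and n_mirnas")
        if self.de_log2fc_magnitude < 0:
            raise ValueError("de_log2fc_magnitude must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        lo, hi = self.mean_log_expression_range
        if not lo < hi:
            raise ValueError("mean_log_expression_range must be non-degenerate")
        llo, lhi = self.library_size_range
        if not (0 < llo < lhi):
            raise ValueError("library_size_range must be positive and non-degenerate")
        if self.de_signs is not None:
            if len(self.de_signs) != self.n_de_mirnas or set(self.de_signs) - {-1, 1}:
                raise ValueError("de_signs must give +1/-1 for each planted DE miRNA")
        de = set(self.de_mirna_names())
        genes = set(self.gene_names())
        for gene, regulators in self.planted_hub_spec:
            if gene not in genes:
                raise ValueError(f"hub gene {gene!r} outside gene universe")
            regs = {normalize_mirna_name(m) for m in regulators}
            if not regs <= de:
                raise ValueError(f"hub {gene!r} cites non-DE regulators {regs - de}")
        for term, block in self.go_term_blocks:
            if not set(block) <= genes:
                raise ValueError(f"GO block {term!r} cites genes outside the universe")

    # deterministic name universes -------------------------------------

    def mirna_names(self) -> list[str]:
        return [
            f"rno-miR-{100 + i}-{'5p' if i % 2 else '3p'}"
            for i in range(self.n_mirnas)
        ]

    def de_mirna_names(self) -> list[str]:
        return self.mirna_names()[: self.n_de_mirnas]

    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    def resolved_de_signs(self) -> np.ndarray:
        if self.de_signs is not None:
            return np.array(self.de_signs, dtype=int)
        rng = np.random.default_rng([self.rng_seed, _STREAM_SIGNS])
        return rng.choice([1, -1], size=self.n_de_mirnas)


@dataclass
class GroundTruth:
    """What was planted, in the terms the downstream stages recover."""

    de_mirnas: dict[str, float]  # miRNA -> signed log2FC (0 under a pure null)
    hub_genes: dict[str, dict]  # gene -> {"degree": int, "strength": int}
    enriched_terms: set[str]
    qpcr_fold_changes: dict[str, float]

    def __post_init__(self) -> None:
        for gene, spec in self.hub_genes.items():
            if abs(spec["strength"]) > spec["degree"]:
                raise ValueError(f"hub {gene!r}: |strength| exceeds degree")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_mirnas": self.de_mirnas,
            "hub_genes": self.hub_genes,
            "enriched_terms": sorted(self.enriched_terms),
            "qpcr_fold_changes": self.qpcr_fold_changes,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            de_mirnas=d["de_mirnas"],
            hub_genes=d["hub_genes"],
            enriched_terms=set(d["enriched_terms"]),
            qpcr_fold_changes=d["qpcr_fold_changes"],
        )


def _ground_truth(config: SimulationConfig) -> GroundTruth:
    signs = config.resolved_de_signs()
    de_names = config.de_mirna_names()
    lfc = {
        name: float(s * config.de_log2fc_magnitude)
        for name, s in zip(de_names, signs)
    }
    sign_of = {name: int(s) for name, s in zip(de_names, signs)}
    hubs = {}
    for gene, regulators in config.planted_hub_spec:
        regs = sorted(normalize_mirna_name(m) for m in regulators)
        hubs[gene] = {
            "degree": len(regs),
            "strength": int(sum(sign_of[m] for m in regs)),
            "regulators": regs,
        }
    return GroundTruth(
        de_mirnas=lfc,
        hub_genes=hubs,
        enriched_terms={t for t, _ in config.go_term_blocks},
        qpcr_fold_changes=dict(config.qpcr_effects),
    )


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw the two-group NB count matrix with planted DE miRNAs.

    Per-miRNA baseline log2 abundances are uniform over
    ``mean_log_expression_range``; planted miRNAs have their treated
    abundance shifted by the signed log2FC.  Counts are
    NB(mean = library size x relative abundance, dispersion phi);
    phi = 0 degenerates to Poisson.
    """
    rng = np.random.default_rng([config.rng_seed, _STREAM_COUNTS])
    truth = _ground_truth(config)
    n = config.n_samples_per_group
    names = config.mirna_names()

    base = rng.uniform(*config.mean_log_expression_range, size=config.n_mirnas)
    shift = np.zeros(config.n_mirnas)
    for i, name in enumerate(config.de_mirna_names()):
        shift[i] = truth.de_mirnas[name]

    w_ctrl = np.power(2.0, base)
    w_trt = np.power(2.0, base + shift)
    p_ctrl = w_ctrl / w_ctrl.sum()
    p_trt = w_trt / w_trt.sum()

    libs = rng.integers(*config.library_size_range, size=2 * n)
    props = np.column_stack([p_ctrl] * n + [p_trt] * n)
    mu = props * libs[None, :]

    phi = config.dispersion
    if phi == 0.0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mu))

    samples = [f"ctrl_{j+1}" for j in range(n)] + [f"trt_{j+1}" for j in range(n)]
    groups = {s: ("control" if s.startswith("ctrl") else "treated") for s in samples}
    df = pd.DataFrame(counts, index=names, columns=samples)
    df.index.name = "mirna"
    return CountMatrix(df, groups), truth


def _maybe_shout(name: str, rng: np.random.Generator) -> str:
    """Occasionally emit an upper-cased name so downstream
    name-normalisation paths are exercised."""
    return name.upper() if rng.random() < 0.2 else name


def simulate_target_databases(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit the three interaction tables with plantable hub structure.

    Each planted hub edge lands in exactly one table with a score that
    passes that table's cutoff; decoy edges carry failing scores (or,
    for the curated table, involve non-DE miRNAs only), so integrating
    at the default cutoffs recovers the planted edge set exactly.
    """
    rng = np.random.default_rng([config.rng_seed, _STREAM_TARGETS])
    truth = _ground_truth(config)
    planted_pairs = {
        (m, gene)
        for gene, spec in truth.hub_genes.items()
        for m in spec["regulators"]
    }

    rows_a, rows_b, rows_c = [], [], []
    for mirna, gene in sorted(planted_pairs):
        table = rng.integers(0, 3)
        name = _maybe_shout(mirna, rng)
        if table == 0:
            rows_a.append({"mirna": name, "gene": gene, "score": round(rng.uniform(80.5, 99.9), 2), "source": "predicted_score_a"})
        elif table == 1:
            rows_b.append({"mirna": name, "gene": gene, "score": round(rng.uniform(-3.0, -1.3), 3), "source": "predicted_score_b"})
        else:
            rows_c.append({"mirna": name, "gene": gene, "evidence": _EVIDENCE_TAGS[rng.integers(0, len(_EVIDENCE_TAGS))], "source": "curated"})

    all_mirnas = config.mirna_names()
    non_de = all_mirnas[config.n_de_mirnas:]
    genes = config.gene_names()
    made = 0
    while made < config.n_decoy_edges:
        mirna = all_mirnas[rng.integers(0, len(all_mirnas))]
        gene = genes[rng.integers(0, len(genes))]
        if (mirna, gene) in planted_pairs:
            continue
        table = rng.integers(0, 3)
        name = _maybe_shout(mirna, rng)
        if table == 0:
            rows_a.append({"mirna": name, "gene": gene, "score": round(rng.uniform(0.0, 80.0), 2), "source": "predicted_score_a"})
        elif table == 1:
            rows_b.append({"mirna": name, "gene": gene, "score": round(rng.uniform(-1.2, 0.0), 3), "source": "predicted_score_b"})
        else:
            if not non_de:
                continue
            name = _maybe_shout(non_de[rng.integers(0, len(non_de))], rng)
            rows_c.append({"mirna": name, "gene": gene, "evidence": _EVIDENCE_TAGS[rng.integers(0, len(_EVIDENCE_TAGS))], "source": "curated"})
        made += 1

    def frame(rows, cols):
        df = pd.DataFrame(rows, columns=cols)
        if len(df):
            df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
        return df

    return (
        frame(rows_a, ["mirna", "gene", "score", "source"]),
        frame(rows_b, ["mirna", "gene", "score", "source"]),
        frame(rows_c, ["mirna", "gene", "evidence", "source"]),
    )


def simulate_go_annotation(config: SimulationConfig) -> dict[str, tuple[str, frozenset]]:
    """GO-style annotation: the configured enriched blocks, random
    background terms, and a root term annotating the whole universe
    (so every gene is covered and the universe is well defined)."""
    rng = np.random.default_rng([config.rng_seed, _STREAM_GO])
    genes = config.gene_names()
    annotation: dict[str, tuple[str, frozenset]] = {}
    for term, block in config.go_term_blocks:
        annotation[term] = (f"planted block {term}", frozenset(g.upper() for g in block))
    for i in range(config.n_background_terms):
        size = int(rng.integers(10, 40))
        members = rng.choice(len(genes), size=size, replace=False)
        annotation[f"GO:BG{i:04d}"] = (
            f"background process {i}",
            frozenset(genes[j].upper() for j in members),
        )
    annotation["GO:0008150"] = ("biological_process (root)", frozenset(g.upper() for g in genes))
    return annotation


def simulate_qpcr(config: SimulationConfig) -> pd.DataFrame:
    """Cp table with planted fold changes.

    Cp = per-gene baseline + per-sample offset - log2(fold) in the
    treated group + Gaussian well noise, in duplicate wells.  The
    per-sample offset models RNA input amount and cancels exactly in
    the dCp against the reference gene.
    """
    rng = np.random.default_rng([config.rng_seed, _STREAM_QPCR])
    genes = [config.reference_gene] + sorted(config.qpcr_effects)
    effects = {config.reference_gene: 1.0, **config.qpcr_effects}
    baselines = {g: rng.uniform(18.0, 26.0) for g in genes}
    n = config.qpcr_samples_per_group
    samples = [(f"c{j+1}", "control") for j in range(n)] + [(f"p{j+1}", "treated") for j in range(n)]
    offsets = {s: rng.normal(0.0, 0.3) for s, _ in samples}

    rows = []
    for s, group in samples:
        for g in genes:
            shift = np.log2(effects[g]) if group == "treated" else 0.0
            for rep in (1, 2):
                noise = rng.normal(0.0, 1.0) * config.qpcr_noise_sd
                rows.append(
                    {
                        "sample": s,
                        "group": group,
                        "gene": g,
                        "replicate": rep,
                        "cp": baselines[g] + offsets[s] - shift + noise,
                    }
                )
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "cp"])


def write_cp_table(cp: pd.DataFrame, path: str | Path) -> None:
    cp.to_csv(path, sep="\t", index=False)


def default_study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A cohort shaped like the motivating cardiac study.

    Five planted DE miRNAs (two up, three down), eleven 3-regulator
    target hubs of which nine have node strength +1 and two have -1,
    GO blocks that place exactly three positive hubs on the
    highest-fold term, and qPCR effects in which three of the five
    selected targets are genuinely repressed.
    """
    base = SimulationConfig(rng_seed=seed)
    de = base.de_mirna_names()  # 5 names
    up1, dn1, up2, dn2, dn3 = de
    signs = (1, -1, 1, -1, -1)

    pos_regs = frozenset({up1, up2, dn1})   # +1 +1 -1 = +1
    neg_regs = frozenset({up1, dn1, dn2})   # +1 -1 -1 = -1
    hubs = [(f"G{i:04d}", pos_regs) for i in range(1, 10)]
    hubs += [("G0010", neg_regs), ("G0011", neg_regs)]

    blocks = [
        ("GO:1000001", frozenset({"G0001", "G0002", "G0003", "G1001", "G1002"})),
        ("GO:1000002", frozenset({f"G{i:04d}" for i in range(4, 10)} | {f"G{j:04d}" for j in range(1100, 1140)})),
        ("GO:1000003", frozenset({"G0010", "G0011"} | {f"G{j:04d}" for j in range(1200, 1220)})),
    ]

    effects = {"G0001": 0.55, "G0002": 0.6, "G0003": 0.5, "G0010": 0.8, "G0011": 1.0}

    params = dict(
        rng_seed=seed,
        de_signs=signs,
        planted_hub_spec=hubs,
        go_term_blocks=blocks,
        qpcr_effects=effects,
    )
    params.update(overrides)
    return SimulationConfig(**params)
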