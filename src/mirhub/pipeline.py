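"""End-to-end orchestration of the analysis stages.

The stage order mirrors the study design: differential expression of
the miRNA counts, target integration at the source cutoffs, signed
network construction with hub detection, GO over-representation of the
predicted target set, the strength/enrichment selection rule, and qPCR
validation statistics for the selected genes.  Every run writes a
manifest recording input checksums, parameters and the package version
so a result bundle is reproducible from its directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

import mirhub
from mirhub import de as de_mod
from mirhub import enrichment as enr_mod
from mirhub import network as net_mod
from mirhub import prioritize as sel_mod
from mirhub import qpcr as qpcr_mod
from mirhub import targets as tgt_mod
from mirhub.de import CountMatrix

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_all", "read_groups"]

# machine-readable error codes
CONFIG_ERROR = "config_error"
INPUT_ERROR = "input_error"
COMPUTATION_ERROR = "computation_error"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    counts: str
    groups: str
    predicted_a: str
    predicted_b: str
    curated: str
    annotation: str
    cp_table: str | None = None
    primers: str | None = None
    transcripts: str | None = None
    reference_gene: str = "HPRT"
    alpha: float = 0.05
    min_total: int = 1
    score_cutoff: float = 80.0
    mirsvr_cutoff: float = -1.2
    hub_policy: str = "max_degree"
    hub_k: int | None = None
    n_positive: int = 3
    correction: str = "BH"
    rng_seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise PipelineError("config", CONFIG_ERROR, f"alpha must be in (0,1), got {self.alpha}")
        for cut in (self.score_cutoff, self.mirsvr_cutoff):
            if not float("-inf") < cut < float("inf"):
                raise PipelineError("config", CONFIG_ERROR, "cutoffs must be finite")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            payload = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise PipelineError("config", CONFIG_ERROR, str(exc)) from exc
        try:
            return cls(**payload)
        except TypeError as exc:
            raise PipelineError("config", CONFIG_ERROR, str(exc)) from exc


def read_groups(path: str | Path) -> dict[str, str]:
    """Sample-to-group TSV (columns: sample, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "group"} <= set(df.columns):
        raise ValueError("groups file needs 'sample' and 'group' columns")
    return dict(zip(df["sample"], df["group"]))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage(name: str, code: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except FileNotFoundError as exc:
        raise PipelineError(name, INPUT_ERROR, str(exc)) from exc
    except Exception as exc:
        raise PipelineError(name, code, str(exc)) from exc


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle under ``config.outdir``.

    Returns a summary dict (the funnel counts and output paths).
    Any stage failure raises :class:`PipelineError` carrying the stage
    name and a machine-readable code.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"funnel": {}, "outputs": {}}

    # --- differential expression
    groups = _stage("de", INPUT_ERROR, read_groups, config.groups)
    counts = _stage("de", INPUT_ERROR, CountMatrix.from_tsv, config.counts, groups)
    summary["funnel"]["mirnas_input"] = len(counts.mirnas)
    filtered = _stage("de", COMPUTATION_ERROR, de_mod.filter_detectable, counts, config.min_total)
    summary["funnel"]["mirnas_detectable"] = len(filtered.mirnas)
    logger.info("detectability filter: %d -> %d miRNAs", len(counts.mirnas), len(filtered.mirnas))
    de_results = _stage("de", COMPUTATION_ERROR, de_mod.test_de, filtered, config.alpha)
    n_sig = sum(r.direction != "ns" for r in de_results)
    summary["funnel"]["mirnas_significant"] = n_sig
    logger.info("differential expression: %d significant of %d", n_sig, len(de_results))
    de_path = out / "de_table.tsv"
    de_mod.write_de_table(de_results, de_path)
    summary["outputs"]["de_table"] = str(de_path)

    # --- target integration
    tables = [
        _stage("integrate", INPUT_ERROR, tgt_mod.read_interaction_table, p, s)
        for p, s in (
            (config.predicted_a, tgt_mod.PREDICTED_SCORE_A),
            (config.predicted_b, tgt_mod.PREDICTED_SCORE_B),
            (config.curated, tgt_mod.CURATED),
        )
    ]
    interactions = _stage(
        "integrate",
        COMPUTATION_ERROR,
        tgt_mod.integrate,
        *tables,
        de_results,
        score_cutoff=config.score_cutoff,
        mirsvr_cutoff=config.mirsvr_cutoff,
    )
    summary["funnel"]["interactions"] = len(interactions)
    summary["funnel"]["target_genes"] = len({r.gene for r in interactions})
    logger.info("integration: %d interactions over %d genes", len(interactions), summary["funnel"]["target_genes"])
    int_path = out / "interactions.tsv"
    tgt_mod.write_interactions(interactions, int_path)
    summary["outputs"]["interactions"] = str(int_path)

    # --- signed network + hubs
    net = _stage("network", COMPUTATION_ERROR, net_mod.build_network, interactions, de_results)
    hubs = _stage("network", COMPUTATION_ERROR, net_mod.find_hubs, net, config.hub_policy, config.hub_k)
    summary["funnel"]["hubs"] = len(hubs.hubs)
    summary["funnel"]["max_degree"] = hubs.max_degree
    logger.info("network: %d edges, max degree %d, %d hubs", net.n_edges, hubs.max_degree, len(hubs.hubs))
    net.to_sif(out / "network.sif")
    net.to_graphml(out / "network.graphml")
    net.write_gene_table(out / "gene_strengths.tsv")
    hub_df = pd.DataFrame(hubs.hubs, columns=["gene", "degree", "strength"])
    hub_df.to_csv(out / "hubs.tsv", sep="\t", index=False)
    summary["outputs"].update(
        {
            "network_sif": str(out / "network.sif"),
            "network_graphml": str(out / "network.graphml"),
            "gene_strengths": str(out / "gene_strengths.tsv"),
            "hubs": str(out / "hubs.tsv"),
        }
    )

    # --- GO enrichment on the full predicted target set
    annotation = _stage("enrich", INPUT_ERROR, enr_mod.read_gmt, config.annotation)
    targets = sorted({r.gene for r in interactions})
    enrichment = _stage("enrich", COMPUTATION_ERROR, enr_mod.enrich, targets, annotation, None, config.correction)
    summary["funnel"]["terms_tested"] = len(enrichment)
    enr_path = out / "enrichment.tsv"
    enr_mod.write_enrichment(enrichment, enr_path)
    summary["outputs"]["enrichment"] = str(enr_path)

    # --- candidate selection
    report = _stage(
        "select",
        COMPUTATION_ERROR,
        sel_mod.select_candidates,
        hubs,
        net,
        enrichment,
        config.n_positive,
        config.alpha,
    )
    summary["funnel"]["selected"] = len(report.selected)
    logger.info("selection: %d candidates (%s)", len(report.selected), ", ".join(report.selected))
    sel_path = out / "selection.json"
    sel_path.write_text(
        json.dumps(
            {
                "hubs_considered": report.hubs_considered,
                "selected_negative": report.selected_negative,
                "selected_positive": report.selected_positive,
                "selected": report.selected,
                "rationale": report.rationale,
            },
            indent=2,
        )
    )
    directions = {r.mirna: r.direction for r in de_results if r.direction != "ns"}
    mark_rows = []
    for gene in report.selected:
        row = {"gene": gene, "strength": net.strength(gene)}
        for m in sorted(directions):
            row[m] = int(net.graph.has_edge(tgt_mod.normalize_mirna_name(m), gene))
        mark_rows.append(row)
    pd.DataFrame(mark_rows).to_csv(out / "selection_marks.tsv", sep="\t", index=False)
    summary["outputs"]["selection"] = str(sel_path)
    summary["outputs"]["selection_marks"] = str(out / "selection_marks.tsv")

    # --- qPCR validation
    if config.cp_table:
        cp = _stage("qpcr", INPUT_ERROR, qpcr_mod.read_cp_table, config.cp_table)
        measured = set(cp["gene"])
        qpcr_results = [
            _stage("qpcr", COMPUTATION_ERROR, qpcr_mod.ddcp, cp, config.reference_gene, gene, config.alpha)
            for gene in report.selected
            if gene in measured
        ]
        q_path = out / "qpcr_results.tsv"
        qpcr_mod.write_qpcr_results(qpcr_results, q_path)
        summary["funnel"]["validated"] = sum(r.significant for r in qpcr_results)
        summary["outputs"]["qpcr_results"] = str(q_path)

    # --- in-silico amplicons
    if config.primers and config.transcripts:
        from Bio import SeqIO

        primers = _stage("qpcr", INPUT_ERROR, qpcr_mod.read_primers, config.primers)
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(config.transcripts, "fasta")}
        amp_rows = []
        for p in primers:
            if p.accession not in seqs:
                continue
            size = _stage("qpcr", COMPUTATION_ERROR, qpcr_mod.verify_amplicon, p, seqs[p.accession])
            amp_rows.append({"gene": p.gene, "accession": p.accession, "product_size": size, "expected": p.expected_size})
        pd.DataFrame(amp_rows).to_csv(out / "amplicons.tsv", sep="\t", index=False)
        summary["outputs"]["amplicons"] = str(out / "amplicons.tsv")

    # --- manifest
    inputs = {
        k: {"path": v, "sha256": _sha256(v)}
        for k, v in (
            ("counts", config.counts),
            ("groups", config.groups),
            ("predicted_a", config.predicted_a),
            ("predicted_b", config.predicted_b),
            ("curated", config.curated),
            ("annotation", config.annotation),
            ("cp_table", config.cp_table),
            ("primers", config.primers),
            ("transcripts", config.transcripts),
        )
        if v
    }
    manifest = {
        "version": mirhub.__version__,
        "parameters": asdict(config),
        "inputs": inputs,
        "funnel": summary["funnel"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    summary["outputs"]["manifest"] = str(out / "manifest.json")
    return summary
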